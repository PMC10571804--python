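"""Synthetic targeted-DamID (TaDa) experiment generator.

Emulates the four-genotype design used for muscle Pol II profiling:
Dam-only and Dam-Pol II constructs, each in a control and an inactivated
(*shi*) condition, with three replicates per group. The generator produces

* a GATC fragment map (DpnI cut model: exponential inter-site spacing,
  expected density one site per 256 bp for a uniform 4-mer),
* a non-overlapping gene annotation with biotypes drawn from the observed
  composition of Pol II-bound genes in larval muscle,
* a ground-truth table marking which genes change occupancy between
  conditions and in which direction,
* negative-binomial fragment counts whose expectations follow
  ``accessibility x 2^occupancy`` so that the log2(fusion/Dam-only) ratio
  recovers the injected occupancy.

A single seed drives three ordered RNG streams (map -> genes -> counts), so
any prefix of the simulation can be reproduced independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("control", "shi")
CONSTRUCTS = ("dam_only", "dam_polii")

#: Biotype mix of Pol II-bound genes in larval muscle (published analyzed-set
#: counts, n=2010), used as default sampling weights.
DEFAULT_BIOTYPE_WEIGHTS = {
    "protein_coding": 1734 / 2010,
    "lncRNA": 201 / 2010,
    "antisense_lncRNA": 49 / 2010,
    "snoRNA": 8 / 2010,
    "miRNA": 6 / 2010,
    "snRNA": 7 / 2010,
    "pseudogene": 3 / 2010,
    "tRNA": 2 / 2010,
}


class InvalidConfigError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Genes cannot be placed without overlap on the simulated genome."""


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Lengths are in bp, occupancies and effect sizes in log2-units,
    ``libsize`` in expected reads per sample. ``dispersion`` is the
    negative-binomial size parameter (variance = mu + mu^2/size);
    ``math.inf`` gives the Poisson limit.
    """

    genome_length: int = 5_000_000
    n_chromosomes: int = 4
    gatc_spacing_mean: float = 256.0
    n_genes: int = 2000
    gene_length_min: int = 1500
    gene_length_max: int = 3500
    biotype_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_WEIGHTS)
    )
    frac_altered: float = 0.06
    effect_size: float = 2.0
    occupancy_min: float = 1.5
    occupancy_mean: float = 2.5
    occupancy_sd: float = 0.7
    accessibility_sigma: float = 0.5
    dispersion: float = 10.0
    libsize: float = 2_000_000.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise InvalidConfigError("genome_length and n_chromosomes must be positive")
        if self.gatc_spacing_mean <= 0 or self.libsize <= 0:
            raise InvalidConfigError("gatc_spacing_mean and libsize must be positive")
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise InvalidConfigError("n_genes and n_replicates must be positive")
        if not 0 <= self.frac_altered <= 1:
            raise InvalidConfigError("frac_altered must lie in [0, 1]")
        if not 0 < self.gene_length_min <= self.gene_length_max:
            raise InvalidConfigError("need 0 < gene_length_min <= gene_length_max")
        if self.dispersion <= 0:
            raise InvalidConfigError("dispersion must be positive (inf = Poisson)")
        total = sum(self.biotype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"biotype_weights sum to {total}, expected 1")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _streams(config: SimConfig):
    """Ordered independent RNG streams: fragment map, genes, counts."""
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(s) for s in ss.spawn(3)]


def simulate_fragment_map(config: SimConfig, rng=None) -> pd.DataFrame:
    """Simulate DpnI GATC fragments tiling each chromosome.

    Inter-site distances are exponential with mean ``gatc_spacing_mean``
    (memoryless 4-mer hit model), so cut sites form a Poisson process.
    Fragments partition each chromosome exactly: no gaps, no overlaps.
    """
    if rng is None:
        rng = _streams(config)[0]
    records = []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.genome_length
        # over-draw gaps, keep cut positions inside (0, L)
        n_draw = int(L / config.gatc_spacing_mean * 1.3) + 32
        cuts = np.array([], dtype=np.int64)
        pos = 0.0
        while True:
            gaps = rng.exponential(config.gatc_spacing_mean, n_draw)
            cum = pos + np.cumsum(gaps)
            cuts = np.concatenate([cuts, cum[cum < L].astype(np.int64)])
            if cum[-1] >= L:
                break
            pos = cum[-1]
        cuts = np.unique(cuts[(cuts > 0) & (cuts < L)])
        bounds = np.concatenate([[0], cuts, [L]])
        starts, ends = bounds[:-1], bounds[1:]
        records.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    fmap = pd.concat(records, ignore_index=True)
    fmap.insert(0, "fragment_id", [f"frag_{i:07d}" for i in range(len(fmap))])
    return fmap


def simulate_genes(config: SimConfig, fmap: pd.DataFrame, rng=None):
    """Place non-overlapping genes and draw the ground truth.

    Returns ``(genes, truth)``. Genes are assigned to chromosomes uniformly,
    lengths uniform in [gene_length_min, gene_length_max], positions with
    uniform random gaps; biotypes multinomial with the configured weights.
    ``round(frac_altered * n_genes)`` genes receive a condition effect of
    ``±effect_size`` log2-units with random sign; control occupancy is
    gamma-distributed (mean ``occupancy_mean``, sd ``occupancy_sd``).
    """
    if fmap is None or len(fmap) == 0:
        raise InvalidConfigError("fragment map is empty")
    if rng is None:
        rng = _streams(config)[1]

    chroms = sorted(fmap["chrom"].unique())
    chrom_len = fmap.groupby("chrom")["end"].max().to_dict()
    assign = rng.integers(0, len(chroms), config.n_genes)
    lengths = rng.integers(config.gene_length_min, config.gene_length_max + 1,
                           config.n_genes)

    rows = []
    for ci, chrom in enumerate(chroms):
        idx = np.flatnonzero(assign == ci)
        if idx.size == 0:
            continue
        L = chrom_len[chrom]
        lens = lengths[idx]
        free = L - int(lens.sum())
        if free < 0:
            raise PlacementError(
                f"{chrom}: {idx.size} genes of total length {lens.sum()} "
                f"exceed chromosome length {L}"
            )
        gaps = np.sort(rng.integers(0, free + 1, idx.size))
        starts = gaps + np.concatenate([[0], np.cumsum(lens[:-1])])
        for gi, s, ln in zip(idx, starts, lens):
            rows.append((gi, chrom, int(s), int(s + ln)))

    rows.sort()
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene_{gi:05d}" for gi, *_ in rows],
            "chrom": [r[1] for r in rows],
            "start": [r[2] for r in rows],
            "end": [r[3] for r in rows],
        }
    )
    genes["strand"] = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    cats = list(config.biotype_weights)
    genes["biotype"] = rng.choice(
        cats, size=len(genes), p=[config.biotype_weights[c] for c in cats]
    )
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    # Simulated genes emulate the Pol II-*bound* gene set (the background
    # sits in intergenic fragments), so control occupancy is bounded away
    # from 0: a floor plus a gamma tail.
    excess = config.occupancy_mean - config.occupancy_min
    if excess <= 0:
        raise InvalidConfigError("occupancy_mean must exceed occupancy_min")
    shape = (excess / config.occupancy_sd) ** 2
    scale = config.occupancy_sd**2 / excess
    occ = config.occupancy_min + rng.gamma(shape, scale, config.n_genes)

    n_alt = round(config.frac_altered * config.n_genes)
    delta = np.zeros(config.n_genes)
    if n_alt:
        altered = rng.choice(config.n_genes, n_alt, replace=False)
        signs = np.where(rng.random(n_alt) < 0.5, 1.0, -1.0)
        delta[altered] = signs * config.effect_size
    truth = pd.DataFrame(
        {
            "gene_id": [f"gene_{i:05d}" for i in range(config.n_genes)],
            "true_occupancy_control": occ,
            "true_delta": delta,
            "direction": np.select([delta > 0, delta < 0], ["up", "down"], "none"),
        }
    )
    return genes, truth


def _fragment_occupancy(fmap, genes, truth):
    """Per-fragment true occupancy (log2) per condition.

    A fragment overlapping a gene by >= 1 bp carries that gene's occupancy;
    where two genes touch one fragment the larger overlap wins. Intergenic
    fragments sit at 0 (pure accessibility background).
    """
    occ = {g: o for g, o in zip(truth["gene_id"], truth["true_occupancy_control"])}
    dlt = {g: d for g, d in zip(truth["gene_id"], truth["true_delta"])}

    control = np.zeros(len(fmap))
    shi = np.zeros(len(fmap))
    best = np.zeros(len(fmap))
    fpos = {c: (sub.index.to_numpy(), sub["start"].to_numpy(), sub["end"].to_numpy())
            for c, sub in fmap.groupby("chrom")}
    for _, g in genes.iterrows():
        if g["chrom"] not in fpos:
            continue
        idx, starts, ends = fpos[g["chrom"]]
        lo = np.searchsorted(ends, g["start"], side="right")
        hi = np.searchsorted(starts, g["end"], side="left")
        if hi <= lo:
            continue
        rows = idx[lo:hi]
        ov = np.minimum(ends[lo:hi], g["end"]) - np.maximum(starts[lo:hi], g["start"])
        take = ov > best[rows]
        rows = rows[take]
        best[rows] = ov[take]
        control[rows] = occ[g["gene_id"]]
        shi[rows] = occ[g["gene_id"]] + dlt[g["gene_id"]]
    return {"control": control, "shi": shi}


def sample_name(construct: str, condition: str, replicate: int) -> str:
    return f"{construct}_{condition}_r{replicate}"


def simulate_counts(config: SimConfig, fmap: pd.DataFrame, genes: pd.DataFrame,
                    truth: pd.DataFrame, rng=None):
    """Draw negative-binomial counts for all four genotypes.

    Expected counts per fragment: ``libsize * w_f / sum(w)`` with
    ``w_f = a_f`` for Dam-only and ``w_f = a_f * 2^occupancy`` for the
    Pol II fusion, where ``a_f`` is a log-normal fragment accessibility
    shared by all samples (the non-specific Dam background the analysis
    normalizes out).

    Returns ``(counts, samples)``: counts indexed by fragment_id with one
    column per sample; samples is the metadata table
    (sample, construct, condition, replicate).
    """
    if rng is None:
        rng = _streams(config)[2]
    access = rng.lognormal(0.0, config.accessibility_sigma, len(fmap))
    occ = _fragment_occupancy(fmap, genes, truth)

    cols, meta = {}, []
    for construct in CONSTRUCTS:
        for condition in CONDITIONS:
            for rep in range(1, config.n_replicates + 1):
                w = access if construct == "dam_only" else access * 2.0 ** occ[condition]
                mu = config.libsize * w / w.sum()
                if np.isinf(config.dispersion):
                    c = rng.poisson(mu)
                else:
                    # NB as gamma-Poisson mixture
                    lam = rng.gamma(config.dispersion, mu / config.dispersion)
                    c = rng.poisson(lam)
                name = sample_name(construct, condition, rep)
                cols[name] = c
                meta.append((name, construct, condition, rep))

    counts = pd.DataFrame(cols, index=pd.Index(fmap["fragment_id"], name="fragment_id"))
    samples = pd.DataFrame(meta, columns=["sample", "construct", "condition", "replicate"])
    return counts, samples


@dataclass
class Experiment:
    """A complete simulated TaDa experiment."""

    config: SimConfig
    fragments: pd.DataFrame
    genes: pd.DataFrame
    truth: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame


def simulate_experiment(config: SimConfig) -> Experiment:
    """Run the three simulation stages under a single ordered seed stream."""
    r_map, r_genes, r_counts = _streams(config)
    fmap = simulate_fragment_map(config, r_map)
    genes, truth = simulate_genes(config, fmap, r_genes)
    counts, samples = simulate_counts(config, fmap, genes, truth, r_counts)
    return Experiment(config, fmap, genes, truth, counts, samples)
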