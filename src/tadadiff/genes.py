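"""Gene-level occupancy: fragment means, GATC-site counts, permutation FDR.

A gene's occupancy in one sample is the unweighted mean of the occupancy of
every GATC fragment overlapping the gene body by at least 1 bp (the fragment
is the observation unit in DamID, so fragments are not length-weighted).
Significance of binding is assessed per sample against an empirical null:
the mean occupancy of random fragment sets of the same size, drawn
genome-wide, with Benjamini-Hochberg adjustment across genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pyranges as pr
from statsmodels.stats.multitest import multipletests

from .occupancy import track_condition
from .simulate import CONDITIONS

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def _check_bounds(genes: pd.DataFrame, fmap: pd.DataFrame) -> None:
    chrom_len = fmap.groupby("chrom")["end"].max()
    for chrom, sub in genes.groupby("chrom"):
        if chrom not in chrom_len.index:
            raise AnnotationError(f"gene chromosome {chrom!r} absent from fragment map")
        if (sub["end"] > chrom_len[chrom]).any() or (sub["start"] < 0).any():
            bad = sub.loc[sub["end"] > chrom_len[chrom], "gene_id"].tolist()[:5]
            raise AnnotationError(
                f"gene(s) beyond {chrom} bounds ({chrom_len[chrom]} bp): {bad}"
            )


def _overlap_join(genes: pd.DataFrame, fmap: pd.DataFrame) -> pd.DataFrame:
    """(gene_id, fragment_id) pairs for >=1 bp overlap."""
    frag = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": fmap["chrom"],
                "Start": fmap["start"],
                "End": fmap["end"],
                "fragment_id": fmap["fragment_id"],
            }
        )
    )
    gen = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": genes["chrom"],
                "Start": genes["start"],
                "End": genes["end"],
                "gene_id": genes["gene_id"],
            }
        )
    )
    j = gen.join(frag).df
    if len(j) == 0:
        return pd.DataFrame({"gene_id": [], "fragment_id": []})
    return j[["gene_id", "fragment_id"]]


def gene_mean_occupancy(tracks: pd.DataFrame, genes: pd.DataFrame,
                        fmap: pd.DataFrame) -> pd.DataFrame:
    """Mean occupancy per gene for every track column.

    Genes with no overlapping fragment get NaN (never 0 — absence of signal
    is not neutral occupancy). Also returns the overlapping-fragment count
    per gene in column ``n_fragments``.
    """
    _check_bounds(genes, fmap)
    pairs = _overlap_join(genes, fmap)
    out = pd.DataFrame(index=pd.Index(genes["gene_id"], name="gene_id"))
    if len(pairs):
        per_frag = tracks.loc[pairs["fragment_id"].to_numpy()]
        per_frag.index = pairs["gene_id"].to_numpy()
        means = per_frag.groupby(level=0).mean()
        n = pairs.groupby("gene_id").size()
        for col in tracks.columns:
            out[f"occ_{col}"] = means[col]
        out["n_fragments"] = n
    else:
        for col in tracks.columns:
            out[f"occ_{col}"] = np.nan
        out["n_fragments"] = 0
    out["n_fragments"] = out["n_fragments"].fillna(0).astype(int)
    return out


def count_gatc_sites(genes: pd.DataFrame, fmap: pd.DataFrame) -> pd.Series:
    """GATC (DpnI cut) sites strictly inside each gene span.

    Cut sites are the internal fragment boundaries; chromosome ends are not
    cut sites. A gene contained in a single fragment has 0.
    """
    counts = pd.Series(0, index=pd.Index(genes["gene_id"], name="gene_id"))
    for chrom, sub in fmap.groupby("chrom"):
        sites = sub["start"].to_numpy()[1:]  # first start is the chromosome edge
        g = genes[genes["chrom"] == chrom]
        if len(g) == 0:
            continue
        lo = np.searchsorted(sites, g["start"].to_numpy(), side="right")
        hi = np.searchsorted(sites, g["end"].to_numpy(), side="left")
        counts.loc[g["gene_id"]] = hi - lo
    return counts.rename("n_gatc_sites")


def occupancy_pvalues(gene_table: pd.DataFrame, tracks: pd.DataFrame,
                      n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-sample, per-gene permutation p-value of mean occupancy.

    For each gene size s (number of overlapping fragments), ``n_perm``
    random fragment sets of size s are drawn genome-wide (with replacement;
    collisions are negligible) and their mean occupancy forms the null.
    The one-sided p-value is add-one smoothed:
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    Genes sharing a size share a null.
    """
    if n_perm < 100:
        raise ConfigError(f"n_perm={n_perm} too small; need >= 100 permutations")
    rng = np.random.default_rng(seed)
    sizes = gene_table["n_fragments"].to_numpy()
    out = pd.DataFrame(index=gene_table.index)
    uniq = np.unique(sizes[sizes > 0])
    for col in tracks.columns:
        vals = tracks[col].to_numpy()
        null = {}
        for s in uniq:
            draws = rng.integers(0, len(vals), size=(n_perm, int(s)))
            null[s] = np.sort(vals[draws].mean(axis=1))
        obs = gene_table[f"occ_{col}"].to_numpy()
        p = np.full(len(gene_table), np.nan)
        for s in uniq:
            mask = sizes == s
            ge = n_perm - np.searchsorted(null[s], obs[mask], side="left")
            p[mask] = (1.0 + ge) / (n_perm + 1.0)
        out[f"p_{col}"] = p
    return out


def occupancy_fdr(gene_table: pd.DataFrame, tracks: pd.DataFrame,
                  n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment of :func:`occupancy_pvalues` per sample."""
    pvals = occupancy_pvalues(gene_table, tracks, n_perm=n_perm, seed=seed)
    out = pd.DataFrame(index=gene_table.index)
    for col in tracks.columns:
        p = pvals[f"p_{col}"].to_numpy()
        fdr = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out[f"fdr_{col}"] = fdr
    return out


def build_gene_table(tracks: pd.DataFrame, genes: pd.DataFrame, fmap: pd.DataFrame,
                     n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Assemble the full per-gene table: occupancy, GATC sites, FDR, means."""
    table = gene_mean_occupancy(tracks, genes, fmap)
    table.insert(0, "biotype", genes.set_index("gene_id")["biotype"])
    table["n_gatc_sites"] = count_gatc_sites(genes, fmap)
    fdr = occupancy_fdr(table, tracks, n_perm=n_perm, seed=seed)
    table = table.join(fdr)
    for condition in CONDITIONS:
        cols = [f"occ_{c}" for c in tracks.columns if track_condition(c) == condition]
        table[f"mean_{condition}"] = table[cols].mean(axis=1)
    return table


def filter_bound_genes(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep genes bound in at least one condition group.

    Bound in a group means FDR < alpha in *every* replicate of that
    condition ("per sample" screening with replicate consistency).
    """
    fdr_cols = [c for c in table.columns if c.startswith("fdr_")]
    if not fdr_cols:
        raise ConfigError("table has no fdr_* columns; run occupancy_fdr first")
    keep = np.zeros(len(table), dtype=bool)
    for condition in CONDITIONS:
        cols = [c for c in fdr_cols if track_condition(c[len("fdr_"):]) == condition]
        if cols:
            keep |= (table[cols] < alpha).all(axis=1).to_numpy()
    bound = table[keep]
    log.info("bound-gene filter (FDR < %g): %d of %d genes retained",
             alpha, len(bound), len(table))
    if len(bound) == 0:
        log.warning("no gene passed the bound filter at alpha=%g", alpha)
    return bound
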