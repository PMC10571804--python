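"""Scalar phenotype metrics: larval motion range and per-nucleus chromatin balance.

Two descriptive read-outs accompany the genomic analysis:

* **motion range** of a crawling larva — the contraction amplitude of its
  body length over a recording, normalized by the maximal length:
  ``(Lmax - Lmin) / Lmax``, dimensionless in [0, 1). Paralyzed larvae score
  near 0, freely crawling ones around 0.2.
* **acetylation/methylation ratio** per muscle nucleus — total H3K9ac
  fluorescence divided by total H3K27me3 fluorescence; an index of the
  active-vs-repressive chromatin balance.

This module starts from extracted tables (length series per larva, total
intensities per segmented nucleus); video and 3-D image segmentation are
upstream and out of scope. Small synthetic generators provide test fixtures
with known group effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class InputError(ValueError):
    pass


class UndefinedRatioError(ZeroDivisionError):
    pass


def motion_range(lengths) -> float:
    """Length-adjusted motion range of one larva: (Lmax - Lmin) / Lmax.

    ``lengths`` is the ordered series of body lengths (mm) over the frames
    of a crawl recording; at least two frames, all positive. The result is
    scale-invariant (units cancel).
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InputError("need an ordered series of >= 2 length measurements")
    if not np.all(arr > 0):
        raise InputError("larval lengths must all be positive")
    lmax = arr.max()
    return float((lmax - arr.min()) / lmax)


def ace_me_ratio(h3k9ac: float, h3k27me3: float) -> float:
    """Total H3K9ac / total H3K27me3 fluorescence of one nucleus."""
    if h3k9ac < 0 or h3k27me3 < 0:
        raise InputError("channel intensities must be non-negative")
    if h3k27me3 == 0:
        raise UndefinedRatioError("zero H3K27me3 signal; ratio undefined for nucleus")
    return float(h3k9ac / h3k27me3)


def nucleus_ratios(nuclei: pd.DataFrame, volume_normalized: bool = False) -> pd.Series:
    """Acetylation/methylation ratio per nucleus of a segmented-intensity table.

    Expects columns ``h3k9ac``, ``h3k27me3`` (total fluorescence) and, when
    ``volume_normalized`` is set, ``volume`` (um^3) — the per-volume
    densities are then ratioed instead of the raw totals (the ratio itself
    is identical; the flag exists for symmetric reporting of densities).
    Nuclei with zero methylation signal are flagged with NaN and reported.
    """
    ac = nuclei["h3k9ac"].astype(float)
    me = nuclei["h3k27me3"].astype(float)
    if volume_normalized:
        vol = nuclei["volume"].astype(float)
        if (vol <= 0).any():
            raise InputError("nuclear volumes must be positive")
        ac, me = ac / vol, me / vol
    out = pd.Series(np.where(me > 0, ac / np.where(me > 0, me, 1.0), np.nan),
                    index=nuclei.index, name="ace_me_ratio")
    return out


def group_summary(values: pd.DataFrame, value_col: str,
                  group_cols=("genotype", "temperature")) -> pd.DataFrame:
    """Mean, sample SD (ddof=1) and n per group; no pooling across levels.

    Groups with a single unit report SD as NaN (undefined); empty groups are
    simply absent. Input row order does not matter.
    """
    group_cols = list(group_cols)
    g = values.dropna(subset=[value_col]).groupby(group_cols, sort=True)[value_col]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size").reset_index()
    out["n"] = out["n"].astype(int)
    return out


# ---------------------------------------------------------------------------
# synthetic fixture generators (known ground truth for tests)

def synthetic_length_series(n_frames: int = 30, base_length: float = 4.0,
                            amplitude: float = 0.2, noise: float = 0.005,
                            seed: int = 0) -> np.ndarray:
    """Sinusoidal crawl cycle: lengths oscillating by ``amplitude`` fraction."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 4 * np.pi, n_frames)
    lengths = base_length * (1 - amplitude / 2 + (amplitude / 2) * np.cos(t))
    return lengths + rng.normal(0, noise * base_length, n_frames)


def synthetic_nucleus_table(n_larvae: int = 5, nuclei_per_larva: int = 20,
                            ratio_shift: float = 1.5, seed: int = 0) -> pd.DataFrame:
    """Nucleus intensity table for 2 genotypes x 2 temperatures.

    The shi/30C (inactive) group's H3K9ac is multiplied by ``ratio_shift``,
    injecting a known increase of the acetylation/methylation ratio.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in ("control", "shi"):
        for temperature in (18, 30):
            shift = ratio_shift if (genotype == "shi" and temperature == 30) else 1.0
            for larva in range(n_larvae):
                for nuc in range(nuclei_per_larva):
                    vol = rng.lognormal(np.log(150), 0.2)
                    me = rng.lognormal(np.log(1000), 0.3) * vol / 150
                    ac = me * rng.lognormal(np.log(shift), 0.2)
                    rows.append((genotype, temperature, f"L{larva}", f"S{nuc % 4}",
                                 f"N{nuc}", vol, ac, me))
    return pd.DataFrame(
        rows,
        columns=["genotype", "temperature", "larva_id", "segment_id",
                 "nucleus_id", "volume", "h3k9ac", "h3k27me3"],
    )
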