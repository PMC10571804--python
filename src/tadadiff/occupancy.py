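"""Per-fragment Pol II occupancy: library scaling and log2 fusion/Dam ratios.

The Dam-only construct methylates GATCs wherever chromatin is accessible;
dividing the Pol II-Dam fusion signal by it removes this non-specific
background. Occupancy is therefore ``log2(fusion / Dam-only)`` per GATC
fragment, computed on reads-per-million-scaled counts with a pseudocount so
every fragment stays finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CONDITIONS

RPM_SCALE = 1_000_000.0
DEFAULT_PSEUDOCOUNT = 0.5  # RPM; stabilizes the log-ratio at low counts


class DegenerateSampleError(ValueError):
    pass


class AlignmentError(ValueError):
    """Fragment sets of paired samples do not match."""


def normalize_library(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample (column) to reads per million.

    Zero counts stay zero; an all-zero sample is rejected by name because a
    ratio against it would be meaningless.
    """
    totals = counts.sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead):
        raise DegenerateSampleError(
            f"sample(s) with zero total reads: {', '.join(map(str, dead.index))}"
        )
    return counts * (RPM_SCALE / totals)


def occupancy_ratio(fusion: pd.DataFrame, dam: pd.DataFrame,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """log2((fusion + pc) / (dam + pc)) per fragment, column-wise paired.

    ``fusion`` and ``dam`` must be RPM-scaled frames over the same fragment
    index with the same number of columns; pairing is positional (column i
    of fusion against column i of dam).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if fusion.shape[1] != dam.shape[1]:
        raise AlignmentError(
            f"{fusion.shape[1]} fusion vs {dam.shape[1]} Dam-only samples"
        )
    if not fusion.index.equals(dam.index):
        offenders = fusion.index.symmetric_difference(dam.index)
        raise AlignmentError(
            f"fragment sets differ between fusion and Dam-only samples; "
            f"{len(offenders)} offending fragments, e.g. {list(offenders[:5])}"
        )
    ratio = np.log2(fusion.to_numpy() + pseudocount) - np.log2(dam.to_numpy() + pseudocount)
    return pd.DataFrame(ratio, index=fusion.index, columns=fusion.columns)


def _density_mode(values: np.ndarray, bins: int = 512, sigma_bins: float = 4.0) -> float:
    """Mode of a sample via a smoothed histogram (cheap kernel density)."""
    hist, edges = np.histogram(values, bins=bins)
    half = int(4 * sigma_bins)
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma_bins) ** 2)
    smooth = np.convolve(hist.astype(float), kernel / kernel.sum(), mode="same")
    centers = (edges[:-1] + edges[1:]) / 2
    return float(centers[np.argmax(smooth)])


def occupancy_tracks(counts: pd.DataFrame, samples: pd.DataFrame,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT,
                     center: str | None = "mode") -> pd.DataFrame:
    """Build all fusion occupancy tracks from a raw four-genotype matrix.

    Replicate pairing is positional within (construct, condition): fusion
    replicate k is normalized against Dam-only replicate k of the same
    condition. Returns one column per fusion sample, named
    ``<condition>_r<k>``.

    With ``center="mode"`` (default) each track is shifted so the mode of
    its log-ratio distribution is 0. Per-million scaling alone leaves a
    composition offset — enriched fragments soak up fusion reads, pushing
    background fragments negative — and since most fragments are
    background, anchoring the distribution's peak at zero makes occupancy
    read as signal over accessibility background (the same reason DamID
    ratio normalization uses a kernel-density mode rather than a plain
    ratio of totals). ``center="median"`` uses the median; ``center=None``
    keeps raw ratios.
    """
    if center not in (None, "median", "mode"):
        raise ValueError(f"unknown centering {center!r}")
    scaled = normalize_library(counts)
    samples = samples.sort_values(["construct", "condition", "replicate"])
    tracks = {}
    for condition in CONDITIONS:
        sub = samples[samples["condition"] == condition]
        fus = sub[sub["construct"] == "dam_polii"]["sample"].tolist()
        dam = sub[sub["construct"] == "dam_only"]["sample"].tolist()
        if len(fus) != len(dam):
            raise AlignmentError(
                f"{condition}: {len(fus)} fusion vs {len(dam)} Dam-only replicates"
            )
        for k, (f, d) in enumerate(zip(fus, dam), start=1):
            track = occupancy_ratio(scaled[[f]], scaled[[d]], pseudocount).iloc[:, 0]
            if center == "median":
                track = track - track.median()
            elif center == "mode":
                track = track - _density_mode(track.to_numpy())
            tracks[f"{condition}_r{k}"] = track
    return pd.DataFrame(tracks, index=counts.index)


def track_condition(track_name: str) -> str:
    cond = track_name.rsplit("_r", 1)[0]
    if cond not in CONDITIONS:
        raise ValueError(f"cannot parse condition from track name {track_name!r}")
    return cond
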