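"""Simulation-based evaluation of the full pipeline.

Runs the whole analysis (simulate -> normalize -> gene table -> differential
call) in memory and scores it against the simulation ground truth: null
calibration of the z-score band and recovery of spiked genes. Used by the
test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .differential import call_differential
from .genes import build_gene_table
from .occupancy import occupancy_tracks
from .simulate import SimConfig, simulate_experiment


def analyze_experiment(config: SimConfig, n_perm: int = 1000):
    """Simulate under ``config`` and run the analysis; returns (exp, diff)."""
    exp = simulate_experiment(config)
    tracks = occupancy_tracks(exp.counts, exp.samples)
    table = build_gene_table(tracks, exp.genes, exp.fragments,
                             n_perm=n_perm, seed=config.seed)
    diff = call_differential(table)
    return exp, diff


def null_band_coverage(seed: int, **config_kw) -> float:
    """Fraction of genes with |z| <= 1.96 when no gene is truly altered."""
    cfg = SimConfig(seed=seed, frac_altered=0.0, **config_kw)
    _, diff = analyze_experiment(cfg)
    return float((diff["z"].abs() <= 1.96).mean())


def spike_recovery(seed: int, **config_kw) -> dict:
    """Recovery of spiked genes: significant call with the correct sign.

    Returns the fraction of truly altered genes that are called significant
    with matching direction, plus the realized false/true call counts.
    """
    cfg = SimConfig(seed=seed, **config_kw)
    exp, diff = analyze_experiment(cfg)
    truth = exp.truth.set_index("gene_id")
    merged = diff.join(truth[["true_delta"]])
    spiked_ids = truth.index[truth["true_delta"] != 0]
    in_bound = merged[merged["true_delta"] != 0]
    hit = in_bound["significant"] & (
        np.sign(in_bound["z"]) == np.sign(in_bound["true_delta"])
    )
    null_called = merged[(merged["true_delta"] == 0) & merged["significant"]]
    return {
        "recovery": float(hit.sum() / len(spiked_ids)),
        "n_spiked": int(len(spiked_ids)),
        "n_recovered": int(hit.sum()),
        "n_false_calls": int(len(null_called)),
        "n_bound": int(len(merged)),
    }
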