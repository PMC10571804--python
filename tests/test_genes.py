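"""Gene-level aggregation: means, GATC sites, permutation FDR, bound filter."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest
from statsmodels.stats.multitest import multipletests

from conftest import manual_fragment_map, manual_genes
from tadadiff.genes import (
    AnnotationError,
    ConfigError,
    count_gatc_sites,
    filter_bound_genes,
    gene_mean_occupancy,
    occupancy_fdr,
)


def brute_force_gene_means(tracks, genes, fmap):
    """Quadratic oracle: rescan every fragment-gene pair."""
    out = {}
    for _, g in genes.iterrows():
        vals = []
        for _, f in fmap.iterrows():
            if (f["chrom"] == g["chrom"] and f["start"] < g["end"]
                    and f["end"] > g["start"]):
                vals.append(tracks.loc[f["fragment_id"]])
        out[g["gene_id"]] = (pd.concat(vals, axis=1).T.mean()
                             if vals else None)
    return out


class TestGeneMeanOccupancy:
    def test_mean_of_two_fragments(self):
        fmap = manual_fragment_map([0, 200, 500, 1000])
        genes = manual_genes([(100, 450)])
        tracks = pd.DataFrame({"t": [1.0, 3.0, 9.0]},
                              index=fmap["fragment_id"])
        out = gene_mean_occupancy(tracks, genes, fmap)
        assert out.loc["g0", "occ_t"] == pytest.approx(2.0)
        assert out.loc["g0", "n_fragments"] == 2

    def test_single_fragment_identity(self):
        fmap = manual_fragment_map([0, 200, 500])
        genes = manual_genes([(250, 400)])
        tracks = pd.DataFrame({"t": [5.0, -0.7]}, index=fmap["fragment_id"])
        out = gene_mean_occupancy(tracks, genes, fmap)
        assert out.loc["g0", "occ_t"] == pytest.approx(-0.7)

    def test_matches_quadratic_overlap_oracle(self):
        rng = np.random.default_rng(2)
        bounds = np.concatenate([[0], np.sort(rng.choice(
            np.arange(1, 10_000), 60, replace=False)), [10_000]])
        fmap = manual_fragment_map(list(bounds))
        starts = rng.integers(0, 9_000, 50)
        genes = manual_genes([(int(s), int(s + rng.integers(50, 900)))
                              for s in starts])
        genes["end"] = genes["end"].clip(upper=10_000)
        genes = genes[genes["end"] > genes["start"]]
        tracks = pd.DataFrame(rng.normal(size=(len(fmap), 3)),
                              columns=["a", "b", "c"], index=fmap["fragment_id"])
        out = gene_mean_occupancy(tracks, genes, fmap)
        oracle = brute_force_gene_means(tracks, genes, fmap)
        for gid, expect in oracle.items():
            assert expect is not None
            for col in ("a", "b", "c"):
                assert out.loc[gid, f"occ_{col}"] == pytest.approx(
                    expect[col], abs=1e-12)

    def test_no_overlap_is_missing_not_zero(self):
        fmap = manual_fragment_map([0, 500], chrom="chr1")
        genes = manual_genes([(100, 200)], chrom="chr1")
        other = manual_genes([(100, 200)], chrom="chr2")
        tracks = pd.DataFrame({"t": [1.0]}, index=fmap["fragment_id"])
        with pytest.raises(AnnotationError):
            gene_mean_occupancy(tracks, other, fmap)  # unknown chromosome
        genes_past_end = manual_genes([(400, 600)])
        with pytest.raises(AnnotationError):
            gene_mean_occupancy(tracks, genes_past_end, fmap)

    def test_invariant_to_fragment_order_on_disk(self):
        rng = np.random.default_rng(3)
        fmap = manual_fragment_map([0, 100, 300, 600, 1000])
        genes = manual_genes([(50, 650), (700, 900)])
        tracks = pd.DataFrame({"t": rng.normal(size=4)}, index=fmap["fragment_id"])
        base = gene_mean_occupancy(tracks, genes, fmap)
        perm = rng.permutation(len(fmap))
        shuffled = gene_mean_occupancy(tracks.iloc[perm], genes,
                                       fmap.iloc[perm].reset_index(drop=True))
        pd.testing.assert_frame_equal(base, shuffled)


class TestCountGatcSites:
    def test_spanning_gene_counts_internal_boundaries(self):
        fmap = manual_fragment_map([0, 200, 500, 1000])
        genes = manual_genes([(0, 1000)])
        assert count_gatc_sites(genes, fmap).loc["g0"] == 2

    def test_gene_inside_single_fragment_has_none(self):
        fmap = manual_fragment_map([0, 200, 500, 1000])
        genes = manual_genes([(210, 480)])
        assert count_gatc_sites(genes, fmap).loc["g0"] == 0

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(4)
        bounds = np.concatenate([[0], np.sort(rng.choice(
            np.arange(1, 50_000), 200, replace=False)), [50_000]])
        fmap = manual_fragment_map(list(bounds))
        sites = bounds[1:-1]
        genes = manual_genes([
            (int(s), int(min(s + rng.integers(10, 3000), 50_000)))
            for s in rng.integers(0, 49_000, 80)
        ])
        counts = count_gatc_sites(genes, fmap)
        for _, g in genes.iterrows():
            expect = int(((sites > g["start"]) & (sites < g["end"])).sum())
            assert counts.loc[g["gene_id"]] == expect


class TestOccupancyFdr:
    def _table_and_tracks(self, occupancies, n_frag_per_gene=2):
        n = len(occupancies) * n_frag_per_gene
        bounds = list(range(0, (n + 1) * 100, 100))
        fmap = manual_fragment_map(bounds)
        genes = manual_genes([
            (i * n_frag_per_gene * 100 + 10, (i + 1) * n_frag_per_gene * 100 - 10)
            for i in range(len(occupancies))
        ])
        vals = np.repeat(occupancies, n_frag_per_gene).astype(float)
        tracks = pd.DataFrame({"t": vals}, index=fmap["fragment_id"])
        table = gene_mean_occupancy(tracks, genes, fmap)
        return table, tracks

    def test_maximum_gene_hits_smoothing_floor(self):
        occ = np.zeros(60)
        occ[0] = 100.0
        table, tracks = self._table_and_tracks(occ)
        fdr = occupancy_fdr(table, tracks, n_perm=400, seed=0)
        # BH leaves the smallest p at p*m/1; recover p from the column
        raw_p_floor = 1.0 / 401.0
        assert fdr["fdr_t"].min() <= raw_p_floor * len(table)
        assert fdr["fdr_t"].idxmin() == "g0"

    def test_requires_enough_permutations(self):
        table, tracks = self._table_and_tracks(np.zeros(4))
        with pytest.raises(ConfigError):
            occupancy_fdr(table, tracks, n_perm=50)

    def test_null_pvalues_uniform(self, default_tracks, default_experiment):
        """Fully shuffled tracks give uniform permutation p-values (KS)."""
        from tadadiff.genes import occupancy_pvalues

        exp = default_experiment
        for seed in (0, 1, 2):
            shuffled = default_tracks.sample(frac=1.0, random_state=seed)
            shuffled.index = default_tracks.index
            t = gene_mean_occupancy(shuffled[["control_r1"]], exp.genes,
                                    exp.fragments)
            p = occupancy_pvalues(t, shuffled[["control_r1"]],
                                  n_perm=500, seed=seed)["p_control_r1"].dropna()
            assert kstest(p, "uniform").pvalue > 0.01
            fdr = occupancy_fdr(t, shuffled[["control_r1"]],
                                n_perm=500, seed=seed)
            assert (fdr["fdr_control_r1"] < 0.05).mean() <= 0.05

    def test_bh_matches_hand_stepup(self):
        p = np.array([0.005, 0.02, 0.04])
        adjusted = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adjusted, [0.015, 0.03, 0.04])

    def test_fdr_monotone_with_pvalue_rank(self):
        from tadadiff.genes import occupancy_pvalues

        rng = np.random.default_rng(5)
        table, tracks = self._table_and_tracks(rng.normal(size=80))
        p = occupancy_pvalues(table, tracks, n_perm=200, seed=1)["p_t"]
        fdr = occupancy_fdr(table, tracks, n_perm=200, seed=1)["fdr_t"]
        ordered = fdr[p.sort_values(kind="stable").index].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()
        assert fdr.between(0, 1).all()


class TestFilterBoundGenes:
    def _table(self, fdr_values):
        cols = [f"fdr_{c}_r{k}" for c in ("control", "shi") for k in (1, 2, 3)]
        df = pd.DataFrame(fdr_values, columns=cols,
                          index=[f"g{i}" for i in range(len(fdr_values))])
        return df

    def test_all_zero_fdr_keeps_everything(self):
        t = self._table(np.zeros((5, 6)))
        assert len(filter_bound_genes(t)) == 5

    def test_all_one_fdr_keeps_nothing(self):
        t = self._table(np.ones((5, 6)))
        assert len(filter_bound_genes(t)) == 0

    def test_one_consistent_condition_suffices(self):
        row = [0.01, 0.02, 0.03, 0.9, 0.9, 0.9]   # control bound, shi not
        mixed = [0.01, 0.2, 0.01, 0.9, 0.9, 0.9]  # control inconsistent
        t = self._table([row, mixed])
        kept = filter_bound_genes(t, alpha=0.05)
        assert list(kept.index) == ["g0"]

    def test_recovers_strong_signal_genes(self, default_experiment,
                                          default_gene_table):
        truth = default_experiment.truth.set_index("gene_id")
        strong = truth[truth["true_occupancy_control"] > 2.0].index
        bound = filter_bound_genes(default_gene_table)
        assert strong.isin(bound.index).mean() >= 0.90
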