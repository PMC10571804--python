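# tadadiff

Analysis pipeline for **targeted DamID (TaDa) profiling of RNA polymerase II
occupancy**, built for the four-genotype design used to study transcription
in inactivated *Drosophila* larval muscle: Dam-only and Dam-Pol II
constructs, each expressed in a control and in a temperature-inactivated
(*shibire^ts^*) background, with three replicates per group.

In DamID, a Dam-methyltransferase fusion marks GATC motifs near its binding
sites; DpnI digestion turns the genome into GATC *fragments*, the unit of
signal. The package takes per-fragment read counts and carries them through:

1. **Fragment occupancy** — reads-per-million scaling, then per fragment
   `log2((fusion + c)/(Dam-only + c))` with pseudocount `c`, paired by
   replicate within condition. Each track is anchored so the mode of its
   ratio distribution (the accessibility background) sits at 0.
2. **Gene occupancy** — unweighted mean occupancy over the GATC fragments
   overlapping each gene body, a GATC-site count per gene, and a per-sample
   empirical FDR from a permutation null (random same-size fragment sets,
   Benjamini–Hochberg across genes).
3. **Replicate QC** — pairwise Pearson correlation of tracks with
   average-linkage clustering, and k-means (k = 3) gene groups.
4. **Differential binding** — the bespoke caller: each bound gene is a point
   (x, y) = (control, inactive) mean occupancy; an **orthogonal (total
   least squares) regression** line is fitted through the first principal
   component of the scatter, and each gene's signed perpendicular residual
   is standardized into a z-score. A gene is called altered when
   `FDR < 0.01`, `|z| > 1.96` (two-tailed) and `GATC sites > 1` all hold;
   positive z means increased Pol II binding in the inactive muscles.
5. **Biotype report** — composition of analyzed vs altered genes per
   biotype and enrichment folds (e.g. lncRNAs among altered genes).

Because the original sequencing data are not publicly deposited, the package
ships a first-class **synthetic experiment generator**
(`tadadiff.simulate`): exponential GATC spacing (mean 256 bp),
non-overlapping genes with the published biotype mix, log-normal fragment
accessibility shared across samples, negative-binomial counts whose means
follow `accessibility × 2^occupancy`, and a ground-truth table of spiked
condition effects. Everything downstream runs unchanged on real
damidseq-style fragment counts.

## Worked example

```python
from tadadiff import (SimConfig, simulate_experiment, occupancy_tracks,
                      build_gene_table, call_differential)

exp = simulate_experiment(SimConfig(seed=1))          # 4 genotypes x 3 reps
tracks = occupancy_tracks(exp.counts, exp.samples)    # log2 fusion/Dam-only
table = build_gene_table(tracks, exp.genes, exp.fragments, seed=1)
diff = call_differential(table)
print(diff[["x", "y", "z", "min_fdr", "n_gatc_sites",
            "significant", "direction"]].round(3).head())
```

```
                x      y      z  min_fdr  n_gatc_sites  significant direction
gene_id
gene_00002  2.157  3.989  3.501    0.002            19         True        up
gene_00005  2.183  2.154  0.123    0.002             6        False        up
gene_00007  2.112  1.895 -0.190    0.003             5        False      down
gene_00011  1.658  1.787  0.606    0.002            17        False        up
gene_00014  2.624  2.587 -0.057    0.002            12        False      down
```

`x` and `y` are per-condition mean occupancies (log2-units); `z` is the
standardized orthogonal residual. Under this seed the run analyzes 78 446
fragments and 2000 genes, retains 1852 as Pol II-bound, and calls 109
significantly altered (49 up, 60 down); 108 of the 120 genes spiked by the
generator are recovered with the correct direction.

The same pipeline is available from the shell:

```sh
tada-diff run --out runs/demo --seed 1          # simulate -> ... -> report
tada-diff call --genes runs/demo/gene_occupancy.tsv --out diff.tsv
```

Each stage writes plain TSV/BED/GFF3/bedGraph files plus a `manifest.json`
of versions, parameters, seeds and output digests; re-running with the same
seed reproduces byte-identical tables.

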