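"""Biotype composition of analyzed vs altered genes and enrichment folds.

Reproduces the standard report shape for a TaDa gene-call: per biotype, the
count and percentage among all analyzed (Pol II-bound) genes and among the
genes whose binding changed, plus the fold-enrichment of a biotype in the
altered set. The canonical vocabulary is the eight categories observed in
the larval-muscle Pol II study, with an "other" catch-all.
"""

from __future__ import annotations

import warnings

import pandas as pd

BIOTYPES = (
    "protein_coding",
    "lncRNA",
    "antisense_lncRNA",
    "snoRNA",
    "miRNA",
    "snRNA",
    "pseudogene",
    "tRNA",
)
OTHER = "other"

#: Published biotype counts for Pol II-bound genes in larval muscle
#: (analyzed set, n=2010) and for the genes altered by muscle inactivity
#: (n=121). Used as the reference fixture for report arithmetic.
REFERENCE_COUNTS = pd.DataFrame(
    {
        "analyzed": [1734, 201, 49, 8, 6, 7, 3, 2],
        "altered": [72, 36, 6, 1, 3, 1, 1, 1],
    },
    index=pd.Index(BIOTYPES, name="biotype"),
)


class ConsistencyError(ValueError):
    pass


def _canon(biotypes: pd.Series) -> pd.Series:
    return biotypes.where(biotypes.isin(BIOTYPES), OTHER)


def biotype_table(analyzed: pd.Series, altered: pd.Series) -> pd.DataFrame:
    """Counts and percentages per biotype in the analyzed and altered sets.

    ``analyzed`` and ``altered`` map gene_id -> biotype; the altered genes
    must be a subset of the analyzed ones. Percentages are reported to one
    decimal alongside the raw proportions; a totals row closes the table.
    """
    stray = altered.index.difference(analyzed.index)
    if len(stray):
        raise ConsistencyError(
            f"{len(stray)} altered gene(s) absent from the analyzed set, "
            f"e.g. {list(stray[:5])}"
        )
    cats = list(BIOTYPES) + [OTHER]
    rows = {}
    for name, s in (("analyzed", _canon(analyzed)), ("altered", _canon(altered))):
        counts = s.value_counts().reindex(cats, fill_value=0)
        total = int(counts.sum())
        pct = counts / total * 100.0 if total else counts * 0.0
        rows[f"{name}_n"] = counts
        rows[f"{name}_pct"] = pct.round(1)
    table = pd.DataFrame(rows)
    table = table[table[["analyzed_n", "altered_n"]].sum(axis=1) > 0]
    table.loc["total"] = [
        table["analyzed_n"].sum(), 100.0 if table["analyzed_n"].sum() else 0.0,
        table["altered_n"].sum(), 100.0 if table["altered_n"].sum() else 0.0,
    ]
    table["analyzed_n"] = table["analyzed_n"].astype(int)
    table["altered_n"] = table["altered_n"].astype(int)
    return table


def enrichment_fold(biotype: str, analyzed: pd.Series, altered: pd.Series) -> float:
    """Fold enrichment of one biotype among altered vs analyzed genes.

    ``(altered% for biotype) / (analyzed% for biotype)``; 1.0 means the
    composition is unchanged. Returns 0.0 with a warning if the biotype is
    missing from the altered set.
    """
    analyzed = _canon(analyzed)
    altered = _canon(altered)
    p_analyzed = (analyzed == biotype).mean()
    if p_analyzed == 0:
        raise ConsistencyError(f"biotype {biotype!r} absent from the analyzed set")
    if len(altered) == 0 or (altered == biotype).sum() == 0:
        warnings.warn(f"biotype {biotype!r} absent from the altered set; fold = 0")
        return 0.0
    return float((altered == biotype).mean() / p_analyzed)


def fold_from_counts(counts: pd.DataFrame, biotype: str) -> float:
    """Enrichment fold straight from a (biotype x {analyzed, altered}) count table."""
    p_analyzed = counts.loc[biotype, "analyzed"] / counts["analyzed"].sum()
    p_altered = counts.loc[biotype, "altered"] / counts["altered"].sum()
    if p_analyzed == 0:
        raise ConsistencyError(f"biotype {biotype!r} absent from the analyzed set")
    return float(p_altered / p_analyzed)


def table_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentage report straight from a (biotype x {analyzed, altered}) count table."""
    table = pd.DataFrame(index=counts.index)
    for col in ("analyzed", "altered"):
        total = counts[col].sum()
        table[f"{col}_n"] = counts[col].astype(int)
        table[f"{col}_pct"] = (counts[col] / total * 100.0).round(1) if total else 0.0
    table.loc["total"] = [counts["analyzed"].sum(), 100.0,
                          counts["altered"].sum(), 100.0]
    table["analyzed_n"] = table["analyzed_n"].astype(int)
    table["altered_n"] = table["altered_n"].astype(int)
    return table


def summarize_calls(differential: pd.DataFrame) -> dict:
    """JSON-ready summary: set sizes, biotype table, lncRNA fold."""
    analyzed = differential["biotype"]
    altered = differential.loc[differential["significant"], "biotype"]
    table = biotype_table(analyzed, altered)
    return {
        "n_analyzed": int(len(analyzed)),
        "n_altered": int(len(altered)),
        "pct_altered": round(len(altered) / len(analyzed) * 100.0, 1) if len(analyzed) else 0.0,
        "biotype_table": table.to_dict(orient="index"),
        "lncRNA_fold": enrichment_fold("lncRNA", analyzed, altered)
        if len(altered) else 0.0,
    }
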