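"""Fisher's-exact term enrichment with FDR control and per-group counting.

Over-representation of annotation terms (e.g. GO biological-process terms)
in a query gene set against an explicit background is tested with the
one-sided hypergeometric tail; p-values are adjusted with Benjamini-
Hochberg across the tested terms and flagged significant at FDR < 0.05.
For group-level annotation the enriched terms are counted per gene group
over the union of member genes' annotations.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .grouping import GeneGroup

FDR_THRESHOLD = 0.05


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a 2-3 column gene/term[/name] TSV into an annotation frame."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype=str,
    ).iloc[:, :3]
    df.columns = ["gene_id", "term_id", "term_name"][: df.shape[1]]
    if "term_name" not in df:
        df["term_name"] = df["term_id"]
    return df.drop_duplicates(subset=["gene_id", "term_id"])


def fisher_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """One-sided over-representation test per term, BH-adjusted.

    Returns one row per term occurring in the background annotation, with
    columns term_id, term_name, k (annotated in query), K (annotated in
    background), n (query size), N (background size), p, fdr, significant;
    sorted by (fdr, term_id).
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError(
            f"query is not a subset of the background "
            f"({sorted(query - background)[:5]} ...)"
        )
    ann = annotations[annotations["gene_id"].isin(background)]
    n, N = len(query), len(background)
    rows = []
    for term_id, sub in ann.groupby("term_id", sort=True):
        genes = set(sub["gene_id"])
        k, K = len(genes & query), len(genes)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term_id": term_id,
            "term_name": sub["term_name"].iloc[0],
            "k": k, "K": K, "n": n, "N": N,
            "p": min(p, 1.0),
        })
    result = pd.DataFrame(rows)
    if result.empty:
        return result.reindex(columns=[
            "term_id", "term_name", "k", "K", "n", "N", "p", "fdr", "significant",
        ])
    _, fdr, _, _ = multipletests(result["p"], method="fdr_bh")
    result["fdr"] = fdr
    result["significant"] = result["fdr"] < FDR_THRESHOLD
    return result.sort_values(["fdr", "term_id"]).reset_index(drop=True)


def group_term_counts(
    groups: Sequence[GeneGroup],
    enriched_terms: Iterable[str],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-group counts of genes annotated with each enriched term.

    Only the supplied (enriched) terms are counted; groups with no annotated
    gene keep their row with zeros. Also reports each group's gene total
    (the tile-matrix semantics: annotated-in-group over group size).
    """
    enriched = sorted(set(enriched_terms))
    by_term = {
        t: set(annotations.loc[annotations["term_id"] == t, "gene_id"])
        for t in enriched
    }
    rows = []
    for g in groups:
        for t in enriched:
            rows.append({
                "group_id": g.group_id or g.represented_gene,
                "term_id": t,
                "count": len(g.genes & by_term[t]),
                "group_size": len(g.genes),
            })
    return pd.DataFrame(
        rows, columns=["group_id", "term_id", "count", "group_size"]
    )
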