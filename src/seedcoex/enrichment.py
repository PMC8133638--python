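"""Term enrichment for candidate gene sets.

Classic one-sided hypergeometric over-representation test with
Benjamini-Hochberg correction. Terms are treated as flat labels: there is NO
ontology (DAG) propagation, so counts differ from DAG-aware tools (e.g.
topGO's elim) that decorrelate parent/child terms. The background universe
is the annotated portion of the filtered transcriptome, and candidates are
restricted to their annotated members before testing, mirroring
annotated-subset counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GOAnnotationMap

__all__ = ["EnrichmentRow", "hypergeometric_enrichment", "category_share", "top_terms"]


@dataclass
class EnrichmentRow:
    """One tested term.

    k of n annotated candidates carry the term; K of N background genes do.
    ``p`` is the hypergeometric upper tail P(X >= k); ``q`` its BH-adjusted
    value across all tested terms.
    """

    term: str
    label: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float


def hypergeometric_enrichment(
    candidates: set[str],
    annotations: GOAnnotationMap,
    background: set[str] | None = None,
) -> list[EnrichmentRow]:
    """Test every term present in the candidate set for over-representation.

    ``background`` defaults to all annotated genes; candidates are first
    restricted to annotated members. Terms with k = 0 are excluded (their
    upper-tail p is 1 by construction). Rows are sorted by ascending p with
    a deterministic tie-break on term id.
    """
    if background is None:
        background = annotations.annotated_genes
    background = set(background) & annotations.annotated_genes
    annotated_candidates = set(candidates) & annotations.annotated_genes
    if not annotated_candidates <= background:
        extra = sorted(annotated_candidates - background)[:5]
        raise ValueError(f"annotated candidates outside the background universe: {extra}")
    if not annotated_candidates:
        raise ValueError("no annotated candidate genes to test")
    n = len(annotated_candidates)
    N = len(background)
    term_bg: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for gene in background:
        for term in annotations.terms_of(gene):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in annotated_candidates:
                term_k[term] = term_k.get(term, 0) + 1
    tested = sorted(term_k)  # k >= 1 only
    pvals = [float(hypergeom.sf(term_k[t] - 1, N, term_bg[t], n)) for t in tested]
    if tested:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = []
    rows = [
        EnrichmentRow(
            term=t,
            label=annotations.term_labels.get(t, ""),
            k=term_k[t],
            K=term_bg[t],
            n=n,
            N=N,
            p=p,
            q=float(q),
        )
        for t, p, q in zip(tested, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def category_share(
    term: str, candidates: set[str], annotations: GOAnnotationMap
) -> tuple[float, int, int]:
    """Share of annotated candidates carrying ``term``.

    Returns (fraction, count with term, annotated candidate count). This is
    the statistic behind statements like "photosynthesis transcripts
    comprised 3%-4% of GO-annotated transcripts".
    """
    annotated = set(candidates) & annotations.annotated_genes
    if not annotated:
        raise ValueError("no annotated candidate genes")
    with_term = {g for g in annotated if term in annotations.terms_of(g)}
    return len(with_term) / len(annotated), len(with_term), len(annotated)


def top_terms(rows: list[EnrichmentRow], n: int = 10) -> pd.DataFrame:
    """Tabulate the n most significant terms (default 10)."""
    sub = rows[:n]
    return pd.DataFrame(
        [(r.term, r.label, r.k, r.K, r.n, r.N, r.p, r.q) for r in sub],
        columns=["term", "label", "k", "K", "n", "N", "p", "q"],
    )
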