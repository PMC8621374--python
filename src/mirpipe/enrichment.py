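"""Hypergeometric term enrichment with Bonferroni correction and rich factor.

GO domains (BP/CC/MF) and pathway sets are handled identically: for each
term with K annotated genes in a universe of N, observing k term genes among
the n target genes has upper-tail probability P(X >= k) under the
hypergeometric null.  Raw p-values are Bonferroni-corrected over all terms
represented in the target set (k >= 1); a term is significant when the
corrected p is below 0.05.  The rich factor k / K ranks pathways by the
fraction of their annotated genes hit by the target set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass
class EnrichmentTerm:
    term_id: str
    domain: str
    k: int  # target genes with the term
    K: int  # universe genes with the term
    n: int  # target-set size
    N: int  # universe size
    p_value: float
    p_bonferroni: float
    rich_factor: float
    significant: bool


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    target_genes,
    gene_terms: pd.DataFrame,
    universe=None,
    *,
    alpha: float = 0.05,
) -> list[EnrichmentTerm]:
    """Per-term enrichment of a target gene set.

    `gene_terms` has columns gene_id / term_id / domain; `universe` defaults
    to every annotated gene.  Terms with no annotated gene are skipped; the
    Bonferroni factor counts the terms actually tested (k >= 1).  Raises
    ``ValueError`` if the target set is not contained in the universe.
    """
    if universe is None:
        universe = set(gene_terms["gene_id"])
    universe = set(universe)
    targets = set(target_genes)
    if not targets <= universe:
        raise ValueError("target set must be a subset of the universe")
    N, n = len(universe), len(targets)
    rows = []
    for (term, domain), sub in gene_terms.groupby(["term_id", "domain"], sort=True):
        genes = set(sub["gene_id"]) & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & targets)
        if k < 1:
            continue
        p = hypergeom_tail(k, N, K, n)
        rows.append((term, domain, k, K, p))
    m = len(rows)
    out = []
    for term, domain, k, K, p in rows:
        p_bonf = min(1.0, m * p)
        out.append(
            EnrichmentTerm(
                term_id=term,
                domain=domain,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=p,
                p_bonferroni=p_bonf,
                rich_factor=k / K,
                significant=p_bonf < alpha,
            )
        )
    out.sort(key=lambda t: (t.p_value, t.term_id))
    return out


def enrichment_table(terms) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                t.term_id,
                t.domain,
                t.k,
                t.K,
                t.n,
                t.N,
                t.p_value,
                t.p_bonferroni,
                t.rich_factor,
                t.significant,
            )
            for t in terms
        ],
        columns=[
            "term_id",
            "domain",
            "k",
            "K",
            "n",
            "N",
            "p_value",
            "p_bonferroni",
            "rich_factor",
            "significant",
        ],
    )


def summarize_pathways(terms, top_m: int = 20, p_max: float = 0.05) -> pd.DataFrame:
    """Dot-plot backing table: the `top_m` smallest-p terms with p < `p_max`.

    Sorted ascending by raw p with deterministic term-id tie-breaks; columns
    term / domain / rich_factor / p_value / p_bonferroni / gene_count.
    """
    kept = sorted(
        (t for t in terms if t.p_value < p_max), key=lambda t: (t.p_value, t.term_id)
    )[:top_m]
    return pd.DataFrame(
        [
            (t.term_id, t.domain, t.rich_factor, t.p_value, t.p_bonferroni, t.k)
            for t in kept
        ],
        columns=["term_id", "domain", "rich_factor", "p_value", "p_bonferroni", "gene_count"],
    )
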