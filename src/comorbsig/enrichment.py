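"""Over-representation analysis with hypergeometric tests, Bonferroni
correction, and kappa-based redundancy clustering.

A query gene list of size n within a background of N genes is tested against
each gene set (size K within the background, overlap k) with the
hypergeometric upper tail P(X >= k).  Raw p-values are Bonferroni-corrected
by the number of tested terms.  Significant terms are grouped into
non-redundant clusters by greedy agglomeration on pairwise Cohen's kappa of
their membership indicator vectors over the background, and each cluster is
represented by its lowest-p member.  TF-regulon enrichment runs the same
machinery with TF target sets as terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import GeneSetCollection, RegulonTable, ValidationError
from .signature_overlap import hypergeom_tail

__all__ = [
    "EnrichmentRow",
    "TermCluster",
    "ora",
    "cohen_kappa",
    "cluster_terms",
    "tf_enrichment",
    "enrichment_table",
]


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_bonf: float
    fold: float
    member_genes: list[str]


@dataclass
class TermCluster:
    members: list[str]
    representative: str
    similarity_threshold: float


def ora(
    query_genes: set[str],
    collection: GeneSetCollection,
    background: set[str],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of a query list against gene sets.

    Query genes outside the background are dropped (with the fold/counts
    computed on the background-restricted sets); terms with no member in the
    background are excluded from testing and from the Bonferroni factor.
    Rows are sorted by p_raw ascending, ties by term id.
    """
    background = set(background)
    if not background:
        raise ValidationError("enrichment background is empty")
    query = set(query_genes) & background
    if not query:
        raise ValidationError("query list is empty (after background restriction)")
    N, n = len(background), len(query)
    rows: list[EnrichmentRow] = []
    for term_id in collection.term_ids():
        members = collection.members(term_id) & background
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(members & query)
        k = len(overlap)
        p_raw = hypergeom_tail(k, K, n, N)
        fold = (k / n) / (K / N)
        rows.append(
            EnrichmentRow(term_id, collection.name(term_id), k, K, n, N, p_raw, 0.0, fold, overlap)
        )
    m = len(rows)
    for row in rows:
        row.p_bonf = min(1.0, m * row.p_raw)
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows


def cohen_kappa(set_a: set[str], set_b: set[str], background: set[str]) -> float:
    """Cohen's kappa between two membership indicators over the background.

    kappa = (p_observed - p_chance) / (1 - p_chance) from the 2x2 table of
    joint membership; 1 when the sets agree everywhere, ~0 for independent
    sets, and defined as 1 when chance agreement is total (identical
    degenerate margins).
    """
    N = len(background)
    if N == 0:
        raise ValidationError("kappa needs a non-empty background")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = N - a - b - c
    if d < 0:
        raise ValidationError("sets must be subsets of the background")
    po = (a + d) / N
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def cluster_terms(
    rows: list[EnrichmentRow],
    collection: GeneSetCollection,
    background: set[str],
    similarity_threshold: float = 0.3,
    alpha: float = 0.05,
) -> list[TermCluster]:
    """Group significant terms into non-redundant clusters.

    Terms with p_bonf < alpha are considered; clustering seeds with the
    lowest-p unclustered term and absorbs every unclustered term whose kappa
    to any current member reaches the threshold, repeating until the cluster
    is stable.  The representative is the member with minimum p_raw.
    """
    significant = sorted(
        (r for r in rows if r.p_bonf < alpha), key=lambda r: (r.p_raw, r.term_id)
    )
    member_sets = {
        r.term_id: set(collection.members(r.term_id)) & set(background) for r in significant
    }
    unclustered = [r.term_id for r in significant]
    clusters: list[TermCluster] = []
    while unclustered:
        seed = unclustered.pop(0)
        members = [seed]
        changed = True
        while changed:
            changed = False
            for tid in list(unclustered):
                if any(
                    cohen_kappa(member_sets[tid], member_sets[m], set(background))
                    >= similarity_threshold
                    for m in members
                ):
                    members.append(tid)
                    unclustered.remove(tid)
                    changed = True
        p_by_id = {r.term_id: r.p_raw for r in significant}
        representative = min(members, key=lambda t: (p_by_id[t], t))
        clusters.append(TermCluster(members, representative, similarity_threshold))
    return clusters


def tf_enrichment(
    query_genes: set[str],
    regulons: RegulonTable,
    background: set[str],
) -> list[EnrichmentRow]:
    """Regulon over-representation: ORA with TF target sets as terms."""
    return ora(query_genes, regulons.to_gene_sets(), background)


def enrichment_table(
    rows: list[EnrichmentRow], clusters: list[TermCluster] | None = None
) -> pd.DataFrame:
    """Flatten enrichment rows (and optional clusters) into a result table."""
    cluster_of: dict[str, int] = {}
    representative: set[str] = set()
    if clusters:
        for i, cl in enumerate(clusters, start=1):
            representative.add(cl.representative)
            for tid in cl.members:
                cluster_of[tid] = i
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "term_name": [r.term_name for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "fold": [r.fold for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_bonf": [r.p_bonf for r in rows],
            "cluster_id": [cluster_of.get(r.term_id, 0) for r in rows],
            "is_representative": [r.term_id in representative for r in rows],
            "member_genes": [";".join(r.member_genes) for r in rows],
        }
    )
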