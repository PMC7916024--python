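"""Directional overlap statistics between two disease DEG signatures.

Two signatures over a shared background of N genes are partitioned into four
directional intersections (up/up, down/down, up/down, down/up).  For each
partition with list sizes nA and nB and observed overlap k, the expected
overlap under independent draws is nA*nB/N and the representation factor is

    RF = k / (nA*nB/N),

with RF > 1 indicating more overlap than chance.  Significance is assessed
with a one-tailed (enrichment-directional) Pearson chi-square on the 2x2
table, and an exact hypergeometric upper tail is computed alongside as the
oracle for the chi-square approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io_formats import ValidationError

__all__ = [
    "Signature",
    "OverlapResult",
    "partition_overlap",
    "representation_factor",
    "overlap_chi2_one_tailed",
    "hypergeom_tail",
    "overlap_table",
]


@dataclass
class Signature:
    """A disease's DEG signature: disjoint up/down gene sets over a background."""

    disease_id: str
    up: frozenset[str]
    down: frozenset[str]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        self.background = frozenset(self.background)
        if self.up & self.down:
            raise ValidationError(
                f"{self.disease_id}: up and down sets overlap: {sorted(self.up & self.down)[:5]}"
            )
        if not (self.up | self.down) <= self.background:
            stray = (self.up | self.down) - self.background
            raise ValidationError(
                f"{self.disease_id}: signature genes outside background: {sorted(stray)[:5]}"
            )

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class OverlapResult:
    """One directional partition of a two-signature comparison."""

    partition: str  # up_up | down_down | upA_downB | downA_upB
    k: int
    nA: int
    nB: int
    N: int
    expected: float
    rf: float
    chi2: float
    p_one_tailed: float
    p_hypergeom: float
    overlap_genes: list[str]


def _validate_counts(k: int, nA: int, nB: int, N: int) -> None:
    if N <= 0:
        raise ValidationError("background size N must be positive")
    if not (0 <= nA <= N and 0 <= nB <= N):
        raise ValidationError(f"list sizes nA={nA}, nB={nB} must lie in [0, N={N}]")
    if k < 0:
        raise ValidationError(f"overlap k={k} must be nonnegative")


def representation_factor(k: int, nA: int, nB: int, N: int) -> tuple[float, float]:
    """Expected overlap nA*nB/N and representation factor k/expected.

    Raises when nA*nB == 0 (the factor is undefined for an empty list).
    """
    _validate_counts(k, nA, nB, N)
    if k > min(nA, nB):
        raise ValidationError(f"overlap k={k} exceeds min(nA, nB)={min(nA, nB)}")
    if nA * nB == 0:
        raise ValidationError("representation factor undefined when a list is empty")
    expected = nA * nB / N
    return expected, k / expected


def overlap_chi2_one_tailed(k: int, nA: int, nB: int, N: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the 2x2 overlap table,
    folded to a one-tailed enrichment p-value.

    The table is [[k, nA-k], [nB-k, N-nA-nB+k]].  The one-tailed p is half the
    two-sided chi-square p when k exceeds its expectation, and 1 minus that
    half otherwise, so depletion is never called significant.
    """
    _validate_counts(k, nA, nB, N)
    cells = (k, nA - k, nB - k, N - nA - nB + k)
    if any(c < 0 for c in cells):
        raise ValidationError(f"2x2 table has a negative cell: {cells}")
    expected = nA * nB / N
    if nA * nB == 0 or nA == N or nB == N:
        # a margin is degenerate: no evidence either way
        return 0.0, 1.0 if k <= expected else 0.5
    a, b, c, d = cells
    num = N * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = num / den if den > 0 else 0.0
    p_two = float(stats.chi2.sf(chi2, df=1))
    p_one = p_two / 2 if k > expected else 1 - p_two / 2
    return float(chi2), float(p_one)


def hypergeom_tail(k: int, nA: int, nB: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, nA, nB).

    X counts the overlap when a list of nB genes is drawn without replacement
    from a background of N containing nA marked genes.  Computed in log space
    by scipy; exact oracle for the chi-square approximation.
    """
    _validate_counts(k, nA, nB, N)
    if k == 0:
        return 1.0
    if k > min(nA, nB):
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, nA, nB))


_PARTITIONS = (
    ("up_up", "up", "up"),
    ("down_down", "down", "down"),
    ("upA_downB", "up", "down"),
    ("downA_upB", "down", "up"),
)


def partition_overlap(sig_a: Signature, sig_b: Signature) -> list[OverlapResult]:
    """Compute the four directional overlap partitions of two signatures.

    Both signatures must carry the identical background (pre-intersect the
    universes upstream).  Empty partitions are reported with RF 0 and
    one-tailed p 1 rather than raising, so null runs emit valid output.
    """
    if sig_a.background != sig_b.background:
        raise ValidationError(
            "signatures have different backgrounds; intersect universes before comparing"
        )
    N = len(sig_a.background)
    results = []
    for label, dir_a, dir_b in _PARTITIONS:
        set_a: frozenset[str] = getattr(sig_a, dir_a)
        set_b: frozenset[str] = getattr(sig_b, dir_b)
        genes = sorted(set_a & set_b)
        k, nA, nB = len(genes), len(set_a), len(set_b)
        if nA * nB == 0:
            results.append(OverlapResult(label, k, nA, nB, N, 0.0, 0.0, 0.0, 1.0, 1.0, genes))
            continue
        expected, rf = representation_factor(k, nA, nB, N)
        chi2, p_one = overlap_chi2_one_tailed(k, nA, nB, N)
        p_hyp = hypergeom_tail(k, nA, nB, N)
        results.append(OverlapResult(label, k, nA, nB, N, expected, rf, chi2, p_one, p_hyp, genes))
    return results


def overlap_table(results: list[OverlapResult]) -> pd.DataFrame:
    """Flatten overlap partitions into a result table (gene lists ';'-joined)."""
    return pd.DataFrame(
        {
            "partition": [r.partition for r in results],
            "k": [r.k for r in results],
            "nA": [r.nA for r in results],
            "nB": [r.nB for r in results],
            "N": [r.N for r in results],
            "expected": [r.expected for r in results],
            "rf": [r.rf for r in results],
            "chi2": [r.chi2 for r in results],
            "p_one_tailed": [r.p_one_tailed for r in results],
            "p_hypergeom": [r.p_hypergeom for r in results],
            "overlap_genes": [";".join(r.overlap_genes) for r in results],
        }
    )
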