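"""Random-effects effect-size meta-analysis across cohorts of one disease.

Each cohort contributes, per gene, Hedges' small-sample-corrected
standardized mean difference

    g = J * (mean_case - mean_control) / s_pooled,
    J = 1 - 3 / (4*(n1 + n0 - 2) - 1),

with sampling variance v = (n1 + n0)/(n1*n0) + g^2 / (2*(n1 + n0)).
Per-gene effects are combined by the DerSimonian-Laird moment estimator of
the between-study variance tau^2; the combined effect mu, its standard error
and z = mu/se give a normal-reference p-value, adjusted by
Benjamini-Hochberg over the shared gene universe (the intersection of the
cohorts' gene lists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionDataset, ValidationError
from .normalize_dge import bh_adjust
from .signature_overlap import Signature

__all__ = [
    "StudyEffect",
    "MetaResult",
    "hedges_g",
    "hedges_g_dataset",
    "dersimonian_laird",
    "run_meta",
]


@dataclass(frozen=True)
class StudyEffect:
    """One cohort's standardized effect for one gene."""

    gene_id: str
    dataset_id: str
    g: float
    v: float
    n_case: int
    n_control: int


@dataclass(frozen=True)
class MetaResult:
    """Combined per-gene result of the random-effects model."""

    gene_id: str
    k: int
    Q: float
    tau2: float
    mu: float
    se: float
    z: float
    p_raw: float


def hedges_g(case_values: np.ndarray, control_values: np.ndarray) -> tuple[float, float]:
    """Hedges' bias-corrected standardized mean difference and its variance."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    n1, n0 = case.size, control.size
    if n1 < 2 or n0 < 2:
        raise ValidationError("hedges_g needs >=2 samples per group")
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n0 - 1) * control.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValidationError("pooled standard deviation is zero; effect size undefined")
    J = 1 - 3 / (4 * df - 1)
    g = J * (case.mean() - control.mean()) / math.sqrt(sp2)
    v = (n1 + n0) / (n1 * n0) + g * g / (2 * (n1 + n0))
    return float(g), float(v)


def hedges_g_dataset(dataset: ExpressionDataset) -> pd.DataFrame:
    """Vectorized Hedges' g for every gene of one cohort.

    Genes with zero pooled variance get NaN effects (excluded downstream).
    """
    case = dataset.case_matrix()
    control = dataset.control_matrix()
    n1, n0 = case.shape[1], control.shape[1]
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n0 - 1) * control.var(axis=1, ddof=1)) / df
    J = 1 - 3 / (4 * df - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = J * (case.mean(axis=1) - control.mean(axis=1)) / np.sqrt(sp2)
    g = np.where(sp2 > 0, g, np.nan)
    v = (n1 + n0) / (n1 * n0) + g * g / (2 * (n1 + n0))
    return pd.DataFrame(
        {
            "gene_id": dataset.gene_ids,
            "dataset_id": dataset.dataset_id,
            "g": g,
            "v": v,
            "n_case": n1,
            "n_control": n0,
        }
    )


def dersimonian_laird(
    effects: list[tuple[float, float]], random_effects: bool = True
) -> MetaResult:
    """Combine (g, v) study effects with the DerSimonian-Laird estimator.

    With ``random_effects`` False, tau^2 is forced to zero (fixed-effects
    inverse-variance weighting).  A single study reduces to its own z-test.
    """
    if not effects:
        raise ValidationError("dersimonian_laird needs at least one study")
    g = np.array([e[0] for e in effects], dtype=float)
    v = np.array([e[1] for e in effects], dtype=float)
    if np.any(v <= 0):
        raise ValidationError("all sampling variances must be positive")
    k = g.size
    w = 1.0 / v
    g_fe = float(np.sum(w * g) / np.sum(w))
    Q = float(np.sum(w * (g - g_fe) ** 2))
    if k >= 2 and random_effects:
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    mu = float(np.sum(w_star * g) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    z = mu / se
    p_raw = float(2 * stats.norm.sf(abs(z)))
    return MetaResult("", k, Q, tau2, mu, se, z, p_raw)


def _dl_combine_matrix(
    g: np.ndarray, v: np.ndarray, random_effects: bool = True
) -> dict[str, np.ndarray]:
    """Row-wise DerSimonian-Laird over a genes x studies effect matrix."""
    k = g.shape[1]
    w = 1.0 / v
    g_fe = np.sum(w * g, axis=1) / np.sum(w, axis=1)
    Q = np.sum(w * (g - g_fe[:, None]) ** 2, axis=1)
    if k >= 2 and random_effects:
        denom = np.sum(w, axis=1) - np.sum(w**2, axis=1) / np.sum(w, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tau2 = np.maximum(0.0, (Q - (k - 1)) / denom)
        tau2 = np.where(denom > 0, tau2, 0.0)
    else:
        tau2 = np.zeros(g.shape[0])
    w_star = 1.0 / (v + tau2[:, None])
    mu = np.sum(w_star * g, axis=1) / np.sum(w_star, axis=1)
    se = 1.0 / np.sqrt(np.sum(w_star, axis=1))
    z = mu / se
    p_raw = 2 * stats.norm.sf(np.abs(z))
    return {"k": np.full(g.shape[0], k), "Q": Q, "tau2": tau2, "mu": mu, "se": se, "z": z, "p_raw": p_raw}


def run_meta(
    datasets: list[ExpressionDataset],
    fdr_threshold: float = 0.1,
    disease_id: str = "disease",
    random_effects: bool = True,
) -> tuple[pd.DataFrame, Signature]:
    """Meta-analyze >=1 cohorts of one disease into a DEG signature.

    The gene universe is the intersection of the cohorts' gene lists (order
    taken from the first cohort).  Genes whose pooled variance is zero in any
    cohort are dropped with the intersection.  Returns the per-gene result
    table (gene_id, k, Q, tau2, mu, se, z, p_raw, p_adj, direction) and the
    signature at p_adj < fdr_threshold with direction = sign(mu).
    """
    if not datasets:
        raise ValidationError("run_meta needs at least one dataset")
    shared = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        shared &= set(ds.gene_ids)
    genes = [g for g in datasets[0].gene_ids if g in shared]
    if not genes:
        raise ValidationError("gene intersection across datasets is empty")

    g_mat = np.empty((len(genes), len(datasets)))
    v_mat = np.empty_like(g_mat)
    for j, ds in enumerate(datasets):
        eff = hedges_g_dataset(ds.subset_genes(genes))
        g_mat[:, j] = eff["g"].to_numpy()
        v_mat[:, j] = eff["v"].to_numpy()
    usable = np.all(np.isfinite(g_mat), axis=1)
    genes = [g for g, ok in zip(genes, usable) if ok]
    g_mat, v_mat = g_mat[usable], v_mat[usable]
    if len(genes) == 0:
        raise ValidationError("no gene has positive pooled variance in every dataset")

    combined = _dl_combine_matrix(g_mat, v_mat, random_effects=random_effects)
    table = pd.DataFrame({"gene_id": genes, **combined})
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table["direction"] = np.where(
        table["mu"] > 0, "up", np.where(table["mu"] < 0, "down", "none")
    )

    hits = table[table["p_adj"] < fdr_threshold]
    signature = Signature(
        disease_id,
        frozenset(hits.loc[hits["direction"] == "up", "gene_id"]),
        frozenset(hits.loc[hits["direction"] == "down", "gene_id"]),
        frozenset(genes),
    )
    return table, signature
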