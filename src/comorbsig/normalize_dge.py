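"""Single-cohort normalization and moderated-t differential expression.

The pipeline for a one-dataset disease arm is: variance-stabilizing
transform (for raw-scale intensities), quantile normalization across
samples, then a per-gene two-group empirical-Bayes moderated t-test with
Benjamini-Hochberg FDR adjustment and a strict FDR < threshold DEG call.

The moderated test shrinks each gene's pooled variance s_g^2 (d_g residual
df) toward a prior (s0^2, d0) estimated across all genes:

    s_tilde^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)
    t_tilde   = (mean_case - mean_control) / (s_tilde * sqrt(1/n1 + 1/n0))

with t_tilde referred to a Student t on d0 + d_g degrees of freedom (the
normal limit when d0 is infinite).  The prior is fit by moment matching on
log s^2 via digamma/trigamma inversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionDataset, ValidationError
from .signature_overlap import Signature

logger = logging.getLogger("comorbsig")

__all__ = [
    "ModeratedPrior",
    "quantile_normalize",
    "vs_transform",
    "normalize_dataset",
    "fit_moderated_prior",
    "moderated_t_test",
    "bh_adjust",
    "call_degs",
]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column (sample) onto the common reference distribution.

    The reference is the vector of row means of the column-sorted matrix.
    Each value is replaced by the reference value at its within-column rank;
    ties within a column receive the mean of the reference values at their
    tied ranks, so tied inputs stay tied.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("quantile_normalize expects a 2-D matrix with >=1 column")
    if not np.all(np.isfinite(X)):
        raise ValidationError("quantile_normalize requires finite entries")
    reference = np.mean(np.sort(X, axis=0), axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(col)
        ranked[order] = reference
        # average reference values over tied groups
        sorted_vals = col[order]
        i = 0
        while i < len(col):
            jj = i
            while jj + 1 < len(col) and sorted_vals[jj + 1] == sorted_vals[i]:
                jj += 1
            if jj > i:
                ranked[order[i : jj + 1]] = reference[i : jj + 1].mean()
            i = jj + 1
        out[:, j] = ranked
    return out


def vs_transform(matrix: np.ndarray, scale: float | None = None) -> np.ndarray:
    """Variance-stabilizing generalized-log transform for raw intensities.

    Applies y = arsinh(x / c) with c the median positive intensity of the
    dataset (or the given ``scale``).  arsinh is linear near zero and
    logarithmic for large x (y ~ log(2x/c)), which stabilizes the
    multiplicative-plus-additive noise typical of array intensities.
    """
    X = np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValidationError("vs_transform expects nonnegative raw intensities")
    if scale is None:
        positive = X[X > 0]
        if positive.size == 0:
            raise ValidationError("vs_transform undefined for an all-zero matrix")
        scale = float(np.median(positive))
    if scale <= 0:
        raise ValidationError("vs_transform scale must be positive")
    return np.arcsinh(X / scale)


def normalize_dataset(
    dataset: ExpressionDataset, method: str = "quantile"
) -> ExpressionDataset:
    """Return a normalized copy of a dataset.

    ``method``: "vsn+quantile" for raw-scale input (arsinh glog then quantile),
    "quantile" for data already on a log-like scale, or "none".
    """
    if method == "none":
        return dataset.with_values(dataset.values.copy())
    if method == "vsn+quantile":
        return dataset.with_values(quantile_normalize(vs_transform(dataset.values)))
    if method == "quantile":
        return dataset.with_values(quantile_normalize(dataset.values))
    raise ValidationError(f"unknown normalization method {method!r}")


# ---------------------------------------------------------------------------
# Empirical-Bayes prior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeratedPrior:
    """Prior degrees of freedom d0 (may be math.inf) and prior variance s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError("prior d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValidationError("prior s0_sq must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        return math.inf
    # trigamma(x) ~ 1/x + 1/(2x^2); start from the 1/x asymptote
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(special.polygamma(1, x))
        step = (tri - y) / float(special.polygamma(2, x))
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        if abs(x_new - x) < 1e-12 * max(1.0, x):
            return x_new
        x = x_new
    return x


def fit_moderated_prior(s2: np.ndarray, df: float) -> ModeratedPrior:
    """Moment-match the scaled-inverse-chi-square prior of gene variances.

    Under the hierarchical model, log s_g^2 has variance
    trigamma(df/2) + trigamma(d0/2); d0 solves
    trigamma(d0/2) = var(log s^2) - trigamma(df/2) (infinite when the
    right-hand side is <= 0), and s0^2 follows from mean(log s^2) through
    the corresponding digamma identity.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ValidationError("need at least 10 genes with positive variance to fit the prior")
    if df < 1:
        raise ValidationError("residual degrees of freedom must be >= 1")
    z = np.log(s2)
    var_z = float(np.var(z, ddof=1))
    rhs = var_z - float(special.polygamma(1, df / 2))
    if rhs <= 0:
        d0 = math.inf
        log_s0 = float(np.mean(z)) - float(special.digamma(df / 2)) + math.log(df / 2)
    else:
        half_d0 = _trigamma_inverse(rhs)
        d0 = 2 * half_d0
        log_s0 = (
            float(np.mean(z))
            - float(special.digamma(df / 2))
            + math.log(df / 2)
            + float(special.digamma(half_d0))
            - math.log(half_d0)
        )
    return ModeratedPrior(d0=d0, s0_sq=float(np.exp(log_s0)))


# ---------------------------------------------------------------------------
# Moderated t-test and DEG calls
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_t_test(
    dataset: ExpressionDataset, prior: ModeratedPrior | None = None
) -> pd.DataFrame:
    """Per-gene moderated two-group t-test on a normalized dataset.

    Returns a DataFrame with columns gene_id, effect, s2, df, t_mod, p_raw,
    p_adj, direction.  ``prior`` overrides the empirical-Bayes fit; a prior
    with d0 = 0 is accepted as an explicit switch to the ordinary t-test.
    """
    case = dataset.case_matrix()
    control = dataset.control_matrix()
    n1, n0 = case.shape[1], control.shape[1]
    d_g = n1 + n0 - 2
    effect = case.mean(axis=1) - control.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + control.var(axis=1, ddof=1) * (n0 - 1)
    s2 = ss / d_g

    if np.all(s2 == 0):
        raise ValidationError("zero within-group variance for every gene")

    if prior is None:
        prior = fit_moderated_prior(s2, d_g)
    d0, s0_sq = prior.d0, prior.s0_sq

    if d0 == 0:
        post_var = s2.copy()
        df_total = float(d_g)
    elif math.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        post_var = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    se_factor = math.sqrt(1 / n1 + 1 / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = effect / (np.sqrt(post_var) * se_factor)

    zero_var = post_var == 0
    t_mod = np.where(zero_var & (effect == 0), 0.0, t_mod)
    if np.any(zero_var & (effect != 0)):
        logger.warning(
            "%d genes with zero variance but nonzero effect; p set to 0",
            int(np.sum(zero_var & (effect != 0))),
        )
    if math.isinf(df_total):
        p_raw = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw = np.where(zero_var & (effect == 0), 1.0, p_raw)
    p_raw = np.where(zero_var & (effect != 0), 0.0, p_raw)

    direction = np.where(effect > 0, "up", np.where(effect < 0, "down", "none"))
    return pd.DataFrame(
        {
            "gene_id": dataset.gene_ids,
            "effect": effect,
            "s2": s2,
            "df": float(d_g),
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "direction": direction,
        }
    )


def call_degs(
    stats_table: pd.DataFrame,
    fdr_threshold: float = 0.1,
    disease_id: str = "disease",
    background: frozenset[str] | None = None,
) -> Signature:
    """Call DEGs at strictly p_adj < fdr_threshold, split by effect sign.

    ``background`` defaults to all genes in the table (the tested universe).
    """
    if not 0 <= fdr_threshold <= 1:
        raise ValidationError("fdr_threshold must lie in [0, 1]")
    if len(stats_table) == 0:
        bg = background or frozenset()
        return Signature(disease_id, frozenset(), frozenset(), bg)
    hits = stats_table[stats_table["p_adj"] < fdr_threshold]
    up = frozenset(hits.loc[hits["direction"] == "up", "gene_id"])
    down = frozenset(hits.loc[hits["direction"] == "down", "gene_id"])
    bg = background if background is not None else frozenset(stats_table["gene_id"])
    return Signature(disease_id, up, down, bg)
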