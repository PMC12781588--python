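"""Per-probe linear modelling with empirical-Bayes moderated statistics.

Each probe's beta values are regressed on an intercept, a case indicator,
and blood-cell-fraction covariates (all but one reference type).  Residual
variances are shrunk toward a common prior fitted by moment matching on
log variances (a scaled-F prior with ``d0`` prior degrees of freedom and
prior variance ``s0_sq``); moderated t-statistics use the posterior
variance and ``d0 + dof`` degrees of freedom.  Multiple testing is
controlled with Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DegenerateDataError, DesignError, ValidationError
from .io_qc import BetaMatrix, SampleSheet


@dataclass
class DesignMatrix:
    """Samples x covariates design: intercept, case indicator, cell fractions."""

    matrix: np.ndarray
    sample_ids: list[str]
    columns: list[str]
    group_col: int = 1

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise DesignError("design matrix is rank deficient")


def build_design(sheet: SampleSheet, adjust_cells: bool = True) -> DesignMatrix:
    """Intercept + case indicator + cell-fraction covariates (dropping the
    last cell type as reference).  With no cell fractions on the sheet the
    model runs unadjusted, with a warning."""
    df = sheet.data
    group = (df["group"] == "case").astype(float).to_numpy()
    cols = [np.ones(len(df)), group]
    names = ["intercept", "group"]
    cf = sheet.cell_fraction_columns
    if adjust_cells and cf:
        for c in cf[:-1]:  # drop one type: fractions sum to 1
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
    elif adjust_cells and not cf:
        warnings.warn("no cell fractions on sample sheet; running unadjusted")
    return DesignMatrix(np.column_stack(cols), list(df["sample_id"]), names)


def fit_probe_models(beta: BetaMatrix, design: DesignMatrix) -> pd.DataFrame:
    """Ordinary least squares per probe (vectorized across probes).

    Returns one row per probe with the group coefficient, its unmoderated
    standard error, the residual variance ``sigma2`` (RSS/dof), the shared
    residual ``dof``, and the raw case-minus-control mean difference
    ``delta_beta`` (unadjusted group means).
    """
    if design.sample_ids != beta.sample_ids:
        raise DesignError("design row order does not match beta sample order")
    X = design.matrix
    n, k = X.shape
    if n < k + 2:
        raise DesignError("need at least 2 more samples than design columns")
    Y = beta.values.to_numpy(dtype=float)  # probes x samples
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = Y @ X @ xtx_inv  # probes x k
    resid = Y - coefs @ X.T
    dof = n - k
    rss = np.einsum("ps,ps->p", resid, resid)
    sigma2 = rss / dof
    sigma2 = np.where(sigma2 < 0, 0.0, sigma2)  # guard tiny negatives
    c_g = float(np.sqrt(xtx_inv[design.group_col, design.group_col]))
    case_mask = X[:, design.group_col] == 1.0
    delta_beta = Y[:, case_mask].mean(axis=1) - Y[:, ~case_mask].mean(axis=1)
    return pd.DataFrame(
        {
            "probe_id": beta.probe_ids,
            "coef": coefs[:, design.group_col],
            "sigma2": sigma2,
            "stderr_unmoderated": np.sqrt(sigma2) * c_g,
            "stderr_factor": c_g,
            "dof": dof,
            "delta_beta": delta_beta,
        }
    ).set_index("probe_id")


@dataclass
class EBayesHyper:
    """Scaled-F prior on residual variances: prior dof ``d0`` (may be
    +inf) and prior variance ``s0_sq``."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValidationError("d0 and s0_sq must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_hyperparameters(sigma2: np.ndarray, dof: float) -> EBayesHyper:
    """Fit the scaled-F variance prior by moment matching on log variances.

    Matches the empirical mean and variance of ``log(sigma2)`` to the
    theoretical mean/variance of log scaled-F variates through digamma /
    trigamma relations.  If the empirical spread does not exceed the
    sampling floor ``trigamma(dof/2)``, the prior is degenerate:
    ``d0 = +inf`` with ``s0_sq`` from the geometric mean.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    pos = sigma2[sigma2 > 0]
    if pos.size == 0:
        raise DegenerateDataError("all residual variances are zero")
    if pos.size < 10:
        raise DegenerateDataError("need at least 10 probes with positive variance")
    z = np.log(pos)
    e_mean = float(np.mean(z))
    e_var = float(np.var(z, ddof=1))
    # log sigma2 = log s0_sq + log F(dof, d0); E[log F] and Var[log F] below.
    mean_part = special.digamma(dof / 2.0) - np.log(dof / 2.0)
    excess = e_var - special.polygamma(1, dof / 2.0)
    if excess <= 0:
        s0 = float(np.exp(e_mean - mean_part))
        return EBayesHyper(d0=np.inf, s0_sq=s0)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0 = float(
        np.exp(e_mean - mean_part + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return EBayesHyper(d0=d0, s0_sq=s0)


def moderated_statistics(fits: pd.DataFrame, hyper: EBayesHyper) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values from shrunken variances.

    Posterior variance ``s2_post = (d0*s0_sq + dof*sigma2) / (d0 + dof)``;
    ``t = coef / (sqrt(s2_post) * c_g)`` on ``d0 + dof`` degrees of
    freedom (standard normal when ``d0`` is infinite).
    """
    sigma2 = fits["sigma2"].to_numpy()
    dof = fits["dof"].to_numpy(dtype=float)
    if np.isinf(hyper.d0):
        s2_post = np.full_like(sigma2, hyper.s0_sq)
        df_total = np.full_like(dof, np.inf)
    else:
        s2_post = (hyper.d0 * hyper.s0_sq + dof * sigma2) / (hyper.d0 + dof)
        df_total = hyper.d0 + dof
    se = np.sqrt(s2_post) * fits["stderr_factor"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits["coef"].to_numpy() / se
    t = np.where(se == 0, 0.0, t)
    if np.isinf(hyper.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "probe_id": fits.index,
            "delta_beta": fits["delta_beta"].to_numpy(),
            "t_moderated": t,
            "p_raw": p,
        }
    ).set_index("probe_id")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def bh_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} ( p_(j) * m / j )`` capped at 1, where probes
    are ranked by raw p; ``m`` defaults to ``len(p)`` but may be set
    larger when the battery includes tests not supplied here.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    if m is None:
        m = n
    if m < n:
        raise ValidationError("m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def differential_analysis(
    beta: BetaMatrix, sheet: SampleSheet, adjust_cells: bool = True
) -> pd.DataFrame:
    """Full per-probe pipeline: design -> OLS -> eBayes -> moderated stats."""
    sub = sheet.data[sheet.data["group"].isin(["case", "control"])]
    sub_sheet = SampleSheet(sub.reset_index(drop=True))
    sub_beta = beta.subset_samples(sub_sheet.sample_ids)
    design = build_design(sub_sheet, adjust_cells=adjust_cells)
    fits = fit_probe_models(sub_beta, design)
    hyper = estimate_hyperparameters(fits["sigma2"].to_numpy(), float(fits["dof"].iloc[0]))
    return moderated_statistics(fits, hyper)
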