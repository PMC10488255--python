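"""Population-averaged logistic models for clustered depolarization data.

Single-cell depolarization calls from one biological replicate are not
independent: the whole culture shares handling, staining and growth history.
The standard remedy in this field is a generalized estimating equation (GEE)
fit of a logit-link marginal model with the biological replicate as the
clustering (panel) unit and a cluster-robust "sandwich" covariance, i.e. a
multilevel logistic regression in the population-averaged sense.

This module implements that estimator from first principles:

* :func:`fit_gee_logit` — iteratively reweighted GEE solution of
  ``sum_i D_i' V_i^-1 (y_i - mu_i) = 0`` with binomial variance, logit link,
  independence or exchangeable working correlation (moment-estimated
  intra-cluster correlation), and the Liang–Zeger sandwich covariance.
* :func:`fit_from_aggregates` — the same model on grouped
  (x, n_total, n_depolarized) counts, which is how coefficients are
  re-derived from published per-condition percentages and sample sizes.
* :func:`reconstruct_counts`, :func:`relative_risk`,
  :func:`pairwise_comparisons` — the surrounding bookkeeping: turning
  printed percentages back into counts (half-up rounding), risk ratios of
  fitted probabilities, and all-pairs group contrasts with Wald p-values.

Under the independence working correlation the GEE point estimates coincide
with ordinary pooled maximum-likelihood logistic regression; the clustering
only changes the standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "GEEFit",
    "ComparisonResult",
    "CompleteSeparationError",
    "fit_gee_logit",
    "fit_from_aggregates",
    "reconstruct_counts",
    "relative_risk",
    "pairwise_comparisons",
    "cells_to_gee_data",
]

WORKING_CORRELATIONS = ("independence", "exchangeable")


class CompleteSeparationError(RuntimeError):
    """The binary outcome is perfectly separated by a covariate."""


@dataclass
class GEEFit:
    """Result of a population-averaged logit fit.

    ``beta`` is on the logit scale (intercept first).  ``robust_se`` are
    cluster-robust sandwich standard errors, ``model_se`` the model-based
    ones; with a single cluster the sandwich is undefined and ``robust_se``
    falls back to ``model_se`` (``se_type`` records which was used).
    ``alpha`` is the moment-estimated exchangeable intra-cluster correlation
    (0 under independence).
    """

    beta: np.ndarray
    robust_se: np.ndarray
    model_se: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    alpha: float
    scale: float
    n_clusters: int
    n_obs: int
    converged: bool
    working_correlation: str
    n_iter: int
    param_names: list[str] = field(default_factory=list)
    se_type: str = "robust"

    def fitted_probability(self, x_row: np.ndarray | list[float]) -> float:
        """Marginal P(y=1) at a design row (including the intercept term)."""
        return float(expit(np.asarray(x_row, dtype=float) @ self.beta))

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "beta": self.beta.tolist(),
            "robust_se": self.robust_se.tolist(),
            "model_se": self.model_se.tolist(),
            "wald_z": self.wald_z.tolist(),
            "p_values": self.p_values.tolist(),
            "alpha": self.alpha,
            "scale": self.scale,
            "n_clusters": self.n_clusters,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "working_correlation": self.working_correlation,
            "se_type": self.se_type,
        }


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group contrast: relative risk plus (optionally) a Wald p-value."""

    group_a: str
    group_b: str
    rr: float
    p_value: float | None = None
    method: str = "ratio"

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ValueError("relative risk must be positive")


# ---------------------------------------------------------------------------
# core estimator


def _as_design(x: np.ndarray) -> np.ndarray:
    """Prepend an intercept column to a covariate vector/matrix."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return np.column_stack([np.ones(len(x)), x])


def _cluster_codes(cluster) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(cluster))
    return codes.astype(np.int64), len(uniques)


def _check_full_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")


def fit_gee_logit(
    y,
    x,
    cluster,
    working_correlation: str = "exchangeable",
    weights=None,
    max_iter: int = 100,
    tol: float = 1e-8,
    param_names: list[str] | None = None,
) -> GEEFit:
    """Fit a logit-link GEE of a binary (or binomial-proportion) outcome.

    Parameters
    ----------
    y : array
        Binary outcomes in {0,1}, or proportions in [0,1] when ``weights``
        carries the binomial denominators.
    x : array
        Covariate vector (one column) or matrix; an intercept is prepended.
    cluster : array
        Cluster (biological replicate) label per observation.
    working_correlation : {"independence", "exchangeable"}
        Within-cluster working structure.  Exchangeable estimates a single
        intra-cluster correlation ``alpha`` by the usual moment estimator.
    weights : array, optional
        Binomial denominators for grouped data (default all 1).

    Notes
    -----
    Solves ``sum_i D_i' V_i^-1 (y_i - mu_i) = 0`` by Fisher scoring with
    ``V_i = phi A_i^1/2 R(alpha) A_i^1/2``.  The exchangeable ``R^-1`` is
    applied in closed form (Sherman–Morrison), so each iteration is O(N p).
    The reported covariance is the cluster-robust sandwich
    ``B^-1 M B^-1``; with one cluster it degrades to the model-based
    ``phi B^-1`` with a warning.
    """
    if working_correlation not in WORKING_CORRELATIONS:
        raise ValueError(
            f"working_correlation must be one of {WORKING_CORRELATIONS}"
        )
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("outcomes must be 0/1 or proportions in [0, 1]")
    X = _as_design(x)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and x have different lengths")
    _check_full_rank(X)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    codes, n_clusters = _cluster_codes(cluster)
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    counts = np.bincount(codes, minlength=n_clusters).astype(float)

    if param_names is None:
        param_names = ["intercept"] + [f"x{i}" for i in range(1, p)]

    # start from an intercept-only fit of the pooled mean
    ybar = float(np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6))
    beta = np.zeros(p)
    beta[0] = math.log(ybar / (1 - ybar))

    alpha = 0.0
    phi = 1.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        var = mu * (1 - mu) / w  # binomial variance of the proportion
        if np.any(var <= 0) or np.any(~np.isfinite(var)):
            raise CompleteSeparationError(
                "fitted probabilities reached 0/1 exactly: complete separation "
                f"(largest coefficient: {param_names[int(np.argmax(np.abs(beta)))]})"
            )
        resid = (y - mu) / np.sqrt(var)  # Pearson residuals
        phi = float(resid @ resid) / max(n - p, 1)

        if working_correlation == "exchangeable" and np.any(counts > 1):
            sum_r = np.bincount(codes, weights=resid, minlength=n_clusters)
            sum_r2 = np.bincount(codes, weights=resid**2, minlength=n_clusters)
            cross = 0.5 * float(np.sum(sum_r**2 - sum_r2))
            n_pairs = 0.5 * float(np.sum(counts * (counts - 1)))
            denom = phi * max(n_pairs - p, 1.0)
            alpha = float(np.clip(cross / denom, -0.99, 0.99))
        else:
            alpha = 0.0

        # D' V^-1 applied via Xt = sqrt(mu(1-mu) w) * X, yt = (y-mu)/sqrt(var):
        # D'V^-1 z = Xt' R^-1 (z scaled), with exchangeable R^-1 closed form.
        sw = np.sqrt(mu * (1 - mu) * w)
        Xt = X * sw[:, None]
        yt = resid  # already (y - mu)/sqrt(var)
        if alpha != 0.0:
            shrink = alpha / (1.0 - alpha + alpha * counts[codes])
            sum_yt = np.bincount(codes, weights=yt, minlength=n_clusters)
            yt_r = (yt - shrink * sum_yt[codes]) / (1.0 - alpha)
            sum_Xt = np.zeros((n_clusters, p))
            np.add.at(sum_Xt, codes, Xt)
            Xt_r = (Xt - shrink[:, None] * sum_Xt[codes]) / (1.0 - alpha)
        else:
            yt_r = yt
            Xt_r = Xt

        score = Xt.T @ yt_r  # sum_i D' V^-1 (y - mu)
        H = Xt.T @ Xt_r  # sum_i D' V^-1 D
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise CompleteSeparationError(
                "singular GEE information matrix; data may be separated"
            ) from exc
        beta = beta + delta
        if np.max(np.abs(delta)) <= tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break

    if not converged:
        if np.max(np.abs(X @ beta)) > 30:
            j = int(np.argmax(np.abs(beta[1:]) * X[:, 1:].std(axis=0))) + 1 if p > 1 else 0
            raise CompleteSeparationError(
                f"diverging linear predictor: covariate {param_names[j]!r} "
                "appears to separate the outcome completely"
            )
        warnings.warn(
            f"GEE did not converge in {max_iter} iterations", RuntimeWarning, stacklevel=2
        )

    # final quantities at the solution
    eta = X @ beta
    mu = expit(eta)
    var = mu * (1 - mu) / w
    resid = (y - mu) / np.sqrt(var)
    phi = float(resid @ resid) / max(n - p, 1)
    sw = np.sqrt(mu * (1 - mu) * w)
    Xt = X * sw[:, None]
    if alpha != 0.0:
        shrink = alpha / (1.0 - alpha + alpha * counts[codes])
        sum_yt = np.bincount(codes, weights=resid, minlength=n_clusters)
        yt_r = (resid - shrink * sum_yt[codes]) / (1.0 - alpha)
        sum_Xt = np.zeros((n_clusters, p))
        np.add.at(sum_Xt, codes, Xt)
        Xt_r = (Xt - shrink[:, None] * sum_Xt[codes]) / (1.0 - alpha)
    else:
        yt_r = resid
        Xt_r = Xt
    H = Xt.T @ Xt_r
    H = 0.5 * (H + H.T)  # symmetric up to round-off
    H_inv = np.linalg.inv(H)
    model_cov = phi * H_inv
    model_se = np.sqrt(np.maximum(np.diag(model_cov), 0.0))

    se_type = "robust"
    if n_clusters >= 2:
        # per-cluster score contributions g_i = X_i' R^-1 y_i (scaled)
        contrib = Xt * yt_r[:, None]
        G = np.zeros((n_clusters, p))
        np.add.at(G, codes, contrib)
        M = G.T @ G
        robust_cov = H_inv @ M @ H_inv.T
        robust_se = np.sqrt(np.maximum(np.diag(robust_cov), 0.0))
    else:
        warnings.warn(
            "single cluster: cluster-robust standard errors are unavailable; "
            "reporting model-based standard errors",
            RuntimeWarning,
            stacklevel=2,
        )
        robust_se = model_se.copy()
        se_type = "model"

    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / robust_se
    pvals = 2.0 * norm.sf(np.abs(z))
    return GEEFit(
        beta=beta,
        robust_se=robust_se,
        model_se=model_se,
        wald_z=z,
        p_values=pvals,
        alpha=alpha,
        scale=phi,
        n_clusters=n_clusters,
        n_obs=n,
        converged=converged,
        working_correlation=working_correlation,
        n_iter=n_iter,
        param_names=param_names,
        se_type=se_type,
    )


def fit_from_aggregates(table: pd.DataFrame) -> GEEFit:
    """Binomial-logit fit on grouped counts ``(x, n_total, n_depolarized)``.

    Point estimates equal a GEE fit under the independence working
    correlation on the corresponding expanded 0/1 rows — exactly — which is
    what makes published per-condition percentages and sample sizes
    sufficient to re-derive a dose–response coefficient.  An optional
    ``cluster`` column groups rows; otherwise each row is its own cluster.
    """
    required = {"x", "n_total", "n_depolarized"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"aggregate table missing columns: {sorted(missing)}")
    if len(table) < 2:
        raise ValueError("need at least two aggregate rows to fit a slope")
    n_total = table["n_total"].to_numpy(float)
    n_dep = table["n_depolarized"].to_numpy(float)
    if np.any(n_dep < 0) or np.any(n_dep > n_total):
        raise ValueError("need 0 <= n_depolarized <= n_total")
    cluster = (
        table["cluster"].to_numpy()
        if "cluster" in table.columns
        else np.arange(len(table))
    )
    return fit_gee_logit(
        y=n_dep / n_total,
        x=table["x"].to_numpy(float),
        cluster=cluster,
        working_correlation="independence",
        weights=n_total,
        param_names=["intercept", "x"],
    )


def reconstruct_counts(
    percentages, totals, x=None
) -> pd.DataFrame:
    """Recover integer depolarized counts from printed percentages.

    ``n_depolarized = round(percentage/100 * total)`` with half-up rounding
    (0.5 always rounds away from zero, the convention of printed tables).
    Returns an aggregate table ready for :func:`fit_from_aggregates`; pass
    ``x`` (e.g. added KCl in mM) to include the covariate column.
    """
    percentages = list(percentages)
    totals = list(totals)
    if len(percentages) != len(totals):
        raise ValueError("percentages and totals must have equal length")
    if x is not None and len(list(x)) != len(totals):
        raise ValueError("x must match the number of conditions")
    counts = []
    for pct, n in zip(percentages, totals):
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"percentage {pct} outside [0, 100]")
        if n < 0:
            raise ValueError("totals must be non-negative")
        counts.append(int(math.floor(pct / 100.0 * n + 0.5)))
    out = {"n_total": [int(n) for n in totals], "n_depolarized": counts}
    if x is not None:
        out = {"x": [float(v) for v in x], **out}
    return pd.DataFrame(out)


def _as_probability(obj) -> float:
    """Accept a float probability, a ConditionSummary, or a percent."""
    if hasattr(obj, "mean_fraction"):
        return float(obj.mean_fraction)
    p = float(obj)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return p


def relative_risk(
    summary_a,
    summary_b,
    label_a: str = "reference",
    label_b: str = "comparison",
    p_value: float | None = None,
) -> ComparisonResult:
    """Relative risk RR = P(depolarized | b) / P(depolarized | a).

    The reference group comes first.  Inputs may be probabilities in (0, 1]
    or condition summaries (whose mean percentage is used).
    """
    p_a = _as_probability(summary_a)
    p_b = _as_probability(summary_b)
    if p_a <= 0:
        raise ValueError("reference probability must be positive")
    label_a = getattr(summary_a, "condition", label_a)
    label_b = getattr(summary_b, "condition", label_b)
    return ComparisonResult(
        group_a=str(label_a),
        group_b=str(label_b),
        rr=p_b / p_a,
        p_value=p_value,
        method="ratio of probabilities",
    )


def cells_to_gee_data(
    table: pd.DataFrame, threshold_value: float
) -> pd.DataFrame:
    """Binary depolarization outcomes from a cell table at a threshold.

    Returns columns ``y`` (1 if strictly above threshold), ``condition`` and
    ``cluster`` (condition x replicate, so replicates of different
    conditions are distinct panels).
    """
    out = pd.DataFrame(
        {
            "y": (table["mean_intensity"] > threshold_value).astype(int),
            "condition": table["condition"].astype(str),
            "cluster": table["condition"].astype(str)
            + "/"
            + table["replicate"].astype(str),
        }
    )
    return out


def pairwise_comparisons(
    data: pd.DataFrame,
    group_col: str = "condition",
    y_col: str = "y",
    cluster_col: str = "cluster",
    working_correlation: str = "exchangeable",
    bonferroni: bool = False,
) -> list[ComparisonResult]:
    """All-pairs GEE contrasts between categorical groups.

    For each pair a single-indicator GEE is fitted; the relative risk is the
    ratio of the marginal fitted probabilities and the p-value is the Wald
    test of the indicator coefficient.  P-values are unadjusted unless
    ``bonferroni`` is set.
    """
    groups = sorted(map(str, pd.unique(data[group_col].astype(str))))
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    n_tests = len(groups) * (len(groups) - 1) // 2
    results = []
    for g_a, g_b in combinations(groups, 2):
        sub = data[data[group_col].astype(str).isin([g_a, g_b])]
        indicator = (sub[group_col].astype(str) == g_b).to_numpy(float)
        fit = fit_gee_logit(
            sub[y_col].to_numpy(float),
            indicator,
            sub[cluster_col].to_numpy(),
            working_correlation=working_correlation,
            param_names=["intercept", f"{g_b} vs {g_a}"],
        )
        p_a = fit.fitted_probability([1.0, 0.0])
        p_b = fit.fitted_probability([1.0, 1.0])
        p = float(fit.p_values[1])
        if bonferroni:
            p = min(1.0, p * n_tests)
        results.append(
            ComparisonResult(
                group_a=g_a,
                group_b=g_b,
                rr=p_b / p_a,
                p_value=p,
                method="GEE marginal probabilities"
                + (" (Bonferroni)" if bonferroni else ""),
            )
        )
    return results
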