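"""Unanchored matching-adjusted indirect comparison (MAIC).

Reweights individual patient data (IPD) from one trial so that the weighted
means/proportions of the matching covariates equal the aggregate baseline of
a comparator trial.  Weights take the log-linear form

    w_i = exp(alpha . x_ci),

where ``x_ci`` are the covariates centred on the target values.  The moment
conditions ``sum_i w_i x_ci = 0`` are the stationarity conditions of the
convex objective ``Q(alpha) = sum_i exp(alpha . x_ci)``, which is minimized
by quasi-Newton iteration (damped Newton fallback).  The weighted day-90
outcome distribution and the effective sample size ESS = (sum w)^2 / sum w^2
are the quantities carried downstream into the cost-effectiveness model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .params import HealthState, StateDistribution
from .synthetic import AggregateBaseline, IPDTable

__all__ = [
    "WeightSet",
    "MAICError",
    "fit_maic_weights",
    "effective_sample_size",
    "weighted_outcome_distribution",
    "balance_table",
]


class MAICError(RuntimeError):
    """Raised when the moment conditions cannot be satisfied."""


@dataclass
class WeightSet:
    """Fitted MAIC weights with diagnostics.

    ``weights`` are normalized to sum to the effective sample size (all
    downstream estimators are invariant to this rescaling); ``alpha`` is on
    the raw covariate scale; ``residuals`` are absolute weighted-mean minus
    target gaps per variable.
    """

    weights: np.ndarray
    alpha: dict[str, float]
    converged: bool
    residuals: dict[str, float]
    ess: float
    variables: tuple[str, ...] = ()

    def validate(self) -> None:
        if len(self.weights) == 0:
            raise ValueError("empty weight vector")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(self.weights > 0):
            raise ValueError("at least one weight must be positive")


def _as_frame(ipd) -> pd.DataFrame:
    if isinstance(ipd, IPDTable):
        return ipd.df
    return ipd


def effective_sample_size(w) -> float:
    """ESS = (sum w)^2 / sum w^2; equals n for uniform weights."""
    arr = np.asarray(w.weights if isinstance(w, WeightSet) else w, dtype=float)
    if arr.size == 0 or not np.any(arr > 0):
        raise ValueError("ESS undefined for an all-zero weight vector")
    if np.any(arr < 0):
        raise ValueError("weights must be non-negative")
    s = arr.sum()
    return float(s * s / np.square(arr).sum())


def fit_maic_weights(
    ipd,
    target: AggregateBaseline,
    variables: Sequence[str],
    tolerance: float = 1e-8,
) -> WeightSet:
    """Solve for weights that match the IPD moments to the target baseline.

    ``tolerance`` bounds the absolute moment gap on the standardized
    (unit-IPD-sd) covariate scale.  Raises :class:`MAICError` when a target
    lies outside the convex hull (range) of the IPD values, when a matching
    covariate is constant, or when the optimizer fails to reach tolerance.
    """
    df = _as_frame(ipd)
    if df.empty:
        raise MAICError("IPD table is empty")
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise MAICError(f"variables missing from IPD: {missing}")
    missing_t = [v for v in variables if v not in target.values]
    if missing_t:
        raise MAICError(f"variables missing from target baseline: {missing_t}")

    X = df.loc[:, list(variables)].to_numpy(dtype=float)
    t = np.array([target.values[v] for v in variables], dtype=float)

    for j, v in enumerate(variables):
        col = X[:, j]
        if col.max() == col.min():
            raise MAICError(f"matching covariate '{v}' is constant in the IPD")
        if not (col.min() <= t[j] <= col.max()):
            raise MAICError(
                f"target for '{v}' ({t[j]}) lies outside the IPD range "
                f"[{col.min()}, {col.max()}]; moments cannot be matched"
            )

    # standardize the centred covariates for optimizer conditioning
    scale = X.std(axis=0, ddof=0)
    Z = (X - t) / scale

    def objective(a):
        e = np.exp(Z @ a)
        return e.sum()

    def grad(a):
        e = np.exp(Z @ a)
        return Z.T @ e

    def hess(a):
        e = np.exp(Z @ a)
        return (Z * e[:, None]).T @ Z

    a0 = np.zeros(len(variables))
    res = optimize.minimize(objective, a0, jac=grad, method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    a = res.x
    if np.max(np.abs(grad(a))) / max(objective(a), 1.0) > tolerance:
        # damped Newton fallback
        a = a0.copy()
        for _ in range(200):
            g = grad(a)
            if np.max(np.abs(g)) / max(objective(a), 1.0) <= tolerance * 1e-2:
                break
            step = np.linalg.solve(hess(a) + 1e-12 * np.eye(len(a)), g)
            lam, f0 = 1.0, objective(a)
            while lam > 1e-12 and objective(a - lam * step) >= f0:
                lam *= 0.5
            a = a - lam * step

    w = np.exp(Z @ a)
    wmean = (w[:, None] * X).sum(axis=0) / w.sum()
    resid_std = np.abs(wmean - t) / scale
    residuals = {v: float(abs(wmean[j] - t[j])) for j, v in enumerate(variables)}
    converged = bool(np.all(resid_std <= tolerance))
    if not converged:
        worst = variables[int(np.argmax(resid_std))]
        raise MAICError(
            f"moment matching did not converge (worst variable '{worst}', "
            f"standardized gap {resid_std.max():.3g} > {tolerance:g})"
        )

    ess = effective_sample_size(w)
    w_report = w * (ess / w.sum())
    alpha = {v: float(a[j] / scale[j]) for j, v in enumerate(variables)}
    return WeightSet(
        weights=w_report,
        alpha=alpha,
        converged=converged,
        residuals=residuals,
        ess=ess,
        variables=tuple(variables),
    )


def weighted_outcome_distribution(ipd, w: WeightSet) -> StateDistribution:
    """Weighted day-90 mRS distribution: sum_i w_i 1[state_i = s] / sum w."""
    df = _as_frame(ipd)
    w.validate()
    if len(df) != len(w.weights):
        raise ValueError(
            f"weights ({len(w.weights)}) do not align with IPD rows ({len(df)})"
        )
    total = w.weights.sum()
    probs = {}
    states = df["day90_state"].to_numpy()
    for s in HealthState:
        probs[s] = float(w.weights[states == s.value].sum() / total)
    return StateDistribution(
        probs[HealthState.MRS01], probs[HealthState.MRS25], probs[HealthState.DEAD]
    )


def balance_table(ipd, target: AggregateBaseline, w: WeightSet) -> pd.DataFrame:
    """Per-variable unweighted mean, weighted mean, target and absolute gap."""
    df = _as_frame(ipd)
    w.validate()
    if len(df) != len(w.weights):
        raise ValueError("weights do not align with IPD rows")
    rows = []
    total = w.weights.sum()
    for v in w.variables:
        col = df[v].to_numpy(dtype=float)
        unw = float(col.mean())
        wm = float((w.weights * col).sum() / total)
        tv = float(target.values[v])
        rows.append(
            {
                "variable": v,
                "unweighted_mean": unw,
                "weighted_mean": wm,
                "target": tv,
                "abs_gap": abs(wm - tv),
            }
        )
    return pd.DataFrame(rows)
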