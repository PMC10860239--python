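"""Deterministic (tornado) and probabilistic sensitivity analyses.

One-way analysis re-runs both arms with each parameter at the low and high
end of its plausible range, all else at base, and ranks parameters by the
swing of the chosen outcome (raw ICER by default).  The probabilistic
analysis samples beta (utilities), gamma (costs) and lognormal (hazard
ratios) distributions fitted to the base value and range — the range is read
as a central 95% interval with mean equal to the base value (method of
moments); lognormal ranges are read as a 95% CI on the ratio scale with
median at base.  Parameters whose range column is empty in the input table
(prices, recurrence rates, mortality, discount rate) are held fixed in the
probabilistic analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cea import incremental_analysis, net_monetary_benefit
from .cohort import run_arm
from .params import HealthState, ModelParameters, SensitivitySpec

__all__ = [
    "TornadoEntry",
    "PSAResults",
    "CEACCurve",
    "get_parameter",
    "set_parameter",
    "fit_psa_distribution",
    "one_way_sensitivity",
    "sample_psa_parameters",
    "run_psa",
    "ceac",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile
_ALIASES = {"by_state": "utilities"}


def _segments(path: str) -> list[str]:
    segs = path.split(".")
    if segs and segs[0] == "model":
        segs = segs[1:]
    return [_ALIASES.get(s, s) for s in segs]


def _dict_key(d: dict, seg: str):
    if seg in d:
        return seg
    try:
        key = HealthState[seg]
    except KeyError:
        raise KeyError(f"key '{seg}' not found")
    if key in d:
        return key
    raise KeyError(f"key '{seg}' not found")


def get_parameter(p: ModelParameters, path: str):
    """Read a value addressed by a config-style dotted path."""
    obj = p
    for seg in _segments(path):
        try:
            if isinstance(obj, dict):
                obj = obj[_dict_key(obj, seg)]
            else:
                obj = getattr(obj, seg)
        except (KeyError, AttributeError) as exc:
            raise KeyError(f"parameter path '{path}' not found at '{seg}'") from exc
    return obj


def set_parameter(p: ModelParameters, path: str, value) -> ModelParameters:
    """Return a copy of the parameters with one path replaced."""

    def rec(obj, segs):
        if not segs:
            return value
        seg, rest = segs[0], segs[1:]
        try:
            if isinstance(obj, dict):
                key = _dict_key(obj, seg)
                new = dict(obj)
                new[key] = rec(obj[key], rest)
                return new
            current = getattr(obj, seg)
        except (KeyError, AttributeError) as exc:
            raise KeyError(f"parameter path '{path}' not found at '{seg}'") from exc
        return dataclasses.replace(obj, **{seg: rec(current, rest)})

    return rec(p, _segments(path))


@dataclass(frozen=True)
class TornadoEntry:
    """Outcome at the low and high end of one parameter's range."""

    path: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _outcome_value(p: ModelParameters, outcome: str, wtp: float | None) -> float:
    res = incremental_analysis(
        run_arm("intervention", p), run_arm("comparator", p)
    )
    if outcome == "icer":
        return res.icer
    if outcome == "nmb":
        lam = wtp if wtp is not None else p.wtp_gdp_per_capita
        return net_monetary_benefit(res.delta_cost, res.delta_qaly, lam)
    raise ValueError(f"unknown outcome '{outcome}' (use 'icer' or 'nmb')")


def one_way_sensitivity(
    p: ModelParameters,
    specs: Sequence[SensitivitySpec] | None = None,
    outcome: str = "icer",
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: entries sorted by descending outcome swing."""
    if specs is None:
        specs = p.sensitivity
    entries = []
    for s in specs:
        out_low = _outcome_value(set_parameter(p, s.path, s.low), outcome, wtp)
        out_high = _outcome_value(set_parameter(p, s.path, s.high), outcome, wtp)
        entries.append(
            TornadoEntry(path=s.path, low=s.low, high=s.high,
                         outcome_low=out_low, outcome_high=out_high)
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_frame(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.path,
                "low": e.low,
                "high": e.high,
                "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high,
                "swing": e.swing,
            }
            for e in entries
        ]
    )


def fit_psa_distribution(base: float, low: float, high: float, family: str,
                         path: str = "?"):
    """Frozen scipy distribution for one parameter, or None when fixed.

    beta/gamma: mean = base, sd = (high - low) / (2 * 1.96) (range read as a
    central 95% interval).  lognormal: median = base,
    sigma = (ln high - ln low) / (2 * 1.96).
    """
    if family == "fixed":
        return None
    if low > high:
        raise ValueError(f"{path}: low > high")
    sd = (high - low) / (2.0 * _Z95)
    if family == "beta":
        if not (0.0 < base < 1.0):
            raise ValueError(f"{path}: beta requires base in (0, 1), got {base}")
        var = sd * sd
        if var <= 0 or var >= base * (1.0 - base):
            raise ValueError(
                f"{path}: infeasible beta moments (mean {base}, sd {sd})"
            )
        k = base * (1.0 - base) / var - 1.0
        return stats.beta(base * k, (1.0 - base) * k)
    if family == "gamma":
        if base <= 0 or sd <= 0:
            raise ValueError(f"{path}: gamma requires positive mean and sd")
        shape = (base / sd) ** 2
        return stats.gamma(shape, scale=sd * sd / base)
    if family == "lognormal":
        if base <= 0 or low <= 0 or high <= 0:
            raise ValueError(f"{path}: lognormal requires positive base and range")
        sigma = (np.log(high) - np.log(low)) / (2.0 * _Z95)
        if sigma <= 0:
            raise ValueError(f"{path}: degenerate lognormal range")
        return stats.lognorm(s=sigma, scale=base)
    raise ValueError(f"{path}: unknown distribution family '{family}'")


def sample_psa_parameters(
    p: ModelParameters,
    specs: Sequence[SensitivitySpec] | None = None,
    rng: np.random.Generator | int = 0,
) -> tuple[ModelParameters, dict[str, float]]:
    """Draw one probabilistic parameter set; fixed-family specs never vary.

    Returns the sampled parameters and the sampled values by path (fixed
    parameters appear at their base value).
    """
    if specs is None:
        specs = p.sensitivity
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sampled: dict[str, float] = {}
    out = p
    for s in specs:
        base = float(get_parameter(p, s.path))
        dist = fit_psa_distribution(base, s.low, s.high, s.family, s.path)
        if dist is None:
            sampled[s.path] = base
            continue
        value = float(dist.rvs(random_state=rng))
        sampled[s.path] = value
        out = set_parameter(out, s.path, value)
    return out, sampled


@dataclass
class PSAResults:
    """Per-draw sampled parameters and two-arm (cost, QALY) outcomes."""

    draws: pd.DataFrame
    n_iter: int
    seed: int

    @property
    def delta_cost(self) -> np.ndarray:
        return (self.draws["cost_intervention"]
                - self.draws["cost_comparator"]).to_numpy()

    @property
    def delta_qaly(self) -> np.ndarray:
        return (self.draws["qaly_intervention"]
                - self.draws["qaly_comparator"]).to_numpy()

    def prob_cost_effective(self, wtp: float) -> float:
        nmb = wtp * self.delta_qaly - self.delta_cost
        return float(np.mean(nmb > 0))


def run_psa(
    p: ModelParameters,
    specs: Sequence[SensitivitySpec] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> PSAResults:
    """Monte-Carlo PSA: sample parameters, run both arms per draw."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if specs is None:
        specs = p.sensitivity
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_iter):
        try:
            pi, sampled = sample_psa_parameters(p, specs, rng)
            a = run_arm("intervention", pi)
            b = run_arm("comparator", pi)
        except Exception as exc:
            raise RuntimeError(f"PSA draw {i} failed: {exc}") from exc
        row = {"draw": i, **sampled,
               "cost_intervention": a.total_cost,
               "qaly_intervention": a.total_qaly,
               "cost_comparator": b.total_cost,
               "qaly_comparator": b.total_qaly}
        rows.append(row)
    return PSAResults(draws=pd.DataFrame(rows), n_iter=n_iter, seed=seed)


@dataclass(frozen=True)
class CEACCurve:
    """Probability the intervention is cost-effective across WTP values."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(results: PSAResults, wtp_grid: Sequence[float]) -> CEACCurve:
    """Fraction of PSA draws with positive NMB at each threshold."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    dq, dc = results.delta_qaly, results.delta_cost
    prob = np.array([np.mean(lam * dq - dc > 0) for lam in grid])
    return CEACCurve(wtp=grid, probability=prob)
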