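"""End-to-end orchestration: inputs -> (MAIC) -> two-arm model -> CEA ->
sensitivity analyses -> machine-readable report.

Two entry modes exist because the published analysis flows from the
already-adjusted day-90 distributions, while the MAIC stage needs patient-
level data that cannot be shipped:

* ``table2-direct`` — day-90 distributions come straight from the config;
* ``maic-from-ipd`` — the intervention arm's distribution is re-derived by
  weighting user-supplied IPD to a target aggregate baseline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cea import CEAResult, incremental_analysis
from .cohort import ArmResult, run_arm
from .maic import balance_table, fit_maic_weights, weighted_outcome_distribution
from .params import (
    ModelParameters,
    StateDistribution,
    load_model_config,
    validate_parameters,
)
from .sensitivity import ceac, one_way_sensitivity, run_psa, tornado_frame
from .synthetic import MATCHING_VARIABLES, AggregateBaseline, IPDTable

__all__ = ["ReportBundle", "run_pipeline", "write_report"]


@dataclass
class ReportBundle:
    """Everything the pipeline produced, re-derivable from config + seeds."""

    base_case: pd.DataFrame
    cea_lifetime: CEAResult
    arm_results: dict[str, ArmResult]
    provenance: dict
    balance: pd.DataFrame | None = None
    ess: float | None = None
    tornado: pd.DataFrame | None = None
    psa_draws: pd.DataFrame | None = None
    psa_summary: dict | None = None
    ceac_curve: pd.DataFrame | None = None


def _base_case_table(
    results: dict[str, ArmResult], p: ModelParameters
) -> pd.DataFrame:
    """Cost/QALY/verdict rows at 90 days, 5 years and the full horizon."""
    horizons = [("day_90", None), ("5_years", 5),
                (f"lifetime_{p.horizon_years}_years", p.horizon_years)]
    rows = []
    for label, years in horizons:
        vals = {}
        for role, res in results.items():
            if years is None:
                c, q = res.tree.cost, res.tree.qaly
            else:
                c, q = res.cumulative(years)
            vals[role] = (c, q)
        dc = vals["intervention"][0] - vals["comparator"][0]
        dq = vals["intervention"][1] - vals["comparator"][1]
        if dc < 0 and dq > 0:
            verdict = "dominant"
        elif dc > 0 and dq < 0:
            verdict = "dominated"
        else:
            verdict = f"ICER={dc / dq:.2f}" if dq != 0 else "undefined"
        rows.append(
            {
                "horizon": label,
                "cost_intervention": vals["intervention"][0],
                "cost_comparator": vals["comparator"][0],
                "incremental_cost": dc,
                "qaly_intervention": vals["intervention"][1],
                "qaly_comparator": vals["comparator"][1],
                "incremental_qaly": dq,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)


def _load_target(path: Path) -> AggregateBaseline:
    if path.suffix.lower() == ".json":
        return AggregateBaseline.from_json(path.read_text())
    df = pd.read_csv(path)
    n = int(df.loc[df["statistic"] == "n", "value"].iloc[0])
    means = df[df["statistic"] == "mean"]
    sds = df[df["statistic"] == "sd"]
    return AggregateBaseline(
        n=n,
        values=dict(zip(means["variable"], means["value"].astype(float))),
        sds=dict(zip(sds["variable"], sds["value"].astype(float))),
    )


def run_pipeline(
    config_path: str | Path | None = None,
    mode: str = "table2-direct",
    ipd_path: str | Path | None = None,
    target_path: str | Path | None = None,
    psa_iters: int = 1000,
    seed: int = 12345,
    with_sensitivity: bool = True,
) -> ReportBundle:
    """Run the full analysis and return a :class:`ReportBundle`.

    Raises ``ValueError`` carrying the validation report when the config is
    invalid.
    """
    if mode not in ("table2-direct", "maic-from-ipd"):
        raise ValueError(f"unknown mode '{mode}'")
    p = load_model_config(config_path)
    report = validate_parameters(p)
    if not report.ok():
        raise ValueError(f"invalid model parameters:\n{report.to_json()}")

    provenance: dict = {"mode": mode, "seed": seed, "psa_iters": psa_iters}
    from . import __version__

    provenance["package_version"] = __version__
    if config_path is not None:
        provenance["config_sha256"] = hashlib.sha256(
            Path(config_path).read_bytes()
        ).hexdigest()
    else:
        provenance["config"] = "packaged default"

    balance = None
    ess = None
    day90_override: StateDistribution | None = None
    if mode == "maic-from-ipd":
        if ipd_path is None or target_path is None:
            raise ValueError("maic-from-ipd mode needs ipd_path and target_path")
        ipd = IPDTable.from_csv(ipd_path)
        target = _load_target(Path(target_path))
        variables = [v for v in MATCHING_VARIABLES if v in target.values]
        weights = fit_maic_weights(ipd, target, variables)
        balance = balance_table(ipd, target, weights)
        ess = weights.ess
        day90_override = weighted_outcome_distribution(ipd, weights)
        provenance["maic"] = {
            "n_ipd": len(ipd),
            "ess": ess,
            "alpha": weights.alpha,
            "weighted_day90": {
                "MRS01": day90_override.mrs01,
                "MRS25": day90_override.mrs25,
                "DEAD": day90_override.dead,
            },
        }

    results = {
        "intervention": run_arm("intervention", p, day90=day90_override),
        "comparator": run_arm("comparator", p),
    }
    base_case = _base_case_table(results, p)
    cea_res = incremental_analysis(
        results["intervention"], results["comparator"], p.wtp_thresholds
    )

    tornado = None
    psa_draws = None
    psa_summary = None
    ceac_df = None
    if with_sensitivity:
        tornado = tornado_frame(one_way_sensitivity(p))
        if psa_iters > 0:
            psa = run_psa(p, n_iter=psa_iters, seed=seed)
            psa_draws = psa.draws
            grid = [0.0] + [0.25 * k * p.wtp_gdp_per_capita for k in range(1, 13)]
            ceac_df = ceac(psa, grid).to_frame()
            psa_summary = {
                "n_iter": psa_iters,
                "seed": seed,
                "mean_incremental_cost": float(psa.delta_cost.mean()),
                "mean_incremental_qaly": float(psa.delta_qaly.mean()),
                "prob_cost_effective": {
                    str(w): psa.prob_cost_effective(w) for w in p.wtp_thresholds
                },
            }

    return ReportBundle(
        base_case=base_case,
        cea_lifetime=cea_res,
        arm_results=results,
        provenance=provenance,
        balance=balance,
        ess=ess,
        tornado=tornado,
        psa_draws=psa_draws,
        psa_summary=psa_summary,
        ceac_curve=ceac_df,
    )


def write_report(bundle: ReportBundle, out_dir: str | Path) -> list[dict]:
    """Write CSV/JSON artifacts; returns a manifest with SHA-256 checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def emit(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        manifest.append(
            {"file": name,
             "sha256": hashlib.sha256(text.encode()).hexdigest()}
        )

    emit("base_case.csv", bundle.base_case.to_csv(index=False))
    summary = {
        "incremental_cost": bundle.cea_lifetime.delta_cost,
        "incremental_qaly": bundle.cea_lifetime.delta_qaly,
        "verdict": bundle.cea_lifetime.label,
        "icer": None
        if not bundle.cea_lifetime.icer_defined
        else bundle.cea_lifetime.icer,
        "nmb": {str(k): v for k, v in bundle.cea_lifetime.nmb.items()},
        "ess": bundle.ess,
        "provenance": bundle.provenance,
    }
    emit("summary.json", json.dumps(summary, indent=2))
    if bundle.balance is not None:
        emit("balance.csv", bundle.balance.to_csv(index=False))
    if bundle.tornado is not None:
        emit("tornado.csv", bundle.tornado.to_csv(index=False))
    if bundle.psa_draws is not None:
        emit("psa_draws.csv", bundle.psa_draws.to_csv(index=False))
        emit("ceac.csv", bundle.ceac_curve.to_csv(index=False))
        emit("psa_summary.json", json.dumps(bundle.psa_summary, indent=2))
    else:
        manifest.append({"file": None, "note": "PSA not run; PSA files omitted"})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
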