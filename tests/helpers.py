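"""Shared test utilities: random parameter sets and a patient-level
microsimulation oracle for the cohort model."""

from __future__ import annotations

import numpy as np

from stroke_cea.params import (
    ALIVE_STATES,
    STATE_ORDER,
    HealthState,
    ModelParameters,
    StateDistribution,
    load_model_config,
)
from stroke_cea.sensitivity import set_parameter


def random_valid_params(
    rng: np.random.Generator, base: ModelParameters | None = None
) -> ModelParameters:
    """Perturb the default parameter set into a random but valid one."""
    p = base if base is not None else load_model_config()
    u25 = rng.uniform(0.1, 0.7)
    u01 = rng.uniform(u25, 1.0)
    p = set_parameter(p, "utilities.by_state.MRS01", u01)
    p = set_parameter(p, "utilities.by_state.MRS25", u25)
    p = set_parameter(p, "utilities.recurrence_disutility",
                      rng.uniform(0.0, min(u01, u25)))
    p = set_parameter(p, "model.discount_rate", rng.uniform(0.0, 0.08))
    p = set_parameter(p, "transitions.death_hazard_ratio.MRS01",
                      rng.uniform(0.5, 2.0))
    p = set_parameter(p, "transitions.death_hazard_ratio.MRS25",
                      rng.uniform(1.0, 4.0))
    rates = tuple(rng.uniform(0.0, 0.15, size=9))
    p = set_parameter(p, "recurrence.annual_rates", rates)
    p = set_parameter(p, "recurrence.terminal_rate", rng.uniform(0.0, 0.05))
    # random post-recurrence destination distributions
    fatal = rng.uniform(0.05, 0.5)
    stay = rng.uniform(0.0, 1.0 - fatal)
    p = set_parameter(p, "transitions.post_recurrence.MRS01",
                      {HealthState.MRS01: stay,
                       HealthState.MRS25: 1.0 - fatal - stay,
                       HealthState.DEAD: fatal})
    fatal2 = rng.uniform(0.05, 0.5)
    p = set_parameter(p, "transitions.post_recurrence.MRS25",
                      {HealthState.MRS25: 1.0 - fatal2,
                       HealthState.DEAD: fatal2})
    return p


def random_distribution(rng: np.random.Generator) -> StateDistribution:
    x = rng.dirichlet(np.ones(3))
    return StateDistribution(float(x[0]), float(x[1]), float(x[2]))


def microsimulate(
    initial: StateDistribution,
    p: ModelParameters,
    n_patients: int,
    seed: int,
) -> dict[str, float]:
    """Patient-level Monte-Carlo twin of ``run_markov`` (undiscounted).

    Applies the same event ordering per cycle — recurrence with
    year-specific probability, destination from the post-recurrence
    distribution, then background mortality with the hazard ratio of the
    post-recurrence state — and the same accrual conventions (half-cycle
    corrected utilities, recurrence disutility, destination hospitalization
    per event, terminal admission per background death).  Returns mean
    per-patient undiscounted QALYs and costs with standard errors.
    """
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(STATE_ORDER)}
    DEAD = idx[HealthState.DEAD]
    u = np.array([p.utilities.of(s) for s in STATE_ORDER])
    hosp = np.array([p.costs.hospitalization[s] for s in STATE_ORDER])
    rehab = np.zeros(3)
    if p.markov_state_costs in ("on", "mrs25_only"):
        targets = ALIVE_STATES if p.markov_state_costs == "on" else (
            HealthState.MRS25,)
        for s in targets:
            rehab[idx[s]] = p.costs.rehab(s)
    terminal = hosp[DEAD] if p.markov_death_costs else 0.0

    state = rng.choice(3, size=n_patients, p=initial.as_array())
    qaly = np.zeros(n_patients)
    cost = np.zeros(n_patients)
    fill = (365.0 - p.short_term_days) / 365.0
    if p.cycle0_fill == "accrue":
        qaly += u[state] * fill
        cost += rehab[state] * fill

    for t in range(1, p.horizon_years):
        m = p.mortality.rate_at(p.start_age + t)
        r = p.recurrence.rate_for_cycle(t)
        start = state.copy()
        alive = start != DEAD
        recur = alive & (rng.random(n_patients) < r)
        after = start.copy()
        for s in ALIVE_STATES:
            sel = recur & (start == idx[s])
            if not sel.any():
                continue
            post = p.transitions.post_recurrence[s]
            dests = np.array([idx[d] for d in post])
            probs = np.array(list(post.values()))
            after[sel] = rng.choice(dests, size=int(sel.sum()), p=probs)
            if p.recurrence_event_costs:
                cost[sel] += hosp[after[sel]]
        # background mortality on post-recurrence survivors
        hr = np.zeros(3)
        for s in ALIVE_STATES:
            hr[idx[s]] = p.transitions.death_hazard_ratio[s]
        alive_after = after != DEAD
        pdie = np.minimum(m * hr[after], 1.0)
        die = alive_after & (rng.random(n_patients) < pdie)
        end = after.copy()
        end[die] = DEAD
        cost[die] += terminal
        qaly += 0.5 * (u[start] + u[end])
        qaly[recur] -= p.utilities.recurrence_disutility
        cost += 0.5 * (rehab[start] + rehab[end])
        state = end

    return {
        "qaly_mean": float(qaly.mean()),
        "qaly_se": float(qaly.std(ddof=1) / np.sqrt(n_patients)),
        "cost_mean": float(cost.mean()),
        "cost_se": float(cost.std(ddof=1) / np.sqrt(n_patients)),
    }
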