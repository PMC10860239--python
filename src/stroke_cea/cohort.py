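"""Two-stage outcome engine: 90-day decision tree + lifetime Markov model.

Stage 1 (decision tree) covers randomization to day 90: patients receive a
14-day drug course, one hospitalization episode, and rehabilitation /
secondary-prevention care from discharge to day 90; on day 90 they are
distributed over the mRS health states.

Stage 2 (Markov) runs annual cycles to the 40-year horizon.  The day-90
distribution seeds the chain; cycle 0 holds the cohort at that distribution
for the remaining 275/365 of year 1.  Under the default ``calendar-only``
policy this cycle only aligns the calendar (the decision tree already
carries year 1's accruals); the ``accrue`` policy instead credits prorated
utilities and continuing-care costs during the fill.  From cycle 1 onwards,
each alive state may suffer a recurrent stroke (moving to a state of equal
or greater disability, or dying from the event's acute case fatality), and
survivors face the age-specific background mortality scaled by the state's
death hazard ratio.  Costs and QALYs of cycles >= 1 are half-cycle corrected
and discounted at the annual rate.

Markov-cycle costs are policy-driven: recurrence events incur the
hospitalization episode of the destination state (fatal recurrences the
mRS-6 admission), background deaths a terminal mRS-6 admission, and
continuing annual rehabilitation/secondary-prevention costs are off by
default (they cover days 15-90 inside the tree) but can be switched on for
alive states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    ALIVE_STATES,
    STATE_ORDER,
    CostInputs,
    DrugRegimen,
    HealthState,
    ModelParameters,
    StateDistribution,
    UtilityInputs,
)

__all__ = [
    "PeriodResult",
    "TransitionMatrix",
    "MarkovTrace",
    "ArmResult",
    "drug_course_cost",
    "run_decision_tree",
    "build_transition_matrix",
    "run_markov",
    "accumulate_outcomes",
    "run_arm",
]

_IDX = {s: i for i, s in enumerate(STATE_ORDER)}
_DAYS_PER_YEAR = 365.0


def drug_course_cost(regimen: DrugRegimen) -> float:
    """Cost of the full treatment course: daily cost x duration (14 days)."""
    return regimen.course_cost()


@dataclass(frozen=True)
class PeriodResult:
    """Expected cost and QALYs of one arm over a fixed period, with the cost
    split into drug, hospitalization, rehabilitation/secondary-prevention and
    recurrence-event components."""

    label: str
    cost: float
    qaly: float
    cost_drug: float
    cost_hospitalization: float
    cost_rehab: float
    cost_recurrence: float = 0.0


def run_decision_tree(
    arm_label: str,
    dist: StateDistribution,
    regimen: DrugRegimen,
    costs: CostInputs,
    utilities: UtilityInputs,
    short_term_days: int = 90,
) -> PeriodResult:
    """Expected 90-day cost and QALYs given the day-90 mRS distribution.

    Cost = drug course + expected hospitalization episode + annual
    rehabilitation/secondary-prevention cost prorated over the period after
    discharge, ``(short_term_days - mean length of stay) / 365``.  QALYs use
    the day-90 state utilities over ``short_term_days / 365`` of a year.
    Nothing inside the 90-day period is discounted.
    """
    problems = dist.problems()
    if problems:
        raise ValueError(f"invalid day-90 distribution: {'; '.join(problems)}")

    c_drug = drug_course_cost(regimen)
    c_hosp = sum(dist.of(s) * costs.hospitalization[s] for s in STATE_ORDER)
    rehab_frac = (short_term_days - costs.mean_length_of_stay_days) / _DAYS_PER_YEAR
    c_rehab = sum(dist.of(s) * costs.rehab(s) for s in ALIVE_STATES) * rehab_frac
    qaly = (
        sum(dist.of(s) * utilities.of(s) for s in ALIVE_STATES)
        * short_term_days
        / _DAYS_PER_YEAR
    )
    return PeriodResult(
        label=arm_label,
        cost=c_drug + c_hosp + c_rehab,
        qaly=qaly,
        cost_drug=c_drug,
        cost_hospitalization=c_hosp,
        cost_rehab=c_rehab,
    )


@dataclass(frozen=True)
class TransitionMatrix:
    """One-cycle transition probabilities plus the per-origin recurrence
    probability used for disutility and event-cost attribution."""

    matrix: np.ndarray  # 3x3, rows indexed by STATE_ORDER
    recurrence: np.ndarray  # per-origin recurrence probability (0 for DEAD)

    def row(self, state: HealthState) -> np.ndarray:
        return self.matrix[_IDX[state]]


def build_transition_matrix(
    age: float, cycle_index: int, p: ModelParameters
) -> TransitionMatrix:
    """Compose recurrence and background mortality into a one-cycle matrix.

    Event order within a cycle: a recurrent stroke happens first (probability
    from the year-specific schedule; destination from the post-recurrence
    distribution, which carries the acute case fatality); survivors then face
    the age-band death probability multiplied by the hazard ratio of the
    state they occupy after the recurrence step, capped at 1.
    """
    if cycle_index < 1:
        raise ValueError("transition matrices apply to Markov cycles >= 1")
    m = p.mortality.rate_at(age)  # raises if age is uncovered
    r = p.recurrence.rate_for_cycle(cycle_index)

    death_prob = {
        s: min(m * p.transitions.death_hazard_ratio[s], 1.0) for s in ALIVE_STATES
    }

    mat = np.zeros((3, 3))
    rec = np.zeros(3)
    mat[_IDX[HealthState.DEAD], _IDX[HealthState.DEAD]] = 1.0

    for origin in ALIVE_STATES:
        post = p.transitions.post_recurrence[origin]
        # state distribution after the recurrence step
        interim = {s: r * post.get(s, 0.0) for s in STATE_ORDER}
        interim[origin] += 1.0 - r
        row = np.zeros(3)
        row[_IDX[HealthState.DEAD]] = interim[HealthState.DEAD]
        for s in ALIVE_STATES:
            stay = interim[s] * (1.0 - death_prob[s])
            row[_IDX[s]] = stay
            row[_IDX[HealthState.DEAD]] += interim[s] * death_prob[s]
        if np.any(row < -1e-12) or np.any(row > 1.0 + 1e-12):
            raise ValueError(
                f"composed transition probabilities outside [0, 1] for {origin}"
            )
        mat[_IDX[origin]] = row
        rec[_IDX[origin]] = r

    row_sums = mat.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-9):
        raise ValueError(f"transition rows do not sum to 1: {row_sums}")
    return TransitionMatrix(matrix=mat, recurrence=rec)


@dataclass
class MarkovTrace:
    """Per-cycle record of the cohort simulation.

    Index ``t`` runs 0..horizon-1; cycle 0 is the 275/365-year fill of the
    first model year (no transition), cycles >= 1 are full years.  Discounted
    accruals equal the undiscounted ones times ``(1 + r)^-t``.
    """

    occupancy_start: np.ndarray  # (T, 3)
    occupancy_end: np.ndarray  # (T, 3)
    recurrence_events: np.ndarray  # (T, 3) expected events by origin state
    cost_undiscounted: np.ndarray  # (T,)
    cost_discounted: np.ndarray
    qaly_undiscounted: np.ndarray
    qaly_discounted: np.ndarray
    cost_recurrence_undiscounted: np.ndarray
    cost_state_undiscounted: np.ndarray
    cost_death_undiscounted: np.ndarray
    label: str | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.cost_undiscounted)

    def to_frame(self):
        """Tidy per-cycle, per-state export of the trace."""
        import pandas as pd

        rows = []
        for t in range(self.n_cycles):
            for i, s in enumerate(STATE_ORDER):
                rows.append(
                    {
                        "cycle": t,
                        "state": s.value,
                        "occupancy_start": self.occupancy_start[t, i],
                        "occupancy_end": self.occupancy_end[t, i],
                        "recurrence_events": self.recurrence_events[t, i],
                        "cycle_cost_undiscounted": self.cost_undiscounted[t],
                        "cycle_cost_discounted": self.cost_discounted[t],
                        "cycle_qaly_undiscounted": self.qaly_undiscounted[t],
                        "cycle_qaly_discounted": self.qaly_discounted[t],
                    }
                )
        return pd.DataFrame(rows)


def _state_cost_weights(p: ModelParameters) -> np.ndarray:
    """Annual continuing-care cost per state under the configured policy."""
    w = np.zeros(3)
    mode = p.markov_state_costs
    if mode not in ("on", "off", "mrs25_only"):
        raise ValueError(f"unknown markov_state_costs mode '{mode}'")
    if mode == "off":
        return w
    states = ALIVE_STATES if mode == "on" else (HealthState.MRS25,)
    for s in states:
        w[_IDX[s]] = p.costs.rehab(s)
    return w


def run_markov(
    initial: StateDistribution, p: ModelParameters, label: str | None = None
) -> MarkovTrace:
    """Run the annual-cycle cohort simulation from the day-90 distribution.

    Cycle 0 holds the cohort at ``initial`` for the remaining
    ``(365 - short_term_days)/365`` of the first year, with no recurrence,
    no half-cycle correction and no discounting; under ``cycle0_fill:
    accrue`` it credits prorated utilities and continuing-care costs, under
    the default ``calendar-only`` it accrues nothing.  Cycles 1..horizon-1
    transition the cohort and accrue, discounted at
    ``(1 + discount_rate)^-t``: half-cycle-corrected utilities minus the
    recurrence disutility; continuing-care costs on the half-cycle-corrected
    alive occupancy (when enabled); recurrence-event hospitalizations of the
    destination state; and a terminal mRS-6 admission per background death.
    """
    problems = initial.problems()
    if problems:
        raise ValueError(f"invalid initial distribution: {'; '.join(problems)}")
    last_age = p.start_age + p.horizon_years - 1
    if not p.mortality.covers(last_age):
        raise ValueError(
            f"horizon reaches age {last_age}, beyond the mortality table"
        )

    T = p.horizon_years
    occ_start = np.zeros((T, 3))
    occ_end = np.zeros((T, 3))
    rec_events = np.zeros((T, 3))
    cost_u = np.zeros(T)
    qaly_u = np.zeros(T)
    cost_rec_u = np.zeros(T)
    cost_state_u = np.zeros(T)
    cost_death_u = np.zeros(T)

    u = np.array([p.utilities.of(s) for s in STATE_ORDER])
    state_cost = _state_cost_weights(p)
    hosp = np.array([p.costs.hospitalization[s] for s in STATE_ORDER])
    terminal_cost = hosp[_IDX[HealthState.DEAD]] if p.markov_death_costs else 0.0
    # expected hospitalization cost of one recurrence, by origin state, and
    # the event's acute case fatality (to keep fatal recurrences out of the
    # background-death cost stream)
    event_cost = np.zeros(3)
    event_fatality = np.zeros(3)
    for s in ALIVE_STATES:
        post = p.transitions.post_recurrence[s]
        event_fatality[_IDX[s]] = post.get(HealthState.DEAD, 0.0)
        if p.recurrence_event_costs:
            event_cost[_IDX[s]] = sum(q * hosp[_IDX[d]] for d, q in post.items())

    occ = initial.as_array()
    fill = (365.0 - p.short_term_days) / 365.0
    occ_start[0] = occ
    occ_end[0] = occ
    if p.cycle0_fill == "accrue":
        qaly_u[0] = float(occ @ u) * fill
        cost_state_u[0] = float(occ @ state_cost) * fill
        cost_u[0] = cost_state_u[0]
    elif p.cycle0_fill != "calendar-only":
        raise ValueError(f"unknown cycle0_fill mode '{p.cycle0_fill}'")

    dead = _IDX[HealthState.DEAD]
    for t in range(1, T):
        age = p.start_age + t
        tm = build_transition_matrix(age, t, p)
        occ_start[t] = occ
        events = occ * tm.recurrence
        rec_events[t] = events
        occ = occ @ tm.matrix
        occ_end[t] = occ
        hcc = 0.5 * (occ_start[t] + occ_end[t])
        qaly_u[t] = float(hcc @ u) - events.sum() * p.utilities.recurrence_disutility
        cost_state_u[t] = float(hcc @ state_cost)
        cost_rec_u[t] = float(events @ event_cost)
        background_deaths = (
            occ_end[t, dead] - occ_start[t, dead] - float(events @ event_fatality)
        )
        cost_death_u[t] = background_deaths * terminal_cost
        cost_u[t] = cost_state_u[t] + cost_rec_u[t] + cost_death_u[t]

    disc = np.ones(T)
    if p.discount_rate != 0.0:
        disc[1:] = (1.0 + p.discount_rate) ** (-np.arange(1, T))

    return MarkovTrace(
        occupancy_start=occ_start,
        occupancy_end=occ_end,
        recurrence_events=rec_events,
        cost_undiscounted=cost_u,
        cost_discounted=cost_u * disc,
        qaly_undiscounted=qaly_u,
        qaly_discounted=qaly_u * disc,
        cost_recurrence_undiscounted=cost_rec_u,
        cost_state_undiscounted=cost_state_u,
        cost_death_undiscounted=cost_death_u,
        label=label,
    )


@dataclass(frozen=True)
class ArmResult:
    """Lifetime discounted totals of one arm plus the underlying pieces."""

    label: str
    total_cost: float
    total_qaly: float
    tree: PeriodResult
    trace: MarkovTrace

    def cumulative(self, years: int) -> tuple[float, float]:
        """Discounted (cost, QALY) accumulated through ``years`` model years.

        Year 1 comprises the decision tree plus the cycle-0 fill; each later
        year is one Markov cycle.
        """
        if years < 1:
            raise ValueError("years must be >= 1")
        k = min(years, self.trace.n_cycles)
        cost = self.tree.cost + float(self.trace.cost_discounted[:k].sum())
        qaly = self.tree.qaly + float(self.trace.qaly_discounted[:k].sum())
        return cost, qaly


def accumulate_outcomes(
    tree: PeriodResult, trace: MarkovTrace, p: ModelParameters
) -> ArmResult:
    """Combine the 90-day tree with the discounted Markov accruals."""
    if trace.label is not None and trace.label != tree.label:
        raise ValueError(
            f"arm mismatch: tree is '{tree.label}', trace is '{trace.label}'"
        )
    total_cost = tree.cost + float(trace.cost_discounted.sum())
    total_qaly = tree.qaly + float(trace.qaly_discounted.sum())
    return ArmResult(
        label=tree.label,
        total_cost=total_cost,
        total_qaly=total_qaly,
        tree=tree,
        trace=trace,
    )


def run_arm(
    role: str,
    p: ModelParameters,
    day90: StateDistribution | None = None,
) -> ArmResult:
    """Run the full two-stage model for one configured arm.

    ``day90`` overrides the configured day-90 distribution (e.g. with a
    MAIC-weighted one).
    """
    arm = p.arms[role]
    dist = day90 if day90 is not None else arm.day90_distribution
    tree = run_decision_tree(
        arm.name, dist, arm.regimen, p.costs, p.utilities, p.short_term_days
    )
    trace = run_markov(dist, p, label=arm.name)
    return accumulate_outcomes(tree, trace, p)
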