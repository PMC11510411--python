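"""Clone-based regimen simulation, probability of target attainment and dose selection.

The decision workflow mirrors routine precision-dosing practice for
ustekinumab maintenance therapy: each patient's clones (draws from the
individual conditional distribution) are simulated deterministically through
5 cycles of the current regimen followed by 5 cycles of a candidate regimen
from the 45/90 mg x q8/12/16/20w grid.  The probability of achieving the
clinical target (absolute PASI <= 1) is the exact fraction of clones at or
below the target at the trough of the evaluation cycle, expressed in percent:

    probability = n_PASI / T_PASI * 100 .

A candidate qualifies when its probability reaches the threshold (90% by
default); among qualifying regimens the least dose-intensive one (mg/week,
ties toward the longer interval) is selected.  Patients with no qualifying
candidate are classified as treatment failures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import pkpd
from .conditional import CloneSet
from .pkpd import DAYS_PER_WEEK, DoseEvent, Regimen

#: per-dose price of a 45 or 90 mg pre-filled syringe (EUR)
DEFAULT_UNIT_PRICE_EUR = 2915.4


@dataclass(frozen=True)
class RegimenGrid:
    """Candidate regimens: the dose-level x interval cross product."""

    dose_levels: tuple = (45.0, 90.0)
    intervals_weeks: tuple = (8.0, 12.0, 16.0, 20.0)

    def regimens(self, n_cycles: int = 5) -> list[Regimen]:
        return [
            Regimen(d, w, n_cycles=n_cycles)
            for d in self.dose_levels for w in self.intervals_weeks
        ]

    def __len__(self) -> int:
        return len(self.dose_levels) * len(self.intervals_weeks)


@dataclass(frozen=True)
class ProbabilityResult:
    """Exact counting probability (percent) of clones at or below the PASI target."""

    patient_id: str
    regimen: Regimen
    cycle: int
    n_target: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_target <= self.n_total):
            raise ValueError("target count outside [0, total]")

    @property
    def probability(self) -> float:
        return 100.0 * self.n_target / self.n_total


@dataclass
class Decision:
    """Final per-patient regimen decision."""

    patient_id: str
    current: Regimen
    selected: Regimen | None
    classification: str                  # maintain / optimize / intensify / failure
    probabilities: dict                  # regimen label -> ProbabilityResult (cycle 10)
    probability_current_c5: float        # current regimen, cycle-5 probability
    trough_ss: float | None              # mg/L at cycle-10 trough under the selection
    median_pasi_c10: float | None


@dataclass
class CycleOutcome:
    """Per-clone outcomes of one current->candidate simulation."""

    patient_id: str
    candidate: Regimen
    pasi_c5: np.ndarray
    trough_c5: np.ndarray
    pasi_c10: np.ndarray
    trough_c10: np.ndarray


def simulate_cycles(
    clones: CloneSet,
    current: Regimen,
    candidate: Regimen,
    n_current_cycles: int = 5,
    n_candidate_cycles: int = 5,
    dt: float = 0.25,
) -> CycleOutcome:
    """Simulate every clone through current-regimen cycles then candidate cycles.

    The latent PASI starts at each clone's baseline (untreated turnover steady
    state), runs without residual noise, and is continuous across the regimen
    switch.  Evaluations are at the troughs: the instant the 5th cycle of the
    current regimen ends (just before the first candidate dose) and the
    instant the 10th cycle ends.
    """
    if len(clones) == 0:
        raise ValueError("empty clone set")
    t_switch = n_current_cycles * current.interval_days
    t_end = t_switch + n_candidate_cycles * candidate.interval_days
    doses = [DoseEvent(k * current.interval_days, current.dose_mg)
             for k in range(n_current_cycles) if current.dose_mg > 0]
    doses += [DoseEvent(t_switch + k * candidate.interval_days, candidate.dose_mg)
              for k in range(n_candidate_cycles) if candidate.dose_mg > 0]
    n_steps = int(round(t_end / dt))
    grid = np.linspace(0.0, t_end, n_steps + 1)
    i_switch = int(round(t_switch / dt))

    pd_list = clones.pd_params()
    kout = np.array([p.kout for p in pd_list])
    pasi0 = np.array([p.pasi0 for p in pd_list])
    imax = np.array([p.imax for p in pd_list])
    ic50 = np.array([p.ic50 for p in pd_list])

    if clones.shared_pk:
        ind = clones.pk_individuals()[0]
        conc = pkpd.pk_concentration(ind, doses, grid)[None, :]
    else:
        conc = np.stack([
            pkpd.pk_concentration(ind, doses, grid) for ind in clones.pk_individuals()
        ])
    inh = imax[:, None] * conc / (ic50[:, None] + conc)
    try:
        pasi = pkpd.pd_trajectory_grid(kout, pasi0, inh, dt)
    except FloatingPointError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"turnover integration failed for clone set "
                           f"{clones.patient_id}: {exc}") from exc

    trough = conc if conc.shape[0] > 1 else np.broadcast_to(conc, pasi.shape)
    return CycleOutcome(
        patient_id=clones.patient_id,
        candidate=candidate,
        pasi_c5=pasi[:, i_switch].copy(),
        trough_c5=trough[:, i_switch].copy(),
        pasi_c10=pasi[:, -1].copy(),
        trough_c10=trough[:, -1].copy(),
    )


def probability_target(
    pasi_values: np.ndarray,
    patient_id: str = "",
    regimen: Regimen | None = None,
    cycle: int = 10,
    target: float = 1.0,
) -> ProbabilityResult:
    """Exact counting probability of PASI at or below the target (inclusive)."""
    vals = np.asarray(pasi_values, dtype=float)
    if vals.size == 0:
        raise ValueError("no PASI values supplied")
    n_hit = int(np.sum(vals <= target))
    return ProbabilityResult(patient_id, regimen, cycle, n_hit, int(vals.size))


def select_regimen(
    probabilities: Sequence[ProbabilityResult],
    current: Regimen,
    threshold: float = 90.0,
    probability_current_c5: float = float("nan"),
    troughs: dict | None = None,
    median_pasi: dict | None = None,
) -> Decision:
    """Apply the >=threshold rule with optimize-preferred tie-breaking.

    Among qualifying candidates the minimal dose intensity (mg/week) wins;
    exact intensity ties go to the longer interval (fewer injections).  The
    classification compares the selection against the current regimen's dose
    intensity: lower = optimize, higher = intensify, same regimen = maintain;
    an equal-intensity different regimen counts as optimize when its dose is
    lower, otherwise intensify.
    """
    pid = probabilities[0].patient_id if probabilities else ""
    qualifying = [p for p in probabilities if p.probability >= threshold]
    prob_map = {p.regimen.label: p for p in probabilities}
    troughs = troughs or {}
    median_pasi = median_pasi or {}
    if not qualifying:
        return Decision(pid, current, None, "failure", prob_map,
                        probability_current_c5, None, None)
    best = min(
        qualifying,
        key=lambda p: (p.regimen.dose_intensity, -p.regimen.interval_weeks),
    )
    sel = best.regimen
    if (sel.dose_mg, sel.interval_weeks) == (current.dose_mg, current.interval_weeks):
        cls = "maintain"
    elif sel.dose_intensity < current.dose_intensity:
        cls = "optimize"
    elif sel.dose_intensity > current.dose_intensity:
        cls = "intensify"
    else:
        cls = "optimize" if sel.dose_mg < current.dose_mg else "intensify"
    return Decision(
        pid, current, sel, cls, prob_map, probability_current_c5,
        troughs.get(sel.label), median_pasi.get(sel.label),
    )


def decide_patient(
    clones: CloneSet,
    current: Regimen,
    grid: RegimenGrid | None = None,
    threshold: float = 90.0,
    target: float = 1.0,
    dt: float = 0.25,
) -> tuple[Decision, list[CycleOutcome]]:
    """Full per-patient decision: simulate the grid, compute probabilities, select."""
    grid = grid or RegimenGrid()
    outcomes = []
    probs = []
    troughs = {}
    medians = {}
    prob_c5 = None
    for cand in grid.regimens():
        out = simulate_cycles(clones, current, cand, dt=dt)
        outcomes.append(out)
        pr = probability_target(out.pasi_c10, clones.patient_id, cand, 10, target)
        probs.append(pr)
        troughs[cand.label] = float(np.median(out.trough_c10))
        medians[cand.label] = float(np.median(out.pasi_c10))
        if prob_c5 is None:
            prob_c5 = probability_target(out.pasi_c5, clones.patient_id, current, 5, target)
    decision = select_regimen(probs, current, threshold, prob_c5.probability,
                              troughs, medians)
    return decision, outcomes


# ---------------------------------------------------------------------------
# Cost arithmetic
# ---------------------------------------------------------------------------

def annual_dose_count(regimen: Regimen, year: str = "maintenance") -> int:
    """Number of administrations in a year.

    First year: label-style induction at weeks 0 and 4, then maintenance
    spacing, counting doses in weeks [0, 52).  Maintenance year:
    floor(52 / interval).
    """
    if regimen.interval_weeks <= 0:
        raise ValueError("interval must be positive")
    if year == "maintenance":
        return int(52.0 // regimen.interval_weeks)
    if year != "first":
        raise ValueError("year must be 'first' or 'maintenance'")
    count, week = 2, 4.0  # induction doses at weeks 0 and 4
    week += regimen.interval_weeks
    while week < 52.0:
        count += 1
        week += regimen.interval_weeks
    return count


def annual_cost(
    regimen: Regimen,
    unit_price: float = DEFAULT_UNIT_PRICE_EUR,
    year: str = "first",
) -> tuple[int, float]:
    """Doses per year and their acquisition cost in EUR."""
    if unit_price <= 0:
        raise ValueError("unit price must be positive")
    n = annual_dose_count(regimen, year)
    return n, n * unit_price


def cost_saving(
    from_regimen: Regimen, to_regimen: Regimen, year: str = "maintenance"
) -> float:
    """Fractional saving of a regimen change: 1 - (dose-count ratio).

    Scale-invariant in the unit price; e.g. moving from q12w (4 maintenance
    doses/year) to q16w (3/year) saves 25%.
    """
    n_from = annual_dose_count(from_regimen, year)
    n_to = annual_dose_count(to_regimen, year)
    return 1.0 - n_to / n_from


# ---------------------------------------------------------------------------
# Exposure-response export
# ---------------------------------------------------------------------------

def exposure_response_table(
    outcomes: Sequence[CycleOutcome],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired (C_trough-ss, PASI) records at cycle 10 for every clone and regimen.

    Returns the record-level table and a per-regimen summary (median trough,
    fraction of patients whose median clone PASI is at or below 1).
    """
    rows = []
    for out in outcomes:
        for j in range(out.pasi_c10.size):
            rows.append({
                "patient_id": out.patient_id,
                "regimen": out.candidate.label,
                "dose_intensity": out.candidate.dose_intensity,
                "clone": j,
                "trough_ss": out.trough_c10[j],
                "pasi": out.pasi_c10[j],
            })
    records = pd.DataFrame(rows)
    per_patient = (
        records.groupby(["regimen", "dose_intensity", "patient_id"])
        .agg(median_trough=("trough_ss", "median"), median_pasi=("pasi", "median"))
        .reset_index()
    )
    summary = (
        per_patient.groupby(["regimen", "dose_intensity"])
        .agg(
            median_trough=("median_trough", "median"),
            frac_patients_pasi_le_1=("median_pasi", lambda s: float(np.mean(s <= 1.0))),
        )
        .reset_index()
        .sort_values("dose_intensity", ignore_index=True)
    )
    return records, summary


def flow_table(decisions: Sequence[Decision]) -> pd.DataFrame:
    """Sankey-ready counts of current regimen -> selected regimen transitions."""
    rows = [
        {
            "current": d.current.label,
            "selected": d.selected.label if d.selected else "failure",
            "classification": d.classification,
        }
        for d in decisions
    ]
    return (
        pd.DataFrame(rows)
        .groupby(["current", "selected", "classification"])
        .size()
        .rename("n_patients")
        .reset_index()
    )


def decisions_frame(decisions: Sequence[Decision]) -> pd.DataFrame:
    """One row per patient: candidate probabilities, selection, classification."""
    rows = []
    for d in decisions:
        row = {
            "patient_id": d.patient_id,
            "current_regimen": d.current.label,
            "prob_current_cycle5": d.probability_current_c5,
            "selected_regimen": d.selected.label if d.selected else "",
            "classification": d.classification,
            "trough_ss": d.trough_ss if d.trough_ss is not None else np.nan,
            "median_pasi_c10": d.median_pasi_c10 if d.median_pasi_c10 is not None else np.nan,
        }
        for label, pr in d.probabilities.items():
            row[f"prob[{label}]"] = pr.probability
        rows.append(row)
    return pd.DataFrame(rows)
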