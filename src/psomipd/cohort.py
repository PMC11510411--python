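"""Virtual-cohort generator mirroring the study's data structure.

Emulates a therapeutic-drug-monitoring cohort of adults with moderate-to-severe
plaque psoriasis on maintenance ustekinumab: body weight and observed baseline
PASI from truncated normals matching the published summary statistics
(92 +/- 18.4 kg in [70, 135]; 14.4 +/- 6.23 in [5, 31.9]), current regimens
drawn from the published regimen frequency table, sparse PK sampling
(pre-dose plus a thinned template of 2-18 weeks post-dose), scheduled PASI
visits (every 3 months in year one, every 6 months thereafter), and assay
censoring at the 0.63-20 mg/L quantification range.

Each synthetic patient carries its hidden truths (individual parameters, latent
trajectories, noise seed) so estimation and decision stages can be scored
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import pkpd
from .data import ASSAY_LOQ, ASSAY_ULOQ, CENS_ALQ, CENS_BLQ, CENS_QUANTIFIED, Patient, PopulationModel
from .pkpd import DoseEvent, PK_PARAM_NAMES, Regimen, apply_covariates

#: current-treatment frequency table: (dose mg, interval weeks) -> patient count
REGIMEN_COUNTS: dict[tuple[float, float], int] = {
    (45.0, 12.0): 1,
    (90.0, 12.0): 8,
    (45.0, 14.0): 1,
    (45.0, 16.0): 3,
    (45.0, 18.0): 1,
    (90.0, 14.0): 1,
    (90.0, 15.0): 2,
    (90.0, 16.0): 3,
    (90.0, 10.0): 1,
    (90.0, 8.0): 2,
}

#: scheduled PASI visit days: every 3 months during year one, then every 6 months
PD_VISIT_DAYS = (91.0, 182.0, 273.0, 364.0, 548.0)

#: post-dose PK sampling template (weeks after the anchor administration)
PK_OFFSET_WEEKS = (2.0, 6.0, 10.0, 12.0, 14.0, 16.0, 18.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the virtual cohort."""

    n_patients: int = 23
    weight_mean: float = 92.0
    weight_sd: float = 18.4
    weight_bounds: tuple[float, float] = (70.0, 135.0)
    pasi0_mean: float = 14.4
    pasi0_sd: float = 6.23
    pasi0_bounds: tuple[float, float] = (5.0, 31.9)
    regimen_counts: dict = field(default_factory=lambda: dict(REGIMEN_COUNTS))
    pk_offsets_weeks: tuple = PK_OFFSET_WEEKS
    include_predose_sample: bool = True
    # distribution of the per-patient PK sample count (template thinning)
    pk_count_support: tuple = (2, 3, 4, 5)
    pk_count_probs: tuple = (0.20, 0.35, 0.30, 0.15)
    pd_visit_days: tuple = PD_VISIT_DAYS
    rich_pd_sampling: bool = False      # biweekly PASI over 18 months instead
    assay_range: tuple[float, float] = (ASSAY_LOQ, ASSAY_ULOQ)
    truths: PopulationModel = field(default_factory=PopulationModel)
    noise_scale: float = 1.0            # 0 collapses residual + baseline noise
    induction: bool = True              # label-style loading doses at weeks 0 and 4
    horizon_days: float = 730.0
    grid_dt: float = 0.25

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        for lo, hi in (self.weight_bounds, self.pasi0_bounds, self.assay_range):
            if lo >= hi:
                raise ValueError("bounds must be ordered low < high")
        if abs(sum(self.pk_count_probs) - 1.0) > 1e-9:
            raise ValueError("PK count probabilities must sum to 1")

    def pd_times(self) -> np.ndarray:
        if self.rich_pd_sampling:
            return np.arange(14.0, 18 * 30.4 + 1e-9, 14.0)
        return np.asarray(self.pd_visit_days, dtype=float)


@dataclass
class SyntheticPatient:
    """A Patient record plus the hidden truths it was generated from."""

    patient: Patient
    regimen: Regimen
    pk_eta: dict
    pk_individual: pkpd.PKIndividual
    eta_kout: float
    eta_rv: float
    pd_true: pkpd.PDParams
    latent_pk: np.ndarray     # noise-free concentrations at the PK sample times
    latent_pd: np.ndarray     # noise-free PASI at the PD visit times
    seed: int                 # per-patient noise stream seed


def _truncated_normal(rng, mean, sd, bounds, size=None):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def build_dosing_history(regimen: Regimen, horizon_days: float, induction: bool = True) -> list[DoseEvent]:
    """Label-style history: loading doses at weeks 0 and 4, then maintenance spacing."""
    times = []
    if induction:
        times.extend([0.0, 28.0])
        t = 28.0 + regimen.interval_days
    else:
        t = 0.0
    while t <= horizon_days:
        times.append(t)
        t += regimen.interval_days
    return [DoseEvent(tt, regimen.dose_mg) for tt in times]


def _anchor_dose_time(doses: Sequence[DoseEvent], target_day: float = 300.0) -> float:
    """Maintenance dose nearest the middle of follow-up, used as TDM anchor."""
    maintenance = [d.time for d in doses if d.time > 28.0]
    times = maintenance or [d.time for d in doses]
    return min(times, key=lambda t: abs(t - target_day))


def generate_patient(
    config: CohortConfig, patient_id: str, seed: int
) -> SyntheticPatient:
    """Draw one virtual patient; fully reproducible from (config, seed)."""
    rng = np.random.default_rng(seed)
    pk_pop, pd_pop = config.truths.pk, config.truths.pd

    weight = float(_truncated_normal(rng, config.weight_mean, config.weight_sd, config.weight_bounds))
    baseline_obs = float(
        _truncated_normal(rng, config.pasi0_mean, config.pasi0_sd, config.pasi0_bounds)
    )

    keys = list(config.regimen_counts)
    counts = np.array([config.regimen_counts[k] for k in keys], dtype=float)
    dose_mg, interval_w = keys[rng.choice(len(keys), p=counts / counts.sum())]
    regimen = Regimen(dose_mg, interval_w)

    pk_eta = {
        name: float(rng.normal(0.0, pk_pop.omega.get(name, 0.0)))
        for name in PK_PARAM_NAMES
        if pk_pop.omega.get(name, 0.0) > 0
    }
    ind = apply_covariates(pk_pop, weight, pk_eta)

    eta_kout = float(rng.normal(0.0, pd_pop.omega_kout))
    eta_rv = float(rng.normal(0.0, pd_pop.sigma_pd)) * config.noise_scale
    pasi0_true = baseline_obs * np.exp(eta_rv)
    pd_true = pkpd.PDParams(
        kout=pd_pop.kout * np.exp(eta_kout), imax=pd_pop.imax,
        ic50=pd_pop.ic50, pasi0=pasi0_true,
    )

    doses = build_dosing_history(regimen, config.horizon_days, config.induction)

    # --- PK sampling: pre-dose at the anchor dose + thinned post-dose template
    anchor = _anchor_dose_time(doses)
    slots = []
    if config.include_predose_sample:
        slots.append(anchor)
    slots.extend(anchor + 7.0 * np.asarray(config.pk_offsets_weeks))
    n_pk = int(rng.choice(config.pk_count_support, p=config.pk_count_probs))
    n_pk = min(n_pk, len(slots))
    pk_times = np.sort(rng.choice(slots, size=n_pk, replace=False))

    latent_pk = pkpd.pk_concentration(ind, doses, pk_times)
    pk_noise = rng.normal(0.0, 1.0, size=n_pk)
    pk_obs = latent_pk * (1.0 + config.noise_scale * pk_pop.sigma_prop * pk_noise)
    pk_obs = np.maximum(pk_obs, 1e-3)
    lo, hi = config.assay_range
    pk_cens = np.where(pk_obs < lo, CENS_BLQ, np.where(pk_obs > hi, CENS_ALQ, CENS_QUANTIFIED))

    # --- PD: latent turnover trajectory sampled at the scheduled visits
    pd_times = config.pd_times()
    grid = np.arange(0.0, pd_times[-1] + config.grid_dt, config.grid_dt)
    conc_grid = pkpd.concentration_on_grid(ind, doses, grid)
    inh = pkpd.inhibition(conc_grid, pd_true)
    latent_grid = pkpd.pd_trajectory_grid(pd_true.kout, pd_true.pasi0, inh, config.grid_dt)
    latent_pd = np.interp(pd_times, grid, latent_grid)
    pd_noise = rng.normal(0.0, 1.0, size=pd_times.size)
    pd_obs = latent_pd * np.exp(config.noise_scale * pd_pop.sigma_pd * pd_noise)

    patient = Patient(
        patient_id=patient_id,
        weight_kg=weight,
        baseline_pasi=baseline_obs,
        doses=doses,
        pk_times=pk_times,
        pk_conc=pk_obs,
        pk_cens=pk_cens,
        pd_times=pd_times,
        pd_pasi=pd_obs,
    )
    return SyntheticPatient(
        patient=patient, regimen=regimen, pk_eta=pk_eta, pk_individual=ind,
        eta_kout=eta_kout, eta_rv=eta_rv, pd_true=pd_true,
        latent_pk=latent_pk, latent_pd=latent_pd, seed=seed,
    )


def generate_cohort(config: CohortConfig, seed: int) -> list[SyntheticPatient]:
    """Generate `config.n_patients` virtual patients, reproducibly from `seed`."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(config.n_patients)]
    return [
        generate_patient(config, f"S{i + 1:03d}", child_seeds[i])
        for i in range(config.n_patients)
    ]


def truth_report(cohort: Sequence[SyntheticPatient]) -> pd.DataFrame:
    """Hidden ground truths, one row per patient, for recovery scoring."""
    rows = []
    for sp in cohort:
        row = {
            "patient_id": sp.patient.patient_id,
            "weight_kg": sp.patient.weight_kg,
            "baseline_pasi_obs": sp.patient.baseline_pasi,
            "regimen": sp.regimen.label,
            "eta_kout": sp.eta_kout,
            "eta_rv": sp.eta_rv,
            "kout_true": sp.pd_true.kout,
            "pasi0_true": sp.pd_true.pasi0,
            "seed": sp.seed,
        }
        for name in PK_PARAM_NAMES:
            row[f"pk_{name}"] = getattr(sp.pk_individual, name)
        for name, val in sp.pk_eta.items():
            row[f"eta_{name}"] = val
        if sp.latent_pd.size:
            row["final_latent_pasi"] = sp.latent_pd[-1]
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def observation_counts(cohort: Sequence[SyntheticPatient]) -> dict:
    """Cohort-level PK/PD observation accounting (incl. censoring tallies)."""
    n_pk = sum(sp.patient.pk_times.size for sp in cohort)
    n_pd = sum(sp.patient.pd_times.size for sp in cohort)
    n_blq = sum(int(np.sum(sp.patient.pk_cens == CENS_BLQ)) for sp in cohort)
    n_alq = sum(int(np.sum(sp.patient.pk_cens == CENS_ALQ)) for sp in cohort)
    return {"n_pk": n_pk, "n_pd": n_pd, "n_blq": n_blq, "n_alq": n_alq}
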