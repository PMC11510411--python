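"""User-facing modelling objects: `PopulationPDModel` and `PopulationPDResults`.

The package follows the model/results idiom of the statsmodels family: a model
object is built from data (a cohort of patients plus their fixed individual PK
parameters), `fit()` runs the Laplace marginal-likelihood estimation and
returns a results object carrying estimates, relative standard errors, the
objective value, empirical-Bayes modes and a text `summary()`.  Diagnostics
(prediction-corrected VPC), conditional-distribution sampling and the dosing
decision engine all hang off the results.

Typical use::

    cohort = generate_cohort(CohortConfig(), seed=1)
    patients = [sp.patient for sp in cohort]
    pk = {sp.patient.patient_id: sp.pk_individual for sp in cohort}
    model = PopulationPDModel(patients, pk)
    res = model.fit()
    print(res.summary())
    clones = res.sample_conditionals()
    decisions = res.mipd_decisions(clones, {p.patient_id: p.infer_current_regimen()
                                            for p in patients})
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimation, mipd
from .conditional import CloneSet, ConditionalTarget, SamplerSettings, mh_sample
from .data import PDPopulation, Patient
from .estimation import FitSettings
from .mipd import Decision, RegimenGrid
from .pkpd import PKIndividual, PKPopulation, Regimen


class PopulationPDModel:
    """Population PASI-turnover model for a cohort on maintenance ustekinumab.

    Parameters
    ----------
    cohort :
        Patients with dosing histories, PK/PD observations and baselines.
    pk_individuals :
        Fixed individual PK parameters per patient id (typically the
        empirical-Bayes estimates from :func:`estimation.map_individual_pk`,
        per the sequential PK->PD approach).
    ic50 :
        Fixed half-maximal concentration (mg/L); excluded from estimation.
    settings :
        Numerical settings of the fit.
    """

    param_names = ("kout", "imax", "omega_kout", "sigma_pd")

    def __init__(
        self,
        cohort: Sequence[Patient],
        pk_individuals: dict[str, PKIndividual],
        ic50: float = 0.07,
        settings: FitSettings | None = None,
    ):
        missing = [p.patient_id for p in cohort if p.patient_id not in pk_individuals]
        if missing:
            raise ValueError(f"no PK individual supplied for: {missing}")
        no_pd = [p.patient_id for p in cohort if p.pd_times.size == 0]
        if no_pd:
            raise ValueError(f"patients without post-baseline PASI: {no_pd}")
        self.cohort = list(cohort)
        self.pk_individuals = dict(pk_individuals)
        self.ic50 = float(ic50)
        self.settings = settings or FitSettings()

    @classmethod
    def from_cohort_with_map_pk(
        cls,
        cohort: Sequence[Patient],
        pk_population: PKPopulation,
        ic50: float = 0.07,
        settings: FitSettings | None = None,
    ) -> "PopulationPDModel":
        """Run empirical-Bayes PK estimation first, then build the PD model."""
        estimates = estimation.estimate_pk_individuals(cohort, pk_population, settings)
        pk_inds = {pid: ind for pid, (ind, _) in estimates.items()}
        model = cls(cohort, pk_inds, ic50, settings)
        model.pk_etas = {pid: etas for pid, (_, etas) in estimates.items()}
        model.pk_population = pk_population
        return model

    def objective(self, theta: dict, method: str = "laplace") -> float:
        """-2 log marginal likelihood at the given parameter values."""
        settings = self.settings
        works = [
            estimation.SubjectWork(p, self.pk_individuals[p.patient_id], settings)
            for p in self.cohort
        ]
        return estimation.objective_value(
            works, theta, self.ic50, method, settings.estimate_baseline_eta
        )

    def fit(self, compute_rse: bool = True) -> "PopulationPDResults":
        raw = estimation.fit_population_pd(
            self.cohort, self.pk_individuals, self.ic50, self.settings, compute_rse
        )
        return PopulationPDResults(self, raw)


class PopulationPDResults:
    """Estimates, uncertainties and downstream operations of a fitted model."""

    def __init__(self, model: PopulationPDModel, raw: dict):
        self.model = model
        self._raw = raw
        self.params = pd.Series(
            {n: raw["theta"][n] for n in model.param_names}, name="estimate"
        )
        self.rse = pd.Series(raw["rse"], name="rse_pct")
        self.objective = float(raw["objective"])
        self.ebes = raw["ebes"]
        self.converged = bool(raw["converged"])
        self.n_function_evals = int(raw["n_eval"])

    # -- presentation ------------------------------------------------------

    @property
    def pd_population(self) -> PDPopulation:
        t = self._raw["theta"]
        return PDPopulation(
            kout=t["kout"], imax=t["imax"], ic50=self.model.ic50,
            omega_kout=t["omega_kout"], sigma_pd=t["sigma_pd"],
        )

    def summary(self) -> str:
        t = self._raw["theta"]
        lines = [
            "Population PK/PD fit (PASI turnover, Laplace marginal likelihood)",
            "=" * 66,
            f"Subjects: {len(self.model.cohort):>5d}    "
            f"PD observations: {sum(p.pd_times.size for p in self.model.cohort)}",
            f"-2 log-likelihood: {self.objective:.3f}    converged: {self.converged}",
            "-" * 66,
            f"{'Parameter':<28s}{'Estimate':>12s}{'RSE (%)':>12s}",
            "-" * 66,
            f"{'kout (1/day)':<28s}{t['kout']:>12.4g}{self.rse['kout']:>12.3g}",
            f"{'Imax':<28s}{t['imax']:>12.4g}{self.rse['imax']:>12.3g}",
            f"{'IC50 (mg/L)':<28s}{self.model.ic50:>12.4g}{'fixed':>12s}",
            f"{'IIV kout (%)':<28s}{100 * t['omega_kout']:>12.4g}{self.rse['omega_kout']:>12.3g}",
            f"{'Residual SD (log PASI)':<28s}{t['sigma_pd']:>12.4g}{self.rse['sigma_pd']:>12.3g}",
            "=" * 66,
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "estimates": {k: float(v) for k, v in self.params.items()},
            "ic50_fixed": self.model.ic50,
            "rse_pct": {k: (None if not np.isfinite(v) else float(v))
                        for k, v in self.rse.items()},
            "objective": self.objective,
            "converged": self.converged,
            "settings": asdict(self.model.settings),
        }
        return json.dumps(payload, indent=2)

    # -- diagnostics -------------------------------------------------------

    def pcvpc(self, n_sim: int = 200, n_bins: int = 5, seed: int = 0) -> pd.DataFrame:
        return estimation.pcvpc(
            self.model.cohort, self.model.pk_individuals, self.pd_population,
            n_sim=n_sim, n_bins=n_bins, seed=seed, settings=self.model.settings,
        )

    # -- conditional sampling and dosing decisions ------------------------

    def conditional_target(self, patient: Patient, sample_pk: bool = False,
                           pk_population: PKPopulation | None = None) -> ConditionalTarget:
        return ConditionalTarget(
            patient, self.model.pk_individuals[patient.patient_id],
            self._raw["theta"], self.model.ic50,
            pk_population=pk_population, sample_pk=sample_pk,
            fit_settings=self.model.settings,
        )

    def sample_conditionals(
        self,
        n_clones: int = 100,
        settings: SamplerSettings | None = None,
        sample_pk: bool = False,
        pk_population: PKPopulation | None = None,
    ) -> dict[str, CloneSet]:
        """Metropolis-Hastings clone sets for every patient in the cohort."""
        settings = settings or SamplerSettings(n_draws=n_clones)
        out = {}
        for p in self.model.cohort:
            target = self.conditional_target(p, sample_pk, pk_population)
            out[p.patient_id] = mh_sample(target, n_clones, settings)
        return out

    def mipd_decisions(
        self,
        clone_sets: dict[str, CloneSet],
        current_regimens: dict[str, Regimen],
        grid: RegimenGrid | None = None,
        threshold: float = 90.0,
        target: float = 1.0,
        dt: float = 0.25,
    ) -> tuple[list[Decision], list]:
        """Run the full regimen-selection engine for every patient."""
        decisions, outcomes = [], []
        for pid, clones in clone_sets.items():
            d, outs = mipd.decide_patient(
                clones, current_regimens[pid], grid, threshold, target, dt
            )
            decisions.append(d)
            outcomes.extend(outs)
        return decisions, outcomes
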