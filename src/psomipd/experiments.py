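"""Reference simulation experiments used for validation and reproduction.

The central one is the parameter-recovery experiment: simulate a virtual
cohort from the final-model population values (kout 0.016/day, Imax 0.97,
IC50 0.07 mg/L fixed, IIV SD on log kout 0.5587, residual log-scale SD 0.86)
under rich PASI sampling (biweekly over 18 months) with the individual PK
parameters known, then re-estimate the population PD parameters and compare
with the simulation truths.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, generate_cohort
from .estimation import FitSettings
from .model import PopulationPDModel

#: simulation ground truths of the recovery experiment
RECOVERY_TRUTHS = {"kout": 0.016, "imax": 0.97, "omega_kout": 0.5587, "sigma_pd": 0.86}


def recovery_experiment(
    cohort_seed: int,
    n_patients: int = 100,
    fit_seed: int = 20240101,
    n_starts: int = 5,
    compute_rse: bool = False,
) -> dict:
    """Simulate-and-refit: returns estimates, truths and relative errors."""
    config = CohortConfig(n_patients=n_patients, rich_pd_sampling=True)
    cohort = generate_cohort(config, cohort_seed)
    patients = [sp.patient for sp in cohort]
    pk_individuals = {sp.patient.patient_id: sp.pk_individual for sp in cohort}
    settings = FitSettings(seed=fit_seed, n_starts=n_starts)
    model = PopulationPDModel(patients, pk_individuals, ic50=0.07, settings=settings)
    results = model.fit(compute_rse=compute_rse)
    estimates = {k: float(v) for k, v in results.params.items()}
    rel_err = {
        k: estimates[k] / RECOVERY_TRUTHS[k] - 1.0 for k in RECOVERY_TRUTHS
    }
    empirical = {
        "sd_eta_kout": float(np.std([sp.eta_kout for sp in cohort], ddof=1)),
        "mean_eta_kout": float(np.mean([sp.eta_kout for sp in cohort])),
    }
    return {
        "n_patients": n_patients,
        "estimates": estimates,
        "truths": dict(RECOVERY_TRUTHS),
        "relative_error": rel_err,
        "empirical": empirical,
        "objective": results.objective,
        "results": results,
    }
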