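"""Shared data containers: per-patient records and the population PK/PD model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pkpd import DoseEvent, PKPopulation, Regimen

#: censoring codes on PK observations
CENS_QUANTIFIED = 0
CENS_BLQ = -1      # below the assay lower limit of quantification
CENS_ALQ = 1       # above the assay upper limit

ASSAY_LOQ = 0.63   # mg/L, Promonitor-UTK lower limit
ASSAY_ULOQ = 20.0  # mg/L, upper limit


@dataclass
class Patient:
    """One subject's covariates, dosing history and TDM observations.

    PK observations are serum concentrations (mg/L) with censoring flags;
    PD observations are post-baseline PASI scores.  The observed baseline
    PASI is kept separate because the baseline model treats it as a noisy
    measurement of the true individual baseline.
    """

    patient_id: str
    weight_kg: float
    baseline_pasi: float
    doses: list[DoseEvent] = field(default_factory=list)
    pk_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    pk_conc: np.ndarray = field(default_factory=lambda: np.empty(0))
    pk_cens: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    pd_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    pd_pasi: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError(f"{self.patient_id}: body weight must be positive")
        if self.baseline_pasi <= 0:
            raise ValueError(f"{self.patient_id}: baseline PASI must be positive")
        self.doses = sorted(self.doses, key=lambda d: d.time)
        for name in ("pk_times", "pk_conc", "pd_times", "pd_pasi"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.pk_cens = np.asarray(self.pk_cens, dtype=int)
        if self.pk_cens.size == 0 and self.pk_times.size:
            self.pk_cens = np.zeros(self.pk_times.size, dtype=int)
        order = np.argsort(self.pk_times, kind="stable")
        self.pk_times, self.pk_conc = self.pk_times[order], self.pk_conc[order]
        self.pk_cens = self.pk_cens[order]
        order = np.argsort(self.pd_times, kind="stable")
        self.pd_times, self.pd_pasi = self.pd_times[order], self.pd_pasi[order]

    @property
    def quantified_pk(self) -> np.ndarray:
        """Boolean mask of PK observations inside the assay range."""
        return self.pk_cens == CENS_QUANTIFIED

    def infer_current_regimen(self) -> Regimen:
        """Reconstruct the maintained regimen from the tail of the dosing history.

        The current dose is the amount of the last administration; the current
        interval is the spacing between the last two administrations, in weeks.
        """
        if not self.doses:
            raise ValueError(f"{self.patient_id}: no dosing history")
        last = self.doses[-1]
        if len(self.doses) == 1:
            return Regimen(last.amount, 12.0)  # labeled maintenance spacing
        interval_w = (last.time - self.doses[-2].time) / 7.0
        return Regimen(last.amount, interval_w)


@dataclass(frozen=True)
class PDPopulation:
    """Population PD fixed effects, the single random effect and residual error.

    Defaults are the final-model point estimates: kout 0.016/day, Imax 0.97,
    IC50 fixed at 0.07 mg/L, log-scale IIV SD on kout 0.5587 and log-scale
    multiplicative residual SD 0.86 (shared with the baseline random
    component per the B2 baseline method).
    """

    kout: float = 0.016
    imax: float = 0.97
    ic50: float = 0.07          # fixed constant, never estimated
    omega_kout: float = 0.5587  # SD of log kout
    sigma_pd: float = 0.86      # log-scale residual SD; also baseline eta SD

    def __post_init__(self) -> None:
        if self.kout <= 0 or self.ic50 <= 0:
            raise ValueError("kout and IC50 must be positive")
        if not (0 < self.imax <= 1):
            raise ValueError("Imax must lie in (0, 1]")
        if self.omega_kout < 0:
            raise ValueError("omega_kout must be non-negative")
        if self.sigma_pd <= 0:
            raise ValueError("sigma_pd must be positive")


@dataclass(frozen=True)
class PopulationModel:
    """Complete population PK/PD specification."""

    pk: PKPopulation = field(default_factory=PKPopulation)
    pd: PDPopulation = field(default_factory=PDPopulation)
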