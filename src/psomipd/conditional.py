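"""Metropolis-Hastings sampling of individual conditional parameter distributions.

Dosing decisions should reflect how precisely a patient's parameters are known,
not just their point estimates.  The individual conditional distribution

    p(psi_i | y_i)  proportional to  p(y_i | psi_i) * p(psi_i)

is sampled by a random-walk Metropolis-Hastings chain on the log-scale
deviations (eta).  By default the sampled dimensions are eta_kout (the single
declared PD random effect) and eta_RV (the baseline deviation of the B2
method, which makes the individual baseline itself uncertain); PK individual
parameters stay fixed at their empirical-Bayes values, with an option to add
PK eta dimensions for full joint uncertainty.

Each retained draw ("clone") is a complete individual parameter vector; the
default 100 clones per patient carry parameter uncertainty into the regimen
simulations.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pkpd
from .data import Patient
from .estimation import FitSettings, SubjectWork
from .pkpd import PKIndividual, PKPopulation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerSettings:
    """Random-walk MH tuning: defaults match the package's reference workflow."""

    n_draws: int = 100
    burn_in: int = 500
    thin: int = 10
    target_accept: float = 0.3
    adapt_window: int = 50
    initial_scale_factor: float = 0.5   # proposal SD = factor * prior SD, per dim
    seed: int = 12345                   # base seed; per-patient streams derive from it

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("need at least one draw")
        if self.thin < 1 or self.burn_in < 0:
            raise ValueError("invalid thinning/burn-in")


@dataclass
class CloneSet:
    """Per-patient draws from the conditional distribution plus sampler metadata."""

    patient_id: str
    draws: pd.DataFrame          # one row per clone: kout, imax, ic50, pasi0, ka, cl, q, v2, v3
    etas: pd.DataFrame           # the underlying sampled eta vectors
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.draws) != self.meta.get("n_draws", len(self.draws)):
            raise ValueError("draw count does not match configured n")

    def __len__(self) -> int:
        return len(self.draws)

    def pd_params(self) -> list[pkpd.PDParams]:
        return [
            pkpd.PDParams(kout=r.kout, imax=r.imax, ic50=r.ic50, pasi0=r.pasi0)
            for r in self.draws.itertuples()
        ]

    def pk_individuals(self) -> list[PKIndividual]:
        return [
            PKIndividual(ka=r.ka, cl=r.cl, q=r.q, v2=r.v2, v3=r.v3)
            for r in self.draws.itertuples()
        ]

    @property
    def shared_pk(self) -> bool:
        cols = ["ka", "cl", "q", "v2", "v3"]
        return bool((self.draws[cols].nunique() == 1).all())


def patient_seed(base_seed: int, patient_id: str) -> int:
    """Stable per-patient seed below 2**31, derived from the id string."""
    return int((base_seed + zlib.crc32(patient_id.encode())) % (2**31 - 1))


def adapt_proposal(scale: np.ndarray, accept_rate: float, target: float,
                   initial: np.ndarray) -> np.ndarray:
    """Scale the proposal toward a target acceptance rate (burn-in only).

    Monotone: acceptance above target grows the scale, below shrinks it;
    capped at x10 / /10 of the initial scale so a pathological window cannot
    run away.
    """
    new = scale * np.exp(accept_rate - target)
    return np.clip(new, initial / 10.0, initial * 10.0)


def mh_chain(
    log_density,
    x0: np.ndarray,
    n_draws: int,
    proposal_sd: np.ndarray,
    settings: SamplerSettings,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Generic random-walk Metropolis-Hastings with burn-in adaptation.

    The proposal scale adapts toward the target acceptance rate during burn-in
    only and is frozen afterwards, so the retained (thinned) draws come from a
    fixed, detailed-balance-preserving kernel.  Returns the retained draws and
    tuning metadata.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    lp = log_density(x)
    if not np.isfinite(lp):
        raise ValueError(f"log density not finite at the chain start {x0}")
    scale = proposal_sd.astype(float).copy()
    initial = scale.copy()
    n_iter = settings.burn_in + n_draws * settings.thin
    draws = np.empty((n_draws, x.size))
    accepted_post = 0
    window_accepts = 0
    kept = 0
    post_iters = 0
    for it in range(n_iter):
        prop = x + scale * rng.normal(size=x.size)
        lp_prop = log_density(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            window_accepts += 1
            if it >= settings.burn_in:
                accepted_post += 1
        in_burn = it < settings.burn_in
        if in_burn and (it + 1) % settings.adapt_window == 0:
            rate = window_accepts / settings.adapt_window
            scale = adapt_proposal(scale, rate, settings.target_accept, initial)
            window_accepts = 0
        if not in_burn:
            post_iters += 1
            if post_iters % settings.thin == 0 and kept < n_draws:
                draws[kept] = x
                kept += 1
    accept_rate = accepted_post / max(post_iters, 1)
    if not (0.05 <= accept_rate <= 0.8):
        logger.warning(
            "MH acceptance rate %.3f outside [0.05, 0.80] after adaptation "
            "(scale %s, initial %s)", accept_rate, scale, initial,
        )
    meta = {
        "seed": seed, "acceptance_rate": float(accept_rate),
        "burn_in": settings.burn_in, "thin": settings.thin,
        "proposal_scale": scale.tolist(), "n_draws": n_draws,
    }
    return draws, meta


class ConditionalTarget:
    """Unnormalized log conditional density of one patient's PD (and optionally PK) etas.

    Dimensions: [eta_kout, eta_RV] and, when `sample_pk` is on, the PK etas of
    every parameter with non-zero IIV.  The PK part of the likelihood enters
    only when PK etas are sampled; otherwise PK is fixed and its likelihood is
    an additive constant that cancels in the MH ratio.
    """

    def __init__(
        self,
        patient: Patient,
        pk_individual: PKIndividual,
        theta: dict,
        ic50: float,
        pk_population: PKPopulation | None = None,
        sample_pk: bool = False,
        fit_settings: FitSettings | None = None,
    ):
        self.patient = patient
        self.theta = dict(theta)
        self.ic50 = ic50
        self.sample_pk = sample_pk
        self.pk_population = pk_population
        self.fit_settings = fit_settings or FitSettings()
        self.dims = ["eta_kout", "eta_rv"]
        self.pk_names: list[str] = []
        if sample_pk:
            if pk_population is None:
                raise ValueError("sampling PK etas requires the PK population model")
            self.pk_names = [n for n in pkpd.PK_PARAM_NAMES
                             if pk_population.omega.get(n, 0.0) > 0]
            self.dims += [f"eta_{n}" for n in self.pk_names]
        self._work = SubjectWork(patient, pk_individual, self.fit_settings)
        self._fixed_ind = pk_individual

    @property
    def n_dim(self) -> int:
        return len(self.dims)

    def prior_sd(self) -> np.ndarray:
        sd = [self.theta["omega_kout"], self.theta["sigma_pd"]]
        if self.sample_pk:
            sd += [self.pk_population.omega[n] for n in self.pk_names]
        return np.array(sd)

    def _pk_loglik(self, ind: PKIndividual) -> float:
        p = self.patient
        quant = p.quantified_pk
        if not np.any(quant):
            return 0.0
        pred = np.maximum(pkpd.pk_concentration(ind, p.doses, p.pk_times[quant]), 1e-6)
        sd = self.pk_population.sigma_prop * pred
        resid = p.pk_conc[quant] - pred
        return float(-0.5 * np.sum((resid / sd) ** 2 + np.log(2 * np.pi * sd**2)))

    def log_density(self, x: np.ndarray) -> float:
        eta_pd = np.asarray(x[:2], dtype=float)
        if self.sample_pk:
            eta_pk = dict(zip(self.pk_names, x[2:]))
            try:
                ind = pkpd.apply_covariates(self.pk_population, self.patient.weight_kg, eta_pk)
            except ValueError:
                return -np.inf
            work = SubjectWork(self.patient, ind, self.fit_settings)
            lp = self._pk_loglik(ind)
            lp += sum(
                -0.5 * (e / self.pk_population.omega[n]) ** 2
                for n, e in eta_pk.items()
            )
        else:
            work = self._work
            lp = 0.0
        inh = work.inhibition_grid(self.theta["imax"], self.ic50)
        try:
            lp += work.joint_loglik(eta_pd, self.theta, inh, True)
        except FloatingPointError:
            return -np.inf
        return lp

    def clone_frame(self, eta_draws: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Turn sampled eta vectors into complete individual parameter vectors."""
        etas = pd.DataFrame(eta_draws, columns=self.dims)
        rows = []
        for x in eta_draws:
            if self.sample_pk:
                eta_pk = dict(zip(self.pk_names, x[2:]))
                ind = pkpd.apply_covariates(self.pk_population, self.patient.weight_kg, eta_pk)
            else:
                ind = self._fixed_ind
            rows.append({
                "kout": self.theta["kout"] * np.exp(x[0]),
                "imax": self.theta["imax"],
                "ic50": self.ic50,
                "pasi0": self.patient.baseline_pasi * np.exp(x[1]),
                "ka": ind.ka, "cl": ind.cl, "q": ind.q, "v2": ind.v2, "v3": ind.v3,
            })
        return pd.DataFrame(rows), etas


def mh_sample(
    target: ConditionalTarget,
    n_draws: int = 100,
    settings: SamplerSettings | None = None,
    x0: np.ndarray | None = None,
) -> CloneSet:
    """Sample a CloneSet from one patient's conditional distribution.

    The chain starts at the empirical-Bayes mode (or a supplied point), with
    initial proposal SDs at half the prior SDs per dimension.
    """
    settings = settings or SamplerSettings(n_draws=n_draws)
    if x0 is None:
        from .estimation import _inner_mode
        inh = target._work.inhibition_grid(target.theta["imax"], target.ic50)
        target._work.eta_hat = np.zeros(2)
        eta, _, _ = _inner_mode(target._work, target.theta, inh, True)
        x0 = np.zeros(target.n_dim)
        x0[:2] = eta
    proposal = settings.initial_scale_factor * target.prior_sd()
    seed = patient_seed(settings.seed, target.patient.patient_id)
    draws, meta = mh_chain(target.log_density, x0, n_draws, proposal, settings, seed)
    clone_df, eta_df = target.clone_frame(draws)
    meta["dims"] = target.dims
    return CloneSet(target.patient.patient_id, clone_df, eta_df, meta)
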