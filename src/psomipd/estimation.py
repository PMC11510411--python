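"""Nonlinear mixed-effects machinery for the PASI turnover model.

Estimation is sequential, as is standard for sparse TDM data against a fixed
literature PK model: individual PK parameters are first set to their empirical
Bayes (MAP) values given the population PK prior, then the population PD layer
(kout, Imax, the IIV of kout and the residual SD, with IC50 fixed) is estimated
by maximizing a Laplace approximation to the marginal likelihood.  Two latent
dimensions are integrated per subject: eta_kout (log-normal IIV on kout) and
eta_RV, the baseline random component of the B2 baseline method

    PASI_i = PASI_i,0 * exp(eta_RV),   eta_RV ~ N(0, sigma_PD^2),

whose variance is constrained equal to the residual-error variance.  PD
residuals are log-normal: log y = log PASI_pred + eps, eps ~ N(0, sigma_PD^2).

A Gauss-Hermite quadrature evaluation of the same marginal likelihood is
provided as an independent numerical oracle for small problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import roots_hermite
from scipy.stats import norm

from . import pkpd
from .data import Patient, PDPopulation
from .pkpd import PKIndividual, PKPopulation, apply_covariates

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitSettings:
    """Numerical settings of the population PD fit."""

    grid_dt: float = 0.5            # days; step of the fixed-grid ODE solution
    pasi_floor: float = 0.1         # floor applied to PASI observations of 0 (log-scale error)
    blq_handling: str = "exclude"   # "exclude" or "censored" (PK likelihood)
    estimate_baseline_eta: bool = True
    n_starts: int = 5
    seed: int = 20240101
    maxiter: int = 400
    xatol: float = 1e-3
    fatol: float = 1e-3
    init: dict = field(default_factory=lambda: {
        "kout": 0.02, "imax": 0.90, "omega_kout": 0.3, "sigma_pd": 0.5,
    })


# ---------------------------------------------------------------------------
# Individual PK empirical-Bayes estimation
# ---------------------------------------------------------------------------

def map_individual_pk(
    patient: Patient,
    pop: PKPopulation,
    settings: FitSettings | None = None,
    loq: float = 0.63,
) -> tuple[PKIndividual, dict]:
    """Empirical-Bayes (MAP) individual PK parameters from sparse TDM samples.

    Maximizes log p(y_PK | eta) + log p(eta | omega) over the log-scale
    deviations of the parameters that carry IIV.  With no quantifiable
    observation the covariate-adjusted typical individual (eta = 0) is
    returned.  Residual error is proportional; below-LOQ samples are excluded
    from the likelihood by default or, optionally, enter as left-censored
    normal terms.
    """
    settings = settings or FitSettings()
    names = [n for n in pkpd.PK_PARAM_NAMES if pop.omega.get(n, 0.0) > 0]
    omegas = np.array([pop.omega[n] for n in names])
    quant = patient.quantified_pk
    blq = patient.pk_cens == -1
    y = patient.pk_conc[quant]
    t_obs = patient.pk_times[quant]
    t_blq = patient.pk_times[blq]
    sigma = pop.sigma_prop

    if not names or (y.size == 0 and (settings.blq_handling == "exclude" or t_blq.size == 0)):
        ind = apply_covariates(pop, patient.weight_kg)
        return ind, {n: 0.0 for n in names}

    def neglog(eta_vec: np.ndarray) -> float:
        eta = dict(zip(names, eta_vec))
        ind = apply_covariates(pop, patient.weight_kg, eta)
        nll = 0.5 * np.sum((eta_vec / omegas) ** 2)
        if y.size:
            pred = np.maximum(pkpd.pk_concentration(ind, patient.doses, t_obs), 1e-6)
            # proportional error with the SD anchored at the observation:
            # keeps the MAP mode at eta = 0 when data sit on the typical
            # prediction and avoids the shrink-the-variance degeneracy
            sd = sigma * np.maximum(y, 1e-6)
            nll += 0.5 * np.sum(((y - pred) / sd) ** 2 + np.log(sd**2) + _LOG2PI)
        if settings.blq_handling == "censored" and t_blq.size:
            pred = np.maximum(pkpd.pk_concentration(ind, patient.doses, t_blq), 1e-6)
            nll -= np.sum(norm.logcdf((loq - pred) / (sigma * pred)))
        return float(nll)

    res = optimize.minimize(neglog, np.zeros(len(names)), method="BFGS",
                            options={"maxiter": 200})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(
            f"{patient.patient_id}: PK MAP estimation did not converge "
            f"(last iterate {res.x}, |grad| {np.linalg.norm(res.jac)})"
        )
    eta_hat = dict(zip(names, map(float, res.x)))
    return apply_covariates(pop, patient.weight_kg, eta_hat), eta_hat


def estimate_pk_individuals(
    cohort: Sequence[Patient],
    pop: PKPopulation,
    settings: FitSettings | None = None,
) -> dict[str, tuple[PKIndividual, dict]]:
    """Run MAP PK estimation for every patient; returns id -> (individual, etas)."""
    return {p.patient_id: map_individual_pk(p, pop, settings) for p in cohort}


# ---------------------------------------------------------------------------
# Population PD marginal likelihood (Laplace / quadrature)
# ---------------------------------------------------------------------------

class SubjectWork:
    """Pre-computed per-subject quantities reused across likelihood evaluations.

    The individual concentration profile is fixed (sequential PK->PD), so the
    analytic PK is evaluated once on a uniform grid; only the turnover
    recursion is re-run inside the inner optimizations.
    """

    def __init__(self, patient: Patient, ind: PKIndividual, settings: FitSettings):
        self.patient = patient
        self.ind = ind
        self.dt = settings.grid_dt
        # zero-observation subjects are allowed (their conditional is the
        # prior); the population fit itself rejects them at model build time
        t_end = float(patient.pd_times.max()) if patient.pd_times.size else self.dt
        self.grid = np.arange(0.0, t_end + self.dt + 1e-9, self.dt)
        self.conc = pkpd.pk_concentration(ind, patient.doses, self.grid)
        self.t_obs = patient.pd_times
        obs = np.asarray(patient.pd_pasi, dtype=float)
        # a PASI of exactly 0 has no density under the log-scale error model;
        # such records are raised to a small configurable floor and logged
        n_floored = int(np.sum(obs <= 0.0))
        if n_floored:
            logger.warning(
                "%s: %d PASI observation(s) of 0 raised to the floor %.3g",
                patient.patient_id, n_floored, settings.pasi_floor,
            )
        obs = np.where(obs <= 0.0, settings.pasi_floor, obs)
        self.log_obs = np.log(obs)
        self.baseline = float(patient.baseline_pasi)
        self.eta_hat = np.zeros(2)  # warm start for the inner optimizer
        self._inh_cache: tuple[tuple[float, float], np.ndarray] | None = None

    def inhibition_grid(self, imax: float, ic50: float) -> np.ndarray:
        key = (imax, ic50)
        if self._inh_cache is None or self._inh_cache[0] != key:
            self._inh_cache = (key, imax * self.conc / (ic50 + self.conc))
        return self._inh_cache[1]

    def mean_log_latent(self, eta_kout: float, theta: dict, inh: np.ndarray) -> np.ndarray:
        """log latent PASI at the observation times with pasi0 = observed baseline.

        The turnover solution is exactly proportional to pasi0, so the
        predicted log observation is ``eta_RV + mean_log_latent(eta_kout)`` —
        the baseline random effect enters additively on the log scale.
        """
        kout_i = theta["kout"] * np.exp(eta_kout)
        if kout_i * self.dt > 50.0:
            raise FloatingPointError("kout out of numerical range")
        latent = pkpd.pd_trajectory_grid(kout_i, self.baseline, inh, self.dt)
        return np.log(np.maximum(np.interp(self.t_obs, self.grid, latent), 1e-300))

    def joint_loglik(self, eta: np.ndarray, theta: dict, inh: np.ndarray,
                     estimate_baseline: bool = True) -> float:
        """log p(y_i | eta) + log p(eta) for eta = (eta_kout, eta_RV)."""
        kout_i = theta["kout"] * np.exp(eta[0])
        pasi0_i = self.baseline * np.exp(eta[1])
        if kout_i * self.dt > 50.0:  # keep exp(-kout*dt) well-behaved
            return -1e10
        latent = pkpd.pd_trajectory_grid(kout_i, pasi0_i, inh, self.dt)
        mu = np.log(np.maximum(np.interp(self.t_obs, self.grid, latent), 1e-12))
        sigma = theta["sigma_pd"]
        resid = self.log_obs - mu
        ll = -0.5 * np.sum((resid / sigma) ** 2) \
            - self.log_obs.size * (np.log(sigma) + 0.5 * _LOG2PI) \
            - np.sum(self.log_obs)
        omega = theta["omega_kout"]
        ll += -0.5 * (eta[0] / omega) ** 2 - np.log(omega) - 0.5 * _LOG2PI
        if estimate_baseline:
            ll += -0.5 * (eta[1] / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI
        return float(ll)


def _inner_mode(work: SubjectWork, theta: dict, inh: np.ndarray,
                estimate_baseline: bool) -> tuple[np.ndarray, float, np.ndarray]:
    """Mode of the subject's joint latent density, its log value and curvature.

    Because the latent trajectory is proportional to the baseline, the
    baseline deviation eta_RV maximizes in closed form given eta_kout, so the
    search is one-dimensional (bounded Brent, warm-started).  The negative
    Hessian at the mode is assembled from exact second derivatives in eta_RV
    and finite differences of the log-latent in eta_kout.
    """
    sigma, omega = theta["sigma_pd"], theta["omega_kout"]
    n = work.log_obs.size

    def parts(ek: float):
        m = work.mean_log_latent(ek, theta, inh)
        c = work.log_obs - m
        erv = c.sum() / (n + 1) if estimate_baseline else 0.0
        return m, c - erv, erv

    def neg_profiled(ek: float) -> float:
        try:
            _, r, erv = parts(ek)
        except FloatingPointError:
            return 1e12
        val = 0.5 * np.sum((r / sigma) ** 2) + 0.5 * (ek / omega) ** 2
        if estimate_baseline:
            val += 0.5 * (erv / sigma) ** 2
        return float(val)

    x0 = float(work.eta_hat[0])
    lo = min(x0, 0.0) - 6.0 * omega - 1.0
    hi = max(x0, 0.0) + 6.0 * omega + 1.0
    res = optimize.minimize_scalar(neg_profiled, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    ek = float(res.x)
    m0, r, erv = parts(ek)
    work.eta_hat = np.array([ek, erv])

    ll = (
        -0.5 * np.sum((r / sigma) ** 2)
        - n * (np.log(sigma) + 0.5 * _LOG2PI)
        - np.sum(work.log_obs)
        - 0.5 * (ek / omega) ** 2 - np.log(omega) - 0.5 * _LOG2PI
    )
    if estimate_baseline:
        ll += -0.5 * (erv / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI

    h = 1e-4
    m_p = work.mean_log_latent(ek + h, theta, inh)
    m_m = work.mean_log_latent(ek - h, theta, inh)
    m1 = (m_p - m_m) / (2 * h)
    m2 = (m_p - 2 * m0 + m_m) / h**2
    h_kk = (np.sum(m1**2) - np.sum(r * m2)) / sigma**2 + 1.0 / omega**2
    if estimate_baseline:
        h_rr = (n + 1.0) / sigma**2
        h_kr = np.sum(m1) / sigma**2
        hess = np.array([[h_kk, h_kr], [h_kr, h_rr]])
        eta = np.array([ek, erv])
    else:
        hess = np.array([[h_kk]])
        eta = np.array([ek])
    return eta, float(ll), hess


def _fd_hessian(fun, x: np.ndarray, step: float = 1e-3) -> np.ndarray:
    n = x.size
    h = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = step
        fpp = fun(x + ei); fmm = fun(x - ei)
        h[i, i] = (fpp - 2 * f0 + fmm) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = step
            fpq = fun(x + ei + ej); fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej); fmn = fun(x - ei - ej)
            h[i, j] = h[j, i] = (fpq - fpm - fmp + fmn) / (4 * step**2)
    return h


def marginal_loglik(
    work: SubjectWork,
    theta: dict,
    ic50: float,
    method: str = "laplace",
    estimate_baseline: bool = True,
    gh_nodes: int = 40,
) -> float:
    """log integral of p(y_i | eta) p(eta) d eta for one subject.

    method="laplace": second-order expansion around the joint mode (the
    production path).  method="gh": adaptive Gauss-Hermite quadrature centered
    and scaled at the Laplace mode — the independent numerical oracle.
    """
    inh = work.inhibition_grid(theta["imax"], ic50)
    eta_hat, l_max, hess = _inner_mode(work, theta, inh, estimate_baseline)
    dim = eta_hat.size

    if estimate_baseline:
        negl = lambda e: -work.joint_loglik(e, theta, inh, True)
    else:
        negl = lambda e: -work.joint_loglik(np.array([e[0], 0.0]), theta, inh, False)
    # guard: fall back to the prior curvature if the curvature is not SPD
    try:
        chol = np.linalg.cholesky(hess)
    except np.linalg.LinAlgError:
        prior_var = [theta["omega_kout"] ** 2, theta["sigma_pd"] ** 2][:dim]
        hess = np.diag(1.0 / np.asarray(prior_var))
        chol = np.linalg.cholesky(hess)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))

    if method == "laplace":
        return float(l_max + 0.5 * dim * _LOG2PI - 0.5 * logdet)

    if method != "gh":
        raise ValueError(f"unknown marginalization method {method!r}")
    nodes, weights = roots_hermite(gh_nodes)
    cov_chol = np.linalg.inv(chol).T  # hess^{-1} = cov_chol @ cov_chol.T
    if dim == 1:
        pts = eta_hat[0] + np.sqrt(2.0) * cov_chol[0, 0] * nodes
        logf = np.array([-negl(np.array([p])) for p in pts])
        logw = np.log(weights) + nodes**2 + logf
        scale = np.log(np.sqrt(2.0) * abs(cov_chol[0, 0]))
    else:
        zz = np.array(np.meshgrid(nodes, nodes)).reshape(2, -1).T
        ww = np.outer(weights, weights).ravel()
        pts = eta_hat + np.sqrt(2.0) * zz @ cov_chol.T
        logf = np.array([-negl(p) for p in pts])
        logw = np.log(ww) + np.sum(zz**2, axis=1) + logf
        scale = np.log(2.0) + np.sum(np.log(np.abs(np.diag(cov_chol))))
    m = logw.max()
    return float(m + np.log(np.sum(np.exp(logw - m))) + scale)


def objective_value(
    works: Sequence[SubjectWork],
    theta: dict,
    ic50: float,
    method: str = "laplace",
    estimate_baseline: bool = True,
) -> float:
    """-2 log marginal likelihood summed over independent subjects."""
    total = 0.0
    for w in works:
        li = marginal_loglik(w, theta, ic50, method, estimate_baseline)
        if not np.isfinite(li):
            raise FloatingPointError(
                f"non-finite likelihood contribution for subject {w.patient.patient_id} "
                f"at theta={theta}"
            )
        total += li
    return -2.0 * total


# ---------------------------------------------------------------------------
# Population fit
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("kout", "imax", "omega_kout", "sigma_pd")
_U_BOUNDS = [(np.log(1e-4), np.log(0.5)), (-6.0, 9.0),
             (np.log(1e-3), np.log(3.0)), (np.log(1e-2), np.log(3.0))]


def _to_theta(u: np.ndarray) -> dict:
    return {
        "kout": float(np.exp(u[0])),
        "imax": float(1.0 / (1.0 + np.exp(-u[1]))),
        "omega_kout": float(np.exp(u[2])),
        "sigma_pd": float(np.exp(u[3])),
    }


def _to_u(theta: dict) -> np.ndarray:
    imax = min(max(theta["imax"], 1e-6), 1.0 - 1e-9)
    return np.array([
        np.log(theta["kout"]),
        np.log(imax / (1.0 - imax)),
        np.log(theta["omega_kout"]),
        np.log(theta["sigma_pd"]),
    ])


def fit_population_pd(
    cohort: Sequence[Patient],
    pk_individuals: dict[str, PKIndividual],
    ic50: float = 0.07,
    settings: FitSettings | None = None,
    compute_rse: bool = True,
) -> dict:
    """Maximize the Laplace marginal likelihood over (kout, Imax, omega_kout, sigma_PD).

    IC50 is a fixed constant.  Optimization runs on transformed coordinates
    (log for positive parameters, logit for Imax) with a derivative-free
    simplex search and multiple perturbed starts.  Returns a raw result dict;
    user-facing access goes through :class:`psomipd.model.PopulationPDModel`.
    """
    settings = settings or FitSettings()
    if not cohort:
        raise ValueError("empty cohort")
    if sum(p.pd_times.size for p in cohort) == 0:
        raise ValueError("cohort has no PD observations")
    works = [SubjectWork(p, pk_individuals[p.patient_id], settings) for p in cohort]
    eb = settings.estimate_baseline_eta

    n_eval = 0

    def nll(u: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return 0.5 * objective_value(works, _to_theta(u), ic50, "laplace", eb)

    rng = np.random.default_rng(settings.seed)
    u0 = _to_u(settings.init)
    starts = [u0]
    for _ in range(settings.n_starts - 1):
        starts.append(u0 + rng.normal(0.0, [0.5, 1.0, 0.4, 0.3]))
    starts = [np.clip(s, [b[0] for b in _U_BOUNDS], [b[1] for b in _U_BOUNDS])
              for s in starts]

    best = None
    for s in starts:
        for w in works:
            w.eta_hat = np.zeros(2)
        res = optimize.minimize(
            nll, s, method="Nelder-Mead", bounds=_U_BOUNDS,
            options={"maxiter": settings.maxiter, "xatol": settings.xatol,
                     "fatol": settings.fatol, "adaptive": True},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = _to_theta(best.x)
    objective = 2.0 * best.fun

    # empirical-Bayes modes at the final estimates
    ebes = []
    for w in works:
        inh = w.inhibition_grid(theta["imax"], ic50)
        w.eta_hat = np.zeros(2)
        eta, _, _ = _inner_mode(w, theta, inh, eb)
        eta_k = float(eta[0])
        eta_rv = float(eta[1]) if eb else 0.0
        ebes.append({
            "patient_id": w.patient.patient_id,
            "eta_kout": eta_k,
            "eta_rv": eta_rv,
            "kout_i": theta["kout"] * np.exp(eta_k),
            "pasi0_i": w.baseline * np.exp(eta_rv),
        })
    ebes = pd.DataFrame(ebes).set_index("patient_id")

    rse = {n: np.nan for n in _PARAM_NAMES}
    cov_u = None
    if compute_rse:
        try:
            h = _fd_hessian(nll, best.x, step=0.05)
            cov_u = np.linalg.inv(h)
            se_u = np.sqrt(np.maximum(np.diag(cov_u), 0.0))
            deriv = np.array([
                theta["kout"], theta["imax"] * (1 - theta["imax"]),
                theta["omega_kout"], theta["sigma_pd"],
            ])
            se_nat = se_u * deriv
            rse = {
                n: 100.0 * se_nat[i] / abs(theta[n]) for i, n in enumerate(_PARAM_NAMES)
            }
        except np.linalg.LinAlgError:  # pragma: no cover - singular information
            logger.warning("information matrix not invertible; RSEs unavailable")

    return {
        "theta": theta,
        "ic50": ic50,
        "objective": objective,
        "rse": rse,
        "cov_u": cov_u,
        "ebes": ebes,
        "converged": bool(best.success),
        "n_eval": n_eval,
        "settings": settings,
        "works": works,
    }


# ---------------------------------------------------------------------------
# Prediction-corrected visual predictive check
# ---------------------------------------------------------------------------

def pcvpc(
    cohort: Sequence[Patient],
    pk_individuals: dict[str, PKIndividual],
    pd_pop: PDPopulation,
    n_sim: int = 200,
    n_bins: int = 5,
    seed: int = 0,
    settings: FitSettings | None = None,
    percentiles: tuple = (5.0, 50.0, 95.0),
    ci: float = 90.0,
) -> pd.DataFrame:
    """Prediction-corrected VPC table for the PD model.

    Every observation (and simulated value) is rescaled by the ratio of its
    time-bin's median population prediction to its own population prediction,
    then observed percentiles are compared with the simulation-based
    confidence bands.  Returns a plot-ready table with one row per
    (bin, percentile).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    settings = settings or FitSettings()
    rng = np.random.default_rng(seed)
    theta = {"kout": pd_pop.kout, "imax": pd_pop.imax,
             "omega_kout": pd_pop.omega_kout, "sigma_pd": pd_pop.sigma_pd}

    works = [SubjectWork(p, pk_individuals[p.patient_id], settings) for p in cohort]
    times, obs, pred_pop, subj_idx = [], [], [], []
    for k, w in enumerate(works):
        inh = w.inhibition_grid(theta["imax"], pd_pop.ic50)
        latent_typ = pkpd.pd_trajectory_grid(theta["kout"], w.baseline, inh, w.dt)
        pp = np.maximum(np.interp(w.t_obs, w.grid, latent_typ), 1e-12)
        times.extend(w.t_obs); obs.extend(np.exp(w.log_obs))
        pred_pop.extend(pp); subj_idx.extend([k] * w.t_obs.size)
    times = np.asarray(times); obs = np.asarray(obs); pred_pop = np.asarray(pred_pop)

    # quantile-based time bins; merge any empty bin with its neighbor
    edges = np.unique(np.quantile(times, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # all observations at a single time point
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    bin_id = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
    for b in range(len(edges) - 1):
        if not np.any(bin_id == b):  # pragma: no cover - guarded by unique()
            logger.warning("pcVPC: empty bin %d merged with neighbor", b)

    bin_median_pred = np.array([
        np.median(pred_pop[bin_id == b]) for b in range(len(edges) - 1)
    ])
    correction = bin_median_pred[bin_id] / pred_pop
    obs_pc = obs * correction

    sim_pc = np.empty((n_sim, times.size))
    for s in range(n_sim):
        vals = np.empty(times.size)
        pos = 0
        for w in works:
            n = w.t_obs.size
            eta_k = rng.normal(0.0, theta["omega_kout"])
            eta_rv = rng.normal(0.0, theta["sigma_pd"])
            inh = w.inhibition_grid(theta["imax"], pd_pop.ic50)
            latent = pkpd.pd_trajectory_grid(
                theta["kout"] * np.exp(eta_k), w.baseline * np.exp(eta_rv), inh, w.dt
            )
            mu = np.maximum(np.interp(w.t_obs, w.grid, latent), 1e-12)
            vals[pos:pos + n] = mu * np.exp(rng.normal(0.0, theta["sigma_pd"], n))
            pos += n
        sim_pc[s] = vals * correction

    rows = []
    alo, ahi = (100 - ci) / 2, 100 - (100 - ci) / 2
    for b in range(len(edges) - 1):
        m = bin_id == b
        t_mid = float(np.median(times[m]))
        for p in percentiles:
            obs_p = float(np.percentile(obs_pc[m], p))
            sim_p = np.percentile(sim_pc[:, m], p, axis=1)
            rows.append({
                "bin": b, "t_mid": t_mid, "n_obs": int(m.sum()), "percentile": p,
                "observed": obs_p,
                "sim_lo": float(np.percentile(sim_p, alo)),
                "sim_med": float(np.percentile(sim_p, 50)),
                "sim_hi": float(np.percentile(sim_p, ahi)),
            })
    return pd.DataFrame(rows)
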