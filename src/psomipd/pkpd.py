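"""Structural PK/PD models for subcutaneous ustekinumab and the PASI response.

Pharmacokinetics: linear two-compartment disposition with first-order
absorption from a subcutaneous depot, evaluated in closed form (sum of three
exponentials) and superposed over arbitrary multi-dose schedules.  Because all
dosing is subcutaneous, parameters default to the *apparent* parameterization
(CL/F, Q/F, V2/F, V3/F with F = 1); an explicit bioavailability F < 1 may be
supplied.

Pharmacodynamics: indirect-response turnover of the Psoriasis Area and
Severity Index (PASI).  Lesion burden is produced at a zero-order rate
``kin = kout * PASI0`` and removed at first order ``kout``; drug inhibits the
production rate through a saturable Imax model,

    dPASI/dt = kin * (1 - Imax*C/(IC50 + C)) - kout * PASI ,

so the untreated steady state is exactly the individual baseline PASI0.

Time unit is days throughout; concentrations are mg/L (equivalently ug/mL,
the unit of the ELISA assay); doses are mg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import lfilter

DAYS_PER_WEEK = 7.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseEvent:
    """A single subcutaneous administration."""

    time: float      # days
    amount: float    # mg
    route: str = "sc"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be non-negative, got {self.time}")


@dataclass(frozen=True)
class Regimen:
    """A repeating dosing schedule: `n_cycles` doses of `dose_mg` every `interval_weeks`."""

    dose_mg: float
    interval_weeks: float
    n_cycles: int = 5
    start_day: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose must be non-negative")
        if self.interval_weeks <= 0:
            raise ValueError("interval must be positive")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")

    @property
    def interval_days(self) -> float:
        return self.interval_weeks * DAYS_PER_WEEK

    @property
    def dose_intensity(self) -> float:
        """Dose intensity in mg/week — the total order used for regimen preference."""
        return self.dose_mg / self.interval_weeks

    @property
    def label(self) -> str:
        iw = self.interval_weeks
        iw_s = f"{iw:g}"
        return f"{self.dose_mg:g} mg q{iw_s}w"

    def doses(self) -> list[DoseEvent]:
        """Expand into explicit dose events (empty for a zero-dose washout regimen)."""
        if self.dose_mg == 0:
            return []
        return [
            DoseEvent(self.start_day + k * self.interval_days, self.dose_mg)
            for k in range(self.n_cycles)
        ]

    @property
    def end_day(self) -> float:
        """Instant the last cycle ends (trough time of the final cycle)."""
        return self.start_day + self.n_cycles * self.interval_days


@dataclass(frozen=True)
class PKIndividual:
    """Individual structural PK parameters (apparent, i.e. scaled by 1/F, when F=1)."""

    ka: float    # 1/day
    cl: float    # L/day
    q: float     # L/day
    v2: float    # L, central
    v3: float    # L, peripheral
    f: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ka", "cl", "q", "v2", "v3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.f <= 1):
            raise ValueError("bioavailability F must lie in (0, 1]")


#: order of the log-normal random-effect / covariate dimensions on PKIndividual
PK_PARAM_NAMES = ("ka", "cl", "q", "v2", "v3")


@dataclass(frozen=True)
class PKPopulation:
    """Typical PK values with allometric body-weight scaling and log-normal IIV.

    The shipped defaults are illustrative values for testing; for real use the
    typical values of a published ustekinumab population PK model must be
    supplied through the configuration file.
    """

    ka: float = 0.35        # 1/day
    cl: float = 0.465       # L/day (CL/F)
    q: float = 0.40         # L/day (Q/F)
    v2: float = 4.6         # L (V2/F)
    v3: float = 2.8         # L (V3/F)
    f: float = 1.0
    ref_weight_kg: float = 70.0
    # allometric exponents: 3/4 power for clearances, linear for volumes
    exponents: dict = field(
        default_factory=lambda: {"ka": 0.0, "cl": 0.75, "q": 0.75, "v2": 1.0, "v3": 1.0}
    )
    # log-scale IIV standard deviations (0 = no variability on that parameter)
    omega: dict = field(
        default_factory=lambda: {"ka": 0.0, "cl": 0.3, "q": 0.0, "v2": 0.3, "v3": 0.0}
    )
    sigma_prop: float = 0.2  # proportional residual error SD on concentrations

    def __post_init__(self) -> None:
        for name in PK_PARAM_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"typical {name} must be positive")
        if self.ref_weight_kg <= 0:
            raise ValueError("reference weight must be positive")
        if any(v < 0 for v in self.omega.values()):
            raise ValueError("IIV standard deviations must be non-negative")


@dataclass(frozen=True)
class PDParams:
    """Indirect-response parameters for one individual.

    ``kin`` is derived, never stored: kin = kout * pasi0, which pins the
    untreated turnover steady state at the individual baseline.
    """

    kout: float          # 1/day
    imax: float          # fraction of kin suppressible
    ic50: float          # mg/L
    pasi0: float         # baseline PASI

    def __post_init__(self) -> None:
        if self.kout <= 0:
            raise ValueError("kout must be positive")
        if not (0 < self.imax <= 1):
            raise ValueError("Imax must lie in (0, 1]")
        if self.ic50 <= 0:
            raise ValueError("IC50 must be positive")
        if self.pasi0 <= 0:
            raise ValueError("baseline PASI must be positive")

    @property
    def kin(self) -> float:
        """Zero-order lesion progression rate (PASI units/day)."""
        return self.kout * self.pasi0


# ---------------------------------------------------------------------------
# Covariate model
# ---------------------------------------------------------------------------

def apply_covariates(
    pop: PKPopulation,
    weight_kg: float,
    eta: dict | None = None,
) -> PKIndividual:
    """Individualize typical PK values by allometric weight scaling and log-normal deviations.

    Each parameter becomes ``P_typ * (WT/WT_ref)**exponent * exp(eta_P)``.
    With ``weight_kg == ref_weight_kg`` and ``eta == 0`` the typical individual
    is returned exactly.
    """
    if weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {weight_kg}")
    eta = eta or {}
    ratio = weight_kg / pop.ref_weight_kg
    values = {}
    for name in PK_PARAM_NAMES:
        e = eta.get(name, 0.0)
        if not np.isfinite(e):
            raise ValueError(f"eta for {name} must be finite")
        values[name] = getattr(pop, name) * ratio ** pop.exponents.get(name, 0.0) * np.exp(e)
    return PKIndividual(f=pop.f, **values)


# ---------------------------------------------------------------------------
# Analytic PK
# ---------------------------------------------------------------------------

def _disposition_eigenvalues(ind: PKIndividual) -> tuple[float, float]:
    """Hybrid rate constants (alpha > beta > 0) of two-compartment disposition."""
    k10 = ind.cl / ind.v2
    k12 = ind.q / ind.v2
    k21 = ind.q / ind.v3
    s = k10 + k12 + k21
    disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return alpha, beta


def _single_dose_coefficients(ind: PKIndividual) -> tuple[np.ndarray, np.ndarray]:
    """Exponents (lambdas) and unit-dose macro-coefficients of the tri-exponential solution.

    C(t) = dose * sum_j coef_j * exp(-lam_j * t).  If the absorption rate
    collides with a disposition eigenvalue, ka is nudged by a machine-safe
    relative epsilon so the generic formula stays valid (the limiting t*exp
    form differs by less than any tolerance used here).
    """
    alpha, beta = _disposition_eigenvalues(ind)
    ka = ind.ka
    for lam in (alpha, beta):
        if abs(ka - lam) < 1e-9 * max(ka, lam):
            ka = ka * (1.0 + 1e-7) + 1e-12
    k21 = ind.q / ind.v3
    pref = ind.f * ka / ind.v2
    c_alpha = pref * (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    c_beta = pref * (k21 - beta) / ((ka - beta) * (alpha - beta))
    c_ka = pref * (k21 - ka) / ((alpha - ka) * (beta - ka))
    lams = np.array([alpha, beta, ka])
    coefs = np.array([c_alpha, c_beta, c_ka])
    return lams, coefs


def pk_concentration(
    ind: PKIndividual,
    doses: Sequence[DoseEvent],
    t: float | np.ndarray,
) -> np.ndarray:
    """Central-compartment concentration (mg/L) under a multi-dose schedule.

    Closed-form superposition of shifted single-dose tri-exponential profiles;
    exactly linear in dose.  Times before the first dose give 0.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("times must be non-negative")
    lams, coefs = _single_dose_coefficients(ind)
    conc = np.zeros_like(t_arr)
    for d in doses:
        dt = t_arr - d.time
        mask = dt > 0
        if not np.any(mask):
            continue
        conc[mask] += d.amount * (coefs * np.exp(-np.outer(dt[mask], lams))).sum(axis=1)
    conc = np.maximum(conc, 0.0)  # clip tri-exponential round-off at t ~ dose time
    return conc if np.ndim(t) else float(conc[0])


def pk_ode_oracle(
    ind: PKIndividual,
    doses: Sequence[DoseEvent],
    t_grid: np.ndarray,
    rtol: float = 1e-8,
) -> dict:
    """Numerically integrate the depot/central/peripheral ODE system.

    Independent check of the closed form; also tracks the eliminated amount so
    mass balance (depot + central + peripheral + eliminated = F * total dose)
    can be asserted.  Dose events are handled by state jumps at event times.
    """
    k10 = ind.cl / ind.v2
    k12 = ind.q / ind.v2
    k21 = ind.q / ind.v3
    ka = ind.ka

    def rhs(_t, y):
        a_depot, a_c, a_p, elim = y
        return [
            -ka * a_depot,
            ka * a_depot + k21 * a_p - (k10 + k12) * a_c,
            k12 * a_c - k21 * a_p,
            k10 * a_c,
        ]

    t_grid = np.asarray(t_grid, dtype=float)
    times = sorted({d.time for d in doses if d.time <= t_grid[-1]})
    y = np.zeros(4)
    out = np.zeros((4, len(t_grid)))
    done = t_grid < 0  # all False
    t_now = t_grid[0]
    # pre-first-dose points are zero
    segments = times + [t_grid[-1] + 1e-9]
    for i, t_seg in enumerate(segments):
        sel = (~done) & (t_grid <= t_seg + 1e-12) & (t_grid >= t_now - 1e-12)
        if np.any(sel):
            t_eval = t_grid[sel]
            if np.any(y != 0):
                sol = solve_ivp(
                    rhs, (t_now, max(t_eval[-1], t_now)), y,
                    t_eval=np.clip(t_eval, t_now, None),
                    rtol=rtol, atol=1e-12, method="LSODA",
                )
                if not sol.success:
                    raise RuntimeError(f"PK oracle integration failed: {sol.message}")
                out[:, sel] = sol.y
            done |= sel
        if i < len(times):
            # advance state to the dose time, then add the dose to the depot
            if np.any(y != 0) and t_seg > t_now:
                sol = solve_ivp(rhs, (t_now, t_seg), y, rtol=rtol, atol=1e-12,
                                method="LSODA")
                y = sol.y[:, -1]
            t_now = t_seg
            amt = sum(d.amount for d in doses if abs(d.time - t_seg) < 1e-12)
            y = y + np.array([ind.f * amt, 0.0, 0.0, 0.0])
    total_in = ind.f * sum(d.amount for d in doses if d.time <= t_grid[-1])
    return {
        "t": t_grid,
        "conc": out[1] / ind.v2,
        "depot": out[0],
        "central": out[1],
        "peripheral": out[2],
        "eliminated": out[3],
        "dosed": total_in,
    }


def terminal_halflife(ind: PKIndividual) -> float:
    """Terminal (beta-phase) half-life in days."""
    _, beta = _disposition_eigenvalues(ind)
    return float(np.log(2.0) / beta)


# ---------------------------------------------------------------------------
# PD: inhibition and turnover
# ---------------------------------------------------------------------------

def inhibition(conc, pd: PDParams):
    """Fractional suppression of kin: Imax*C/(IC50 + C), in [0, Imax]."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = pd.imax * c / (pd.ic50 + c)
    return out if out.ndim else float(out)


def steady_state_pasi(pd: PDParams, c_const: float) -> float:
    """PASI plateau under a constant concentration: PASI0*(1 - Imax*C/(IC50+C))."""
    if c_const < 0:
        raise ValueError("concentration must be non-negative")
    return pd.pasi0 * (1.0 - pd.imax * c_const / (pd.ic50 + c_const))


def conc_for_target_pasi(pd: PDParams, target: float) -> float:
    """Constant concentration whose plateau equals `target` (inverse of steady_state_pasi).

    Returns inf when even complete suppression of the drug-sensitive fraction
    cannot reach the target (target/PASI0 <= 1 - Imax).
    """
    if not (0 < target):
        raise ValueError("target must be positive")
    r = target / pd.pasi0
    if r >= 1.0:
        return 0.0
    if r <= 1.0 - pd.imax:
        return float("inf")
    return pd.ic50 * (1.0 - r) / (r - (1.0 - pd.imax))


def pd_trajectory(
    pd: PDParams,
    conc_fn: Callable[[np.ndarray], np.ndarray],
    t_grid: np.ndarray,
    rtol: float = 1e-6,
) -> np.ndarray:
    """Integrate the PASI turnover ODE with an adaptive solver.

    ``conc_fn`` maps time (days) to central concentration (mg/L); the response
    starts at its untreated steady state PASI0.  This is the reference
    integrator; inner loops use the much faster fixed-grid
    :func:`pd_trajectory_grid`.
    """
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(t, y):
        c = float(np.atleast_1d(conc_fn(t))[0])
        return [pd.kin * (1.0 - inhibition(c, pd)) - pd.kout * y[0]]

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), [pd.pasi0], t_eval=t_grid,
        rtol=rtol, atol=1e-10 * pd.pasi0, method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(
            f"PASI turnover integration failed: {sol.message}; "
            f"last state {sol.y[:, -1] if sol.y.size else 'none'}"
        )
    return sol.y[0]


def pd_trajectory_grid(
    kout: np.ndarray | float,
    pasi0: np.ndarray | float,
    inhibition_grid: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Exponential-stepping solution of the turnover ODE on a uniform grid.

    Treats the inhibition as constant over each step (midpoint of the node
    values), for which the linear ODE is solved exactly:

        P_{k+1} = P_k * a + PASI0 * (1 - Ibar_k) * (1 - a),   a = exp(-kout*dt).

    Unconditionally stable and vectorized over individuals/clones:  `kout`
    and `pasi0` may be scalars or shape-(m,) arrays; `inhibition_grid` may be
    shape (n,) (shared concentration) or (m, n).  Returns PASI at every node,
    shape (n,) or (m, n).
    """
    kout = np.asarray(kout, dtype=float)
    pasi0 = np.asarray(pasi0, dtype=float)
    inh = np.asarray(inhibition_grid, dtype=float)
    n = inh.shape[-1]
    ibar = 0.5 * (inh[..., :-1] + inh[..., 1:])
    scalar = kout.ndim == 0 and pasi0.ndim == 0 and inh.ndim == 1
    m = max(kout.size, pasi0.size, 1 if inh.ndim == 1 else inh.shape[0])
    a = np.exp(-np.broadcast_to(kout, (m,)).ravel() * dt)
    p0 = np.broadcast_to(pasi0, (m,)).ravel().astype(float)
    ibar2 = np.broadcast_to(ibar, (m, n - 1))
    out = np.empty((m, n))
    # closed form of the recursion: P_k = P0 * (1 - (1-a) * T_k) with
    # T_k = sum_{j<k} a^(k-1-j) * Ibar_j, evaluated by an IIR filter.
    for i in range(m):
        t_acc = lfilter([1.0], [1.0, -a[i]], ibar2[i])
        out[i, 0] = p0[i]
        out[i, 1:] = p0[i] * (1.0 - (1.0 - a[i]) * t_acc)
    return out[0] if scalar else out


def concentration_on_grid(
    ind: PKIndividual, doses: Sequence[DoseEvent], t_grid: np.ndarray
) -> np.ndarray:
    """Analytic concentrations evaluated on a grid (convenience wrapper)."""
    return pk_concentration(ind, doses, np.asarray(t_grid, dtype=float))


def individual_from_etas(
    pop: PKPopulation, weight_kg: float, eta_vector: np.ndarray | None
) -> PKIndividual:
    """Build a PKIndividual from a dense eta vector ordered as PK_PARAM_NAMES."""
    eta = {}
    if eta_vector is not None:
        eta = {name: float(e) for name, e in zip(PK_PARAM_NAMES, eta_vector)}
    return apply_covariates(pop, weight_kg, eta)


def with_params(ind: PKIndividual, **kwargs) -> PKIndividual:
    return replace(ind, **kwargs)
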