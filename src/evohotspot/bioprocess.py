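"""Monod-kinetics batch fermentation model, multi-batch fitting and KPIs.

State variables: biomass X (g CDW L^-1), glucose S (g L^-1), product P
(mM l-histidine).  The default model couples Monod growth with a
Herbert-Pirt substrate balance and substrate-saturated product formation:

    mu    = mu_max * S / (K_S + S)
    dX/dt = mu * X
    dP/dt = q_P_max * S / (K_S + S) * X          (optionally q_P ~ mu)
    dS/dt = -(mu / Y_XS) * X - q_P * X * M_his / (1000 * Y_PS)

Several batches are fitted jointly: parameters declared *global* are shared
across batches, *local* ones are estimated per batch.  Asymmetric confidence
bounds come from a parametric bootstrap (simulate from the fitted model plus
the estimated relative noise, refit, take percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "M_HISTIDINE",
    "M_GLUCOSE",
    "MonodParameters",
    "BatchTimeCourse",
    "MonodFit",
    "KPIReport",
    "simulate_batch",
    "fit_batches",
    "bootstrap_bounds",
    "compute_kpis",
    "read_batch_csv",
    "write_batch_csv",
]

M_HISTIDINE = 155.15  # g mol^-1, C6
M_GLUCOSE = 180.16  # g mol^-1, C6

DEFAULT_SCOPE: dict[str, str] = {
    "mu_max": "local",
    "K_S": "global",
    "Y_XS": "global",
    "q_P_max": "local",
}

_PARAM_NAMES = ("mu_max", "K_S", "Y_XS", "q_P_max")


@dataclass(frozen=True)
class MonodParameters:
    """Kinetic parameters of one batch.

    mu_max   maximum specific growth rate, h^-1
    K_S      Monod affinity constant for glucose, g L^-1
    Y_XS     biomass yield on glucose, g CDW per g glucose
    q_P_max  maximum specific production rate, mmol (g CDW)^-1 h^-1
    y_ps     product yield on the glucose routed to product, g per g
             (fixed stoichiometric constant, not fitted; default assumes
             one histidine per glucose, 155.15/180.16)
    growth_coupled  make q_P proportional to mu/mu_max instead of the
             substrate saturation term
    """

    mu_max: float
    K_S: float
    Y_XS: float
    q_P_max: float
    y_ps: float = M_HISTIDINE / M_GLUCOSE
    growth_coupled: bool = False

    def __post_init__(self) -> None:
        for name in ("mu_max", "K_S", "Y_XS", "y_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.q_P_max < 0:
            raise ValueError("q_P_max must be non-negative")

    @property
    def q_S_max(self) -> float:
        """Implied maximum specific glucose uptake, mmol (g CDW)^-1 h^-1."""
        g_per_g_h = self.mu_max / self.Y_XS + self.q_P_max * M_HISTIDINE / (1000.0 * self.y_ps)
        return g_per_g_h * 1000.0 / M_GLUCOSE


@dataclass
class BatchTimeCourse:
    """Measured (or simulated) trajectories of one batch cultivation."""

    batch_id: str
    times: np.ndarray  # h
    biomass: np.ndarray  # g CDW L^-1
    glucose: np.ndarray  # g L^-1
    histidine: np.ndarray  # mM
    init: tuple[float, float, float]  # X0, S0, P0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.histidine = np.asarray(self.histidine, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("biomass", "glucose", "histidine"):
            arr = getattr(self, name)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} length does not match times")
            if (arr < 0).any():
                raise ValueError(f"negative {name} values")

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass
class MonodFit:
    """Joint fit result: point estimates, loss, optional bootstrap bounds."""

    estimates: dict[str, float]  # flat: 'K_S' for globals, 'mu_max[b1]' for locals
    scope: dict[str, str]
    batch_ids: list[str]
    loss: float
    noise_sd: dict[str, float]  # relative residual sd per observable
    seed: Optional[int] = None
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    y_ps: float = M_HISTIDINE / M_GLUCOSE
    growth_coupled: bool = False

    def parameters_for(self, batch_id: str) -> MonodParameters:
        values = {}
        for name in _PARAM_NAMES:
            key = name if self.scope[name] == "global" else f"{name}[{batch_id}]"
            values[name] = self.estimates[key]
        return MonodParameters(**values, y_ps=self.y_ps, growth_coupled=self.growth_coupled)

    def summary(self) -> pd.DataFrame:
        """Table mirroring the usual report layout: estimate [low, high]."""
        rows = []
        for key, est in self.estimates.items():
            low, high = self.bounds.get(key, (np.nan, np.nan))
            rows.append({"parameter": key, "estimate": est, "low": low, "high": high})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class KPIReport:
    """Process key performance indicators derived from end-point measurements."""

    titer_mm: float
    titer_g_l: float
    yield_cmol: float  # C-mol product per C-mol glucose
    yield_mol: float  # mol per mol (equals yield_cmol for C6 -> C6)
    yield_g_g: float
    volumetric_productivity: float  # g L^-1 h^-1
    final_cdw: float


# ---------------------------------------------------------------------------
# simulation


def _rhs(t, y, p: MonodParameters):
    X, S, P = y
    S_eff = S if S > 0.0 else 0.0
    sat = S_eff / (p.K_S + S_eff)
    mu = p.mu_max * sat
    qP = p.q_P_max * (mu / p.mu_max if p.growth_coupled else sat)
    dX = mu * X
    dP = qP * X
    dS = -(mu / p.Y_XS) * X - qP * X * M_HISTIDINE / (1000.0 * p.y_ps)
    return (dX, dS, dP)


def simulate_batch(
    params: MonodParameters,
    init: tuple[float, float, float],
    t_grid: Sequence[float],
    batch_id: str = "batch",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> BatchTimeCourse:
    """Integrate the batch model over ``t_grid`` (hours).

    Glucose is floored at zero (all rates vanish once the substrate is
    depleted, so biomass and product plateau).  Deterministic for fixed
    tolerances.
    """
    X0, S0, P0 = init
    if X0 <= 0 or S0 <= 0:
        raise ValueError("initial biomass and glucose must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        _rhs,
        (t_grid[0], t_grid[-1]),
        (X0, S0, P0),
        t_eval=t_grid,
        args=(params,),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.isfinite(sol.y).all():
        raise RuntimeError(f"integration failed: {sol.message}")
    X, S, P = sol.y
    return BatchTimeCourse(
        batch_id=batch_id,
        times=t_grid,
        biomass=np.maximum(X, 0.0),
        glucose=np.maximum(S, 0.0),
        histidine=np.maximum(P, 0.0),
        init=(X0, S0, P0),
    )


# ---------------------------------------------------------------------------
# fitting


class _ParamLayout:
    """Maps the flat optimizer vector onto per-batch parameter sets."""

    def __init__(self, scope: Mapping[str, str], batch_ids: Sequence[str]):
        unknown = set(scope) - set(_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters in scope: {sorted(unknown)}")
        self.scope = {name: scope.get(name, DEFAULT_SCOPE[name]) for name in _PARAM_NAMES}
        for name, sc in self.scope.items():
            if sc not in ("global", "local"):
                raise ValueError(f"scope for {name} must be 'global' or 'local'")
        self.batch_ids = list(batch_ids)
        self.keys: list[str] = []
        for name in _PARAM_NAMES:
            if self.scope[name] == "global":
                self.keys.append(name)
            else:
                self.keys.extend(f"{name}[{b}]" for b in self.batch_ids)

    def vector_from(self, estimates: Mapping[str, float]) -> np.ndarray:
        return np.array([estimates[k] for k in self.keys], dtype=float)

    def estimates_from(self, vector: np.ndarray) -> dict[str, float]:
        return dict(zip(self.keys, (float(v) for v in vector)))

    def params_for(
        self, vector: np.ndarray, batch_id: str, y_ps: float, growth_coupled: bool
    ) -> MonodParameters:
        est = self.estimates_from(vector)
        values = {
            name: est[name if self.scope[name] == "global" else f"{name}[{batch_id}]"]
            for name in _PARAM_NAMES
        }
        return MonodParameters(**values, y_ps=y_ps, growth_coupled=growth_coupled)


_OBSERVABLES = ("biomass", "glucose", "histidine")


def _initial_guess(courses: Sequence[BatchTimeCourse]) -> dict[str, float]:
    """Crude data-driven starting values (refined by multi-start)."""
    mu, yxs, qp = [], [], []
    for c in courses:
        X = np.maximum(c.biomass, 1e-6)
        grow = X > X[0]
        if grow.sum() >= 2:
            k = np.flatnonzero(grow)[-1]
            mu.append(max(np.log(X[k] / X[0]) / max(c.times[k] - c.times[0], 1e-6), 1e-3))
        dS = c.glucose[0] - c.glucose.min()
        if dS > 0:
            yxs.append(max((c.biomass.max() - c.biomass[0]) / dS, 1e-3))
        x_mean = float(X.mean())
        dt = c.times[-1] - c.times[0]
        qp.append(max((c.histidine[-1] - c.histidine[0]) / max(x_mean * dt, 1e-6), 1e-4))
    return {
        "mu_max": float(np.median(mu)) if mu else 0.2,
        "K_S": 0.1,
        "Y_XS": float(np.median(yxs)) if yxs else 0.4,
        "q_P_max": float(np.median(qp)) if qp else 0.1,
    }


def _residuals(
    log_vector: np.ndarray,
    layout: _ParamLayout,
    courses: Sequence[BatchTimeCourse],
    scales: Mapping[str, float],
    y_ps: float,
    growth_coupled: bool,
) -> np.ndarray:
    vector = np.exp(np.clip(log_vector, -20.0, 10.0))
    chunks = []
    for c in courses:
        params = layout.params_for(vector, c.batch_id, y_ps, growth_coupled)
        try:
            sim = simulate_batch(params, c.init, c.times, rtol=1e-7, atol=1e-9)
        except (RuntimeError, ValueError):
            return np.full(sum(3 * c.n_points for c in courses), 1e6)
        for obs in _OBSERVABLES:
            data = getattr(c, obs)
            # per-point relative residuals (multiplicative-noise likelihood),
            # floored at 5% of the observable's cohort scale so depleted /
            # near-zero points keep finite weight
            w = np.maximum(np.abs(data), 0.05 * scales[obs])
            chunks.append((getattr(sim, obs) - data) / w)
    return np.concatenate(chunks)


def fit_batches(
    courses: Sequence[BatchTimeCourse],
    scope: Optional[Mapping[str, str]] = None,
    seed: Optional[int] = None,
    n_starts: int = 3,
    y_ps: float = M_HISTIDINE / M_GLUCOSE,
    growth_coupled: bool = False,
    start: Optional[Mapping[str, float]] = None,
    max_nfev: int = 500,
) -> MonodFit:
    """Weighted least-squares fit of the Monod model to one or more batches.

    Residuals are scaled per observable (by the cohort mean magnitude) so
    g L^-1 and mM series weigh comparably.  Parameters are optimized in log
    space (positivity built in) from ``n_starts`` seeded initial guesses;
    the best converged start wins.  Raises if no start converges.
    """
    if not courses:
        raise ValueError("need at least one batch")
    ids = [c.batch_id for c in courses]
    if len(set(ids)) != len(ids):
        raise ValueError("batch ids must be unique")
    for c in courses:
        if c.n_points < 5:
            raise ValueError(f"batch {c.batch_id}: need >= 5 time points, got {c.n_points}")
    layout = _ParamLayout(scope or DEFAULT_SCOPE, ids)
    scales = {
        obs: max(float(np.mean([np.abs(getattr(c, obs)).mean() for c in courses])), 1e-6)
        for obs in _OBSERVABLES
    }
    guess = dict(_initial_guess(courses))
    if start:
        guess.update(start)
    base = np.log(layout.vector_from(
        {k: guess[k.split("[")[0]] for k in layout.keys}
        | {k: guess[k] for k in layout.keys if k in guess}
    ))
    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_starts):
        x0 = base if i == 0 else base + rng.normal(0.0, 0.3, size=base.shape)
        res = least_squares(
            _residuals,
            x0,
            args=(layout, courses, scales, y_ps, growth_coupled),
            method="lm",
            xtol=1e-10,
            ftol=1e-10,
            max_nfev=max_nfev,
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(f"Monod fit did not converge in {n_starts} starts")

    vector = np.exp(best.x)
    estimates = layout.estimates_from(vector)
    # per-observable relative residual standard deviation (noise model for
    # the parametric bootstrap)
    noise_sd = {}
    offset = 0
    resid = best.fun
    obs_chunks: dict[str, list[np.ndarray]] = {o: [] for o in _OBSERVABLES}
    for c in courses:
        for obs in _OBSERVABLES:
            n = c.n_points
            obs_chunks[obs].append(resid[offset : offset + n])
            offset += n
    for obs in _OBSERVABLES:
        relative = np.concatenate(obs_chunks[obs])
        noise_sd[obs] = float(np.sqrt(np.mean(relative**2)))
    return MonodFit(
        estimates=estimates,
        scope=layout.scope,
        batch_ids=ids,
        loss=float(best.cost),
        noise_sd=noise_sd,
        seed=seed,
        y_ps=y_ps,
        growth_coupled=growth_coupled,
    )


def bootstrap_bounds(
    fit: MonodFit,
    courses: Sequence[BatchTimeCourse],
    n_boot: int = 200,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Parametric-bootstrap confidence bounds for every fitted parameter.

    New datasets are simulated from the fitted trajectories with the fitted
    relative noise, refitted (starting from the point estimate), and the
    (1-level)/2 and (1+level)/2 percentiles taken per parameter.  Bounds may
    be asymmetric about the estimate; the result is stored on ``fit.bounds``.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    rng = np.random.default_rng(seed)
    scales = {obs: fit.noise_sd[obs] for obs in _OBSERVABLES}
    fitted = {
        c.batch_id: simulate_batch(fit.parameters_for(c.batch_id), c.init, c.times)
        for c in courses
    }
    replicates: list[dict[str, float]] = []
    start = dict(fit.estimates)  # keyed names: refits begin at the point estimate
    for _ in range(n_boot):
        boot_courses = []
        for c in courses:
            sim = fitted[c.batch_id]
            noisy = {}
            for obs in _OBSERVABLES:
                clean = getattr(sim, obs)
                noisy[obs] = np.maximum(clean * (1.0 + scales[obs] * rng.standard_normal(len(clean))), 0.0)
            boot_courses.append(
                BatchTimeCourse(
                    batch_id=c.batch_id,
                    times=c.times,
                    biomass=noisy["biomass"],
                    glucose=noisy["glucose"],
                    histidine=noisy["histidine"],
                    init=c.init,
                )
            )
        try:
            bfit = fit_batches(
                boot_courses,
                scope=fit.scope,
                seed=int(rng.integers(2**31 - 1)),
                n_starts=1,
                y_ps=fit.y_ps,
                growth_coupled=fit.growth_coupled,
                start=start,
                max_nfev=200,
            )
        except RuntimeError:
            continue
        replicates.append(bfit.estimates)
    if len(replicates) < max(10, n_boot // 2):
        raise RuntimeError(f"only {len(replicates)}/{n_boot} bootstrap refits converged")
    alpha = (1.0 - level) / 2.0
    bounds = {}
    for key, est in fit.estimates.items():
        values = np.array([r[key] for r in replicates])
        # anchored so the interval always brackets the point estimate
        bounds[key] = (
            min(float(np.quantile(values, alpha)), est),
            max(float(np.quantile(values, 1.0 - alpha)), est),
        )
    fit.bounds = bounds
    fit.n_boot = len(replicates)
    return bounds


# ---------------------------------------------------------------------------
# KPIs


def compute_kpis(
    final_titer_mm: float,
    initial_glucose_g_l: float,
    duration_h: float,
    final_cdw_g_l: float,
) -> KPIReport:
    """End-point KPIs from directly measured quantities.

    Yields are per glucose supplied (batch, full depletion).  Because both
    glucose and histidine carry 6 carbons, the C-mol and mol/mol yields are
    identical.
    """
    if initial_glucose_g_l <= 0:
        raise ValueError("initial glucose must be positive")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    titer_g_l = final_titer_mm * M_HISTIDINE / 1000.0
    glucose_mm = 1000.0 * initial_glucose_g_l / M_GLUCOSE
    yield_mol = final_titer_mm / glucose_mm
    yield_cmol = (final_titer_mm * 6.0) / (glucose_mm * 6.0)
    return KPIReport(
        titer_mm=final_titer_mm,
        titer_g_l=titer_g_l,
        yield_cmol=yield_cmol,
        yield_mol=yield_mol,
        yield_g_g=titer_g_l / initial_glucose_g_l,
        volumetric_productivity=titer_g_l / duration_h,
        final_cdw=final_cdw_g_l,
    )


# ---------------------------------------------------------------------------
# CSV I/O

_CSV_COLUMNS = ["time_h", "cdw_g_l", "glucose_g_l", "histidine_mm"]


def write_batch_csv(course: BatchTimeCourse, sink) -> None:
    pd.DataFrame(
        {
            "time_h": course.times,
            "cdw_g_l": course.biomass,
            "glucose_g_l": course.glucose,
            "histidine_mm": course.histidine,
        }
    ).to_csv(sink, index=False)


def read_batch_csv(source, batch_id: str) -> BatchTimeCourse:
    df = pd.read_csv(source)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"batch CSV missing columns: {missing}")
    return BatchTimeCourse(
        batch_id=batch_id,
        times=df["time_h"].to_numpy(float),
        biomass=df["cdw_g_l"].to_numpy(float),
        glucose=df["glucose_g_l"].to_numpy(float),
        histidine=df["histidine_mm"].to_numpy(float),
        init=(
            float(df["cdw_g_l"].iloc[0]),
            float(df["glucose_g_l"].iloc[0]),
            float(df["histidine_mm"].iloc[0]),
        ),
    )
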