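"""Two-stage estimation of delay-coupled model parameters.

Stage 1: for each joint trial's asynchrony profile, a global search with a
genetic algorithm over (Δω, k1, k2, τ), each winner refined by a
bound-constrained local search; the best of ``n_restarts`` refined fits is
kept.  The median of the best-fit τ across trials is then computed.

Stage 2: the procedure is repeated with τ fixed to that median, fitting
(Δω, k1, k2) only.  Restarts whose refined parameters land on the search
boundary (k ≥ 49 or |Δω| ≥ 299 ms) are excluded before the per-trial
minimum-RMSE fit is selected; a trial with no surviving restart is flagged
rather than silently dropped.

The reduced model sets k1 = k2 = 0 (which also cancels τ) and fits the
intrinsic-period difference only; comparing its RMSE with the full model's
tests whether coupling is needed to account for the dyad's asynchronies.

The objective is the RMSE between the observed per-position asynchrony
profile and the model's predicted profile; the model's initial phase
offset is taken from the trial's first observed asynchrony when available
(without it, k is not identifiable from rep-averaged profiles of
near-identical-period dyads, whose noise-free profile is flat at zero for
every k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .metrics import AsynchronyProfile
from .model import (
    COUPLING_ALPHA,
    DCSParameters,
    IntegrationError,
    NOMINAL_PERIOD_MS,
    drift_closed_form,
    profile_from_events,
    simulate,
)
from .trials import DyadSyncError


class FitFailureError(DyadSyncError):
    """All restarts produced non-finite objectives."""


@dataclass(frozen=True)
class FitBounds:
    """Search bounds for the model parameters."""

    delta_omega_range: tuple[float, float] = (-300.0, 300.0)
    k_range: tuple[float, float] = (0.0, 50.0)
    tau_range: tuple[float, float] = (0.0, 50.0)
    # boundary-case exclusion thresholds
    k_boundary: float = 49.0
    delta_omega_boundary: float = 299.0

    def is_boundary_case(self, delta_omega: float, k1: float, k2: float) -> bool:
        return (
            k1 >= self.k_boundary
            or k2 >= self.k_boundary
            or abs(delta_omega) >= self.delta_omega_boundary
        )


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the evolutionary global search."""

    population_size: int = 40
    generations: int = 40
    tournament_size: int = 3
    crossover_rate: float = 0.7
    mutation_scale: float = 0.05  # sd as a fraction of each bound's width
    mutation_prob: float = 0.25
    n_elite: int = 1
    patience: int = 12  # generations without improvement before stopping


@dataclass
class FitResult:
    """Outcome of fitting one trial."""

    params: DCSParameters
    rmse: float
    n_restarts: int
    stage: str  # {"global", "tau_fixed", "reduced"}
    boundary_excluded: bool
    seed: int
    trial_ref: str = ""
    restart_rmses: list = field(default_factory=list)
    restart_boundary_flags: list = field(default_factory=list)
    n_surviving_restarts: int = 0


def rmse(observed, predicted) -> float:
    """Root mean square error between two equal-length sequences (ms)."""
    obs = np.asarray(getattr(observed, "values_ms", observed), dtype=float)
    pred = np.asarray(getattr(predicted, "predicted_profile", predicted), dtype=float)
    if obs.shape != pred.shape:
        raise DyadSyncError(f"length mismatch: {obs.shape} vs {pred.shape}")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _profile_target(profile: AsynchronyProfile) -> tuple[np.ndarray, int, float]:
    obs = profile.values_ms
    n_events = profile.melody_length * profile.n_repetitions_averaged
    a0 = (
        float(profile.initial_asynchrony_ms)
        if profile.initial_asynchrony_ms is not None
        else 0.0
    )
    return obs, n_events, a0


def make_objective(
    profile: AsynchronyProfile,
    tau_ms: float | None,
    dt_ms: float = 1.0,
    alpha: float = COUPLING_ALPHA,
    shared_k: bool = False,
) -> tuple[Callable[[np.ndarray], float], Callable[[np.ndarray], DCSParameters]]:
    """Build the RMSE objective over the fit vector.

    Fit vector layout: [Δω, k1, k2, (τ)] — τ present only when ``tau_ms`` is
    None (stage 1); with ``shared_k`` a single k gene drives both partners.
    Returns (objective, vector→parameters decoder).
    """
    obs, n_events, a0 = _profile_target(profile)
    L = profile.melody_length

    def decode(x: np.ndarray) -> DCSParameters:
        delta = float(x[0])
        if shared_k:
            k1 = k2 = float(x[1])
            tau = float(x[2]) if tau_ms is None else tau_ms
        else:
            k1, k2 = float(x[1]), float(x[2])
            tau = float(x[3]) if tau_ms is None else tau_ms
        return DCSParameters.from_delta(delta, k1, k2, tau)

    def objective(x: np.ndarray) -> float:
        try:
            pred = simulate(
                decode(x),
                n_events=n_events,
                dt_ms=dt_ms,
                initial_asynchrony_ms=a0,
                melody_length=L,
                alpha=alpha,
            )
        except IntegrationError:
            return np.inf
        return rmse(obs, pred.predicted_profile)

    return objective, decode


def _vector_bounds(
    bounds: FitBounds, tau_free: bool, shared_k: bool
) -> tuple[np.ndarray, np.ndarray]:
    lo = [bounds.delta_omega_range[0], bounds.k_range[0]]
    hi = [bounds.delta_omega_range[1], bounds.k_range[1]]
    if not shared_k:
        lo.append(bounds.k_range[0])
        hi.append(bounds.k_range[1])
    if tau_free:
        lo.append(bounds.tau_range[0])
        hi.append(bounds.tau_range[1])
    return np.array(lo), np.array(hi)


def _ga_search(
    objective: Callable[[np.ndarray], float],
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
    cfg: GAConfig,
    seeds: Sequence[np.ndarray] = (),
) -> tuple[np.ndarray, float]:
    """Tournament-selection GA with uniform crossover and Gaussian mutation."""
    width = hi - lo
    P, D = cfg.population_size, lo.size
    pop = rng.uniform(lo, hi, size=(P, D))
    for i, s in enumerate(seeds[: P // 2]):
        pop[i] = np.clip(np.asarray(s, dtype=float), lo, hi)
    fit = np.array([objective(x) for x in pop])

    best_idx = int(np.nanargmin(fit))
    best_x, best_f = pop[best_idx].copy(), float(fit[best_idx])
    stall = 0

    for _ in range(cfg.generations):
        order = np.argsort(fit)
        elite = pop[order[: cfg.n_elite]].copy()
        children = []
        while len(children) < P - cfg.n_elite:
            # tournament selection of two parents
            cand = rng.integers(0, P, size=cfg.tournament_size)
            p1 = pop[cand[np.argmin(fit[cand])]]
            cand = rng.integers(0, P, size=cfg.tournament_size)
            p2 = pop[cand[np.argmin(fit[cand])]]
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(D) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            mmask = rng.random(D) < cfg.mutation_prob
            if mmask.any():
                child = child + mmask * rng.normal(0.0, cfg.mutation_scale * width)
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([elite, np.array(children)])
        fit = np.array([objective(x) for x in pop])
        gen_best = int(np.nanargmin(fit))
        if fit[gen_best] < best_f - 1e-12:
            best_x, best_f = pop[gen_best].copy(), float(fit[gen_best])
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return best_x, best_f


def _refine(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    max_evals: int = 500,
) -> tuple[np.ndarray, float]:
    """Bound-constrained Nelder–Mead polish of a GA winner."""
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=optimize.Bounds(lo, hi),
        options={"maxfev": max_evals, "fatol": 1e-6, "xatol": 1e-4},
    )
    if np.isfinite(res.fun) and res.fun < objective(x0):
        return np.clip(res.x, lo, hi), float(res.fun)
    return x0, float(objective(x0))


def _level_consistent_guesses(
    profile: AsynchronyProfile,
    tau_ms: float,
    bounds: FitBounds,
    alpha: float,
    shared_k: bool,
    mean_period_ms: float = NOMINAL_PERIOD_MS,
) -> list[np.ndarray]:
    """Warm starts along the steady-state manifold of the fixed-τ fit.

    A phase-locked dyad's mean asynchrony L satisfies
    sin(2πL/ω̄) = Δω / ((k1+k2)·α·cos(Ωτ)), so for each candidate coupling a
    matching Δω reproduces the observed level; seeding the search with these
    lets the transient (rather than the level alone) select the coupling.
    """
    L = float(np.mean(profile.values_ms))
    psi = np.clip(L * 2.0 * np.pi / mean_period_ms, -np.pi / 2, np.pi / 2)
    cos = np.cos(2.0 * np.pi * tau_ms / mean_period_ms)
    guesses = []
    for k in (2.0, 5.0, 8.0, 12.0, 16.0, 22.0, 30.0, 40.0):
        delta = float(np.clip(
            np.sin(psi) * 2.0 * k * alpha * cos, *bounds.delta_omega_range
        ))
        x = [delta, k] if shared_k else [delta, k, k]
        guesses.append(np.array(x))
    return guesses


def _run_restarts(
    profile: AsynchronyProfile,
    tau_ms: float | None,
    bounds: FitBounds,
    n_restarts: int,
    seed: int,
    ga: GAConfig,
    dt_ms: float,
    alpha: float,
    shared_k: bool,
    stage: str,
    exclude_boundary: bool,
    initial_guesses: Sequence[np.ndarray] = (),
) -> FitResult:
    objective, decode = make_objective(profile, tau_ms, dt_ms, alpha, shared_k)
    lo, hi = _vector_bounds(bounds, tau_free=tau_ms is None, shared_k=shared_k)
    if tau_ms is not None:
        initial_guesses = list(initial_guesses) + _level_consistent_guesses(
            profile, tau_ms, bounds, alpha, shared_k
        )
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_restarts)

    candidates: list[tuple[np.ndarray, float, bool]] = []
    for cs in child_seeds:
        rng = np.random.Generator(np.random.PCG64(cs))
        x_ga, _ = _ga_search(objective, lo, hi, rng, ga, seeds=initial_guesses)
        x, f = _refine(objective, x_ga, lo, hi)
        p = decode(x)
        flag = bounds.is_boundary_case(p.delta_omega_ms, p.k1, p.k2)
        candidates.append((x, f, flag))

    rmses = [f for _, f, _ in candidates]
    flags = [b for _, _, b in candidates]
    if not any(np.isfinite(rmses)):
        raise FitFailureError(
            f"all {n_restarts} restarts non-finite for {profile.trial_ref}"
        )

    surviving = [
        (x, f) for (x, f, b) in candidates if np.isfinite(f) and not (exclude_boundary and b)
    ]
    all_excluded = len(surviving) == 0
    pool = surviving if surviving else [(x, f) for (x, f, _) in candidates if np.isfinite(f)]
    x_best, f_best = min(pool, key=lambda t: t[1])
    p_best = decode(x_best)
    return FitResult(
        params=p_best,
        rmse=f_best,
        n_restarts=n_restarts,
        stage=stage,
        boundary_excluded=all_excluded
        or bounds.is_boundary_case(p_best.delta_omega_ms, p_best.k1, p_best.k2),
        seed=seed,
        trial_ref=profile.trial_ref,
        restart_rmses=rmses,
        restart_boundary_flags=flags,
        n_surviving_restarts=len(surviving),
    )


def fit_trial_global(
    profile: AsynchronyProfile,
    bounds: FitBounds = FitBounds(),
    n_restarts: int = 10,
    seed: int = 0,
    ga: GAConfig = GAConfig(),
    dt_ms: float = 1.0,
    alpha: float = COUPLING_ALPHA,
    shared_k: bool = False,
) -> FitResult:
    """Stage-1 fit: global GA + local refinement over (Δω, k1, k2, τ).

    τ is shared between the two oscillators (a single memory delay per
    trial); the best refined restart by RMSE is returned.
    """
    return _run_restarts(
        profile, None, bounds, n_restarts, seed, ga, dt_ms, alpha,
        shared_k, stage="global", exclude_boundary=False,
    )


def fit_trial_tau_fixed(
    profile: AsynchronyProfile,
    tau_ms: float,
    bounds: FitBounds = FitBounds(),
    n_restarts: int = 10,
    seed: int = 0,
    ga: GAConfig = GAConfig(),
    dt_ms: float = 1.0,
    alpha: float = COUPLING_ALPHA,
    shared_k: bool = False,
    initial_guesses: Sequence[np.ndarray] = (),
) -> FitResult:
    """Stage-2 fit with τ fixed; boundary-case restarts are excluded.

    If every restart is a boundary case the best one is still reported but
    flagged via ``boundary_excluded`` so callers can log the trial as unfit.
    """
    if not (bounds.tau_range[0] <= tau_ms <= bounds.tau_range[1]):
        raise DyadSyncError(f"tau {tau_ms} outside bounds {bounds.tau_range}")
    return _run_restarts(
        profile, tau_ms, bounds, n_restarts, seed, ga, dt_ms, alpha,
        shared_k, stage="tau_fixed", exclude_boundary=True,
        initial_guesses=initial_guesses,
    )


def median_tau(results: Sequence[FitResult]) -> float:
    """Median best-fit τ across trials (even count → midpoint of central pair)."""
    if len(results) == 0:
        raise DyadSyncError("no fit results")
    return float(np.median([r.params.tau1_ms for r in results]))


def fit_reduced(
    profile: AsynchronyProfile,
    bounds: FitBounds = FitBounds(),
    n_grid: int = 121,
) -> FitResult:
    """Fit the coupling-free model (k = 0): intrinsic-period drift only.

    With k = 0 the predicted profile is the closed-form linear drift, so a
    deterministic coarse grid over Δω followed by a local polish suffices.
    """
    obs, n_events, a0 = _profile_target(profile)
    L = profile.melody_length
    lo, hi = bounds.delta_omega_range

    def obj(delta: float) -> float:
        p = DCSParameters.from_delta(float(delta), 0.0, 0.0, 0.0)
        drift = drift_closed_form(p, n_events=n_events, initial_asynchrony_ms=a0)
        return rmse(obs, profile_from_events(drift, L))

    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([obj(d) for d in grid])
    d0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        obj, bounds=(max(lo, d0 - 10), min(hi, d0 + 10)), method="bounded",
        options={"xatol": 1e-6},
    )
    d_best = float(res.x) if res.fun <= obj(d0) else float(d0)
    return FitResult(
        params=DCSParameters.from_delta(d_best, 0.0, 0.0, 0.0),
        rmse=float(obj(d_best)),
        n_restarts=1,
        stage="reduced",
        boundary_excluded=abs(d_best) >= bounds.delta_omega_boundary,
        seed=0,
        trial_ref=profile.trial_ref,
    )


def compare_models(
    profiles: Sequence[AsynchronyProfile],
    tau_ms: float,
    bounds: FitBounds = FitBounds(),
    seed: int = 0,
    n_restarts: int = 10,
    ga: GAConfig = GAConfig(),
    dt_ms: float = 1.0,
    shared_k: bool = False,
) -> pd.DataFrame:
    """Per-trial RMSE of the full model vs the reduced (k = 0) model.

    The full fit's search is warm-started with the reduced optimum, so the
    nested full model can never lose to the reduced one by more than local
    optimizer tolerance.
    """
    if len(profiles) == 0:
        raise DyadSyncError("no profiles to compare")
    rows = []
    rng = np.random.Generator(np.random.PCG64(seed))
    for prof in profiles:
        red = fit_reduced(prof, bounds)
        warm = np.array(
            [red.params.delta_omega_ms, 0.0]
            if shared_k else [red.params.delta_omega_ms, 0.0, 0.0]
        )
        full = fit_trial_tau_fixed(
            prof, tau_ms, bounds,
            n_restarts=n_restarts,
            seed=int(rng.integers(2**31)),
            ga=ga, dt_ms=dt_ms, shared_k=shared_k,
            initial_guesses=[warm],
        )
        rows.append(
            {
                "trial_ref": prof.trial_ref,
                "rmse_full": full.rmse,
                "rmse_reduced": red.rmse,
                "delta_rmse": red.rmse - full.rmse,
                "k1": full.params.k1,
                "k2": full.params.k2,
                "delta_omega_full": full.params.delta_omega_ms,
                "delta_omega_reduced": red.params.delta_omega_ms,
                "boundary_excluded": full.boundary_excluded,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_rmse_full"] = float(df["rmse_full"].mean())
    df.attrs["mean_rmse_reduced"] = float(df["rmse_reduced"].mean())
    return df


def grid_search_slice(
    profile: AsynchronyProfile,
    tau_ms: float,
    bounds: FitBounds = FitBounds(),
    n_delta: int = 200,
    n_k: int = 200,
    dt_ms: float = 1.0,
    alpha: float = COUPLING_ALPHA,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustive search on the 2-D (Δω, shared k) slice with τ fixed.

    Independent oracle for the optimizer: returns (best RMSE, rmse grid,
    Δω grid, k grid).
    """
    objective, _ = make_objective(profile, tau_ms, dt_ms, alpha, shared_k=True)
    deltas = np.linspace(*bounds.delta_omega_range, n_delta)
    ks = np.linspace(*bounds.k_range, n_k)
    grid = np.empty((n_delta, n_k))
    x = np.empty(2)
    for i, d in enumerate(deltas):
        x[0] = d
        for j, k in enumerate(ks):
            x[1] = k
            grid[i, j] = objective(x)
    return float(np.nanmin(grid)), grid, deltas, ks
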