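"""Maximization of the simulation-estimated composite likelihood.

The objective is noisy (each evaluation re-estimates the expected SFS from
fresh coalescent simulations), so derivative-based optimizers are out. Each
free parameter is instead maximized in turn by Brent's bounded 1-D method
while the others stay at their last value (expectation/conditional
maximization, ECM), cycling until the estimates stabilize. Because the
composite-likelihood surface can be multimodal and the objective stochastic,
several independent ECM runs are started from random in-bounds points and
the best final, re-scored solution is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from .demography import ParameterSpace, bind_parameters, sample_initial_parameters
from .likelihood import DEFAULT_FLOOR, composite_log_likelihood, pairwise_product_cl
from .sfs import (
    AscertainmentScheme,
    ObservedSFS,
    estimate_expected_pairwise,
    estimate_expected_sfs,
    marginal_pair,
)

__all__ = [
    "ECMConfig",
    "FitResult",
    "RunRecord",
    "brent_maximize",
    "ecm_fit",
    "multi_start_fit",
    "sfs_objective",
]

log = logging.getLogger(__name__)


@dataclass
class ECMConfig:
    """Settings for ECM composite-likelihood maximization.

    ``z_start``/``z_end`` ramp the number of coalescent simulations per
    likelihood evaluation linearly across cycles (cheap early cycles, precise
    late ones). ``mu`` is the per-bp per-generation mutation rate, needed for
    the monomorphic (clock-calibrated) likelihood terms.
    """

    cycles: int = 20
    runs: int = 20
    z_start: int = 50_000
    z_end: int = 250_000
    stop_tol: float = 0.005
    brent_tol: float = 0.01
    brent_maxiter: int = 20
    # After the first cycle each parameter's 1-D search interval is centred
    # on its current value and shrunk geometrically (factor per cycle), so a
    # modest brent_maxiter still reaches fine precision. 1.0 = always search
    # the full range; min_window is in native-scale units (log10 for
    # log-scale parameters).
    window_shrink: float = 0.5
    min_window: float = 0.1
    # evaluations averaged for the final re-score at z_end; the winner of a
    # multi-start fit is chosen on this value, and averaging keeps the
    # selection from favouring runs whose single re-score drew high noise
    final_rescore_evals: int = 1
    # iterate averaging: report the (geometric, for log-scale parameters)
    # mean of the last k cycles' vectors instead of the last one. Each
    # cycle's conditional argmax is an independent noisy draw around the
    # optimum once the run is stationary, so averaging shrinks the
    # Monte-Carlo scatter of weakly identified parameters. 1 = off.
    avg_last_cycles: int = 1
    use_monomorphic: bool = True
    epsilon: float = 0.0
    floor: float | None = DEFAULT_FLOOR
    mu: float | None = None
    asc: AscertainmentScheme | None = None
    pairwise: bool = False

    def __post_init__(self) -> None:
        if self.cycles < 1 or self.runs < 1:
            raise ValueError("cycles and runs must be >= 1")
        if self.z_start > self.z_end:
            raise ValueError("z_start must be <= z_end")
        if self.stop_tol <= 0:
            raise ValueError("stop_tol must be > 0")

    def z_for_cycle(self, cycle: int) -> int:
        if self.cycles == 1:
            return self.z_end
        frac = cycle / (self.cycles - 1)
        return int(round(self.z_start + frac * (self.z_end - self.z_start)))


@dataclass
class RunRecord:
    """One ECM run: per-cycle parameter vectors and log-likelihoods."""

    start_theta: np.ndarray
    trajectory: list = field(default_factory=list)  # (cycle, theta, logCL, Z)
    final_theta: np.ndarray | None = None
    final_logCL: float = -np.inf
    cycles_used: int = 0
    error: str | None = None


@dataclass
class FitResult:
    """Outcome of composite-likelihood maximization."""

    free_names: list[str]
    best_theta: np.ndarray
    best_logCL: float
    runs: list[RunRecord]
    winner: int = 0

    def best_params(self, space: ParameterSpace) -> dict[str, float]:
        return space.full_params(self.best_theta)


def brent_maximize(
    objective: Callable[[float], float],
    lo: float,
    hi: float,
    tol: float = 1e-5,
    maxiter: int = 100,
) -> tuple[float, float]:
    """Maximize a 1-D function on [lo, hi] by Brent's bounded method
    (golden-section bracketing with parabolic interpolation). Returns the
    argmax and the objective value there."""
    if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
        raise ValueError(f"invalid bounds [{lo}, {hi}]")
    if lo == hi:
        return lo, objective(lo)
    res = minimize_scalar(
        lambda x: -objective(x),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol, "maxiter": maxiter},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("objective non-finite at Brent optimum")
    return float(res.x), float(-res.fun)


def sfs_objective(
    obs,
    space: ParameterSpace,
    cfg: ECMConfig,
) -> Callable[[np.ndarray, int, np.random.Generator], float]:
    """Build the noisy objective: theta -> ln CL with a freshly simulated
    expected SFS (no common random numbers; two evaluations at the same theta
    differ by Monte-Carlo noise, as they do for the bundled optimizer)."""
    if cfg.pairwise:
        if isinstance(obs, ObservedSFS):
            demes = list(range(obs.num_demes))
            obs = {
                (i, j): marginal_pair(obs, i, j)
                for i in demes
                for j in demes[i + 1:]
            }
        obs_pairs: Mapping = obs

        def objective(theta, Z, rng):
            d = bind_parameters(space, theta)
            exp_pairs = estimate_expected_pairwise(d, Z, rng, asc=cfg.asc)
            return pairwise_product_cl(
                obs_pairs, exp_pairs, epsilon=cfg.epsilon, floor=cfg.floor
            ).logCL

        return objective

    if cfg.use_monomorphic and cfg.mu is None:
        raise ValueError("use_monomorphic requires cfg.mu")

    def objective(theta, Z, rng):
        d = bind_parameters(space, theta)
        exp = estimate_expected_sfs(
            d, Z, rng, asc=cfg.asc,
            mu_locus=cfg.mu if cfg.use_monomorphic else None,
        )
        return composite_log_likelihood(
            obs, exp,
            use_monomorphic=cfg.use_monomorphic,
            epsilon=cfg.epsilon,
            floor=cfg.floor,
        ).logCL

    return objective


def _to_native(x: float, scale: str) -> float:
    return np.log10(x) if scale == "log10" else x


def _from_native(x: float, scale: str) -> float:
    return 10.0 ** x if scale == "log10" else x


def ecm_fit(
    obs,
    space: ParameterSpace,
    cfg: ECMConfig,
    rng: np.random.Generator,
    theta0: np.ndarray | None = None,
    objective: Callable | None = None,
) -> FitResult:
    """One ECM maximization run.

    Per cycle, each free parameter is maximized by Brent's method on its
    native scale (log10 for sizes/times/rates, linear for proportions) with
    the others fixed; every objective evaluation re-estimates the expected
    SFS with the cycle's simulation count. Stops when the largest relative
    parameter change over a full cycle drops below ``stop_tol`` or at the
    cycle cap, then re-scores the final vector once at ``z_end``.
    """
    if objective is None:
        objective = sfs_objective(obs, space, cfg)
    free = space.free_parameters
    theta = (
        np.asarray(theta0, dtype=float)
        if theta0 is not None
        else sample_initial_parameters(space, rng)
    )
    rec = RunRecord(start_theta=theta.copy())

    if not free:
        val = objective(theta, cfg.z_end, rng)
        rec.final_theta = theta.copy()
        rec.final_logCL = val
        rec.trajectory.append((0, theta.copy(), val, cfg.z_end))
        return FitResult(
            free_names=[], best_theta=theta, best_logCL=val, runs=[rec]
        )

    last_val = -np.inf
    for cycle in range(cfg.cycles):
        Z = cfg.z_for_cycle(cycle)
        prev = theta.copy()
        for i, p in enumerate(free):
            lo, hi = _to_native(p.lo, p.scale), _to_native(p.hi, p.scale)
            if lo == hi:
                continue
            if cycle > 0 and cfg.window_shrink < 1.0:
                half = max(
                    (hi - lo) * cfg.window_shrink ** cycle, cfg.min_window
                ) / 2.0
                x_now = _to_native(theta[i], p.scale)
                lo = max(lo, x_now - half)
                hi = min(hi, x_now + half)

            def g(x, _i=i, _scale=p.scale):
                th = theta.copy()
                th[_i] = _from_native(x, _scale)
                return objective(th, Z, rng)

            xstar, val = brent_maximize(
                g, lo, hi, tol=cfg.brent_tol, maxiter=cfg.brent_maxiter
            )
            theta[i] = _from_native(xstar, p.scale)
            last_val = val
        rec.trajectory.append((cycle, theta.copy(), last_val, Z))
        rec.cycles_used = cycle + 1
        log.info(
            "cycle %d Z=%d logCL=%.3f theta=%s",
            cycle, Z, last_val, np.array2string(theta, precision=4),
        )
        rel = np.max(np.abs(theta - prev) / np.maximum(np.abs(prev), 1e-300))
        if rel < cfg.stop_tol:
            break

    if cfg.avg_last_cycles > 1 and len(rec.trajectory) >= 2:
        k = min(cfg.avg_last_cycles, len(rec.trajectory))
        last = np.array([th for (_, th, _, _) in rec.trajectory[-k:]])
        for i, p in enumerate(free):
            if p.scale == "log10":
                theta[i] = 10.0 ** np.mean(np.log10(last[:, i]))
            else:
                theta[i] = np.mean(last[:, i])

    rec.final_theta = theta.copy()
    rec.final_logCL = float(np.mean(
        [objective(theta, cfg.z_end, rng)
         for _ in range(max(1, cfg.final_rescore_evals))]
    ))
    return FitResult(
        free_names=space.free_names,
        best_theta=theta.copy(),
        best_logCL=rec.final_logCL,
        runs=[rec],
    )


def multi_start_fit(
    obs,
    space: ParameterSpace,
    cfg: ECMConfig,
    rng: np.random.Generator,
    objective: Callable | None = None,
) -> FitResult:
    """``cfg.runs`` independent ECM runs from random starts; the run with the
    highest final re-scored log-likelihood wins (ties to the earliest)."""
    records: list[RunRecord] = []
    streams = rng.spawn(cfg.runs)
    for r, sub in enumerate(streams):
        try:
            fit = ecm_fit(obs, space, cfg, sub, objective=objective)
            records.append(fit.runs[0])
        except Exception as exc:  # noqa: BLE001 - a run may fail, others go on
            log.warning("run %d failed: %s", r, exc)
            rec = RunRecord(start_theta=np.full(space.num_free, np.nan))
            rec.error = str(exc)
            records.append(rec)
    ok = [r for r in records if r.error is None]
    if not ok:
        raise RuntimeError(
            "all optimization runs failed: "
            + "; ".join(r.error or "?" for r in records)
        )
    winner = int(np.argmax([r.final_logCL if r.error is None else -np.inf
                            for r in records]))
    best = records[winner]
    return FitResult(
        free_names=space.free_names,
        best_theta=best.final_theta.copy(),
        best_logCL=best.final_logCL,
        runs=records,
        winner=winner,
    )
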