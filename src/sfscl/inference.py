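"""Uncertainty and model assessment for composite-likelihood fits.

Three tools built on the parametric bootstrap and the composite likelihood:

* percentile confidence intervals, obtained by simulating replicate datasets
  at the maximum-composite-likelihood (MCL) estimates and re-estimating;
* AIC / Akaike-weight model comparison, with the model log-likelihood taken
  as the maximum over repeated re-evaluations at the MCL parameters (the
  likelihood itself is a Monte-Carlo estimate, so a single draw is noisy);
* a goodness-of-fit test on the likelihood-ratio G statistic
  G = 2 (ln CL_saturated - ln CL_model), whose null distribution comes from
  the same parametric bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import ParameterSpace, bind_parameters
from .likelihood import saturated_log_likelihood
from .optimize import ECMConfig, FitResult, multi_start_fit, sfs_objective
from .sfs import ObservedSFS, estimate_expected_sfs, simulate_observed_sfs

__all__ = [
    "BootstrapResult",
    "ModelComparison",
    "CLRTestResult",
    "parametric_bootstrap_ci",
    "aic_weights",
    "clr_gtest",
    "rescore_logcl",
    "multinomial_replicate",
]

log = logging.getLogger(__name__)


def rescore_logcl(
    obs: ObservedSFS,
    space: ParameterSpace,
    theta: np.ndarray,
    cfg: ECMConfig,
    rng: np.random.Generator,
    repeats: int = 100,
) -> float:
    """Maximum of ``repeats`` independent log-likelihood re-evaluations at a
    fixed parameter vector, each with ``cfg.z_end`` simulations."""
    objective = sfs_objective(obs, space, cfg)
    return max(objective(theta, cfg.z_end, rng) for _ in range(repeats))


def multinomial_replicate(
    obs: ObservedSFS, probs: np.ndarray, rng: np.random.Generator
) -> ObservedSFS:
    """Fast parametric-bootstrap dataset: resample the observed number of
    polymorphic sites S from the expected class probabilities (L kept)."""
    mask = ~obs.mask
    p = probs[mask].astype(float)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    counts = np.zeros_like(obs.counts)
    counts[mask] = rng.multinomial(obs.S, p)
    return ObservedSFS(sample_sizes=obs.sample_sizes, counts=counts, L=obs.L)


@dataclass
class BootstrapResult:
    """Percentile confidence intervals from B parametric-bootstrap fits."""

    names: list[str]
    estimates: np.ndarray  # (successes, k)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    B: int
    failures: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "median": np.median(self.estimates, axis=0),
                "ci_2.5%": self.ci_lower,
                "ci_97.5%": self.ci_upper,
            }
        )


def _bootstrap_datasets(
    obs: ObservedSFS,
    space: ParameterSpace,
    theta: np.ndarray,
    cfg: ECMConfig,
    B: int,
    rng: np.random.Generator,
    exact: bool,
    num_loci: int | None,
    locus_length: float | None,
):
    """Yield B replicate datasets simulated at the MCL estimates.

    The fast path resamples S sites multinomially from the expected SFS; the
    exact path re-simulates every locus (required when the monomorphic count
    itself should vary, and used to validate the fast path)."""
    d = bind_parameters(space, theta)
    if exact:
        if num_loci is None or locus_length is None or cfg.mu is None:
            raise ValueError("exact bootstrap needs num_loci, locus_length and cfg.mu")
        for _ in range(B):
            yield simulate_observed_sfs(
                d, num_loci, locus_length, cfg.mu, rng, asc=cfg.asc
            )
    else:
        exp = estimate_expected_sfs(
            d, cfg.z_end, rng, asc=cfg.asc,
            mu_locus=cfg.mu if cfg.use_monomorphic else None,
        )
        for _ in range(B):
            yield multinomial_replicate(obs, exp.probs, rng)


def parametric_bootstrap_ci(
    obs: ObservedSFS,
    space: ParameterSpace,
    fit: FitResult,
    cfg: ECMConfig,
    rng: np.random.Generator,
    B: int = 100,
    runs_per_replicate: int = 10,
    min_success: float = 0.5,
    exact: bool = False,
    num_loci: int | None = None,
    locus_length: float | None = None,
    refit_cfg: ECMConfig | None = None,
) -> BootstrapResult:
    """Percentile CIs from B datasets simulated at the MCL estimates, each
    re-fitted with a reduced number of starts (``refit_cfg`` overrides the
    whole per-replicate configuration when the refits should also use fewer
    cycles or simulations)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    boot_cfg = refit_cfg if refit_cfg is not None else replace(
        cfg, runs=runs_per_replicate)
    estimates = []
    failures = 0
    for b, obs_b in enumerate(
        _bootstrap_datasets(
            obs, space, fit.best_theta, cfg, B, rng, exact, num_loci, locus_length
        )
    ):
        try:
            refit = multi_start_fit(obs_b, space, boot_cfg, rng)
            estimates.append(refit.best_theta)
        except Exception as exc:  # noqa: BLE001
            log.warning("bootstrap replicate %d failed: %s", b, exc)
            failures += 1
    if len(estimates) < max(1, min_success * B):
        raise RuntimeError(
            f"only {len(estimates)}/{B} bootstrap replicates succeeded"
        )
    est = np.asarray(estimates)
    lo, hi = np.percentile(est, [2.5, 97.5], axis=0)
    return BootstrapResult(
        names=space.free_names,
        estimates=est,
        ci_lower=lo,
        ci_upper=hi,
        B=B,
        failures=failures,
    )


@dataclass
class ModelComparison:
    """AIC table: AIC_i = 2 d_i - 2 ln CL_i, Akaike weight
    w_i proportional to exp(-(AIC_i - AIC_min)/2)."""

    names: list[str]
    d: np.ndarray
    logCL: np.ndarray
    aic: np.ndarray = field(init=False)
    delta: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.logCL = np.asarray(self.logCL, dtype=float)
        self.aic = 2.0 * self.d - 2.0 * self.logCL
        self.delta = self.aic - self.aic.min()
        w = np.exp(-0.5 * self.delta)
        self.weights = w / w.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.names,
                "d": self.d.astype(int),
                "logCL": self.logCL,
                "AIC": self.aic,
                "deltaAIC": self.delta,
                "weight": self.weights,
            }
        )


def aic_weights(
    models: Mapping[str, tuple[int, float]] | Sequence[tuple[str, int, float]],
) -> ModelComparison:
    """Akaike weights for a set of models fitted to the same data.

    ``models`` maps name -> (number of free parameters, ln CL); the ln CL of
    each model should be the re-scored value at its MCL parameters (see
    :func:`rescore_logcl`)."""
    if isinstance(models, Mapping):
        items = [(k, *v) for k, v in models.items()]
    else:
        items = list(models)
    if not items:
        raise ValueError("need at least one model")
    names = [it[0] for it in items]
    return ModelComparison(
        names=names,
        d=np.array([it[1] for it in items]),
        logCL=np.array([it[2] for it in items]),
    )


@dataclass
class CLRTestResult:
    """Goodness-of-fit G-test against a parametric-bootstrap null."""

    G_obs: float
    null_G: np.ndarray
    p_value: float
    replicate_failures: int = 0


def clr_gtest(
    obs: ObservedSFS,
    space: ParameterSpace,
    fit: FitResult,
    cfg: ECMConfig,
    rng: np.random.Generator,
    B: int = 100,
    runs_per_replicate: int = 10,
    rescore_repeats: int = 10,
    min_success: float = 0.5,
    refit_cfg: ECMConfig | None = None,
) -> CLRTestResult:
    """Composite-likelihood-ratio goodness-of-fit test.

    G_obs = 2 (ln CL_saturated - ln CL_model), with the model term re-scored
    at the MCL parameters. The null distribution of G comes from B datasets
    simulated at those parameters, each re-fitted and scored the same way;
    the p-value is the fraction of null G at or above G_obs. Replicate
    refits may use a cheaper configuration (``refit_cfg``); the G scoring
    itself always uses the main configuration, so observed and null values
    are computed identically.
    """
    boot_cfg = refit_cfg if refit_cfg is not None else replace(
        cfg, runs=runs_per_replicate)

    def g_for(data: ObservedSFS, theta: np.ndarray) -> float:
        sat = saturated_log_likelihood(
            data, use_monomorphic=cfg.use_monomorphic, epsilon=cfg.epsilon
        ).logCL
        model = rescore_logcl(data, space, theta, cfg, rng, repeats=rescore_repeats)
        return 2.0 * (sat - model)

    G_obs = g_for(obs, fit.best_theta)
    null = []
    failures = 0
    for b, obs_b in enumerate(
        _bootstrap_datasets(
            obs, space, fit.best_theta, cfg, B, rng, False, None, None
        )
    ):
        try:
            refit = multi_start_fit(obs_b, space, boot_cfg, rng)
            null.append(g_for(obs_b, refit.best_theta))
        except Exception as exc:  # noqa: BLE001
            log.warning("G-test replicate %d failed: %s", b, exc)
            failures += 1
    if len(null) < max(1, min_success * B):
        raise RuntimeError(f"only {len(null)}/{B} G-test replicates succeeded")
    null = np.asarray(null)
    return CLRTestResult(
        G_obs=G_obs,
        null_G=null,
        p_value=float(np.mean(null >= G_obs)),
        replicate_failures=failures,
    )
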