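"""Composite log-likelihoods of observed spectra.

The composite likelihood of a model given an observed SFS X with S
polymorphic sites over L surveyed bp is

    ln CL = (L - S) ln p0 + S ln(1 - p0) + sum_i X_i ln p_hat_i,

a binomial term for the polymorphic/monomorphic split times a multinomial
over the polymorphic classes (conditional on one mutation). When monomorphic
counts are unavailable or meaningless (ascertained SNP chips) the binomial
terms are dropped, which leaves exactly the multinomial composite likelihood
up to a data-dependent constant. For models with many demes the product of
all pairwise 2-D composite likelihoods (C2L) replaces the joint CL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .sfs import (
    CollapsedPair,
    ExpectedSFS,
    ObservedSFS,
    collapse_entries,
    nonabsorbing,
)

__all__ = [
    "CLResult",
    "composite_log_likelihood",
    "pairwise_product_cl",
    "saturated_log_likelihood",
]

DEFAULT_FLOOR = 1e-12


@dataclass
class CLResult:
    """A composite log-likelihood and its per-class decomposition."""

    logCL: float
    per_entry: np.ndarray
    used_monomorphic: bool
    floored_entries: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    monomorphic_term: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.logCL):
            raise ValueError(f"non-finite log composite likelihood: {self.logCL}")

    def to_frame(self):
        """Per-class contributions as a table (TSV-ready diagnostic)."""
        import pandas as pd

        return pd.DataFrame(
            {"class": np.arange(len(self.per_entry)),
             "contribution": self.per_entry}
        )


def _poly_loglik(
    counts: np.ndarray,
    probs: np.ndarray,
    epsilon: float,
    floor: float | None,
    renormalize: bool,
) -> tuple[float, np.ndarray, np.ndarray, CollapsedPair]:
    probs = np.asarray(probs, dtype=float)
    if renormalize and probs.sum() > 0:
        probs = probs / probs.sum()
    pair = collapse_entries(counts, probs, epsilon)
    x, p = pair.counts.astype(float), pair.probs.copy()
    bad = (x > 0) & (p <= 0)
    if bad.any():
        if floor is None:
            raise ValueError(
                f"{int(bad.sum())} observed classes have zero expected "
                "probability and the floor is disabled"
            )
        p[bad] = floor
    per_entry = np.zeros_like(p)
    nz = x > 0
    per_entry[nz] = x[nz] * np.log(p[nz])
    return float(per_entry.sum()), per_entry, np.nonzero(bad)[0], pair


def composite_log_likelihood(
    obs: ObservedSFS,
    exp: ExpectedSFS,
    use_monomorphic: bool = True,
    epsilon: float = 0.0,
    floor: float | None = DEFAULT_FLOOR,
    renormalize: bool = True,
) -> CLResult:
    """Composite log-likelihood of an observed SFS given an expected SFS.

    With ``use_monomorphic`` (requires ``obs.L`` and ``exp.p0``) the binomial
    monomorphic/polymorphic terms supply the molecular-clock calibration;
    without it (SNP data, option ``-0``) only the multinomial class terms
    remain. Entries with observed count below ``epsilon`` are pooled first;
    observed classes with zero expected probability are set to ``floor``
    after collapsing.
    """
    counts, probs = nonabsorbing(obs, exp)
    poly, per_entry, floored, _ = _poly_loglik(
        counts, probs, epsilon, floor, renormalize
    )
    mono = 0.0
    if use_monomorphic:
        if obs.L is None:
            raise ValueError("use_monomorphic requires obs.L (surveyed length)")
        if exp.p0 is None:
            raise ValueError("use_monomorphic requires exp.p0 (supply mu_locus)")
        S = obs.S
        mono = (obs.L - S) * np.log(exp.p0)
        if S > 0:
            mono += S * np.log1p(-exp.p0)
    return CLResult(
        logCL=poly + mono,
        per_entry=per_entry,
        used_monomorphic=use_monomorphic,
        floored_entries=floored,
        monomorphic_term=mono,
    )


def pairwise_product_cl(
    obs_pairs: Mapping[tuple[int, int], ObservedSFS],
    exp_pairs: Mapping[tuple[int, int], ExpectedSFS],
    epsilon: float = 0.0,
    floor: float | None = DEFAULT_FLOOR,
    renormalize: bool = True,
) -> CLResult:
    """Product of all pairwise 2-D composite likelihoods (ln C2L).

    Monomorphic terms are always excluded here: each pair would count them
    again, so the product only makes sense over polymorphic classes.
    """
    missing = set(exp_pairs) - set(obs_pairs)
    if missing:
        raise ValueError(f"missing observed pairs: {sorted(missing)}")
    missing = set(obs_pairs) - set(exp_pairs)
    if missing:
        raise ValueError(f"missing expected pairs: {sorted(missing)}")
    total = 0.0
    pieces = []
    floored = []
    for key in sorted(obs_pairs):
        r = composite_log_likelihood(
            obs_pairs[key],
            exp_pairs[key],
            use_monomorphic=False,
            epsilon=epsilon,
            floor=floor,
            renormalize=renormalize,
        )
        total += r.logCL
        pieces.append(r.per_entry)
        floored.append(r.floored_entries)
    return CLResult(
        logCL=total,
        per_entry=np.concatenate(pieces),
        used_monomorphic=False,
        floored_entries=np.concatenate(floored),
    )


def saturated_log_likelihood(
    obs: ObservedSFS,
    use_monomorphic: bool = True,
    epsilon: float = 0.0,
) -> CLResult:
    """Maximum achievable composite log-likelihood for the data.

    Plugs the relative observed SFS p_hat_i = X_i / S (and p0 = (L - S)/L
    when monomorphic sites are used) into the composite likelihood; by the
    multinomial MLE property no expected SFS can do better.
    """
    if obs.S < 1:
        raise ValueError("saturated likelihood needs S >= 1 polymorphic sites")
    counts = obs.counts[~obs.mask]
    probs = counts / counts.sum()
    poly, per_entry, _, _ = _poly_loglik(counts, probs, epsilon, None, False)
    mono = 0.0
    if use_monomorphic:
        if obs.L is None:
            raise ValueError("use_monomorphic requires obs.L")
        S, L = obs.S, obs.L
        if L > S:
            mono = (L - S) * np.log((L - S) / L) + S * np.log(S / L)
        # L == S: all sites polymorphic, binomial term is 0
    return CLResult(
        logCL=poly + mono,
        per_entry=per_entry,
        used_monomorphic=use_monomorphic,
        monomorphic_term=mono,
    )
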