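"""Observed and expected site-frequency spectra.

The expected SFS under a demographic model is estimated from Z simulated
genealogies as a ratio of branch lengths,

    p_hat_i = sum_k sum_{j in Omega_i} t_ij^(k) / sum_k T^(k),

where Omega_i is the set of branches whose mutations produce the joint
frequency class i and T^(k) is the total length of the k-th genealogy.
Numerator and denominator are accumulated over the *same* simulations, which
implicitly weights each genealogy by the probability that a mutation occurs
on it. With SNP-chip ascertainment ("sites heterozygous in one individual of
a given deme"), both the compatible branch set and the denominator are
restricted to the subtree joining the two ascertainment lineages to their
MRCA, while frequency classes still count the full sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .coalescent import DEFAULT_TIME_CAP
from .demography import Demography

__all__ = [
    "ObservedSFS",
    "ExpectedSFS",
    "AscertainmentScheme",
    "CollapsedPair",
    "estimate_expected_sfs",
    "estimate_expected_pairwise",
    "estimate_p0",
    "simulate_observed_sfs",
    "collapse_entries",
    "marginal_pair",
]


def _absorbing_mask(shape: tuple[int, ...]) -> np.ndarray:
    """Boolean mask flagging the all-ancestral and all-derived corners."""
    mask = np.zeros(shape, dtype=bool)
    mask[(0,) * len(shape)] = True
    mask[tuple(s - 1 for s in shape)] = True
    return mask


@dataclass
class ObservedSFS:
    """A (possibly joint) observed derived-allele frequency spectrum.

    ``counts`` is dense with shape (n_1+1, ..., n_v+1); the two absorbing
    corners (all-ancestral, all-derived in the whole sample) are excluded
    from the polymorphic count S. ``L`` is the total surveyed length in bp
    when monomorphic sites are known, else None (e.g. SNP-chip data).
    """

    sample_sizes: tuple[int, ...]
    counts: np.ndarray
    L: float | None = None

    def __post_init__(self) -> None:
        self.sample_sizes = tuple(int(n) for n in self.sample_sizes)
        shape = tuple(n + 1 for n in self.sample_sizes)
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(shape)
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")
        if self.L is not None and self.L < self.S:
            raise ValueError(f"L={self.L} smaller than S={self.S}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.counts.shape

    @property
    def num_demes(self) -> int:
        return len(self.sample_sizes)

    @property
    def mask(self) -> np.ndarray:
        return _absorbing_mask(self.shape)

    @property
    def S(self) -> int:
        """Number of polymorphic sites."""
        return int(self.counts[~self.mask].sum())


@dataclass
class ExpectedSFS:
    """Simulation-estimated class probabilities, plus the monomorphic
    probability p0 (per site) when a mutation rate was supplied."""

    sample_sizes: tuple[int, ...]
    probs: np.ndarray
    Z: int
    p0: float | None = None
    mean_T: float = float("nan")

    def __post_init__(self) -> None:
        self.sample_sizes = tuple(int(n) for n in self.sample_sizes)
        shape = tuple(n + 1 for n in self.sample_sizes)
        self.probs = np.asarray(self.probs, dtype=float).reshape(shape)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.probs.shape

    @property
    def mask(self) -> np.ndarray:
        return _absorbing_mask(self.shape)


@dataclass
class AscertainmentScheme:
    """SNPs ascertained as heterozygous between two random gene copies of one
    deme (the SNP-array discovery-panel scheme)."""

    deme: int
    chromosomes: int = 2
    included_in_sample: bool = True

    def __post_init__(self) -> None:
        if self.chromosomes != 2:
            raise ValueError("only the 2-chromosome (heterozygous-individual) scheme is supported")


def _check_asc(d: Demography, asc: AscertainmentScheme | None) -> int:
    if asc is None:
        return -1
    if not 0 <= asc.deme < d.num_pops:
        raise ValueError(f"ascertained deme {asc.deme} out of range")
    if asc.included_in_sample and d.sample_sizes[asc.deme] < asc.chromosomes:
        raise ValueError(
            f"ascertained deme {asc.deme} has sample size "
            f"{d.sample_sizes[asc.deme]} < {asc.chromosomes}"
        )
    return asc.deme


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def estimate_expected_sfs(
    d: Demography,
    Z: int,
    rng: np.random.Generator,
    asc: AscertainmentScheme | None = None,
    mu_locus: float | None = None,
    time_cap: float = DEFAULT_TIME_CAP,
) -> ExpectedSFS:
    """Estimate the expected (joint) SFS from Z coalescent simulations.

    Parameters
    ----------
    mu_locus
        Per-locus mutation rate (mu per bp per generation times locus length
        in bp). When given, the monomorphic probability p0 is estimated as
        the Monte-Carlo mean of exp(-mu_locus * T_k) (Poisson zero class,
        always from the full tree lengths).
    """
    if Z < 1:
        raise ValueError("Z must be >= 1")
    arrays = _kernels.demography_arrays(d)
    (nsam, sizes, growths, migs, rowsum, ev_time, ev_src, ev_snk, ev_prop,
     ev_nsize, ev_ngrow, ev_mig, strides, nclasses) = arrays
    asc_deme = _check_asc(d, asc)
    accum, asc_accum, T_arr, Tasc_sum, status = _kernels.expected_sfs_kernel(
        Z, _kernel_seed(rng), nsam, sizes, growths, migs, rowsum,
        ev_time, ev_src, ev_snk, ev_prop, ev_nsize, ev_ngrow, ev_mig,
        strides, nclasses, asc_deme, time_cap,
    )
    _raise_status(status, time_cap)
    num = asc_accum if asc_deme >= 0 else accum
    den = Tasc_sum if asc_deme >= 0 else float(T_arr.sum())
    probs = num / den
    p0 = None
    if mu_locus is not None:
        p0 = estimate_p0(T_arr, mu_locus, 1.0)
    return ExpectedSFS(
        sample_sizes=tuple(int(n) for n in d.sample_sizes),
        probs=probs,
        Z=Z,
        p0=p0,
        mean_T=float(T_arr.mean()),
    )


def _raise_status(status: int, time_cap: float) -> None:
    if status == _kernels.STUCK:
        raise RuntimeError(
            "simulation stuck: no coalescence or migration possible and no "
            "events left; model is not closable"
        )
    if status == _kernels.TIME_CAP:
        raise RuntimeError(f"simulation exceeded time cap {time_cap:g} generations")


def estimate_expected_pairwise(
    d: Demography,
    Z: int,
    rng: np.random.Generator,
    asc: AscertainmentScheme | None = None,
    time_cap: float = DEFAULT_TIME_CAP,
) -> dict[tuple[int, int], ExpectedSFS]:
    """Expected 2-D marginal spectra for every sampled deme pair.

    Used for the pairwise-product composite likelihood when the model has
    many demes and the dense joint spectrum is impractical. Each pair is
    estimated from its own Z simulations.
    """
    sampled = [k for k in range(d.num_pops) if d.sample_sizes[k] >= 1]
    pairs = [p for p in itertools.combinations(sampled, 2)]
    if not pairs:
        raise ValueError("need at least two sampled demes")
    arrays = _kernels.demography_arrays(d)
    (nsam, sizes, growths, migs, rowsum, ev_time, ev_src, ev_snk, ev_prop,
     ev_nsize, ev_ngrow, ev_mig, _strides, _nc) = arrays
    asc_deme = _check_asc(d, asc)
    out: dict[tuple[int, int], ExpectedSFS] = {}
    for (i, j) in pairs:
        strides, nclasses = _kernels.pair_strides(d, i, j)
        accum, asc_accum, T_arr, Tasc_sum, status = _kernels.expected_sfs_kernel(
            Z, _kernel_seed(rng), nsam, sizes, growths, migs, rowsum,
            ev_time, ev_src, ev_snk, ev_prop, ev_nsize, ev_ngrow, ev_mig,
            strides, nclasses, asc_deme, time_cap,
        )
        _raise_status(status, time_cap)
        num = asc_accum if asc_deme >= 0 else accum
        den = Tasc_sum if asc_deme >= 0 else float(T_arr.sum())
        out[(i, j)] = ExpectedSFS(
            sample_sizes=(int(d.sample_sizes[i]), int(d.sample_sizes[j])),
            probs=num / den,
            Z=Z,
            mean_T=float(T_arr.mean()),
        )
    return out


def simulate_observed_sfs(
    d: Demography,
    num_loci: int,
    locus_length: float,
    mu: float,
    rng: np.random.Generator,
    asc: AscertainmentScheme | None = None,
    time_cap: float = DEFAULT_TIME_CAP,
) -> ObservedSFS:
    """Simulate a pseudo-observed SFS from unlinked non-recombining loci.

    Each locus gets an independent genealogy; mutations are dropped under the
    infinite-sites model at rate ``mu`` per bp per generation and tabulated
    by joint frequency class. With ascertainment only sites heterozygous
    between the two ascertainment lineages are kept, and the total surveyed
    length is not meaningful (``L=None``), as on a SNP chip.
    """
    if num_loci < 1:
        raise ValueError("num_loci must be >= 1")
    arrays = _kernels.demography_arrays(d)
    (nsam, sizes, growths, migs, rowsum, ev_time, ev_src, ev_snk, ev_prop,
     ev_nsize, ev_ngrow, ev_mig, strides, nclasses) = arrays
    asc_deme = _check_asc(d, asc)
    counts, status = _kernels.pseudo_data_kernel(
        num_loci, mu * locus_length, _kernel_seed(rng), nsam, sizes, growths,
        migs, rowsum, ev_time, ev_src, ev_snk, ev_prop, ev_nsize, ev_ngrow,
        ev_mig, strides, nclasses, asc_deme, time_cap,
    )
    _raise_status(status, time_cap)
    return ObservedSFS(
        sample_sizes=tuple(int(n) for n in d.sample_sizes),
        counts=counts,
        L=None if asc is not None else float(num_loci) * float(locus_length),
    )


def estimate_p0(total_lengths: np.ndarray, mu: float, L: float = 1.0) -> float:
    """Monte-Carlo probability that a locus of length L carries no mutation.

    p0_hat = (1/Z) sum_k exp(-mu L T_k): the Poisson zero class averaged over
    the tree-length distribution (unbiased, unlike exp(-mu L mean(T))).
    """
    if mu < 0 or L < 1:
        raise ValueError("need mu >= 0 and L >= 1")
    total_lengths = np.asarray(total_lengths, dtype=float)
    if total_lengths.size < 1:
        raise ValueError("need at least one simulated tree length")
    return float(np.exp(-mu * L * total_lengths).mean())


def marginal_pair(obs: ObservedSFS, i: int, j: int) -> ObservedSFS:
    """Project a multi-D observed SFS onto the (i, j) deme pair.

    Sites monomorphic within the pair land in the pair's absorbing corners
    and are ignored by the pairwise likelihood.
    """
    axes = tuple(k for k in range(obs.num_demes) if k not in (i, j))
    counts = obs.counts.sum(axis=axes)
    if i > j:
        counts = counts.T
    return ObservedSFS(
        sample_sizes=(obs.sample_sizes[i], obs.sample_sizes[j]),
        counts=counts,
        L=obs.L,
    )


@dataclass
class CollapsedPair:
    """Observed counts and expected probabilities after pooling all entries
    whose observed count falls below the collapsing threshold epsilon.

    ``counts``/``probs`` list the kept classes; when any entry was pooled the
    last element is the pooled class. Totals are conserved.
    """

    counts: np.ndarray
    probs: np.ndarray
    kept_index: np.ndarray  # flat indices of kept classes, -1 for the pooled class
    num_pooled: int = 0

    @property
    def num_classes(self) -> int:
        return len(self.counts)


def collapse_entries(
    counts, probs, epsilon: float
) -> CollapsedPair:
    """Pool all classes with observed count < epsilon into a single class.

    Accepts either an (ObservedSFS, ExpectedSFS) pair — collapsed over their
    matched non-absorbing entries — or two matched 1-D vectors. Conserves
    both the total count and probability mass.
    """
    if isinstance(counts, ObservedSFS):
        if not isinstance(probs, ExpectedSFS):
            raise ValueError("expected an ExpectedSFS alongside the ObservedSFS")
        counts, probs = nonabsorbing(counts, probs)
    counts = np.asarray(counts)
    probs = np.asarray(probs, dtype=float)
    if counts.shape != probs.shape:
        raise ValueError(f"dims mismatch: {counts.shape} vs {probs.shape}")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    low = counts < epsilon
    if epsilon <= 0 or not low.any():
        return CollapsedPair(
            counts=counts.copy(), probs=probs.copy(),
            kept_index=np.arange(len(counts)), num_pooled=0,
        )
    keep = ~low
    return CollapsedPair(
        counts=np.append(counts[keep], counts[low].sum()),
        probs=np.append(probs[keep], probs[low].sum()),
        kept_index=np.append(np.nonzero(keep)[0], -1),
        num_pooled=int(low.sum()),
    )


def nonabsorbing(
    obs: ObservedSFS, exp: ExpectedSFS
) -> tuple[np.ndarray, np.ndarray]:
    """Matched flat vectors of counts and probabilities over the
    non-absorbing entries of an observed/expected pair."""
    if obs.shape != exp.shape:
        raise ValueError(f"dims mismatch: obs {obs.shape} vs exp {exp.shape}")
    mask = ~obs.mask
    return obs.counts[mask], exp.probs[mask]
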