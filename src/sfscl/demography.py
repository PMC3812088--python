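"""Multi-population demographic models and parameter spaces.

A :class:`Demography` describes the backward-time structured coalescent a
genealogy is simulated under: per-deme effective sizes (diploid individuals),
exponential growth rates (forward-time sign convention, so a positive rate
means the deme was smaller in the past), backward per-lineage migration rates,
and a time-ordered list of :class:`HistoricalEvent` (divergences, admixture
pulses, bottleneck boundaries, size/growth/migration changes).

A :class:`ParameterSpace` holds the named free and fixed parameters of a model
together with their search bounds and scales, optional derived-parameter
expressions, and a *binder* that maps a full parameter dictionary to a
concrete :class:`Demography`.
"""

from __future__ import annotations

import ast
import math
import operator
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Demography",
    "HistoricalEvent",
    "Parameter",
    "ParameterSpace",
    "validate_demography",
    "bind_parameters",
    "sample_initial_parameters",
]


@dataclass
class HistoricalEvent:
    """A demographic event at a fixed time in the past.

    Parameters
    ----------
    time
        Generations before present.
    source, sink
        Deme indices. Going backward in time, each lineage currently in
        ``source`` moves to ``sink`` independently with probability
        ``proportion`` (1.0 = full fusion of source into sink).
    new_size
        If given, the sink deme's size (diploid) is reset to this value at the
        event time (re-anchoring any exponential growth).
    new_growth
        If given, the sink deme's growth rate is reset.
    migration_matrix
        If given, index of the migration matrix active past this event.
    """

    time: float
    source: int = 0
    sink: int = 0
    proportion: float = 1.0
    new_size: float | None = None
    new_growth: float | None = None
    migration_matrix: int | None = None


@dataclass
class Demography:
    """A multi-deme demographic model plus a sampling configuration.

    ``sizes`` are *diploid* effective sizes; the pairwise coalescence rate
    within a deme of size N is 1/(2N) per generation. ``migration_matrices``
    use the backward convention: entry ``[k][j]`` is the per-generation rate
    at which a lineage currently in deme k moves to deme j, looking back in
    time. ``sample_sizes`` count haploid gene copies per deme.
    """

    sizes: Sequence[float]
    sample_sizes: Sequence[int]
    growth_rates: Sequence[float] | None = None
    migration_matrices: Sequence[np.ndarray] | None = None
    events: Sequence[HistoricalEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=int)
        v = self.num_pops
        if self.growth_rates is None:
            self.growth_rates = np.zeros(v)
        else:
            self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        if self.migration_matrices is None:
            self.migration_matrices = [np.zeros((v, v))]
        else:
            self.migration_matrices = [
                np.asarray(m, dtype=float) for m in self.migration_matrices
            ]
        self.events = sorted(self.events, key=lambda e: e.time)

    @property
    def num_pops(self) -> int:
        return len(self.sizes)

    @property
    def total_samples(self) -> int:
        return int(np.sum(self.sample_sizes))


def validate_demography(d: Demography) -> list[str]:
    """Return a list of violations; an empty list means the model is valid.

    Besides range checks this verifies the model is *closable*: tracing events
    backward, all sampled lineages must be able to reach a common deme, so
    that the grand MRCA exists with probability one.
    """
    issues: list[str] = []
    v = d.num_pops
    if np.any(d.sizes <= 0):
        issues.append("all deme sizes must be > 0")
    if np.any(d.sample_sizes < 0):
        issues.append("sample sizes must be >= 0")
    if d.total_samples < 2:
        issues.append("total sample size must be >= 2")
    for i, m in enumerate(d.migration_matrices):
        if m.shape != (v, v):
            issues.append(f"migration matrix {i} is not {v}x{v}")
            continue
        if np.any(m < 0):
            issues.append(f"migration matrix {i} has negative rates")
    times = [e.time for e in d.events]
    if any(t < 0 for t in times):
        issues.append("event times must be >= 0")
    for i, e in enumerate(d.events):
        if not 0.0 <= e.proportion <= 1.0:
            issues.append(f"event {i}: proportion {e.proportion} out of range [0, 1]")
        if not (0 <= e.source < v and 0 <= e.sink < v):
            issues.append(f"event {i}: deme index out of range")
        if e.new_size is not None and e.new_size <= 0:
            issues.append(f"event {i}: new_size must be > 0")
        if e.migration_matrix is not None and not (
            0 <= e.migration_matrix < len(d.migration_matrices)
        ):
            issues.append(f"event {i}: unknown migration matrix {e.migration_matrix}")
    if not issues and not _closable(d):
        issues.append("non-closable: lineages can never reach a common deme")
    return issues


def _reach_closure(occupied: set[int], mig: np.ndarray) -> set[int]:
    out = set(occupied)
    frontier = list(occupied)
    while frontier:
        k = frontier.pop()
        for j in np.nonzero(mig[k] > 0)[0]:
            if int(j) not in out:
                out.add(int(j))
                frontier.append(int(j))
    return out


def _closable(d: Demography) -> bool:
    # Track the set of demes that may still hold lineages, expanding it along
    # positive migration rates and event moves; after the last event every
    # occupied deme must be able to reach some common deme.
    occupied = {int(k) for k in np.nonzero(d.sample_sizes > 0)[0]}
    mig_id = 0
    for e in d.events:
        occupied = _reach_closure(occupied, d.migration_matrices[mig_id])
        if e.source in occupied and e.proportion > 0:
            occupied.add(e.sink)
            if e.proportion >= 1.0:
                # a later closure re-adds the source if migration refills it
                occupied.discard(e.source)
        if e.migration_matrix is not None:
            mig_id = e.migration_matrix
    mig = d.migration_matrices[mig_id]
    reach = [_reach_closure({k}, mig) for k in occupied]
    common = set.intersection(*reach) if reach else set()
    return bool(common)


# ---------------------------------------------------------------------------
# Parameter spaces


_KINDS = ("size", "time", "rate", "proportion")


@dataclass
class Parameter:
    """One named model parameter, free (with bounds) or fixed."""

    name: str
    kind: str = "size"
    lo: float | None = None
    hi: float | None = None
    scale: str = "log10"
    value: float | None = None  # set -> fixed

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "proportion":
            self.scale = "linear"
        if self.free:
            if self.lo is None or self.hi is None:
                raise ValueError(f"free parameter {self.name!r} needs bounds")
            if not self.lo <= self.hi:
                raise ValueError(f"parameter {self.name!r}: lo > hi")
            if self.kind == "proportion" and not (0 <= self.lo and self.hi <= 1):
                raise ValueError(f"proportion {self.name!r} must be within [0, 1]")
            if self.scale == "log10" and self.lo <= 0:
                raise ValueError(f"log10 parameter {self.name!r} needs lo > 0")

    @property
    def free(self) -> bool:
        return self.value is None


_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
}
_CALLS = {"min": min, "max": max}


def _eval_expr(expr: str, env: Mapping[str, float]) -> float:
    """Evaluate a restricted arithmetic expression (+, -, *, /, min, max)."""

    def ev(node: ast.AST) -> float:
        if isinstance(node, ast.Expression):
            return ev(node.body)
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            return float(node.value)
        if isinstance(node, ast.Name):
            if node.id not in env:
                raise KeyError(f"unknown name {node.id!r} in expression {expr!r}")
            return float(env[node.id])
        if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
            return _BINOPS[type(node.op)](ev(node.left), ev(node.right))
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            return -ev(node.operand)
        if (
            isinstance(node, ast.Call)
            and isinstance(node.func, ast.Name)
            and node.func.id in _CALLS
        ):
            return _CALLS[node.func.id](*(ev(a) for a in node.args))
        raise ValueError(f"unsupported syntax in expression {expr!r}")

    return ev(ast.parse(expr, mode="eval"))


def _expr_names(expr: str) -> set[str]:
    return {
        n.id
        for n in ast.walk(ast.parse(expr, mode="eval"))
        if isinstance(n, ast.Name) and n.id not in _CALLS
    }


@dataclass
class ParameterSpace:
    """Named parameters, derived expressions and a binding rule.

    ``builder`` receives a mapping of every parameter name (free, fixed and
    derived) to its numeric value and must return a :class:`Demography`.
    """

    parameters: Sequence[Parameter]
    builder: Callable[[Mapping[str, float]], Demography]
    derived: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        self._check_derived_acyclic()

    def _check_derived_acyclic(self) -> None:
        base = {p.name for p in self.parameters}
        order: list[str] = []
        remaining = dict(self.derived)
        known = set(base)
        while remaining:
            ready = [
                n for n, e in remaining.items() if _expr_names(e) <= known
            ]
            if not ready:
                raise ValueError(
                    f"cyclic or unresolvable derived parameters: {sorted(remaining)}"
                )
            for n in ready:
                known.add(n)
                order.append(n)
                del remaining[n]
        self._derived_order = order

    @property
    def free_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters if p.free]

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self.free_parameters]

    @property
    def num_free(self) -> int:
        return len(self.free_parameters)

    def full_params(self, theta: Sequence[float]) -> dict[str, float]:
        """Expand a free-parameter vector into the full named mapping."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.num_free,):
            raise ValueError(
                f"theta has length {theta.size}, expected {self.num_free}"
            )
        env: dict[str, float] = {}
        it = iter(theta)
        for p in self.parameters:
            x = next(it) if p.free else p.value
            if p.free and not (p.lo <= x <= p.hi):
                raise ValueError(
                    f"parameter {p.name!r} = {x} outside bounds [{p.lo}, {p.hi}]"
                )
            if p.kind in ("size", "time"):
                x = max(1.0, round(x))
            env[p.name] = float(x)
        for name in self._derived_order:
            env[name] = _eval_expr(self.derived[name], env)
        return env


def bind_parameters(space: ParameterSpace, theta: Sequence[float]) -> Demography:
    """Map a free-parameter vector to a concrete, validated Demography.

    Size and time parameters are rounded to the nearest integer >= 1 before
    binding; the likelihood is evaluated on the rounded values.
    """
    d = space.builder(space.full_params(theta))
    issues = validate_demography(d)
    if issues:
        raise ValueError("bound demography invalid: " + "; ".join(issues))
    return d


def sample_initial_parameters(
    space: ParameterSpace, rng: np.random.Generator
) -> np.ndarray:
    """Draw a random in-bounds starting vector for the free parameters.

    Uniform on [lo, hi] for linear-scale parameters; uniform on
    [log10 lo, log10 hi] for log10-scale parameters (search ranges commonly
    span several orders of magnitude).
    """
    out = np.empty(space.num_free)
    for i, p in enumerate(space.free_parameters):
        if p.scale == "log10":
            out[i] = 10.0 ** rng.uniform(math.log10(p.lo), math.log10(p.hi))
        else:
            out[i] = rng.uniform(p.lo, p.hi)
    return out
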