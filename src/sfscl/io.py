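"""Readers and writers for observed-SFS files and model configuration files.

Observed-SFS text dialects (one observation block per file):

* 1-D: line 1 ``1 observations``, line 2 a header ``d0_0 .. d0_n``, line 3
  the n+1 counts, tab-separated.
* 2-D: line 1 ``1 observations``, a header row of ``d0_i`` labels (columns =
  deme 0), then n1+1 rows labelled ``d1_j`` (rows = deme 1) with counts.
* Multi-D: line 1 ``1 observations``, line 2 the dims ``n1+1 n2+1 ..``, then
  all prod(n_k+1) counts in lexicographic order with the last deme's index
  varying fastest.

When the number of monomorphic sites is known it sits in the all-ancestral
cell, so the file total equals the surveyed length L in bp.

The model config is a sectioned text format: ``[populations]`` (id, size,
growth, sample_size per deme), ``[migration]`` (labelled matrices),
``[events]`` (time source sink proportion new_size new_growth matrix, ``.``
for "unchanged"), ``[parameters]`` (name kind lo hi scale free|fixed=value)
and ``[derived]`` (name = expression). Any numeric field in populations,
migration or events may be a parameter name or arithmetic expression. Times
are in generations, rates per generation, sizes in diploid individuals.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .demography import (
    Demography,
    HistoricalEvent,
    Parameter,
    ParameterSpace,
    _eval_expr,
)
from .sfs import ObservedSFS

__all__ = [
    "read_observed_sfs",
    "write_observed_sfs",
    "parse_model_config",
]


class ParseError(ValueError):
    def __init__(self, path, lineno: int | None, msg: str) -> None:
        where = f"{path}:{lineno}" if lineno else str(path)
        super().__init__(f"{where}: {msg}")


# ---------------------------------------------------------------------------
# Observed SFS


def _materialized_counts(obs: ObservedSFS) -> np.ndarray:
    counts = obs.counts.copy()
    if obs.L is not None:
        corner = (0,) * obs.num_demes
        other = tuple(n for n in obs.sample_sizes)
        counts[corner] = int(obs.L) - obs.S - int(counts[other])
    return counts


def write_observed_sfs(obs: ObservedSFS, path) -> None:
    counts = _materialized_counts(obs)
    lines = ["1 observations"]
    if obs.num_demes == 1:
        n = obs.sample_sizes[0]
        lines.append("\t".join(f"d0_{i}" for i in range(n + 1)))
        lines.append("\t".join(str(int(c)) for c in counts))
    elif obs.num_demes == 2:
        n0, n1 = obs.sample_sizes
        lines.append("\t".join(f"d0_{i}" for i in range(n0 + 1)))
        for j in range(n1 + 1):
            row = "\t".join(str(int(counts[i, j])) for i in range(n0 + 1))
            lines.append(f"d1_{j}\t{row}")
    else:
        lines.append("\t".join(str(s) for s in counts.shape))
        lines.append("\t".join(str(int(c)) for c in counts.ravel()))
    Path(path).write_text("\n".join(lines) + "\n")


def read_observed_sfs(
    path, expected_dims: Sequence[int] | None = None
) -> ObservedSFS:
    """Parse an observed SFS file, auto-detecting the dialect.

    ``expected_dims`` (per-deme sample sizes) is validated against the file
    when given. If the all-ancestral cell is non-zero the file is taken to
    include monomorphic sites and L is set to the file total.
    """
    raw = Path(path).read_text().splitlines()
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(raw)
             if ln.strip() and not ln.strip().startswith("#")]
    if not lines or "observations" not in lines[0][1]:
        raise ParseError(path, lines[0][0] if lines else 1,
                         "expected '1 observations' header")
    lineno, second = lines[1]
    toks = second.split()
    if toks[0].startswith("d0_"):
        n0 = len(toks) - 1
        if len(lines) >= 3 and lines[2][1].split()[0].startswith("d1_"):
            rows = lines[2:]
            n1 = len(rows) - 1
            counts = np.zeros((n0 + 1, n1 + 1), dtype=np.int64)
            for j, (ln_no, ln) in enumerate(rows):
                parts = ln.split()
                if parts[0] != f"d1_{j}":
                    raise ParseError(path, ln_no, f"expected row label d1_{j}, got {parts[0]}")
                if len(parts) != n0 + 2:
                    raise ParseError(path, ln_no,
                                     f"expected {n0 + 1} counts, got {len(parts) - 1}")
                counts[:, j] = [int(float(x)) for x in parts[1:]]
            dims = (n0, n1)
        else:
            ln_no, ln = lines[2]
            vals = ln.split()
            if len(vals) != n0 + 1:
                raise ParseError(path, ln_no,
                                 f"expected {n0 + 1} counts, got {len(vals)}")
            counts = np.array([int(float(x)) for x in vals], dtype=np.int64)
            dims = (n0,)
    else:
        try:
            shape = tuple(int(x) for x in toks)
        except ValueError:
            raise ParseError(path, lineno, f"cannot parse dims line {second!r}")
        flat: list[int] = []
        for ln_no, ln in lines[2:]:
            flat.extend(int(float(x)) for x in ln.split())
        expected = int(np.prod(shape))
        if len(flat) != expected:
            raise ParseError(path, lines[-1][0],
                             f"expected {expected} counts, got {len(flat)}")
        counts = np.array(flat, dtype=np.int64).reshape(shape)
        dims = tuple(s - 1 for s in shape)
    if expected_dims is not None and tuple(expected_dims) != dims:
        raise ParseError(
            path, None,
            f"sample sizes in file {dims} do not match model {tuple(expected_dims)}",
        )
    corner = (0,) * len(dims)
    L = None
    if counts[corner] > 0:
        L = float(counts.sum())
    return ObservedSFS(sample_sizes=dims, counts=counts, L=L)


# ---------------------------------------------------------------------------
# Model config


def _split_sections(path) -> dict[str, list[tuple[int, str]]]:
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip().lower()
            sections.setdefault(current, [])
            continue
        if current is None:
            raise ParseError(path, i, f"content before any [section]: {line!r}")
        sections[current].append((i, line))
    return sections


def _opt(tok: str) -> str | None:
    return None if tok == "." else tok


def parse_model_config(path) -> ParameterSpace:
    """Parse a model config file into a ParameterSpace.

    The returned space's binder substitutes a parameter dictionary into the
    population, migration and event templates; a model with no free
    parameters binds to its fixed demography with ``theta=[]``.
    """
    sections = _split_sections(path)
    if "populations" not in sections:
        raise ParseError(path, None, "missing [populations] section")

    pops: list[tuple[str, str, int]] = []  # (size, growth, sample) expressions
    for ln_no, line in sections["populations"]:
        toks = line.split()
        if len(toks) != 4:
            raise ParseError(path, ln_no,
                             "populations row needs: id size growth sample_size")
        idx = int(toks[0])
        if idx != len(pops):
            raise ParseError(path, ln_no,
                             f"population ids must be consecutive; got {idx}")
        pops.append((toks[1], toks[2], int(toks[3])))
    v = len(pops)

    matrices: list[list[list[str]]] = []
    rows_seen: list[list[str]] = []
    for ln_no, line in sections.get("migration", []):
        toks = line.split()
        if toks[0].lower() == "matrix":
            if rows_seen:
                matrices.append(rows_seen)
                rows_seen = []
            continue
        if len(toks) != v:
            raise ParseError(path, ln_no, f"migration row needs {v} entries")
        rows_seen.append(toks)
    if rows_seen:
        matrices.append(rows_seen)
    for m in matrices:
        if len(m) != v:
            raise ParseError(path, None, f"migration matrix needs {v} rows")

    events: list[tuple] = []
    for ln_no, line in sections.get("events", []):
        toks = line.split()
        if len(toks) != 7:
            raise ParseError(
                path, ln_no,
                "events row needs: time source sink proportion new_size new_growth matrix",
            )
        events.append(tuple(toks))

    params: list[Parameter] = []
    for ln_no, line in sections.get("parameters", []):
        toks = line.split()
        if len(toks) != 6:
            raise ParseError(
                path, ln_no,
                "parameters row needs: name kind lo hi scale free|fixed=value",
            )
        name, kind, lo, hi, scale, status = toks
        try:
            if status == "free":
                if _opt(lo) is None or _opt(hi) is None:
                    raise ValueError(f"free parameter {name!r} needs bounds")
                params.append(
                    Parameter(name, kind, float(lo), float(hi),
                              scale if _opt(scale) else "log10")
                )
            elif status.startswith("fixed="):
                params.append(Parameter(name, kind, value=float(status[6:])))
            else:
                raise ValueError(f"status must be 'free' or 'fixed=VALUE', got {status!r}")
        except ValueError as exc:
            raise ParseError(path, ln_no, str(exc)) from None

    derived: dict[str, str] = {}
    for ln_no, line in sections.get("derived", []):
        if "=" not in line:
            raise ParseError(path, ln_no, "derived row needs: name = expression")
        name, expr = line.split("=", 1)
        derived[name.strip()] = expr.strip()

    def build(env: Mapping[str, float]) -> Demography:
        def ev(expr: str) -> float:
            return _eval_expr(expr, env)

        sizes = [ev(s) for s, _, _ in pops]
        growths = [ev(g) for _, g, _ in pops]
        samples = [s for _, _, s in pops]
        migs = [
            np.array([[ev(x) for x in row] for row in m]) for m in matrices
        ] or None
        evs = []
        for (t, src, snk, prop, nsize, ngrow, mid) in events:
            evs.append(
                HistoricalEvent(
                    time=ev(t),
                    source=int(ev(src)),
                    sink=int(ev(snk)),
                    proportion=ev(prop) if _opt(prop) else 1.0,
                    new_size=ev(nsize) if _opt(nsize) else None,
                    new_growth=ev(ngrow) if _opt(ngrow) else None,
                    migration_matrix=int(ev(mid)) if _opt(mid) else None,
                )
            )
        return Demography(
            sizes=sizes,
            growth_rates=growths,
            sample_sizes=samples,
            migration_matrices=migs,
            events=evs,
        )

    try:
        return ParameterSpace(parameters=params, builder=build, derived=derived)
    except ValueError as exc:
        raise ParseError(path, None, str(exc)) from None
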