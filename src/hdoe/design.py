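"""D-optimal experimental designs over normalized factor grids.

Designs are pandas DataFrames with one column per factor (``x1`` .. ``xk``)
plus optional bookkeeping columns (``uo``, ``run_type``, ``load``).  Model
terms are plain strings: ``"1"`` (intercept), ``"x2"`` (main effect),
``"x1:x3"`` (two-factor interaction, lower index first), ``"x2^2"``
(quadratic) and ``"load"`` (the carried-over pool of the upstream unit
operation).  The design criterion is the determinant of the information
matrix X'X; rows are selected from a candidate set by a Fedorov-style
single-row exchange with seeded multistart.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpace",
    "ModelSpec",
    "build_model_matrix",
    "candidate_set",
    "d_criterion",
    "d_optimal_augment",
]

DEFAULT_LEVELS = (-1.0, 0.0, 1.0)


@dataclass(frozen=True)
class FactorSpace:
    """Normalized factor space of one unit operation.

    Parameters are coded so the setpoint is 0 and the screening range is
    [-1, +1].  ``has_load`` marks downstream unit operations whose input
    material (load) acts as an additional, continuous pseudo-factor.
    """

    names: tuple[str, ...]
    levels: dict[str, tuple[float, ...]] = field(default_factory=dict)
    setpoint: dict[str, float] = field(default_factory=dict)
    has_load: bool = False

    def __post_init__(self):
        if len(self.names) < 1:
            raise ValueError("a factor space needs at least one factor")
        for name in self.names:
            lv = self.levels_of(name)
            if len(lv) < 2:
                raise ValueError(f"factor {name!r} needs >= 2 levels")
            sp = self.setpoint_of(name)
            if not (min(lv) <= sp <= max(lv)):
                raise ValueError(f"setpoint of {name!r} outside level range")

    @classmethod
    def regular(cls, k: int, levels: tuple[float, ...] = DEFAULT_LEVELS,
                has_load: bool = False) -> "FactorSpace":
        names = tuple(f"x{i + 1}" for i in range(k))
        return cls(names=names, levels={n: tuple(levels) for n in names},
                   has_load=has_load)

    def levels_of(self, name: str) -> tuple[float, ...]:
        return tuple(self.levels.get(name, DEFAULT_LEVELS))

    def setpoint_of(self, name: str) -> float:
        return float(self.setpoint.get(name, 0.0))

    @property
    def k(self) -> int:
        return len(self.names)


class ModelSpec:
    """Ordered, duplicate-free list of regression terms.

    The intercept is always present (and always first).
    """

    def __init__(self, terms):
        terms = list(terms)
        if "1" not in terms:
            terms = ["1"] + terms
        if len(set(terms)) != len(terms):
            dupes = sorted({t for t in terms if terms.count(t) > 1})
            raise ValueError(f"duplicate terms in model spec: {dupes}")
        for t in terms:
            _parse_term(t)  # validates syntax
        # keep intercept first, otherwise preserve given order
        self.terms: tuple[str, ...] = tuple(
            ["1"] + [t for t in terms if t != "1"])

    @property
    def p(self) -> int:
        return len(self.terms)

    def factors(self) -> tuple[str, ...]:
        """Factor names referenced by any term (load excluded)."""
        out: list[str] = []
        for t in self.terms:
            for f in _parse_term(t)[1]:
                if f not in out:
                    out.append(f)
        return tuple(out)

    def has_load(self) -> bool:
        return "load" in self.terms

    def drop_load(self) -> "ModelSpec":
        return ModelSpec([t for t in self.terms if t != "load"])

    def __iter__(self):
        return iter(self.terms)

    def __contains__(self, term):
        return term in self.terms

    def __eq__(self, other):
        return isinstance(other, ModelSpec) and self.terms == other.terms

    def __repr__(self):
        return f"ModelSpec({list(self.terms)!r})"

    @classmethod
    def main_effects(cls, k: int, load: bool = False) -> "ModelSpec":
        terms = ["1"] + [f"x{i + 1}" for i in range(k)]
        if load:
            terms.append("load")
        return cls(terms)

    @classmethod
    def full_quadratic(cls, k: int, load: bool = False) -> "ModelSpec":
        """Intercept, k mains, k(k-1)/2 interactions, k quadratics (+ load).

        For k = 5 this is the 20-effect scope (plus intercept) used
        throughout the benchmark studies.
        """
        terms = ["1"] + [f"x{i + 1}" for i in range(k)]
        terms += [f"x{i + 1}:x{j + 1}"
                  for i in range(k) for j in range(i + 1, k)]
        terms += [f"x{i + 1}^2" for i in range(k)]
        if load:
            terms.append("load")
        return cls(terms)


def _parse_term(term: str):
    """Return (kind, factors) for a term string; raise on bad syntax."""
    if term == "1":
        return "intercept", ()
    if term == "load":
        return "load", ()
    if ":" in term:
        a, b = term.split(":")
        if not (a.startswith("x") and b.startswith("x")):
            raise ValueError(f"bad interaction term {term!r}")
        if int(a[1:]) >= int(b[1:]):
            raise ValueError(
                f"interaction {term!r} must list the lower factor first")
        return "interaction", (a, b)
    if term.endswith("^2"):
        return "quadratic", (term[:-2],)
    if term.startswith("x"):
        return "main", (term,)
    raise ValueError(f"unrecognized model term {term!r}")


def term_column(term: str, data: pd.DataFrame) -> np.ndarray:
    kind, facs = _parse_term(term)
    n = len(data)
    if kind == "intercept":
        return np.ones(n)
    if kind == "load":
        if "load" not in data.columns:
            raise KeyError("design has no 'load' column for the load term")
        return data["load"].to_numpy(float)
    for f in facs:
        if f not in data.columns:
            raise KeyError(f"unknown factor {f!r} in model spec")
    if kind == "main":
        return data[facs[0]].to_numpy(float)
    if kind == "interaction":
        return data[facs[0]].to_numpy(float) * data[facs[1]].to_numpy(float)
    # quadratic
    col = data[facs[0]].to_numpy(float)
    return col * col


def build_model_matrix(design: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """N x p model matrix in the spec's term order (intercept first)."""
    if len(design) == 0:
        raise ValueError("empty design")
    cols = [term_column(t, design) for t in spec]
    return np.column_stack(cols)


def candidate_set(space: FactorSpace, max_rows: int = 100_000) -> pd.DataFrame:
    """Full factorial candidate set: Cartesian product of factor levels.

    Rows are in lexicographic order of the level indices, so the set is
    deterministic; every row is unique.
    """
    n_rows = int(np.prod([len(space.levels_of(n)) for n in space.names]))
    if n_rows > max_rows:
        raise ValueError(
            f"candidate set would have {n_rows} rows (> cap {max_rows}); "
            "subsample the levels or raise max_rows")
    rows = itertools.product(*(space.levels_of(n) for n in space.names))
    return pd.DataFrame(rows, columns=list(space.names), dtype=float)


def d_criterion(model_matrix: np.ndarray) -> float:
    """|X'X|, the D-optimality criterion; 0 for rank-deficient matrices."""
    X = np.asarray(model_matrix, float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("model matrix must have at least one row")
    sign, logdet = np.linalg.slogdet(X.T @ X)
    if sign <= 0 or not np.isfinite(logdet):
        return 0.0
    return float(np.exp(logdet))


def _logdet_gram(G: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(G)
    return ld if sign > 0 else -np.inf


def best_augmentation_row(candidates: pd.DataFrame, spec: ModelSpec,
                          existing: pd.DataFrame,
                          rng: np.random.Generator | None = None) -> int:
    """Index of the single candidate row maximizing |X'X| after augmentation.

    Exhaustive over the candidate set.  Ties go to the lowest index unless
    an ``rng`` is given, in which case one of the tied rows is picked
    uniformly — important for degenerate scopes (e.g. intercept-only
    models), where every candidate ties and a deterministic tie-break
    would propose the same replicate run forever, providing no contrast
    for effect detection.
    """
    Xc = build_model_matrix(candidates, spec)
    Xe = build_model_matrix(existing, spec)
    G = Xe.T @ Xe
    base = _logdet_gram(G)
    if np.isfinite(base):
        # rank-one update: |G + xx'| = |G| (1 + x'G^-1 x)
        Ginv = np.linalg.inv(G)
        gains = 1.0 + np.einsum("ij,jk,ik->i", Xc, Ginv, Xc)
        scores = base + np.log(np.maximum(gains, 1e-300))
    else:
        scores = np.array([_logdet_gram(G + np.outer(x, x)) for x in Xc])
    top = scores.max()
    tied = np.flatnonzero(scores >= top - 1e-9 * max(abs(top), 1.0))
    if rng is None or len(tied) == 1:
        return int(tied[0])
    return int(tied[int(rng.integers(len(tied)))])


def d_optimal_augment(candidates: pd.DataFrame, spec: ModelSpec, n_new: int,
                      existing: pd.DataFrame | None = None, *,
                      seed: int | None = 0, restarts: int = 10,
                      max_sweeps: int = 100,
                      return_trace: bool = False):
    """Select ``n_new`` rows from ``candidates`` to D-optimally augment
    ``existing`` (which may be None/empty for a fresh design).

    Fedorov-style single-row exchange: starting from a random selection,
    repeatedly replace the selected row whose best exchange most increases
    |X'X| until no exchange improves it; the best of ``restarts`` seeded
    starts is returned.  Ties in exchange gains break toward the lowest
    candidate index, so the result is deterministic given the seed.
    Replicated candidate rows are allowed in the selection.
    """
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    fac_cols = [c for c in candidates.columns]
    if existing is None:
        existing = candidates.iloc[0:0]
    if n_new == 0:
        return (existing.copy(), []) if return_trace else existing.copy()

    Xc = build_model_matrix(candidates, spec)
    n_cand, p = Xc.shape
    if len(existing) + n_new < p:
        warnings.warn(
            f"{len(existing) + n_new} runs cannot support {p} terms; "
            "the D-criterion will be singular", stacklevel=2)
    Xe = (build_model_matrix(existing, spec) if len(existing)
          else np.empty((0, p)))
    Ge = Xe.T @ Xe
    if len(existing) + n_new < p:
        # |X'X| is identically zero for every selection; a tiny ridge keeps
        # the exchange ranking meaningful (it then spreads the rows the way
        # a Bayesian D-criterion with a vague prior would)
        Ge = Ge + 1e-6 * np.eye(p)

    rng = np.random.default_rng(seed)
    best_sel, best_ld = None, -np.inf
    best_trace: list[float] = []
    for _ in range(max(1, restarts)):
        if n_new <= n_cand:
            sel = list(rng.choice(n_cand, size=n_new, replace=False))
        else:
            sel = list(rng.choice(n_cand, size=n_new, replace=True))
        sel, ld, trace = _exchange(Xc, Ge, sel, max_sweeps)
        if best_sel is None or ld > best_ld:
            best_sel, best_ld, best_trace = sel, ld, trace

    new_rows = candidates.iloc[best_sel][fac_cols].reset_index(drop=True)
    out = pd.concat([existing[fac_cols] if len(existing) else existing,
                     new_rows], ignore_index=True)
    if return_trace:
        return out, best_trace
    return out


def _exchange(Xc, Ge, sel, max_sweeps):
    """Single-row exchange loop; returns (selection, logdet, criterion trace).

    The trace records |X'X| (determinant scale) after each accepted
    exchange; it is non-decreasing by construction.
    """
    n_cand = Xc.shape[0]
    G = Ge + Xc[sel].T @ Xc[sel]
    ld = _logdet_gram(G)
    trace = [float(np.exp(ld)) if np.isfinite(ld) else 0.0]
    for _ in range(max_sweeps):
        improved = False
        for pos in range(len(sel)):
            xi = Xc[sel[pos]]
            Gi = G - np.outer(xi, xi)
            ldi = _logdet_gram(Gi)
            if np.isfinite(ldi):
                Giinv = np.linalg.inv(Gi)
                gains = 1.0 + np.einsum("ij,jk,ik->i", Xc, Giinv, Xc)
                scores = ldi + np.log(np.maximum(gains, 1e-300))
            else:
                scores = np.fromiter(
                    (_logdet_gram(Gi + np.outer(x, x)) for x in Xc),
                    float, count=n_cand)
            j = int(np.argmax(scores))  # argmax takes the lowest index on ties
            # accept only a strict, non-trivial improvement
            if scores[j] > ld + 1e-10 and j != sel[pos]:
                G = Gi + np.outer(Xc[j], Xc[j])
                sel[pos] = j
                ld = scores[j]
                trace.append(float(np.exp(ld)) if np.isfinite(ld) else 0.0)
                improved = True
        if not improved:
            break
    return sel, ld, trace
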