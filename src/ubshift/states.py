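"""Discrete conformational-state model of an n-unit ubiquitin chain.

A chain of n units adopts states in which disjoint pairs of units shield
each other's hydrophobic patches; a state is therefore a *matching* on the
unit-contact graph (each unit closed in at most one contact), including the
empty matching where every unit is open.  For the triubiquitin chain with
all contacts allowed this gives exactly four states:

    A — no contacts (all units open)
    B — Ub2-Ub3 contact (Ub1 open)
    C — Ub1-Ub2 contact (Ub3 open)
    D — Ub1-Ub3 "end-to-end" contact (Ub2 open)

The 0/1 incidence matrix M (units x states, M[i,s] = 1 iff unit i is open
in state s) links state populations P to the per-unit open fractions f
measured by the dividing-ratio analysis:

    M P = f,   sum(P) = 1,   P >= 0.

For n = 3 with all contacts the augmented system is square and nonsingular,
giving the closed form P_A = (sum(f) - 1)/2; longer chains are
underdetermined and are handled by constrained least squares plus linear
programming feasibility bounds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

__all__ = [
    "ChainTopology",
    "StateSpace",
    "PopulationSolution",
    "enumerate_states",
    "forward_unit_fractions",
    "solve_populations",
    "feasibility_bounds",
    "bootstrap_populations",
    "StatePopulationSolver",
]

Pair = Tuple[int, int]


@dataclass(frozen=True)
class ChainTopology:
    """Topology of an n-unit chain.

    Units are numbered 1..n with unit 1 the distal end (free Lys48) and
    unit n the proximal end (free C-terminus).  ``allowed_contacts`` is the
    set of unit pairs that may form a closed contact; by default all pairs,
    which includes non-adjacent ("end-to-end") contacts.
    """

    n_units: int
    allowed_contacts: Optional[frozenset[Pair]] = None

    def __post_init__(self):
        if self.n_units < 2:
            raise ValueError(f"n_units must be >= 2, got {self.n_units}")
        if self.allowed_contacts is not None:
            norm = frozenset(tuple(sorted(p)) for p in self.allowed_contacts)
            for i, j in norm:
                if not (1 <= i < j <= self.n_units):
                    raise ValueError(f"invalid contact pair ({i}, {j})")
            object.__setattr__(self, "allowed_contacts", norm)

    @property
    def labels(self) -> List[str]:
        return [f"Ub{i}" for i in range(1, self.n_units + 1)]

    def contacts(self) -> List[Pair]:
        if self.allowed_contacts is None:
            return list(itertools.combinations(range(1, self.n_units + 1), 2))
        return sorted(self.allowed_contacts)


def _matchings(pairs: Sequence[Pair]) -> List[frozenset[Pair]]:
    """All matchings (sets of pairwise-disjoint pairs), incl. the empty one."""
    out: List[frozenset[Pair]] = []

    def extend(start: int, used: set[int], current: List[Pair]) -> None:
        out.append(frozenset(current))
        for k in range(start, len(pairs)):
            i, j = pairs[k]
            if i in used or j in used:
                continue
            current.append(pairs[k])
            used |= {i, j}
            extend(k + 1, used, current)
            used -= {i, j}
            current.pop()

    extend(0, set(), [])
    return out


# Fig.-style canonical order for the 3-unit, all-contacts chain.
_TRIUB_ORDER = [frozenset(), frozenset({(2, 3)}), frozenset({(1, 2)}), frozenset({(1, 3)})]
_TRIUB_LABELS = ["A", "B", "C", "D"]


@dataclass
class StateSpace:
    """Enumerated states of a chain with their unit-openness incidence matrix."""

    topology: ChainTopology
    states: List[frozenset[Pair]]
    state_labels: List[str]
    open_matrix: np.ndarray  # (n_units, n_states), 0/1

    @property
    def n_states(self) -> int:
        return len(self.states)

    def describe(self) -> pd.DataFrame:
        rows = []
        for lbl, st, col in zip(self.state_labels, self.states, self.open_matrix.T):
            contacts = ", ".join(f"Ub{i}-Ub{j}" for i, j in sorted(st)) or "none"
            open_units = ", ".join(
                f"Ub{i+1}" for i in range(self.topology.n_units) if col[i]
            ) or "none"
            rows.append({"state": lbl, "contacts": contacts, "open_units": open_units})
        return pd.DataFrame(rows)


def enumerate_states(topology: ChainTopology) -> StateSpace:
    """Enumerate all matchings of the contact graph as conformational states.

    States are ordered by number of contacts, then lexicographically, except
    for the 3-unit all-contacts chain where the conventional A-D order is
    used (A all-open, B = Ub2-Ub3, C = Ub1-Ub2, D = Ub1-Ub3).
    """
    n = topology.n_units
    matchings = _matchings(topology.contacts())
    is_triub_full = n == 3 and set(matchings) == set(_TRIUB_ORDER)
    if is_triub_full:
        states = list(_TRIUB_ORDER)
        labels = list(_TRIUB_LABELS)
    else:
        states = sorted(matchings, key=lambda m: (len(m), sorted(m)))
        labels = [f"S{k}" for k in range(len(states))]
    M = np.ones((n, len(states)), dtype=float)
    for s, st in enumerate(states):
        for i, j in st:
            M[i - 1, s] = 0.0
            M[j - 1, s] = 0.0
    return StateSpace(topology=topology, states=states, state_labels=labels, open_matrix=M)


def forward_unit_fractions(ss: StateSpace, populations: Sequence[float]) -> np.ndarray:
    """Per-unit open fractions implied by state populations: f = M P."""
    P = np.asarray(populations, dtype=float)
    if P.shape != (ss.n_states,):
        raise ValueError(
            f"expected {ss.n_states} populations, got shape {P.shape}"
        )
    if np.any(P < -1e-12) or abs(P.sum() - 1.0) > 1e-8:
        raise ValueError("populations must be nonnegative and sum to 1")
    return ss.open_matrix @ P


@dataclass
class PopulationSolution:
    """Result of inverting per-unit open fractions into state populations."""

    populations: np.ndarray
    state_labels: List[str]
    method: str  # "exact" or "nnls"
    residual: float
    feasible: bool
    bounds: Optional[List[Tuple[float, float]]] = None

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.state_labels, self.populations))

    def percentages(self) -> Dict[str, int]:
        """Populations rounded to integer percent (report convention)."""
        return {lbl: int(round(100 * p)) for lbl, p in self.as_dict().items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (lbl, p) in enumerate(zip(self.state_labels, self.populations)):
            row = {
                "state_label": lbl,
                "population": p,
                "pct_rounded": int(round(100 * p)),
                "feasible": self.feasible,
            }
            if self.bounds is not None:
                row["bound_min"], row["bound_max"] = self.bounds[k]
            rows.append(row)
        return pd.DataFrame(rows)


def solve_populations(
    ss: StateSpace,
    fractions: Sequence[float],
    method: str = "auto",
) -> PopulationSolution:
    """Invert per-unit open fractions into state populations.

    Solves ``M P = f`` subject to ``sum(P) = 1``.

    * ``exact`` — requires the augmented system [M; 1] to be square and
      nonsingular (true for the 3-unit all-contacts chain); solves it
      directly.  Negative components are reported as-is with
      ``feasible=False``, never clipped.
    * ``nnls`` — nonnegative least squares on ``M P = f`` with the
      normalization as a hard equality constraint; residual reported.
    * ``auto`` — exact when available, else nnls.
    """
    f = np.asarray(fractions, dtype=float)
    n, k = ss.open_matrix.shape
    if f.shape != (n,):
        raise ValueError(f"expected {n} unit fractions, got shape {f.shape}")
    A = np.vstack([ss.open_matrix, np.ones((1, k))])
    b = np.concatenate([f, [1.0]])

    square_exact = (A.shape[0] == A.shape[1]) and (
        abs(np.linalg.det(A)) > 1e-12
    )
    if method == "auto":
        method = "exact" if square_exact else "nnls"
    if method == "exact":
        if not square_exact:
            raise ValueError(
                "exact solve requires a square nonsingular augmented system; "
                f"got {A.shape[0]} equations for {k} states"
            )
        P = np.linalg.solve(A, b)
        residual = float(np.linalg.norm(ss.open_matrix @ P - f))
    elif method == "nnls":
        res = optimize.minimize(
            lambda p: 0.5 * np.sum((ss.open_matrix @ p - f) ** 2),
            x0=np.full(k, 1.0 / k),
            jac=lambda p: ss.open_matrix.T @ (ss.open_matrix @ p - f),
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if not res.success:
            raise RuntimeError(f"constrained least squares failed: {res.message}")
        P = res.x
        residual = float(np.linalg.norm(ss.open_matrix @ P - f))
    else:
        raise ValueError(f"unknown method {method!r}")

    feasible = bool(np.all(P >= -1e-8))
    return PopulationSolution(
        populations=P,
        state_labels=list(ss.state_labels),
        method=method,
        residual=residual,
        feasible=feasible,
    )


def feasibility_bounds(
    ss: StateSpace,
    fractions: Sequence[float],
) -> List[Tuple[float, float]]:
    """Per-state [min, max] population over the constraint polytope.

    The polytope is ``{P >= 0, sum(P) = 1, M P = f}``; for each state the
    extremes of P_s are found by linear programming.  For a uniquely
    determined system every interval collapses to the exact solution.

    Raises
    ------
    ValueError
        If the polytope is empty (the fractions are inconsistent with any
        nonnegative state distribution), listing the constraints.
    """
    f = np.asarray(fractions, dtype=float)
    n, k = ss.open_matrix.shape
    if f.shape != (n,):
        raise ValueError(f"expected {n} unit fractions, got shape {f.shape}")
    A_eq = np.vstack([ss.open_matrix, np.ones((1, k))])
    b_eq = np.concatenate([f, [1.0]])
    bounds = []
    for s in range(k):
        c = np.zeros(k)
        c[s] = 1.0
        lo = optimize.linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, 1), method="highs")
        hi = optimize.linprog(-c, A_eq=A_eq, b_eq=b_eq, bounds=(0, 1), method="highs")
        if not (lo.success and hi.success):
            raise ValueError(
                "infeasible fraction vector: no nonnegative population "
                f"distribution satisfies M P = {f.tolist()} with sum(P) = 1 "
                f"(LP status: {lo.message})"
            )
        bounds.append((float(lo.fun), float(-hi.fun)))
    return bounds


def bootstrap_populations(
    ss: StateSpace,
    fractions: Sequence[float],
    uncertainties: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "auto",
    ci: float = 95.0,
) -> pd.DataFrame:
    """Percentile confidence intervals on populations by parametric bootstrap.

    Unit fractions are resampled from independent normals (the simplest
    defensible noise model given that measurement uncertainties on the
    dividing ratios are small and per-unit); each draw is re-solved and
    per-state percentile intervals are reported.  Deterministic given seed.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    f = np.asarray(fractions, dtype=float)
    sig = np.asarray(uncertainties, dtype=float)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, ss.n_states))
    for b in range(n_boot):
        fb = f + rng.normal(0.0, 1.0, size=f.shape) * sig
        draws[b] = solve_populations(ss, fb, method=method).populations
    lo_q, hi_q = (100 - ci) / 2.0, 100 - (100 - ci) / 2.0
    lo = np.percentile(draws, lo_q, axis=0)
    hi = np.percentile(draws, hi_q, axis=0)
    point = solve_populations(ss, f, method=method).populations
    return pd.DataFrame(
        {
            "state_label": ss.state_labels,
            "population": point,
            "ci_low": lo,
            "ci_high": hi,
        }
    )


class StatePopulationSolver(BaseEstimator):
    """Estimator inverting per-unit open fractions into state populations.

    Parameters
    ----------
    n_units : int
        Number of chain units.
    allowed_contacts : iterable of (i, j) pairs, optional
        Contact graph; default all pairs (includes end-to-end contacts).
    method : {"auto", "exact", "nnls"}
        Inversion route; see :func:`solve_populations`.

    Attributes (after fit)
    ----------------------
    state_space_ : StateSpace
    populations_ : ndarray, per-state populations
    state_labels_ : list of str
    residual_ : float, norm of the fit residual on the unit fractions
    feasible_ : bool, True when all populations are nonnegative
    """

    def __init__(self, n_units: int = 3, allowed_contacts=None, method: str = "auto"):
        self.n_units = n_units
        self.allowed_contacts = allowed_contacts
        self.method = method

    def _build_space(self) -> StateSpace:
        contacts = (
            None if self.allowed_contacts is None
            else frozenset(tuple(p) for p in self.allowed_contacts)
        )
        return enumerate_states(ChainTopology(self.n_units, contacts))

    def fit(self, X, y=None):
        """Fit on a vector of per-unit open fractions (length ``n_units``)."""
        f = np.asarray(X, dtype=float).ravel()
        ss = self._build_space()
        sol = solve_populations(ss, f, method=self.method)
        self.state_space_ = ss
        self.populations_ = sol.populations
        self.state_labels_ = sol.state_labels
        self.residual_ = sol.residual
        self.feasible_ = sol.feasible
        self.solution_ = sol
        return self

    def predict(self, P=None) -> np.ndarray:
        """Forward-map populations to unit open fractions (default: fitted)."""
        ss = self.state_space_ if hasattr(self, "state_space_") else self._build_space()
        if P is None:
            if not hasattr(self, "populations_"):
                raise RuntimeError("solver is not fitted and no populations given")
            return ss.open_matrix @ self.populations_
        return forward_unit_fractions(ss, P)
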