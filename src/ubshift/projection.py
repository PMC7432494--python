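"""Open/closed dividing ratios from HSQC peak positions.

Under fast two-site exchange an amide cross peak sits at the
population-weighted average of the open-state and closed-state positions.
For a residue with reference peaks ``o`` (fully open, monomeric Ub) and
``c`` (fully closed, cyclic diUb), the observed peak ``x`` divides the
segment o->c internally at the closed-state fraction:

    t = f_closed,   x ≈ o + t (c - o),   f_open = 1 - t.

The ratio is computed by orthogonal projection of ``x`` onto the line
through ``o`` and ``c`` in composite-shift coordinates ``(dH, alpha_N*dN)``;
the orthogonal residual (perpendicular deviation) is the collinearity
diagnostic — a peak far off the reference line violates the two-site
fast-exchange picture and is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .peaklist import PeakList

__all__ = [
    "DEFAULT_ALPHA_N",
    "DEFAULT_MIN_SEPARATION",
    "DEFAULT_REL_DEVIATION_THRESHOLD",
    "ReferencePair",
    "ProjectionResult",
    "UnitFractions",
    "composite_coords",
    "project_fraction",
    "PeakProjector",
    "unit_open_fractions",
    "collinearity_report",
    "build_reference_pairs",
]

# 15N scaling for composite amide shift distances.  Ratios on exactly
# collinear triples are invariant to this weight; it only shapes the
# deviation metric and noisy projections.
DEFAULT_ALPHA_N = 0.14
# Reference pairs closer than this (composite ppm) carry no population
# information: dividing a near-zero segment amplifies noise.
DEFAULT_MIN_SEPARATION = 0.02
# Relative perpendicular deviation above which a residue is excluded.
DEFAULT_REL_DEVIATION_THRESHOLD = 0.10

Point = Tuple[float, float]


def composite_coords(peak: Point, alpha_N: float = DEFAULT_ALPHA_N) -> Tuple[float, float]:
    """Scale a (shift_H, shift_N) ppm pair into composite coordinates.

    Returns ``(shift_H, alpha_N * shift_N)``; all distances in this module
    are Euclidean in this space.
    """
    if alpha_N <= 0:
        raise ValueError(f"alpha_N must be positive, got {alpha_N}")
    return (peak[0], alpha_N * peak[1])


@dataclass(frozen=True)
class ReferencePair:
    """Matched open/closed reference positions for one residue."""

    residue_number: int
    open_ref: Point
    closed_ref: Point

    def separation(self, alpha_N: float = DEFAULT_ALPHA_N) -> float:
        o = np.asarray(composite_coords(self.open_ref, alpha_N))
        c = np.asarray(composite_coords(self.closed_ref, alpha_N))
        return float(np.linalg.norm(c - o))


@dataclass(frozen=True)
class ProjectionResult:
    """Dividing ratio of one observed peak against its reference pair.

    ``f_closed`` is the projection parameter t (0 at the open reference,
    1 at the closed reference); ``f_open = 1 - t`` always holds exactly.
    ``perp_deviation`` is the orthogonal residual in composite ppm and
    ``rel_deviation`` its ratio to the reference separation.
    """

    residue_number: int
    unit_label: str
    f_closed: float
    f_open: float
    perp_deviation: float
    rel_deviation: float
    separation: float
    flag: str  # ok | off_line | out_of_range | uninformative

    @property
    def usable(self) -> bool:
        return self.flag in ("ok", "out_of_range")


def project_fraction(
    open_ref: Point,
    closed_ref: Point,
    observed: Point,
    alpha_N: float = DEFAULT_ALPHA_N,
    *,
    residue_number: int = 0,
    unit_label: str = "",
    min_separation: float = DEFAULT_MIN_SEPARATION,
    rel_deviation_threshold: float = DEFAULT_REL_DEVIATION_THRESHOLD,
) -> ProjectionResult:
    """Project an observed peak onto the open->closed reference segment.

    Computes the orthogonal-projection parameter t of ``observed`` onto the
    line through ``open_ref`` and ``closed_ref`` in composite coordinates.
    t is reported raw (not clamped); the flag is ``out_of_range`` when t
    falls outside [-0.05, 1.05] and ``off_line`` when the relative
    perpendicular deviation exceeds the threshold.

    Raises
    ------
    ValueError
        If the references coincide exactly.
    """
    o = np.asarray(composite_coords(open_ref, alpha_N), dtype=float)
    c = np.asarray(composite_coords(closed_ref, alpha_N), dtype=float)
    x = np.asarray(composite_coords(observed, alpha_N), dtype=float)
    d = c - o
    sep = float(np.linalg.norm(d))
    if sep == 0.0:
        raise ValueError(
            f"coincident open/closed references for residue {residue_number}: "
            "dividing ratio undefined"
        )
    t = float(np.dot(x - o, d) / np.dot(d, d))
    perp = float(np.linalg.norm((x - o) - t * d))
    rel = perp / sep
    if sep < min_separation:
        flag = "uninformative"
    elif rel > rel_deviation_threshold:
        flag = "off_line"
    elif t < -0.05 or t > 1.05:
        flag = "out_of_range"
    else:
        flag = "ok"
    return ProjectionResult(
        residue_number=residue_number,
        unit_label=unit_label,
        f_closed=t,
        f_open=1.0 - t,
        perp_deviation=perp,
        rel_deviation=rel,
        separation=sep,
        flag=flag,
    )


@dataclass
class UnitFractions:
    """Per-unit open fractions with uncertainties.

    ``table`` maps unit label -> (open_fraction, uncertainty, n_residues).
    Open fractions are clamped to [0, 1] at this (aggregation) stage only.
    """

    table: Dict[str, Tuple[float, float, int]]

    def open_fractions(self, unit_order: Sequence[str]) -> np.ndarray:
        return np.array([self.table[u][0] for u in unit_order])

    def uncertainties(self, unit_order: Sequence[str]) -> np.ndarray:
        return np.array([self.table[u][1] for u in unit_order])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"unit_label": u, "open_fraction": f, "uncertainty": s, "n_residues": n}
            for u, (f, s, n) in self.table.items()
        ]
        return pd.DataFrame(rows, columns=["unit_label", "open_fraction", "uncertainty", "n_residues"])


def build_reference_pairs(
    open_list: PeakList,
    closed_list: PeakList,
    residues: Optional[Iterable[int]] = None,
) -> list[ReferencePair]:
    """Match open- and closed-reference peak lists residue by residue."""
    if residues is None:
        residues = sorted(set(open_list.residues()) & set(closed_list.residues()))
    pairs = []
    for r in residues:
        op = open_list.get(r)
        cp = closed_list.get(r)
        if op is None or cp is None:
            raise ValueError(f"residue {r} missing from a reference peak list")
        pairs.append(
            ReferencePair(
                residue_number=r,
                open_ref=(op.shift_H, op.shift_N),
                closed_ref=(cp.shift_H, cp.shift_N),
            )
        )
    return pairs


class PeakProjector(BaseEstimator, TransformerMixin):
    """Transformer mapping observed peak lists to per-residue dividing ratios.

    Fit on the open/closed reference pair (two reference peak lists or a
    list of :class:`ReferencePair`); transform one peak list per chain unit
    into :class:`ProjectionResult` rows.

    Parameters
    ----------
    alpha_N : float
        15N weight of the composite-shift metric.
    min_separation : float
        Composite-ppm separation below which a residue is uninformative.
    rel_deviation_threshold : float
        Relative orthogonal deviation above which a peak is flagged
        ``off_line`` and excluded from aggregation.
    """

    def __init__(
        self,
        alpha_N: float = DEFAULT_ALPHA_N,
        min_separation: float = DEFAULT_MIN_SEPARATION,
        rel_deviation_threshold: float = DEFAULT_REL_DEVIATION_THRESHOLD,
    ):
        self.alpha_N = alpha_N
        self.min_separation = min_separation
        self.rel_deviation_threshold = rel_deviation_threshold

    def fit(self, open_list, closed_list=None, residues=None):
        """Store reference pairs.

        ``open_list`` may be a list of :class:`ReferencePair` (then
        ``closed_list`` is ignored) or a :class:`PeakList` paired with the
        closed-reference :class:`PeakList`.
        """
        if closed_list is None:
            pairs = list(open_list)
            if not all(isinstance(p, ReferencePair) for p in pairs):
                raise TypeError("fit without closed_list requires ReferencePair objects")
        else:
            pairs = build_reference_pairs(open_list, closed_list, residues)
        if not pairs:
            raise ValueError("no reference pairs to fit on")
        self.reference_pairs_ = {p.residue_number: p for p in pairs}
        return self

    def transform(self, unit_peaklists: Mapping[str, PeakList]) -> list[ProjectionResult]:
        """Project each unit's observed peaks onto the reference segments.

        Parameters
        ----------
        unit_peaklists : mapping of unit label -> PeakList

        Returns
        -------
        list of ProjectionResult, one per (unit, residue) with a matched
        reference pair; residues without references are skipped.
        """
        if not hasattr(self, "reference_pairs_"):
            raise RuntimeError("PeakProjector must be fitted before transform")
        results: list[ProjectionResult] = []
        for unit, pl in unit_peaklists.items():
            for peak in pl:
                pair = self.reference_pairs_.get(peak.residue_number)
                if pair is None:
                    continue
                results.append(
                    project_fraction(
                        pair.open_ref,
                        pair.closed_ref,
                        (peak.shift_H, peak.shift_N),
                        self.alpha_N,
                        residue_number=peak.residue_number,
                        unit_label=unit,
                        min_separation=self.min_separation,
                        rel_deviation_threshold=self.rel_deviation_threshold,
                    )
                )
        return results


def unit_open_fractions(
    results: Iterable[ProjectionResult],
    policy: str = "single_probe",
    probe_residue: int = 70,
) -> UnitFractions:
    """Aggregate per-residue ratios into one open fraction per unit.

    Policies
    --------
    ``single_probe``
        Use the named probe residue only (default Val70, the canonical
        hydrophobic-patch reporter).  Uncertainty is 0 (single value).
    ``weighted_mean``
        Average ``f_open`` over all usable residues, weighted by the squared
        reference separation (longer segments divide more precisely), with
        a weighted standard error.

    Peaks flagged ``off_line`` or ``uninformative`` never contribute.
    Aggregated fractions are clamped to [0, 1].
    """
    all_units: set = set()
    by_unit: Dict[str, list[ProjectionResult]] = {}
    for r in results:
        all_units.add(r.unit_label)
        if not r.usable:
            continue
        by_unit.setdefault(r.unit_label, []).append(r)
    if not by_unit:
        raise ValueError("no usable projection results in any unit")
    empty = sorted(all_units - set(by_unit))
    if empty:
        raise ValueError(
            f"no usable residues for unit(s): {', '.join(empty)} "
            "(all peaks off-line or uninformative)"
        )

    table: Dict[str, Tuple[float, float, int]] = {}
    for unit, rs in by_unit.items():
        if policy == "single_probe":
            probe = [r for r in rs if r.residue_number == probe_residue]
            if not probe:
                raise ValueError(
                    f"unit {unit}: probe residue {probe_residue} has no usable peak"
                )
            f = probe[0].f_open
            table[unit] = (float(np.clip(f, 0.0, 1.0)), 0.0, 1)
        elif policy == "weighted_mean":
            f = np.array([r.f_open for r in rs])
            w = np.array([r.separation**2 for r in rs])
            w = w / w.sum()
            mean = float(np.sum(w * f))
            if len(rs) > 1:
                var = float(np.sum(w * (f - mean) ** 2) / (1.0 - np.sum(w**2)))
                se = float(np.sqrt(var * np.sum(w**2)))
            else:
                se = 0.0
            table[unit] = (float(np.clip(mean, 0.0, 1.0)), se, len(rs))
        else:
            raise ValueError(f"unknown aggregation policy {policy!r}")
    return UnitFractions(table=table)


def collinearity_report(
    results: Iterable[ProjectionResult],
    threshold: float = DEFAULT_REL_DEVIATION_THRESHOLD,
) -> pd.DataFrame:
    """Tabulate per-peak deviations from the reference line.

    Returns a DataFrame with one row per (unit, residue) listing the
    relative perpendicular deviation and whether the peak is excluded at
    the given threshold.  Excluded peaks must not enter unit aggregation.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "unit_label": r.unit_label,
                "residue_number": r.residue_number,
                "f_closed": r.f_closed,
                "perp_deviation": r.perp_deviation,
                "rel_deviation": r.rel_deviation,
                "separation": r.separation,
                "flag": r.flag,
                "excluded": bool(r.rel_deviation > threshold or r.flag == "uninformative"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_label", "residue_number", "f_closed", "perp_deviation",
            "rel_deviation", "separation", "flag", "excluded",
        ],
    )
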