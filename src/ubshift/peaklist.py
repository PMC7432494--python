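"""Assigned 2D peak-list I/O.

Reads and writes backbone-amide peak lists in two plain-text dialects:

* a Sparky-style ``.list`` dialect — whitespace-delimited lines whose first
  token is an assignment such as ``V70N-H`` followed by two chemical-shift
  columns (ppm), with a declared axis order mapping the columns onto the
  (1H, 15N) axes;
* a CSV dialect with explicit ``residue_number``, ``residue_code``,
  ``shift_H``, ``shift_N`` columns (extra columns are preserved as metadata).

Peak positions are stored as read, in ppm, with no referencing correction.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Tuple

__all__ = [
    "Peak",
    "PeakList",
    "PeakListError",
    "ParseError",
    "read_sparky_peaklist",
    "read_csv_peaklist",
    "write_peaklist",
]

logger = logging.getLogger(__name__)

AMINO_CODES = set("ACDEFGHIKLMNPQRSTVWY")

# Backbone amide assignment token: one-letter code, residue number, N-H pair.
_ASSIGNMENT_RE = re.compile(r"^([A-Z])(\d+)N-H$", re.IGNORECASE)

# Sanity windows for amide resonances (ppm); configurable at read time.
DEFAULT_H_WINDOW = (0.0, 15.0)
DEFAULT_N_WINDOW = (90.0, 140.0)


class PeakListError(ValueError):
    """Invalid peak-list content (duplicate assignment, bad shifts, schema)."""


class ParseError(PeakListError):
    """A line of a peak-list file could not be parsed."""


@dataclass(frozen=True)
class Peak:
    """One assigned backbone-amide cross peak.

    Parameters
    ----------
    residue_number : int
        Sequence position (1-based).
    residue_code : str
        One-letter amino-acid code.
    shift_H : float
        Amide 1H chemical shift in ppm.
    shift_N : float
        Amide 15N chemical shift in ppm.
    intensity : float, optional
        Peak height or volume in arbitrary units.
    """

    residue_number: int
    residue_code: str
    shift_H: float
    shift_N: float
    intensity: Optional[float] = None

    def validate(
        self,
        h_window: Tuple[float, float] = DEFAULT_H_WINDOW,
        n_window: Tuple[float, float] = DEFAULT_N_WINDOW,
    ) -> None:
        if self.residue_number < 1:
            raise PeakListError(
                f"residue_number must be >= 1, got {self.residue_number}"
            )
        if not (h_window[0] <= self.shift_H <= h_window[1]):
            raise PeakListError(
                f"shift_H {self.shift_H} ppm outside window {h_window} "
                f"for residue {self.residue_number}"
            )
        if not (n_window[0] <= self.shift_N <= n_window[1]):
            raise PeakListError(
                f"shift_N {self.shift_N} ppm outside window {n_window} "
                f"for residue {self.residue_number}"
            )

    @property
    def assignment(self) -> str:
        return f"{self.residue_code}{self.residue_number}N-H"


@dataclass
class PeakList:
    """A collection of assigned peaks from one spectrum.

    At most one peak per residue number; duplicates raise ``PeakListError``.
    """

    spectrum_id: str = ""
    peaks: list[Peak] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_unique()

    def _check_unique(self) -> None:
        seen: dict[int, Peak] = {}
        for p in self.peaks:
            if p.residue_number in seen:
                raise PeakListError(
                    f"duplicate assignment for residue {p.residue_number} "
                    f"in spectrum '{self.spectrum_id}'"
                )
            seen[p.residue_number] = p

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def get(self, residue_number: int) -> Optional[Peak]:
        for p in self.peaks:
            if p.residue_number == residue_number:
                return p
        return None

    def residues(self) -> list[int]:
        return sorted(p.residue_number for p in self.peaks)

    def validate(
        self,
        h_window: Tuple[float, float] = DEFAULT_H_WINDOW,
        n_window: Tuple[float, float] = DEFAULT_N_WINDOW,
    ) -> None:
        self._check_unique()
        for p in self.peaks:
            p.validate(h_window, n_window)


def _parse_assignment(token: str) -> Optional[Tuple[str, int]]:
    m = _ASSIGNMENT_RE.match(token)
    if m is None:
        return None
    code = m.group(1).upper()
    if code not in AMINO_CODES:
        return None
    return code, int(m.group(2))


def read_sparky_peaklist(
    path,
    axis_order: Sequence[str] = ("N", "H"),
    spectrum_id: Optional[str] = None,
    h_window: Tuple[float, float] = DEFAULT_H_WINDOW,
    n_window: Tuple[float, float] = DEFAULT_N_WINDOW,
) -> PeakList:
    """Read a Sparky-style ``.list`` file.

    Parameters
    ----------
    path : path-like
        File to read.
    axis_order : sequence of {"H", "N"}
        Mapping of the two shift columns (w1, w2) onto the 1H/15N axes.
        The conventional 1H-15N HSQC list order is ``("N", "H")``, but the
        mapping must be stated explicitly for any non-default file.
    spectrum_id : str, optional
        Identifier stored on the returned list; defaults to the file stem.
    h_window, n_window : (float, float)
        Acceptable ppm windows used for validation.

    Notes
    -----
    Header lines (starting with ``Assignment``) and comment lines (``#``)
    are skipped.  Tokens that do not match the backbone ``<code><num>N-H``
    pattern (sidechains, unassigned peaks) are skipped with a warning.
    """
    axis_order = tuple(a.upper() for a in axis_order)
    if sorted(axis_order) != ["H", "N"]:
        raise ValueError(f"axis_order must be a permutation of ('H','N'), got {axis_order}")
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if tokens[0].lower() in ("assignment", "assig"):
                continue
            parsed = _parse_assignment(tokens[0])
            if parsed is None:
                logger.warning(
                    "%s:%d: skipping non-backbone assignment token %r",
                    path.name, lineno, tokens[0],
                )
                continue
            code, resnum = parsed
            if len(tokens) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected two shift columns after "
                    f"assignment, got {len(tokens) - 1}"
                )
            try:
                w1, w2 = float(tokens[1]), float(tokens[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric shift column: {exc}"
                ) from None
            intensity = None
            if len(tokens) >= 4:
                try:
                    intensity = float(tokens[3])
                except ValueError:
                    intensity = None
            shifts = dict(zip(axis_order, (w1, w2)))
            peaks.append(
                Peak(
                    residue_number=resnum,
                    residue_code=code,
                    shift_H=shifts["H"],
                    shift_N=shifts["N"],
                    intensity=intensity,
                )
            )
    pl = PeakList(spectrum_id=spectrum_id or path.stem, peaks=peaks)
    pl.validate(h_window, n_window)
    return pl


REQUIRED_CSV_COLUMNS = ("residue_number", "residue_code", "shift_H", "shift_N")


def read_csv_peaklist(
    path,
    spectrum_id: Optional[str] = None,
    h_window: Tuple[float, float] = DEFAULT_H_WINDOW,
    n_window: Tuple[float, float] = DEFAULT_N_WINDOW,
) -> PeakList:
    """Read the CSV dialect (explicit per-axis columns, extras kept as metadata)."""
    path = Path(path)
    peaks: list[Peak] = []
    extra_rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_CSV_COLUMNS if c not in header]
        if missing:
            raise PeakListError(
                f"{path.name}: missing required column(s): {', '.join(missing)}"
            )
        extra_cols = [c for c in header if c not in REQUIRED_CSV_COLUMNS + ("intensity",)]
        for row in reader:
            intensity = None
            if row.get("intensity") not in (None, ""):
                intensity = float(row["intensity"])
            peaks.append(
                Peak(
                    residue_number=int(row["residue_number"]),
                    residue_code=row["residue_code"].strip().upper(),
                    shift_H=float(row["shift_H"]),
                    shift_N=float(row["shift_N"]),
                    intensity=intensity,
                )
            )
            if extra_cols:
                extra_rows.append({c: row[c] for c in extra_cols})
    metadata = {"extra_columns": extra_rows} if extra_rows else {}
    pl = PeakList(spectrum_id=spectrum_id or path.stem, peaks=peaks, metadata=metadata)
    pl.validate(h_window, n_window)
    return pl


def write_peaklist(
    pl: PeakList,
    path,
    dialect: str = "csv",
    axis_order: Sequence[str] = ("N", "H"),
) -> Path:
    """Write ``pl`` to ``path`` in the requested dialect.

    Shifts are written with 4 decimal places, so a read-after-write
    round-trip reproduces every field to 1e-4 ppm.
    """
    path = Path(path)
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["residue_number", "residue_code", "shift_H", "shift_N", "intensity"])
            for p in pl.peaks:
                writer.writerow(
                    [
                        p.residue_number,
                        p.residue_code,
                        f"{p.shift_H:.4f}",
                        f"{p.shift_N:.4f}",
                        "" if p.intensity is None else f"{p.intensity:.6g}",
                    ]
                )
    elif dialect == "sparky":
        axis_order = tuple(a.upper() for a in axis_order)
        if sorted(axis_order) != ["H", "N"]:
            raise ValueError(f"axis_order must be a permutation of ('H','N'), got {axis_order}")
        with open(path, "w") as fh:
            fh.write("Assignment w1 w2\n")
            for p in pl.peaks:
                shifts = {"H": p.shift_H, "N": p.shift_N}
                w1, w2 = shifts[axis_order[0]], shifts[axis_order[1]]
                line = f"{p.assignment} {w1:.4f} {w2:.4f}"
                if p.intensity is not None:
                    line += f" {p.intensity:.6g}"
                fh.write(line + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'sparky' or 'csv'")
    return path
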