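"""End-to-end analysis pipeline: ingest peak lists -> dividing ratios ->
per-unit open fractions -> state populations -> reports.

The pipeline is deliberately thin: it wires :class:`PeakProjector` and
:class:`StatePopulationSolver` together, writes machine-readable CSV
outputs plus a human-readable summary that echoes the unit-fraction
equation system with the numbers substituted, and logs the effective
configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import projection as proj
from .peaklist import PeakList, read_csv_peaklist, read_sparky_peaklist
from .projection import PeakProjector, UnitFractions, collinearity_report, unit_open_fractions
from .states import (
    ChainTopology,
    PopulationSolution,
    StateSpace,
    bootstrap_populations,
    enumerate_states,
    solve_populations,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "compare_runs", "ValidationError"]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Configuration invalid before any computation was attempted."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``unit_paths`` maps chain-unit labels (Ub1..Ubn, distal first) to their
    peak-list files; the dialect is inferred from the extension (``.csv`` ->
    CSV, anything else -> Sparky-style).
    """

    open_ref_path: str
    closed_ref_path: str
    unit_paths: Dict[str, str]
    n_units: Optional[int] = None
    policy: str = "single_probe"
    probe_residue: int = 70
    alpha_N: float = proj.DEFAULT_ALPHA_N
    min_separation: float = proj.DEFAULT_MIN_SEPARATION
    rel_deviation_threshold: float = proj.DEFAULT_REL_DEVIATION_THRESHOLD
    solver_method: str = "auto"
    n_boot: int = 0  # 0 disables the bootstrap
    bootstrap_sigma: float = 0.0
    output_dir: Optional[str] = None
    seed: int = 0
    axis_order: Tuple[str, str] = ("N", "H")

    def validate(self) -> None:
        paths = [self.open_ref_path, self.closed_ref_path, *self.unit_paths.values()]
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise ValidationError(f"missing input file(s): {', '.join(map(str, missing))}")
        if not self.unit_paths:
            raise ValidationError("no unit peak lists configured")
        if self.min_separation <= 0 or self.rel_deviation_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if self.n_units is not None and self.n_units != len(self.unit_paths):
            raise ValidationError(
                f"n_units={self.n_units} but {len(self.unit_paths)} unit files given"
            )


@dataclass
class RunResult:
    """Everything one pipeline run produced."""

    config: RunConfig
    projections: pd.DataFrame
    collinearity: pd.DataFrame
    unit_fractions: UnitFractions
    state_space: StateSpace
    solution: PopulationSolution
    bootstrap: Optional[pd.DataFrame]
    summary: str

    @property
    def unit_order(self) -> List[str]:
        return list(self.config.unit_paths.keys())


def _read_peaklist(path: str, axis_order) -> PeakList:
    p = Path(path)
    if p.suffix.lower() == ".csv":
        return read_csv_peaklist(p)
    return read_sparky_peaklist(p, axis_order=axis_order)


def _equation_summary(ss: StateSpace, fractions: np.ndarray, sol: PopulationSolution) -> str:
    """Human-readable report echoing the unit-fraction equations with values."""
    lines = []
    labels = ss.topology.labels
    pct = sol.percentages()
    lines.append("State populations from per-unit open fractions")
    lines.append("=" * 48)
    if ss.n_states > len(labels) + 1:
        lines.append(
            f"NOTE: {ss.topology.n_units}-unit chain -> {ss.n_states} states; "
            "the system is underdetermined (generalized model, reported with "
            "feasibility bounds rather than a unique solution)."
        )
    for i, unit in enumerate(labels):
        open_states = [
            ss.state_labels[s] for s in range(ss.n_states) if ss.open_matrix[i, s] > 0
        ]
        closed_states = [
            ss.state_labels[s] for s in range(ss.n_states) if ss.open_matrix[i, s] == 0
        ]
        lines.append(
            f"{unit} open:closed = {'+'.join('P_' + s for s in open_states)}"
            f" : {'+'.join('P_' + s for s in closed_states) or '0'}"
            f" = {fractions[i]:.2f}:{1 - fractions[i]:.2f}"
        )
    lines.append("sum of populations = 1")
    lines.append("")
    lines.append(f"Solution ({sol.method}): residual = {sol.residual:.3e}, "
                 f"feasible = {sol.feasible}")
    for lbl, p in sol.as_dict().items():
        lines.append(f"  P_{lbl} = {p:.4f}  ({pct[lbl]}%)")
    check = ss.open_matrix @ sol.populations
    lines.append("")
    lines.append(
        "Consistency check (M @ P): "
        + ", ".join(f"{u}={v:.4f}" for u, v in zip(labels, check))
    )
    if not sol.feasible:
        lines.append(
            "WARNING: solution has negative components — the four-state model "
            "cannot reproduce these fractions with nonnegative populations."
        )
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> RunResult:
    """Run ingest -> project -> aggregate -> solve -> report.

    Writes ``projections.csv``, ``unit_fractions.csv``, ``populations.csv``,
    ``collinearity.csv``, ``summary.txt`` and ``effective_config.json`` to
    ``config.output_dir`` when set.  Raises :class:`ValidationError` before
    touching any data if the configuration is invalid.  An infeasible
    solution is returned (and written) with ``feasible=False``, never
    clipped; callers decide the exit status.
    """
    config.validate()
    logger.info("ingest: reading reference and unit peak lists")
    open_list = _read_peaklist(config.open_ref_path, config.axis_order)
    closed_list = _read_peaklist(config.closed_ref_path, config.axis_order)
    unit_lists = {
        u: _read_peaklist(p, config.axis_order) for u, p in config.unit_paths.items()
    }

    logger.info("project: computing dividing ratios")
    projector = PeakProjector(
        alpha_N=config.alpha_N,
        min_separation=config.min_separation,
        rel_deviation_threshold=config.rel_deviation_threshold,
    ).fit(open_list, closed_list)
    results = projector.transform(unit_lists)
    colin = collinearity_report(results, threshold=config.rel_deviation_threshold)

    fractions_tbl = unit_open_fractions(
        results, policy=config.policy, probe_residue=config.probe_residue
    )
    unit_order = list(config.unit_paths.keys())
    f = fractions_tbl.open_fractions(unit_order)

    logger.info("solve: inverting unit fractions into state populations")
    topo = ChainTopology(len(unit_order))
    ss = enumerate_states(topo)
    sol = solve_populations(ss, f, method=config.solver_method)

    boot = None
    if config.n_boot > 0:
        sig = fractions_tbl.uncertainties(unit_order)
        if config.bootstrap_sigma > 0:
            sig = np.maximum(sig, config.bootstrap_sigma)
        boot = bootstrap_populations(
            ss, f, sig, n_boot=config.n_boot, seed=config.seed,
            method=config.solver_method,
        )

    summary = _equation_summary(ss, f, sol)

    proj_df = pd.DataFrame(
        [dataclasses.asdict(r) for r in results],
        columns=[
            "unit_label", "residue_number", "f_closed", "f_open",
            "perp_deviation", "rel_deviation", "separation", "flag",
        ],
    )

    result = RunResult(
        config=config,
        projections=proj_df,
        collinearity=colin,
        unit_fractions=fractions_tbl,
        state_space=ss,
        solution=sol,
        bootstrap=boot,
        summary=summary,
    )

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        proj_df.to_csv(outdir / "projections.csv", index=False, float_format="%.6f")
        colin.to_csv(outdir / "collinearity.csv", index=False, float_format="%.6f")
        fractions_tbl.to_frame().to_csv(
            outdir / "unit_fractions.csv", index=False, float_format="%.6f"
        )
        sol.to_frame().to_csv(outdir / "populations.csv", index=False, float_format="%.6f")
        if boot is not None:
            boot.to_csv(outdir / "bootstrap.csv", index=False, float_format="%.6f")
        (outdir / "summary.txt").write_text(summary + "\n")
        cfg = dataclasses.asdict(config)
        (outdir / "effective_config.json").write_text(json.dumps(cfg, indent=2, default=str))
        logger.info("outputs written to %s", outdir)

    return result


def compare_runs(run_a, run_b) -> pd.DataFrame:
    """Per-state population deltas and per-unit open-fraction deltas (b - a).

    Intended for mutant-versus-wild-type comparisons; both runs must share
    the same chain topology.  Accepts full :class:`RunResult` bundles or
    bare :class:`PopulationSolution` objects (e.g. solved directly from
    reported dividing ratios, with no peak files); unit-fraction deltas are
    included only when both inputs carry them.
    """
    if isinstance(run_a, RunResult) and isinstance(run_b, RunResult):
        ss_a, ss_b = run_a.state_space, run_b.state_space
        if ss_a.topology.n_units != ss_b.topology.n_units or ss_a.states != ss_b.states:
            raise ValueError(
                "cannot compare runs with different topologies "
                f"({ss_a.topology.n_units} vs {ss_b.topology.n_units} units)"
            )
    sol_a = run_a.solution if isinstance(run_a, RunResult) else run_a
    sol_b = run_b.solution if isinstance(run_b, RunResult) else run_b
    if sol_a.state_labels != sol_b.state_labels:
        raise ValueError(
            "cannot compare solutions over different state spaces "
            f"({sol_a.state_labels} vs {sol_b.state_labels})"
        )
    rows = []
    pa = sol_a.as_dict()
    pb = sol_b.as_dict()
    for lbl in sol_a.state_labels:
        rows.append(
            {
                "kind": "state",
                "label": lbl,
                "value_a": pa[lbl],
                "value_b": pb[lbl],
                "delta": pb[lbl] - pa[lbl],
                "delta_pct_points": round(100 * (pb[lbl] - pa[lbl]), 6),
            }
        )
    if not (isinstance(run_a, RunResult) and isinstance(run_b, RunResult)):
        return pd.DataFrame(rows)
    order = run_a.unit_order
    fa = run_a.unit_fractions.open_fractions(order)
    fb = run_b.unit_fractions.open_fractions(run_b.unit_order)
    for u, a, b in zip(order, fa, fb):
        rows.append(
            {
                "kind": "unit_open_fraction",
                "label": u,
                "value_a": a,
                "value_b": b,
                "delta": b - a,
                "delta_pct_points": round(100 * (b - a), 6),
            }
        )
    return pd.DataFrame(rows)
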