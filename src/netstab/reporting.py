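"""Deterministic serialization of analysis reports to JSON and CSV.

All writers produce byte-identical output for identical inputs: field order
is fixed, floats are written with full round-trip precision, and complex
eigenvalues are stored as ``[re, im]`` pairs so nothing is lost on
round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from netstab.dynamics import TrajectoryResult
from netstab.network import ConfigurationError
from netstab.nonlinear import NonlinearFixedPoint
from netstab.spectral import BoundarySlice, EquivalenceReport, StabilityReport


def _complex_pairs(values: np.ndarray) -> list[list[float]]:
    return [[float(v.real), float(v.imag)] for v in np.asarray(values, dtype=complex)]


def stability_report_to_dict(report: StabilityReport) -> dict:
    return {
        "scheme": report.scheme,
        "classification": report.classification,
        "spectral_radius": float(report.spectral_radius),
        "dominant_eigenvalue": [
            float(report.dominant_eigenvalue.real),
            float(report.dominant_eigenvalue.imag),
        ],
        "eigenvalues": _complex_pairs(report.eigenvalues),
        "marginal_tol": float(report.marginal_tol),
    }


def stability_report_from_dict(data: dict) -> StabilityReport:
    ev = np.array([complex(re, im) for re, im in data["eigenvalues"]])
    dom = data["dominant_eigenvalue"]
    return StabilityReport(
        eigenvalues=ev,
        spectral_radius=float(data["spectral_radius"]),
        classification=data["classification"],
        dominant_eigenvalue=complex(dom[0], dom[1]),
        scheme=data["scheme"],
        marginal_tol=float(data["marginal_tol"]),
    )


def equivalence_report_to_dict(report: EquivalenceReport) -> dict:
    return {
        "is_single_distance": bool(report.is_single_distance),
        "q": None if report.q is None else int(report.q),
        "k3": int(report.k3),
        "nonzero_root_match": bool(report.nonzero_root_match),
        "max_root_mismatch": float(report.max_root_mismatch),
    }


def equivalence_report_from_dict(data: dict) -> EquivalenceReport:
    return EquivalenceReport(
        is_single_distance=bool(data["is_single_distance"]),
        k3=int(data["k3"]),
        nonzero_root_match=bool(data["nonzero_root_match"]),
        max_root_mismatch=float(data["max_root_mismatch"]),
        q=None if data["q"] is None else int(data["q"]),
    )


def fixed_point_to_dict(fp: NonlinearFixedPoint) -> dict:
    return {
        "converged": bool(fp.converged),
        "residual": float(fp.residual),
        "h_star": [float(v) for v in fp.h_star],
        "i_star": [float(v) for v in fp.i_star],
    }


def fixed_point_from_dict(data: dict) -> NonlinearFixedPoint:
    return NonlinearFixedPoint(
        h_star=np.array(data["h_star"], dtype=float),
        i_star=np.array(data["i_star"], dtype=float),
        residual=float(data["residual"]),
        converged=bool(data["converged"]),
    )


def trajectory_frame(traj: TrajectoryResult) -> pd.DataFrame:
    """Trajectory as a table with columns t, h_1, ..., h_N."""
    n = traj.states.shape[1]
    frame = pd.DataFrame(traj.states, columns=[f"h_{i + 1}" for i in range(n)])
    frame.insert(0, "t", np.arange(len(traj.states)))
    return frame


def trajectory_sidecar(traj: TrajectoryResult) -> dict:
    return {
        "verdict": traj.verdict,
        "steps_to_converge": traj.steps_to_converge,
        "fixed_point_estimate": (
            None
            if traj.fixed_point_estimate is None
            else [float(v) for v in traj.fixed_point_estimate]
        ),
        "n_states": int(len(traj.states)),
    }


def boundary_grid_frame(sl: BoundarySlice) -> pd.DataFrame:
    """Grid classifications: columns param1, param2, scheme, classification, spectral_radius."""
    rows = []
    for scheme in sorted(sl.classification):
        cls = sl.classification[scheme]
        rho = sl.spectral_radius[scheme]
        for i, p1 in enumerate(sl.axis1_values):
            for j, p2 in enumerate(sl.axis2_values):
                rows.append((p1, p2, scheme, cls[i, j], rho[i, j]))
    return pd.DataFrame(
        rows,
        columns=[
            sl.axis_names[0],
            sl.axis_names[1],
            "scheme",
            "classification",
            "spectral_radius",
        ],
    )


def boundary_points_frame(sl: BoundarySlice) -> pd.DataFrame:
    rows = []
    for scheme in sorted(sl.boundary_points):
        for p1, p2 in sl.boundary_points[scheme]:
            rows.append((p1, p2, scheme))
    return pd.DataFrame(rows, columns=[sl.axis_names[0], sl.axis_names[1], "scheme"])


def write_json(data: dict, path: str | Path) -> Path:
    path = Path(path)
    if not path.parent.exists():
        raise ConfigurationError(f"parent directory {path.parent} does not exist")
    path.write_text(json.dumps(data, indent=2, sort_keys=False) + "\n")
    return path


def write_report(report, path: str | Path) -> list[Path]:
    """Serialize a report; JSON for scalar reports, CSV (+sidecar) for tables.

    ``TrajectoryResult`` writes ``<stem>.csv`` plus ``<stem>.json``;
    ``BoundarySlice`` writes ``<stem>_grid.csv`` and ``<stem>_points.csv``.
    Returns the list of files written.
    """
    path = Path(path)
    if isinstance(report, StabilityReport):
        return [write_json(stability_report_to_dict(report), path)]
    if isinstance(report, EquivalenceReport):
        return [write_json(equivalence_report_to_dict(report), path)]
    if isinstance(report, NonlinearFixedPoint):
        return [write_json(fixed_point_to_dict(report), path)]
    if isinstance(report, TrajectoryResult):
        csv_path = path.with_suffix(".csv")
        trajectory_frame(report).to_csv(csv_path, index=False)
        side = write_json(trajectory_sidecar(report), path.with_suffix(".json"))
        return [csv_path, side]
    if isinstance(report, BoundarySlice):
        grid_path = path.parent / f"{path.stem}_grid.csv"
        pts_path = path.parent / f"{path.stem}_points.csv"
        boundary_grid_frame(report).to_csv(grid_path, index=False)
        boundary_points_frame(report).to_csv(pts_path, index=False)
        return [grid_path, pts_path]
    raise ConfigurationError(f"do not know how to serialize {type(report).__name__}")
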