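"""Reading and writing the pipeline's file formats.

Formats are deliberately plain: two-page TIFF (YFP, CFP) or paired
single-channel images for colonies, CSV for traces / ground truth /
tables, JSON for geometry and result sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .boundary import BoundaryTrace, ColonyGeometry, ColonyImagePair, TraceSet
from .synthetic import GroundTruthBoundary, SyntheticColonySpec


def write_colony_tiff(path, pair: ColonyImagePair) -> None:
    """Two-page 16-bit TIFF, channel order YFP then CFP."""
    stack = np.stack([
        np.asarray(pair.yfp, dtype=np.uint16),
        np.asarray(pair.cfp, dtype=np.uint16),
    ])
    tifffile.imwrite(str(path), stack)


def read_colony(path, cfp_path=None, pixel_size: float | None = None) -> ColonyImagePair:
    """Load a two-page TIFF, or two single-channel files (YFP, CFP)."""
    if cfp_path is None:
        stack = tifffile.imread(str(path))
        if stack.ndim != 3 or stack.shape[0] != 2:
            raise ValueError("expected a two-page (YFP, CFP) TIFF")
        yfp, cfp = stack[0], stack[1]
    else:
        import imageio.v3 as iio

        yfp = iio.imread(str(path))
        cfp = iio.imread(str(cfp_path))
    return ColonyImagePair(yfp, cfp, pixel_size=pixel_size)


def write_ground_truth_csv(path, boundaries: list[GroundTruthBoundary]) -> None:
    rows = []
    for k, b in enumerate(boundaries):
        for r, phi in zip(b.r, b.phi):
            rows.append((k, r, phi))
    pd.DataFrame(rows, columns=["boundary_id", "r_um", "phi_rad"]).to_csv(
        path, index=False
    )


def read_ground_truth_csv(path) -> list[GroundTruthBoundary]:
    df = pd.read_csv(path)
    out = []
    for k, grp in df.groupby("boundary_id"):
        r = grp["r_um"].to_numpy()
        phi = grp["phi_rad"].to_numpy()
        out.append(GroundTruthBoundary(phi0=float(phi[0]), r=r, phi=phi))
    return out


def write_spec_json(path, spec: SyntheticColonySpec) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(spec), indent=2))


def write_traces_csv(path, traceset: TraceSet) -> None:
    rows = []
    for tr in traceset.traces:
        for i, (r, phi) in enumerate(zip(tr.r, tr.phi)):
            rows.append((tr.colony_id, tr.trace_id, i, r, phi))
    pd.DataFrame(
        rows, columns=["colony_id", "trace_id", "point_index", "r", "phi_rad"]
    ).to_csv(path, index=False)


def read_traces_csv(path) -> TraceSet:
    df = pd.read_csv(path)
    traces = []
    for (colony_id, trace_id), grp in df.groupby(["colony_id", "trace_id"]):
        grp = grp.sort_values("point_index")
        traces.append(
            BoundaryTrace(
                grp["r"].to_numpy(), grp["phi_rad"].to_numpy(),
                colony_id=str(colony_id), trace_id=int(trace_id),
            )
        )
    return TraceSet(traces=traces)


def write_geometry_json(path, geometry: ColonyGeometry) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(geometry), indent=2))


def read_center_csv(path) -> np.ndarray:
    """Manually picked rim points as an (n, 2) array of (x_px, y_px)."""
    df = pd.read_csv(path)
    return df[["x_px", "y_px"]].to_numpy(dtype=float)


def read_hints_csv(path):
    """Curation hints: colony_id, trace_id, action[, index]."""
    from .boundary import CurationHint

    df = pd.read_csv(path)
    hints = []
    for _, row in df.iterrows():
        idx = row.get("index")
        hints.append(
            CurationHint(
                colony_id=str(row["colony_id"]),
                trace_id=int(row["trace_id"]),
                action=str(row["action"]),
                index=None if pd.isna(idx) else int(idx),
            )
        )
    return hints
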