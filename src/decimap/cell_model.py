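"""Domain types and tabular I/O for segmented-cell data.

The pipeline operates on cell tables derived from segmented multiplexed
images of decidua basalis: one row per cell with its centroid position
(μm, image convention: origin top-left, y increasing downward, 1 px = 1 μm)
and, per marker, the fraction of segmentation-mask pixels classified
positive for that marker ("binarized" expression in [0, 1] — a value of
0.5 means half the cell's pixels stain positive).

Cells are grouped into ROIs (imaged rectangles of tissue); each ROI knows
its annotated basalis tissue area in mm², the denominator for all
cells-per-mm² densities. Samples carry a pregnancy-group label
(fully/semi-allogeneic oocyte-donation, pre-eclamptic, IVF) and parity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "PARITIES",
    "UNASSIGNED",
    "MarkerPanel",
    "CellRecord",
    "ROIFrame",
    "SampleMeta",
    "CellTableFormatError",
    "CellTableValidationError",
    "read_cell_table",
    "write_cell_table",
    "read_sample_table",
    "write_sample_table",
    "write_roi_table",
    "density_per_mm2",
]

#: The four comparison arms of the cohort.
GROUPS = ("fully_allo_healthy", "semi_allo_healthy", "fully_allo_PE", "ivf_healthy")
PARITIES = ("nulliparous", "multiparous", "unknown")
UNASSIGNED = "unassigned"

_BASE_COLUMNS = ["sample_id", "roi_id", "cell_id", "x_um", "y_um"]
_LABEL_COLUMNS = ["lineage", "cluster"]


class CellTableFormatError(ValueError):
    """A cell table file is structurally malformed (e.g. missing column)."""


class CellTableValidationError(ValueError):
    """A cell table violates a domain invariant (e.g. fraction outside [0,1])."""


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered antibody panel plus the per-cell positivity cut.

    A marker is called positive on a cell when the fraction of positive
    pixels reaches ``positivity_threshold`` (``>=`` convention). The
    default of 0.25 tolerates partial-cell staining while excluding
    stray positive pixels.
    """

    markers: tuple[str, ...]
    positivity_threshold: float = 0.25

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        if not (0.0 < self.positivity_threshold <= 1.0):
            raise ValueError(
                f"positivity_threshold must lie in (0, 1], got {self.positivity_threshold}"
            )
        object.__setattr__(self, "markers", tuple(self.markers))

    def frac_col(self, marker: str) -> str:
        if marker not in self.markers:
            raise KeyError(f"unknown marker {marker!r}")
        return f"{marker}_frac"

    @property
    def frac_columns(self) -> list[str]:
        return [f"{m}_frac" for m in self.markers]


@dataclass
class CellRecord:
    """One segmented cell: position, marker pixel-fractions, labels."""

    cell_id: str
    sample_id: str
    roi_id: str
    x: float
    y: float
    marker_frac: dict[str, float]
    lineage: str = UNASSIGNED
    cluster: str = UNASSIGNED

    def validate(self, panel: MarkerPanel) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise CellTableValidationError(f"cell {self.cell_id}: non-finite coordinates")
        if self.x < 0 or self.y < 0:
            raise CellTableValidationError(f"cell {self.cell_id}: negative coordinates")
        for marker, frac in self.marker_frac.items():
            if marker not in panel.markers:
                raise CellTableValidationError(
                    f"cell {self.cell_id}: marker {marker!r} not in panel"
                )
            if not (0.0 <= frac <= 1.0):
                raise CellTableValidationError(
                    f"cell {self.cell_id}: {marker} fraction {frac} outside [0, 1]"
                )


@dataclass
class ROIFrame:
    """One imaged region of interest and its cells.

    ``cells`` is a DataFrame with columns ``sample_id, roi_id, cell_id,
    x_um, y_um, <marker>_frac..., lineage, cluster`` (canonical order).
    """

    roi_id: str
    sample_id: str
    width_um: float
    height_um: float
    basalis_area_mm2: float
    cells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.basalis_area_mm2 <= 0:
            raise ValueError(f"ROI {self.roi_id}: basalis_area_mm2 must be > 0")
        roi_area_mm2 = self.width_um * self.height_um / 1e6
        if self.basalis_area_mm2 > roi_area_mm2 * (1 + 1e-9):
            raise ValueError(
                f"ROI {self.roi_id}: basalis area {self.basalis_area_mm2} mm² exceeds "
                f"ROI area {roi_area_mm2} mm²"
            )
        if self.cells["cell_id"].duplicated().any():
            dup = self.cells.loc[self.cells["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValueError(f"ROI {self.roi_id}: duplicate cell_id {dup!r}")
        x = self.cells["x_um"].to_numpy(float)
        y = self.cells["y_um"].to_numpy(float)
        if len(x) and (
            not np.all(np.isfinite(x) & np.isfinite(y))
            or x.min() < 0
            or y.min() < 0
            or x.max() > self.width_um
            or y.max() > self.height_um
        ):
            raise ValueError(f"ROI {self.roi_id}: cell coordinates outside ROI bounds")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def positions(self) -> np.ndarray:
        """(n, 2) centroid coordinates in μm."""
        return self.cells[["x_um", "y_um"]].to_numpy(float)

    def cell_records(self, panel: MarkerPanel) -> Iterator[CellRecord]:
        for _, row in self.cells.iterrows():
            yield CellRecord(
                cell_id=str(row["cell_id"]),
                sample_id=str(row["sample_id"]),
                roi_id=str(row["roi_id"]),
                x=float(row["x_um"]),
                y=float(row["y_um"]),
                marker_frac={m: float(row[f"{m}_frac"]) for m in panel.markers},
                lineage=str(row.get("lineage", UNASSIGNED)),
                cluster=str(row.get("cluster", UNASSIGNED)),
            )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical grouping."""

    sample_id: str
    group: str
    parity: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.parity not in PARITIES:
            raise ValueError(f"parity must be one of {PARITIES}, got {self.parity!r}")


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def canonical_columns(panel: MarkerPanel) -> list[str]:
    return _BASE_COLUMNS + panel.frac_columns + _LABEL_COLUMNS


def _validate_cell_frame(df: pd.DataFrame, panel: MarkerPanel, source: str) -> None:
    for col in _BASE_COLUMNS + panel.frac_columns:
        if col not in df.columns:
            raise CellTableFormatError(f"{source}: missing required column {col!r}")
    for col in panel.frac_columns:
        vals = df[col].to_numpy(float)
        bad = np.where(~((vals >= 0.0) & (vals <= 1.0)))[0]
        if bad.size:
            i = int(bad[0])
            raise CellTableValidationError(
                f"{source}: row {i}: {col} value {vals[i]} outside [0, 1]"
            )
    xy = df[["x_um", "y_um"]].to_numpy(float)
    bad = np.where(~np.isfinite(xy).all(axis=1) | (xy < 0).any(axis=1))[0]
    if bad.size:
        raise CellTableValidationError(
            f"{source}: row {int(bad[0])}: non-finite or negative coordinates"
        )


def _sorted_canonical(df: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    out = df.copy()
    for col in _LABEL_COLUMNS:
        if col not in out.columns:
            out[col] = UNASSIGNED
    out = out[canonical_columns(panel)]
    return out.sort_values(["sample_id", "roi_id", "cell_id"], kind="mergesort").reset_index(
        drop=True
    )


def read_cell_table(
    path: str | Path,
    panel: MarkerPanel,
    rois: str | Path | pd.DataFrame | None = None,
) -> list[ROIFrame]:
    """Read a cells.csv into validated per-ROI frames.

    ``rois`` optionally supplies ROI geometry (columns ``roi_id,
    sample_id, width_um, height_um, basalis_area_mm2``); without it the
    ROI rectangle is the coordinate bounding box and the basalis area
    defaults to that box's area.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "roi_id": str, "cell_id": str})
    _validate_cell_frame(df, panel, source=path.name)
    geom: pd.DataFrame | None
    if rois is None:
        geom = None
    elif isinstance(rois, pd.DataFrame):
        geom = rois.astype({"roi_id": str, "sample_id": str})
    else:
        geom = pd.read_csv(rois, dtype={"roi_id": str, "sample_id": str})
    frames: list[ROIFrame] = []
    for (sample_id, roi_id), sub in df.groupby(["sample_id", "roi_id"], sort=True):
        sub = _sorted_canonical(sub, panel)
        if geom is not None:
            row = geom[geom["roi_id"] == roi_id]
            if row.empty:
                raise CellTableFormatError(f"rois table: no geometry for ROI {roi_id!r}")
            row = row.iloc[0]
            width, height = float(row["width_um"]), float(row["height_um"])
            area = float(row["basalis_area_mm2"])
        else:
            width = float(sub["x_um"].max()) if len(sub) else 1.0
            height = float(sub["y_um"].max()) if len(sub) else 1.0
            width, height = max(width, 1.0), max(height, 1.0)
            area = width * height / 1e6
        frames.append(
            ROIFrame(
                roi_id=str(roi_id),
                sample_id=str(sample_id),
                width_um=width,
                height_um=height,
                basalis_area_mm2=area,
                cells=sub,
            )
        )
    return frames


def write_cell_table(rois: Sequence[ROIFrame], path: str | Path, panel: MarkerPanel) -> None:
    """Write ROIs to CSV with canonical column order and deterministic row order."""
    path = Path(path)
    if rois:
        df = pd.concat([r.cells for r in rois], ignore_index=True)
        df = _sorted_canonical(df, panel)
    else:
        df = pd.DataFrame(columns=canonical_columns(panel))
    df.to_csv(path, index=False)


def write_roi_table(rois: Sequence[ROIFrame], path: str | Path) -> None:
    rows = [
        {
            "roi_id": r.roi_id,
            "sample_id": r.sample_id,
            "width_um": r.width_um,
            "height_um": r.height_um,
            "basalis_area_mm2": r.basalis_area_mm2,
        }
        for r in rois
    ]
    df = pd.DataFrame(rows, columns=["roi_id", "sample_id", "width_um", "height_um", "basalis_area_mm2"])
    df.sort_values(["sample_id", "roi_id"], kind="mergesort").to_csv(path, index=False)


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise CellTableFormatError(f"samples table: missing required column {col!r}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                parity=str(row["parity"]) if "parity" in df.columns else "unknown",
            )
        )
    return metas


def write_sample_table(samples: Iterable[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"sample_id": s.sample_id, "group": s.group, "parity": s.parity} for s in samples],
        columns=["sample_id", "group", "parity"],
    )
    df.sort_values("sample_id", kind="mergesort").to_csv(path, index=False)


def density_per_mm2(roi: ROIFrame, phenotype: str, level: str = "lineage") -> float:
    """Cells of ``phenotype`` per mm² of annotated basalis area.

    ``level`` selects the label column to match (``lineage`` or
    ``cluster``); densities are reported per basalis area, not per ROI
    rectangle, following the tissue-annotation convention.
    """
    if roi.basalis_area_mm2 <= 0:
        raise ValueError("basalis_area_mm2 must be positive")
    if level not in roi.cells.columns:
        raise KeyError(f"label column {level!r} not present")
    count = int((roi.cells[level] == phenotype).sum())
    return count / roi.basalis_area_mm2
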