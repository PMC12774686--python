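"""Deterministic marker-logic phenotyping of segmented cells.

Replaces interactive embedding-based clustering with an explicit,
reproducible Boolean gate hierarchy:

* binarize per-cell pixel fractions into positivity calls
  (``frac >= threshold``),
* exclude blank cells (no positive marker at all),
* assign major lineages — trophoblast (HLA-G+), and within the CD45+
  immune compartment: myeloid (CD68+ or CD14+), T (CD3+; CD4/CD8a/double-
  negative subsets), NK (CD56+ and CD7+), granulocyte (CD15+) — with
  lineage priority myeloid > T > NK > granulocyte on conflicts,
* assign each myeloid cell to one of twelve decidual myeloid clusters
  (dM1–dM12) via a declarative rule table; the most specific matching
  rule wins, ties break by table order.

All gating is vectorised over cell tables and independent of row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cell_model import MarkerPanel, ROIFrame, UNASSIGNED

__all__ = [
    "GateRule",
    "DEFAULT_MARKERS",
    "MYELOID_CLUSTERS",
    "default_panel",
    "default_cluster_table",
    "binarize",
    "binarize_frame",
    "exclude_blank",
    "assign_lineage",
    "assign_myeloid_cluster",
    "label_rois",
    "is_cd163_hladr_myeloid",
    "subset_labels",
    "phenotype_fractions",
    "gates_to_json",
    "gates_from_json",
]

#: Full default panel: lineage markers + myeloid-phenotype markers.
DEFAULT_MARKERS: tuple[str, ...] = (
    "HLA-G", "CD45", "CD68", "CD14", "CD3", "CD4", "CD8a", "CD56", "CD7", "CD15",
    "CD163", "HLA-DR", "CD206", "DC-SIGN", "CD38", "CD45RO", "CD45RA",
    "CD11b", "CD16", "CD204", "S100A9",
)

IMMUNE_LINEAGES = ("myeloid", "T", "NK", "granulocyte")
T_SUBSETS = ("CD4_T", "CD8_T", "dnT")


def default_panel(positivity_threshold: float = 0.25) -> MarkerPanel:
    return MarkerPanel(markers=DEFAULT_MARKERS, positivity_threshold=positivity_threshold)


@dataclass(frozen=True)
class GateRule:
    """One declarative phenotype gate: required-positive and required-negative markers."""

    name: str
    require_positive: frozenset[str]
    require_negative: frozenset[str] = frozenset()
    parent: str = "all_cells"
    priority: int = 0

    def __post_init__(self) -> None:
        overlap = self.require_positive & self.require_negative
        if overlap:
            raise ValueError(f"rule {self.name!r}: markers both required and forbidden: {sorted(overlap)}")
        object.__setattr__(self, "require_positive", frozenset(self.require_positive))
        object.__setattr__(self, "require_negative", frozenset(self.require_negative))

    @property
    def specificity(self) -> int:
        return len(self.require_positive) + len(self.require_negative)

    def matches(self, pos: pd.DataFrame) -> np.ndarray:
        """Vectorised match against a boolean positivity frame (cells × markers)."""
        ok = np.ones(len(pos), dtype=bool)
        for m in self.require_positive:
            ok &= pos[m].to_numpy()
        for m in self.require_negative:
            ok &= ~pos[m].to_numpy()
        return ok


def _rule(name: str, pos: Sequence[str], neg: Sequence[str], priority: int) -> GateRule:
    return GateRule(
        name=name,
        require_positive=frozenset(pos),
        require_negative=frozenset(neg),
        parent="myeloid",
        priority=priority,
    )


def default_cluster_table() -> list[GateRule]:
    """The twelve decidual myeloid clusters as Boolean rules.

    Transcribed from the textual cluster descriptions: eight CD163+
    clusters (dM1–dM6, dM8, dM10) and four CD163− clusters (dM7, dM9,
    dM11, dM12). "Solely positive for" phrasing is encoded as explicit
    negativity for the sibling cluster's extra markers so the rules are
    mutually exclusive where the descriptions are.
    """
    return [
        _rule("dM1", ["CD163", "HLA-DR", "CD206", "DC-SIGN", "CD38", "CD45RO", "CD11b", "CD16"], [], 1),
        _rule("dM2", ["CD163", "HLA-DR", "CD206", "DC-SIGN"], ["CD38", "CD45RO", "CD11b", "CD16"], 2),
        _rule("dM5", ["CD163", "HLA-DR", "CD206"], ["DC-SIGN", "CD38", "CD45RO", "CD11b", "CD16"], 3),
        _rule("dM4", ["CD163", "HLA-DR", "CD38", "CD45RO"], ["CD206"], 4),
        _rule("dM10", ["CD163", "HLA-DR", "S100A9"], ["CD206"], 5),
        _rule("dM6", ["CD163", "CD206", "CD204"], ["HLA-DR"], 6),
        _rule("dM8", ["CD163"], ["HLA-DR", "CD206", "CD204"], 7),
        _rule("dM3", ["CD163", "CD56", "CD7", "CD38", "CD45RA"], [], 8),
        _rule("dM7", ["HLA-DR", "CD204"], ["CD163", "S100A9"], 9),
        _rule("dM11", ["HLA-DR", "S100A9", "CD11b"], ["CD163"], 10),
        _rule("dM12", ["HLA-DR", "S100A9", "CD204"], ["CD163"], 11),
        _rule(
            "dM9",
            ["CD14"],
            ["CD163", "HLA-DR", "CD206", "DC-SIGN", "CD204", "S100A9",
             "CD38", "CD45RO", "CD45RA", "CD11b", "CD16", "CD56", "CD7"],
            12,
        ),
    ]


MYELOID_CLUSTERS: tuple[str, ...] = tuple(r.name for r in default_cluster_table())


# ---------------------------------------------------------------------------
# gating primitives
# ---------------------------------------------------------------------------

def binarize(marker_frac: dict[str, float], panel: MarkerPanel) -> dict[str, bool]:
    """Per-marker positivity call for one cell (``>= threshold`` convention)."""
    calls = {}
    for marker, frac in marker_frac.items():
        if marker not in panel.markers:
            raise KeyError(f"unknown marker {marker!r}")
        calls[marker] = frac >= panel.positivity_threshold
    return calls


def binarize_frame(cells: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Boolean positivity frame (cells × markers) from a cell table."""
    pos = pd.DataFrame(index=cells.index)
    for m in panel.markers:
        pos[m] = cells[f"{m}_frac"].to_numpy(float) >= panel.positivity_threshold
    return pos


def exclude_blank(cells: pd.DataFrame, panel: MarkerPanel) -> tuple[pd.DataFrame, int]:
    """Drop cells without any positive marker; returns (retained, n_dropped)."""
    pos = binarize_frame(cells, panel)
    keep = pos.to_numpy().any(axis=1)
    return cells.loc[keep].reset_index(drop=True), int((~keep).sum())


def assign_lineage(pos: pd.DataFrame) -> pd.Series:
    """Vectorised lineage assignment from a positivity frame.

    Hierarchy: HLA-G+ cells are trophoblast regardless of other markers;
    all other lineages require CD45; conflicts within the immune
    compartment resolve myeloid > T > NK > granulocyte.
    """
    troph = pos["HLA-G"].to_numpy()
    immune = pos["CD45"].to_numpy() & ~troph
    myeloid = immune & (pos["CD68"].to_numpy() | pos["CD14"].to_numpy())
    t_cell = immune & ~myeloid & pos["CD3"].to_numpy()
    nk = immune & ~myeloid & ~t_cell & pos["CD56"].to_numpy() & pos["CD7"].to_numpy()
    gran = immune & ~myeloid & ~t_cell & ~nk & pos["CD15"].to_numpy()
    cd4 = t_cell & pos["CD4"].to_numpy()
    cd8 = t_cell & ~cd4 & pos["CD8a"].to_numpy()
    dnt = t_cell & ~cd4 & ~cd8
    lineage = np.full(len(pos), UNASSIGNED, dtype=object)
    lineage[troph] = "trophoblast"
    lineage[myeloid] = "myeloid"
    lineage[cd4] = "CD4_T"
    lineage[cd8] = "CD8_T"
    lineage[dnt] = "dnT"
    lineage[nk] = "NK"
    lineage[gran] = "granulocyte"
    return pd.Series(lineage, index=pos.index, name="lineage")


def assign_myeloid_cluster(
    pos: pd.DataFrame,
    lineage: pd.Series,
    cluster_table: Sequence[GateRule] | None = None,
) -> pd.Series:
    """Assign dM1–dM12 labels to myeloid cells; non-matches are "unclassified".

    Raises if any input cell is not myeloid: cluster gating is only
    defined within the myeloid compartment.
    """
    if cluster_table is None:
        cluster_table = default_cluster_table()
    is_myeloid = (lineage == "myeloid").to_numpy()
    if not is_myeloid.all():
        raise ValueError("assign_myeloid_cluster requires myeloid cells only")
    # most-specific match wins; ties broken by table priority (ascending)
    ranked = sorted(cluster_table, key=lambda r: (-r.specificity, r.priority))
    label = np.full(len(pos), "unclassified", dtype=object)
    unset = np.ones(len(pos), dtype=bool)
    for rule in ranked:
        hit = rule.matches(pos) & unset
        label[hit] = rule.name
        unset &= ~hit
    return pd.Series(label, index=pos.index, name="cluster")


def is_cd163_hladr_myeloid(pos: pd.DataFrame, lineage: pd.Series) -> pd.Series:
    """Coarse CD163+HLA-DR+ myeloid gate (the immunofluorescence-panel phenotype).

    Usable independently of the 12-cluster table; under the default
    cluster rules it contains dM1, dM2, dM4, dM5 and dM10.
    """
    return pd.Series(
        (lineage == "myeloid").to_numpy() & pos["CD163"].to_numpy() & pos["HLA-DR"].to_numpy(),
        index=pos.index,
        name="cd163_hladr_myeloid",
    )


_T_LABELS = set(T_SUBSETS)


def subset_labels(cells: pd.DataFrame, panel: MarkerPanel) -> pd.Series:
    """Analysis-level partition: trophoblast / CD163+HLA-DR+ myeloid /
    other myeloid / CD4_T / CD8_T / dnT / NK / granulocyte.

    Requires a labelled table (``lineage`` column present)."""
    pos = binarize_frame(cells, panel)
    lineage = cells["lineage"]
    coarse = is_cd163_hladr_myeloid(pos, lineage)
    out = lineage.astype(object).copy()
    out[(lineage == "myeloid") & coarse] = "CD163_HLADR_myeloid"
    out[(lineage == "myeloid") & ~coarse] = "other_myeloid"
    out.name = "subset"
    return out


def label_rois(
    rois: Sequence[ROIFrame],
    panel: MarkerPanel,
    cluster_table: Sequence[GateRule] | None = None,
    drop_blank: bool = True,
) -> tuple[list[ROIFrame], dict[str, int]]:
    """Full gating pass over ROIs: blank exclusion, lineages, myeloid clusters.

    Returns new ROIFrames with ``lineage``/``cluster`` filled and a
    counter dict auditing how many cells were read, dropped as blank and
    retained.
    """
    stats = {"n_input": 0, "n_blank_dropped": 0, "n_retained": 0}
    out: list[ROIFrame] = []
    for roi in rois:
        cells = roi.cells
        stats["n_input"] += len(cells)
        if drop_blank:
            cells, dropped = exclude_blank(cells, panel)
            stats["n_blank_dropped"] += dropped
        stats["n_retained"] += len(cells)
        pos = binarize_frame(cells, panel)
        lineage = assign_lineage(pos)
        cluster = pd.Series(UNASSIGNED, index=cells.index, dtype=object, name="cluster")
        myeloid_mask = lineage == "myeloid"
        if myeloid_mask.any():
            cluster.loc[myeloid_mask] = assign_myeloid_cluster(
                pos.loc[myeloid_mask], lineage.loc[myeloid_mask], cluster_table
            )
        cells = cells.copy()
        cells["lineage"] = lineage
        cells["cluster"] = cluster
        out.append(
            ROIFrame(
                roi_id=roi.roi_id,
                sample_id=roi.sample_id,
                width_um=roi.width_um,
                height_um=roi.height_um,
                basalis_area_mm2=roi.basalis_area_mm2,
                cells=cells,
            )
        )
    return out, stats


def phenotype_fractions(rois: Sequence[ROIFrame], level: str = "lineage") -> pd.DataFrame:
    """Per-sample composition percentages.

    ``level="lineage"``: % of each immune lineage among immune cells
    (trophoblast and unassigned excluded). ``level="cluster"``: % of
    each myeloid cluster among myeloid cells. Percentages sum to 100
    per sample.
    """
    df = pd.concat([r.cells for r in rois], ignore_index=True)
    if level == "lineage":
        t_collapsed = df["lineage"].replace(dict.fromkeys(T_SUBSETS, "T"))
        sub = df.loc[t_collapsed.isin(IMMUNE_LINEAGES)].copy()
        sub["label"] = t_collapsed.loc[sub.index]
    elif level == "cluster":
        sub = df.loc[df["lineage"] == "myeloid"].copy()
        sub["label"] = sub["cluster"]
    else:
        raise ValueError(f"level must be 'lineage' or 'cluster', got {level!r}")
    if sub.empty:
        return pd.DataFrame()
    counts = sub.groupby(["sample_id", "label"], sort=True).size().unstack(fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct


# ---------------------------------------------------------------------------
# gate (de)serialisation
# ---------------------------------------------------------------------------

def gates_to_json(cluster_table: Sequence[GateRule], path: str | Path) -> None:
    doc = {
        "clusters": [
            {
                "name": r.name,
                "require_positive": sorted(r.require_positive),
                "require_negative": sorted(r.require_negative),
                "parent": r.parent,
                "priority": r.priority,
            }
            for r in cluster_table
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def gates_from_json(path: str | Path) -> list[GateRule]:
    doc = json.loads(Path(path).read_text())
    return [
        GateRule(
            name=d["name"],
            require_positive=frozenset(d["require_positive"]),
            require_negative=frozenset(d.get("require_negative", [])),
            parent=d.get("parent", "myeloid"),
            priority=int(d.get("priority", i)),
        )
        for i, d in enumerate(doc["clusters"])
    ]
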