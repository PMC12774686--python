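"""Frequency-corrected microenvironment (proximity) enrichment.

For an ordered phenotype pair (A, B) within one ROI:

* ``observed%`` — the percentage of A-cells with at least one B-cell
  within the neighbourhood radius (default 10 μm, centroid-to-centroid,
  ``<=`` inclusion; a cell is never its own neighbour),
* ``expected%`` — the frequency of B among all phenotype-assigned cells
  in the ROI (×100): the percentage expected if partners were picked at
  random, used as a cell-frequency correction,
* ``corrected = observed% − expected%`` — the enrichment that is
  compared between samples and groups,
* a permutation null: the complete phenotype label vector is shuffled
  across the fixed cell positions (within each ROI) K times and
  observed% recomputed, giving ``z = (obs − mean)/sd``; |z| > 1.96 flags
  pairs whose proximity does not occur at random.

Note the deliberate asymmetry: observed%(A→B) conditions on A-cells, so
it generally differs from observed%(B→A) even though the underlying
neighbour relation is symmetric. Undefined quantities (no source cells,
zero permutation spread) propagate as flagged NaNs, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .cell_model import ROIFrame, UNASSIGNED

__all__ = [
    "NeighborhoodSpec",
    "PairEnrichment",
    "neighbors_within",
    "adjacency_matrix",
    "observed_pct",
    "expected_pct",
    "corrected_enrichment",
    "permutation_null",
    "aggregate_sample",
    "enrichment_matrix",
    "row_zscore",
]

_EXCLUDED_LABELS = (UNASSIGNED,)


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Neighbourhood and permutation-null settings."""

    radius_um: float = 10.0
    min_neighbors: int = 1
    n_permutations: int = 1000
    z_cutoff: float = 1.96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.z_cutoff <= 0:
            raise ValueError("z_cutoff must be > 0")


@dataclass
class PairEnrichment:
    """Enrichment result for one ordered phenotype pair at one level."""

    source: str
    target: str
    level: str  # "roi" or "sample"
    unit_id: str
    n_source: int
    observed_pct: float  # NaN when n_source == 0
    expected_pct: float
    corrected: float
    perm_mean: float = math.nan
    perm_sd: float = math.nan
    perm_z: float = math.nan
    z_defined: bool = False
    significant: bool = False

    @property
    def defined(self) -> bool:
        return self.n_source > 0

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "unit_id": self.unit_id,
            "source": self.source,
            "target": self.target,
            "n_source": self.n_source,
            "observed_pct": self.observed_pct,
            "expected_pct": self.expected_pct,
            "corrected": self.corrected,
            "perm_mean": self.perm_mean,
            "perm_sd": self.perm_sd,
            "perm_z": self.perm_z,
            "z_defined": self.z_defined,
            "significant": self.significant,
        }


# ---------------------------------------------------------------------------
# neighbourhood graph
# ---------------------------------------------------------------------------

def neighbors_within(roi: ROIFrame, spec: NeighborhoodSpec) -> np.ndarray:
    """Unordered neighbour pairs (i, j), i < j, at distance <= radius.

    Indices refer to row positions in ``roi.cells``. Self-pairs are never
    produced; the relation is symmetric by construction.
    """
    pts = roi.positions()
    if len(pts) == 0:
        return np.empty((0, 2), dtype=np.intp)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=spec.radius_um, output_type="ndarray")
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def adjacency_matrix(roi: ROIFrame, spec: NeighborhoodSpec) -> sparse.csr_matrix:
    """Symmetric boolean CSR adjacency of the neighbour relation."""
    n = roi.n_cells
    pairs = neighbors_within(roi, spec)
    if pairs.size == 0:
        return sparse.csr_matrix((n, n), dtype=np.int8)
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return sparse.csr_matrix(
        (np.ones(len(i), dtype=np.int8), (i, j)), shape=(n, n)
    )


def _labels(roi: ROIFrame, label_col: str) -> np.ndarray:
    if label_col not in roi.cells.columns:
        raise KeyError(f"label column {label_col!r} not present in ROI {roi.roi_id}")
    return roi.cells[label_col].to_numpy(dtype=object)


def _check_phenotype(phenotype: str, universe: set | frozenset | None) -> None:
    if universe is not None and phenotype not in universe:
        raise KeyError(f"unknown phenotype {phenotype!r}")


def _observed_from_adj(
    adj: sparse.csr_matrix,
    is_source: np.ndarray,
    is_target: np.ndarray,
    min_neighbors: int,
) -> tuple[float, int, int]:
    """(observed %, n_source_with_partner, n_source); NaN % when no sources."""
    n_source = int(is_source.sum())
    if n_source == 0:
        return math.nan, 0, 0
    n_target_neighbors = adj @ is_target.astype(np.int32)
    hits = int(np.count_nonzero(n_target_neighbors[is_source] >= min_neighbors))
    return 100.0 * hits / n_source, hits, n_source


def observed_pct(
    roi: ROIFrame, source: str, target: str, spec: NeighborhoodSpec,
    label_col: str = "lineage",
    universe: set | frozenset | None = None,
) -> float:
    """% of source-phenotype cells with >= min_neighbors target cells in radius.

    For source == target the focal cell never counts itself. Returns NaN
    (undefined, never 0) when the ROI holds no source cells. Passing a
    phenotype ``universe`` turns misspelt phenotype names into errors
    instead of silently-undefined results.
    """
    labels = _labels(roi, label_col)
    _check_phenotype(source, universe)
    _check_phenotype(target, universe)
    adj = adjacency_matrix(roi, spec)
    pct, _, _ = _observed_from_adj(adj, labels == source, labels == target, spec.min_neighbors)
    return pct


def expected_pct(roi: ROIFrame, target: str, label_col: str = "lineage") -> float:
    """Frequency of the target among phenotype-assigned cells (%), the
    expected microenvironment percentage under random partnering."""
    labels = _labels(roi, label_col)
    assigned = ~np.isin(labels, _EXCLUDED_LABELS)
    n_assigned = int(assigned.sum())
    if n_assigned == 0:
        raise ValueError(f"ROI {roi.roi_id}: no phenotype-assigned cells")
    return 100.0 * int((labels[assigned] == target).sum()) / n_assigned


def corrected_enrichment(
    roi: ROIFrame, source: str, target: str, spec: NeighborhoodSpec,
    label_col: str = "lineage",
) -> PairEnrichment:
    """Observed − expected for one ROI, without the permutation fields."""
    obs = observed_pct(roi, source, target, spec, label_col)
    exp = expected_pct(roi, target, label_col)
    labels = _labels(roi, label_col)
    n_source = int((labels == source).sum())
    return PairEnrichment(
        source=source,
        target=target,
        level="roi",
        unit_id=roi.roi_id,
        n_source=n_source,
        observed_pct=obs,
        expected_pct=exp,
        corrected=obs - exp,
    )


def _fill_permutation_fields(
    result: PairEnrichment, perm_obs: np.ndarray, spec: NeighborhoodSpec
) -> PairEnrichment:
    perm_obs = perm_obs[np.isfinite(perm_obs)]
    if perm_obs.size < 2 or not math.isfinite(result.observed_pct):
        return result
    result.perm_mean = float(perm_obs.mean())
    result.perm_sd = float(perm_obs.std(ddof=1))
    if result.perm_sd > 0:
        result.perm_z = (result.observed_pct - result.perm_mean) / result.perm_sd
        result.z_defined = True
        result.significant = abs(result.perm_z) > spec.z_cutoff
    return result


def permutation_null(
    roi: ROIFrame, source: str, target: str, spec: NeighborhoodSpec,
    label_col: str = "lineage",
) -> PairEnrichment:
    """Full ROI-level enrichment with permutation mean/sd/z.

    Each replicate shuffles the entire label vector over the fixed
    positions (preserving the label multiset) and recomputes observed%.
    Degenerate nulls (sd = 0, e.g. a single-phenotype ROI) leave the z
    flagged undefined and not significant.
    """
    result = corrected_enrichment(roi, source, target, spec, label_col)
    labels = _labels(roi, label_col)
    adj = adjacency_matrix(roi, spec)
    is_source = labels == source
    is_target = labels == target
    rng = np.random.default_rng(spec.seed)
    n = len(labels)
    perm_obs = np.empty(spec.n_permutations)
    for k in range(spec.n_permutations):
        perm = rng.permutation(n)
        pct, _, _ = _observed_from_adj(
            adj, is_source[perm], is_target[perm], spec.min_neighbors
        )
        perm_obs[k] = pct
    return _fill_permutation_fields(result, perm_obs, spec)


def aggregate_sample(
    rois: Sequence[ROIFrame], source: str, target: str, spec: NeighborhoodSpec,
    label_col: str = "lineage",
    with_permutation: bool = True,
) -> PairEnrichment:
    """Sample-level enrichment pooled over a sample's ROIs.

    Cells, not ROIs, are the units: pooled observed% is the
    source-cell-count-weighted mean (Σ hits / Σ n_source) and pooled
    expected% the assigned-cell-count-weighted mean. The permutation
    null permutes labels within each ROI independently and pools each
    replicate the same way.
    """
    if not rois:
        raise ValueError("aggregate_sample needs at least one ROI")
    sample_ids = {r.sample_id for r in rois}
    if len(sample_ids) > 1:
        raise ValueError(f"ROIs span multiple samples: {sorted(sample_ids)}")
    per_roi = []
    total_hits = total_source = 0
    total_target = total_assigned = 0
    for roi in rois:
        labels = _labels(roi, label_col)
        adj = adjacency_matrix(roi, spec)
        is_source = labels == source
        is_target = labels == target
        _, hits, n_src = _observed_from_adj(adj, is_source, is_target, spec.min_neighbors)
        total_hits += hits
        total_source += n_src
        assigned = ~np.isin(labels, _EXCLUDED_LABELS)
        total_assigned += int(assigned.sum())
        total_target += int((labels[assigned] == target).sum())
        per_roi.append((adj, is_source, is_target, len(labels)))
    if total_assigned == 0:
        raise ValueError("no phenotype-assigned cells in sample")
    obs = 100.0 * total_hits / total_source if total_source else math.nan
    exp = 100.0 * total_target / total_assigned
    result = PairEnrichment(
        source=source,
        target=target,
        level="sample",
        unit_id=next(iter(sample_ids)),
        n_source=total_source,
        observed_pct=obs,
        expected_pct=exp,
        corrected=obs - exp,
    )
    if not with_permutation or total_source == 0:
        return result
    rng = np.random.default_rng(spec.seed)
    perm_obs = np.empty(spec.n_permutations)
    for k in range(spec.n_permutations):
        hits_k = 0
        for adj, is_source, is_target, n in per_roi:
            perm = rng.permutation(n)
            _, hits, _ = _observed_from_adj(
                adj, is_source[perm], is_target[perm], spec.min_neighbors
            )
            hits_k += hits
        perm_obs[k] = 100.0 * hits_k / total_source
    return _fill_permutation_fields(result, perm_obs, spec)


def enrichment_matrix(
    rois_by_sample: dict[str, Sequence[ROIFrame]],
    phenotypes: Sequence[str],
    spec: NeighborhoodSpec,
    label_col: str = "lineage",
    with_permutation: bool = False,
) -> tuple[pd.DataFrame, list[PairEnrichment]]:
    """Corrected-enrichment matrix over all ordered phenotype pairs × samples.

    Rows are "A->B" pairs, columns sample IDs; entries are sample-level
    corrected enrichments (NaN where undefined). Also returns the flat
    list of PairEnrichment results for downstream tabulation.
    """
    if len(rois_by_sample) < 2:
        raise ValueError("enrichment_matrix needs >= 2 samples")
    results: list[PairEnrichment] = []
    data: dict[str, dict[str, float]] = {}
    for sample_id in sorted(rois_by_sample):
        col: dict[str, float] = {}
        for a in phenotypes:
            for b in phenotypes:
                res = aggregate_sample(
                    rois_by_sample[sample_id], a, b, spec,
                    label_col=label_col, with_permutation=with_permutation,
                )
                results.append(res)
                col[f"{a}->{b}"] = res.corrected
        data[sample_id] = col
    matrix = pd.DataFrame(data)
    matrix.index.name = "pair"
    return matrix, results


def row_zscore(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row z-transform: (x − row mean) / row SD (sample SD, ddof = 1).

    Rows with zero SD come back all-zero and flagged. NaNs are ignored in
    the row moments and preserved in the output.
    """
    mean = matrix.mean(axis=1, skipna=True)
    sd = matrix.std(axis=1, ddof=1, skipna=True)
    degenerate = (sd == 0) | sd.isna()
    safe_sd = sd.where(~degenerate, 1.0)
    z = matrix.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[degenerate] = z.loc[degenerate].where(matrix.loc[degenerate].isna(), 0.0)
    flags = degenerate.rename("zero_sd")
    return z, flags
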