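"""End-to-end orchestration: simulate → phenotype → microenv → compare.

A :class:`RunConfig` describes one deterministic analysis run: either a
synthetic cohort (embedded :class:`~decimap.synth.SynthConfig`) or
on-disk cell/ROI/sample tables, the marker positivity threshold, the
neighbourhood/permutation settings, the ordered phenotype pairs to
quantify and the between-group comparisons to test. ``run_all`` writes
five CSV outputs plus a JSON manifest; identical config + seed gives
byte-identical files. All stage seeds derive from the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_model import (
    GROUPS,
    ROIFrame,
    SampleMeta,
    density_per_mm2,
    read_cell_table,
    read_sample_table,
)
from .microenv import (
    NeighborhoodSpec,
    aggregate_sample,
    enrichment_matrix,
    row_zscore,
)
from .phenotype import DEFAULT_MARKERS, default_panel, label_rois, subset_labels
from .stats import bonferroni, mwu_exact
from .synth import SynthConfig, generate_cohort, paper_like_scenario

__all__ = ["RunConfig", "RunResult", "validate_config", "run_all"]

log = logging.getLogger("decimap")

#: Analysis-level phenotype universe used for the pair matrix.
SUBSET_PHENOTYPES = (
    "trophoblast",
    "CD163_HLADR_myeloid",
    "other_myeloid",
    "CD4_T",
    "CD8_T",
    "dnT",
    "NK",
    "granulocyte",
)

OUTPUT_FILES = (
    "cells_labeled.csv",
    "enrichment.csv",
    "tests.csv",
    "densities.csv",
    "matrix_rowz.csv",
    "manifest.json",
)


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run (synthetic or file-based input)."""

    seed: int = 0
    out_dir: str = "decimap_out"
    synth: SynthConfig | None = None
    cells_path: str | None = None
    rois_path: str | None = None
    samples_path: str | None = None
    positivity_threshold: float = 0.25
    radius_um: float = 10.0
    min_neighbors: int = 1
    n_permutations: int = 1000
    z_cutoff: float = 1.96
    label_level: str = "subset"
    pairs: tuple[tuple[str, str], ...] = (
        ("CD163_HLADR_myeloid", "CD4_T"),
        ("CD4_T", "CD163_HLADR_myeloid"),
    )
    comparisons: tuple[tuple[str, str], ...] = (("fully_allo_healthy", "semi_allo_healthy"),)
    family_size: int | None = None
    log_level: str = "INFO"

    def neighborhood(self, seed: int) -> NeighborhoodSpec:
        return NeighborhoodSpec(
            radius_um=self.radius_um,
            min_neighbors=self.min_neighbors,
            n_permutations=self.n_permutations,
            z_cutoff=self.z_cutoff,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "synth": self.synth.to_dict() if self.synth is not None else None,
            "cells_path": self.cells_path,
            "rois_path": self.rois_path,
            "samples_path": self.samples_path,
            "positivity_threshold": self.positivity_threshold,
            "radius_um": self.radius_um,
            "min_neighbors": self.min_neighbors,
            "n_permutations": self.n_permutations,
            "z_cutoff": self.z_cutoff,
            "label_level": self.label_level,
            "pairs": [list(p) for p in self.pairs],
            "comparisons": [list(c) for c in self.comparisons],
            "family_size": self.family_size,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        synth = doc.pop("synth", None)
        return cls(
            seed=int(doc.get("seed", 0)),
            out_dir=doc.get("out_dir", "decimap_out"),
            synth=SynthConfig.from_dict(synth) if synth else None,
            cells_path=doc.get("cells_path"),
            rois_path=doc.get("rois_path"),
            samples_path=doc.get("samples_path"),
            positivity_threshold=float(doc.get("positivity_threshold", 0.25)),
            radius_um=float(doc.get("radius_um", 10.0)),
            min_neighbors=int(doc.get("min_neighbors", 1)),
            n_permutations=int(doc.get("n_permutations", 1000)),
            z_cutoff=float(doc.get("z_cutoff", 1.96)),
            label_level=doc.get("label_level", "subset"),
            pairs=tuple(tuple(p) for p in doc.get("pairs", [])) or cls.pairs,
            comparisons=tuple(tuple(c) for c in doc.get("comparisons", []))
            or cls.comparisons,
            family_size=doc.get("family_size"),
            log_level=doc.get("log_level", "INFO"),
        )

    @classmethod
    def paper_like(cls, seed: int = 0, out_dir: str = "decimap_out") -> "RunConfig":
        """Default end-to-end run on the paper-like synthetic scenario."""
        return cls(seed=seed, out_dir=out_dir, synth=paper_like_scenario(seed))


@dataclass
class RunResult:
    out_dir: Path
    cells_labeled: pd.DataFrame
    enrichment: pd.DataFrame
    tests: pd.DataFrame
    densities: pd.DataFrame
    matrix_rowz: pd.DataFrame
    manifest: dict


def validate_config(config: RunConfig) -> list[str]:
    """All violations found in a config; empty list iff valid."""
    issues: list[str] = []
    has_synth = config.synth is not None
    has_files = config.cells_path is not None
    if has_synth == has_files:
        issues.append("exactly one input source required: embedded synth config xor cell table paths")
    if has_files:
        for name in ("cells_path", "samples_path"):
            p = getattr(config, name)
            if p is not None and not Path(p).exists():
                issues.append(f"{name}: file not found: {p}")
    if not (0.0 < config.positivity_threshold <= 1.0):
        issues.append(f"positivity_threshold {config.positivity_threshold} outside (0, 1]")
    if config.radius_um <= 0:
        issues.append(f"radius_um must be > 0, got {config.radius_um}")
    if config.n_permutations < 100:
        issues.append(f"n_permutations must be >= 100, got {config.n_permutations}")
    if config.label_level not in ("subset", "lineage", "cluster"):
        issues.append(f"unknown label_level {config.label_level!r}")
    known = set(SUBSET_PHENOTYPES)
    if config.label_level == "subset":
        for a, b in config.pairs:
            for ph in (a, b):
                if ph not in known:
                    issues.append(f"pair references unknown phenotype {ph!r}")
    for g1, g2 in config.comparisons:
        for g in (g1, g2):
            if g not in GROUPS:
                issues.append(f"comparison references unknown group {g!r}")
    if config.synth is not None:
        total = sum(config.synth.phenotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            issues.append(f"synth phenotype frequencies sum to {total}, expected 1")
        for ph, ms in config.synth.marker_profiles.items():
            for m in ms:
                if m not in DEFAULT_MARKERS:
                    issues.append(f"synth profile {ph!r}: unknown marker {m!r}")
    return issues


def _child_seed(master: int, *key: int) -> int:
    """Deterministic sub-2^31 child seed from the master seed and a key."""
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0] % (2**31))


def _load_inputs(config: RunConfig) -> tuple[list[ROIFrame], list[SampleMeta]]:
    panel = default_panel(config.positivity_threshold)
    if config.synth is not None:
        synth = replace(config.synth, seed=_child_seed(config.seed, 0))
        rois, samples = generate_cohort(synth)
        log.info("simulated %d ROIs across %d samples", len(rois), len(samples))
        return rois, samples
    rois = read_cell_table(config.cells_path, panel, rois=config.rois_path)
    samples = read_sample_table(config.samples_path)
    log.info("read %d ROIs, %d samples", len(rois), len(samples))
    return rois, samples


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all outputs.

    Stages: input (simulate or read) → gating (blank exclusion,
    lineages, myeloid clusters, analysis subsets) → per-ROI densities →
    sample-level pair enrichment with permutation z → enrichment matrix
    + row z-transform → exact MWU group comparisons with Bonferroni
    adjustment. Any stage failure removes partial outputs and raises
    with the stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config:\n" + "\n".join(f"- {s}" for s in issues))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    panel = default_panel(config.positivity_threshold)
    stage = "input"
    try:
        rois, samples = _load_inputs(config)

        stage = "phenotype"
        labeled, gate_stats = label_rois(rois, panel)
        for roi in labeled:
            roi.cells["subset"] = subset_labels(roi.cells, panel)
        log.info(
            "gating: %(n_input)d cells in, %(n_blank_dropped)d blank excluded, %(n_retained)d retained",
            gate_stats,
        )
        cells_labeled = pd.concat([r.cells for r in labeled], ignore_index=True)
        path = out_dir / "cells_labeled.csv"
        cells_labeled.to_csv(path, index=False)
        written.append(path)

        stage = "densities"
        dens_rows = []
        lineages = sorted(cells_labeled["lineage"].unique())
        for roi in labeled:
            for lin in lineages:
                dens_rows.append(
                    {
                        "sample_id": roi.sample_id,
                        "roi_id": roi.roi_id,
                        "lineage": lin,
                        "cells_per_mm2": density_per_mm2(roi, lin, level="lineage"),
                    }
                )
        densities = pd.DataFrame(dens_rows)
        path = out_dir / "densities.csv"
        densities.to_csv(path, index=False)
        written.append(path)

        stage = "microenv"
        label_col = "subset" if config.label_level == "subset" else config.label_level
        by_sample: dict[str, list[ROIFrame]] = {}
        for roi in labeled:
            by_sample.setdefault(roi.sample_id, []).append(roi)
        group_of = {s.sample_id: s.group for s in samples}
        enr_rows = []
        for si, sample_id in enumerate(sorted(by_sample)):
            for pi, (a, b) in enumerate(config.pairs):
                spec = config.neighborhood(_child_seed(config.seed, 1, si, pi))
                res = aggregate_sample(
                    by_sample[sample_id], a, b, spec, label_col=label_col
                )
                row = res.as_dict()
                row["group"] = group_of.get(sample_id, "unknown")
                enr_rows.append(row)
        enrichment = pd.DataFrame(enr_rows)
        path = out_dir / "enrichment.csv"
        enrichment.to_csv(path, index=False)
        written.append(path)

        stage = "matrix"
        spec0 = config.neighborhood(_child_seed(config.seed, 2))
        matrix, _ = enrichment_matrix(
            by_sample, SUBSET_PHENOTYPES, spec0, label_col="subset", with_permutation=False
        )
        rowz, flags = row_zscore(matrix)
        rowz_out = rowz.copy()
        rowz_out["zero_sd"] = flags
        path = out_dir / "matrix_rowz.csv"
        rowz_out.to_csv(path)
        written.append(path)

        stage = "compare"
        test_rows = []
        m = config.family_size or len(config.comparisons)
        for a, b in config.pairs:
            metric = f"corrected_enrichment[{a}->{b}]"
            sub = enrichment[(enrichment["source"] == a) & (enrichment["target"] == b)]
            results = []
            for g1, g2 in config.comparisons:
                v1 = sub.loc[sub["group"] == g1, "corrected"].dropna().to_numpy()
                v2 = sub.loc[sub["group"] == g2, "corrected"].dropna().to_numpy()
                results.append(
                    mwu_exact(
                        v1, v2, metric=metric, group1=g1, group2=g2,
                        seed=_child_seed(config.seed, 3),
                    )
                )
            adj = bonferroni([r.p_two_sided for r in results], max(m, len(results)))
            for r, pa in zip(results, adj):
                r.p_adjusted = float(pa)
                test_rows.append(r.as_dict())
        tests = pd.DataFrame(test_rows)
        path = out_dir / "tests.csv"
        tests.to_csv(path, index=False)
        written.append(path)

        stage = "manifest"
        cfg_doc = config.to_dict()
        cfg_json = json.dumps(cfg_doc, sort_keys=True)
        manifest = {
            "package": "decimap",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "config": cfg_doc,
            "gating": gate_stats,
            "n_samples": len(samples),
            "n_rois": len(labeled),
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
        written.append(path)
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return RunResult(
        out_dir=out_dir,
        cells_labeled=cells_labeled,
        enrichment=enrichment,
        tests=tests,
        densities=densities,
        matrix_rowz=rowz_out,
        manifest=manifest,
    )
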