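"""End-to-end orchestration of the dual-disorder ALE analysis.

``run_dual_ale`` wires the stages together for one effect direction:
study table → quality filter → voxel grid → per-study likelihood maps →
condition means → joint map → permutation null → FDR threshold → clusters →
contribution percentages, study scores and meta-regression — and writes
every artifact (NIfTI maps, CSV tables, JSON summaries) with provenance
(config hash, seed). Reductions and increases are independent invocations,
never merged. Re-running with the same config and seed reproduces the
cluster table byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ale_maps import KernelSpec, LikelihoodMap, condition_mean_map, joint_map, study_map
from .contribution import (
    MetaRegressionResult,
    annotate_contributions,
    covariate_frame,
    meta_regress,
    study_contribution_scores,
)
from .inference import (
    ClusterResult,
    NullDistribution,
    extract_clusters,
    fdr_threshold,
    p_map,
    permute_null,
)
from .stereotax import MNI152_BOUNDS, VoxelGrid, make_grid
from .study_io import (
    DemographicsSummary,
    Direction,
    StudyRecord,
    aggregate_demographics,
    filter_by_quality,
    parse_study_table,
)

__all__ = ["RunConfig", "RunResult", "run_dual_ale", "packaged_study_table"]


def packaged_study_table() -> Path:
    """Path of the packaged 20-study metadata fixture (no foci)."""
    return Path(__file__).parent / "data" / "table2_studies.csv"


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run depends on."""

    studies_path: str
    foci_path: str | None = None
    mask_path: str | None = None
    outdir: str = "dualale_out"
    conditions: tuple[str, str] = ("T1DM", "T2DM")
    direction: Direction = Direction.REDUCTION
    voxel_size: float = 2.0
    bounds: tuple[tuple[float, float], ...] = MNI152_BOUNDS
    fwhm: float = 10.0
    n_permutations: int = 10_000
    q: float = 0.05
    min_cluster_mm3: float = 100.0
    connectivity: int = 18
    quality_threshold: float = 8.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from YAML or JSON (JSON being a YAML subset)."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path}: expected a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "direction" in raw and not isinstance(raw["direction"], Direction):
            raw["direction"] = Direction.parse(raw["direction"])
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        if "bounds" in raw:
            raw["bounds"] = tuple(tuple(map(float, b)) for b in raw["bounds"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> dict:
        d = asdict(self)
        d["direction"] = self.direction.value
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunResult:
    """Artifacts of one completed run (in memory + manifest on disk)."""

    config: RunConfig
    records: tuple[StudyRecord, ...]
    demographics: DemographicsSummary
    grid: VoxelGrid
    mean_maps: Mapping[str, LikelihoodMap]
    joint: LikelihoodMap
    null: NullDistribution
    clusters: tuple[ClusterResult, ...]
    study_scores: Mapping[str, float]
    meta_regression: MetaRegressionResult | None
    meta_regression_error: str | None
    manifest: Mapping[str, Path]

    def cluster_table(self) -> pd.DataFrame:
        """Cluster table mirroring the published layout: cluster id, MNI
        peak, free-text location (left blank — anatomical labeling is out of
        scope), and per-condition contribution percentages."""
        a, b = self.config.conditions
        rows = []
        for c in self.clusters:
            pct = c.contributions or {}
            rows.append(
                {
                    "cluster": c.cluster_id,
                    "peak_x": float(c.peak_mni[0]),
                    "peak_y": float(c.peak_mni[1]),
                    "peak_z": float(c.peak_mni[2]),
                    "location": "",
                    f"pct_{a}": round(pct.get(a, float("nan")), 2),
                    f"pct_{b}": round(pct.get(b, float("nan")), 2),
                    "volume_mm3": c.volume_mm3,
                    "peak_joint": c.peak_value,
                    "n_voxels": c.n_voxels,
                }
            )
        cols = ["cluster", "peak_x", "peak_y", "peak_z", "location",
                f"pct_{a}", f"pct_{b}", "volume_mm3", "peak_joint", "n_voxels"]
        return pd.DataFrame(rows, columns=cols)


def _save_map(lmap: LikelihoodMap, path: Path) -> None:
    nib.save(lmap.to_nifti(), str(path))


def run_dual_ale(config: RunConfig) -> RunResult:
    """Execute the full analysis for one effect direction and write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = parse_study_table(
        config.studies_path, config.foci_path, conditions=config.conditions
    )
    kept = filter_by_quality(records, config.quality_threshold)
    for cond in config.conditions:
        if not any(r.condition == cond for r in kept):
            raise ValueError(
                f"condition {cond!r} has no studies left after the quality "
                f"filter (threshold {config.quality_threshold})"
            )
    demographics = aggregate_demographics(kept)

    grid = make_grid(config.voxel_size, config.bounds, config.mask_path)
    kernel = KernelSpec(fwhm=config.fwhm)

    pairs = [(r, study_map(r, grid, kernel, config.direction)) for r in kept]
    mean_maps = {
        cond: condition_mean_map(
            [m for r, m in pairs if r.condition == cond], label=cond
        )
        for cond in config.conditions
    }
    a, b = config.conditions
    joint = joint_map(mean_maps[a], mean_maps[b])

    null = permute_null(
        kept, grid, kernel, config.direction,
        n_permutations=config.n_permutations, seed=config.seed,
    )
    p = p_map(joint, null)
    sig = fdr_threshold(p, grid, config.q)
    clusters = extract_clusters(
        sig, joint, config.min_cluster_mm3, config.connectivity
    )
    clusters = annotate_contributions(clusters, mean_maps)

    scores = study_contribution_scores(pairs, clusters)
    meta: MetaRegressionResult | None = None
    meta_error: str | None = None
    try:
        meta = meta_regress(scores, covariate_frame(kept))
    except ValueError as exc:
        meta_error = str(exc)

    run_tag = f"{config.direction.value}"
    manifest: dict[str, Path] = {}

    def _register(name: str, path: Path) -> Path:
        manifest[name] = path
        return path

    _save_map(joint, _register("joint_map", outdir / f"ale_{run_tag}_joint.nii.gz"))
    for cond, m in mean_maps.items():
        _save_map(m, _register(f"mean_map_{cond}",
                               outdir / f"ale_{run_tag}_mean_{cond}.nii.gz"))
    p_img = nib.Nifti1Image(p.astype(np.float32), grid.affine)
    nib.save(p_img, str(_register("p_map", outdir / f"ale_{run_tag}_p.nii.gz")))
    sig_img = nib.Nifti1Image(sig.astype(np.uint8), grid.affine)
    nib.save(sig_img, str(_register("sig_map", outdir / f"ale_{run_tag}_sig.nii.gz")))

    result = RunResult(
        config=config,
        records=tuple(kept),
        demographics=demographics,
        grid=grid,
        mean_maps=mean_maps,
        joint=joint,
        null=null,
        clusters=tuple(clusters),
        study_scores=scores,
        meta_regression=meta,
        meta_regression_error=meta_error,
        manifest=manifest,
    )

    provenance = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "dualale_version": __version__,
        "n_studies": len(kept),
        "n_masked_voxels": grid.n_masked,
        "config": config.canonical(),
    }

    result.cluster_table().to_csv(
        _register("clusters", outdir / "clusters.csv"), index=False
    )
    pd.DataFrame(
        [{"study_id": sid, "score": s} for sid, s in scores.items()]
    ).to_csv(_register("study_scores", outdir / "study_scores.csv"), index=False)

    demo_json = {
        "total_patients": demographics.total_patients,
        "total_controls": demographics.total_controls,
        "quality_mean": demographics.quality_mean,
        "quality_sd": demographics.quality_sd,
        "per_condition": {
            cond: {
                "n_studies": s.n_studies,
                "total_patients": s.total_patients,
                "total_controls": s.total_controls,
                "mean_of_means": dict(s.mean_of_means),
                "mean_of_sds": dict(s.mean_of_sds),
                "n_missing": dict(s.n_missing),
            }
            for cond, s in demographics.per_condition.items()
        },
        "tests": {k: dict(v) for k, v in demographics.tests.items()},
    }
    _register("demographics_json", outdir / "demographics.json").write_text(
        json.dumps(demo_json, indent=2)
    )
    demographics.to_frame().to_csv(
        _register("demographics_csv", outdir / "demographics.csv"), index=False
    )

    meta_json: dict[str, object]
    if meta is not None:
        meta_json = {
            name: {
                "params": dict(fit.params),
                "bse": dict(fit.bse),
                "tvalues": dict(fit.tvalues),
                "pvalues": dict(fit.pvalues),
                "n_used": fit.n_used,
                "n_dropped": fit.n_dropped,
                "r_squared": fit.r_squared,
            }
            for name, fit in meta.models.items()
        }
    else:
        meta_json = {"error": meta_error}
    _register("meta_regression", outdir / "meta_regression.json").write_text(
        json.dumps(meta_json, indent=2)
    )
    _register("provenance", outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2)
    )
    return result
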