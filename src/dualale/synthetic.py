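"""Synthetic multi-study foci corpora with known ground truth.

The per-study peak tables behind published coordinate-based meta-analyses
are rarely deposited, so pipeline validation here runs on generated corpora
whose truth is known: a handful of planted effect centers, each expressed by
a study of condition c with probability p_c; an expressed center emits a
fixed number of foci scattered isotropically (Gaussian, default sd 5 mm —
matching the kernel's spatial-uncertainty assumption) around it; on top of
that every study reports a Poisson number of uniform background foci inside
the brain mask. Study covariates (sample sizes, age, duration, HbA1c) are
drawn from ranges typical of the diabetes VBM literature.

The analytic expectation of a planted center's contribution split
(:func:`expected_contribution`) is the oracle recovery tests compare
against: the condition mean map is an average over that condition's
studies, so its expected amplitude at a center is
p_c · foci_per_center · (scatter⊛kernel density), and group sizes cancel in
the ratio.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .stereotax import VoxelGrid, mm_to_voxel, voxel_to_mm
from .study_io import (
    Direction,
    FocusCoordinate,
    Space,
    StudyRecord,
    score_quality,
    write_study_table,
)

__all__ = [
    "EffectCenter",
    "SyntheticTruth",
    "default_truth",
    "generate_corpus",
    "expected_contribution",
    "write_corpus",
]


@dataclass(frozen=True)
class EffectCenter:
    """A planted true-effect location with per-condition expression."""

    xyz: tuple[float, float, float]
    expression: Mapping[str, float]   # condition label -> P(study expresses it)
    scatter_sd: float = 5.0           # mm, isotropic

    def __post_init__(self) -> None:
        if self.scatter_sd <= 0:
            raise ValueError("scatter_sd must be > 0")
        for cond, p in self.expression.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"expression probability for {cond!r} must be in [0, 1]"
                )


@dataclass(frozen=True)
class SyntheticTruth:
    """Full generative configuration for a corpus."""

    centers: tuple[EffectCenter, ...]
    n_studies: Mapping[str, int]      # condition label -> number of studies
    foci_per_center: int = 3
    background_rate: float = 2.0      # expected uniform foci per study
    direction: Direction = Direction.REDUCTION
    seed: int = 1

    def __post_init__(self) -> None:
        if self.foci_per_center < 1:
            raise ValueError("foci_per_center must be >= 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for cond, n in self.n_studies.items():
            if n < 1:
                raise ValueError(f"condition {cond!r} needs >= 1 study")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.n_studies)


#: Default planted configuration: three well-separated interior MNI centers
#: chosen near regions the diabetes VBM literature implicates — a shared
#: caudate-like center expressed equally by both conditions, a posterior
#: cingulate-like center exclusive to T2DM, and a cuneus-like center with a
#: 25/75 expected split.
def default_truth(
    conditions: tuple[str, str] = ("T1DM", "T2DM"),
    n_per_condition: int = 10,
    seed: int = 1,
) -> SyntheticTruth:
    a, b = conditions
    return SyntheticTruth(
        centers=(
            EffectCenter(xyz=(-8.0, 16.0, 8.0), expression={a: 0.9, b: 0.9}),
            EffectCenter(xyz=(0.0, -30.0, 40.0), expression={a: 0.0, b: 0.9}),
            EffectCenter(xyz=(-6.0, -80.0, 42.0), expression={a: 0.3, b: 0.9}),
        ),
        n_studies={a: n_per_condition, b: n_per_condition},
        foci_per_center=3,
        background_rate=2.0,
        seed=seed,
    )


def _draw_scattered_focus(
    rng: np.random.Generator,
    center: np.ndarray,
    sd: float,
    grid: VoxelGrid,
    max_tries: int = 100,
) -> np.ndarray:
    """Gaussian-scattered position, redrawn until inside the mask."""
    for _ in range(max_tries):
        pos = center + rng.normal(0.0, sd, size=3)
        try:
            ijk = mm_to_voxel(grid, pos)
        except ValueError:
            continue
        if grid.mask[ijk]:
            return pos
    return center.copy()


def generate_corpus(
    truth: SyntheticTruth, grid: VoxelGrid
) -> list[StudyRecord]:
    """Draw a full multi-study corpus from the generative model.

    Fully reproducible from ``truth.seed``. Every generated focus lies
    inside the mask. Raises if any planted center falls outside the mask.
    """
    for c in truth.centers:
        ijk = mm_to_voxel(grid, np.asarray(c.xyz))
        if not grid.mask[ijk]:
            raise ValueError(f"planted center {c.xyz} lies outside the mask")

    rng = np.random.default_rng(truth.seed)
    masked_ijk = grid.masked_indices()
    records: list[StudyRecord] = []
    for cond in truth.conditions:
        for i in range(truth.n_studies[cond]):
            foci: list[FocusCoordinate] = []
            for c in truth.centers:
                if rng.random() < c.expression.get(cond, 0.0):
                    for _ in range(truth.foci_per_center):
                        pos = _draw_scattered_focus(
                            rng, np.asarray(c.xyz, dtype=float), c.scatter_sd, grid
                        )
                        foci.append(
                            FocusCoordinate(*map(float, pos), space=Space.MNI,
                                            direction=truth.direction)
                        )
            n_bg = int(rng.poisson(truth.background_rate))
            if n_bg:
                picks = masked_ijk[rng.integers(0, len(masked_ijk), size=n_bg)]
                for ijk in picks:
                    pos = voxel_to_mm(grid, ijk)
                    foci.append(
                        FocusCoordinate(*map(float, pos), space=Space.MNI,
                                        direction=truth.direction)
                    )
            # study-level covariates in ranges typical of the VBM literature
            n_pat = int(rng.integers(15, 120))
            n_ctl = int(rng.integers(15, 120))
            age = float(rng.uniform(25.0, 65.0))
            dur = float(rng.uniform(1.0, 25.0))
            hba1c = float(rng.uniform(6.5, 11.0))
            n_ones = int(rng.integers(8, 13))
            quality = score_quality([1.0] * n_ones + [0.0] * (12 - n_ones))
            records.append(
                StudyRecord(
                    study_id=f"{cond.lower()}_{i + 1:02d}",
                    condition=cond,
                    n_patients=n_pat,
                    n_controls=n_ctl,
                    age_mean=round(age, 1),
                    age_sd=round(float(rng.uniform(2.0, 10.0)), 1),
                    ctrl_age_mean=round(age + float(rng.normal(0.0, 1.5)), 1),
                    ctrl_age_sd=round(float(rng.uniform(2.0, 10.0)), 1),
                    duration_mean=round(dur, 1),
                    duration_sd=round(float(rng.uniform(1.0, 8.0)), 1),
                    hba1c_mean=round(hba1c, 1),
                    hba1c_sd=round(float(rng.uniform(0.5, 2.5)), 1),
                    quality=quality,
                    foci=tuple(foci),
                )
            )
    return records


def expected_contribution(
    truth: SyntheticTruth, center: EffectCenter | int
) -> dict[str, float]:
    """Analytic expected contribution percentages at a planted center.

    The condition mean map's expected amplitude at the center scales with
    p_c · foci_per_center (the per-study expected number of foci there);
    study counts cancel in the mean, so
    pct_c = 100 · p_c / Σ_{c'} p_{c'} for equal foci counts.
    """
    if isinstance(center, int):
        center = truth.centers[center]
    elif center not in truth.centers:
        raise ValueError("center is not part of this truth")
    weights = {
        cond: center.expression.get(cond, 0.0) * truth.foci_per_center
        for cond in truth.conditions
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("center is expressed by no condition")
    return {cond: 100.0 * w / total for cond, w in weights.items()}


def write_corpus(
    records: Sequence[StudyRecord],
    truth: SyntheticTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit studies.csv + foci.csv (the study_io dialect) and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    studies = outdir / "studies.csv"
    foci = outdir / "foci.csv"
    write_study_table(records, studies, foci)
    truth_path = outdir / "truth.json"
    payload = asdict(truth)
    payload["direction"] = truth.direction.value
    payload["centers"] = [
        {"xyz": list(c.xyz), "expression": dict(c.expression),
         "scatter_sd": c.scatter_sd}
        for c in truth.centers
    ]
    payload["n_studies"] = dict(truth.n_studies)
    truth_path.write_text(json.dumps(payload, indent=2))
    return {"studies": studies, "foci": foci, "truth": truth_path}
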