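"""Synthetic aligned PET-like cohorts and synthetic decision tables.

Real D2/3-receptor PET cohorts for the PD-vs-APS problem are not publicly
deposited, so every downstream stage of the pipeline is exercised on phantoms:
per-subject 3D volumes on a common grid, an integer-labeled atlas of R
disjoint box regions (a stand-in for an anatomical parcellation), and binary
group labels.  The generative model is deliberately the simplest one
satisfying the assumptions of the downstream two-sample t-test:

* every brain voxel (atlas label > 0) has mean ``baseline_mean``;
* for PD subjects the mean in each *affected* region is lowered by
  ``effect_size`` (PD hypointensity relative to APS);
* i.i.d. Gaussian noise of standard deviation ``noise_sd`` is added per brain
  voxel, and intensities are clipped at 0 (PET counts are non-negative);
* background voxels are exactly 0.

Defaults mirror the study cohort this package emulates: 87 subjects
(39 PD / 48 APS), 8 atlas regions of which 4 carry the group effect and 2 are
tagged striatal.

`simulate_decision_table` generates, separately, binary region-decision
tables with a prescribed per-region agreement with the label — a direct
fixture for the Bayesian-network fusion stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._common import LABEL_PD, LABEL_APS, LABEL_NAMES, NAME_LABELS, ConfigurationError
from .preprocess import Volume
from .bayesnet import DiscreteDataset

Box = tuple[tuple[int, int, int], tuple[int, int, int]]  # (start, size) in voxels


@dataclass
class AtlasVolume:
    """Integer region labels on the cohort grid; 0 is background."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    striatal_regions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(r) for r in ids if r > 0]

    def region_mask(self, region_id: int) -> np.ndarray:
        if region_id not in self.region_ids:
            raise ValueError(f"unknown region id {region_id}")
        return self.labels == region_id

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class PhantomConfig:
    """Generating parameters of a synthetic cohort (see module docstring)."""

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_regions: int = 8
    region_boxes: tuple[Box, ...] | None = None  # None -> automatic lattice layout
    n_pd: int = 39
    n_aps: int = 48
    affected_regions: tuple[int, ...] = (1, 2, 3, 4)
    striatal_regions: tuple[int, ...] = (1, 2)
    effect_size: float = 20.0
    baseline_mean: float = 100.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ConfigurationError(f"invalid grid shape {self.grid_shape}")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.n_pd < 2 or self.n_aps < 2:
            raise ConfigurationError("each group needs at least 2 subjects")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        region_set = set(range(1, self.n_regions + 1))
        self.affected_regions = tuple(int(r) for r in self.affected_regions)
        self.striatal_regions = tuple(int(r) for r in self.striatal_regions)
        if not set(self.affected_regions) <= region_set:
            raise ConfigurationError("affected_regions must be a subset of 1..R")
        if not set(self.striatal_regions) <= region_set:
            raise ConfigurationError("striatal_regions must be a subset of 1..R")

    @property
    def n_subjects(self) -> int:
        return self.n_pd + self.n_aps


@dataclass
class SyntheticCohort:
    """Volumes + labels + atlas + the config that generated them."""

    volumes: list[Volume]
    labels: np.ndarray  # int array, LABEL_PD / LABEL_APS
    atlas: AtlasVolume
    truth: PhantomConfig = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.volumes) != len(self.labels):
            raise ValueError("volumes and labels length mismatch")
        for v in self.volumes:
            if v.shape != self.atlas.shape:
                raise ValueError("all volumes must share the atlas grid")

    @property
    def n_subjects(self) -> int:
        return len(self.volumes)


def _auto_boxes(grid_shape: tuple[int, int, int], n_regions: int) -> tuple[Box, ...]:
    """Lay out R disjoint boxes on a regular lattice inside the grid.

    The grid is split into k^3 cells (k = smallest integer with k^3 >= R) and
    each region occupies the central half of one cell, guaranteeing
    disjointness and a margin between regions.
    """
    k = max(1, math.ceil(n_regions ** (1.0 / 3.0)))
    while k**3 < n_regions:  # guard against float round-off
        k += 1
    cells = [tuple(s // k for s in grid_shape)]
    cell = cells[0]
    if any(c < 2 for c in cell):
        raise ConfigurationError(
            f"grid {grid_shape} too small for {n_regions} auto-layout regions"
        )
    boxes: list[Box] = []
    for idx in range(n_regions):
        ijk = (idx // (k * k), (idx // k) % k, idx % k)
        start = tuple(ijk[a] * cell[a] + cell[a] // 4 for a in range(3))
        size = tuple(max(1, cell[a] // 2) for a in range(3))
        boxes.append((start, size))
    return tuple(boxes)


def make_atlas(config: PhantomConfig) -> AtlasVolume:
    """Build the integer-labeled atlas of disjoint box regions.

    Raises :class:`ConfigurationError` if a box leaves the grid or two boxes
    overlap.
    """
    boxes = config.region_boxes or _auto_boxes(config.grid_shape, config.n_regions)
    if len(boxes) != config.n_regions:
        raise ConfigurationError(
            f"{len(boxes)} boxes given for {config.n_regions} regions"
        )
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    for rid, (start, size) in enumerate(boxes, start=1):
        if any(s < 0 for s in start) or any(sz < 1 for sz in size):
            raise ConfigurationError(f"invalid box for region {rid}: {start}, {size}")
        stop = tuple(start[a] + size[a] for a in range(3))
        if any(stop[a] > config.grid_shape[a] for a in range(3)):
            raise ConfigurationError(f"region {rid} box exceeds the grid")
        sl = tuple(slice(start[a], stop[a]) for a in range(3))
        if np.any(labels[sl] != 0):
            raise ConfigurationError(f"region {rid} overlaps a previous region")
        labels[sl] = rid
    return AtlasVolume(
        labels=labels,
        voxel_size=config.voxel_size,
        striatal_regions=config.striatal_regions,
    )


def simulate_cohort(config: PhantomConfig) -> SyntheticCohort:
    """Draw one synthetic cohort; identical seed gives a bit-identical cohort.

    PD subjects' expected intensity in each affected region is exactly
    ``effect_size`` below the APS expectation; all other brain voxels are
    identically distributed across groups.
    """
    atlas = make_atlas(config)
    rng = np.random.default_rng(config.seed)
    brain = atlas.brain_mask()
    affected = np.isin(atlas.labels, config.affected_regions)

    mean_aps = np.where(brain, config.baseline_mean, 0.0)
    mean_pd = mean_aps - np.where(affected, config.effect_size, 0.0)

    labels = np.concatenate(
        [np.full(config.n_pd, LABEL_PD), np.full(config.n_aps, LABEL_APS)]
    )
    volumes: list[Volume] = []
    for i, lab in enumerate(labels):
        mean = mean_pd if lab == LABEL_PD else mean_aps
        data = mean.copy()
        if config.noise_sd > 0:
            data[brain] += config.noise_sd * rng.standard_normal(int(brain.sum()))
        np.clip(data, 0.0, None, out=data)
        sid = f"{LABEL_NAMES[int(lab)].lower()}_{i:03d}"
        volumes.append(Volume(data=data, voxel_size=config.voxel_size, subject_id=sid))
    return SyntheticCohort(volumes=volumes, labels=labels, atlas=atlas, truth=config)


def simulate_decision_table(
    n_subjects: int,
    m_regions: int,
    per_region_accuracy,
    label_prevalence: float = 39 / 87,
    seed: int = 0,
) -> DiscreteDataset:
    """Binary region-decision table with prescribed label agreement.

    Column m equals the label with probability ``per_region_accuracy[m]``,
    independently across regions given the label — the conditional-independence
    model under which the per-region accuracies fully parameterize a naive
    (label -> decision) Bayesian network.
    """
    acc = np.broadcast_to(np.asarray(per_region_accuracy, dtype=float), (m_regions,))
    if np.any(acc < 0) or np.any(acc > 1):
        raise ValueError("accuracies must lie in [0, 1]")
    if not 0.0 <= label_prevalence <= 1.0:
        raise ValueError("label_prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    y = (rng.random(n_subjects) < label_prevalence).astype(np.uint8)
    agree = rng.random((n_subjects, m_regions)) < acc[None, :]
    x = np.where(agree, y[:, None], 1 - y[:, None]).astype(np.uint8)
    return DiscreteDataset(data=np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# cohort I/O: one NIfTI per subject + atlas NIfTI + labels CSV + config JSON
# ---------------------------------------------------------------------------

def _affine(voxel_size) -> np.ndarray:
    aff = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    return aff


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id,label"]
    for vol, lab in zip(cohort.volumes, cohort.labels):
        img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size))
        nib.save(img, directory / f"{vol.subject_id}.nii")
        rows.append(f"{vol.subject_id},{LABEL_NAMES[int(lab)]}")
    atlas_img = nib.Nifti1Image(
        cohort.atlas.labels.astype(np.int16), _affine(cohort.atlas.voxel_size)
    )
    nib.save(atlas_img, directory / "atlas.nii")
    (directory / "labels.csv").write_text("\n".join(rows) + "\n")
    cfg = asdict(cohort.truth)
    (directory / "phantom_config.json").write_text(json.dumps(cfg, indent=2) + "\n")


def read_cohort(directory: str | Path) -> SyntheticCohort:
    import nibabel as nib

    directory = Path(directory)
    cfg_path = directory / "phantom_config.json"
    raw = json.loads(cfg_path.read_text())
    raw["grid_shape"] = tuple(raw["grid_shape"])
    raw["voxel_size"] = tuple(raw["voxel_size"])
    if raw.get("region_boxes"):
        raw["region_boxes"] = tuple(
            (tuple(b[0]), tuple(b[1])) for b in raw["region_boxes"]
        )
    config = PhantomConfig(**raw)

    atlas_img = nib.load(str(directory / "atlas.nii"))
    atlas = AtlasVolume(
        labels=np.asarray(atlas_img.dataobj).astype(np.int32),
        voxel_size=config.voxel_size,
        striatal_regions=config.striatal_regions,
    )
    volumes: list[Volume] = []
    labels: list[int] = []
    for line in (directory / "labels.csv").read_text().splitlines()[1:]:
        sid, name = line.strip().split(",")
        img = nib.load(str(directory / f"{sid}.nii"))
        data = np.asarray(img.dataobj, dtype=np.float64)
        volumes.append(Volume(data=data, voxel_size=config.voxel_size, subject_id=sid))
        labels.append(NAME_LABELS[name])
    return SyntheticCohort(
        volumes=volumes, labels=np.asarray(labels), atlas=atlas, truth=config
    )
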