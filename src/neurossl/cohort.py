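"""Synthetic multi-site longitudinal two-modality cohort generator.

The generator emulates the structure that the pretraining and prognosis
stages assume about a real dementia imaging cohort, with every ground-truth
quantity recorded so downstream behaviour can be verified:

* a per-subject latent disease *severity* (unit scale, roughly 0 = healthy,
  1 = advanced) drawn from a three-component mixture over the diagnostic
  classes CN / MCI / AD, progressing linearly in time with a strictly
  positive per-subject slope;
* structural volumes (MRI-like) in which the mean intensity of an interior
  target region falls linearly with severity (an atrophy surrogate), and
  tracer volumes (PET-like) in which the target-region uptake rises with
  severity;
* per-site affine intensity effects (additive shift and multiplicative
  scale) applied inside the brain mask, mimicking scanner differences;
* per-visit PET missingness;
* time-to-conversion drawn from an exponential proportional-hazards model
  whose log-hazard is linear in baseline severity, censored administratively.

Volumes are rendered on a shared grid for both modalities, so MRI/PET pairs
are co-registered by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SubjectState",
    "Volume",
    "generate_cohort",
    "render_volume",
    "generate_volumes",
    "write_cohort",
    "read_cohort",
]

DIAGNOSES = ("CN", "MCI", "AD")


class ConfigurationError(ValueError):
    """Raised when a cohort configuration field is invalid."""


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of the synthetic cohort.

    Severity is on a unit scale; intensities are arbitrary scanner units;
    times are months.  ``site_shift`` / ``site_scale`` parameterize the
    per-site affine intensity transform: site ``s`` (0-based) applies
    ``v -> v * site_scale**s + site_shift * s`` inside the brain mask.
    """

    n_subjects: int = 100
    n_sites: int = 2
    visits_range: tuple[int, int] = (1, 3)
    visit_spacing: float = 12.0          # months between visits
    grid_size: int = 16                  # voxels per axis
    class_probs: tuple[float, float, float] = (0.40, 0.35, 0.25)
    class_severity_means: tuple[float, float, float] = (0.15, 0.45, 0.75)
    class_severity_sd: float = 0.08
    diagnosis_thresholds: tuple[float, float] = (0.30, 0.60)
    progression_rate: float = 0.006      # mean severity slope, /month
    site_shift: float = 5.0              # additive intensity offset per site index
    site_scale: float = 1.0              # multiplicative factor per site index
    pet_missing_prob: float = 0.30
    hazard_baseline: float = 0.01        # events/month at severity 0
    hazard_log_ratio: float = 2.0        # log hazard per severity unit
    censoring_time: float = 48.0         # months
    noise_sd: float = 2.0                # intensity units, inside mask
    healthy_intensity: float = 100.0     # target-region mean at severity 0
    mri_atrophy_slope: float = 40.0      # MRI target intensity drop per severity unit
    pet_uptake_slope: float = 50.0       # PET target intensity rise per severity unit
    texture_amplitude: float = 25.0      # fixed cortical texture outside the target
    contrast_loss: float = 0.4           # fractional texture-contrast loss at severity 1
    anatomy_sd: float = 12.0             # per-subject smooth anatomical field
    gain_sd: float = 0.05                # per-scan multiplicative gain jitter
    voxel_mm: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_sites < 2:
            raise ConfigurationError("n_sites must be >= 2")
        if self.grid_size < 8:
            raise ConfigurationError("grid_size must be >= 8")
        lo, hi = self.visits_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("visits_range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.pet_missing_prob <= 1.0:
            raise ConfigurationError("pet_missing_prob must be in [0, 1]")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or min(self.class_probs) < 0:
            raise ConfigurationError("class_probs must be a probability vector")
        if self.hazard_baseline <= 0:
            raise ConfigurationError("hazard_baseline must be positive")
        if self.hazard_log_ratio < 0:
            raise ConfigurationError("hazard_log_ratio must be non-negative")
        if self.censoring_time <= 0:
            raise ConfigurationError("censoring_time must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.progression_rate <= 0:
            raise ConfigurationError("progression_rate must be positive")
        t0, t1 = self.diagnosis_thresholds
        if not t0 < t1:
            raise ConfigurationError("diagnosis_thresholds must be increasing")


@dataclass
class SubjectState:
    subject_id: int
    site_id: int
    age: float
    sex: int                       # 0/1
    visit_times: np.ndarray        # months from baseline
    severity: np.ndarray           # per visit, non-decreasing
    diagnosis: list[str]           # per visit
    conversion_time: float         # T_p, months
    event: int                     # delta_p
    has_pet: np.ndarray            # per-visit availability flag

    @property
    def n_visits(self) -> int:
        return len(self.visit_times)


@dataclass
class Volume:
    """One 3D intensity grid for one subject-visit-modality."""

    data: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    modality: str                  # "MRI" or "PET"
    subject_id: int
    visit_time: float
    site_id: int

    def validate(self) -> None:
        if self.modality not in ("MRI", "PET"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.data.shape != self.mask.shape:
            raise ValueError("data/mask shape mismatch")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite voxels")
        if not self.mask.any():
            raise ValueError("empty brain mask")


def _diagnosis_of(severity: float, thresholds: tuple[float, float]) -> str:
    if severity < thresholds[0]:
        return "CN"
    if severity < thresholds[1]:
        return "MCI"
    return "AD"


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, list[SubjectState]]:
    """Draw subject states and assemble the per-visit cohort table.

    Deterministic given ``config`` (all randomness flows from a single
    generator seeded with ``config.seed``).  Returns the visit-level table
    (one row per subject-visit, survival outcome repeated across a subject's
    rows) and the list of subject states carrying the latent ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectState] = []
    rows = []
    lo, hi = config.visits_range
    for p in range(config.n_subjects):
        site = int(rng.integers(0, config.n_sites))
        age = float(rng.normal(72.0, 6.0))
        sex = int(rng.integers(0, 2))
        cls = int(rng.choice(3, p=config.class_probs))
        base = float(rng.normal(config.class_severity_means[cls], config.class_severity_sd))
        base = max(base, 0.0)
        # gamma-distributed slope: strictly positive, mean = progression_rate
        slope = float(rng.gamma(shape=4.0, scale=config.progression_rate / 4.0))
        slope = max(slope, 1e-6)
        n_vis = int(rng.integers(lo, hi + 1))
        times = np.arange(n_vis) * config.visit_spacing
        severity = base + slope * times
        diagnosis = [_diagnosis_of(s, config.diagnosis_thresholds) for s in severity]
        lam = config.hazard_baseline * np.exp(config.hazard_log_ratio * base)
        t_raw = float(rng.exponential(1.0 / lam))
        if t_raw <= config.censoring_time:
            T, delta = t_raw, 1
        else:
            T, delta = config.censoring_time, 0
        has_pet = rng.random(n_vis) >= config.pet_missing_prob
        state = SubjectState(
            subject_id=p, site_id=site, age=age, sex=sex,
            visit_times=times, severity=severity, diagnosis=diagnosis,
            conversion_time=T, event=delta, has_pet=has_pet,
        )
        subjects.append(state)
        for k in range(n_vis):
            rows.append({
                "subject_id": p,
                "visit_index": k,
                "visit_time_months": float(times[k]),
                "site_id": site,
                "age": age,
                "sex": sex,
                "diagnosis": diagnosis[k],
                "severity": float(severity[k]),
                "has_mri": True,
                "has_pet": bool(has_pet[k]),
                "T_months": T,
                "event": delta,
            })
    table = pd.DataFrame(rows)
    return table, subjects


def _geometry(grid: int) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal brain mask and interior spherical target region."""
    ax = np.arange(grid)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    c = (grid - 1) / 2.0
    rx, ry, rz = 0.42 * grid, 0.45 * grid, 0.38 * grid
    mask = ((x - c) / rx) ** 2 + ((y - c) / ry) ** 2 + ((z - c) / rz) ** 2 <= 1.0
    tc = (0.60 * (grid - 1), 0.45 * (grid - 1), 0.50 * (grid - 1))
    tr = 0.20 * grid
    target = ((x - tc[0]) ** 2 + (y - tc[1]) ** 2 + (z - tc[2]) ** 2) <= tr**2
    target &= mask
    return mask, target


def _cortical_texture(grid: int) -> np.ndarray:
    """Fixed smooth intensity texture shared by all subjects (a crude
    gray/white contrast surrogate); breaks the degeneracy of a constant
    tissue compartment."""
    ax = np.arange(grid) / grid
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (np.sin(2 * np.pi * x) * np.sin(2 * np.pi * 1.3 * y + 0.7)
            + np.cos(2 * np.pi * 0.8 * z + 0.3))


def _anatomy_field(grid: int, seed: int, subject_id: int) -> np.ndarray:
    """Per-subject smooth anatomical deviation, identical across modalities
    and visits of the subject (co-registered anatomy)."""
    from scipy.ndimage import zoom

    rng = np.random.default_rng([seed, 104729, subject_id])
    coarse = rng.normal(0.0, 1.0, size=(4, 4, 4))
    return zoom(coarse, grid / 4.0, order=1)[:grid, :grid, :grid]


def render_volume(state: SubjectState, visit_index: int, modality: str,
                  config: CohortConfig, rng: np.random.Generator) -> Volume:
    """Render one subject-visit-modality volume.

    Intensity model (inside the brain mask): background tissue at
    ``healthy_intensity``; the target region's mean decreases linearly in
    severity for MRI and increases for PET; then the site affine transform
    and i.i.d. Gaussian noise are applied.  Background voxels are zero.
    """
    if visit_index < 0 or visit_index >= state.n_visits:
        raise IndexError(f"subject {state.subject_id} has no visit {visit_index}")
    if modality not in ("MRI", "PET"):
        raise ValueError(f"unknown modality {modality!r}")
    g = config.grid_size
    mask, target = _geometry(g)
    sev = float(state.severity[visit_index])
    data = np.zeros((g, g, g), dtype=np.float64)
    data[mask] = config.healthy_intensity
    tissue = mask & ~target
    if config.texture_amplitude > 0:
        # gray/white contrast fades with disease severity — a global signature
        # that survives intensity normalization
        amp = config.texture_amplitude * (1.0 - config.contrast_loss * min(sev, 1.0))
        data[tissue] += amp * _cortical_texture(g)[tissue]
    if config.anatomy_sd > 0:
        field = _anatomy_field(g, config.seed, state.subject_id)
        data[tissue] += config.anatomy_sd * field[tissue]
    if modality == "MRI":
        data[target] = config.healthy_intensity - config.mri_atrophy_slope * sev
    else:
        data[target] = config.healthy_intensity + config.pet_uptake_slope * sev
    s = state.site_id
    scale = config.site_scale**s
    shift = config.site_shift * s
    data[mask] = data[mask] * scale + shift
    if config.gain_sd > 0:
        data[mask] *= np.exp(rng.normal(0.0, config.gain_sd))
    if config.noise_sd > 0:
        data[mask] += rng.normal(0.0, config.noise_sd, size=int(mask.sum()))
    vol = Volume(
        data=data, mask=mask, spacing=(config.voxel_mm,) * 3,
        modality=modality, subject_id=state.subject_id,
        visit_time=float(state.visit_times[visit_index]), site_id=s,
    )
    vol.validate()
    return vol


def target_region_mean(vol: Volume, grid: int | None = None) -> float:
    """Mean intensity in the generator's target region (ground-truth probe)."""
    _, target = _geometry(vol.data.shape[0])
    return float(vol.data[target].mean())


def generate_volumes(subjects: list[SubjectState], config: CohortConfig) -> list[Volume]:
    """Render all available volumes, deterministically given the config seed.

    Each volume gets its own child generator keyed by (seed, subject, visit,
    modality), so the output is independent of rendering order.
    """
    vols: list[Volume] = []
    for st in subjects:
        for k in range(st.n_visits):
            mods = ["MRI"] + (["PET"] if st.has_pet[k] else [])
            for mod in mods:
                rng = np.random.default_rng(
                    [config.seed, 7919, st.subject_id, k, 0 if mod == "MRI" else 1]
                )
                vols.append(render_volume(st, k, mod, config, rng))
    return vols


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "subject_id", "visit_index", "visit_time_months", "site_id", "age", "sex",
    "diagnosis", "severity", "has_mri", "has_pet", "T_months", "event",
]


def _volume_filename(v: Volume) -> str:
    k = int(round(v.visit_time))
    return f"sub-{v.subject_id:04d}_t{k:03d}_{v.modality.lower()}.nii.gz"


def write_cohort(volumes: list[Volume], table: pd.DataFrame, directory,
                 config: CohortConfig | None = None) -> Path:
    """Serialize volumes as NIfTI (RAS, spacing on the diagonal), table as CSV.

    Returns the manifest path.  Masks are stored once per subject-visit.
    Volumes containing non-finite voxels are rejected before anything is
    written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for v in volumes:
        v.validate()
    entries = []
    masks_written = set()
    for v in volumes:
        affine = np.diag(list(v.spacing) + [1.0])
        fname = _volume_filename(v)
        nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), directory / fname)
        mask_name = fname.replace(f"_{v.modality.lower()}.nii.gz", "_mask.nii.gz")
        if mask_name not in masks_written:
            nib.save(nib.Nifti1Image(v.mask.astype(np.uint8), affine), directory / mask_name)
            masks_written.add(mask_name)
        entries.append({
            "file": fname, "mask": mask_name, "modality": v.modality,
            "subject_id": int(v.subject_id), "visit_time": float(v.visit_time),
            "site_id": int(v.site_id), "shape": list(v.data.shape),
            "spacing": list(v.spacing),
        })
    table[TABLE_COLUMNS].to_csv(directory / "cohort.csv", index=False)
    manifest = {"volumes": entries, "table": "cohort.csv"}
    if config is not None:
        manifest["config"] = config_to_dict(config)
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_cohort(directory) -> tuple[list[Volume], pd.DataFrame]:
    """Load a cohort written by :func:`write_cohort`.

    Raises ``IOError`` naming the subject-visit if a listed file is missing
    or its shape disagrees with the manifest.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    table = pd.read_csv(directory / manifest["table"])
    vols: list[Volume] = []
    for e in manifest["volumes"]:
        fpath = directory / e["file"]
        who = f"subject {e['subject_id']} visit {e['visit_time']} {e['modality']}"
        if not fpath.exists():
            raise IOError(f"missing volume file {e['file']} for {who}")
        mpath = directory / e["mask"]
        if not mpath.exists():
            raise IOError(f"missing mask file {e['mask']} for {who}")
        img = nib.load(fpath)
        data = np.asarray(img.dataobj, dtype=np.float64)
        if list(data.shape) != e["shape"]:
            raise IOError(f"shape mismatch for {e['file']} ({who})")
        mask = np.asarray(nib.load(mpath).dataobj) > 0
        vols.append(Volume(
            data=data, mask=mask, spacing=tuple(e["spacing"]),
            modality=e["modality"], subject_id=e["subject_id"],
            visit_time=e["visit_time"], site_id=e["site_id"],
        ))
    return vols, table


def config_to_dict(config: CohortConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    for key in ("visits_range", "class_probs", "class_severity_means", "diagnosis_thresholds"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return CohortConfig(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(CohortConfig)}})
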