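"""Synthetic multimodal cohort generator with known ground truth.

Emulates the data structure of a region-wise brain-age study: a healthy
training cohort (default 230 subjects, ages 20-84), held-out healthy and
patient cohorts, and per-subject parcellated voxel maps for three
modalities — gray-matter intensity (GM, 90 regions), voxel-wise average
functional connectivity (FC, 90 regions, Fisher-z units) and fractional
anisotropy (FA, 48 white-matter tracts, bounded in [0, 1]).

Within each region a fixed fraction of voxels carries a linear age signal;
the rest are pure noise. Patient maps can additionally receive
region-specific "accelerated aging" offsets calibrated in years, so the
injected brain-age gap is recoverable downstream. Every generated dataset
carries machine-readable truth (informative voxel indices, injected gaps)
for use as a test oracle.

No anatomy, smoothing, scanner or motion effects are simulated: maps are
emitted already normalized and parcellated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GM", "FC", "FA", "MODALITIES",
    "SubjectRecord", "ModalitySpec", "SyntheticConfig", "Region", "Atlas", "CohortMaps",
    "make_atlas", "generate_subjects", "generate_region_maps", "generate_bold",
    "inject_pathology", "default_effect_spec", "subjects_to_frame", "read_subjects",
    "assemble_volume", "write_cohort", "informative_correlation", "slope_for_correlation",
]

GM = "GM"
FC = "FC"
FA = "FA"
MODALITIES = (GM, FC, FA)

# Optional clinical fields carried only by the patient group.
_SCZ_ONLY_FIELDS = (
    "illness_duration", "age_of_onset",
    "panss_positive", "panss_negative", "panss_general", "cpz_dose",
)


@dataclass
class SubjectRecord:
    """One participant: demographics, group label and clinical covariates.

    Clinical fields (PANSS subscales, illness duration, onset, CPZ dose) are
    populated only for the patient group and are ``None`` for controls.
    """

    subject_id: str
    chronological_age: float
    sex: str                      # "M" | "F"
    group: str                    # "HC" | "SCZ"
    mmse: float
    education: float
    illness_duration: float | None = None
    age_of_onset: float | None = None
    panss_positive: float | None = None
    panss_negative: float | None = None
    panss_general: float | None = None
    cpz_dose: float | None = None
    nicotine_use: bool | None = None
    bmi: float | None = None

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.group not in ("HC", "SCZ"):
            raise ValueError(f"group must be 'HC' or 'SCZ', got {self.group!r}")
        if self.age_of_onset is not None and self.age_of_onset > self.chronological_age:
            raise ValueError("age_of_onset must not exceed chronological_age")
        if self.group == "HC":
            for f in _SCZ_ONLY_FIELDS:
                if getattr(self, f) is not None:
                    raise ValueError(f"{f} may only be set for group='SCZ'")


@dataclass
class ModalitySpec:
    """Atlas size and value scaling for one modality.

    ``baseline`` and ``value_scale`` place the dimensionless signal+noise
    process on the modality's native scale (GM intensity a.u., FC Fisher-z,
    FA in [0, 1]); ``slope_sign`` sets the direction of the aging effect
    (GM intensity and FA decline with age, average connectivity is modeled
    as increasing so the three modalities are not trivially identical).
    """

    n_regions: int
    n_voxels: int = 200
    baseline: float = 0.0
    value_scale: float = 1.0
    slope_sign: int = -1


def _default_atlas_spec() -> dict[str, ModalitySpec]:
    return {
        GM: ModalitySpec(n_regions=90, n_voxels=200, baseline=10.0, value_scale=1.0, slope_sign=-1),
        FC: ModalitySpec(n_regions=90, n_voxels=200, baseline=0.5, value_scale=0.1, slope_sign=+1),
        FA: ModalitySpec(n_regions=48, n_voxels=200, baseline=0.5, value_scale=0.005, slope_sign=-1),
    }


def slope_for_correlation(r: float, noise_sd: float, age_sd: float) -> float:
    """Signal slope (voxel-units/year) giving population voxel-age correlation r.

    Inverts r = slope*age_sd / sqrt(slope^2*age_sd^2 + noise_sd^2).
    """
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    return float(noise_sd * r / (np.sqrt(1.0 - r * r) * age_sd))


def informative_correlation(slope: float, noise_sd: float, age_sd: float) -> float:
    """Population |correlation| of an informative voxel with age (closed form)."""
    s = abs(slope) * age_sd
    return float(s / np.hypot(s, noise_sd))


def default_effect_spec() -> dict[str, dict[int, float]]:
    """Accelerated aging of +5 years in 10 gray-matter regions.

    The ten region ids stand in for the bilateral insula / inferior frontal /
    superior temporal set where patient cohorts show the largest gaps.
    """
    return {GM: {rid: 5.0 for rid in (29, 30, 12, 15, 17, 23, 26, 81, 83, 84)}}


def _uniform_sd(lo: float, hi: float) -> float:
    return (hi - lo) / np.sqrt(12.0)


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate the study design: 230 healthy training subjects with
    ages uniform on [20, 84], held-out cohorts of 100 controls and 194
    patients, 90/90/48 regions of 200 voxels, 20% of voxels per region
    age-informative with population |r| ~= 0.6, and a +5-year gap injected
    into ten GM regions of the patient group.
    """

    n_hc_train: int = 230
    n_hc_test: int = 100
    n_scz: int = 194
    age_range: tuple[float, float] = (20.0, 84.0)
    atlas_spec: dict[str, ModalitySpec] = field(default_factory=_default_atlas_spec)
    signal_fraction: float = 0.2
    signal_slope: float = slope_for_correlation(0.6, 1.0, _uniform_sd(20.0, 84.0))
    noise_sd: float = 1.0
    effect_spec: dict[str, dict[int, float]] = field(default_factory=default_effect_spec)
    duration_scaled: bool = False
    male_fraction: float = 0.4
    # reporting jitter on illness duration (years); keeps {duration, onset, age}
    # from being exactly collinear in clinical regression designs
    duration_jitter_sd: float = 1.5
    # BOLD generation (used when FC maps are built from time series)
    bold_n_timepoints: int = 120
    bold_tr: float = 2.0
    bold_band: tuple[float, float] = (0.01, 0.1)
    bold_common_weight: float = 0.6
    bold_weight_age_slope: float = 0.15
    bold_idio_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must satisfy min < max, got {self.age_range}")
        for name in ("n_hc_train", "n_hc_test", "n_scz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_hc_train <= 0:
            raise ValueError("n_hc_train must be positive")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for mod, spec in self.atlas_spec.items():
            if mod not in MODALITIES:
                raise ValueError(f"unknown modality {mod!r}")
            if spec.n_regions <= 0 or spec.n_voxels <= 0:
                raise ValueError(f"{mod}: region and voxel counts must be positive")

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    @property
    def age_sd(self) -> float:
        return _uniform_sd(*self.age_range)


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    region_id: int
    name: str
    voxel_indices: np.ndarray  # sorted linear indices into the label volume


@dataclass
class Atlas:
    """A parcellation: positive integer labels over a 3-D volume.

    Region voxel sets are pairwise disjoint, nonempty, and stored as sorted
    linear (row-major) indices, which fixes the voxel order of every
    downstream region map.
    """

    modality: str
    regions: list[Region]
    shape: tuple[int, int, int]

    def __post_init__(self):
        seen: set[int] = set()
        total = int(np.prod(self.shape))
        for reg in self.regions:
            if reg.region_id <= 0:
                raise ValueError("region labels must be positive integers")
            idx = np.asarray(reg.voxel_indices)
            if idx.size == 0:
                raise ValueError(f"region {reg.region_id} is empty")
            if idx.min() < 0 or idx.max() >= total:
                raise ValueError(f"region {reg.region_id} indices out of volume bounds")
            s = set(int(i) for i in idx)
            if seen & s:
                raise ValueError("region voxel sets must be pairwise disjoint")
            seen |= s

    @property
    def region_ids(self) -> list[int]:
        return [r.region_id for r in self.regions]

    @property
    def n_voxels_total(self) -> int:
        return int(sum(r.voxel_indices.size for r in self.regions))

    def region(self, region_id: int) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"region id {region_id} not in {self.modality} atlas")

    def label_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=np.int16)
        flat = vol.reshape(-1)
        for r in self.regions:
            flat[r.voxel_indices] = r.region_id
        return vol


def make_atlas(modality: str, n_regions: int, n_voxels: int) -> Atlas:
    """Compact synthetic label atlas: regions tile a near-cubic volume.

    Region ids are 1..n_regions and each region occupies ``n_voxels``
    consecutive linear indices, so parcellation order is unambiguous.
    """
    total = n_regions * n_voxels
    side = int(np.ceil(total ** (1.0 / 3.0)))
    shape = (side, side, int(np.ceil(total / (side * side))))
    regions = [
        Region(region_id=i + 1, name=f"{modality}_{i + 1:03d}",
               voxel_indices=np.arange(i * n_voxels, (i + 1) * n_voxels))
        for i in range(n_regions)
    ]
    return Atlas(modality=modality, regions=regions, shape=shape)


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

def _clip_round(x, lo, hi):
    return float(np.clip(np.round(x), lo, hi))


def generate_subjects(config: SyntheticConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    """Draw the three cohorts (HC-train, HC-test, SCZ).

    Ages are uniform over ``config.age_range`` for every cohort. Covariate
    distributions follow the study's clinicodemographic table: controls
    score near ceiling on the MMSE (29 +/- 1) with ~16 years of education;
    patients score lower (26.8 +/- 3.4, ~12.5 years), carry PANSS subscale
    scores, an onset age near 27.7 +/- 9.4 truncated below the subject's
    age, illness duration = age - onset, and an antipsychotic dose
    (chlorpromazine-equivalent, 402 +/- 324 mg/day) recorded for ~83% of
    them. Covariates are drawn independently of age.
    """
    lo, hi = config.age_range
    subjects: list[SubjectRecord] = []

    def draw_hc(i: int, cohort: str) -> SubjectRecord:
        age = float(rng.uniform(lo, hi))
        return SubjectRecord(
            subject_id=f"{cohort}-{i:04d}",
            chronological_age=age,
            sex="M" if rng.random() < config.male_fraction else "F",
            group="HC",
            mmse=_clip_round(rng.normal(29.0, 1.0), 0, 30),
            education=float(np.clip(rng.normal(15.9, 3.7), 6.0, 25.0)),
            nicotine_use=bool(rng.random() < 0.12),
            bmi=float(np.clip(rng.normal(23.4, 3.3), 15.0, 45.0)),
        )

    for i in range(config.n_hc_train):
        subjects.append(draw_hc(i, "TRN"))
    for i in range(config.n_hc_test):
        subjects.append(draw_hc(i, "HC"))
    for i in range(config.n_scz):
        age = float(rng.uniform(lo, hi))
        onset = float(np.clip(rng.normal(27.7, 9.4), 12.0, age - 0.5))
        duration = float(max(0.25, age - onset + rng.normal(0.0, config.duration_jitter_sd)))
        cpz = float(max(25.0, rng.normal(402.0, 324.0))) if rng.random() < 0.83 else None
        subjects.append(SubjectRecord(
            subject_id=f"SCZ-{i:04d}",
            chronological_age=age,
            sex="M" if rng.random() < 0.44 else "F",
            group="SCZ",
            mmse=_clip_round(rng.normal(26.8, 3.4), 0, 30),
            education=float(np.clip(rng.normal(12.5, 3.6), 6.0, 25.0)),
            illness_duration=duration,
            age_of_onset=onset,
            panss_positive=_clip_round(rng.normal(10.7, 3.4), 7, 49),
            panss_negative=_clip_round(rng.normal(10.0, 3.8), 7, 49),
            panss_general=_clip_round(rng.normal(21.3, 5.2), 16, 112),
            cpz_dose=cpz,
            nicotine_use=bool(rng.random() < 0.335),
            bmi=float(np.clip(rng.normal(25.1, 4.4), 15.0, 45.0)),
        ))
    return subjects


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate records; column names match SubjectRecord field names."""
    cols = [f.name for f in dataclasses.fields(SubjectRecord)]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in subjects], columns=cols)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: not a subject metadata table (no subject_id column)")
    return df


# ---------------------------------------------------------------------------
# Region maps
# ---------------------------------------------------------------------------

@dataclass
class CohortMaps:
    """Per-region voxel-value matrices for one modality and one subject list.

    ``values[region_id]`` is an (n_subjects, n_voxels) array whose column
    order matches the atlas region's sorted voxel order.  ``informative``
    carries the ground-truth age-signal voxel indices per region.
    """

    modality: str
    subject_ids: list[str]
    values: dict[int, np.ndarray]
    informative: dict[int, np.ndarray]

    def copy(self) -> "CohortMaps":
        return CohortMaps(
            modality=self.modality,
            subject_ids=list(self.subject_ids),
            values={k: v.copy() for k, v in self.values.items()},
            informative={k: v.copy() for k, v in self.informative.items()},
        )


def generate_region_maps(
    subjects: Sequence[SubjectRecord],
    atlas: Atlas,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> CohortMaps:
    """Generate voxel values for every subject x region of one modality.

    Within each region, ``floor(signal_fraction * n_voxels)`` voxels (chosen
    at random per region) have expectation
    ``baseline + value_scale * slope_sign * signal_slope * (age - age_mid)``;
    the remainder are pure noise around the baseline. All voxels receive iid
    Gaussian noise of sd ``value_scale * noise_sd``. FA values are clipped
    to [0, 1].
    """
    spec = config.atlas_spec.get(atlas.modality) or ModalitySpec(
        n_regions=len(atlas.regions))
    ages = np.array([s.chronological_age for s in subjects], dtype=float)
    n = len(subjects)
    centered = ages - config.age_mid
    slope = spec.slope_sign * config.signal_slope

    values: dict[int, np.ndarray] = {}
    informative: dict[int, np.ndarray] = {}
    for reg in atlas.regions:
        V = reg.voxel_indices.size
        k = int(np.floor(config.signal_fraction * V))
        info = np.sort(rng.choice(V, size=k, replace=False)) if k else np.array([], dtype=int)
        x = rng.normal(0.0, config.noise_sd, size=(n, V))
        if k:
            x[:, info] += slope * centered[:, None]
        x = spec.baseline + spec.value_scale * x
        if atlas.modality == FA:
            np.clip(x, 0.0, 1.0, out=x)
        values[reg.region_id] = x
        informative[reg.region_id] = info
    return CohortMaps(
        modality=atlas.modality,
        subject_ids=[s.subject_id for s in subjects],
        values=values,
        informative=informative,
    )


def inject_pathology(
    maps: CohortMaps,
    subjects: Sequence[SubjectRecord],
    effect_spec: Mapping[int, float],
    config: SyntheticConfig,
    duration_scaled: bool | None = None,
) -> CohortMaps:
    """Shift informative voxels of listed regions for patient subjects only.

    The voxel-level offset for a gap of g years is
    ``slope_sign * value_scale * signal_slope * g`` — i.e. exactly the map
    change a subject g years older would show on the informative voxels, so
    a downstream age model recovers the injected gap 1:1 in expectation.
    With ``duration_scaled`` the offset is multiplied by
    ``illness_duration / mean(illness_duration)`` across dosed patients.
    Returns a modified copy; the input is untouched.
    """
    if duration_scaled is None:
        duration_scaled = config.duration_scaled
    out = maps.copy()
    if not effect_spec:
        return out
    spec = config.atlas_spec[maps.modality]
    slope = spec.slope_sign * spec.value_scale * config.signal_slope

    scz = [(i, s) for i, s in enumerate(subjects) if s.group == "SCZ"]
    if duration_scaled:
        durs = np.array([s.illness_duration or 0.0 for _, s in scz], dtype=float)
        mean_dur = durs.mean() if len(durs) and durs.mean() > 0 else 1.0

    for region_id, gap_years in effect_spec.items():
        if region_id not in out.values:
            raise KeyError(f"effect_spec region id {region_id} not in {maps.modality} atlas")
        info = out.informative[region_id]
        if info.size == 0:
            continue
        vals = out.values[region_id]
        for j, (i, s) in enumerate(scz):
            factor = (s.illness_duration or 0.0) / mean_dur if duration_scaled else 1.0
            vals[np.ix_([i], info)] += slope * gap_years * factor
    return out


# ---------------------------------------------------------------------------
# BOLD time series
# ---------------------------------------------------------------------------

def _bandlimited_noise(rng: np.random.Generator, shape_vt: tuple[int, int],
                       tr: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance noise restricted to [band] Hz (FFT masking)."""
    v, t = shape_vt
    white = rng.standard_normal((v, t))
    freqs = np.fft.rfftfreq(t, d=tr)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        mask[min(1, len(mask) - 1)] = True  # degenerate short series: keep one bin
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~mask] = 0.0
    x = np.fft.irfft(spec, n=t, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_bold(
    subjects: Sequence[SubjectRecord],
    atlas: Atlas,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Band-limited voxel x time series with an age-modulated shared signal.

    Each subject's voxel v follows ``w(age) * s(t) + idio_sd * e_v(t)`` with
    s and e_v independent unit-variance band-limited processes, so expected
    pairwise voxel correlation is ``w^2 / (w^2 + idio_sd^2)`` and average
    connectivity rises with the age-dependent weight
    ``w(age) = common_weight + weight_age_slope * (age - mid)/(range/2)``
    (clipped to [0, 1]). Returns (series by subject, true weight by subject).

    Memory scales as n_subjects x V x T; intended for desk-scale atlases.
    """
    t = config.bold_n_timepoints
    if t < 2:
        raise ValueError("bold_n_timepoints must be >= 2 (correlation undefined)")
    V = atlas.n_voxels_total
    half_range = 0.5 * (config.age_range[1] - config.age_range[0])
    series: dict[str, np.ndarray] = {}
    weights: dict[str, float] = {}
    for s in subjects:
        w = float(np.clip(
            config.bold_common_weight
            + config.bold_weight_age_slope * (s.chronological_age - config.age_mid) / half_range,
            0.0, 1.0))
        common = _bandlimited_noise(rng, (1, t), config.bold_tr, config.bold_band)
        idio = _bandlimited_noise(rng, (V, t), config.bold_tr, config.bold_band)
        series[s.subject_id] = w * common + config.bold_idio_sd * idio
        weights[s.subject_id] = w
    return series, weights


# ---------------------------------------------------------------------------
# Volume assembly and on-disk cohort
# ---------------------------------------------------------------------------

def assemble_volume(region_values: Mapping[int, np.ndarray], atlas: Atlas) -> np.ndarray:
    """Place one subject's per-region voxel vectors into the atlas volume."""
    vol = np.zeros(atlas.shape, dtype=np.float64)
    flat = vol.reshape(-1)
    for reg in atlas.regions:
        vals = np.asarray(region_values[reg.region_id])
        if vals.shape != (reg.voxel_indices.size,):
            raise ValueError(
                f"region {reg.region_id}: expected {reg.voxel_indices.size} voxels, "
                f"got shape {vals.shape}")
        flat[reg.voxel_indices] = vals
    return vol


def write_cohort(
    out_dir,
    subjects: Sequence[SubjectRecord],
    maps_by_modality: Mapping[str, CohortMaps],
    atlases: Mapping[str, Atlas],
    config: SyntheticConfig | None = None,
) -> Path:
    """Write a cohort to disk: subjects.tsv, per-modality label atlas and
    per-subject 3-D NIfTI volumes, plus a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects_to_frame(subjects).to_csv(out / "subjects.tsv", sep="\t", index=False)
    eye = np.eye(4)
    truth: dict = {"informative_voxels": {}, "effect_spec": {}}
    for mod, maps in maps_by_modality.items():
        atlas = atlases[mod]
        nib.save(nib.Nifti1Image(atlas.label_volume().astype(np.int16), eye),
                 out / f"atlas_{mod}.nii.gz")
        for i, sid in enumerate(maps.subject_ids):
            vol = assemble_volume({rid: maps.values[rid][i] for rid in maps.values}, atlas)
            # float64 so file-based stage reruns reproduce in-memory runs exactly
            nib.save(nib.Nifti1Image(vol, eye), out / f"sub-{sid}_{mod}.nii.gz")
        truth["informative_voxels"][mod] = {
            str(rid): idx.tolist() for rid, idx in maps.informative.items()}
    if config is not None:
        truth["effect_spec"] = {m: {str(k): v for k, v in d.items()}
                                for m, d in config.effect_spec.items()}
        truth["signal_slope"] = config.signal_slope
        truth["noise_sd"] = config.noise_sd
    (out / "truth.json").write_text(json.dumps(truth))
    return out
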