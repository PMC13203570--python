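"""Synthetic multi-channel phantom cohorts with known habitat structure.

Each patient gets two disjoint ellipsoidal regions of interest (a larger
primary tumor, GTVp, and a smaller merged metastatic-lymph-node region,
MLN) on a common grid.  Inside the ROIs a spatially smooth latent class
field over ``k_true`` habitat classes is planted by thresholding a
smoothed Gaussian random field at fixed standard-normal quantile cuts;
each class has its own per-channel intensity mean and SD.  Overall
survival is drawn from a proportional-hazards model whose linear
predictor loads on the true per-region habitat-class proportions plus
clinical covariates, with independent exponential censoring truncated
administratively.

Because the latent field is a correlated random field, the per-patient
class proportions fluctuate around 1/k_true, which is what gives the
habitat-composition features prognostic signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .preprocess import RegionMask, Volume3D

CHANNELS = ("T1", "T1C", "T2")
REGIONS = ("GTVp", "MLN")

PATIENT_CSV_COLUMNS = [
    "patient_id",
    "time_months",
    "event",
    "age_years",
    "t_stage",
    "n_stage",
    "ebv_dna_copies_per_ml",
]


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


def default_channel_means(k_true: int, separation: float = 5.0) -> np.ndarray:
    """Class-mean intensity matrix (k_true x 3) with classes ``separation``
    intensity units apart in every channel.

    The class ordering differs per channel (identity / reversed / rolled)
    so that no two channels are copies of each other.
    """
    base = separation * np.arange(k_true, dtype=float)
    return np.column_stack([base, base[::-1], np.roll(base, k_true // 2)])


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort; the seed determines
    every array and survival time bit-for-bit."""

    n_patients: int = 120
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    k_true: int = 6
    channel_means: np.ndarray | None = None  # k_true x 3
    channel_sds: np.ndarray | None = None  # k_true x 3
    blob_smoothness: float = 6.0
    gtvp_radius_range: tuple[float, float] = (9.0, 13.0)
    mln_radius_range: tuple[float, float] = (4.5, 7.0)
    hazard_betas: np.ndarray | None = None  # on 2*k_true true proportions
    clinical_betas: tuple[float, float, float, float] = (0.3, 0.2, 0.25, 0.5)
    baseline_hazard_rate: float = 0.0025  # events per month
    censor_rate: float = 0.010  # per month
    admin_censor_time: float = 96.0  # months
    background_noise_sd: float = 0.05
    class_prevalence: np.ndarray | None = None  # expected class shares
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise CohortConfigError("k_true must be >= 2")
        if self.n_patients < 1:
            raise CohortConfigError("n_patients must be >= 1")
        if min(self.baseline_hazard_rate, self.censor_rate) <= 0:
            raise CohortConfigError("hazard and censor rates must be > 0")
        if self.admin_censor_time <= 0:
            raise CohortConfigError("admin_censor_time must be > 0")
        if self.channel_means is None:
            self.channel_means = default_channel_means(self.k_true)
        self.channel_means = np.asarray(self.channel_means, dtype=float)
        if self.channel_sds is None:
            self.channel_sds = np.ones((self.k_true, 3))
        self.channel_sds = np.asarray(self.channel_sds, dtype=float)
        if self.channel_means.shape != (self.k_true, 3):
            raise CohortConfigError("channel_means must be k_true x 3")
        if self.channel_sds.shape != (self.k_true, 3):
            raise CohortConfigError("channel_sds must be k_true x 3")
        if self.hazard_betas is None:
            b = np.zeros(self.k_true)
            b[0], b[1] = 3.0, -2.0
            self.hazard_betas = np.concatenate([b, b])
        self.hazard_betas = np.asarray(self.hazard_betas, dtype=float)
        if self.hazard_betas.shape != (2 * self.k_true,):
            raise CohortConfigError("hazard_betas must have length 2*k_true")
        if self.class_prevalence is not None:
            self.class_prevalence = np.asarray(self.class_prevalence, float)
            if self.class_prevalence.shape != (self.k_true,):
                raise CohortConfigError(
                    "class_prevalence must have length k_true"
                )
            if np.any(self.class_prevalence <= 0):
                raise CohortConfigError("class_prevalence must be positive")
            self.class_prevalence = (
                self.class_prevalence / self.class_prevalence.sum()
            )
        for rng_ in (self.gtvp_radius_range, self.mln_radius_range):
            if rng_[0] > rng_[1] or rng_[0] <= 0:
                raise CohortConfigError("invalid radius range")
        if 2 * self.gtvp_radius_range[1] >= min(self.grid_shape):
            raise CohortConfigError("GTVp radii do not fit inside the grid")


@dataclass
class PatientRecord:
    patient_id: str
    time_months: float
    event: int
    age_years: float
    t_stage: int
    n_stage: int
    ebv_dna_copies_per_ml: float

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError("time_months must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class LatentTruth:
    """Ground truth for one phantom, kept for parameter-recovery tests."""

    label_field: np.ndarray  # 0 outside ROIs, 1..k_true inside
    proportions: dict[str, np.ndarray]  # region -> length-k_true simplex
    linear_predictor: float | None = None

    def feature_vector(self) -> np.ndarray:
        """GTVp proportions followed by MLN proportions (length 2k)."""
        return np.concatenate(
            [self.proportions["GTVp"], self.proportions["MLN"]]
        )


def _rng_for(config: CohortConfig, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(patient_index), stream])
    )


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _place_regions(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint ellipsoids: GTVp in the front half of the grid, MLN
    behind it.  Raises if the sampled geometry cannot be disjoint."""
    shape = np.array(config.grid_shape, dtype=float)
    g_rad = rng.uniform(*config.gtvp_radius_range, size=3)
    m_rad = rng.uniform(*config.mln_radius_range, size=3)
    jitter = rng.uniform(-1.5, 1.5, size=(2, 2))
    # anchor GTVp near the low-x end and MLN near the high-x end so the
    # sampled radii always leave the largest possible axial gap
    g_center = np.array(
        [1.5 + g_rad[0], shape[1] / 2 + jitter[0, 0], shape[2] / 2 + jitter[0, 1]]
    )
    m_center = np.array(
        [
            shape[0] - 2.5 - m_rad[0],
            shape[1] / 2 + jitter[1, 0],
            shape[2] / 2 + jitter[1, 1],
        ]
    )
    gtvp = _ellipsoid_mask(config.grid_shape, g_center, g_rad)
    mln = _ellipsoid_mask(config.grid_shape, m_center, m_rad)
    touching = (
        ndimage.binary_dilation(gtvp, iterations=2) & mln
    ).any()
    if touching:
        raise CohortConfigError(
            "GTVp and MLN ellipsoids cannot be placed disjointly; "
            "reduce the radius ranges or enlarge the grid"
        )
    for name, m in (("GTVp", gtvp), ("MLN", mln)):
        if not m.any():
            raise CohortConfigError(f"{name} ellipsoid is empty on this grid")
    return gtvp, mln


def _prevalence_offsets(p: np.ndarray) -> np.ndarray:
    """Per-field additive offsets c such that the voxel-wise argmax of k
    unit-variance Gaussian fields shifted by c hits the target class
    shares p.  Solved by a fixed-point iteration on the closed-form
    argmax probabilities (1-D integrals); spatial correlation leaves the
    per-voxel marginals untouched, so this is exact for the mosaic."""
    k = len(p)
    c = np.zeros(k)
    x = np.linspace(-8.0, 8.0, 2001)
    for _ in range(60):
        logcdf = np.stack([norm.logcdf(x - ci) for ci in c])
        tot = logcdf.sum(axis=0)
        cur = np.array(
            [
                np.trapezoid(np.exp(norm.logpdf(x - c[j]) + tot - logcdf[j]), x)
                for j in range(k)
            ]
        )
        cur /= cur.sum()
        c += np.log(p) - np.log(cur)
        c -= c.mean()
        if np.max(np.abs(np.log(p) - np.log(cur))) < 1e-10:
            break
    return c


def _latent_field(
    config: CohortConfig, roi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Spatially coherent habitat mosaic: the voxel-wise argmax of
    k_true independent smoothed Gaussian random fields (optionally
    shifted to hit a target prevalence profile).

    Each class forms compact blobs whose realized per-patient
    proportions fluctuate around the expected shares, which is what
    gives the habitat-composition features prognostic signal.  Labels
    are 1..k_true inside roi, 0 outside.
    """
    offsets = np.zeros(config.k_true)
    if config.class_prevalence is not None:
        offsets = _prevalence_offsets(config.class_prevalence)
    fields = np.empty((config.k_true,) + tuple(config.grid_shape))
    for j in range(config.k_true):
        f = ndimage.gaussian_filter(
            rng.standard_normal(config.grid_shape),
            sigma=config.blob_smoothness,
        )
        fields[j] = (f - f.mean()) / f.std() + offsets[j]
    labels = (np.argmax(fields, axis=0) + 1).astype(np.int16)
    labels[~roi] = 0
    return labels


def make_truth(config: CohortConfig, patient_index: int) -> tuple[
    dict[str, RegionMask], LatentTruth
]:
    """Geometry + latent habitat field only (no intensity volumes).

    A fast path for survival-level experiments that work from the true
    habitat maps.
    """
    if patient_index >= config.n_patients:
        raise IndexError("patient_index out of range")
    rng = _rng_for(config, patient_index, 0)
    gtvp, mln = _place_regions(config, rng)
    roi = gtvp | mln
    labels = _latent_field(config, roi, rng)
    props = {}
    for name, m in (("GTVp", gtvp), ("MLN", mln)):
        counts = np.bincount(labels[m], minlength=config.k_true + 1)[1:]
        props[name] = counts / counts.sum()
    masks = {
        "GTVp": RegionMask(gtvp, region="GTVp"),
        "MLN": RegionMask(mln, region="MLN"),
    }
    return masks, LatentTruth(label_field=labels, proportions=props)


def make_phantom(config: CohortConfig, patient_index: int) -> tuple[
    dict[str, Volume3D], dict[str, RegionMask], LatentTruth
]:
    """Generate one patient's three channel volumes, two region masks and
    the latent truth.  Deterministic in (config.seed, patient_index)."""
    masks, truth = make_truth(config, patient_index)
    rng = _rng_for(config, patient_index, 1)
    roi = masks["GTVp"].values | masks["MLN"].values
    labels = truth.label_field
    volumes: dict[str, Volume3D] = {}
    for c, channel in enumerate(CHANNELS):
        noise = rng.standard_normal(config.grid_shape)
        vals = config.background_noise_sd * noise
        cls = labels[roi] - 1
        vals[roi] = (
            config.channel_means[cls, c]
            + config.channel_sds[cls, c] * noise[roi]
        )
        volumes[channel] = Volume3D(vals.astype(np.float32), channel=channel)
    return volumes, masks, truth


def _clinical_covariates(
    config: CohortConfig, rng: np.random.Generator
) -> dict[str, float | int]:
    """Covariates matching the marginal mix of a locoregionally advanced
    NPC cohort: median age ~43, mostly T3-4 / N1-3, EBV DNA lognormal
    with ~59% of patients at or above 4000 copies/mL."""
    age = float(np.clip(rng.normal(43.0, 10.0), 18.0, 80.0))
    t_stage = int(rng.choice([1, 2, 3, 4], p=[0.065, 0.083, 0.549, 0.303]))
    n_stage = int(rng.choice([0, 1, 2, 3], p=[0.028, 0.356, 0.346, 0.270]))
    ebv = float(rng.lognormal(mean=np.log(4000.0) + 0.326, sigma=1.5))
    return {
        "age_years": age,
        "t_stage": t_stage,
        "n_stage": n_stage,
        "ebv_dna_copies_per_ml": ebv,
    }


def _clinical_lp(config: CohortConfig, cov: dict[str, float | int]) -> float:
    """Clinical part of the linear predictor, centered at the cohort's
    expected covariate mix so baseline_hazard_rate keeps its meaning."""
    b_age, b_t, b_n, b_ebv = config.clinical_betas
    return (
        b_age * (cov["age_years"] - 43.0) / 10.0
        + b_t * (cov["t_stage"] - 3.09)
        + b_n * (cov["n_stage"] - 2.06)
        + b_ebv * (float(cov["ebv_dna_copies_per_ml"] >= 4000.0) - 0.586)
    )


def simulate_survival(
    truth: LatentTruth,
    record_covariates: dict[str, float | int],
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str = "P000",
) -> PatientRecord:
    """Draw (time, event) from the proportional-hazards model.

    Event time is exponential with rate ``baseline_hazard_rate *
    exp(beta' x)`` where x stacks the true habitat proportions of both
    regions (centered at the uniform composition 1/k) and the clinical
    covariates; censoring is exponential(censor_rate) truncated at the
    administrative horizon.
    """
    x = truth.feature_vector() - 1.0 / config.k_true
    lp = float(config.hazard_betas @ x) + _clinical_lp(config, record_covariates)
    truth.linear_predictor = lp
    rate = config.baseline_hazard_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_censor = min(rng.exponential(1.0 / config.censor_rate), config.admin_censor_time)
    time = max(min(t_event, t_censor), 1e-6)
    event = int(t_event <= t_censor)
    return PatientRecord(
        patient_id=patient_id,
        time_months=float(time),
        event=event,
        **record_covariates,
    )


@dataclass
class SyntheticPatient:
    record: PatientRecord
    truth: LatentTruth
    masks: dict[str, RegionMask]
    volumes: dict[str, Volume3D] | None = None


@dataclass
class SyntheticCohort:
    config: CohortConfig
    patients: list[SyntheticPatient]

    @property
    def records_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(p.record) for p in self.patients]
        return pd.DataFrame(rows, columns=PATIENT_CSV_COLUMNS)


def _patient_id(i: int) -> str:
    return f"P{i:04d}"


def generate_patient(
    config: CohortConfig, patient_index: int, with_volumes: bool = True
) -> SyntheticPatient:
    if with_volumes:
        volumes, masks, truth = make_phantom(config, patient_index)
    else:
        masks, truth = make_truth(config, patient_index)
        volumes = None
    rng = _rng_for(config, patient_index, 2)
    cov = _clinical_covariates(config, rng)
    record = simulate_survival(
        truth, cov, config, rng, patient_id=_patient_id(patient_index)
    )
    return SyntheticPatient(record=record, truth=truth, masks=masks, volumes=volumes)


def generate_cohort(config: CohortConfig, with_volumes: bool = True) -> SyntheticCohort:
    """Generate the full cohort in memory (volumes are float32)."""
    patients = [
        generate_patient(config, i, with_volumes=with_volumes)
        for i in range(config.n_patients)
    ]
    return SyntheticCohort(config=config, patients=patients)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict:
    """Write the cohort to disk: one NIfTI per channel per patient, one
    NIfTI per region mask, a patient CSV, and a JSON truth sidecar.

    Returns a manifest mapping artifact kinds to file paths.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str] | str] = {"volumes": [], "masks": []}
    affine = np.eye(4)
    truth_blob = {}
    for i, pat in enumerate(cohort.patients):
        pid = pat.record.patient_id
        if pat.volumes is None:
            raise ValueError("cohort was generated without volumes")
        for channel, vol in pat.volumes.items():
            p = out / f"{pid}_{channel}.nii.gz"
            nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), p)
            manifest["volumes"].append(str(p))
        for region, mask in pat.masks.items():
            p = out / f"{pid}_mask_{region}.nii.gz"
            nib.save(
                nib.Nifti1Image(mask.values.astype(np.uint8), affine), p
            )
            manifest["masks"].append(str(p))
        truth_blob[pid] = {
            "proportions": {
                r: pat.truth.proportions[r].tolist() for r in REGIONS
            },
            "linear_predictor": pat.truth.linear_predictor,
        }
    table_path = out / "patients.csv"
    cohort.records_frame.to_csv(table_path, index=False)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth_blob, indent=1, sort_keys=True))
    manifest["patient_table"] = str(table_path)
    manifest["truth"] = str(truth_path)
    return manifest


def read_patient_volumes(
    cohort_dir: str | Path, patient_id: str
) -> tuple[dict[str, Volume3D], dict[str, RegionMask]]:
    """Re-read one patient's NIfTI volumes and masks from a cohort dir."""
    import nibabel as nib

    d = Path(cohort_dir)
    volumes = {}
    for channel in CHANNELS:
        img = nib.load(d / f"{patient_id}_{channel}.nii.gz")
        volumes[channel] = Volume3D(np.asarray(img.dataobj), channel=channel)
    masks = {}
    for region in REGIONS:
        img = nib.load(d / f"{patient_id}_mask_{region}.nii.gz")
        masks[region] = RegionMask(np.asarray(img.dataobj) > 0, region=region)
    return volumes, masks
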