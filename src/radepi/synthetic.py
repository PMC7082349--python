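"""Reproducible phantom cohorts with a planted feature--label effect.

Each phantom is an axis-aligned ellipsoidal "tumor" with multiplicative
correlated Gaussian texture, embedded in a uniform low-intensity
background with additive Gaussian noise. Two latent covariates are planted
per patient -- the Chebyshev distance of the tumor centroid from the AC
reference point and the texture-heterogeneity parameter -- and the binary
epilepsy-type label is drawn from a logistic model on the standardized
covariates, with the intercept calibrated so the cohort prevalence matches
the configured base prevalence.

All randomness flows from a single seed through per-patient
``numpy.random.SeedSequence`` substreams, so cohorts are bit-identical
under a fixed (config, seed) and individual phantoms can be regenerated
in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import expit

from radepi.volume import ImageVolume, RoiMask

LATENT_NAMES: tuple[str, ...] = ("chebyshev_mm", "heterogeneity")


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of a phantom cohort."""

    n_patients: int = 205
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    tumor_radius_range: tuple[float, float] = (6.0, 14.0)  # mm, per semi-axis
    texture_heterogeneity_range: tuple[float, float] = (0.05, 0.6)
    effect_coefficients: tuple[float, ...] = (1.0, 1.0)  # log-odds per SD of each latent
    base_prevalence: float = 0.678  # P(generalized)
    tumor_intensity: float = 100.0
    background_intensity: float = 20.0
    noise_sigma: float = 1.0
    texture_smoothness: float = 1.5  # Gaussian-filter sigma (voxels) of the texture field
    first_surgery: date = date(2012, 9, 1)
    surgery_interval_days: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError(f"n_patients must be >= 4, got {self.n_patients}")
        if not 0.0 < self.base_prevalence < 1.0:
            raise ValueError(f"base_prevalence must be in (0,1), got {self.base_prevalence}")
        if len(self.effect_coefficients) != len(LATENT_NAMES):
            raise ValueError(
                f"need {len(LATENT_NAMES)} effect coefficients "
                f"(for {LATENT_NAMES}), got {len(self.effect_coefficients)}"
            )
        if not all(np.isfinite(self.effect_coefficients)):
            raise ValueError("effect coefficients must be finite")
        lo, hi = self.tumor_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad tumor_radius_range {self.tumor_radius_range}")
        h0, h1 = self.texture_heterogeneity_range
        if not (0.0 <= h0 <= h1 <= 1.0):
            raise ValueError(f"heterogeneity range must lie in [0,1], got {h0, h1}")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: int
    gender: str  # male | female
    histopathology: str  # oligodendroglial | astrocytoma
    surgery_date: date
    epilepsy_type: str | None  # generalized | focal; None until assigned


@dataclass
class PhantomStudy:
    volume: ImageVolume
    mask: RoiMask
    ac_coordinate: np.ndarray  # mm
    record: PatientRecord
    latent_covariates: dict[str, float] = field(default_factory=dict)


def _grid_center_mm(config: SyntheticConfig) -> np.ndarray:
    shape = np.asarray(config.grid_shape, dtype=float)
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    return (shape - 1.0) / 2.0 * spacing


def generate_phantom(
    config: SyntheticConfig,
    patient_index: int,
    rng: np.random.Generator | None = None,
    centroid_mm: np.ndarray | None = None,
) -> PhantomStudy:
    """One ellipsoid-plus-noise phantom with recorded latent covariates.

    The label field of the returned record is ``None``; labels are assigned
    cohort-wide by :func:`assign_epilepsy_type` (via :func:`generate_cohort`)
    so that the intercept can be calibrated against the whole cohort.
    """
    if patient_index >= config.n_patients:
        raise ValueError(f"patient_index {patient_index} out of range (n={config.n_patients})")
    if rng is None:
        rng = _patient_rng(config, patient_index)

    shape = config.grid_shape
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    extent = (np.asarray(shape, dtype=float) - 1.0) * spacing

    semi_axes = rng.uniform(*config.tumor_radius_range, size=3)  # mm
    if np.any(2.0 * semi_axes >= extent):
        raise ValueError(
            f"tumor semi-axes {semi_axes} mm do not fit the grid extent {extent} mm; "
            "reduce tumor_radius_range or enlarge the grid"
        )
    if centroid_mm is None:
        centroid_mm = np.array(
            [rng.uniform(a, e - a) for a, e in zip(semi_axes, extent)]
        )
    else:
        centroid_mm = np.asarray(centroid_mm, dtype=float)

    idx = np.indices(shape).astype(float)
    coords = idx * spacing.reshape(3, 1, 1, 1)
    d2 = sum(
        ((coords[a] - centroid_mm[a]) / semi_axes[a]) ** 2 for a in range(3)
    )
    support = d2 <= 1.0
    if not support.any():  # ellipsoid smaller than one voxel; keep nearest voxel
        nearest = tuple(int(round(c / s)) for c, s in zip(centroid_mm, spacing))
        support[nearest] = True

    heterogeneity = float(rng.uniform(*config.texture_heterogeneity_range))
    field_ = ndimage.gaussian_filter(rng.normal(size=shape), config.texture_smoothness)
    sd = field_.std()
    if sd > 0:
        field_ /= sd
    intensities = np.full(shape, config.background_intensity, dtype=float)
    intensities[support] = config.tumor_intensity * (1.0 + heterogeneity * field_[support])
    if config.noise_sigma > 0:
        intensities += rng.normal(scale=config.noise_sigma, size=shape)

    ac = _grid_center_mm(config)
    mask = RoiMask(support)
    volume = ImageVolume(intensities, tuple(spacing), (0.0, 0.0, 0.0))
    roi_centroid = np.argwhere(support).mean(axis=0) * spacing
    latents = {
        "chebyshev_mm": float(np.max(np.abs(roi_centroid - ac))),
        "heterogeneity": heterogeneity,
    }
    record = PatientRecord(
        patient_id=f"P{patient_index:04d}",
        age=int(rng.integers(15, 67)),
        gender="male" if rng.random() < 0.62 else "female",
        histopathology="oligodendroglial" if rng.random() < 0.66 else "astrocytoma",
        surgery_date=config.first_surgery
        + timedelta(days=config.surgery_interval_days * patient_index),
        epilepsy_type=None,
    )
    return PhantomStudy(volume, mask, ac, record, latents)


def _patient_rng(config: SyntheticConfig, patient_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(patient_index,))
    return np.random.default_rng(ss)


def assign_epilepsy_type(
    latent_matrix: np.ndarray,
    effect_coefficients,
    base_prevalence: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw binary labels (1 = generalized) from a calibrated logistic model.

    The latent covariates are standardized across the cohort, the linear
    predictor is ``intercept + coeffs . z``, and the intercept is solved so
    the mean probability equals ``base_prevalence``.

    Returns ``(labels, probabilities)``.
    """
    beta = np.asarray(effect_coefficients, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("effect coefficients must be finite")
    x = np.atleast_2d(np.asarray(latent_matrix, dtype=float))
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    eta = (x - mu) / sd @ beta

    def mean_prob(intercept: float) -> float:
        return float(np.mean(expit(intercept + eta))) - base_prevalence

    # expit saturates, so the root lies well inside +-60 even for huge |beta|
    intercept = optimize.brentq(mean_prob, -60.0, 60.0, xtol=1e-12)
    prob = expit(intercept + eta)
    labels = (rng.random(len(prob)) < prob).astype(int)
    return labels, prob


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[PhantomStudy], pd.DataFrame]:
    """The full cohort plus its manifest, deterministic under (config, seed).

    The manifest has one row per patient: patient_id, age, gender,
    histopathology, surgery_date (ISO-8601), epilepsy_type, the AC
    coordinate and the latent covariates.
    """
    studies = [generate_phantom(config, i) for i in range(config.n_patients)]
    latent = np.array(
        [[s.latent_covariates[k] for k in LATENT_NAMES] for s in studies]
    )
    label_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(config.n_patients,))
    )
    labels, prob = assign_epilepsy_type(
        latent, config.effect_coefficients, config.base_prevalence, label_rng
    )
    rows = []
    for study, y, p in zip(studies, labels, prob):
        study.record = dataclasses.replace(
            study.record, epilepsy_type="generalized" if y == 1 else "focal"
        )
        r = study.record
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "gender": r.gender,
                "histopathology": r.histopathology,
                "surgery_date": r.surgery_date.isoformat(),
                "epilepsy_type": r.epilepsy_type,
                "ac_x_mm": study.ac_coordinate[0],
                "ac_y_mm": study.ac_coordinate[1],
                "ac_z_mm": study.ac_coordinate[2],
                **{k: study.latent_covariates[k] for k in LATENT_NAMES},
                "true_probability": float(p),
            }
        )
    manifest = pd.DataFrame(rows)
    return studies, manifest
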