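"""Synthetic brain-like volumes and clinical tables.

Real cohorts for this kind of analysis (MNI-registered, segmentation-normalized
T1 volumes plus symptom scores) are not redistributable, so this module
generates a stand-in cohort with the statistical structure the downstream
stages assume:

* an ellipsoidal "brain" with three nested tissue compartments (a CSF-, GM-
  and WM-like intensity shell), whose inner boundaries are blurred by a
  class-specific smoothness scale and whose outer surface is perturbed by
  smooth random undulations (a cortical-folding analogue);
* clinical scores (PANSS-factor, SANS, GAF, BDI-II and VisDys analogues)
  coupled to a latent severity through a Gaussian copula with controllable
  Spearman targets, at a baseline (T0) and a follow-up (T1) timepoint.

The two texture classes are labelled ``VisDys+`` / ``VisDys-`` after the
binary label the classifier predicts.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

__all__ = [
    "INSTRUMENT_RANGES",
    "RawVolume",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "generate_brain_volume",
    "generate_cohort",
    "compartment_atlas",
]

#: Plausible instrument ranges for the generated score analogues.  These are
#: the ranges scores are clipped to; the generator keeps the clipped fraction
#: well below 1% by construction (marginal sd = range/6).
INSTRUMENT_RANGES: dict[str, tuple[float, float]] = {
    "panss_positive": (7.0, 49.0),
    "panss_negative": (7.0, 49.0),
    "panss_distress": (4.0, 28.0),
    "panss_excitement": (4.0, 28.0),
    "panss_disorganization": (3.0, 21.0),
    "sans_anhedonia": (0.0, 25.0),
    "sans_asociality": (0.0, 25.0),
    "gaf": (1.0, 100.0),
    "bdi_ii": (0.0, 63.0),
    "visdys": (0.0, 56.0),
}

#: Normalized semi-axis fractions of the three nested compartments
#: (outer CSF-like shell, middle GM-like shell, inner WM-like core).
_OUTER_FRAC = 0.42
_MID_FRAC = 0.31
_INNER_FRAC = 0.19

#: Compartment intensities (background is exactly 0).
_INTENSITIES = (1.0, 2.0, 3.0)

MIN_SHAPE = 16


@dataclass
class RawVolume:
    """A registered brain-like volume: intensities, voxel spacing and mask."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_mask: np.ndarray = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.brain_mask is None:
            self.brain_mask = self.voxels != 0
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")
        if np.any(self.voxels[~self.brain_mask] != 0):
            raise ValueError("voxels outside brain_mask must be 0")


def _normalized_radius(shape, frac):
    """Per-voxel ellipsoidal radius, 1.0 on the compartment boundary."""
    axes = [np.arange(n, dtype=np.float64) - (n - 1) / 2.0 for n in shape]
    semi = [frac * n for n in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(
        (zz / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (xx / semi[2]) ** 2
    )


def _folding_field(shape, rng):
    """Smooth zero-mean, unit-sd random field plus a sinusoidal undulation.

    Drives the outer-boundary perturbation; the Gaussian-process part gives
    irregular folds, the sinusoid guarantees periodic undulation even for
    unlucky seeds.
    """
    noise = rng.standard_normal(shape)
    sigma = max(min(shape) / 12.0, 1.0)
    smooth = gaussian_filter(noise, sigma)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    axes = [np.arange(n, dtype=np.float64) - (n - 1) / 2.0 for n in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    theta = np.arctan2(yy, xx + 1e-9)
    phi = np.arctan2(np.sqrt(xx**2 + yy**2), zz + 1e-9)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    sinus = np.sin(4 * theta + ph1) * np.sin(3 * phi + ph2)
    return 0.7 * smooth + 0.3 * sinus


def _compartment_labels(shape, folding_amplitude, rng):
    """Integer compartment labels: 0 background, 1 CSF-, 2 GM-, 3 WM-like."""
    rho_outer = _normalized_radius(shape, _OUTER_FRAC)
    rho_mid = _normalized_radius(shape, _MID_FRAC)
    rho_inner = _normalized_radius(shape, _INNER_FRAC)
    # Perturb only the outer surface; relative amplitude in units of the
    # mean outer semi-axis so `folding_amplitude` is approximately voxels.
    mean_semi = _OUTER_FRAC * float(np.mean(shape))
    perturb = (folding_amplitude / mean_semi) * _folding_field(shape, rng)
    brain = rho_outer <= 1.0 + perturb
    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = 1
    labels[brain & (rho_mid <= 1.0)] = 2
    labels[brain & (rho_inner <= 1.0)] = 3
    return labels


def compartment_atlas(shape, folding_amplitude=0.0, seed=0):
    """Compartment label volume usable as a synthetic region atlas.

    With the same ``shape``, ``folding_amplitude`` and ``seed`` as a call to
    :func:`generate_brain_volume` this reproduces that volume's compartment
    geometry exactly.
    """
    rng = np.random.default_rng(seed)
    return _compartment_labels(tuple(shape), folding_amplitude, rng)


def generate_brain_volume(
    shape,
    smoothness=0.0,
    folding_amplitude=0.0,
    noise_sd=0.0,
    seed=0,
    spacing=(1.0, 1.0, 1.0),
):
    """Generate one ellipsoidal three-compartment brain-like volume.

    Parameters
    ----------
    shape : triple of int
        Volume dimensions in voxels; each axis must be at least 16 so the
        three nested compartments fit.
    smoothness : float
        Gaussian blur scale (voxels) applied to the compartment boundaries;
        0 leaves them perfectly sharp (piecewise-constant volume).
    folding_amplitude : float
        Amplitude (approximately voxels) of the smooth random undulation of
        the outer surface.
    noise_sd : float
        Standard deviation of additive Gaussian intensity noise inside the
        brain mask.
    seed : int
        Seed; identical arguments and seed give a bit-identical volume.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or min(shape) < MIN_SHAPE:
        raise ValueError(
            f"shape must be a 3-tuple with every axis >= {MIN_SHAPE} voxels "
            f"(got {shape}); smaller volumes cannot hold three nested "
            "compartments"
        )
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    rng = np.random.default_rng(seed)
    labels = _compartment_labels(shape, folding_amplitude, rng)
    brain = labels > 0
    intensity = np.zeros(shape, dtype=np.float64)
    for lab, val in zip((1, 2, 3), _INTENSITIES):
        intensity[labels == lab] = val
    if smoothness > 0:
        # Blur inside the mask only: boundaries between compartments become
        # gradual while the outer edge stays a hard cut to background 0.
        intensity = gaussian_filter(intensity, smoothness)
        intensity[~brain] = 0.0
    if noise_sd > 0:
        intensity[brain] += rng.normal(0.0, noise_sd, size=int(brain.sum()))
    return RawVolume(voxels=intensity, spacing=tuple(spacing), brain_mask=brain)


@dataclass
class SyntheticCohortSpec:
    """Full description of a synthetic two-class cohort.

    ``smoothness_by_class`` / ``folding_amplitude_by_class`` set the texture
    contrast between the VisDys+ and VisDys- classes.  ``clinical_targets``
    lists (variable, target Spearman rho to the latent severity) pairs; the
    latent severity has a higher mean in the VisDys+ class, so a positive
    target couples the score to both class membership and within-class
    severity.
    """

    n_per_class: int = 20
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    smoothness_by_class: dict[str, float] = field(
        default_factory=lambda: {"VisDys-": 0.5, "VisDys+": 2.0}
    )
    folding_amplitude_by_class: dict[str, float] = field(
        default_factory=lambda: {"VisDys-": 2.5, "VisDys+": 1.5}
    )
    noise_sd: float = 0.05
    clinical_targets: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("panss_positive", 0.5),
            ("panss_negative", 0.0),
            ("gaf", -0.4),
            ("bdi_ii", 0.3),
            ("visdys", 0.6),
        ]
    )
    followup_shift: dict[str, float] = field(
        default_factory=lambda: {"panss_positive": -3.0, "bdi_ii": -2.0}
    )
    followup_noise_sd: float = 1.0
    severity_gap: float = 1.5
    group_label: str = "ROP"
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        self.volume_shape = tuple(int(n) for n in self.volume_shape)
        for cls in ("VisDys-", "VisDys+"):
            if cls not in self.smoothness_by_class:
                raise ValueError(f"smoothness_by_class missing class {cls!r}")
            if cls not in self.folding_amplitude_by_class:
                raise ValueError(
                    f"folding_amplitude_by_class missing class {cls!r}"
                )
            if self.smoothness_by_class[cls] < 0:
                raise ValueError("smoothness scales must be >= 0")
        for var, rho in self.clinical_targets:
            if not abs(rho) < 1:
                raise ValueError(
                    f"|target rho| must be < 1 (variable {var!r}: {rho})"
                )
            if var not in INSTRUMENT_RANGES:
                raise ValueError(f"unknown clinical variable {var!r}")
        self._check_copula_feasible()

    def _check_copula_feasible(self):
        """The implied latent-factor correlation matrix must be PSD."""
        r = np.array(
            [2 * np.sin(np.pi * rho / 6) for _, rho in self.clinical_targets]
        )
        full = np.outer(r, r)
        np.fill_diagonal(full, 1.0)
        if len(r) and np.linalg.eigvalsh(full).min() < -1e-10:
            raise ValueError(
                "clinical_targets imply a correlation matrix that is not "
                "positive semi-definite"
            )

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["volume_shape"] = list(d["volume_shape"])
        d["clinical_targets"] = [list(t) for t in d["clinical_targets"]]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text_or_stream) -> "SyntheticCohortSpec":
        if isinstance(text_or_stream, (str, bytes)):
            text_or_stream = io.StringIO(
                text_or_stream.decode()
                if isinstance(text_or_stream, bytes)
                else text_or_stream
            )
        d = yaml.safe_load(text_or_stream)
        d["clinical_targets"] = [tuple(t) for t in d.get("clinical_targets", [])]
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A generated cohort: volumes, clinical table and generator internals."""

    volumes: dict[str, RawVolume]
    clinical: pd.DataFrame
    latent_severity: pd.Series
    spec: SyntheticCohortSpec

    @property
    def subject_ids(self) -> list[str]:
        return list(self.volumes)

    @property
    def labels(self) -> pd.Series:
        t0 = self.clinical[self.clinical["timepoint"] == "T0"]
        return t0.set_index("subject_id")["visdys_label"]


def _copula_scores(spec: SyntheticCohortSpec, severity, rng):
    """Draw clinical scores tied to the latent severity via a Gaussian copula.

    For a bivariate Gaussian with correlation r the Spearman correlation is
    (6/pi)·asin(r/2); the generator inverts that so each variable's rank
    correlation with the latent approaches its target.
    """
    n = len(severity)
    z_lat = (severity - severity.mean()) / (severity.std() or 1.0)
    scores = {}
    for var, rho_target in spec.clinical_targets:
        r = 2 * np.sin(np.pi * rho_target / 6)
        z = r * z_lat + np.sqrt(1 - r**2) * rng.standard_normal(n)
        lo, hi = INSTRUMENT_RANGES[var]
        mid, sd = (lo + hi) / 2.0, (hi - lo) / 6.0
        scores[var] = np.clip(mid + sd * z, lo, hi)
    return scores


def generate_cohort(spec: SyntheticCohortSpec,
                    generate_volumes: bool = True) -> SyntheticCohort:
    """Generate a full two-class cohort: one volume and T0/T1 scores each.

    Deterministic: the same spec (including its seed) reproduces the cohort
    bit-identically.  ``generate_volumes=False`` skips the (comparatively
    expensive) imaging part for clinical-score studies at large n; the
    clinical table is unchanged by the switch.
    """
    rng = np.random.default_rng(spec.seed)
    classes = ["VisDys-"] * spec.n_per_class + ["VisDys+"] * spec.n_per_class
    n = len(classes)
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    # Latent severity: within-class N(0,1) plus a between-class gap.
    severity = rng.standard_normal(n) + spec.severity_gap * np.array(
        [c == "VisDys+" for c in classes], dtype=float
    )
    volume_seeds = rng.integers(0, 2**31 - 1, size=n)
    volumes = {}
    for sid, cls, vseed in zip(subject_ids, classes, volume_seeds):
        if not generate_volumes:
            continue
        volumes[sid] = generate_brain_volume(
            spec.volume_shape,
            smoothness=spec.smoothness_by_class[cls],
            folding_amplitude=spec.folding_amplitude_by_class[cls],
            noise_sd=spec.noise_sd,
            seed=int(vseed),
        )
    t0_scores = _copula_scores(spec, severity, rng)
    variables = [v for v, _ in spec.clinical_targets]
    rows = []
    for tp in ("T0", "T1"):
        for i, (sid, cls) in enumerate(zip(subject_ids, classes)):
            row = {
                "subject_id": sid,
                "group": spec.group_label + ("+" if cls == "VisDys+" else "-"),
                "visdys_label": cls,
                "timepoint": tp,
            }
            for var in variables:
                if tp == "T0":
                    row[var] = t0_scores[var][i]
                else:
                    lo, hi = INSTRUMENT_RANGES[var]
                    shift = spec.followup_shift.get(var, 0.0)
                    row[var] = float(
                        np.clip(
                            t0_scores[var][i]
                            + shift
                            + rng.normal(0.0, spec.followup_noise_sd),
                            lo,
                            hi,
                        )
                    )
            rows.append(row)
    clinical = pd.DataFrame(rows)
    return SyntheticCohort(
        volumes=volumes,
        clinical=clinical,
        latent_severity=pd.Series(severity, index=subject_ids),
        spec=spec,
    )
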