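"""Synthetic free-breathing lung-MRI cohort generator with known ground truth.

Builds phantom subjects — two ellipsoidal lungs minus a branching vessel
tree — breathing periodically, and renders registered phase-resolved 4D
image series plus navigator time series the way a self-gated free-breathing
acquisition would deliver them after reconstruction and registration.

Signal model (proton-density dilution): inside parenchyma the noise-free
signal at inflation fraction u is

    S(x, u) = signal_scale / (1 + sv(x) * u)

where sv(x) is the voxel's specific ventilation (fractional volume change
per breath). Signal is inversely proportional to local air volume, so the
regional-ventilation formula applied to these images recovers

    RVent_true(x) = sv(x) / (1 + sv(x))

in closed form, which is what makes every downstream stage verifiable.
Scanner differences (e.g. 1.5 T vs 3 T) are modeled purely as an SNR and a
ventilation-heterogeneity multiplier; no susceptibility/T2* physics is
simulated. Noise is additive zero-mean Gaussian with sigma = mean
parenchymal signal / SNR.

All randomness flows from one root seed per subject through named
substreams, so a cohort is bit-for-bit reproducible and the same subject's
ventilation field is identical across scanners and repeated measurements.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.ndimage import gaussian_filter

from .gating import GatingSeries
from .ventmaps import PhaseResolvedImage

__all__ = [
    "Grid",
    "ScannerProfile",
    "SubjectSpec",
    "Perturbation",
    "RepeatVariability",
    "SimulationSettings",
    "GroundTruth",
    "LungGeometry",
    "SyntheticMeasurement",
    "GeometryError",
    "ParameterError",
    "substream",
    "make_lung_geometry",
    "sample_ventilation_field",
    "phase_inflation",
    "render_phase_images",
    "make_navigator",
    "navigator_image_series",
    "simulate_measurement",
    "iter_cohort_measurements",
    "generate_cohort",
    "SV_REL_SD",
]

# In-mask relative standard deviation of specific ventilation at
# heterogeneity_scale = 1. Chosen so the CoV of the derived RVent map in a
# default subject lands near 30%, the level typical of healthy-lung
# ventilation heterogeneity.
SV_REL_SD = 0.375

BACKGROUND_FRACTION = 0.10  # background signal as a fraction of signal_scale
VESSEL_FRACTION = 2.0  # vessel signal (bright, phase-constant blood pool)


class GeometryError(ValueError):
    """Raised when the requested lung geometry cannot fit the grid."""


class ParameterError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class Grid:
    """Voxel grid descriptor: shape (nx, ny, nz) and voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size) != 3:
            raise ParameterError("grid shape and voxel size must be 3-vectors")
        if any(s < 16 for s in self.shape):
            raise ParameterError("grid dimensions must be >= 16 per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel size must be positive")

    @property
    def voxel_volume(self) -> float:
        """mm^3 per voxel."""
        return float(np.prod(self.voxel_size))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical field of view in mm."""
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    def coordinates(self) -> np.ndarray:
        """(nx, ny, nz, 3) voxel-center coordinates in mm."""
        axes = [
            (np.arange(n) + 0.5) * v for n, v in zip(self.shape, self.voxel_size)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


DEFAULT_GRID = Grid((24, 24, 24), (8.0, 8.0, 8.0))


@dataclass(frozen=True)
class ScannerProfile:
    """Scanner/field-strength behavior as seen by the ventilation pipeline.

    snr: ratio of mean parenchymal signal to the noise standard deviation
    (np.inf for a noise-free scanner). heterogeneity_scale multiplies the
    spatial standard deviation of the ventilation field, emulating the more
    heterogeneous ventilation-weighted signal seen at higher field strength.
    """

    label: str
    field_strength: float  # tesla
    snr: float
    heterogeneity_scale: float
    signal_scale: float = 100.0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ParameterError("snr must be > 0")
        if not self.heterogeneity_scale >= 0:
            raise ParameterError("heterogeneity_scale must be >= 0")
        if not self.signal_scale > 0:
            raise ParameterError("signal_scale must be > 0")


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated volunteer."""

    subject_id: str
    age: float  # years
    sex: str  # 'F' | 'M'
    center: str
    breathing_frequency: float  # breaths/min
    tidal_volume_target: float  # mL
    lung_semiaxes: tuple[float, float, float] = (40.0, 50.0, 75.0)  # mm
    sv_mean: float = 0.25
    sv_correlation_length: float = 20.0  # mm
    defect_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ParameterError("subjects must be adults (age >= 18)")
        if self.sex not in ("F", "M"):
            raise ParameterError("sex must be 'F' or 'M'")
        if not self.breathing_frequency > 0:
            raise ParameterError("breathing_frequency must be > 0")
        if not self.tidal_volume_target > 0:
            raise ParameterError("tidal_volume_target must be > 0")
        if not 0 <= self.defect_fraction <= 1:
            raise ParameterError("defect_fraction must be in [0, 1]")


@dataclass(frozen=True)
class Perturbation:
    """Multiplicative change applied to the second measurement.

    tidal_factor scales the breathing-cycle amplitude (hence effective
    specific ventilation and tidal volume); frequency_factor scales the
    breathing frequency. tidal_factor = 0.85 emulates the habituation effect
    of a calmer second scan.
    """

    tidal_factor: float = 1.0
    frequency_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tidal_factor > 0 and self.frequency_factor > 0):
            raise ParameterError("perturbation factors must be > 0")


@dataclass(frozen=True)
class RepeatVariability:
    """Physiological scan-to-scan variability of repeated measurements.

    Repeated scans of the same subject differ even without habituation: the
    subject breathes a little deeper or faster, and regional ventilation
    redistributes (plus registration/segmentation differences on real data).
    Modeled as independent per-measurement lognormal factors — a global
    cycle-amplitude factor (sigma ``amplitude_sd``, drives tidal-volume and
    mean-RVent repeat variability), a breathing-frequency factor
    (``frequency_sd``) — and a spatially smooth multiplicative
    redistribution field exp(``regional_sd`` x z(x)) on specific
    ventilation. Defaults emulate healthy-cohort repeat variability
    (between-measurement CoV of roughly 5-12% per parameter, ventilated-map
    overlap in the low-to-mid 90s %). Disabled entirely for noise-free
    (snr = inf) scanner profiles so null designs are exactly reproducible.
    """

    amplitude_sd: float = 0.10
    frequency_sd: float = 0.08
    regional_sd: float = 0.12
    # sd (in cycle fractions) of a smooth regional time-lag field: regional
    # ventilation timing heterogeneity, the physiological driver of
    # scan-to-scan FVL-CM variability
    lag_sd: float = 0.03

    def __post_init__(self) -> None:
        if min(self.amplitude_sd, self.frequency_sd, self.regional_sd, self.lag_sd) < 0:
            raise ParameterError("repeat variability sigmas must be >= 0")


@dataclass(frozen=True)
class SimulationSettings:
    """Shared rendering settings for a simulated study."""

    grid: Grid = DEFAULT_GRID
    n_phases: int = 12
    navigator_duration_s: float = 120.0
    navigator_dt_s: float = 0.1
    navigator_noise_sd: float = 0.05
    repeat_variability: RepeatVariability = RepeatVariability()


@dataclass(frozen=True)
class GroundTruth:
    """True counterparts of every quantity the pipeline estimates."""

    sv_field: np.ndarray  # per-voxel specific ventilation (dimensionless)
    rvent_true_field: np.ndarray  # sv/(1+sv), mL/mL
    defect_mask: np.ndarray
    cycle_waveform: np.ndarray  # inflation fraction u(t) at navigator rate
    true_tidal_volume: float  # mL
    true_breathing_frequency: float  # breaths/min


@dataclass(frozen=True)
class LungGeometry:
    parenchyma_mask: np.ndarray
    vessel_mask: np.ndarray
    exp_lung_mask: np.ndarray
    insp_lung_mask: np.ndarray


@dataclass(frozen=True)
class SyntheticMeasurement:
    """One simulated scan with everything the analysis pipeline consumes."""

    images: PhaseResolvedImage
    parenchyma_mask: np.ndarray
    vessel_mask: np.ndarray
    insp_lung_mask: np.ndarray
    exp_lung_mask: np.ndarray
    navigator: GatingSeries
    ground_truth: GroundTruth
    subject_id: str
    scanner: str
    measurement_index: int
    seed: int

    @property
    def analysis_mask(self) -> np.ndarray:
        """Parenchyma with the large vessels extracted."""
        return self.parenchyma_mask & ~self.vessel_mask


def substream(root_seed: int, *keys) -> np.random.Generator:
    """Named, reproducible random substream derived from one root seed.

    Text keys are hashed with CRC32 so the stream depends only on the
    (seed, keys) identity, never on call order.
    """
    words = [int(root_seed) & 0x7FFFFFFF]
    words += [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(words))


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point (N, 3) to segment a-b (mm)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def make_lung_geometry(spec: SubjectSpec, grid: Grid = DEFAULT_GRID) -> LungGeometry:
    """Two ellipsoidal lungs minus a branching vessel tree, at two volumes.

    The end-inspiratory lung mask is the full ellipsoid pair; the
    end-expiratory mask removes exactly round(tidal_volume_target /
    voxel volume) of the outermost shell voxels, so the mask-derived tidal
    volume matches the target within one voxel volume. The vessel tree
    (trunk plus two branches per lung) lies inside the expiratory mask,
    hence inside the lungs at every phase.
    """
    ax, ay, az = spec.lung_semiaxes
    if min(ax, ay, az) <= 0:
        raise GeometryError("lung semiaxes must be positive")
    ex, ey, ez = grid.extent
    gap = grid.voxel_size[0]
    cy, cz = ey / 2.0, ez / 2.0
    centers_x = (ex / 2.0 - gap / 2.0 - ax, ex / 2.0 + gap / 2.0 + ax)
    for cx in centers_x:
        if cx - ax < 0 or cx + ax > ex:
            raise GeometryError("lung semiaxes exceed the grid along x")
    if cy - ay < 0 or cy + ay > ey or cz - az < 0 or cz + az > ez:
        raise GeometryError("lung semiaxes exceed the grid")

    coords = grid.coordinates()
    rho2 = np.full(grid.shape, np.inf)
    for cx in centers_x:
        r2 = (
            ((coords[..., 0] - cx) / ax) ** 2
            + ((coords[..., 1] - cy) / ay) ** 2
            + ((coords[..., 2] - cz) / az) ** 2
        )
        rho2 = np.minimum(rho2, r2)
    insp = rho2 <= 1.0
    n_insp = int(insp.sum())
    if n_insp == 0:
        raise GeometryError("lungs contain no voxels at this resolution")

    k = int(round(spec.tidal_volume_target * 1000.0 / grid.voxel_volume))
    if k >= n_insp:
        raise GeometryError(
            f"tidal volume {spec.tidal_volume_target} mL needs {k} voxels but the "
            f"lungs hold only {n_insp}"
        )
    # Expiration: peel off the k outermost lung voxels (largest ellipsoidal
    # radius), leaving an inner, deflated lung of the exact target difference.
    flat_idx = np.flatnonzero(insp.ravel())
    order = np.argsort(rho2.ravel()[flat_idx], kind="stable")
    exp = np.zeros(grid.shape, dtype=bool).ravel()
    exp[flat_idx[order[: n_insp - k]]] = True
    exp = exp.reshape(grid.shape)

    # Vessel tree: per lung a vertical trunk from the hilum down the lung
    # center, with two diagonal branches.
    pts = coords[insp].reshape(-1, 3)
    radius = 0.9 * min(grid.voxel_size)
    vessel_flat = np.zeros(pts.shape[0], dtype=bool)
    for cx in centers_x:
        top = np.array([cx, cy, cz + 0.55 * az])
        mid = np.array([cx, cy, cz + 0.05 * az])
        low = np.array([cx, cy, cz - 0.35 * az])
        segs = [
            (top, low),
            (mid, np.array([cx + 0.45 * ax, cy + 0.30 * ay, cz - 0.45 * az])),
            (mid, np.array([cx - 0.45 * ax, cy - 0.30 * ay, cz - 0.45 * az])),
        ]
        for a, b in segs:
            vessel_flat |= _segment_distance(pts, a, b) < radius
    vessel = np.zeros(grid.shape, dtype=bool)
    vessel[insp] = vessel_flat
    vessel &= exp  # keep vessels inside the lung at all phases
    if not vessel.any():  # coarse grids: guarantee a nonempty vessel tree
        centers_vox = tuple(
            np.clip(np.round(np.array([cx, cy, cz]) / grid.voxel_size - 0.5), 0,
                    np.array(grid.shape) - 1).astype(int)
            for cx in centers_x
        )
        for cvx in centers_vox:
            if exp[tuple(cvx)]:
                vessel[tuple(cvx)] = True

    return LungGeometry(
        parenchyma_mask=insp,
        vessel_mask=vessel,
        exp_lung_mask=exp,
        insp_lung_mask=insp,
    )


def sample_ventilation_field(
    spec: SubjectSpec,
    profile: ScannerProfile,
    parenchyma_mask: np.ndarray,
    grid: Grid,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially smooth specific-ventilation field with optional defects.

    Gaussian white noise smoothed to the subject's correlation length,
    standardized in-mask, scaled to sv_mean * SV_REL_SD *
    heterogeneity_scale, shifted to sv_mean and clipped at zero. A
    defect_fraction > 0 zeroes a contiguous region of that fraction of the
    parenchyma. Returns (sv_field, defect_mask); the true RVent field is
    sv/(1+sv).
    """
    if spec.sv_mean < 0:
        raise ParameterError("sv_mean must be >= 0")
    mask = np.asarray(parenchyma_mask, dtype=bool)
    sv = np.zeros(grid.shape, dtype=float)
    if profile.heterogeneity_scale == 0 or spec.sv_mean == 0:
        sv[mask] = spec.sv_mean
        # consume the same draws as the heterogeneous path so substreams stay
        # aligned across profiles
        rng.standard_normal(grid.shape)
    else:
        white = rng.standard_normal(grid.shape)
        sigma_vox = [spec.sv_correlation_length / v for v in grid.voxel_size]
        smooth = gaussian_filter(white, sigma_vox)
        vals = smooth[mask]
        sd = vals.std()
        z = (smooth - vals.mean()) / (sd if sd > 0 else 1.0)
        target_sd = spec.sv_mean * SV_REL_SD * profile.heterogeneity_scale
        sv[mask] = np.clip(spec.sv_mean + target_sd * z[mask], 0.0, None)

    defect = np.zeros(grid.shape, dtype=bool)
    n_mask = int(mask.sum())
    k_def = int(round(spec.defect_fraction * n_mask))
    if k_def > 0:
        coords = grid.coordinates()[mask]
        seed_idx = int(rng.integers(n_mask))
        d = np.linalg.norm(coords - coords[seed_idx], axis=1)
        pick = np.argsort(d, kind="stable")[:k_def]
        flat = np.flatnonzero(mask.ravel())
        defect_flat = np.zeros(n_mask, dtype=bool)
        defect_flat[pick] = True
        defect.ravel()[flat[defect_flat]] = True
        sv[defect] = 0.0
    else:
        rng.integers(1 << 16)  # keep substream alignment
    return sv, defect


def phase_inflation(n_phases: int) -> np.ndarray:
    """Inflation fraction u(p) over one sorted cycle, u(0)=0, max u = 1.

    Raised-cosine sampling of a full respiratory cycle, normalized so
    end-expiration (index 0) is exactly 0 and end-inspiration (index
    n_phases//2) is exactly 1.
    """
    if n_phases < 3:
        raise ParameterError("need at least 3 respiratory phases")
    p = np.arange(n_phases)
    raw = 1.0 - np.cos(2.0 * np.pi * p / n_phases)
    return raw / raw[n_phases // 2]


def render_phase_images(
    sv_field: np.ndarray,
    geometry: LungGeometry,
    n_phases: int,
    profile: ScannerProfile,
    grid: Grid,
    rng: np.random.Generator,
    lag_field: np.ndarray | None = None,
) -> PhaseResolvedImage:
    """Render the registered phase-resolved 4D series under the signal model.

    Parenchyma: S = signal_scale / (1 + sv * u(p)); vessels: bright,
    phase-constant; background: constant low signal. Additive Gaussian noise
    with sigma = mean parenchymal signal / snr (none for snr = inf).

    An optional per-voxel lag field (in cycle fractions) shifts each voxel's
    inflation curve in time, emulating regional ventilation timing
    heterogeneity: u becomes u((p/n − lag(x)) mod 1).
    """
    u = phase_inflation(n_phases)
    par = geometry.parenchyma_mask & ~geometry.vessel_mask
    scale = profile.signal_scale
    data = np.full(grid.shape + (n_phases,), BACKGROUND_FRACTION * scale, dtype=float)
    if lag_field is None:
        u_vox = np.broadcast_to(u, (int(par.sum()), n_phases))
    else:
        # continuous raised cosine with the same normalization as
        # phase_inflation, evaluated at the lagged cycle fraction
        frac = np.arange(n_phases) / n_phases - np.asarray(lag_field)[par][:, None]
        norm = 1.0 - np.cos(2.0 * np.pi * (n_phases // 2) / n_phases)
        u_vox = (1.0 - np.cos(2.0 * np.pi * frac)) / norm
    data[par] = scale / (1.0 + sv_field[par][:, None] * u_vox)
    data[geometry.vessel_mask] = VESSEL_FRACTION * scale
    if np.isfinite(profile.snr):
        sigma = float(data[par].mean()) / profile.snr
        data = data + rng.normal(0.0, sigma, size=data.shape)
    return PhaseResolvedImage(
        data=data,
        voxel_size=grid.voxel_size,
        exp_idx=0,
        insp_idx=n_phases // 2,
    )


def _waveform(frequency_bpm: float, t: np.ndarray) -> np.ndarray:
    """Inflation fraction u(t) in [0, 1]; 0 at end-expiration each cycle."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * frequency_bpm / 60.0 * t))


def make_navigator(
    frequency_bpm: float,
    duration_s: float = 120.0,
    dt_s: float = 0.1,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
) -> GatingSeries:
    """Scalar respiratory navigator: the cycle waveform plus Gaussian noise.

    Default dt of 0.1 s matches a 100-ms low-resolution navigator; 480 s at
    0.1 s gives the 4800 samples of an 8-minute acquisition.
    """
    if dt_s <= 0:
        raise ParameterError("navigator dt must be > 0")
    if frequency_bpm <= 0:
        raise ParameterError("breathing frequency must be > 0")
    n = int(round(duration_s / dt_s))
    if n < 2:
        raise ParameterError("navigator duration too short")
    t = np.arange(n) * dt_s
    amp = _waveform(frequency_bpm, t)
    if noise_sd > 0:
        if rng is None:
            raise ParameterError("rng required when noise_sd > 0")
        amp = amp + rng.normal(0.0, noise_sd, size=n)
    return GatingSeries(t, amp)


def navigator_image_series(
    series: GatingSeries,
    matrix: int = 32,
    pixel_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Broadcast a scalar navigator to (T, matrix, matrix) low-res frames."""
    frames = np.repeat(
        series.amplitude[:, None, None], matrix * matrix, axis=1
    ).reshape(series.n, matrix, matrix)
    if pixel_noise_sd > 0:
        if rng is None:
            raise ParameterError("rng required when pixel_noise_sd > 0")
        frames = frames + rng.normal(0.0, pixel_noise_sd, size=frames.shape)
    return frames


def simulate_measurement(
    spec: SubjectSpec,
    profile: ScannerProfile,
    measurement_index: int = 1,
    perturbation: Perturbation | None = None,
    settings: SimulationSettings = SimulationSettings(),
) -> SyntheticMeasurement:
    """Simulate one scan of one subject on one scanner.

    The subject's ventilation field and lung shape are deterministic in
    (seed, subject); only noise differs across scanners and repeats. For
    measurement_index 2 the perturbation's tidal_factor scales the cycle
    amplitude — effective specific ventilation and tidal volume — and
    frequency_factor scales the breathing frequency, with the ground truth
    updated consistently.
    """
    if measurement_index not in (1, 2):
        raise ParameterError("measurement_index must be 1 or 2")
    pert = perturbation if (perturbation and measurement_index == 2) else Perturbation()

    # Physiological scan-to-scan variability: independent draw per
    # (subject, scanner, measurement); off for noise-free profiles.
    grid = settings.grid
    amp_factor, freq_factor = 1.0, 1.0
    regional = None
    lag_raw = None
    if np.isfinite(profile.snr):
        rv = settings.repeat_variability
        rng_phys = substream(
            spec.seed, "phys", spec.subject_id, profile.label, measurement_index
        )
        amp_factor = float(np.exp(rng_phys.normal(0.0, rv.amplitude_sd)))
        freq_factor = float(np.exp(rng_phys.normal(0.0, rv.frequency_sd)))
        sigma_vox = [spec.sv_correlation_length / v for v in grid.voxel_size]
        if rv.regional_sd > 0:
            regional = gaussian_filter(rng_phys.standard_normal(grid.shape), sigma_vox)
        if rv.lag_sd > 0:
            lag_raw = gaussian_filter(rng_phys.standard_normal(grid.shape), sigma_vox)

    tv = spec.tidal_volume_target * pert.tidal_factor * amp_factor
    freq = spec.breathing_frequency * pert.frequency_factor * freq_factor
    geometry = make_lung_geometry(replace(spec, tidal_volume_target=tv), grid)

    rng_field = substream(spec.seed, "field", spec.subject_id)
    sv, defect = sample_ventilation_field(
        spec, profile, geometry.parenchyma_mask, grid, rng_field
    )
    sv_eff = sv * pert.tidal_factor * amp_factor
    mask = geometry.parenchyma_mask

    def _zscore(fieldvals: np.ndarray) -> np.ndarray:
        vals = fieldvals[mask]
        sd = vals.std()
        return (fieldvals - vals.mean()) / (sd if sd > 0 else 1.0)

    if regional is not None:
        sv_eff = sv_eff * np.exp(settings.repeat_variability.regional_sd * _zscore(regional))
    lag_field = None
    if lag_raw is not None:
        lag_field = settings.repeat_variability.lag_sd * _zscore(lag_raw)
    rvent_true = sv_eff / (1.0 + sv_eff)

    rng_noise = substream(spec.seed, "noise", spec.subject_id, profile.label, measurement_index)
    images = render_phase_images(
        sv_eff, geometry, settings.n_phases, profile, grid, rng_noise, lag_field
    )

    rng_nav = substream(spec.seed, "nav", spec.subject_id, profile.label, measurement_index)
    nav_noise = 0.0 if not np.isfinite(profile.snr) else settings.navigator_noise_sd
    navigator = make_navigator(
        freq, settings.navigator_duration_s, settings.navigator_dt_s, nav_noise, rng_nav
    )
    waveform = _waveform(freq, navigator.timestamps)

    true_tv = (
        (int(geometry.insp_lung_mask.sum()) - int(geometry.exp_lung_mask.sum()))
        * grid.voxel_volume
        / 1000.0
    )
    gt = GroundTruth(
        sv_field=sv_eff,
        rvent_true_field=rvent_true,
        defect_mask=defect,
        cycle_waveform=waveform,
        true_tidal_volume=true_tv,
        true_breathing_frequency=freq,
    )
    return SyntheticMeasurement(
        images=images,
        parenchyma_mask=geometry.parenchyma_mask,
        vessel_mask=geometry.vessel_mask,
        insp_lung_mask=geometry.insp_lung_mask,
        exp_lung_mask=geometry.exp_lung_mask,
        navigator=navigator,
        ground_truth=gt,
        subject_id=spec.subject_id,
        scanner=profile.label,
        measurement_index=measurement_index,
        seed=spec.seed,
    )


def _sample_subjects(config) -> list[SubjectSpec]:
    """Demographics sampled within the configured ranges, one spec/subject."""
    demo = config.demographics
    rng = substream(config.seed, "cohort")
    specs: list[SubjectSpec] = []
    seen: set[str] = set()
    for center in config.centers:
        for i in range(center.n_subjects):
            sid = f"{center.name}-S{i + 1:02d}"
            if sid in seen:
                raise ParameterError(f"duplicate subject id {sid}")
            seen.add(sid)
            age = float(rng.uniform(*demo.age_range))
            sex = "F" if rng.random() < demo.female_fraction else "M"
            bf = float(rng.uniform(*demo.breathing_frequency_range))
            tv = float(rng.uniform(*demo.tidal_volume_range))
            sv_mean = float(rng.uniform(*demo.sv_mean_range))
            jit = demo.semiaxes_jitter
            semi = tuple(
                float(a * rng.uniform(1.0 - jit, 1.0 + jit))
                for a in demo.semiaxes_base
            )
            subject_seed = int(rng.integers(1 << 31))
            specs.append(
                SubjectSpec(
                    subject_id=sid,
                    age=age,
                    sex=sex,
                    center=center.name,
                    breathing_frequency=bf,
                    tidal_volume_target=tv,
                    lung_semiaxes=semi,
                    sv_mean=sv_mean,
                    sv_correlation_length=demo.sv_correlation_length,
                    defect_fraction=demo.defect_fraction,
                    seed=subject_seed,
                )
            )
    return specs


def iter_cohort_measurements(config) -> Iterator[tuple[SubjectSpec, SyntheticMeasurement]]:
    """Lazily generate every measurement of the configured study.

    Each center's subjects are scanned twice on each of the center's scanner
    profiles; the study perturbation applies to measurement 2.
    """
    settings = config.simulation_settings()
    profile_of = {name: config.profiles[name] for c in config.centers for name in c.profiles}
    for spec in _sample_subjects(config):
        center = next(c for c in config.centers if c.name == spec.center)
        for pname in center.profiles:
            profile = profile_of[pname]
            for m in (1, 2):
                yield spec, simulate_measurement(
                    spec, profile, m, config.perturbation, settings
                )


def generate_cohort(config):
    """Generate the full cohort in memory.

    Returns (measurements, cohort_table) where cohort_table is a pandas
    DataFrame with one row per measurement (subject id, age, sex, center,
    scanner, measurement, seed, true tidal volume, true frequency).
    """
    import pandas as pd

    measurements: list[SyntheticMeasurement] = []
    rows = []
    for spec, meas in iter_cohort_measurements(config):
        measurements.append(meas)
        rows.append(
            {
                "subject_id": spec.subject_id,
                "age": spec.age,
                "sex": spec.sex,
                "center": spec.center,
                "scanner": meas.scanner,
                "measurement": meas.measurement_index,
                "seed": spec.seed,
                "true_tidal_volume": meas.ground_truth.true_tidal_volume,
                "true_breathing_frequency": meas.ground_truth.true_breathing_frequency,
            }
        )
    return measurements, pd.DataFrame(rows)
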