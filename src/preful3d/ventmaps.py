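"""Regional ventilation maps and scalar ventilation parameters.

Given a registered phase-resolved 4D image series (one 3D volume per
respiratory phase, all aligned to the end-inspiratory reference) and lung
masks, this module derives the standard ventilation-weighted outputs:

* per-phase regional ventilation, RVent(x, p) = S_Ref(x)/S_p(x) −
  S_Ref(x)/S_Exp(x), with the end-inspiratory image as reference, so the
  static map reduces to 1 − S_Insp/S_Exp;
* per-voxel flow-volume loops (volume = RVent over the cycle starting at
  end-expiration; flow = cyclic central difference) and their zero-lag
  correlation with the whole-lung reference loop (FVL-CM);
* ventilated-volume percentages — RVent above 40% of its in-mask 90th
  percentile, FVL-CM above a fixed 0.9 — plus the binary ventilated-volume
  maps behind them;
* map mean/CoV summaries, tidal volume from the end-inspiratory and
  end-expiratory lung masks, and the assembled per-measurement summary row.

Because MR signal is inversely related to local air content, RVent is
positive where lung tissue ventilates; in healthy lungs FVL-CM is close to 1
everywhere and both VVPs are close to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import gating

__all__ = [
    "PhaseResolvedImage",
    "RVentCycle",
    "FVLSet",
    "VentilationSummary",
    "MeasurementMaps",
    "DataError",
    "MaskError",
    "compute_rvent_cycle",
    "summarize_map",
    "vvp_rvent",
    "build_fvl",
    "fvl_cm_map",
    "vvp_fvlcm",
    "tidal_volume",
    "analyze_measurement",
    "summarize_measurement",
]


class DataError(ValueError):
    """Raised for unusable image data (e.g. non-positive in-mask signal)."""


class MaskError(ValueError):
    """Raised for empty or mismatched masks."""


@dataclass(frozen=True)
class PhaseResolvedImage:
    """Registered signal volumes over one sorted respiratory cycle.

    data is (x, y, z, phase) in arbitrary units; exp_idx / insp_idx locate
    end-expiration and end-inspiration in the cyclic phase order. The
    end-inspiratory phase is also the registration reference.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    exp_idx: int
    insp_idx: int

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4:
            raise DataError("phase-resolved image must be 4-D (x, y, z, phase)")
        if d.shape[3] < 3:
            raise DataError("need at least 3 respiratory phases")
        if not (0 <= self.exp_idx < d.shape[3] and 0 <= self.insp_idx < d.shape[3]):
            raise DataError("phase indices out of range")
        if self.exp_idx == self.insp_idx:
            raise DataError("end-expiration and end-inspiration must differ")
        object.__setattr__(self, "data", d)

    @property
    def n_phases(self) -> int:
        return int(self.data.shape[3])

    @property
    def ref_idx(self) -> int:
        return self.insp_idx

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])


@dataclass(frozen=True)
class RVentCycle:
    """Per-voxel, per-phase regional ventilation (mL/mL); zero outside mask."""

    data: np.ndarray
    exp_idx: int
    insp_idx: int

    @property
    def n_phases(self) -> int:
        return int(self.data.shape[3])

    @property
    def static_map(self) -> np.ndarray:
        """RVent at end-inspiration: 1 − S_Insp/S_Exp (reference = insp)."""
        return self.data[..., self.insp_idx]


@dataclass(frozen=True)
class FVLSet:
    """Per-voxel flow-volume loops for the in-mask voxels, plus the reference.

    volume/flow are (n_voxels, n_phases) in cyclic order starting at
    end-expiration; the reference loop is the in-mask voxel-wise mean loop.
    """

    volume: np.ndarray
    flow: np.ndarray
    reference_volume: np.ndarray
    reference_flow: np.ndarray
    mask: np.ndarray

    @property
    def n_phases(self) -> int:
        return int(self.volume.shape[1])


@dataclass(frozen=True)
class VentilationSummary:
    """The scalar ventilation parameters of one measurement."""

    mean_rvent: float  # mL/mL
    cov_rvent: float  # %
    vvp_rvent: float  # %
    mean_fvlcm: float  # dimensionless, in [-1, 1]
    cov_fvlcm: float  # %
    vvp_fvlcm: float  # %
    tidal_volume: float  # mL
    breathing_frequency: float  # breaths/min

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_rvent": self.mean_rvent,
            "cov_rvent": self.cov_rvent,
            "vvp_rvent": self.vvp_rvent,
            "mean_fvlcm": self.mean_fvlcm,
            "cov_fvlcm": self.cov_fvlcm,
            "vvp_fvlcm": self.vvp_fvlcm,
            "tidal_volume": self.tidal_volume,
            "breathing_frequency": self.breathing_frequency,
        }


@dataclass(frozen=True)
class MeasurementMaps:
    """Full analysis output for one measurement: summary row plus the maps."""

    summary: VentilationSummary
    rvent_static: np.ndarray
    fvlcm: np.ndarray
    vv_rvent: np.ndarray
    vv_fvlcm: np.ndarray
    analysis_mask: np.ndarray


def _in_mask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MaskError("empty mask")
    return values[mask]


def compute_rvent_cycle(img: PhaseResolvedImage, mask: np.ndarray) -> RVentCycle:
    """Per-phase RVent: S_Ref/S_p − S_Ref/S_Exp, reference = end-inspiration.

    Requires strictly positive in-mask signal at every phase; identically
    zero at the end-expiratory phase by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.grid_shape:
        raise MaskError("mask grid does not match image grid")
    sig = _in_mask(img.data, mask)  # (n_voxels, n_phases)
    n_bad = int(np.sum(np.any(sig <= 0, axis=1)))
    if n_bad:
        raise DataError(f"non-positive in-mask signal in {n_bad} voxel(s)")
    ref = sig[:, img.ref_idx]
    exp = sig[:, img.exp_idx]
    cyc = ref[:, None] / sig - (ref / exp)[:, None]
    out = np.zeros(img.data.shape, dtype=float)
    out[mask] = cyc
    return RVentCycle(data=out, exp_idx=img.exp_idx, insp_idx=img.insp_idx)


def summarize_map(
    values_map: np.ndarray, mask: np.ndarray, ddof: int = 0
) -> tuple[float, float]:
    """In-mask (mean, CoV%) of a map; CoV = 100 x sd/mean.

    Population (ddof=0) standard deviation by default.
    """
    vals = _in_mask(np.asarray(values_map, dtype=float), mask)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
    if mean == 0.0:
        if sd == 0.0:
            return 0.0, 0.0
        raise DataError("CoV undefined: zero mean with nonzero standard deviation")
    return mean, 100.0 * sd / mean


def vvp_rvent(
    static_map: np.ndarray,
    mask: np.ndarray,
    fraction: float = 0.4,
    percentile: float = 90.0,
) -> tuple[float, np.ndarray]:
    """Ventilated volume percentage from the static RVent map.

    Threshold = ``fraction`` x the in-mask ``percentile``-th percentile
    (linear-interpolation percentile); a voxel counts as ventilated when
    strictly above the threshold. Returns (VVP %, binary ventilated map).
    """
    mask = np.asarray(mask, dtype=bool)
    vals = _in_mask(np.asarray(static_map, dtype=float), mask)
    threshold = fraction * float(np.percentile(vals, percentile))
    above = vals > threshold
    vv = np.zeros(mask.shape, dtype=bool)
    vv[mask] = above
    return 100.0 * float(above.mean()), vv


def build_fvl(cycle: RVentCycle, mask: np.ndarray) -> FVLSet:
    """Per-voxel flow-volume loops over the cyclic phase order.

    Volume samples are RVent re-ordered to start at end-expiration; flow is
    the cyclic central difference of volume (a.u. per phase step), so the
    loop is closed (cyclic flow sums to zero). The reference loop is the
    voxel-wise mean over the in-mask voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    p = cycle.n_phases
    order = (np.arange(p) + cycle.exp_idx) % p
    vol = _in_mask(cycle.data, mask)[:, order]
    flow = (np.roll(vol, -1, axis=1) - np.roll(vol, 1, axis=1)) / 2.0
    return FVLSet(
        volume=vol,
        flow=flow,
        reference_volume=vol.mean(axis=0),
        reference_flow=flow.mean(axis=0),
        mask=mask,
    )


def _standardize_rows(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores; rows with zero variance become 0 and are flagged."""
    m = a.mean(axis=-1, keepdims=True)
    s = a.std(axis=-1, keepdims=True)
    ok = (s > 0).reshape(s.shape[:-1])
    z = np.where(s > 0, (a - m) / np.where(s > 0, s, 1.0), 0.0)
    return z, ok


def fvl_cm_map(fvls: FVLSet) -> tuple[np.ndarray, np.ndarray]:
    """Flow-volume-loop correlation metric map in [-1, 1].

    Per voxel: the zero-lag Pearson correlation between the concatenated
    (volume ‖ flow) vector of the voxel and that of the reference loop, each
    sub-vector standardized before concatenation. Degenerate voxels (a
    constant volume or flow loop) are set to 0 and flagged.

    Returns (fvlcm map on the full grid, degenerate-voxel mask).
    """
    p = fvls.n_phases
    zrv, ok_rv = _standardize_rows(fvls.reference_volume[None, :])
    zrf, ok_rf = _standardize_rows(fvls.reference_flow[None, :])
    if not (ok_rv[0] and ok_rf[0]):
        raise DataError("reference flow-volume loop has zero variance")
    zv, ok_v = _standardize_rows(fvls.volume)
    zf, ok_f = _standardize_rows(fvls.flow)
    ok = ok_v & ok_f
    r = (zv @ zrv[0] + zf @ zrf[0]) / (2.0 * p)
    r = np.clip(np.where(ok, r, 0.0), -1.0, 1.0)
    out = np.zeros(fvls.mask.shape, dtype=float)
    out[fvls.mask] = r
    degenerate = np.zeros(fvls.mask.shape, dtype=bool)
    degenerate[fvls.mask] = ~ok
    return out, degenerate


def vvp_fvlcm(
    fvlcm: np.ndarray, mask: np.ndarray, threshold: float = 0.9
) -> tuple[float, np.ndarray]:
    """VVP from the FVL-CM map: fraction strictly above a fixed threshold."""
    mask = np.asarray(mask, dtype=bool)
    vals = _in_mask(np.asarray(fvlcm, dtype=float), mask)
    above = vals > threshold
    vv = np.zeros(mask.shape, dtype=bool)
    vv[mask] = above
    return 100.0 * float(above.mean()), vv


def tidal_volume(
    insp_mask: np.ndarray,
    exp_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> float:
    """Tidal volume in mL from end-inspiratory and end-expiratory lung masks.

    (insp voxel count − exp voxel count) x voxel volume. A negative result is
    physiologically inverted; it is returned as-is with a warning.
    """
    insp = np.asarray(insp_mask, dtype=bool)
    exp = np.asarray(exp_mask, dtype=bool)
    if insp.shape != exp.shape:
        raise MaskError("inspiration/expiration masks must share the grid")
    voxel_volume_mm3 = float(np.prod(voxel_size))
    tv = (int(insp.sum()) - int(exp.sum())) * voxel_volume_mm3 / 1000.0
    if tv < 0:
        warnings.warn("negative tidal volume: expiratory mask exceeds inspiratory mask")
    return tv


def analyze_measurement(
    measurement,
    vvp_fraction: float = 0.4,
    vvp_percentile: float = 90.0,
    fvlcm_threshold: float = 0.9,
    cov_ddof: int = 0,
    invert_gating: bool = False,
) -> MeasurementMaps:
    """Full ventilation analysis of one (synthetic or real) measurement.

    ``measurement`` needs: images (PhaseResolvedImage), parenchyma_mask,
    vessel_mask, insp_lung_mask, exp_lung_mask, navigator. Vessel voxels are
    excluded from the parenchyma mask before all statistics.
    """
    mask = np.asarray(measurement.parenchyma_mask, bool) & ~np.asarray(
        measurement.vessel_mask, bool
    )
    img: PhaseResolvedImage = measurement.images
    cycle = compute_rvent_cycle(img, mask)
    static = cycle.static_map
    mean_rv, cov_rv = summarize_map(static, mask, ddof=cov_ddof)
    vvp_rv, vv_rv = vvp_rvent(static, mask, fraction=vvp_fraction, percentile=vvp_percentile)
    fvls = build_fvl(cycle, mask)
    try:
        fvlcm, _ = fvl_cm_map(fvls)
    except DataError:
        # zero-variance reference loop (no ventilation at all): the loop
        # correlation is undefined everywhere; report a flagged all-zero map
        fvlcm = np.zeros(mask.shape, dtype=float)
    mean_cm, cov_cm = summarize_map(fvlcm, mask, ddof=cov_ddof)
    vvp_cm, vv_cm = vvp_fvlcm(fvlcm, mask, threshold=fvlcm_threshold)
    tv = tidal_volume(measurement.insp_lung_mask, measurement.exp_lung_mask, img.voxel_size)
    nav = gating.extract_gating_signal(measurement.navigator, invert=invert_gating)
    bf = float(gating.estimate_breathing_frequency(nav))
    summary = VentilationSummary(
        mean_rvent=mean_rv,
        cov_rvent=cov_rv,
        vvp_rvent=vvp_rv,
        mean_fvlcm=mean_cm,
        cov_fvlcm=cov_cm,
        vvp_fvlcm=vvp_cm,
        tidal_volume=tv,
        breathing_frequency=bf,
    )
    return MeasurementMaps(
        summary=summary,
        rvent_static=static,
        fvlcm=fvlcm,
        vv_rvent=vv_rv,
        vv_fvlcm=vv_cm,
        analysis_mask=mask,
    )


def summarize_measurement(measurement, **kwargs) -> VentilationSummary:
    """Scalar parameter row for one measurement (see analyze_measurement)."""
    return analyze_measurement(measurement, **kwargs).summary
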