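"""Respiratory self-gating: signal extraction, frequency, phase, and binning.

Free-breathing acquisitions are sorted retrospectively by respiratory state.
A rapidly sampled low-resolution navigator (32x32 frames every ~100 ms, or an
equivalent scalar series) tracks thoracic inflation; from it we estimate the
breathing frequency, assign each time point a respiratory phase in [0, 1)
(0 = end-expiration, 0.5 = end-inspiration), and sort acquisitions into
cyclic phase bins with a minimum occupancy and view sharing from neighboring
bins.

Amplitude convention: higher navigator amplitude means more inflated
(inspiration). Pass ``invert=True`` to :func:`extract_gating_signal` for data
with the opposite polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "GatingSeries",
    "BinAssignment",
    "GatingError",
    "BinningError",
    "extract_gating_signal",
    "estimate_breathing_frequency",
    "compute_respiratory_phase",
    "assign_bins",
]


class GatingError(ValueError):
    """Raised when a gating signal is unusable (too short, flat, no cycles)."""


class BinningError(ValueError):
    """Raised when acquisitions cannot satisfy the bin occupancy constraint."""


@dataclass(frozen=True)
class GatingSeries:
    """A scalar respiratory amplitude series sampled at known times.

    timestamps are seconds, strictly increasing; amplitude is in arbitrary
    units with higher values at inspiration.
    """

    timestamps: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        if t.ndim != 1 or a.ndim != 1 or t.shape != a.shape:
            raise GatingError("timestamps and amplitude must be 1-D and equal length")
        if t.size < 2:
            raise GatingError("gating series needs at least 2 samples")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(a)):
            raise GatingError("gating series contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise GatingError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "amplitude", a)

    @property
    def n(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.timestamps)))


@dataclass(frozen=True)
class BinAssignment:
    """Result of sorting phased acquisitions into cyclic respiratory bins.

    core_bin holds, per input acquisition, the index of its (single) core bin,
    or -1 for acquisitions dropped before phasing. shared lists, per bin, the
    acquisition indices borrowed from the two cyclic neighbor bins.
    phase_edges are the n_bins+1 boundaries (after any merging) in [0, 1].
    """

    n_bins: int
    core_bin: np.ndarray
    shared: tuple[tuple[int, ...], ...]
    phase_edges: np.ndarray

    def core_count(self, b: int) -> int:
        return int(np.sum(self.core_bin == b))

    def core_indices(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.core_bin == b)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    return uniform_filter1d(x, size=int(window), mode="nearest")


def extract_gating_signal(
    source,
    timestamps: np.ndarray | None = None,
    roi: tuple[slice, slice] | None = None,
    smooth_window: int = 3,
    invert: bool = False,
) -> GatingSeries:
    """Reduce a navigator to a smoothed scalar respiratory amplitude series.

    source may be a :class:`GatingSeries`, a 1-D scalar series (with
    ``timestamps``), or a (T, H, W) low-resolution image series (with
    ``timestamps``). For image input the amplitude is the spatial mean over
    ``roi`` (default: the central half field of view) per frame. The series is
    then moving-average smoothed with ``smooth_window`` samples.
    """
    if isinstance(source, GatingSeries):
        t, amp = source.timestamps, source.amplitude.copy()
    else:
        arr = np.asarray(source, dtype=float)
        if timestamps is None:
            raise GatingError("timestamps are required for array input")
        t = np.asarray(timestamps, dtype=float)
        if arr.ndim == 1:
            amp = arr.copy()
        elif arr.ndim == 3:
            if arr.shape[0] < 2:
                raise GatingError("image series needs at least 2 frames")
            if roi is None:
                h, w = arr.shape[1], arr.shape[2]
                roi = (slice(h // 4, h // 4 + h // 2), slice(w // 4, w // 4 + w // 2))
            sub = arr[:, roi[0], roi[1]]
            if sub.size == 0:
                raise GatingError("empty navigator ROI")
            amp = sub.mean(axis=(1, 2))
        else:
            raise GatingError("navigator must be 1-D scalar or (T, H, W) image series")
    amp = _moving_average(amp, smooth_window)
    if invert:
        amp = -amp
    return GatingSeries(t, amp)


def _detect_peaks(
    g: GatingSeries,
    min_prominence_frac: float,
    min_separation_s: float,
    negate: bool = False,
) -> np.ndarray:
    amp = -g.amplitude if negate else g.amplitude
    q75, q25 = np.percentile(g.amplitude, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise GatingError("gating amplitude has zero interquartile range (flat signal)")
    distance = max(1, int(round(min_separation_s / g.dt)))
    peaks, _ = find_peaks(amp, prominence=min_prominence_frac * iqr, distance=distance)
    return peaks


def estimate_breathing_frequency(
    g: GatingSeries,
    min_prominence_frac: float = 0.2,
    min_separation_s: float = 1.5,
) -> float:
    """Breathing frequency in breaths/min from end-inspiration peak spacing.

    Detects end-inspiration peaks (minimum prominence 0.2 x the amplitude
    interquartile range, minimum separation 1.5 s by default) and returns
    (n_peaks - 1) / (time spanned by the peaks), converted to per minute.
    """
    peaks = _detect_peaks(g, min_prominence_frac, min_separation_s)
    if peaks.size < 2:
        raise GatingError("fewer than 2 breathing cycles detected")
    span = g.timestamps[peaks[-1]] - g.timestamps[peaks[0]]
    return 60.0 * (peaks.size - 1) / span


def compute_respiratory_phase(
    g: GatingSeries,
    min_prominence_frac: float = 0.2,
    min_separation_s: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Respiratory phase in [0, 1) per sample, trough-anchored.

    Phase is 0 at detected troughs (end-expiration), 0.5 at peaks
    (end-inspiration), and piecewise linear in time within each half cycle.
    Samples before the first or after the last detected extremum cannot be
    phased; they are returned as NaN with ``valid`` False.

    Returns (phase, valid).
    """
    peaks = _detect_peaks(g, min_prominence_frac, min_separation_s)
    troughs = _detect_peaks(g, min_prominence_frac, min_separation_s, negate=True)
    if peaks.size == 0 or troughs.size == 0:
        raise GatingError("no respiratory extrema detected")

    # Merge extrema in time, enforcing trough/peak alternation: of two
    # consecutive extrema of the same kind keep the more extreme one.
    idx = np.concatenate([peaks, troughs])
    kind = np.concatenate([np.ones(peaks.size, bool), np.zeros(troughs.size, bool)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    keep_idx: list[int] = []
    keep_kind: list[bool] = []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            prev = keep_idx[-1]
            better = g.amplitude[i] > g.amplitude[prev] if k else g.amplitude[i] < g.amplitude[prev]
            if better:
                keep_idx[-1] = int(i)
        else:
            keep_idx.append(int(i))
            keep_kind.append(bool(k))
    if len(keep_idx) < 2:
        raise GatingError("fewer than one half respiratory cycle detected")

    ex_t = g.timestamps[keep_idx]
    # Unwrapped phase: troughs sit at integers, peaks at integer + 0.5, each
    # successive extremum advances by half a cycle.
    start = 0.5 if keep_kind[0] else 0.0
    ex_phase = start + 0.5 * np.arange(len(keep_idx))

    phase = np.interp(g.timestamps, ex_t, ex_phase)
    valid = (g.timestamps >= ex_t[0]) & (g.timestamps <= ex_t[-1])
    phase = np.where(valid, np.mod(phase, 1.0), np.nan)
    return phase, valid


def _cyclic_gap(a: np.ndarray, b: float) -> np.ndarray:
    """Cyclic distance from phases ``a`` forward to boundary ``b`` in [0,1)."""
    return np.mod(b - a, 1.0)


def assign_bins(
    phases: np.ndarray,
    min_count: int = 100,
    share_fraction: float = 0.2,
    n_bins: int | None = None,
    max_bins: int = 51,
) -> BinAssignment:
    """Sort phased acquisitions into cyclic respiratory bins with view sharing.

    If ``n_bins`` is not given it defaults to floor(N / min_count), clipped to
    [1, max_bins]. Acquisitions fall into equal-width cyclic phase bins;
    adjacent under-full bins are merged until every core count reaches
    ``min_count``; each bin then borrows its nearest-in-phase acquisitions
    from its two cyclic neighbors, floor(share_fraction * core_count / 2)
    from each side.

    NaN phases (samples dropped during phasing) get core_bin -1.
    """
    phases = np.asarray(phases, dtype=float)
    retained = np.flatnonzero(np.isfinite(phases))
    n = retained.size
    if min_count < 1:
        raise BinningError("min_count must be >= 1")
    if n < min_count:
        raise BinningError(f"{n} phased acquisitions < min_count {min_count}")
    ph = np.mod(phases[retained], 1.0)

    if n_bins is None:
        n_bins = min(int(max_bins), max(1, n // min_count))
    if n_bins < 1:
        raise BinningError("n_bins must be >= 1")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    raw_bin = np.clip(np.floor(ph * n_bins).astype(int), 0, n_bins - 1)

    # Merge adjacent (non-cyclic) bins until occupancy holds; ties toward the
    # smaller neighbor index. Bins are contiguous runs of raw bins.
    groups: list[list[int]] = [[b] for b in range(n_bins)]
    counts = [int(np.sum(raw_bin == b)) for b in range(n_bins)]
    while len(groups) > 1 and min(counts) < min_count:
        i = int(np.argmin(counts))
        cands = [j for j in (i - 1, i + 1) if 0 <= j < len(groups)]
        j = min(cands, key=lambda c: (counts[c], c))
        lo, hi = min(i, j), max(i, j)
        groups[lo] = groups[lo] + groups[hi]
        counts[lo] = counts[lo] + counts[hi]
        del groups[hi], counts[hi]
    if min(counts) < min_count:
        raise BinningError("cannot satisfy min_count even after merging all bins")

    n_final = len(groups)
    remap = np.empty(n_bins, dtype=int)
    for g_idx, grp in enumerate(groups):
        for b in grp:
            remap[b] = g_idx
    core_of_retained = remap[raw_bin]
    core_bin = np.full(phases.size, -1, dtype=int)
    core_bin[retained] = core_of_retained
    phase_edges = np.array([edges[grp[0]] for grp in groups] + [1.0])

    shared: list[tuple[int, ...]] = []
    for b in range(n_final):
        core_n = int(np.sum(core_of_retained == b))
        per_side = int(np.floor(share_fraction * core_n / 2.0))
        lo_edge, hi_edge = phase_edges[b], phase_edges[b + 1]
        borrow: list[int] = []
        if n_final >= 2 and per_side > 0:
            left, right = (b - 1) % n_final, (b + 1) % n_final
            for donor, edge, forward in ((left, lo_edge, True), (right, hi_edge, False)):
                if donor == b:
                    continue
                members = np.flatnonzero(core_of_retained == donor)
                if forward:  # donors just below the recipient's lower edge
                    gaps = _cyclic_gap(ph[members], edge)
                else:  # donors just above the recipient's upper edge
                    gaps = np.mod(ph[members] - edge, 1.0)
                take = members[np.argsort(gaps, kind="stable")[:per_side]]
                borrow.extend(int(retained[m]) for m in take)
        shared.append(tuple(borrow))

    return BinAssignment(
        n_bins=n_final,
        core_bin=core_bin,
        shared=tuple(shared),
        phase_edges=phase_edges,
    )
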