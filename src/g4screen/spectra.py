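"""Preprocessing of 1D ¹H NMR spectra for the G-quadruplex screen.

The operations mirror the screen's sorting workflow: isolate the imino-proton
region (10–12 ppm) where G-quadruplex tetrad formation is diagnosed, scale to
[0, 1], estimate noise, filter spectra with no signals, pick and count peaks,
and compare the same sample at two timepoints to flag slow folders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

__all__ = [
    "Spectrum",
    "PeakList",
    "WindowError",
    "trim_region",
    "scale01",
    "estimate_noise",
    "has_g4_signals",
    "pick_peaks",
    "subtract_rolling_min",
    "compare_timepoints",
]


class WindowError(ValueError):
    """Requested window does not overlap the spectrum axis."""


@dataclass
class Spectrum:
    """A 1D spectrum on a ppm axis.

    ``ppm`` must be strictly monotone (either direction); intensities are
    finite and the same length.  ``timepoint`` is a free label, typically
    ``t0`` or ``t2months`` for the two screening timepoints.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    seq_id: str = ""
    timepoint: str = "t0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1D arrays of equal length")
        if self.ppm.size < 16:
            raise ValueError("spectrum must have at least 16 points")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def ascending(self) -> "Spectrum":
        """View with ppm increasing (interpolation-friendly)."""
        if self.ppm[0] < self.ppm[-1]:
            return self
        return replace(self, ppm=self.ppm[::-1].copy(), intensity=self.intensity[::-1].copy())


@dataclass
class PeakList:
    """Picked imino peaks: positions, heights and per-peak SNR.

    ``span_ppm`` is the distance between the outermost peaks (0 with fewer
    than 2 peaks); it distinguishes e.g. the compact 17.4 pattern (~0.9 ppm)
    from the wide 17.4s26 pattern (~1.5 ppm).
    """

    positions_ppm: np.ndarray
    heights: np.ndarray
    snr: np.ndarray

    @property
    def n_signals(self) -> int:
        return int(self.positions_ppm.size)

    @property
    def span_ppm(self) -> float:
        if self.n_signals < 2:
            return 0.0
        return float(self.positions_ppm.max() - self.positions_ppm.min())


def trim_region(s: Spectrum, lo: float = 10.0, hi: float = 12.0) -> Spectrum:
    """Restrict to the imino window [lo, hi] ppm, preserving metadata."""
    if not lo < hi:
        raise WindowError(f"need lo < hi, got ({lo}, {hi})")
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if not mask.any():
        raise WindowError(
            f"window ({lo}, {hi}) does not overlap axis "
            f"[{s.ppm.min():g}, {s.ppm.max():g}]"
        )
    return replace(s, ppm=s.ppm[mask].copy(), intensity=s.intensity[mask].copy())


def scale01(s: Spectrum) -> Spectrum:
    """Linearly map intensities so min→0 and max→1.

    A constant spectrum cannot be scaled; it is returned as all zeros with a
    warning (such spectra are filtered out downstream anyway).
    """
    lo, hi = float(s.intensity.min()), float(s.intensity.max())
    if hi == lo:
        warnings.warn(
            f"constant spectrum {s.seq_id or '<unnamed>'}: returning zeros",
            stacklevel=2,
        )
        return replace(s, intensity=np.zeros_like(s.intensity))
    return replace(s, intensity=(s.intensity - lo) / (hi - lo))


def estimate_noise(s: Spectrum) -> float:
    """Robust noise SD from first differences.

    Successive differences of white noise with SD sigma have SD sigma*sqrt(2);
    the MAD-based estimate 1.4826 * MAD(diff) / sqrt(2) ignores the sparse
    peaks riding on the baseline.
    """
    if s.ppm.size < 64:
        raise ValueError("need at least 64 points for noise estimation")
    d = np.diff(s.intensity)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def has_g4_signals(s: Spectrum, k: float = 5.0) -> bool:
    """True iff the maximum intensity clears ``k`` times the noise floor.

    Heights are measured from the baseline (median intensity), so the test
    is invariant to intensity offsets — in particular to the offset that
    0–1 scaling introduces when the raw minimum is a negative noise
    excursion.  This is the filter that discards spectra with no signals in
    the G-quadruplex region before clustering.
    """
    noise = estimate_noise(s)
    baseline = float(np.median(s.intensity))
    if noise == 0.0:
        return bool(s.intensity.max() > baseline)
    return bool(s.intensity.max() - baseline >= k * noise)


def pick_peaks(s: Spectrum, k: float = 5.0, min_sep_ppm: float = 0.03) -> PeakList:
    """Pick local maxima higher than ``k`` × noise above the baseline
    (median intensity), merging peaks closer than ``min_sep_ppm`` (the
    higher one is kept)."""
    sp = s.ascending
    noise = estimate_noise(sp)
    baseline = float(np.median(sp.intensity))
    threshold = baseline + (k * noise if noise > 0 else np.finfo(float).tiny)
    idx, _ = _signal.find_peaks(sp.intensity, height=threshold)
    pos = sp.ppm[idx]
    hts = sp.intensity[idx]

    # greedy merge: visit by descending height, drop peaks within min_sep
    order = np.argsort(hts)[::-1]
    kept: list[int] = []
    for j in order:
        if all(abs(pos[j] - pos[i]) >= min_sep_ppm for i in kept):
            kept.append(j)
    kept.sort(key=lambda j: pos[j])
    pos, hts = pos[kept], hts[kept]
    snr = hts / noise if noise > 0 else np.full_like(hts, np.inf)
    return PeakList(positions_ppm=pos, heights=hts, snr=snr)


def subtract_rolling_min(s: Spectrum, window_ppm: float = 0.2) -> Spectrum:
    """Optional baseline correction: subtract a rolling minimum.

    Off by default in the pipeline — synthetic spectra are baseline-free —
    but useful for instrument exports with slow baseline drift.  The window
    should be much wider than a linewidth so peaks are not eroded.
    """
    sp = s.ascending
    step = float(np.median(np.diff(sp.ppm)))
    half = max(1, int(round(window_ppm / step / 2)))
    n = sp.intensity.size
    baseline = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        baseline[i] = sp.intensity[lo:hi].min()
    return replace(sp, intensity=sp.intensity - baseline)


def compare_timepoints(a: Spectrum, b: Spectrum, threshold: float = 0.2) -> tuple[float, bool]:
    """Difference score between two spectra of the same sample.

    Both spectra are interpolated onto the coarser common grid; the score is
    1 − Pearson r of the intensities, clipped to [0, 1].  Returns
    ``(score, changed)`` where ``changed`` is ``score > threshold`` — the
    flag used to spot slow-folding sequences whose spectra differ between
    the first measurement and the two-month remeasurement.
    """
    aa, bb = a.ascending, b.ascending
    lo = max(aa.ppm[0], bb.ppm[0])
    hi = min(aa.ppm[-1], bb.ppm[-1])
    if not lo < hi:
        raise WindowError("spectra have no common ppm range")
    coarse = aa if aa.ppm.size <= bb.ppm.size else bb
    grid = coarse.ppm[(coarse.ppm >= lo) & (coarse.ppm <= hi)]
    if grid.size < 16:
        raise WindowError("common grid too short")
    ya = np.interp(grid, aa.ppm, aa.intensity)
    yb = np.interp(grid, bb.ppm, bb.intensity)
    if ya.std() == 0 or yb.std() == 0:
        # a flat trace has no pattern to correlate; treat as maximally
        # different unless both are flat
        score = 0.0 if ya.std() == yb.std() == 0 else 1.0
    else:
        r = float(np.corrcoef(ya, yb)[0, 1])
        score = float(np.clip(1.0 - r, 0.0, 1.0))
        if score < 1e-12:  # round-off from the correlation of identical traces
            score = 0.0
    return score, score > threshold
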