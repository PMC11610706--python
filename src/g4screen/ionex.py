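"""Ion-exchange chromatogram peak typing.

In the screen's secondary characterization, MonoQ ion-exchange elution
volumes diagnose the multimeric state of a library member: monomeric,
dimeric and tetrameric G-quadruplexes and two non-G4 categories elute in
distinct, calibrated volume windows.  This module detects chromatogram
apexes and classifies them into those windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "Chromatogram",
    "PEAK_TYPE_WINDOWS",
    "classify_peak",
    "detect_chromatogram_peaks",
    "infer_multimeric_states",
]

#: elution-volume windows (mL, inclusive bounds) per peak type
PEAK_TYPE_WINDOWS: dict[str, tuple[float, float]] = {
    "not_G4": (5.1, 5.4),
    "many_mutations": (5.55, 5.7),
    "dimeric": (6.1, 6.7),
    "tetrameric": (6.8, 7.4),
    "monomeric": (7.7, 9.0),
}


@dataclass
class Chromatogram:
    """An ion-exchange trace: absorbance versus elution volume (mL)."""

    volume_ml: np.ndarray
    absorbance: np.ndarray
    seq_id: str = ""

    def __post_init__(self) -> None:
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.volume_ml.shape != self.absorbance.shape or self.volume_ml.ndim != 1:
            raise ValueError("volume and absorbance must be 1D arrays of equal length")
        if not np.all(np.diff(self.volume_ml) > 0):
            raise ValueError("volume axis must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")


def _robust_noise_sd(y: np.ndarray) -> float:
    """Same first-difference MAD estimator used for NMR spectra."""
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def classify_peak(
    v: float, table: dict[str, tuple[float, float]] | None = None
) -> str:
    """Peak type whose window contains the apex volume, else ``unclassified``.

    The windows are pairwise disjoint, so at most one can match; apexes in
    the gaps between windows are reported as ``unclassified`` rather than
    snapped to the nearest window.
    """
    table = table if table is not None else PEAK_TYPE_WINDOWS
    for name, (lo, hi) in table.items():
        if lo <= v <= hi:
            return name
    return "unclassified"


def detect_chromatogram_peaks(
    c: Chromatogram, k: float = 5.0, merge_ml: float = 0.1
) -> list[tuple[float, float]]:
    """Apexes above ``k`` × noise as (volume mL, height), merged within
    ``merge_ml`` keeping the higher apex."""
    if c.volume_ml.size < 64:
        raise ValueError("need at least 64 points for peak detection")
    noise = _robust_noise_sd(c.absorbance)
    baseline = float(np.median(c.absorbance))
    threshold = baseline + (k * noise if noise > 0 else np.finfo(float).tiny)
    idx, _ = _signal.find_peaks(c.absorbance, height=threshold)
    pos = c.volume_ml[idx]
    hts = c.absorbance[idx]
    order = np.argsort(hts)[::-1]
    kept: list[int] = []
    for j in order:
        if all(abs(pos[j] - pos[i]) >= merge_ml for i in kept):
            kept.append(j)
    kept.sort(key=lambda j: pos[j])
    return [(float(pos[j]), float(hts[j])) for j in kept]


def infer_multimeric_states(
    c: Chromatogram,
    table: dict[str, tuple[float, float]] | None = None,
    *,
    k: float = 5.0,
    merge_ml: float = 0.1,
) -> set[str]:
    """Set of classified peak types over all detected apexes.

    Mixed populations (e.g. a monomer/tetramer mixture) yield multi-element
    sets; a flat trace yields the empty set.  Unclassified apexes do not
    contribute a state.
    """
    peaks = detect_chromatogram_peaks(c, k=k, merge_ml=merge_ml)
    states = {classify_peak(v, table) for v, _ in peaks}
    states.discard("unclassified")
    return states
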