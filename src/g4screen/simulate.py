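"""Class-conditioned synthetic data for the G-quadruplex NMR screen.

No raw screen data are deposited, so every downstream stage is exercised on
synthetic inputs that emulate the screen's qualitative structure:

* ¹H spectra — Lorentzian imino peaks in the 10–12 ppm window plus white
  Gaussian noise.  Each spectral class has a fixed chemical-shift
  *fingerprint* (a reproducible set of peak positions derived from the class
  name), so that members of one class share a pattern while classes differ —
  the property the screen's clustering step exploits.  Peak counts, spectral
  spans and signal-to-noise ratios follow the class descriptions: the
  monomeric 17.3 class shows ~12 sharp, intense peaks; 17.4 up to six peaks
  within ~0.9 ppm; 17.4s26 eleven or more weaker peaks spread over ~1.5 ppm;
  17.63 a few broad, weak peaks; three-to-four-mutation classes few peaks or
  none at all.
* ion-exchange chromatograms — one Gaussian peak per multimeric state,
  centred inside that state's elution window.
* activity tables — five activities (Flu, Tet, Dim, Per, GTP) drawn around
  class means with a small within-class relative SD, encoding the screen's
  functional contrasts (17.3 maximal fluorescence and peroxidase activity,
  17.63 ~12-fold the GTP binding of 17.4 but ~3-fold lower peroxidase
  activity, the 17.4 family dimer-prone, non-G4 sequences at background).

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ionex import PEAK_TYPE_WINDOWS, Chromatogram
from .library import SpectralClass
from .spectra import Spectrum

__all__ = [
    "ClassSpectrumTemplate",
    "SimConfig",
    "SPECTRUM_TEMPLATES",
    "DEFAULT_ACTIVITY_MEANS",
    "ACTIVITIES",
    "simulate_spectrum",
    "simulate_chromatogram",
    "simulate_activities",
    "class_fingerprint",
]

ACTIVITIES = ("Flu", "Tet", "Dim", "Per", "GTP")


@dataclass(frozen=True)
class ClassSpectrumTemplate:
    """Spectral caricature of one class.

    ``n_peaks_range`` and ``snr_range`` are inclusive; ``span_ppm`` is the
    width of the region holding the class fingerprint; ``center_ppm_range``
    bounds the fingerprint centre (all within the 10–12 ppm imino window).
    ``linewidth_scale`` broadens lines relative to the config linewidth
    (multimeric species give broader signals).  ``per_sample_fingerprint``
    marks classes with no shared pattern (each sample gets fresh positions).
    """

    n_peaks_range: tuple[int, int]
    span_ppm: float
    snr_range: tuple[float, float]
    center_ppm_range: tuple[float, float]
    linewidth_scale: float = 1.0
    per_sample_fingerprint: bool = False


SPECTRUM_TEMPLATES: dict[SpectralClass, ClassSpectrumTemplate] = {
    # monomeric reference fold: many sharp, intense imino peaks
    SpectralClass.C17_3: ClassSpectrumTemplate((12, 12), 1.6, (30, 60), (10.9, 11.1)),
    # dimer class: compact pattern of up to six peaks, good SNR
    SpectralClass.C17_4: ClassSpectrumTemplate((4, 6), 0.8, (15, 30), (11.0, 11.2)),
    # wide, signal-rich, weaker pattern (more than one conformer)
    SpectralClass.C17_4s26: ClassSpectrumTemplate((11, 13), 1.5, (8, 15), (10.8, 11.0)),
    # union of the 17.4 and 17.4s26 patterns; built specially below
    SpectralClass.C17_4_plus_17_4s26: ClassSpectrumTemplate(
        (15, 19), 1.5, (8, 15), (10.9, 11.1)
    ),
    # tetramer class: few broad, weak peaks
    SpectralClass.C17_63: ClassSpectrumTemplate(
        (2, 4), 0.6, (6, 10), (11.2, 11.5), linewidth_scale=3.0
    ),
    SpectralClass.C17_36: ClassSpectrumTemplate((6, 8), 1.0, (10, 20), (10.55, 10.7)),
    # up to 11 signals from 10 guanosines: multiple conformations
    SpectralClass.C17_28: ClassSpectrumTemplate((9, 11), 1.2, (8, 15), (10.6, 10.8)),
    # strikingly 17.3-like spectra
    SpectralClass.C17_49: ClassSpectrumTemplate((10, 12), 1.6, (25, 50), (10.9, 11.05)),
    # 3-4 tetrad mutations but residual structured signals (≤4 peaks)
    SpectralClass.C17_180: ClassSpectrumTemplate((2, 4), 0.5, (6, 12), (11.4, 11.7)),
    SpectralClass.C17_154: ClassSpectrumTemplate((2, 4), 0.5, (6, 12), (10.3, 10.5)),
    # signals with no shared pattern
    SpectralClass.no_pattern: ClassSpectrumTemplate(
        (2, 6), 1.6, (5, 15), (10.95, 11.05), per_sample_fingerprint=True
    ),
    # flat noise: no imino signals
    SpectralClass.no_G4_signals: ClassSpectrumTemplate((0, 0), 0.0, (0, 0), (11.0, 11.0)),
}

#: class mean activities in arbitrary units with background 1.0; encodes the
#: screen's qualitative functional profile (ratios, not absolute scales,
#: are meaningful).  GTP(17.63)/GTP(17.4) = 12, Per(17.63)/Per(17.4) = 1/3.
DEFAULT_ACTIVITY_MEANS: dict[SpectralClass, dict[str, float]] = {
    SpectralClass.C17_3: dict(Flu=10.0, Tet=1.5, Dim=1.5, Per=9.0, GTP=8.0),
    SpectralClass.C17_4: dict(Flu=2.0, Tet=1.5, Dim=8.0, Per=6.0, GTP=0.5),
    SpectralClass.C17_4s26: dict(Flu=1.8, Tet=2.0, Dim=7.0, Per=5.0, GTP=0.6),
    SpectralClass.C17_4_plus_17_4s26: dict(Flu=1.9, Tet=2.0, Dim=7.5, Per=5.5, GTP=0.55),
    SpectralClass.C17_63: dict(Flu=1.2, Tet=8.0, Dim=1.5, Per=2.0, GTP=6.0),
    SpectralClass.C17_36: dict(Flu=1.1, Tet=2.0, Dim=2.0, Per=1.5, GTP=1.2),
    SpectralClass.C17_28: dict(Flu=1.1, Tet=1.8, Dim=2.5, Per=1.4, GTP=1.1),
    SpectralClass.C17_49: dict(Flu=5.0, Tet=1.2, Dim=1.3, Per=4.0, GTP=3.0),
    SpectralClass.C17_180: dict(Flu=1.2, Tet=1.1, Dim=1.2, Per=1.1, GTP=1.3),
    SpectralClass.C17_154: dict(Flu=1.1, Tet=1.2, Dim=1.3, Per=1.1, GTP=1.2),
    SpectralClass.no_pattern: dict(Flu=1.0, Tet=1.1, Dim=1.1, Per=1.0, GTP=1.0),
    SpectralClass.no_G4_signals: dict(Flu=1.0, Tet=1.0, Dim=1.0, Per=1.0, GTP=1.0),
}


@dataclass
class SimConfig:
    """Shared parameters of the synthetic-data generator."""

    seed: int = 0
    points_per_spectrum: int = 2048
    ppm_min: float = 10.0
    ppm_max: float = 12.0
    linewidth_ppm: float = 0.02  # FWHM of Lorentzian lines
    noise_sd: float = 0.01
    position_jitter_ppm: float = 0.003
    within_class_rsd: float = 0.1
    class_activity_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ACTIVITY_MEANS.items()}
    )
    # chromatogram axis and peak shape
    volume_min_ml: float = 4.5
    volume_max_ml: float = 10.0
    points_per_trace: int = 1100
    peak_width_ml: float = 0.05  # Gaussian SD
    trace_snr_range: tuple[float, float] = (30.0, 60.0)
    trace_noise_sd: float = 0.01

    def ppm_axis(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.points_per_spectrum)

    def volume_axis(self) -> np.ndarray:
        return np.linspace(self.volume_min_ml, self.volume_max_ml, self.points_per_trace)


def _class_rng(label: SpectralClass) -> np.random.Generator:
    # fingerprint identity derives from the class name, not the user seed:
    # the same class always shows the same chemical-shift pattern
    return np.random.default_rng(zlib.crc32(label.value.encode()))


def _fingerprint_from_template(
    tpl: ClassSpectrumTemplate, rng: np.random.Generator
) -> np.ndarray:
    """Peak positions: evenly spread over the span, perturbed, order shuffled.

    The even spread guarantees peaks stay resolvable (pairwise separation
    well above the linewidth); the fixed shuffle makes per-sample subsets
    cover the span rather than truncate it.
    """
    n_max = tpl.n_peaks_range[1]
    if n_max == 0:
        return np.empty(0)
    center = rng.uniform(*tpl.center_ppm_range)
    if n_max == 1:
        pos = np.array([center])
    else:
        pos = np.linspace(center - tpl.span_ppm / 2, center + tpl.span_ppm / 2, n_max)
        step = tpl.span_ppm / (n_max - 1)
        pos = pos + rng.uniform(-0.15 * step, 0.15 * step, size=n_max)
    rng.shuffle(pos)
    return pos


def class_fingerprint(label: SpectralClass) -> np.ndarray:
    """The fixed chemical-shift fingerprint of a class (shuffled order)."""
    tpl = SPECTRUM_TEMPLATES[label]
    if label is SpectralClass.C17_4_plus_17_4s26:
        # the mixed class shows the signals of both parent classes; peaks
        # that happen to land closer than 0.05 ppm would not be resolvable
        # and are dropped so the generated count stays honest
        combined = np.concatenate(
            [
                class_fingerprint(SpectralClass.C17_4),
                class_fingerprint(SpectralClass.C17_4s26),
            ]
        )
        kept: list[float] = []
        for p in combined:
            if all(abs(p - q) >= 0.05 for q in kept):
                kept.append(float(p))
        return np.array(kept)
    return _fingerprint_from_template(tpl, _class_rng(label))


def _lorentzian(x: np.ndarray, x0: float, height: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return height * gamma**2 / (gamma**2 + (x - x0) ** 2)


def simulate_spectrum(
    label: SpectralClass,
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    seq_id: str = "",
    timepoint: str = "t0",
) -> tuple[Spectrum, dict]:
    """Draw one synthetic spectrum of the given class.

    Returns ``(spectrum, truth)`` where ``truth`` holds the generated peak
    positions, heights and count for downstream round-trip checks.
    """
    if label not in SPECTRUM_TEMPLATES:
        raise KeyError(f"no spectrum template for class {label!r}")
    tpl = SPECTRUM_TEMPLATES[label]
    x = cfg.ppm_axis()

    if tpl.per_sample_fingerprint:
        fingerprint = _fingerprint_from_template(tpl, rng)
    else:
        fingerprint = class_fingerprint(label)

    n_lo, n_hi = tpl.n_peaks_range
    if label is SpectralClass.C17_4_plus_17_4s26:
        n_lo, n_hi = len(fingerprint) - 4, len(fingerprint)
    n_peaks = int(rng.integers(n_lo, n_hi + 1)) if n_hi > 0 else 0
    positions = np.sort(
        fingerprint[:n_peaks] + rng.normal(0.0, cfg.position_jitter_ppm, n_peaks)
    )
    positions = np.clip(positions, cfg.ppm_min, cfg.ppm_max)

    snr = rng.uniform(*tpl.snr_range) if n_peaks else 0.0
    amplitude = snr * (cfg.noise_sd if cfg.noise_sd > 0 else 1.0)
    heights = amplitude * rng.uniform(0.6, 1.0, size=n_peaks)

    y = np.zeros_like(x)
    fwhm = cfg.linewidth_ppm * tpl.linewidth_scale
    for x0, h in zip(positions, heights):
        y += _lorentzian(x, x0, h, fwhm)
    if cfg.noise_sd > 0:
        y += rng.normal(0.0, cfg.noise_sd, size=x.size)

    spec = Spectrum(ppm=x, intensity=y, seq_id=seq_id, timepoint=timepoint,
                    meta={"class": label.value})
    truth = {
        "class": label,
        "n_peaks": n_peaks,
        "positions_ppm": positions,
        "heights": heights,
        "fwhm_ppm": fwhm,
    }
    return spec, truth


def simulate_chromatogram(
    states: set[str],
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    seq_id: str = "",
) -> tuple[Chromatogram, dict]:
    """One Gaussian elution peak per multimeric state, inside its window."""
    if not states:
        raise ValueError("state set must be non-empty")
    unknown = set(states) - set(PEAK_TYPE_WINDOWS)
    if unknown:
        raise KeyError(f"unknown multimeric state(s): {sorted(unknown)}")

    v = cfg.volume_axis()
    y = np.zeros_like(v)
    apexes: dict[str, float] = {}
    for state in sorted(states):
        lo, hi = PEAK_TYPE_WINDOWS[state]
        margin = min(0.05, (hi - lo) / 4.0)
        apex = rng.uniform(lo + margin, hi - margin)
        snr = rng.uniform(*cfg.trace_snr_range)
        height = snr * (cfg.trace_noise_sd if cfg.trace_noise_sd > 0 else 1.0)
        y += height * np.exp(-0.5 * ((v - apex) / cfg.peak_width_ml) ** 2)
        apexes[state] = apex
    if cfg.trace_noise_sd > 0:
        y += rng.normal(0.0, cfg.trace_noise_sd, size=v.size)

    chrom = Chromatogram(volume_ml=v, absorbance=y, seq_id=seq_id)
    return chrom, {"states": set(states), "apexes_ml": apexes}


def simulate_activities(
    labels: list[SpectralClass],
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    seq_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sequence activity table with class-specific means.

    Each activity is drawn Normal(mean, ``within_class_rsd`` × mean), clipped
    at zero; with ``within_class_rsd = 0`` every member sits exactly at its
    class mean.
    """
    labels = [SpectralClass(lb) for lb in labels]
    means = cfg.class_activity_means
    missing = [lb for lb in set(labels) if lb not in means]
    if missing:
        raise KeyError(
            f"no activity means configured for class(es): "
            f"{sorted(lb.value for lb in missing)}"
        )
    if seq_ids is None:
        seq_ids = [f"s{i:04d}" for i in range(len(labels))]
    rows = []
    for sid, lb in zip(seq_ids, labels):
        row: dict[str, object] = {"seq_id": sid, "class": lb.value}
        for act in ACTIVITIES:
            mu = float(means[lb][act])
            val = mu if cfg.within_class_rsd == 0 else rng.normal(
                mu, cfg.within_class_rsd * mu
            )
            row[act] = max(0.0, float(val))
        rows.append(row)
    return pd.DataFrame(rows, columns=["seq_id", "class", *ACTIVITIES])
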