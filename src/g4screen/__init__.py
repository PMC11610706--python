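"""g4screen: analysis pipeline for an NMR screen of a G-quadruplex variant library.

The package enumerates a 496-member variant library of a 17-nt monomeric
reference G-quadruplex, assigns structural classes from mutational
signatures, generates class-conditioned synthetic ¹H spectra, ion-exchange
chromatograms and activity tables, and implements the screen's downstream
analysis: imino-region preprocessing and peak picking, spectral clustering
with class agreement scoring, chromatogram peak typing, and renormalized
class activity profiles with a permutation homogeneity test.
"""

__version__ = "0.1.0"

from .library import (
    ClassLabel,
    LibrarySequence,
    ReferenceTopology,
    SpectralClass,
    annotate,
    assign_rule_class,
    count_by_tetrad_mutations,
    enumerate_library,
    match_tetrad_pattern,
)
from .simulate import (
    SimConfig,
    simulate_activities,
    simulate_chromatogram,
    simulate_spectrum,
)
from .spectra import (
    PeakList,
    Spectrum,
    compare_timepoints,
    estimate_noise,
    has_g4_signals,
    pick_peaks,
    scale01,
    trim_region,
)
from .cluster import (
    cluster_class_agreement,
    hierarchical_cluster,
    spectra_distance_matrix,
)
from .ionex import (
    PEAK_TYPE_WINDOWS,
    Chromatogram,
    classify_peak,
    detect_chromatogram_peaks,
    infer_multimeric_states,
)
from .profiles import (
    ActivityProfile,
    class_profiles,
    rsd_random_null,
    rsd_within_class,
)
from .pipeline import PipelineConfig, run_pipeline

__all__ = [
    "__version__",
    "ClassLabel", "LibrarySequence", "ReferenceTopology", "SpectralClass",
    "annotate", "assign_rule_class", "count_by_tetrad_mutations",
    "enumerate_library", "match_tetrad_pattern",
    "SimConfig", "simulate_activities", "simulate_chromatogram",
    "simulate_spectrum",
    "PeakList", "Spectrum", "compare_timepoints", "estimate_noise",
    "has_g4_signals", "pick_peaks", "scale01", "trim_region",
    "cluster_class_agreement", "hierarchical_cluster",
    "spectra_distance_matrix",
    "PEAK_TYPE_WINDOWS", "Chromatogram", "classify_peak",
    "detect_chromatogram_peaks", "infer_multimeric_states",
    "ActivityProfile", "class_profiles", "rsd_random_null",
    "rsd_within_class",
    "PipelineConfig", "run_pipeline",
]
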