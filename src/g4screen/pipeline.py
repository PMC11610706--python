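"""End-to-end orchestration of the synthetic screen.

``run_pipeline`` executes the full workflow on synthetic data: enumerate the
library, simulate a class-conditioned spectrum, chromatogram cohort and
activity table, preprocess and filter spectra, cluster them and score the
agreement with the rule-based classes, type the chromatogram peaks, and
compute renormalized activity profiles.  A JSON manifest records the seed,
per-stage outputs and their SHA-256 hashes, so any stage can be re-run and
checked bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import ionex as _ionex
from . import library as _library
from . import profiles as _profiles
from . import simulate as _simulate
from . import spectra as _spectra
from .library import SpectralClass
from .simulate import SimConfig

log = logging.getLogger("g4screen")

__all__ = ["PipelineConfig", "ConfigError", "load_config", "run_pipeline",
           "CLASS_MULTIMERIC_STATES"]

#: nominal multimeric state(s) per spectral class, used when simulating the
#: ion-exchange trace of a class representative
CLASS_MULTIMERIC_STATES: dict[SpectralClass, set[str]] = {
    SpectralClass.C17_3: {"monomeric"},
    SpectralClass.C17_4: {"dimeric"},
    SpectralClass.C17_4s26: {"dimeric"},
    SpectralClass.C17_4_plus_17_4s26: {"dimeric", "monomeric"},
    SpectralClass.C17_63: {"tetrameric"},
    SpectralClass.C17_36: {"dimeric"},
    SpectralClass.C17_28: {"dimeric"},
    SpectralClass.C17_49: {"monomeric"},
    SpectralClass.C17_180: {"many_mutations"},
    SpectralClass.C17_154: {"many_mutations"},
    SpectralClass.no_pattern: {"not_G4"},
    SpectralClass.no_G4_signals: {"not_G4"},
}


class ConfigError(ValueError):
    """Invalid or unknown configuration key."""


@dataclass
class PrepConfig:
    window: tuple[float, float] = (10.0, 12.0)
    k: float = 5.0
    min_sep_ppm: float = 0.03


@dataclass
class ClusterConfig:
    metric: str = "euclidean"
    linkage: str = "average"
    k_policy: str = "n_classes"  # "n_classes", "silhouette" or an integer


@dataclass
class IonexConfig:
    k: float = 5.0
    merge_ml: float = 0.1


@dataclass
class ProfileConfig:
    n_perm: int = 500


@dataclass
class PipelineConfig:
    seed: int = 0
    ref_sequence: str = "GGGTGGGTTGGGTGGGA"
    tggt_to_17_36: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    ionex: IonexConfig = field(default_factory=IonexConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    out_dir: str = "g4screen_run"


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    nested = {
        "sim": SimConfig,
        "prep": PrepConfig,
        "clustering": ClusterConfig,
        "ionex": IonexConfig,
        "profile": ProfileConfig,
    }
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in data.items():
        if key in nested:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            sub_fields = {f.name for f in dataclasses.fields(nested[key])}
            bad = set(value) - sub_fields
            if bad:
                raise ConfigError(f"unknown key(s) {sorted(bad)} in section {key!r}")
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            kwargs[key] = nested[key](**value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on synthetic data and return the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {}}
    rng = np.random.default_rng(cfg.seed)

    def _record(stage: str, files: list[Path], **extra) -> None:
        manifest["stages"][stage] = {"status": "ok", **extra}
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)

    try:
        stage = "enumerate"
        ref = _library.ReferenceTopology(sequence=cfg.ref_sequence)
        library = _library.enumerate_library(ref, tggt_to_17_36=cfg.tggt_to_17_36)
        fasta = out / "library.fasta"
        annot = out / "library.tsv"
        _library.write_fasta(library, fasta)
        _library.library_table(library).to_csv(annot, sep="\t", index=False)
        _record(stage, [fasta, annot], n_sequences=len(library))

        stage = "simulate"
        spectra = []
        truths = []
        for rec in library:
            sp, truth = _simulate.simulate_spectrum(
                rec.class_label.major, cfg.sim, rng, seq_id=rec.seq_id
            )
            spectra.append(sp)
            truths.append(truth)
        activities = _simulate.simulate_activities(
            [rec.class_label.major for rec in library],
            cfg.sim,
            rng,
            seq_ids=[rec.seq_id for rec in library],
        )
        act_path = out / "activities.tsv"
        activities.to_csv(act_path, sep="\t", index=False)
        chroms = {}
        for cls in sorted({rec.class_label.major for rec in library},
                          key=lambda c: c.value):
            chrom, truth = _simulate.simulate_chromatogram(
                CLASS_MULTIMERIC_STATES[cls], cfg.sim, rng,
                seq_id=f"rep_{cls.value}",
            )
            chroms[cls] = (chrom, truth)
        _record(stage, [act_path], n_spectra=len(spectra))

        stage = "prep"
        prepped, kept_idx = [], []
        peak_rows = []
        for i, sp in enumerate(spectra):
            t = _spectra.trim_region(sp, *cfg.prep.window)
            if not _spectra.has_g4_signals(t, k=cfg.prep.k):
                continue
            t = _spectra.scale01(t)
            peaks = _spectra.pick_peaks(
                t, k=cfg.prep.k, min_sep_ppm=cfg.prep.min_sep_ppm
            )
            prepped.append(t)
            kept_idx.append(i)
            peak_rows.append(
                {
                    "seq_id": sp.seq_id,
                    "n_signals": peaks.n_signals,
                    "span_ppm": round(peaks.span_ppm, 4),
                    "positions_ppm": ",".join(f"{p:.3f}" for p in peaks.positions_ppm),
                }
            )
        peaks_path = out / "peaks.tsv"
        pd.DataFrame(peak_rows).to_csv(peaks_path, sep="\t", index=False)
        _record(stage, [peaks_path], n_kept=len(prepped),
                n_filtered=len(spectra) - len(prepped))

        stage = "cluster"
        truth_labels = [library[i].class_label.major.value for i in kept_idx]
        d = _cluster.spectra_distance_matrix(prepped, metric=cfg.clustering.metric)
        policy = cfg.clustering.k_policy
        if policy == "n_classes":
            k = len(set(truth_labels))
        elif policy == "silhouette":
            k = _cluster.choose_k_silhouette(d, linkage=cfg.clustering.linkage)
        else:
            k = int(policy)
        result = _cluster.hierarchical_cluster(d, linkage=cfg.clustering.linkage, k=k)
        agreement = _cluster.cluster_class_agreement(result.labels, truth_labels)
        clusters_path = out / "clusters.tsv"
        pd.DataFrame(
            {
                "seq_id": [library[i].seq_id for i in kept_idx],
                "cluster": result.labels,
                "rule_class": truth_labels,
            }
        ).to_csv(clusters_path, sep="\t", index=False)
        agree_path = out / "agreement.json"
        agree_path.write_text(json.dumps({"k": k, **agreement}, indent=2))
        _record(stage, [clusters_path, agree_path], **agreement)

        stage = "ionex"
        state_rows = []
        for cls, (chrom, truth) in chroms.items():
            inferred = _ionex.infer_multimeric_states(
                chrom, k=cfg.ionex.k, merge_ml=cfg.ionex.merge_ml
            )
            state_rows.append(
                {
                    "seq_id": chrom.seq_id,
                    "class": cls.value,
                    "simulated_states": "+".join(sorted(truth["states"])),
                    "inferred_states": "+".join(sorted(inferred)),
                    "match": inferred == truth["states"],
                }
            )
        states_path = out / "states.tsv"
        pd.DataFrame(state_rows).to_csv(states_path, sep="\t", index=False)
        _record(stage, [states_path],
                n_matched=int(sum(r["match"] for r in state_rows)))

        stage = "profile"
        profiles = _profiles.class_profiles(activities)
        prof_path = out / "profiles.tsv"
        _profiles.profiles_table(profiles).to_csv(prof_path, sep="\t", index=False)
        radar_path = out / "radar.json"
        _profiles.write_radar_json(profiles, radar_path)
        null_report = {}
        null_rng = np.random.default_rng(cfg.seed + 1)
        for cls in (SpectralClass.C17_3, SpectralClass.C17_63):
            res = _profiles.rsd_random_null(
                activities, cls.value, "Flu",
                n_perm=cfg.profile.n_perm, seed=null_rng,
            )
            null_report[cls.value] = {
                "observed_rsd": res["observed_rsd"],
                "p": res["p"],
                "class_size": res["class_size"],
            }
        null_path = out / "rsd_null.json"
        null_path.write_text(json.dumps(null_report, indent=2))
        _record(stage, [prof_path, radar_path, null_path])

    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
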