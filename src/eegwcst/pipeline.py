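"""End-to-end orchestration: cohort -> preprocessing -> features -> stats.

A run is driven by one :class:`RunConfig` (constructed in code or loaded
from YAML) and produces a bundle of artifacts in the output directory:

* ``features_wide.csv`` - one row per subject (FeatureTable);
* ``features_tidy.csv`` - one row per subject x feature;
* ``stats.csv`` - the statistical design results;
* ``clusters.csv`` / ``performance.csv`` - performance levels and scores;
* ``rejection_report.csv`` - per-subject epoch rejection counts;
* ``band_schemes.json`` - per-subject alpha peaks and band limits;
* ``manifest.json`` - config, seed, software version and counts.

Per-subject failures (e.g. too few accepted epochs) are logged, recorded
in the manifest and skipped; they are fatal only when no subject survives.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import preprocess_recording
from .recording import (
    ANALYSIS_CHANNELS,
    POOL_COUPLINGS,
    POOLS,
    read_recording,
    write_brainvision,
)
from .spectral import (
    apf_asymmetry,
    band_power,
    band_scheme_for,
    baseline_correct,
    estimate_spectra,
    pool_coherence,
)
from .stats import run_design
from .synthdata import CohortConfig, iter_cohort
from .wcst import TrialLog, score_cohort

logger = logging.getLogger("eegwcst")

__all__ = ["RunConfig", "RunResult", "run_all", "simulate_to_files",
           "compute_subject_features"]


@dataclasses.dataclass
class RunConfig:
    mode: str = "synthetic"  # synthetic | files
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    input_dir: str | None = None  # files mode
    out_dir: str | None = None
    seed: int | None = None
    ocular_correction: bool = True
    epoch_length: float = 5.0
    amplitude_threshold: float = 500.0
    ptp_threshold: float = 800.0
    baseline_mode: str = "subtract"
    pooling_weights: tuple = (1.0, -1.0, -1.0)
    kmeans_n_init: int = 25
    run_stats: bool = True
    subgroup_stats: bool = True

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires an explicit seed")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("files mode requires input_dir")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("cohort", {}) or {}).items()
        })
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pooling_weights" in raw:
            raw["pooling_weights"] = tuple(raw["pooling_weights"])
        return cls(cohort=cohort, **raw)


@dataclasses.dataclass
class RunResult:
    features: pd.DataFrame  # wide FeatureTable incl. metadata
    stats: pd.DataFrame
    cluster_summary: pd.DataFrame
    rejections: pd.DataFrame
    band_schemes: dict
    manifest: dict


def compute_subject_features(
    task_eps, baseline_eps, baseline_mode: str = "subtract"
) -> tuple:
    """Spectral features for one subject from accepted task/baseline epochs.

    The alpha peak is detected on the task span and anchors the band
    limits for both spans.  Coupling bands use the mean of the two pools'
    alpha peaks.  Returns ``(features dict, band-scheme dict)``.
    """
    channels = [c for c in ANALYSIS_CHANNELS if c in task_eps.channels]
    spec_task = estimate_spectra(task_eps, channels)
    spec_base = estimate_spectra(baseline_eps, channels)
    scheme = band_scheme_for(spec_task)

    feats = {}
    for pool in POOLS:
        for band in ("theta", "alpha"):
            lims = scheme.band(pool, band)
            task_val = band_power(spec_task, POOLS[pool], lims)
            base_val = band_power(spec_base, POOLS[pool], lims)
            feats[f"power_{pool}_{band}_task"] = task_val
            feats[f"power_{pool}_{band}_baseline"] = base_val
            feats[f"power_{pool}_{band}_bc"] = baseline_correct(
                task_val, base_val, baseline_mode
            )
        feats[f"apf_{pool}"] = scheme.apf[pool].frequency

    for a, b in POOL_COUPLINGS:
        for band in ("theta", "alpha"):
            la, lb = scheme.band(a, band), scheme.band(b, band)
            lims = ((la[0] + lb[0]) / 2, (la[1] + lb[1]) / 2)
            task_val = pool_coherence(spec_task, POOLS[a], POOLS[b], lims)
            base_val = pool_coherence(spec_base, POOLS[a], POOLS[b], lims)
            feats[f"coh_{a}_{b}_{band}_task"] = task_val
            feats[f"coh_{a}_{b}_{band}_baseline"] = base_val
            feats[f"coh_{a}_{b}_{band}_bc"] = task_val - base_val

    feats["apf_asym_frontal"] = apf_asymmetry(
        scheme.apf["FL"], scheme.apf["FR"]
    ).frequency
    feats["apf_asym_parietal"] = apf_asymmetry(
        scheme.apf["PL"], scheme.apf["PR"]
    ).frequency

    scheme_info = {
        pool: {
            "apf": scheme.apf[pool].frequency,
            "low_confidence": scheme.apf[pool].low_confidence,
            "alpha": list(scheme.alpha[pool]),
            "theta": list(scheme.theta[pool]),
        }
        for pool in scheme.apf
    }
    scheme_info["n_epochs"] = {
        "task": spec_task.n_epochs_used,
        "baseline": spec_base.n_epochs_used,
    }
    return feats, scheme_info


def _iter_file_subjects(config: RunConfig):
    """Yield (subject_id, meta row, task Recording, baseline Recording,
    TrialLog) from an input directory."""
    root = Path(config.input_dir)
    meta_path = root / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing {meta_path}")
    meta = pd.read_csv(meta_path)
    for row in meta.itertuples():
        sid = str(row.subject_id)
        task = None
        for suffix in (".vhdr", ".edf"):
            cand = root / f"{sid}_task{suffix}"
            if cand.exists():
                task = cand
                break
        if task is None:
            raise FileNotFoundError(f"no task recording for {sid} in {root}")
        base = task.with_name(task.name.replace("_task", "_baseline"))
        if not base.exists():
            raise FileNotFoundError(f"missing {base}")
        log = TrialLog.from_csv(root / f"{sid}_trials.csv", subject_id=sid)
        yield sid, row, read_recording(task), read_recording(base), log


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline and (optionally) write the artifact bundle."""
    config.validate()
    seed = int(config.seed if config.seed is not None else 0)

    if config.mode == "synthetic":
        cohort_cfg = dataclasses.replace(config.cohort, seed=seed)
        subjects = (
            (s.truth.subject_id, s.truth, s.recording_task,
             s.recording_baseline, s.trial_log)
            for s in iter_cohort(cohort_cfg)
        )
    else:
        subjects = _iter_file_subjects(config)

    rows, logs, schemes, reject_rows, skipped = [], [], {}, [], []
    for i, (sid, meta, rec_task, rec_base, log) in enumerate(subjects):
        try:
            task_eps, _ = preprocess_recording(
                rec_task,
                seed=seed + 1000 + i,
                epoch_length=config.epoch_length,
                ocular=config.ocular_correction,
                amplitude_threshold=config.amplitude_threshold,
                ptp_threshold=config.ptp_threshold,
            )
            base_eps, _ = preprocess_recording(
                rec_base,
                seed=seed + 2000 + i,
                epoch_length=config.epoch_length,
                ocular=config.ocular_correction,
                amplitude_threshold=config.amplitude_threshold,
                ptp_threshold=config.ptp_threshold,
            )
            feats, scheme_info = compute_subject_features(
                task_eps, base_eps, config.baseline_mode
            )
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            logger.warning("subject %s skipped: %s", sid, exc)
            skipped.append({"subject_id": sid, "reason": str(exc)})
            continue
        age = float(meta.age)
        age_group = str(getattr(meta, "age_group"))
        sex = str(getattr(meta, "sex", ""))
        rows.append({"subject_id": sid, "age": age, "age_group": age_group,
                     "sex": sex, **feats})
        logs.append(log)
        schemes[sid] = scheme_info
        rejected = [
            (e, r)
            for e, r in enumerate(task_eps.rejection_reason)
            if r != "none"
        ]
        reject_rows.append(
            {
                "subject_id": sid,
                "n_epochs_task": task_eps.n_epochs,
                "n_rejected_task": len(rejected),
                "rejected_epochs": ";".join(str(e) for e, _ in rejected),
                "rejected_reasons": ";".join(r for _, r in rejected),
                "n_epochs_baseline": base_eps.n_epochs,
                "n_rejected_baseline": int((~base_eps.accepted).sum()),
            }
        )
        logger.info(
            "subject %s: %d/%d task epochs kept",
            sid, task_eps.n_accepted, task_eps.n_epochs,
        )

    if not rows:
        raise RuntimeError("no subject completed the pipeline")

    features = pd.DataFrame(rows)
    measures, clusters = score_cohort(
        logs,
        weights=config.pooling_weights,
        cluster_seed=seed,
        n_init=config.kmeans_n_init,
    )
    perf = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "completed_categories": m.completed_categories,
                "perseverative_errors": m.perseverative_errors,
                "nonperseverative_errors": m.nonperseverative_errors,
                "z_score": m.z_score,
            }
            for m in measures
        ]
    )
    features = features.merge(perf, on="subject_id")
    features["performance_cluster"] = (
        features["subject_id"].map(clusters.labels).astype(str)
    )

    if config.run_stats:
        stat_cols = [
            c for c in features.columns
            if c.startswith(("power_", "coh_", "apf_"))
        ]
        stats = run_design(
            features, feature_columns=stat_cols,
            subgroups=config.subgroup_stats,
        )
    else:
        stats = pd.DataFrame()

    manifest = {
        "version": __version__,
        "seed": seed,
        "mode": config.mode,
        "config": _jsonable(dataclasses.asdict(config)),
        "n_subjects_completed": len(rows),
        "n_subjects_skipped": len(skipped),
        "skipped": skipped,
    }
    result = RunResult(
        features=features,
        stats=stats,
        cluster_summary=clusters.summary,
        rejections=pd.DataFrame(reject_rows),
        band_schemes=schemes,
        manifest=manifest,
    )
    if config.out_dir:
        _write_bundle(result, Path(config.out_dir))
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_bundle(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features_wide.csv", index=False)
    tidy = result.features.melt(
        id_vars=[c for c in ("subject_id", "age", "age_group", "sex",
                             "z_score", "performance_cluster")
                 if c in result.features.columns],
        var_name="feature",
        value_name="value",
    )
    tidy.to_csv(out / "features_tidy.csv", index=False)
    result.stats.to_csv(out / "stats.csv", index=False)
    result.cluster_summary.to_csv(out / "clusters.csv", index=False)
    with open(out / "clusters.json", "w") as fh:
        json.dump(result.cluster_summary.to_dict(orient="records"), fh,
                  indent=1)
    perf_cols = [
        c for c in ("subject_id", "completed_categories",
                    "perseverative_errors", "nonperseverative_errors",
                    "z_score", "performance_cluster")
        if c in result.features.columns
    ]
    result.features[perf_cols].to_csv(out / "performance.csv", index=False)
    result.rejections.to_csv(out / "rejection_report.csv", index=False)
    with open(out / "band_schemes.json", "w") as fh:
        json.dump(result.band_schemes, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1)


def simulate_to_files(cohort_cfg: CohortConfig, out_dir) -> Path:
    """Materialize a synthetic cohort on disk (BrainVision + CSV + JSON),
    in the layout the files mode reads back."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for subject in iter_cohort(cohort_cfg):
        sid = subject.truth.subject_id
        write_brainvision(subject.recording_task, out / f"{sid}_task")
        write_brainvision(subject.recording_baseline, out / f"{sid}_baseline")
        subject.trial_log.to_csv(out / f"{sid}_trials.csv")
        subject.truth.to_json(out / f"{sid}_truth.json")
        meta_rows.append(
            {
                "subject_id": sid,
                "age": subject.truth.age,
                "age_group": subject.truth.age_group,
                "sex": subject.truth.sex,
            }
        )
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
    return out
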