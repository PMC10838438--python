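"""End-to-end orchestration: audio -> QC -> features -> classification.

A single master seed fans out to per-stage seeds through a stable hash so
that runs are reproducible end to end while stages stay independently
seeded. All signal-processing and QC defaults equal the reference
protocol's printed values (0.025 s noise-reduction window, 80 Hz - 10 kHz
suppression band, 40 Hz smoothing, >= 0.25 s noise sample, SNR > 30 dB,
clipping < 1%), so an empty override section reproduces that protocol.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audio import read_wav
from .features import extract_features
from .interactions import compare_interaction_models
from .manifest import METADATA_COLUMNS, load_manifest
from .model import (
    ComparisonResult,
    ModelConfig,
    run_binary_comparison,
    stratify_cohort,
)
from .preprocess import (
    CLIP_THRESHOLD_FRACTION,
    SNR_THRESHOLD_DB,
    compute_snr,
    estimate_noise_profile,
    qc_gate,
    spectral_subtract,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "export_report"]


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Run configuration; defaults reproduce the reference protocol."""

    input_mode: str = "features"        # "features" | "audio"
    feature_csv: str | None = None
    audio_dir: str | None = None
    metadata_csv: str | None = None
    snr_threshold_db: float = SNR_THRESHOLD_DB
    clip_threshold: float = CLIP_THRESHOLD_FRACTION
    manifest_path: str | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    n_reps: int = 10
    run_interactions: bool = True
    seed: int = 0
    output_dir: str = "bulbarvoice_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model = ModelConfig(**raw.pop("model", {}))
        return cls(model=model, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one pipeline run produced, ready for export."""

    qc_reports: list
    kept_subjects: list[str]
    discarded_subjects: dict[str, list[str]]   # subject -> reasons
    feature_table: pd.DataFrame
    comparisons: dict[str, ComparisonResult]
    interaction: dict | None
    warnings: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "qc": {
                "kept": len(self.kept_subjects),
                "discarded": self.discarded_subjects,
            },
            "comparisons": {k: v.to_dict() for k, v in self.comparisons.items()},
            "interaction": self.interaction,
            "warnings": self.warnings,
        }


def _load_audio_cohort(cfg: PipelineConfig) -> tuple[pd.DataFrame, list, dict]:
    meta = pd.read_csv(cfg.metadata_csv)
    if "frs_bulb" not in meta.columns:
        meta["frs_bulb"] = np.nan
    manifest = load_manifest(cfg.manifest_path)
    qc_reports, rows, discarded = [], [], {}
    for _, m in meta.iterrows():
        wav = Path(cfg.audio_dir) / f"{m['subject_id']}.wav"
        rec = read_wav(wav, subject_id=str(m["subject_id"]))
        snr_pre = compute_snr(rec)
        profile = estimate_noise_profile(rec)
        denoised = spectral_subtract(rec, profile)
        report = qc_gate(denoised, cfg.snr_threshold_db, cfg.clip_threshold)
        qc_reports.append((report, snr_pre))
        if not report.passed:
            discarded[report.subject_id] = list(report.reasons)
            continue
        fv = extract_features(denoised, manifest)
        rows.append({**{c: m.get(c, np.nan) for c in METADATA_COLUMNS}, **fv.values})
    table = pd.DataFrame(rows)
    return table, qc_reports, discarded


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute QC, feature extraction, the three binary contrasts and the
    sex-interaction check, as the input mode allows."""
    manifest = load_manifest(cfg.manifest_path)
    warnings_list: list[str] = []
    if cfg.input_mode == "audio":
        if not cfg.audio_dir or not cfg.metadata_csv:
            raise ValueError("audio mode needs audio_dir and metadata_csv")
        table, qc_reports, discarded = _load_audio_cohort(cfg)
        if table.empty:
            raise RuntimeError(
                "no recording passed QC: "
                + "; ".join(f"{k}: {v}" for k, v in discarded.items())
            )
    elif cfg.input_mode == "features":
        if not cfg.feature_csv:
            raise ValueError("features mode needs feature_csv")
        table = pd.read_csv(cfg.feature_csv, float_precision="round_trip")
        qc_reports, discarded = [], {}
    else:
        raise ValueError(f"unknown input_mode {cfg.input_mode!r}")

    missing_cols = set(manifest.names) - set(table.columns)
    if missing_cols:
        raise ValueError(f"feature table lacks manifest columns: {sorted(missing_cols)}")

    strata = stratify_cohort(table)
    contrasts = ["control_vs_als"]
    if (strata == "ALS-E").sum() >= 2 and (strata == "ALS-L").sum() >= 2:
        contrasts += ["control_vs_alse", "alse_vs_alsl"]
    else:
        warnings_list.append(
            "severity strata unavailable or too small; running control-vs-ALS only"
        )

    comparisons = {}
    for name in contrasts:
        comparisons[name] = run_binary_comparison(
            table, name, cfg.model, manifest,
            n_reps=cfg.n_reps, seed=_stage_seed(cfg.seed, f"split:{name}"),
        )

    interaction = None
    if cfg.run_interactions and "sex" in table.columns:
        interaction = compare_interaction_models(
            table, cfg.model, contrast="control_vs_als", manifest=manifest,
            n_reps=cfg.n_reps, seed=_stage_seed(cfg.seed, "interaction"),
        )

    return RunReport(
        qc_reports=qc_reports,
        kept_subjects=list(table.get("subject_id", pd.Series(dtype=str))),
        discarded_subjects=discarded,
        feature_table=table,
        comparisons=comparisons,
        interaction=interaction,
        warnings=warnings_list,
        provenance={
            "package_version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "manifest_version": manifest.version,
        },
    )


def export_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Write features.csv, qc.jsonl, per-fold ROC points, coefficients.csv
    (features x contrasts) and report.json. Fails before any partial write
    if the directory cannot be created."""
    from sklearn.metrics import roc_curve

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    manifest = load_manifest()
    cols = [c for c in list(METADATA_COLUMNS) + list(manifest.names)
            if c in report.feature_table.columns]
    p = out / "features.csv"
    report.feature_table[cols].to_csv(p, index=False)
    written.append(p)

    p = out / "qc.jsonl"
    with open(p, "w") as fh:
        for rep, snr_pre in report.qc_reports:
            row = json.loads(rep.to_json())
            row["snr_db_pre_reduction"] = (
                None if np.isnan(snr_pre) else round(float(snr_pre), 3)
            )
            fh.write(json.dumps(row) + "\n")
    written.append(p)

    coef = pd.DataFrame(
        {name: res.median_coefficients for name, res in report.comparisons.items()}
    )
    p = out / "coefficients.csv"
    coef.to_csv(p, index_label="feature")
    written.append(p)

    for name, res in report.comparisons.items():
        for rec in res.fold_records:
            if "scores" not in rec:
                continue
            fpr, tpr, _ = roc_curve(rec["labels"], rec["scores"])
            p = out / f"roc_points_{name}_{rec['rep']}.csv"
            pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(p, index=False)
            written.append(p)

    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    written.append(p)
    return written
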