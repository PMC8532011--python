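"""Study orchestration: generate -> label -> constrain -> report.

Every run emits a manifest (config hash, input checksums, output list,
warnings) so that identical inputs provably produce identical outputs. A
failing stage removes the files it already wrote and re-raises with the
stage name, leaving no partial bundle behind.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_constraint import (
    ConstraintParams,
    DISEASES,
    FollowUpWindow,
    patient_min_distances_km,
    per_hospital_report,
    select_subcohort,
    subgroup_report,
    sweep,
)
from .config import StudyConfig, sha256_file
from .ehr_model import EHRDataset, filter_cohort, load_dataset, write_dataset
from .errors import CarefragError
from .icd_codes import default_vocabulary
from .phenotypes import label_all
from .reference import verify_arithmetic
from .synthetic_ehr import generate

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    input_checksums: dict = field(default_factory=dict)
    output_files: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def write_labels(labels: pd.DataFrame, labels_path, evidence_path=None) -> None:
    out = labels.drop(columns=["evidence"]).copy()
    for col in ("asthma", "ckd", "copd", "diabetes", "t1d", "t2d"):
        out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(labels_path, index=False)
    if evidence_path is not None:
        with open(evidence_path, "w", encoding="utf-8") as fh:
            for row in labels.itertuples():
                fh.write(json.dumps({"patient_id": row.patient_id,
                                     "evidence": row.evidence}) + "\n")


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("asthma", "ckd", "copd", "diabetes", "t1d", "t2d"):
        df[col] = df[col].map({"true": True, "false": False, True: True, False: False})
    df["evidence"] = [[] for _ in range(len(df))]
    return df


def compute_labels(ds: EHRDataset, cfg: StudyConfig) -> pd.DataFrame:
    vocab = default_vocabulary()
    span = (pd.Timestamp(cfg.klompas_span[0]), pd.Timestamp(cfg.klompas_span[1]))
    return label_all(
        ds, cohort_year=cfg.cohort_year, index_date=cfg.index_timestamp, vocab=vocab,
        ckd_window=cfg.ckd_window, ckd_mixed_pairs=cfg.ckd_mixed_pairs,
        klompas_span=span, klompas_distinct_days=cfg.klompas_distinct_days,
    )


def study_windows(cfg: StudyConfig) -> list[FollowUpWindow]:
    return [FollowUpWindow.from_index_date(cfg.index_timestamp, m)
            for m in cfg.window_months]


def _fmt_percent_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if str(col).endswith("_pct") or "_pct_" in str(col):
            out[col] = out[col].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.2f}")
    return out


def sweep_all_subgroups(ds: EHRDataset, registry: pd.DataFrame, labels: pd.DataFrame,
                        cohort_ids, cfg: StudyConfig,
                        distances: pd.Series | None = None) -> pd.DataFrame:
    windows = study_windows(cfg)
    if distances is None:
        pats = ds.patients[ds.patients["patient_id"].isin(set(cohort_ids))]
        distances = patient_min_distances_km(pats, ds.facilities)
    frames = []
    groups = [("all", sorted(cohort_ids))]
    groups += [(d, list(labels.loc[labels[d], "patient_id"])) for d in DISEASES]
    for name, ids in groups:
        df = sweep(cfg.d_grid, ids, ds, registry, windows, distances=distances)
        df.insert(0, "subgroup", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plot_sweeps(sweep_df: pd.DataFrame, out_dir, windows) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    paths = []
    views = [("full", None), ("fine", 10.0)]
    for view, dmax in views:
        for which in ("fulfilling", "in_system"):
            fig, ax = plt.subplots(figsize=(7, 4.5))
            for sg, grp in sweep_df.groupby("subgroup"):
                g = grp if dmax is None else grp[grp["d_km"] <= dmax]
                if which == "fulfilling":
                    ax.plot(g["d_km"], pd.to_numeric(g["fulfilling_pct"],
                                                     errors="coerce"), label=sg)
                else:
                    for w in windows:
                        ax.plot(g["d_km"],
                                pd.to_numeric(g[f"in_system_pct_{w.label}"],
                                              errors="coerce"),
                                label=f"{sg} ({w.label})")
            ax.set_xlabel("d (km)")
            ax.set_ylabel("fulfilling %" if which == "fulfilling" else "in-system %")
            ax.legend(fontsize=7)
            fig.tight_layout()
            path = out_dir / f"{which}_vs_d_{view}.svg"
            fig.savefig(path)
            plt.close(fig)
            paths.append(path)
    return paths


def run_study(cfg: StudyConfig, data_dir=None, out_dir="outputs",
              generate_data: bool = False) -> RunManifest:
    """Run the full pipeline; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.config_hash(), version=__version__)
    written: list[Path] = []
    stage = "setup"
    try:
        if generate_data:
            stage = "generate"
            gen_cfg = cfg.generator.model_copy(update={"seed": cfg.seed})
            ds = generate(gen_cfg).dataset
            data_dir = out / "data"
            written += write_dataset(ds, data_dir)
        else:
            stage = "load"
            if data_dir is None:
                raise CarefragError("data_dir required unless generating")
            ds = load_dataset(data_dir)
        manifest.input_checksums = {
            p.name: sha256_file(p) for p in sorted(Path(data_dir).glob("*.csv"))
        }
        registry = ds.registry
        manifest.stage_counts["patients"] = int(len(ds.patients))
        manifest.stage_counts["registry_visits"] = int(len(registry))

        stage = "label"
        cohort = filter_cohort(ds, cfg.cohort_year, cfg.index_timestamp)
        manifest.stage_counts["cohort"] = len(cohort)
        labels = compute_labels(ds, cfg)
        labels_path = out / "labels.csv"
        write_labels(labels, labels_path, out / "evidence.jsonl")
        written += [labels_path, out / "evidence.jsonl"]
        logger.info("label: %d cohort patients", len(labels))

        stage = "select"
        pats = ds.patients[ds.patients["patient_id"].isin(cohort)]
        distances = patient_min_distances_km(pats, ds.facilities)
        params = ConstraintParams(d_km=cfg.d_km, pcp_as_of_date=cfg.index_timestamp)
        sel = select_subcohort(sorted(cohort), ds, params, distances=distances)
        manifest.warnings += sel.warnings
        pd.DataFrame({"patient_id": sorted(sel.selected)}).to_csv(
            out / "subcohort.csv", index=False)
        written.append(out / "subcohort.csv")
        manifest.stage_counts["fulfilling"] = sel.fraction.numerator

        stage = "report"
        windows = study_windows(cfg)
        report = subgroup_report(ds, registry, labels, params, windows,
                                 distances=distances)
        _fmt_percent_columns(report).to_csv(out / "report_table2.csv", index=False)
        written.append(out / "report_table2.csv")
        pct_cols = [c for c in report.columns if "pct" in str(c)]
        for _, r in report.iterrows():
            for c in pct_cols:
                if pd.isna(r[c]):
                    manifest.warnings.append(
                        f"subgroup {r['subgroup']}: undefined percentage in {c}"
                    )

        ph_frames = []
        for disease in DISEASES:
            members = list(labels.loc[labels[disease], "patient_id"])
            sub = select_subcohort(members, ds, params, distances=distances).selected
            ph = per_hospital_report(registry, sub, windows, ds.facilities)
            ph.insert(0, "subgroup", disease)
            ph_frames.append(ph)
        per_hosp = pd.concat(ph_frames, ignore_index=True)
        _fmt_percent_columns(per_hosp).to_csv(out / "per_hospital.csv", index=False)
        written.append(out / "per_hospital.csv")

        stage = "sweep"
        sweep_df = sweep_all_subgroups(ds, registry, labels, cohort, cfg,
                                       distances=distances)
        _fmt_percent_columns(sweep_df).to_csv(out / "sweep_curves.csv", index=False)
        written.append(out / "sweep_curves.csv")

        if cfg.plots:
            stage = "plots"
            written += plot_sweeps(sweep_df, out, windows)

        stage = "manifest"
        manifest.output_files = [
            {"path": str(p.relative_to(out)) if p.is_relative_to(out) else str(p),
             "sha256": sha256_file(p)}
            for p in written
        ]
        (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
        return manifest
    except Exception:
        logger.error("stage %r failed; removing partial outputs", stage)
        for p in written:
            try:
                Path(p).unlink(missing_ok=True)
            except OSError:
                pass
        raise


def verify_paper_arithmetic() -> pd.DataFrame:
    """Per-cell pass/fail of the published ratio arithmetic."""
    return verify_arithmetic()
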