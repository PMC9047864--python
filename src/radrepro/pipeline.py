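"""End-to-end orchestration: simulate -> extract -> screen -> compare -> PCA.

``analyze_cohort`` does the science on an in-memory cohort and returns a
:class:`PipelineResults`; ``run_pipeline`` wraps it with file I/O (volumes,
CSV reports, YAML config snapshot, JSON manifest) for a reproducible on-disk
run. Every stage is deterministic given the design's master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import GroupComparisonResult, PcaResult, compare_tissues, pca_reduce
from .cohort import MODALITY_PREFIX, CohortBundle, generate_cohort
from .config import PipelineConfig, save_config, to_dict
from .features import ALL_FEATURE_NAMES, extract_all
from .geometry import RoiMask
from .io import write_image, write_mask
from .reliability import (
    FeatureTable,
    ReproResults,
    arm_qcd,
    format_count,
    pairwise_icc,
    select_robust,
)

__all__ = ["PipelineResults", "RunManifest", "analyze_cohort", "run_pipeline", "report_counts"]

log = logging.getLogger("radrepro")

META_COLUMNS = ("subject", "tissue", "modality", "observer", "session", "arm_label")


def extract_feature_table(bundle: CohortBundle, bin_width: float = 25.0,
                          gldm_alpha: int = 0) -> pd.DataFrame:
    """107-feature row per delineation record (metadata + feature columns)."""
    rows = []
    t0 = time.perf_counter()
    for rec in bundle.records:
        vec = extract_all(
            bundle.images[rec.subject], rec.mask, bin_width=bin_width, gldm_alpha=gldm_alpha
        )
        row = {
            "subject": rec.subject,
            "tissue": rec.tissue,
            "modality": rec.modality,
            "observer": rec.observer,
            "session": rec.session,
            "arm_label": rec.arm_label,
        }
        row.update(vec.values)
        rows.append(row)
    log.info("extracted %d feature vectors in %.1f s", len(rows), time.perf_counter() - t0)
    return pd.DataFrame(rows)


def _arm_tables(df: pd.DataFrame, tissue: str, modality: str) -> list[FeatureTable]:
    sub = df[(df.tissue == tissue) & (df.modality == modality)]
    tables = []
    for arm in sorted(sub.arm_label.unique(), key=lambda s: int(s[-1])):
        block = sub[sub.arm_label == arm].set_index("subject").sort_index()
        tables.append(FeatureTable(arm=arm, tissue=tissue, data=block[list(ALL_FEATURE_NAMES)]))
    return tables


@dataclass
class PipelineResults:
    """All analysis products of one simulated study."""

    feature_df: pd.DataFrame
    repro: ReproResults  # both tissues, all modality comparisons
    robust_features: list[str]
    comparisons: list[GroupComparisonResult]
    pca: dict[str, PcaResult | None]  # per tissue
    config: PipelineConfig

    def counts_frame(self) -> pd.DataFrame:
        """Per-tissue, per-comparison ICC-excellent counts in long format."""
        rows = []
        for tissue in self.repro.icc_records:
            total = self.repro.n_features(tissue)
            counts = self.repro.counts(tissue)
            for comp, cnt in counts["icc"].items():
                rows.append(
                    {
                        "tissue": tissue,
                        "kind": "icc",
                        "label": comp,
                        "count": cnt,
                        "total": total,
                        "rendered": format_count(cnt, total),
                    }
                )
            for arm, cnt in counts["qcd"].items():
                rows.append(
                    {
                        "tissue": tissue,
                        "kind": "qcd",
                        "label": arm,
                        "count": cnt,
                        "total": total,
                        "rendered": format_count(cnt, total),
                    }
                )
        return pd.DataFrame(rows)


def analyze_cohort(bundle: CohortBundle, config: PipelineConfig,
                   feature_df: pd.DataFrame | None = None) -> PipelineResults:
    """Run feature extraction and the full statistical analysis on a cohort."""
    ana = config.analysis
    if feature_df is None:
        feature_df = extract_feature_table(
            bundle, bin_width=config.extraction.bin_width, gldm_alpha=config.extraction.gldm_alpha
        )
    tissues = list(bundle.design.tissues)
    modalities = list(bundle.design.modalities)

    icc_records = {}
    qcd_tables = {}
    for tissue in tissues:
        recs = []
        qcds = []
        for modality in modalities:
            tables = _arm_tables(feature_df, tissue, modality)
            if len(tables) >= 2:
                recs.extend(pairwise_icc(tables))
            for table in tables:
                qcds.append(arm_qcd(table, inclusive_small=ana.inclusive_small_qcd))
        icc_records[tissue] = recs
        qcd_tables[tissue] = (
            pd.concat(qcds, ignore_index=True) if qcds else pd.DataFrame()
        )
    repro = ReproResults(
        icc_records=icc_records,
        qcd_tables=qcd_tables,
        icc_threshold=ana.icc_threshold,
        qcd_threshold=ana.qcd_threshold,
    )

    # robust selection on the configured modality group, both tissues
    prefix = MODALITY_PREFIX.get(ana.robust_modality, ana.robust_modality)
    robust: list[str] = []
    comparisons: list[GroupComparisonResult] = []
    pca_out: dict[str, PcaResult | None] = {}
    if {"tumor", "peritumor"} <= set(tissues):
        def _mod_icc(tissue):
            return [r for r in icc_records[tissue] if r.comparison.startswith(prefix)]

        def _mod_qcd(tissue):
            tab = qcd_tables[tissue]
            return tab[tab.arm.str.startswith(prefix)]

        robust = select_robust(
            _mod_icc("tumor"),
            _mod_icc("peritumor"),
            _mod_qcd("tumor"),
            _mod_qcd("peritumor"),
            icc_threshold=ana.icc_threshold,
            qcd_threshold=ana.qcd_threshold,
            semantics=ana.robust_semantics,
        )

        arm_df = feature_df[feature_df.arm_label == ana.comparison_arm]
        tumor_df = arm_df[arm_df.tissue == "tumor"].sort_values("subject")
        peri_df = arm_df[arm_df.tissue == "peritumor"].sort_values("subject")
        if len(tumor_df) >= 3 and len(peri_df) >= 3:
            for feat in robust:
                comparisons.append(
                    compare_tissues(tumor_df[feat], peri_df[feat], feature=feat)
                )
        elif robust:
            log.warning("fewer than 3 subjects; skipping tissue comparison")

    # PCA per tissue on the features reproducible across the chosen group
    for tissue in tissues:
        per_feature: dict[str, list[bool]] = {}
        for r in icc_records[tissue]:
            if r.comparison.startswith(prefix):
                per_feature.setdefault(r.feature, []).append(
                    r.icc is not None and r.icc >= ana.icc_threshold
                )
        keep = [f for f in ALL_FEATURE_NAMES if all(per_feature.get(f, [False]))]
        sub = feature_df[(feature_df.tissue == tissue) & (feature_df.arm_label == ana.pca_arm)]
        if len(keep) >= 1 and len(sub) >= 2:
            mat = sub.sort_values("subject")[keep].to_numpy()
            pca_out[tissue] = pca_reduce(mat, keep, fraction=ana.pca_fraction)
        else:
            pca_out[tissue] = None

    return PipelineResults(
        feature_df=feature_df,
        repro=repro,
        robust_features=robust,
        comparisons=comparisons,
        pca=pca_out,
        config=config,
    )


def report_counts(results: PipelineResults, decimals: int = 1) -> str:
    """Human-readable reliability report with intra/inter group means."""
    lines = [results.repro.summary(), ""]
    for tissue in results.repro.icc_records:
        counts = results.repro.counts(tissue)["icc"]
        total = results.repro.n_features(tissue)
        by_prefix: dict[str, dict[str, list[int]]] = {}
        for comp, cnt in counts.items():
            a, b = comp.split("/")
            pfx = a.rstrip("0123456789")
            pair = tuple(sorted((int(a[-1]), int(b[-1]))))
            kind = "intra" if pair in ((1, 2), (3, 4)) else "inter"
            by_prefix.setdefault(pfx, {"intra": [], "inter": []})[kind].append(cnt)
        for pfx, groups in by_prefix.items():
            for kind in ("intra", "inter"):
                if groups[kind]:
                    mean = float(np.mean(groups[kind]))
                    pct = 100.0 * mean / total if total else 0.0
                    lines.append(
                        f"{tissue} {pfx} {kind}-observer mean: "
                        f"{mean:.{decimals}f}/{total} ({pct:.{decimals}f}%)"
                    )
    lines.append("")
    lines.append(f"robust features ({len(results.robust_features)}): "
                 + ", ".join(results.robust_features))
    return "\n".join(lines)


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config, outputs, hashes, timing."""

    config: dict
    version: str
    started: float
    finished: float
    file_hashes: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "started": self.started,
                "finished": self.finished,
                "file_hashes": self.file_hashes,
                "summary": self.summary,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write all artifacts to the output dir."""
    started = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    stage = "simulate"
    try:
        log.info("stage %s: generating cohort (%d records)", stage, config.design.n_records)
        bundle = generate_cohort(config.design, config.phantom, config.profiles)
        manifest_rows = []
        if config.write_volumes:
            vol_dir = out / "volumes"
            for subj, image in bundle.images.items():
                written.append(write_image(vol_dir / f"subject{subj:03d}_image.nrrd", image))
                written.append(
                    write_mask(vol_dir / f"subject{subj:03d}_truth.nrrd", bundle.true_masks[subj])
                )
            for i, rec in enumerate(bundle.records):
                p = vol_dir / (
                    f"subject{rec.subject:03d}_{rec.arm_label}_{rec.tissue}.nrrd"
                )
                written.append(write_mask(p, rec.mask))
                manifest_rows.append(
                    {
                        "subject": rec.subject,
                        "tissue": rec.tissue,
                        "modality": rec.modality,
                        "observer": rec.observer,
                        "session": rec.session,
                        "arm_label": rec.arm_label,
                        "path": str(p.relative_to(out)),
                    }
                )
            cohort_csv = out / "cohort_manifest.csv"
            pd.DataFrame(manifest_rows).to_csv(cohort_csv, index=False)
            written.append(cohort_csv)

        stage = "extract"
        log.info("stage %s: 107 features per record", stage)
        results = analyze_cohort(bundle, config)
        feat_csv = out / "features.csv"
        results.feature_df.to_csv(feat_csv, index=False)
        written.append(feat_csv)

        stage = "reproducibility"
        for tissue in results.repro.icc_records:
            p = out / f"icc_{tissue}.csv"
            results.repro.icc_frame(tissue).to_csv(p, index=False)
            written.append(p)
            p = out / f"qcd_{tissue}.csv"
            results.repro.qcd_tables[tissue].to_csv(p, index=False)
            written.append(p)
        counts_csv = out / "counts.csv"
        results.counts_frame().to_csv(counts_csv, index=False)
        written.append(counts_csv)
        report_txt = out / "report.txt"
        report_txt.write_text(report_counts(results) + "\n")
        written.append(report_txt)

        stage = "compare"
        comp_csv = out / "comparison.csv"
        pd.DataFrame([c.__dict__ for c in results.comparisons]).to_csv(comp_csv, index=False)
        written.append(comp_csv)

        stage = "pca"
        for tissue, pca in results.pca.items():
            if pca is None:
                continue
            p = out / f"pca_{tissue}.csv"
            pd.DataFrame(
                {
                    "component": np.arange(1, len(pca.eigenvalues) + 1),
                    "eigenvalue": pca.eigenvalues,
                    "proportion": pca.proportions,
                    "cumulative": pca.cumulative,
                }
            ).to_csv(p, index=False)
            written.append(p)
            p = out / f"pca_scores_{tissue}.csv"
            pd.DataFrame(
                pca.scores,
                columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
            ).to_csv(p, index=False)
            written.append(p)
    except Exception:
        (out / f"{stage}.partial").write_text(f"stage '{stage}' failed; outputs incomplete\n")
        raise

    config_yaml = out / "config.yaml"
    save_config(config, config_yaml)
    written.append(config_yaml)

    manifest = RunManifest(
        config=to_dict(config),
        version=__version__,
        started=started,
        finished=time.time(),
        file_hashes={str(p.relative_to(out)): _sha256(p) for p in written},
        summary={
            "n_records": len(bundle.records),
            "n_features": len(ALL_FEATURE_NAMES),
            "robust_features": results.robust_features,
            "pca_n90": {
                t: (None if p is None else p.n90) for t, p in results.pca.items()
            },
        },
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
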