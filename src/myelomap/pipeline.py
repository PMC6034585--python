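"""Cohort orchestration: simulate → classify → measure → sweep → statistics.

`run_subject` processes one manifest row (NIfTI paths) into per-subject
metrics; `analyze_subject` is the in-memory core.  `run_cohort` assembles the
per-subject records into a cohort table and runs the group-level battery:
stroke-vs-control t-test on the hemispheric ratio, repeated-measures ANOVA
across lesion-adjacency classes, and optional outcome correlations with
Bonferroni control.

All grids of one subject must share a voxel grid; resampling is a
pre-processing responsibility, not performed here.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from . import stats as mstats
from .classify import Parcellation, classify_regions
from .intensity import hemispheric_asymmetry_ratio, region_means
from .phantom import (
    CONTRALESIONAL_HOMOLOGUE,
    IPSILESIONAL_REMOTE,
    PERILESIONAL,
    TISSUE_BACKGROUND,
    TISSUE_WM,
)
from .sweep import sweep_volume

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "analyze_subject", "run_subject", "run_cohort"]

CLASS_COLUMNS = {
    PERILESIONAL: "perilesional_mean",
    IPSILESIONAL_REMOTE: "remote_mean",
    CONTRALESIONAL_HOMOLOGUE: "homologue_mean",
}


@dataclass
class RunConfig:
    """Reproducible run settings; every field is echoed into the run log."""

    connectivity: int = 26
    min_bilateral_pixels: int = 1
    min_visible_pixels: int = 1
    quantization: str = "volume"  # per-volume 1..255 rescaling
    aggregation: str = "voxel_weighted"  # or "parcel_mean"
    overlap_fraction: float = 0.5
    seed: int = 0
    out_dir: str | None = None
    pearson_outcomes: tuple = ("aha_logit", "ma_percent")
    spearman_outcomes: tuple = ()

    @property
    def weighted(self) -> bool:
        return self.aggregation == "voxel_weighted"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pearson_outcomes"] = list(self.pearson_outcomes)
        d["spearman_outcomes"] = list(self.spearman_outcomes)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})


def analyze_subject(
    intensity: np.ndarray,
    parcellation: Parcellation,
    wm_mask: np.ndarray,
    brain_mask: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    config: RunConfig | None = None,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> dict:
    """Run classification, regional intensity metrics and the threshold sweep
    for one subject.  Controls pass ``lesion_mask=None`` and get right/left
    metrics with no class means."""
    config = config or RunConfig()
    classification = None
    if lesion_mask is not None and lesion_mask.any():
        classification = classify_regions(
            parcellation, lesion_mask,
            connectivity=config.connectivity,
            overlap_fraction=config.overlap_fraction,
        )
    table = region_means(intensity, parcellation, wm_mask, lesion_mask, classification)
    asym = hemispheric_asymmetry_ratio(
        table,
        lesion_hemisphere=classification.lesion_hemisphere if classification else None,
        weighted=config.weighted,
    )
    score = sweep_volume(
        intensity,
        wm_mask,
        lesion_mask=lesion_mask,
        voxel_size_mm=voxel_size_mm,
        brain_mask=brain_mask,
        min_bilateral_pixels=config.min_bilateral_pixels,
        min_visible_pixels=config.min_visible_pixels,
    )
    record = {
        "hemispheric_ratio": asym.hemispheric_ratio,
        "remote_vs_homologue_ratio": asym.remote_vs_homologue_ratio,
        "sweep_score": score.total_score,
        "lesion_volume_mm3": score.lesion_volume_mm3,
        "brain_volume_mm3": score.brain_volume_mm3,
        "lesion_fraction_percent": score.lesion_fraction_percent,
    }
    for cls, col in CLASS_COLUMNS.items():
        record[col] = asym.per_class_means.get(cls, np.nan)
    return {
        "record": record,
        "region_table": table,
        "asymmetry": asym,
        "classification": classification,
        "sweep": score,
    }


def _load_grid(path: str, subject_id: str, ref_shape=None):
    if not path or not Path(path).exists():
        raise FileNotFoundError(f"subject {subject_id}: missing file {path!r}")
    data, affine = mio.read_nifti(path)
    if ref_shape is not None and data.shape != ref_shape:
        raise ValueError(
            f"subject {subject_id}: grid of {path!r} {data.shape} does not "
            f"match {ref_shape}"
        )
    return data, affine


def run_subject(config: RunConfig, row) -> dict:
    """Process one cohort-manifest row (file paths) into subject metrics."""
    sid = row["subject_id"]
    t1, affine = _load_grid(row["t1_path"], sid)
    tissue, _ = _load_grid(row["tissue_path"], sid, t1.shape)
    labels, _ = _load_grid(row["parcellation_path"], sid, t1.shape)
    lut = mio.read_lut(row["lut_path"])
    parc = Parcellation(labels.astype(np.int32), lut)

    lesion = None
    lesion_path = row.get("lesion_path", "") if hasattr(row, "get") else row["lesion_path"]
    if isinstance(lesion_path, str) and lesion_path:
        lesion, _ = _load_grid(lesion_path, sid, t1.shape)
        lesion = lesion.astype(bool)
    elif row["group"] == "stroke":
        raise ValueError(f"subject {sid}: stroke subject without a lesion mask")

    voxel_size = tuple(np.abs(np.diag(affine))[:3])
    out = analyze_subject(
        t1,
        parc,
        wm_mask=tissue == TISSUE_WM,
        brain_mask=tissue != TISSUE_BACKGROUND,
        lesion_mask=lesion,
        config=config,
        voxel_size_mm=voxel_size,
    )
    out["record"] = {"subject_id": sid, "group": row["group"], **out["record"]}
    return out


def run_cohort(config: RunConfig, manifest: pd.DataFrame):
    """Process every manifest row and run the group-level statistics.

    Returns ``(cohort_table, stat_results)`` where ``stat_results`` is a list
    of :class:`myelomap.stats.StatResult`; families with insufficient n are
    reported as entries with NaN estimates and a note instead of numbers.
    Writes ``cohort.csv``, ``stats.csv`` and ``run_log.json`` under
    ``config.out_dir`` when set.
    """
    if manifest is None or len(manifest) == 0:
        raise ValueError("empty manifest")
    records = []
    passthrough = [
        c for c in manifest.columns
        if c not in {"t1_path", "tissue_path", "parcellation_path", "lut_path",
                     "lesion_path", "truth_path"}
        and c not in {"subject_id", "group"}
    ]
    for _, row in manifest.iterrows():
        out = run_subject(config, row)
        rec = out["record"]
        for c in passthrough:
            rec[c] = row[c]
        records.append(rec)
    cohort = pd.DataFrame(records)

    results = _stats_battery(config, cohort)

    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        _results_frame(results).to_csv(out_dir / "stats.csv", index=False)
        (out_dir / "run_log.json").write_text(
            json.dumps({"config": config.to_dict(), "n_subjects": len(cohort)}, indent=2)
        )
    return cohort, results


def _note(test: str, msg: str) -> mstats.StatResult:
    return mstats.StatResult(test, float("nan"), float("nan"), 0, details={"note": msg})


def _stats_battery(config: RunConfig, cohort: pd.DataFrame):
    results = []
    stroke = cohort[cohort["group"] == "stroke"]
    control = cohort[cohort["group"] == "control"]

    # stroke vs control hemispheric asymmetry
    if len(stroke) >= 2 and len(control) >= 2:
        res = mstats.group_compare(
            stroke["hemispheric_ratio"], control["hemispheric_ratio"]
        )
        res.test = "ratio:stroke-vs-control:" + res.test
        results.append(res)
    else:
        results.append(_note("ratio:stroke-vs-control", "insufficient n"))

    # location effect across lesion-adjacency classes, within stroke subjects
    class_cols = ["perilesional_mean", "remote_mean", "homologue_mean"]
    complete = stroke.dropna(subset=class_cols)
    if len(complete) >= 3:
        long = complete.melt(
            id_vars=["subject_id"], value_vars=class_cols,
            var_name="location", value_name="value",
        )
        try:
            results.extend(
                mstats.mixed_anova(
                    long, dv="value", within="location",
                    subject="subject_id", between=None,
                )
            )
        except ValueError as exc:
            results.append(_note("rm-anova:location", str(exc)))
    else:
        results.append(_note("rm-anova:location", "insufficient n"))

    # outcome correlations in stroke subjects, Bonferroni within each family
    for method, cols in (
        ("pearson", config.pearson_outcomes),
        ("spearman", config.spearman_outcomes),
    ):
        family = []
        for col in cols:
            if col not in stroke.columns:
                continue
            paired = stroke.dropna(subset=["hemispheric_ratio", col])
            if len(paired) < 3:
                results.append(_note(f"{method}:ratio-vs-{col}", "insufficient n"))
                continue
            res = mstats.correlate(
                paired["hemispheric_ratio"], paired[col], method=method
            )
            res.test = f"ratio-vs-{col}:" + res.test
            family.append(res)
        if family:
            adj = mstats.bonferroni([r.p_value for r in family])
            for r, pa in zip(family, adj):
                r.p_adjusted = float(pa)
            results.extend(family)
    return results


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "test": [r.test for r in results],
            "estimate": [r.estimate for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "n": [r.n for r in results],
            "note": [r.details.get("note", "") for r in results],
        }
    )
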