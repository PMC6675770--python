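"""Study-level aggregation, paired modality comparison, and the pipeline driver.

Each lesion is imaged under all three modalities, so modality comparisons are
paired at the lesion level: per-modality means and standard deviations of the
Mahalanobis distance and the F1 measure are reported, and each modality pair
is compared with a two-sided paired Wilcoxon signed-rank test (primary; no
normality assumption at n = 18) alongside a paired t-test.  P-values are
reported uncorrected, with a Holm-adjusted column per metric for transparency.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .base import (
    MODALITY_ORDER,
    STAGE_SAMPLE,
    STAGE_SPLIT,
    ChromosepError,
    CompletenessError,
    Modality,
    derive_seed,
)
from .config import PipelineConfig
from .diagnosis import ClassificationResult, SplitSpec, diagnose_image
from .roi import LabeledImage, extract_region_pixels, load_labeled_image, read_manifest
from .base import RegionLabel
from .sampling import luminance_matched_sample
from .separation import estimate_class_stats, mahalanobis_distance

__all__ = ["LesionModalityRecord", "StudyReport", "analyze_image", "run_study",
           "run_synthetic_study", "aggregate", "write_report",
           "records_to_frame", "records_from_frame"]

logger = logging.getLogger("chromosep")

_PAIRS = [(Modality.WL, Modality.INDIGO),
          (Modality.WL, Modality.AIM),
          (Modality.INDIGO, Modality.AIM)]


@dataclasses.dataclass(frozen=True)
class LesionModalityRecord:
    """Per-image outcome: separation distance plus the SVM diagnosis scores."""

    lesion_id: str
    modality: Modality
    mahalanobis_distance: float
    regularized: bool
    classification: ClassificationResult
    n_sampled: int  # total luminance-matched pixels (both classes)


@dataclasses.dataclass(frozen=True)
class StudyReport:
    """Per-modality summaries and paired cross-modality comparisons.

    ``comparisons`` rows: (metric, modality pair, test name, statistic,
    p-value, Holm-adjusted p-value).  ``modality_means`` maps metric →
    modality → (mean, sd).
    """

    n_lesions: int
    modality_means: dict
    comparisons: list[dict]

    def mean(self, metric: str, modality: Modality) -> float:
        return self.modality_means[metric][modality.value]["mean"]


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjustment (family = the 3 pairs of one metric/test)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


# --- per-image pipeline ----------------------------------------------------

def analyze_image(img: LabeledImage, config: PipelineConfig,
                  sample_seed: int, split_seed: int) -> LesionModalityRecord:
    """Run sampling → separation → diagnosis on one labeled image."""
    rgb_c, coords_c = extract_region_pixels(img, RegionLabel.CANCER)
    rgb_n, coords_n = extract_region_pixels(img, RegionLabel.NONCANCER)
    set_c, set_n = luminance_matched_sample(
        rgb_c, coords_c, rgb_n, coords_n,
        n_per_class=config.n_per_class, n_bins=config.n_bins,
        seed=sample_seed, weights=config.rgb_weights)
    sep = mahalanobis_distance(estimate_class_stats(set_c),
                               estimate_class_stats(set_n),
                               pooled_weighting=config.pooled_weighting)
    result = diagnose_image(set_c, set_n,
                            SplitSpec(config.n_train_per_class, split_seed),
                            c=config.svm_c, gamma=config.svm_gamma)
    logger.info(
        "image %s/%s: sample_seed=%d split_seed=%d sampled=%d distance=%.4f "
        "f1=%.4f", img.lesion_id, img.modality.value, sample_seed, split_seed,
        set_c.n + set_n.n, sep.distance, result.f1)
    return LesionModalityRecord(
        lesion_id=img.lesion_id, modality=img.modality,
        mahalanobis_distance=sep.distance, regularized=sep.regularized,
        classification=result, n_sampled=set_c.n + set_n.n)


def run_study(manifest_path: "str | Path", config: PipelineConfig,
              master_seed: int) -> list[LesionModalityRecord]:
    """Run the full pipeline over every image listed in a manifest CSV.

    Per-image seeds are derived from the master seed and the image's stable
    address (lesion ordinal in sorted lesion_id order, modality ordinal), so
    results do not depend on manifest row order.
    """
    entries = read_manifest(manifest_path)
    lesion_ids = sorted({e["lesion_id"] for e in entries})
    ordinal = {lid: i for i, lid in enumerate(lesion_ids)}
    mod_ordinal = {m: i for i, m in enumerate(MODALITY_ORDER)}
    records = []
    for e in sorted(entries, key=lambda e: (e["lesion_id"],
                                            mod_ordinal[e["modality"]])):
        img = load_labeled_image(e["image_path"], e["mask_path"],
                                 e["lesion_id"], e["modality"],
                                 boundary_erode=config.boundary_erode)
        li, mi = ordinal[e["lesion_id"]], mod_ordinal[e["modality"]]
        records.append(analyze_image(
            img, config,
            sample_seed=derive_seed(master_seed, li, mi, STAGE_SAMPLE),
            split_seed=derive_seed(master_seed, li, mi, STAGE_SPLIT)))
    return records


def run_synthetic_study(spec, config: PipelineConfig
                        ) -> list[LesionModalityRecord]:
    """Generate a synthetic study in memory and run the pipeline on it.

    Equivalent to ``write_study`` + ``run_study`` with master seed =
    ``spec.master_seed``, minus the PNG round trip (8-bit quantization happens
    at render time either way).
    """
    from .synthetic import StudySpec, generate_study  # local: avoid cycle

    assert isinstance(spec, StudySpec)
    mod_ordinal = {m: i for i, m in enumerate(MODALITY_ORDER)}
    records = []
    for lesion_spec, image, mask in generate_study(spec):
        img = LabeledImage(pixels=image, mask=(mask != 0).astype(np.uint8),
                           lesion_id=lesion_spec.lesion_id,
                           modality=lesion_spec.modality)
        li = int(lesion_spec.lesion_id.lstrip("L")) - 1
        mi = mod_ordinal[lesion_spec.modality]
        records.append(analyze_image(
            img, config,
            sample_seed=derive_seed(spec.master_seed, li, mi, STAGE_SAMPLE),
            split_seed=derive_seed(spec.master_seed, li, mi, STAGE_SPLIT)))
    return records


# --- aggregation -----------------------------------------------------------

def _metric_values(records: list[LesionModalityRecord], metric: str,
                   lesion_ids: list[str]) -> dict[Modality, np.ndarray]:
    by_cell = {(r.lesion_id, r.modality): r for r in records}
    out = {}
    for m in MODALITY_ORDER:
        vals = []
        for lid in lesion_ids:
            r = by_cell[(lid, m)]
            vals.append(r.mahalanobis_distance if metric == "mahalanobis_distance"
                        else r.classification.f1)
        out[m] = np.asarray(vals)
    return out


def aggregate(records: list[LesionModalityRecord]) -> StudyReport:
    """Summarize per-image records into the study report.

    Requires a complete 3-modality × n-lesion grid.  With fewer than two
    lesions the means are still reported but paired testing is impossible,
    which is raised as an error per the contract.
    """
    cells = {(r.lesion_id, r.modality) for r in records}
    if len(cells) != len(records):
        raise ChromosepError("duplicate (lesion, modality) records")
    lesion_ids = sorted({lid for lid, _ in cells})
    missing = [(lid, m.value) for lid in lesion_ids for m in MODALITY_ORDER
               if (lid, m) not in cells]
    if missing:
        raise CompletenessError(f"missing (lesion, modality) records: {missing}")
    if len(lesion_ids) < 2:
        raise ChromosepError(
            "paired testing needs at least 2 lesions; got "
            f"{len(lesion_ids)} (per-image records are still available)")

    modality_means: dict = {}
    comparisons: list[dict] = []
    for metric in ("mahalanobis_distance", "f1"):
        values = _metric_values(records, metric, lesion_ids)
        modality_means[metric] = {
            m.value: {"mean": float(values[m].mean()),
                      "sd": float(values[m].std(ddof=1))}
            for m in MODALITY_ORDER}
        for test in ("wilcoxon", "paired_t"):
            rows = []
            for a, b in _PAIRS:
                diff = values[a] - values[b]
                if test == "wilcoxon":
                    if np.allclose(diff, 0.0):
                        # all-zero differences: degenerate, no evidence either way
                        stat, p = 0.0, 1.0
                    else:
                        res = stats.wilcoxon(diff, alternative="two-sided",
                                             zero_method="wilcox")
                        stat, p = float(res.statistic), float(res.pvalue)
                else:
                    if np.allclose(diff - diff.mean(), 0.0):
                        stat, p = 0.0, 1.0
                    else:
                        res = stats.ttest_rel(values[a], values[b])
                        stat, p = float(res.statistic), float(res.pvalue)
                rows.append({"metric": metric, "pair": f"{a.value}-{b.value}",
                             "test": test, "statistic": stat, "p_value": p,
                             "mean_difference": float(diff.mean())})
            for row, p_adj in zip(rows, _holm([r["p_value"] for r in rows])):
                row["p_holm"] = p_adj
            comparisons.extend(rows)

    return StudyReport(n_lesions=len(lesion_ids),
                       modality_means=modality_means, comparisons=comparisons)


# --- serialization ---------------------------------------------------------

def records_to_frame(records: list[LesionModalityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.classification
        rows.append({
            "lesion_id": r.lesion_id, "modality": r.modality.value,
            "n_sampled": r.n_sampled,
            "mahalanobis_distance": r.mahalanobis_distance,
            "regularized": r.regularized,
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "sensitivity": c.sensitivity, "ppv": c.ppv, "f1": c.f1,
        })
    mod_rank = {m.value: i for i, m in enumerate(MODALITY_ORDER)}
    rows.sort(key=lambda r: (r["lesion_id"], mod_rank[r["modality"]]))
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[LesionModalityRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(LesionModalityRecord(
            lesion_id=row.lesion_id, modality=Modality.from_string(row.modality),
            mahalanobis_distance=float(row.mahalanobis_distance),
            regularized=bool(row.regularized),
            classification=ClassificationResult(tp=int(row.tp), fp=int(row.fp),
                                                tn=int(row.tn), fn=int(row.fn)),
            n_sampled=int(row.n_sampled)))
    return records


def write_report(report: StudyReport, records: list[LesionModalityRecord],
                 out_dir: "str | Path", figures: bool = False) -> dict[str, Path]:
    """Write the per-image CSV, the JSON study report, a short human-readable
    summary (values rounded to 3 decimals), and optional bar charts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"csv": out / "per_image_results.csv",
             "json": out / "study_report.json",
             "summary": out / "summary.txt"}
    records_to_frame(records).to_csv(paths["csv"], index=False)
    payload = {"n_lesions": report.n_lesions,
               "modality_means": report.modality_means,
               "comparisons": report.comparisons}
    paths["json"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    lines = [f"Study of {report.n_lesions} lesions x 3 modalities", ""]
    for metric, label in (("mahalanobis_distance", "Mahalanobis distance"),
                          ("f1", "F1 measure")):
        lines.append(f"Mean {label}:")
        for m in MODALITY_ORDER:
            cell = report.modality_means[metric][m.value]
            lines.append(f"  {m.value:>6}: {cell['mean']:.3f} (sd {cell['sd']:.3f})")
        lines.append("")
    lines.append("Paired Wilcoxon signed-rank (two-sided), uncorrected p:")
    for row in report.comparisons:
        if row["test"] != "wilcoxon":
            continue
        lines.append(f"  {row['metric']:>20} {row['pair']:>13}: "
                     f"p={row['p_value']:.3f} (Holm {row['p_holm']:.3f})")
    paths["summary"].write_text("\n".join(lines) + "\n")

    if figures:
        paths["figures"] = _write_figures(report, out)
    return paths


def _write_figures(report: StudyReport, out: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, (metric, label) in zip(axes, (("mahalanobis_distance",
                                           "Mean Mahalanobis distance"),
                                          ("f1", "Mean F1 measure"))):
        means = [report.modality_means[metric][m.value]["mean"]
                 for m in MODALITY_ORDER]
        sds = [report.modality_means[metric][m.value]["sd"]
               for m in MODALITY_ORDER]
        ax.bar([m.value for m in MODALITY_ORDER], means, yerr=sds,
               color=["#888", "#4477aa", "#66ccee"], capsize=4)
        ax.set_ylabel(label)
    fig.tight_layout()
    path = out / "modality_means.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
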