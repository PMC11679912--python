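"""Prediction-accuracy metrics and the modality experiment matrix.

Per-slice accuracy is reported as the Prediction Deviation
``PD = MAE_GT - MAE_predicted`` (signed, HU) and the Absolute Prediction
Deviation ``APD = |PD|``; both the ground-truth and predicted MAE are
saturated at the scheme's upper bound before the deviations are taken.
Summaries give the median and the 5th/25th/75th/95th percentiles.

Pipelines are compared slice-wise with the two-sided Wilcoxon rank-sum
test on APD: exact enumeration for small tie-free samples, normal
approximation with tie correction otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sctqa.binning import BinScheme
from sctqa.io_volumes import VolumePair
from sctqa.labeling import build_corpus

PERCENTILES = (5, 25, 50, 75, 95)

#: the four modality experiments: (pipeline name, test-set name)
EXPERIMENT_MATRIX = [
    ("CBCT", "sCT_CBCT"),
    ("MR", "sCT_MR"),
    ("MIXED", "sCT_CBCT"),
    ("MIXED", "sCT_MR"),
]

#: single-modality vs mixed comparisons, per test set
COMPARISONS = [
    ("CBCT", "MIXED", "sCT_CBCT"),
    ("MR", "MIXED", "sCT_MR"),
]


@dataclass
class PredictionRecord:
    """Per-slice cascade output, optionally with ground truth attached."""

    patient_id: str
    modality: str
    slice_index: int
    class_predicted: int
    mae_predicted: float  # HU
    mae_gt: float | None = None  # HU; evaluation only
    pd: float | None = None  # signed, HU
    apd: float | None = None  # |pd|, HU


def compute_deviations(
    records: Sequence[PredictionRecord], scheme: BinScheme
) -> list[PredictionRecord]:
    """Fill PD/APD in place; both MAE values saturated first."""
    sat = scheme.saturation
    for rec in records:
        if rec.mae_gt is None:
            raise ValueError(
                f"record {rec.patient_id}/{rec.slice_index} has no ground-truth MAE"
            )
        gt = min(float(rec.mae_gt), sat)
        pred = min(float(rec.mae_predicted), sat)
        rec.pd = gt - pred
        rec.apd = abs(rec.pd)
    return list(records)


def records_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "modality": [r.modality for r in records],
            "slice_index": [r.slice_index for r in records],
            "class_predicted": [r.class_predicted for r in records],
            "mae_predicted": [r.mae_predicted for r in records],
            "mae_gt": [r.mae_gt for r in records],
            "pd": [r.pd for r in records],
            "apd": [r.apd for r in records],
        }
    )


def summarize(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Percentile table of PD and APD (linear-interpolation quantiles).

    One row per metric with the median, 5th/25th/75th/95th percentiles,
    slice count and patient count; invariant to record order.
    """
    if not records:
        raise ValueError("no records to summarize")
    if any(r.pd is None for r in records):
        raise ValueError("deviations not computed; call compute_deviations first")
    pd_vals = np.array([r.pd for r in records], dtype=np.float64)
    apd_vals = np.array([r.apd for r in records], dtype=np.float64)
    n_patients = len({r.patient_id for r in records})
    rows = []
    for name, vals in (("PD", pd_vals), ("APD", apd_vals)):
        pct = np.percentile(vals, PERCENTILES, method="linear")
        rows.append(
            {
                "metric": name,
                "p5": pct[0],
                "p25": pct[1],
                "median": pct[2],
                "p75": pct[3],
                "p95": pct[4],
                "n_slices": len(vals),
                "n_patients": n_patients,
            }
        )
    return pd.DataFrame(rows)


def compare_pipelines(
    values_a: Sequence[float] | Sequence[PredictionRecord],
    values_b: Sequence[float] | Sequence[PredictionRecord],
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on per-slice APD.

    Accepts raw value sequences or records (APD is used).  Uses exact
    enumeration for small tie-free samples and the normal approximation
    with tie correction otherwise.  Returns ``(U statistic, p value)``;
    identical pooled values short-circuit to p = 1 with a warning.
    """
    a = _as_values(values_a)
    b = _as_values(values_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; rank-sum test degenerate (p=1)",
                      stacklevel=2)
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size <= 25 and b.size <= 25
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _as_values(seq) -> np.ndarray:
    seq = list(seq)
    if seq and isinstance(seq[0], PredictionRecord):
        if any(r.apd is None for r in seq):
            raise ValueError("records lack APD; call compute_deviations first")
        return np.array([r.apd for r in seq], dtype=np.float64)
    return np.asarray(seq, dtype=np.float64)


def evaluate_pipeline(
    model, test_pairs: Sequence[VolumePair]
) -> list[PredictionRecord]:
    """Run a cascade on labeled pairs and fill ground truth + deviations."""
    from sctqa.cascade import predict_volume

    records: list[PredictionRecord] = []
    corpus = build_corpus(test_pairs, saturation=None)
    labels = {(s.patient_id, s.slice_index): s.mae_gt for s in corpus}
    for pair in test_pairs:
        recs, _ = predict_volume(
            model, pair.sct, pair.geometry, pair.patient_id, pair.modality
        )
        for rec in recs:
            key = (pair.patient_id, rec.slice_index)
            if key not in labels:  # slice excluded by the inclusion rule
                continue
            rec.mae_gt = labels[key]
            records.append(rec)
    return compute_deviations(records, model.scheme)


def run_experiment_matrix(
    pipelines: dict[str, "object"],
    test_sets: dict[str, Sequence[VolumePair]],
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the four modality experiments and the two comparisons.

    ``pipelines`` maps {"CBCT", "MR", "MIXED"} to trained cascades;
    ``test_sets`` maps {"sCT_CBCT", "sCT_MR"} to labeled pairs.  Runs
    CBCT->sCT_CBCT, MR->sCT_MR, MIXED->sCT_CBCT, MIXED->sCT_MR, then
    compares each single-modality pipeline against MIXED on the matching
    test set.  Any other pipeline/test-set combination is rejected.
    """
    missing = [p for p, _ in EXPERIMENT_MATRIX if p not in pipelines]
    missing += [t for _, t in EXPERIMENT_MATRIX if t not in test_sets]
    if missing:
        raise ValueError(f"experiment matrix incomplete; missing {sorted(set(missing))}")
    results: dict[tuple[str, str], list[PredictionRecord]] = {}
    summaries = {}
    for pipe_name, test_name in EXPERIMENT_MATRIX:
        recs = evaluate_pipeline(pipelines[pipe_name], test_sets[test_name])
        results[(pipe_name, test_name)] = recs
        summaries[(pipe_name, test_name)] = summarize(recs)
    comparisons = []
    for single, mixed, test_name in COMPARISONS:
        stat, p = compare_pipelines(
            results[(single, test_name)], results[(mixed, test_name)]
        )
        comparisons.append(
            {
                "pipeline_a": single,
                "pipeline_b": mixed,
                "test_set": test_name,
                "statistic": stat,
                "p_value": p,
                "median_apd_a": float(np.median([r.apd for r in results[(single, test_name)]])),
                "median_apd_b": float(np.median([r.apd for r in results[(mixed, test_name)]])),
            }
        )
    report = {"summaries": summaries, "comparisons": comparisons, "records": results}
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def check_in_matrix(pipeline_name: str, test_name: str) -> None:
    """Reject pipeline/test-set combinations outside the four experiments."""
    if (pipeline_name, test_name) not in EXPERIMENT_MATRIX:
        raise ValueError(
            f"({pipeline_name}, {test_name}) is not one of the four "
            f"experiments {EXPERIMENT_MATRIX}"
        )


def write_report(report: dict, out_dir: str | Path) -> Path:
    """CSV tables + static box plots; numeric output 2-decimal HU."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for metric in ("PD", "APD"):
        rows = []
        for (pipe, test), summ in report["summaries"].items():
            row = summ[summ.metric == metric].iloc[0].to_dict()
            row.update({"pipeline": pipe, "test_set": test})
            rows.append(row)
        df = pd.DataFrame(rows)[
            ["pipeline", "test_set", "p5", "p25", "median", "p75", "p95",
             "n_slices", "n_patients"]
        ]
        df.to_csv(out_dir / f"summary_{metric.lower()}.csv", index=False,
                  float_format="%.2f")
    pd.DataFrame(report["comparisons"]).to_csv(
        out_dir / "comparisons.csv", index=False
    )
    _plot_distributions(report, out_dir)
    return out_dir


def _plot_distributions(report: dict, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, attr in (("PD", "pd"), ("APD", "apd")):
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, test_name in zip(axes, ("sCT_CBCT", "sCT_MR")):
            data, labels = [], []
            for (pipe, test), recs in report["records"].items():
                if test != test_name:
                    continue
                data.append([getattr(r, attr) for r in recs])
                labels.append(pipe)
            ax.boxplot(data, tick_labels=labels)
            ax.set_title(test_name)
            ax.set_ylabel(f"{metric} (HU)")
        fig.tight_layout()
        fig.savefig(out_dir / f"{metric.lower()}_distributions.png", dpi=100)
        plt.close(fig)
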