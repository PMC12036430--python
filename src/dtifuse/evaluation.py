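"""Binary-classifier evaluation of prediction records against labels.

Final scores are binarized at a threshold (default 0.5, score >= threshold
counts as a positive call) and summarized as F1, precision, recall,
specificity, AUROC, and AUPRC.  AUROC is the rank statistic (probability a
random positive outranks a random negative, ties half credit); AUPRC is the
step-wise integral of the precision-recall curve with no interpolation.
Zero-denominator conventions: precision is 0 with no positive calls; AUROC
and specificity are NaN when only one class is present.

The repeated-subset harness draws seeded subsets without replacement and
reports a per-metric mean and standard deviation, the usual protocol for
benchmark tables of the form "0.514 (±0.084)".
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .aggregation import PredictionRecord
from .errors import ContractError, JoinError

logger = logging.getLogger(__name__)

METRICS = ("f1", "precision", "recall", "specificity", "auroc", "auprc")


@dataclass(frozen=True)
class LabeledPair:
    drug: str
    target: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ContractError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class MetricsReport:
    f1: float
    precision: float
    recall: float
    specificity: float
    auroc: float
    auprc: float
    threshold: float
    n_pos: int
    n_neg: int
    confusion: tuple[int, int, int, int]  # (tp, fp, tn, fn)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


def _pair_key(drug: str, target: str) -> tuple[str, str]:
    return (drug.strip().casefold(), target.strip().casefold())


def join_scores(records: list[PredictionRecord],
                labels: list[LabeledPair]) -> tuple[np.ndarray, np.ndarray]:
    """Match records to labels one-to-one by (drug, target); return (scores, y)."""
    by_pair = {_pair_key(r.drug, r.target): r for r in records}
    if len(by_pair) != len(records):
        raise JoinError("duplicate (drug, target) pairs among records")
    scores, y = [], []
    missing = []
    for lab in labels:
        rec = by_pair.pop(_pair_key(lab.drug, lab.target), None)
        if rec is None or rec.final_score is None:
            missing.append((lab.drug, lab.target))
            continue
        scores.append(rec.final_score)
        y.append(lab.label)
    offenders = missing + [(r.drug, r.target) for r in by_pair.values()]
    if offenders:
        raise JoinError(
            f"{len(offenders)} unmatched pair(s): {offenders[:5]}...",
            offenders=offenders)
    return np.asarray(scores, dtype=float), np.asarray(y, dtype=int)


def compute_metrics(records: list[PredictionRecord],
                    labels: list[LabeledPair],
                    threshold: float = 0.5) -> MetricsReport:
    scores, y = join_scores(records, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp

    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / n_pos if n_pos > 0 else math.nan
    specificity = tn / n_neg if n_neg > 0 else math.nan
    f1 = (2 * precision * recall / (precision + recall)
          if n_pos > 0 and (precision + recall) > 0 else 0.0)
    if n_pos > 0 and n_neg > 0:
        auroc = float(roc_auc_score(y, scores))
        auprc = float(average_precision_score(y, scores))
    else:
        auroc = auprc = math.nan
    return MetricsReport(f1=f1, precision=precision, recall=recall,
                         specificity=specificity, auroc=auroc, auprc=auprc,
                         threshold=threshold, n_pos=n_pos, n_neg=n_neg,
                         confusion=(tp, fp, tn, fn))


def repeated_subset_eval(records: list[PredictionRecord],
                         labels: list[LabeledPair],
                         n_subsets: int = 5, subset_size: int = 50,
                         seed: int = 0, threshold: float = 0.5,
                         ) -> dict[str, tuple[float, float]]:
    """Mean and SD of each metric over seeded subsets drawn without replacement."""
    if subset_size > len(labels):
        raise ContractError(
            f"subset_size {subset_size} exceeds available pairs {len(labels)}")
    rng = np.random.default_rng(seed)
    per_metric: dict[str, list[float]] = {m: [] for m in METRICS}
    for _ in range(n_subsets):
        idx = rng.choice(len(labels), size=subset_size, replace=False)
        sub = [labels[i] for i in idx]
        by_pair = {_pair_key(r.drug, r.target): r for r in records}
        sub_records = [by_pair[_pair_key(l.drug, l.target)] for l in sub]
        report = compute_metrics(sub_records, sub, threshold=threshold)
        for m in METRICS:
            per_metric[m].append(getattr(report, m))
    return {m: (float(np.mean(v)), float(np.std(v)))
            for m, v in per_metric.items()}


def format_report(summary: dict[str, tuple[float, float]]) -> str:
    """Render a repeated-subset summary as benchmark-table rows."""
    lines = []
    for m in METRICS:
        mean, sd = summary[m]
        lines.append(f"{m.capitalize():<12} {mean:.3f} (±{sd:.3f})")
    return "\n".join(lines)


def read_labels(path: str) -> list[LabeledPair]:
    """Read a labels CSV (``drug,target,label``; header optional)."""
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if i == 1 and row[0].strip().lower() == "drug":
                continue
            if len(row) < 3:
                raise ContractError(f"labels file line {i}: expected drug,target,label")
            out.append(LabeledPair(drug=row[0].strip(), target=row[1].strip(),
                                   label=int(row[2])))
    return out
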