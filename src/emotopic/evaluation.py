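"""Agreement and validity statistics for annotations and classifier output.

Implements Cohen's kappa with the good/excellent banding convention
(0.61–0.80 good, 0.81–1 excellent), one-vs-rest multi-class
precision/recall/F1 with macro and micro averaging, a threshold gate for
the usual excellent-validity criteria (accuracy >= 0.85, recall >= 0.80,
F1 >= 0.80), and agreement between two topic-to-theme mappings (topics as
items, themes as labels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class LabelVectorPair:
    """Two equal-length label sequences over the same items (reference first
    when one side is a gold standard)."""

    ids: tuple[str, ...]
    labels_a: tuple[str, ...]
    labels_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.labels_a) == len(self.labels_b)):
            raise ValueError("ids, labels_a, labels_b must have equal lengths")
        if len(self.ids) == 0:
            raise ValueError("need at least one labelled item")

    @classmethod
    def from_sequences(cls, labels_a: Sequence[str], labels_b: Sequence[str],
                       ids: Sequence[str] | None = None) -> "LabelVectorPair":
        if ids is None:
            ids = [str(i) for i in range(len(labels_a))]
        return cls(tuple(str(i) for i in ids),
                   tuple(labels_a), tuple(labels_b))

    @property
    def label_set(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels_a) | set(self.labels_b)))


@dataclass(frozen=True)
class ConfusionMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # rows = reference (a), columns = prediction (b)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def confusion_matrix(pair: LabelVectorPair) -> ConfusionMatrix:
    labels = pair.label_set
    index = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, b in zip(pair.labels_a, pair.labels_b):
        m[index[a], index[b]] += 1
    return ConfusionMatrix(labels=labels, matrix=m)


@dataclass(frozen=True)
class AgreementReport:
    kappa: float
    band: str            # below_good | good | excellent | degenerate
    po: float
    pe: float
    degenerate: bool = False


def _band(kappa: float) -> str:
    if kappa >= 0.81:
        return "excellent"
    if kappa >= 0.61:
        return "good"
    return "below_good"


def cohen_kappa(pair: LabelVectorPair) -> AgreementReport:
    """Chance-corrected agreement κ = (po − pe) / (1 − pe).

    po is the observed agreement fraction; pe the chance agreement from the
    two raters' marginal label distributions.  When both raters assign one
    identical constant label, pe = 1 and κ is undefined: reported as
    degenerate with po = 1.
    """
    cm = confusion_matrix(pair)
    n = cm.total
    po = float(np.trace(cm.matrix)) / n
    marg_a = cm.matrix.sum(axis=1) / n
    marg_b = cm.matrix.sum(axis=0) / n
    pe = float(marg_a @ marg_b)
    if pe >= 1.0:
        return AgreementReport(kappa=math.nan, band="degenerate",
                               po=po, pe=pe, degenerate=True)
    kappa = (po - pe) / (1.0 - pe)
    return AgreementReport(kappa=kappa, band=_band(kappa), po=po, pe=pe)


@dataclass(frozen=True)
class ValidityReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str
    per_class: Mapping[str, dict]  # label -> precision/recall/f1/support


def prf_multiclass(pair: LabelVectorPair, averaging: str = "macro") -> ValidityReport:
    """Multi-class precision/recall/F1 from one-vs-rest counts, with
    ``labels_a`` as the reference.

    macro = unweighted mean over classes observed in either sequence;
    micro = pooled counts (for single-label classification micro precision,
    recall and F1 all equal accuracy).
    """
    if averaging not in ("macro", "micro"):
        raise ValueError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    cm = confusion_matrix(pair)
    m = cm.matrix
    n = cm.total
    tp = np.diag(m).astype(float)
    fn = m.sum(axis=1) - tp   # reference count minus hits
    fp = m.sum(axis=0) - tp
    per_class = {}
    for i, lab in enumerate(cm.labels):
        p = tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] > 0 else 0.0
        r = tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        per_class[lab] = {"precision": p, "recall": r, "f1": f,
                          "support": int(tp[i] + fn[i])}
    accuracy = float(tp.sum()) / n
    if averaging == "macro":
        vals = list(per_class.values())
        precision = float(np.mean([v["precision"] for v in vals]))
        recall = float(np.mean([v["recall"] for v in vals]))
        f1 = float(np.mean([v["f1"] for v in vals]))
    else:
        tp_s, fp_s, fn_s = tp.sum(), fp.sum(), fn.sum()
        precision = tp_s / (tp_s + fp_s) if tp_s + fp_s > 0 else 0.0
        recall = tp_s / (tp_s + fn_s) if tp_s + fn_s > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
    return ValidityReport(accuracy=accuracy, precision=precision,
                          recall=recall, f1=f1, averaging=averaging,
                          per_class=per_class)


DEFAULT_THRESHOLDS = {"accuracy": 0.85, "recall": 0.80, "f1": 0.80}


def validity_gate(report: ValidityReport,
                  thresholds: Mapping[str, float] | None = None) -> dict[str, bool]:
    """Pass/fail flags: each metric passes iff it is >= its threshold."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    return {metric: getattr(report, metric) >= bound
            for metric, bound in th.items()}


def theme_mapping_agreement(map_a: Mapping[str, str],
                            map_b: Mapping[str, str]) -> AgreementReport:
    """Agreement between two topic→theme mappings: topics are the items,
    themes the labels; delegates to :func:`cohen_kappa`."""
    if set(map_a) != set(map_b):
        raise ValueError("the two mappings must cover the same topic set")
    topics = sorted(map_a, key=str)
    pair = LabelVectorPair.from_sequences(
        [map_a[t] for t in topics], [map_b[t] for t in topics],
        ids=[str(t) for t in topics])
    return cohen_kappa(pair)
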