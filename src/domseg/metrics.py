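"""Scoring predicted against ground-truth domain assignments.

* per-domain intersect-over-union with maximum-intersection one-to-one
  matching (Hungarian assignment) and true-domain-length weighting;
* boundary Matthews correlation with a +/- m residue tolerance (m = 20 by
  default) over the N-1 inter-residue junctions;
* domain-count mean absolute error with under/over tallies;
* best-of-two-ground-truths scoring (e.g. CATH vs ECOD), keeping whichever
  reference scores higher.

Residues labelled 0 (NDR) in the ground truth are excluded from IoU
entirely; residues the prediction leaves unassigned inside true domains
count against the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .structio import DomainMap

CORRECT_IOU_THRESH = 0.8  # a predicted domain is "correct" at IoU >= 0.8
DEFAULT_TOLERANCE = 20    # residues, for boundary matching


@dataclass
class MetricsReport:
    weighted_iou: float
    per_domain_iou: dict
    mcc: float
    tolerance: int
    ndom_pred: int
    ndom_true: int
    correct_domains: int

    def to_dict(self):
        return {
            "weighted_iou": self.weighted_iou,
            "per_domain_iou": {int(k): float(v) for k, v in self.per_domain_iou.items()},
            "mcc": self.mcc,
            "tolerance": self.tolerance,
            "ndom_pred": self.ndom_pred,
            "ndom_true": self.ndom_true,
            "correct_domains": self.correct_domains,
        }


def domain_iou(pred: DomainMap, truth: DomainMap):
    """Per-true-domain IoU and the domain-length-weighted average.

    True and predicted domains are matched one-to-one to maximise total
    residue intersection; each matched pair scores |A∩B|/|A∪B| over residue
    sets restricted to ground-truth domain residues; unmatched true domains
    score 0.  The weighted average weights each true domain by its length.
    """
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lengths differ")
    keep = truth.labels > 0
    if not keep.any():
        raise ValueError("no ground-truth domains")
    t = truth.labels[keep]
    p = pred.labels[keep]
    t_labels = sorted(set(t))
    p_labels = sorted(set(p[p > 0]))
    inter = np.zeros((len(t_labels), len(p_labels)))
    for i, tl in enumerate(t_labels):
        for j, pl in enumerate(p_labels):
            inter[i, j] = np.sum((t == tl) & (p == pl))
    per = {}
    if p_labels:
        rows, cols = linear_sum_assignment(-inter)
        matched = dict(zip(rows, cols))
    else:
        matched = {}
    for i, tl in enumerate(t_labels):
        size_t = np.sum(t == tl)
        j = matched.get(i)
        if j is None or inter[i, j] == 0:
            per[tl] = 0.0
        else:
            size_p = np.sum(p == p_labels[j])
            union = size_t + size_p - inter[i, j]
            per[tl] = float(inter[i, j] / union)
    sizes = np.array([np.sum(t == tl) for tl in t_labels], dtype=float)
    weighted = float(sum(per[tl] * s for tl, s in zip(t_labels, sizes)) / sizes.sum())
    return per, weighted


def _boundaries(labels: np.ndarray) -> np.ndarray:
    """Junction indices i where labels[i] != labels[i+1] (termini excluded)."""
    return np.flatnonzero(labels[:-1] != labels[1:])


def boundary_mcc(pred: DomainMap, truth: DomainMap, m: int = DEFAULT_TOLERANCE) -> float:
    """Matthews correlation of boundary placement with +/- m tolerance.

    Predicted boundaries are matched one-to-one to true boundaries greedily
    by increasing separation; a match within m residues is a true positive.
    True negatives are the remaining junctions among the N-1 candidates.
    """
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lengths differ")
    n_junctions = len(pred) - 1
    pb = _boundaries(pred.labels)
    tb = _boundaries(truth.labels)
    pairs = sorted(
        (abs(int(p) - int(t)), pi, ti)
        for pi, p in enumerate(pb) for ti, t in enumerate(tb)
        if abs(int(p) - int(t)) <= m
    )
    used_p, used_t = set(), set()
    tp = 0
    for _, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        tp += 1
    fp = len(pb) - tp
    fn = len(tb) - tp
    tn = n_junctions - tp - fp - fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom <= 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def ndom_errors(predictions, truths):
    """MAE of domain counts plus summed under- and over-prediction tallies."""
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    diffs = np.array([int(p) - int(t) for p, t in zip(predictions, truths)])
    mae = float(np.abs(diffs).mean())
    under = int(-diffs[diffs < 0].sum())
    over = int(diffs[diffs > 0].sum())
    return mae, under, over


def evaluate(pred: DomainMap, truth: DomainMap, m: int = DEFAULT_TOLERANCE) -> MetricsReport:
    per, weighted = domain_iou(pred, truth)
    return MetricsReport(
        weighted_iou=weighted,
        per_domain_iou=per,
        mcc=boundary_mcc(pred, truth, m=m),
        tolerance=m,
        ndom_pred=pred.ndom,
        ndom_true=truth.ndom,
        correct_domains=int(sum(v >= CORRECT_IOU_THRESH for v in per.values())),
    )


def best_of_ground_truths(pred: DomainMap, truthA: DomainMap, truthB: DomainMap,
                          m: int = DEFAULT_TOLERANCE) -> MetricsReport:
    """Score against both references and keep the higher weighted IoU (ties -> A)."""
    ra = evaluate(pred, truthA, m=m)
    rb = evaluate(pred, truthB, m=m)
    return ra if ra.weighted_iou >= rb.weighted_iou else rb


def corpus_weighted_iou(pairs) -> float:
    """Length-weighted IoU pooled over all true domains of many targets."""
    num = den = 0.0
    for pred, truth in pairs:
        per, _ = domain_iou(pred, truth)
        keep = truth.labels > 0
        t = truth.labels[keep]
        for tl, iou in per.items():
            size = float(np.sum(t == tl))
            num += size * iou
            den += size
    return num / den if den else 0.0
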