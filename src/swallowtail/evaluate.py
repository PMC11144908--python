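"""Patient-level decision rule and model evaluation statistics.

Every classifier in the pipeline scores individual axial images; a
subject contributes 4 images (one per ROI-bearing slice).  Diagnosis is
patient-wise: a subject is called PD when at least 3 of their 4 images
are classified PD.  All reported metrics are computed downstream of
that vote.

Model comparison uses the category-free (continuous) net
reclassification improvement and the integrated discrimination
improvement; segmentation agreement uses the Dice similarity
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PatientPrediction",
    "EvalReport",
    "vote_patient",
    "patient_predictions",
    "confusion_metrics",
    "roc_auc",
    "nri",
    "idi",
    "dice",
]

VOTE_THRESHOLD = 3  # of 4 images


@dataclass
class PatientPrediction:
    case_id: str
    image_probs: np.ndarray  # 4 probabilities of PD
    image_labels: np.ndarray  # 4 binary image calls

    def __post_init__(self) -> None:
        self.image_probs = np.asarray(self.image_probs, dtype=float)
        self.image_labels = np.asarray(self.image_labels, dtype=int)

    @property
    def patient_label(self) -> int:
        return vote_patient(self.image_labels)

    @property
    def patient_prob(self) -> float:
        return float(self.image_probs.mean())


@dataclass
class EvalReport:
    acc: float
    sen: float
    spe: float
    ppv: float
    npv: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        out = {
            "ACC": self.acc, "SEN": self.sen, "SPE": self.spe,
            "PPV": self.ppv, "NPV": self.npv, "F1": self.f1,
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
        }
        if self.auc is not None:
            out["AUC"] = self.auc
            out["AUC_CI"] = list(self.auc_ci) if self.auc_ci else None
        return out


def vote_patient(image_labels) -> int:
    """Patient call from 4 image calls: PD (1) iff at least 3 are PD."""
    labels = np.asarray(image_labels, dtype=int)
    if labels.shape != (4,):
        raise ValueError(f"expected exactly 4 image labels, got shape {labels.shape}")
    return int(labels.sum() >= VOTE_THRESHOLD)


def patient_predictions(case_ids, image_probs, threshold: float = 0.5):
    """Group per-image probabilities (n, 4) into PatientPrediction objects."""
    probs = np.asarray(image_probs, dtype=float)
    return [
        PatientPrediction(cid, p, (p >= threshold).astype(int))
        for cid, p in zip(case_ids, probs)
    ]


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def confusion_metrics(pred, truth) -> EvalReport:
    """ACC/SEN/SPE/PPV/NPV/F1 from binary predictions against truth."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != truth.shape:
        raise ValueError("pred/truth length mismatch")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    sen = _safe_div(tp, tp + fn)
    ppv = _safe_div(tp, tp + fp)
    return EvalReport(
        acc=(tp + tn) / pred.size,
        sen=sen,
        spe=_safe_div(tn, tn + fp),
        ppv=ppv,
        npv=_safe_div(tn, tn + fn),
        f1=_safe_div(2 * ppv * sen, ppv + sen),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def roc_auc(
    scores,
    truth,
    n_boot: int = 2000,
    seed: int = 0,
    ci: bool = True,
) -> tuple[float, tuple[float, float] | None]:
    """AUC via the rank (Mann-Whitney) formulation with a bootstrap CI.

    Ties in the scores contribute 1/2 per tied case-control pair.  The
    confidence interval is a stratified percentile bootstrap (resampling
    cases and controls separately), 95% by convention.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present for ROC analysis")

    def _auc(s, y):
        ranks = stats.rankdata(s)
        n1 = int(np.sum(y == 1))
        n0 = y.size - n1
        return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    value = float(_auc(scores, truth))
    if not ci:
        return value, None
    rng = np.random.default_rng(seed)
    pos = np.nonzero(truth == 1)[0]
    neg = np.nonzero(truth == 0)[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        boots[b] = _auc(scores[idx], truth[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return value, (float(lo), float(hi))


def _updown(p_old, p_new):
    return (p_new > p_old).astype(float), (p_new < p_old).astype(float)


def nri(p_old, p_new, truth) -> tuple[float, float]:
    """Continuous (category-free) net reclassification improvement.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)],
    where "up" means the new model assigns a strictly higher probability.
    Exact ties count as neither direction.  Returns (NRI, p-value) with
    an asymptotic normal test; all-ties input gives (0, 1).
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present")
    up, down = _updown(p_old, p_new)
    ev, ne = truth == 1, truth == 0
    if not np.any(up + down):
        return 0.0, 1.0
    pu_e, pd_e = up[ev].mean(), down[ev].mean()
    pu_n, pd_n = up[ne].mean(), down[ne].mean()
    value = (pu_e - pd_e) + (pd_n - pu_n)
    var = (
        (pu_e + pd_e - (pu_e - pd_e) ** 2) / ev.sum()
        + (pu_n + pd_n - (pu_n - pd_n) ** 2) / ne.sum()
    )
    if var <= 0:
        return float(value), 1.0 if value == 0 else 0.0
    z = value / np.sqrt(var)
    return float(value), float(2 * stats.norm.sf(abs(z)))


def idi(p_old, p_new, truth) -> tuple[float, float]:
    """Integrated discrimination improvement.

    IDI = [mean(p_new|event) - mean(p_old|event)]
        - [mean(p_new|nonevent) - mean(p_old|nonevent)],
    i.e. the change in the discrimination slope.  The p-value is a
    Welch t-test comparing the paired differences d = p_new - p_old
    between events and nonevents.
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present")
    d = p_new - p_old
    d_e, d_n = d[truth == 1], d[truth == 0]
    value = float(d_e.mean() - d_n.mean())
    if np.allclose(d, 0):
        return 0.0, 1.0
    tstat = stats.ttest_ind(d_e, d_n, equal_var=False)
    return value, float(tstat.pvalue)


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1.0 if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / total
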