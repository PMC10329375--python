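"""Diagnostic-test performance and method-agreement statistics.

Implements the standard 2x2 diagnostic metrics (sensitivity, specificity,
predictive values, likelihood ratios, accuracy, Youden index), Bland-Altman
limits of agreement with Spearman correlation, cohort-level scoring of a
detector against ground truth, and an exhaustive reconstruction of a
confusion matrix from its printed (rounded) metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .detect import AOPResult

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "AgreementReport",
    "CaseTruth",
    "compute_metrics",
    "bland_altman",
    "evaluate_detector",
    "reconstruct_confusion",
]


def _round_half_up(x: float, ndigits: int = 0) -> float:
    factor = 10.0 ** ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 detection counts: true/false positives and negatives."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Diagnostic-performance record; fractions in [0, 1], NaN if undefined.

    ``display()`` renders the clinical convention: percentages rounded
    half-up to integers, likelihood ratios and the Youden index to two
    decimals.
    """

    sens: float
    spec: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    accuracy: float
    youden: float

    def display(self) -> Dict[str, float]:
        def pct(x: float) -> float:
            return float("nan") if math.isnan(x) else _round_half_up(100.0 * x)

        def two(x: float) -> float:
            return float("nan") if math.isnan(x) else _round_half_up(x, 2)

        return {
            "sens": pct(self.sens), "spec": pct(self.spec),
            "ppv": pct(self.ppv), "npv": pct(self.npv),
            "lr_pos": two(self.lr_pos), "lr_neg": two(self.lr_neg),
            "accuracy": pct(self.accuracy), "youden": two(self.youden),
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Standard formulas on a 2x2 table; undefined metrics come back NaN."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    lr_pos = _ratio(sens, 1.0 - spec) if not math.isnan(sens) and not math.isnan(spec) \
        else float("nan")
    lr_neg = _ratio(1.0 - sens, spec) if not math.isnan(sens) and not math.isnan(spec) \
        else float("nan")
    accuracy = (cm.tp + cm.tn) / cm.total
    youden = sens + spec - 1.0
    return DiagnosticMetrics(sens=sens, spec=spec, ppv=ppv, npv=npv,
                             lr_pos=lr_pos, lr_neg=lr_neg,
                             accuracy=accuracy, youden=youden)


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman agreement summary for paired measurements.

    ``bias`` is the mean of the differences taken with the stated
    ``convention`` (e.g. ``"a-b"``); the 95% limits of agreement are
    ``bias +/- 1.96 * sd`` with the sample (n-1) standard deviation.
    """

    bias: float
    loa_low: float
    loa_high: float
    spearman_r: float
    n: int
    convention: str = "a-b"

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


def bland_altman(a: Sequence[float], b: Sequence[float],
                 convention: str = "a-b") -> AgreementReport:
    """Bland-Altman agreement of paired values, differences ``a - b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        rho = float("nan")  # correlation undefined for a constant vector
    else:
        rho = float(stats.spearmanr(a, b).statistic)
    return AgreementReport(bias=bias, loa_low=bias - 1.96 * sd,
                           loa_high=bias + 1.96 * sd, spearman_r=rho,
                           n=int(n), convention=convention)


@dataclass(frozen=True)
class CaseTruth:
    """Ground truth for one cohort case."""

    case_id: str
    closure: bool
    aop: Optional[float] = None
    rrs: Optional[float] = None
    crs: Optional[float] = None


def evaluate_detector(truths: Mapping[str, CaseTruth],
                      calls: Mapping[str, AOPResult],
                      ) -> Tuple[ConfusionMatrix, Optional[AgreementReport]]:
    """Score per-case detector calls against ground truth.

    Closure detection is scored into a confusion matrix over all cases; AOP
    agreement (Bland-Altman, difference = reference minus detected) is
    computed over the cases positive by both truth and detector, and is
    ``None`` when fewer than two such cases exist.
    """
    missing = sorted(set(truths) ^ set(calls))
    if missing:
        raise ValueError(f"case identifiers do not match; unmatched: {missing}")
    tp = fn = fp = tn = 0
    ref_aop: List[float] = []
    det_aop: List[float] = []
    for cid, truth in truths.items():
        call = calls[cid]
        if truth.closure and call.closure_detected:
            tp += 1
            ref_aop.append(float(truth.aop))
            det_aop.append(float(call.aop))
        elif truth.closure:
            fn += 1
        elif call.closure_detected:
            fp += 1
        else:
            tn += 1
    cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
    agreement = None
    if len(ref_aop) >= 2:
        agreement = bland_altman(ref_aop, det_aop,
                                 convention="reference-minus-detected")
    return cm, agreement


def reconstruct_confusion(n_total: int, n_positive: int,
                          reported: Mapping[str, float]) -> List[ConfusionMatrix]:
    """Recover 2x2 tables consistent with printed (rounded) metrics.

    Enumerates every integer table with the stated margins (``n_positive``
    condition-positive cases out of ``n_total``) and keeps those whose
    metrics, rendered at the clinical display rounding (integer percents,
    two-decimal ratios), match all entries of ``reported``.  An empty list
    signals inconsistent inputs.
    """
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    n_negative = n_total - n_positive
    matches: List[ConfusionMatrix] = []
    for tp in range(n_positive + 1):
        for tn in range(n_negative + 1):
            cm = ConfusionMatrix(tp=tp, fn=n_positive - tp,
                                 fp=n_negative - tn, tn=tn)
            disp = compute_metrics(cm).display()
            ok = True
            for key, want in reported.items():
                got = disp[key]
                if math.isnan(got) or abs(got - float(want)) > 1e-9:
                    ok = False
                    break
            if ok:
                matches.append(cm)
    return matches
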