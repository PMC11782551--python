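"""Diagnostic-validation statistics for paired IMR measurements.

Implements the validation layer of a wire-free IMR method against the
wire-based reference: confusion-matrix diagnostics with Wald 95% CIs,
Bland–Altman agreement, Spearman correlation, ROC/AUC with a DeLong CI,
observer-reproducibility summaries, and an exhaustive reconstruction of a
confusion matrix from printed summary percentages (useful for auditing
published diagnostic tables).

Percentages are rounded half-up to one decimal, matching how clinical tables
are typically printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (so 0.25 -> 0.3 at one decimal), not banker's."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricCI:
    """A proportion metric in %, with its Wald 95% CI, or undefined."""

    pct: float | None
    ci_low: float | None
    ci_high: float | None
    n: int
    defined: bool


@dataclass(frozen=True)
class DiagnosticReport:
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI
    accuracy: MetricCI
    n: int


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman summary; differences are reference - test."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def confusion_matrix(test, reference, threshold: float = 25.0) -> ConfusionMatrix:
    """Cross-classify two measurement series at a shared positivity threshold.

    A value is positive iff >= threshold (boundary inclusive) in both series;
    the reference series defines disease status.
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape or test.ndim != 1 or test.size < 1:
        raise ValueError("test and reference must be equal-length 1D series")
    tpos = test >= threshold
    rpos = reference >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(tpos & rpos)),
        fp=int(np.sum(tpos & ~rpos)),
        fn=int(np.sum(~tpos & rpos)),
        tn=int(np.sum(~tpos & ~rpos)),
    )


def _wald_metric(numer: int, denom: int) -> MetricCI:
    if denom == 0:
        return MetricCI(None, None, None, 0, False)
    p = numer / denom
    half = 1.96 * np.sqrt(p * (1.0 - p) / denom)
    return MetricCI(
        pct=round_half_up(100.0 * p),
        ci_low=round_half_up(max(0.0, 100.0 * (p - half))),
        ci_high=round_half_up(min(100.0, 100.0 * (p + half))),
        n=denom,
        defined=True,
    )


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticReport:
    """Sensitivity/specificity/PPV/NPV/accuracy with Wald 95% CIs.

    Each metric uses its own denominator for the normal-approximation CI,
    clipped to [0, 100] and rounded half-up to one decimal.  A metric with a
    zero denominator is flagged undefined rather than raising.
    """
    return DiagnosticReport(
        sensitivity=_wald_metric(cm.tp, cm.tp + cm.fn),
        specificity=_wald_metric(cm.tn, cm.tn + cm.fp),
        ppv=_wald_metric(cm.tp, cm.tp + cm.fp),
        npv=_wald_metric(cm.tn, cm.tn + cm.fn),
        accuracy=_wald_metric(cm.tp + cm.tn, cm.total),
        n=cm.total,
    )


def reconstruct_confusion_from_summary(
    n: int, sens_pct: float, spec_pct: float, acc_pct: float
) -> list[ConfusionMatrix]:
    """All integer confusion matrices of size n matching printed summaries.

    Exhaustive search over matrices whose sensitivity, specificity and
    accuracy — rounded half-up to one decimal, in % — equal the given values.
    Returns every solution (callers can check uniqueness); raises if none
    exists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")

    def matches(numer: np.ndarray, denom: int, target: float) -> np.ndarray:
        pct = 100.0 * numer / denom
        return np.array([round_half_up(v) == target for v in pct])

    solutions: list[ConfusionMatrix] = []
    for pos in range(1, n):  # need both classes for sens and spec to be defined
        neg = n - pos
        tps = np.arange(pos + 1)
        tns = np.arange(neg + 1)
        ok_tp = tps[matches(tps, pos, sens_pct)]
        if ok_tp.size == 0:
            continue
        ok_tn = tns[matches(tns, neg, spec_pct)]
        if ok_tn.size == 0:
            continue
        for tp in ok_tp:
            for tn in ok_tn:
                if round_half_up(100.0 * (tp + tn) / n) == acc_pct:
                    solutions.append(
                        ConfusionMatrix(
                            tp=int(tp), fp=int(neg - tn), fn=int(pos - tp), tn=int(tn)
                        )
                    )
    if not solutions:
        raise ValueError(
            f"no confusion matrix of size {n} reproduces "
            f"sens={sens_pct}, spec={spec_pct}, acc={acc_pct}"
        )
    return solutions


def bland_altman(test, reference) -> AgreementStats:
    """Bland–Altman agreement of paired series.

    Differences are reference - test (a positive mean difference means the
    test method underestimates the reference).  SD uses n-1; limits of
    agreement are mean +/- 1.96 SD.
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape or test.size < 2:
        raise ValueError("need at least 2 equal-length pairs")
    d = reference - test
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementStats(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=d.size,
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    p_value: float | None
    defined: bool


def spearman_correlation(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 equal-length pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(None, None, False)
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(float(r), float(p), True)


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> RocResult:
    """AUC by the Mann–Whitney statistic (ties count half), DeLong 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    # DeLong structural components via placement values
    v_pos = np.empty(pos.size)
    v_neg = np.empty(neg.size)
    for i, s in enumerate(pos):
        v_pos[i] = (np.sum(s > neg) + 0.5 * np.sum(s == neg)) / neg.size
    for j, s in enumerate(neg):
        v_neg[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / pos.size
    auc = float(np.mean(v_pos))
    s10 = float(np.var(v_pos, ddof=1)) if pos.size > 1 else 0.0
    s01 = float(np.var(v_neg, ddof=1)) if neg.size > 1 else 0.0
    se = float(np.sqrt(s10 / pos.size + s01 / neg.size))
    return RocResult(
        auc=auc,
        ci_low=max(0.0, auc - 1.96 * se),
        ci_high=min(1.0, auc + 1.96 * se),
        se=se,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


@dataclass(frozen=True)
class ReproducibilityReport:
    r: float
    p_paired_t: float
    agreement: AgreementStats


def reproducibility_report(series_a, series_b) -> ReproducibilityReport:
    """Observer agreement: Pearson r, two-sided paired t-test, Bland–Altman.

    Identical series give r = 1 and, by convention, a paired-t p of 1.0
    (the t statistic is 0/0 there).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need at least 3 equal-length pairs")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        r = 1.0 if np.allclose(a, b) else float("nan")
    else:
        r = float(stats.pearsonr(a, b)[0])
    t = stats.ttest_rel(a, b)
    p = float(t.pvalue)
    if np.isnan(p):  # zero-variance differences: no evidence of a shift
        p = 1.0
    return ReproducibilityReport(r=r, p_paired_t=p, agreement=bland_altman(b, a))


def two_proportion_z(successes_a: int, n_a: int, successes_b: int, n_b: int) -> tuple[float, float]:
    """Two-sided two-proportion z-test (pooled), for subgroup-accuracy contrasts."""
    if min(n_a, n_b) < 1:
        raise ValueError("group sizes must be >= 1")
    p_pool = (successes_a + successes_b) / (n_a + n_b)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n_a + 1 / n_b))
    if se == 0:
        return 0.0, 1.0
    z = (successes_a / n_a - successes_b / n_b) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))
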