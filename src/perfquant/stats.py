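"""Agreement, group-comparison, and diagnostic-accuracy statistics.

ROC areas use the Mann-Whitney concordance (ties count one half), with
standard errors and paired AUC comparisons from the DeLong structural
components.  Operating thresholds are chosen by the Youden index over
midpoints of adjacent sorted unique marker values, with ties broken
toward the threshold balancing sensitivity and specificity and then
toward higher specificity.  Disease direction is always explicit: every
perfusion metric here is lower-is-positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_model_io import DegenerateInputError, ParameterError

__all__ = [
    "RocResult",
    "ThresholdResult",
    "AgreementResult",
    "pearson_r",
    "bland_altman",
    "mann_whitney",
    "roc",
    "delong_test",
    "youden_threshold",
    "mcnemar",
    "evaluate_cohort",
    "proportion_percent",
    "accuracy_from_rates",
]

LOWER = "lower-is-positive"
HIGHER = "higher-is-positive"


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    direction: str
    # oriented scores/labels retained for paired DeLong comparisons
    _scores: np.ndarray = None  # type: ignore[assignment]
    _labels: np.ndarray = None  # type: ignore[assignment]


@dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    youden_j: float  # sens + spec - 1, as a fraction


@dataclass
class AgreementResult:
    pearson_r: float
    bias: float
    loa: tuple[float, float]
    bias_p: float


# ---------------------------------------------------------------------------
# agreement / group comparison
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ParameterError("pearson_r needs paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("pearson_r requires finite input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


def bland_altman(auto, manual) -> AgreementResult:
    """Bland-Altman agreement of paired measurements (auto - manual)."""
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.size < 3:
        raise ParameterError("bland_altman needs paired samples with n >= 3")
    d = auto - manual
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if sd == 0:
        p = 1.0 if bias == 0 else 0.0
    else:
        p = float(sps.ttest_1samp(d, 0.0).pvalue)
    try:
        r = pearson_r(auto, manual)
    except DegenerateInputError:
        r = float("nan")
    return AgreementResult(pearson_r=r, bias=bias, loa=loa, bias_p=p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Rank-sum test; exact p for min(n1, n2) <= 8 with no ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _oriented(values, labels, direction):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if values.shape != labels.shape:
        raise ParameterError("values and labels must align")
    if labels.all() or not labels.any():
        raise ParameterError("both classes must be present")
    if direction not in (LOWER, HIGHER):
        raise ParameterError(f"unknown direction {direction!r}")
    scores = -values if direction == LOWER else values.copy()
    return scores, labels


def _structural_components(scores, labels):
    """DeLong V10 (per positive) and V01 (per negative) components."""
    pos = scores[labels]
    neg = scores[~labels]
    # psi(x, y): 1 if x > y, 0.5 if tied, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


def roc(values, labels, direction: str = LOWER) -> RocResult:
    """ROC curve with Mann-Whitney AUC and DeLong standard error.

    ``labels`` are truthy for disease; ``direction`` states whether low
    or high marker values indicate disease.
    """
    scores, lab = _oriented(values, labels, direction)
    v10, v01 = _structural_components(scores, lab)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    # curve points over all score thresholds (classify positive if score >= thr)
    thr = np.unique(scores)[::-1]
    sens = np.array([(scores[lab] >= t).mean() for t in thr])
    spec = np.array([(scores[~lab] < t).mean() for t in thr])
    # anchor the curve at (0,0) and (1,1) in (1-spec, sens) space
    sens = np.concatenate([[0.0], sens, [1.0]])
    spec = np.concatenate([[1.0], spec, [0.0]])
    thresholds = np.concatenate([[np.inf], thr, [-np.inf]])
    if direction == LOWER:
        thresholds = -thresholds
    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_se=se,
        ci95=ci,
        direction=direction,
        _scores=scores,
        _labels=lab,
    )


def _delong_se_diff(roc1: RocResult, roc2: RocResult) -> float:
    """Standard error of AUC1 - AUC2 from paired structural components."""
    if roc1._labels is None or roc2._labels is None:
        raise ParameterError("RocResult objects must come from roc()")
    if roc1._labels.shape != roc2._labels.shape or np.any(roc1._labels != roc2._labels):
        raise ParameterError("paired comparison requires identical subjects and labels")
    v10_1, v01_1 = _structural_components(roc1._scores, roc1._labels)
    v10_2, v01_2 = _structural_components(roc2._scores, roc2._labels)
    m, n = v10_1.size, v01_1.size
    d10 = v10_1 - v10_2
    d01 = v01_1 - v01_2
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    return float(np.sqrt(max(var, 0.0)))


def delong_test(roc1: RocResult, roc2: RocResult) -> float:
    """Two-sided p for a paired difference of correlated AUCs."""
    se = _delong_se_diff(roc1, roc2)
    diff = roc1.auc - roc2.auc
    if se <= 0:
        if diff == 0:
            return 1.0
        raise DegenerateInputError("zero variance of AUC difference")
    z = diff / se
    return float(2.0 * sps.norm.sf(abs(z)))


def youden_threshold(roc_result: RocResult, values, labels) -> ThresholdResult:
    """Operating point maximizing the Youden index.

    Candidate thresholds are midpoints of adjacent sorted unique marker
    values.  Ties on J are broken by smaller |sens - spec|, then by
    higher specificity.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    lower = roc_result.direction == LOWER
    uniq = np.unique(values)
    if uniq.size >= 2:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    else:
        candidates = uniq

    best = None
    npos = int(labels.sum())
    nneg = int((~labels).sum())
    for thr in candidates:
        pred = values <= thr if lower else values >= thr
        sens = float((pred & labels).sum() / npos)
        spec = float((~pred & ~labels).sum() / nneg)
        j = sens + spec - 1.0
        key = (-j, abs(sens - spec), -spec)
        if best is None or key < best[0]:
            acc = ((pred & labels).sum() + (~pred & ~labels).sum()) / labels.size
            best = (key, thr, sens, spec, acc, j)
    _, thr, sens, spec, acc, j = best
    return ThresholdResult(
        threshold=float(thr),
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        accuracy=100.0 * acc,
        youden_j=float(j),
    )


def mcnemar(b: int, c: int) -> float:
    """Two-sided McNemar p from the discordant-pair counts.

    Exact binomial for b + c < 25, continuity-corrected chi-square
    otherwise; b + c = 0 returns 1 by convention.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise ParameterError("b and c must be nonnegative integers")
    b, c = int(b), int(c)
    n = b + c
    if n == 0:
        return 1.0
    if n < 25:
        return float(sps.binomtest(b, n, 0.5, alternative="two-sided").pvalue)
    stat = (abs(b - c) - 1) ** 2 / n
    return float(sps.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------

def evaluate_cohort(summaries: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Diagnostic-accuracy report over a cohort of summary values.

    Parameters
    ----------
    summaries : DataFrame with columns (unit_id, level, metric, value)
        One minimum summary value per metric per unit; ``level`` is
        "patient" or "vessel".
    truth : DataFrame with columns (unit_id, level, label)
        Binary disease truth per unit.

    Returns a dict with a Table-3-shaped ``table`` (AUC, CI, threshold,
    sensitivity, specificity, accuracy per metric and level), plus
    pairwise ``delong``, ``mcnemar_sensitivity`` and
    ``mcnemar_specificity`` frames.  All metrics are lower-is-positive.
    """
    required = {"unit_id", "level", "metric", "value"}
    if not required.issubset(summaries.columns):
        raise ParameterError(f"summaries needs columns {sorted(required)}")
    rows, delong_rows, mcn_sens_rows, mcn_spec_rows = [], [], [], []
    for level in summaries["level"].unique():
        t_level = truth[truth["level"] == level].set_index("unit_id")["label"]
        per_metric: dict[str, tuple] = {}
        for metric in summaries.loc[summaries["level"] == level, "metric"].unique():
            sub = summaries[(summaries["level"] == level) & (summaries["metric"] == metric)]
            sub = sub.set_index("unit_id").join(t_level.rename("label"), how="inner")
            vals = sub["value"].to_numpy(dtype=float)
            labs = sub["label"].to_numpy().astype(bool)
            rr = roc(vals, labs, LOWER)
            th = youden_threshold(rr, vals, labs)
            per_metric[metric] = (rr, th, vals, labs)
            rows.append(
                {
                    "level": level,
                    "metric": metric,
                    "auc": rr.auc,
                    "ci_lo": rr.ci95[0],
                    "ci_hi": rr.ci95[1],
                    "threshold": th.threshold,
                    "sensitivity": th.sensitivity,
                    "specificity": th.specificity,
                    "accuracy": th.accuracy,
                }
            )
        for ma, mb in combinations(per_metric, 2):
            ra, tha, va, la = per_metric[ma]
            rb, thb, vb, lb = per_metric[mb]
            try:
                p = delong_test(ra, rb)
            except DegenerateInputError:
                p = float("nan")
            delong_rows.append({"level": level, "metric_a": ma, "metric_b": mb, "p": p})
            pred_a = va <= tha.threshold
            pred_b = vb <= thb.threshold
            for rows_out, sel in ((mcn_sens_rows, la), (mcn_spec_rows, ~la)):
                ok_a = pred_a[sel] == la[sel]
                ok_b = pred_b[sel] == lb[sel]
                b_cnt = int((ok_a & ~ok_b).sum())
                c_cnt = int((~ok_a & ok_b).sum())
                rows_out.append(
                    {
                        "level": level,
                        "metric_a": ma,
                        "metric_b": mb,
                        "p": mcnemar(b_cnt, c_cnt),
                    }
                )
    return {
        "table": pd.DataFrame(rows),
        "delong": pd.DataFrame(delong_rows),
        "mcnemar_sensitivity": pd.DataFrame(mcn_sens_rows),
        "mcnemar_specificity": pd.DataFrame(mcn_spec_rows),
    }


# ---------------------------------------------------------------------------
# cohort bookkeeping helpers
# ---------------------------------------------------------------------------

def _round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero, the convention of published tables.

    Python's built-in ``round`` rounds half to even (91.25 -> 91.2),
    which does not match how clinical tables are typeset.
    """
    factor = 10.0**decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


def proportion_percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100 * numerator / denominator rounded (half-up) to ``decimals`` places."""
    if denominator <= 0:
        raise ParameterError("denominator must be positive")
    return _round_half_up(100.0 * numerator / denominator, decimals)


def accuracy_from_rates(
    sensitivity_pct: float, specificity_pct: float, n_pos: int, n_neg: int, decimals: int = 1
) -> float:
    """Overall accuracy implied by stated sensitivity/specificity.

    True-positive and true-negative counts are rounded to whole units
    before combining, matching how published rates back out of integer
    confusion tables.
    """
    tp = _round_half_up(sensitivity_pct / 100.0 * n_pos)
    tn = _round_half_up(specificity_pct / 100.0 * n_neg)
    return _round_half_up(100.0 * (tp + tn) / (n_pos + n_neg), decimals)
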