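"""Cohort-level statistics: outcome labelling, ROC/Youden, group tests, agreement.

Conventions used throughout (documented once, here):

* Pseudoprogression (PsP) is the positive class, and lower %rCBV>2
  indicates positivity — treated lesions that later regress are the
  hypo-vascularized ones.
* Reported cutoffs are midpoints between adjacent distinct pooled score
  values; a case is called positive when its score is strictly below the
  cutoff (under the lower-is-positive orientation).
* All tests are two-sided at alpha = 0.05.
* Group summaries are median [Q1-Q3] with Moore-McCabe quartiles
  (median-exclusive halves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.integrate import cumulative_trapezoid  # noqa: F401  (re-export site)

__all__ = [
    "PSP",
    "TP",
    "OutcomeLabel",
    "RocResult",
    "CutoffResult",
    "AgreementStats",
    "LogisticFit",
    "median_iqr",
    "classify_outcome",
    "roc_analysis",
    "youden_cutoff",
    "threshold_sweep",
    "logistic_model",
    "hosmer_lemeshow",
    "mann_whitney",
    "fisher_exact",
    "spearman_rho",
    "bland_altman",
    "icc_consistency",
    "cohen_kappa",
    "method_agreement",
]

PSP = "PsP"
TP = "TP"


# ---------------------------------------------------------------------------
# outcome labelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeLabel:
    value: str  # PSP or TP
    basis: str  # imaging_followup, histopathology, clinical_decline


def classify_outcome(
    enhancing_volume_postop: float,
    v_crt1: float,
    v_crt3: float,
    new_lesion_outside_field: bool = False,
    clinical_decline: bool = False,
    progression_threshold: float = 0.25,
    regression_threshold: float = 0.50,
) -> OutcomeLabel:
    """Label a case as true progression or pseudoprogression.

    Inclusion requires enhancing-lesion progression between the
    postoperative scan and the first follow-up (CRT+1). True progression:
    a new lesion outside the radiation field, rapid clinical decline, or
    a >= 25% further increase at CRT+3. Otherwise pseudoprogression:
    >= 50% regression, or stabilisation (any change below both bounds).
    TP criteria take precedence.
    """
    if min(enhancing_volume_postop, v_crt1, v_crt3) < 0:
        raise ValueError("volumes must be non-negative")
    if not v_crt1 > enhancing_volume_postop:
        raise ValueError(
            "inclusion requires progression at CRT+1 "
            f"(v_crt1={v_crt1} <= postop={enhancing_volume_postop})"
        )
    if clinical_decline:
        return OutcomeLabel(TP, "clinical_decline")
    if new_lesion_outside_field:
        return OutcomeLabel(TP, "imaging_followup")
    change = (v_crt3 - v_crt1) / v_crt1
    if change >= progression_threshold:
        return OutcomeLabel(TP, "imaging_followup")
    return OutcomeLabel(PSP, "imaging_followup")


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with Moore-McCabe quartiles.

    Q1/Q3 are medians of the lower/upper halves, excluding the overall
    median itself when n is odd.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 values for quartiles")
    med = float(np.median(v))
    half = n // 2
    return med, float(np.median(v[:half])), float(np.median(v[n - half:]))


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray  # ascending, in score units
    sensitivity: np.ndarray  # per threshold
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    lower_is_positive: bool


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _binary_labels(labels, pos_label) -> np.ndarray:
    y = np.asarray(labels)
    pos = y == pos_label
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present")
    return pos


def _sens_spec_at(scores, pos, cutoff, lower_is_positive):
    called = scores < cutoff if lower_is_positive else scores > cutoff
    sens = called[pos].mean()
    spec = (~called[~pos]).mean()
    return float(sens), float(spec)


def _auc_trapezoid(scores: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Empirical ROC over all distinct cutoffs; trapezoid AUC.

    ``scores`` must already be oriented so that higher indicates
    positive. Ties between classes contribute half via the trapezoid
    over the tied step.
    """
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tp = np.cumsum(p)[distinct]
    fp = np.cumsum(~p)[distinct]
    tpr = np.r_[0.0, tp / p.sum()]
    fpr = np.r_[0.0, fp / (~p).sum()]
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.r_[np.inf, s[distinct]]
    return thresholds, tpr, fpr, auc


def roc_analysis(
    scores,
    labels,
    pos_label=PSP,
    lower_is_positive: bool = True,
    n_boot: int = 2000,
    ci_seed: int = 0,
) -> RocResult:
    """Empirical ROC with trapezoid AUC and a stratified bootstrap CI.

    The AUC equals the pairwise concordance statistic (probability that
    a random positive scores on the positive side of a random negative,
    ties counting one half). The 95% CI is a percentile interval over
    ``n_boot`` class-stratified resamples.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = _binary_labels(labels, pos_label)
    oriented = -scores if lower_is_positive else scores
    thresholds, tpr, fpr, auc = _auc_trapezoid(oriented, pos)

    rng = np.random.default_rng(ci_seed)
    pos_scores, neg_scores = oriented[pos], oriented[~pos]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos_scores, size=pos_scores.size, replace=True)
        ns = rng.choice(neg_scores, size=neg_scores.size, replace=True)
        bs = np.concatenate([ps, ns])
        bp = np.zeros(bs.size, dtype=bool)
        bp[: ps.size] = True
        aucs[b] = _auc_trapezoid(bs, bp)[3]
    ci_low, ci_high = np.percentile(aucs, [2.5, 97.5])

    # report thresholds on the original score scale, ascending
    thr = -thresholds[::-1] if lower_is_positive else thresholds[::-1]
    sens = tpr[::-1]
    spec = (1.0 - fpr)[::-1]
    return RocResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_pos=int(pos.sum()),
        n_neg=int((~pos).sum()),
        lower_is_positive=lower_is_positive,
    )


def youden_cutoff(
    scores,
    labels,
    pos_label=PSP,
    lower_is_positive: bool = True,
) -> CutoffResult:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between adjacent distinct pooled
    values, plus one extreme on each side. Ties in J break toward higher
    sensitivity, then toward the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _binary_labels(labels, pos_label)
    v = np.unique(scores)
    span = v[-1] - v[0] if v.size > 1 else 1.0
    candidates = np.r_[v[0] - 0.5 * span - 1.0,
                       (v[:-1] + v[1:]) / 2.0,
                       v[-1] + 0.5 * span + 1.0]
    best: CutoffResult | None = None
    for c in candidates:
        sens, spec = _sens_spec_at(scores, pos, c, lower_is_positive)
        cand = CutoffResult(float(c), sens, spec)
        if (
            best is None
            or cand.youden_j > best.youden_j + 1e-12
            or (
                abs(cand.youden_j - best.youden_j) <= 1e-12
                and (cand.sensitivity, -cand.cutoff)
                > (best.sensitivity, -best.cutoff)
            )
        ):
            best = cand
    assert best is not None
    return best


def threshold_sweep(
    pct_maps: list[dict[float, float]],
    labels,
    pos_label=PSP,
    lower_is_positive: bool = True,
    n_boot: int = 2000,
    ci_seed: int = 0,
) -> pd.DataFrame:
    """One ROC per tested threshold x; flags the AUC-maximizing row."""
    keys = sorted(pct_maps[0])
    for m in pct_maps:
        missing = [x for x in keys if x not in m]
        if missing or len(m) != len(keys):
            raise KeyError(f"records disagree on threshold keys (missing {missing})")
    rows = []
    for x in keys:
        scores = np.array([m[x] for m in pct_maps], dtype=float)
        roc = roc_analysis(scores, labels, pos_label, lower_is_positive,
                           n_boot=n_boot, ci_seed=ci_seed)
        cut = youden_cutoff(scores, labels, pos_label, lower_is_positive)
        rows.append(
            {
                "x": x,
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "cutoff": cut.cutoff,
                "sensitivity": cut.sensitivity,
                "specificity": cut.specificity,
                "youden_j": cut.youden_j,
            }
        )
    df = pd.DataFrame(rows)
    df["is_best"] = df["auc"] == df["auc"].max()
    return df


# ---------------------------------------------------------------------------
# logistic model and calibration
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    intercept: float
    slope: float
    fitted: np.ndarray
    converged: bool
    n_iter: int
    log_likelihood: float


def logistic_model(x, y, tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Univariate logistic regression by iteratively reweighted least squares.

    Complete separation is detected (diverging coefficients or perfect
    fitted probabilities) and reported as non-converged rather than an
    error: the coefficients are then the last iterate, not an MLE.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    if not set(np.unique(y)) <= {0.0, 1.0} or len(np.unique(y)) < 2:
        raise ValueError("y must be binary with both classes present")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        if w.max() < 1e-12 or np.linalg.norm(beta) > 1e6:
            break  # separation: weights vanish / coefficients diverge
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-15, 1 - 1e-15)
    if converged and (np.max(np.abs(y - p)) < 1e-8 or np.linalg.norm(beta) > 1e4):
        converged = False  # perfectly separated data admit no finite MLE
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        fitted=p,
        converged=converged,
        n_iter=it,
        log_likelihood=ll,
    )


def hosmer_lemeshow(
    fitted_probabilities, y, g: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit chi-square over deciles of risk.

    Tied probabilities collapse bins; fewer than 3 effective bins raise.
    Returns (chi2, df, p) with df = g_effective - 2.
    """
    p = np.asarray(fitted_probabilities, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.size != y.size:
        raise ValueError("lengths differ")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, g + 1)))
    if edges.size - 1 < 3:
        raise ValueError(
            f"only {edges.size - 1} distinct risk bins; need at least 3"
        )
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)
    chi2 = 0.0
    g_eff = 0
    for b in range(edges.size - 1):
        sel = idx == b
        n_b = int(sel.sum())
        if n_b == 0:
            continue
        g_eff += 1
        o = y[sel].sum()
        e = p[sel].sum()
        denom = e * (1.0 - e / n_b)
        if denom <= 0:
            denom = np.finfo(float).tiny
        chi2 += (o - e) ** 2 / denom
    if g_eff < 3:
        raise ValueError(f"only {g_eff} populated risk bins; need at least 3")
    df = g_eff - 2
    return float(chi2), df, float(sps.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# group comparison tests (thin fronts over scipy with fixed conventions)
# ---------------------------------------------------------------------------

def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U of ``a``, p).

    Exact p when min(n, m) <= 8 and the pooled sample is tie-free;
    otherwise the normal approximation with tie and continuity
    corrections. A perfectly balanced statistic (U = nm/2, e.g.
    identical groups) reports p = 1 by symmetry.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u, p = float(res.statistic), float(res.pvalue)
    if u == a.size * b.size / 2.0:
        p = 1.0
    return u, p


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has an empty margin")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero rank variance")
    return float(sps.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementStats:
    bland_altman: tuple[float, float, float]  # bias, loa_low, loa_high
    spearman_rho: float
    icc: tuple[float, float, float]  # estimate, ci_low, ci_high
    kappa: float | None = None


def bland_altman(values_method1, values_method2) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement (method1 minus method2)."""
    a = np.asarray(values_method1, dtype=float)
    b = np.asarray(values_method2, dtype=float)
    if a.size != b.size:
        raise ValueError("lengths differ")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def icc_consistency(ratings, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(C,1): two-way model, single-measure consistency, with F-based CI.

    ``ratings`` is an (n_subjects, k_raters) array without missing cells.
    The estimate is (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)
    from the two-way ANOVA decomposition; consistency ignores fixed
    rater offsets.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValueError("ratings must be n_subjects x k_raters with k >= 2")
    n, k = r.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.all(np.isfinite(r)):
        raise ValueError("missing cells are not supported")
    grand = r.mean()
    ms_subj = k * np.sum((r.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_rater = n * np.sum((r.mean(axis=0) - grand) ** 2) / (k - 1)
    sst = np.sum((r - grand) ** 2)
    ss_err = sst - ms_subj * (n - 1) - ms_rater * (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_subj <= 0:
        raise ValueError("zero between-subject variance")
    if ms_err == 0:
        return 1.0, (1.0, 1.0)
    icc = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
    f0 = ms_subj / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = f0 / sps.f.ppf(1 - alpha / 2, df1, df2)
    fu = f0 * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    return float(icc), (float(ci[0]), float(ci[1]))


def cohen_kappa(labels1, labels2) -> float:
    """Cohen's kappa for two binary raters: (p_o - p_e) / (1 - p_e).

    When both raters are constant and identical, chance agreement p_e is
    1 and kappa is defined as 1 by convention.
    """
    a = np.asarray(labels1)
    b = np.asarray(labels2)
    if a.size != b.size or a.size == 0:
        raise ValueError("need equal-length non-empty label sequences")
    cats = np.unique(np.concatenate([a, b]))
    if cats.size > 2:
        raise ValueError("kappa here is for binary labels")
    po = float((a == b).mean())
    pe = float(
        sum((a == c).mean() * (b == c).mean() for c in cats)
    )
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def method_agreement(values_method1, values_method2,
                     labels1=None, labels2=None) -> AgreementStats:
    """Bundle Bland-Altman, Spearman, ICC (and kappa when labels given)."""
    ba = bland_altman(values_method1, values_method2)
    rho = spearman_rho(values_method1, values_method2)
    icc, ci = icc_consistency(np.column_stack([values_method1, values_method2]))
    kappa = None
    if labels1 is not None and labels2 is not None:
        kappa = cohen_kappa(labels1, labels2)
    return AgreementStats(
        bland_altman=ba, spearman_rho=rho, icc=(icc, *ci), kappa=kappa
    )
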