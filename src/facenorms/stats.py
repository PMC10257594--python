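"""Nonparametric inferential toolkit.

Rank correlations (plain and first-order partial), Mann-Whitney U, the
two-way random-effects intraclass correlation, the paired two-one-sided
equivalence test (TOST), Bonferroni correction, and ROC analysis with
Youden-index cutoff selection.  Everything the norming pipeline infers is
nonparametric by design; normality screening, where wanted, should go
through an established omnibus routine (e.g. ``scipy.stats.shapiro``) and is
used for reporting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._utils import round_half_away
from .exceptions import DegenerateDistributionError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "MannWhitneyResult",
    "IccResult",
    "TostResult",
    "RocResult",
    "spearman_rho",
    "partial_spearman",
    "mann_whitney_u",
    "icc_test_retest",
    "tost_paired",
    "bonferroni_alpha",
    "roc_analysis",
    "confusion_from_rates",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    partial_covariate: str | None = None

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p": self.p, "n": self.n, "partial_covariate": self.partial_covariate}


def _as_vec(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return v


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties; p via the t
    approximation with n - 2 degrees of freedom."""
    x, y = _as_vec(x, "x"), _as_vec(y, "y")
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 4:
        raise ValidationError(f"need at least 4 pairs, got {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("constant vector has no rank correlation")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=len(x))


def partial_spearman(x, y, z) -> CorrelationResult:
    """First-order partial Spearman correlation of x and y controlling for z.

    Computed on the rank-transformed data via
    rho_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),
    with p from a t reference with n - 3 degrees of freedom.  A constant
    covariate carries no rank information, so the plain Spearman correlation
    is returned (with its n - 2 df p-value).
    """
    x, y, z = _as_vec(x, "x"), _as_vec(y, "y"), _as_vec(z, "z")
    if not (len(x) == len(y) == len(z)):
        raise ValidationError("x, y, z must have equal lengths")
    n = len(x)
    if n < 5:
        raise ValidationError(f"need at least 5 triples, got {n}")
    if np.all(z == z[0]):
        res = spearman_rho(x, y)
        return CorrelationResult(rho=res.rho, p=res.p, n=n, partial_covariate="constant")
    rx, ry, rz = sps.rankdata(x), sps.rankdata(y), sps.rankdata(z)
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    if min(1 - r_xz**2, 1 - r_yz**2) <= 1e-14:
        raise DegenerateDistributionError("covariate is perfectly rank-correlated with x or y")
    rho = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    df = n - 3
    t = rho * np.sqrt(df / max(1.0 - rho**2, 1e-300))
    p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(rho=float(rho), p=float(p), n=n, partial_covariate="z")


@dataclass(frozen=True)
class MannWhitneyResult:
    u1: float
    u2: float
    p: float
    method: str

    def to_dict(self) -> dict:
        return {"u1": self.u1, "u2": self.u2, "p": self.p, "method": self.method}


def _exact_u_pvalue(pooled: np.ndarray, n1: int, u1_obs: float) -> float:
    """Exact two-sided permutation p-value of the Mann-Whitney U.

    Dynamic program over subsets of size n1 of the pooled mid-ranks (doubled
    so tied half-ranks become integers); two-sided via the symmetry of the
    permutation distribution of U about n1*n2/2.
    """
    n = len(pooled)
    n2 = n - n1
    ranks2 = np.rint(2.0 * sps.rankdata(pooled)).astype(int)  # doubled mid-ranks
    max_s = int(ranks2.sum())
    # ways[k][s] = number of size-k subsets with doubled-rank sum s
    ways = np.zeros((n1 + 1, max_s + 1))
    ways[0, 0] = 1.0
    for r in ranks2:
        for k in range(n1, 0, -1):
            ways[k, r:] += ways[k - 1, : max_s + 1 - r]
    total = ways[n1].sum()
    sums = np.nonzero(ways[n1])[0]
    # u1 = ranksum - n1(n1+1)/2, with ranksum = doubled_sum / 2
    u_vals = sums / 2.0 - n1 * (n1 + 1) / 2.0
    dev = np.abs(u_vals - n1 * n2 / 2.0)
    dev_obs = abs(u1_obs - n1 * n2 / 2.0)
    p = ways[n1][sums][dev >= dev_obs - 1e-9].sum() / total
    return float(min(p, 1.0))


def mann_whitney_u(x, y, exact_limit: int = 400) -> MannWhitneyResult:
    """Mann-Whitney U test (two-sided).

    U1 counts pairs with x > y plus half the ties.  The p-value comes from
    exact permutation enumeration (tie-aware) when n1*n2 <= ``exact_limit``,
    otherwise from the normal approximation with tie correction.
    """
    x, y = _as_vec(x, "x"), _as_vec(y, "y")
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = float(n1 * n2 - u1)
    if n1 * n2 <= exact_limit:
        p = _exact_u_pvalue(pooled, n1, u1)
        method = "exact"
    else:
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
        method = "asymptotic"
    return MannWhitneyResult(u1=u1, u2=u2, p=p, method=method)


@dataclass(frozen=True)
class IccResult:
    icc: float
    model_form: str
    n_subjects: int
    n_sessions: int

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "model_form": self.model_form,
            "n_subjects": self.n_subjects,
            "n_sessions": self.n_sessions,
        }


def icc_test_retest(session1, session2) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the ANOVA mean squares of the subjects x sessions table:
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    s1, s2 = _as_vec(session1, "session1"), _as_vec(session2, "session2")
    if len(s1) != len(s2):
        raise ValidationError("sessions must have equal lengths")
    n = len(s1)
    if n < 5:
        raise ValidationError(f"need at least 5 subjects, got {n}")
    y = np.column_stack([s1, s2])
    k = y.shape[1]
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise DegenerateDistributionError("zero between-subject variance")
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return IccResult(
        icc=float(icc),
        model_form="two-way random effects, absolute agreement, single measures (ICC2,1)",
        n_subjects=n,
        n_sessions=k,
    )


@dataclass(frozen=True)
class TostResult:
    mean_diff: float
    df: int
    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    bounds: tuple[float, float]
    equivalent: bool

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "df": self.df,
            "t_lower": self.t_lower,
            "t_upper": self.t_upper,
            "p_lower": self.p_lower,
            "p_upper": self.p_upper,
            "bounds": list(self.bounds),
            "equivalent": self.equivalent,
        }


def tost_paired(x, y, low: float = -0.5, high: float = 0.5, alpha: float = 0.05) -> TostResult:
    """Two-one-sided equivalence test for paired samples.

    With d = x - y: t_lower = (dbar - low)/se tested upper-tail and
    t_upper = (dbar - high)/se tested lower-tail, se = sd(d)/sqrt(n),
    df = n - 1.  Equivalence is declared when both one-sided p < alpha.
    A zero-variance difference strictly inside the bounds is equivalent by
    convention (logged); outside, not equivalent.
    """
    x, y = _as_vec(x, "x"), _as_vec(y, "y")
    if len(x) != len(y):
        raise ValidationError("paired samples must have equal lengths")
    n = len(x)
    if n < 3:
        raise ValidationError(f"need at least 3 pairs, got {n}")
    if not low < high:
        raise ValidationError(f"bounds must satisfy low < high, got ({low}, {high})")
    d = x - y
    dbar = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        inside = low < dbar < high
        logger.info("zero-variance paired difference (dbar=%.4g): equivalent=%s by convention", dbar, inside)
        t_l = np.inf if dbar > low else -np.inf
        t_u = -np.inf if dbar < high else np.inf
        return TostResult(dbar, df, t_l, t_u, 0.0 if inside else 1.0, 0.0 if inside else 1.0,
                          (low, high), inside)
    se = sd / np.sqrt(n)
    t_lower = (dbar - low) / se
    t_upper = (dbar - high) / se
    p_lower = float(sps.t.sf(t_lower, df))
    p_upper = float(sps.t.cdf(t_upper, df))
    return TostResult(
        mean_diff=dbar,
        df=df,
        t_lower=float(t_lower),
        t_upper=float(t_upper),
        p_lower=p_lower,
        p_upper=p_upper,
        bounds=(low, high),
        equivalent=bool(max(p_lower, p_upper) < alpha),
    )


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Family-wise corrected per-test alpha: alpha / k (report at 3 dp)."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if k < 1 or int(k) != k:
        raise ValidationError(f"k must be a positive integer, got {k}")
    return alpha / k


@dataclass(frozen=True)
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    confusion: dict
    orientation: str
    curve: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "confusion": self.confusion,
            "orientation": self.orientation,
        }


def roc_analysis(scores, labels, lower_is_positive: bool = True) -> RocResult:
    """ROC analysis with Youden-index cutoff selection.

    AUC uses the rank (Mann-Whitney) formulation: the probability that a
    positive case scores below a negative one (under the lower-is-positive
    orientation), ties counted half.  Candidate cutoffs are the midpoints
    between adjacent distinct scores; a case is called positive when its
    score is at or below the cutoff.  The selected cutoff maximizes
    J = sensitivity + specificity - 1, ties broken toward higher
    sensitivity.
    """
    scores = _as_vec(scores, "scores")
    labels = np.asarray(labels, dtype=bool)
    if len(scores) != len(labels):
        raise ValidationError("scores and labels must have equal lengths")
    if labels.all() or (~labels).all():
        raise ValidationError("both classes must be present")
    s = scores if lower_is_positive else -scores
    pos, neg = s[labels], s[~labels]
    n_pos, n_neg = len(pos), len(neg)

    # AUC = P(pos < neg) + 0.5 P(pos == neg) via rank sums
    ranks = sps.rankdata(np.concatenate([neg, pos]))
    u_neg_gt_pos = ranks[:n_neg].sum() - n_neg * (n_neg + 1) / 2.0
    auc = float(u_neg_gt_pos / (n_pos * n_neg))

    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValidationError("scores are all identical; no ROC curve exists")
    cutoffs = (uniq[:-1] + uniq[1:]) / 2.0
    sens = np.array([(pos <= c).mean() for c in cutoffs])
    spec = np.array([(neg > c).mean() for c in cutoffs])
    j = sens + spec - 1.0
    order = np.lexsort((sens, j))  # last entry: max J, then max sensitivity
    best = order[-1]
    cut = float(cutoffs[best])
    tp = int((pos <= cut).sum())
    fn = n_pos - tp
    tn = int((neg > cut).sum())
    fp = n_neg - tn
    curve = pd.DataFrame({"fpr": 1.0 - spec, "tpr": sens, "cutoff": cutoffs if lower_is_positive else -cutoffs})
    return RocResult(
        auc=auc,
        cutoff=cut if lower_is_positive else -cut,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        accuracy=(tp + tn) / (n_pos + n_neg),
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        orientation="lower-score-indicates-positive" if lower_is_positive else "higher-score-indicates-positive",
        curve=curve,
    )


def confusion_from_rates(sensitivity: float, specificity: float, n_pos: int, n_neg: int) -> dict:
    """Reconstruct confusion counts from reported rates and group sizes.

    tp and tn are rounded half away from zero; accuracy is reported as a
    percentage at 2 decimals.
    """
    for name, r in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 <= r <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {r}")
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("group sizes must be >= 1")
    tp = int(round_half_away(sensitivity * n_pos))
    tn = int(round_half_away(specificity * n_neg))
    fn = n_pos - tp
    fp = n_neg - tn
    accuracy = (tp + tn) / (n_pos + n_neg)
    return {
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "accuracy": accuracy,
        "accuracy_percent": round_half_away(100.0 * accuracy, 2),
    }
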