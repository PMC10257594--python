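"""Non-parametric tolerance limits and the five-level equivalent-score scale.

Equivalent scores (ES) are an ordinal norm scale built from order statistics
of the adjusted-score distribution in the normative sample:

* ES 0 ("pathological"): at or below the outer one-sided non-parametric
  tolerance limit — with 95% confidence at most 5% of the healthy
  population scores there;
* ES 4: above the sample median;
* ES 1-3: a quasi-interval partition of the left half of the distribution,
  obtained by splitting the standard-normal interval
  [Phi^-1(proportion), 0] into three equal z-segments and mapping the two
  interior boundaries to sample ranks via ceil(n * Phi(z)).

Scores between the outer and inner tolerance limits are clinically
"borderline".  All binomial tail computations are exact — no normal
approximation — which removes platform drift and is cheap at these n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateDistributionError, SampleTooSmallError, ValidationError

ES_LABELS = {0: "pathological", 1: "borderline-low", 2: "low-normal", 3: "normal", 4: "above-median"}

IMPAIRED = "impaired"
BORDERLINE = "borderline"
NORMAL = "normal"


@dataclass(frozen=True)
class ToleranceSpec:
    """A one-sided non-parametric tolerance-limit request."""

    proportion: float = 0.05
    confidence: float = 0.95
    side: str = "outer"

    def __post_init__(self):
        if not (0.0 < self.proportion < 1.0):
            raise ValidationError(f"proportion must lie in (0, 1), got {self.proportion}")
        if not (0.0 < self.confidence < 1.0):
            raise ValidationError(f"confidence must lie in (0, 1), got {self.confidence}")
        if self.side not in ("outer", "inner"):
            raise ValidationError(f"side must be 'outer' or 'inner', got {self.side!r}")


def tolerance_rank(n: int, spec: ToleranceSpec) -> int:
    """1-based rank of the order statistic realizing the tolerance limit.

    Outer side: the largest rank r such that P(Binomial(n, p) >= r) >=
    confidence, so the r-th smallest observation is, with the stated
    confidence, below the p-quantile of the population.  Inner side: the
    smallest rank r with P(Binomial(n, p) <= r - 1) >= confidence.  Exact
    binomial tails throughout.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    p, conf = spec.proportion, spec.confidence
    ranks = np.arange(1, n + 1)
    if spec.side == "outer":
        ok = ranks[sps.binom.sf(ranks - 1, n, p) >= conf]
        if ok.size == 0:
            n_min = math.ceil(math.log(1.0 - conf) / math.log(1.0 - p))
            raise SampleTooSmallError(
                f"sample too small for tolerance limit: n = {n}, minimal n = {n_min}",
                minimal_n=n_min,
            )
        return int(ok.max())
    ok = ranks[sps.binom.cdf(ranks - 1, n, p) >= conf]
    if ok.size == 0:
        n_min = math.ceil(math.log(1.0 - conf) / math.log(p))
        raise SampleTooSmallError(
            f"sample too small for tolerance limit: n = {n}, minimal n = {n_min}",
            minimal_n=n_min,
        )
    return int(ok.min())


@dataclass
class ESThresholds:
    """Equivalent-score boundaries on the adjusted-score scale.

    ES 0: adjusted <= outer_limit; ES 1: (outer_limit, b12];
    ES 2: (b12, b23]; ES 3: (b23, median]; ES 4: > median.
    Clinically, (outer_limit, inner_limit] is the borderline band.
    """

    outer_limit: float
    inner_limit: float
    b12: float
    b23: float
    median: float
    n: int
    ranks: dict | None = None

    def __post_init__(self):
        seq = [self.outer_limit, self.b12, self.b23, self.median]
        if any(a > b + 1e-12 for a, b in zip(seq, seq[1:])):
            raise ValidationError(f"ES thresholds out of order: {seq}")
        if self.outer_limit > self.inner_limit + 1e-12:
            raise ValidationError("outer limit exceeds inner limit")

    def to_dict(self) -> dict:
        return {
            "outer": self.outer_limit,
            "inner": self.inner_limit,
            "b12": self.b12,
            "b23": self.b23,
            "median": self.median,
            "ranks": self.ranks,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ESThresholds":
        return cls(
            outer_limit=float(d["outer"]),
            inner_limit=float(d["inner"]),
            b12=float(d["b12"]),
            b23=float(d["b23"]),
            median=float(d["median"]),
            n=int(d["n"]),
            ranks=d.get("ranks"),
        )


def es_boundary_ranks(n: int, proportion: float = 0.05) -> tuple[int, int]:
    """Sample ranks of the ES1/ES2 and ES2/ES3 boundaries.

    The z-interval [Phi^-1(proportion), 0] is split into three equal parts;
    the interior cut points map to ranks ceil(n * Phi(z)).
    """
    z = sps.norm.ppf(proportion)
    r12 = math.ceil(n * sps.norm.cdf(z * 2.0 / 3.0))
    r23 = math.ceil(n * sps.norm.cdf(z / 3.0))
    return max(r12, 1), max(r23, 1)


def compute_es_thresholds(
    adjusted,
    proportion: float = 0.05,
    confidence: float = 0.95,
) -> ESThresholds:
    """Derive ES thresholds from a normative sample of adjusted scores."""
    x = np.sort(np.asarray(adjusted, dtype=float))
    n = x.size
    if n == 0:
        raise ValidationError("empty sample")
    if np.all(x == x[0]):
        raise DegenerateDistributionError("all adjusted scores are identical")
    r_outer = tolerance_rank(n, ToleranceSpec(proportion, confidence, "outer"))
    r_inner = tolerance_rank(n, ToleranceSpec(proportion, confidence, "inner"))
    r12, r23 = es_boundary_ranks(n, proportion)
    median = float(np.median(x))
    ranks = {
        "outer": r_outer,
        "inner": r_inner,
        "b12": r12,
        "b23": r23,
        "median": (n + 1) / 2,
    }
    return ESThresholds(
        outer_limit=float(x[r_outer - 1]),
        inner_limit=float(x[r_inner - 1]),
        b12=float(x[r12 - 1]),
        b23=float(x[r23 - 1]),
        median=median,
        n=n,
        ranks=ranks,
    )


def assign_es(adjusted: float, thresholds: ESThresholds) -> int:
    """Map an adjusted score to its equivalent score (0-4).

    Boundary inclusivity follows the published intervals: ES 0 includes the
    outer limit; ES 4 is strictly above the median.  Comparisons are at full
    precision; every real maps to exactly one ES.
    """
    if adjusted <= thresholds.outer_limit:
        return 0
    if adjusted <= thresholds.b12:
        return 1
    if adjusted <= thresholds.b23:
        return 2
    if adjusted <= thresholds.median:
        return 3
    return 4


def classify_clinical(adjusted: float, thresholds: ESThresholds) -> str:
    """Clinical banding: impaired / borderline / normal via the two limits."""
    if adjusted <= thresholds.outer_limit:
        return IMPAIRED
    if adjusted <= thresholds.inner_limit:
        return BORDERLINE
    return NORMAL
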