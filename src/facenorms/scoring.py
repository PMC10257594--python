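"""Score new individuals against published (or fitted) norms.

The published constants live in ``data/face_published.json`` and encode the
printed correction formula

    adjusted = raw + 0.0723 * (age - 53.275) - 1.6493 * (sqrt(education) - 3.595)

together with the equivalent-score intervals and the outer/inner tolerance
limits.  Those constants depend on the original participant-level data and
are shipped verbatim as a fixture; they are not recomputed here.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .cohort import Cohort
from .equivalent import ESThresholds, assign_es, classify_clinical
from .exceptions import ValidationError
from .regression import IDENTITY, SQUARE_ROOT, NormModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PublishedNorms:
    """Norming constants as printed: correction coefficients, ES intervals.

    ``age_coef`` and ``sqrt_edu_coef`` are the *correction* coefficients
    (what is added to the raw score), i.e. the negatives of the fitted
    regression slopes.
    """

    age_coef: float
    center_age: float
    sqrt_edu_coef: float
    center_sqrt_edu: float
    es_intervals: dict
    outer_limit: float
    inner_limit: float
    score_range: tuple[int, int] = (0, 36)
    n: int | None = None
    name: str = "published norms"
    grid_ages: tuple = ()
    grid_educations: tuple = ()
    grid_min_age: dict | None = None

    def __post_init__(self):
        edges = [
            self.es_intervals["es0_max"],
            self.es_intervals["es1_max"],
            self.es_intervals["es2_max"],
            self.es_intervals["es3_max"],
        ]
        if any(a >= b for a, b in zip(edges, edges[1:])):
            raise ValidationError(f"ES interval boundaries must be strictly increasing: {edges}")
        if self.es_intervals["es0_max"] != self.outer_limit:
            raise ValidationError("es0_max must equal the outer tolerance limit")

    def correction(self, age: float, education: float) -> float:
        if education < 0:
            raise ValidationError(f"education must be >= 0, got {education}")
        return self.age_coef * (age - self.center_age) + self.sqrt_edu_coef * (
            np.sqrt(education) - self.center_sqrt_edu
        )

    def thresholds(self) -> ESThresholds:
        """View of the ES intervals as :class:`ESThresholds` for assignment."""
        return ESThresholds(
            outer_limit=self.es_intervals["es0_max"],
            inner_limit=self.inner_limit,
            b12=self.es_intervals["es1_max"],
            b23=self.es_intervals["es2_max"],
            median=self.es_intervals["es3_max"],
            n=self.n or 0,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PublishedNorms":
        return cls(
            age_coef=float(d["age_coef"]),
            center_age=float(d["center_age"]),
            sqrt_edu_coef=float(d["sqrt_edu_coef"]),
            center_sqrt_edu=float(d["center_sqrt_edu"]),
            es_intervals={k: float(v) for k, v in d["es_intervals"].items()},
            outer_limit=float(d["outer_limit"]),
            inner_limit=float(d["inner_limit"]),
            score_range=tuple(d.get("score_range", (0, 36))),
            n=d.get("n"),
            name=d.get("name", "published norms"),
            grid_ages=tuple(d.get("grid_ages", ())),
            grid_educations=tuple(d.get("grid_educations", ())),
            grid_min_age=d.get("grid_min_age"),
        )

    @classmethod
    def from_fit(cls, model: NormModel, thresholds: ESThresholds, name: str = "fitted norms"):
        """Package a fitted model + thresholds in the published-norms layout.

        Requires the canonical transform pair (age: identity,
        education: square root); other selections cannot be expressed in the
        printed formula's shape.
        """
        terms = model.predictors
        if set(terms) != {"age", "education"}:
            raise ValidationError("from_fit requires both age and education retained")
        if terms["age"].transform != IDENTITY or terms["education"].transform != SQUARE_ROOT:
            raise ValidationError(
                "from_fit requires (age: identity, education: square_root) transforms"
            )
        return cls(
            age_coef=-terms["age"].beta,
            center_age=terms["age"].center,
            sqrt_edu_coef=-terms["education"].beta,
            center_sqrt_edu=terms["education"].center,
            es_intervals={
                "es0_max": thresholds.outer_limit,
                "es1_max": thresholds.b12,
                "es2_max": thresholds.b23,
                "es3_max": thresholds.median,
                "es4_min": thresholds.median,
            },
            outer_limit=thresholds.outer_limit,
            inner_limit=thresholds.inner_limit,
            n=model.n,
            name=name,
        )


def published_norms() -> PublishedNorms:
    """Load the shipped FACE published-norms fixture."""
    text = resources.files("facenorms").joinpath("data/face_published.json").read_text()
    return PublishedNorms.from_dict(json.loads(text))


@dataclass(frozen=True)
class ScoreReport:
    adjusted: float  # full precision
    adjusted_rounded: float  # 2 decimals, for reporting
    es: int
    band: str


def face_score(raw: float, age: float, education: float, norms: PublishedNorms | None = None) -> ScoreReport:
    """Adjust a raw score and classify it against the norms.

    Emits a ``UserWarning`` (never an error) when the demographics fall
    outside the normed grid lattice — extrapolated corrections deserve
    caution, especially for poorly educated young adults.
    """
    if norms is None:
        norms = published_norms()
    lo, hi = norms.score_range
    if not (lo <= raw <= hi):
        raise ValidationError(f"raw score must lie in [{lo}, {hi}], got {raw}")
    _warn_if_extrapolating(age, education, norms)
    adjusted = float(raw + norms.correction(age, education))
    thr = norms.thresholds()
    return ScoreReport(
        adjusted=adjusted,
        adjusted_rounded=round_half_away(adjusted, 2),
        es=assign_es(adjusted, thr),
        band=classify_clinical(adjusted, thr),
    )


def _warn_if_extrapolating(age: float, education: float, norms: PublishedNorms) -> None:
    if not norms.grid_ages or not norms.grid_educations:
        return
    a_lo, a_hi = min(norms.grid_ages), max(norms.grid_ages)
    e_lo, e_hi = min(norms.grid_educations), max(norms.grid_educations)
    outside = not (a_lo <= age <= a_hi) or not (e_lo <= education <= e_hi)
    if not outside and norms.grid_min_age:
        # e.g. the low-education rows of the published grid start at age 40/60
        bands = sorted(int(k) for k in norms.grid_min_age)
        band = max((b for b in bands if b <= education), default=bands[0])
        outside = age < norms.grid_min_age[str(band)]
    if outside:
        warnings.warn(
            f"demographics (age={age}, education={education}) fall outside the "
            f"normed lattice; the correction is an extrapolation",
            UserWarning,
            stacklevel=3,
        )


def score_cohort(cohort: Cohort, norms: PublishedNorms | None = None) -> pd.DataFrame:
    """Score every participant; returns a copy of the cohort table with
    ``adjusted_score`` (2 dp), ``equivalent_score`` and ``band`` appended."""
    if norms is None:
        norms = published_norms()
    df = cohort.data.copy()
    reports = [
        face_score(r, a, e, norms)
        for r, a, e in zip(df["raw_score"], df["age"], df["education"])
    ]
    df["adjusted_score"] = [rep.adjusted_rounded for rep in reports]
    df["equivalent_score"] = [rep.es for rep in reports]
    df["band"] = [rep.band for rep in reports]
    return df


@dataclass(frozen=True)
class ShortFormConversion:
    """18-item to 36-point conversion table (equipercentile style)."""

    version: str
    mapping: dict  # raw18 -> raw36 equivalent (real)

    def __post_init__(self):
        missing = [r for r in range(19) if r not in self.mapping]
        if missing:
            raise ValidationError(f"conversion table missing raw values {missing}")
        vals = [self.mapping[r] for r in range(19)]
        if any(a > b for a, b in zip(vals, vals[1:])):
            raise ValidationError("conversion table must be monotone non-decreasing")

    def convert(self, raw18: int) -> float:
        return float(self.mapping[raw18])

    def rounded(self, raw18: int) -> int:
        return int(round_half_away(self.convert(raw18)))


def shortform_to_full(
    raw18: int,
    version: str = "A",
    conversion: ShortFormConversion | None = None,
) -> float:
    """Convert an 18-item short-form score to the 36-point scale.

    With no table supplied the fallback is linear doubling — monotone and
    endpoint-exact, but only a stand-in for the equipercentile conversion
    table published in the supplementary material, which should be supplied
    via ``conversion`` whenever available.
    """
    if not (0 <= raw18 <= 18) or int(raw18) != raw18:
        raise ValidationError(f"short-form raw score must be an integer in [0, 18], got {raw18}")
    if conversion is not None:
        if conversion.version != version:
            raise ValidationError(
                f"conversion table is for version {conversion.version!r}, not {version!r}"
            )
        return conversion.convert(int(raw18))
    logger.info(
        "no conversion table supplied for version %s; using linear doubling "
        "(prefer the supplementary equipercentile table when available)",
        version,
    )
    return float(2 * int(raw18))


def prevalence_flagged(scored: pd.DataFrame) -> dict:
    """Fraction of a scored cohort in the impaired-or-borderline bands.

    Equivalently: adjusted score at or below the inner tolerance limit.
    Percent is integer-rounded half away from zero.
    """
    if len(scored) == 0:
        raise ValidationError("empty cohort")
    if "band" not in scored.columns:
        raise ValidationError("scored cohort must carry a 'band' column")
    flagged = scored["band"].isin(["impaired", "borderline"])
    n_flagged = int(flagged.sum())
    n_total = int(len(scored))
    return {
        "n_flagged": n_flagged,
        "n_total": n_total,
        "percent": int(round_half_away(100.0 * n_flagged / n_total)),
    }
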