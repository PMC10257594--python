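"""Regression-based norms: transform search, adjusted scores, correction grid.

The norming procedure regresses raw test scores on demographic predictors
(age, education), trying for each predictor the identity, quadratic,
logarithmic, inverse and square-root transforms as well as outright
exclusion, and keeps the combination that is most effective in reducing the
residual variance (equivalently, that maximizes adjusted R^2) subject to a
per-coefficient significance gate.  The fitted model yields demographically
adjusted scores

    adjusted = raw - sum_v beta_v * (t_v(x_v) - mean(t_v(x_v)))

i.e. the fitted demographic contribution, evaluated relative to the sample
mean of the transformed predictor, is removed.  A correction grid tabulates
this adjustment over an age x education lattice for pen-and-paper use.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from ._utils import round_half_away
from .cohort import Cohort
from .exceptions import DomainError, FitError, ValidationError

logger = logging.getLogger(__name__)

IDENTITY = "identity"
QUADRATIC = "quadratic"
LOGARITHMIC = "logarithmic"
INVERSE = "inverse"
SQUARE_ROOT = "square_root"
EXCLUDED = "excluded"

#: Tie-break order for equal fits (fewer parameters first, then this order).
TRANSFORM_ORDER = [IDENTITY, QUADRATIC, LOGARITHMIC, INVERSE, SQUARE_ROOT, EXCLUDED]

_TRANSFORM_FUNCS = {
    IDENTITY: lambda x: x,
    QUADRATIC: lambda x: x**2,
    LOGARITHMIC: np.log,
    INVERSE: lambda x: 1.0 / x,
    SQUARE_ROOT: np.sqrt,
}


def apply_transform(values, kind: str) -> np.ndarray:
    """Apply one of the candidate predictor transforms elementwise.

    Raises :class:`DomainError` naming the offending value when the transform
    is undefined (log/inverse of non-positive values, sqrt of negatives).
    """
    x = np.asarray(values, dtype=float)
    if kind == EXCLUDED:
        raise ValidationError("cannot apply the 'excluded' pseudo-transform to data")
    if kind not in _TRANSFORM_FUNCS:
        raise ValidationError(f"unknown transform {kind!r}")
    if kind in (LOGARITHMIC, INVERSE) and np.any(x <= 0):
        bad = x[x <= 0][0]
        raise DomainError(f"{kind} transform requires strictly positive input, got {bad}")
    if kind == SQUARE_ROOT and np.any(x < 0):
        bad = x[x < 0][0]
        raise DomainError(f"square_root transform requires non-negative input, got {bad}")
    return _TRANSFORM_FUNCS[kind](x)


@dataclass(frozen=True)
class PredictorTerm:
    """One retained predictor: its transform, slope and centering constant."""

    transform: str
    beta: float
    center: float


@dataclass
class NormModel:
    """A fitted norming model.

    ``predictors`` maps variable name ('age', 'education') to its retained
    :class:`PredictorTerm`; excluded variables are absent.  Centers are the
    sample means of the transformed predictors, so the adjustment evaluated
    at the centering demographics is exactly zero.
    """

    predictors: dict[str, PredictorTerm]
    intercept: float
    adjusted_r2: float
    n: int
    breusch_pagan_p: float | None = None
    residuals: np.ndarray | None = field(default=None, repr=False)

    def correction(self, age, education) -> float | np.ndarray:
        """The amount added to a raw score for these demographics."""
        values = {"age": age, "education": education}
        corr = 0.0
        for var, term in self.predictors.items():
            t = apply_transform(np.asarray(values[var], dtype=float), term.transform)
            corr = corr - term.beta * (t - term.center)
        if not self.predictors:
            corr = np.zeros(np.broadcast(np.asarray(age), np.asarray(education)).shape)
        out = np.asarray(corr, dtype=float)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "predictors": {
                v: {"transform": t.transform, "beta": t.beta, "center": t.center}
                for v, t in self.predictors.items()
            },
            "intercept": self.intercept,
            "adjusted_r2": self.adjusted_r2,
            "n": self.n,
            "breusch_pagan_p": self.breusch_pagan_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormModel":
        return cls(
            predictors={
                v: PredictorTerm(t["transform"], float(t["beta"]), float(t["center"]))
                for v, t in d["predictors"].items()
            },
            intercept=float(d["intercept"]),
            adjusted_r2=float(d["adjusted_r2"]),
            n=int(d["n"]),
            breusch_pagan_p=(
                float(d["breusch_pagan_p"]) if d.get("breusch_pagan_p") is not None else None
            ),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NormModel":
        return cls.from_dict(json.loads(text))


def _candidate_combinations(candidates: dict[str, list[str]] | None):
    default = list(TRANSFORM_ORDER)
    cand = {
        "age": list((candidates or {}).get("age", default)),
        "education": list((candidates or {}).get("education", default)),
    }
    for var, opts in cand.items():
        if EXCLUDED not in opts:
            opts.append(EXCLUDED)
    return list(itertools.product(cand["age"], cand["education"]))


def fit_norm_model(
    cohort: Cohort,
    candidates: dict[str, list[str]] | None = None,
    entry_alpha: float = 0.05,
) -> NormModel:
    """Exhaustive transform search with per-coefficient significance gating.

    Every combination of one transform per variable (including exclusion) is
    fitted by OLS on centered transformed predictors.  A combination is
    admissible only when every included coefficient has p < ``entry_alpha``
    (set ``entry_alpha=1`` to disable the gate); among admissible fits the
    one maximizing adjusted R^2 wins, with ties broken toward fewer
    parameters and then the transform order ``TRANSFORM_ORDER``.
    """
    df = cohort.data
    y = df["raw_score"].to_numpy(dtype=float)
    n = len(y)
    combos = _candidate_combinations(candidates)
    n_vars = 2
    if n < 10 + n_vars:
        raise FitError(f"need at least {10 + n_vars} observations to fit norms, got {n}")

    raw_x = {"age": df["age"].to_numpy(dtype=float), "education": df["education"].to_numpy(dtype=float)}

    best = None  # (adj_r2, -n_params, -order_penalty, payload)
    for ta, te in combos:
        terms = []
        cols = []
        skip = False
        for var, kind in (("age", ta), ("education", te)):
            if kind == EXCLUDED:
                continue
            try:
                t = apply_transform(raw_x[var], kind)
            except DomainError:
                logger.warning("skipping %s transform for %s: domain violation", kind, var)
                skip = True
                break
            if np.std(t) == 0:
                logger.warning("skipping %s transform for %s: zero variance", kind, var)
                skip = True
                break
            terms.append((var, kind, float(np.mean(t))))
            cols.append(t - np.mean(t))
        if skip:
            continue
        X = sm.add_constant(np.column_stack(cols)) if cols else np.ones((n, 1))
        if n <= X.shape[1]:
            raise FitError(f"fewer observations ({n}) than parameters ({X.shape[1]})")
        res = sm.OLS(y, X).fit()
        if cols and np.any(res.pvalues[1:] >= entry_alpha):
            continue
        adj_r2 = float(res.rsquared_adj) if cols else 0.0
        order_rank = (TRANSFORM_ORDER.index(ta), TRANSFORM_ORDER.index(te))
        key = (adj_r2, -len(cols), tuple(-r for r in order_rank))
        if best is None or key > best[0]:
            best = (key, terms, res)

    if best is None:
        raise FitError("no admissible model (all candidate fits failed)")

    _, terms, res = best
    predictors = {
        var: PredictorTerm(kind, float(res.params[i + 1]), center)
        for i, (var, kind, center) in enumerate(terms)
    }
    residuals = np.asarray(res.resid, dtype=float)
    bp_p = None
    if terms:
        _, bp_p = breusch_pagan(residuals, np.asarray(res.model.exog))
    model = NormModel(
        predictors=predictors,
        intercept=float(res.params[0]),
        adjusted_r2=float(res.rsquared_adj) if terms else 0.0,
        n=n,
        breusch_pagan_p=bp_p,
        residuals=residuals,
    )
    # centering identity: adjustment at the sample-mean demographics is 0
    for var, term in model.predictors.items():
        t = apply_transform(raw_x[var], term.transform)
        assert abs(float(np.mean(t)) - term.center) < 1e-9
    return model


def adjust_score(raw: float, age: float, education: float, model: NormModel) -> float:
    """Remove the fitted demographic contribution from a raw score.

    Returns the adjusted score at full precision (report at 2 decimals); the
    result is deliberately not clamped to the raw-score range.
    """
    if not (0 <= raw <= 36):
        raise ValidationError(f"raw score must lie in [0, 36], got {raw}")
    return float(raw + model.correction(age, education))


@dataclass
class AdjustmentGrid:
    """Correction factors over an age x education lattice (education rows)."""

    age_points: list[float]
    education_points: list[float]
    cells: np.ndarray  # shape (len(education_points), len(age_points)), NaN = unavailable

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.education_points, columns=self.age_points)

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "education"
        frame.to_csv(path, na_rep="NA")

    def lookup(self, age: float, education: float) -> float:
        i = self.education_points.index(education)
        j = self.age_points.index(age)
        return float(self.cells[i, j])


def build_adjustment_grid(
    model: NormModel,
    ages,
    educations,
    availability_mask: np.ndarray | None = None,
) -> AdjustmentGrid:
    """Tabulate ``adjust_score(0, age, education)`` rounded to 2 decimals.

    ``availability_mask`` (same shape as the grid, True = available) marks
    cells absent from the normed demographic lattice; they come out as NaN.
    """
    ages = list(ages)
    educations = list(educations)
    if not ages or not educations:
        raise ValidationError("grid axes must be non-empty")
    cells = np.empty((len(educations), len(ages)))
    for i, e in enumerate(educations):
        for j, a in enumerate(ages):
            cells[i, j] = round_half_away(adjust_score(0, a, e, model), 2)
    if availability_mask is not None:
        mask = np.asarray(availability_mask, dtype=bool)
        if mask.shape != cells.shape:
            raise ValidationError("availability_mask shape does not match the grid")
        cells = np.where(mask, cells, np.nan)
    return AdjustmentGrid(ages, educations, cells)


def breusch_pagan(residuals, design) -> tuple[float, float]:
    """Breusch-Pagan heteroscedasticity test (LM form).

    Squared residuals are regressed on the design matrix; the statistic is
    n * R^2 of that auxiliary regression, with a chi-square reference whose
    degrees of freedom equal the number of (non-constant) predictors.
    """
    resid = np.asarray(residuals, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.allclose(X[:, 0], 1.0):
        X = sm.add_constant(X)
    n, k = X.shape
    if len(resid) != n:
        raise FitError("residuals and design have different lengths")
    if n <= k + 1:
        raise FitError(f"need more than {k + 1} observations for {k - 1} predictors, got {n}")
    if np.linalg.matrix_rank(X) < k:
        raise FitError("design matrix is rank deficient")
    lm, lm_p, _, _ = het_breuschpagan(resid, X)
    return float(lm), float(lm_p)
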