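"""Regression and ANOVA of primer-extension activity against T-density scores.

The extension activity of a primer panel (percent of the oligo(dT) reference)
is regressed on the position-weighted T-density of the terminal *n* bases by
ordinary least squares.  Sweeping *n* from 1 to the primer length traces an
R²-versus-n curve: R² climbs while added positions still carry priming
information and plateaus once they do not (around n = 10 for the L1 RNP,
which is why 10 bases define the snap + velcro context).

The snap/velcro categorization of the same panel is summarized per category
(mean, SEM, count) and tested with a two-way ANOVA of activity on snap state,
velcro state and their interaction (Type II sums of squares for unbalanced
panels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .scoring import (
    CONTEXT_LENGTH,
    Category,
    PrimerRecord,
    categorize,
    position_weighted_t_density,
    t_density,
)

__all__ = [
    "RegressionFit",
    "RegressionCurve",
    "CategorySummary",
    "fit_activity_regression",
    "r2_curve",
    "category_summary",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of activity on a primer score."""

    slope: float
    intercept: float
    r2: float
    p: float
    stderr: float
    n_points: int


@dataclass
class RegressionCurve:
    """R² of activity ~ position-weighted T-density for each terminal window n."""

    n_values: list[int]
    fits: dict[int, RegressionFit]
    summary_n: int = CONTEXT_LENGTH

    @property
    def r2(self) -> dict[int, float]:
        return {n: f.r2 for n, f in self.fits.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n_values,
                "r2": [self.fits[n].r2 for n in self.n_values],
                "slope": [self.fits[n].slope for n in self.n_values],
                "intercept": [self.fits[n].intercept for n in self.n_values],
                "p": [self.fits[n].p for n in self.n_values],
            }
        )


@dataclass
class CategorySummary:
    """Per-category activity means with a two-way snap x velcro ANOVA."""

    mean: dict[Category, float]
    sem: dict[Category, float]
    count: dict[Category, int]
    p_snap: float
    p_velcro: float
    p_interaction: float
    anova: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": [c.value for c in Category],
                "count": [self.count[c] for c in Category],
                "mean": [self.mean[c] for c in Category],
                "sem": [self.sem[c] for c in Category],
            }
        )


def _usable(panel: Sequence[PrimerRecord]) -> list[PrimerRecord]:
    return [p for p in panel if p.activity is not None and not p.excluded]


def _score(record: PrimerRecord, n: int, score: str) -> float:
    if score == "pwtd":
        return position_weighted_t_density(record.sequence, n)
    if score == "tdensity":
        return t_density(record.sequence[-n:])
    raise ValueError(f"unknown score {score!r}; use 'pwtd' or 'tdensity'")


def fit_activity_regression(
    panel: Sequence[PrimerRecord], n: int = CONTEXT_LENGTH, score: str = "pwtd"
) -> RegressionFit:
    """OLS regression of activity on the chosen score over the terminal n bases.

    Hairpin-flagged (``excluded``) primers and primers without an activity
    value are omitted.  Raises with fewer than 3 usable primers or when the
    score has zero variance across the panel (degenerate design).
    """
    usable = _usable(panel)
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable primers, got {len(usable)}")
    short = [p.name for p in usable if len(p.sequence) < n]
    if short:
        raise ValueError(f"primers shorter than n={n}: {short}")
    x = np.array([_score(p, n, score) for p in usable])
    y = np.array([p.activity for p in usable])
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate design: score has zero variance at n={n}")
    if np.ptp(y) == 0:
        # constant activity: flat line, no explainable variance
        return RegressionFit(
            slope=0.0, intercept=float(y[0]), r2=0.0, p=1.0, stderr=0.0,
            n_points=len(usable),
        )
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        stderr=float(res.stderr),
        n_points=len(usable),
    )


def r2_curve(
    panel: Sequence[PrimerRecord],
    n_max: Optional[int] = None,
    score: str = "pwtd",
    summary_n: int = CONTEXT_LENGTH,
) -> RegressionCurve:
    """R² of the activity regression for every terminal window n = 1..n_max.

    ``n_max`` defaults to the shortest usable primer length.  A window whose
    added position is the same base in every primer leaves R² unchanged
    relative to n - 1.
    """
    usable = _usable(panel)
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable primers, got {len(usable)}")
    if n_max is None:
        n_max = min(len(p.sequence) for p in usable)
    fits: dict[int, RegressionFit] = {}
    for n in range(1, n_max + 1):
        try:
            fits[n] = fit_activity_regression(panel, n=n, score=score)
        except ValueError:
            # zero score variance at this window (e.g. shared terminal base)
            fits[n] = RegressionFit(
                slope=math.nan, intercept=math.nan, r2=0.0, p=1.0,
                stderr=math.nan, n_points=len(usable),
            )
    return RegressionCurve(
        n_values=list(range(1, n_max + 1)),
        fits=fits,
        summary_n=min(summary_n, n_max),
    )


def category_summary(panel: Sequence[PrimerRecord]) -> CategorySummary:
    """Per-category activity summary with a two-way snap x velcro ANOVA.

    Uses Type II sums of squares, which is robust to unbalanced category
    counts.  A factor with a single observed level cannot be tested and is
    reported with p = NaN; terms whose sum of squares is (numerically) zero
    are reported with F = 0, p = 1 rather than NaN.
    """
    usable = _usable(panel)
    rows = []
    for p in usable:
        if len(p.sequence) < CONTEXT_LENGTH:
            continue
        status = categorize(p.sequence)
        rows.append(
            {
                "activity": p.activity,
                "snap": status.snap.value,
                "velcro": status.velcro.value,
                "category": status.category,
            }
        )
    if not rows:
        raise ValueError("no usable primers with a defined category")
    df = pd.DataFrame(rows)
    if df["category"].nunique() < 2:
        raise ValueError("need >= 2 populated categories for a summary")

    mean = {c: math.nan for c in Category}
    sem = {c: math.nan for c in Category}
    count = {c: 0 for c in Category}
    for cat, group in df.groupby("category"):
        count[cat] = len(group)
        mean[cat] = float(group["activity"].mean())
        sem[cat] = float(group["activity"].sem()) if len(group) > 1 else math.nan

    p_snap, p_velcro, p_inter, table = _two_way_anova(df)
    return CategorySummary(
        mean=mean,
        sem=sem,
        count=count,
        p_snap=p_snap,
        p_velcro=p_velcro,
        p_interaction=p_inter,
        anova=table,
    )


def _two_way_anova(df: pd.DataFrame) -> tuple[float, float, float, Optional[pd.DataFrame]]:
    """Type II two-way ANOVA of activity on snap and velcro.

    Degrades to the estimable effects: a factor observed at a single level
    is dropped; the interaction is fitted only when all four cells are
    populated.
    """
    factors = [f for f in ("snap", "velcro") if df[f].nunique() > 1]
    if not factors:
        return math.nan, math.nan, math.nan, None
    full_cross = df.groupby(["snap", "velcro"]).size().shape[0] == 4
    terms = [f"C({f})" for f in factors]
    if len(factors) == 2 and full_cross:
        terms.append("C(snap):C(velcro)")
    model = smf.ols(f"activity ~ {' + '.join(terms)}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    scale = max(float(df["activity"].abs().max()), 1.0)

    def term_p(name: str) -> float:
        if name not in table.index:
            return math.nan
        ss = float(table.loc[name, "sum_sq"])
        p = float(table.loc[name, "PR(>F)"])
        if ss <= 1e-12 * scale**2:
            return 1.0  # no variance attributable to this term
        return p

    return (
        term_p("C(snap)"),
        term_p("C(velcro)"),
        term_p("C(snap):C(velcro)"),
        table,
    )
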