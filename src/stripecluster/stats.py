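"""Normalization, assumption checks, factorial ANOVA effects and t tests.

The analysis mirrors how striped-micropattern measurements are pooled:
each property is normalized within its image by the mean over the
(strain × stimulus) combos present there, so that images and experiments
with different staining intensities can be pooled; normality and
variance-homogeneity of the pooled subgroups are then verified, and the
factor effects are estimated with an additive two-factor linear model and
expressed as fractions of the overall mean with 95% confidence intervals.

The unit of replication is the image: combo values are per-image
aggregates, and every image contributes one value per combo.  Because the
within-image normalization fixes each image's combo mean, the model by
default includes the image as a blocking factor; this leaves the balanced
effect estimates unchanged but keeps standard errors, confidence-interval
coverage and type-I error rates at their nominal levels.  The plain
two-factor model (no blocks) is available via ``block_by_image=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .errors import MissingDesignCellError

FACTORS = ("strain", "stimulus")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_within_image(df: pd.DataFrame, value_col: str = "value",
                           image_col: str = "image_id",
                           property_col: str = "property") -> pd.DataFrame:
    """Divide each value by the mean over all combos of its (image,
    property) group.

    Missing combos are simply absent from the denominator.  Groups whose
    mean is zero (or that contain fewer than two combos) are flagged
    ``excluded`` and carry NaN normalized values; exclude them from
    pooling.  Within every retained group the mean of the normalized
    values is exactly 1, which makes re-normalization the identity.
    """
    out = df.copy()
    grp = out.groupby([image_col, property_col])[value_col]
    mean = grp.transform("mean")
    count = grp.transform("count")
    excluded = (mean == 0) | (count < 2) | mean.isna()
    out["normalized"] = np.where(excluded, np.nan, out[value_col] / mean)
    out["excluded"] = excluded
    return out


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

@dataclass
class AssumptionReport:
    """Normality (KS) and variance-homogeneity (Levene) checks for the
    subgroups of one property."""

    property: str
    alpha: float
    ks_p: dict = field(default_factory=dict)       # subgroup -> p
    skipped: dict = field(default_factory=dict)    # subgroup -> reason
    levene_p: Optional[float] = None
    normality_pass: bool = True
    variance_pass: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [{"property": self.property, "test": "ks", "subgroup": sg,
                 "p_value": p, "passed": p >= self.alpha}
                for sg, p in self.ks_p.items()]
        rows += [{"property": self.property, "test": "skipped",
                  "subgroup": sg, "p_value": np.nan, "passed": False}
                 for sg in self.skipped]
        if self.levene_p is not None:
            rows.append({"property": self.property, "test": "levene",
                         "subgroup": "all", "p_value": self.levene_p,
                         "passed": self.levene_p >= self.alpha})
        return pd.DataFrame(rows)


def check_assumptions(df: pd.DataFrame, property_name: str,
                      value_col: str = "normalized",
                      alpha: float = 0.05) -> AssumptionReport:
    """KS-test each (strain × stimulus) subgroup against a normal with the
    subgroup's own mean/sd, and Levene's test across subgroups.

    Subgroups with n < 3 or degenerate (zero) variance are flagged and
    skipped rather than tested.
    """
    sub = df[df["property"] == property_name].dropna(subset=[value_col])
    report = AssumptionReport(property=property_name, alpha=alpha)
    groups = []
    for keys, g in sub.groupby(list(FACTORS)):
        name = "|".join(str(k) for k in keys)
        vals = g[value_col].to_numpy(dtype=float)
        if len(vals) < 3:
            report.skipped[name] = "n < 3"
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            report.skipped[name] = "degenerate variance"
            report.variance_pass = False
            continue
        p = sps.kstest(vals, "norm", args=(vals.mean(), sd)).pvalue
        report.ks_p[name] = float(p)
        if p < alpha:
            report.normality_pass = False
        groups.append(vals)
    if len(groups) >= 2:
        report.levene_p = float(sps.levene(*groups).pvalue)
        if report.levene_p < alpha:
            report.variance_pass = False
    return report


# ---------------------------------------------------------------------------
# ANOVA effect fractions
# ---------------------------------------------------------------------------

@dataclass
class EffectEstimate:
    """One factor's effect as a fraction of the overall mean."""

    property: str
    factor: str
    contrast: str            # "levelA - levelB"
    effect_fraction: float
    ci_low: float
    ci_high: float
    p_value: float
    n_images: int

    def __post_init__(self):
        if not (self.ci_low <= self.effect_fraction <= self.ci_high):
            raise ValueError("effect estimate outside its own CI")


@dataclass
class AnovaResult:
    property: str
    effects: list
    model_p: float           # corrected-model p: joint F of the factor terms
    interaction_p: Optional[float]
    n_images: int
    balanced: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [{"property": e.property, "factor": e.factor,
                 "contrast": e.contrast,
                 "effect_fraction": e.effect_fraction,
                 "ci_low": e.ci_low, "ci_high": e.ci_high,
                 "p_value": e.p_value, "n_images": e.n_images,
                 "model_p": self.model_p,
                 "interaction_p": self.interaction_p}
                for e in self.effects]
        return pd.DataFrame(rows)


def anova_effects(df: pd.DataFrame, property_name: str,
                  value_col: str = "normalized",
                  include_interaction: bool = False,
                  block_by_image: bool = True,
                  check_interaction: bool = True,
                  alpha: float = 0.05) -> AnovaResult:
    """Additive two-factor (strain × stimulus) linear model on normalized
    per-image values, sum-to-zero factor coding.

    A factor's effect is the difference between its two model-predicted
    level means (with sum coding, twice the level coefficient) divided by
    the overall mean of the response; its CI comes from the coefficient's
    standard error.  ``model_p`` is the joint F-test of the factor terms.
    When ``check_interaction`` (or ``include_interaction``) is set, the
    interaction p-value from a model with the product term is reported.
    """
    sub = df[(df["property"] == property_name)].dropna(subset=[value_col])
    sub = sub[~sub.get("excluded", pd.Series(False, index=sub.index))]
    for strain in sorted(sub["strain"].unique()):
        for stim in sorted(sub["stimulus"].unique()):
            if ((sub["strain"] == strain) & (sub["stimulus"] == stim)).sum() == 0:
                raise MissingDesignCellError(
                    f"empty design cell: strain={strain!r}, stimulus={stim!r} "
                    f"for property {property_name!r}")
    if sub["strain"].nunique() != 2 or sub["stimulus"].nunique() != 2:
        raise MissingDesignCellError(
            f"property {property_name!r} does not form a 2x2 design")

    terms = ["C(strain, Sum)", "C(stimulus, Sum)"]
    if include_interaction:
        terms.append("C(strain, Sum):C(stimulus, Sum)")
    if block_by_image:
        terms.append("C(image_id)")
    formula = f"{value_col} ~ " + " + ".join(terms)
    data = sub.rename(columns={value_col: value_col})
    res = smf.ols(formula, data=data).fit()

    grand = float(sub[value_col].mean())
    if grand == 0:
        raise ValueError("overall mean is zero; effect fractions undefined")
    n_images = int(sub["image_id"].nunique())

    effects = []
    factor_param_idx = []
    for factor in FACTORS:
        prefix = f"C({factor}, Sum)[S."
        names = [p for p in res.params.index
                 if p.startswith(prefix) and ":" not in p]
        assert len(names) == 1
        name = names[0]
        factor_param_idx.append(list(res.params.index).index(name))
        named_level = name[len(prefix):-1]
        other = [lv for lv in sorted(sub[factor].astype(str).unique())
                 if lv != named_level][0]
        coef = float(res.params[name])
        lo, hi = (float(x) for x in res.conf_int(alpha=alpha).loc[name])
        effects.append(EffectEstimate(
            property=property_name, factor=factor,
            contrast=f"{named_level} - {other}",
            effect_fraction=2.0 * coef / grand,
            ci_low=2.0 * lo / grand, ci_high=2.0 * hi / grand,
            p_value=float(res.pvalues[name]), n_images=n_images))

    if include_interaction:
        inter = [p for p in res.params.index if ":" in p]
        factor_param_idx += [list(res.params.index).index(p) for p in inter]
    R = np.zeros((len(factor_param_idx), len(res.params)))
    for i, j in enumerate(factor_param_idx):
        R[i, j] = 1.0
    model_p = float(res.f_test(R).pvalue)

    interaction_p = None
    if include_interaction:
        inter_names = [p for p in res.params.index if ":" in p]
        interaction_p = float(res.pvalues[inter_names[0]])
    elif check_interaction:
        inter_res = smf.ols(
            formula + " + C(strain, Sum):C(stimulus, Sum)", data=data).fit()
        inter_names = [p for p in inter_res.params.index if ":" in p]
        interaction_p = float(inter_res.pvalues[inter_names[0]])

    counts = sub.groupby(list(FACTORS))[value_col].count()
    balanced = counts.nunique() == 1
    return AnovaResult(property=property_name, effects=effects,
                       model_p=model_p, interaction_p=interaction_p,
                       n_images=n_images, balanced=balanced)


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    statistic: float
    df: float
    p_value: float
    n: int
    mean: float


def two_sample_t(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sample t test (equal-variance by default, as justified by a
    passing Levene test; set ``equal_var=False`` for Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, len(x) + len(y) - 2, 1.0,
                               len(x) + len(y), float(x.mean()))
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df),
                       float(res.pvalue), len(x) + len(y),
                       float(x.mean() - y.mean()))


def one_sample_t(values, popmean: float = 1.0) -> TTestResult:
    """One-sample t test, by default against 1 — the no-preference value of
    the surface-preference score."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need n >= 2")
    if values.std(ddof=1) == 0:
        if values[0] == popmean:
            return TTestResult(0.0, len(values) - 1, 1.0, len(values),
                               float(values.mean()))
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(values, popmean)
    return TTestResult(float(res.statistic), float(res.df),
                       float(res.pvalue), len(values), float(values.mean()))


def bonferroni_adjust(p_values, family_size: Optional[int] = None,
                      alpha: float = 0.05):
    """Bonferroni correction: adjusted p = min(1, p × m).

    Returns ``(adjusted, significant)`` arrays; ``family_size`` defaults to
    the number of p-values supplied.
    """
    p = np.asarray(p_values, dtype=float)
    m = family_size if family_size is not None else p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    adjusted = np.minimum(1.0, p * m)
    return adjusted, adjusted < alpha
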