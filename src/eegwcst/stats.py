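"""The age/performance statistical design applied to a feature table.

Three designs per EEG marker, mirroring a study in which age and cognitive
performance are strongly collinear (Pearson r about -0.62):

* two-way ANOVA of age group x performance cluster (Type II sums of
  squares, appropriate for the unbalanced design);
* ordinary least squares of the marker on age and performance z-score;
* partial correlations of the marker with age controlling performance,
  and with performance controlling age,

      r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)),

  with the p-value from a t statistic on n - 3 degrees of freedom.

Confirmatory subgroup modes re-run the correlations on good performers
only (age effects) and on elders only (performance effects).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "StatsError",
    "two_way_anova",
    "linear_regression",
    "partial_correlation",
    "pearson",
    "run_design",
]


class StatsError(ValueError):
    pass


@dataclasses.dataclass
class StatResult:
    feature_id: str
    design: str  # anova2 | regression | partial_corr | pearson
    estimates: dict  # F per factor, beta per predictor, or {"r": r}
    p_values: dict
    dof: float
    n: int
    subgroup: str = "all"

    def to_rows(self):
        rows = []
        for term in self.estimates:
            rows.append(
                {
                    "feature": self.feature_id,
                    "design": self.design,
                    "term": term,
                    "estimate": self.estimates[term],
                    "p": self.p_values.get(term, np.nan),
                    "dof": self.dof,
                    "n": self.n,
                    "subgroup": self.subgroup,
                }
            )
        return rows


def two_way_anova(
    df: pd.DataFrame,
    feature: str,
    factor_a: str = "age_group",
    factor_b: str = "performance_cluster",
) -> StatResult:
    """Unbalanced two-way ANOVA with Type II sums of squares.

    The interaction term is included when every non-empty cell holds at
    least two observations, otherwise a main-effects model is fit.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df[[feature, factor_a, factor_b]].dropna()
    for factor in (factor_a, factor_b):
        levels = data[factor].value_counts()
        if (levels == 0).any() or len(levels) < 2:
            empty = [lv for lv in df[factor].unique()
                     if lv not in levels.index or levels.get(lv, 0) == 0]
            raise StatsError(
                f"factor {factor!r} needs >= 2 non-empty levels "
                f"(empty: {empty})"
            )
    if np.ptp(data[feature].to_numpy()) == 0:
        raise StatsError(
            f"feature {feature!r} is constant; F is undefined"
        )
    cells = data.groupby([factor_a, factor_b], observed=True).size()
    with_interaction = bool((cells >= 2).all()) and len(cells) == (
        data[factor_a].nunique() * data[factor_b].nunique()
    )
    rhs = f"C({factor_a}) + C({factor_b})"
    if with_interaction:
        rhs += f" + C({factor_a}):C({factor_b})"
    model = smf.ols(f"Q('{feature}') ~ {rhs}", data=data).fit()
    if model.df_resid <= 0:
        raise StatsError(
            f"saturated design for {feature!r}: no residual degrees of "
            f"freedom with n={len(data)}"
        )
    try:
        table = sm.stats.anova_lm(model, typ=2)
    except ValueError as exc:  # degenerate small-sample layouts
        raise StatsError(f"ANOVA failed for {feature!r}: {exc}") from exc

    estimates, p_values = {}, {}
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        name = (
            term.replace(f"C({factor_a})", factor_a)
            .replace(f"C({factor_b})", factor_b)
        )
        estimates[name] = float(row["F"])
        p_values[name] = float(row["PR(>F)"])
    return StatResult(
        feature_id=feature,
        design="anova2",
        estimates=estimates,
        p_values=p_values,
        dof=float(table.loc["Residual", "df"]),
        n=len(data),
    )


def linear_regression(
    df: pd.DataFrame, feature: str, predictors=("age", "z_score")
) -> StatResult:
    """OLS of a marker on the predictors, with intercept."""
    import statsmodels.api as sm

    data = df[[feature, *predictors]].dropna()
    n = len(data)
    if n <= len(predictors) + 1:
        raise StatsError(
            f"need n > {len(predictors) + 1} observations, got {n}"
        )
    x = data[list(predictors)].to_numpy(dtype=float)
    corr = np.corrcoef(x, rowvar=False)
    if x.shape[1] > 1:
        off = np.abs(corr[np.triu_indices_from(corr, k=1)])
        if np.any(off > 1 - 1e-12):
            i, j = np.unravel_index(
                np.argmax(np.abs(np.triu(corr, k=1))), corr.shape
            )
            raise StatsError(
                f"perfectly collinear predictors: "
                f"({predictors[i]}, {predictors[j]})"
            )
    design = sm.add_constant(x)
    fit = sm.OLS(data[feature].to_numpy(dtype=float), design).fit()
    names = ("const", *predictors)
    return StatResult(
        feature_id=feature,
        design="regression",
        estimates={nm: float(b) for nm, b in zip(names, fit.params)},
        p_values={nm: float(p) for nm, p in zip(names, fit.pvalues)},
        dof=float(fit.df_resid),
        n=n,
    )


def partial_correlation(x, y, z, feature_id: str = "") -> StatResult:
    """Partial correlation of x and y controlling z, with a t-based
    p-value on n - 3 degrees of freedom.

    Equals the correlation of the residuals from regressing x on z and y
    on z (an identity used as an independent cross-check in the tests).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise StatsError("x, y, z must have the same length")
    n = len(x)
    if n < 4:
        raise StatsError("partial correlation needs n >= 4")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1 - 1e-12 or abs(r_yz) >= 1 - 1e-12:
        raise StatsError("degenerate control: |r| with z equals 1")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    dof = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), dof))
    return StatResult(
        feature_id=feature_id,
        design="partial_corr",
        estimates={"r": r},
        p_values={"r": p},
        dof=float(dof),
        n=n,
    )


def pearson(x, y, feature_id: str = "") -> StatResult:
    """Plain Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, p = sps.pearsonr(x, y)
    return StatResult(
        feature_id=feature_id,
        design="pearson",
        estimates={"r": float(r)},
        p_values={"r": float(p)},
        dof=float(len(x) - 2),
        n=len(x),
    )


def run_design(
    features: pd.DataFrame,
    feature_columns=None,
    subgroups: bool = True,
    adjust: str | None = None,
    log_power: bool = False,
) -> pd.DataFrame:
    """Apply the full statistical design to every EEG marker column.

    Expects metadata columns ``age``, ``z_score``, ``age_group`` and
    ``performance_cluster``.  Returns a tidy results frame with one row
    per (feature, design, term, subgroup).

    ``adjust="bh"`` appends a Benjamini-Hochberg corrected ``q`` column
    (the raw per-feature p-values stay untouched).  ``log_power=True``
    analyses strictly positive ``power_*`` markers on a log10 scale.
    """
    required = {"age", "z_score", "age_group", "performance_cluster"}
    missing = required - set(features.columns)
    if missing:
        raise StatsError(f"feature table lacks columns {sorted(missing)}")
    if adjust not in (None, "bh"):
        raise StatsError(f"unknown p-value adjustment {adjust!r}")
    if feature_columns is None:
        feature_columns = [
            c
            for c in features.columns
            if c not in required
            and c not in ("subject_id", "sex")
            and pd.api.types.is_numeric_dtype(features[c])
        ]
    if log_power:
        features = features.copy()
        for c in feature_columns:
            if c.startswith("power_") and (features[c] > 0).all():
                features[c] = np.log10(features[c])

    rows = []

    def _collect(result):
        rows.extend(result.to_rows())

    for feat in feature_columns:
        sub = features[[feat, "age", "z_score", "age_group",
                        "performance_cluster"]].dropna()
        try:
            _collect(two_way_anova(sub, feat))
        except StatsError:
            pass
        _collect(linear_regression(sub, feat))
        r_age = partial_correlation(
            sub[feat], sub["age"], sub["z_score"], feature_id=feat
        )
        r_age.estimates = {"age|z_score": r_age.estimates["r"]}
        r_age.p_values = {"age|z_score": r_age.p_values["r"]}
        _collect(r_age)
        r_perf = partial_correlation(
            sub[feat], sub["z_score"], sub["age"], feature_id=feat
        )
        r_perf.estimates = {"z_score|age": r_perf.estimates["r"]}
        r_perf.p_values = {"z_score|age": r_perf.p_values["r"]}
        _collect(r_perf)

        if subgroups:
            good = sub[features.loc[sub.index, "performance_cluster"] == "good"]
            elders = sub[features.loc[sub.index, "age_group"] == "elder"]
            if len(good) == 0:
                raise StatsError("requested subgroup 'good_performers' is empty")
            if len(elders) == 0:
                raise StatsError("requested subgroup 'elders' is empty")
            if len(good) >= 4:
                r = pearson(good[feat], good["age"], feature_id=feat)
                r.design, r.subgroup = "pearson", "good_performers"
                r.estimates = {"age": r.estimates["r"]}
                r.p_values = {"age": r.p_values["r"]}
                _collect(r)
            if len(elders) >= 4:
                r = pearson(elders[feat], elders["z_score"], feature_id=feat)
                r.design, r.subgroup = "pearson", "elders"
                r.estimates = {"z_score": r.estimates["r"]}
                r.p_values = {"z_score": r.p_values["r"]}
                _collect(r)

    out = pd.DataFrame(rows)
    if adjust == "bh" and len(out):
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(
                out.loc[ok, "p"], method="fdr_bh"
            )[1]
        out["q"] = q
    return out
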