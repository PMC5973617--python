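"""Heteroscedastic one-way models, multiple comparisons and trait-effect
regressions.

The group-comparison model is a one-way fixed-effects mean structure with a
separate residual variance per group, estimated by REML (the
generalized-least-squares / variance-structure model familiar from
ecological statistics).  Because the mean structure is saturated, the REML
variance estimates have the closed form s_k^2 = SS_k / (n_k - 1), and the
group-factor test is a Wald F on the estimated means with covariance
diag(s_k^2 / n_k).  With the variances constrained equal the F statistic
collapses to the textbook one-way ANOVA F, and with two groups the
unconstrained F equals the squared Welch t statistic.

Pairwise comparisons use group-specific standard errors, Satterthwaite
degrees of freedom per pair and the Tukey-Kramer studentized-range
adjustment, summarised as a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .records import DataError, ValidationError

__all__ = [
    "HeteroOnewayFit",
    "fit_hetero_oneway",
    "tukey_pairwise",
    "compact_letter_display",
    "welch_t",
    "WelchT",
    "RegressionFit",
    "regress_effect_on_trait",
    "HeteroscedasticOneWay",
    "TraitEffectRegression",
    "diversity_loss_anova",
]


@dataclass(frozen=True)
class HeteroOnewayFit:
    """Fitted heteroscedastic (or pooled-variance) one-way model."""

    labels: tuple[str, ...]
    n: dict[str, int]
    means: dict[str, float]
    variances: dict[str, float]
    f: float
    df_num: int
    df_den: int
    p: float
    loglik_reml: float
    equal_var: bool


def _as_groups(values, groups) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(values, dtype=float).ravel()
    g = np.asarray(groups).ravel()
    if y.shape[0] != g.shape[0]:
        raise ValidationError("values and groups must have equal length")
    return y, g


def fit_hetero_oneway(values, groups, equal_var: bool = False) -> HeteroOnewayFit:
    """Fit a one-way model with per-group REML variances and Wald F test.

    ``equal_var=True`` constrains a single pooled variance, reproducing the
    classic one-way ANOVA F.  Denominator degrees of freedom are the
    containment df, N - K.
    """
    y, g = _as_groups(values, groups)
    labels = tuple(pd.unique(g))
    k = len(labels)
    if k < 2:
        raise DataError("need at least two groups")
    n: dict[str, int] = {}
    means: dict[str, float] = {}
    ss: dict[str, float] = {}
    for lab in labels:
        vals = y[g == lab]
        if len(vals) < 2:
            raise DataError(f"group {lab!r} has fewer than two observations")
        n[lab] = len(vals)
        means[lab] = float(vals.mean())
        ss[lab] = float(((vals - vals.mean()) ** 2).sum())
    n_tot = int(sum(n.values()))
    if equal_var:
        pooled = sum(ss.values()) / (n_tot - k)
        variances = {lab: pooled for lab in labels}
    else:
        variances = {lab: ss[lab] / (n[lab] - 1) for lab in labels}

    mean_vec = np.array([means[lab] for lab in labels])
    var_of_mean = np.array([variances[lab] / n[lab] for lab in labels])
    # Wald F for equality of the K means, contrasts vs the first group.
    contrast = np.zeros((k - 1, k))
    contrast[:, 0] = -1.0
    contrast[np.arange(k - 1), np.arange(1, k)] = 1.0
    lb = contrast @ mean_vec
    lcl = contrast @ np.diag(var_of_mean) @ contrast.T
    if np.allclose(lb, 0.0):
        f = 0.0
    elif np.linalg.matrix_rank(lcl) < k - 1:
        f = np.inf
    else:
        f = float(lb @ np.linalg.solve(lcl, lb) / (k - 1))
    df_num, df_den = k - 1, n_tot - k
    p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0

    # REML log-likelihood of the fitted variance structure; degenerate
    # zero-variance groups make it unbounded.
    if any(v <= 0 for v in variances.values()):
        loglik = np.inf
    else:
        log_v = np.array([n[lab] * np.log(variances[lab]) for lab in labels])
        quad = np.array([ss[lab] / variances[lab] for lab in labels])
        log_xvx = np.array([np.log(n[lab] / variances[lab]) for lab in labels])
        loglik = float(
            -0.5
            * ((n_tot - k) * np.log(2 * np.pi) + log_v.sum() + quad.sum() + log_xvx.sum())
        )
    return HeteroOnewayFit(
        labels=labels,
        n=n,
        means=means,
        variances=variances,
        f=f,
        df_num=df_num,
        df_den=df_den,
        p=p,
        loglik_reml=loglik,
        equal_var=equal_var,
    )


def compact_letter_display(
    labels: list[str],
    means: dict[str, float],
    significant: set[tuple[str, str]],
) -> dict[str, str]:
    """Assign lower-case letters so that groups sharing no letter differ
    significantly (sweep algorithm: start from one all-inclusive set, split
    on each significant pair, drop absorbed subsets)."""
    sets: list[set[str]] = [set(labels)]
    for a, b in significant:
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # drop empty sets and sets absorbed by a superset
        pruned: list[set[str]] = []
        for s in new_sets:
            if s and not any(s < t or (s == t and s in pruned) for t in new_sets if t is not s):
                if s not in pruned:
                    pruned.append(s)
        sets = pruned
    # order letter sets by the mean of their lowest-mean member; ties by label
    sets.sort(key=lambda s: (min(means[m] for m in s), sorted(s)[0]))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, list[str]] = {lab: [] for lab in labels}
    for i, s in enumerate(sets):
        for lab in s:
            assigned[lab].append(alphabet[i % len(alphabet)])
    return {lab: "".join(sorted(letters)) for lab, letters in assigned.items()}


def tukey_pairwise(fit: HeteroOnewayFit, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise group contrasts with Tukey-Kramer adjusted p-values.

    Standard errors use the group-specific variances, degrees of freedom
    are Satterthwaite per pair, and the adjustment is the studentized-range
    tail with K groups.  Includes raw p, adjusted p and compact letters.
    """
    labels = list(fit.labels)
    k = len(labels)
    if k < 2:
        raise DataError("pairwise comparisons need at least two groups")
    rows = []
    sig: set[tuple[str, str]] = set()
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            va, vb = fit.variances[a] / fit.n[a], fit.variances[b] / fit.n[b]
            est = fit.means[a] - fit.means[b]
            se = np.sqrt(va + vb)
            if se == 0:
                t = 0.0 if est == 0 else np.inf
                df = fit.n[a] + fit.n[b] - 2
            else:
                t = est / se
                df = (va + vb) ** 2 / (
                    va**2 / (fit.n[a] - 1) + vb**2 / (fit.n[b] - 1)
                )
            if np.isfinite(t):
                p_raw = float(2 * stats.t.sf(abs(t), df))
                p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df))
            else:
                p_raw = p_adj = 0.0
            p_adj = float(min(1.0, max(p_adj, p_raw)))
            if p_adj < alpha:
                sig.add((a, b))
            rows.append(
                {
                    "group_1": a,
                    "group_2": b,
                    "estimate": est,
                    "se": se,
                    "df": df,
                    "t": t,
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                }
            )
    table = pd.DataFrame(rows)
    letters = compact_letter_display(labels, fit.means, sig)
    table.attrs["letters"] = letters
    table["significant"] = table["p_adj"] < alpha
    return table


@dataclass(frozen=True)
class WelchT:
    t: float
    df: float
    p: float


def welch_t(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> WelchT:
    """Two-sample unequal-variance t-test from summary statistics.

    ``se1``/``se2`` are standard errors of the means.  Degrees of freedom
    by Welch-Satterthwaite.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValidationError("standard errors must be positive")
    if n1 < 2 or n2 < 2:
        raise ValidationError("need at least two observations per sample")
    v1, v2 = se1**2, se2**2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return WelchT(t=float(t), df=float(df), p=p)


@dataclass(frozen=True)
class RegressionFit:
    """Simple linear regression of a diversity effect on a trait summary."""

    slope: float
    intercept: float
    f: float
    p: float
    r2: float
    transform: str
    n: int
    warnings: tuple[str, ...] = field(default=())


def regress_effect_on_trait(
    effects,
    predictor,
    log_transform: bool = True,
) -> RegressionFit:
    """OLS of (optionally log-transformed) diversity effects on a trait
    predictor, with the F-test of the slope.

    With ``log_transform`` both sides are logged when all values are
    positive.  Non-positive predictor values under the log are an error
    (listing the offending rows); non-positive effects trigger a warning
    and an untransformed response (selection effects can be negative).
    """
    y = np.asarray(effects, dtype=float).ravel()
    x = np.asarray(predictor, dtype=float).ravel()
    if y.shape[0] != x.shape[0]:
        raise ValidationError("effects and predictor must have equal length")
    if y.shape[0] < 3:
        raise DataError("need at least three observations to regress")
    notes: list[str] = []
    transform = "none"
    if log_transform:
        bad_x = np.where(x <= 0)[0]
        if bad_x.size:
            raise ValidationError(
                f"log transform impossible: non-positive predictor at rows {bad_x.tolist()}"
            )
        x = np.log(x)
        if np.all(y > 0):
            y = np.log(y)
            transform = "log-log"
        else:
            transform = "log-x"
            msg = "non-positive effect values: response left untransformed"
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
    if np.ptp(y) == 0:  # flat response: slope 0, no explained variance
        return RegressionFit(
            slope=0.0, intercept=float(y[0]), f=0.0, p=1.0, r2=0.0,
            transform=transform, n=len(y), warnings=tuple(notes),
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    if model.df_resid <= 0:
        raise DataError("no residual degrees of freedom")
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        f=float(model.fvalue),
        p=float(model.f_pvalue),
        r2=float(model.rsquared),
        transform=transform,
        n=int(model.nobs),
        warnings=tuple(notes),
    )


class HeteroscedasticOneWay(BaseEstimator):
    """sklearn-style wrapper for the heteroscedastic one-way model.

    ``fit(groups, values)`` estimates group means, per-group REML variances
    and the Wald F test; ``pairwise()`` returns the Tukey table.
    """

    def __init__(self, equal_var: bool = False, alpha: float = 0.05):
        self.equal_var = equal_var
        self.alpha = alpha

    def fit(self, X, y) -> "HeteroscedasticOneWay":
        self.fit_ = fit_hetero_oneway(y, X, equal_var=self.equal_var)
        self.group_means_ = dict(self.fit_.means)
        self.group_variances_ = dict(self.fit_.variances)
        self.f_ = self.fit_.f
        self.p_ = self.fit_.p
        self.df_ = (self.fit_.df_num, self.fit_.df_den)
        self.loglik_reml_ = self.fit_.loglik_reml
        return self

    def pairwise(self) -> pd.DataFrame:
        return tukey_pairwise(self.fit_, alpha=self.alpha)


class TraitEffectRegression(BaseEstimator):
    """sklearn-style wrapper for the log-transformed trait-effect OLS."""

    def __init__(self, log_transform: bool = True):
        self.log_transform = log_transform

    def fit(self, X, y) -> "TraitEffectRegression":
        res = regress_effect_on_trait(y, X, log_transform=self.log_transform)
        self.result_ = res
        self.slope_ = res.slope
        self.intercept_ = res.intercept
        self.f_ = res.f
        self.p_ = res.p
        self.r2_ = res.r2
        return self


def diversity_loss_anova(
    metrics: pd.DataFrame,
    focal_species: tuple[str, ...],
    response: str,
    detritivores: bool = True,
    equal_var: bool = False,
    alpha: float = 0.05,
) -> tuple[HeteroOnewayFit, pd.DataFrame]:
    """Test the effect of diversity loss within a focal species set.

    Pools all treatments whose species are a subset of ``focal_species``
    and compares richness levels (e.g. the 4-species set compares richness
    1, 2, 3, 4).  Returns the heteroscedastic fit and the Tukey table.
    """
    from .records import Composition

    focal = set(focal_species)
    arm = metrics[metrics["detritivores"] == detritivores]
    keep = arm["mixture"].map(
        lambda lab: set(Composition.parse(str(lab)).species) <= focal
    )
    sub = arm[keep]
    if sub.empty:
        raise DataError(f"no microcosms within focal set {sorted(focal)}")
    vals = sub[response].astype(float)
    groups = sub["richness"].astype(int).astype(str).to_numpy()
    fit = fit_hetero_oneway(vals.to_numpy(), groups, equal_var=equal_var)
    return fit, tukey_pairwise(fit, alpha=alpha)
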