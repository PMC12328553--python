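"""Rating-matrix analyses: rater consistency, preference groups, regression.

The rating experiment yields a complete raters x stimuli matrix of beauty
ratings on a 1-100 visual-analog scale.  The analysis chain here is

1. rater consistency via the intraclass correlation ICC(C,k) (two-way model,
   consistency definition, average of k raters),
2. discovery of preference groups by k-means on the raw rating rows, with a
   canonical relabeling to A / L / G by the correlation of each cluster
   centroid with the stimulus balance (DCM) profile,
3. per-group mean rating profiles and their Pearson correlations with the
   stimulus features,
4. per-group ordinary least squares on (width, path length, DCM), and
5. a random-intercept linear mixed model on the individual ratings with
   group interactions, plus the variance decomposition (ICC, marginal and
   conditional R^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.cluster import KMeans

GROUP_LABELS = ("A", "L", "G")
LMM_PREDICTORS = ("width", "path_length", "dcm")


def _as_matrix(m: pd.DataFrame) -> pd.DataFrame:
    m = m.astype(float)
    if m.isna().any().any():
        raise ValueError("rating matrix contains missing cells")
    return m


def icc_consistency_avg(m: pd.DataFrame) -> float:
    """ICC(C,k): two-way, consistency, average over the k raters.

    Computed as (MS_stimuli - MS_residual) / MS_stimuli from the two-way
    rater x stimulus ANOVA decomposition, with stimuli as targets.  Equals 1
    exactly when raters differ only by additive shifts.
    """
    m = _as_matrix(m)
    k, n = m.shape  # k raters, n stimuli
    if k < 2 or n < 2:
        raise ValueError("need at least 2 raters and 2 stimuli")
    x = m.to_numpy()
    grand = x.mean()
    ss_stim = k * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_rater = n * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_resid = ss_total - ss_stim - ss_rater
    ms_stim = ss_stim / (n - 1)
    ms_resid = ss_resid / ((n - 1) * (k - 1))
    if ms_stim == 0:
        raise ValueError("ICC undefined: no between-stimulus variance")
    return float((ms_stim - ms_resid) / ms_stim)


@dataclass
class GroupAssignment:
    """Cluster labels per rater plus centroids and explained variance."""

    labels: pd.Series  # rater -> group label
    centroids: pd.DataFrame  # label x stimulus
    explained_variance: float
    seed: int | None = None

    def members(self, label: str) -> list:
        return list(self.labels.index[self.labels == label])

    @property
    def sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def cluster_raters(
    m: pd.DataFrame,
    k: int = 3,
    restarts: int = 100,
    seed: int = 0,
    dcm: pd.Series | None = None,
) -> GroupAssignment:
    """k-means over raw rating rows, best of ``restarts`` runs by within-SS.

    With k = 3 and a stimulus DCM profile, clusters are canonically relabeled:
    the centroid correlating most negatively with DCM becomes group A, the most
    positive becomes G, the remainder L (groups are named by the direction of
    their balance preference).
    """
    m = _as_matrix(m)
    if not 1 <= k <= len(m):
        raise ValueError(f"k must be in [1, {len(m)}]")
    x = m.to_numpy()
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(x)
    ss_total = ((x - x.mean(axis=0)) ** 2).sum()
    explained = 0.0 if ss_total == 0 else 1.0 - km.inertia_ / ss_total
    centroids = pd.DataFrame(km.cluster_centers_, columns=m.columns)
    if k == 3 and dcm is not None:
        dcm = dcm.reindex(m.columns)
        r = [stats.pearsonr(centroids.loc[i], dcm)[0] for i in range(3)]
        order = np.argsort(r)  # most negative, middle, most positive
        name_of = {order[0]: "A", order[1]: "L", order[2]: "G"}
    else:
        name_of = {i: str(i) for i in range(k)}
    labels = pd.Series(
        [name_of[c] for c in km.labels_], index=m.index, name="group"
    )
    centroids.index = [name_of[i] for i in range(k)]
    return GroupAssignment(
        labels=labels,
        centroids=centroids.sort_index(),
        explained_variance=float(explained),
        seed=seed,
    )


def group_profiles(m: pd.DataFrame, g: GroupAssignment) -> pd.DataFrame:
    """Mean rating per (group, stimulus); rows indexed by group label."""
    m = _as_matrix(m)
    labels = g.labels.reindex(m.index)
    if labels.isna().any():
        raise ValueError("group assignment does not cover all raters")
    prof = m.groupby(labels).mean()
    if (m.groupby(labels).size() == 0).any():
        raise ValueError("empty group")
    return prof


def rating_feature_correlations(
    profiles: pd.DataFrame, features: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and two-sided p) of each group profile with each feature."""
    if not profiles.columns.equals(features.index):
        if set(profiles.columns) != set(features.index):
            raise ValueError("stimulus ids of profiles and features differ")
        features = features.reindex(profiles.columns)
    cols = [c for c in features.columns if features[c].dtype.kind in "fi"]
    r = pd.DataFrame(index=profiles.index, columns=cols, dtype=float)
    p = r.copy()
    for grp in profiles.index:
        for c in cols:
            res = stats.pearsonr(profiles.loc[grp], features[c])
            r.loc[grp, c] = res.statistic
            p.loc[grp, c] = res.pvalue
    return r, p


@dataclass
class OlsResult:
    """Per-group OLS of mean ratings on (width, path_length, dcm)."""

    params: pd.DataFrame  # group x (Intercept, width, path_length, dcm)
    pvalues: pd.DataFrame
    r_squared: pd.Series


def ols_group_regression(
    profiles: pd.DataFrame,
    features: pd.DataFrame,
    predictors: tuple[str, ...] = LMM_PREDICTORS,
) -> OlsResult:
    """Ordinary least squares per group on the raw-scale feature columns."""
    X = features.reindex(profiles.columns)[list(predictors)].astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(axis=0))
    if rank < len(predictors):
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; collinear columns include {pair}")
    Xc = sm.add_constant(X.to_numpy())
    names = ["Intercept", *predictors]
    params, pvals, r2 = {}, {}, {}
    for grp in profiles.index:
        fit = sm.OLS(profiles.loc[grp].to_numpy(), Xc).fit()
        params[grp] = dict(zip(names, fit.params))
        pvals[grp] = dict(zip(names, fit.pvalues))
        y = profiles.loc[grp].to_numpy()
        # constant response: R^2 is 0 by convention rather than 0/0
        r2[grp] = 0.0 if np.allclose(y, y.mean()) else fit.rsquared
    return OlsResult(
        params=pd.DataFrame(params).T[names],
        pvalues=pd.DataFrame(pvals).T[names],
        r_squared=pd.Series(r2, name="r_squared"),
    )


def to_long(m: pd.DataFrame) -> pd.DataFrame:
    """Rating matrix -> long table (rater_id, stimulus_id, rating)."""
    long = _as_matrix(m).stack().rename("rating").reset_index()
    long.columns = ["rater_id", "stimulus_id", "rating"]
    return long


@dataclass
class LmmResult:
    """Random-intercept mixed-model fit on standardized ratings."""

    fixed_effects: pd.DataFrame  # beta, se, z, p per term
    sigma2: float  # residual variance
    tau00: float  # random-intercept variance
    sigma2_fixed: float  # variance of the fixed-effect linear predictor
    n_raters: int
    n_obs: int
    converged: bool

    @property
    def icc(self) -> float:
        return self.tau00 / (self.tau00 + self.sigma2)

    @property
    def marginal_r2(self) -> float:
        return lmm_variance_summary(self.sigma2, self.tau00, self.sigma2_fixed)[1]

    @property
    def conditional_r2(self) -> float:
        return lmm_variance_summary(self.sigma2, self.tau00, self.sigma2_fixed)[2]


def lmm_random_intercept(
    long: pd.DataFrame,
    features: pd.DataFrame,
    groups: pd.Series,
    predictors: tuple[str, ...] = LMM_PREDICTORS,
    standardize: bool = True,
    reference_group: str = "A",
) -> LmmResult:
    """REML fit of rating ~ (width + path_length + dcm) * group + (1 | rater).

    Continuous predictors (and the rating, so coefficients are on the
    standardized scale) are Z-scored over the full long table.
    """
    data = long.merge(
        features[list(predictors)], left_on="stimulus_id", right_index=True
    )
    data["group"] = groups.reindex(data["rater_id"]).to_numpy()
    if data["group"].isna().any():
        raise ValueError("group labels missing for some raters")
    if data["rater_id"].nunique() < 2:
        raise ValueError("random intercept unidentifiable with a single rater")
    if standardize:
        for c in (*predictors, "rating"):
            col = data[c].astype(float)
            data[c] = (col - col.mean()) / col.std(ddof=1)
    rhs = " + ".join(predictors)
    formula = f"rating ~ ({rhs}) * C(group, Treatment('{reference_group}'))"
    model = smf.mixedlm(formula, data, groups=data["rater_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
        if not fit.converged:
            # gradient methods stall when tau00 sits on the zero boundary
            fit = model.fit(reml=True, method="powell", maxiter=2000)
    fe = pd.DataFrame(
        {
            "beta": fit.fe_params,
            "se": fit.bse_fe,
            "z": fit.fe_params / fit.bse_fe,
            "p": fit.pvalues[fit.fe_params.index],
        }
    )
    # fixed-effects-only predictions; their variance feeds the R^2 decomposition
    yhat_fixed = np.asarray(fit.model.exog @ fit.fe_params, dtype=float)
    return LmmResult(
        fixed_effects=fe,
        sigma2=float(fit.scale),
        tau00=float(fit.cov_re.iloc[0, 0]),
        sigma2_fixed=float(yhat_fixed.var(ddof=0)),
        n_raters=int(data["rater_id"].nunique()),
        n_obs=len(data),
        converged=bool(fit.converged),
    )


def lmm_variance_summary(
    sigma2: float,
    tau00: float,
    sigma2_fixed: float | None = None,
    marginal_r2: float | None = None,
) -> tuple[float, float, float]:
    """(ICC, marginal R^2, conditional R^2) from the variance components.

    ICC = tau00 / (tau00 + sigma2); marginal R^2 is the share of total
    variance carried by the fixed effects, conditional R^2 by fixed plus
    random.  Supply either the fixed-effect variance ``sigma2_fixed`` or an
    already-known ``marginal_r2`` (from which sigma2_fixed is recovered).
    """
    if sigma2 < 0 or tau00 < 0:
        raise ValueError("variances must be non-negative")
    if sigma2 + tau00 == 0:
        raise ValueError("variance decomposition undefined: all variances zero")
    icc = tau00 / (tau00 + sigma2)
    if sigma2_fixed is None:
        if marginal_r2 is None:
            raise ValueError("need sigma2_fixed or marginal_r2")
        sigma2_fixed = marginal_r2 * (sigma2 + tau00) / (1.0 - marginal_r2)
    total = sigma2_fixed + tau00 + sigma2
    return (
        float(icc),
        float(sigma2_fixed / total),
        float((sigma2_fixed + tau00) / total),
    )
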