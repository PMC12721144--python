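"""Statistical stages: condition contrasts, non-parametric confirmations,
prenatal-covariate correlations with FDR, PCA of baseline features, and a
Monte-Carlo sensitivity power analysis.

Conventions: trials enter the mixed models at trial level (condition as a
fixed factor, random intercept per subject); group summaries, Friedman
tests, and correlations first aggregate trials to subject x condition
means.  Pairwise condition contrasts are Tukey-adjusted over the six
pairs; correlation p-values are Benjamini-Hochberg adjusted within each
condition's feature x covariate family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .lmm import ContrastResult, FTestResult, LMMFit, RandomInterceptLMM
from .types import BINARY_COVARIATES, COVARIATES, CONDITIONS, Condition, FeatureTable, NNS_FEATURES

logger = logging.getLogger("nnskit")

#: The four variables significantly modulated by condition, which enter the
#: prenatal-covariate correlations.
CORRELATED_FEATURES = ["cycles_trial", "cycles_burst", "burst_duration", "cycles_burst_interval"]

#: The seven variables entering the baseline PCA (bursts/trial excluded).
PCA_FEATURES = [
    "cycles_burst",
    "burst_interval",
    "burst_duration",
    "cycles_burst_interval",
    "amplitude",
    "cycle_interval",
    "cycles_trial",
]


# ---------------------------------------------------------------------------
# Summaries

def summarize_by_condition(features: FeatureTable) -> pd.DataFrame:
    """Per-condition mean and SD of each NNS variable.

    Trials are first averaged within subject, then M and SD are taken
    across subjects, so every newborn contributes one value per cell.
    """
    subj = features.subject_level()
    rows = []
    for cond in [c.value for c in CONDITIONS]:
        sel = subj[subj["condition"] == cond]
        for feat in NNS_FEATURES:
            vals = sel[feat].dropna()
            rows.append(
                {
                    "condition": cond,
                    "feature": feat,
                    "n": int(len(vals)),
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def cohens_d(x1: np.ndarray, x2: np.ndarray) -> float:
    """Cohen's d with pooled SD; invariant to adding a constant to all values."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        return np.nan
    s2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        return np.nan
    return float((np.mean(x1) - np.mean(x2)) / np.sqrt(s2))


# ---------------------------------------------------------------------------
# Condition-contrast mixed model

@dataclass
class PairwiseContrast:
    pair: Tuple[str, str]
    estimate: float
    t: float
    df: float
    p_adj: float
    d: float


@dataclass
class ConditionContrastResult:
    feature: str
    f: float
    df_num: float
    df_den: float
    p: float
    condition_summary: pd.DataFrame
    contrasts: List[PairwiseContrast]
    fit: LMMFit
    warnings: List[str] = field(default_factory=list)


def _trial_level(features: FeatureTable, feature_name: str) -> pd.DataFrame:
    df = features.df[["subject_id", "condition", feature_name]].dropna()
    return df.rename(columns={feature_name: "y"})


def _condition_design(conditions: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
    """Treatment-coded design with baseline as the reference level."""
    levels = [c.value for c in CONDITIONS]
    present = [lv for lv in levels if lv in set(conditions)]
    if len(present) < 2:
        raise ValueError("no contrast estimable: fewer than 2 conditions observed")
    cols = [np.ones(len(conditions))]
    names = ["intercept"]
    for lv in present[1:]:
        cols.append(np.asarray([1.0 if c == lv else 0.0 for c in conditions]))
        names.append(lv)
    return np.column_stack(cols), names


def _condition_mean_vector(cond: str, names: List[str]) -> np.ndarray:
    l = np.zeros(len(names))
    l[0] = 1.0
    if cond in names:
        l[names.index(cond)] = 1.0
    return l


def fit_condition_lmm(
    features: FeatureTable,
    feature_name: str,
    alpha: float = 0.05,
    force_zero_variance: bool = False,
) -> ConditionContrastResult:
    """LMM of one NNS variable on condition with a subject random intercept.

    Fits by REML on trial-level rows, reports the omnibus condition F with
    Satterthwaite denominator df, Tukey-adjusted pairwise contrasts among
    the observed conditions, and Cohen's d computed on subject-level means.
    A singular fit (zero random-intercept variance) is reported with a
    warning; fixed effects are still returned.
    """
    data = _trial_level(features, feature_name)
    if data["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    X, names = _condition_design(data["condition"].tolist())
    model = RandomInterceptLMM(data["y"].to_numpy(), X, data["subject_id"].to_numpy(), names=names)
    fit = model.fit(force_zero_variance=force_zero_variance)

    # omnibus: all non-intercept coefficients zero
    L = np.zeros((len(names) - 1, len(names)))
    for i in range(len(names) - 1):
        L[i, i + 1] = 1.0
    omni = fit.wald_f(L)

    subj = features.subject_level(feature_name)
    k = len([lv for lv in [c.value for c in CONDITIONS] if lv in set(data["condition"])])
    contrasts = []
    observed = [lv for lv in [c.value for c in CONDITIONS] if lv in set(data["condition"])]
    for c1, c2 in combinations(observed, 2):
        l = _condition_mean_vector(c1, names) - _condition_mean_vector(c2, names)
        res = fit.contrast(l)
        p_adj = float(studentized_range.sf(abs(res.t) * np.sqrt(2.0), k, res.df)) if np.isfinite(res.t) else np.nan
        v1 = subj.loc[subj["condition"] == c1, feature_name].dropna().to_numpy()
        v2 = subj.loc[subj["condition"] == c2, feature_name].dropna().to_numpy()
        contrasts.append(
            PairwiseContrast(
                pair=(c1, c2), estimate=res.estimate, t=res.t, df=res.df,
                p_adj=min(1.0, p_adj) if np.isfinite(p_adj) else np.nan,
                d=cohens_d(v1, v2),
            )
        )
    summary = summarize_by_condition(features)
    summary = summary[summary["feature"] == feature_name].reset_index(drop=True)
    return ConditionContrastResult(
        feature=feature_name,
        f=omni.f, df_num=omni.df_num, df_den=omni.df_den, p=omni.p,
        condition_summary=summary,
        contrasts=contrasts,
        fit=fit,
        warnings=list(fit.warnings),
    )


# ---------------------------------------------------------------------------
# Non-parametric confirmations

def subject_condition_matrix(features: FeatureTable, feature_name: str) -> pd.DataFrame:
    """Complete subject x condition matrix of subject means for one feature."""
    subj = features.subject_level(feature_name)
    mat = subj.pivot(index="subject_id", columns="condition", values=feature_name)
    return mat


def friedman_test(matrix) -> Tuple[float, int, float]:
    """Friedman chi-square on a complete subject x condition matrix.

    chi2 = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1), with within-row
    average ranks for ties; df = k - 1.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2, k >= 2")
    if np.isnan(M).any():
        raise ValueError(
            "matrix has missing cells; aggregate trials to subject means (or impute) upstream"
        )
    n, k = M.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, M)
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(R**2)) - 3.0 * n * (k + 1)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return float(chi2), int(df), p


def durbin_conover(matrix) -> pd.DataFrame:
    """Pairwise Durbin-Conover t comparisons of rank sums after Friedman.

    t = (R_i - R_j) / sqrt(2 n (A - B) / ((n-1)(k-1))) with A the sum of
    squared ranks and B = sum_j R_j^2 / n; df = (n-1)(k-1).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 3:
        raise ValueError("Durbin-Conover needs k >= 3 conditions")
    if np.isnan(M).any():
        raise ValueError("matrix has missing cells")
    n, k = M.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, M)
    R = ranks.sum(axis=0)
    A = float(np.sum(ranks**2))
    B = float(np.sum(R**2)) / n
    df = (n - 1) * (k - 1)
    denom2 = 2.0 * n * (A - B) / df
    cols = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else list(range(k))
    rows = []
    for i, j in combinations(range(k), 2):
        if denom2 > 0:
            t = (R[i] - R[j]) / np.sqrt(denom2)
            p = 2.0 * sps.t.sf(abs(t), df)
        else:
            t, p = 0.0, 1.0
        rows.append({"pair": (cols[i], cols[j]), "t": float(t), "df": int(df), "p": float(p)})
    return pd.DataFrame(rows)


def art_anova(
    features: FeatureTable, feature_name: str, force_zero_variance: bool = False
) -> FTestResult:
    """Aligned Rank Transform test of the condition effect.

    For the single within-subject factor: responses are aligned by
    removing estimated subject effects (subject mean minus grand mean),
    ranked with average ranks, and the same random-intercept LMM is fit
    on the ranks; the omnibus condition F with Satterthwaite df is
    returned.
    """
    data = _trial_level(features, feature_name)
    grand = data["y"].mean()
    subj_means = data.groupby("subject_id")["y"].transform("mean")
    aligned = data["y"] - subj_means + grand
    ranks = sps.rankdata(aligned)
    X, names = _condition_design(data["condition"].tolist())
    model = RandomInterceptLMM(ranks, X, data["subject_id"].to_numpy(), names=names)
    fit = model.fit(force_zero_variance=force_zero_variance)
    L = np.zeros((len(names) - 1, len(names)))
    for i in range(len(names) - 1):
        L[i, i + 1] = 1.0
    return fit.wald_f(L)


# ---------------------------------------------------------------------------
# Correlations with FDR

def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


@dataclass
class CorrelationResult:
    condition: str
    table: pd.DataFrame  # feature, covariate, r, n, p, p_adj, flag


def correlate_prenatal(
    features: FeatureTable,
    questionnaire: pd.DataFrame,
    condition: str,
    feature_names: Optional[List[str]] = None,
    covariates: Optional[List[str]] = None,
    min_n: int = 4,
) -> CorrelationResult:
    """Correlations between subject-level NNS features and prenatal covariates.

    Pearson correlations for ordinal covariates and point-biserial (the
    same computation on 0/1 codes) for binary ones, over pairwise-complete
    observations.  p-values are Benjamini-Hochberg adjusted over all
    feature x covariate pairs within the condition.  Cells with fewer
    than `min_n` complete pairs get a missing r and are flagged.
    """
    condition = Condition.parse(condition).value
    feats = feature_names or CORRELATED_FEATURES
    covs = covariates or COVARIATES
    subj = features.subject_level()
    subj = subj[subj["condition"] == condition]
    merged = subj.merge(questionnaire, on="subject_id", how="left")
    rows = []
    for f in feats:
        for c in covs:
            pair = merged[[f, c]].dropna()
            n = len(pair)
            if n < min_n or pair[c].nunique() < 2 or pair[f].nunique() < 2:
                rows.append({"feature": f, "covariate": c, "r": np.nan, "n": n,
                             "p": np.nan, "kind": "point-biserial" if c in BINARY_COVARIATES else "pearson",
                             "flag": "insufficient data"})
                continue
            r, p = sps.pearsonr(pair[f], pair[c])
            rows.append({"feature": f, "covariate": c, "r": float(r), "n": n, "p": float(p),
                         "kind": "point-biserial" if c in BINARY_COVARIATES else "pearson",
                         "flag": ""})
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["p_adj"] = np.nan
    if ok.any():
        table.loc[ok, "p_adj"] = benjamini_hochberg(table.loc[ok, "p"].to_numpy())
    return CorrelationResult(condition=condition, table=table)


# ---------------------------------------------------------------------------
# PCA of baseline sucking

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray
    loadings: pd.DataFrame  # variables x retained components (orthonormal columns)
    square_cosines: pd.DataFrame
    scores: np.ndarray
    n_components: int
    variables: List[str]
    log_eps: pd.Series
    transformed: pd.DataFrame


def pca_baseline(
    features: FeatureTable,
    n_components: int = 2,
    eps_fraction: float = 1e-3,
    variables: Optional[List[str]] = None,
) -> PCAResult:
    """PCA of the baseline-condition NNS variables on a common log scale.

    Each variable x is transformed to log(x + eps) with eps a small
    fraction of its median, then the PCA is run on the covariance of the
    transformed variables over complete cases.  Eigenvalues and variance
    proportions cover all components; loadings (orthonormal eigenvector
    columns), square cosines, and scores are reported for the retained
    `n_components`.
    """
    variables = variables or PCA_FEATURES
    subj = features.subject_level()
    base = subj[subj["condition"] == Condition.BASELINE.value][variables].dropna()
    if len(base) <= len(variables):
        raise ValueError(
            f"need more complete baseline cases ({len(base)}) than variables ({len(variables)})"
        )
    med = base.median()
    eps = eps_fraction * med
    if ((base + eps) <= 0).any().any():
        raise ValueError(
            "non-positive values under the log transform; increase eps_fraction"
        )
    logged = np.log(base + eps)
    pca = PCA()  # full decomposition on the covariance of centred data
    scores_full = pca.fit_transform(logged.to_numpy())
    eigenvalues = pca.explained_variance_
    proportion = pca.explained_variance_ratio_
    cumulative = np.cumsum(proportion)
    n_components = int(min(n_components, len(eigenvalues)))
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    V = pca.components_[:n_components].T  # variables x components, orthonormal cols
    loadings = pd.DataFrame(V, index=variables, columns=comp_names)
    var_x = logged.var(ddof=1).to_numpy()
    cos2 = (V**2) * eigenvalues[:n_components] / var_x[:, None]
    square_cosines = pd.DataFrame(cos2, index=variables, columns=comp_names)
    return PCAResult(
        eigenvalues=eigenvalues,
        proportion=proportion,
        cumulative=cumulative,
        loadings=loadings,
        square_cosines=square_cosines,
        scores=scores_full[:, :n_components],
        n_components=n_components,
        variables=list(variables),
        log_eps=eps,
        transformed=logged,
    )


# ---------------------------------------------------------------------------
# Sensitivity power analysis

@dataclass
class PowerModelParams:
    """Variance components and design for the Monte-Carlo power curve."""

    n_subjects: int = 30
    baseline_trials: int = 1
    stim_trials: int = 4
    intercept: float = 40.0
    sigma_b: float = 8.0  # between-subject SD
    sigma_e: float = 9.0  # residual (trial) SD


@dataclass
class PowerResult:
    effect_grid: np.ndarray
    power: np.ndarray
    alpha: float
    n_sims: int
    smallest_detectable: float  # smallest grid effect with power >= 0.80


def power_sensitivity(
    model_params: PowerModelParams,
    effect_grid: Sequence[float],
    n_sims: int = 200,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    target_power: float = 0.80,
) -> PowerResult:
    """Monte-Carlo power of the synthesized-vs-baseline contrast.

    For each candidate effect size (shift of the synthesized condition in
    the units of the response), cohorts are simulated from the
    random-intercept LMM, refit, and the contrast's Satterthwaite t-test
    rejection counted.  Reports the smallest grid effect reaching the
    target power.
    """
    if n_sims < 100:
        warnings.warn("n_sims < 100 gives a wide Monte-Carlo CI on power", UserWarning)
    rng = rng or np.random.default_rng()
    mp = model_params
    conds = (
        ["baseline"] * mp.baseline_trials
        + ["narrated"] * mp.stim_trials
        + ["hummed"] * mp.stim_trials
        + ["synthesized"] * mp.stim_trials
    )
    conditions = conds * mp.n_subjects
    subjects = np.repeat(np.arange(mp.n_subjects), len(conds))
    X, names = _condition_design(conditions)
    l = _condition_mean_vector("synthesized", names) - _condition_mean_vector("baseline", names)
    synth = np.asarray([c == "synthesized" for c in conditions], dtype=float)
    powers = []
    for effect in effect_grid:
        rejections = 0
        for _ in range(n_sims):
            u = rng.normal(0.0, mp.sigma_b, mp.n_subjects)
            y = (
                mp.intercept
                + effect * synth
                + u[subjects]
                + rng.normal(0.0, mp.sigma_e, len(conditions))
            )
            fit = RandomInterceptLMM(y, X, subjects, names=names).fit()
            if fit.contrast(l).p < alpha:
                rejections += 1
        powers.append(rejections / n_sims)
    powers = np.asarray(powers)
    grid = np.asarray(list(effect_grid), dtype=float)
    order = np.argsort(np.abs(grid))
    detectable = np.nan
    for idx in order:
        if powers[idx] >= target_power:
            detectable = float(grid[idx])
            break
    return PowerResult(
        effect_grid=grid, power=powers, alpha=alpha, n_sims=n_sims,
        smallest_detectable=detectable,
    )


# ---------------------------------------------------------------------------
# Normality screen

def normality_screen(features: FeatureTable, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk W and p per feature x condition on subject-level means.

    Cells with fewer than 3 observations (or constant samples) are
    reported missing; cells with p < alpha are flagged for the
    non-parametric confirmations.
    """
    subj = features.subject_level()
    rows = []
    for cond in [c.value for c in CONDITIONS]:
        sel = subj[subj["condition"] == cond]
        for feat in NNS_FEATURES:
            vals = sel[feat].dropna().to_numpy()
            if len(vals) < 3 or np.ptp(vals) == 0:
                rows.append({"condition": cond, "feature": feat, "n": len(vals),
                             "W": np.nan, "p": np.nan, "non_normal": False})
                continue
            W, p = sps.shapiro(vals)
            rows.append({"condition": cond, "feature": feat, "n": len(vals),
                         "W": float(W), "p": float(p), "non_normal": bool(p < alpha)})
    return pd.DataFrame(rows)
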