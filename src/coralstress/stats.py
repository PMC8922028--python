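"""General statistical machinery for the biomarker matrices.

Assumption-gated preprocessing (Shapiro-Wilk normality on within-cell
residuals, Levene homoscedasticity across treatment cells; natural-log
transform plus autoscaling when either fails), the moderate/severe
two-tier split of an incomplete design, factorial MANOVA/ANOVA with
Type III (marginal) sums of squares and Tukey-Kramer post-hocs, PCA on
autoscaled variables, and Euclidean/complete-linkage heatmap ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA as _SKPCA
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .condition import TestResult, extract_wilks, manova_wilks
from .exceptions import DegeneracyError, DesignError, TransformError

DEFAULT_RESPONSES = ("hsp70", "ub", "tac")
DEFAULT_FACTORS = ("species", "temperature", "predation")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


@dataclass
class PreprocessReport:
    """Per-response assumption tests and the transform decision taken."""

    table: pd.DataFrame  # response, shapiro_w, shapiro_p, levene_stat, levene_p, transform
    alpha: float


def autoscale(values: pd.Series | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegeneracyError("autoscale: zero standard deviation")
    return (arr - arr.mean()) / sd


def preprocess(
    matrix: pd.DataFrame,
    responses: tuple[str, ...] = DEFAULT_RESPONSES,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Test assumptions per response; log-transform + autoscale on failure.

    Shapiro-Wilk runs on residuals from treatment-cell means (the ANOVA
    residuals whose normality matters); Levene runs across treatment
    cells.  A response is transformed iff either test rejects at
    ``alpha``: natural log (raises TransformError on non-positive values,
    no silent offset) followed by autoscaling to mean 0, SD 1.
    """
    factors = [f for f in factors if f in matrix.columns]
    if not factors:
        raise DesignError("preprocess: no grouping factors present in matrix")
    cells = matrix.groupby(list(factors), sort=False)
    out = matrix.copy()
    rows = []
    for resp in responses:
        values = matrix[resp].to_numpy(dtype=float)
        resid = values - cells[resp].transform("mean").to_numpy(dtype=float)
        w, shapiro_p = sps.shapiro(resid)
        groups = [g[resp].to_numpy(dtype=float) for _, g in cells if len(g) > 1]
        if len(groups) > 1:
            lev_stat, lev_p = sps.levene(*groups)
        else:
            lev_stat, lev_p = 0.0, 1.0
        failed = shapiro_p < alpha or lev_p < alpha
        if failed:
            if (values <= 0).any():
                bad = matrix.index[values <= 0].tolist()[:5]
                raise TransformError(
                    f"preprocess: log transform of {resp!r} impossible, "
                    f"non-positive values at rows {bad}"
                )
            out[resp] = autoscale(np.log(values))
        rows.append(
            {
                "response": resp,
                "shapiro_w": float(w),
                "shapiro_p": float(shapiro_p),
                "levene_stat": float(lev_stat),
                "levene_p": float(lev_p),
                "transform": "log+autoscale" if failed else "none",
            }
        )
    return out, PreprocessReport(table=pd.DataFrame(rows), alpha=alpha)


# ---------------------------------------------------------------------------
# two-tier split of the incomplete design
# ---------------------------------------------------------------------------


def two_tier_split(
    matrix: pd.DataFrame,
    temperature_col: str = "temperature",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an incomplete design into moderate- and severe-stress tiers.

    Mortality at the highest temperature removes whole cells, so factorial
    tests run twice: the moderate tier keeps every species at all but the
    highest temperature; the severe tier keeps all temperatures but only
    species with data at every temperature.
    """
    temps = sorted(matrix[temperature_col].unique())
    if len(temps) < 2:
        raise DesignError("two_tier_split: need >= 2 temperature levels")
    highest = temps[-1]
    moderate = matrix[matrix[temperature_col] != highest].copy()
    per_species = matrix.groupby("species")[temperature_col].nunique()
    survivors = per_species[per_species == len(temps)].index
    severe = matrix[matrix["species"].isin(survivors)].copy()
    return moderate, severe


# ---------------------------------------------------------------------------
# factorial MANOVA / ANOVA
# ---------------------------------------------------------------------------


@dataclass
class MultivariateResult:
    """Wilks tests per term plus univariate follow-ups and post-hocs."""

    multivariate: dict[str, TestResult]
    univariate: pd.DataFrame  # response, term, ms, F, p
    tukey: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)


def _sum_coded(factors: tuple[str, ...]) -> str:
    return " * ".join(f"C({f}, Sum)" for f in factors)


def _term_names(factors: tuple[str, ...]) -> dict[str, str]:
    """Map statsmodels term labels to plain factor names, all interactions."""
    from itertools import combinations

    out = {}
    for r in range(1, len(factors) + 1):
        for combo in combinations(factors, r):
            raw = ":".join(f"C({f}, Sum)" for f in combo)
            out[raw] = ":".join(combo)
    return out


def factorial_manova(
    matrix: pd.DataFrame,
    responses: tuple[str, ...] = DEFAULT_RESPONSES,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    alpha: float = 0.05,
    run_tukey: bool = True,
) -> MultivariateResult:
    """Factorial MANOVA (Wilks) with Type III univariate ANOVAs and Tukey HSD.

    Sum-to-zero factor coding makes the tests marginal (Type III,
    weighted-squares-of-means), appropriate for the mortality-unbalanced
    design.  Tukey-Kramer post-hocs run per response for significant main
    effects with more than two levels.
    """
    factors = tuple(f for f in factors if matrix[f].nunique() > 1)
    if not factors:
        raise DesignError("factorial_manova: no factor with >= 2 levels")
    rename = _term_names(factors)
    rhs = _sum_coded(factors)

    if len(responses) == 1:
        multivariate = {}
    else:
        formula = " + ".join(responses) + " ~ " + rhs
        try:
            mv = manova_wilks(formula, matrix)
        except Exception as exc:
            raise DegeneracyError(f"factorial_manova: covariance degenerate ({exc})") from exc
        multivariate = extract_wilks(mv, rename)

    uni_rows = []
    tukey: dict[tuple[str, str], pd.DataFrame] = {}
    for resp in responses:
        model = ols(f"{resp} ~ {rhs}", data=matrix).fit()
        if model.model.exog.shape[1] > np.linalg.matrix_rank(model.model.exog):
            raise DesignError(
                "factorial_manova: design matrix is rank-deficient (empty design "
                "cells make Type III terms inestimable); analyze a complete tier, "
                "e.g. via two_tier_split"
            )
        tbl = sm.stats.anova_lm(model, typ=3)
        for raw, term in rename.items():
            if raw not in tbl.index:
                continue
            row = tbl.loc[raw]
            ms = float(row["sum_sq"] / row["df"])
            uni_rows.append(
                {
                    "response": resp,
                    "term": term,
                    "ms": ms,
                    "F": float(row["F"]),
                    "p": float(row["PR(>F)"]),
                }
            )
            if (
                run_tukey
                and term in factors
                and row["PR(>F)"] < alpha
                and matrix[term].nunique() > 2
            ):
                hsd = pairwise_tukeyhsd(
                    matrix[resp].to_numpy(dtype=float),
                    matrix[term].astype(str).to_numpy(),
                    alpha=alpha,
                )
                tukey[(resp, term)] = pd.DataFrame(
                    hsd.summary().data[1:], columns=hsd.summary().data[0]
                )
        if len(responses) == 1:
            # MANOVA on one response is just its ANOVA.
            for raw, term in rename.items():
                if raw in tbl.index:
                    r = tbl.loc[raw]
                    multivariate[term] = TestResult(
                        "F", float(r["F"]),
                        (float(r["df"]), float(tbl.loc["Residual", "df"])),
                        float(r["PR(>F)"]), term=term,
                    )
    return MultivariateResult(
        multivariate=multivariate,
        univariate=pd.DataFrame(uni_rows),
        tukey=tukey,
    )


# ---------------------------------------------------------------------------
# ordination and clustering
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    percent_variance: np.ndarray


def pca(matrix: pd.DataFrame, responses: tuple[str, ...] = DEFAULT_RESPONSES) -> PCAResult:
    """Correlation-matrix PCA (variables autoscaled before decomposition)."""
    if len(responses) < 2:
        raise DesignError("pca: need >= 2 variables")
    if len(matrix) < 3:
        raise DesignError("pca: need >= 3 observations")
    X = np.column_stack([autoscale(matrix[r]) for r in responses])
    model = _SKPCA(n_components=len(responses))
    scores = model.fit_transform(X)
    comps = [f"PC{i + 1}" for i in range(len(responses))]
    return PCAResult(
        scores=pd.DataFrame(scores, columns=comps, index=matrix.index),
        loadings=pd.DataFrame(model.components_.T, index=responses, columns=comps),
        percent_variance=model.explained_variance_ratio_ * 100.0,
    )


@dataclass
class HeatmapResult:
    group_means: pd.DataFrame  # groups x responses, autoscaled then averaged
    row_order: list[str]  # responses, clustered
    col_order: list[str]  # groups, clustered
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def cluster_heatmap(
    matrix: pd.DataFrame,
    group_by: str,
    responses: tuple[str, ...] = DEFAULT_RESPONSES,
) -> HeatmapResult:
    """Group-averaged heatmap ordering: Euclidean distance, complete linkage.

    Variables are autoscaled across all observations, then averaged per
    group; rows (responses) and columns (groups) are each ordered by
    complete-linkage hierarchical clustering of the group-mean matrix.
    No figure is rendered — orders, linkages and the matrix are returned
    for external plotting.
    """
    groups = matrix[group_by].unique()
    scaled = matrix.copy()
    for r in responses:
        scaled[r] = autoscale(matrix[r])
    means = scaled.groupby(group_by, sort=False)[list(responses)].mean()
    if len(groups) < 2:
        warnings.warn(
            f"cluster_heatmap: single group in {group_by!r}, order is trivial",
            stacklevel=2,
        )
        row_link = linkage(means.to_numpy().T, method="complete", metric="euclidean")
        return HeatmapResult(
            group_means=means,
            row_order=[responses[i] for i in leaves_list(row_link)],
            col_order=list(means.index),
            row_linkage=row_link,
            col_linkage=np.empty((0, 4)),
        )
    col_link = linkage(means.to_numpy(), method="complete", metric="euclidean")
    row_link = linkage(means.to_numpy().T, method="complete", metric="euclidean")
    return HeatmapResult(
        group_means=means,
        row_order=[responses[i] for i in leaves_list(row_link)],
        col_order=[means.index[i] for i in leaves_list(col_link)],
        row_linkage=row_link,
        col_linkage=col_link,
    )
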