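"""Health-condition tabulation, group aggregation, and condition inference.

Fragments are scored visually into four categories — normal, pale,
bleached (total endosymbiont loss), dead — at the end of exposure.
This module turns fragment records into per-cell percentage tables,
aggregates species into thermal-sensitivity groups, and runs the
sensitivity contrasts (pooled two-sample t on species x treatment
percentages) and the temperature x predation condition MANOVA.

Rounding follows the published display convention: species rows to one
decimal, grouped rows to the printed integer precision, both
half-away-from-zero (77.5 -> 78.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA

from .datasets import CONDITION_CATEGORIES
from .exceptions import DegeneracyError, DesignError, GroupingError

CELL_KEYS = ["species", "temperature", "predation"]


@dataclass
class TestResult:
    """A single named test statistic with its degrees of freedom and p-value."""

    name: str  # "t", "F", "wilks"
    statistic: float
    df: tuple[float, ...]
    pvalue: float
    term: str | None = None
    wilks_lambda: float | None = None


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (the convention of the published tables).

    numpy/python round() is banker's rounding (22.5 -> 22); published
    grouped cells need 22.5 -> 23.
    """
    arr = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def tabulate_condition(records: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Percentage of fragments per category, per (species, temperature, predation).

    Empty design cells are simply absent from the output (not zero-filled).
    Percentages are 100 x count / N rounded half-away-from-zero to
    ``decimals``; each row therefore sums to 100 within rounding slack.
    """
    if records.empty:
        raise DesignError("tabulate_condition: empty record set")
    missing = [c for c in CELL_KEYS + ["condition"] if c not in records.columns]
    if missing:
        raise DesignError(f"tabulate_condition: missing columns {missing}")
    rows = []
    for (species, temp, pred), cell in records.groupby(CELL_KEYS, sort=False):
        n = len(cell)
        counts = cell["condition"].value_counts()
        row = {"species": species, "temperature": temp, "predation": pred, "n": n}
        for cat in CONDITION_CATEGORIES:
            row[cat] = round_half_away(100.0 * counts.get(cat, 0) / n, decimals)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_groups(
    table: pd.DataFrame,
    grouping: dict[str, str],
    decimals: int = 0,
) -> pd.DataFrame:
    """Aggregate species rows into group rows by UNWEIGHTED species means.

    For each (group, temperature, predation), the group percentage per
    category is the plain mean of the member species' percentages, rounded
    half-away-from-zero to ``decimals`` (default: the integer precision of
    the published grouped rows).  N is the summed member fragment count —
    the arithmetically correct value, which can disagree with a printed N.
    """
    unmapped = sorted(set(table["species"]) - set(grouping))
    if unmapped:
        raise GroupingError(f"aggregate_groups: species without group assignment: {unmapped}")
    work = table.copy()
    work["group"] = work["species"].map(grouping)
    rows = []
    for (group, temp, pred), sub in work.groupby(["group", "temperature", "predation"], sort=False):
        row = {"group": group, "temperature": temp, "predation": pred, "n": int(sub["n"].sum())}
        for cat in CONDITION_CATEGORIES:
            row[cat] = round_half_away(sub[cat].mean(), decimals)
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_ttest(
    table: pd.DataFrame,
    grouping: dict[str, str],
    category: str,
) -> TestResult:
    """Pooled two-sample t between sensitivity groups on one category.

    The observation unit is one species x treatment-combination percentage
    (six rows per species), the unit that reproduces the published
    contrasts.  Two-sided, pooled (not Welch) variance, df = n1 + n2 - 2.
    """
    if category not in CONDITION_CATEGORIES:
        raise DesignError(f"sensitivity_ttest: unknown category {category!r}")
    unmapped = sorted(set(table["species"]) - set(grouping))
    if unmapped:
        raise GroupingError(f"sensitivity_ttest: species without group assignment: {unmapped}")
    groups = sorted(set(grouping.values()))
    if len(groups) != 2:
        raise DesignError(f"sensitivity_ttest: need exactly 2 groups, got {groups}")
    g = table["species"].map(grouping)
    a = table.loc[g == groups[0], category].to_numpy(dtype=float)
    b = table.loc[g == groups[1], category].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DesignError("sensitivity_ttest: need >= 2 observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("t", 0.0, (len(a) + len(b) - 2,), 1.0, term=category)
        return TestResult(
            "t", math.inf if a.mean() > b.mean() else -math.inf,
            (len(a) + len(b) - 2,), 0.0, term=category,
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult("t", float(t), (len(a) + len(b) - 2,), float(p), term=category)


def condition_manova(
    table: pd.DataFrame,
    drop_category: str | None = "bleached",
) -> dict[str, TestResult]:
    """Temperature x predation MANOVA on per-species condition percentages.

    Each individual-species row is one multivariate observation; one
    category (default the rarest, "bleached") is dropped so the dependent
    block is not degenerate under the sum-to-100 constraint.  Returns
    Wilks' lambda, its F approximation and p per term.
    """
    responses = [c for c in CONDITION_CATEGORIES if c != drop_category]
    dv = table[responses].to_numpy(dtype=float)
    if np.allclose(dv, dv[0]):
        # No between-row variance at all: nothing to test.
        return {
            term: TestResult("wilks", 0.0, (0.0, 0.0), 1.0, term=term, wilks_lambda=1.0)
            for term in ("temperature", "predation", "temperature:predation")
        }
    data = table.copy()
    formula = (
        " + ".join(responses)
        + " ~ C(temperature, Sum) * C(predation, Sum)"
    )
    rename = {
        "C(temperature, Sum)": "temperature",
        "C(predation, Sum)": "predation",
        "C(temperature, Sum):C(predation, Sum)": "temperature:predation",
    }
    try:
        mv = manova_wilks(formula, data)
    except Exception as exc:  # singular within-group covariance
        raise DegeneracyError(
            f"condition MANOVA failed ({exc}); try dropping another category or pooling cells"
        ) from exc
    return extract_wilks(mv, rename)


def manova_wilks(formula: str, data: pd.DataFrame):
    """MANOVA mv_test over every non-intercept term of ``formula``.

    The intercept hypothesis is excluded explicitly: on mean-centered
    responses its SSCP is numerically zero, which crashes statsmodels'
    default all-terms test.
    """
    mv = MANOVA.from_formula(formula, data=data)
    if mv.exog.shape[1] > np.linalg.matrix_rank(mv.exog):
        raise DegeneracyError(
            "MANOVA design matrix is rank-deficient (empty design cells); "
            "analyze a complete tier, e.g. via two_tier_split"
        )
    di = mv.data.design_info
    ncols = len(di.column_names)
    hypotheses = []
    for term in di.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = di.slice(term)
        L = np.zeros((sl.stop - sl.start, ncols))
        L[np.arange(sl.stop - sl.start), np.arange(sl.start, sl.stop)] = 1.0
        hypotheses.append((name, L, None))
    return mv.mv_test(hypotheses=hypotheses)


def extract_wilks(mv_result, rename: dict[str, str]) -> dict[str, TestResult]:
    """Pull Wilks' lambda rows out of a statsmodels MANOVA result."""
    out: dict[str, TestResult] = {}
    for raw_name, term in rename.items():
        tbl = mv_result.results[raw_name]["stat"]
        row = tbl.loc["Wilks' lambda"]
        out[term] = TestResult(
            name="wilks",
            statistic=float(row["F Value"]),
            df=(float(row["Num DF"]), float(row["Den DF"])),
            pvalue=float(row["Pr > F"]),
            term=term,
            wilks_lambda=float(row["Value"]),
        )
    return out
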