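"""Integrated Biomarker Response (IBR) index with explicit star-plot geometry.

The IBR condenses a panel of n biomarkers into one index per experimental
condition.  Per species and biomarker:

    X  = mean biomarker value at a condition
    Y  = (X - m) / s            standardization over that species' conditions
    Z  = Y (stimulation) or -Y (inhibition)
    S  = Z + |min Z|            so min S = 0 and all S >= 0

The n scores of a condition are placed clockwise on a star plot with
equal spoke angle alpha = 2*pi/n; the index is the polygon area,

    IBR = sum_i A_i,   A_i = 1/2 * S_i * S_{i+1} * sin(alpha)

with wrap-around S_{n+1} = S_1 (polygon closure; an open n-1-segment sum
is available via ``closed=False``).  The triangle decomposition equals
the shoelace area of the star polygon exactly.  A historically published
beta-angle expression for A_i circulates in corrupted typography and is
NOT a polygon area; it is provided as ``variant="beta"`` for audit only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .condition import TestResult
from .exceptions import DegeneracyError, DesignError, GeometryError

DEFAULT_BIOMARKER_ORDER = ("hsp70", "ub", "tac")
CONDITION_KEYS = ["temperature", "predation"]


@dataclass
class ScoreSet:
    """Per-species standardization artifacts for the IBR.

    Frames are indexed by condition (temperature, predation) with one
    column per biomarker, in clockwise star order.
    """

    species: str
    biomarkers: tuple[str, ...]
    directions: dict[str, str]
    m: pd.Series  # overall mean per biomarker
    s: pd.Series  # overall SD per biomarker
    x: pd.DataFrame  # condition means
    y: pd.DataFrame  # standardized
    z: pd.DataFrame  # signed
    score: pd.DataFrame  # S = Z + |min Z|
    min_z: pd.Series  # minimum signed deviation per biomarker


@dataclass
class IBRResult:
    """One star plot: ordered scores, per-segment areas and the summed index."""

    scores: np.ndarray
    areas: np.ndarray
    alpha: float
    value: float
    closed: bool
    variant: str
    betas: np.ndarray | None = None
    species: str | None = None
    condition: tuple | None = None

    def vertices(self) -> pd.DataFrame:
        """Polar star-plot vertex coordinates (clockwise spokes)."""
        n = len(self.scores)
        return pd.DataFrame(
            {
                "spoke": np.arange(1, n + 1),
                "angle": -self.alpha * np.arange(n),
                "radius": self.scores,
            }
        )


def condition_means(
    matrix: pd.DataFrame,
    species: str | None = None,
    biomarkers: tuple[str, ...] = DEFAULT_BIOMARKER_ORDER,
) -> pd.DataFrame:
    """Arithmetic mean per (biomarker, condition) for one species.

    Conditions with no surviving measurements are simply absent (they do
    not appear in the matrix).  Raises DesignError if fewer than two
    conditions remain, since standardization then has no spread to use.
    """
    sub = matrix if species is None else matrix[matrix["species"] == species]
    if sub.empty:
        raise DesignError(f"condition_means: no measurements for species {species!r}")
    means = sub.groupby(CONDITION_KEYS, sort=True)[list(biomarkers)].mean()
    if len(means) < 2:
        raise DesignError(
            f"condition_means: species {species!r} has {len(means)} surviving "
            "condition(s); standardization needs >= 2"
        )
    return means


def standardize_scores(
    x: pd.DataFrame,
    directions: dict[str, str] | None = None,
    species: str = "",
    ddof: int = 1,
    on_degenerate: str = "error",
) -> ScoreSet:
    """Standardize condition means into star-plot scores.

    m and s are computed over the condition means (within-species pooling);
    s uses the sample SD (ddof=1) by default.  Direction "stimulation"
    keeps the sign (Z = Y), "inhibition" flips it (Z = -Y); all-stimulation
    is the default since the emulated panel consists of induced defenses.

    A biomarker with zero spread across conditions has no standardized
    deviation: ``on_degenerate="error"`` (default) raises naming it,
    ``"zero"`` sets its Y to 0 everywhere (a flat response carries no
    signal, so its score contributes nothing to the star area).
    """
    biomarkers = tuple(x.columns)
    directions = {b: (directions or {}).get(b, "stimulation") for b in biomarkers}
    for b, d in directions.items():
        if d not in ("stimulation", "inhibition"):
            raise DesignError(f"standardize_scores: unknown direction {d!r} for {b!r}")
    if on_degenerate not in ("error", "zero"):
        raise DesignError(f"standardize_scores: unknown on_degenerate {on_degenerate!r}")
    m = x.mean(axis=0)
    s = x.std(axis=0, ddof=ddof)
    degenerate = s[s == 0].index.tolist()
    if degenerate and on_degenerate == "error":
        raise DegeneracyError(
            f"standardize_scores: zero spread across conditions for biomarker(s) {degenerate}"
        )
    y = (x - m) / s.replace(0.0, np.nan)
    y = y.fillna(0.0)
    sign = pd.Series({b: 1.0 if directions[b] == "stimulation" else -1.0 for b in biomarkers})
    z = y * sign
    min_z = z.min(axis=0)
    score = z + min_z.abs()
    return ScoreSet(
        species=species, biomarkers=biomarkers, directions=directions,
        m=m, s=s, x=x, y=y, z=z, score=score, min_z=min_z,
    )


def star_area(
    scores,
    closed: bool = True,
    variant: str = "triangle",
    species: str | None = None,
    condition: tuple | None = None,
) -> IBRResult:
    """Area-based index of an ordered, non-negative score vector.

    variant="triangle" (default): exact star-polygon area, A_i = 1/2 *
    S_i * S_{i+1} * sin(2*pi/n).  variant="beta": the historical
    beta-angle expression, computed for audit; it does not equal the
    polygon area in general.
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    if n < 3:
        raise GeometryError(f"star_area: need >= 3 scores, got {n}")
    if (s < 0).any():
        raise GeometryError("star_area: scores must be non-negative")
    if variant not in ("triangle", "beta"):
        raise GeometryError(f"star_area: unknown variant {variant!r}")
    alpha = 2.0 * math.pi / n
    nxt = np.roll(s, -1)  # S_{i+1} with wrap-around
    k = n if closed else n - 1
    betas = None
    if variant == "triangle":
        areas = 0.5 * s * nxt * math.sin(alpha)
    else:
        betas = np.arctan2(nxt * math.sin(alpha), s - nxt * math.cos(alpha))
        areas = 0.5 * s * np.sin(betas) * (s * np.cos(betas) + nxt * np.sin(betas))
    areas = areas[:k]
    if betas is not None:
        betas = betas[:k]
    return IBRResult(
        scores=s, areas=areas, alpha=alpha, value=float(areas.sum()),
        closed=closed, variant=variant, betas=betas,
        species=species, condition=condition,
    )


def ibr_table(
    matrix: pd.DataFrame,
    biomarkers: tuple[str, ...] = DEFAULT_BIOMARKER_ORDER,
    directions: dict[str, str] | None = None,
    closed: bool = True,
    pooling: str = "condition_means",
    ddof: int = 1,
    on_degenerate: str = "error",
    return_scores: bool = False,
):
    """One IBR per surviving (species, temperature, predation) cell.

    Standardization is pooled WITHIN species across that species'
    surviving conditions.  ``pooling="replicates"`` instead computes m and
    s from the raw replicate values of the species (the alternative
    reading of "overall mean"); condition means X are unchanged.
    Missing (all-dead) cells are dropped, never imputed.
    """
    if pooling not in ("condition_means", "replicates"):
        raise DesignError(f"ibr_table: unknown pooling {pooling!r}")
    rows = []
    score_sets: dict[str, ScoreSet] = {}
    for species in pd.unique(matrix["species"]):
        x = condition_means(matrix, species, biomarkers)
        ss = standardize_scores(
            x, directions, species=species, ddof=ddof, on_degenerate=on_degenerate
        )
        if pooling == "replicates":
            raw = matrix.loc[matrix["species"] == species, list(biomarkers)]
            m = raw.mean(axis=0)
            s = raw.std(axis=0, ddof=ddof)
            if (s == 0).any():
                raise DegeneracyError(f"ibr_table: zero replicate spread for {species!r}")
            y = (x - m) / s
            sign = pd.Series(
                {b: 1.0 if ss.directions[b] == "stimulation" else -1.0 for b in biomarkers}
            )
            z = y * sign
            score = z + z.min(axis=0).abs()
            ss = ScoreSet(
                species=species, biomarkers=tuple(biomarkers), directions=ss.directions,
                m=m, s=s, x=x, y=y, z=z, score=score, min_z=z.min(axis=0),
            )
        score_sets[species] = ss
        for cond, srow in ss.score.iterrows():
            res = star_area(
                srow[list(biomarkers)].to_numpy(), closed=closed,
                species=species, condition=cond,
            )
            row = {"species": species, "temperature": cond[0], "predation": cond[1]}
            for b in biomarkers:
                row[f"s_{b}"] = float(srow[b])
            row["ibr"] = res.value
            rows.append(row)
    table = pd.DataFrame(rows)
    return (table, score_sets) if return_scores else table


def ibr_anova(ibr: pd.DataFrame, response: str = "ibr") -> dict[str, TestResult]:
    """Two-factor (temperature x predation) Type III ANOVA on IBR values.

    Species x condition IBRs are the replicate observations; the design
    may be unbalanced (missing highest-temperature cells), which is why
    marginal (Yates weighted-squares-of-means) sums of squares are used,
    via sum-to-zero factor coding.
    """
    for factor in ("temperature", "predation"):
        counts = ibr[factor].value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise DesignError(
                f"ibr_anova: factor {factor!r} needs >= 2 levels with >= 2 observations each"
            )
    values = ibr[response].to_numpy(dtype=float)
    terms = ("temperature", "predation", "temperature:predation")
    if np.allclose(values, values[0]):
        return {t: TestResult("F", 0.0, (0.0, 0.0), 1.0, term=t) for t in terms}
    data = ibr.copy()
    model = ols(
        f"{response} ~ C(temperature, Sum) * C(predation, Sum)", data=data
    ).fit()
    tbl = sm.stats.anova_lm(model, typ=3)
    rename = {
        "C(temperature, Sum)": "temperature",
        "C(predation, Sum)": "predation",
        "C(temperature, Sum):C(predation, Sum)": "temperature:predation",
    }
    resid_df = float(tbl.loc["Residual", "df"])
    out = {}
    for raw, term in rename.items():
        row = tbl.loc[raw]
        out[term] = TestResult(
            name="F",
            statistic=float(row["F"]),
            df=(float(row["df"]), resid_df),
            pvalue=float(row["PR(>F)"]),
            term=term,
        )
    return out
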