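"""Plate-assay quantification: standard curves, interpolation, normalization.

Converts raw microplate absorbances into biomarker concentrations via
ordinary-least-squares linear calibration (absorbance = slope x conc +
intercept), then normalizes per total protein.  Calibration ranges follow
the assays the pipeline emulates: Bradford total protein against BSA
standards 0-2.0 mg ml-1 read at 595 nm; indirect ELISAs for Hsp70 and
total ubiquitin against purified-protein standards 0-2.0 mg ml-1 read at
405 nm; Trolox-equivalent total antioxidant capacity 0-0.330 mM read at
410 nm.

Sample duplicates are averaged before interpolation; values interpolated
outside the standard range are flagged ``extrapolated`` and duplicate
coefficients of variation above a QC threshold (default 20%) are flagged
``high_cv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateCurveError, NormalizationError

#: Published calibration range per assay kind (units: mg ml-1, TAC in mM).
STANDARD_RANGES: dict[str, tuple[float, float]] = {
    "bradford": (0.0, 2.0),
    "hsp70_elisa": (0.0, 2.0),
    "ub_elisa": (0.0, 2.0),
    "tac": (0.0, 0.330),
}

#: Read wavelength (nm) per assay kind.
WAVELENGTHS: dict[str, int] = {
    "bradford": 595,
    "hsp70_elisa": 405,
    "ub_elisa": 405,
    "tac": 410,
}

#: Default duplicate-CV QC threshold (fraction, common plate practice).
DEFAULT_CV_THRESHOLD = 0.20


@dataclass
class PlateAssay:
    """One plate: known standards plus replicated sample absorbances."""

    assay_kind: str
    standards: list[tuple[float, float]]  # (known concentration, absorbance)
    samples: list[tuple[str, tuple[float, ...]]]  # (sample id, replicate absorbances)
    wavelength: int | None = None

    def __post_init__(self) -> None:
        if self.assay_kind not in STANDARD_RANGES:
            raise ValueError(f"unknown assay kind {self.assay_kind!r}")
        if self.wavelength is None:
            self.wavelength = WAVELENGTHS[self.assay_kind]
        if len({c for c, _ in self.standards}) < 2:
            raise DegenerateCurveError(
                f"{self.assay_kind}: need >= 2 distinct standard concentrations"
            )
        for sid, reps in self.samples:
            if len(reps) < 1:
                raise ValueError(f"sample {sid!r}: at least one absorbance reading required")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (well, role, sample_id, replicate, concentration, absorbance)."""
        rows = []
        for i, (conc, absorb) in enumerate(self.standards):
            rows.append(
                {"role": "standard", "sample_id": f"STD{i}", "replicate": 1,
                 "concentration": conc, "absorbance": absorb}
            )
        for sid, reps in self.samples:
            for j, absorb in enumerate(reps, start=1):
                rows.append(
                    {"role": "sample", "sample_id": sid, "replicate": j,
                     "concentration": np.nan, "absorbance": absorb}
                )
        df = pd.DataFrame(rows)
        df.insert(0, "assay_kind", self.assay_kind)
        df.insert(1, "wavelength", self.wavelength)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateAssay":
        kind = str(df["assay_kind"].iloc[0])
        std = df[df["role"] == "standard"]
        standards = list(zip(std["concentration"].astype(float), std["absorbance"].astype(float)))
        samples = []
        for sid, grp in df[df["role"] == "sample"].groupby("sample_id", sort=False):
            samples.append((str(sid), tuple(grp["absorbance"].astype(float))))
        return cls(assay_kind=kind, standards=standards, samples=samples)


@dataclass
class CurveFit:
    """An OLS calibration line with its validity range."""

    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float

    def invert(self, absorbance: float) -> float:
        """Concentration at a given absorbance."""
        if self.slope == 0:
            raise DegenerateCurveError("cannot invert a zero-slope curve")
        return (absorbance - self.intercept) / self.slope


@dataclass
class BiomarkerMeasurement:
    """Protein-normalized biomarker concentrations for one sample."""

    sample_id: str
    total_protein: float  # mg ml-1
    hsp70: float | None = None  # ug mg-1 protein
    ub: float | None = None  # ug mg-1 protein
    tac: float | None = None  # mM mg-1 protein
    flags: list[str] = field(default_factory=list)


def fit_standard_curve(assay: PlateAssay) -> CurveFit:
    """OLS line absorbance = slope x concentration + intercept over the standards."""
    conc = np.array([c for c, _ in assay.standards], dtype=float)
    absorb = np.array([a for _, a in assay.standards], dtype=float)
    if np.unique(conc).size < 2:
        raise DegenerateCurveError("standards are rank-deficient (single concentration)")
    res = stats.linregress(conc, absorb)
    return CurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        conc_min=float(conc.min()),
        conc_max=float(conc.max()),
    )


def quantify(
    assay: PlateAssay,
    curve: CurveFit | None = None,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> pd.DataFrame:
    """Interpolate sample concentrations from a standard curve.

    Duplicates are averaged first; concentration = (mean absorbance -
    intercept) / slope.  Returns one row per sample with columns
    sample_id, concentration, cv, extrapolated, high_cv.
    """
    if curve is None:
        curve = fit_standard_curve(assay)
    if curve.slope == 0:
        raise DegenerateCurveError("quantify: degenerate curve with zero slope")
    rows = []
    for sid, reps in assay.samples:
        arr = np.asarray(reps, dtype=float)
        mean_abs = float(arr.mean())
        conc = curve.invert(mean_abs)
        cv = float(arr.std(ddof=1) / abs(mean_abs)) if arr.size > 1 and mean_abs != 0 else 0.0
        rows.append(
            {
                "sample_id": sid,
                "concentration": conc,
                "cv": cv,
                "extrapolated": not (curve.conc_min <= conc <= curve.conc_max),
                "high_cv": cv > cv_threshold,
            }
        )
    return pd.DataFrame(rows)


def normalize_to_protein(raw_conc, total_protein_conc):
    """Normalize a biomarker concentration per total protein.

    Unit bookkeeping: ug ml-1 / (mg ml-1) -> ug mg-1; mM / (mg ml-1) ->
    mM mg-1 (volume-matched homogenate).  Accepts scalars or arrays;
    raises NormalizationError on non-positive protein.
    """
    protein = np.asarray(total_protein_conc, dtype=float)
    if (protein <= 0).any():
        raise NormalizationError("total protein must be > 0 for normalization")
    result = np.asarray(raw_conc, dtype=float) / protein
    return float(result) if result.ndim == 0 else result


def measure_sample(
    sample_id: str,
    protein_conc: float,
    raw: dict[str, float],
    cv_flags: list[str] | None = None,
) -> BiomarkerMeasurement:
    """Assemble a protein-normalized measurement record for one sample."""
    if protein_conc <= 0:
        raise NormalizationError(f"sample {sample_id!r}: total protein must be > 0")
    return BiomarkerMeasurement(
        sample_id=sample_id,
        total_protein=protein_conc,
        hsp70=normalize_to_protein(raw["hsp70"], protein_conc) if "hsp70" in raw else None,
        ub=normalize_to_protein(raw["ub"], protein_conc) if "ub" in raw else None,
        tac=normalize_to_protein(raw["tac"], protein_conc) if "tac" in raw else None,
        flags=list(cv_flags or []),
    )
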