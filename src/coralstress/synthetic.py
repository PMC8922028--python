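"""Seeded synthetic data for the crossed species x temperature x predation design.

The generator emulates the experiment the analysis pipeline assumes:
seven coral species (four thermosensitive, three thermotolerant) held for
60 days at 26/30/32 degC with and without a simulated predation wound,
10 fragments per cell (420 total), end-point visual condition scoring,
100% mortality of the thermosensitive species at 32 degC, and five
fragments per surviving cell sampled for biomarker assays (Hsp70, total
ubiquitin, total antioxidant capacity).

Biomarker levels follow a multiplicative model with lognormal noise —
concentrations are positive and right-skewed, so noise is applied on the
log scale:

    value = baseline * temp_mult * predation_mult * interaction_mult * exp(eps),
    eps ~ Normal(0, sigma)

Default effect multipliers trace the qualitative trends the experiment
reported: all biomarkers low at 26 degC, TAC and Hsp70 peaking at 30 degC,
ubiquitin rising further at 32 degC, predation raising Hsp70/Ub and
lowering TAC.  Magnitudes are the package's own calibration (the source
experiment reports no effect sizes); see docs/methods.md.

A single global seed is split into independent substreams per stage so a
stage can be regenerated without re-running the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import PlateAssay, STANDARD_RANGES
from .datasets import CONDITION_CATEGORIES, MORPHOLOGY, THERMAL_SENSITIVITY
from .exceptions import (
    ConfigurationError,
    DegenerateCurveError,
    ModelCoverageError,
    SamplingError,
)

SENSITIVITIES = ("thermosensitive", "thermotolerant")
STRATEGIES = ("inducible", "constitutive", "biphasic")
BIOMARKERS = ("hsp70", "ub", "tac")
PREDATION_LEVELS = ("no_lesion", "lesion")


@dataclass(frozen=True)
class SpeciesArchetype:
    """One simulated species: its name, thermal sensitivity class and the
    cellular response strategy that shapes its biomarker multipliers."""

    name: str
    sensitivity: str
    strategy: str
    morphology: str = "branching"

    def __post_init__(self) -> None:
        if self.sensitivity not in SENSITIVITIES:
            raise ConfigurationError(
                f"species_archetypes: unknown sensitivity {self.sensitivity!r}"
            )
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(
                f"species_archetypes: unknown response_strategy {self.strategy!r}"
            )


def default_archetypes() -> tuple[SpeciesArchetype, ...]:
    """The seven species of the emulated experiment.

    Response strategies are assigned from the reported biomarker profiles:
    constitutive for species with high standing defenses (E. lamellosa's
    TAC, P. contigua's Hsp70/Ub), biphasic for species whose condition
    degraded sharply past 30 degC, inducible otherwise.
    """
    strategies = {
        "Acropora tenuis": "inducible",
        "Echinopora lamellosa": "constitutive",
        "Montipora capricornis BM": "biphasic",
        "Montipora capricornis GM": "inducible",
        "Galaxea fascicularis": "biphasic",
        "Psammocora contigua": "constitutive",
        "Turbinaria reniformis": "inducible",
    }
    return tuple(
        SpeciesArchetype(name, THERMAL_SENSITIVITY[name], strategies[name], MORPHOLOGY[name])
        for name in THERMAL_SENSITIVITY
    )


@dataclass
class DesignConfig:
    """Factorial design: species archetypes x temperatures x predation levels.

    Defaults reproduce the emulated experiment's 7 x 3 x 2 design with 10
    fragments per cell (420 fragments) and 5 biomarker replicates sampled
    per surviving cell.
    """

    species_archetypes: tuple[SpeciesArchetype, ...] = field(default_factory=default_archetypes)
    temperatures: tuple[int, ...] = (26, 30, 32)
    predation_levels: tuple[str, ...] = PREDATION_LEVELS
    fragments_per_cell: int = 10
    biomarker_replicates: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not self.species_archetypes:
            raise ConfigurationError("species_archetypes: at least one species required")
        if not self.temperatures:
            raise ConfigurationError("temperatures: at least one level required")
        if not self.predation_levels:
            raise ConfigurationError("predation_levels: at least one level required")
        if self.fragments_per_cell < 1:
            raise ConfigurationError("fragments_per_cell: must be >= 1")
        if self.biomarker_replicates < 1:
            raise ConfigurationError("biomarker_replicates: must be >= 1")
        if self.fragments_per_cell < self.biomarker_replicates:
            raise ConfigurationError(
                "fragments_per_cell: must be >= biomarker_replicates "
                f"({self.fragments_per_cell} < {self.biomarker_replicates})"
            )
        names = [a.name for a in self.species_archetypes]
        if len(set(names)) != len(names):
            raise ConfigurationError("species_archetypes: duplicate species names")

    # Independent substreams per stage so stages can be regenerated alone.
    def rng(self, stage: str) -> np.random.Generator:
        offsets = {"condition": 1, "biomarkers": 2, "plates": 3}
        if stage not in offsets:
            raise ConfigurationError(f"unknown rng stage {stage!r}")
        ss = np.random.SeedSequence(self.seed, spawn_key=(offsets[stage],))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# condition model
# ---------------------------------------------------------------------------

ConditionKey = tuple[str, int, str]  # (sensitivity, temperature, predation)


@dataclass
class ConditionModel:
    """Multinomial end-point condition probabilities per design cell.

    ``probs`` maps (sensitivity, temperature, predation) to a probability
    vector over (normal, pale, bleached, dead).
    """

    probs: dict[ConditionKey, tuple[float, float, float, float]]

    def validate(self) -> None:
        for key, p in self.probs.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (4,) or (arr < 0).any():
                raise ConfigurationError(f"condition probabilities for {key}: invalid vector")
            if abs(arr.sum() - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"condition probabilities for {key}: sum {arr.sum()!r} != 1"
                )

    def vector(self, key: ConditionKey) -> np.ndarray:
        try:
            return np.asarray(self.probs[key], dtype=float)
        except KeyError:
            raise ModelCoverageError(
                f"no condition probabilities for cell {key}"
            ) from None


def default_condition_model(temperatures: tuple[int, ...] = (26, 30, 32)) -> ConditionModel:
    """Condition probabilities read off the published group-level frequencies.

    Thermosensitive species are deterministically dead at the highest
    temperature (the 100%-mortality outcome the design must emulate).
    Vectors are the sensitivity-group mean percentages at full precision,
    renormalized to sum exactly to 1.
    """
    t26, t30, t32 = temperatures
    raw: dict[ConditionKey, tuple[float, float, float, float]] = {
        ("thermosensitive", t26, "no_lesion"): (1.0, 0.0, 0.0, 0.0),
        ("thermosensitive", t26, "lesion"): (0.95, 0.0, 0.0, 0.05),
        ("thermosensitive", t30, "no_lesion"): (0.85, 0.15, 0.0, 0.0),
        ("thermosensitive", t30, "lesion"): (0.775, 0.225, 0.0, 0.0),
        ("thermosensitive", t32, "no_lesion"): (0.0, 0.0, 0.0, 1.0),
        ("thermosensitive", t32, "lesion"): (0.0, 0.0, 0.0, 1.0),
        ("thermotolerant", t26, "no_lesion"): (1.0, 0.0, 0.0, 0.0),
        ("thermotolerant", t26, "lesion"): (1.0, 0.0, 0.0, 0.0),
        ("thermotolerant", t30, "no_lesion"): (0.488667, 0.511333, 0.0, 0.0),
        ("thermotolerant", t30, "lesion"): (0.366667, 0.633333, 0.0, 0.0),
        ("thermotolerant", t32, "no_lesion"): (0.133333, 0.6, 0.166667, 0.1),
        ("thermotolerant", t32, "lesion"): (0.033333, 0.566667, 0.233333, 0.166667),
    }
    probs = {}
    for key, p in raw.items():
        arr = np.asarray(p, dtype=float)
        probs[key] = tuple(arr / arr.sum())
    model = ConditionModel(probs)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# biomarker model
# ---------------------------------------------------------------------------


@dataclass
class BiomarkerParams:
    """Multiplicative response of one biomarker under one strategy."""

    baseline: float
    temp_multipliers: dict[int, float]
    predation_multiplier: float
    interaction_multiplier: float
    sigma: float

    def validate(self, name: str) -> None:
        if self.baseline <= 0:
            raise ConfigurationError(f"{name}: baseline must be > 0")
        if any(m <= 0 for m in self.temp_multipliers.values()):
            raise ConfigurationError(f"{name}: temperature multipliers must be > 0")
        if self.predation_multiplier <= 0 or self.interaction_multiplier <= 0:
            raise ConfigurationError(f"{name}: multipliers must be > 0")
        if self.sigma < 0:
            raise ConfigurationError(f"{name}: sigma must be >= 0")


@dataclass
class BiomarkerModel:
    """Per (strategy, biomarker) multiplicative parameters.

    The interaction multiplier applies when a fragment has a lesion AND is
    above control temperature (synergy of heat and wounding).
    """

    params: dict[tuple[str, str], BiomarkerParams]
    control_temperature: int = 26

    def validate(self) -> None:
        for (strategy, biomarker), p in self.params.items():
            p.validate(f"({strategy}, {biomarker})")

    def lookup(self, strategy: str, biomarker: str) -> BiomarkerParams:
        try:
            return self.params[(strategy, biomarker)]
        except KeyError:
            raise ModelCoverageError(
                f"no biomarker parameters for strategy={strategy!r}, biomarker={biomarker!r}"
            ) from None

    def expected_value(self, strategy: str, biomarker: str, temperature: int, predation: str) -> float:
        """Noise-free (median) value for a design cell."""
        p = self.lookup(strategy, biomarker)
        try:
            tm = p.temp_multipliers[temperature]
        except KeyError:
            raise ModelCoverageError(
                f"no temperature multiplier for {temperature} degC "
                f"(strategy={strategy!r}, biomarker={biomarker!r})"
            ) from None
        pm = p.predation_multiplier if predation == "lesion" else 1.0
        im = (
            p.interaction_multiplier
            if predation == "lesion" and temperature != self.control_temperature
            else 1.0
        )
        return p.baseline * tm * pm * im


def default_biomarker_model() -> BiomarkerModel:
    """Trend-faithful default effect sizes (see module docstring).

    Baselines: Hsp70 and Ub in ug mg-1 protein, TAC in mM mg-1 protein.
    """
    # (baseline, {26,30,32 multipliers}) per strategy; shared predation /
    # interaction / noise per biomarker.
    hsp70 = {
        "inducible": (1.0, {26: 1.0, 30: 2.8, 32: 1.6}),
        "constitutive": (1.6, {26: 1.0, 30: 1.7, 32: 1.3}),
        "biphasic": (1.2, {26: 1.0, 30: 2.4, 32: 0.9}),
    }
    ub = {
        "inducible": (0.8, {26: 1.0, 30: 2.0, 32: 3.5}),
        "constitutive": (1.3, {26: 1.0, 30: 1.6, 32: 2.4}),
        "biphasic": (0.9, {26: 1.0, 30: 2.1, 32: 3.0}),
    }
    tac = {
        "inducible": (0.06, {26: 1.0, 30: 2.2, 32: 1.2}),
        "constitutive": (0.10, {26: 1.0, 30: 1.6, 32: 1.1}),
        "biphasic": (0.07, {26: 1.0, 30: 2.4, 32: 0.8}),
    }
    shared = {"hsp70": (1.4, 1.1), "ub": (1.5, 1.2), "tac": (0.75, 0.85)}
    sigma = 0.3
    params: dict[tuple[str, str], BiomarkerParams] = {}
    for biomarker, table in (("hsp70", hsp70), ("ub", ub), ("tac", tac)):
        pm, im = shared[biomarker]
        for strategy, (baseline, tmult) in table.items():
            params[(strategy, biomarker)] = BiomarkerParams(baseline, dict(tmult), pm, im, sigma)
    model = BiomarkerModel(params)
    model.validate()
    return model


def null_biomarker_model(sigma: float = 0.3) -> BiomarkerModel:
    """A no-effect model: common baselines, all multipliers 1.

    Used for type-I-error calibration of the downstream factorial tests.
    """
    baselines = {"hsp70": 1.0, "ub": 0.8, "tac": 0.06}
    params = {
        (strategy, biomarker): BiomarkerParams(
            baselines[biomarker], {26: 1.0, 30: 1.0, 32: 1.0}, 1.0, 1.0, sigma
        )
        for strategy in STRATEGIES
        for biomarker in BIOMARKERS
    }
    return BiomarkerModel(params)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_design(config: DesignConfig) -> pd.DataFrame:
    """Enumerate one record per fragment of the crossed design.

    Returns a fragment table with columns fragment_id, species, morphology,
    sensitivity, strategy, temperature, predation.  Deterministic: the
    design is a plain cross product, enumerated species-major.
    """
    config.validate()
    rows = []
    i = 0
    for arch in config.species_archetypes:
        for temp in config.temperatures:
            for pred in config.predation_levels:
                for _ in range(config.fragments_per_cell):
                    rows.append(
                        {
                            "fragment_id": f"F{i:04d}",
                            "species": arch.name,
                            "morphology": arch.morphology,
                            "sensitivity": arch.sensitivity,
                            "strategy": arch.strategy,
                            "temperature": temp,
                            "predation": pred,
                        }
                    )
                    i += 1
    return pd.DataFrame(rows)


def simulate_condition_outcomes(
    design: pd.DataFrame,
    model: ConditionModel | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Assign each fragment a condition category by an independent draw.

    Probabilities come from the model cell matching the fragment's
    (sensitivity, temperature, predation).  Raises ModelCoverageError if a
    design cell has no probability vector.
    """
    model = model or default_condition_model()
    model.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = design.copy()
    conditions = np.empty(len(design), dtype=object)
    for idx, row in enumerate(design.itertuples(index=False)):
        p = model.vector((row.sensitivity, row.temperature, row.predation))
        conditions[idx] = CONDITION_CATEGORIES[rng.choice(4, p=p)]
    out["condition"] = conditions
    return out


def simulate_biomarkers(
    design: pd.DataFrame,
    model: BiomarkerModel | None = None,
    seed: int | np.random.Generator = 0,
    replicates: int = 5,
    on_shortfall: str = "error",
) -> pd.DataFrame:
    """Draw normalized biomarker values for sampled surviving fragments.

    From every cell with at least one non-dead fragment, ``replicates``
    fragments are sampled without replacement and each receives one value
    per biomarker from the multiplicative lognormal model.  Cells that are
    entirely dead yield no rows, emulating the incomplete design.

    on_shortfall: "error" raises SamplingError when a surviving cell has
    fewer fragments than requested; "all" samples every survivor instead
    (what the emulated experiment did when mortality left fewer than five).
    """
    if "condition" not in design.columns:
        raise ConfigurationError("design must carry condition outcomes; run simulate_condition_outcomes first")
    if on_shortfall not in ("error", "all"):
        raise ConfigurationError(f"on_shortfall: unknown policy {on_shortfall!r}")
    model = model or default_biomarker_model()
    model.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows = []
    keys = ["species", "temperature", "predation"]
    for (species, temp, pred), cell in design.groupby(keys, sort=False):
        survivors = cell[cell["condition"] != "dead"]
        if survivors.empty:
            continue
        if len(survivors) < replicates:
            if on_shortfall == "error":
                raise SamplingError(
                    f"cell ({species}, {temp}, {pred}): {replicates} replicates "
                    f"requested but only {len(survivors)} surviving fragments"
                )
            take = len(survivors)
        else:
            take = replicates
        picked = survivors.iloc[np.sort(rng.choice(len(survivors), size=take, replace=False))]
        strategy = cell["strategy"].iloc[0]
        for frag in picked.itertuples(index=False):
            rec = {
                "fragment_id": frag.fragment_id,
                "species": species,
                "sensitivity": frag.sensitivity,
                "strategy": strategy,
                "temperature": temp,
                "predation": pred,
                "condition": frag.condition,
            }
            for biomarker in BIOMARKERS:
                mu = model.expected_value(strategy, biomarker, temp, pred)
                sigma = model.lookup(strategy, biomarker).sigma
                noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                rec[biomarker] = mu * noise
            rows.append(rec)
    return pd.DataFrame(rows)


def expected_sampled_fragments(
    config: DesignConfig, model: ConditionModel | None = None
) -> int:
    """Structural count of biomarker-sampled fragments.

    Counts ``biomarker_replicates`` for every design cell whose condition
    model leaves survivors with certainty (P(dead) < 1); deterministic-death
    cells contribute zero.  With the default design and condition model
    this is 34 cells x 5 = 170.
    """
    config.validate()
    model = model or default_condition_model(config.temperatures)
    n = 0
    for arch in config.species_archetypes:
        for temp in config.temperatures:
            for pred in config.predation_levels:
                p_dead = model.vector((arch.sensitivity, temp, pred))[3]
                if p_dead < 1.0:
                    n += config.biomarker_replicates
    return n


def simulate_plate(
    true_concentrations: dict[str, float],
    curve_slope: float,
    curve_intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    assay_kind: str = "bradford",
    n_standards: int = 9,
) -> PlateAssay:
    """Simulate a plate read: standards plus duplicate sample absorbances.

    Absorbance = slope * concentration + intercept + Normal(0, noise_sd).
    Standards span the assay's published calibration range (0-2.0 mg ml-1
    for Bradford and the ELISAs, 0-0.330 mM Trolox for TAC).
    """
    if curve_slope == 0:
        raise DegenerateCurveError("simulate_plate: slope must be non-zero")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd: must be >= 0")
    lo, hi = STANDARD_RANGES[assay_kind]
    for sid, conc in true_concentrations.items():
        if not (lo <= conc <= hi):
            raise ConfigurationError(
                f"sample {sid!r}: concentration {conc} outside standard range [{lo}, {hi}]"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def read(conc: float) -> float:
        return curve_slope * conc + curve_intercept + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)

    standards = [(float(c), read(float(c))) for c in np.linspace(lo, hi, n_standards)]
    samples = [(sid, (read(conc), read(conc))) for sid, conc in true_concentrations.items()]
    return PlateAssay(assay_kind=assay_kind, standards=standards, samples=samples)
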