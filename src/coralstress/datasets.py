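"""Published summary datasets bundled with the package.

These are the printed end-of-experiment summaries of a 60-day
7 species x 3 temperatures (26/30/32 degC) x 2 predation levels coral
stress experiment: the per-species health-condition percentage table,
its published sensitivity-group aggregation, and the 34 integrated
biomarker response (IBR) index values printed in the star-plot figure
captions.  They serve as reference inputs for the tabulation,
aggregation and inference routines; the raw fragment-level deposit is
not bundled (synthetic equivalents are generated by
:mod:`coralstress.synthetic`).
"""

from __future__ import annotations

import io

import pandas as pd

#: Species -> thermal-sensitivity class.  "thermosensitive" species showed
#: 100% mortality after 60 days at 32 degC; "thermotolerant" species survived.
THERMAL_SENSITIVITY: dict[str, str] = {
    "Acropora tenuis": "thermosensitive",
    "Echinopora lamellosa": "thermosensitive",
    "Montipora capricornis BM": "thermosensitive",
    "Montipora capricornis GM": "thermosensitive",
    "Galaxea fascicularis": "thermotolerant",
    "Psammocora contigua": "thermotolerant",
    "Turbinaria reniformis": "thermotolerant",
}

#: Species -> colony morphology.
MORPHOLOGY: dict[str, str] = {
    "Acropora tenuis": "branching",
    "Echinopora lamellosa": "plating",
    "Montipora capricornis BM": "plating",
    "Montipora capricornis GM": "encrusting",
    "Galaxea fascicularis": "massive",
    "Psammocora contigua": "branching",
    "Turbinaria reniformis": "plating",
}

CONDITION_CATEGORIES = ("normal", "pale", "bleached", "dead")

_TABLE1_SPECIES = """\
species,temperature,predation,n,normal,pale,bleached,dead
Acropora tenuis,26,no_lesion,10,100.0,0.0,0.0,0.0
Acropora tenuis,26,lesion,10,80.0,0.0,0.0,20.0
Acropora tenuis,30,no_lesion,10,100.0,0.0,0.0,0.0
Acropora tenuis,30,lesion,10,100.0,0.0,0.0,0.0
Acropora tenuis,32,no_lesion,10,0.0,0.0,0.0,100.0
Acropora tenuis,32,lesion,10,0.0,0.0,0.0,100.0
Echinopora lamellosa,26,no_lesion,10,100.0,0.0,0.0,0.0
Echinopora lamellosa,26,lesion,10,100.0,0.0,0.0,0.0
Echinopora lamellosa,30,no_lesion,10,100.0,0.0,0.0,0.0
Echinopora lamellosa,30,lesion,10,100.0,0.0,0.0,0.0
Echinopora lamellosa,32,no_lesion,10,0.0,0.0,0.0,100.0
Echinopora lamellosa,32,lesion,10,0.0,0.0,0.0,100.0
Montipora capricornis BM,26,no_lesion,10,100.0,0.0,0.0,0.0
Montipora capricornis BM,26,lesion,10,100.0,0.0,0.0,0.0
Montipora capricornis BM,30,no_lesion,10,40.0,60.0,0.0,0.0
Montipora capricornis BM,30,lesion,10,10.0,90.0,0.0,0.0
Montipora capricornis BM,32,no_lesion,10,0.0,0.0,0.0,100.0
Montipora capricornis BM,32,lesion,10,0.0,0.0,0.0,100.0
Montipora capricornis GM,26,no_lesion,10,100.0,0.0,0.0,0.0
Montipora capricornis GM,26,lesion,10,100.0,0.0,0.0,0.0
Montipora capricornis GM,30,no_lesion,10,100.0,0.0,0.0,0.0
Montipora capricornis GM,30,lesion,10,100.0,0.0,0.0,0.0
Montipora capricornis GM,32,no_lesion,10,0.0,0.0,0.0,100.0
Montipora capricornis GM,32,lesion,10,0.0,0.0,0.0,100.0
Galaxea fascicularis,26,no_lesion,10,100.0,0.0,0.0,0.0
Galaxea fascicularis,26,lesion,10,100.0,0.0,0.0,0.0
Galaxea fascicularis,30,no_lesion,10,100.0,0.0,0.0,0.0
Galaxea fascicularis,30,lesion,10,100.0,0.0,0.0,0.0
Galaxea fascicularis,32,no_lesion,10,40.0,10.0,50.0,0.0
Galaxea fascicularis,32,lesion,10,10.0,20.0,70.0,0.0
Psammocora contigua,26,no_lesion,10,100.0,0.0,0.0,0.0
Psammocora contigua,26,lesion,10,100.0,0.0,0.0,0.0
Psammocora contigua,30,no_lesion,10,37.5,62.5,0.0,0.0
Psammocora contigua,30,lesion,10,10.0,90.0,0.0,0.0
Psammocora contigua,32,no_lesion,10,0.0,70.0,0.0,30.0
Psammocora contigua,32,lesion,10,0.0,50.0,0.0,50.0
Turbinaria reniformis,26,no_lesion,10,100.0,0.0,0.0,0.0
Turbinaria reniformis,26,lesion,10,100.0,0.0,0.0,0.0
Turbinaria reniformis,30,no_lesion,10,9.1,90.9,0.0,0.0
Turbinaria reniformis,30,lesion,10,0.0,100.0,0.0,0.0
Turbinaria reniformis,32,no_lesion,10,0.0,100.0,0.0,0.0
Turbinaria reniformis,32,lesion,10,0.0,100.0,0.0,0.0
"""

# Grouped rows exactly as printed, including N = 40 for the thermotolerant
# group even though that group has only 3 species x 10 fragments = 30.
_TABLE1_GROUPED = """\
group,temperature,predation,n,normal,pale,bleached,dead
thermosensitive,26,no_lesion,40,100.0,0.0,0.0,0.0
thermosensitive,26,lesion,40,95.0,0.0,0.0,5.0
thermosensitive,30,no_lesion,40,85.0,15.0,0.0,0.0
thermosensitive,30,lesion,40,78.0,23.0,0.0,0.0
thermosensitive,32,no_lesion,40,0.0,0.0,0.0,100.0
thermosensitive,32,lesion,40,0.0,0.0,0.0,100.0
thermotolerant,26,no_lesion,40,100.0,0.0,0.0,0.0
thermotolerant,26,lesion,40,100.0,0.0,0.0,0.0
thermotolerant,30,no_lesion,40,49.0,51.0,0.0,0.0
thermotolerant,30,lesion,40,37.0,63.0,0.0,0.0
thermotolerant,32,no_lesion,40,13.0,60.0,17.0,10.0
thermotolerant,32,lesion,40,3.0,57.0,23.0,17.0
"""

_IBR_CAPTIONS = """\
species,temperature,predation,ibr
Acropora tenuis,26,no_lesion,1.29
Acropora tenuis,26,lesion,1.30
Acropora tenuis,30,no_lesion,2.07
Acropora tenuis,30,lesion,1.28
Echinopora lamellosa,26,no_lesion,4.58
Echinopora lamellosa,26,lesion,2.22
Echinopora lamellosa,30,no_lesion,4.97
Echinopora lamellosa,30,lesion,0.49
Montipora capricornis BM,26,no_lesion,2.21
Montipora capricornis BM,26,lesion,3.37
Montipora capricornis BM,30,no_lesion,6.86
Montipora capricornis BM,30,lesion,1.22
Montipora capricornis GM,26,no_lesion,3.00
Montipora capricornis GM,26,lesion,2.38
Montipora capricornis GM,30,no_lesion,0.35
Montipora capricornis GM,30,lesion,2.48
Galaxea fascicularis,26,no_lesion,0.47
Galaxea fascicularis,26,lesion,3.85
Galaxea fascicularis,30,no_lesion,3.63
Galaxea fascicularis,30,lesion,0.37
Galaxea fascicularis,32,no_lesion,2.28
Galaxea fascicularis,32,lesion,1.99
Psammocora contigua,26,no_lesion,2.05
Psammocora contigua,26,lesion,4.74
Psammocora contigua,30,no_lesion,1.17
Psammocora contigua,30,lesion,6.50
Psammocora contigua,32,no_lesion,0.13
Psammocora contigua,32,lesion,4.16
Turbinaria reniformis,26,no_lesion,1.60
Turbinaria reniformis,26,lesion,1.30
Turbinaria reniformis,30,no_lesion,0.41
Turbinaria reniformis,30,lesion,4.03
Turbinaria reniformis,32,no_lesion,1.44
Turbinaria reniformis,32,lesion,6.34
"""


def _read(csv: str) -> pd.DataFrame:
    df = pd.read_csv(io.StringIO(csv))
    if "temperature" in df.columns:
        df["temperature"] = df["temperature"].astype(int)
    return df


def condition_table() -> pd.DataFrame:
    """Per-species health-condition percentages (42 rows, 7 species x 6 cells).

    Dashes in the printed table (no fragments in a category) are encoded
    as 0.0.  Columns: species, temperature, predation, n, normal, pale,
    bleached, dead.
    """
    return _read(_TABLE1_SPECIES)


def condition_table_grouped() -> pd.DataFrame:
    """Published sensitivity-group aggregation of :func:`condition_table`.

    Values exactly as printed, including the printed N = 40 for the
    thermotolerant group (arithmetically 30; the discrepancy is in the
    source and is preserved here verbatim).
    """
    return _read(_TABLE1_GROUPED)


def ibr_values() -> pd.DataFrame:
    """The 34 published per-species, per-condition IBR index values.

    One value per surviving (species, temperature, predation) cell:
    7 species x 2 predation levels at 26 and 30 degC, plus the 3
    thermotolerant species at 32 degC.
    """
    return _read(_IBR_CAPTIONS)
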