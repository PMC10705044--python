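"""Compound database (PCDL) of parent pharmaceuticals and degradation products.

The built-in database covers the three dosed parents — diclofenac (DCF),
erythromycin (ERY), gemfibrozil (GEM) — and their literature-reported
degradation products, keyed by short codes (DCF1, ERY2, ...). Users may
supply a larger database as a delimited table in the same dialect:
columns ``code, name, formula, parent, pathway_position``.

Note on diclofenac: the parent formula used here is C14H11Cl2NO2
(molecular weight ~296.1 g/mole, consistent with diclofenac's published
properties). Its mono-hydroxylated primary degradation product DCF1 is
C14H11Cl2NO3 (~312.1). Sources occasionally swap the two formulas; the
database keeps the pair consistent with the quoted molecular weights.
"""

from __future__ import annotations

import io

import pandas as pd

from .chem import parse_formula
from .errors import DataError

DB_COLUMNS = ["code", "name", "formula", "parent", "pathway_position"]

_BUILTIN = """\
code,name,formula,parent,pathway_position
DCF,diclofenac,C14H11Cl2NO2,DCF,parent
ERY,erythromycin,C37H67NO13,ERY,parent
GEM,gemfibrozil,C15H22O3,GEM,parent
DCF1,hydroxy-diclofenac,C14H11Cl2NO3,DCF,primary
DCF2,1-(2-chloro-4-hydroxyphenyl)-3H-indol-2-one,C14H10ClNO2,DCF,secondary
DCF3,1-(4-hydroxyphenyl)-2-3-dihydro-1H-indol-2-one,C14H11NO2,DCF,tertiary
ERY1,3-depyranosyloxy-erythromycin,C29H53NO10,ERY,primary
ERY2,"7,12-dihydroxy-6-deoxyerythronolide B",C21H38O8,ERY,secondary
GEM1,5-[2-(hydroxymethyl)phenoxy]-2-2-dimethylpentanoic acid,C15H22O4,GEM,primary
GEM2,5-(2-formylphenoxy)-2-2-dimethylpentanoic acid,C15H20O4,GEM,secondary
GEM3,2-[(4-carboxy-4-methylpentyl)oxy]benzoic acid,C15H20O5,GEM,tertiary
"""


def validate_compound_db(db: pd.DataFrame) -> pd.DataFrame:
    """Check a compound table's structural invariants and return it.

    Every formula must parse; every non-parent record's ``parent`` code
    must itself be present in the table.
    """
    missing = [c for c in DB_COLUMNS if c not in db.columns]
    if missing:
        raise DataError(f"compound database missing columns: {missing}")
    if db["code"].duplicated().any():
        dupes = db.loc[db["code"].duplicated(), "code"].tolist()
        raise DataError(f"duplicate compound codes: {dupes}")
    for _, row in db.iterrows():
        parse_formula(row["formula"])  # raises FormulaError if malformed
    codes = set(db["code"])
    orphans = db.loc[~db["parent"].isin(codes), "code"].tolist()
    if orphans:
        raise DataError(f"records with unknown parent compound: {orphans}")
    return db


def default_compound_db() -> pd.DataFrame:
    """Return the built-in PCDL as a DataFrame."""
    return validate_compound_db(pd.read_csv(io.StringIO(_BUILTIN)))


def load_compound_db(path=None) -> pd.DataFrame:
    """Load a compound database from ``path``, or the built-in one."""
    if path is None:
        return default_compound_db()
    return validate_compound_db(pd.read_csv(path))


#: Codes of the parent pharmaceuticals.
PARENTS = ("DCF", "ERY", "GEM")

#: Codes of the built-in degradation products, by parent.
PRODUCTS = {
    "DCF": ("DCF1", "DCF2", "DCF3"),
    "ERY": ("ERY1", "ERY2"),
    "GEM": ("GEM1", "GEM2", "GEM3"),
}
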