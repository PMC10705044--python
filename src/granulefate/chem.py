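"""Chemical-formula arithmetic for suspect screening.

Exact masses underpin the ppm mass-error filter used to accept or reject
degradation-product peaks, so the element masses are embedded here as a
versioned constant table rather than looked up from an external resource:
results are then bit-stable across installations.

``average_mass`` uses conventional standard atomic weights (for comparing
against molecular weights quoted in g/mole); ``monoisotopic_mass`` uses the
mass of each element's most abundant isotope (what a high-resolution
time-of-flight instrument actually measures for the monoisotopic peak).
"""

from __future__ import annotations

import re

from .errors import FormulaError

#: Version tag for the embedded mass tables (CIAAW/IUPAC values).
MASS_TABLE_VERSION = "2021.1"

#: Conventional standard atomic weights, g/mole.
ATOMIC_WEIGHT: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Na": 22.98976928,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.0983,
    "Ca": 40.078,
    "Fe": 55.845,
    "Br": 79.904,
    "I": 126.90447,
}

#: Mass of each element's most abundant isotope, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.985041699,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Br": 78.9183371,
    "I": 126.904473,
}

PROTON_MASS = 1.007276466879
ELECTRON_MASS = 0.000548579909

#: Supported electrospray adducts: name -> (mass shift in Da, |charge|).
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, 1),
    "[M+Na]+": (MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, 1),
    "[M-H]-": (-PROTON_MASS, 1),
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into element counts.

    Parameters
    ----------
    formula:
        Element symbols with optional positive integer counts,
        e.g. ``"C14H11Cl2NO3"``. Repeated symbols are summed.

    Returns
    -------
    dict mapping element symbol to a positive integer count.

    Raises
    ------
    FormulaError
        If the string contains anything other than known element symbols
        and counts, or an explicit count of zero.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {formula!r} near position {pos}"
            )
        symbol, digits = match.groups()
        if symbol not in ATOMIC_WEIGHT:
            raise FormulaError(f"unknown element {symbol!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"zero count for {symbol!r} in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"trailing garbage in formula {formula!r}")
    return counts


def _mass(formula: str, table: dict[str, float]) -> float:
    counts = parse_formula(formula)
    return sum(table[el] * n for el, n in counts.items())


def average_mass(formula: str) -> float:
    """Average molecular mass (g/mole) from standard atomic weights."""
    return _mass(formula, ATOMIC_WEIGHT)


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (exact) mass in Da from most-abundant-isotope masses."""
    return _mass(formula, MONOISOTOPIC_MASS)


def adduct_mz(neutral_mass: float, adduct: str = "[M+H]+") -> float:
    """m/z of an adduct ion for a neutral monoisotopic mass.

    Raises
    ------
    ScreenError-like KeyError replacement: FormulaError for unknown adducts.
    """
    try:
        shift, charge = ADDUCTS[adduct]
    except KeyError:
        raise FormulaError(
            f"unknown adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        ) from None
    return (neutral_mass + shift) / charge


def mass_error_ppm(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass error in parts per million.

    ``1e6 * (observed - theoretical) / theoretical``; positive when the
    observed m/z is higher than theory.
    """
    if theoretical_mz <= 0:
        raise FormulaError(
            f"theoretical m/z must be positive, got {theoretical_mz}"
        )
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz
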