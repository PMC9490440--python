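"""Oxide <-> element conversions and apatite stoichiometry.

Wavelength-dispersive microprobe results are quantified as oxide weight
percent (K2O, CaO, ...) while the decision rules and most of the bone
literature quote elemental weight percent (K, Ca, ...).  The conversion is
purely gravimetric: element wt% = oxide wt% x n_el * M_el / M_oxide.
Chlorine is analysed as the element and passes through unchanged.
"""

from __future__ import annotations

from .errors import ConfigurationError

# IUPAC standard atomic weights (conventional values), g/mol.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "O": 15.999,
    "Na": 22.98977,
    "Mg": 24.305,
    "Al": 26.98154,
    "Si": 28.085,
    "P": 30.973762,
    "Cl": 35.45,
    "K": 39.0983,
    "Ca": 40.078,
    "Mn": 54.93804,
    "Fe": 55.845,
    "Sr": 87.62,
}

# analyte -> (element symbol, atoms of element, atoms of oxygen)
OXIDE_COMPOSITION: dict[str, tuple[str, int, int]] = {
    "P2O5": ("P", 2, 5),
    "Al2O3": ("Al", 2, 3),
    "Na2O": ("Na", 2, 1),
    "SiO2": ("Si", 1, 2),
    "K2O": ("K", 2, 1),
    "CaO": ("Ca", 1, 1),
    "Cl": ("Cl", 1, 0),
    "MgO": ("Mg", 1, 1),
    "SrO": ("Sr", 1, 1),
    "FeO": ("Fe", 1, 1),
    "MnO": ("Mn", 1, 1),
}

ANALYTES: tuple[str, ...] = tuple(OXIDE_COMPOSITION)
ELEMENTS: tuple[str, ...] = tuple(e for e, _, _ in OXIDE_COMPOSITION.values())


def oxide_molar_mass(oxide: str) -> float:
    try:
        element, n_el, n_o = OXIDE_COMPOSITION[oxide]
    except KeyError:
        raise ConfigurationError(f"unknown oxide analyte: {oxide!r}") from None
    return n_el * ATOMIC_MASS[element] + n_o * ATOMIC_MASS["O"]


def element_fraction(oxide: str) -> float:
    """Mass fraction of the reported element in one formula unit of oxide."""
    if oxide not in OXIDE_COMPOSITION:
        raise ConfigurationError(f"unknown oxide analyte: {oxide!r}")
    element, n_el, _ = OXIDE_COMPOSITION[oxide]
    return n_el * ATOMIC_MASS[element] / oxide_molar_mass(oxide)


def element_for(oxide: str) -> str:
    if oxide not in OXIDE_COMPOSITION:
        raise ConfigurationError(f"unknown oxide analyte: {oxide!r}")
    return OXIDE_COMPOSITION[oxide][0]


def oxide_for(element: str) -> str:
    for oxide, (el, _, _) in OXIDE_COMPOSITION.items():
        if el == element:
            return oxide
    raise ConfigurationError(f"no oxide analyte carries element {element!r}")


def hydroxyapatite_wt() -> dict[str, float]:
    """Oxide wt% implied by stoichiometric hydroxyapatite Ca10(PO4)6(OH)2.

    Useful as an analytic fixed point: the Ca/P molar ratio computed from
    these weights must equal 10/6 = 1.667.
    """
    m = ATOMIC_MASS
    mass = 10 * m["Ca"] + 6 * m["P"] + 26 * m["O"] + 2 * m["H"]
    cao = 10 * oxide_molar_mass("CaO") / mass * 100.0
    p2o5 = 3 * oxide_molar_mass("P2O5") / mass * 100.0
    return {"CaO": cao, "P2O5": p2o5}
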