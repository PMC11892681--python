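"""Monoisotopic masses and adduct m/z arithmetic.

Accurate-mass annotation works on the m/z of an ionised *adduct* of a
neutral metabolite.  The deltas below are the standard singly charged
adduct offsets (proton/electron-corrected, Da); ppm error follows the
usual convention (observed - theoretical) / theoretical * 1e6.
"""

from __future__ import annotations

from pyteomics import mass as _ptmass

#: Mass added to the neutral monoisotopic mass M for each supported adduct.
ADDUCT_DELTAS: dict[str, float] = {
    "[M+H]+": 1.007276,
    "[M-H]-": -1.007276,
    "[M+Na]+": 22.989218,
    "[M+K]+": 38.963158,
    "[M+Cl]-": 34.969402,
}

#: Conventional adduct sets per ionisation polarity.
POLARITY_ADDUCTS: dict[str, tuple[str, ...]] = {
    "positive": ("[M+H]+", "[M+Na]+", "[M+K]+"),
    "negative": ("[M-H]-", "[M+Cl]-"),
}


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic neutral mass (Da) of an elemental formula, e.g. ``C25H30N6O3``."""
    return float(_ptmass.calculate_mass(formula=formula))


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Theoretical m/z of ``adduct`` of a neutral of given monoisotopic mass.

    Raises
    ------
    KeyError
        If the adduct name is not one of :data:`ADDUCT_DELTAS`.
    ValueError
        If ``neutral_mass`` is not positive.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral_mass must be > 0, got {neutral_mass}")
    if adduct not in ADDUCT_DELTAS:
        raise KeyError(
            f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_DELTAS)}"
        )
    return neutral_mass + ADDUCT_DELTAS[adduct]


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass deviation in parts per million."""
    return (observed - theoretical) / theoretical * 1e6
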