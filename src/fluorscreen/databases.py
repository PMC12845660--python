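"""Built-in diagnostic-fragment and neutral-loss reference values.

A compact, code-generated subset of the fragment chemistry used to support
structural identification of PFAS in negative ESI: characteristic anions
(CF3-, C2F5-, SO3-, ...) and neutral losses (CO2, HF, CF2, ...). Fragment
ion m/z includes the electron mass; neutral losses are neutral masses.
"""

from __future__ import annotations

from .chem import ELECTRON_MASS, MONO_MASS, monoisotopic_mass


def _anion(formula: str) -> float:
    return monoisotopic_mass(formula) + ELECTRON_MASS


def _deprot(formula: str) -> float:
    """[X-H]- style fragment from a neutral formula."""
    return monoisotopic_mass(formula) - 1.007276


#: Diagnostic PFAS fragment anions, name -> m/z.
DIAGNOSTIC_FRAGMENTS: dict[str, float] = {
    "CF3-": _anion("CF3"),
    "C2F5-": _anion("C2F5"),
    "C3F7-": _anion("C3F7"),
    "C4F9-": _anion("C4F9"),
    "C2F5O-": _anion("C2F5O"),
    "C3F5O2-": _anion("C3F5O2"),
    "SO3-": _anion("SO3"),
    "FSO3-": _anion("FSO3"),
    "HSO3-": _anion("HSO3"),
    "SO2F- (FSO2-)": _anion("FSO2"),
    "PO3-": _anion("PO3"),
    "C2F3O2- (TFA frag)": _deprot("C2HF3O2"),
}

#: PFAS-specific neutral losses, name -> neutral mass (Da).
NEUTRAL_LOSSES: dict[str, float] = {
    "CO2": monoisotopic_mass("CO2"),
    "HF": monoisotopic_mass("HF"),
    "CF2": MONO_MASS["C"] + 2 * MONO_MASS["F"],
    "C2F4": 2 * MONO_MASS["C"] + 4 * MONO_MASS["F"],
    "CO2+HF": monoisotopic_mass("CO2") + monoisotopic_mass("HF"),
    "SO3": monoisotopic_mass("SO3"),
    "H2O": monoisotopic_mass("H2O"),
}
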