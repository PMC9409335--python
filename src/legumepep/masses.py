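"""Neutral monoisotopic mass of (modified) peptides and ppm mass error.

The calculated mass is the residue-mass sum plus one water plus the
monoisotopic deltas of any modifications:

    M = Σ m(residue) + m(H2O) + Σ Δm(mod)

Residue masses come from the standard Unimod/IUPAC monoisotopic table
(via :mod:`pyteomics`).  The default modification registry mirrors a typical
peptide-identification search: fixed carbamidomethyl-C, variable acetylation,
oxidation, deamidation and phosphorylation.  Mass error against an observed
(deconvoluted, neutral) mass is

    ppm = (observed − calculated) / observed × 10⁶
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pyteomics import mass as _ptmass

from .errors import ModificationPlacementError, RegistryError
from .sequences import PeptideSequence

#: Monoisotopic residue masses (Da), standard Unimod/IUPAC values.
RESIDUE_MASSES: dict[str, float] = dict(_ptmass.std_aa_mass)

#: Monoisotopic mass of water (Da).
WATER_MONO: float = _ptmass.calculate_mass(formula="H2O")

N_TERM = "N-term"
C_TERM = "C-term"


@dataclass(frozen=True)
class ModificationSpec:
    """A named mass shift with the residues (or terminus) it may target."""

    modification_id: str
    delta_mass_Da: float
    allowed_residues: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed_residues", frozenset(self.allowed_residues))
        if not math.isfinite(self.delta_mass_Da):
            raise ValueError(f"{self.modification_id}: delta mass must be finite")


#: Default registry with Unimod monoisotopic deltas.
DEFAULT_MODIFICATIONS: dict[str, ModificationSpec] = {
    m.modification_id: m
    for m in (
        ModificationSpec("carbamidomethyl", 57.021464, frozenset("C")),
        ModificationSpec("oxidation", 15.994915, frozenset("MW")),
        ModificationSpec("deamidation", 0.984016, frozenset("NQ")),
        ModificationSpec("acetylation", 42.010565, frozenset({"K", N_TERM})),
        ModificationSpec("phospho", 79.966331, frozenset("STY")),
    )
}


@dataclass(frozen=True)
class MassResult:
    peptide: PeptideSequence
    calculated_mass_Da: float
    observed_mass_Da: float | None = None
    ppm_error: float | None = None


def monoisotopic_mass(
    peptide: PeptideSequence | str,
    registry: dict[str, ModificationSpec] | None = None,
) -> float:
    """Neutral monoisotopic mass (Da) of a peptide with its modifications.

    Raises :class:`~legumepep.errors.RegistryError` for an unknown
    modification id and :class:`~legumepep.errors.ModificationPlacementError`
    when a modification targets a residue outside its allowed set.
    """
    pep = peptide if isinstance(peptide, PeptideSequence) else PeptideSequence(peptide)
    registry = DEFAULT_MODIFICATIONS if registry is None else registry
    total = WATER_MONO + sum(RESIDUE_MASSES[ch] for ch in pep.residues)
    n = len(pep)
    for pos, mod_id in pep.modifications:
        if mod_id not in registry:
            raise RegistryError(f"unknown modification {mod_id!r}")
        spec = registry[mod_id]
        residue = pep.residues[pos - 1]
        legal = (
            residue in spec.allowed_residues
            or (N_TERM in spec.allowed_residues and pos == 1)
            or (C_TERM in spec.allowed_residues and pos == n)
        )
        if not legal:
            raise ModificationPlacementError(
                f"{mod_id} cannot target {residue} at position {pos}"
            )
        total += spec.delta_mass_Da
    return total


def ppm_error(observed_Da: float, calculated_Da: float) -> float:
    """Mass error in parts per million, relative to the observed mass."""
    if not observed_Da > 0:
        raise ValueError("observed mass must be positive")
    return (observed_Da - calculated_Da) / observed_Da * 1e6


def mass_result(
    peptide: PeptideSequence | str,
    observed_Da: float | None = None,
    registry: dict[str, ModificationSpec] | None = None,
) -> MassResult:
    """Bundle calculated mass and (optional) ppm error for one peptide."""
    pep = peptide if isinstance(peptide, PeptideSequence) else PeptideSequence(peptide)
    calc = monoisotopic_mass(pep, registry)
    ppm = ppm_error(observed_Da, calc) if observed_Da is not None else None
    return MassResult(pep, calc, observed_Da, ppm)
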