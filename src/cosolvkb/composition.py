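"""Formulation arithmetic: mole/mass fractions, counterions, molecule counts.

These helpers reproduce the bookkeeping used to set up cosolvent mixtures
and protein formulations: converting between mole and mass fraction for a
binary solute/solvent pair, neutralising a charged protein with counterions,
and turning target mass fractions into integer molecule counts for a box of
a given reference density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AVOGADRO


def mole_to_mass_fraction(x: float, m_solute: float, m_solvent: float) -> float:
    """Mass fraction of the solute in a binary mixture at mole fraction x."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("mole fraction must lie in [0, 1]")
    if m_solute <= 0 or m_solvent <= 0:
        raise ValueError("molar masses must be positive")
    num = x * m_solute
    return num / (num + (1.0 - x) * m_solvent)


def mass_to_mole_fraction(w: float, m_solute: float, m_solvent: float) -> float:
    """Exact algebraic inverse of :func:`mole_to_mass_fraction`."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("mass fraction must lie in [0, 1]")
    if m_solute <= 0 or m_solvent <= 0:
        raise ValueError("molar masses must be positive")
    num = w / m_solute
    return num / (num + (1.0 - w) / m_solvent)


def counterion_count(net_charge: float, ion_valence: int) -> tuple[int, str]:
    """Number and sign of counterions neutralising ``net_charge``.

    Returns ``(count, "anion" | "cation")``; a +10 protein with monovalent
    chloride gives ``(10, "anion")``.  Raises if the charge is not an
    integer multiple of the ion valence.
    """
    if ion_valence == 0:
        raise ValueError("ion valence must be nonzero")
    if net_charge == 0:
        return 0, "anion" if ion_valence < 0 else "cation"
    if net_charge * ion_valence > 0:
        raise ValueError("counterion must be opposite in sign to the solute")
    ratio = abs(net_charge) / abs(ion_valence)
    count = round(ratio)
    if abs(ratio - count) > 1e-9:
        raise ValueError(
            f"charge {net_charge} is not neutralizable by valence "
            f"{ion_valence} ions")
    return count, "anion" if net_charge > 0 else "cation"


@dataclass
class SpeciesSpec:
    """One species of a formulation.

    Exactly one of ``mass_fraction``/``mole_fraction`` is set for bulk
    species; a species with ``fixed_count`` (e.g. one protein copy) ignores
    fractions and its mass is subtracted from the box total before the bulk
    mass is distributed.
    """

    name: str
    molar_mass: float
    mass_fraction: float | None = None
    mole_fraction: float | None = None
    fixed_count: int | None = None

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        if self.fixed_count is None:
            given = [f for f in (self.mass_fraction, self.mole_fraction)
                     if f is not None]
            if len(given) != 1:
                raise ValueError(
                    f"{self.name}: give exactly one of mass_fraction / "
                    f"mole_fraction (or fixed_count)")
            if not 0.0 <= given[0] <= 1.0:
                raise ValueError(f"{self.name}: fraction outside [0, 1]")


@dataclass
class FormulationSpec:
    species: list[SpeciesSpec]
    box: tuple[float, float, float]
    reference_density: float = 1.0  # g/cm^3
    protein_net_charge: float = 0.0

    def __post_init__(self):
        if self.reference_density <= 0:
            raise ValueError("reference density must be positive")
        if any(e <= 0 for e in self.box):
            raise ValueError("box edges must be positive")

    def bulk_mass_fractions(self) -> dict[str, float]:
        """Mass fractions of the non-fixed species, normalised to sum to 1."""
        bulk = [s for s in self.species if s.fixed_count is None]
        if not bulk:
            return {}
        if any(s.mole_fraction is not None for s in bulk):
            if not all(s.mole_fraction is not None for s in bulk):
                raise ValueError(
                    "mix of mole and mass fractions among bulk species")
            tot_x = sum(s.mole_fraction for s in bulk)
            if abs(tot_x - 1.0) > 1e-9:
                raise ValueError(f"mole fractions sum to {tot_x}, not 1")
            denom = sum(s.mole_fraction * s.molar_mass for s in bulk)
            return {s.name: s.mole_fraction * s.molar_mass / denom
                    for s in bulk}
        tot_w = sum(s.mass_fraction for s in bulk)
        if abs(tot_w - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {tot_w}, not 1")
        return {s.name: s.mass_fraction for s in bulk}


def molecule_counts_for_box(spec: FormulationSpec) -> dict:
    """Integer molecule counts realising a formulation in a periodic box.

    The box is filled to ``reference_density``; fixed-count species (one
    protein copy, counterions) take their share of the mass first and the
    remaining mass is split by the bulk mass fractions, with per-species
    counts rounded to the nearest integer.  Returns the counts together
    with the realized (post-rounding) bulk mass fractions.
    """
    volume_nm3 = float(np.prod(spec.box))
    total_mass_g = spec.reference_density * volume_nm3 * 1e-21
    fixed_mass = sum(s.fixed_count * s.molar_mass / AVOGADRO
                     for s in spec.species if s.fixed_count is not None)
    bulk_mass = total_mass_g - fixed_mass
    if bulk_mass < 0:
        raise ValueError("fixed species exceed the box mass budget")
    fractions = spec.bulk_mass_fractions()
    counts, realized_mass = {}, {}
    for s in spec.species:
        if s.fixed_count is not None:
            counts[s.name] = int(s.fixed_count)
            continue
        n = int(round(fractions[s.name] * bulk_mass * AVOGADRO
                      / s.molar_mass))
        counts[s.name] = n
        realized_mass[s.name] = n * s.molar_mass / AVOGADRO
    tot = sum(realized_mass.values())
    realized = {k: (v / tot if tot > 0 else 0.0)
                for k, v in realized_mass.items()}
    return {"counts": counts, "realized_mass_fractions": realized,
            "total_mass_g": total_mass_g, "volume_nm3": volume_nm3}
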