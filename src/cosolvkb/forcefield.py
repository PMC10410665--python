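"""Lennard-Jones parameter conventions, combination rules and the TBAff set.

Two equivalent parameterisations of the 12-6 potential are handled:

* sigma/epsilon:  U(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6]
* C6/C12:         U(r) = C12/r^12 - C6/r^6

related by C6 = 4 eps sigma^6 and C12 = 4 eps sigma^12.  Cross terms come
from either geometric combination on C6/C12 ("rule 1", GROMOS style) or
Lorentz-Berthelot on sigma/epsilon ("rule 2", CHARMM style), unless an
explicit pair override is registered — overrides always win.

The packaged TBAff set describes tert-butyl alcohol with a united-atom
hydroxyl hydrogen (all-zero LJ parameters), an oxygen, a central carbon and
a methyl type, plus refitted carbon-oxygen and methyl-oxygen pair terms
that deliberately do not follow either combination rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Achievable self-consistency between the two published conventions given
# 4-significant-figure sigma/epsilon values.
SELF_CONSISTENCY_RTOL = 1e-3

GEOMETRIC = "geometric_c6c12"
LORENTZ_BERTHELOT = "lorentz_berthelot"
_RULES = (GEOMETRIC, LORENTZ_BERTHELOT)


def sigma_eps_to_c6c12(sigma: float, epsilon: float) -> tuple[float, float]:
    """Convert (sigma [nm], epsilon [kJ/mol]) to (C6 [nm^6 kJ/mol], C12)."""
    if sigma < 0 or epsilon < 0:
        raise ValueError("sigma and epsilon must be >= 0")
    return 4.0 * epsilon * sigma**6, 4.0 * epsilon * sigma**12


def c6c12_to_sigma_eps(c6: float, c12: float) -> tuple[float, float]:
    """Convert (C6, C12) to (sigma, epsilon); (0, 0) maps to (0, 0)."""
    if c6 < 0 or c12 < 0:
        raise ValueError("C6 and C12 must be >= 0")
    if c6 == 0 and c12 == 0:
        return 0.0, 0.0
    if c6 == 0 or c12 == 0:
        raise ValueError("exactly one of C6/C12 zero: sigma/eps undefined")
    return (c12 / c6) ** (1.0 / 6.0), c6 * c6 / (4.0 * c12)


@dataclass
class LJAtomType:
    """One atom type with both LJ representations populated.

    ``convention`` records which representation is primary (as published in
    the source table); the other is derived on construction when absent.
    """

    name: str
    sigma: float = 0.0
    epsilon: float = 0.0
    c6: float = 0.0
    c12: float = 0.0
    convention: str = "sigma_eps"

    @classmethod
    def from_sigma_eps(cls, name, sigma, epsilon):
        c6, c12 = sigma_eps_to_c6c12(sigma, epsilon)
        return cls(name, sigma, epsilon, c6, c12, convention="sigma_eps")

    @classmethod
    def from_c6_c12(cls, name, c6, c12):
        sigma, epsilon = c6c12_to_sigma_eps(c6, c12)
        return cls(name, sigma, epsilon, c6, c12, convention="c6_c12")

    def __post_init__(self):
        for v in (self.sigma, self.epsilon, self.c6, self.c12):
            if v < 0:
                raise ValueError("LJ parameters must be >= 0")
        if self.convention not in ("sigma_eps", "c6_c12"):
            raise ValueError(f"unknown convention {self.convention!r}")

    def check_consistency(self, rtol: float = SELF_CONSISTENCY_RTOL) -> None:
        """Verify the two representations agree (relative ``rtol``)."""
        if self.epsilon == 0 and self.c6 == 0 and self.c12 == 0:
            return
        c6, c12 = sigma_eps_to_c6c12(self.sigma, self.epsilon)
        for have, want, label in ((self.c6, c6, "C6"), (self.c12, c12, "C12")):
            if want == 0 and have == 0:
                continue
            if abs(have - want) > rtol * max(abs(want), abs(have)):
                raise ValueError(
                    f"{self.name}: {label} inconsistent between "
                    f"representations ({have} vs {want})")


@dataclass
class LJPairOverride:
    """Explicit cross-term parameters for one unordered type pair."""

    type_a: str
    type_b: str
    parameters: LJAtomType

    @property
    def key(self) -> frozenset:
        return frozenset((self.type_a, self.type_b))


@dataclass
class LJParameterSet:
    convention_label: str
    rule: str
    atom_types: dict[str, LJAtomType] = field(default_factory=dict)
    overrides: dict[frozenset, LJPairOverride] = field(default_factory=dict)

    def __post_init__(self):
        if self.rule not in _RULES:
            raise ValueError(f"unknown combination rule {self.rule!r}")

    def add_atom_type(self, t: LJAtomType) -> None:
        if t.name in self.atom_types:
            raise ValueError(f"duplicate atom type {t.name!r}")
        self.atom_types[t.name] = t

    def add_override(self, ov: LJPairOverride) -> None:
        for label in (ov.type_a, ov.type_b):
            if label not in self.atom_types:
                raise ValueError(f"override references unknown type {label!r}")
        self.overrides[ov.key] = ov


def combine_pair(pset: LJParameterSet, type_a: str, type_b: str) -> LJAtomType:
    """Effective pair parameters: override if present, else the set's rule."""
    for label in (type_a, type_b):
        if label not in pset.atom_types:
            raise KeyError(f"unknown atom type {label!r}")
    ov = pset.overrides.get(frozenset((type_a, type_b)))
    if ov is not None:
        return ov.parameters
    ta, tb = pset.atom_types[type_a], pset.atom_types[type_b]
    if pset.rule == GEOMETRIC:
        c6 = (ta.c6 * tb.c6) ** 0.5
        c12 = (ta.c12 * tb.c12) ** 0.5
        if c6 == 0 or c12 == 0:
            return LJAtomType(f"{type_a}-{type_b}", 0.0, 0.0, c6, c12,
                              convention="c6_c12")
        return LJAtomType.from_c6_c12(f"{type_a}-{type_b}", c6, c12)
    sigma = 0.5 * (ta.sigma + tb.sigma)
    epsilon = (ta.epsilon * tb.epsilon) ** 0.5
    return LJAtomType.from_sigma_eps(f"{type_a}-{type_b}", sigma, epsilon)


# ------------------------------------------------------------- TBAff ------

SPCE_RULE1 = "spce_rule1"
CHARMM_TIP3P_RULE2 = "charmm_tip3p_rule2"

# (C6 [nm^6 kJ/mol], C12 [nm^12 kJ/mol]) — rule-1 column, and
# (sigma [nm], epsilon [kJ/mol]) — rule-2 column, as published.
_TBAFF_SELF = {
    "hydrogen": ((0.0, 0.0), (0.0, 0.0)),
    "oxygen": ((2.261954e-03, 1.505529e-06), (0.2955, 0.8496)),
    "carbon": ((2.397081e-03, 2.053489e-04), (0.6639, 0.007)),
    "methyl": ((9.613802e-03, 2.664624e-05), (0.3748, 0.8672)),
}
_TBAFF_PAIRS = {
    ("carbon", "oxygen"): ((2.1344443e-03, 1.950104e-07), (0.3846, 0.1123)),
    ("methyl", "oxygen"): ((5.321969e-04, 1.502845e-06), (0.3271, 0.4492)),
}


def tbaff_parameters(convention: str) -> LJParameterSet:
    """The packaged TBAff nonbonded parameter set for tert-butyl alcohol.

    ``spce_rule1`` carries the C6/C12 column (geometric combination, for use
    with SPC/E water); ``charmm_tip3p_rule2`` carries the sigma/epsilon
    column (Lorentz-Berthelot, for use with CHARMM TIP3P water).  Both
    include the refitted carbon-oxygen and methyl-oxygen pair overrides.
    """
    if convention == SPCE_RULE1:
        col, rule = 0, GEOMETRIC
        label = "SPCE/combination rule 1"
    elif convention == CHARMM_TIP3P_RULE2:
        col, rule = 1, LORENTZ_BERTHELOT
        label = "CHARMM TIP3P/combination rule 2"
    else:
        raise ValueError(f"unknown TBAff convention {convention!r}")
    pset = LJParameterSet(convention_label=label, rule=rule)
    for name, cols in _TBAFF_SELF.items():
        a, b = cols[col]
        if a == 0 and b == 0:
            t = LJAtomType(name, convention="c6_c12" if col == 0
                           else "sigma_eps")
        elif col == 0:
            t = LJAtomType.from_c6_c12(name, a, b)
        else:
            t = LJAtomType.from_sigma_eps(name, a, b)
        pset.add_atom_type(t)
    for (ta, tb), cols in _TBAFF_PAIRS.items():
        a, b = cols[col]
        if col == 0:
            p = LJAtomType.from_c6_c12(f"{ta}-{tb}", a, b)
        else:
            p = LJAtomType.from_sigma_eps(f"{ta}-{tb}", a, b)
        pset.add_override(LJPairOverride(ta, tb, p))
    return pset


# ------------------------------------------------- parameter file I/O ------

def _fmt(x: float) -> str:
    return f"{x:.10g}"


def write_parameter_file(pset: LJParameterSet, path) -> None:
    """Write a topology-include-style text file for the set.

    The dialect has a ``[ meta ]`` section, one ``[ atomtypes ]`` line per
    type (name sigma epsilon c6 c12 convention) and one ``[ pairtypes ]``
    line per override.  Ordering is insertion order, so write -> read ->
    write is a fixed point.
    """
    if not pset.atom_types:
        raise ValueError("refusing to write an empty parameter set")
    lines = ["; cosolvkb LJ parameter set", "[ meta ]",
             f"convention_label = {pset.convention_label}",
             f"rule = {pset.rule}", "[ atomtypes ]",
             "; name sigma epsilon c6 c12 convention"]
    for t in pset.atom_types.values():
        lines.append(f"{t.name} {_fmt(t.sigma)} {_fmt(t.epsilon)} "
                     f"{_fmt(t.c6)} {_fmt(t.c12)} {t.convention}")
    lines.append("[ pairtypes ]")
    lines.append("; type_a type_b sigma epsilon c6 c12 convention")
    for ov in pset.overrides.values():
        p = ov.parameters
        lines.append(f"{ov.type_a} {ov.type_b} {_fmt(p.sigma)} "
                     f"{_fmt(p.epsilon)} {_fmt(p.c6)} {_fmt(p.c12)} "
                     f"{p.convention}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_parameter_file(path) -> LJParameterSet:
    """Read a file written by :func:`write_parameter_file`."""
    meta, atoms, pairs = {}, [], []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] ").lower()
                continue
            if section == "meta":
                key, _, val = line.partition("=")
                meta[key.strip()] = val.strip()
            elif section == "atomtypes":
                toks = line.split()
                atoms.append(LJAtomType(
                    toks[0], float(toks[1]), float(toks[2]),
                    float(toks[3]), float(toks[4]), toks[5]))
            elif section == "pairtypes":
                toks = line.split()
                pairs.append(LJPairOverride(
                    toks[0], toks[1],
                    LJAtomType(f"{toks[0]}-{toks[1]}", float(toks[2]),
                               float(toks[3]), float(toks[4]),
                               float(toks[5]), toks[6])))
    pset = LJParameterSet(convention_label=meta.get("convention_label", ""),
                          rule=meta.get("rule", GEOMETRIC))
    for t in atoms:
        pset.add_atom_type(t)
    for p in pairs:
        pset.add_override(p)
    return pset
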