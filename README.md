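# cosolvkb

Analysis toolkit for cosolvent–protein molecular simulations: Kirkwood–Buff
integrals from finite-size-corrected radial distribution functions,
β-parameter preferential-inclusion profiles measured from the protein
surface, per-residue cosolvent contact occupancy, interfacial density
profiles, and compactness/surface descriptors (radius of gyration,
solvent-accessible surface area with hydrophobic fraction). It also packages
the TBAff nonbonded parameter set for *tert*-butyl alcohol (TBA) in both
Lennard-Jones conventions, plus the formulation arithmetic (mole/mass
fractions, counterions, molecule counts) used to set such systems up.

The intended users are simulators of protein formulations — e.g. myoglobin
in TBA/water co-solvent mixtures with sugar or cyclodextrin excipients —
who need to quantify whether a cosolute is preferentially included at or
excluded from the protein surface, and how it behaves at the air–water
interface.

## The quantities computed

**Kirkwood–Buff integral.** For species *i*, *j* with pair correlation
g<sub>ij</sub>(r),

&nbsp;&nbsp;&nbsp;&nbsp;G<sub>ij</sub>(R) = ∫₀ᴿ [g<sub>ij</sub>(r) − 1] 4πr² dr ,

with G > 0 indicating net accumulation of *j* around *i* and G < 0
exclusion. Closed-system (N,V) simulations bias g at order 1/N; the
excess-particle correction

&nbsp;&nbsp;&nbsp;&nbsp;g<sup>corr</sup>(r) = g(r) ·
N<sub>j</sub>(1 − v(r)/V) / [N<sub>j</sub>(1 − v(r)/V) − ΔN<sub>j</sub>(r) − δ<sub>ij</sub>]

(v(r) the sphere volume, ΔN<sub>j</sub>(r) the running excess of *j* within
r) removes the bias so the running integral plateaus at the open-system
value. The plateau is reported as a window mean with its standard
deviation as a convergence diagnostic.

**β-parameter profile.** With n(r) the frame-averaged cumulative number of
molecules whose centre of mass lies within distance r of the protein
surface (minimum over protein atoms),

&nbsp;&nbsp;&nbsp;&nbsp;β(r) = [n<sub>solute</sub>(r)/n<sub>solute</sub>(∞)] /
[n<sub>solvent</sub>(r)/n<sub>solvent</sub>(∞)] ,

so β(r) > 1 means preferential inclusion of the cosolute, β(r) < 1
preferential exclusion, and β → 1 once r covers the whole box.

**Contact occupancy.** A protein residue is in contact in a frame when any
cosolvent centre of mass lies within a cutoff (default 0.3 nm) of any of
its atoms; occupancies are aggregated into positive / negative / polar /
apolar residue-class means.

**Interfacial profiles and descriptors.** Dimensionless density
ρ(z)/⟨ρ⟩ along the slab normal; mass-weighted radius of gyration;
Shrake–Rupley-style SASA (0.14 nm probe, deterministic golden-spiral point
set) with the carbon/sulfur fraction as the hydrophobic fraction.

Because no public trajectories accompany systems like these, the package
ships generators with analytically known structure (ideal mixtures, a
Metropolis Lennard-Jones fluid, a rigid shell-decorated toy protein, vacuum
slabs) that every analysis stage is validated against.

## Worked example

`cosolvkb run -c config.yaml` drives the whole pipeline; the same run from
Python:

```python
from cosolvkb import validate_config, run_pipeline

cfg = validate_config({
    "generator": {"kind": "shell_protein", "n_residues": 20,
                  "shell_spec": [[0.25, 12]], "bulk": [20, 400],
                  "box": [6.0, 6.0, 6.0], "frames": 30},
    "seed": 421,
    "selections": {"protein": "protein", "solute": "tba",
                   "solvent": "water"},
    "analyses": {"rdf": {"dr": 0.05, "pairs": [["solute", "solute"]]},
                 "beta": {"dr": 0.1}, "contacts": {},
                 "density": {"dz": 0.5},
                 "descriptors": {"n_sphere_points": 240}},
    "output_dir": "demo_out",
})
report = run_pipeline(cfg)
print(report.summary)
```

which prints (abridged):

```
beta_at_0.3_nm                 110.98
beta_at_1.0_nm                   8.11
kbi_plateau_solute_solute_nm3   32.48
mean_rg_nm                       0.400
mean_sasa_nm2                    6.56
occupancy_positive               0.464
occupancy_apolar                 0.448
```

The fixture pins 12 of 32 cosolute molecules on a 0.25 nm shell around the
toy protein, so β at 0.3 nm is far above 1 (strong preferential inclusion
by construction) and decays toward 1 with distance; the solute–solute KBI
plateau is large and positive because the shell population clusters the
solute; Rg ≈ 0.4 nm is the bead-sphere radius of the rigid toy protein.
Per-stage curves land in `demo_out/*.tsv` and the same scalars in
`demo_out/report.json`.

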