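# discbelt

Construction and trajectory analysis of **double-belt lipid nanodiscs** —
discoidal phospholipid bilayer patches encircled by belt-like amphipathic
scaffold proteins, such as the apoE3 N-terminal domain (apoE3-NT) wrapped
around DMPC.

The package is for structural/computational membrane biophysicists who
build nanodisc models for molecular dynamics and analyse the resulting
trajectories. It provides, as an importable library:

- **Model building** (`discbelt.builder`): unwind a four-helix bundle into
  an extended chain (helices kept internally rigid), bend two copies into a
  tandem ring with a 0.5 nm terminal Cα gap, stack a second ring 3 nm below
  in *parallel* or *antiparallel* N→C sense, and hex-pack a DMPC disc
  inside the belt.
- **Synthetic trajectories** (`discbelt.synthetic`): idealized nanodiscs
  and periodic bilayer patches with fully known ground truth (radius,
  thickness, acyl-tail orientation statistics), built from an
  explicit-hydrogen DMPC surrogate (C36H72NO8P, CHARMM-style atom names)
  so every analysis below is testable without running MD.
- **The analysis suite**:
  - mass-density profiles (100 bins) along any axis with symmetrization;
    bilayer thickness as the phosphate peak-to-peak distance; disc
    diameters from the outermost protein-density maxima and from the
    1 kg/m³ lipid-density threshold (`discbelt.density`);
  - reorientation of frames so the bilayer normal is z, radius of
    gyration, Kabsch superposition and backbone RMSD series, escaped-lipid
    detection (`discbelt.geometry`);
  - Shrake–Rupley SASA with 48 sphere points and 0.14 nm (all-atom) or
    0.265 nm (coarse-grained) water probes (`discbelt.sasa`);
  - inter-chain residue contacts at a 0.4 nm side-chain cutoff (1 nm
    prefilter), classified polar / nonpolar / nonspecific with a
    salt-bridge (ionic) flag for (R|K|H)×(D|E) pairs, plus
    parallel-vs-antiparallel comparison statistics (`discbelt.contacts`);
  - C–H (deuterium) order parameters per tail carbon,
    S_CD = ⟨(3 cos²θ − 1)/2⟩ with θ the C–H bond angle to the bilayer
    normal, averaged over Sn1/Sn2 chains, with full/core/rim lipid
    partitioning (`discbelt.order`);
  - a pipeline composing all of the above into machine-readable JSON
    reports, with per-stage failure isolation (`discbelt.pipeline`).

A thin `discbelt` CLI (`synth`, `build`, `analyze`, `compare`, `sasa`,
`scd`) wraps the library for shell use; `examples/` holds one narrative
script per capability.

## Worked example

```bash
python examples/02_density_and_size.py
```

builds a 240-DMPC antiparallel disc (20 jittered snapshots) and recovers
its geometry from density profiles:

```
system               : 240-A
thickness            : 3.41 nm  (built: 3.4)
lipid diameter       : 9.63 nm  (built envelope: 9.79)
protein diameter     : 11.27 nm  (belt at 11.57)
radius of gyration   : 3.60 nm (lipids only)
```

The thickness is the phosphate peak-to-peak distance of the symmetrized
z-profile and matches the built plane separation to within half a bin.
The lipid diameter (1 kg/m³ threshold crossing) tracks the constructed
atom envelope, and the protein diameter exceeds it — the belt encircles
the bilayer, the signature of the double-belt architecture.  Similarly,

```bash
python examples/04_contact_comparison.py
```

compares the reference inter-chain contact counts of parallel vs
antiparallel apoE3-NT/DMPC systems: antiparallel belts form 2.3× the
nonpolar and 3.2× the ionic (salt-bridge) contacts of parallel ones over
the common 260–400-DMPC range, with total contacts spanning 140–205 —
the quantitative basis for the antiparallel arrangement's higher
stability.

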