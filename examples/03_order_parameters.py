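"""C-H order parameters with core/rim partitioning.

Builds a nanodisc whose rim lipids carry extra tail tilt (emulating
belt-induced disorder at the disc edge) and compares |S_CD| for the full
disc, the 3 nm core and the 1.4 nm rim.  Expected: the core profile stays
near the ordered construction value while the rim is visibly lower —
the ordering a discoidal bilayer shows next to its scaffold belt.
"""

from discbelt import DiscSpec, generate_nanodisc, select_atoms
from discbelt.order import partition_regions, scd_profile

spec = DiscSpec(n_lipids_per_leaflet=120, n_frames=10, noise_sigma=0.02,
                tail_tilt=("fixed_angle", 0.1), rim_extra_tilt_sigma=0.4,
                seed=2)
traj, truth = generate_nanodisc(spec)
f0 = traj.frames[0]
lipids = select_atoms(f0, residue_name="DMPC")
protein = select_atoms(f0, residue_name="ALA")

parts = [partition_regions(f, lipids, protein, core_radius=3.0,
                           rim_distance=1.4) for f in traj.frames]
full = scd_profile(traj, lipids, "full")
core = scd_profile(traj, lipids, "core", [p.core for p in parts])
rim = scd_profile(traj, lipids, "rim", [p.rim for p in parts])

print(f"system: {truth.label};  lipids used  "
      f"full={full.n_lipids_used} core={core.n_lipids_used} "
      f"rim={rim.n_lipids_used}")
print("carbon   |S_CD| full   core    rim")
for i, k in enumerate(full.carbon_index):
    print(f"  C{k:<4d}      {full.abs_scd[i]:.3f}  "
          f"{core.abs_scd[i]:.3f}  {rim.abs_scd[i]:.3f}")
print("(core > rim: ordering decays toward the belt)")
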