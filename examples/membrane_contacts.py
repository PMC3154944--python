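"""Protein-lipid contacts, membrane-region strings, area per lipid."""

from memtun import synthetic as syn
from memtun.contacts import (area_per_lipid, count_contacts, frame_geometry,
                             peptide_location_string,
                             percent_domain_in_contact)
from memtun.structio import Trajectory

protein = syn.build_toy_anchored_protein()
bilayer = syn.build_toy_bilayer(8, 8, 8.0, seed=1)
system = syn.combine(protein, bilayer)

geometry = frame_geometry(system)
print(f"head-group planes: {geometry.upper_head_z:.1f} / "
      f"{geometry.lower_head_z:.1f} A; lipid-tail region "
      f"{geometry.tail_interval[0]:.1f} .. {geometry.tail_interval[1]:.1f} A")

# region traversal of the anchor + linker, N- to C-terminus
print("TM helix (1-22) location:",
      peptide_location_string(system, (1, 22), geometry))
print("linker (23-37) location:",
      peptide_location_string(system, (23, 37), geometry))

table = count_contacts(system, cutoff=4.0)
print("contacts by residue category x lipid part (head/middle/tail):")
print(table.counts)

traj = Trajectory(system, system.xyz[None])
mean, sd = percent_domain_in_contact(traj, (1, 37))
print(f"% of anchor+linker residues touching lipids: {mean:.1f} +/- {sd:.1f}")

print(f"area per lipid: {area_per_lipid(system, 'upper'):.2f} A^2 "
      f"(box area / lipids per leaflet)")
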