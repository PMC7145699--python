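"""Contact analysis and methylation-sensitivity rules on an ideal fixture.

Builds the composite interface fixture (the five printed readout
geometries of the WER-class interface plus the second adenine's N6 bond),
enumerates contacts, and applies the 5mC-steric / 6mA-donor-occlusion
rules.
"""

from mybdna import find_contacts, predict_methyl_sensitivity, readout_map
from mybdna.synthetic import build_fixture, wer_interface_placements

model, truth = build_fixture(wer_interface_placements())
contacts = find_contacts(model)

print("contacts:")
for c in contacts:
    print(f"  {c.protein_atom.id:<16} {c.dna_atom.id:<12} "
          f"{c.distance:4.2f} A  {c.kind}")

rmap = readout_map(contacts)
base_specific = [r for r, e in rmap["dna_residues"].items()
                 if e["label"] == "base-specific"]
print(f"base-specific DNA residues: {sorted(base_specific)}")

print("methylation sensitivity:")
for s in predict_methyl_sensitivity(model, contacts):
    chain, num, name = s.dna_residue
    print(f"  {chain}/{name}{num}: {s.modification} ({s.mechanism})")
# A 5mC flag means a methyl at cytosine C5 would clash with the packed
# protein atom; a 6mA flag means the adenine's N6 amine donates an H-bond
# that N6 methylation would compromise.
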