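"""Show the atom-group decomposition of salicylaldehyde.

Every heavy atom that is a group center contributes exactly one
atom-centered group; halogens and multiply-bonded terminal atoms are part
of their neighbour's descriptor.  Special groups are whole-molecule
corrections -- here the intramolecular hydrogen bond between the phenolic
OH and the ortho aldehyde oxygen.
"""

from thermogroups import fragment, read_smiles

g = read_smiles("O=Cc1ccccc1O", "salicylaldehyde")
fv = fragment(g)

print("atom groups (key -> count):")
for key, count in fv.group_counts.items():
    print(f"  {key:24s} {count}")
print("special groups:")
for key, count in fv.special_counts.items():
    if count:
        print(f"  {key:24s} {count}")
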