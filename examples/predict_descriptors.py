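"""Predict phase-change descriptors for a few molecules from SMILES.

Each prediction is the exact sum of the molecule's atom-group and
special-group contributions plus the descriptor's constant; sigma is the
model's cross-validated standard deviation.  Molecules containing a group
supported by fewer than three training molecules are refused rather than
extrapolated.
"""

from thermogroups import DescriptorId, load_all_tables, predict, read_smiles

tables = load_all_tables()

molecules = {
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "triethylborane": "CCB(CC)CC",  # carries an under-supported boron group
}

for name, smiles in molecules.items():
    g = read_smiles(smiles, name)
    print(f"\n{name} ({smiles})")
    for d in (DescriptorId.DHVAP, DescriptorId.DHSUB, DescriptorId.DSFUS):
        r = predict(g, tables[d])
        if r.predictable:
            print(f"  {d.value:6s} = {r.value:8.2f} +- {r.sigma:5.2f} {r.units}")
        else:
            print(f"  {d.value:6s}   not predictable ({r.status}): "
                  f"{', '.join(r.missing_or_invalid)}")
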