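"""Enthalpy of fusion at 298.15 K as sublimation minus vaporization.

The fusion model is not fitted directly: both parents are predicted and
subtracted, and the quoted uncertainty propagates the two cross-validated
standard deviations (sqrt(11.39^2 + 4.56^2) = 12.27 kJ/mol).
"""

from thermogroups import predict_fusion_enthalpy, read_smiles

for name, smiles in {
    "benzene": "c1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "benzoic acid": "OC(=O)c1ccccc1",
}.items():
    r = predict_fusion_enthalpy(read_smiles(smiles, name))
    print(f"{name:14s} dHfus = {r.value:6.2f} +- {r.sigma:.2f} {r.units}")
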