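# thermogroups

Group-additivity prediction of five phase-change thermodynamic descriptors
of organic molecules at standard conditions (298.15 K, 100 kPa):

| descriptor | meaning | units |
|---|---|---|
| `dHvap`  | enthalpy of vaporization (liquid → gas) | kJ/mol |
| `dHsub`  | enthalpy of sublimation (solid → gas) | kJ/mol |
| `dHsolv` | enthalpy of solvation in water (gas → solution) | kJ/mol |
| `dSfus`  | entropy of fusion (crystal → isotropic melt) | J/mol/K |
| `tpcE`   | total phase-change entropy of liquid crystals (0 K → clearing) | J/mol/K |

plus the enthalpy of fusion `dHfus`, derived by difference
(ΔH°fus = ΔH°sub − ΔH°vap).

## The model

Each descriptor is an additive function of atom-centered groups,

Y = Σᵢ aᵢ·Aᵢ + Σⱼ bⱼ·Bⱼ + C,

where `Aᵢ` counts the occurrences of the *i*-th atom group -- a heavy atom
identified by element, hybridization and charge together with its
first-shell neighbourhood (e.g. `C sp3|H2CO` for the methylene of ethanol,
`C aromatic|H:C2` for a benzene CH) -- and `Bⱼ` counts whole-molecule
*special groups*: an intramolecular hydrogen-bond correction, per-carbon
corrections for pure hydrocarbons, the number of endocyclic single bonds,
and small-ring angle-strain counts. The contributions `aᵢ`, `bⱼ` and the
constant `C` ship as packaged parameter tables for all five descriptors,
with the occurrence and molecule-support metadata of every group.

Predictions are *gated*: a group must be supported by at least three
independent training molecules to be usable, and a molecule containing any
unsupported, unknown or blank group is refused (reported as unpredictable
with the offending groups named) rather than extrapolated. The quoted
per-prediction uncertainty is the descriptor's cross-validated standard
deviation.

The training side is included: design-matrix construction with the
support gate iterated to a fixed point, Gauss-Seidel solution of the
least-squares normal equations, iterative outlier removal against the
cross-validated deviation, and 10-fold cross-validation with in-fold
gating (Q² = 1 − PRESS/SS_tot).

## Worked example

```python
from thermogroups import DescriptorId, load_all_tables, predict, read_smiles

tables = load_all_tables()
r = predict(read_smiles("CCO", "ethanol"), tables[DescriptorId.DHVAP])
print(r.value, r.sigma, r.units)   # 42.02 4.56 kJ/mol
```

The value is the exact sum 8.61 (constant) + 3.07 (`C sp3|H3C`) + 15.79
(`C sp3|H2CO`) + 14.55 (`O|HC`) = 42.02 kJ/mol, and 4.56 kJ/mol is the
vaporization model's cross-validated standard deviation. Running
`python examples/predict_descriptors.py` prints, among others:

```
ethanol (CCO)
  dHvap  =    42.02 +-  4.56 kJ/mol
  dHsub  =    61.13 +- 11.39 kJ/mol
  dSfus  =    45.54 +- 17.93 J/mol/K

triethylborane (CCB(CC)CC)
  dHvap    not predictable (missing or invalid groups): B|C3, C sp3|H2BC
```

Triethylborane is refused because its boron groups rest on only two
training molecules. `examples/fusion_by_difference.py` shows the derived
fusion enthalpy (benzene: 52.59 − 36.03 = 16.56 ± 12.27 kJ/mol, the
uncertainty being √(11.39² + 4.56²)); the other example scripts cover
fragmentation, synthetic fitting/cross-validation and the table audit.

A thin CLI mirrors the library:

```bash
thermogroups predict --descriptor dHvap --smiles CCO
thermogroups fragment --smiles "O=Cc1ccccc1O"
thermogroups tables dSfus --audit
thermogroups fit --descriptor dHvap --sdf train.sdf --values train.csv --out fitted.tsv
```

## Layout

- `src/thermogroups/chemgraph.py` -- SDF/SMILES input, perception (heavy-atom
  graphs, Kekulé hybridization, six-ring typing aromaticity)
- `src/thermogroups/grouptyper.py` -- the descriptor grammar and special groups
- `src/thermogroups/paramtables.py` -- packaged tables, validity gate, audit
- `src/thermogroups/predictor.py` -- additive predictions, fusion by difference
- `src/thermogroups/fitter.py` -- gating, Gauss-Seidel fit, outlier loop
- `src/thermogroups/validation.py` -- 10-fold cross-validation, statistics
- `src/thermogroups/fixtures.py` -- hand-decomposed reference molecules,
  synthetic training sets
- `docs/methods.md` -- model assumptions, conventions and limitations
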