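"""Reference molecules with hand-decomposed feature vectors, and synthetic
linear training sets.

The reference library spans the structural classes the group vocabulary
covers -- alkanes, aromatics, five-membered heteroaromatics, alcohols,
acids, esters, amines, nitro compounds, halides, small rings, an
intramolecular hydrogen-bond case -- plus molecules that deliberately hit an
invalid (under-supported) group of each parameter table.  Every expected
feature vector was decomposed by hand against the printed group vocabulary;
they are the independent oracle for the typer and the predictor.

Synthetic training sets realise the additivity model as a data-generating
process: integer group counts, known coefficients, Gaussian noise.  They
exercise the fitter and cross-validation machinery without any chemistry in
the loop.  The default generator mimics the vaporization training
conditions: coefficients from common printed contributions and a noise
standard deviation of 4.5 kJ/mol, the order of the reported cross-validated
deviation of that descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemgraph import MolecularGraph, read_smiles, write_sdf
from .fitter import TrainingRecord, TrainingSet
from .grouptyper import SpecialGroup
from .paramtables import DescriptorId, ParameterTable, load_all_tables

_A = SpecialGroup  # local shorthand


@dataclass
class ReferenceMolecule:
    name: str
    smiles: str
    expected_groups: dict[str, int]
    expected_specials: dict[str, int] = field(default_factory=dict)
    expected_predictions: dict[DescriptorId, float] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = dict(self.expected_groups)
        out.update({k: v for k, v in self.expected_specials.items() if v})
        return out

    def graph(self) -> MolecularGraph:
        return read_smiles(self.smiles, self.name)


def _ref(name, smiles, groups, specials=None) -> ReferenceMolecule:
    return ReferenceMolecule(
        name=name,
        smiles=smiles,
        expected_groups=groups,
        expected_specials=specials or {},
    )


_LIBRARY: list[ReferenceMolecule] = [
    _ref("ethanol", "CCO",
         {"C sp3|H3C": 1, "C sp3|H2CO": 1, "O|HC": 1}),
    _ref("n-butane", "CCCC",
         {"C sp3|H3C": 2, "C sp3|H2C2": 2},
         {_A.ALKANE_CARBONS: 4}),
    _ref("n-hexane", "CCCCCC",
         {"C sp3|H3C": 2, "C sp3|H2C2": 4},
         {_A.ALKANE_CARBONS: 6}),
    _ref("isobutane", "CC(C)C",
         {"C sp3|H3C": 3, "C sp3|HC3": 1},
         {_A.ALKANE_CARBONS: 4}),
    _ref("benzene", "c1ccccc1",
         {"C aromatic|H:C2": 6},
         {_A.UNSATURATED_CARBONS: 6}),
    _ref("toluene", "Cc1ccccc1",
         {"C sp3|H3C": 1, "C aromatic|C:C2": 1, "C aromatic|H:C2": 5},
         {_A.UNSATURATED_CARBONS: 7}),
    _ref("styrene", "C=Cc1ccccc1",
         {"C sp2|H2=C": 1, "C sp2|HC=C": 1, "C aromatic|C:C2": 1,
          "C aromatic|H:C2": 5},
         {_A.UNSATURATED_CARBONS: 8}),
    _ref("naphthalene", "c1ccc2ccccc2c1",
         {"C aromatic|:C3": 2, "C aromatic|H:C2": 8},
         {_A.UNSATURATED_CARBONS: 10}),
    _ref("pyridine", "c1ccncc1",
         {"N aromatic|:C2": 1, "C aromatic|H:C:N": 2, "C aromatic|H:C2": 3}),
    _ref("aniline", "Nc1ccccc1",
         {"N sp3|H2C(pi)": 1, "C aromatic|:C2N": 1, "C aromatic|H:C2": 5}),
    _ref("phenol", "Oc1ccccc1",
         {"O|HC(pi)": 1, "C aromatic|:C2O": 1, "C aromatic|H:C2": 5}),
    _ref("anisole", "COc1ccccc1",
         {"C sp3|H3O": 1, "O|C2(pi)": 1, "C aromatic|:C2O": 1,
          "C aromatic|H:C2": 5}),
    _ref("acetic acid", "CC(=O)O",
         {"C sp3|H3C": 1, "C sp2|CO=O": 1, "O|HC(pi)": 1}),
    _ref("benzoic acid", "OC(=O)c1ccccc1",
         {"O|HC(pi)": 1, "C sp2|CO=O": 1, "C aromatic|C:C2": 1,
          "C aromatic|H:C2": 5}),
    _ref("ethyl acetate", "CCOC(C)=O",
         {"C sp3|H3C": 2, "C sp3|H2CO": 1, "O|C2(pi)": 1, "C sp2|CO=O": 1}),
    _ref("diethyl ether", "CCOCC",
         {"C sp3|H3C": 2, "C sp3|H2CO": 2, "O|C2": 1}),
    _ref("acetone", "CC(C)=O",
         {"C sp3|H3C": 2, "C sp2|C2=O": 1}),
    _ref("acetonitrile", "CC#N",
         {"C sp3|H3C": 1, "C sp|C#N": 1}),
    _ref("methylamine", "CN",
         {"C sp3|H3N": 1, "N sp3|H2C": 1}),
    _ref("triethylamine", "CCN(CC)CC",
         {"C sp3|H3C": 3, "C sp3|H2CN": 3, "N sp3|C3": 1}),
    _ref("nitromethane", "C[N+](=O)[O-]",
         {"C sp3|H3N(+)": 1, "N(+) sp2|CO=O(-)": 1}),
    _ref("dimethyl sulfoxide", "CS(C)=O",
         {"C sp3|H3S": 2, "S4|C2=O": 1}),
    _ref("chlorobenzene", "Clc1ccccc1",
         {"C aromatic|:C2Cl": 1, "C aromatic|H:C2": 5}),
    _ref("1-bromobutane", "CCCCBr",
         {"C sp3|H3C": 1, "C sp3|H2C2": 2, "C sp3|H2CBr": 1}),
    _ref("1-fluorobutane", "CCCCF",
         {"C sp3|H3C": 1, "C sp3|H2C2": 2, "C sp3|H2CF": 1}),
    _ref("cyclopropane", "C1CC1",
         {"C sp3|H2C2": 3},
         {_A.ALKANE_CARBONS: 3, _A.ENDOCYCLIC_BONDS: 3, _A.ANGLE60: 3}),
    _ref("cyclobutane", "C1CCC1",
         {"C sp3|H2C2": 4},
         {_A.ALKANE_CARBONS: 4, _A.ENDOCYCLIC_BONDS: 4, _A.ANGLE90: 4}),
    _ref("cyclopentane", "C1CCCC1",
         {"C sp3|H2C2": 5},
         {_A.ALKANE_CARBONS: 5, _A.ENDOCYCLIC_BONDS: 5, _A.ANGLE102: 5}),
    _ref("cyclohexane", "C1CCCCC1",
         {"C sp3|H2C2": 6},
         {_A.ALKANE_CARBONS: 6, _A.ENDOCYCLIC_BONDS: 6}),
    _ref("cyclohexene", "C1=CCCCC1",
         {"C sp2|HC=C": 2, "C sp3|H2C2": 4},
         {_A.UNSATURATED_CARBONS: 6, _A.ENDOCYCLIC_BONDS: 5}),
    _ref("thiophene", "c1ccsc1",
         {"S2|C2(2pi)": 1, "C sp2|H=CS": 2, "C sp2|HC=C": 2}),
    _ref("furan", "c1ccoc1",
         {"O|C2(2pi)": 1, "C sp2|H=CO": 2, "C sp2|HC=C": 2}),
    _ref("pyrrole", "c1cc[nH]c1",
         {"N sp3|HC2(2pi)": 1, "C sp2|H=CN": 2, "C sp2|HC=C": 2}),
    _ref("salicylaldehyde", "O=Cc1ccccc1O",
         {"C sp2|HC=O": 1, "C aromatic|C:C2": 1, "C aromatic|:C2O": 1,
          "C aromatic|H:C2": 4, "O|HC(pi)": 1},
         {_A.H_ACCEPTOR: 1}),
    _ref("ethylene glycol", "OCCO",
         {"C sp3|H2CO": 2, "O|HC": 2},
         {_A.H_ACCEPTOR: 1}),
    _ref("triethylborane", "CCB(CC)CC",
         {"B|C3": 1, "C sp3|H3C": 3, "C sp3|H2BC": 3}),
]


def reference_library(tables: dict[DescriptorId, ParameterTable] | None = None,
                      min_support: int = 3) -> list[ReferenceMolecule]:
    """Hand-decomposed reference molecules with expected predictions.

    Expected predictions are recomputed here from the hand-written feature
    vectors and the packaged tables -- never through the typer -- so they are
    an independent oracle for the full prediction path.  A molecule gets an
    expected value only for descriptors where all its groups are valid.
    """
    tables = tables or load_all_tables()
    special_names = set(SpecialGroup.ALL)
    out: list[ReferenceMolecule] = []
    for ref in _LIBRARY:
        expected: dict[DescriptorId, float] = {}
        for d, table in tables.items():
            valid = table.valid_groups(min_support)
            total = table.constant
            ok = True
            # canonical (sorted) summation order: bit-identical to predict()
            for key, count in sorted(ref.counts().items()):
                if key in valid:
                    total += count * table.get(key).contribution
                elif key in special_names and key not in table:
                    continue
                else:
                    ok = False
                    break
            if ok:
                expected[d] = total
        out.append(
            ReferenceMolecule(
                name=ref.name,
                smiles=ref.smiles,
                expected_groups=dict(ref.expected_groups),
                expected_specials=dict(ref.expected_specials),
                expected_predictions=expected,
            )
        )
    return out


def export_reference_library(out_dir: str | Path) -> tuple[Path, Path]:
    """Write the library as an SDF file plus a CSV of expected values."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    library = reference_library()
    sdf_path = out_dir / "reference_molecules.sdf"
    csv_path = out_dir / "expected_values.csv"
    write_sdf([m.graph() for m in library], sdf_path)
    with open(csv_path, "w") as fh:
        fh.write("name,descriptor,expected_value,units\n")
        for m in library:
            for d, v in m.expected_predictions.items():
                fh.write(f"{m.name},{d.value},{v:.2f},{d.units}\n")
    return sdf_path, csv_path


# ---------------------------------------------------------------------------
# Synthetic linear training sets
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Generator of additive-model data: y = C + Σ a_i A_i + ε."""

    vocabulary: list[str]
    coefficients: dict[str, float]
    constant: float
    n: int
    noise_sigma: float = 0.0
    seed: int = 0
    max_count: int = 4

    def __post_init__(self) -> None:
        missing = set(self.vocabulary) - set(self.coefficients)
        if missing:
            raise ValueError(f"coefficients missing for {sorted(missing)}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def default_synthetic_spec(
    n: int = 500, noise_sigma: float = 4.5, seed: int = 0
) -> SyntheticSpec:
    """Vaporization-like generator: common printed contributions as the
    ground truth, 4.5 kJ/mol noise (the order of that model's cv deviation)."""
    table = load_all_tables()[DescriptorId.DHVAP]
    keys = [
        "C sp3|H3C", "C sp3|H2C2", "C sp3|H2CO", "C sp3|HC3", "C sp3|C4",
        "C sp3|H2CN", "C sp3|H2CCl", "C aromatic|H:C2", "C aromatic|C:C2",
        "C aromatic|:C2O", "C sp2|C2=O", "C sp2|CO=O", "C sp2|HC=C",
        "O|HC", "O|C2", "O|HC(pi)", "N sp3|H2C", "N sp3|C3",
        "S2|C2", "C sp|C#N",
    ]
    coeffs = {k: table.get(k).contribution for k in keys}
    return SyntheticSpec(
        vocabulary=keys,
        coefficients=coeffs,
        constant=table.constant,
        n=n,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def generate_synthetic_training(spec: SyntheticSpec) -> TrainingSet:
    """Draw a reproducible training set from the additive generator.

    Count vectors are integer draws over the vocabulary (each record gets at
    least one nonzero count).  Raises when the problem is unidentifiable
    (fewer records than coefficients plus constant, or a rank-deficient
    draw).
    """
    p = len(spec.vocabulary)
    if spec.n < p + 1:
        raise ValueError(
            f"unidentifiable: n={spec.n} records for {p} coefficients + constant"
        )
    rng = np.random.default_rng(spec.seed)
    counts = rng.integers(0, spec.max_count + 1, size=(spec.n, p))
    empty = np.where(counts.sum(axis=1) == 0)[0]
    for i in empty:
        counts[i, rng.integers(0, p)] = 1
    design = np.column_stack([counts, np.ones(spec.n)])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("unidentifiable: rank-deficient count draw")
    coef = np.array([spec.coefficients[k] for k in spec.vocabulary])
    y = spec.constant + counts @ coef + rng.normal(0.0, spec.noise_sigma, spec.n)
    records = [
        TrainingRecord(
            name=f"synth_{i}",
            features={
                k: int(c) for k, c in zip(spec.vocabulary, counts[i]) if c
            },
            value=float(y[i]),
        )
        for i in range(spec.n)
    ]
    return TrainingSet(records=records, descriptor="synthetic")
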