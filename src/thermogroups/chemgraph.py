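"""Molecular graphs with the annotations the atom-group typing grammar needs.

Molecules are read from MDL SDF (V2000) files or SMILES strings through RDKit
and converted into a light-weight, heavy-atom-only :class:`MolecularGraph`.
Hydrogens are folded into per-atom implicit counts.  Perception assigns, per
atom: hybridization derived from Kekulé bond orders, a typing-aromaticity flag
(six-membered aromatic rings only -- see below), ring membership, and whether
the atom participates in a π system.

Aromaticity model
-----------------
Two notions of aromaticity coexist:

* *toolkit aromaticity* -- RDKit's default perception, which includes
  five-membered heteroaromatics (furan, thiophene, pyrrole).  It is retained
  on bonds (``BondRecord.delocalized``) and used when counting endocyclic
  single bonds and small-ring angle corrections, where any delocalized ring
  is rigid.
* *typing aromaticity* -- restricted to six-membered aromatic rings
  (benzenoid and pyridine-type).  Atoms and bonds of five-membered
  heteroaromatic rings are typed from their Kekulé structure instead: the
  ring heteroatom becomes an ordinary divalent O / S2 / sp3-N center whose π
  neighbourhood is expressed through the ``(kpi)`` annotation, and the ring
  carbons become sp2 centers.  This is the convention of the group
  vocabulary: it distinguishes e.g. a thiophene sulfur (``S2|C2(2pi)``) from
  a benzene carbon (``C aromatic|H:C2``).

Nitro, azide and amine-oxide groups are normalized to their charge-separated
form before perception, since the group vocabulary spells these centers only
with explicit charges (``N(+)``, ``O(-)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Elements the group-additivity scheme covers (hydrogen, boron, carbon,
#: nitrogen, oxygen, phosphorus, sulfur, silicon and the halogens).
ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "P", "S", "Si", "F", "Cl", "Br", "I"}
)

#: Halogens: always terminal substituents, never group centers.
HALOGENS = frozenset({"F", "Cl", "Br", "I"})

_HYBRIDIZATIONS = ("sp3", "sp2", "sp", "aromatic", "other")
_BOND_ORDERS = ("single", "double", "triple", "aromatic")


class SdfRecordError(Exception):
    """A single SDF record could not be parsed; carries the record index."""

    def __init__(self, index: int, message: str):
        super().__init__(f"SDF record {index}: {message}")
        self.index = index


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with its perceived annotations.

    ``hybridization`` is derived purely from bond orders of the Kekulé
    structure (``aromatic`` only for atoms of six-membered aromatic rings),
    not from geometry.  ``in_pi_system`` marks atoms that are toolkit-aromatic
    or carry any multiple bond; it feeds the ``(kpi)`` neighbour annotation.
    """

    index: int
    element: str
    formal_charge: int = 0
    implicit_h: int = 0
    hybridization: str = "other"
    is_aromatic: bool = False
    ring_sizes: frozenset[int] = frozenset()
    in_pi_system: bool = False

    def __post_init__(self) -> None:
        if self.hybridization not in _HYBRIDIZATIONS:
            raise ValueError(f"unknown hybridization {self.hybridization!r}")
        if self.is_aromatic and self.hybridization != "aromatic":
            raise ValueError("aromatic atom must have aromatic hybridization")


@dataclass(frozen=True)
class BondRecord:
    """A heavy-atom bond.

    ``order`` is ``aromatic`` only inside six-membered aromatic rings; bonds
    of five-membered heteroaromatics carry their Kekulé order and
    ``delocalized=True``.
    """

    atoms: tuple[int, int]
    order: str = "single"
    in_ring: bool = False
    delocalized: bool = False

    def __post_init__(self) -> None:
        if self.atoms[0] == self.atoms[1]:
            raise ValueError("self-bonds are not allowed")
        if self.order not in _BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with perception annotations."""

    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: list[BondRecord] = field(default_factory=list)
    name: str = ""
    properties: dict = field(default_factory=dict)

    # -- basic graph queries -------------------------------------------------

    def neighbors(self, index: int) -> list[int]:
        out = []
        for b in self.bonds:
            if index in b.atoms:
                out.append(b.atoms[0] if b.atoms[1] == index else b.atoms[1])
        return out

    def bond_between(self, i: int, j: int) -> BondRecord | None:
        key = tuple(sorted((i, j)))
        for b in self.bonds:
            if b.atoms == key:
                return b
        return None

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    @property
    def total_implicit_h(self) -> int:
        return sum(a.implicit_h for a in self.atoms)

    def elements(self) -> set[str]:
        return {a.element for a in self.atoms}

    def elements_in_scope(self) -> bool:
        return self.elements() <= ALLOWED_ELEMENTS

    def substituent_count(self, index: int) -> int:
        """Heavy neighbours plus implicit hydrogens of one atom."""
        return len(self.neighbors(index)) + self.atoms[index].implicit_h


# ---------------------------------------------------------------------------
# RDKit conversion and perception
# ---------------------------------------------------------------------------

# Minimal normalization to the charge-separated spellings the group
# vocabulary uses: nitro, azide and amine-oxide nitrogens become N(+) with
# O(-)/N(-).  Deliberately NOT the toolkit's full default set, which would
# also charge-separate sulfoxides/phosphine oxides -- the vocabulary spells
# those with "=O".
_NORMALIZATIONS = "\n".join(
    [
        "Nitro to N+(O-)=O\t[N;X3:1](=[O:2])=[O:3]>>[N+1:1]([O-1:2])=[O:3]",
        "Azide to N=N+=N-\t[N;X2:1]=[N;X2:2]#[N;X1:3]>>[N:1]=[N+1:2]=[N-1:3]",
        "Amine oxide to N+-O-\t[N;X4;v5:1]=[O:2]>>[N+1:1]-[O-1:2]",
    ]
)
_normalizer = rdMolStandardize.NormalizerFromData(
    _NORMALIZATIONS, rdMolStandardize.CleanupParameters()
)


def _aromatic6_atoms_bonds(mol: Chem.Mol) -> tuple[set[int], set[int]]:
    """Atoms/bonds of six-membered rings whose bonds are all aromatic."""
    atoms: set[int] = set()
    bonds: set[int] = set()
    ri = mol.GetRingInfo()
    for ring_bonds, ring_atoms in zip(ri.BondRings(), ri.AtomRings()):
        if len(ring_atoms) != 6:
            continue
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring_bonds):
            atoms.update(ring_atoms)
            bonds.update(ring_bonds)
    return atoms, bonds


def graph_from_rdkit(mol: Chem.Mol, name: str = "", properties: dict | None = None) -> MolecularGraph:
    """Convert a sanitized RDKit molecule into a perceived MolecularGraph."""
    mol = _normalizer.normalize(mol)
    Chem.SanitizeMol(mol)
    mol = Chem.RemoveHs(mol)

    arom_atoms, arom_bonds = _aromatic6_atoms_bonds(mol)

    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)

    ri = mol.GetRingInfo()
    atom_rings = ri.AtomRings()

    atoms: list[AtomRecord] = []
    for a in mol.GetAtoms():
        idx = a.GetIdx()
        ring_sizes = frozenset(len(r) for r in atom_rings if idx in r)
        ka = kek.GetAtomWithIdx(idx)
        n_double = n_triple = 0
        for b in ka.GetBonds():
            bt = b.GetBondType()
            if bt == Chem.BondType.DOUBLE:
                n_double += 1
            elif bt == Chem.BondType.TRIPLE:
                n_triple += 1
        if idx in arom_atoms:
            hyb = "aromatic"
        elif n_triple or n_double >= 2:
            hyb = "sp"
        elif n_double == 1:
            hyb = "sp2"
        else:
            hyb = "sp3"
        atoms.append(
            AtomRecord(
                index=idx,
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                implicit_h=a.GetTotalNumHs(),
                hybridization=hyb,
                is_aromatic=idx in arom_atoms,
                ring_sizes=ring_sizes,
                in_pi_system=a.GetIsAromatic() or n_double > 0 or n_triple > 0,
            )
        )

    bonds: list[BondRecord] = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if b.GetIdx() in arom_bonds:
            order = "aromatic"
        else:
            kt = kek.GetBondBetweenAtoms(i, j).GetBondType()
            order = {
                Chem.BondType.SINGLE: "single",
                Chem.BondType.DOUBLE: "double",
                Chem.BondType.TRIPLE: "triple",
            }.get(kt, "single")
        bonds.append(
            BondRecord(
                atoms=(i, j),
                order=order,
                in_ring=b.IsInRing(),
                delocalized=b.GetIsAromatic(),
            )
        )

    return MolecularGraph(
        atoms=atoms, bonds=bonds, name=name, properties=dict(properties or {})
    )


def graph_to_rdkit(graph: MolecularGraph) -> Chem.Mol:
    """Rebuild an RDKit molecule from a MolecularGraph (inverse of conversion)."""
    rw = Chem.RWMol()
    for a in graph.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.formal_charge)
        atom.SetNumExplicitHs(a.implicit_h)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    order_map = {
        "single": Chem.BondType.SINGLE,
        "double": Chem.BondType.DOUBLE,
        "triple": Chem.BondType.TRIPLE,
        "aromatic": Chem.BondType.AROMATIC,
    }
    for b in graph.bonds:
        rw.AddBond(b.atoms[0], b.atoms[1], order_map[b.order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def perceive(graph: MolecularGraph) -> MolecularGraph:
    """(Re)assign hybridization, aromaticity, ring and π annotations.

    Deterministic and idempotent: annotations are derived from connectivity,
    bond orders and formal charges only; charges are never invented.
    """
    mol = graph_to_rdkit(graph)
    out = graph_from_rdkit(mol, name=graph.name, properties=graph.properties)
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_smiles(smiles: str, name: str = "") -> MolecularGraph:
    """Parse a SMILES string into a perceived MolecularGraph."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    return graph_from_rdkit(mol, name=name or smiles)


def read_sdf(path: str | Path, errors: list[SdfRecordError] | None = None) -> list[MolecularGraph]:
    """Read a (multi-record) MDL SDF V2000 file.

    Malformed records are reported (logged, and appended to ``errors`` when a
    list is supplied) and the remaining records are still returned.  Records
    with elements outside the supported set are returned as graphs -- the
    element-scope gate lives in the predictor, so the molecule is flagged as
    unpredictable rather than silently dropped here.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    graphs: list[MolecularGraph] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            err = SdfRecordError(i, "unparsable record")
            logger.warning(str(err))
            if errors is not None:
                errors.append(err)
            continue
        try:
            Chem.SanitizeMol(mol)
            props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record_{i}"
            graphs.append(graph_from_rdkit(mol, name=name, properties=props))
        except Exception as exc:  # sanitization/valence failures
            err = SdfRecordError(i, str(exc))
            logger.warning(str(err))
            if errors is not None:
                errors.append(err)
    return graphs


def write_sdf(graphs: list[MolecularGraph], path: str | Path) -> None:
    """Write graphs as an SDF V2000 file, preserving name and properties."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for g in graphs:
        mol = graph_to_rdkit(g)
        mol.SetProp("_Name", g.name)
        for k, v in g.properties.items():
            mol.SetProp(str(k), str(v))
        writer.write(mol)
    writer.close()


def to_smiles(graph: MolecularGraph) -> str:
    """Canonical SMILES of a graph (round-trip/debug helper)."""
    return Chem.MolToSmiles(graph_to_rdkit(graph))
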