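"""The typing grammar: atom groups, special groups, canonical descriptors."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermogroups import chemgraph as cg
from thermogroups import grouptyper as gt
from thermogroups.grouptyper import SpecialGroup


def _group_of(smiles: str, predicate) -> str:
    """Type the first atom of the molecule matching a predicate."""
    g = cg.read_smiles(smiles)
    for a in g.atoms:
        if predicate(a):
            return str(gt.type_atom(g, a.index))
    raise AssertionError("no atom matched")


@pytest.mark.parametrize(
    "smiles, predicate, expected",
    [
        # printed-vocabulary spot checks across the type system
        ("CCO", lambda a: a.element == "C" and a.implicit_h == 3, "C sp3|H3C"),
        ("CCO", lambda a: a.element == "C" and a.implicit_h == 2, "C sp3|H2CO"),
        ("CCO", lambda a: a.element == "O", "O|HC"),
        ("Nc1ccccc1", lambda a: a.element == "N", "N sp3|H2C(pi)"),
        ("CC(=O)O", lambda a: a.element == "C" and a.implicit_h == 0, "C sp2|CO=O"),
        ("c1ccccc1", lambda a: True, "C aromatic|H:C2"),
        ("C[N+](=O)[O-]", lambda a: a.element == "N", "N(+) sp2|CO=O(-)"),
        ("CC#N", lambda a: a.element == "C" and a.implicit_h == 0, "C sp|C#N"),
        ("c1ccsc1", lambda a: a.element == "S", "S2|C2(2pi)"),
        ("COc1ccccc1", lambda a: a.element == "O", "O|C2(pi)"),
        ("Oc1ccccc1O", lambda a: a.element == "O", "O|HC(pi)"),
        ("CP(C)(C)=O", lambda a: a.element == "P", "P4|C3=O"),
        ("CP(C)C", lambda a: a.element == "P", "P3|C3"),
        ("CS(C)(=O)=O", lambda a: a.element == "S", "S4|C2=O2"),
        ("C[Si](C)(C)C", lambda a: a.element == "Si", "Si|C4"),
        ("CCI", lambda a: a.implicit_h == 2, "C sp3|H2CJ"),
    ],
)
def test_type_atom_vocabulary_spellings(smiles, predicate, expected):
    assert _group_of(smiles, predicate) == expected


def test_hydrogens_and_terminal_atoms_are_not_centers():
    g = cg.read_smiles("CC(=O)Cl")  # acetyl chloride
    keys = [gt.type_atom(g, a.index) for a in g.atoms]
    # carbonyl O and Cl are terminal: only the two carbons are centers
    assert sum(k is not None for k in keys) == 2


def test_fragment_matches_hand_decomposition(library):
    for mol in library:
        fv = gt.fragment(mol.graph())
        assert fv.fully_typed, mol.name
        assert fv.group_counts == mol.expected_groups, mol.name
        expected_specials = {k: v for k, v in mol.expected_specials.items() if v}
        got_specials = {k: v for k, v in fv.special_counts.items() if v}
        assert got_specials == expected_specials, mol.name


def test_partition_covers_every_center_exactly_once(library):
    for mol in library:
        g = mol.graph()
        fv = gt.fragment(g)
        n_centers = sum(
            1
            for a in g.atoms
            if a.element not in cg.HALOGENS and g.substituent_count(a.index) >= 2
        )
        assert sum(fv.group_counts.values()) == n_centers, mol.name


def test_fragment_invariant_under_atom_permutation(library):
    from rdkit import Chem

    rng = random.Random(11)
    for mol in library:
        base = gt.fragment(mol.graph())
        rd = Chem.MolFromSmiles(mol.smiles)
        order = list(range(rd.GetNumAtoms()))
        rng.shuffle(order)
        shuffled = cg.graph_from_rdkit(Chem.RenumberAtoms(rd, order))
        fv = gt.fragment(shuffled)
        assert fv.group_counts == base.group_counts
        assert fv.special_counts == base.special_counts


def test_vocabulary_closure_against_tables(library, tables):
    """Every group the typer produces for the library exists in a table."""
    all_keys = set()
    for t in tables.values():
        all_keys.update(e.key for e in t.entries)
    for mol in library:
        for key in gt.fragment(mol.graph()).group_counts:
            assert key in all_keys, f"{mol.name}: {key} not in any table"


@pytest.mark.parametrize(
    "smiles, expected",
    [
        ("C1CCCCC1", 6),   # cyclohexane: all six ring bonds single
        ("c1ccccc1", 0),   # benzene: aromatic bonds excluded
        ("C1=CCCCC1", 5),  # cyclohexene: ring bonds minus the double bond
        ("c1ccsc1", 0),    # thiophene: delocalized ring, nothing counts
        ("C1CC1CC1CC1", 6),
    ],
)
def test_endocyclic_single_bonds(smiles, expected):
    assert gt.count_endocyclic_single_bonds(cg.read_smiles(smiles)) == expected


@pytest.mark.parametrize(
    "smiles, a60, a90, a102",
    [
        ("C1CC1", 3, 0, 0),
        ("C1CCC1", 0, 4, 0),
        ("C1CCCC1", 0, 0, 5),
        ("c1ccccc1", 0, 0, 0),
        ("c1ccsc1", 0, 0, 0),       # delocalized 5-ring excluded
        ("C1CC12CC2", 5, 0, 0),     # spiropentane: every atom in a 3-ring
    ],
)
def test_angle_group_counts(smiles, a60, a90, a102):
    counts = gt.count_angle_groups(cg.read_smiles(smiles))
    assert counts[SpecialGroup.ANGLE60] == a60
    assert counts[SpecialGroup.ANGLE90] == a90
    assert counts[SpecialGroup.ANGLE102] == a102


@pytest.mark.parametrize(
    "smiles, key, count",
    [
        ("CCCCCC", SpecialGroup.ALKANE_CARBONS, 6),
        ("C=Cc1ccccc1", SpecialGroup.UNSATURATED_CARBONS, 8),
        ("CCO", None, 0),
        ("C1CCCCC1", SpecialGroup.ALKANE_CARBONS, 6),
    ],
)
def test_hydrocarbon_correction(smiles, key, count):
    assert gt.count_hydrocarbon_correction(cg.read_smiles(smiles)) == (key, count)


@pytest.mark.parametrize(
    "smiles, expected",
    [
        ("O=Cc1ccccc1O", 1),  # salicylaldehyde: OH to ortho carbonyl O
        ("Oc1ccccc1", 0),     # phenol: no acceptor in range
        ("OCCO", 1),          # ethylene glycol: one donor-acceptor pair
        ("OCCCO", 1),         # 1,3-propanediol: six-membered ring
        ("OCCCCCO", 0),       # 1,6-hexanediol: too far apart
        ("NCCO", 1),          # ethanolamine
    ],
)
def test_h_acceptor_counts(smiles, expected):
    assert gt.count_h_acceptor(cg.read_smiles(smiles)) == expected


def test_out_of_scope_molecule_untypable_as_whole():
    g = cg.read_smiles("C[Se]C")
    fv = gt.fragment(g)
    assert not fv.fully_typed
    assert not fv.group_counts
    assert len(fv.untypable_atoms) == g.n_heavy


# -- descriptor grammar ------------------------------------------------------


def test_parse_serialize_round_trip_on_all_printed_spellings(tables):
    """Canonicalisation is a projection: stable after one application."""
    for t in tables.values():
        for e in t.entries:
            if e.key in SpecialGroup.ALL:
                continue
            canonical = gt.canonicalize_descriptor(e.printed_neighbours)
            assert gt.canonicalize_descriptor(canonical) == canonical


def test_floating_charge_reattachment():
    # printed spellings that float the charge behind a halogen still match
    # the chemically-equivalent token multiset
    assert gt.canonicalize_descriptor("CN2F(+)") == gt.canonicalize_descriptor(
        "CNN(+)F"
    )


def test_unparsable_descriptor_raises():
    with pytest.raises(ValueError, match="descriptor"):
        gt.parse_descriptor("H2Qx")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    h=st.integers(0, 3),
    tokens=st.lists(
        st.tuples(
            st.sampled_from(["", "=", "#", ":"]),
            st.sampled_from(["C", "N", "O", "S", "Cl", "J"]),
            st.sampled_from([0, 0, 0, 1, -1]),
        ),
        min_size=1,
        max_size=4,
    ),
    pi=st.integers(0, 3),
)
def test_serialization_is_order_invariant(h, tokens, pi):
    from collections import Counter

    rng = random.Random(0)
    shuffled = list(tokens)
    rng.shuffle(shuffled)
    assert gt.serialize_descriptor(h, Counter(tokens), pi) == gt.serialize_descriptor(
        h, Counter(shuffled), pi
    )


def test_pi_annotation_monotone_under_aromatic_substitution():
    """Adding an aromatic substituent never decreases an sp3-center π count."""
    pairs = [
        ("CN", "CNc1ccccc1"),      # methylamine -> N-methylaniline
        ("CO", "COc1ccccc1"),      # methanol O -> anisole O
        ("CSC", "CSc1ccccc1"),     # dimethyl sulfide -> thioanisole
    ]
    import re

    def pi_of(smiles, element):
        g = cg.read_smiles(smiles)
        for a in g.atoms:
            if a.element == element:
                key = gt.type_atom(g, a.index)
                if key is None:
                    continue
                m = re.search(r"\((\d?)pi\)$", key.neighbours)
                return int(m.group(1) or "1") if m else 0
        raise AssertionError

    for before, after in pairs:
        el = "N" if "N" in before else ("O" if "O" in before else "S")
        assert pi_of(after, el) >= pi_of(before, el)
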