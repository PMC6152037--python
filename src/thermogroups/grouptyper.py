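"""Atom-centered group typing: the descriptor grammar behind group additivity.

Every *center* atom of a molecule is assigned exactly one atom-group key of
the form ``"<atom type>|<neighbours>"``, e.g. ``"C sp3|H2CO"`` for the
methylene carbon of ethanol or ``"C aromatic|H:C2"`` for a benzene CH.  The
group counts, together with a handful of whole-molecule *special groups*
(intramolecular H-bond correction, per-carbon hydrocarbon corrections,
endocyclic single bonds, small-ring angle corrections), form the feature
vector of the additivity model ``Y = sum_i a_i A_i + sum_j b_j B_j + C``.

Center atoms
------------
An atom is a center when it has at least two substituents (heavy neighbours
plus hydrogens).  Halogens and atoms attached through a lone multiple bond
(carbonyl O, thiono S, nitrile N, nitro O...) are therefore terminal: they
appear inside their neighbour's descriptor, never as centers of their own.
Hydrogen is never a center.

Descriptor grammar
------------------
``neighbours`` is the canonical serialization of the center's first shell:

* implicit hydrogens first (``H``, ``H2``, ``H3``);
* each heavy neighbour as ``[marker][element][charge]`` where the marker is
  empty for a single bond, ``=`` double, ``#`` triple, ``:`` aromatic
  (six-ring); iodine is written ``J``;
* tokens sorted by element priority B < C < N < O < S < P < Si < F < Cl <
  Br < J and, within an element, by marker priority single < ``=`` < ``#``
  < ``:``; equal tokens aggregate to ``C2``, ``:C3``...;
* neighbour formal charges are normalized to a per-element net charge and
  rendered after that element's last token (``CO=O(-)``, ``C2N(+)``), so
  that matching never depends on which same-element neighbour the printed
  table happens to hang the charge on;
* for neutral ``N sp3``, ``O`` and ``S2`` centers a trailing ``(pi)`` /
  ``(2pi)`` / ``(3pi)`` counts neighbours engaged in a π system (aromatic,
  or carrying a double/triple bond).
"""

from __future__ import annotations

import re
from collections import Counter, deque
from dataclasses import dataclass, field

from .chemgraph import ALLOWED_ELEMENTS, HALOGENS, MolecularGraph

# table convention: iodine is spelled J inside descriptors
_TO_TABLE_SYMBOL = {"I": "J"}
_FROM_TABLE_SYMBOL = {"J": "I"}

ELEMENT_PRIORITY = ["B", "C", "N", "O", "S", "P", "Si", "F", "Cl", "Br", "J"]
MARKER_PRIORITY = ["", "=", "#", ":"]

_ORDER_TO_MARKER = {"single": "", "double": "=", "triple": "#", "aromatic": ":"}


class SpecialGroup:
    """Closed enumeration of the whole-molecule correction terms."""

    H_ACCEPTOR = "H/H Acceptor"
    ALKANE_CARBONS = "Alkane/No. of C atoms"
    UNSATURATED_CARBONS = "Unsaturated HC/No. of C atoms"
    ENDOCYCLIC_BONDS = "Endocyclic bonds"
    ANGLE60 = "Angle60"
    ANGLE90 = "Angle90"
    ANGLE102 = "Angle102"

    ALL = (
        H_ACCEPTOR,
        ALKANE_CARBONS,
        UNSATURATED_CARBONS,
        ENDOCYCLIC_BONDS,
        ANGLE60,
        ANGLE90,
        ANGLE102,
    )


@dataclass(frozen=True)
class AtomGroupKey:
    """Canonical identity of an atom-centered group."""

    atom_type: str
    neighbours: str

    def __str__(self) -> str:
        return f"{self.atom_type}|{self.neighbours}"


@dataclass
class FeatureVector:
    """Group and special-group counts of one molecule (the A_i and B_j)."""

    group_counts: dict[str, int] = field(default_factory=dict)
    special_counts: dict[str, int] = field(default_factory=dict)
    untypable_atoms: list[int] = field(default_factory=list)

    @property
    def fully_typed(self) -> bool:
        return not self.untypable_atoms

    def counts(self) -> dict[str, int]:
        """Merged feature dict: atom groups plus nonzero special groups."""
        out = dict(self.group_counts)
        for k, v in self.special_counts.items():
            if v:
                out[k] = v
        return out


# ---------------------------------------------------------------------------
# Descriptor parsing / serialization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"([=#:]?)(Cl|Br|Si|[BCNOPSFJ])(\d*)(\(\+\)|\(-\))?"
)
_PI_RE = re.compile(r"\((\d?)pi\)$")
_H_RE = re.compile(r"^H(\d*)(?![a-z])")  # H but not He/Hf...; tables use bare H


def parse_descriptor(text: str) -> tuple[int, Counter, int]:
    """Parse a printed neighbour descriptor.

    Returns ``(h_count, tokens, pi_count)`` where ``tokens`` is a Counter of
    ``(marker, element, charge)`` triples (element in table spelling, so
    iodine is ``J``).  Charges that the table floats to the end of the
    spelling behind a halogen (e.g. ``CN2F(+)``) are re-attached to the last
    chargeable (non-halogen) element.  Raises ``ValueError`` on any text the
    grammar does not cover.
    """
    s = text.strip()
    pi_count = 0
    m = _PI_RE.search(s)
    if m:
        pi_count = int(m.group(1) or "1")
        s = s[: m.start()]

    h_count = 0
    m = _H_RE.match(s)
    if m:
        h_count = int(m.group(1) or "1")
        s = s[m.end():]

    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m or m.start() != pos:
            raise ValueError(f"cannot parse descriptor {text!r} at {s[pos:]!r}")
        marker, elem, count, charge = m.groups()
        n = int(count or "1")
        q = {"(+)": 1, "(-)": -1, None: 0}[charge]
        # the charge belongs to one neighbour even when the count aggregates
        for k in range(n):
            tokens.append((marker, elem, q if k == n - 1 else 0))
        pos = m.end()

    # floating charge printed behind a halogen belongs to a chargeable atom
    fixed: list[tuple[str, str, int]] = list(tokens)
    for i, (marker, elem, q) in enumerate(tokens):
        if q and elem in ("F", "Cl", "Br", "J"):
            for pref in ("N", "O", "S", "C"):
                cands = [j for j, t in enumerate(fixed) if t[1] == pref]
                if cands:
                    j = cands[-1]
                    fixed[j] = (fixed[j][0], fixed[j][1], fixed[j][2] + q)
                    fixed[i] = (marker, elem, 0)
                    break
    return h_count, Counter(fixed), pi_count


def serialize_descriptor(h_count: int, tokens: Counter, pi_count: int = 0) -> str:
    """Canonical spelling of a neighbour shell.

    Within each element the net charge is rendered once, after the element's
    last bond-group, which makes the serialization independent of the charge
    placement in ``tokens``.
    """
    parts: list[str] = []
    if h_count:
        parts.append("H" if h_count == 1 else f"H{h_count}")
    # regroup: element -> {marker: count}, element -> net charge
    by_elem: dict[str, Counter] = {}
    charge: dict[str, int] = {}
    for (marker, elem, q), n in tokens.items():
        by_elem.setdefault(elem, Counter())[marker] += n
        charge[elem] = charge.get(elem, 0) + q * n
    for elem in sorted(by_elem, key=ELEMENT_PRIORITY.index):
        markers = by_elem[elem]
        last = max(markers, key=MARKER_PRIORITY.index)
        for marker in sorted(markers, key=MARKER_PRIORITY.index):
            n = markers[marker]
            parts.append(f"{marker}{elem}" + (str(n) if n > 1 else ""))
            if marker == last:
                q = charge.get(elem, 0)
                parts.append("(+)" * q if q > 0 else "(-)" * (-q))
    if pi_count:
        parts.append(f"({pi_count if pi_count > 1 else ''}pi)")
    return "".join(parts)


def canonicalize_descriptor(text: str) -> str:
    """Printed table spelling -> canonical spelling (parse + serialize)."""
    return serialize_descriptor(*parse_descriptor(text))


def canonical_key(atom_type: str, neighbours: str) -> AtomGroupKey:
    return AtomGroupKey(atom_type, canonicalize_descriptor(neighbours))


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

#: center types whose descriptor carries the π-neighbour annotation
_PI_ANNOTATED_TYPES = {"N sp3", "O", "S2"}


def _is_center(graph: MolecularGraph, idx: int) -> bool:
    a = graph.atoms[idx]
    if a.element == "H" or a.element in HALOGENS:
        return False
    return graph.substituent_count(idx) >= 2


def _atom_type(graph: MolecularGraph, idx: int) -> str:
    a = graph.atoms[idx]
    el = a.element
    if el in ("B", "Si"):
        return el
    if el == "O":
        return "O" if a.formal_charge == 0 else f"O({'+' if a.formal_charge > 0 else '-'})"
    if el == "P":
        orders = [graph.bond_between(idx, j).order for j in graph.neighbors(idx)]
        hyperv = any(o in ("double", "triple") for o in orders)
        return "P4" if hyperv or graph.substituent_count(idx) > 3 else "P3"
    if el == "S":
        orders = [graph.bond_between(idx, j).order for j in graph.neighbors(idx)]
        plain = graph.substituent_count(idx) == 2 and all(o == "single" for o in orders)
        return "S2" if plain and a.formal_charge == 0 else "S4"
    # C and N
    sign = ""
    if a.formal_charge > 0:
        sign = "(+)"
    elif a.formal_charge < 0:
        sign = "(-)"
    return f"{el}{sign} {a.hybridization}"


def type_atom(graph: MolecularGraph, idx: int) -> AtomGroupKey | None:
    """Atom-group key of one atom, or ``None`` when the atom is not a center.

    Raises ``ValueError`` for elements outside the supported set.
    """
    a = graph.atoms[idx]
    if a.element not in ALLOWED_ELEMENTS:
        raise ValueError(f"element {a.element} outside supported set")
    if not _is_center(graph, idx):
        return None

    atom_type = _atom_type(graph, idx)

    tokens: Counter = Counter()
    pi = 0
    for j in graph.neighbors(idx):
        nb = graph.atoms[j]
        bond = graph.bond_between(idx, j)
        marker = _ORDER_TO_MARKER[bond.order]
        elem = _TO_TABLE_SYMBOL.get(nb.element, nb.element)
        tokens[(marker, elem, nb.formal_charge)] += 1
        if nb.in_pi_system:
            pi += 1

    if atom_type not in _PI_ANNOTATED_TYPES:
        pi = 0
    neighbours = serialize_descriptor(a.implicit_h, tokens, pi)
    return AtomGroupKey(atom_type, neighbours)


# ---------------------------------------------------------------------------
# Special groups
# ---------------------------------------------------------------------------


def count_endocyclic_single_bonds(graph: MolecularGraph) -> int:
    """Single-order ring bonds; aromatic/delocalized ring bonds never count."""
    return sum(
        1
        for b in graph.bonds
        if b.in_ring and b.order == "single" and not b.delocalized
    )


def count_angle_groups(graph: MolecularGraph) -> dict[str, int]:
    """Small-ring strain counts: one per atom whose smallest (non-aromatic)
    ring has size 3, 4 or 5 (Angle60 / Angle90 / Angle102).

    Atoms of delocalized (toolkit-aromatic) rings are excluded: their
    geometry is already encoded by their aromatic/Kekulé group types.
    """
    out = {SpecialGroup.ANGLE60: 0, SpecialGroup.ANGLE90: 0, SpecialGroup.ANGLE102: 0}
    arom_atoms = set()
    for b in graph.bonds:
        if b.delocalized:
            arom_atoms.update(b.atoms)
    for a in graph.atoms:
        if not a.ring_sizes or a.index in arom_atoms:
            continue
        smallest = min(a.ring_sizes)
        if smallest == 3:
            out[SpecialGroup.ANGLE60] += 1
        elif smallest == 4:
            out[SpecialGroup.ANGLE90] += 1
        elif smallest == 5:
            out[SpecialGroup.ANGLE102] += 1
    return out


def count_hydrocarbon_correction(graph: MolecularGraph) -> tuple[str | None, int]:
    """Per-carbon correction for pure hydrocarbons.

    Saturated C/H molecules count one ``Alkane/No. of C atoms`` per carbon;
    any multiple bond or aromatic ring switches the molecule to
    ``Unsaturated HC/No. of C atoms``.  Molecules with heteroatoms get none.
    """
    elements = graph.elements()
    if not elements or not elements <= {"C", "H"}:
        return None, 0
    n_carbons = sum(1 for a in graph.atoms if a.element == "C")
    unsaturated = any(b.order != "single" or b.delocalized for b in graph.bonds)
    key = SpecialGroup.UNSATURATED_CARBONS if unsaturated else SpecialGroup.ALKANE_CARBONS
    return key, n_carbons


def _shortest_path_len(graph: MolecularGraph, i: int, j: int) -> int:
    """Bond count of the shortest heavy-atom path between two atoms."""
    if i == j:
        return 0
    seen = {i}
    frontier = deque([(i, 0)])
    while frontier:
        node, d = frontier.popleft()
        for nb in graph.neighbors(node):
            if nb == j:
                return d + 1
            if nb not in seen:
                seen.add(nb)
                frontier.append((nb, d + 1))
    return -1  # disconnected


def count_h_acceptor(graph: MolecularGraph) -> int:
    """Intramolecular hydrogen-bond (acid-base) correction count.

    A topological motif: a donor heteroatom (N, O or S bearing at least one
    hydrogen) and an acceptor (N or O with an available lone pair, i.e.
    uncharged-or-negative and not valence-saturated) separated by exactly 3
    or 4 bonds, closing a five- or six-membered hydrogen-bonded ring.  Each
    unordered donor-acceptor pair counts once, so e.g. ethylene glycol
    counts a single correction although both hydroxyls could donate.
    """
    donors = [
        a.index
        for a in graph.atoms
        if a.element in ("N", "O", "S") and a.implicit_h >= 1
    ]
    acceptors = [
        a.index
        for a in graph.atoms
        if a.element in ("N", "O")
        and a.formal_charge <= 0
        and graph.substituent_count(a.index) <= (3 if a.element == "N" else 2)
    ]
    pairs = set()
    for d in donors:
        for acc in acceptors:
            if acc == d:
                continue
            if _shortest_path_len(graph, d, acc) in (3, 4):
                pairs.add(tuple(sorted((d, acc))))
    return len(pairs)


# ---------------------------------------------------------------------------
# Whole-molecule fragmentation
# ---------------------------------------------------------------------------


def fragment(graph: MolecularGraph) -> FeatureVector:
    """Complete breakdown of a molecule into atom groups and special groups.

    Deterministic and independent of atom order.  A molecule containing an
    element outside the supported set is marked untypable as a whole (every
    atom listed in ``untypable_atoms``); no exception is raised.
    """
    if not graph.elements_in_scope():
        return FeatureVector(untypable_atoms=[a.index for a in graph.atoms])

    groups: Counter = Counter()
    untypable: list[int] = []
    for a in graph.atoms:
        key = type_atom(graph, a.index)
        if key is not None:
            groups[str(key)] += 1

    specials = {name: 0 for name in SpecialGroup.ALL}
    specials[SpecialGroup.ENDOCYCLIC_BONDS] = count_endocyclic_single_bonds(graph)
    specials.update(count_angle_groups(graph))
    hc_key, hc_count = count_hydrocarbon_correction(graph)
    if hc_key:
        specials[hc_key] = hc_count
    specials[SpecialGroup.H_ACCEPTOR] = count_h_acceptor(graph)

    return FeatureVector(
        group_counts=dict(sorted(groups.items())),
        special_counts=specials,
        untypable_atoms=untypable,
    )
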