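"""Packaged group-contribution parameter tables for the five descriptors.

The tables ship as plain-text TSV package data (one file per descriptor plus
a shared file of reported fit/cross-validation statistics), protected by a
SHA-256 manifest.  Each table holds the additive constant ``C``, per-group
contributions ``a_i`` / ``b_j`` with their occurrence and molecule-support
counts, and the descriptor's reported training and cross-validation
statistics (rows A-H: valid-group count, R², mean/standard deviation, K,
Q², cv mean/standard deviation).

A group is *valid* -- usable for prediction -- only when it is supported by
at least ``min_support`` (default 3) independent training molecules and its
printed contribution cell is not blank.  The transcription audit recounts
the valid groups from the Molecules column and reports the result against
the printed row A value; discrepancies are surfaced as data notes, never
silently reconciled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

from .grouptyper import SpecialGroup, canonical_key


class DescriptorId(str, Enum):
    """The five thermodynamic descriptors the parameter tables cover."""

    DHVAP = "dHvap"   # standard enthalpy of vaporization, kJ/mol
    DHSUB = "dHsub"   # standard enthalpy of sublimation, kJ/mol
    DHSOLV = "dHsolv"  # standard enthalpy of solvation (water), kJ/mol
    DSFUS = "dSfus"   # entropy of fusion, J/mol/K
    TPCE = "tpcE"     # total phase-change entropy (liquid crystals), J/mol/K

    @property
    def units(self) -> str:
        return "kJ/mol" if self in (DescriptorId.DHVAP, DescriptorId.DHSUB, DescriptorId.DHSOLV) else "J/mol/K"


#: derived descriptor: enthalpy of fusion = sublimation - vaporization
FUSION_ENTHALPY = "dHfus"

_SPECIAL_ROWS = {
    ("H", "H Acceptor"): SpecialGroup.H_ACCEPTOR,
    ("Alkane", "No. of C atoms"): SpecialGroup.ALKANE_CARBONS,
    ("Unsaturated HC", "No. of C atoms"): SpecialGroup.UNSATURATED_CARBONS,
    ("Endocyclic bonds", "No. of single bonds"): SpecialGroup.ENDOCYCLIC_BONDS,
    ("Endocyclic bonds", "No of single bonds"): SpecialGroup.ENDOCYCLIC_BONDS,
    ("Angle60", ""): SpecialGroup.ANGLE60,
    ("Angle90", ""): SpecialGroup.ANGLE90,
    ("Angle102", ""): SpecialGroup.ANGLE102,
}


class TableIntegrityError(Exception):
    """Packaged table data does not match its SHA-256 manifest."""


@dataclass(frozen=True)
class ParameterEntry:
    """One table row: an atom group, special group, or the constant."""

    key: str                      # canonical group key, special name, or "Const"
    contribution: float | None    # None for blank printed cells
    occurrences: int
    molecule_support: int
    entry_number: int
    printed_atom_type: str = ""
    printed_neighbours: str = ""

    @property
    def usable(self) -> bool:
        return self.contribution is not None


@dataclass
class ReportedStats:
    """Printed rows A-H of one table."""

    valid_groups: int
    r2: float
    avg_dev: float
    std_dev: float
    k: int
    q2: float
    cv_avg_dev: float
    cv_std_dev: float
    n_train_total: int
    n_train: int
    n_cv: int


@dataclass
class ParameterTable:
    descriptor: DescriptorId
    constant: float
    entries: list[ParameterEntry] = field(default_factory=list)
    reported_stats: ReportedStats | None = None
    _lookup: dict[str, ParameterEntry] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._lookup:
            self._lookup = {e.key: e for e in self.entries}

    @property
    def units(self) -> str:
        return self.descriptor.units

    @property
    def sigma(self) -> float:
        """Cross-validated standard deviation (row H), the quoted prediction
        uncertainty."""
        return self.reported_stats.cv_std_dev

    def get(self, key: str) -> ParameterEntry | None:
        return self._lookup.get(key)

    def __contains__(self, key: str) -> bool:
        return key in self._lookup

    def valid_groups(self, min_support: int = 3) -> set[str]:
        """Keys usable for prediction: supported by >= ``min_support``
        molecules and carrying a printed contribution."""
        return {
            e.key
            for e in self.entries
            if e.usable and e.molecule_support >= min_support
        }

    def audit(self, min_support: int = 3) -> dict:
        """Transcription audit: recounted valid groups vs printed row A.

        Returns the computed count, the printed row A value, and explicit
        notes for every discrepancy.  Blank-contribution rows are listed.
        """
        computed = len(self.valid_groups(min_support))
        printed = self.reported_stats.valid_groups
        notes = []
        if computed != printed:
            notes.append(
                f"{self.descriptor.value}: recounted valid groups "
                f"(molecule support >= {min_support}) = {computed}, printed "
                f"row A = {printed}; printed value kept as reported, "
                f"recount surfaced as a data note"
            )
        if self.descriptor is DescriptorId.DHVAP:
            notes.append(
                "dHvap: the running text quotes 187 valid groups while row A "
                "prints 185; both retained, neither reconciled"
            )
        blanks = [e.key for e in self.entries if not e.usable]
        return {
            "descriptor": self.descriptor.value,
            "computed_valid": computed,
            "printed_valid": printed,
            "match": computed == printed,
            "blank_entries": blanks,
            "notes": notes,
        }


def _data_text(filename: str) -> str:
    pkg = resources.files("thermogroups") / "data"
    raw = (pkg / filename).read_bytes()
    manifest = json.loads((pkg / "manifest.json").read_text())
    digest = hashlib.sha256(raw).hexdigest()
    if manifest.get(filename) != digest:
        raise TableIntegrityError(
            f"{filename}: SHA-256 {digest} does not match manifest entry "
            f"{manifest.get(filename)}"
        )
    return raw.decode()


def _load_stats(descriptor: DescriptorId) -> ReportedStats:
    rows: dict[str, tuple[float, int]] = {}
    for line in _data_text("reported_stats.tsv").splitlines()[1:]:
        desc, row, _l1, _l2, value, n = line.split("\t")
        if desc == descriptor.value:
            rows[row] = (float(value), int(n))
    return ReportedStats(
        valid_groups=int(rows["A"][0]),
        r2=rows["B"][0],
        avg_dev=rows["C"][0],
        std_dev=rows["D"][0],
        k=int(rows["E"][0]),
        q2=rows["F"][0],
        cv_avg_dev=rows["G"][0],
        cv_std_dev=rows["H"][0],
        n_train_total=rows["A"][1],
        n_train=rows["B"][1],
        n_cv=rows["F"][1],
    )


def load_table(descriptor: DescriptorId | str) -> ParameterTable:
    """Load one descriptor's packaged parameter table.

    Verifies the SHA-256 manifest before parsing; a mismatch refuses the
    load.  Printed spellings are canonicalised through the descriptor
    grammar so that lookup keys match typer output exactly.
    """
    descriptor = DescriptorId(descriptor)
    text = _data_text(f"{descriptor.value}.tsv")
    entries: list[ParameterEntry] = []
    constant: float | None = None
    for line in text.splitlines()[1:]:
        entry_s, atom_type, neighbours, contrib_s, occ_s, mol_s = line.split("\t")
        number = int(entry_s)
        contribution = float(contrib_s) if contrib_s else None
        occurrences, support = int(occ_s), int(mol_s)
        if atom_type == "Const":
            constant = contribution
            continue
        special = _SPECIAL_ROWS.get((atom_type, neighbours))
        if special is not None:
            key = special
        else:
            key = str(canonical_key(atom_type, neighbours))
        entries.append(
            ParameterEntry(
                key=key,
                contribution=contribution,
                occurrences=occurrences,
                molecule_support=support,
                entry_number=number,
                printed_atom_type=atom_type,
                printed_neighbours=neighbours,
            )
        )
    if constant is None:
        raise TableIntegrityError(f"{descriptor.value}: no Const row")
    keys = [e.key for e in entries]
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise TableIntegrityError(
            f"{descriptor.value}: canonicalisation collided on {sorted(dupes)}"
        )
    return ParameterTable(
        descriptor=descriptor,
        constant=constant,
        entries=entries,
        reported_stats=_load_stats(descriptor),
    )


def load_all_tables() -> dict[DescriptorId, ParameterTable]:
    return {d: load_table(d) for d in DescriptorId}


def valid_groups(table: ParameterTable, min_support: int = 3) -> set[str]:
    """Module-level convenience mirroring :meth:`ParameterTable.valid_groups`."""
    return table.valid_groups(min_support)
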