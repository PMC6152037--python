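"""Apply the additivity model to a molecule; derive fusion enthalpy by
difference.

A prediction is the exact sum ``Y = C + sum_i a_i A_i + sum_j b_j B_j`` over
the molecule's feature vector and one descriptor's parameter table.  The
model refuses to predict (``predictable=False``) when

* the molecule contains an element outside the supported set,
* any atom could not be typed,
* any of its atom groups is absent from the table, has a blank printed
  contribution, or rests on fewer than ``min_support`` training molecules.

Special groups absent from a descriptor's table (e.g. the hydrocarbon
corrections for the entropy models) are simply not part of that
descriptor's model and are ignored; a special group that is *present* but
invalid blocks prediction like any other group.

The standard enthalpy of fusion at 298.15 K is not fitted directly: it is
the difference between the sublimation and vaporization predictions, with
the uncertainty obtained by error propagation of the two cross-validated
standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chemgraph import MolecularGraph
from .grouptyper import SpecialGroup, fragment
from .paramtables import (
    FUSION_ENTHALPY,
    DescriptorId,
    ParameterTable,
    load_table,
)

#: statuses a refused prediction can carry
STATUS_OK = "ok"
STATUS_OUT_OF_SCOPE = "out of element scope"
STATUS_UNTYPABLE = "untypable atoms"
STATUS_MISSING_GROUPS = "missing or invalid groups"
STATUS_PARENT_FAILED = "parent prediction unpredictable"


@dataclass
class PredictionResult:
    descriptor: str
    value: float | None
    predictable: bool
    sigma: float | None = None
    units: str = ""
    status: str = STATUS_OK
    matched: list[tuple[str, int, float]] = field(default_factory=list)
    missing_or_invalid: list[str] = field(default_factory=list)
    untypable_atoms: list[int] = field(default_factory=list)
    name: str = ""


def predict(
    graph: MolecularGraph,
    table: ParameterTable,
    min_support: int = 3,
) -> PredictionResult:
    """Predict one descriptor for one molecule from a parameter table."""
    descriptor = table.descriptor.value
    base = dict(
        descriptor=descriptor,
        units=table.units,
        sigma=table.sigma,
        name=graph.name,
    )
    if not graph.elements_in_scope():
        return PredictionResult(
            value=None, predictable=False, status=STATUS_OUT_OF_SCOPE, **base
        )

    fv = fragment(graph)
    if not fv.fully_typed:
        return PredictionResult(
            value=None,
            predictable=False,
            status=STATUS_UNTYPABLE,
            untypable_atoms=list(fv.untypable_atoms),
            **base,
        )

    valid = table.valid_groups(min_support)
    matched: list[tuple[str, int, float]] = []
    missing: list[str] = []
    special_names = set(SpecialGroup.ALL)
    # sorted iteration fixes the floating-point summation order, making
    # predictions bit-for-bit reproducible and matchable by any oracle that
    # sums in the same canonical order
    for key, count in sorted(fv.counts().items()):
        if key in valid:
            matched.append((key, count, table.get(key).contribution))
        elif key in special_names and key not in table:
            continue  # not a term of this descriptor's model
        else:
            missing.append(key)

    if missing:
        return PredictionResult(
            value=None,
            predictable=False,
            status=STATUS_MISSING_GROUPS,
            matched=matched,
            missing_or_invalid=sorted(missing),
            **base,
        )

    value = table.constant
    for _, count, contrib in matched:  # left-to-right: oracle-reproducible
        value += count * contrib
    return PredictionResult(value=value, predictable=True, matched=matched, **base)


def propagate_sigma(s1: float, s2: float) -> float:
    """Error propagation for a difference/sum: sqrt(s1² + s2²)."""
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    return math.hypot(s1, s2)


def predict_fusion_enthalpy(
    graph: MolecularGraph,
    sub_table: ParameterTable | None = None,
    vap_table: ParameterTable | None = None,
    min_support: int = 3,
) -> PredictionResult:
    """Standard enthalpy of fusion at 298.15 K by difference:
    sublimation prediction minus vaporization prediction."""
    sub_table = sub_table or load_table(DescriptorId.DHSUB)
    vap_table = vap_table or load_table(DescriptorId.DHVAP)
    sub = predict(graph, sub_table, min_support)
    vap = predict(graph, vap_table, min_support)
    sigma = propagate_sigma(sub_table.sigma, vap_table.sigma)
    if not (sub.predictable and vap.predictable):
        failed = [
            r.descriptor for r in (sub, vap) if not r.predictable
        ]
        missing = sorted(set(sub.missing_or_invalid) | set(vap.missing_or_invalid))
        return PredictionResult(
            descriptor=FUSION_ENTHALPY,
            value=None,
            predictable=False,
            sigma=sigma,
            units="kJ/mol",
            status=f"{STATUS_PARENT_FAILED}: {', '.join(failed)}",
            missing_or_invalid=missing,
            name=graph.name,
        )
    return PredictionResult(
        descriptor=FUSION_ENTHALPY,
        value=sub.value - vap.value,
        predictable=True,
        sigma=sigma,
        units="kJ/mol",
        matched=[("dHsub", 1, sub.value), ("dHvap", -1, vap.value)],
        name=graph.name,
    )
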