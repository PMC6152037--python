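"""Group-contribution fitting: Gauss-Seidel least squares with valid-group
gating and iterative outlier removal.

The contributions solve the ordinary least-squares problem for the linear
additivity model.  Following the original procedure, the normal equations
``(XᵀX) β = Xᵀy`` are solved by Gauss-Seidel iteration -- coordinate-wise
sweeps in fixed column order from a zero start.  For a full-rank design the
normal matrix is symmetric positive definite, for which Gauss-Seidel
converges unconditionally; correctness is nevertheless anchored to a direct
least-squares factorization in the test suite, not to the iteration scheme.

Gating: groups supported by fewer than ``min_support`` training molecules
are removed, molecules containing a removed group are dropped, and the two
steps iterate to a fixed point (dropping molecules can push further groups
below the threshold).

Outliers: records whose full-fit residual exceeds ``outlier_k`` times the
cross-validated standard deviation are removed and the fit repeated, up to
``max_rounds`` times (k = 4 for the enthalpies of vaporization/sublimation,
3 for the entropy models, per the reported procedure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemgraph import MolecularGraph
from .grouptyper import FeatureVector, fragment

CONSTANT_KEY = "Const"


class FitError(Exception):
    pass


@dataclass
class TrainingRecord:
    """One training observation: a feature dict and an experimental value."""

    name: str
    features: dict[str, int]
    value: float

    @classmethod
    def from_graph(cls, graph: MolecularGraph, value: float) -> "TrainingRecord":
        fv = fragment(graph)
        if not fv.fully_typed:
            raise FitError(f"{graph.name}: molecule not fully typable")
        return cls(name=graph.name, features=fv.counts(), value=value)


@dataclass
class TrainingSet:
    records: list[TrainingRecord]
    descriptor: str = ""
    at_reference_temperature: bool = True

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise FitError("duplicate molecule ids in training set")

    @classmethod
    def from_graphs(
        cls,
        graphs: list[MolecularGraph],
        values: list[float],
        descriptor: str = "",
    ) -> "TrainingSet":
        if len(graphs) != len(values):
            raise FitError("graphs and values differ in length")
        return cls(
            records=[TrainingRecord.from_graph(g, v) for g, v in zip(graphs, values)],
            descriptor=descriptor,
        )

    @classmethod
    def from_features(
        cls,
        feature_vectors: list[FeatureVector | dict],
        values: list[float],
        names: list[str] | None = None,
        descriptor: str = "",
    ) -> "TrainingSet":
        names = names or [f"rec_{i}" for i in range(len(values))]
        recs = []
        for name, fv, v in zip(names, feature_vectors, values):
            feats = fv.counts() if isinstance(fv, FeatureVector) else dict(fv)
            recs.append(TrainingRecord(name=name, features=feats, value=v))
        return cls(records=recs, descriptor=descriptor)


@dataclass
class DesignMatrix:
    """Gated count matrix with a trailing constant column of ones."""

    columns: list[str]            # group keys, CONSTANT_KEY last
    x: np.ndarray                 # (n_molecules, n_columns)
    y: np.ndarray
    names: list[str]
    support: dict[str, int]       # molecule support of retained groups
    dropped_groups: dict[str, int] = field(default_factory=dict)
    dropped_molecules: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class StatsSummary:
    """Deviation statistics of one set of (experimental, predicted) pairs.

    ``std_dev`` is the root mean square residual without degrees-of-freedom
    correction; ``avg_dev`` the mean absolute residual -- the conventions of
    the printed tables' rows C/D and G/H.
    """

    n: int
    r2: float
    avg_dev: float
    std_dev: float
    regression_intercept: float = float("nan")
    regression_slope: float = float("nan")
    frac_within_1sigma: float = float("nan")
    frac_beyond_2sigma: float = float("nan")


@dataclass
class FitResult:
    contributions: dict[str, float]
    constant: float
    stats: StatsSummary
    support: dict[str, int]
    converged: bool = True
    unique: bool = True
    n_iterations: int = 0
    removed_outliers: list[tuple[str, float, float, float]] = field(default_factory=list)
    dropped_molecules: list[str] = field(default_factory=list)
    cv_sigma: float | None = None

    def predict_features(self, features: dict[str, int]) -> float:
        return self.constant + sum(
            c * self.contributions.get(k, 0.0) for k, c in features.items()
        )


def build_design_matrix(
    data: TrainingSet, min_support: int = 3, include_constant: bool = True
) -> DesignMatrix:
    """Count matrix after iterating the valid-group gate to a fixed point."""
    records = list(data.records)
    dropped_groups: dict[str, int] = {}
    dropped_molecules: list[str] = []
    while True:
        support: dict[str, int] = {}
        for r in records:
            for k, c in r.features.items():
                if c:
                    support[k] = support.get(k, 0) + 1
        bad = {k for k, s in support.items() if s < min_support}
        if not bad:
            break
        for k in bad:
            dropped_groups[k] = support[k]
        keep = []
        for r in records:
            if any(r.features.get(k, 0) for k in bad):
                dropped_molecules.append(r.name)
            else:
                keep.append(r)
        records = keep
        if not records:
            raise FitError("gating removed every training record")
    if not records:
        raise FitError("empty training set")
    columns = sorted(support)
    if include_constant:
        columns.append(CONSTANT_KEY)
    x = np.zeros((len(records), len(columns)))
    for i, r in enumerate(records):
        for j, k in enumerate(columns):
            if k == CONSTANT_KEY:
                x[i, j] = 1.0
            else:
                x[i, j] = r.features.get(k, 0)
    y = np.array([r.value for r in records], dtype=float)
    return DesignMatrix(
        columns=columns,
        x=x,
        y=y,
        names=[r.name for r in records],
        support={k: support[k] for k in support},
        dropped_groups=dropped_groups,
        dropped_molecules=dropped_molecules,
    )


def _training_stats(y: np.ndarray, yhat: np.ndarray) -> StatsSummary:
    r = y - yhat
    n = len(y)
    if n > 1 and np.std(y) > 0 and np.std(yhat) > 0:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    else:
        r2 = float("nan")
    return StatsSummary(
        n=n,
        r2=r2,
        avg_dev=float(np.mean(np.abs(r))),
        std_dev=float(math.sqrt(np.mean(r**2))),
    )


def solve_gauss_seidel(
    matrix: DesignMatrix,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> FitResult:
    """Gauss-Seidel solution of the least-squares normal equations.

    Sweeps coordinates in canonical column order from a zero start until the
    largest scaled coefficient change ``|Δβ_i| / (1 + |β_i|)`` falls below
    ``tol``.  A zero diagonal (all-zero column) raises; failure to converge
    within ``max_iter`` sweeps is reported on the result, never silent.
    """
    x, y = matrix.x, matrix.y
    m = x.T @ x
    b = x.T @ y
    diag = np.diag(m)
    zero = np.where(diag == 0)[0]
    if zero.size:
        raise FitError(
            f"zero diagonal in normal matrix for column(s) "
            f"{[matrix.columns[i] for i in zero]}"
        )
    p = len(b)
    beta = np.zeros(p)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        delta = 0.0
        for i in range(p):
            new = (b[i] - m[i] @ beta + m[i, i] * beta[i]) / m[i, i]
            delta = max(delta, abs(new - beta[i]) / (1.0 + abs(new)))
            beta[i] = new
        if delta < tol:
            converged = True
            break
    unique = bool(np.linalg.matrix_rank(m) == p)
    yhat = x @ beta
    contributions = {
        k: float(v) for k, v in zip(matrix.columns, beta) if k != CONSTANT_KEY
    }
    constant = float(beta[matrix.columns.index(CONSTANT_KEY)]) if CONSTANT_KEY in matrix.columns else 0.0
    return FitResult(
        contributions=contributions,
        constant=constant,
        stats=_training_stats(y, yhat),
        support=dict(matrix.support),
        converged=converged,
        unique=unique,
        n_iterations=iterations,
        dropped_molecules=list(matrix.dropped_molecules),
    )


def fit_descriptor(
    data: TrainingSet,
    outlier_k: float = math.inf,
    min_support: int = 3,
    max_rounds: int = 5,
    cv_seed: int = 0,
    cv_k: int = 10,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> FitResult:
    """Full fitting loop: gate -> solve -> cross-validate -> remove outliers.

    Records whose absolute full-fit residual exceeds ``outlier_k`` times the
    cross-validated standard deviation are removed; the loop repeats until
    no record is removed or ``max_rounds`` is reached.  All removals are
    recorded with (name, experimental, predicted, residual).
    """
    from .validation import CVConfig, cross_validate  # local: avoids cycle

    working = TrainingSet(
        records=list(data.records), descriptor=data.descriptor
    )
    removed: list[tuple[str, float, float, float]] = []
    fit: FitResult | None = None
    for _round in range(max_rounds):
        matrix = build_design_matrix(working, min_support)
        fit = solve_gauss_seidel(matrix, tol=tol, max_iter=max_iter)
        if math.isinf(outlier_k):
            fit.cv_sigma = None
            break
        cv = cross_validate(
            working,
            CVConfig(k=cv_k, seed=cv_seed, min_support=min_support),
        )
        cv_sigma = cv.stats.std_dev
        fit.cv_sigma = cv_sigma
        beta = np.array(
            [fit.constant if c == CONSTANT_KEY else fit.contributions[c]
             for c in matrix.columns]
        )
        resids = matrix.y - matrix.x @ beta
        outliers = [
            (name, float(matrix.y[i]), float(matrix.y[i] - resids[i]), float(resids[i]))
            for i, name in enumerate(matrix.names)
            if abs(resids[i]) > outlier_k * cv_sigma
        ]
        if not outliers:
            break
        removed.extend(outliers)
        names_out = {o[0] for o in outliers}
        working = TrainingSet(
            records=[r for r in working.records if r.name not in names_out],
            descriptor=data.descriptor,
        )
        if not working.records:
            raise FitError("outlier removal emptied the training set")
    fit.removed_outliers = removed
    return fit
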