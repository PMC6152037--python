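"""K-fold cross-validation of group-contribution fits and summary statistics.

Each record is held out exactly once: the folds partition the training set,
the model is refitted on the other k−1 folds (with the valid-group gate
re-applied *inside* the fold), and the held-out records are predicted.
Records whose groups become invalid inside a fold cannot be predicted by it
and are excluded from the cross-validation statistics but counted -- this is
why the cross-validated N is smaller than the training N.

Definitions (printed on every report to avoid ambiguity):

* training R² -- squared Pearson correlation of experimental vs fitted;
* Q² = 1 − Σ(y−ŷ_cv)² / Σ(y−ȳ)² with ȳ the full-data mean (PRESS form);
* "Deviation Standard" -- √(Σr²/N), no degrees-of-freedom correction;
* "Deviation Average" -- mean |r|;
* the regression line reported is calculated-on-experimental.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fitter import (
    CONSTANT_KEY,
    FitError,
    FitResult,
    StatsSummary,
    TrainingSet,
    build_design_matrix,
    solve_gauss_seidel,
)


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    seed: int = 0
    min_support: int = 3


@dataclass
class CVResult:
    stats: StatsSummary
    predictions: dict[str, float]         # name -> held-out prediction
    excluded: list[str]                   # records no fold could predict
    fold_failures: list[int] = field(default_factory=list)
    config: CVConfig | None = None
    q2_definition: str = "Q2 = 1 - PRESS/SS_tot (full-data mean)"
    r2_definition: str = "R2 = squared Pearson correlation"

    @property
    def q2(self) -> float:
        return self.stats.r2


def kfold_split(n: int, config: CVConfig) -> list[np.ndarray]:
    """Disjoint index sets partitioning range(n); sizes differ by <= 1.

    Uniform random assignment by record, reproducible under the seed.
    """
    if n < config.k:
        raise ValueError(f"cannot split {n} records into {config.k} folds")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, config.k)]


def cross_validate(data: TrainingSet, config: CVConfig) -> CVResult:
    """K-fold cross-validation with in-fold gating.

    A fold whose refit fails (e.g. gating empties it) is reported in
    ``fold_failures`` and the run continues; its records join ``excluded``.
    """
    records = list(data.records)
    n = len(records)
    folds = kfold_split(n, config)
    y_all = np.array([r.value for r in records])
    y_mean = float(np.mean(y_all))

    predictions: dict[str, float] = {}
    excluded: list[str] = []
    failures: list[int] = []
    press_pairs: list[tuple[float, float]] = []

    for fold_idx, test_idx in enumerate(folds):
        test = set(int(i) for i in test_idx)
        train = TrainingSet(
            records=[r for i, r in enumerate(records) if i not in test],
            descriptor=data.descriptor,
        )
        try:
            matrix = build_design_matrix(train, config.min_support)
            fit = solve_gauss_seidel(matrix)
        except FitError:
            failures.append(fold_idx)
            excluded.extend(records[i].name for i in sorted(test))
            continue
        usable = set(matrix.columns)
        for i in sorted(test):
            rec = records[i]
            keys = {k for k, c in rec.features.items() if c}
            if not keys <= usable:
                excluded.append(rec.name)
                continue
            yhat = fit.predict_features(rec.features)
            predictions[rec.name] = yhat
            press_pairs.append((rec.value, yhat))

    if not press_pairs:
        raise FitError("cross-validation produced no predictions")
    exp = np.array([p[0] for p in press_pairs])
    pred = np.array([p[1] for p in press_pairs])
    r = exp - pred
    ss_tot = float(np.sum((exp - y_mean) ** 2))
    q2 = 1.0 - float(np.sum(r**2)) / ss_tot if ss_tot > 0 else float("nan")
    stats = StatsSummary(
        n=len(press_pairs),
        r2=q2,
        avg_dev=float(np.mean(np.abs(r))),
        std_dev=float(math.sqrt(np.mean(r**2))),
    )
    return CVResult(
        stats=stats,
        predictions=predictions,
        excluded=excluded,
        fold_failures=failures,
        config=config,
    )


def summary_stats(
    pairs: list[tuple[float, float]], sigma: float | None = None
) -> StatsSummary:
    """Statistics of (experimental, calculated) pairs.

    Reports squared Pearson correlation, the ordinary least-squares line of
    calculated on experimental, mean absolute and root-mean-square
    deviations, and -- when a ``sigma`` is supplied -- the fractions of
    records deviating by at most one and by more than two sigma.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    exp = np.array([p[0] for p in pairs], dtype=float)
    calc = np.array([p[1] for p in pairs], dtype=float)
    r = exp - calc
    if np.std(exp) == 0:
        r2 = float("nan")  # zero experimental variance: correlation undefined
        slope = float("nan")
        intercept = float("nan")
    else:
        if np.std(calc) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(exp, calc)[0, 1] ** 2)
        slope, intercept = (float(v) for v in np.polyfit(exp, calc, 1))
    frac1 = frac2 = float("nan")
    if sigma is not None and sigma > 0:
        frac1 = float(np.mean(np.abs(r) <= sigma))
        frac2 = float(np.mean(np.abs(r) > 2 * sigma))
    return StatsSummary(
        n=len(pairs),
        r2=r2,
        avg_dev=float(np.mean(np.abs(r))),
        std_dev=float(math.sqrt(np.mean(r**2))),
        regression_intercept=intercept,
        regression_slope=slope,
        frac_within_1sigma=frac1,
        frac_beyond_2sigma=frac2,
    )


def fit_report(
    data: TrainingSet,
    fit: FitResult,
    cv: CVResult,
) -> dict:
    """Rows A-H style report of a fit plus its cross-validation."""
    return {
        "valid_groups": len(fit.contributions),
        "r2": fit.stats.r2,
        "avg_dev": fit.stats.avg_dev,
        "std_dev": fit.stats.std_dev,
        "n_train": fit.stats.n,
        "k": cv.config.k if cv.config else None,
        "q2": cv.q2,
        "cv_avg_dev": cv.stats.avg_dev,
        "cv_std_dev": cv.stats.std_dev,
        "n_cv": cv.stats.n,
        "cv_excluded": len(cv.excluded),
        "seed": cv.config.seed if cv.config else None,
        "definitions": [cv.r2_definition, cv.q2_definition],
    }
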