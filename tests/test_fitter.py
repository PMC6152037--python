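"""Gauss-Seidel fitting, gating fixed point, outlier loop."""

import math

import numpy as np
import pytest

from thermogroups.fitter import (
    CONSTANT_KEY,
    DesignMatrix,
    FitError,
    TrainingRecord,
    TrainingSet,
    build_design_matrix,
    fit_descriptor,
    solve_gauss_seidel,
)
from thermogroups.fixtures import SyntheticSpec, generate_synthetic_training


def _matrix_from_arrays(x, y, columns=None):
    n, p = x.shape
    columns = columns or [f"g{i}" for i in range(p - 1)] + [CONSTANT_KEY]
    support = {c: int(np.count_nonzero(x[:, i])) for i, c in enumerate(columns)}
    return DesignMatrix(
        columns=columns,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        names=[f"m{i}" for i in range(n)],
        support=support,
    )


def test_single_group_no_constant_is_mean():
    m = _matrix_from_arrays(np.ones((3, 1)), [10.0, 12.0, 14.0], columns=["g"])
    fit = solve_gauss_seidel(m)
    assert fit.converged
    assert fit.contributions["g"] == pytest.approx(12.0, abs=1e-9)


def test_gauss_seidel_matches_direct_least_squares_oracle():
    rng = np.random.default_rng(123)
    for _ in range(100):
        n, p = 20, 5
        x = np.column_stack(
            [rng.integers(0, 5, size=(n, p - 1)), np.ones(n)]
        ).astype(float)
        if np.linalg.matrix_rank(x) < p:
            continue
        y = rng.normal(size=n)
        fit = solve_gauss_seidel(_matrix_from_arrays(x, y))
        beta_gs = np.array(
            [fit.contributions[f"g{i}"] for i in range(p - 1)] + [fit.constant]
        )
        beta_ls, *_ = np.linalg.lstsq(x, y, rcond=None)
        assert fit.converged
        scale = max(1.0, float(np.max(np.abs(beta_ls))))
        assert np.max(np.abs(beta_gs - beta_ls)) / scale < 1e-6


def test_zero_column_raises_naming_the_column():
    x = np.column_stack([np.zeros(4), np.ones(4)])
    with pytest.raises(FitError, match="g0"):
        solve_gauss_seidel(_matrix_from_arrays(x, np.arange(4.0)))


def test_collinear_duplicate_columns_flagged_non_unique():
    rng = np.random.default_rng(5)
    col = rng.integers(1, 4, size=10).astype(float)
    x = np.column_stack([col, col, np.ones(10)])
    y = rng.normal(size=10)
    fit = solve_gauss_seidel(_matrix_from_arrays(x, y), max_iter=20_000)
    assert (not fit.unique) or (not fit.converged)


def test_permutation_of_records_does_not_change_fit():
    ts = generate_synthetic_training(
        SyntheticSpec(
            vocabulary=["a", "b", "c"],
            coefficients={"a": 2.0, "b": -1.0, "c": 0.5},
            constant=5.0,
            n=40,
            noise_sigma=1.0,
            seed=3,
        )
    )
    fit1 = solve_gauss_seidel(build_design_matrix(ts))
    rng = np.random.default_rng(9)
    shuffled = TrainingSet(
        records=[ts.records[i] for i in rng.permutation(len(ts.records))]
    )
    fit2 = solve_gauss_seidel(build_design_matrix(shuffled))
    for k in fit1.contributions:
        assert fit1.contributions[k] == pytest.approx(
            fit2.contributions[k], abs=1e-8
        )


# -- gating ------------------------------------------------------------------


def _record(name, feats, value=0.0):
    return TrainingRecord(name=name, features=feats, value=value)


def test_gate_drops_undersupported_group_and_its_molecules():
    ts = TrainingSet(
        records=[
            _record("a", {"g": 1}, 1.0),
            _record("b", {"g": 2}, 2.0),
            _record("c", {"g": 1}, 1.5),
            _record("d", {"g": 1, "h": 1}, 3.0),
            _record("e", {"h": 2}, 4.0),
        ]
    )
    m = build_design_matrix(ts, min_support=3)
    assert "h" in m.dropped_groups and m.dropped_groups["h"] == 2
    assert sorted(m.dropped_molecules) == ["d", "e"]
    assert m.columns == ["g", CONSTANT_KEY]
    assert m.n == 3


def test_gate_iterates_to_fixed_point():
    # dropping h's molecules pushes g below support 3 as well
    ts = TrainingSet(
        records=[
            _record("a", {"g": 1, "h": 1}, 1.0),
            _record("b", {"g": 1}, 2.0),
            _record("c", {"g": 1}, 1.5),
            _record("d", {"f": 1}, 3.0),
            _record("e", {"f": 1}, 4.0),
            _record("f", {"f": 1}, 5.0),
        ]
    )
    m = build_design_matrix(ts, min_support=3)
    assert set(m.dropped_groups) == {"g", "h"}
    assert m.columns == ["f", CONSTANT_KEY]


def test_gate_emptying_everything_raises():
    ts = TrainingSet(records=[_record("a", {"g": 1}, 1.0), _record("b", {"g": 1}, 2.0)])
    with pytest.raises(FitError):
        build_design_matrix(ts, min_support=3)


def test_block_diagonal_vocabularies_preserved():
    recs = [_record(f"a{i}", {"g": 1 + i % 2}, 1.0) for i in range(3)]
    recs += [_record(f"b{i}", {"h": 2 - i % 2}, 2.0) for i in range(3)]
    m = build_design_matrix(TrainingSet(records=recs), min_support=3)
    gi, hi = m.columns.index("g"), m.columns.index("h")
    assert np.all(m.x[:3, hi] == 0) and np.all(m.x[3:, gi] == 0)


# -- full fitting loop --------------------------------------------------------


def _clean_spec(n=120, noise=1.0, seed=0):
    return SyntheticSpec(
        vocabulary=["a", "b", "c", "d"],
        coefficients={"a": 3.0, "b": -2.0, "c": 10.0, "d": 0.7},
        constant=4.0,
        n=n,
        noise_sigma=noise,
        seed=seed,
    )


def test_clean_data_fits_without_outlier_removal():
    ts = generate_synthetic_training(_clean_spec())
    fit = fit_descriptor(ts, outlier_k=4.0, cv_seed=1)
    assert fit.removed_outliers == []
    for k, truth in {"a": 3.0, "b": -2.0, "c": 10.0, "d": 0.7}.items():
        assert fit.contributions[k] == pytest.approx(truth, abs=0.35)


def test_contaminated_records_are_the_ones_removed():
    ts = generate_synthetic_training(_clean_spec(seed=2))
    cv_sigma_scale = 1.0  # noise sigma of the generator
    bad = {"synth_5", "synth_17", "synth_40", "synth_77", "synth_99"}
    for r in ts.records:
        if r.name in bad:
            r.value += 10 * cv_sigma_scale * (1 if int(r.name[6:]) % 2 else -1)
    fit = fit_descriptor(ts, outlier_k=4.0, cv_seed=1)
    removed = {name for name, *_ in fit.removed_outliers}
    assert removed == bad


def test_infinite_outlier_k_is_single_round():
    ts = generate_synthetic_training(_clean_spec(seed=4))
    fit = fit_descriptor(ts, outlier_k=math.inf)
    assert fit.removed_outliers == [] and fit.cv_sigma is None


def test_noise_free_fit_recovers_generator_exactly():
    ts = generate_synthetic_training(_clean_spec(noise=0.0, seed=6))
    fit = solve_gauss_seidel(build_design_matrix(ts))
    assert fit.constant == pytest.approx(4.0, abs=1e-7)
    assert fit.stats.std_dev == pytest.approx(0.0, abs=1e-7)
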