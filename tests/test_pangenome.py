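"""Partitioning, accumulation curves, Heaps/exponential fits, openness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bacpan.cluster import PresenceAbsenceMatrix
from bacpan.errors import InputError
from bacpan.pangenome import (
    CoreExponentialModel,
    CurvePoint,
    HeapsLawModel,
    classify_openness,
    fit_core_exponential,
    fit_heaps,
    partition,
    sample_curves,
)
from bacpan.simulate import SimulationConfig, simulate_family_table

from oracles import naive_curve_medians


def matrix_from_rows(rows, strains=None):
    strains = strains or [f"S{i}" for i in range(len(rows[0]))]
    df = pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))],
                      columns=strains)
    return PresenceAbsenceMatrix(df)


class TestPartition:
    def test_three_strain_toy(self):
        mat = matrix_from_rows([[1, 1, 1], [1, 1, 0], [0, 0, 1]])
        part = partition(mat)
        assert (part.n_pan, part.n_core, part.n_dispensable, part.n_specific) == \
               (3, 1, 1, 1)

    def test_identity_always_holds(self, clustered_panel):
        *_, matrix = clustered_panel
        part = partition(matrix)
        assert part.n_pan == part.n_core + part.n_dispensable + part.n_specific
        assert sum(part.per_strain_specific.values()) == part.n_specific

    def test_single_strain_rejected(self):
        df = pd.DataFrame([[1]], index=["f0"], columns=["S0"])
        with pytest.raises(InputError):
            partition(PresenceAbsenceMatrix(df))

    def test_core_count_matches_generator(self, clustered_panel):
        cfg, *_rest, matrix = clustered_panel
        part = partition(matrix)
        assert part.n_core == cfg.n_core


@given(st.integers(2, 5), st.integers(1, 15), st.integers(0, 2 ** 31 - 1))
def test_partition_identity_fuzz(n_strains, n_fams, seed):
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, 3, size=(n_fams, n_strains))
    rows = rows[rows.sum(axis=1) > 0]
    if len(rows) == 0:
        rows = np.ones((1, n_strains), dtype=int)
    part = partition(matrix_from_rows(rows.tolist()))
    assert part.n_pan == part.n_core + part.n_dispensable + part.n_specific


class TestSampleCurves:
    def test_full_depth_equals_partition(self, clustered_panel):
        *_, matrix = clustered_panel
        part = partition(matrix)
        pan, core, new = sample_curves(matrix, 50, seed=1)
        assert all(s == part.n_pan for s in pan[-1].y_samples)
        assert all(s == part.n_core for s in core[-1].y_samples)

    def test_depth_one_counts_single_strain_families(self):
        mat = matrix_from_rows([[1, 1], [1, 0], [0, 1]])
        pan, core, new = sample_curves(mat, 2, seed=0)
        assert set(pan[0].y_samples) == {2}
        assert pan[0].y_samples == core[0].y_samples == new[0].y_samples

    def test_exhaustive_medians_match_enumeration_oracle(self, rng):
        rows = (rng.random((12, 4)) < 0.5)
        rows = rows[rows.sum(axis=1) > 0]
        mat = matrix_from_rows(rows.astype(int).tolist())
        pan, core, new = sample_curves(mat, n_orderings=100)  # 4! = 24 <= 100
        opan, ocore, onew = naive_curve_medians(rows.tolist())
        assert [p.y_median for p in pan] == opan
        assert [p.y_median for p in core] == ocore
        assert [p.y_median for p in new] == onew

    def test_monotone_within_every_ordering(self, clustered_panel):
        *_, matrix = clustered_panel
        pan, core, new = sample_curves(matrix, 200, seed=3)
        pan_arr = np.array([p.y_samples for p in pan])
        core_arr = np.array([p.y_samples for p in core])
        assert (np.diff(pan_arr, axis=0) >= 0).all()
        assert (np.diff(core_arr, axis=0) <= 0).all()
        assert ([p.y_median for p in pan] ==
                sorted(p.y_median for p in pan))


class TestHeapsFit:
    def test_refit_recovers_printed_coefficients(self):
        x = np.arange(1, 18)
        y = 624.45 * x ** 0.48 + 3033.86
        res = HeapsLawModel(x, y).fit()
        assert res.A_pan == pytest.approx(624.45, rel=1e-3)
        assert res.B_pan == pytest.approx(0.48, rel=1e-3)
        assert res.C_pan == pytest.approx(3033.86, rel=1e-3)
        assert res.openness == "open"

    def test_exact_linear_curve_is_boundary_closed(self):
        x = np.arange(1, 9)
        res = HeapsLawModel(x, 2.0 * x).fit()
        assert res.B_pan == pytest.approx(1.0, abs=1e-6)
        assert res.openness == "closed"

    def test_flat_curve_degenerates_to_constant(self):
        res = HeapsLawModel(np.arange(1, 6), np.full(5, 100.0)).fit()
        assert res.C_pan == pytest.approx(100.0)
        assert res.openness == "closed"

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            HeapsLawModel([1, 2, 3], [1, 2, 3])

    def test_parameter_recovery_under_noise(self):
        """Median |B error| < 0.05 across 100 noisy replicates (1% noise)."""
        rng = np.random.default_rng(7)
        x = np.arange(1, 18)
        errors = []
        for _ in range(100):
            a, b, c = rng.uniform(200, 800), rng.uniform(0.2, 0.8), rng.uniform(1000, 4000)
            y = (a * x ** b + c) * (1 + 0.01 * rng.standard_normal(x.size))
            res = HeapsLawModel(x, y).fit()
            errors.append(abs(res.B_pan - b))
        assert np.median(errors) < 0.05

    def test_summary_mentions_fit_and_openness(self):
        x = np.arange(1, 18)
        res = HeapsLawModel(x, 624.45 * x ** 0.48 + 3033.86).fit()
        text = res.summary()
        assert "B_pan" in text and "openness: open" in text


class TestClassifyOpenness:
    @pytest.mark.parametrize("b,verdict", [
        (0.48, "open"), (1.2, "closed"), (0.0, "closed"), (1.0, "closed"),
        (-0.3, "closed"), (0.999, "open"),
    ])
    def test_strict_interval(self, b, verdict):
        assert classify_openness(b) == verdict

    def test_non_finite_rejected(self):
        with pytest.raises(InputError):
            classify_openness(float("nan"))


class TestCoreExponentialFit:
    def test_noise_free_recovery(self):
        x = np.arange(1, 18)
        y = 500 * np.exp(-0.3 * x) + 3000
        res = CoreExponentialModel(x, y).fit()
        assert res.A_core == pytest.approx(500, rel=1e-3)
        assert res.B_core == pytest.approx(-0.3, rel=1e-3)
        assert res.C_core == pytest.approx(3000, rel=1e-3)

    def test_constant_core_degenerate(self):
        res = CoreExponentialModel(np.arange(1, 6), np.full(5, 3157.0)).fit()
        assert res.C_core == pytest.approx(3157.0)

    def test_fitted_core_curve_non_increasing_on_synthetic(self, clustered_panel):
        *_, matrix = clustered_panel
        _, core, _ = sample_curves(matrix, 200, seed=5)
        res = fit_core_exponential(core)
        fitted = res.predict(np.array([p.x for p in core], dtype=float))
        assert (np.diff(fitted) <= 1e-9).all()


class TestNewGenes:
    def test_direct_evaluation_of_pan_fit_difference(self):
        x = np.arange(1, 18)
        res = HeapsLawModel(x, 624.45 * x ** 0.48 + 3033.86).fit()
        expected = 624.45 * (18 ** 0.48 - 17 ** 0.48)
        assert res.new_genes_at_next(17) == pytest.approx(expected, rel=1e-6)

    def test_linear_fit_gives_constant_increment(self):
        x = np.arange(1, 9)
        res = HeapsLawModel(x, 5.0 * x + 10).fit()
        assert res.new_genes_at_next(3) == pytest.approx(5.0, abs=1e-6)

    def test_small_exponent_increment_vanishes(self):
        x = np.arange(1, 18)
        y = 100 * x ** 0.01 + 50
        res = HeapsLawModel(x, y).fit()
        assert 0 < res.new_genes_at_next(17) < 0.1


class TestOpennessRecovery:
    def test_gaining_panels_open_gain_free_closed(self):
        """Panels with per-strain unique gain read open; panels with a fixed
        family universe read closed (spot check; the full 100-seed study is
        in the acceptance suite)."""
        open_count = closed_count = 0
        for seed in range(10):
            cfg = SimulationConfig(n_strains=12, n_core=30, dispensable_rate=2.0,
                                   unique_per_strain=3.0, seed=seed)
            table, _ = simulate_family_table(cfg)
            mat = PresenceAbsenceMatrix(table)
            pan, *_ = sample_curves(mat, 200, seed=seed)
            open_count += fit_heaps(pan).openness == "open"

            cfg0 = SimulationConfig(n_strains=12, n_core=30, dispensable_rate=0.0,
                                    unique_per_strain=0.0, seed=seed)
            table0, _ = simulate_family_table(cfg0)
            pan0, *_ = sample_curves(PresenceAbsenceMatrix(table0), 200, seed=seed)
            closed_count += fit_heaps(pan0).openness == "closed"
        assert open_count >= 9
        assert closed_count >= 9
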