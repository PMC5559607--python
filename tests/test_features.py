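"""Predictor computation, the 7-minute growth-rate window, and cell filters."""

import numpy as np
import pytest

from sibfate.features import (
    FeatureError,
    InsufficientDataError,
    MissingParentError,
    build_training_set,
    colony_growth_rate,
    extract_features,
    extract_features_from_lineage,
    filter_cells,
    fit_growth_rate,
    instantaneous_growth_rate,
)

from conftest import make_cell, make_lineage


class TestFitGrowthRate:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(0, 10, 0.5)
        assert fit_growth_rate(t, 2.0 * np.exp(0.03 * t)) == pytest.approx(
            0.03, abs=1e-9
        )

    def test_constant_length_gives_zero(self):
        t = np.arange(5.0)
        assert fit_growth_rate(t, np.full(5, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariant(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 8, 0.5)
        l = 2.0 * np.exp(0.031 * t) * np.exp(rng.normal(0, 0.02, len(t)))
        assert fit_growth_rate(t, 7.3 * l) == pytest.approx(
            fit_growth_rate(t, l), abs=1e-12
        )

    def test_too_few_frames(self):
        with pytest.raises(InsufficientDataError):
            fit_growth_rate([0, 1], [1.0, 1.1])

    def test_noisy_recovery_within_five_percent(self):
        # 2% multiplicative noise, known rate, averaged over 100 seeds
        lam = 0.0296
        t = np.arange(0, 23.5, 0.5)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            l = 2.1 * np.exp(lam * t) * np.exp(rng.normal(0, 0.02, len(t)))
            errs.append(abs(fit_growth_rate(t, l) - lam) / lam)
        assert np.mean(errs) < 0.05


class TestInstantaneousGrowthRate:
    def _mother_daughter(self, share=0.5, lam=0.03):
        # mother runs 0..10 min and divides; daughter continues 10..20 min
        t_m = np.arange(0, 10.5, 0.5)
        l_m = 2.0 * np.exp(lam * t_m)
        mother = make_cell("m", division=10.0, times=t_m, lengths=l_m)
        t_d = np.arange(10.0, 20.5, 0.5)
        l_d = share * l_m[-1] * np.exp(lam * (t_d - 10.0))
        daughter = make_cell(
            "d", parent_id="m", birth=10.0, times=t_d, lengths=l_d
        )
        return mother, daughter

    def test_window_inside_single_cell_is_exact(self):
        _, d = self._mother_daughter()
        assert instantaneous_growth_rate(d, None, at=19.0) == pytest.approx(
            0.03, abs=1e-9
        )

    def test_symmetric_division_splice(self):
        m, d = self._mother_daughter(share=0.5)
        # window [6, 13] crosses the division at t=10
        assert instantaneous_growth_rate(d, m, at=13.0) == pytest.approx(
            0.03, abs=1e-3
        )

    def test_asymmetric_division_share_makes_splice_continuous(self):
        m, d = self._mother_daughter(share=0.6)
        assert instantaneous_growth_rate(d, m, at=13.0) == pytest.approx(
            0.03, abs=1e-3
        )

    def test_missing_mother_raises(self):
        _, d = self._mother_daughter()
        with pytest.raises(MissingParentError):
            instantaneous_growth_rate(d, None, at=13.0)


class TestExtractFeatures:
    def _cell(self):
        t = np.arange(10.0, 30.5, 0.5)
        l = 2.0 * np.exp(0.03 * (t - 10.0))
        return make_cell(
            "c", birth=10.0, division=30.0, times=t, lengths=l, fluor=100 * l
        )

    def test_at_birth_all_deltas_zero(self):
        fv = extract_features(self._cell(), None, at=10.0, window=0.0)
        assert fv.dt == 0.0
        assert fv.dL == pytest.approx(0.0, abs=1e-12)
        assert fv.dF == pytest.approx(0.0, abs=1e-9)
        assert fv.x == pytest.approx(0.0)

    def test_at_division_x_is_one(self):
        fv = extract_features(self._cell(), None, at=30.0)
        assert fv.x == pytest.approx(1.0)

    def test_quarter_cycle(self):
        fv = extract_features(self._cell(), None, at=15.0)
        assert fv.x == pytest.approx(0.25)
        assert fv.dt == pytest.approx(5.0)

    def test_outside_span_raises(self):
        with pytest.raises(FeatureError, match="outside tracked span"):
            extract_features(self._cell(), None, at=40.0)

    def test_matches_ground_truth_on_simulated_cells(self, small_growth):
        ls, gt, cfg = small_growth
        sched = dict(zip(gt.cells.cell_id, gt.cells.scheduled_division))
        checked = 0
        for cell in ls:
            if cell.division_time is None or cell.parent_id is None:
                continue
            at = cell.times[len(cell.times) // 2]
            fv = extract_features_from_lineage(ls, cell.cell_id, at)
            x_true = (at - cell.birth_time) / (sched[cell.cell_id] - cell.birth_time)
            assert fv.x == pytest.approx(x_true, abs=1e-9)
            checked += 1
        assert checked > 10


class TestFilters:
    def _with_length(self, peak):
        t = np.arange(0, 5.0, 1.0)
        l = np.linspace(2.0, peak, len(t))
        return make_cell("big", times=t, lengths=l)

    def test_filament_above_threshold_excluded(self):
        res = filter_cells(make_lineage([self._with_length(11.5)]))
        assert res.n_filament_removed == 1
        assert len(res.lineage_set) == 0

    def test_exactly_eleven_retained(self):
        res = filter_cells(make_lineage([self._with_length(11.0)]))
        assert res.n_filament_removed == 0
        assert len(res.lineage_set) == 1

    def test_required_divisions_excludes_undivided_founder(self):
        founder = make_cell("f")  # never divides
        res = filter_cells(make_lineage([founder], shock_time=10.0), required_divisions=1)
        assert res.n_division_rule_removed == 1
        assert len(res.lineage_set) == 0

    def test_required_divisions_keeps_single_division_lineage(self):
        m = make_cell("m", division=2.0, times=[0, 1, 2], lengths=[2.0, 2.2, 2.4])
        d1 = make_cell("d1", parent_id="m", birth=2.0, times=[2, 3], lengths=[1.2, 1.3])
        d2 = make_cell("d2", parent_id="m", birth=2.0, times=[2, 3], lengths=[1.2, 1.3])
        ls = make_lineage([m, d1, d2], shock_time=10.0)
        res = filter_cells(ls, required_divisions=1)
        assert len(res.lineage_set) == 3

    def test_idempotent(self, shocked):
        ls, _, _ = shocked
        once = filter_cells(ls, required_divisions=None).lineage_set
        twice = filter_cells(once, required_divisions=None).lineage_set
        assert set(once.cells) == set(twice.cells)


class TestTrainingSet:
    def test_no_completed_cycles_warns_and_returns_empty(self):
        ls = make_lineage([make_cell("f")])
        with pytest.warns(UserWarning, match="no eligible"):
            table = build_training_set(ls, seed=0)
        assert len(table) == 0

    def test_one_row_per_eligible_cell(self, small_growth):
        ls, _, _ = small_growth
        table = build_training_set(ls, seed=0)
        eligible = [
            c
            for c in ls
            if c.division_time is not None and c.parent_id is not None
        ]
        assert len(table) == len(eligible)
        assert table.cell_id.is_unique

    def test_deterministic_given_seed(self, small_growth):
        ls, _, _ = small_growth
        t1 = build_training_set(ls, seed=3)
        t2 = build_training_set(ls, seed=3)
        assert t1.equals(t2)
        t3 = build_training_set(ls, seed=4)
        assert not t1.x.equals(t3.x)

    def test_x_in_unit_interval_and_features_sane(self, training_table):
        t = training_table
        assert ((t.x >= 0) & (t.x <= 1)).all()
        assert (t.Lb > 0).all()
        assert (t.dt >= 0).all()
        assert (t.dL >= -0.1).all()


def test_colony_growth_rate_close_to_population_rate(small_growth):
    ls, _, cfg = small_growth
    lam = colony_growth_rate(ls, "col0000")
    assert lam == pytest.approx(cfg.growth_rate, rel=0.15)
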