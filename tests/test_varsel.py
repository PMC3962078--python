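import itertools

import numpy as np
import pytest

from rdcvpls.crossval import CVConfig
from rdcvpls.data_io import DescriptorTable
from rdcvpls.synthetic import SyntheticSpec, generate
from rdcvpls.varsel import (
    combine_prefilter_stepwise,
    eliminate_corr_xx,
    filter_almost_constant,
    filter_low_corr_y,
    select_by_pls_coeff,
    select_top_corr_y,
    stepwise_bic,
)


def make_table(X, y):
    n, m = X.shape
    return DescriptorTable(
        X=X,
        variable_names=[f"x{j}" for j in range(m)],
        object_names=[f"o{i}" for i in range(n)],
        y=y,
    )


class TestAlmostConstant:
    def test_single_exception_column(self, rng):
        X = np.column_stack([
            np.array([5.0, 5.0, 5.0, 5.0, 7.0]),
            rng.standard_normal(5),
        ])
        assert filter_almost_constant(X, k=1).mask.tolist() == [False, True]
        assert filter_almost_constant(X, k=0).mask.tolist() == [True, True]

    def test_constant_column_always_dropped(self, rng):
        X = np.column_stack([np.full(6, 3.0), rng.standard_normal(6)])
        for k in (0, 1, 3):
            assert filter_almost_constant(X, k=k).mask.tolist() == [False, True]

    def test_rounding_merges_near_equal_values(self):
        col = np.array([1.0000004, 1.0000001, 2.0])
        X = col.reshape(-1, 1)
        # rounded to 6 decimals the values are [1, 1, 2]
        assert filter_almost_constant(X, k=1, round_decimals=6).mask.tolist() == [False]
        assert filter_almost_constant(X, k=0, round_decimals=6).mask.tolist() == [True]
        # at full precision all three values differ
        assert filter_almost_constant(X, k=1, round_decimals=12).mask.tolist() == [True]


class TestCorrelationWithY:
    def test_exact_dependence_always_selected(self, rng):
        X = rng.standard_normal((30, 5))
        y = X[:, 3].copy()
        for m_sel in (1, 3):
            assert select_top_corr_y(X, y, m_sel).mask[3]

    def test_m_sel_equals_m_is_identity(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        assert select_top_corr_y(X, y, 6).mask.all()
        assert filter_low_corr_y(X, y, 0.0).mask.all()

    def test_matches_brute_force_pearson_ranking(self, rng):
        X = rng.standard_normal((50, 10))
        y = X[:, 2] + 0.5 * X[:, 7] + rng.standard_normal(50)
        r2 = np.array([np.corrcoef(X[:, j], y)[0, 1] ** 2 for j in range(10)])
        for m_sel in (1, 4, 9):
            mask = select_top_corr_y(X, y, m_sel).mask
            expected = set(np.argsort(-r2, kind="stable")[:m_sel])
            assert set(np.flatnonzero(mask)) == expected
        for r2_min in (0.05, 0.3):
            mask = filter_low_corr_y(X, y, r2_min).mask
            np.testing.assert_array_equal(mask, r2 >= r2_min)

    def test_zero_variance_column_warns_and_scores_zero(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 4.0
        y = X[:, 0]
        with pytest.warns(UserWarning, match="zero-variance"):
            mask = select_top_corr_y(X, y, 2).mask
        assert not mask[1]

    def test_r2_min_out_of_range(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            filter_low_corr_y(X, X[:, 0], 1.0 + 1e-9)


class TestEliminateCorrXX:
    def test_three_variable_hand_case(self, rng):
        # x0 and x1 share a common factor z (pair R^2 > 0.9); x2 is made
        # exactly orthogonal to z in-sample but enters x0 with a larger
        # coefficient than x1 -> x0 has the larger correlation sum and is
        # the member deleted from the offending pair
        n = 200
        z = rng.standard_normal(n)
        raw = rng.standard_normal(n)
        z_c = z - z.mean()
        x2 = raw - z_c * ((raw - raw.mean()) @ z_c) / (z_c @ z_c)
        x0 = z + 0.3 * x2
        x1 = z + 0.1 * x2
        X = np.column_stack([x0, x1, x2])
        R2 = np.corrcoef(X, rowvar=False) ** 2
        assert R2[0, 1] > 0.9
        sums = R2.sum(axis=1) - 1.0
        assert sums[0] > sums[1]
        mask = eliminate_corr_xx(X, r2_limit=0.9).mask
        assert mask.tolist() == [False, True, True]

    def test_limit_above_max_r2_keeps_all(self, rng):
        X = rng.standard_normal((40, 5))
        R2 = np.corrcoef(X, rowvar=False) ** 2
        np.fill_diagonal(R2, 0)
        mask = eliminate_corr_xx(X, r2_limit=min(1.0, R2.max() + 0.01))
        assert mask.mask.all()

    def test_survivors_verified_by_brute_force(self, rng):
        X = rng.standard_normal((30, 8))
        # build in collinear structure
        X[:, 3] = X[:, 0] + 0.05 * rng.standard_normal(30)
        X[:, 6] = -X[:, 1] + 0.05 * rng.standard_normal(30)
        limit = 0.9
        mask = eliminate_corr_xx(X, r2_limit=limit).mask
        survivors = np.flatnonzero(mask)
        R2 = np.corrcoef(X, rowvar=False) ** 2
        for g, h in itertools.combinations(survivors, 2):
            assert R2[g, h] <= limit
        # removals match the fixed-sum rule replayed independently
        sums = R2.sum(axis=1) - 1.0
        pairs = [
            (g, h)
            for g, h in itertools.combinations(range(8), 2)
            if R2[g, h] > limit
        ]
        pairs.sort(key=lambda p: -R2[p])
        deleted = set()
        for g, h in pairs:
            if g in deleted or h in deleted:
                continue
            if sums[g] > sums[h]:
                deleted.add(g)
            elif sums[h] > sums[g]:
                deleted.add(h)
            else:
                deleted.add(max(g, h))
        assert set(np.flatnonzero(~mask)) == deleted

    def test_limit_monotone_survivor_sets(self, rng):
        X = rng.standard_normal((40, 10))
        X[:, 5] = X[:, 0] + 0.1 * rng.standard_normal(40)
        X[:, 8] = X[:, 2] + 0.3 * rng.standard_normal(40)
        s_low = set(np.flatnonzero(eliminate_corr_xx(X, 0.5).mask))
        s_high = set(np.flatnonzero(eliminate_corr_xx(X, 0.9).mask))
        assert s_low <= s_high

    def test_zero_variance_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="filter_almost_constant"):
            eliminate_corr_xx(X, 0.9)


class TestSelectByPlsCoeff:
    def test_informative_variable_ranked_first_over_seeds(self):
        cfg = CVConfig(r=5, s_outer=3, s_inner=4, A_max=4, seed=0)
        for seed in range(10):
            table, _ = generate(
                SyntheticSpec(
                    n=100,
                    m_noise=14,
                    blocks=((1, 0.0),),
                    support=((0, 3.0),),
                    noise_sd=0.5,
                    seed=seed,
                )
            )
            mask = select_by_pls_coeff(table, m_sel=1, cv=cfg)
            assert mask.mask.tolist().index(True) == 0

    def test_m_sel_equal_m_identity(self, small_table):
        table, _ = small_table
        cfg = CVConfig(r=3, s_outer=3, s_inner=3, A_max=3, seed=1)
        assert select_by_pls_coeff(table, m_sel=table.m, cv=cfg).mask.all()

    def test_duplicated_informative_column_both_top_ranked(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((60, 6))
        X[:, 1] = X[:, 0]
        y = 2.0 * X[:, 0] + rng.standard_normal(60) * 0.3
        table = make_table(X, y)
        cfg = CVConfig(r=5, s_outer=3, s_inner=4, A_max=4, seed=2)
        mask = select_by_pls_coeff(table, m_sel=2, cv=cfg)
        assert mask.mask.tolist() == [True, True, False, False, False, False]


class TestStepwiseBIC:
    def test_first_forward_pick_is_max_r2_variable(self, rng):
        X = rng.standard_normal((40, 8))
        y = 1.5 * X[:, 5] + rng.standard_normal(40)
        r2 = np.array([np.corrcoef(X[:, j], y)[0, 1] ** 2 for j in range(8)])
        mask, trace = stepwise_bic(X, y, max_steps=1)
        assert trace.steps[0].variable == int(np.argmax(r2))

    def test_planted_two_variable_model_recovered(self):
        rng = np.random.default_rng(55)
        n, m = 60, 20
        X = rng.standard_normal((n, m))
        y = 2.0 * X[:, 2] - 1.0 * X[:, 5] + rng.standard_normal(n) * 0.01
        mask, trace = stepwise_bic(X, y, mode="forward")
        assert {2, 5} <= set(np.flatnonzero(mask.mask))
        bics = trace.bic_values()
        assert all(b2 < b1 for b1, b2 in zip(bics, bics[1:]))

    def test_max_steps_zero_returns_empty(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        mask, trace = stepwise_bic(X, y, max_steps=0)
        assert not mask.mask.any()
        assert trace.stop_reason == "max_steps"

    def test_both_mode_can_remove_a_variable(self):
        # x0 = x1 + x2 (plus tiny noise); forward may pick x0 first, but once
        # x1 and x2 enter, x0 is redundant and the both-mode search drops it
        rng = np.random.default_rng(13)
        n = 80
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        x0 = x1 + x2 + 0.01 * rng.standard_normal(n)
        noise = rng.standard_normal((n, 3))
        X = np.column_stack([x0, x1, x2, noise])
        y = 3.0 * x1 - 2.0 * x2 + 0.05 * rng.standard_normal(n)
        mask_b, trace_b = stepwise_bic(X, y, mode="both")
        assert {1, 2} <= set(np.flatnonzero(mask_b.mask))
        assert not mask_b.mask[0]

    def test_deterministic_rerun(self, rng):
        X = rng.standard_normal((30, 10))
        y = X[:, 1] + rng.standard_normal(30) * 0.2
        m1, t1 = stepwise_bic(X, y, mode="both")
        m2, t2 = stepwise_bic(X, y, mode="both")
        np.testing.assert_array_equal(m1.mask, m2.mask)
        assert t1.bic_values() == t2.bic_values()


class TestCombinePrefilterStepwise:
    def test_keep_all_prefilter_equals_plain_stepwise(self, rng):
        X = rng.standard_normal((40, 8))
        y = X[:, 3] + rng.standard_normal(40) * 0.1
        table = make_table(X, y)
        combined, _ = combine_prefilter_stepwise(
            table, [lambda Xs, ys: filter_low_corr_y(Xs, ys, 0.0)]
        )
        plain, _ = stepwise_bic(X, y)
        np.testing.assert_array_equal(combined.mask, plain.mask)

    def test_prefilter_removes_weak_true_variable(self):
        # one planted variable engineered to have R2 with y below 0.1: the
        # prefilter eliminates it before stepwise ever sees it
        rng = np.random.default_rng(42)
        n = 200
        strong = rng.standard_normal(n)
        weak = rng.standard_normal(n)
        noise_cols = rng.standard_normal((n, 5))
        y = 3.0 * strong + 0.3 * weak + rng.standard_normal(n)
        X = np.column_stack([strong, weak, noise_cols])
        r2_weak = np.corrcoef(X[:, 1], y)[0, 1] ** 2
        assert r2_weak < 0.1
        mask, _ = combine_prefilter_stepwise(
            make_table(X, y), [lambda Xs, ys: filter_low_corr_y(Xs, ys, 0.1)]
        )
        assert not mask.mask[1]
        assert mask.mask[0]

    def test_empty_intermediate_mask_names_stage(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        with pytest.raises(ValueError, match="stage 1"):
            combine_prefilter_stepwise(
                make_table(X, y), [lambda Xs, ys: filter_low_corr_y(Xs, ys, 1.0)]
            )

    def test_provenance_round_trips(self, rng, tmp_path):
        from rdcvpls.data_io import load_mask, save_mask

        X = rng.standard_normal((40, 6))
        y = X[:, 0] + rng.standard_normal(40) * 0.1
        mask, _ = combine_prefilter_stepwise(
            make_table(X, y),
            [lambda Xs, ys: filter_low_corr_y(Xs, ys, 0.05)],
            stepwise_kwargs={"mode": "both"},
        )
        save_mask(mask, tmp_path / "m.json")
        loaded = load_mask(tmp_path / "m.json")
        assert loaded.provenance == mask.provenance
        assert "low_corr_y" in loaded.provenance and "stepwise" in loaded.provenance


class TestMaskInvariants:
    def test_every_operator_preserves_length_and_order(self, rng):
        X = rng.standard_normal((30, 7))
        y = X[:, 0] + rng.standard_normal(30)
        masks = [
            filter_almost_constant(X),
            select_top_corr_y(X, y, 3),
            filter_low_corr_y(X, y, 0.01),
            eliminate_corr_xx(X, 0.95),
            stepwise_bic(X, y, max_steps=3)[0],
        ]
        for mask in masks:
            assert mask.mask.shape == (7,)
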