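import numpy as np
import pytest

from ssgic import (
    Dataset,
    GICPenalty,
    LassoPath,
    LossSpec,
    build_nested_family,
    build_union_family,
    exhaustive_gic,
    gic,
    lambda_grid,
    lft_select,
    order_support,
    parse_penalty,
    penalty_value,
    refit_erm,
    ss_select,
    ssnet_select,
    sscv_select,
)

from conftest import make_logistic_data


class TestOrderSupport:
    @pytest.mark.parametrize(
        "coef, expected",
        [
            ([0, 2.5, -3, 0, 1], [2, 1, 4]),  # magnitude descending
            ([0, 0, 0], []),
            ([1.0, -1.0], [0, 1]),  # tie -> smaller index first
        ],
    )
    def test_ordering(self, coef, expected):
        assert order_support(np.array(coef, dtype=float)) == expected


class TestBuildNestedFamily:
    def test_chain_construction(self):
        assert build_nested_family([2, 1, 4]) == [(), (2,), (1, 2), (1, 2, 4)]

    def test_empty_gives_null_chain(self):
        assert build_nested_family([]) == [()]

    def test_chain_length(self):
        assert len(build_nested_family([5, 0, 3])) == 4

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            build_nested_family([1, 1])


def _path_from_coefs(lambdas, coefs):
    coefs = np.asarray(coefs, dtype=float)
    return LassoPath(
        np.asarray(lambdas, dtype=float),
        np.zeros(len(lambdas)),
        coefs,
        np.ones(len(lambdas), dtype=bool),
        LossSpec("quadratic"),
    )


class TestBuildUnionFamily:
    def test_duplicate_chains_collapse(self):
        path = _path_from_coefs([0.2, 0.1], [[0, 2.0, 1.0], [0, 2.0, 1.0]])
        fam = build_union_family(path, size_cap=None, n=100)
        assert fam.merged == [(), (1,), (1, 2)]

    def test_oversized_support_contributes_nothing(self):
        # 3 nonzero coefficients but n=2: that lambda is dropped entirely
        path = _path_from_coefs([0.2, 0.1], [[1.0, 0, 0], [3.0, 2.0, 1.0]])
        fam = build_union_family(path, size_cap=None, n=2)
        assert fam.dropped_lambdas == [0.1]
        assert fam.merged == [(), (0,)]

    def test_merged_size_union_bound(self, small_data):
        loss = LossSpec("logistic")
        grid = lambda_grid(small_data, loss, m=8)
        from ssgic import fit_lasso_path

        path = fit_lasso_path(small_data, loss, grid)
        fam = build_union_family(path, size_cap=None, n=small_data.n)
        assert len(fam.merged) <= 1 + sum(len(c) - 1 for c in fam.families)

    def test_size_cap_filters(self):
        path = _path_from_coefs([0.1], [[3.0, 2.0, 1.0]])
        fam = build_union_family(path, size_cap=2, n=100)
        assert all(len(w) <= 2 for w in fam.merged)


class TestPenaltyValue:
    def test_aic_constant(self):
        assert penalty_value(GICPenalty("aic"), 1000, 50) == 2.0

    def test_bic_log_n(self):
        n = int(round(np.e**2))  # log n ~ 2 at n = e^2
        assert penalty_value(GICPenalty("bic"), n, 10) == pytest.approx(np.log(n))

    def test_ebic_formula(self):
        val = penalty_value(GICPenalty("ebic", d=1.0), 100, 150)
        assert val == pytest.approx(np.log(100) + 2 * np.log(150), abs=1e-12)
        assert val == pytest.approx(14.6265, abs=5e-4)

    def test_lft_formula(self):
        val = penalty_value(GICPenalty("lft"), 500, 150)
        assert val == pytest.approx(np.log(np.log(500)) * np.log(150), abs=1e-12)

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            penalty_value(GICPenalty("lft"), 1, 10)

    def test_parse_penalty_strings(self):
        assert parse_penalty("ebic1") == GICPenalty("ebic", d=1.0)
        assert parse_penalty("bic").name == "bic"
        assert parse_penalty(GICPenalty("aic")).name == "aic"


class TestGIC:
    def test_null_model_closed_form(self):
        r = np.random.default_rng(3)
        X = r.standard_normal((100, 5))
        y = np.array([0.0, 1.0] * 50)
        val, refit = gic(Dataset(X, y), (), LossSpec("logistic"), GICPenalty("bic"))
        assert val == pytest.approx(100 * np.log(2) + np.log(100), abs=1e-6)
        assert val == pytest.approx(73.92, abs=0.005)

    def test_penalty_term_increases_with_size(self, small_data):
        pen = GICPenalty("bic")
        vals = []
        for w in [(), (0,), (0, 1)]:
            v, refit = gic(small_data, w, LossSpec("logistic"), pen)
            vals.append(v - small_data.n * refit.risk)
        assert vals[0] < vals[1] < vals[2]

    def test_aic_below_bic_for_n_at_least_8(self, small_data):
        # BIC's weight exceeds AIC's once log n > 2, i.e. from n = 8 on
        for w in [(), (0,), (2, 4)]:
            v_aic, r = gic(small_data, w, LossSpec("logistic"), GICPenalty("aic"))
            v_bic, _ = gic(small_data, w, LossSpec("logistic"), GICPenalty("bic"))
            assert v_aic <= v_bic

    def test_count_intercept_offset(self, small_data):
        pen_with = GICPenalty("bic", count_intercept=True)
        pen_bare = GICPenalty("bic", count_intercept=False)
        a_n = penalty_value(pen_with, small_data.n, small_data.p)
        v1, _ = gic(small_data, (0, 1), LossSpec("logistic"), pen_with)
        v2, _ = gic(small_data, (0, 1), LossSpec("logistic"), pen_bare)
        assert v1 - v2 == pytest.approx(a_n, abs=1e-9)


class TestSSSelect:
    def test_huge_lambda_selects_null(self, small_data):
        res = ss_select(small_data, LossSpec("logistic"), 10.0, GICPenalty("bic"))
        assert res.family == [()]
        assert res.selected_support == ()

    def test_two_model_comparison_single_predictor(self):
        ds = make_logistic_data(200, 1, np.array([2.0]), seed=11)
        res = ss_select(ds, LossSpec("logistic"), 0.02, GICPenalty("bic"))
        trace = {t["support"]: t["gic"] for t in res.gic_trace}
        if trace[(0,)] < trace[()]:
            assert res.selected_support == (0,)

    def test_selected_attains_trace_minimum(self, small_data):
        res = ss_select(small_data, LossSpec("logistic"), 0.05, GICPenalty("bic"))
        best = min(t["gic"] for t in res.gic_trace)
        sel = [t for t in res.gic_trace if t["support"] == res.selected_support]
        assert sel[0]["gic"] == pytest.approx(best)


class TestSSnetSelect:
    def test_single_lambda_grid_reduces_to_ss(self, small_data):
        loss = LossSpec("logistic")
        lam = 0.05
        res_net = ssnet_select(small_data, loss, GICPenalty("bic"), lambdas=np.array([lam]))
        res_ss = ss_select(small_data, loss, lam, GICPenalty("bic"))
        assert res_net.selected_support == res_ss.selected_support

    def test_merged_minimum_below_chain_minima(self, small_data):
        loss = LossSpec("logistic")
        grid = lambda_grid(small_data, loss, m=6)
        res = ssnet_select(small_data, loss, GICPenalty("bic"), lambdas=grid)
        from ssgic import fit_lasso_path

        path = fit_lasso_path(small_data, loss, grid)
        fam = build_union_family(path, None, small_data.n)
        merged_min = min(t["gic"] for t in res.gic_trace)
        trace = {t["support"]: t["gic"] for t in res.gic_trace}
        for chain in fam.families:
            chain_min = min(trace[w] for w in chain if w in trace)
            assert merged_min <= chain_min + 1e-9

    def test_selected_size_nonincreasing_in_penalty_weight(self, small_data):
        # a_n grows from AIC -> BIC -> EBIC(1): the GIC winner cannot grow
        loss = LossSpec("logistic")
        sizes = []
        for pen in ["aic", "bic", "ebic1"]:
            res = ssnet_select(small_data, loss, pen, m=8)
            sizes.append(len(res.selected_support))
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestSSCVSelect:
    def test_single_lambda_reduces_to_ss(self, small_data):
        loss = LossSpec("logistic")
        res = sscv_select(small_data, loss, GICPenalty("bic"), lambdas=np.array([0.05]))
        ref = ss_select(small_data, loss, 0.05, GICPenalty("bic"))
        assert res.selected_support == ref.selected_support
        assert res.procedure == "sscv"

    def test_deterministic_given_seed(self, small_data):
        loss = LossSpec("logistic")
        r1 = sscv_select(small_data, loss, GICPenalty("bic"), m=6, K=5, seed=42)
        r2 = sscv_select(small_data, loss, GICPenalty("bic"), m=6, K=5, seed=42)
        assert r1.selected_support == r2.selected_support
        assert r1.lam == r2.lam

    def test_family_no_larger_than_ssnet(self, small_data):
        loss = LossSpec("logistic")
        grid = lambda_grid(small_data, loss, m=6)
        r_cv = sscv_select(small_data, loss, GICPenalty("bic"), lambdas=grid, K=5, seed=1)
        r_net = ssnet_select(small_data, loss, GICPenalty("bic"), lambdas=grid)
        assert len(r_cv.family) <= len(r_net.family)


class TestLFTSelect:
    def test_null_data_selects_empty(self):
        r = np.random.default_rng(5)
        ds = Dataset(r.standard_normal((100, 8)), (r.random(100) < 0.5).astype(float))
        res = lft_select(ds, LossSpec("logistic"), m=6)
        assert res.selected_support == ()

    def test_criterion_no_worse_than_largest_lambda(self, small_data):
        res = lft_select(small_data, LossSpec("logistic"), m=8)
        sel = min(t["gic"] for t in res.gic_trace)
        at_lam1 = res.gic_trace[0]["gic"]
        assert sel <= at_lam1 + 1e-12

    def test_no_refit_coefficients_are_lasso(self, small_data):
        from ssgic import fit_lasso

        res = lft_select(small_data, LossSpec("logistic"), m=8)
        fit = fit_lasso(small_data, LossSpec("logistic"), res.lam)
        assert np.allclose(res.coef_std, fit.coef, atol=1e-6)


class TestExhaustiveGIC:
    def test_single_predictor_two_models(self):
        ds = make_logistic_data(80, 1, np.array([1.5]), seed=2)
        res = exhaustive_gic(ds, LossSpec("logistic"), GICPenalty("bic"), kmax=1)
        assert {t["support"] for t in res.gic_trace} == {(), (0,)}

    def test_guard_rejects_large_problems(self, rng):
        ds = Dataset(rng.standard_normal((30, 16)), (rng.random(30) < 0.5).astype(float))
        with pytest.raises(ValueError, match="exhaustive"):
            exhaustive_gic(ds, LossSpec("logistic"), GICPenalty("bic"), kmax=2)

    def test_minimum_no_worse_than_ssnet(self):
        loss = LossSpec("logistic")
        for seed in range(5):
            ds = make_logistic_data(
                60, 6, np.array([1.5, -1.0, 0.5, 0.0, 0.0, 0.0]), seed=seed
            ).standardize()
            ex = exhaustive_gic(ds, loss, GICPenalty("bic"), kmax=6)
            net = ssnet_select(ds, loss, GICPenalty("bic"), m=10)
            assert min(t["gic"] for t in ex.gic_trace) <= min(
                t["gic"] for t in net.gic_trace
            ) + 1e-7
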