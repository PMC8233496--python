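import numpy as np
import pytest

from chronotree.errors import ConfigurationError, ConstraintError
from chronotree.node_dating import (
    CalibrationDensity,
    _feasible_interval,
    fit_time_scale,
    fixed_rate_scale,
    parse_calibration_line,
    read_calibration_file,
)
from chronotree.reltime import relative_rates_and_times
from conftest import simulated_phylogram, true_times


@pytest.fixture
def clock_rt(clock_tree):
    return relative_rates_and_times(clock_tree)


def cal(kind, selector=("mrca", "A", "B"), **params):
    return CalibrationDensity(selector, kind, params)


class TestCalibrationDensity:
    @pytest.mark.parametrize(
        "kind,params",
        [
            ("normal", dict(mean=50, sd=0)),
            ("lognormal", dict(offset=-1, mean=1, sd=0.5)),
            ("exponential", dict(offset=0, decay=0)),
            ("uniform", dict(min=60, max=40)),
            ("nonsense", dict()),
        ],
    )
    def test_invalid_parameters_rejected(self, kind, params):
        with pytest.raises(ConfigurationError):
            cal(kind, **params)

    def test_density_support(self):
        c = cal("exponential", offset=30, decay=0.1)
        assert c.pdf(29.0) == 0.0
        assert c.pdf(31.0) > 0.0

    def test_lognormal_offset_parameterization(self):
        c = cal("lognormal", offset=10, mean=np.log(20), sd=0.5)
        # median of offset-lognormal is offset + exp(meanlog)
        assert c._dist().median() == pytest.approx(30.0, rel=1e-9)


class TestFitTimeScale:
    def test_single_point_calibration_scales_exactly(self, clock_rt):
        res = fit_time_scale(
            clock_rt, [cal("point", time=50)], n_samples=200, seed=0
        )
        assert res.f == pytest.approx(100.0, abs=1e-12)
        assert res.times[clock_rt.tree.root.id] == pytest.approx(100.0, abs=1e-9)
        # linear through the origin: every node time = f * rel_time
        np.testing.assert_allclose(res.times, res.f * clock_rt.rel_times, atol=1e-9)

    def test_two_normal_calibrations_hand_solution(self, clock_rt):
        """d/df [logN(f/2; 50,5) + logN(f; 90,10)] = 0 at f = 95."""
        cals = [
            cal("normal", mean=50, sd=5),
            cal("normal", selector=("mrca", "A", "C"), mean=90, sd=10),
        ]
        res = fit_time_scale(clock_rt, cals, n_samples=200, seed=0)
        assert res.f == pytest.approx(95.0, abs=1e-6)
        ab = clock_rt.tree.mrca(["A", "B"])
        assert res.times[ab.id] == pytest.approx(47.5, abs=1e-6)

    def test_uniform_plus_point(self, clock_rt):
        cals = [
            cal("uniform", min=40, max=60),
            cal("point", selector=("mrca", "A", "C"), time=100),
        ]
        res = fit_time_scale(clock_rt, cals, n_samples=200, seed=0)
        ab = clock_rt.tree.mrca(["A", "B"])
        assert res.f == pytest.approx(100.0, abs=1e-9)
        assert res.times[ab.id] == pytest.approx(50.0, abs=1e-9)
        assert res.ci_lo[ab.id] >= 40.0 and res.ci_hi[ab.id] <= 60.0

    def test_minbound_maxbound_constrain_f(self, clock_rt):
        res = fit_time_scale(
            clock_rt,
            [cal("minbound", time=40), cal("maxbound", time=40)],
            n_samples=200,
            seed=0,
        )
        assert res.f == pytest.approx(80.0, abs=1e-9)

    def test_infeasible_bounds_error(self, clock_rt):
        with pytest.raises(ConstraintError, match="infeasible"):
            fit_time_scale(
                clock_rt,
                [
                    cal("minbound", time=60),
                    cal("maxbound", selector=("mrca", "A", "C"), time=100),
                ],
                n_samples=200,
            )

    def test_zero_density_on_feasible_interval_error(self, clock_rt):
        with pytest.raises(ConstraintError, match="zero density"):
            fit_time_scale(
                clock_rt,
                [
                    cal("uniform", min=40, max=60),
                    cal("point", selector=("mrca", "A", "C"), time=200),
                ],
                n_samples=200,
            )

    def test_requires_a_calibration(self, clock_rt):
        with pytest.raises(ConfigurationError):
            fit_time_scale(clock_rt, [])

    def test_adding_calibration_narrows_feasible_interval(self, clock_rt):
        tree = clock_rt.tree
        base = _feasible_interval(
            [(c, c.resolve(tree)) for c in [cal("minbound", time=30)]],
            clock_rt.rel_times,
        )
        extra = _feasible_interval(
            [
                (c, c.resolve(tree))
                for c in [cal("minbound", time=30), cal("maxbound", time=70)]
            ],
            clock_rt.rel_times,
        )
        assert extra[0] >= base[0] and extra[1] <= base[1]

    def test_ci_brackets_point_estimate(self, clock_rt):
        res = fit_time_scale(
            clock_rt, [cal("normal", mean=50, sd=5)], n_samples=500, seed=3
        )
        assert np.all(res.ci_lo <= res.times + 1e-12)
        assert np.all(res.ci_hi >= res.times - 1e-12)

    def test_parent_child_monotonic(self):
        _, phylo = simulated_phylogram(61, n_tips=20, rate_model="iid_lognormal")
        rt = relative_rates_and_times(phylo)
        tips = rt.tree.tip_names()
        res = fit_time_scale(
            rt,
            [CalibrationDensity(("mrca", tips[0], tips[-1]), "point", {"time": 10})],
            n_samples=200,
            seed=0,
        )
        for nd in rt.tree.preorder():
            if not nd.is_root:
                assert res.times[nd.parent.id] >= res.times[nd.id] - 1e-9


class TestFixedRate:
    def test_clock_tree_heights_over_rate(self, clock_rt):
        res = fixed_rate_scale(clock_rt, 0.01, n_samples=200, seed=0)
        assert res.times[clock_rt.tree.root.id] == pytest.approx(200.0, abs=1e-9)
        ab = clock_rt.tree.mrca(["A", "B"])
        assert res.times[ab.id] == pytest.approx(100.0, abs=1e-9)

    def test_rate_one_is_identity(self, clock_rt):
        res = fixed_rate_scale(clock_rt, 1.0, n_samples=200, seed=0)
        np.testing.assert_allclose(res.times, clock_rt.heights, atol=1e-12)

    def test_doubling_rate_halves_times(self, clock_rt):
        a = fixed_rate_scale(clock_rt, 0.01, n_samples=200, seed=0)
        b = fixed_rate_scale(clock_rt, 0.02, n_samples=200, seed=0)
        np.testing.assert_allclose(b.times, a.times / 2, atol=1e-12)

    def test_nonpositive_rate_rejected(self, clock_rt):
        with pytest.raises(ValueError):
            fixed_rate_scale(clock_rt, 0.0)


class TestCalibrationGrammar:
    @pytest.mark.parametrize(
        "line,kind",
        [
            ("mrca TaxonA TaxonB normal mean=50 sd=5", "normal"),
            ("node NodeName uniform min=40 max=60", "uniform"),
            ("mrca A B exponential offset=30 decay=0.1", "exponential"),
            ("mrca A B point time=100", "point"),
            ("mrca A B minbound time=40", "minbound"),
            ("node X maxbound time=60", "maxbound"),
            ("mrca A B lognormal offset=10 mean=2 sd=0.5", "lognormal"),
        ],
    )
    def test_record_kinds(self, line, kind):
        rec = parse_calibration_line(line)
        assert rec.kind == kind

    def test_rate_record(self):
        assert parse_calibration_line("rate value=0.01") == ("rate", 0.01)

    @pytest.mark.parametrize(
        "bad",
        ["mrca A B", "banana A B point time=1", "mrca A B point time=abc",
         "mrca A B normal mean=50"],
    )
    def test_malformed_records(self, bad):
        with pytest.raises(ConfigurationError):
            parse_calibration_line(bad)

    def test_file_with_comments(self, tmp_path):
        p = tmp_path / "cal.txt"
        p.write_text(
            "# header comment\n"
            "mrca A B normal mean=50 sd=5\n"
            "\n"
            "rate value=0.02  # trailing comment\n"
        )
        cals, rate = read_calibration_file(p)
        assert len(cals) == 1 and cals[0].kind == "normal"
        assert rate == 0.02
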