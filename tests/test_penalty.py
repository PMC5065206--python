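"""Penalty-driven smoothing score: unit oracles, invariances, bounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucmorph.errors import ParameterError
from nucmorph.geometry import Contour, compute_centroid, radial_distances
from nucmorph.penalty import (
    PENALTY_TABLE,
    PenaltyConfig,
    absolute_difference,
    normalized_ratios,
    partition_fractions,
    pd_score,
    penalty_driven_score,
    smooth_profile,
)
from nucmorph.synthetic import Harmonic, Notch, ShapeSpec, make_contour


# ---------------------------------------------------------------- oracles
def smooth_oracle(d, span):
    """Naive double-loop circular moving average."""
    n = len(d)
    half = span // 2
    out = np.empty(n)
    for i in range(n):
        out[i] = np.mean([d[(i + j) % n] for j in range(-half, half + 1)])
    return out


def pd_oracle(contour_points, span, penalties, edges=(0.1, 0.2, 0.3)):
    """Straight-line reimplementation of the whole PD computation."""
    pts = np.asarray(contour_points, dtype=float)
    n = len(pts)
    cx, cy = pts[:, 0].sum() / n, pts[:, 1].sum() / n
    d = np.array([np.sqrt((cx - x) ** 2 + (cy - y) ** 2) for x, y in pts])
    ds = smooth_oracle(d, span)
    diff = np.array([abs(a - b) for a, b in zip(d, ds)])
    mu = diff.sum() / n
    rat = diff / mu if mu > 0 else np.zeros(n)
    counts = [0, 0, 0, 0]
    for r in rat:
        if r < edges[0]:
            counts[0] += 1
        elif r < edges[1]:
            counts[1] += 1
        elif r < edges[2]:
            counts[2] += 1
        else:
            counts[3] += 1
    p = [c / n for c in counts]
    return sum(c * pj for c, pj in zip(penalties, p))


def star_contour(seed=0, freq=12, amp=8.0):
    return make_contour(
        ShapeSpec(base_radius=50, seed=seed, harmonics=(Harmonic(freq, amp, 0.7),))
    ).contour


# ------------------------------------------------------------- unit tests
class TestSmoothProfile:
    def test_constant_profile_fixed_point(self):
        assert np.allclose(smooth_profile(np.full(5, 5.0), 3), 5.0)

    def test_impulse_span3_circular(self):
        out = smooth_profile(np.array([0.0, 0, 1, 0, 0, 0]), 3)
        assert np.allclose(out, [0, 1 / 3, 1 / 3, 1 / 3, 0, 0])

    def test_wrap_reaches_across_ends(self):
        out = smooth_profile(np.array([9.0, 0, 0, 0, 0, 0]), 3)
        assert out[-1] == pytest.approx(3.0) and out[0] == pytest.approx(3.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(0.1, 100), min_size=9, max_size=40),
        st.sampled_from([3, 5, 7, 9]),
    )
    def test_matches_double_loop_oracle(self, values, span):
        d = np.array(values)
        assert np.allclose(smooth_profile(d, span), smooth_oracle(d, span), atol=1e-9)

    def test_invalid_spans_rejected(self):
        d = np.arange(10.0)
        for span in (2, 4, 11):
            with pytest.raises(ParameterError):
                smooth_profile(d, span)

    def test_shrink_boundary_matches_endpoint_convention(self):
        d = np.array([1.0, 2, 3, 4, 5, 6, 7])
        out = smooth_profile(d, 5, boundary="shrink")
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(np.mean(d[:3]))
        assert out[2] == pytest.approx(np.mean(d[:5]))
        assert out[-1] == pytest.approx(7.0)


class TestRatioAndPartitions:
    def test_uniform_diff(self):
        mu, rat = normalized_ratios(np.ones(4))
        assert mu == 1.0 and np.allclose(rat, 1.0)

    def test_zero_diff_convention(self):
        mu, rat = normalized_ratios(np.zeros(3))
        assert mu == 0.0 and np.allclose(rat, 0.0)

    def test_hand_example(self):
        mu, rat = normalized_ratios(np.array([0.0, 2.0]))
        assert mu == 1.0 and rat.tolist() == [0.0, 2.0]

    def test_mean_ratio_is_one_when_nonzero(self):
        rng = np.random.default_rng(0)
        _, rat = normalized_ratios(rng.random(100) + 0.01)
        assert rat.mean() == pytest.approx(1.0, abs=1e-12)

    def test_partition_trivial_cases(self):
        assert partition_fractions(np.zeros(7)) == (1, 0, 0, 0)
        assert partition_fractions(np.array([0.05, 0.15, 0.25, 0.35])) == (
            0.25, 0.25, 0.25, 0.25,
        )

    def test_half_open_bin_edges(self):
        # boundary values 0.1/0.2/0.3 fall in the *upper* bin
        p = partition_fractions(np.array([0.1, 0.2, 0.3]))
        assert p == (0.0, pytest.approx(1 / 3), pytest.approx(1 / 3), pytest.approx(1 / 3))

    def test_fractions_always_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = partition_fractions(rng.exponential(0.2, size=50))
            assert sum(p) == pytest.approx(1.0, abs=1e-12)


class TestPDScore:
    def test_all_smooth_gives_c1(self):
        assert pd_score((1, 0, 0, 0), PenaltyConfig(function="linear")) == 1.0

    def test_cubic_c4_value(self):
        assert pd_score((0, 0, 0, 1), PenaltyConfig(function="cubic")) == 64.0

    def test_quadratic_uniform_partition(self):
        cfg = PenaltyConfig(function="quadratic")
        assert pd_score((0.25, 0.25, 0.25, 0.25), cfg) == pytest.approx(7.5)

    def test_invalid_fraction_sum_rejected(self):
        with pytest.raises(ParameterError):
            pd_score((0.5, 0.5, 0.5, 0.5), PenaltyConfig())

    def test_penalty_table_constants(self):
        assert PENALTY_TABLE["linear"] == (1.0, 2.0, 3.0, 4.0)
        assert PENALTY_TABLE["quadratic"] == (1.0, 4.0, 9.0, 16.0)
        assert PENALTY_TABLE["cubic"] == (1.0, 8.0, 27.0, 64.0)


# ------------------------------------------------------- end-to-end tests
class TestPenaltyDrivenScore:
    def test_analytic_circle_profile_scores_c1(self):
        # a constant radial profile is untouched by smoothing: PD = c1
        d = np.full(360, 50.0)
        for span in (3, 5, 7, 9):
            mu, rat = normalized_ratios(absolute_difference(d, smooth_profile(d, span)))
            assert mu == 0.0
            for fn in PENALTY_TABLE:
                cfg = PenaltyConfig(span=span, function=fn)
                assert pd_score(partition_fractions(rat), cfg) == cfg.penalties[0]

    @pytest.mark.parametrize("span", [3, 5, 7, 9])
    @pytest.mark.parametrize("fn", ["linear", "quadratic", "cubic"])
    def test_star_contour_matches_oracle(self, span, fn):
        c = star_contour()
        got = penalty_driven_score(c, PenaltyConfig(span=span, function=fn)).pd
        want = pd_oracle(c.points, span, PENALTY_TABLE[fn])
        assert got == pytest.approx(want, abs=1e-9)

    def test_smoothing_deviation_grows_with_span(self):
        c = star_contour()
        mu3 = penalty_driven_score(c, PenaltyConfig(span=3)).mu_pd
        mu9 = penalty_driven_score(c, PenaltyConfig(span=9)).mu_pd
        assert mu9 > mu3

    def test_scale_invariance(self):
        d = radial_distances(star_contour())
        for k in (0.5, 3.0, 17.0):
            a = absolute_difference(d, smooth_profile(d, 3))
            b = absolute_difference(k * d, smooth_profile(k * d, 3))
            _, rat_a = normalized_ratios(a)
            _, rat_b = normalized_ratios(b)
            assert np.allclose(rat_a, rat_b, atol=1e-9)
            assert partition_fractions(rat_a) == partition_fractions(rat_b)

    def test_start_point_rotation_invariance(self):
        c = star_contour()
        cfg = PenaltyConfig(span=5, function="quadratic")
        base = penalty_driven_score(c, cfg).pd
        for shift in (1, 17, 100):
            rolled = Contour(np.roll(c.points, shift, axis=0))
            assert penalty_driven_score(rolled, cfg).pd == pytest.approx(base, abs=1e-9)

    def test_bounds_and_monotone_penalty_functions(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            c = make_contour(
                ShapeSpec(
                    base_radius=float(rng.uniform(30, 60)),
                    seed=seed,
                    harmonics=(Harmonic(int(rng.integers(3, 12)), float(rng.uniform(0, 6)), 1.0),),
                    notches=(Notch(1.0, float(rng.uniform(0, 5)), 0.3),),
                    noise_sigma=float(rng.uniform(0, 0.5)),
                )
            ).contour
            scores = {}
            for fn in PENALTY_TABLE:
                res = penalty_driven_score(c, PenaltyConfig(span=3, function=fn))
                c1, _, _, c4 = res.config.penalties
                assert c1 <= res.pd <= c4
                assert sum(res.fractions) == pytest.approx(1.0, abs=1e-12)
                scores[fn] = res
            # with more weight beyond the last edge than below the first,
            # steeper penalty functions must score higher
            f = scores["linear"].fractions
            if f[3] > f[0]:
                assert scores["cubic"].pd >= scores["quadratic"].pd >= scores["linear"].pd
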