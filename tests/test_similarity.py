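import numpy as np
import pytest

from trsaxs.errors import DataError, RatioError, WindowError
from trsaxs.io import CurveMeta, FrameSeries, ScatteringCurve
from trsaxs.similarity import (
    VRTrace,
    benchmark_envelope,
    classify_transition,
    similarity_matrix,
    volatility_of_ratio,
    vr_trace,
)
from trsaxs.synth import (
    DimerizationKinetics,
    ParticleModel,
    SimConfig,
    simulate_two_state_series,
    sphere_profile,
)

from .conftest import make_curve

WINDOW = (0.015, 0.15)


def vr_oracle(q, ia, ib, window=WINDOW, nbins=25):
    """Independent straight-line arithmetic evaluation of V_R.

    Bins the window into nbins equal-width q bins, averages each curve's
    intensity per bin, ratios the bin means, and sums relative first
    differences — plain Python, no shared code with the library.
    """
    lo, hi = window
    width = (hi - lo) / nbins
    bins = [[] for _ in range(nbins)]
    for k in range(len(q)):
        if lo <= q[k] <= hi:
            j = int((q[k] - lo) / width)
            if j == nbins:
                j -= 1
            bins[j].append(k)
    ratios = []
    for idx in bins:
        if idx:
            ma = sum(ia[k] for k in idx) / len(idx)
            mb = sum(ib[k] for k in idx) / len(idx)
            ratios.append(ma / mb)
    total = 0.0
    for r1, r2 in zip(ratios, ratios[1:]):
        total += abs(r2 - r1) / ((r2 + r1) / 2.0)
    return total


def random_curve_pair(rng, n=None):
    n = n or rng.integers(80, 200)
    q = np.linspace(0.012, 0.18, n)
    def one():
        coef = rng.normal(0, 1, 3)
        return np.exp(coef[0] + coef[1] * q * 5 + coef[2] * (q * 5) ** 2) * (
            1.2 + np.sin(q * rng.uniform(10, 60)))
    return q, one(), one()


class TestVolatilityOfRatio:
    def test_identity_is_zero(self):
        q = np.linspace(0.01, 0.2, 100)
        c = make_curve(q, 1.0 + q)
        assert volatility_of_ratio(c, c).value == 0.0

    def test_scale_invariance_both_arguments(self):
        rng = np.random.default_rng(11)
        q, ia, ib = random_curve_pair(rng)
        base = volatility_of_ratio(make_curve(q, ia), make_curve(q, ib)).value
        for c in (1e-4, 0.37, 42.0, 1e5):
            va = volatility_of_ratio(make_curve(q, c * ia), make_curve(q, ib)).value
            vb = volatility_of_ratio(make_curve(q, ia), make_curve(q, c * ib)).value
            assert va == pytest.approx(base, rel=1e-12)
            assert vb == pytest.approx(base, rel=1e-12)

    def test_exact_symmetry_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(12):
            q, ia, ib = random_curve_pair(rng)
            a, b = make_curve(q, ia), make_curve(q, ib)
            assert volatility_of_ratio(a, b).value == volatility_of_ratio(b, a).value

    def test_oracle_agreement_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(12):
            q, ia, ib = random_curve_pair(rng)
            got = volatility_of_ratio(make_curve(q, ia), make_curve(q, ib)).value
            want = vr_oracle(q, ia, ib)
            assert got == pytest.approx(want, rel=1e-9)

    def test_sphere_vs_mixture_matches_oracle(self):
        q = np.linspace(0.015, 0.15, 136)
        mono = sphere_profile(q, 30.0).intensity
        from trsaxs.synth import dimer_profile
        dim = dimer_profile(q, 30.0).intensity
        mix = 0.5 * mono + 0.25 * dim
        got = volatility_of_ratio(make_curve(q, mono), make_curve(q, mix)).value
        assert got == pytest.approx(vr_oracle(q, mono, mix), rel=1e-9)
        assert got > 0

    def test_nonpositive_intensity_in_window(self):
        q = np.linspace(0.01, 0.2, 100)
        ia = 1.0 + q
        ib = ia.copy()
        ib[50] = -0.1
        with pytest.raises(RatioError):
            volatility_of_ratio(make_curve(q, ia), make_curve(q, ib))

    def test_window_not_covered(self):
        q = np.linspace(0.05, 0.2, 50)
        c = make_curve(q, 1.0 + q)
        with pytest.raises(WindowError):
            volatility_of_ratio(c, c, window=(0.015, 0.15))


class TestVrPropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(c=st.floats(min_value=1e-6, max_value=1e6),
           seed=st.integers(min_value=0, max_value=2**16))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_scale_invariance_and_symmetry(self, c, seed):
        rng = np.random.default_rng(seed)
        q, ia, ib = random_curve_pair(rng, n=90)
        a, b = make_curve(q, ia), make_curve(q, ib)
        v = volatility_of_ratio(a, b).value
        assert volatility_of_ratio(b, a).value == v
        assert volatility_of_ratio(a, make_curve(q, c * ib)).value == \
            pytest.approx(v, rel=1e-9)


class TestSimilarityMatrix:
    def test_identical_pair_is_zero_matrix(self):
        q = np.linspace(0.01, 0.2, 100)
        c = make_curve(q, 1.0 + q)
        m = similarity_matrix([("a", c), ("b", c)])
        np.testing.assert_array_equal(m.values, np.zeros((2, 2)))

    def test_entries_match_pairwise_calls_and_transpose(self):
        rng = np.random.default_rng(9)
        q, ia, ib = random_curve_pair(rng, n=150)
        ic = ib * (1.3 + q)
        curves = [("a", make_curve(q, ia)), ("b", make_curve(q, ib)), ("c", make_curve(q, ic))]
        m = similarity_matrix(curves)
        np.testing.assert_array_equal(m.values, m.values.T)
        for i, (la, ca) in enumerate(curves):
            for j, (lb, cb) in enumerate(curves):
                if i < j:
                    assert m.values[i, j] == volatility_of_ratio(ca, cb).value

    def test_label_permutation_reorders_entries_bit_exactly(self):
        rng = np.random.default_rng(13)
        q, ia, ib = random_curve_pair(rng, n=120)
        ic = ia + ib
        curves = {"a": make_curve(q, ia), "b": make_curve(q, ib), "c": make_curve(q, ic)}
        m1 = similarity_matrix(curves)
        perm = ["c", "a", "b"]
        m2 = similarity_matrix([(k, curves[k]) for k in perm])
        idx = [perm.index(l) for l in m1.labels]
        np.testing.assert_array_equal(m1.values, m2.values[np.ix_(idx, idx)])


def test_ssm_heatmap_png_written(tmp_path):
    rng = np.random.default_rng(3)
    q, ia, ib = random_curve_pair(rng, n=120)
    m = similarity_matrix([("a", make_curve(q, ia)), ("b", make_curve(q, ib)),
                           ("c", make_curve(q, ia + ib))])
    from trsaxs.similarity import plot_ssm_heatmap
    out = plot_ssm_heatmap(m, tmp_path / "ssm.png")
    assert out.exists() and out.stat().st_size > 0


class TestVrTrace:
    def _series(self, intensities, times, q):
        frames = tuple(ScatteringCurve(q, i, None, CurveMeta(label="s", frame_time=t))
                       for i, t in zip(intensities, times))
        return FrameSeries("s", frames)

    def test_copies_of_reference_give_zero_trace(self):
        q = np.linspace(0.01, 0.2, 100)
        ref = make_curve(q, np.exp(-((q * 25) ** 2) / 3) * 100, label="ref")
        ser = self._series([ref.intensity] * 4, [0.3, 0.6, 0.9, 1.2], q)
        tr = vr_trace(ser, ref)
        np.testing.assert_array_equal(tr.values, np.zeros(4))

    def test_noiseless_dimerization_trace_strictly_decreasing(self):
        model = ParticleModel()
        cfg = SimConfig(seed=0)
        ser = simulate_two_state_series(model, DimerizationKinetics(1.0, 1.0), cfg,
                                        noisy=False)
        dimer_end = ScatteringCurve(cfg.q_grid, 0.5 * model.dimer(cfg.q_grid).intensity,
                                    None, CurveMeta(label="dimer-end"))
        tr = vr_trace(ser, dimer_end)
        assert np.all(np.diff(tr.values) < 0)
        # oracle: direct per-frame evaluation
        for frame, v in zip(ser.frames, tr.values):
            assert v == pytest.approx(
                vr_oracle(cfg.q_grid, frame.intensity, dimer_end.intensity), rel=1e-9)

    def test_time_matched_self_reference_is_zero(self):
        q = np.linspace(0.01, 0.2, 100)
        rng = np.random.default_rng(1)
        ser = self._series([1.0 + q + rng.uniform(0, 0.1) for _ in range(3)],
                           [0.3, 0.6, 0.9], q)
        tr = vr_trace(ser, ser)
        np.testing.assert_array_equal(tr.values, np.zeros(3))


class TestBenchmarkEnvelope:
    def test_identical_replicates(self):
        t = np.array([1.0, 2.0])
        tr = VRTrace("m", "d", t, np.array([0.4, 0.3]))
        env = benchmark_envelope([tr, tr], k=3.0, sense="lower")
        assert env.sigma_bar == 0.0
        np.testing.assert_array_equal(env.threshold, env.mean)

    def test_hand_arithmetic_example(self):
        t = np.array([1.0, 2.0])
        r1 = VRTrace("m", "d", t, np.array([0.3, 0.2]))
        r2 = VRTrace("m", "d", t, np.array([0.5, 0.4]))
        env = benchmark_envelope([r1, r2], k=3.0, sense="lower")
        np.testing.assert_allclose(env.mean, [0.4, 0.3])
        np.testing.assert_allclose(env.sd, [0.14142136, 0.14142136], rtol=1e-6)
        assert env.sigma_bar == pytest.approx(0.1 * np.sqrt(2), rel=1e-9)
        np.testing.assert_allclose(env.threshold, [0.4 - 0.3 * np.sqrt(2),
                                                   0.3 - 0.3 * np.sqrt(2)], rtol=1e-9)

    def test_k_zero_threshold_is_mean(self):
        t = np.array([1.0, 2.0, 3.0])
        r1 = VRTrace("m", "d", t, np.array([0.3, 0.2, 0.15]))
        r2 = VRTrace("m", "d", t, np.array([0.5, 0.4, 0.30]))
        env = benchmark_envelope([r1, r2], k=0.0, sense="upper")
        np.testing.assert_array_equal(env.threshold, env.mean)

    def test_single_replicate_is_error(self):
        t = np.array([1.0, 2.0])
        tr = VRTrace("m", "d", t, np.array([0.4, 0.3]))
        with pytest.raises(DataError):
            benchmark_envelope([tr])


class TestClassify:
    t = np.array([0.3, 0.6, 0.9])

    def _envs(self):
        mono = benchmark_envelope(
            [VRTrace("m", "d", self.t, np.array([1.0, 1.0, 1.0])),
             VRTrace("m", "d", self.t, np.array([1.2, 1.2, 1.2]))],
            k=3.0, sense="lower")
        dim = benchmark_envelope(
            [VRTrace("d", "d", self.t, np.array([0.05, 0.05, 0.05])),
             VRTrace("d", "d", self.t, np.array([0.07, 0.07, 0.07]))],
            k=3.0, sense="upper")
        return mono, dim

    def test_trace_at_monomer_mean_is_monomer_like(self):
        mono, dim = self._envs()
        tr = VRTrace("s", "d", self.t, mono.mean.copy())
        labels, summary = classify_transition(tr, mono, dim)
        assert labels == ["monomer-like"] * 3
        assert summary["first_significant"] == "none"

    def test_transitioning_trace_enters_dimer_envelope(self):
        mono, dim = self._envs()
        tr = VRTrace("s", "d", self.t, np.array([1.1, 0.5, 0.06]))
        labels, summary = classify_transition(tr, mono, dim)
        assert labels[-1] == "dimer-entered"
        assert summary["first_dimer_entered"] == pytest.approx(0.9)

    def test_trace_above_thresholds_summary_none(self):
        mono, dim = self._envs()
        tr = VRTrace("s", "d", self.t, np.array([1.3, 1.25, 1.2]))
        _, summary = classify_transition(tr, mono, dim)
        assert summary == {"first_significant": "none", "first_dimer_entered": "none"}
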