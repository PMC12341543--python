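"""Double-exponential relaxation fitting: normalization, recovery, aggregation."""

import numpy as np
import pytest

import sarcotrem as st
from sarcotrem.relaxation import DEFAULT_T_STARTS


# ------------------------------------------------------------- normalization
def test_normalize_constant_series():
    t = np.arange(30.0)
    trace = st.normalize_fluorescence(t, np.full(30, 500.0), t0_index=0)
    np.testing.assert_allclose(trace.y, 1.0)
    assert trace.t_s[0] == 0.0


def test_normalize_divides_by_chase_start():
    t = np.arange(30.0)
    raw = np.linspace(1000.0, 500.0, 30)
    trace = st.normalize_fluorescence(t, raw, t0_index=0)
    assert trace.y[0] == pytest.approx(1.0)
    assert trace.y[-1] == pytest.approx(0.5)


def test_normalize_round_trips_scaled_truth():
    truth = st.DecayGroundTruth()
    clean = st.generate_decay_trace(truth)
    trace = st.normalize_fluorescence(clean.t_s, 800.0 * clean.y, t0_index=0)
    np.testing.assert_allclose(trace.y, clean.y, rtol=1e-12)


def test_normalize_rejects_bad_input():
    with pytest.raises(ValueError, match="20 samples"):
        st.normalize_fluorescence(np.arange(5.0), np.ones(5))
    with pytest.raises(ValueError, match="positive"):
        st.normalize_fluorescence(np.arange(30.0), np.zeros(30), t0_index=0)


# ---------------------------------------------------------------- fitting
@pytest.mark.parametrize("with_baseline", [True, False])
def test_noiseless_round_trip(with_baseline):
    """Noise-free traces return the generating parameters to 0.1%."""
    truth = st.DecayGroundTruth(p1_frac=0.2, t1_s=20.0, p2_frac=0.8,
                                t2_s=200.0)
    fit = st.DoubleExponentialDecay(
        st.generate_decay_trace(truth), with_baseline=with_baseline
    ).fit()
    assert fit.converged
    assert fit.P1 == pytest.approx(0.2, rel=1e-3)
    assert fit.T1_s == pytest.approx(20.0, rel=1e-3)
    assert fit.P2 == pytest.approx(0.8, rel=1e-3)
    assert fit.T2_s == pytest.approx(200.0, rel=1e-3)


def test_amplitudes_sum_to_one_without_baseline():
    truth = st.DecayGroundTruth(p1_frac=0.35, t1_s=15.0, p2_frac=0.65,
                                t2_s=180.0)
    fit = st.DoubleExponentialDecay(
        st.generate_decay_trace(truth), with_baseline=False
    ).fit()
    assert fit.P1 + fit.P2 == pytest.approx(1.0, abs=0.02)


def test_canonical_ordering_invariant_to_start_order():
    """Swapping the two components' initial guesses changes nothing."""
    trace = st.generate_decay_trace(
        st.DecayGroundTruth(noise_sd=0.01, seed=9)
    )
    model = st.DoubleExponentialDecay(trace)
    fit_fwd = model.fit(t_starts=DEFAULT_T_STARTS)
    swapped = tuple((t2, t1) for t1, t2 in DEFAULT_T_STARTS)
    fit_rev = model.fit(t_starts=swapped)
    assert fit_fwd.T1_s < fit_fwd.T2_s
    assert fit_rev.P1 == pytest.approx(fit_fwd.P1, rel=1e-4)
    assert fit_rev.T1_s == pytest.approx(fit_fwd.T1_s, rel=1e-4)


def test_single_exponential_degenerates_gracefully():
    """A pure slow component leaves essentially nothing in the fast one."""
    truth = st.DecayGroundTruth(p1_frac=0.0, t1_s=20.0, p2_frac=1.0,
                                t2_s=100.0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = st.DoubleExponentialDecay(
            st.generate_decay_trace(truth), with_baseline=False
        ).fit()
    assert fit.P1 < 0.02 or not fit.well_separated


def test_drx_srx_percentages():
    fit = st.DoubleExponentialDecay(
        st.generate_decay_trace(st.DecayGroundTruth())
    ).fit()
    assert fit.drx_percent == pytest.approx(20.0, abs=0.5)
    assert fit.srx_percent == pytest.approx(80.0, abs=0.5)
    assert fit.drx_percent + fit.srx_percent == pytest.approx(100.0)


def test_summary_reports_parameters():
    fit = st.DoubleExponentialDecay(
        st.generate_decay_trace(st.DecayGroundTruth(noise_sd=0.01, seed=2))
    ).fit()
    text = fit.summary()
    assert "DRX" in text and "SRX" in text and "P1" in text


# ------------------------------------------------------------- aggregation
def _fit(p1=0.2, **kw):
    base = dict(P1=p1, T1_s=20.0, P2=0.8, T2_s=200.0, baseline=0.0,
                rss=0.0, converged=True, fiber_id="f1")
    base.update(kw)
    return st.RelaxationFit(**base)


def test_aggregate_identical_rois():
    fits = [_fit(), _fit(), _fit()]
    summary = st.aggregate_fiber(fits)
    assert summary.P1 == pytest.approx(0.2)
    assert summary.T2_s == pytest.approx(200.0)
    assert summary.n_rois == 3


def test_aggregate_is_arithmetic_mean():
    fits = [_fit(p1=0.1), _fit(p1=0.2), _fit(p1=0.3)]
    assert st.aggregate_fiber(fits).P1 == pytest.approx(0.2)


def test_aggregate_skips_non_converged():
    fits = [_fit(p1=0.1), _fit(p1=0.3), _fit(p1=99.0, converged=False)]
    summary = st.aggregate_fiber(fits)
    assert summary.P1 == pytest.approx(0.2)
    assert summary.n_rois == 2
    with pytest.raises(ValueError, match="no converged"):
        st.aggregate_fiber([_fit(converged=False)])


def test_fit_directory_layout(tmp_path):
    """fiber_id/roi_id.csv trees fit into tidy per-ROI and per-fiber tables."""
    for fiber in ("f1", "f2"):
        d = tmp_path / fiber
        d.mkdir()
        for i, seed in enumerate((1, 2, 3)):
            trace = st.generate_decay_trace(
                st.DecayGroundTruth(noise_sd=0.01, seed=seed)
            )
            trace.to_csv(d / f"roi{i}.csv")
    fits, fibers = st.fit_directory(tmp_path)
    assert len(fits) == 6
    assert len(fibers) == 2
    assert set(fibers["fiber_id"]) == {"f1", "f2"}
    assert (fibers["n_rois"] == 3).all()
    assert fibers["P1"].between(0.15, 0.25).all()
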