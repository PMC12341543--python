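"""Force-trace reduction: peaks, specific force, PCSA, rates."""

import dataclasses as dc

import numpy as np
import pytest

import sarcotrem as st
from sarcotrem.synthetic import ForceTrace


def _manual_trace(force, dt=1e-4, stim_start=0.1, stim_dur=0.5, **kw):
    t = np.arange(len(force)) * dt
    return ForceTrace(t_s=t, force_mN=np.asarray(force, float),
                      freq_hz=kw.pop("freq_hz", 150.0),
                      stim_start_s=stim_start, stim_dur_s=stim_dur, **kw)


# ---------------------------------------------------------------- peak force
def test_flat_trace_zero_peak():
    tr = _manual_trace(np.zeros(10000))
    assert st.peak_force(tr) == 0.0


def test_synthetic_tetanus_peak_matches_truth():
    tr = st.generate_force_trace(st.ForceGroundTruth(freq_hz=200.0))
    assert st.peak_force(tr) == pytest.approx(300.0, rel=0.02)


def test_peak_force_baseline_invariant():
    tr = st.generate_force_trace(st.ForceGroundTruth(freq_hz=100.0))
    shifted = dc.replace(tr, force_mN=tr.force_mN + 10.0)
    assert st.peak_force(shifted) == pytest.approx(st.peak_force(tr))


def test_peak_requires_baseline_window():
    tr = _manual_trace(np.ones(10000), stim_start=0.0)
    with pytest.raises(ValueError, match="baseline"):
        st.peak_force(tr)


# ------------------------------------------------------------ force-frequency
def test_force_frequency_curve_sorted_and_monotone():
    traces = st.generate_force_frequency_family(
        st.ForceGroundTruth(), [1, 10, 30, 50, 80, 100, 150, 200]
    )
    curve = st.force_frequency(traces)
    assert list(curve["freq_hz"]) == sorted(curve["freq_hz"])
    assert (np.diff(curve["peak_force_mN"]) >= -1e-6).all()
    assert curve.loc[curve["tetanic"], "freq_hz"].item() == 200


def test_force_frequency_tetanic_entry_matches_truth():
    traces = st.generate_force_frequency_family(
        st.ForceGroundTruth(), [50, 100, 200]
    )
    curve = st.force_frequency(traces)
    tet = curve.loc[curve["tetanic"], "peak_force_mN"].item()
    assert tet == pytest.approx(300.0, rel=0.02)


def test_force_frequency_input_validation():
    tr = st.generate_force_trace(st.ForceGroundTruth(freq_hz=100.0))
    with pytest.raises(ValueError, match="at least 2"):
        st.force_frequency([tr])
    with pytest.raises(ValueError, match="duplicate"):
        st.force_frequency([tr, tr])


# ----------------------------------------------------------------- PCSA
def test_pcsa_identity_and_scaling():
    m = st.MuscleMorphometry(mass_mg=10.6, L0_mm=10.0)
    assert st.pcsa(m) == pytest.approx(1.0)
    doubled = st.MuscleMorphometry(mass_mg=10.6, L0_mm=20.0)
    assert st.pcsa(doubled) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        st.MuscleMorphometry(mass_mg=10.6, L0_mm=0.0)


def test_specific_force_arithmetic_and_round_trip():
    sf, units = st.specific_force(300.0, 1.5, "ex_vivo")
    assert sf == pytest.approx(200.0)
    assert units == "mN/mm^2"
    sf_iv, units_iv = st.specific_force(300.0, 50.0, "in_vivo")
    assert sf_iv == pytest.approx(6.0)
    assert units_iv == "mN/mg"
    # inverse pair: specific force times the normalizer restores the peak
    assert sf * 1.5 == pytest.approx(300.0)
    with pytest.raises(ValueError):
        st.specific_force(300.0, 0.0, "ex_vivo")
    with pytest.raises(ValueError):
        st.specific_force(300.0, 1.0, "in_situ")


def test_specific_force_homogeneity():
    sf, _ = st.specific_force(300.0, 1.5, "ex_vivo")
    sf2, _ = st.specific_force(600.0, 3.0, "ex_vivo")
    assert sf2 == pytest.approx(sf)


# --------------------------------------------------------------- rates
def test_linear_ramp_contraction_rate_exact():
    """0 -> 100 mN over 0.1 s gives exactly 1000 mN/s."""
    dt = 1e-4
    n = 15000
    t = np.arange(n) * dt
    force = np.zeros(n)
    ramp = (t >= 0.1) & (t < 0.2)
    force[ramp] = (t[ramp] - 0.1) * 1000.0
    force[t >= 0.2] = 100.0
    tr = ForceTrace(t_s=t, force_mN=force, freq_hz=150.0,
                    stim_start_s=0.1, stim_dur_s=0.5)
    cr, _ = st.contraction_relaxation_rates(tr)
    assert cr == pytest.approx(1000.0, rel=0.01)


def test_symmetric_rise_fall_rates_match():
    dt = 1e-4
    t = np.arange(15000) * dt
    tri = np.interp(t, [0.1, 0.6, 1.1], [0.0, 100.0, 0.0], left=0, right=0)
    tr = ForceTrace(t_s=t, force_mN=tri, freq_hz=150.0,
                    stim_start_s=0.1, stim_dur_s=0.5)
    cr, rr = st.contraction_relaxation_rates(tr)
    assert cr == pytest.approx(rr, rel=0.02)


def test_relaxation_rate_tracks_exponential_slope():
    """Max decay slope equals fmax/tau_rel; doubling tau halves the rate."""
    base = st.ForceGroundTruth(freq_hz=200.0)
    _, rr = st.contraction_relaxation_rates(st.generate_force_trace(base))
    expected = base.fmax_mN / (base.tau_rel_ms / 1000.0)
    assert rr == pytest.approx(expected, rel=0.05)
    doubled = dc.replace(base, tau_rel_ms=2 * base.tau_rel_ms)
    _, rr2 = st.contraction_relaxation_rates(st.generate_force_trace(doubled))
    assert rr / rr2 == pytest.approx(2.0, rel=0.05)


def test_rates_invariant_to_baseline_and_time_offset():
    tr = st.generate_force_trace(st.ForceGroundTruth(freq_hz=200.0))
    cr, rr = st.contraction_relaxation_rates(tr)
    shifted = ForceTrace(
        t_s=tr.t_s + 2.0,
        force_mN=tr.force_mN + 25.0,
        freq_hz=tr.freq_hz,
        stim_start_s=tr.stim_start_s + 2.0,
        stim_dur_s=tr.stim_dur_s,
    )
    cr2, rr2 = st.contraction_relaxation_rates(shifted)
    assert cr2 == pytest.approx(cr, rel=1e-6)
    assert rr2 == pytest.approx(rr, rel=1e-6)
    assert st.peak_force(shifted) == pytest.approx(st.peak_force(tr), abs=1e-6)


def test_smoothing_window_must_fit():
    tr = _manual_trace(np.zeros(2000))
    with pytest.raises(ValueError, match="window"):
        st.contraction_relaxation_rates(tr, smooth_ms=10000.0)


# --------------------------------------------------------------- summary
def test_summarize_trace_ex_vivo():
    tr = st.generate_force_trace(st.ForceGroundTruth(freq_hz=200.0))
    m = st.MuscleMorphometry(mass_mg=10.6, L0_mm=10.0)
    s = st.summarize_trace(tr, morphometry=m)
    assert s.peak_force_mN == pytest.approx(300.0, rel=0.02)
    assert s.specific_force == pytest.approx(s.peak_force_mN / 1.0, rel=1e-6)
    assert s.specific_force_units == "mN/mm^2"
    assert s.contraction_rate_mN_s > 0 and s.relaxation_rate_mN_s > 0


def test_downsampling_for_figures():
    from sarcotrem.contractility import downsample_for_plotting

    tr = st.generate_force_trace(st.ForceGroundTruth())
    t_ds, f_ds = downsample_for_plotting(tr)
    dt = np.diff(t_ds)
    assert np.allclose(dt, dt[0])
    assert 1.0 / dt[0] == pytest.approx(125.0, rel=0.01)
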