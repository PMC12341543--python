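"""Generators: reproducibility, geometry, and closed-form values."""

import dataclasses as dc

import numpy as np
import pytest

import sarcotrem as st


# ------------------------------------------------------------ reproducibility
@pytest.mark.parametrize("kind", ["image", "decay", "force"])
def test_generators_are_reproducible(kind):
    """Identical seed and parameters give bit-identical output."""
    if kind == "image":
        make = lambda seed: st.generate_striated_image(
            st.ImageGroundTruth(break_rate=3.0, register_jitter_um=0.2,
                                noise_sd=0.05, seed=seed),
            128, 128,
        ).image.pixels
    elif kind == "decay":
        make = lambda seed: st.generate_decay_trace(
            st.DecayGroundTruth(noise_sd=0.02, seed=seed)
        ).y
    else:
        make = lambda seed: st.generate_force_trace(
            st.ForceGroundTruth(noise_sd=0.01, seed=seed)
        ).force_mN
    a, b, c = make(7), make(7), make(8)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


# ------------------------------------------------------------------- images
def test_perfect_grating_autocorrelation_peak(clean_grating):
    """A noiseless 2.5 um / 0.1 um-px grating repeats every 25 px."""
    profile = clean_grating.image.pixels.mean(axis=0)
    prof = profile - profile.mean()
    ac = np.correlate(prof, prof, mode="full")[prof.size - 1 :]
    lags = np.arange(ac.size)
    interior = (lags >= 10) & (lags <= 40)
    assert lags[interior][np.argmax(ac[interior])] == 25
    # no broken pixels anywhere along the bands
    assert clean_grating.n_gaps == 0


def test_doublet_has_two_maxima_per_period(clean_doublet):
    profile = clean_doublet.image.pixels.mean(axis=0)
    period_px = 25
    # count local maxima inside one interior period window
    from scipy.signal import find_peaks

    start = 3 * period_px
    window = profile[start : start + period_px]
    peaks, _ = find_peaks(window, prominence=0.05)
    assert len(peaks) == 2


def test_gap_log_matches_poisson_rate():
    """Recorded gap counts follow the requested Poisson breakage rate."""
    rate = 5.0  # per 100 um of band
    counts = []
    for seed in range(40):
        fld = st.generate_striated_image(
            st.ImageGroundTruth(break_rate=rate, seed=seed), 256, 256
        )
        assert fld.n_gaps == len(fld.gaps)
        for k, vc in fld.gaps:
            assert 0.0 <= vc <= fld.image.height_um
        counts.append(fld.n_gaps)
    # 11 bands x 25.5 um transverse extent ~ 280 um of band
    expected = rate * 11 * 25.5 / 100.0
    mean = np.mean(counts)
    tol = 3 * np.sqrt(expected / len(counts))
    assert abs(mean - expected) < tol + 1.0


def test_image_power_concentrates_at_period_frequency(clean_grating):
    ps = st.power_spectrum(clean_grating.image, orientation_deg=0.0)
    peak = ps.freqs[np.argmax(ps.power)]
    assert abs(peak - 1.0 / 2.5) <= ps.df


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(period_um=0.15, pixel_size_um=0.1),  # Nyquist violation
        dict(break_rate=-1.0),
        dict(noise_sd=-0.1),
        dict(pattern="czone_doublet", doublet_gap_um=3.0),
    ],
)
def test_image_truth_invariants_rejected(kwargs):
    with pytest.raises(ValueError):
        st.ImageGroundTruth(**kwargs)


def test_image_requires_four_periods():
    with pytest.raises(ValueError, match="4 sarcomere periods"):
        st.generate_striated_image(st.ImageGroundTruth(), 32, 32)


# ------------------------------------------------------------------- decays
def test_decay_closed_form_values():
    truth = st.DecayGroundTruth(p1_frac=0.2, t1_s=20, p2_frac=0.8, t2_s=200)
    # y(0) = 1 when amplitudes sum to 1
    assert truth.evaluate(np.array([0.0]))[0] == pytest.approx(1.0)
    # y(20) = 0.2 e^-1 + 0.8 e^-0.1
    expected = 0.2 * np.exp(-1) + 0.8 * np.exp(-0.1)
    assert truth.evaluate(np.array([20.0]))[0] == pytest.approx(expected)
    half = st.DecayGroundTruth(p1_frac=0.5, t1_s=20, p2_frac=0.5, t2_s=200)
    assert half.evaluate(np.array([0.0]))[0] == pytest.approx(1.0)


def test_noiseless_decay_recovered_by_truth():
    trace = st.generate_decay_trace(st.DecayGroundTruth(noise_sd=0.0))
    residual = np.abs(trace.y - trace.truth.evaluate(trace.t_s))
    assert residual.max() < 1e-9


def test_decay_warns_when_slow_component_not_covered():
    with pytest.warns(UserWarning, match="3\\*t2_s"):
        st.generate_decay_trace(st.DecayGroundTruth(duration_s=100.0))


def test_decay_truth_rejects_bad_parameters():
    with pytest.raises(ValueError):
        st.DecayGroundTruth(t1_s=-5.0)
    with pytest.raises(ValueError):
        st.DecayGroundTruth(t1_s=300.0, t2_s=200.0)
    with pytest.raises(ValueError):
        st.DecayGroundTruth(p1_frac=0.6, p2_frac=0.6)


# ------------------------------------------------------------------- forces
def test_single_twitch_below_tetanic_plateau():
    tw = st.generate_force_trace(st.ForceGroundTruth(freq_hz=1.0))
    assert st.peak_force(tw) < 0.5 * tw.truth.fmax_mN


def test_full_fusion_reaches_fmax():
    tet = st.generate_force_trace(st.ForceGroundTruth(freq_hz=200.0))
    assert st.peak_force(tet) == pytest.approx(300.0, rel=0.02)


def test_force_frequency_monotone():
    truth = st.ForceGroundTruth()
    peaks = [
        st.peak_force(st.generate_force_trace(dc.replace(truth, freq_hz=f)))
        for f in (50.0, 100.0, 150.0)
    ]
    assert peaks[0] < peaks[1] < peaks[2]


def test_force_nonnegative_and_frequency_bounds():
    tr = st.generate_force_trace(st.ForceGroundTruth(freq_hz=20.0))
    assert (tr.force_mN >= 0).all()
    with pytest.raises(ValueError):
        st.ForceGroundTruth(freq_hz=500.0)


# --------------------------------------------------------------- file round trips
def test_image_tiff_sidecar_round_trip(tmp_path, clean_grating):
    path = clean_grating.image.to_tiff(tmp_path / "field.tif")
    loaded = st.StriatedImage.from_tiff(path)
    assert loaded.pixel_size_um == clean_grating.image.pixel_size_um
    assert loaded.channel == "alpha_actinin"
    np.testing.assert_allclose(
        loaded.pixels, clean_grating.image.pixels, atol=2e-5
    )


def test_trace_csv_round_trip(tmp_path):
    trace = st.generate_decay_trace(st.DecayGroundTruth(noise_sd=0.01, seed=3))
    path = trace.to_csv(tmp_path / "roi1.csv")
    model = st.DoubleExponentialDecay.from_csv(path, normalize=False)
    np.testing.assert_allclose(model.trace.y, trace.y, rtol=1e-9)
    assert path.with_suffix(".json").exists()
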