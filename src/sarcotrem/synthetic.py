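"""Synthetic fixtures with known ground truth.

Three generators emulate the raw data the analysis consumes:

* striated immunofluorescence fields (Z-disk singlets or C-zone doublets)
  with controllable period, orientation, lateral breakage, waviness,
  register jitter and noise;
* Mant-ATP chase fluorescence decays with DRX/SRX amplitudes and lifetimes;
* isometric twitch/tetanus force traces across 1-200 Hz stimulation.

Every generator is a pure function of its ground-truth record (including the
seed), so identical inputs give bit-identical outputs, and each output
retains its truth for parameter-recovery tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .images import StriatedImage

GAP_LENGTH_UM = 0.5  # fixed lateral-gap extent along a band
BAND_SIGMA_FRAC = 0.15  # Gaussian band cross-section, sigma = frac * period
DOUBLET_SIGMA_SCALE = 0.6  # C-zone sub-bands are thinner than Z-disks


# --------------------------------------------------------------------------
# ground-truth records
# --------------------------------------------------------------------------
@dataclass
class ImageGroundTruth:
    """Parameters of one synthetic striated field.

    ``pattern`` selects a Z-disk singlet (one band per sarcomere) or a
    C-zone doublet (two bands per sarcomere, ``doublet_gap_um`` apart).
    ``register_jitter_um`` shifts each band rigidly along the fiber axis by
    an independent normal offset, producing out-of-register sarcomeres
    without lateral breakage. ``break_rate`` is the expected number of
    lateral discontinuities per 100 um of band length.
    """

    period_um: float = 2.5
    pixel_size_um: float = 0.1
    orientation_deg: float = 0.0
    pattern: str = "zdisk_singlet"
    doublet_gap_um: float = 0.9
    n_fibers: int = 10
    break_rate: float = 0.0
    waviness_amp_um: float = 0.0
    waviness_period_um: float = 8.0
    register_jitter_um: float = 0.0
    noise_sd: float = 0.0
    phase_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("zdisk_singlet", "czone_doublet"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not self.period_um > 2 * self.pixel_size_um:
            raise ValueError(
                "period_um must exceed 2*pixel_size_um (Nyquist limit)"
            )
        if self.break_rate < 0:
            raise ValueError("break_rate must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.pattern == "czone_doublet" and not (
            0 < self.doublet_gap_um < self.period_um
        ):
            raise ValueError("doublet_gap_um must lie in (0, period_um)")


@dataclass
class DecayGroundTruth:
    """Parameters of one synthetic Mant-ATP chase decay.

    The fast component (``p1_frac``, ``t1_s``) is the DRX population, the
    slow one (``p2_frac``, ``t2_s``) the SRX population; any remainder
    ``1 - p1 - p2`` persists as a constant baseline.
    """

    p1_frac: float = 0.2
    t1_s: float = 20.0
    p2_frac: float = 0.8
    t2_s: float = 200.0
    duration_s: float = 900.0
    dt_s: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t1_s <= 0 or self.t2_s <= 0:
            raise ValueError("time constants must be positive")
        if not self.t1_s < self.t2_s:
            raise ValueError("t1_s must be smaller than t2_s (DRX decays first)")
        if self.p1_frac < 0 or self.p2_frac < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.p1_frac + self.p2_frac > 1 + 1e-12:
            raise ValueError("p1_frac + p2_frac must not exceed 1")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")

    @property
    def baseline(self) -> float:
        return 1.0 - self.p1_frac - self.p2_frac

    def evaluate(self, t_s: np.ndarray) -> np.ndarray:
        """Noise-free model value at times ``t_s``."""
        t = np.asarray(t_s, dtype=float)
        return (
            self.p1_frac * np.exp(-t / self.t1_s)
            + self.p2_frac * np.exp(-t / self.t2_s)
            + self.baseline
        )


@dataclass
class ForceGroundTruth:
    """Parameters of one synthetic isometric force trace.

    A 500 ms train of pulses at ``freq_hz`` drives a twitch kernel with
    rise constant ``tau_act_ms`` and decay constant ``tau_rel_ms``; the
    kernel superposition saturates at ``fmax_mN`` (full fusion at and above
    ``fusion_freq_hz``).
    """

    fmax_mN: float = 300.0
    freq_hz: float = 150.0
    train_ms: float = 500.0
    tau_act_ms: float = 15.0
    tau_rel_ms: float = 80.0
    twitch_halfwidth_ms: float | None = None
    fusion_freq_hz: float = 150.0
    sample_rate_hz: float = 10_000.0
    stim_start_s: float = 0.1
    duration_s: float = 1.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 <= self.freq_hz <= 200.0):
            raise ValueError("freq_hz must lie in [1, 200]")
        if self.fmax_mN <= 0:
            raise ValueError("fmax_mN must be positive")
        if self.tau_act_ms <= 0 or self.tau_rel_ms <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_act_ms >= self.tau_rel_ms:
            raise ValueError("tau_act_ms must be smaller than tau_rel_ms")
        if self.twitch_halfwidth_ms is None:
            # realized FWHM of the unit twitch kernel (derived, not tunable)
            t = np.arange(0.0, 12 * self.tau_rel_ms, 0.05) / 1000.0
            k = _twitch_kernel(t, self.tau_act_ms / 1e3, self.tau_rel_ms / 1e3)
            above = t[k >= 0.5]
            self.twitch_halfwidth_ms = float((above[-1] - above[0]) * 1000.0)


# --------------------------------------------------------------------------
# outputs that carry their truth
# --------------------------------------------------------------------------
@dataclass
class SimulatedField:
    """A generated striated image together with its rendering log."""

    image: StriatedImage
    truth: ImageGroundTruth
    gaps: list[tuple[int, float]] = field(default_factory=list)
    band_offsets_um: dict[int, float] = field(default_factory=dict)

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)


@dataclass
class DecayTrace:
    """Normalized fluorescence decay versus time from chase start."""

    t_s: np.ndarray
    y: np.ndarray
    roi_id: str = "roi"
    fiber_id: str = "fiber"
    truth: DecayGroundTruth | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t_s.ndim != 1 or self.t_s.shape != self.y.shape:
            raise ValueError("t_s and y must be matching 1-D arrays")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        arr = np.column_stack([self.t_s, self.y])
        np.savetxt(path, arr, delimiter=",", header="time_s,value", comments="")
        if self.truth is not None:
            path.with_suffix(".json").write_text(
                json.dumps(asdict(self.truth), indent=2)
            )
        return path


@dataclass
class ForceTrace:
    """Sampled isometric force versus time for one stimulation train."""

    t_s: np.ndarray
    force_mN: np.ndarray
    freq_hz: float
    muscle: str = "soleus"
    mode: str = "ex_vivo"
    stim_start_s: float = 0.1
    stim_dur_s: float = 0.5
    truth: ForceGroundTruth | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.force_mN = np.asarray(self.force_mN, dtype=float)
        if self.t_s.shape != self.force_mN.shape or self.t_s.ndim != 1:
            raise ValueError("t_s and force_mN must be matching 1-D arrays")
        dt = np.diff(self.t_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("sampling must be uniform")
        if not np.all(np.isfinite(self.force_mN)):
            raise ValueError("force must be finite")
        if not (0 <= self.stim_start_s < self.t_s[-1]):
            raise ValueError("stimulus window must lie within the trace")

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        arr = np.column_stack([self.t_s, self.force_mN])
        np.savetxt(
            path, arr, delimiter=",", header="time_s,force_mN", comments=""
        )
        if self.truth is not None:
            path.with_suffix(".json").write_text(
                json.dumps(asdict(self.truth), indent=2)
            )
        return path


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------
def _band_centers(truth: ImageGroundTruth, u_min: float, u_max: float):
    """Indices and nominal centers of bands intersecting [u_min, u_max]."""
    pad = truth.period_um  # one extra band each side
    k_lo = int(np.floor((u_min - pad - truth.phase_um) / truth.period_um))
    k_hi = int(np.ceil((u_max + pad - truth.phase_um) / truth.period_um))
    ks = np.arange(k_lo, k_hi + 1)
    return ks, ks * truth.period_um + truth.phase_um


def generate_striated_image(
    truth: ImageGroundTruth, width_px: int = 256, height_px: int = 256
) -> SimulatedField:
    """Render a striated field from its ground truth.

    Bands are Gaussian-profiled stripes perpendicular to the fiber axis at
    spacing ``period_um``; the doublet pattern renders two thinner bands per
    period separated by ``doublet_gap_um``. Lateral breakage inserts
    zero-intensity gaps (fixed length 0.5 um) at Poisson-distributed
    midpoints along bands. Intensities are scaled to [0, 1] before additive
    Gaussian noise.
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError("image dimensions must be positive")
    theta = np.deg2rad(truth.orientation_deg)
    px = truth.pixel_size_um
    # axial extent along the fiber axis must cover >= 4 periods
    diag_extent = (
        abs(np.cos(theta)) * width_px + abs(np.sin(theta)) * height_px
    ) * px
    if diag_extent < 4 * truth.period_um:
        raise ValueError("field must span at least 4 sarcomere periods")

    rng = np.random.default_rng(truth.seed)
    cols, rows = np.meshgrid(np.arange(width_px), np.arange(height_px))
    x = cols * px
    y = rows * px
    u = x * np.cos(theta) + y * np.sin(theta)  # axial coordinate, um
    v = -x * np.sin(theta) + y * np.cos(theta)  # transverse coordinate, um

    if truth.waviness_amp_um > 0:
        u = u - truth.waviness_amp_um * np.sin(
            2 * np.pi * v / truth.waviness_period_um
        )

    ks, centers = _band_centers(truth, float(u.min()), float(u.max()))
    offsets = (
        rng.normal(0.0, truth.register_jitter_um, size=ks.size)
        if truth.register_jitter_um > 0
        else np.zeros(ks.size)
    )
    centers = centers + offsets

    sigma_z = BAND_SIGMA_FRAC * truth.period_um
    if truth.pattern == "czone_doublet":
        sigma = DOUBLET_SIGMA_SCALE * sigma_z
        sub = np.array([-0.5, 0.5]) * truth.doublet_gap_um
    else:
        sigma = sigma_z
        sub = np.array([0.0])

    intensity = np.zeros_like(u)
    # nearest band via rounding, then sum contributions of the 3 neighbours
    k_near = np.rint((u - truth.phase_um) / truth.period_um).astype(int)
    for dk in (-1, 0, 1):
        idx = np.clip(k_near + dk - ks[0], 0, ks.size - 1)
        c = centers[idx]
        for s in sub:
            d = u - (c + s)
            intensity += np.exp(-0.5 * (d / sigma) ** 2)

    # lateral breakage: Poisson gaps along bands
    gaps: list[tuple[int, float]] = []
    if truth.break_rate > 0:
        v_lo, v_hi = float(v.min()), float(v.max())
        band_len = v_hi - v_lo
        in_field = (centers >= u.min() - sigma) & (centers <= u.max() + sigma)
        total_len = band_len * int(in_field.sum())
        n_gaps = rng.poisson(truth.break_rate * total_len / 100.0)
        candidates = ks[in_field]
        half_w = 2.5 * sigma + (
            truth.doublet_gap_um / 2 if truth.pattern == "czone_doublet" else 0
        )
        for _ in range(n_gaps):
            k = int(rng.choice(candidates))
            vc = rng.uniform(v_lo, v_hi)
            gaps.append((k, vc))
            c = centers[k - ks[0]]
            mask = (np.abs(u - c) <= half_w) & (
                np.abs(v - vc) <= GAP_LENGTH_UM / 2
            )
            intensity[mask] = 0.0

    peak = intensity.max()
    if peak > 0:
        intensity = intensity / peak
    if truth.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, truth.noise_sd, intensity.shape)
        intensity = np.clip(intensity, 0.0, None)

    channel = "smybpc" if truth.pattern == "czone_doublet" else "alpha_actinin"
    img = StriatedImage(
        intensity, px, channel=channel, meta={"truth": asdict(truth)}
    )
    return SimulatedField(
        image=img,
        truth=truth,
        gaps=gaps,
        band_offsets_um=dict(zip(ks.tolist(), offsets.tolist())),
    )


def generate_decay_trace(truth: DecayGroundTruth) -> DecayTrace:
    """Sample a double-exponential chase decay (plus baseline and noise)."""
    if truth.duration_s < 3 * truth.t2_s:
        warnings.warn(
            "duration_s covers less than 3*t2_s; the slow component may "
            "not be identifiable",
            stacklevel=2,
        )
    rng = np.random.default_rng(truth.seed)
    t = np.arange(0.0, truth.duration_s + truth.dt_s / 2, truth.dt_s)
    y = truth.evaluate(t)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=t.size)
    return DecayTrace(t_s=t, y=y, truth=truth)


def _twitch_kernel(t: np.ndarray, tau_act_s: float, tau_rel_s: float):
    """Unit-peak twitch kernel: difference of exponentials."""
    k = np.where(
        t >= 0, np.exp(-t / tau_rel_s) - np.exp(-t / tau_act_s), 0.0
    )
    # analytic peak of the difference of exponentials
    tp = (
        tau_act_s
        * tau_rel_s
        / (tau_rel_s - tau_act_s)
        * np.log(tau_rel_s / tau_act_s)
    )
    peak = np.exp(-tp / tau_rel_s) - np.exp(-tp / tau_act_s)
    return k / peak


def _kernel_sum(
    t: np.ndarray, truth: ForceGroundTruth, freq_hz: float
) -> np.ndarray:
    """Superposition of per-pulse twitch kernels over the train."""
    tau_a = truth.tau_act_ms / 1000.0
    tau_r = truth.tau_rel_ms / 1000.0
    n_pulses = max(1, int(np.floor(truth.train_ms / 1000.0 * freq_hz)) + 1)
    s = np.zeros_like(t)
    for i in range(n_pulses):
        s += _twitch_kernel(t - truth.stim_start_s - i / freq_hz, tau_a, tau_r)
    return s


def generate_force_trace(truth: ForceGroundTruth) -> ForceTrace:
    """Render an isometric force trace for one stimulation train.

    The twitch-kernel superposition is scaled so the tetanic plateau reaches
    ``fmax_mN`` at ``fusion_freq_hz`` and is clipped at ``fmax_mN`` above
    it; below fusion the peak grows monotonically with frequency (unfused
    ripple at low frequencies). After the train the force relaxes as a pure
    exponential with ``tau_rel_ms`` from its end-of-train value, the
    canonical shape of post-tetanic relaxation.
    """
    rng = np.random.default_rng(truth.seed)
    dt = 1.0 / truth.sample_rate_hz
    t = np.arange(0.0, truth.duration_s, dt)
    s = _kernel_sum(t, truth, truth.freq_hz)
    # calibrate the linear gain at the fusion frequency
    s_fusion = _kernel_sum(t, truth, truth.fusion_freq_hz)
    gain = truth.fmax_mN / s_fusion.max()
    force = np.minimum(gain * s, truth.fmax_mN)
    # exponential relaxation after the train
    t_end = truth.stim_start_s + truth.train_ms / 1000.0
    after = t > t_end
    if after.any():
        i_end = int(np.searchsorted(t, t_end))
        f_end = force[min(i_end, t.size - 1)]
        tau_r = truth.tau_rel_ms / 1000.0
        force[after] = f_end * np.exp(-(t[after] - t_end) / tau_r)
    if truth.noise_sd > 0:
        force = force + rng.normal(
            0.0, truth.noise_sd * truth.fmax_mN, size=t.size
        )
    return ForceTrace(
        t_s=t,
        force_mN=force,
        freq_hz=truth.freq_hz,
        stim_start_s=truth.stim_start_s,
        stim_dur_s=truth.train_ms / 1000.0,
        truth=truth,
    )


def generate_force_frequency_family(
    truth: ForceGroundTruth, freqs_hz: list[float]
) -> list[ForceTrace]:
    """One trace per stimulation frequency, shared kinetics and seed."""
    from dataclasses import replace

    return [generate_force_trace(replace(truth, freq_hz=f)) for f in freqs_hz]
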