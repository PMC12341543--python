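"""Reduction of isometric force traces to contractile outcome variables.

For each stimulation train the trace yields a baseline-subtracted peak
force; a family of traces across stimulation frequencies yields the
force-frequency curve with its tetanic entry; the tetanic trace yields
maximal contraction and relaxation rates (extrema of the smoothed force
derivative). Peak forces are normalized to specific force by the
physiological cross-sectional area (PCSA, ex vivo) or the muscle mass
(in vivo).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .synthetic import ForceTrace

MUSCLE_DENSITY_MG_MM3 = 1.06  # mammalian skeletal muscle density

#: tail after stimulus end still searched for the force peak, seconds
PEAK_TAIL_S = 0.2

#: display sampling rate used when down-sampling traces for figures, Hz
PLOT_RATE_HZ = 125.0


@dataclass
class MuscleMorphometry:
    """Mass, optimal length and derived PCSA of one muscle."""

    mass_mg: float
    L0_mm: float
    density_mg_mm3: float = MUSCLE_DENSITY_MG_MM3

    def __post_init__(self) -> None:
        if min(self.mass_mg, self.L0_mm, self.density_mg_mm3) <= 0:
            raise ValueError("mass, L0 and density must all be positive")

    @property
    def pcsa_mm2(self) -> float:
        return pcsa(self)


def pcsa(m: MuscleMorphometry) -> float:
    """Physiological cross-sectional area, mm^2: mass / (density * L0)."""
    denom = m.density_mg_mm3 * m.L0_mm
    if denom <= 0:
        raise ValueError("density * L0 must be positive")
    return m.mass_mg / denom


@dataclass
class ContractileSummary:
    """Outcome variables of one force trace."""

    freq_hz: float
    peak_force_mN: float
    specific_force: float | None = None
    specific_force_units: str | None = None
    contraction_rate_mN_s: float | None = None
    relaxation_rate_mN_s: float | None = None


def _baseline(trace: ForceTrace) -> float:
    pre = trace.t_s < trace.stim_start_s
    if not pre.any():
        raise ValueError("no baseline window before the stimulus")
    return float(trace.force_mN[pre].mean())


def peak_force(trace: ForceTrace) -> float:
    """Baseline-subtracted maximum force in [stim start, stim end + 0.2 s]."""
    t_end = trace.stim_start_s + trace.stim_dur_s
    window = (trace.t_s >= trace.stim_start_s) & (
        trace.t_s <= t_end + PEAK_TAIL_S
    )
    if not window.any():
        raise ValueError("stimulus window missing from the trace")
    return float(trace.force_mN[window].max() - _baseline(trace))


def specific_force(
    peak_force_mN: float, normalizer: float, mode: str
) -> tuple[float, str]:
    """Peak force per PCSA (ex vivo, mN/mm^2) or per mass (in vivo, mN/mg)."""
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    if mode == "ex_vivo":
        return peak_force_mN / normalizer, "mN/mm^2"
    if mode == "in_vivo":
        return peak_force_mN / normalizer, "mN/mg"
    raise ValueError("mode must be 'ex_vivo' or 'in_vivo'")


def force_frequency(
    traces: list[ForceTrace], tetanic_freq_hz: float | None = None
) -> pd.DataFrame:
    """Peak force versus stimulation frequency, sorted, with tetanic flag.

    ``tetanic_freq_hz`` defaults to the highest frequency present
    (200 Hz ex vivo, 150 Hz in vivo in the standard protocols).
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 stimulation frequencies")
    freqs = [tr.freq_hz for tr in traces]
    if len(set(freqs)) != len(freqs):
        raise ValueError(
            "duplicate stimulation frequency without replicate labeling"
        )
    rows = sorted(
        ((tr.freq_hz, peak_force(tr)) for tr in traces), key=lambda r: r[0]
    )
    df = pd.DataFrame(rows, columns=["freq_hz", "peak_force_mN"])
    if tetanic_freq_hz is None:
        tetanic_freq_hz = df["freq_hz"].max()
    df["tetanic"] = df["freq_hz"] == tetanic_freq_hz
    return df


def contraction_relaxation_rates(
    trace: ForceTrace, smooth_ms: float = 5.0
) -> tuple[float, float]:
    """Max dF/dt during stimulation and max -dF/dt after stimulus end.

    The force is smoothed with a moving-average window of ``smooth_ms``
    before differentiation; rates are in mN/s.
    """
    win = max(1, int(round(smooth_ms / 1000.0 / trace.dt_s)))
    if win >= trace.t_s.size:
        raise ValueError("smoothing window exceeds the trace")
    f = uniform_filter1d(trace.force_mN, size=win)
    dfdt = np.gradient(f, trace.t_s)
    t_end = trace.stim_start_s + trace.stim_dur_s
    rising = (trace.t_s >= trace.stim_start_s) & (trace.t_s <= t_end)
    falling = trace.t_s > t_end
    if not rising.any() or not falling.any():
        raise ValueError("stimulus window missing from the trace")
    contraction = float(dfdt[rising].max())
    relaxation = float(-dfdt[falling].min())
    return contraction, relaxation


def summarize_trace(
    trace: ForceTrace,
    morphometry: MuscleMorphometry | None = None,
    smooth_ms: float = 5.0,
    rates: bool = True,
) -> ContractileSummary:
    """All outcome variables for one trace."""
    pk = peak_force(trace)
    sf = units = None
    if morphometry is not None:
        normalizer = (
            morphometry.pcsa_mm2
            if trace.mode == "ex_vivo"
            else morphometry.mass_mg
        )
        sf, units = specific_force(pk, normalizer, trace.mode)
    cr = rr = None
    if rates:
        cr, rr = contraction_relaxation_rates(trace, smooth_ms=smooth_ms)
    return ContractileSummary(
        freq_hz=trace.freq_hz,
        peak_force_mN=pk,
        specific_force=sf,
        specific_force_units=units,
        contraction_rate_mN_s=cr,
        relaxation_rate_mN_s=rr,
    )


def downsample_for_plotting(
    trace: ForceTrace, rate_hz: float = PLOT_RATE_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Down-sampled (t, force) for figures; analysis uses the native rate."""
    step = max(1, int(round(1.0 / (rate_hz * trace.dt_s))))
    return trace.t_s[::step], trace.force_mN[::step]
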