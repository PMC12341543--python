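"""Mant-ATP chase relaxation-state fitting.

In a single-nucleotide-turnover (Mant-ATP chase) experiment the normalized
fluorescence of a skinned myofiber decays as unlabeled ATP displaces the
fluorescent nucleotide. The decay is a double exponential

    y(t) = P1 * exp(-t / T1) + P2 * exp(-t / T2) [+ baseline]

whose fast component (P1, T1) reports the disordered-relaxed (DRX, fast
ATP turnover) myosin population and whose slow component (P2, T2) the
super-relaxed (SRX, slow turnover) population. "Unconstrained" means the
amplitudes are free (not tied to P1 + P2 = 1); nonnegativity is enforced
as a bound at zero.

The module follows a model/results split: build a
:class:`DoubleExponentialDecay` from a :class:`~sarcotrem.synthetic.DecayTrace`
(or CSV), call :meth:`~DoubleExponentialDecay.fit`, and read estimates,
uncertainties and a summary table off the returned :class:`RelaxationFit`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError
from .synthetic import DecayTrace

#: multi-start grid of (T1, T2) initial guesses in seconds, spanning
#: published DRX/SRX lifetimes
DEFAULT_T_STARTS = tuple(itertools.product((1.0, 10.0), (100.0, 300.0)))

#: fitted components closer than this lifetime ratio are flagged as
#: poorly separated
SEPARATION_RATIO = 3.0


def normalize_fluorescence(
    t_s: np.ndarray,
    intensity: np.ndarray,
    t0_index: int | None = None,
    roi_id: str = "roi",
    fiber_id: str = "fiber",
) -> DecayTrace:
    """Normalize a raw chase series to y(t0) = 1 and shift t0 to zero.

    The chase start defaults to the intensity maximum (``t0_index=None``).
    """
    t_s = np.asarray(t_s, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if t_s.size < 20:
        raise ValueError("need at least 20 samples to identify the chase")
    if t0_index is None:
        t0_index = int(np.argmax(intensity))
    ref = intensity[t0_index]
    if not ref > 0:
        raise ValueError("intensity at the chase start must be positive")
    return DecayTrace(
        t_s=t_s[t0_index:] - t_s[t0_index],
        y=intensity[t0_index:] / ref,
        roi_id=roi_id,
        fiber_id=fiber_id,
    )


def _model(params: np.ndarray, t: np.ndarray, with_baseline: bool):
    p1, t1, p2, t2 = params[:4]
    y = p1 * np.exp(-t / t1) + p2 * np.exp(-t / t2)
    if with_baseline:
        y = y + params[4]
    return y


class DoubleExponentialDecay:
    """Unconstrained double-exponential decay model for one ROI trace.

    Parameters
    ----------
    trace : DecayTrace
        Normalized fluorescence versus time from chase start.
    with_baseline : bool
        Include a constant offset term (real chases plateau above zero).
    """

    def __init__(self, trace: DecayTrace, with_baseline: bool = True):
        self.trace = trace
        self.with_baseline = with_baseline

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        with_baseline: bool = True,
        roi_id: str | None = None,
        fiber_id: str = "fiber",
        normalize: bool = True,
    ) -> "DoubleExponentialDecay":
        """Build from a 2-column CSV (time_s, intensity-or-normalized)."""
        path = Path(path)
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(float)
        y = df.iloc[:, 1].to_numpy(float)
        rid = roi_id if roi_id is not None else path.stem
        if normalize:
            trace = normalize_fluorescence(t, y, roi_id=rid, fiber_id=fiber_id)
        else:
            trace = DecayTrace(t_s=t, y=y, roi_id=rid, fiber_id=fiber_id)
        return cls(trace, with_baseline=with_baseline)

    def fit(
        self,
        t_starts: tuple[tuple[float, float], ...] = DEFAULT_T_STARTS,
    ) -> "RelaxationFit":
        """Nonlinear least squares with multi-start initialization.

        Every (T1, T2) pair on the start grid is tried; the converged
        solution with the lowest residual sum of squares wins. Components
        are reordered so T1 < T2 (fast DRX first).
        """
        t, y = self.trace.t_s, self.trace.y
        span = t[-1] - t[0]
        fastest = min(min(pair) for pair in t_starts)
        if span <= 5 * fastest:
            warnings.warn(
                "trace duration is short relative to the fast component; "
                "fit may be unreliable",
                stacklevel=2,
            )
        base0 = max(float(y.min()), 0.0) if self.with_baseline else 0.0
        amp0 = max((float(y[0]) - base0) / 2.0, 1e-3)
        n_par = 5 if self.with_baseline else 4
        lower = np.zeros(n_par)
        lower[1] = lower[3] = 1e-6  # time constants strictly positive
        upper = np.full(n_par, np.inf)

        best = None
        for t1_0, t2_0 in t_starts:
            x0 = [amp0, t1_0, amp0, t2_0]
            if self.with_baseline:
                x0.append(base0)
            try:
                sol = least_squares(
                    lambda p: _model(p, t, self.with_baseline) - y,
                    x0=np.asarray(x0, dtype=float),
                    bounds=(lower, upper),
                    method="trf",
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[1] - 1e-15:
                best = (sol, rss)
        if best is None:
            raise FitError("double-exponential fit failed from every start")
        sol, rss = best

        p1, t1, p2, t2 = sol.x[:4]
        baseline = float(sol.x[4]) if self.with_baseline else 0.0
        if t1 > t2:  # canonical ordering: fast DRX component first
            p1, p2, t1, t2 = p2, p1, t2, t1
        well_separated = t2 / max(t1, 1e-12) >= SEPARATION_RATIO
        if not well_separated:
            warnings.warn(
                "poorly separated components (T2/T1 < "
                f"{SEPARATION_RATIO:g})",
                stacklevel=2,
            )
        dof = max(t.size - sol.x.size, 1)
        sigma2 = rss / dof
        # parameter covariance from the Gauss-Newton approximation
        try:
            jtj = sol.jac.T @ sol.jac
            cov = sigma2 * np.linalg.pinv(jtj)
            bse_raw = np.sqrt(np.clip(np.diag(cov), 0, None))
        except Exception:
            bse_raw = np.full(sol.x.size, np.nan)
        return RelaxationFit(
            P1=float(p1),
            T1_s=float(t1),
            P2=float(p2),
            T2_s=float(t2),
            baseline=baseline,
            rss=rss,
            converged=True,
            well_separated=bool(well_separated),
            n_obs=int(t.size),
            bse={
                "P1": float(bse_raw[0]),
                "T1_s": float(bse_raw[1]),
                "P2": float(bse_raw[2]),
                "T2_s": float(bse_raw[3]),
            },
            roi_id=self.trace.roi_id,
            fiber_id=self.trace.fiber_id,
            with_baseline=self.with_baseline,
        )


@dataclass
class RelaxationFit:
    """Results of one double-exponential decay fit.

    ``P1``/``T1_s`` describe the fast DRX component, ``P2``/``T2_s`` the
    slow SRX component (canonical ordering T1 < T2). ``drx_percent`` and
    ``srx_percent`` express the amplitudes as percentages of P1 + P2, the
    convention for reporting myosin head populations.
    """

    P1: float
    T1_s: float
    P2: float
    T2_s: float
    baseline: float
    rss: float
    converged: bool
    well_separated: bool = True
    n_obs: int = 0
    bse: dict = field(default_factory=dict)
    roi_id: str = "roi"
    fiber_id: str = "fiber"
    with_baseline: bool = True

    @property
    def drx_percent(self) -> float:
        total = self.P1 + self.P2
        return 100.0 * self.P1 / total if total > 0 else float("nan")

    @property
    def srx_percent(self) -> float:
        total = self.P1 + self.P2
        return 100.0 * self.P2 / total if total > 0 else float("nan")

    def predict(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        return (
            self.P1 * np.exp(-t / self.T1_s)
            + self.P2 * np.exp(-t / self.T2_s)
            + self.baseline
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        rows = [
            ("P1 (DRX amplitude)", self.P1, self.bse.get("P1")),
            ("T1 (DRX lifetime, s)", self.T1_s, self.bse.get("T1_s")),
            ("P2 (SRX amplitude)", self.P2, self.bse.get("P2")),
            ("T2 (SRX lifetime, s)", self.T2_s, self.bse.get("T2_s")),
        ]
        lines = [
            "Double-exponential relaxation fit",
            f"  ROI {self.roi_id} (fiber {self.fiber_id}), "
            f"n = {self.n_obs}, baseline term: {self.with_baseline}",
            f"  {'parameter':<22}{'estimate':>12}{'std err':>12}",
        ]
        for name, val, se in rows:
            se_txt = f"{se:12.4g}" if se is not None else " " * 12
            lines.append(f"  {name:<22}{val:12.4g}{se_txt}")
        lines.append(
            f"  baseline {self.baseline:.4g}   RSS {self.rss:.4g}   "
            f"DRX {self.drx_percent:.1f}%  SRX {self.srx_percent:.1f}%"
        )
        if not self.well_separated:
            lines.append("  warning: poorly separated components")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "fiber_id": self.fiber_id,
            "roi_id": self.roi_id,
            "P1": self.P1,
            "T1_s": self.T1_s,
            "P2": self.P2,
            "T2_s": self.T2_s,
            "baseline": self.baseline,
            "drx_percent": self.drx_percent,
            "srx_percent": self.srx_percent,
            "rss": self.rss,
            "converged": self.converged,
            "well_separated": self.well_separated,
        }


@dataclass
class FiberSummary:
    """Per-fiber means of the relaxation parameters over converged ROIs."""

    fiber_id: str
    P1: float
    T1_s: float
    P2: float
    T2_s: float
    drx_percent: float
    srx_percent: float
    n_rois: int


def aggregate_fiber(fits: list[RelaxationFit]) -> FiberSummary:
    """Average converged ROI fits to a fiber-level summary.

    The experimental protocol scores 3 ROIs per myofiber; non-converged
    fits are excluded and the converged count reported.
    """
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no converged ROI fits for this fiber")
    fiber_id = good[0].fiber_id
    return FiberSummary(
        fiber_id=fiber_id,
        P1=float(np.mean([f.P1 for f in good])),
        T1_s=float(np.mean([f.T1_s for f in good])),
        P2=float(np.mean([f.P2 for f in good])),
        T2_s=float(np.mean([f.T2_s for f in good])),
        drx_percent=float(np.mean([f.drx_percent for f in good])),
        srx_percent=float(np.mean([f.srx_percent for f in good])),
        n_rois=len(good),
    )


def fit_directory(
    root: str | Path, with_baseline: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every ``fiber_id/roi_id.csv`` under ``root``.

    Returns (per-ROI fit table, per-fiber summary table).
    """
    root = Path(root)
    fit_rows, fiber_rows = [], []
    for fiber_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        fits = []
        for csv in sorted(fiber_dir.glob("*.csv")):
            model = DoubleExponentialDecay.from_csv(
                csv, with_baseline=with_baseline, fiber_id=fiber_dir.name
            )
            try:
                fits.append(model.fit())
            except FitError:
                warnings.warn(f"fit failed for {csv}", stacklevel=2)
        fit_rows.extend(f.to_dict() for f in fits)
        if any(f.converged for f in fits):
            fiber_rows.append(aggregate_fiber(fits).__dict__)
    return pd.DataFrame(fit_rows), pd.DataFrame(fiber_rows)
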