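"""Air-exchange-rate estimation from tracer-gas concentration decay.

In a well-mixed room with no indoor source, a tracer released above its
background level decays exponentially at the air-exchange rate λ:

    C(t) = C_bg + (C_0 − C_bg) · exp(−λ·t)

so ordinary least squares of ln(C − C_bg) against time gives −λ as the
slope.  Exhaled CO₂ immediately after occupants leave is a convenient
tracer; its background is outdoor/ambient CO₂ (~400 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TracerSeries", "AerEstimate", "fit_tracer_decay", "aggregate_aer"]


@dataclass(frozen=True)
class TracerSeries:
    """Tracer concentration time series with a constant background level.

    ``t_h`` is in hours and must be strictly increasing; the decaying
    excess ``conc − background`` must stay positive over the fitted window.
    """

    t_h: np.ndarray
    conc: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t_h, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("t_h and conc must be 1-d arrays of equal length")
        if len(t) < 3:
            raise ValueError("need at least 3 samples to fit a decay")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "t_h", t)
        object.__setattr__(self, "conc", c)

    def window(self, t_start: float | None = None, t_end: float | None = None) -> "TracerSeries":
        """Restrict to t ∈ [t_start, t_end]."""
        mask = np.ones_like(self.t_h, dtype=bool)
        if t_start is not None:
            mask &= self.t_h >= t_start
        if t_end is not None:
            mask &= self.t_h <= t_end
        return TracerSeries(self.t_h[mask], self.conc[mask], self.background)


@dataclass(frozen=True)
class AerEstimate:
    """Fitted air-exchange rate with regression diagnostics."""

    aer_per_h: float
    stderr_per_h: float
    r_squared: float
    window_h: tuple[float, float]
    n_samples: int


def fit_tracer_decay(series: TracerSeries) -> AerEstimate:
    """Fit λ by OLS of ln(conc − background) vs time; AER = −slope (1/h).

    A noiseless exponential is recovered exactly.  Raises if any sample's
    excess over background is non-positive, naming the offending time.
    """
    excess = series.conc - series.background
    bad = np.nonzero(excess <= 0)[0]
    if len(bad):
        raise ValueError(
            f"tracer excess over background is non-positive at t = "
            f"{series.t_h[bad[0]]:g} h (conc {series.conc[bad[0]]:g} <= "
            f"background {series.background:g}); narrow the fit window"
        )
    res = stats.linregress(series.t_h, np.log(excess))
    return AerEstimate(
        aer_per_h=-res.slope,
        stderr_per_h=res.stderr,
        r_squared=res.rvalue**2,
        window_h=(float(series.t_h[0]), float(series.t_h[-1])),
        n_samples=len(series.t_h),
    )


def aggregate_aer(estimates: list[AerEstimate]) -> dict:
    """Mean ± sample s.d. of AER across replicate tracer releases."""
    if not estimates:
        raise ValueError("no AER estimates to aggregate")
    vals = np.array([e.aer_per_h for e in estimates])
    n = len(vals)
    return {
        "mean_per_h": float(vals.mean()),
        "sd_per_h": float(vals.std(ddof=1)) if n > 1 else 0.0,
        "n": n,
        "single_estimate": n == 1,
    }
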