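"""Kinetic analyses of real-time luminescence assays.

Two readouts drive the biology here.  In lysate translation reactions the
luminescence slope is a translation rate (RLU/s) and the *maximal* sliding-
window slope compares reaction conditions.  In termination (release) assays
nanoluciferase liberated from pre-termination ribosomes follows an
exponential-plateau time course,

    Y(t) = YM - (YM - Y0) * exp(-k_obs * t),

whose rate constant k_obs quantifies termination; oligos annealing near the
mRNA entry channel lower it.  Dose-response curves (readthrough vs ASO
concentration) are summarized by a four-parameter logistic EC50 fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class TraceError(ValueError):
    """Invalid kinetic trace."""


@dataclass(frozen=True)
class KineticTrace:
    """A luminescence time series (time in s, signal in RLU)."""

    times: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)
        if t.size < 5:
            raise TraceError(f"trace {self.label!r}: need >= 5 points, got {t.size}")
        if t.size != y.size:
            raise TraceError(f"trace {self.label!r}: time/signal length mismatch")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise TraceError(f"trace {self.label!r}: non-finite values")
        if np.any(np.diff(t) <= 0):
            raise TraceError(f"trace {self.label!r}: times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def baseline_subtracted(self, baseline_seconds: float) -> "KineticTrace":
        """Subtract the mean signal of the initial baseline window."""
        mask = self.times <= self.times[0] + baseline_seconds
        if mask.sum() < 1:
            return self
        return KineticTrace(self.times, self.signal - self.signal[mask].mean(),
                            self.label)


def read_traces_csv(path: str | Path) -> list[KineticTrace]:
    """Read traces from a CSV with columns time_s, signal_rlu, label."""
    df = pd.read_csv(path)
    for col in ("time_s", "signal_rlu"):
        if col not in df.columns:
            raise TraceError(f"missing required column {col!r}")
    if "label" not in df.columns:
        df["label"] = ""
    traces = []
    for label, grp in df.groupby("label", sort=False):
        traces.append(KineticTrace(grp["time_s"].to_numpy(),
                                   grp["signal_rlu"].to_numpy(), str(label)))
    return traces


def write_traces_csv(traces: list[KineticTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"time_s": t.times, "signal_rlu": t.signal, "label": t.label})
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclass(frozen=True)
class RateResult:
    max_rate: float  # RLU/s
    window_center_s: float
    window_size_points: int


def max_translation_rate(trace: KineticTrace, window_points: int = 5) -> RateResult:
    """Maximal sliding-window translation rate in RLU/s.

    An ordinary least-squares line is fit in every contiguous window of
    ``window_points`` samples; the maximal slope and its window center are
    returned.  Invariant to adding a constant to the signal, equivariant to
    scaling it.
    """
    n = len(trace)
    if not 3 <= window_points <= n:
        raise TraceError(
            f"window_points must be in 3..{n}, got {window_points}"
        )
    t, y = trace.times, trace.signal
    best_slope, best_center = -np.inf, 0.0
    for i in range(n - window_points + 1):
        tw = t[i : i + window_points]
        yw = y[i : i + window_points]
        tc = tw - tw.mean()
        slope = float(tc @ (yw - yw.mean()) / (tc @ tc))
        if slope > best_slope:
            best_slope, best_center = slope, float(tw.mean())
    return RateResult(max_rate=best_slope, window_center_s=best_center,
                      window_size_points=window_points)


@dataclass(frozen=True)
class PlateauFit:
    """Exponential-plateau fit Y(t) = YM - (YM - Y0) exp(-k_obs t)."""

    y0: float
    ym: float
    k_obs: float
    rss: float
    converged: bool
    degenerate: bool = False
    message: str = ""


def _plateau(t, y0, ym, k):
    return ym - (ym - y0) * np.exp(-k * t)


def fit_exponential_plateau(
    trace: KineticTrace,
    baseline_seconds: float | None = None,
    ftol: float = 1e-10,
    max_nfev: int = 10_000,
) -> PlateauFit:
    """Bounded least-squares fit of the exponential-plateau release model.

    Initialization: Y0 from the first point, YM from the last, k_obs from a
    log-linear regression of (YM - Y) / (YM - Y0).  Flat traces (dynamic
    range below 1e-9 of the signal scale) return a degenerate,
    non-converged result rather than a spurious rate.
    """
    if baseline_seconds is not None:
        trace = trace.baseline_subtracted(baseline_seconds)
    t, y = trace.times, trace.signal
    y0_init, ym_init = float(y[0]), float(y[-1])
    scale = max(abs(y).max(), 1.0)
    if abs(ym_init - y0_init) <= 1e-9 * scale:
        return PlateauFit(y0=y0_init, ym=ym_init, k_obs=float("nan"),
                          rss=float(np.sum((y - y.mean()) ** 2)),
                          converged=False, degenerate=True,
                          message="flat trace: YM ~ Y0, k_obs undefined")
    # log-linear k estimate from the fraction remaining
    frac = (ym_init - y) / (ym_init - y0_init)
    mask = frac > 1e-6
    if mask.sum() >= 2:
        A = np.vstack([t[mask], np.ones(mask.sum())]).T
        slope = np.linalg.lstsq(A, np.log(frac[mask]), rcond=None)[0][0]
        k_init = max(-slope, 1e-6)
    else:
        k_init = 1.0 / max(t[-1] - t[0], 1.0)
    try:
        popt, _ = curve_fit(
            _plateau, t, y,
            p0=[y0_init, ym_init, k_init],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            ftol=ftol, xtol=ftol, max_nfev=max_nfev,
        )
    except RuntimeError as exc:
        return PlateauFit(y0=y0_init, ym=ym_init, k_obs=float("nan"),
                          rss=float("nan"), converged=False,
                          message=f"fit did not converge: {exc}")
    y0, ym, k = (float(v) for v in popt)
    rss = float(np.sum((y - _plateau(t, y0, ym, k)) ** 2))
    return PlateauFit(y0=y0, ym=ym, k_obs=k, rss=rss, converged=True)


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic fit on log-dose."""

    ec50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    degenerate: bool = False


def _four_pl(logd, log_ec50, hill, top, bottom):
    return bottom + (top - bottom) / (1.0 + 10 ** ((log_ec50 - logd) * hill))


def fit_dose_response(doses, responses) -> DoseResponseFit:
    """Fit a 4PL dose-response curve; EC50 is in the input dose units.

    Requires >= 5 strictly positive dose levels.  Constant responses give a
    degenerate flag instead of an arbitrary EC50.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.size < 5:
        raise TraceError(f"need >= 5 dose levels, got {d.size}")
    if np.any(d <= 0):
        raise TraceError("doses must be > 0")
    if np.ptp(r) <= 1e-12 * max(np.abs(r).max(), 1.0):
        return DoseResponseFit(float("nan"), float("nan"), float(r[0]), float(r[0]),
                               0.0, converged=False, degenerate=True)
    logd = np.log10(d)
    p0 = [float(np.median(logd)), 1.0, float(r.max()), float(r.min())]
    try:
        popt, _ = curve_fit(_four_pl, logd, r, p0=p0,
                            bounds=([logd.min() - 6, 0.01, -np.inf, -np.inf],
                                    [logd.max() + 6, 100.0, np.inf, np.inf]),
                            ftol=1e-12, xtol=1e-12, max_nfev=20_000)
    except RuntimeError:
        return DoseResponseFit(float("nan"), float("nan"), float("nan"),
                               float("nan"), float("nan"), converged=False)
    log_ec50, hill, top, bottom = (float(v) for v in popt)
    rss = float(np.sum((r - _four_pl(logd, *popt)) ** 2))
    return DoseResponseFit(ec50=10 ** log_ec50, hill=hill, top=top,
                           bottom=bottom, rss=rss, converged=True)
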