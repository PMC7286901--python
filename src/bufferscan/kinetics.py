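"""Fitting of kinetic and equilibrium reporter readouts.

Four quantifications, each mirroring a standard folding-biology assay:

* refolding traces — fluorescence gain after dilution out of denaturant,
  fit to a single rising exponential ``y0 + A (1 - exp(-k t))``;
* chloramphenicol-chase decays — intact protein after translation arrest,
  fit to ``P + (1 - P) exp(-k_app t)`` after normalizing to the zero point;
* thermal melts — fluorescence across a temperature ramp, fit to a
  two-state transition with linear folded/unfolded baselines; ``Tm`` is the
  transition midpoint;
* two-channel reporter events — per-event GFP/mCherry ratios summarized as
  a median and a log2 fold-change against a reference median, which cancels
  expression differences between conditions.

All nonlinear fits use multi-start Levenberg-Marquardt (5 data-driven
restarts) and are invariant to uniform rescaling of the signal: rates and
Tm are unchanged, only amplitudes scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._exceptions import DataError, FitError, NoTransitionError

__all__ = [
    "KineticTrace",
    "FitResult",
    "RatioSummary",
    "fit_refolding_rate",
    "fit_chase_decay",
    "fit_melt_tm",
    "summarize_fluorescence_ratio",
]

TRACE_KINDS = ("refolding", "chase", "melt")
N_RESTARTS = 5


@dataclass(frozen=True)
class KineticTrace:
    """(x, y) series: x is time (s or min) or temperature (°C)."""

    x: np.ndarray
    y: np.ndarray
    kind: str

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"kind must be one of {TRACE_KINDS}")
        # chase gels can carry as few as 4 time points; other kinds need 5+
        min_points = 4 if self.kind == "chase" else 5
        if x.ndim != 1 or len(x) < min_points:
            raise ValueError(f"{self.kind} trace needs at least {min_points} points")
        if y.shape != x.shape:
            raise ValueError("x and y must have equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\n")
            pd.DataFrame({"x": self.x, "y": self.y}).to_csv(
                fh, index=False, float_format="%.10g"
            )

    @classmethod
    def from_csv(cls, path, kind: Optional[str] = None) -> "KineticTrace":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# kind="):
                file_kind = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh)
            else:
                file_kind = None
                fh.seek(0)
                df = pd.read_csv(fh, comment="#")
        kind = kind or file_kind
        if kind is None:
            raise ValueError(f"{path}: no kind header; pass kind= explicitly")
        return cls(x=df["x"].to_numpy(), y=df["y"].to_numpy(), kind=kind)


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with standard errors and diagnostics."""

    parameters: dict
    stderr: dict
    residual_norm: float
    converged: bool
    warnings: tuple = field(default_factory=tuple)

    def __getitem__(self, key):
        return self.parameters[key]


def _multistart_fit(model, x, y, p0_list, bounds, context: str):
    """Best-of-N bounded least-squares fit.

    Returns (popt, pcov, residual_norm, converged).  ``converged`` is False
    when every start only exhausted its evaluation budget (e.g. on a ridge
    of an ill-posed model); the best iterate is still returned so callers
    can attach diagnostics.  Raises :class:`FitError` only when no start
    produced any iterate at all.
    """
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    best = None
    for p0 in p0_list[:max(N_RESTARTS, 1)]:
        p0 = np.clip(np.asarray(p0, float), lo, hi)
        try:
            res = least_squares(lambda p: model(x, *p) - y, p0,
                                bounds=(lo, hi), max_nfev=2000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(res.fun))
        conv = res.status > 0
        if best is None or (resid, not conv) < (best[2], not best[3]):
            best = (res, None, resid, conv)
    if best is None:
        raise FitError(
            f"{context}: no start converged",
            diagnostics={"restarts": len(p0_list), "n_points": len(x)},
        )
    res, _, resid, conv = best
    popt = res.x
    dof = len(x) - len(popt)
    if dof > 0:
        s_sq = 2.0 * res.cost / dof
        try:
            pcov = s_sq * np.linalg.pinv(res.jac.T @ res.jac)
        except np.linalg.LinAlgError:
            pcov = np.full((len(popt), len(popt)), np.nan)
    else:
        pcov = np.full((len(popt), len(popt)), np.nan)
    return popt, pcov, resid, conv


def fit_refolding_rate(trace: KineticTrace) -> FitResult:
    """Fit a refolding trace to ``y(t) = y0 + A (1 - exp(-k t))``.

    Returns k (units of 1/x), amplitude A and baseline y0 with standard
    errors.  A trace that decreases overall is fit anyway but tagged with a
    ``model_mismatch`` warning.
    """
    if trace.kind != "refolding":
        raise ValueError("trace kind must be 'refolding'")
    t, y = trace.x, trace.y
    warnings = ()
    if y[-1] < y[0]:
        warnings = ("model_mismatch: signal decreases overall",)
    # fit on a unit-scaled signal so the result is invariant to rescaling
    scale = max(np.abs(y).max(), 1e-300)
    ys = y / scale
    y0_guess = ys[0]
    span = ys[-1] - ys[0]
    A_guess = span if span != 0 else 1e-6
    k_guesses = _rise_rate_guesses(t, ys)
    p0s = [(y0_guess, A_guess, k) for k in k_guesses]
    lo = [-np.inf, -np.inf, 0.0]
    hi = [np.inf, np.inf, np.inf]
    model = lambda tt, y0, A, k: y0 + A * -np.expm1(-k * tt)
    popt, pcov, resid, conv = _multistart_fit(model, t, ys, p0s, (lo, hi),
                                               "refolding fit")
    se = _stderr(pcov)
    return FitResult(
        parameters={"k": float(popt[2]), "amplitude": float(popt[1]) * scale,
                    "baseline": float(popt[0]) * scale},
        stderr={"k": se[2], "amplitude": se[1] * scale, "baseline": se[0] * scale},
        residual_norm=resid * scale, converged=conv, warnings=warnings,
    )


def _rise_rate_guesses(t, y):
    """Rate guesses from the time to half the observed rise, bracketed."""
    span = y[-1] - y[0]
    if abs(span) > 0:
        half = y[0] + 0.5 * span
        idx = np.argmin(np.abs(y - half))
        t_half = max(t[idx], t[1] if t[0] == 0 else t[0])
        k0 = np.log(2.0) / t_half
    else:
        k0 = 1.0 / max(t[-1], 1e-12)
    return [k0, 5 * k0, k0 / 5, 25 * k0, k0 / 25]


def fit_chase_decay(trace: KineticTrace, *, fix_plateau: bool = False) -> FitResult:
    """Fit a chase decay to ``y(t) = P + (1 - P) exp(-k_app t)``.

    The trace is renormalized so y at the first time point is 1 (chase
    quantifications are conventionally expressed as fraction of the signal
    at arrest).  With only 4-5 chase time points the 2-parameter variant
    with the plateau pinned at 0 (``fix_plateau=True``) is often better
    determined; both are exposed.  A flat trace returns k_app = 0 with a
    ``stable_protein`` warning instead of a degenerate fit.
    """
    if trace.kind != "chase":
        raise ValueError("trace kind must be 'chase'")
    if len(trace.x) < 4:
        raise ValueError("chase fit needs at least 4 time points")
    t = trace.x - trace.x[0]
    if trace.y[0] == 0:
        raise DataError("zero signal at the first chase point")
    y = trace.y / trace.y[0]

    if (y.max() - y.min()) < 1e-9:
        return FitResult(
            parameters={"k_app": 0.0, "plateau": float(y.mean())},
            stderr={"k_app": 0.0, "plateau": 0.0},
            residual_norm=0.0, converged=True,
            warnings=("stable_protein: no decay detected",),
        )

    k_guesses = _decay_rate_guesses(t, y)
    if fix_plateau:
        model = lambda tt, k: np.exp(-k * tt)
        p0s = [(k,) for k in k_guesses]
        bounds = ([0.0], [np.inf])
    else:
        model = lambda tt, p, k: p + (1.0 - p) * np.exp(-k * tt)
        p0s = [(max(y.min(), 0.0), k) for k in k_guesses]
        bounds = ([0.0, 0.0], [1.0, np.inf])
    popt, pcov, resid, conv = _multistart_fit(model, t, y, p0s, bounds,
                                               "chase fit")
    se = _stderr(pcov)
    if fix_plateau:
        params = {"k_app": float(popt[0]), "plateau": 0.0}
        stderr = {"k_app": se[0], "plateau": 0.0}
    else:
        params = {"k_app": float(popt[1]), "plateau": float(popt[0])}
        stderr = {"k_app": se[1], "plateau": se[0]}
    return FitResult(parameters=params, stderr=stderr,
                     residual_norm=resid, converged=conv)


def _decay_rate_guesses(t, y):
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        k0 = max(-slope, 1e-12)
    else:
        k0 = 1.0 / max(t[-1], 1e-12)
    return [k0, 5 * k0, k0 / 5, 1.0 / max(t[-1], 1e-12), 1e-4]


def _theta(T, Tm, width):
    """Folded fraction of a two-state transition, logistic in temperature."""
    z = np.clip((T - Tm) / width, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def _melt_model(T, Tm, width, aN, bN, aU, bU):
    th = _theta(T, Tm, width)
    return (aN + bN * T) * th + (aU + bU * T) * (1.0 - th)


def fit_melt_tm(trace: KineticTrace, *, method: str = "sigmoid") -> FitResult:
    """Extract the melting temperature Tm from a thermal melt.

    ``method="sigmoid"`` (default) fits a two-state logistic transition with
    linear folded and unfolded baselines; Tm is the half-transition
    temperature.  ``method="linear_midpoint"`` reads Tm off a straight-line
    fit through the transition region at the midpoint between the baseline
    levels — the classical graphical reading, retained because it is how
    melt midpoints are often reported.

    Raises :class:`NoTransitionError` when the transition amplitude is not
    resolvable above the noise floor.
    """
    if trace.kind != "melt":
        raise ValueError("trace kind must be 'melt'")
    T, y = trace.x, trace.y
    noise = _noise_sd(y)
    y_scale = max(np.ptp(y), 1e-300)
    span_floor = max(5.0 * noise, 1e-3 * max(np.abs(y).max(), 1e-300))
    if y_scale < span_floor:
        raise NoTransitionError(
            "no resolvable unfolding transition (signal span below noise floor)"
        )
    if method == "linear_midpoint":
        return _linear_midpoint_tm(T, y)
    if method != "sigmoid":
        raise ValueError("method must be 'sigmoid' or 'linear_midpoint'")

    # fit on a unit-scaled signal so Tm is invariant to signal rescaling
    scale = max(np.abs(y).max(), 1e-300)
    ys = y / scale
    tm0 = _tm_guess(T, ys)
    n_edge = max(3, len(T) // 8)
    aN, bN = _line(T[:n_edge], ys[:n_edge])
    aU, bU = _line(T[-n_edge:], ys[-n_edge:])
    widths = [1.0, 2.0, 4.0, 0.5, 8.0]
    p0s = [(tm0, w, aN, bN, aU, bU) for w in widths]
    lo = [T[0], 0.05, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [T[-1], (T[-1] - T[0]), np.inf, np.inf, np.inf, np.inf]
    popt, pcov, resid, conv = _multistart_fit(_melt_model, T, ys, p0s,
                                              (lo, hi), "melt fit")
    tm, width = popt[0], popt[1]
    amplitude = scale * abs((popt[2] + popt[3] * tm) - (popt[4] + popt[5] * tm))
    resid *= scale
    if amplitude < span_floor:
        raise NoTransitionError(
            "fitted transition amplitude below the noise floor",
        )
    se = _stderr(pcov)
    return FitResult(
        parameters={"Tm": float(tm), "width": float(width),
                    "amplitude": float(amplitude)},
        stderr={"Tm": se[0], "width": se[1]},
        residual_norm=resid, converged=conv,
    )


def _linear_midpoint_tm(T, y) -> FitResult:
    """Straight-line read-off of the melt midpoint.

    Baselines are medians of the outer octiles; a line is fit through the
    points lying between 25% and 75% of the baseline-to-baseline span and
    solved for the temperature at the half-span level.
    """
    n_edge = max(3, len(T) // 8)
    yN = np.median(y[:n_edge])
    yU = np.median(y[-n_edge:])
    frac = (y - yN) / (yU - yN) if yU != yN else np.zeros_like(y)
    core = (frac > 0.25) & (frac < 0.75)
    if core.sum() < 2:
        raise NoTransitionError("transition region too narrow for a linear fit")
    a, b = _line(T[core], y[core])
    midpoint = 0.5 * (yN + yU)
    if b == 0:
        raise NoTransitionError("flat transition region")
    tm = (midpoint - a) / b
    resid = float(np.linalg.norm(a + b * T[core] - y[core]))
    return FitResult(
        parameters={"Tm": float(tm), "slope": float(b), "midpoint_level": midpoint},
        stderr={"Tm": float("nan")},
        residual_norm=resid, converged=True,
        warnings=("linear_midpoint: graphical method, no Tm standard error",),
    )


def _line(x, y):
    b, a = np.polyfit(x, y, 1)
    return a, b


def _tm_guess(T, y):
    """Temperature of steepest signal change on a lightly smoothed curve."""
    if len(y) >= 7:
        kernel = np.ones(5) / 5.0
        ys = np.convolve(y, kernel, mode="same")
    else:
        ys = y
    grad = np.abs(np.gradient(ys, T))
    interior = slice(2, -2) if len(T) > 6 else slice(None)
    idx = np.arange(len(T))[interior][np.argmax(grad[interior])]
    return T[idx]


def _noise_sd(y):
    """Noise estimate from second differences (trend-insensitive)."""
    if len(y) < 3:
        return 0.0
    return float(np.std(np.diff(y, 2)) / np.sqrt(6.0))


def _stderr(pcov):
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.diag(pcov)).tolist()


@dataclass(frozen=True)
class RatioSummary:
    """Median two-channel ratio and its log2 fold-change vs a reference."""

    median_ratio: float
    log2_fold_change: float
    n_events: int
    n_dropped: int


def summarize_fluorescence_ratio(
    events: pd.DataFrame, reference_median: float = 1.0,
    *, gfp_col: str = "gfp", mcherry_col: str = "mcherry",
) -> RatioSummary:
    """Summarize per-event GFP/mCherry ratios against a reference median.

    Events with a non-positive value in either channel are dropped (and
    counted); the summary is the median ratio over retained events and
    ``log2(median / reference_median)``.
    """
    for col in (gfp_col, mcherry_col):
        if col not in events.columns:
            raise DataError(f"events table missing column {col!r}")
    if reference_median <= 0:
        raise ValueError("reference_median must be positive")
    if len(events) < 100:
        raise ValueError("need at least 100 events")
    keep = (events[gfp_col] > 0) & (events[mcherry_col] > 0)
    n_dropped = int((~keep).sum())
    retained = events[keep]
    if len(retained) == 0:
        raise DataError("all events dropped (non-positive channel values)")
    ratio = retained[gfp_col] / retained[mcherry_col]
    med = float(ratio.median())
    return RatioSummary(
        median_ratio=med,
        log2_fold_change=float(np.log2(med / reference_median)),
        n_events=int(len(retained)),
        n_dropped=n_dropped,
    )
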