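"""Kinetic model of synthesis / folding / degradation competition under
translation arrest.

The model tracks four species:

``S``
    template complex (mRNA/ribosome) competent to make protein, µM;
``U``
    nascent, not-yet-folded polypeptide, µM;
``F``
    natively folded protein, µM;
``I``
    translation inhibitor (chloramphenicol-like), µM, dosed at ``t_arrest``.

Catalytic mode (default — templates are reused by translation):

.. math::

    dS/dt = -k_{block} S I, \\quad
    dU/dt = k_{trans} S - (k_f + k_{deg}) U, \\quad
    dF/dt = k_f U

with :math:`S(0)=S_0`, :math:`U(0)=F(0)=0` and :math:`I` stepped from 0 to
``I_dose`` at ``t_arrest``.  Consuming mode additionally removes template on
each initiation event (``dS/dt -= k_trans*S``).

By default the inhibitor is treated in the pseudo-first-order approximation:
after dosing, ``I`` is held constant at ``I_dose`` so that the template is
quenched as :math:`S(t) = S_1 e^{-k_{block} I_{dose} (t - t_{arrest})}`.
This makes the whole system linear and admits the closed-form solution in
:func:`closed_form_chase`, which serves as the analytic oracle for the
numerical integrator.  Set ``inhibitor_depletion=True`` to consume ``I``
stoichiometrically with ``S`` instead.

The experimentally observable quantity is the intact (undegraded) protein
``U + F`` after arrest — the in-silico analogue of a chloramphenicol chase.
Time is in seconds and concentrations in µM throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from ._exceptions import FitError, IntegrationError

__all__ = [
    "SimParams",
    "Trajectory",
    "ChaseState",
    "ApparentRate",
    "FoldingRateScan",
    "simulate_chase",
    "closed_form_chase",
    "scan_folding_rates",
    "apparent_degradation_rate",
]

_MODES = ("catalytic", "consuming")


@dataclass(frozen=True)
class SimParams:
    """Rate constants and protocol for a simulated translation-arrest chase.

    Parameters
    ----------
    k_trans : float
        First-order synthesis rate constant (s^-1); lumps transcription and
        translation into one template-turnover rate.
    k_f : float
        Folding rate constant (s^-1) taking U to F.
    k_deg : float
        Degradation rate constant (s^-1) acting on U only; the native state
        is assumed protease-resistant.
    k_block : float
        Second-order inhibition rate constant (µM^-1 s^-1) for S + I.
    S0 : float
        Initial template concentration (µM).
    I_dose : float
        Inhibitor concentration dosed at arrest (µM).
    t_arrest : float
        Time of inhibitor addition (s).
    template_mode : str
        ``"catalytic"`` (template reused; default) or ``"consuming"``.
    inhibitor_depletion : bool
        If True, I is consumed stoichiometrically with S; default holds I
        constant at ``I_dose`` after dosing (pseudo-first-order quench).
    """

    k_trans: float = 0.01
    k_f: float = 0.03
    k_deg: float = 0.01
    k_block: float = 10.0
    S0: float = 1000.0
    I_dose: float = 1000.0
    t_arrest: float = 300.0
    template_mode: str = "catalytic"
    inhibitor_depletion: bool = False

    def __post_init__(self):
        for name in ("k_trans", "k_f", "k_deg", "k_block", "S0", "I_dose", "t_arrest"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if self.template_mode not in _MODES:
            raise ValueError(
                f"template_mode must be one of {_MODES}, got {self.template_mode!r}"
            )

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown SimParams keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimParams":
        """Load parameters from a JSON or YAML file keyed by field name."""
        text = open(path).read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of SimParams fields")
        return cls.from_dict(data)


class ChaseState(NamedTuple):
    """Closed-form species concentrations at one or more time points."""

    S: np.ndarray
    U: np.ndarray
    F: np.ndarray
    intact: np.ndarray


@dataclass(frozen=True)
class Trajectory:
    """Time-resolved species concentrations from a chase simulation."""

    t: np.ndarray
    S: np.ndarray
    U: np.ndarray
    F: np.ndarray
    I: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("t must be a strictly increasing 1-D grid")
        for name in ("S", "U", "F", "I"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must match the time grid shape")

    @property
    def intact(self) -> np.ndarray:
        """Undegraded protein U + F — the chase observable."""
        return self.U + self.F

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "S": self.S, "U": self.U, "F": self.F, "I": self.I,
             "intact": self.intact}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        required = {"t", "S", "U", "F", "I"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(
            t=df["t"].to_numpy(), S=df["S"].to_numpy(), U=df["U"].to_numpy(),
            F=df["F"].to_numpy(), I=df["I"].to_numpy(),
        )


def _eint(r: float, t: np.ndarray) -> np.ndarray:
    """(1 - exp(-r t)) / r, stable for r -> 0 (limit t)."""
    if r == 0.0:
        return np.asarray(t, dtype=float).copy()
    return -np.expm1(-r * np.asarray(t, dtype=float)) / r


def _ramp_integral(lam: float, t: np.ndarray) -> np.ndarray:
    """Integral of _eint(lam, s) ds from 0 to t: (t - _eint(lam, t)) / lam."""
    t = np.asarray(t, dtype=float)
    if lam == 0.0:
        return 0.5 * t * t
    return (t - _eint(lam, t)) / lam


def _forced_decay(lam: float, beta: float, tau: np.ndarray) -> np.ndarray:
    """(exp(-beta tau) - exp(-lam tau)) / (lam - beta), repeated-root safe.

    Particular response of dU/dt = e^{-beta t} - lam U; both exponentials are
    bounded so no overflow for widely separated rates; near-coincident rates
    switch to a series in (lam - beta) tau to avoid cancellation.
    """
    tau = np.asarray(tau, dtype=float)
    x = (lam - beta) * tau
    small = np.abs(x) < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        direct = (np.exp(-beta * tau) - np.exp(-lam * tau)) / (lam - beta)
    series = np.exp(-beta * tau) * tau * (1.0 - x / 2.0 + x * x / 6.0)
    return np.where(small, series, direct)


def _forced_decay_integral(lam: float, beta: float, tau: np.ndarray) -> np.ndarray:
    """Integral of _forced_decay over [0, tau]."""
    tau = np.asarray(tau, dtype=float)
    scale = max(lam, beta, 1e-300)
    if abs(lam - beta) < 1e-6 * scale:
        # repeated root: integral of s e^{-lam s}
        if lam == 0.0:
            return 0.5 * tau * tau
        return (1.0 - (1.0 + lam * tau) * np.exp(-lam * tau)) / (lam * lam)
    return (_eint(beta, tau) - _eint(lam, tau)) / (lam - beta)


def closed_form_chase(params: SimParams, t) -> ChaseState:
    """Analytic solution of the catalytic-mode chase at time(s) ``t``.

    Before arrest the template is constant at ``S0``; after arrest the
    inhibitor is treated as constant at ``I_dose`` (pseudo-first-order
    quench), so every equation is linear with an exponentially decaying
    source and solves in elementary functions.

    Returns a :class:`ChaseState`; scalar ``t`` yields 0-d arrays.
    """
    if params.template_mode != "catalytic":
        raise ValueError("closed_form_chase supports catalytic mode only")
    if params.inhibitor_depletion:
        raise ValueError(
            "closed_form_chase requires the pseudo-first-order inhibitor model"
        )
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time points must be >= 0")
    lam = params.k_f + params.k_deg
    a = params.k_trans * params.S0
    t1 = np.minimum(t, params.t_arrest)

    # phase 1: constant template
    S = np.full_like(t, params.S0, dtype=float)
    U = a * _eint(lam, t1)
    F = params.k_f * a * _ramp_integral(lam, t1)

    after = t > params.t_arrest
    if np.any(after):
        tau = t[after] - params.t_arrest
        beta = params.k_block * params.I_dose
        U1 = a * _eint(lam, params.t_arrest)
        F1 = params.k_f * a * _ramp_integral(lam, params.t_arrest)
        S[after] = params.S0 * np.exp(-beta * tau)
        U[after] = U1 * np.exp(-lam * tau) + a * _forced_decay(lam, beta, tau)
        F_after = F1 + params.k_f * (
            U1 * _eint(lam, tau) + a * _forced_decay_integral(lam, beta, tau)
        )
        if params.k_f == 0.0:
            F_after = np.zeros_like(tau)
        F[after] = F_after
    return ChaseState(S=S, U=U, F=F, intact=U + F)


def _rhs(params: SimParams, I_const: float):
    """RHS for the (S, U, F, I) system; I_const is the held inhibitor level
    in the pseudo-first-order model (ignored when depletion is on)."""
    k_trans, k_f, k_deg, k_block = (
        params.k_trans, params.k_f, params.k_deg, params.k_block,
    )
    consuming = params.template_mode == "consuming"
    depleting = params.inhibitor_depletion

    def rhs(_t, y):
        S, U, F, I = y
        inhibitor = I if depleting else I_const
        block = k_block * S * inhibitor
        dS = -block - (k_trans * S if consuming else 0.0)
        dU = k_trans * S - (k_f + k_deg) * U
        dF = k_f * U
        dI = -block if depleting else 0.0
        return (dS, dU, dF, dI)

    return rhs


def simulate_chase(
    params: SimParams,
    t_grid: Sequence[float],
    *,
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> Trajectory:
    """Numerically integrate the chase model over ``t_grid``.

    The inhibitor dose at ``t_arrest`` is a discontinuous event: integration
    stops exactly at the arrest time and restarts with the inhibitor present,
    so no step ever straddles the jump.  The implicit Radau method is used
    because the quench time-scale (``1/(k_block*I_dose)``, sub-millisecond at
    the default 1 mM dose) is far stiffer than the folding/degradation
    time-scales.

    Raises :class:`IntegrationError` if the solver fails, distinguishable
    from the :class:`ValueError` raised for bad arguments.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must be 1-D with at least two points")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")

    scale = max(params.S0, params.I_dose, 1.0)
    atol_abs = atol * scale
    t_arr = params.t_arrest
    pre_mask = t_grid <= t_arr
    post_mask = ~pre_mask

    def integrate(t0, t1, y0, I_const):
        sol = solve_ivp(
            _rhs(params, I_const), (t0, t1), y0, method="Radau",
            rtol=rtol, atol=atol_abs, dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed: {sol.message}")
        return sol

    y0 = np.array([params.S0, 0.0, 0.0, 0.0])
    out = np.zeros((4, len(t_grid)))

    if t_arr > 0:
        sol_pre = integrate(0.0, t_arr, y0, 0.0)
        if pre_mask.any():
            out[:, pre_mask] = sol_pre.sol(t_grid[pre_mask])
        y_at_arrest = sol_pre.y[:, -1]
    else:
        y_at_arrest = y0

    if post_mask.any():
        y1 = np.array(y_at_arrest, dtype=float)
        y1[3] = params.I_dose  # dose event: integration restarts here
        sol_post = integrate(t_arr, float(t_grid[-1]), y1, params.I_dose)
        out[:, post_mask] = sol_post.sol(t_grid[post_mask])

    # pseudo-first-order bookkeeping: report the held inhibitor level
    if not params.inhibitor_depletion:
        out[3, pre_mask] = 0.0
        out[3, post_mask] = params.I_dose

    # integrator round-off can leave tiny negatives; clip within tolerance
    if np.any(out < -10 * atol_abs):
        raise IntegrationError("negative concentrations beyond solver tolerance")
    out = np.clip(out, 0.0, None)
    return Trajectory(t=t_grid, S=out[0], U=out[1], F=out[2], I=out[3])


@dataclass(frozen=True)
class FoldingRateScan:
    """Family of chase trajectories sharing everything but ``k_f``."""

    kf_values: tuple
    trajectories: tuple  # of Trajectory, same order as kf_values

    def __iter__(self):
        return iter(zip(self.kf_values, self.trajectories))

    def intact_at(self, time: float) -> np.ndarray:
        """Intact protein at ``time`` (linear interpolation), one value per k_f."""
        return np.array(
            [np.interp(time, traj.t, traj.intact) for traj in self.trajectories]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kf, traj in self:
            df = traj.to_frame()
            df.insert(0, "k_f", kf)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def scan_folding_rates(
    base: SimParams, kf_values: Sequence[float], t_grid: Sequence[float]
) -> FoldingRateScan:
    """Simulate one chase per folding rate, all else fixed, ordered by k_f.

    Duplicated k_f entries are retained (and produce identical trajectories).
    """
    kf_values = list(kf_values)
    if len(kf_values) == 0:
        raise ValueError("kf_values must be non-empty")
    if any((not np.isfinite(k)) or k < 0 for k in kf_values):
        raise ValueError("all kf_values must be finite and >= 0")
    order = sorted(range(len(kf_values)), key=lambda i: kf_values[i])
    kf_sorted = tuple(float(kf_values[i]) for i in order)
    trajs = tuple(simulate_chase(base.with_(k_f=kf), t_grid) for kf in kf_sorted)
    return FoldingRateScan(kf_values=kf_sorted, trajectories=trajs)


@dataclass(frozen=True)
class ApparentRate:
    """Single-exponential summary of a post-arrest intact-protein decay."""

    k_app: float            # s^-1
    plateau: float          # µM
    amplitude: float        # µM
    residual_norm: float
    converged: bool
    stable: bool = False    # True when the series shows no resolvable decay


def apparent_degradation_rate(
    traj: Trajectory, t_arrest: float, *, fix_plateau: bool = False
) -> ApparentRate:
    """Fit ``intact(t >= t_arrest)`` to ``P + A exp(-k_app (t - t_arrest))``.

    Summarizes a simulated chase the way gel-quantified chases are
    summarized: one apparent first-order decay rate for total intact protein.
    With ``fix_plateau=True`` the plateau P is pinned to zero (useful in the
    k_f = 0 limit where all synthesized protein is eventually degraded).
    """
    mask = traj.t >= t_arrest
    if mask.sum() < 5:
        raise ValueError("need at least 5 trajectory points at or after t_arrest")
    tau = traj.t[mask] - t_arrest
    y = traj.intact[mask]
    span = y.max() - y.min()
    scale = max(abs(y).max(), 1e-300)
    if span / scale < 1e-9:
        return ApparentRate(
            k_app=0.0, plateau=float(y.mean()), amplitude=0.0,
            residual_norm=0.0, converged=True, stable=True,
        )

    if fix_plateau:
        model = lambda t, a, k: a * np.exp(-k * t)
        p0s = [(y[0], k0) for k0 in _rate_guesses(tau, y, 0.0)]
        bounds = ([0.0, 0.0], [np.inf, np.inf])
    else:
        model = lambda t, p, a, k: p + a * np.exp(-k * t)
        p_guess = min(y.min(), y[-1])
        p0s = [(p_guess, y[0] - p_guess, k0) for k0 in _rate_guesses(tau, y, p_guess)]
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])

    best = None
    for p0 in p0s:
        try:
            popt, _ = curve_fit(model, tau, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(model(tau, *popt) - y))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise FitError(
            "apparent-rate fit did not converge",
            diagnostics={"n_points": int(mask.sum()), "restarts": len(p0s)},
        )
    popt, resid = best
    if fix_plateau:
        plateau, amplitude, k_app = 0.0, popt[0], popt[1]
    else:
        plateau, amplitude, k_app = popt
    return ApparentRate(
        k_app=float(k_app), plateau=float(plateau), amplitude=float(amplitude),
        residual_norm=resid, converged=True,
    )


def _rate_guesses(tau, y, plateau):
    """Initial decay-rate guesses: log-linear slope plus bracketing scales."""
    z = y - plateau
    pos = z > 0
    if pos.sum() >= 2:
        slope = np.polyfit(tau[pos], np.log(z[pos]), 1)[0]
        k0 = max(-slope, 1e-12)
    else:
        k0 = 1.0 / max(tau[-1], 1e-12)
    return [k0, k0 * 5.0, k0 / 5.0, 1.0 / max(tau[-1], 1e-12), 1e-4]
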