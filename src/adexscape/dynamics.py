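"""Phase-plane and excitability-landscape analysis of AdEx models.

The two-variable AdEx system has fixed points where the V- and w-nullclines
intersect.  Linearising around a fixed point gives the Jacobian

    J = [[ (-g_L + g_L * exp((V* - V_th)/Delta_T)) / C,  -1/C   ],
         [ a / tau_w,                                    -1/tau_w ]]

whose eigenvalues determine local stability.  The local bifurcation that
terminates the resting state as current increases is decided by the ratios
``R_a = a/g_L`` and ``R_tau = tau_m/tau_w`` (with ``tau_m = C/g_L``): a
strong-and-fast adaptation brake (``R_a > R_tau``, equivalently
``a*tau_w > C``) yields a subcritical Hopf onset (Class II excitability); a
weak-or-slow brake (``a*tau_w < C``) yields a saddle-node on invariant circle
(Class I).  Exact equality is the codimension-2 Bogdanov-Takens (BT) point.
In the (R_a, R_tau) plane — the excitability landscape — a neuromodulator
either *switches* a neuron across the diagonal (class change) or *scales* its
existing behaviour on the same side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

from .model import (
    EXP_ARG_MAX,
    AdExParameters,
    IntegrationError,
    StimulusProtocol,
    simulate,
    v_nullcline,
    w_nullcline,
)
from .features import Trace, extract_features

__all__ = [
    "FixedPoint",
    "ExcitabilityPoint",
    "ModulationShift",
    "FIPoint",
    "find_fixed_points",
    "classify_fixed_point",
    "excitability_point",
    "classify_shift",
    "compute_fi_curve",
    "rheobase_current",
]

#: |Re(lambda)| below this (1/ms) is treated as a zero real part.
NONHYPERBOLIC_TOL = 1e-9

#: Relative width of the Bogdanov-Takens band around a*tau_w == C.
BT_TOL = 1e-6

_GRID_STEP = 0.01  # mV, bracketing grid for fixed-point search
_BISECT_TOL = 1e-10  # mV


@dataclass(frozen=True)
class FixedPoint:
    """A nullcline intersection with its linear stability."""

    V_star: float  # mV
    w_star: float  # pA
    eigenvalues: tuple  # pair of complex rates, 1/ms
    stability: str  # stable/unstable node/focus, saddle, nonhyperbolic


@dataclass(frozen=True)
class ExcitabilityPoint:
    """Coordinates of one model in the excitability landscape."""

    R_a: float
    R_tau: float
    excitability_class: str  # "Class I" | "Class II" | "BT"

    def __post_init__(self):
        if not self.R_tau > 0:
            raise ValueError("R_tau must be positive")


@dataclass(frozen=True)
class ModulationShift:
    """Centroid displacement of an ensemble under neuromodulation."""

    control_centroid: tuple  # (R_a, R_tau)
    modulated_centroid: tuple
    control_class: str
    modulated_class: str
    kind: str  # "switch" | "scale"
    displacement: tuple  # modulated - control


@dataclass(frozen=True)
class FIPoint:
    """One sample of an f-I curve; ``error`` holds a failure message if any."""

    current: float  # pA
    freq: float  # spikes/s (nan when the simulation failed)
    error: str | None = None


def _fp_residual(params: AdExParameters, I: float, V):
    """g_L*Delta_T*exp((V - V_th)/Delta_T) - (g_L + a)(V - E_L) + I.

    Roots in V are the fixed-point voltages (difference of the two
    nullclines).  The exponent guard of the model applies.
    """
    V = np.asarray(V, dtype=float)
    arg = np.minimum((V - params.V_th) / params.Delta_T, EXP_ARG_MAX)
    r = (
        params.g_L * params.Delta_T * np.exp(arg)
        - (params.g_L + params.a) * (V - params.E_L)
        + I
    )
    return r if r.ndim else float(r)


def find_fixed_points(params: AdExParameters, I: float) -> list:
    """All fixed points of the AdEx vector field at constant current ``I``.

    Roots are bracketed by sign changes on a 0.01 mV grid over
    ``[E_L - 60 mV, V_peak]`` and refined by bisection to 1e-10 mV; each root
    is returned with ``w* = a (V* - E_L)`` and its stability label.  The list
    is empty above the saddle-node current.
    """
    lo = params.E_L - 60.0
    hi = params.V_peak
    n = int(np.ceil((hi - lo) / _GRID_STEP)) + 1
    grid = np.linspace(lo, hi, n)
    vals = _fp_residual(params, I, grid)

    roots = []
    for i in range(len(grid) - 1):
        f0, f1 = vals[i], vals[i + 1]
        if f0 == 0.0:
            roots.append(grid[i])
        elif f0 * f1 < 0:
            roots.append(
                bisect(
                    lambda V: _fp_residual(params, I, V),
                    grid[i],
                    grid[i + 1],
                    xtol=_BISECT_TOL,
                )
            )
    if len(vals) and vals[-1] == 0.0:
        roots.append(grid[-1])

    points = []
    for V_star in roots:
        w_star = w_nullcline(params, V_star)
        fp = FixedPoint(
            V_star=float(V_star),
            w_star=float(w_star),
            eigenvalues=(0j, 0j),
            stability="",
        )
        points.append(classify_fixed_point(params, fp))
    return points


def jacobian(params: AdExParameters, V_star: float) -> np.ndarray:
    """Analytic Jacobian of the AdEx vector field at voltage ``V_star``."""
    arg = min((V_star - params.V_th) / params.Delta_T, EXP_ARG_MAX)
    dV_dV = (-params.g_L + params.g_L * math.exp(arg)) / params.C
    return np.array(
        [
            [dV_dV, -1.0 / params.C],
            [params.a / params.tau_w, -1.0 / params.tau_w],
        ]
    )


def classify_fixed_point(params: AdExParameters, fp: FixedPoint) -> FixedPoint:
    """Return ``fp`` with closed-form eigenvalues and a stability label.

    Labels: saddle (det < 0); stable/unstable node (real eigenvalues) or
    focus (complex pair) by the sign of the real parts; nonhyperbolic when a
    real part is within 1e-9/ms of zero.
    """
    J = jacobian(params, fp.V_star)
    tr = J[0, 0] + J[1, 1]
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = complex(tr * tr - 4.0 * det)
    sq = np.sqrt(disc)
    lam1 = (tr + sq) / 2.0
    lam2 = (tr - sq) / 2.0
    re1, re2 = lam1.real, lam2.real
    complex_pair = abs(lam1.imag) > 0

    if min(abs(re1), abs(re2)) < NONHYPERBOLIC_TOL:
        label = "nonhyperbolic"
    elif det < 0:
        label = "saddle"
    elif re1 < 0 and re2 < 0:
        label = "stable focus" if complex_pair else "stable node"
    else:
        label = "unstable focus" if complex_pair else "unstable node"

    return FixedPoint(
        V_star=fp.V_star,
        w_star=fp.w_star,
        eigenvalues=(complex(lam1), complex(lam2)),
        stability=label,
    )


def _classify_ratio(R_a: float, R_tau: float) -> str:
    if R_a > R_tau * (1.0 + BT_TOL):
        return "Class II"
    if R_a < R_tau * (1.0 - BT_TOL):
        return "Class I"
    return "BT"


def excitability_point(params: AdExParameters) -> ExcitabilityPoint:
    """Project a parameter set onto the excitability landscape.

    ``R_a = a/g_L`` and ``R_tau = C/(g_L*tau_w)``; the class follows from
    ``a*tau_w`` vs ``C`` with a relative BT band of 1e-6 (exact equality is
    measure-zero in floating point).
    """
    R_a = params.a / params.g_L
    R_tau = params.C / (params.g_L * params.tau_w)
    return ExcitabilityPoint(
        R_a=R_a, R_tau=R_tau, excitability_class=_classify_ratio(R_a, R_tau)
    )


def classify_shift(control: list, modulated: list) -> ModulationShift:
    """Switch-or-scale label for a control -> modulated ensemble displacement.

    Centroids are the coordinate means of each ensemble in the landscape.
    The shift is a *switch* exactly when the centroid classes differ; a
    centroid inside the BT band sits on the boundary and is treated as not
    having crossed it (scale).
    """
    if not control or not modulated:
        raise ValueError("both ensembles must be nonempty")

    def centroid(points):
        return (
            float(np.mean([p.R_a for p in points])),
            float(np.mean([p.R_tau for p in points])),
        )

    c = centroid(control)
    m = centroid(modulated)
    c_class = _classify_ratio(*c)
    m_class = _classify_ratio(*m)
    switched = (
        c_class != m_class and c_class != "BT" and m_class != "BT"
    )
    return ModulationShift(
        control_centroid=c,
        modulated_centroid=m,
        control_class=c_class,
        modulated_class=m_class,
        kind="switch" if switched else "scale",
        displacement=(m[0] - c[0], m[1] - c[1]),
    )


def rheobase_current(params: AdExParameters) -> float:
    """Saddle-node (rheobase) current in pA, closed form.

    Valid for ``g_L + a > 0``: the resting and saddle points annihilate where
    the V-nullcline touches the w-nullcline, at
    ``V_sn = V_th + Delta_T * ln((g_L + a)/g_L)``.
    """
    g_tot = params.g_L + params.a
    if g_tot <= 0:
        raise ValueError("rheobase is undefined for g_L + a <= 0")
    return g_tot * (
        params.V_th
        - params.E_L
        + params.Delta_T * math.log(g_tot / params.g_L)
        - params.Delta_T
    )


def _lowest_root_bracket(params: AdExParameters, I: float, v_step: float):
    """Coarse bracket of the lowest fixed-point voltage, or None."""
    lo = params.E_L - 60.0
    hi = params.V_peak
    grid = np.arange(lo, hi + v_step, v_step)
    vals = _fp_residual(params, I, grid)
    sign_change = np.nonzero(vals[:-1] * vals[1:] <= 0)[0]
    if len(sign_change) == 0:
        return None
    i = int(sign_change[0])
    return float(grid[i]), float(grid[i + 1])


def sweep_excitability_class(
    params: AdExParameters,
    n_currents: int = 300,
    v_step: float = 0.02,
    fd_eps: float = 1e-5,
) -> str:
    """Excitability class by numerical bifurcation sweep (cross-check).

    Independent of the algebraic ``a*tau_w`` vs ``C`` rule: the injected
    current is swept upward from 0 to the saddle-node value (located by
    bisection on the existence of a resting point); at each current the
    lowest fixed point is found by sign-change bracketing and its stability
    assessed from the eigenvalues of a finite-difference Jacobian of the
    vector field.  If the resting point loses stability through a complex
    pair crossing zero real part while it still exists, the onset is a
    subcritical Hopf (Class II); if it remains stable until it annihilates
    with the saddle, the onset is a saddle-node on invariant circle
    (Class I).
    """

    def field(V, w, I):
        dV = (v_nullcline(params, I, V) - w) / params.C
        dw = (w_nullcline(params, V) - w) / params.tau_w
        return dV, dw

    def fd_jacobian(V, w, I):
        eV = fd_eps * max(1.0, abs(V))
        ew = fd_eps * max(1.0, abs(w))
        f0V, f0w = field(V, w, I)
        fVp = field(V + eV, w, I)
        fwp = field(V, w + ew, I)
        return np.array(
            [
                [(fVp[0] - f0V) / eV, (fwp[0] - f0V) / ew],
                [(fVp[1] - f0w) / eV, (fwp[1] - f0w) / ew],
            ]
        )

    if _lowest_root_bracket(params, 0.0, v_step) is None:
        raise ValueError("no resting point at I = 0; sweep undefined")

    # bracket the saddle-node current by doubling, then bisect
    I_lo, I_hi = 0.0, 100.0
    while _lowest_root_bracket(params, I_hi, v_step) is not None:
        I_hi *= 2.0
        if I_hi > 1e8:
            raise RuntimeError("no saddle-node found below 1e8 pA")
    for _ in range(50):
        mid = 0.5 * (I_lo + I_hi)
        if _lowest_root_bracket(params, mid, v_step) is None:
            I_hi = mid
        else:
            I_lo = mid
    i_sn = I_lo

    # destabilisation can occur arbitrarily close to the fold, so densify the
    # sweep geometrically toward the saddle-node current
    currents = np.concatenate(
        [
            np.linspace(0.0, i_sn, n_currents),
            i_sn * (1.0 - np.logspace(-7, -1.3, 40)),
        ]
    )
    for I in np.sort(currents):
        bracket = _lowest_root_bracket(params, I, v_step)
        if bracket is None:
            continue
        a_v, b_v = bracket
        for _ in range(30):  # bisection refinement of the resting voltage
            m_v = 0.5 * (a_v + b_v)
            if _fp_residual(params, I, a_v) * _fp_residual(params, I, m_v) <= 0:
                b_v = m_v
            else:
                a_v = m_v
        V_star = 0.5 * (a_v + b_v)
        w_star = w_nullcline(params, V_star)
        lam = np.linalg.eigvals(fd_jacobian(V_star, w_star, I))
        if np.prod(lam).real > 0 and np.max(lam.real) > 0:
            return "Class II"
    return "Class I"


def compute_fi_curve(
    params: AdExParameters,
    currents,
    window: StimulusProtocol,
    dt: float = 0.01,
    detection_threshold: float | None = None,
) -> list:
    """Firing frequency (spikes/s) versus step amplitude.

    Each current replaces ``window.step_amplitude``; timing, holding current
    and initial voltage are shared across the sweep, as is ``dt``.  The
    detection threshold defaults to the midpoint of ``V_th`` and ``V_peak``.
    Simulation failures are reported per current with ``freq = nan``.
    """
    currents = list(currents)
    if not currents:
        raise ValueError("currents must be nonempty")
    if detection_threshold is None:
        detection_threshold = 0.5 * (params.V_th + params.V_peak)

    points = []
    for I in currents:
        protocol = StimulusProtocol(
            step_amplitude=float(I),
            stim_delay=window.stim_delay,
            stim_end=window.stim_end,
            duration=window.duration,
            initial_voltage=window.initial_voltage,
            holding_current=window.holding_current,
        )
        try:
            sim = simulate(params, protocol, dt=dt)
        except IntegrationError as exc:
            points.append(FIPoint(current=float(I), freq=math.nan, error=str(exc)))
            continue
        feats = extract_features(
            Trace(sim.times, sim.voltages), protocol, detection_threshold
        )
        points.append(FIPoint(current=float(I), freq=feats.freq))
    return points
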