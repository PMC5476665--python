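"""Single-link inverted pendulum with intermittent active PD control.

The body is a rigid rod of mass ``m`` pivoting at the ankle, its
center of mass at height ``h``.  Gravity destabilises the upright
fixed point; a continuous passive controller (stiffness ``K``,
damping ``B``, muscle tone) and a delayed active controller
(stiffness ``P``, damping ``D``, CNS action, delay ``delta``)
stabilise it.  The active controller is switched ON only in a sector
of the (theta, theta_dot) phase plane described by the slope ``a_s``
(equivalently the level of control ``c_on``) and outside a quiet zone
of radius ``r``.  Gaussian torque noise of intensity ``sigma`` drives
the sway.  The resulting stochastic delay differential equation

    I theta'' = m g h theta - [K theta + B theta' +
                 f_P(theta(t - delta)) + f_D(theta'(t - delta))]
               + sigma xi(t)

is integrated with the Euler-Maruyama scheme; the observable is the
center-of-mass displacement COM(t) = h sin(theta(t)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

G = 9.81
"""Gravitational acceleration (m/s^2)."""

ANKLE_HEIGHT = 0.085
"""Ankle-joint height above the floor (m)."""

DEFAULT_THETA_MAX = 0.5
"""Tilt angle (rad) beyond which a trial is flagged as a fall."""


def derive_com_height(h_sub: float) -> float:
    """Estimate COM height above the ankle from standing height.

    Uses the anthropometric rule h = 0.55 * h_sub - 0.085 m, where the
    constant subtracts the ankle-joint height.

    Parameters
    ----------
    h_sub : float
        Standing height in meters (0.5 < h_sub < 2.5).
    """
    if not 0.5 < h_sub < 2.5:
        raise ValueError(f"standing height {h_sub} m outside plausible range (0.5, 2.5)")
    h = 0.55 * h_sub - ANKLE_HEIGHT
    if h <= 0:
        raise ValueError(f"derived COM height {h} m is non-positive")
    return h


def c_on_to_slope(c_on: float) -> float:
    """Convert level of control to the phase-plane sector slope a_s.

    The level of control is the fraction of the (theta, theta_dot)
    plane where the active controller engages,
    c_on = 0.5 + atan(-a_s)/pi; this inverts that mapping.
    """
    if not 0.0 < c_on < 1.0:
        raise ValueError(f"c_on must lie strictly in (0, 1), got {c_on}")
    return -math.tan(math.pi * (c_on - 0.5))


def slope_to_c_on(a_s: float) -> float:
    """Level of control corresponding to a phase-plane slope a_s."""
    return 0.5 + math.atan(-a_s) / math.pi


@dataclass(frozen=True)
class PendulumPlant:
    """Fixed physical and passive-control quantities of one subject.

    Passive stiffness defaults to 0.8*m*g*h: below the gravitational
    toppling stiffness m*g*h, so passive control alone cannot keep the
    pendulum upright and active control is required.
    """

    m: float
    h: float
    h_sub: float | None = None
    K: float | None = None
    B: float = 4.0
    r: float = 0.004
    g: float = G

    def __post_init__(self):
        if self.m <= 0 or self.h <= 0:
            raise ValueError("mass and COM height must be positive")
        if self.K is None:
            object.__setattr__(self, "K", 0.8 * self.m * self.g * self.h)
        if self.K < 0 or self.B < 0 or self.r < 0:
            raise ValueError("K, B and r must be non-negative")

    @property
    def I(self) -> float:
        """Moment of inertia about the ankle, m*h^2 (point-mass rod)."""
        return self.m * self.h ** 2

    @property
    def mgh(self) -> float:
        return self.m * self.g * self.h

    @classmethod
    def from_anthropometrics(cls, mass_kg: float, height_m: float, **kw) -> "PendulumPlant":
        """Build a plant from body mass and standing height."""
        return cls(m=mass_kg, h=derive_com_height(height_m), h_sub=height_m, **kw)


@dataclass(frozen=True)
class ControlParams:
    """The five inferable control parameters.

    P : active stiffness (Nm/rad)
    D : active damping (Nms/rad)
    delta : feedback delay (s)
    sigma : noise torque intensity (Nm)
    c_on : level of control, fraction of the phase plane with active
        control ON, strictly in (0, 1)
    """

    P: float
    D: float
    delta: float
    sigma: float
    c_on: float

    def __post_init__(self):
        if self.P <= 0 or self.D <= 0:
            raise ValueError("P and D must be positive")
        if self.delta < 0 or self.sigma < 0:
            # zero delay / zero noise are admitted as deterministic and
            # undelayed limits (used by the linear-limit diagnostics)
            raise ValueError("delta and sigma must be non-negative")
        if not 0.0 < self.c_on < 1.0:
            raise ValueError("c_on must lie strictly in (0, 1)")

    @property
    def a_s(self) -> float:
        """Phase-plane sector slope implied by the level of control."""
        return c_on_to_slope(self.c_on)

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.D, self.delta, self.sigma, self.c_on])

    @classmethod
    def from_array(cls, x) -> "ControlParams":
        return cls(P=float(x[0]), D=float(x[1]), delta=float(x[2]),
                   sigma=float(x[3]), c_on=float(x[4]))


@dataclass
class SimState:
    """Retained trajectory of one simulated trial.

    Holds the angle/velocity sample paths, the innovation sequence and
    the transformed coefficients a..e of the first-order system, enough
    to reconstruct every torque term offline.
    """

    theta: np.ndarray
    omega: np.ndarray
    active: np.ndarray  # boolean ON mask per step (delayed-state decision)
    xi: np.ndarray
    dt: float
    k: int
    eta: float
    a: float
    b: float
    c: float
    d: float
    e: float
    fell: bool = False


@dataclass
class SwayTrial:
    """A uniformly sampled COM displacement signal.

    Samples are stored in millimeters (the unit of all downstream sway
    statistics and of trial files).
    """

    samples: np.ndarray  # mm
    fs: float
    state: SimState | None = field(default=None, repr=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def fell(self) -> bool:
        return bool(self.state.fell) if self.state is not None else False


def active_control_on(theta_d: float, omega_d: float, a_s: float, r: float) -> bool:
    """Intermittent switching law, evaluated on the delayed state.

    The controller is ON iff theta_d*(omega_d - a_s*theta_d) > 0 and
    theta_d^2 + omega_d^2 > r^2 (both strict).  The radius is compared
    numerically in the mixed-unit (rad, rad/s) plane.
    """
    return (theta_d * (omega_d - a_s * theta_d) > 0.0
            and theta_d * theta_d + omega_d * omega_d > r * r)


@njit(cache=True)
def _euler_maruyama(n_steps, k, a, b, c, d, e, a_s, r, eta, xi, dt,
                    theta_max, force_mode):
    # force_mode: 0 = intermittent law, 1 = always ON, -1 = always OFF
    theta = np.empty(n_steps)
    omega = np.empty(n_steps)
    active = np.zeros(n_steps, dtype=np.uint8)
    theta[0] = eta
    omega[0] = 0.0
    fell = False
    sqdt = math.sqrt(dt)
    for n in range(n_steps - 1):
        nd = n - k
        th_d = theta[nd] if nd >= 0 else 0.0
        om_d = omega[nd] if nd >= 0 else 0.0
        if force_mode == 1:
            on = True
        elif force_mode == -1:
            on = False
        else:
            on = (th_d * (om_d - a_s * th_d) > 0.0
                  and th_d * th_d + om_d * om_d > r * r)
        if on:
            active[n] = 1
            drift = a * theta[n] + b * omega[n] + c * th_d + d * om_d
        else:
            drift = a * theta[n] + b * omega[n]
        theta[n + 1] = theta[n] + omega[n] * dt
        omega[n + 1] = omega[n] + drift * dt + e * xi[n] * sqdt
        if abs(theta[n + 1]) > theta_max or not math.isfinite(theta[n + 1]):
            fell = True
            # hold the escape value so the returned path stays defined
            for m in range(n + 2, n_steps):
                theta[m] = theta[n + 1]
                omega[m] = omega[n + 1]
            break
    return theta, omega, active, fell


def simulate_sway(
    plant: PendulumPlant,
    params: ControlParams,
    duration: float = 60.0,
    dt: float | None = None,
    seed=None,
    n_trials: int = 1,
    fs: float = 50.0,
    force_active: int = 0,
    eta: float | None = None,
    theta_max: float = DEFAULT_THETA_MAX,
) -> list[SwayTrial]:
    """Simulate COM sway trials by Euler-Maruyama integration.

    Each trial draws its initial tilt eta ~ U(-0.01, 0.01) rad and its
    innovation sequence from a common seeded stream, starts from zero
    pre-history over the delay window, and is flagged ``fell`` (never
    truncated silently) if |theta| exceeds ``theta_max`` at any step.

    Parameters
    ----------
    duration : float
        Trial length in seconds.
    dt : float, optional
        Integration step; defaults to the sampling interval 1/fs.
    seed : int or numpy Generator, optional
        Source of randomness; a fixed seed reproduces trials bitwise.
    n_trials : int
        Number of independent trials from the same stream.
    force_active : int
        0 uses the intermittent switching law; 1 forces the active
        controller permanently ON, -1 permanently OFF (testing hooks).
    eta : float, optional
        Fix the initial tilt instead of drawing it.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt is None:
        dt = 1.0 / fs
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    I = plant.I
    a = (plant.mgh - plant.K) / I
    b = -plant.B / I
    c = -params.P / I
    d = -params.D / I
    e = params.sigma / I
    if params.delta == 0.0:
        k = 0
    else:
        k = max(1, int(round(params.delta / dt)))
    a_s = params.a_s

    n_steps = int(round(duration / dt))
    stride = max(1, int(round((1.0 / fs) / dt)))

    trials = []
    for _ in range(n_trials):
        eta_i = float(rng.uniform(-0.01, 0.01)) if eta is None else float(eta)
        xi = rng.standard_normal(n_steps)
        theta, omega, active, fell = _euler_maruyama(
            n_steps, k, a, b, c, d, e, a_s, plant.r, eta_i, xi, dt,
            theta_max, force_active)
        state = SimState(theta=theta, omega=omega, active=active.astype(bool),
                         xi=xi, dt=dt, k=k, eta=eta_i,
                         a=a, b=b, c=c, d=d, e=e, fell=fell)
        com_mm = plant.h * np.sin(theta[::stride]) * 1000.0
        trials.append(SwayTrial(samples=com_mm, fs=fs, state=state))
    return trials


def torque_components(state: SimState, params: ControlParams, plant: PendulumPlant):
    """Per-step torque terms (Nm) reconstructed from a simulated path.

    Returns a dict with active stiffness f_P = P*theta(t-delta) and
    active damping f_D = D*omega(t-delta) (zero on OFF steps), the
    passive torque K*theta + B*omega, and the gravitational torque
    m*g*h*theta.
    """
    k = state.k
    n = len(state.theta)
    theta_d = np.zeros(n)
    omega_d = np.zeros(n)
    if k == 0:
        theta_d[:] = state.theta
        omega_d[:] = state.omega
    else:
        theta_d[k:] = state.theta[:n - k]
        omega_d[k:] = state.omega[:n - k]
    on = state.active.astype(float)
    f_P = params.P * theta_d * on
    f_D = params.D * omega_d * on
    passive = plant.K * state.theta + plant.B * state.omega
    gravity = plant.mgh * state.theta
    return {"f_P": f_P, "f_D": f_D, "passive": passive, "gravity": gravity,
            "active_mask": state.active}
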