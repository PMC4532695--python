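"""Macrocolumnar Liley model: right-hand side, Jacobian, equilibria, simulation.

Two mean populations (excitatory ``e``, inhibitory ``i``) interact through
critically damped second-order synaptic kinetics.  State ordering (see
:data:`lileychaos.params.STATE_NAMES`)::

    (h_e, h_i, I_ee, J_ee, I_ei, J_ei, I_ie, J_ie, I_ii, J_ii)

with the ten equations (times in ms)::

    tau_e dh_e/dt = (h_e_rest - h_e) + psi_ee(h_e) I_ee + psi_ie(h_e) I_ie
    tau_i dh_i/dt = (h_i_rest - h_i) + psi_ei(h_i) I_ei + psi_ii(h_i) I_ii
    dI_jk/dt = J_jk
    dJ_jk/dt = -2 gamma_jk J_jk - gamma_jk^2 I_jk
               + e Gamma_jk gamma_jk (N_jk S_j(h_j) + p_jk)

for jk in {ee, ei, ie, ii}; the excitatory rate S_e(h_e) drives ee and ei,
the inhibitory rate S_i(h_i) drives ie and ii.  The exp(1) factor normalizes
the synaptic alpha-function impulse response to peak at exactly Gamma_jk
(at time 1/gamma_jk).  The reversal-potential weights are

    psi_ek(h) = (h_e_eq - h) / |h_e_eq - h_k_rest|
    psi_ik(h) = (h_i_eq - h) / |h_i_eq - h_k_rest|

and the population firing rate is the logistic sigmoid

    S_q(h) = S_q_max / (1 + exp(-sqrt(2) (h - mu_q) / sigma_q)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import STATE_NAMES, LileyParameters

__all__ = [
    "sigmoid_rate",
    "synaptic_weight",
    "rhs",
    "jacobian",
    "find_equilibrium",
    "simulate",
    "Trajectory",
    "DivergenceError",
    "DEFAULT_DIVERGENCE_BOUND",
]

#: Any state component exceeding this magnitude marks a run as diverged.
DEFAULT_DIVERGENCE_BOUND = 1e6

_SQRT2 = math.sqrt(2.0)
_E = math.e


class DivergenceError(RuntimeError):
    """Raised when a model evaluation produces non-finite values."""

    def __init__(self, message: str, state: np.ndarray | None = None):
        super().__init__(message)
        self.state = None if state is None else np.asarray(state, float)


def _logistic(x):
    # 1/(1+e^-x) via tanh, stable for large |x|
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def sigmoid_rate(h, pop: str, params: LileyParameters):
    """Mean population firing rate S_q(h) in ms^-1 for ``pop`` in {'e','i'}.

    Strictly increasing in ``h`` with range (0, S_q_max); equals S_q_max/2 at
    the threshold mu_q.
    """
    if pop == "e":
        s_max, mu, sigma = params.S_e_max, params.mu_e, params.sigma_e
    elif pop == "i":
        s_max, mu, sigma = params.S_i_max, params.mu_i, params.sigma_i
    else:
        raise ValueError(f"pop must be 'e' or 'i', got {pop!r}")
    h = np.asarray(h, float)
    if not np.all(np.isfinite(h)):
        raise DivergenceError("non-finite membrane potential in sigmoid_rate", h)
    out = s_max * _logistic(_SQRT2 * (h - mu) / sigma)
    return out if out.ndim else float(out)


def _sigmoid_slope(h, s_max, mu, sigma):
    """dS/dh for the logistic rate function."""
    s = _logistic(_SQRT2 * (np.asarray(h, float) - mu) / sigma)
    return s_max * (_SQRT2 / sigma) * s * (1.0 - s)


def synaptic_weight(h, syn: str, target: str, params: LileyParameters):
    """Reversal-potential weight psi_{syn,target}(h), dimensionless.

    ``syn`` is the synapse type ('e' or 'i'), ``target`` the population whose
    membrane potential ``h`` is supplied.  Positive below the corresponding
    reversal potential, zero at it, negative above.
    """
    if syn == "e":
        h_eq = params.h_e_eq
    elif syn == "i":
        h_eq = params.h_i_eq
    else:
        raise ValueError(f"syn must be 'e' or 'i', got {syn!r}")
    if target == "e":
        h_rest = params.h_e_rest
    elif target == "i":
        h_rest = params.h_i_rest
    else:
        raise ValueError(f"target must be 'e' or 'i', got {target!r}")
    denom = abs(h_eq - h_rest)
    if denom == 0.0:
        raise ValueError("degenerate parameters: reversal potential equals rest")
    h = np.asarray(h, float)
    out = (h_eq - h) / denom
    return out if out.ndim else float(out)


def rhs(y: np.ndarray, params: LileyParameters) -> np.ndarray:
    """Time derivative of the 10-dimensional state (units per ms)."""
    y = np.asarray(y, float)
    if y.shape != (10,):
        raise ValueError(f"state must have shape (10,), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise DivergenceError("non-finite state passed to rhs", y)
    p = params
    h_e, h_i = y[0], y[1]
    I = y[2::2]  # I_ee, I_ei, I_ie, I_ii
    J = y[3::2]

    S_e = sigmoid_rate(h_e, "e", p)
    S_i = sigmoid_rate(h_i, "i", p)

    psi_ee = synaptic_weight(h_e, "e", "e", p)
    psi_ie = synaptic_weight(h_e, "i", "e", p)
    psi_ei = synaptic_weight(h_i, "e", "i", p)
    psi_ii = synaptic_weight(h_i, "i", "i", p)

    dy = np.empty(10)
    dy[0] = (p.h_e_rest - h_e + psi_ee * I[0] + psi_ie * I[2]) / p.tau_e
    dy[1] = (p.h_i_rest - h_i + psi_ei * I[1] + psi_ii * I[3]) / p.tau_i

    drives = (
        p.N_ee * S_e + p.p_ee,
        p.N_ei * S_e + p.p_ei,
        p.N_ie * S_i + p.p_ie,
        p.N_ii * S_i + p.p_ii,
    )
    Gammas = (p.Gamma_ee, p.Gamma_ei, p.Gamma_ie, p.Gamma_ii)
    gammas = (p.gamma_ee, p.gamma_ei, p.gamma_ie, p.gamma_ii)
    for m in range(4):
        g = gammas[m]
        dy[2 + 2 * m] = J[m]
        dy[3 + 2 * m] = -2.0 * g * J[m] - g * g * I[m] + _E * Gammas[m] * g * drives[m]
    if not np.all(np.isfinite(dy)):
        raise DivergenceError("non-finite derivative", y)
    return dy


def jacobian(y: np.ndarray, params: LileyParameters) -> np.ndarray:
    """Exact analytic Jacobian d(rhs)/dy, shape (10, 10), units per ms.

    The eight synaptic rows are state-independent apart from the columns
    entering through S_e(h_e) and S_i(h_i).
    """
    y = np.asarray(y, float)
    if y.shape != (10,):
        raise ValueError(f"state must have shape (10,), got {y.shape}")
    p = params
    h_e, h_i = y[0], y[1]
    I = y[2::2]

    A = np.zeros((10, 10))

    psi_ee = synaptic_weight(h_e, "e", "e", p)
    psi_ie = synaptic_weight(h_e, "i", "e", p)
    psi_ei = synaptic_weight(h_i, "e", "i", p)
    psi_ii = synaptic_weight(h_i, "i", "i", p)
    # d psi/dh = -1/|h_eq - h_rest|
    dpsi_ee = -1.0 / abs(p.h_e_eq - p.h_e_rest)
    dpsi_ie = -1.0 / abs(p.h_i_eq - p.h_e_rest)
    dpsi_ei = -1.0 / abs(p.h_e_eq - p.h_i_rest)
    dpsi_ii = -1.0 / abs(p.h_i_eq - p.h_i_rest)

    A[0, 0] = (-1.0 + dpsi_ee * I[0] + dpsi_ie * I[2]) / p.tau_e
    A[0, 2] = psi_ee / p.tau_e
    A[0, 6] = psi_ie / p.tau_e
    A[1, 1] = (-1.0 + dpsi_ei * I[1] + dpsi_ii * I[3]) / p.tau_i
    A[1, 4] = psi_ei / p.tau_i
    A[1, 8] = psi_ii / p.tau_i

    dS_e = _sigmoid_slope(h_e, p.S_e_max, p.mu_e, p.sigma_e)
    dS_i = _sigmoid_slope(h_i, p.S_i_max, p.mu_i, p.sigma_i)
    Gammas = (p.Gamma_ee, p.Gamma_ei, p.Gamma_ie, p.Gamma_ii)
    gammas = (p.gamma_ee, p.gamma_ei, p.gamma_ie, p.gamma_ii)
    Ns = (p.N_ee, p.N_ei, p.N_ie, p.N_ii)
    src_col = (0, 0, 1, 1)  # h_e drives ee/ei, h_i drives ie/ii
    src_slope = (dS_e, dS_e, dS_i, dS_i)
    for m in range(4):
        g = gammas[m]
        A[2 + 2 * m, 3 + 2 * m] = 1.0
        A[3 + 2 * m, 2 + 2 * m] = -g * g
        A[3 + 2 * m, 3 + 2 * m] = -2.0 * g
        A[3 + 2 * m, src_col[m]] = _E * Gammas[m] * g * Ns[m] * src_slope[m]
    return A


def find_equilibrium(
    params: LileyParameters,
    guess: np.ndarray | None = None,
    tol: float = 1e-12,
) -> np.ndarray:
    """Find a fixed point of the model, ``||rhs||_inf < 1e-10`` guaranteed.

    At equilibrium the synaptic blocks reduce to J_jk = 0 and
    I_jk = e Gamma_jk (N_jk S_j + p_jk) / gamma_jk, so the problem collapses
    to a 2-dimensional root find in (h_e, h_i), solved with a hybrid Powell
    method.
    """
    p = params
    if guess is None:
        guess = p.resting_state
    guess = np.asarray(guess, float)
    if not np.all(np.isfinite(guess)):
        raise ValueError("equilibrium guess must be finite")

    def eq_I(h_e: float, h_i: float) -> np.ndarray:
        S_e = sigmoid_rate(h_e, "e", p)
        S_i = sigmoid_rate(h_i, "i", p)
        drives = np.array(
            [p.N_ee * S_e + p.p_ee, p.N_ei * S_e + p.p_ei,
             p.N_ie * S_i + p.p_ie, p.N_ii * S_i + p.p_ii]
        )
        Gam = np.array([p.Gamma_ee, p.Gamma_ei, p.Gamma_ie, p.Gamma_ii])
        gam = np.array([p.gamma_ee, p.gamma_ei, p.gamma_ie, p.gamma_ii])
        return _E * Gam * drives / gam

    def residual(hh: np.ndarray) -> np.ndarray:
        h_e, h_i = hh
        I = eq_I(h_e, h_i)
        r1 = (p.h_e_rest - h_e
              + synaptic_weight(h_e, "e", "e", p) * I[0]
              + synaptic_weight(h_e, "i", "e", p) * I[2])
        r2 = (p.h_i_rest - h_i
              + synaptic_weight(h_i, "e", "i", p) * I[1]
              + synaptic_weight(h_i, "i", "i", p) * I[3])
        return np.array([r1, r2])

    sol = root(residual, guess[:2], method="hybr", tol=tol)
    h_e, h_i = sol.x
    y = np.zeros(10)
    y[0], y[1] = h_e, h_i
    y[2::2] = eq_I(h_e, h_i)
    res = np.max(np.abs(rhs(y, p)))
    if not sol.success or res >= 1e-10:
        raise RuntimeError(
            f"equilibrium search did not converge (residual {res:.3e} per ms)"
        )
    return y


@dataclass
class Trajectory:
    """Sampled solution of the model with solver provenance."""

    times: np.ndarray  # ms, strictly increasing
    states: np.ndarray  # (len(times), 10)
    params: LileyParameters
    method: str
    rtol: float
    atol: float
    diverged: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.diverged and not np.all(np.isfinite(self.states)):
            raise ValueError("non-finite states without divergence flag")

    def to_csv(self, path) -> None:
        header = "t_ms," + ",".join(STATE_NAMES)
        data = np.column_stack([self.times, self.states])
        np.savetxt(path, data, delimiter=",", header=header, comments="")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def simulate(
    params: LileyParameters,
    y0: np.ndarray,
    t_span: tuple[float, float] | float,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    divergence_bound: float = DEFAULT_DIVERGENCE_BOUND,
) -> Trajectory:
    """Integrate the model with an adaptive (stiffness-capable) solver.

    ``t_span`` may be a (t0, t1) pair or a single duration in ms.  A state
    component exceeding ``divergence_bound`` in magnitude terminates the run
    and flags the returned (partial) trajectory as diverged instead of
    propagating NaNs.
    """
    if np.isscalar(t_span):
        t_span = (0.0, float(t_span))
    if not t_span[1] > t_span[0]:
        raise ValueError("t_span must have positive duration")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    y0 = np.asarray(y0, float)

    def f(t, y):
        return rhs(y, params)

    def jac(t, y):
        return jacobian(y, params)

    def blowup(t, y):
        return divergence_bound - np.max(np.abs(y))

    blowup.terminal = True
    blowup.direction = -1

    kwargs = dict(method=method, rtol=rtol, atol=atol, events=blowup, dense_output=False)
    if method in ("LSODA", "BDF", "Radau"):
        kwargs["jac"] = jac
    sol = solve_ivp(f, t_span, y0, t_eval=t_eval, **kwargs)
    diverged = bool(sol.status == 1)  # terminated by the blow-up event
    if sol.status < 0:
        raise RuntimeError(f"solver failure: {sol.message}")
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        params=params,
        method=method,
        rtol=rtol,
        atol=atol,
        diverged=diverged,
        meta={"solver_message": sol.message, "nfev": int(sol.nfev)},
    )
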