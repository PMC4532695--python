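"""Benchmark dynamical systems with known Lyapunov structure.

These synthetic systems exercise every stage of the spectrum/classification
pipeline against analytic truth (diagonal linear flow, Hopf normal form) or
against internal consistency oracles (Lorenz-63: cross-method agreement and
the trace identity), independently of any physiological parameter set.

The benchmarks deliberately use the same unit convention as the cortical
model — time in ms, rates per ms, reported exponents per second — so the
unit-conversion path is exercised too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

__all__ = ["BenchmarkSystem", "diagonal_linear", "hopf_normal_form", "lorenz63", "get_benchmark"]


@dataclass(frozen=True)
class BenchmarkSystem:
    """A named ODE system usable by both Lyapunov backends.

    ``known_spectrum`` (s^-1, sorted descending, possibly partial) is only
    present when an analytic value exists; its provenance is recorded in
    ``spectrum_note``.
    """

    name: str
    n: int
    sys_id: int
    p: np.ndarray
    y0: np.ndarray
    dt: float  # suggested RK4 step, ms
    t_transient: float  # ms
    t_run: float  # ms
    known_spectrum: tuple[float, ...] | None = None
    spectrum_note: str = ""

    def __post_init__(self):
        if self.known_spectrum is not None:
            ks = self.known_spectrum
            if len(ks) > self.n or any(b > a for a, b in zip(ks, ks[1:])):
                raise ValueError("known_spectrum must be sorted descending, length <= n")

    def rhs(self, y: np.ndarray) -> np.ndarray:
        out = np.empty(self.n)
        K.sys_rhs(self.sys_id, np.asarray(y, float), self.p, out)
        return out

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        A = np.empty((self.n, self.n))
        K.sys_jac(self.sys_id, np.asarray(y, float), self.p, A)
        return A


def diagonal_linear(rates) -> BenchmarkSystem:
    """Uncoupled linear flow dx_i/dt = a_i x_i (rates in ms^-1).

    The Lyapunov spectrum is exactly the sorted rates; tangent dynamics with
    the standard basis gives instantaneous expansion rates a_i with no
    transient at all.
    """
    rates = np.asarray(rates, float)
    spectrum = tuple(sorted((rates * 1000.0).tolist(), reverse=True))
    return BenchmarkSystem(
        name="diagonal",
        n=len(rates),
        sys_id=K.SYS_DIAG,
        p=rates.copy(),
        y0=np.ones(len(rates)),
        dt=0.01,
        t_transient=0.0,
        t_run=200.0,
        known_spectrum=spectrum,
        spectrum_note="exact: eigenvalues of a constant diagonal Jacobian",
    )


def hopf_normal_form(mu: float = 1.0, omega: float = 1.0) -> BenchmarkSystem:
    """Supercritical Hopf normal form in Cartesian coordinates (rates per ms).

    dr/dt = mu r - r^3, dtheta/dt = omega.  For mu > 0 the attractor is the
    circle r = sqrt(mu) with exponents exactly (0, -2 mu).
    """
    if mu <= 0:
        raise ValueError("mu must be positive for a limit-cycle attractor")
    return BenchmarkSystem(
        name="hopf",
        n=2,
        sys_id=K.SYS_HOPF,
        p=np.array([mu, omega], float),
        y0=np.array([0.1, 0.0]),
        dt=0.01,
        t_transient=50.0 / mu,
        t_run=2000.0,
        known_spectrum=(0.0, -2.0 * mu * 1000.0),
        spectrum_note="exact: radial linearization on the limit cycle",
    )


def lorenz63(sigma: float = 10.0, rho: float = 28.0, beta: float = 8.0 / 3.0) -> BenchmarkSystem:
    """Lorenz-63 in chaotic regime; rates per ms under this package's units.

    No external spectrum is asserted; it serves the cross-method agreement
    and trace-identity oracles.  Its Jacobian trace is constant,
    -(sigma + 1 + beta), so the full spectrum must sum to that exactly.
    """
    return BenchmarkSystem(
        name="lorenz63",
        n=3,
        sys_id=K.SYS_LORENZ,
        p=np.array([sigma, rho, beta], float),
        y0=np.array([1.0, 1.0, 1.0]),
        dt=0.002,
        t_transient=50.0,
        t_run=2000.0,
        known_spectrum=None,
        spectrum_note="chaotic oracle; used for cross-method and trace-identity checks",
    )


_FACTORIES = {
    "diagonal": diagonal_linear,
    "hopf": hopf_normal_form,
    "lorenz63": lorenz63,
}


def get_benchmark(name: str, **kwargs) -> BenchmarkSystem:
    """Construct a benchmark by name ('diagonal' needs rates=...)."""
    if name not in _FACTORIES:
        raise KeyError(f"unknown benchmark {name!r}; choose from {sorted(_FACTORIES)}")
    if name == "diagonal" and "rates" not in kwargs:
        kwargs["rates"] = (-1.0, -2.0, -3.0)
    return _FACTORIES[name](**kwargs)
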