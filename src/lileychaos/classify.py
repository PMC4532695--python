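"""Attractor taxonomy from a Lyapunov spectrum.

Given ordered exponents lambda_1 >= lambda_2 >= ... (s^-1, base e):

* topological dimension D: largest integer with lambda_1 + ... + lambda_D >= 0
  (0 for an all-negative spectrum — a point attractor); the attractor needs at
  least D + 1 integer dimensions to exist in.
* Kaplan-Yorke dimension D_KY = D + (sum_{i<=D} lambda_i) / |lambda_{D+1}|.
* four-dimensional chaos (FDC): a single positive exponent
  (lambda_1 >= chaos threshold, lambda_2 = 0 within tolerance) with
  lambda_1 > |lambda_3|.  Then lambda_1+lambda_2+lambda_3 > 0 and the sum
  through lambda_4 is negative, so D >= 3, the attractor needs at least four
  dimensions, and D_KY > 3 — all decidable from the top three exponents alone.
  Distinct from hyperchaos, which has two or more positive exponents.

The chaos threshold (default 1 s^-1) guards against exponents that converge
slowly to zero on periodic orbits; the zero tolerance (default 0.5 s^-1) is
the band within which an exponent is accepted as the flow's zero exponent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttractorClassification",
    "topological_dimension",
    "kaplan_yorke",
    "classify",
    "DEFAULT_CHAOS_THRESHOLD",
    "DEFAULT_ZERO_TOL",
]

DEFAULT_CHAOS_THRESHOLD = 1.0  # s^-1, base e
DEFAULT_ZERO_TOL = 0.5  # s^-1


def _validated(lambdas) -> np.ndarray:
    lam = np.asarray(lambdas, float)
    if lam.ndim != 1 or lam.size == 0:
        raise ValueError("need a non-empty 1-d sequence of exponents")
    if np.any(np.diff(lam) > 1e-9):
        raise ValueError("exponents must be sorted descending")
    return lam


def topological_dimension(lambdas) -> int:
    """Largest D with a non-negative partial sum of the ordered exponents."""
    lam = _validated(lambdas)
    sums = np.cumsum(lam)
    nonneg = np.nonzero(sums >= 0.0)[0]
    return 0 if len(nonneg) == 0 else int(nonneg[-1]) + 1


def kaplan_yorke(lambdas) -> float:
    """Kaplan-Yorke (Lyapunov) dimension D + (sum_{i<=D} lambda_i)/|lambda_{D+1}|.

    Returns 0.0 for an all-negative spectrum (point attractor).  Raises
    ``ValueError`` if the supplied exponents are insufficient: either fewer
    than D+1 of them, or a non-negative total sum (no converged dissipation,
    the dimension is undefined).
    """
    lam = _validated(lambdas)
    D = topological_dimension(lam)
    if D == 0:
        return 0.0
    if D >= len(lam):
        raise ValueError(
            f"need at least D+1={D + 1} exponents to place the dimension, got {len(lam)}"
        )
    # lambda_{D+1} < 0 by construction of D (partial sum turns negative at D+1)
    return float(D + lam[:D].sum() / abs(lam[D]))


@dataclass(frozen=True)
class AttractorClassification:
    """Label plus dimensions for one spectrum, with the thresholds used."""

    label: str  # point | periodic | chaotic | chaotic_4d
    D: int
    D_KY: float | None  # None when undefined from the supplied exponents
    hyperchaos_flag: bool
    chaos_threshold: float
    zero_tol: float

    def __post_init__(self):
        if self.label not in ("point", "periodic", "chaotic", "chaotic_4d"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.D_KY is not None and self.D_KY < self.D - 1e-12:
            raise ValueError("D_KY must be >= D when defined")


def classify(
    lambdas,
    chaos_threshold: float = DEFAULT_CHAOS_THRESHOLD,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> AttractorClassification:
    """Classify an attractor from its leading Lyapunov exponents (s^-1).

    * ``point``: lambda_1 < -zero_tol.
    * ``periodic``: |lambda_1| <= zero_tol, or lambda_1 in the indeterminate
      band below the chaos threshold (the raw exponents are retained by the
      caller, so relabeling is lossless).
    * ``chaotic``: lambda_1 >= chaos_threshold (needs >= 3 exponents).
    * ``chaotic_4d``: chaotic with the zero exponent present
      (|lambda_2| <= zero_tol) and lambda_1 > |lambda_3|.

    ``hyperchaos_flag`` marks lambda_2 > zero_tol (two positive exponents) —
    diagnostic only, the label stays ``chaotic``.
    """
    lam = _validated(lambdas)
    if zero_tol < 0 or chaos_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lam1 = lam[0]

    if lam1 < -zero_tol:
        label = "point"
        hyper = False
    elif lam1 < chaos_threshold:
        label = "periodic"
        hyper = False
    else:
        if len(lam) < 3:
            raise ValueError("need at least 3 exponents to test four-dimensional chaos")
        hyper = bool(lam[1] > zero_tol)
        if abs(lam[1]) <= zero_tol and lam1 > abs(lam[2]):
            label = "chaotic_4d"
        else:
            label = "chaotic"

    D = topological_dimension(lam)
    try:
        dky = kaplan_yorke(lam)
    except ValueError:
        dky = None
    return AttractorClassification(
        label=label,
        D=D,
        D_KY=dky,
        hyperchaos_flag=hyper,
        chaos_threshold=chaos_threshold,
        zero_tol=zero_tol,
    )
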