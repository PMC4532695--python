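"""Physiological parameterization of the macrocolumnar Liley model.

The model describes two interacting mean neural populations (excitatory ``e``
and inhibitory ``i``) of a cortical macrocolumn.  Synaptic connections are
indexed ``jk`` = source ``j`` onto target ``k``, so ``ie`` means "inhibitory
onto excitatory".  All times are in milliseconds, potentials in millivolts,
rates in ms^-1; Lyapunov exponents elsewhere in the package are reported in
s^-1 (base e).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "LileyParameters",
    "STATE_NAMES",
    "load_parameters",
    "save_parameters",
    "load_fixture",
    "list_fixtures",
]

#: Fixed component ordering of the 10-dimensional state vector, used
#: everywhere including the tangent dynamics.  ``h`` are mean soma membrane
#: potentials (mV); ``I_jk`` are postsynaptic activations (mV) and
#: ``J_jk = dI_jk/dt`` their rates (mV/ms).
STATE_NAMES = (
    "h_e", "h_i",
    "I_ee", "J_ee", "I_ei", "J_ei",
    "I_ie", "J_ie", "I_ii", "J_ii",
)

_SYNAPSES = ("ee", "ei", "ie", "ii")

# TOML schema: table -> keys (exact field names).
_TOML_SCHEMA = {
    "membrane": ("h_e_rest", "h_i_rest", "h_e_eq", "h_i_eq", "tau_e", "tau_i"),
    "synaptic": tuple(f"Gamma_{s}" for s in _SYNAPSES)
    + tuple(f"gamma_{s}" for s in _SYNAPSES),
    "sigmoid": ("S_e_max", "S_i_max", "mu_e", "mu_i", "sigma_e", "sigma_i"),
    "connectivity": tuple(f"N_{s}" for s in _SYNAPSES),
    "inputs": tuple(f"p_{s}" for s in _SYNAPSES),
}


@dataclass(frozen=True)
class LileyParameters:
    """Full physiological parameter set of the macrocolumnar model.

    Attributes
    ----------
    h_e_rest, h_i_rest :
        Resting mean soma membrane potentials (mV).
    h_e_eq, h_i_eq :
        Excitatory / inhibitory synaptic reversal potentials (mV).  The
        excitatory reversal must lie above both resting potentials and the
        inhibitory reversal below both (enforced).
    tau_e, tau_i :
        Passive membrane time constants (ms).
    Gamma_ee, Gamma_ei, Gamma_ie, Gamma_ii :
        Peak postsynaptic-potential amplitudes (mV); the synaptic impulse
        response is an alpha function normalized to peak at exactly Gamma.
    gamma_ee, gamma_ei, gamma_ie, gamma_ii :
        PSP rate constants (ms^-1); double pole of the critically damped
        second-order synaptic kinetics.
    N_ee, N_ei, N_ie, N_ii :
        Mean intracortical synaptic connection counts (dimensionless).
    S_e_max, S_i_max :
        Maximal mean population firing rates (ms^-1).
    mu_e, mu_i :
        Population firing thresholds (mV).
    sigma_e, sigma_i :
        Threshold spreads (mV).
    p_ee, p_ei, p_ie, p_ii :
        Extracortical (thalamic) input pulse densities (ms^-1).  ``p_ee`` and
        ``p_ei`` are the inputs swept when mapping chaos over the thalamic
        input plane; ``p_ie`` and ``p_ii`` default to zero.
    """

    h_e_rest: float
    h_i_rest: float
    h_e_eq: float
    h_i_eq: float
    tau_e: float
    tau_i: float
    Gamma_ee: float
    Gamma_ei: float
    Gamma_ie: float
    Gamma_ii: float
    gamma_ee: float
    gamma_ei: float
    gamma_ie: float
    gamma_ii: float
    N_ee: float
    N_ei: float
    N_ie: float
    N_ii: float
    S_e_max: float
    S_i_max: float
    mu_e: float
    mu_i: float
    sigma_e: float
    sigma_i: float
    p_ee: float = 0.0
    p_ei: float = 0.0
    p_ie: float = 0.0
    p_ii: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "tau_e", "tau_i", "S_e_max", "S_i_max", "sigma_e", "sigma_i",
            *(f"gamma_{s}" for s in _SYNAPSES),
            *(f"Gamma_{s}" for s in _SYNAPSES),
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in (*(f"N_{s}" for s in _SYNAPSES), *(f"p_{s}" for s in _SYNAPSES)):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.h_e_eq > self.h_e_rest and self.h_e_eq > self.h_i_rest):
            raise ValueError("excitatory reversal h_e_eq must exceed both resting potentials")
        if not (self.h_i_eq < self.h_e_rest and self.h_i_eq < self.h_i_rest):
            raise ValueError("inhibitory reversal h_i_eq must lie below both resting potentials")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")

    def replace(self, **changes: float) -> "LileyParameters":
        """Return a copy with the given fields changed (invariants re-checked)."""
        return dataclasses.replace(self, **changes)

    def to_array(self) -> np.ndarray:
        """Pack into the flat float64 layout used by the compiled kernels."""
        return np.array(
            [
                self.h_e_rest, self.h_i_rest, self.h_e_eq, self.h_i_eq,
                self.tau_e, self.tau_i,
                self.Gamma_ee, self.Gamma_ei, self.Gamma_ie, self.Gamma_ii,
                self.gamma_ee, self.gamma_ei, self.gamma_ie, self.gamma_ii,
                self.N_ee, self.N_ei, self.N_ie, self.N_ii,
                self.S_e_max, self.S_i_max, self.mu_e, self.mu_i,
                self.sigma_e, self.sigma_i,
                self.p_ee, self.p_ei, self.p_ie, self.p_ii,
            ],
            dtype=np.float64,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable sha256 over the canonical JSON of the parameter values."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @property
    def resting_state(self) -> np.ndarray:
        """State (h_e_rest, h_i_rest, 0, ..., 0) — the decoupled equilibrium."""
        y = np.zeros(10)
        y[0], y[1] = self.h_e_rest, self.h_i_rest
        return y


def load_parameters(path: str | Path) -> LileyParameters:
    """Read a parameter set from a TOML file.

    The file must contain exactly the tables ``membrane``, ``synaptic``,
    ``sigmoid``, ``connectivity`` and ``inputs`` with keys named after the
    :class:`LileyParameters` fields; unknown tables or keys raise
    ``ValueError``.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    values: dict[str, float] = {}
    known_tables = set(_TOML_SCHEMA)
    for table, entries in doc.items():
        if table not in known_tables:
            raise ValueError(f"unknown table [{table}] in {path}")
        if not isinstance(entries, dict):
            raise ValueError(f"[{table}] must be a table of keys")
        allowed = set(_TOML_SCHEMA[table])
        for key, val in entries.items():
            if key not in allowed:
                raise ValueError(f"unknown key {key!r} in table [{table}] of {path}")
            values[key] = float(val)
    missing = {k for keys in _TOML_SCHEMA.values() for k in keys} - set(values)
    # inputs may be omitted (default 0)
    missing -= set(_TOML_SCHEMA["inputs"])
    if missing:
        raise ValueError(f"missing parameter keys: {sorted(missing)}")
    return LileyParameters(**values)


def save_parameters(params: LileyParameters, path: str | Path) -> None:
    """Write a parameter set as TOML, one table per parameter group."""
    lines: list[str] = []
    for table, keys in _TOML_SCHEMA.items():
        lines.append(f"[{table}]")
        for key in keys:
            lines.append(f"{key} = {getattr(params, key)!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def list_fixtures() -> list[str]:
    """Names of the parameter fixtures shipped with the package."""
    pkg = resources.files("lileychaos") / "fixtures"
    return sorted(p.name[: -len(".toml")] for p in pkg.iterdir() if p.name.endswith(".toml"))


def load_fixture(name: str) -> LileyParameters:
    """Load a named parameter fixture shipped with the package.

    ``standard`` is the standard physiological parameterization of the
    macrocolumnar model family, with the thalamic inputs set at the
    four-dimensional-chaos reference point; see the fixture file's header for
    its transcription status.  ``demo`` is a clearly labeled plausible set
    that satisfies all invariants but is not a literature transcription.
    """
    if name.endswith(".toml") or "/" in name or "\\" in name:
        return load_parameters(name)
    pkg = resources.files("lileychaos") / "fixtures" / f"{name}.toml"
    if not pkg.is_file():
        raise FileNotFoundError(
            f"no fixture named {name!r}; available: {list_fixtures()}"
        )
    with resources.as_file(pkg) as path:
        return load_parameters(path)
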