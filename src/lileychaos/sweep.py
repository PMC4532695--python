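"""Random sweep of the thalamic-input plane (p_ee, p_ei).

Each sampled input pair gets an independent, reproducible spectrum run: the
per-point seed is derived from the sweep seed and the point index through
``numpy.random.SeedSequence((sweep_seed, index))``, so results are identical
whether points are computed serially, in parallel, or resumed from a
checkpoint.  Per-point records carry the three leading exponents and the
attractor classification; the summary reports the fraction of clearly
chaotic points (LLE >= 1 s^-1) and the fraction of those exhibiting
four-dimensional chaos, each with a Wilson 95% binomial interval so that
scaled-down sweeps can be compared against fractions measured on much larger
samples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import __version__
from .classify import (
    DEFAULT_CHAOS_THRESHOLD,
    DEFAULT_ZERO_TOL,
    AttractorClassification,
    classify,
)
from .params import LileyParameters, load_fixture
from .tangent import compute_spectrum

__all__ = ["SweepSpec", "SweepPoint", "SweepSummary", "SweepResult",
           "sample_plane", "run_sweep", "summarize", "point_seed"]

CSV_HEADER = "idx,p_ee,p_ei,seed,lambda1,lambda2,lambda3,label,D,D_KY,diverged,t_run_ms"


@dataclass(frozen=True)
class SweepSpec:
    """Specification of a random rectangle sweep.

    Ranges are open at the lower bound and closed at the upper bound, in
    ms^-1; defaults cover the biologically relevant thalamic-input rectangle
    0 < p_ee <= 30, 0 < p_ei <= 10.
    """

    n_points: int
    seed: int
    p_ee_range: tuple[float, float] = (0.0, 30.0)
    p_ei_range: tuple[float, float] = (0.0, 10.0)
    k: int = 3
    fixture: str = "standard"
    t_transient: float = 10_000.0
    t_run: float = 100_000.0
    dt: float | None = None
    method: str = "continuous"
    chaos_threshold: float = DEFAULT_CHAOS_THRESHOLD
    zero_tol: float = DEFAULT_ZERO_TOL

    def __post_init__(self):
        if self.n_points < 0:
            raise ValueError("n_points must be >= 0")
        for lo, hi in (self.p_ee_range, self.p_ei_range):
            if not (0 <= lo < hi):
                raise ValueError("ranges must be ordered and non-negative")
        if self.k < 3:
            raise ValueError("k >= 3 required to decide four-dimensional chaos")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SweepPoint:
    """One evaluated input pair."""

    idx: int
    p_ee: float
    p_ei: float
    seed: int
    exponents: np.ndarray  # s^-1, sorted descending
    classification: AttractorClassification | None
    diverged: bool
    t_run: float

    def csv_row(self) -> str:
        lam = [repr(float(v)) for v in np.asarray(self.exponents, float)[:3]]
        while len(lam) < 3:
            lam.append("nan")
        c = self.classification
        label = c.label if c is not None else "diverged"
        D = str(c.D) if c is not None else ""
        dky = "" if (c is None or c.D_KY is None) else repr(float(c.D_KY))
        return ",".join(
            [str(self.idx), repr(float(self.p_ee)), repr(float(self.p_ei)),
             str(self.seed), *lam, label, D, dky, str(int(self.diverged)),
             repr(float(self.t_run))]
        )


@dataclass
class SweepSummary:
    n_total: int
    n_diverged: int
    n_chaotic: int
    n_fdc: int
    frac_chaotic: float | None
    frac_fdc_of_chaotic: float | None
    frac_fdc_of_total: float | None
    ci_chaotic: tuple[float, float] | None
    ci_fdc_of_chaotic: tuple[float, float] | None
    ci_fdc_of_total: tuple[float, float] | None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SweepResult:
    spec: SweepSpec
    points: list[SweepPoint]
    summary: SweepSummary

    def to_csv(self, path) -> None:
        lines = [
            f"# lileychaos {__version__} config={self.spec.config_hash()}",
            CSV_HEADER,
            *(pt.csv_row() for pt in self.points),
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def summary_json(self, path=None) -> str:
        doc = {
            "package_version": __version__,
            "config_hash": self.spec.config_hash(),
            "spec": self.spec.to_dict(),
            "summary": self.summary.to_dict(),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def sample_plane(spec: SweepSpec) -> np.ndarray:
    """Sample n_points i.i.d. uniform pairs from the open-closed rectangle.

    Deterministic given the sweep seed.  Draws on (lo, hi] by reflecting the
    half-open uniform [lo, hi) draw, so the open lower bound of the spec is
    honored exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xA11CE)))
    out = np.empty((spec.n_points, 2))
    for col, (lo, hi) in enumerate((spec.p_ee_range, spec.p_ei_range)):
        u = rng.uniform(lo, hi, size=spec.n_points)  # [lo, hi)
        out[:, col] = hi + lo - u  # (lo, hi]
    return out


def point_seed(sweep_seed: int, idx: int) -> int:
    """Stable per-point seed: first word of SeedSequence((sweep_seed, idx))."""
    return int(np.random.SeedSequence((sweep_seed, idx)).generate_state(1)[0])


def evaluate_point(
    base: LileyParameters, spec: SweepSpec, idx: int, p_ee: float, p_ei: float
) -> SweepPoint:
    """Evaluate one input pair: spectrum plus classification."""
    params = base.replace(p_ee=float(p_ee), p_ei=float(p_ei))
    seed = point_seed(spec.seed, idx)
    res = compute_spectrum(
        params,
        k=spec.k,
        t_transient=spec.t_transient,
        t_run=spec.t_run,
        seed=seed,
        method=spec.method,
        dt=spec.dt,
    )
    cls = None
    if not res.diverged:
        cls = classify(res.exponents, spec.chaos_threshold, spec.zero_tol)
    return SweepPoint(
        idx=idx,
        p_ee=float(p_ee),
        p_ei=float(p_ei),
        seed=seed,
        exponents=res.exponents,
        classification=cls,
        diverged=res.diverged,
        t_run=res.t_run,
    )


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def summarize(points: list[SweepPoint]) -> SweepSummary:
    """Counts, fractions and Wilson 95% intervals over the valid points.

    Diverged points are excluded from every denominator; a zero denominator
    leaves the corresponding fraction (and interval) undefined rather than 0.
    """
    if not points:
        raise ValueError("cannot summarize an empty sweep")
    n_div = sum(pt.diverged for pt in points)
    valid = [pt for pt in points if not pt.diverged]
    if not valid:
        raise ValueError("all points diverged; nothing to summarize")
    n_valid = len(valid)
    n_chaotic = sum(pt.classification.label in ("chaotic", "chaotic_4d") for pt in valid)
    n_fdc = sum(pt.classification.label == "chaotic_4d" for pt in valid)

    frac_chaotic = n_chaotic / n_valid
    ci_chaotic = _wilson(n_chaotic, n_valid)
    if n_chaotic > 0:
        frac_fc = n_fdc / n_chaotic
        ci_fc = _wilson(n_fdc, n_chaotic)
    else:
        frac_fc, ci_fc = None, None
    frac_ft = n_fdc / n_valid
    ci_ft = _wilson(n_fdc, n_valid)
    return SweepSummary(
        n_total=n_valid,
        n_diverged=n_div,
        n_chaotic=n_chaotic,
        n_fdc=n_fdc,
        frac_chaotic=frac_chaotic,
        frac_fdc_of_chaotic=frac_fc,
        frac_fdc_of_total=frac_ft,
        ci_chaotic=ci_chaotic,
        ci_fdc_of_chaotic=ci_fc,
        ci_fdc_of_total=ci_ft,
    )


def _read_checkpoint(path: Path) -> dict[int, str]:
    done: dict[int, str] = {}
    if path.exists():
        for line in path.read_text().splitlines():
            if not line or line.startswith("#") or line.startswith("idx,"):
                continue
            idx = int(line.split(",", 1)[0])
            done[idx] = line
    return done


def run_sweep(
    spec: SweepSpec,
    base: LileyParameters | None = None,
    checkpoint: str | Path | None = None,
    n_jobs: int = 1,
    progress: bool = False,
) -> SweepResult:
    """Run the full sweep, optionally resuming from an append-only checkpoint.

    The checkpoint file accumulates finished per-point CSV rows; rerunning
    with the same spec skips completed indices and reproduces the remaining
    points bit-for-bit, so a killed sweep can be resumed with identical
    results.  Points are independent; ``n_jobs > 1`` distributes them with
    joblib without changing any output.
    """
    if base is None:
        base = load_fixture(spec.fixture)  # fail before any computation if missing
    pairs = sample_plane(spec)

    done: dict[int, str] = {}
    ckpt_path = Path(checkpoint) if checkpoint is not None else None
    if ckpt_path is not None:
        done = _read_checkpoint(ckpt_path)

    todo = [i for i in range(spec.n_points) if i not in done]
    if n_jobs != 1 and len(todo) > 1:
        from joblib import Parallel, delayed

        computed = Parallel(n_jobs=n_jobs)(
            delayed(evaluate_point)(base, spec, i, pairs[i, 0], pairs[i, 1])
            for i in todo
        )
        new_points = dict(zip(todo, computed))
    else:
        new_points = {}
        for i in todo:
            new_points[i] = evaluate_point(base, spec, i, pairs[i, 0], pairs[i, 1])
            if progress:
                print(f"[sweep] point {i + 1}/{spec.n_points} done", flush=True)
            if ckpt_path is not None:
                with open(ckpt_path, "a") as fh:
                    fh.write(new_points[i].csv_row() + "\n")

    points: list[SweepPoint] = []
    for i in range(spec.n_points):
        if i in new_points:
            points.append(new_points[i])
        else:
            points.append(_point_from_row(done[i]))
    if ckpt_path is not None and n_jobs != 1:
        # parallel path: write rows after the fact to keep the file complete
        with open(ckpt_path, "a") as fh:
            for i in todo:
                fh.write(new_points[i].csv_row() + "\n")
    return SweepResult(spec=spec, points=points, summary=summarize(points))


def load_results_csv(path: str | Path) -> SweepResult:
    """Rebuild a SweepResult from a per-point results CSV (e.g. for plotting).

    The sweep spec is reconstructed minimally (point count and default
    thresholds); per-point values are exact.
    """
    rows = [
        line
        for line in Path(path).read_text().splitlines()
        if line and not line.startswith("#") and not line.startswith("idx,")
    ]
    if not rows:
        raise ValueError(f"no data rows in {path}")
    points = [_point_from_row(r) for r in rows]
    spec = SweepSpec(n_points=len(points), seed=0)
    return SweepResult(spec=spec, points=points, summary=summarize(points))


def _point_from_row(row: str) -> SweepPoint:
    cols = row.split(",")
    (idx, p_ee, p_ei, seed, l1, l2, l3, label, D, dky, div, t_run) = cols
    diverged = bool(int(div))
    lam = np.array([float(l1), float(l2), float(l3)])
    cls = None
    if not diverged:
        cls = AttractorClassification(
            label=label,
            D=int(D),
            D_KY=float(dky) if dky else None,
            hyperchaos_flag=False,
            chaos_threshold=DEFAULT_CHAOS_THRESHOLD,
            zero_tol=DEFAULT_ZERO_TOL,
        )
    return SweepPoint(
        idx=int(idx), p_ee=float(p_ee), p_ei=float(p_ei), seed=int(seed),
        exponents=lam, classification=cls, diverged=diverged, t_run=float(t_run),
    )
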