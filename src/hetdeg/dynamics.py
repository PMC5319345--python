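"""Chaotic-system simulators producing scalar time series.

Flows (Lorenz, Rössler, Duffing, Ueda) are integrated with fixed-step
fourth-order Runge–Kutta (step 0.01) and sampled stroboscopically every
0.05 time units; maps (Hénon, Lozi, Arnold cat) are iterated directly with
unit sampling interval.  The first 10 000 samples are discarded as
transient.  Parameter defaults are the canonical chaotic regimes:

=========  ============================================================
Lorenz     sigma=10, r=28, b=8/3; observable x
Rössler    a=0.2, b=0.2, c=5.7; observable x
Duffing    two-well driven: x'' = x - x^3 - 0.25 x' + 0.3 cos t
Ueda       x'' = -x^3 - 0.05 x' + 7.5 cos t
Hénon      a=1.4, b=0.3
Lozi       a=1.7, b=0.5
cat        (x, y) -> (x + y, x + 2y) mod 1 on the unit torus
=========  ============================================================

Every system's default initial condition is perturbed deterministically by
the seed, which is how independent realizations ("different initial
conditions") are produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "SystemSpec",
    "SYSTEMS",
    "FLOWS",
    "MAPS",
    "simulate",
    "add_noise",
    "gaussian_series",
]

DEFAULT_TRANSIENT = 10_000
_DIVERGENCE_LIMIT = 1e6


@dataclass(frozen=True)
class TimeSeries:
    """Scalar observable of one system realization.

    ``dt`` is the sampling interval (0.05 for flows, 1 for maps and for
    generic sample-indexed series such as white noise).
    """

    values: np.ndarray
    dt: float
    system: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite samples in series from {self.system!r}")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SystemSpec:
    name: str
    kind: str  # "flow" | "map"
    func: Callable  # rhs(t, state, params) for flows; map(state, params) for maps
    params: dict
    default_ic: tuple
    observable: int = 0
    dt: float = 0.05  # stroboscopic sampling interval (flows)
    step: float = 0.01  # RK4 integrator step (flows)
    ic_scale: float = 0.01  # amplitude of the seed perturbation of the IC


def _lorenz(t, s, p):
    x, y, z = s
    return (p["sigma"] * (y - x), x * (p["r"] - z) - y, x * y - p["b"] * z)


def _rossler(t, s, p):
    x, y, z = s
    return (-y - z, x + p["a"] * y, p["b"] + z * (x - p["c"]))


def _duffing(t, s, p):
    x, v, = s
    return (v, x - x**3 - p["delta"] * v + p["f"] * math.cos(t))


def _ueda(t, s, p):
    x, v = s
    return (v, -(x**3) - p["delta"] * v + p["f"] * math.cos(t))


def _henon(s, p):
    x, y = s
    return (1.0 - p["a"] * x * x + y, p["b"] * x)


def _lozi(s, p):
    x, y = s
    return (1.0 - p["a"] * abs(x) + y, p["b"] * x)


def _cat(s, p):
    x, y = s
    return ((x + y) % 1.0, (x + 2.0 * y) % 1.0)


SYSTEMS: dict[str, SystemSpec] = {
    "lorenz": SystemSpec("lorenz", "flow", _lorenz,
                         {"sigma": 10.0, "r": 28.0, "b": 8.0 / 3.0}, (1.0, 1.0, 20.0)),
    "rossler": SystemSpec("rossler", "flow", _rossler,
                          {"a": 0.2, "b": 0.2, "c": 5.7}, (1.0, 1.0, 0.0)),
    "duffing": SystemSpec("duffing", "flow", _duffing,
                          {"delta": 0.25, "f": 0.3}, (0.5, 0.0)),
    "ueda": SystemSpec("ueda", "flow", _ueda,
                       {"delta": 0.05, "f": 7.5}, (2.5, 0.0)),
    "henon": SystemSpec("henon", "map", _henon, {"a": 1.4, "b": 0.3}, (0.1, 0.1), dt=1.0),
    "lozi": SystemSpec("lozi", "map", _lozi, {"a": 1.7, "b": 0.5}, (0.1, 0.1), dt=1.0),
    "cat": SystemSpec("cat", "map", _cat, {}, (0.23456, 0.65432), dt=1.0, ic_scale=0.1),
}

FLOWS = tuple(name for name, s in SYSTEMS.items() if s.kind == "flow")
MAPS = tuple(name for name, s in SYSTEMS.items() if s.kind == "map")


def _perturbed_ic(spec: SystemSpec, seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    ic = np.asarray(spec.default_ic, dtype=float)
    ic = ic + rng.uniform(-1.0, 1.0, ic.size) * spec.ic_scale
    if spec.name == "cat":
        ic = ic % 1.0
    return tuple(float(v) for v in ic)


def _integrate_flow(spec: SystemSpec, ic: Sequence[float], n_samples: int) -> np.ndarray:
    """Fixed-step RK4 with stroboscopic sampling every ``spec.dt``."""
    h = spec.step
    per_sample = round(spec.dt / h)
    f, p = spec.func, spec.params
    s = tuple(float(v) for v in ic)
    t = 0.0
    out = np.empty(n_samples)
    obs = spec.observable
    for i in range(n_samples):
        for _ in range(per_sample):
            k1 = f(t, s, p)
            k2 = f(t + h / 2, tuple(si + h / 2 * ki for si, ki in zip(s, k1)), p)
            k3 = f(t + h / 2, tuple(si + h / 2 * ki for si, ki in zip(s, k2)), p)
            k4 = f(t + h, tuple(si + h * ki for si, ki in zip(s, k3)), p)
            s = tuple(si + h / 6 * (a + 2 * b + 2 * c + d)
                      for si, a, b, c, d in zip(s, k1, k2, k3, k4))
            t += h
        out[i] = s[obs]
        if not math.isfinite(out[i]) or abs(out[i]) > _DIVERGENCE_LIMIT:
            raise RuntimeError(f"integration of {spec.name!r} diverged at sample {i}")
    return out


def _iterate_map(spec: SystemSpec, ic: Sequence[float], n_samples: int) -> np.ndarray:
    s = tuple(float(v) for v in ic)
    out = np.empty(n_samples)
    obs = spec.observable
    for i in range(n_samples):
        s = spec.func(s, spec.params)
        out[i] = s[obs]
        if not math.isfinite(out[i]) or abs(out[i]) > _DIVERGENCE_LIMIT:
            raise RuntimeError(f"iteration of {spec.name!r} diverged at sample {i}")
    return out


def simulate(system: str | SystemSpec, length: int, seed: int = 0,
             initial_condition: Sequence[float] | None = None,
             transient: int = DEFAULT_TRANSIENT) -> TimeSeries:
    """Simulate ``length`` post-transient samples of a registered system.

    The initial condition defaults to the system's canonical one perturbed
    deterministically by ``seed``.  Identical (system, initial condition,
    seed) give bitwise-identical output.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    spec = SYSTEMS[system] if isinstance(system, str) else system
    ic = tuple(initial_condition) if initial_condition is not None else _perturbed_ic(spec, seed)
    total = transient + length
    if spec.kind == "flow":
        values = _integrate_flow(spec, ic, total)
    else:
        values = _iterate_map(spec, ic, total)
    return TimeSeries(values=values[transient:], dt=spec.dt, system=spec.name,
                      meta={"params": dict(spec.params), "seed": seed,
                            "initial_condition": list(ic), "transient": transient})


def add_noise(ts: TimeSeries, percent: float, seed: int = 0) -> TimeSeries:
    """Add white Gaussian noise with std ``percent/100 * std(ts)``."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must lie in [0, 100]")
    if percent == 0.0:
        return ts
    rng = np.random.default_rng(seed)
    sigma = percent / 100.0 * float(np.std(ts.values))
    noisy = ts.values + rng.normal(0.0, sigma, ts.values.size)
    meta = dict(ts.meta)
    meta.update({"noise_percent": percent, "noise_seed": seed})
    return TimeSeries(values=noisy, dt=ts.dt, system=ts.system, meta=meta)


def gaussian_series(length: int, seed: int = 0) -> TimeSeries:
    """I.i.d. standard-normal series (the 'random time series' reference)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return TimeSeries(values=rng.standard_normal(length), dt=1.0,
                      system="gaussian", meta={"seed": seed})
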