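"""Seeded parameter sweeps over the generators and the RN pipeline.

Each experiment averages Hm over several independent realizations
(different generator seeds, or different initial conditions for the
dynamical systems) and reports the mean with the standard deviation over
realizations as the error, mirroring the standard 10-realization protocol.
A master seed deterministically spawns all per-run seeds, so every sweep is
exactly rerunnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import generators, measures, recurrence
from .dynamics import FLOWS, MAPS, SYSTEMS, add_noise, gaussian_series, simulate

__all__ = [
    "SweepResult",
    "spawn_seeds",
    "sweep_er",
    "sweep_sf_kmin",
    "sweep_sf_n",
    "table1",
    "noise_sweep",
    "compare3way",
    "rn_convergence_n",
    "rn_convergence_m",
]

#: delay guess used when sizing simulated series before tau is known
_TAU_GUESS = 150


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """``n`` independent 31-bit seeds derived deterministically from one master."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) % (2**31)]


@dataclass(frozen=True)
class SweepResult:
    """Tidy table of a sweep: one row per parameter combination.

    ``table`` has the swept parameter columns plus ``hm_mean``, ``hm_std``
    and ``n_seeds``.
    """

    params: tuple[str, ...]
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.table["hm_std"] < 0).any() or (self.table["n_seeds"] < 1).any():
            raise ValueError("invalid sweep statistics")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def _summarize(rows: list[dict], params: tuple[str, ...], **metadata) -> SweepResult:
    return SweepResult(params=params, table=pd.DataFrame(rows), metadata=metadata)


def sweep_er(n_values, p_values, seeds: int = 10, master_seed: int = 0) -> SweepResult:
    """Mean/std of Hm for G(n, p) over a (n, p) grid."""
    rows = []
    for n in n_values:
        for p in p_values:
            run_seeds = spawn_seeds(master_seed + 1000 * n, seeds)
            vals = [measures.hm(generators.erdos_renyi(n, p, s)) for s in run_seeds]
            rows.append({"n": n, "p": p, "hm_mean": float(np.mean(vals)),
                         "hm_std": float(np.std(vals)), "n_seeds": seeds})
    return _summarize(rows, ("n", "p"), family="erdos_renyi")


def sweep_sf_kmin(kmin_values, n: int = 2000, seeds: int = 10,
                  master_seed: int = 0) -> SweepResult:
    """Hm of preferential-attachment graphs versus the minimum degree."""
    rows = []
    for kmin in kmin_values:
        run_seeds = spawn_seeds(master_seed + 7 * kmin, seeds)
        vals = [measures.hm(generators.barabasi_albert(n, kmin, s)) for s in run_seeds]
        rows.append({"kmin": kmin, "n": n, "hm_mean": float(np.mean(vals)),
                     "hm_std": float(np.std(vals)), "n_seeds": seeds})
    return _summarize(rows, ("kmin", "n"), family="barabasi_albert")


def sweep_sf_n(kmin_values, n_grid, seeds: int = 10,
               master_seed: int = 0) -> tuple[SweepResult, dict[int, float]]:
    """Hm versus N for preferential-attachment graphs, with the decay exponent.

    For each ``kmin`` the mean Hm over seeds is computed on the ``n_grid``
    and ``log(mean Hm)`` is regressed on ``log N``; the negated slope is
    the scaling exponent of the approximate power-law decay ``Hm ∝ N^-rho``.
    """
    n_grid = list(n_grid)
    if len(n_grid) < 2:
        raise ValueError("need at least two N values to fit a scaling exponent")
    rows = []
    exponents: dict[int, float] = {}
    for kmin in kmin_values:
        means = []
        for n in n_grid:
            run_seeds = spawn_seeds(master_seed + 13 * kmin + n, seeds)
            vals = [measures.hm(generators.barabasi_albert(n, kmin, s)) for s in run_seeds]
            means.append(float(np.mean(vals)))
            rows.append({"kmin": kmin, "n": n, "hm_mean": means[-1],
                         "hm_std": float(np.std(vals)), "n_seeds": seeds})
        slope = np.polyfit(np.log(n_grid), np.log(means), 1)[0]
        exponents[kmin] = float(-slope)
    return _summarize(rows, ("kmin", "n"), family="barabasi_albert"), exponents


def _system_series(system: str, n_nodes: int, m_max: int, seed: int):
    """Simulate a series long enough for an ``n_nodes``-node RN at dimension ``m_max``.

    Flows need ``n_nodes + (m_max-1)*tau`` samples but ``tau`` is only known
    after simulating, so a pilot length based on a generous delay guess is
    tried first and extended (deterministically, same initial condition) if
    the measured delay turns out larger.
    """
    spec = SYSTEMS[system]
    if spec.kind == "map":
        return simulate(system, length=n_nodes + (m_max - 1), seed=seed)
    ts = simulate(system, length=n_nodes + (m_max - 1) * _TAU_GUESS, seed=seed)
    tau = recurrence.first_acf_minimum(ts)
    headroom = (m_max - 1) * (tau // 4 + 5)  # allow tau drift on the longer series
    need = n_nodes + (m_max - 1) * tau
    if len(ts) < need + headroom:
        ts = simulate(system, length=need + headroom, seed=seed)
    return ts


def _system_hm(system: str, n_nodes: int, m: int, seed: int,
               ts=None) -> float:
    ts = ts if ts is not None else _system_series(system, n_nodes, m, seed)
    return recurrence.hm_from_series(ts, m=m, n_nodes=n_nodes).hm


def table1(systems=None, n_nodes: int = 2000, n_seeds: int = 10,
           m_values=(3, 5), master_seed: int = 0) -> pd.DataFrame:
    """Hm of RNs from the standard chaotic systems.

    For each system, ``n_seeds`` series with perturbed initial conditions
    are simulated once and the RN heterogeneity is computed at each
    embedding dimension in ``m_values`` (the largest is the reported,
    converged value; the smaller ones allow the M-convergence check).
    Returns one row per system with per-M means and the mean/std at the
    largest M.
    """
    systems = list(systems) if systems is not None else list(SYSTEMS)
    m_values = sorted(m_values)
    rows = []
    for sys_idx, system in enumerate(systems):
        run_seeds = spawn_seeds(master_seed + 101 * sys_idx, n_seeds)
        per_m: dict[int, list[float]] = {m: [] for m in m_values}
        for s in run_seeds:
            ts = _system_series(system, n_nodes, max(m_values), s)
            for m in m_values:
                per_m[m].append(recurrence.hm_from_series(ts, m=m, n_nodes=n_nodes).hm)
        m_top = m_values[-1]
        row = {"system": system, "kind": SYSTEMS[system].kind,
               "hm_mean": float(np.mean(per_m[m_top])),
               "hm_std": float(np.std(per_m[m_top])),
               "n_seeds": n_seeds, "n_nodes": n_nodes}
        for m in m_values:
            row[f"hm_mean_m{m}"] = float(np.mean(per_m[m]))
            row[f"hm_std_m{m}"] = float(np.std(per_m[m]))
        rows.append(row)
    return pd.DataFrame(rows)


def noise_sweep(percent_grid, seeds: int = 10, system: str = "lorenz",
                n_nodes: int = 2000, m: int = 3, master_seed: int = 0) -> SweepResult:
    """Hm of the Lorenz RN as observational noise is added to the series."""
    percent_grid = list(percent_grid)
    if any(not 0 <= p <= 100 for p in percent_grid):
        raise ValueError("noise percentages must lie in [0, 100]")
    run_seeds = spawn_seeds(master_seed + 4242, seeds)
    base = [_system_series(system, n_nodes, m, s) for s in run_seeds]
    rows = []
    for pct in percent_grid:
        vals = [recurrence.hm_from_series(add_noise(ts, pct, seed=s + 1), m=m,
                                          n_nodes=n_nodes).hm
                for ts, s in zip(base, run_seeds)]
        rows.append({"percent": pct, "hm_mean": float(np.mean(vals)),
                     "hm_std": float(np.std(vals)), "n_seeds": seeds})
    return _summarize(rows, ("percent",), system=system, n_nodes=n_nodes, m=m)


def compare3way(n: int = 2000, seeds: int = 10, p: float = 0.0035,
                gamma: float = 2.124, kmin: int = 1, m: int = 3,
                master_seed: int = 0) -> pd.DataFrame:
    """Gaussian-series RN vs an ER graph of matched mean degree vs an SF graph.

    All three are evaluated at the same number of nodes; the result is one
    row per family with mean and std of Hm over the realizations.
    """
    run_seeds = spawn_seeds(master_seed + 31337, seeds)
    gauss = [recurrence.hm_from_series(gaussian_series(n + (m - 1), seed=s),
                                       m=m, n_nodes=n).hm for s in run_seeds]
    er = [measures.hm(generators.erdos_renyi(n, p, s)) for s in run_seeds]
    sf = [measures.hm(generators.powerlaw_configuration(n, gamma, kmin, s))
          for s in run_seeds]
    rows = [
        {"family": "gaussian_rn", "hm_mean": float(np.mean(gauss)),
         "hm_std": float(np.std(gauss)), "n_seeds": seeds},
        {"family": "erdos_renyi", "hm_mean": float(np.mean(er)),
         "hm_std": float(np.std(er)), "n_seeds": seeds},
        {"family": "scale_free", "hm_mean": float(np.mean(sf)),
         "hm_std": float(np.std(sf)), "n_seeds": seeds},
    ]
    return pd.DataFrame(rows)


def rn_convergence_n(system: str = "lorenz", n_grid=(800, 1400, 2000), m: int = 3,
                     seeds: int = 10, master_seed: int = 0) -> SweepResult:
    """Hm of a system's RN versus the number of nodes (large-N plateau check)."""
    n_grid = sorted(n_grid)
    run_seeds = spawn_seeds(master_seed + 555, seeds)
    base = [_system_series(system, max(n_grid), m, s) for s in run_seeds]
    rows = []
    for n in n_grid:
        vals = [recurrence.hm_from_series(ts, m=m, n_nodes=n).hm for ts in base]
        rows.append({"n": n, "hm_mean": float(np.mean(vals)),
                     "hm_std": float(np.std(vals)), "n_seeds": seeds})
    return _summarize(rows, ("n",), system=system, m=m)


def rn_convergence_m(system: str = "lorenz", m_values=(3, 4, 5), n_nodes: int = 2000,
                     seeds: int = 10, master_seed: int = 0) -> SweepResult:
    """Hm of a system's RN versus the embedding dimension (M-invariance check)."""
    m_values = sorted(m_values)
    run_seeds = spawn_seeds(master_seed + 777, seeds)
    base = [_system_series(system, n_nodes, max(m_values), s) for s in run_seeds]
    rows = []
    for m in m_values:
        vals = [recurrence.hm_from_series(ts, m=m, n_nodes=n_nodes).hm for ts in base]
        rows.append({"m": m, "hm_mean": float(np.mean(vals)),
                     "hm_std": float(np.std(vals)), "n_seeds": seeds})
    return _summarize(rows, ("m",), system=system, n_nodes=n_nodes)
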