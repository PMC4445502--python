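"""Population observables: type classification, time series, survival sweeps.

Replicators are classified by the set of reactions they catalyse: the seven
non-empty subsets of {1, 2, 3} plus "P" for parasites (no activity at all;
weak 0.1 sites count as active).  A Snapshot records, for one generation,
the per-type lattice frequencies F, the mean raw activities A_1..A_3 over
their carriers, the per-type mean lengths, per-type folding-energy
histograms and the overall occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import Grid, RunConfig, Simulation

__all__ = [
    "TYPE_LABELS",
    "classify",
    "Snapshot",
    "record",
    "snapshots_to_frame",
    "write_timeseries",
    "energy_histograms_to_frame",
    "survival_sweep",
]

TYPE_LABELS: Tuple[str, ...] = ("1", "2", "3", "12", "13", "23", "123", "P")


def classify(alphas: Sequence[float]) -> str:
    """Label a replicator by its set of catalysed reactions, or "P"."""
    active = "".join(str(i + 1) for i, a in enumerate(alphas) if a > 0)
    return active if active else "P"


@dataclass(frozen=True)
class Snapshot:
    """Observables of one generation.

    ``frequencies`` are fractions of *lattice sites* (so they sum with the
    empty fraction to 1); ``mean_alpha[j]`` is the mean raw activity of
    reaction j + 1 over the replicators that carry it (NaN if none);
    ``mean_length`` is per type label (NaN for absent types);
    ``energy_hist`` maps each label to counts on ``energy_edges`` (1
    kcal/mol bins spanning [e_min, 0] by default).
    """

    generation: int
    occupancy: float
    frequencies: Dict[str, float]
    mean_alpha: Tuple[float, float, float]
    mean_length: Dict[str, float]
    energy_edges: np.ndarray
    energy_hist: Dict[str, np.ndarray]

    @property
    def empty_fraction(self) -> float:
        return 1.0 - sum(self.frequencies.values())


def record(
    grid: Grid,
    generation: int,
    e_min: float = -25.0,
    bin_width: float = 1.0,
) -> Snapshot:
    """Take a read-only snapshot of the grid at *generation*."""
    n_sites = grid.size * grid.size
    edges = np.arange(e_min, 0.0 + bin_width / 2, bin_width)
    counts: Dict[str, int] = {label: 0 for label in TYPE_LABELS}
    lengths: Dict[str, List[int]] = {label: [] for label in TYPE_LABELS}
    energies: Dict[str, List[float]] = {label: [] for label in TYPE_LABELS}
    alpha_sums = [0.0, 0.0, 0.0]
    alpha_counts = [0, 0, 0]
    n_occ = 0
    for rep in grid.cells.flat:
        if rep is None:
            continue
        n_occ += 1
        label = classify(rep.alphas)
        counts[label] += 1
        lengths[label].append(rep.length)
        energies[label].append(rep.energy)
        for j, a in enumerate(rep.alphas):
            if a > 0:
                alpha_sums[j] += a
                alpha_counts[j] += 1
    freq = {label: counts[label] / n_sites for label in TYPE_LABELS}
    mean_alpha = tuple(
        alpha_sums[j] / alpha_counts[j] if alpha_counts[j] else float("nan")
        for j in range(3)
    )
    mean_length = {
        label: (float(np.mean(lengths[label])) if lengths[label] else float("nan"))
        for label in TYPE_LABELS
    }
    hist = {
        label: np.histogram(np.clip(energies[label], e_min, 0.0), bins=edges)[0]
        if energies[label]
        else np.zeros(len(edges) - 1, dtype=int)
        for label in TYPE_LABELS
    }
    return Snapshot(
        generation=generation,
        occupancy=n_occ / n_sites,
        frequencies=freq,
        mean_alpha=mean_alpha,  # type: ignore[arg-type]
        mean_length=mean_length,
        energy_edges=edges,
        energy_hist=hist,
    )


def snapshots_to_frame(snapshots: Sequence[Snapshot]) -> pd.DataFrame:
    """Flatten snapshots into a tidy one-row-per-generation table."""
    rows = []
    for s in snapshots:
        row: Dict[str, float] = {"t": s.generation, "occupancy": s.occupancy}
        for label in TYPE_LABELS:
            row[f"F_{label}"] = s.frequencies[label]
        for j in range(3):
            row[f"A_{j + 1}"] = s.mean_alpha[j]
        for label in TYPE_LABELS:
            row[f"L_{label}"] = s.mean_length[label]
        rows.append(row)
    return pd.DataFrame(rows)


def write_timeseries(snapshots: Sequence[Snapshot], path) -> None:
    snapshots_to_frame(snapshots).to_csv(path, sep="\t", index=False)


def energy_histograms_to_frame(snapshots: Sequence[Snapshot]) -> pd.DataFrame:
    """Long-format per-type folding-energy histograms (one row per bin)."""
    rows = []
    for s in snapshots:
        mids = (s.energy_edges[:-1] + s.energy_edges[1:]) / 2.0
        for label in TYPE_LABELS:
            for mid, count in zip(mids, s.energy_hist[label]):
                rows.append(
                    {
                        "t": s.generation,
                        "type": label,
                        "energy_bin_mid": float(mid),
                        "count": int(count),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """One row of a survival sweep: a config, its survival fraction, and
    stationary means over the surviving replicates."""

    label: str
    replicates: int
    survived: int

    @property
    def survival_fraction(self) -> float:
        return self.survived / self.replicates if self.replicates else float("nan")


def _activity_present(grid: Grid) -> Tuple[bool, bool, bool]:
    present = [False, False, False]
    for rep in grid.cells.flat:
        if rep is None:
            continue
        for j, a in enumerate(rep.alphas):
            if a > 0:
                present[j] = True
        if all(present):
            break
    return tuple(present)  # type: ignore[return-value]


def survival_sweep(
    configs: Dict[str, RunConfig],
    replicates: int,
    generations: int,
    base_seed: int = 0,
    backend_factory=None,
    extinction_grace: int = 50,
    initializer=None,
) -> pd.DataFrame:
    """Run independent replicates per config and tabulate survival.

    ``initializer(sim)``, when given, seeds the lattice instead of the
    default random initial population — e.g. to sweep from an established
    community rather than a random pool.

    A run is extinct when the lattice empties, or when some reaction type
    has had no carrier anywhere for *extinction_grace* consecutive
    generations (metabolism is then impossible everywhere; the grace window
    tolerates transient local loss).  Survivors contribute their final
    occupancy and per-type frequencies to the reported means.

    Replicate seeds are ``base_seed + 1000 * index`` offsets per config so
    replicates are independent and reproducible.
    """
    rows = []
    for ci, (label, config) in enumerate(sorted(configs.items())):
        survived = 0
        final_occ: List[float] = []
        final_freq: List[Dict[str, float]] = []
        for r in range(replicates):
            cfg = RunConfig.from_dict(config.to_dict())
            cfg.seed = base_seed + 1000 * (ci * max(replicates, 1) + r)
            backend = backend_factory() if backend_factory else None
            sim = Simulation(cfg, backend=backend)
            if initializer is None:
                sim.init_population()
            else:
                initializer(sim)
            missing_streak = 0
            extinct = False
            for _ in range(generations):
                sim.run_generation()
                if sim.grid.occupancy() == 0:
                    extinct = True
                    break
                if all(_activity_present(sim.grid)):
                    missing_streak = 0
                else:
                    missing_streak += 1
                    if missing_streak >= extinction_grace:
                        extinct = True
                        break
            if not extinct:
                survived += 1
                snap = record(sim.grid, sim.generation, cfg.e_min)
                final_occ.append(snap.occupancy)
                final_freq.append(snap.frequencies)
        row: Dict[str, float] = {
            "config": label,
            "replicates": replicates,
            "survived": survived,
            "survival_fraction": survived / replicates if replicates else np.nan,
            "mean_occupancy": float(np.mean(final_occ)) if final_occ else np.nan,
        }
        for t in TYPE_LABELS:
            row[f"F_{t}"] = (
                float(np.mean([f[t] for f in final_freq])) if final_freq else np.nan
            )
        rows.append(row)
    columns = (
        ["config", "replicates", "survived", "survival_fraction", "mean_occupancy"]
        + [f"F_{t}" for t in TYPE_LABELS]
    )
    return pd.DataFrame(rows, columns=columns)
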