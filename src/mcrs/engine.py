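"""The stochastic cellular automaton driving replicator dynamics.

State is a G x G toroidal grid of optional replicators.  One generation
performs G*G asynchronous site updates, each on an independently drawn
uniform-random site (with replacement): an occupied site decays with its
structure-dependent probability p_deg; an empty site runs the replication
lottery among its von Neumann neighbours and, on a win, receives a mutated
copy of the winning template.  After every site update the Toffoli-Margolus
diffusion operator runs on average D times: a random 2x2 block is rotated
90 degrees clockwise or counter-clockwise with equal probability, which
mixes replicators while conserving them exactly.

All randomness flows through a single seeded ``numpy.random.Generator``.
The draw order is fixed and documented on each operation, so a fixed seed
yields a bit-identical trajectory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterator, List, Optional, Tuple

import numpy as np

from . import fitness
from .folding import FoldingBackend, ViennaRNABackend, BASES
from .replicator import PhenotypeFactory, Replicator

__all__ = [
    "Grid",
    "MutationRates",
    "RunConfig",
    "mutate",
    "schedule_diffusion",
    "Simulation",
]


@dataclass(frozen=True)
class MutationRates:
    """Per-base probabilities of substitution, insertion and deletion.

    The three processes act independently on each base of the template copy.
    """

    p_sub: float = 0.01
    p_ins: float = 0.001
    p_del: float = 0.001

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


class Grid:
    """G x G toroidal lattice of optional replicators."""

    def __init__(self, size: int) -> None:
        if size < 2:
            raise ValueError("grid size must be at least 2")
        self.size = size
        self.cells: np.ndarray = np.empty((size, size), dtype=object)

    def get(self, x: int, y: int) -> Optional[Replicator]:
        return self.cells[x % self.size, y % self.size]

    def set(self, x: int, y: int, rep: Optional[Replicator]) -> None:
        self.cells[x % self.size, y % self.size] = rep

    def occupancy(self) -> int:
        return int(np.sum(self.cells != None))  # noqa: E711

    def occupied_replicators(self) -> List[Replicator]:
        return [rep for rep in self.cells.flat if rep is not None]

    def iter_occupied(self) -> Iterator[Tuple[int, int, Replicator]]:
        for (x, y), rep in np.ndenumerate(self.cells):
            if rep is not None:
                yield x, y, rep

    def sequences(self) -> List[Optional[str]]:
        """Row-major list of resident sequences (None for empty sites)."""
        return [
            rep.sequence if rep is not None else None for rep in self.cells.flat
        ]

    def copy(self) -> "Grid":
        g = Grid(self.size)
        g.cells = self.cells.copy()
        return g


@dataclass
class RunConfig:
    """Full parameter set of a run; defaults are the model's defaults."""

    grid_size: int = 300
    diffusion: float = 4.0  # D: mean diffusion updates per site update
    h: int = 3  # metabolic Moore neighbourhood is h x h
    l_max: int = 70
    epsilon: float = 0.1
    c: float = 0.3
    p_sub: float = 0.01
    p_ins: float = 0.001
    p_del: float = 0.001
    g: float = 10.0
    sigma: float = 1.1
    l: float = 1.0
    b1: float = 1.0
    b2: float = 0.05
    e_min: float = -25.0
    initial_occupancy: float = 0.8
    init_length_min: int = 25
    init_length_max: int = 60
    generations: int = 1000
    snapshot_every: int = 100
    seed: int = 0

    @property
    def kinetics(self) -> fitness.KineticParams:
        return fitness.KineticParams(
            g=self.g,
            b1=self.b1,
            b2=self.b2,
            l=self.l,
            e_min=self.e_min,
            epsilon=self.epsilon,
            c=self.c,
            sigma=self.sigma,
        )

    @property
    def mutation_rates(self) -> MutationRates:
        return MutationRates(self.p_sub, self.p_ins, self.p_del)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def mutate(
    sequence: str,
    rates: MutationRates,
    rng: np.random.Generator,
    l_max: int = 70,
) -> str:
    """Return a mutated copy of *sequence*.

    Per base, independently: substitution with p_sub (uniform over the three
    other bases), deletion with p_del; insertion of a uniform-random base
    occurs with p_ins in each of the L + 1 inter-base gaps (before the first
    base and after every base).  If insertions would push the result past
    *l_max*, the excess insertions are rejected 5'->3' (the copy itself
    still succeeds).  The empty string is a legal outcome.

    Draw order (fixed for reproducibility): substitution uniforms (L),
    deletion uniforms (L), gap-insertion uniforms (L + 1), then replacement
    and inserted bases in 5'->3' scan order.
    """
    n = len(sequence)
    u_sub = rng.random(n)
    u_del = rng.random(n)
    u_ins = rng.random(n + 1)
    sub = u_sub < rates.p_sub
    dele = u_del < rates.p_del
    ins = u_ins < rates.p_ins

    kept = int(n - dele.sum())
    budget = l_max - kept  # insertions allowed

    out: List[str] = []
    if ins[0] and budget > 0:
        out.append(BASES[rng.integers(4)])
        budget -= 1
    for i, base in enumerate(sequence):
        if not dele[i]:
            if sub[i]:
                others = BASES.replace(base, "")
                base = others[rng.integers(3)]
            out.append(base)
        if ins[i + 1] and budget > 0:
            out.append(BASES[rng.integers(4)])
            budget -= 1
    return "".join(out)


def schedule_diffusion(d: float, rng: np.random.Generator) -> int:
    """Number of diffusion block rotations to run after one site update.

    Returns floor(D) plus a Bernoulli(frac(D)) extra so the long-run mean is
    exactly D.  When D is integral no random draw is consumed.
    """
    if d < 0:
        raise ValueError("diffusion strength must be non-negative")
    base = int(d)
    frac = d - base
    if frac > 0.0 and rng.random() < frac:
        base += 1
    return base


class Simulation:
    """Owns the grid, the RNG stream, the phenotype cache and the schedule."""

    def __init__(
        self,
        config: RunConfig,
        backend: Optional[FoldingBackend] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.config = config
        self.backend = backend if backend is not None else ViennaRNABackend()
        self.factory = PhenotypeFactory(self.backend, config.kinetics)
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.grid = Grid(config.grid_size)
        self.generation = 0
        self.c_e = fitness.empty_claim(config.kinetics)
        self._rates = config.mutation_rates

    # ------------------------------------------------------------------ init

    def init_population(self) -> Grid:
        """Seed the lattice with a random population.

        Scanning sites row-major: each site is occupied with probability
        ``initial_occupancy`` (default 0.8); an occupied site draws a length
        uniformly from [init_length_min, init_length_max] (default [25, 60])
        and a uniform-random sequence of that length.
        """
        cfg = self.config
        g = cfg.grid_size
        for x in range(g):
            for y in range(g):
                if self.rng.random() < cfg.initial_occupancy:
                    length = int(
                        self.rng.integers(
                            cfg.init_length_min, cfg.init_length_max + 1
                        )
                    )
                    seq = "".join(
                        BASES[i] for i in self.rng.integers(0, 4, size=length)
                    )
                    self.grid.set(x, y, self.factory.build(seq))
        return self.grid

    # --------------------------------------------------------------- updates

    def update_site(self, x: int, y: int) -> str:
        """Update one site; returns the event kind for bookkeeping.

        Occupied: one uniform draw against p_deg — decay removes the
        replicator.  Empty: the replication lottery; a winning neighbour
        places a mutated copy (folded and phenotyped immediately).
        """
        rep = self.grid.get(x, y)
        if rep is not None:
            if self.rng.random() < rep.p_deg:
                self.grid.set(x, y, None)
                return "decay"
            return "survive"
        winner = fitness.replication_lottery(
            self.grid, x, y, self.c_e, self.rng, self.config.h
        )
        if winner is None:
            return "empty"
        parent = self.grid.get(*winner)
        child = mutate(parent.sequence, self._rates, self.rng, self.config.l_max)
        self.grid.set(x, y, self.factory.build(child))
        return "birth"

    def diffusion_step(self) -> None:
        """Rotate one random 2x2 block 90 degrees CW or CCW (p = 0.5 each).

        The block's anchor is drawn uniformly; blocks wrap toroidally.
        Draw order: anchor index, then direction.  Cell contents (including
        emptiness) are permuted, never created or destroyed.
        """
        g = self.config.grid_size
        idx = int(self.rng.integers(g * g))
        x, y = divmod(idx, g)
        clockwise = self.rng.random() < 0.5
        self.rotate_block(self.grid, x, y, clockwise)

    @staticmethod
    def rotate_block(grid: Grid, x: int, y: int, clockwise: bool) -> None:
        x1, y1 = (x + 1) % grid.size, (y + 1) % grid.size
        a = grid.get(x, y)  # NW
        b = grid.get(x, y1)  # NE
        c = grid.get(x1, y1)  # SE
        d = grid.get(x1, y)  # SW
        if clockwise:  # NW<-SW, NE<-NW, SE<-NE, SW<-SE
            grid.set(x, y, d)
            grid.set(x, y1, a)
            grid.set(x1, y1, b)
            grid.set(x1, y, c)
        else:
            grid.set(x, y, b)
            grid.set(x, y1, c)
            grid.set(x1, y1, d)
            grid.set(x1, y, a)

    def run_generation(self) -> dict:
        """Run one generation: G*G site updates interleaved with diffusion.

        Per step: draw the target site uniformly (one integer draw), update
        it, then run ``schedule_diffusion(D)`` block rotations.  Returns the
        event tally of the generation.
        """
        g = self.config.grid_size
        d = self.config.diffusion
        tally = {"decay": 0, "survive": 0, "birth": 0, "empty": 0}
        for _ in range(g * g):
            idx = int(self.rng.integers(g * g))
            x, y = divmod(idx, g)
            tally[self.update_site(x, y)] += 1
            for _ in range(schedule_diffusion(d, self.rng)):
                self.diffusion_step()
        self.generation += 1
        return tally

    def run(self, generations: int) -> None:
        for _ in range(generations):
            self.run_generation()

    # ----------------------------------------------------------------- state

    def state_dict(self) -> dict:
        """Serialisable run state: config, generation, sequences, RNG state."""
        return {
            "config": self.config.to_dict(),
            "generation": self.generation,
            "backend_id": self.backend.id,
            "sequences": self.grid.sequences(),
            "rng_state": _encode_rng_state(self.rng.bit_generator.state),
        }

    @classmethod
    def from_state_dict(
        cls, state: dict, backend: Optional[FoldingBackend] = None
    ) -> "Simulation":
        config = RunConfig.from_dict(state["config"])
        sim = cls(config, backend=backend)
        sim.generation = int(state["generation"])
        sim.rng.bit_generator.state = _decode_rng_state(state["rng_state"])
        g = config.grid_size
        for i, seq in enumerate(state["sequences"]):
            if seq is not None:
                x, y = divmod(i, g)
                sim.grid.set(x, y, sim.factory.build(seq))
        return sim


def _encode_rng_state(state: dict) -> dict:
    """Make a numpy BitGenerator state JSON-safe (ints can exceed 2**63)."""
    def enc(v):
        if isinstance(v, dict):
            return {k: enc(x) for k, x in v.items()}
        if isinstance(v, np.ndarray):
            return {"__ndarray__": [int(x) for x in v], "dtype": str(v.dtype)}
        if isinstance(v, (np.integer,)):
            return int(v)
        return v

    return enc(state)


def _decode_rng_state(state: dict) -> dict:
    def dec(v):
        if isinstance(v, dict):
            if "__ndarray__" in v:
                return np.array(v["__ndarray__"], dtype=v["dtype"])
            return {k: dec(x) for k, x in v.items()}
        return v

    return dec(state)
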