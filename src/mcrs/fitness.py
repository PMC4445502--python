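"""Per-replicator dynamical quantities: decay, replicability, claims.

A replicator's fate couples three structure-mediated traits:

* decay — compact folds are durable: p_deg is linear in E between 0.9
  (E = 0) and 0.1 (E = E_min = -25 kcal/mol);
* replicability — only the unfolded state can be copied and longer
  templates take longer: R = g * [l + (1 - p_fold)] / (b1 + b2 * L);
* metabolism — a replicator is only copied if all three reactions are
  catalysed within its metabolic (Moore) neighbourhood; the local metabolic
  activity M is the geometric mean of the three per-reaction activity sums.

An empty site runs a lottery among the occupied von Neumann neighbours with
weights C = M * R, against a constant "stay empty" claim C_e set to an
epsilon fraction of the theoretical maximum claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, List, Optional, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Grid

__all__ = [
    "KineticParams",
    "degradation_prob",
    "replicability",
    "metabolic_activity",
    "claim",
    "empty_claim",
    "replication_lottery",
]

#: von Neumann offsets in the fixed order used by the lottery (N, S, W, E).
VON_NEUMANN = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants of the model with their default values.

    g       : overall replicability scale
    b1      : length-independent replication (initiation/termination) time
    b2      : per-nucleotide elongation time, the "length penalty"
    l       : baseline replicability floor (even tightly folded ribozymes
              replicate a little)
    e_min   : empirical lower bound of the MFE (kcal/mol) over the length
              range the model explores
    epsilon : empty-site claim as a fraction of the theoretical maximum claim
    c       : steepness of the Boltzmann folding-probability logistic
    sigma   : promiscuity penalty exponent (> 1)
    alpha_hat, l_ref : optimal single-site activity (1.1) and reference
              length (35 nt) entering the theoretical-maximum-claim formula
    """

    g: float = 10.0
    b1: float = 1.0
    b2: float = 0.05
    l: float = 1.0
    e_min: float = -25.0
    epsilon: float = 0.1
    c: float = 0.3
    sigma: float = 1.1
    alpha_hat: float = 1.1
    l_ref: float = 35.0

    def __post_init__(self) -> None:
        if self.e_min >= 0:
            raise ValueError("e_min must be negative")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        for name in ("g", "b1", "b2", "l", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def degradation_prob(energy: float, params: KineticParams) -> float:
    """Per-update decay probability, linear in the folding free energy.

    E is clamped to [e_min, 0]; the result spans [0.1, 0.9]: loose folds
    (E ~ 0) decay at 0.9 per update, optimally stable folds at 0.1 (the
    floor prevents unlimited longevity).
    """
    e = min(0.0, max(params.e_min, energy))
    return 0.9 - 0.8 * e / params.e_min


def replicability(length: int, p_fold: float, params: KineticParams) -> float:
    """Copying propensity R of a template of *length* nt.

    Replication requires the unfolded state, hence the (1 - p_fold) term;
    the l > 0 offset lets even permanently folded ribozymes replicate.  The
    denominator is the replication time: fixed initiation cost b1 plus
    elongation b2 per base.  R is strictly positive and decreases in both
    length and p_fold.
    """
    if length < 0:
        raise ValueError("length must be non-negative")
    return params.g * (params.l + (1.0 - p_fold)) / (params.b1 + params.b2 * length)


def metabolic_activity(grid: "Grid", x: int, y: int, h: int = 3) -> float:
    """Local metabolic activity M around site (x, y).

    Sums the effective activities of every occupied site in the h x h Moore
    neighbourhood centred on (x, y) — including the focal site — per
    reaction, and returns the geometric mean of the three sums.  Any
    reaction missing from the neighbourhood makes M = 0: metabolism needs
    all three.  ``h >= grid size`` degenerates to the mean-field case where
    the whole lattice is one neighbourhood.
    """
    s1 = s2 = s3 = 0.0
    g = grid.size
    if h >= g:
        cells = grid.occupied_replicators()
    else:
        r = h // 2
        cells = []
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                rep = grid.get((x + dx) % g, (y + dy) % g)
                if rep is not None:
                    cells.append(rep)
    for rep in cells:
        a1, a2, a3 = rep.effective
        s1 += a1
        s2 += a2
        s3 += a3
    if s1 <= 0.0 or s2 <= 0.0 or s3 <= 0.0:
        return 0.0
    return (s1 * s2 * s3) ** (1.0 / 3.0)


def claim(metabolic: float, repl: float) -> float:
    """Replication claim C = M * R of a template competing for an empty site."""
    return metabolic * repl


def empty_claim(params: KineticParams) -> float:
    """The constant claim C_e of an empty site to remain empty.

    Defined as an epsilon fraction of the theoretical maximum claim: a
    focal replicator whose eight Moore neighbours are optimally active
    mono-specialists split 3/3/2 across the reactions (alpha_hat = 1.1
    each, p_fold = 1) has M = cbrt(18) * alpha_hat, and at the reference
    length of 35 nt a replicability of g * l / (b1 + b2 * 35).  With the
    defaults the maximum claim is 10.48 and C_e = 1.048.
    """
    m_hat = (18.0 ** (1.0 / 3.0)) * params.alpha_hat
    r_hat = params.g * params.l / (params.b1 + params.b2 * params.l_ref)
    return params.epsilon * m_hat * r_hat


def replication_lottery(
    grid: "Grid",
    x: int,
    y: int,
    c_e: float,
    rng: np.random.Generator,
    h: int = 3,
) -> Optional[Tuple[int, int]]:
    """Draw the winner of the replication lottery at empty site (x, y).

    Competitors are the occupied von Neumann neighbours; each wins with
    probability C_s / (C_e + sum C_l), and with the remaining probability
    the site stays empty (return ``None``).  If no neighbour has a positive
    claim the site stays empty without consuming a random draw.

    Neighbours are scanned in the fixed order N, S, W, E so that
    trajectories are reproducible for a fixed seed.
    """
    g = grid.size
    entries: List[Tuple[Tuple[int, int], float]] = []
    total = 0.0
    for dx, dy in VON_NEUMANN:
        nx, ny = (x + dx) % g, (y + dy) % g
        rep = grid.get(nx, ny)
        if rep is None:
            continue
        c = claim(metabolic_activity(grid, nx, ny, h), rep.replicability)
        if c > 0.0:
            entries.append(((nx, ny), c))
            total += c
    if total <= 0.0:
        return None
    u = rng.random() * (c_e + total)
    acc = 0.0
    for pos, c in entries:
        acc += c
        if u < acc:
            return pos
    return None
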