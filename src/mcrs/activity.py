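"""Structure -> ribozyme-activity mapping.

Three metabolic reactions are each catalysed by a specific loop motif:

1. an internal or bulge loop of length 5 with A at loop position 3
   (alpha1 = 1.0; an unpaired U at position 2 or 4 boosts it to 1.1; a
   length-4 loop with A at position 2 or 3 gives a weak 0.1);
2. a hairpin loop of length 9 with G at position 5 (helper A at 4/6 ->
   1.1; length 8 with G at 4/5 -> 0.1);
3. a hairpin loop of length 13 with U at position 7 (helper C at 6/8 ->
   1.1; length 12 with U at 6/7 -> 0.1).

Loop positions are counted 1-based along the loop's unpaired bases, 5' run
before 3' run for internal loops.  Any other loop is catalytically inert.
A molecule carrying sites for several reactions is a promiscuous enzyme and
pays a sub-additive penalty: each effective activity is divided by m**sigma
where m is the number of distinct reactions it catalyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from .folding import LoopElement

__all__ = [
    "ActiveSite",
    "detect_sites",
    "raw_alphas",
    "effective_activities",
]

Alphas = Tuple[float, float, float]


@dataclass(frozen=True)
class ActiveSite:
    """A catalytic motif found in one loop: reaction type 1-3 and raw alpha."""

    reaction_type: int
    alpha: float
    loop: LoopElement


def _site_in_loop(seq: str, loop: LoopElement) -> Optional[ActiveSite]:
    """Apply the motif rules to one loop; at most one site per loop.

    The rules are mutually exclusive by loop kind and length, so the first
    match is the only match.
    """
    up = loop.unpaired
    n = len(up)
    if loop.kind in ("internal", "bulge"):
        if n == 5 and seq[up[2]] == "A":
            boosted = seq[up[1]] == "U" or seq[up[3]] == "U"
            return ActiveSite(1, 1.1 if boosted else 1.0, loop)
        if n == 4 and (seq[up[1]] == "A" or seq[up[2]] == "A"):
            return ActiveSite(1, 0.1, loop)
    elif loop.kind == "hairpin":
        if n == 9 and seq[up[4]] == "G":
            boosted = seq[up[3]] == "A" or seq[up[5]] == "A"
            return ActiveSite(2, 1.1 if boosted else 1.0, loop)
        if n == 8 and (seq[up[3]] == "G" or seq[up[4]] == "G"):
            return ActiveSite(2, 0.1, loop)
        if n == 13 and seq[up[6]] == "U":
            boosted = seq[up[5]] == "C" or seq[up[7]] == "C"
            return ActiveSite(3, 1.1 if boosted else 1.0, loop)
        if n == 12 and (seq[up[5]] == "U" or seq[up[6]] == "U"):
            return ActiveSite(3, 0.1, loop)
    return None


def detect_sites(seq: str, loops: Iterable[LoopElement]) -> List[ActiveSite]:
    """Scan the loop decomposition of a fold for catalytic motifs.

    Returns one :class:`ActiveSite` per matching loop; an open chain (no
    loops) yields an empty list.
    """
    sites = []
    for loop in loops:
        site = _site_in_loop(seq, loop)
        if site is not None:
            sites.append(site)
    return sites


def raw_alphas(sites: Sequence[ActiveSite]) -> Alphas:
    """Aggregate detected sites into per-reaction raw activities.

    Several loops may carry sites for the same reaction; the molecule's raw
    activity for that reaction is the maximum over them (the best site does
    the catalysis; weaker duplicates add nothing).
    """
    best = [0.0, 0.0, 0.0]
    for site in sites:
        idx = site.reaction_type - 1
        if site.alpha > best[idx]:
            best[idx] = site.alpha
    return (best[0], best[1], best[2])


def effective_activities(
    alphas: Alphas, p_fold: float, sigma: float = 1.1
) -> Alphas:
    """Effective per-reaction activities a_i = p_fold * alpha_i / m**sigma.

    m is the number of distinct reactions with nonzero raw activity; the
    m**sigma divisor (sigma > 1) is the promiscuity penalty: a molecule
    time-sharing its fold between reactions is worse at each of them than a
    specialist.  All-inactive molecules return (0, 0, 0).
    """
    if sigma <= 1:
        raise ValueError("sigma must exceed 1 (sub-additive penalty)")
    if not 0.0 <= p_fold <= 1.0:
        raise ValueError("p_fold must be a probability")
    m = sum(1 for a in alphas if a > 0)
    if m == 0:
        return (0.0, 0.0, 0.0)
    penalty = m**sigma
    return tuple(p_fold * a / penalty for a in alphas)  # type: ignore[return-value]
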