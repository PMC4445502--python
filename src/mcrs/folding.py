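"""RNA minimum-free-energy folding and secondary-structure decomposition.

The genotype of a replicator is its nucleotide sequence; its phenotype is
derived entirely from the MFE secondary structure and its free energy.  This
module wraps a pluggable folding backend (ViennaRNA by default), memoises
fold results, computes the Boltzmann folding probability, and decomposes a
dot-bracket structure into loop elements (hairpin / bulge / internal /
multiloop / exterior) on which the catalytic-site rules operate.

Sequence positions are 0-based throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

__all__ = [
    "BASES",
    "FoldResult",
    "LoopElement",
    "FoldingBackend",
    "ViennaRNABackend",
    "OpenChainBackend",
    "validate_sequence",
    "p_fold",
    "pair_table",
    "decompose",
]

BASES = "ACGU"
_BASE_SET = frozenset(BASES)

#: Empirical lower bound on the MFE in the sequence-length range the model
#: operates in (<= ~75 nt), in kcal/mol.
E_MIN_DEFAULT = -25.0


def validate_sequence(seq: str, l_max: Optional[int] = None) -> str:
    """Check that *seq* is a string over {A,C,G,U}; return it unchanged.

    Raises ``ValueError`` on foreign characters or when *l_max* is given and
    exceeded.  The empty sequence is permitted (it arises from deletion
    mutations and behaves as an unfoldable parasite).
    """
    if not _BASE_SET.issuperset(seq):
        bad = sorted(set(seq) - _BASE_SET)
        raise ValueError(f"sequence contains non-RNA characters: {bad!r}")
    if l_max is not None and len(seq) > l_max:
        raise ValueError(f"sequence length {len(seq)} exceeds maximum {l_max}")
    return seq


@dataclass(frozen=True)
class FoldResult:
    """One MFE structure for a sequence.

    ``energy`` is in kcal/mol and is never positive: a sequence the backend
    cannot stabilise is represented by the open chain with E = 0.
    """

    sequence: str
    structure: str
    energy: float
    backend_id: str

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure and sequence lengths differ")
        if self.energy > 0:
            raise ValueError("FoldResult energy must be <= 0")


class FoldingBackend:
    """Interface of a folding engine: sequence -> (dot-bracket, kcal/mol).

    Results are memoised per backend instance keyed by the exact sequence
    string; the simulated population revisits genotypes constantly, so the
    cache is unbounded within a run.  Backends must be deterministic.
    """

    id: str = "abstract"

    def __init__(self) -> None:
        self._cache: Dict[str, FoldResult] = {}

    def _fold_raw(self, seq: str) -> Tuple[str, float]:
        raise NotImplementedError

    def fold(self, seq: str) -> FoldResult:
        """Return the memoised MFE fold of *seq*.

        A backend returning a positive free energy is clamped to the open
        chain with E = 0 (such a "fold" is less stable than no fold at all,
        and downstream formulas expect E <= 0).
        """
        hit = self._cache.get(seq)
        if hit is not None:
            return hit
        validate_sequence(seq)
        if not seq:
            structure, energy = "", 0.0
        else:
            structure, energy = self._fold_raw(seq)
            if energy > 0.0:
                structure, energy = "." * len(seq), 0.0
        result = FoldResult(seq, structure, float(energy), self.id)
        self._cache[seq] = result
        return result

    @property
    def cache_size(self) -> int:
        return len(self._cache)


class ViennaRNABackend(FoldingBackend):
    """MFE folding via the ViennaRNA Python bindings (``import RNA``)."""

    def __init__(self) -> None:
        super().__init__()
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - configuration error
            raise RuntimeError(
                "ViennaRNA Python bindings are not importable; install the "
                "viennarna package or supply another FoldingBackend"
            ) from exc
        self._rna = RNA
        self.id = f"ViennaRNA-{getattr(RNA, '__version__', 'unknown')}"

    def _fold_raw(self, seq: str) -> Tuple[str, float]:
        structure, energy = self._rna.fold(seq)
        return structure, float(energy)


class OpenChainBackend(FoldingBackend):
    """Trivial deterministic backend: every sequence is an open chain, E = 0.

    Useful for engine tests that must not depend on thermodynamics.
    """

    id = "open-chain"

    def _fold_raw(self, seq: str) -> Tuple[str, float]:
        return "." * len(seq), 0.0


def p_fold(energy: float, c: float = 0.3) -> float:
    """Probability that a sequence with MFE *energy* is in the folded state.

    Boltzmann-type logistic ``1 / (1 + exp(c*E))`` with c > 0: an
    unstructured sequence (E = 0) folds with probability exactly 0.5 and the
    probability increases monotonically towards 1 as E decreases.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    return 1.0 / (1.0 + math.exp(c * energy))


def pair_table(structure: str) -> List[int]:
    """Map each position to its pairing partner (or -1 if unpaired).

    Raises ``ValueError`` on unbalanced brackets or foreign characters.
    """
    pt = [-1] * len(structure)
    stack: List[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unmatched ')' at position {i}")
            j = stack.pop()
            pt[j] = i
            pt[i] = j
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at {i}")
    if stack:
        raise ValueError(f"unmatched '(' at position {stack[-1]}")
    return pt


@dataclass(frozen=True)
class LoopElement:
    """A loop face of a secondary structure.

    ``unpaired`` lists the loop's unpaired sequence positions 5'->3'; for an
    internal loop the 5'-side run precedes the 3'-side run, and the rules in
    :mod:`mcrs.activity` index into that concatenated ordering.
    ``closing_pairs`` are the helix-terminal base pairs delimiting the loop
    (one for a hairpin, two for a bulge/internal loop, three or more for a
    multiloop, none for the exterior loop).
    """

    kind: str  # hairpin | bulge | internal | multiloop | exterior
    unpaired: Tuple[int, ...]
    closing_pairs: Tuple[Tuple[int, int], ...] = field(default=())

    @property
    def loop_length(self) -> int:
        return len(self.unpaired)


def decompose(fold: FoldResult) -> List[LoopElement]:
    """Decompose a dot-bracket structure into its loop elements.

    Every unpaired position belongs to exactly one returned element and
    every base pair to exactly one stem, so that
    ``sum(loop lengths) + 2 * n_pairs == L``.  Stacked helix pairs produce
    no element.  A multiloop is emitted even if it has no unpaired bases;
    the exterior loop is emitted only when it contains unpaired bases.
    """
    structure = fold.structure
    pt = pair_table(structure)
    n = len(structure)
    elements: List[LoopElement] = []

    # Exterior loop: unpaired positions at the top level.
    exterior: List[int] = []
    i = 0
    while i < n:
        if pt[i] == -1:
            exterior.append(i)
            i += 1
        else:
            i = pt[i] + 1
    if exterior:
        elements.append(LoopElement("exterior", tuple(exterior)))

    for i in range(n):
        j = pt[i]
        if j <= i:
            continue
        # The loop closed by pair (i, j): scan its interior.
        unpaired: List[int] = []
        children: List[Tuple[int, int]] = []
        k = i + 1
        while k < j:
            if pt[k] == -1:
                unpaired.append(k)
                k += 1
            else:
                children.append((k, pt[k]))
                k = pt[k] + 1
        if not children:
            elements.append(LoopElement("hairpin", tuple(unpaired), ((i, j),)))
        elif len(children) == 1:
            p, q = children[0]
            five = [u for u in unpaired if u < p]
            three = [u for u in unpaired if u > q]
            if not unpaired:
                continue  # stacked pair, part of a stem
            kind = "internal" if (five and three) else "bulge"
            elements.append(
                LoopElement(kind, tuple(five + three), ((i, j), (p, q)))
            )
        else:
            elements.append(
                LoopElement(
                    "multiloop", tuple(unpaired), tuple([(i, j)] + children)
                )
            )
    return elements
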