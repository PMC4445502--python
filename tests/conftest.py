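"""Shared fixtures: folding backends, designed ribozymes, reference parsers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("fixed", derandomize=True, deadline=None, database=None)
_hyp_settings.load_profile("fixed")

from mcrs.folding import (
    FoldingBackend,
    FoldResult,
    OpenChainBackend,
    ViennaRNABackend,
    BASES,
)

# --------------------------------------------------------------------------
# Designed mono-active ribozymes (synthetic test genotypes).  Each sequence
# was verified to fold, under the ViennaRNA backend, into a structure whose
# single catalytic loop matches the intended motif, with MFE below the
# -25 kcal/mol optimum (so p_deg is at its 0.1 floor).  test_activity
# re-verifies the motif assignments at run time.
RIBOZYME_1 = "GGGGGGGG" + "AA" + "GGGGGG" + "AAA" + "CCCCCC" + "AAA" + "CCCCCCCC"
RIBOZYME_2 = "GGGGGGGGGGGG" + "AAAAGAAAA" + "CCCCCCCCCCCC"
RIBOZYME_3 = "GGGGGGGGGGGG" + "AAAAACUCAAAAA" + "CCCCCCCCCCCC"
DESIGNED_RIBOZYMES = (RIBOZYME_1, RIBOZYME_2, RIBOZYME_3)


# --------------------------------------------------------------------------
# A synthetic tri-active genotype for engine tests that must not depend on
# real thermodynamics: TriActiveBackend maps any 51-nt sequence onto a fixed
# structure containing an internal loop of 5, a hairpin of 9 and a hairpin
# of 13.  TRI_SEQ places the catalytic bases (A/G/U) at the right loop
# positions, so a single molecule supplies all three activities.
TRI_STRUCT = (
    "((("        # outer stem 0-2
    + ".."       # internal loop 5' side 3-4
    + "((("      # inner stem 5-7
    + "((("      # hairpin-9 stem 8-10
    + "." * 9    # hairpin-9 loop 11-19
    + ")))"      # 20-22
    + "((("      # hairpin-13 stem 23-25
    + "." * 13   # hairpin-13 loop 26-38
    + ")))"      # 39-41
    + ")))"      # close inner stem 42-44
    + "..."      # internal loop 3' side 45-47
    + ")))"      # close outer stem 48-50
)
_tri = ["C"] * 51
_tri[45] = "A"  # internal-loop position 3 (concatenated ordering)
_tri[15] = "G"  # hairpin-9 position 5
_tri[32] = "U"  # hairpin-13 position 7
TRI_SEQ = "".join(_tri)


class TriActiveBackend(FoldingBackend):
    """Stub: every 51-nt sequence folds to TRI_STRUCT at -10 kcal/mol."""

    id = "tri-active-stub"

    def _fold_raw(self, seq):
        if len(seq) == len(TRI_STRUCT):
            return TRI_STRUCT, -10.0
        return "." * len(seq), 0.0


# --------------------------------------------------------------------------
# Independent reference parser for loop decomposition (test oracle).  It
# groups each unpaired position by its innermost enclosing pair, then
# classifies each group by the helix count directly below that pair —
# deliberately a different algorithm from mcrs.folding.decompose.


def reference_loops(structure: str):
    """Return {closing_pair_or_None: (kind, sorted unpaired positions)}."""
    stack = []
    pairs = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    pairs.sort()
    by_pair = {}

    def innermost(i):
        best = None
        for p, q in pairs:
            if p < i < q and (best is None or p > best[0]):
                best = (p, q)
        return best

    for i, ch in enumerate(structure):
        if ch == ".":
            by_pair.setdefault(innermost(i), []).append(i)

    paired = {p for pr in pairs for p in pr}

    def direct_children(p, q):
        kids = []
        k = p + 1
        while k < q:
            if k in paired and structure[k] == "(":
                mate = next(b for a, b in pairs if a == k)
                kids.append((k, mate))
                k = mate + 1
            else:
                k += 1
        return kids

    out = {}
    for key, positions in by_pair.items():
        if key is None:
            out[None] = ("exterior", sorted(positions))
            continue
        kids = direct_children(*key)
        if len(kids) == 0:
            kind = "hairpin"
        elif len(kids) == 1:
            (p, q) = kids[0]
            five = [u for u in positions if u < p]
            three = [u for u in positions if u > q]
            kind = "internal" if (five and three) else "bulge"
        else:
            kind = "multiloop"
        out[key] = (kind, sorted(positions))
    # multiloops with no unpaired bases
    for p, q in pairs:
        if (p, q) in out:
            continue
        kids = direct_children(p, q)
        if len(kids) >= 2:
            out[(p, q)] = ("multiloop", [])
    return out


def reference_rule_checker(seq: str, structure: str):
    """Literal, brute-force application of the three motif rules.

    Independent oracle: enumerates loops via reference_loops and tests each
    rule exactly as stated, returning the per-reaction maximum raw alphas.
    """
    best = [0.0, 0.0, 0.0]

    def consider(ridx, val):
        if val > best[ridx - 1]:
            best[ridx - 1] = val

    for key, (kind, pos) in reference_loops(structure).items():
        n = len(pos)
        if kind in ("internal", "bulge"):
            if n == 5 and seq[pos[2]] == "A":
                helper = seq[pos[1]] == "U" or seq[pos[3]] == "U"
                consider(1, 1.1 if helper else 1.0)
            if n == 4 and "A" in (seq[pos[1]], seq[pos[2]]):
                consider(1, 0.1)
        if kind == "hairpin":
            if n == 9 and seq[pos[4]] == "G":
                helper = seq[pos[3]] == "A" or seq[pos[5]] == "A"
                consider(2, 1.1 if helper else 1.0)
            if n == 8 and "G" in (seq[pos[3]], seq[pos[4]]):
                consider(2, 0.1)
            if n == 13 and seq[pos[6]] == "U":
                helper = seq[pos[5]] == "C" or seq[pos[7]] == "C"
                consider(3, 1.1 if helper else 1.0)
            if n == 12 and "U" in (seq[pos[5]], seq[pos[6]]):
                consider(3, 0.1)
    return tuple(best)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


# ------------------------------------------------------------------ fixtures


@pytest.fixture(scope="session")
def vienna():
    return ViennaRNABackend()


@pytest.fixture()
def open_chain():
    return OpenChainBackend()


@pytest.fixture()
def tri_backend():
    return TriActiveBackend()
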