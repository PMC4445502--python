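"""The Replicator: a sequence with its cached fold and derived phenotype."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from . import activity, fitness, folding

__all__ = ["Replicator", "PhenotypeFactory"]


@dataclass(frozen=True)
class Replicator:
    """An immutable genotype + phenotype bundle occupying one lattice site.

    Instances for identical sequences are shared (built once per genotype by
    :class:`PhenotypeFactory`), so the grid may hold many references to one
    object.
    """

    sequence: str
    structure: str
    energy: float
    alphas: Tuple[float, float, float]
    effective: Tuple[float, float, float]
    m: int
    p_fold: float
    p_deg: float
    replicability: float

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_parasite(self) -> bool:
        return self.m == 0


class PhenotypeFactory:
    """Builds (and memoises) the full phenotype of a genotype.

    Pipeline: fold to the MFE structure, decompose into loops, detect
    catalytic motifs, then derive p_fold, the promiscuity-penalised
    effective activities, the decay probability and the replicability.
    """

    def __init__(
        self,
        backend: folding.FoldingBackend,
        params: fitness.KineticParams,
    ) -> None:
        self.backend = backend
        self.params = params
        self._cache: Dict[str, Replicator] = {}

    def build(self, sequence: str) -> Replicator:
        hit = self._cache.get(sequence)
        if hit is not None:
            return hit
        params = self.params
        fold = self.backend.fold(sequence)
        loops = folding.decompose(fold)
        sites = activity.detect_sites(sequence, loops)
        alphas = activity.raw_alphas(sites)
        pf = folding.p_fold(fold.energy, params.c)
        eff = activity.effective_activities(alphas, pf, params.sigma)
        rep = Replicator(
            sequence=sequence,
            structure=fold.structure,
            energy=fold.energy,
            alphas=alphas,
            effective=eff,
            m=sum(1 for a in alphas if a > 0),
            p_fold=pf,
            p_deg=fitness.degradation_prob(fold.energy, params),
            replicability=fitness.replicability(len(sequence), pf, params),
        )
        self._cache[sequence] = rep
        return rep

    @property
    def cache_size(self) -> int:
        return len(self._cache)
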