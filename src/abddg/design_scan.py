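"""Design mode: systematic interface mutation scanning.

Enumerates every double- or triple-point mutation of interface residues on
one side of the complex (all site combinations × 19 substitutions per site,
lazily streamed) and ranks candidates by predicted ΔΔG, keeping only the top
increasing and decreasing lists in memory.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Iterator

from .model import Featurizer, TrainedModel, predict
from .structure_io import (
    AA1_TO_3,
    Complex,
    MultiMutation,
    MutationSpec,
    StructureError,
    distance_to_partner,
    interface_residues,
)

__all__ = ["DesignResult", "enumerate_designs", "rank_designs"]

logger = logging.getLogger(__name__)

AA_LETTERS = sorted(AA1_TO_3)
STRAIN_PRONE = {"P", "G"}  # flagged, not excluded: template grafting ignores backbone strain


@dataclass
class DesignResult:
    mutation: MultiMutation
    predicted_ddg: float
    site_interface_distances: list[float]
    rank: int
    backbone_strain_flag: bool = False


def enumerate_designs(
    complex_: Complex,
    side: str,
    order: int = 2,
    interface_cutoff: float = 5.0,
) -> Iterator[MultiMutation]:
    """Lazily yield all C(n_sites, order) × 19^order candidate multi-mutations
    over the interface residues of one side ('antibody' or 'antigen')."""
    if side not in ("antibody", "antigen"):
        raise ValueError("side must be 'antibody' or 'antigen'")
    if order < 1:
        raise ValueError("order must be at least 1")
    chains = complex_.antibody_chains if side == "antibody" else complex_.antigen_chains
    sites = sorted(
        k for k in interface_residues(complex_, interface_cutoff) if k[0] in chains
    )
    sites = [k for k in sites if complex_.residue(k).aa1 is not None]
    if not sites:
        raise StructureError(f"no interface residues on the {side} side")
    for combo in combinations(sites, order):
        wt = [complex_.residue(k).aa1 for k in combo]
        options = [[aa for aa in AA_LETTERS if aa != w] for w in wt]
        for mts in product(*options):
            yield MultiMutation(
                tuple(
                    MutationSpec(k[0], w, k[1], k[2], m)
                    for k, w, m in zip(combo, wt, mts)
                )
            )


def rank_designs(
    model: TrainedModel,
    featurizer: Featurizer,
    complex_: Complex,
    candidates: Iterable[MultiMutation],
    top_n: int = 100,
    log_every: int = 1000,
) -> tuple[list[DesignResult], list[DesignResult]]:
    """Score candidates and return (top increasing, top decreasing) lists,
    each of length ≤ top_n, sorted by predicted ΔΔG descending / ascending.

    Streaming: only two bounded heaps of size top_n are resident regardless
    of candidate count. Deterministic given the model (ties broken by the
    mutation string so ranking is reproducible)."""
    top_inc: list = []  # min-heap of (ddg, tiebreak, mutation)
    top_dec: list = []  # max-heap via negated ddg
    n_scored = 0
    for mutation in candidates:
        ddg = predict(model, featurizer, complex_, mutation)
        tiebreak = str(mutation)
        entry_inc = (ddg, tiebreak, mutation)
        entry_dec = (-ddg, tiebreak, mutation)
        if len(top_inc) < top_n:
            heapq.heappush(top_inc, entry_inc)
        elif entry_inc > top_inc[0]:
            heapq.heapreplace(top_inc, entry_inc)
        if len(top_dec) < top_n:
            heapq.heappush(top_dec, entry_dec)
        elif entry_dec > top_dec[0]:
            heapq.heapreplace(top_dec, entry_dec)
        n_scored += 1
        if log_every and n_scored % log_every == 0:
            logger.info("design scan: %d candidates scored", n_scored)

    def finalize(heap, sign: float) -> list[DesignResult]:
        # heap entries are (sign * ddg, ...); best-first = largest entry first
        entries = sorted(heap, reverse=True)
        results = []
        for rank, entry in enumerate(entries, start=1):
            ddg = sign * entry[0]
            mutation = entry[2]
            results.append(
                DesignResult(
                    mutation=mutation,
                    predicted_ddg=float(ddg),
                    site_interface_distances=[
                        distance_to_partner(complex_, s) for s in mutation.sites
                    ],
                    rank=rank,
                    backbone_strain_flag=any(
                        s.mt_aa in STRAIN_PRONE for s in mutation
                    ),
                )
            )
        return results

    return finalize(top_inc, 1.0), finalize(top_dec, -1.0)
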