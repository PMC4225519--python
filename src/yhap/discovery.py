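"""Candidate novel haplogroup markers from converged free rows of H*.

After EM, a free row whose allele distribution has converged toward a
degenerate {0,1} or {1,0} in exactly one haplogroup — while every other
haplogroup retains the opposite allele — marks a mutation exclusive to
that haplogroup in the population studied: a candidate new marker for the
tree.  Marker rows are fixed by construction and can never be reported.

Thresholds (characteristic-allele probability, maximum probability of the
same allele in any other haplogroup, and minimum effective sample support
sum_j r_jl) are reporting choices, all exposed as parameters and CLI
flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NotFittedError
from .likelihood import AugmentedMatrix

__all__ = ["CandidateMarker", "discover", "write_candidates"]


@dataclass(frozen=True)
class CandidateMarker:
    """A free-row site proposed as a new marker for one haplogroup."""

    position: int
    ref: str
    alt: str
    node_label: str
    characteristic_allele: str  # "ref" or "alt"
    allele_prob: float  # converged probability of that allele in the haplogroup
    exclusivity: float  # max probability of the same allele in any other node
    support: float  # effective sample count sum_j r_jl


def discover(
    h_star: AugmentedMatrix,
    responsibilities: np.ndarray | None,
    active_nodes: list[str],
    min_prob: float = 0.95,
    max_other: float = 0.05,
    min_support: float = 2.0,
) -> list[CandidateMarker]:
    """Scan free rows for haplogroup-exclusive alleles.

    A candidate requires one active node's probability of an allele to be
    at least ``min_prob`` (alt-characteristic if H*_il1 >= min_prob,
    ref-characteristic if H*_il1 <= 1 - min_prob), every other active
    node's probability of that same allele at most ``max_other``, and
    effective support sum_j r_jl at least ``min_support``.  Candidates are
    sorted by decreasing exclusivity margin (allele_prob - exclusivity).

    Exclusivity is taken over the *informed* competitors only: a
    haplogroup whose support falls below ``min_support`` has no samples in
    the population, its allele distribution was never updated from the
    uninformative prior, and exclusivity "in the population studied"
    cannot be contradicted by it.

    Raises :class:`NotFittedError` when called on an H* whose free rows
    were never fit (all still exactly {0.5,0.5} and no responsibilities
    supplied).
    """
    free = h_star.free_rows
    cols = np.array([h_star.node_order.index(lab) for lab in active_nodes])
    never_fit = free.size > 0 and bool(np.all(h_star.alt_probs[free][:, cols] == 0.5))
    if responsibilities is None:
        if never_fit or free.size == 0:
            raise NotFittedError("H* free rows were never fit by EM")
        raise NotFittedError("responsibilities are required to compute support")

    support = np.asarray(responsibilities, dtype=float).sum(axis=0)  # (A,)
    informed = support >= min_support
    alt_p = h_star.alt_probs[np.ix_(free, cols)]  # (F, A)
    out: list[CandidateMarker] = []
    for f, row_idx in enumerate(free):
        site = h_star.sites[row_idx]
        for a, lab in enumerate(active_nodes):
            for allele_name, p_allele in (("alt", alt_p[f]), ("ref", 1.0 - alt_p[f])):
                if p_allele[a] < min_prob:
                    continue
                other_mask = informed.copy()
                other_mask[a] = False
                others = p_allele[other_mask]
                excl = float(others.max()) if others.size else 0.0
                if excl > max_other or support[a] < min_support:
                    continue
                out.append(
                    CandidateMarker(
                        site.pos, site.ref, site.alt, lab, allele_name,
                        float(p_allele[a]), excl, float(support[a]),
                    )
                )
    out.sort(key=lambda cand: -(cand.allele_prob - cand.exclusivity))
    return out


_COLUMNS = [
    "pos", "ref", "alt", "node", "characteristic_allele",
    "allele_prob", "exclusivity", "support",
]


def write_candidates(candidates: list[CandidateMarker], path: str | Path) -> None:
    """TSV report (header always written, even when empty)."""
    pd.DataFrame(
        [
            {
                "pos": c.position, "ref": c.ref, "alt": c.alt, "node": c.node_label,
                "characteristic_allele": c.characteristic_allele,
                "allele_prob": c.allele_prob, "exclusivity": c.exclusivity,
                "support": c.support,
            }
            for c in candidates
        ],
        columns=_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
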