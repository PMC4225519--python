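"""Known Y-SNP markers and the haplogroup allele-probability matrix H.

Each marker is a bi-allelic SNV whose derived ("mutant") allele defines
membership in the clade below one tree node.  The marker table is required
to be pre-normalized: forward strand, explicit ref/alt, and a flag saying
whether the derived allele equals the VCF alternate.  From the table and
the tree we build the fixed matrix H of per-site, per-node allele
probability 2-vectors {H_ilg}, g in {0=ref, 1=alt}:

* at a leaf the vector is degenerate, {0,1} or {1,0}, depending on whether
  the leaf lies inside the marker's clade;
* at an internal node it is the proportion of descendant leaves carrying
  each allele (each leaf counted once; branch lengths play no role).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DuplicateSiteError, UnknownNodeError
from .tree import HaplogroupTree

__all__ = ["MarkerRecord", "MarkerMatrix", "build_marker_matrix", "read_markers", "write_markers"]

logger = logging.getLogger(__name__)

_NUCS = frozenset("ACGT")


@dataclass(frozen=True)
class MarkerRecord:
    """One pre-normalized Y-SNP marker.

    position is 1-based on the Y reference; ``mutant_is_alt`` says whether
    the derived allele is the VCF alternate (True) or the reference (False).
    """

    name: str
    position: int
    ref_allele: str
    alt_allele: str
    node_label: str
    mutant_is_alt: bool

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"marker {self.name}: position must be positive")
        if self.ref_allele not in _NUCS or self.alt_allele not in _NUCS:
            raise ValueError(f"marker {self.name}: alleles must be single A/C/G/T bases")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"marker {self.name}: ref and alt alleles are identical")


@dataclass
class MarkerMatrix:
    """The N_ref x L matrix H of allele-probability 2-vectors.

    Only the alternate-allele probability is stored (``alt_probs``); the
    reference probability is its complement, so every 2-vector sums to 1
    by construction.
    """

    sites: list[MarkerRecord]
    node_order: list[str]
    alt_probs: np.ndarray  # (N_ref, L)
    positions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.positions = np.array([m.position for m in self.sites], dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def probs(self) -> np.ndarray:
        """Full (N_ref, L, 2) array of {ref, alt} probability vectors."""
        return np.stack([1.0 - self.alt_probs, self.alt_probs], axis=-1)


def build_marker_matrix(
    tree: HaplogroupTree,
    markers: list[MarkerRecord],
    allow_duplicate_positions: bool = False,
) -> MarkerMatrix:
    """Place markers on the tree and build H.

    For marker i defining node m: every leaf in the clade below m carries
    the derived allele with probability 1, every other leaf the ancestral
    allele; internal-node vectors are leaf-count-weighted means over their
    descendant leaves.

    Duplicate positions are rejected unless ``allow_duplicate_positions``,
    in which case the first marker at a position wins and a warning is
    logged.
    """
    kept: list[MarkerRecord] = []
    seen_pos: dict[int, str] = {}
    for m in markers:
        if m.node_label not in tree.index:
            raise UnknownNodeError(f"marker {m.name}: unknown node {m.node_label!r}")
        if m.position in seen_pos:
            if not allow_duplicate_positions:
                raise DuplicateSiteError(
                    f"markers {seen_pos[m.position]} and {m.name} share position {m.position}"
                )
            logger.warning(
                "dropping marker %s: position %d already used by %s",
                m.name, m.position, seen_pos[m.position],
            )
            continue
        seen_pos[m.position] = m.name
        kept.append(m)

    desc = tree.descendant_leaf_mask()  # (L, n_leaves)
    leaf_counts = desc.sum(axis=1).astype(float)
    # derived-allele indicator per leaf, converted to alt-allele space
    leaf_alt = np.empty((len(kept), desc.shape[1]))
    for i, m in enumerate(kept):
        in_clade = desc[tree.index[m.node_label]]
        leaf_alt[i] = in_clade if m.mutant_is_alt else ~in_clade
    alt_probs = leaf_alt @ desc.T / leaf_counts  # (N_ref, L)
    return MarkerMatrix(kept, list(tree.labels), alt_probs)


_COLUMNS = ["name", "pos", "ref", "alt", "node", "mutant_is_alt"]


def read_markers(path: str | Path) -> list[MarkerRecord]:
    """Read a marker table TSV (columns name, pos, ref, alt, node,
    mutant_is_alt; '#' comment lines ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"name": str, "node": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker table missing columns: {missing}")
    return [
        MarkerRecord(
            name=row["name"],
            position=int(row["pos"]),
            ref_allele=str(row["ref"]).upper(),
            alt_allele=str(row["alt"]).upper(),
            node_label=row["node"],
            mutant_is_alt=str(row["mutant_is_alt"]).lower() in ("true", "1", "yes"),
        )
        for _, row in df.iterrows()
    ]


def write_markers(markers: list[MarkerRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": m.name,
                "pos": m.position,
                "ref": m.ref_allele,
                "alt": m.alt_allele,
                "node": m.node_label,
                "mutant_is_alt": m.mutant_is_alt,
            }
            for m in markers
        ],
        columns=_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
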