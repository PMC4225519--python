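"""Haplogroup assignment: sample likelihoods and posteriors.

For sample j and haplogroup node l the model assumes sites are independent
given the haplogroup:

    P(G_.j | H*_.l) = prod_i sum_g P(G_ij | g) P(g | H*_il),
    P(g | H*_il) = H*_ilg,  P(G_ij | g) = G_ijg

and the posterior over an active node set follows by Bayes' rule with a
(by default uniform) haplogroup prior.  All products are accumulated in
log space with log-sum-exp normalization; a naive product underflows once
N reaches the thousands.

The active node set is configurable: the 20 major clades (A-T by default),
all leaves (finest resolution), or every node.  A MAP call at the fine
level can additionally be rolled up into major clades by summing leaf
posteriors within each clade — an explicit report, never an implicit
renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import (
    EmptyNodeSetError,
    NumericalUnderflowError,
    ShapeError,
    UnknownNodeError,
)
from .likelihood import AugmentedMatrix, LikelihoodMatrix
from .tree import HaplogroupTree

__all__ = [
    "HaplogroupPrior",
    "AssignmentResult",
    "sample_log_likelihood",
    "cohort_log_likelihoods",
    "restrict_nodes",
    "posterior_for_sample",
    "assign_cohort",
    "rollup_major",
    "write_assignments",
    "read_assignments",
]

DEFAULT_MAJOR_CLADES = tuple(chr(c) for c in range(ord("A"), ord("T") + 1))


@dataclass
class HaplogroupPrior:
    """Prior P(H*_.l) over the active haplogroup set."""

    node_order: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.node_order),):
            raise ShapeError("prior length does not match node set")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("prior must be a probability distribution")

    @classmethod
    def uniform(cls, node_order: list[str]) -> "HaplogroupPrior":
        n = len(node_order)
        if n == 0:
            raise EmptyNodeSetError("cannot build a prior over an empty node set")
        return cls(list(node_order), np.full(n, 1.0 / n))


@dataclass
class AssignmentResult:
    """One sample's posterior over the active set, with its MAP call."""

    sample_id: str
    node_order: list[str]
    posterior: np.ndarray
    map_call: str
    map_prob: float
    log_evidence: float
    tie: bool = False


def sample_log_likelihood(G_col: np.ndarray, H_col: np.ndarray) -> float:
    """Log of Eq.-style product-sum likelihood for one sample and one node.

    Parameters are (N, 2) arrays of likelihood and allele-probability
    vectors over the same N sites.  Missing sites ({1,1} likelihood)
    contribute log(H_il0 + H_il1) = 0.
    """
    G_col = np.asarray(G_col, dtype=float)
    H_col = np.asarray(H_col, dtype=float)
    if G_col.shape != H_col.shape or G_col.ndim != 2 or G_col.shape[1] != 2:
        raise ShapeError(f"incompatible shapes {G_col.shape} vs {H_col.shape}")
    inner = G_col[:, 0] * H_col[:, 0] + G_col[:, 1] * H_col[:, 1]
    with np.errstate(divide="ignore"):
        return float(np.log(inner).sum())


def cohort_log_likelihoods(
    G: LikelihoodMatrix, H_star: AugmentedMatrix, active_nodes: list[str]
) -> np.ndarray:
    """(M, A) matrix of log P(G_.j | H*_.l) over the active node set."""
    if not active_nodes:
        raise EmptyNodeSetError("active node set is empty")
    if G.n_sites != H_star.n_sites:
        raise ShapeError(
            f"likelihoods cover {G.n_sites} sites but H* has {H_star.n_sites}"
        )
    node_idx = {lab: i for i, lab in enumerate(H_star.node_order)}
    try:
        cols = [node_idx[lab] for lab in active_nodes]
    except KeyError as exc:
        raise UnknownNodeError(f"active node {exc.args[0]!r} not in H*") from None
    g0, g1 = G.lik[:, :, 0], G.lik[:, :, 1]  # (N, M)
    out = np.empty((G.n_samples, len(cols)))
    with np.errstate(divide="ignore"):
        for a, c in enumerate(cols):
            p = H_star.alt_probs[:, c]  # (N,)
            inner = g0 * (1.0 - p)[:, None] + g1 * p[:, None]
            out[:, a] = np.log(inner).sum(axis=0)
    return out


def restrict_nodes(
    tree: HaplogroupTree,
    level: str,
    major_labels: list[str] | None = None,
) -> list[str]:
    """Choose the active haplogroup set.

    ``major`` selects the configured major-clade roots (default: the
    single-letter clades A-T, keeping those present in the tree; an
    explicitly configured label must exist).  ``leaves`` selects all leaf
    labels, ``all`` every node.
    """
    if level == "leaves":
        return tree.leaf_labels
    if level == "all":
        return list(tree.labels)
    if level == "major":
        if major_labels is not None:
            missing = [m for m in major_labels if m not in tree.index]
            if missing:
                raise UnknownNodeError(f"configured major clades not in tree: {missing}")
            return list(major_labels)
        present = [m for m in DEFAULT_MAJOR_CLADES if m in tree.index]
        if not present:
            raise UnknownNodeError(
                "none of the default major clades A-T are in the tree; "
                "pass an explicit major-clade list"
            )
        return present
    raise ValueError(f"unknown level {level!r} (expected major/leaves/all)")


def _posteriors_from_loglik(
    loglik: np.ndarray, prior: HaplogroupPrior
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize (M, A) log-likelihoods against the prior; returns
    (posterior (M, A), log-evidence (M,))."""
    with np.errstate(divide="ignore"):
        log_joint = loglik + np.log(prior.probs)[None, :]
    log_ev = logsumexp(log_joint, axis=1)
    if np.any(np.isneginf(log_ev)):
        bad = int(np.flatnonzero(np.isneginf(log_ev))[0])
        raise NumericalUnderflowError(
            f"sample index {bad}: zero likelihood for every active haplogroup "
            "(epsilon floor disabled?)"
        )
    post = np.exp(log_joint - log_ev[:, None])
    return post, log_ev


def _result(
    sample_id: str, active_nodes: list[str], post: np.ndarray, log_ev: float
) -> AssignmentResult:
    best = int(np.argmax(post))  # argmax takes the first maximum: preorder tie-break
    tie = bool(np.sum(post == post[best]) > 1)
    return AssignmentResult(
        sample_id, list(active_nodes), post, active_nodes[best], float(post[best]),
        float(log_ev), tie,
    )


def posterior_for_sample(
    G_col: np.ndarray,
    H_star: AugmentedMatrix,
    prior: HaplogroupPrior,
    active_nodes: list[str],
    sample_id: str = "sample",
) -> AssignmentResult:
    """Posterior over ``active_nodes`` for a single sample's (N, 2)
    likelihood column."""
    G = LikelihoodMatrix(list(H_star.sites), [sample_id], np.asarray(G_col, float)[:, None, :])
    return assign_cohort(G, H_star, prior, active_nodes)[0]


def assign_cohort(
    G: LikelihoodMatrix,
    H_star: AugmentedMatrix,
    prior: HaplogroupPrior,
    active_nodes: list[str],
) -> list[AssignmentResult]:
    """Posterior for every sample in the cohort, order preserved."""
    if list(prior.node_order) != list(active_nodes):
        raise ValueError("prior is not defined on the active node set")
    loglik = cohort_log_likelihoods(G, H_star, active_nodes)
    post, log_ev = _posteriors_from_loglik(loglik, prior)
    return [
        _result(s, active_nodes, post[j], log_ev[j])
        for j, s in enumerate(G.sample_ids)
    ]


def rollup_major(
    results: list[AssignmentResult],
    tree: HaplogroupTree,
    major_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Sum fine-level (leaf) posteriors within each major clade.

    Leaves not below any configured major clade are collected under
    ``OTHER``.  Returns one row per sample with per-clade posterior mass
    and the major-level MAP call.
    """
    majors = restrict_nodes(tree, "major", major_labels)
    clade_of: dict[str, str] = {}
    for m in majors:
        for leaf in tree.leaf_set(m):
            clade_of[leaf] = m
    cols = majors + ["OTHER"]
    rows = []
    for r in results:
        mass = dict.fromkeys(cols, 0.0)
        for lab, p in zip(r.node_order, r.posterior):
            mass[clade_of.get(lab, "OTHER")] += float(p)
        best = max(cols, key=lambda c: mass[c])
        rows.append({"sample_id": r.sample_id, "map_major": best, **mass})
    df = pd.DataFrame(rows)
    if (df["OTHER"] == 0).all():
        df = df.drop(columns=["OTHER"])
    return df


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_assignments(results: list[AssignmentResult], path: str | Path) -> None:
    """Write per-sample results: sample_id, map_call, map_prob,
    log_evidence, tie, then one posterior column per active node."""
    if not results:
        raise EmptyNodeSetError("no results to write")
    nodes = results[0].node_order
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id,
            "map_call": r.map_call,
            "map_prob": r.map_prob,
            "log_evidence": r.log_evidence,
            "tie": r.tie,
        }
        row.update({lab: float(p) for lab, p in zip(r.node_order, r.posterior)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_assignments(path: str | Path) -> list[AssignmentResult]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = ["sample_id", "map_call", "map_prob", "log_evidence", "tie"]
    nodes = [c for c in df.columns if c not in meta]
    return [
        AssignmentResult(
            str(row["sample_id"]),
            nodes,
            row[nodes].to_numpy(dtype=float),
            str(row["map_call"]),
            float(row["map_prob"]),
            float(row["log_evidence"]),
            bool(row["tie"]),
        )
        for _, row in df.iterrows()
    ]
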