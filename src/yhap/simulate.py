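"""Synthetic haplogroup trees, marker tables, cohorts and read likelihoods.

The generator emulates the data regime the model targets: a population
sample of haploid Y chromosomes, each belonging to one leaf haplogroup of
a known tree, sequenced at low coverage (mean depth around 1-2 reads per
site, Poisson) with a small per-read error rate.  Three site classes are
produced:

* marker sites — known Y-SNPs placed on tree branches (every non-root
  branch carries a configurable number);
* clade-private free sites — the derived allele occurs only in one
  designated leaf haplogroup: the signal class EM learns and discovery
  reports;
* shared noise sites — alleles drawn per sample at frequency 0.5,
  independent of haplogroup: uninformative background.

Everything is deterministic given the spec and seed; per-stage RNGs are
derived from a single :class:`numpy.random.SeedSequence` so byte-identical
outputs (including VCFs) are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import LikelihoodMatrix, Site, _floor
from .markers import MarkerRecord
from .tree import HaplogroupTree, _build

__all__ = [
    "SimulationSpec",
    "TruthSet",
    "SimulatedData",
    "simulate_tree",
    "simulate_markers",
    "simulate_cohort",
    "simulate_read_likelihoods",
    "simulate_dataset",
]

_POS_RANGE = (1, 20_000_000)
_PL_CAP = 255


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the low-coverage population-sequencing regime the
    method targets: a 20-leaf haplogroup tree with 3 markers per branch, a
    40-sample cohort drawn uniformly over leaves, mean depth 1.5 reads per
    site and a 0.5% per-read error rate; 5 clade-private sites per leaf
    and 30 uninformative noise sites.
    """

    n_leaves: int = 20
    markers_per_branch: int = 3
    private_free_sites_per_leaf: int = 5
    shared_noise_sites: int = 30
    cohort_size: int = 40
    haplogroup_freqs: tuple[float, ...] | None = None  # None -> uniform over leaves
    mean_depth: float = 1.5
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.haplogroup_freqs is not None:
            f = np.asarray(self.haplogroup_freqs, dtype=float)
            if f.size != self.n_leaves or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("haplogroup_freqs must be a distribution over leaves")

    def freqs(self) -> np.ndarray:
        if self.haplogroup_freqs is None:
            return np.full(self.n_leaves, 1.0 / self.n_leaves)
        return np.asarray(self.haplogroup_freqs, dtype=float)


@dataclass
class TruthSet:
    """Ground truth backing one simulated cohort.

    ``leaf_alt`` holds each leaf haplogroup's true alternate-allele
    indicator per site; noise-site rows are per-sample (leaf-independent)
    and marked NaN here, with the realized draws in ``genotypes``.
    """

    sample_ids: list[str]
    true_leaf: list[str]
    sites: list[Site]
    site_kind: list[str]  # 'marker' | 'private' | 'noise'
    private_leaf: list[str | None]  # designated leaf for private sites
    leaf_order: list[str]
    leaf_alt: np.ndarray  # (N, n_leaves), NaN on noise rows
    genotypes: np.ndarray  # (N, M) of 0/1

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": self.sample_ids, "true_haplogroup": self.true_leaf}
        ).to_csv(path, sep="\t", index=False)

    def planted_sites(self) -> list[int]:
        """Row indices of clade-private (planted) sites."""
        return [i for i, k in enumerate(self.site_kind) if k == "private"]


@dataclass
class SimulatedData:
    """Bundle returned by :func:`simulate_dataset`."""

    spec: SimulationSpec
    tree: HaplogroupTree
    markers: list[MarkerRecord]
    truth: TruthSet
    likelihoods: LikelihoodMatrix
    depths: np.ndarray = field(repr=False)  # (N, M) read depths
    alt_reads: np.ndarray = field(repr=False)  # (N, M) alt-supporting reads


def simulate_tree(n_leaves: int, seed: int) -> HaplogroupTree:
    """Random rooted bifurcating tree with deterministic labels.

    Grown by repeatedly splitting a uniformly chosen leaf into two
    children; leaves are labelled HG001.. and internal nodes IN001.. (root
    ROOT) in preorder, so the same seed always yields the same newick.
    """
    rng = np.random.default_rng(seed)
    children: dict[int, list[int]] = {0: []}
    leaves = [0]
    nxt = 1
    while len(leaves) < n_leaves:
        k = int(rng.integers(len(leaves)))
        node = leaves.pop(k)
        kids = [nxt, nxt + 1]
        nxt += 2
        children[node] = kids
        for c in kids:
            children[c] = []
        leaves.extend(kids)

    # preorder relabel
    labels: dict[int, str] = {}
    n_leaf = n_int = 0
    order: list[tuple[int, int | None]] = []  # (node, parent)
    stack: list[tuple[int, int | None]] = [(0, None)]
    while stack:
        node, par = stack.pop()
        order.append((node, par))
        for c in reversed(children[node]):
            stack.append((c, node))
    for node, par in order:
        if children[node]:
            labels[node] = "ROOT" if par is None else f"IN{n_int:03d}"
            n_int += 1
        else:
            n_leaf += 1
            labels[node] = f"HG{n_leaf:03d}"
    return _build(
        [(labels[n], None if p is None else labels[p]) for n, p in order]
    )


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    nucs = np.array(list("ACGT"))
    ref = nucs[rng.integers(4, size=n)]
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    return ref, alt


def _unique_positions(rng: np.random.Generator, n: int, exclude: set[int]) -> np.ndarray:
    out: list[int] = []
    taken = set(exclude)
    while len(out) < n:
        cand = rng.integers(_POS_RANGE[0], _POS_RANGE[1], size=2 * (n - len(out)))
        for p in cand:
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
                if len(out) == n:
                    break
    return np.array(out, dtype=np.int64)


def simulate_markers(
    tree: HaplogroupTree,
    markers_per_branch: int,
    seed: int,
    exclude_positions: set[int] | None = None,
) -> list[MarkerRecord]:
    """Place ``markers_per_branch`` markers on every non-root branch, with
    unique random positions and 50/50 derived-allele orientation."""
    rng = np.random.default_rng(seed)
    branch_nodes = [lab for lab in tree.labels if lab != tree.root]
    n = len(branch_nodes) * markers_per_branch
    pos = _unique_positions(rng, n, exclude_positions or set())
    ref, alt = _draw_alleles(rng, n)
    mutant_is_alt = rng.random(n) < 0.5
    out = []
    i = 0
    for node in branch_nodes:
        for _ in range(markers_per_branch):
            out.append(
                MarkerRecord(
                    name=f"M{i + 1:04d}",
                    position=int(pos[i]),
                    ref_allele=str(ref[i]),
                    alt_allele=str(alt[i]),
                    node_label=node,
                    mutant_is_alt=bool(mutant_is_alt[i]),
                )
            )
            i += 1
    return out


def simulate_cohort(
    tree: HaplogroupTree,
    markers: list[MarkerRecord],
    spec: SimulationSpec,
    seed: int | None = None,
) -> TruthSet:
    """Draw sample haplogroups and true genotypes at all site classes.

    Marker-site alleles follow clade membership; each leaf receives
    ``private_free_sites_per_leaf`` sites carrying the alternate allele in
    that leaf only; noise-site alleles are drawn per sample at frequency
    0.5 regardless of haplogroup.  Sites are ordered by position.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    leaf_order = tree.leaf_labels
    leaf_idx = {lab: k for k, lab in enumerate(leaf_order)}
    desc = tree.descendant_leaf_mask()
    M = spec.cohort_size

    sample_leaves = rng.choice(len(leaf_order), size=M, p=spec.freqs())
    sample_ids = [f"S{j + 1:03d}" for j in range(M)]
    true_leaf = [leaf_order[int(k)] for k in sample_leaves]

    sites: list[Site] = []
    kind: list[str] = []
    priv_leaf: list[str | None] = []
    leaf_alt_rows: list[np.ndarray] = []

    for m in markers:
        in_clade = desc[tree.index[m.node_label]]
        row = in_clade if m.mutant_is_alt else ~in_clade
        sites.append(Site(m.position, m.ref_allele, m.alt_allele))
        kind.append("marker")
        priv_leaf.append(None)
        leaf_alt_rows.append(row.astype(float))

    used = {m.position for m in markers}
    n_priv = spec.private_free_sites_per_leaf * len(leaf_order)
    n_noise = spec.shared_noise_sites
    pos = _unique_positions(rng, n_priv + n_noise, used)
    ref, alt = _draw_alleles(rng, n_priv + n_noise)
    i = 0
    for leaf in leaf_order:
        for _ in range(spec.private_free_sites_per_leaf):
            row = np.zeros(len(leaf_order))
            row[leaf_idx[leaf]] = 1.0
            sites.append(Site(int(pos[i]), str(ref[i]), str(alt[i])))
            kind.append("private")
            priv_leaf.append(leaf)
            leaf_alt_rows.append(row)
            i += 1
    for _ in range(n_noise):
        sites.append(Site(int(pos[i]), str(ref[i]), str(alt[i])))
        kind.append("noise")
        priv_leaf.append(None)
        leaf_alt_rows.append(np.full(len(leaf_order), np.nan))
        i += 1

    leaf_alt = np.vstack(leaf_alt_rows) if leaf_alt_rows else np.empty((0, len(leaf_order)))
    N = len(sites)
    genotypes = np.zeros((N, M), dtype=np.int8)
    noise_mask = np.array([k == "noise" for k in kind])
    for j, k in enumerate(sample_leaves):
        genotypes[~noise_mask, j] = leaf_alt[~noise_mask, int(k)].astype(np.int8)
    genotypes[noise_mask] = (rng.random((int(noise_mask.sum()), M)) < 0.5).astype(np.int8)

    order = np.argsort([s.pos for s in sites], kind="stable")
    return TruthSet(
        sample_ids=sample_ids,
        true_leaf=true_leaf,
        sites=[sites[i] for i in order],
        site_kind=[kind[i] for i in order],
        private_leaf=[priv_leaf[i] for i in order],
        leaf_order=list(leaf_order),
        leaf_alt=leaf_alt[order],
        genotypes=genotypes[order],
    )


def simulate_read_likelihoods(
    truth: TruthSet,
    spec: SimulationSpec,
    seed: int | None = None,
    epsilon: float = 1e-10,
) -> tuple[LikelihoodMatrix, np.ndarray]:
    """Poisson read depths and per-read errors -> haploid likelihoods.

    Per sample and site: depth d ~ Poisson(mean_depth); each read shows
    the true allele with probability 1 - error_rate.  With k alt reads
    out of d, P(reads | g) = (1-e)^(matches) e^(mismatches); likelihoods
    are phred-quantized exactly as written to VCF (PL integers, capped at
    255), so the in-memory matrix round-trips through VCF bit-for-bit up
    to the epsilon floor.  d = 0 yields missing ({1,1}).

    Returns (likelihoods, depths, alt_read_counts).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    N, M = truth.genotypes.shape
    d = rng.poisson(spec.mean_depth, size=(N, M))
    p_alt_read = np.where(truth.genotypes == 1, 1.0 - spec.error_rate, spec.error_rate)
    k_alt = rng.binomial(d, p_alt_read)

    eps = spec.error_rate
    log_e = np.log10(eps) if eps > 0 else -np.inf
    log_1me = np.log10(1.0 - eps)

    def _nlog(n: np.ndarray, logp: float) -> np.ndarray:
        # n * logp with the 0 * (-inf) = 0 convention (no reads, no term)
        with np.errstate(invalid="ignore"):
            return np.where(n == 0, 0.0, n * logp)

    # phred for g=0 (alt reads are errors) and g=1 (ref reads are errors)
    pl0 = -10.0 * (_nlog(k_alt, log_e) + _nlog(d - k_alt, log_1me))
    pl1 = -10.0 * (_nlog(d - k_alt, log_e) + _nlog(k_alt, log_1me))
    pl = np.stack([pl0, pl1], axis=-1)
    pl = pl - pl.min(axis=-1, keepdims=True)
    pl = np.rint(np.minimum(pl, _PL_CAP))
    lik = np.power(10.0, -pl / 10.0)
    lik[d == 0] = 1.0  # no reads: uninformative
    lik = _floor(lik, epsilon)
    return (
        LikelihoodMatrix(list(truth.sites), list(truth.sample_ids), lik),
        d,
        k_alt,
    )


def simulate_dataset(spec: SimulationSpec) -> SimulatedData:
    """End-to-end generation: tree, markers, cohort truth and likelihoods.

    Stage seeds are derived from ``spec.seed`` via SeedSequence spawning,
    so every artifact is reproducible from the single seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_tree, s_mark, s_cohort, s_reads = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )
    tree = simulate_tree(spec.n_leaves, s_tree)
    markers = simulate_markers(tree, spec.markers_per_branch, s_mark)
    truth = simulate_cohort(tree, markers, spec, seed=s_cohort)
    lik, depths, alt_reads = simulate_read_likelihoods(truth, spec, seed=s_reads)
    return SimulatedData(spec, tree, markers, truth, lik, depths, alt_reads)
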