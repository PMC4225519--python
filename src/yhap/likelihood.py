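"""Per-sample haploid genotype likelihoods and the augmented matrix H*.

The likelihood matrix G holds, for each of N sites and M samples, a
2-vector {G_ijg} proportional to P(read data | allele g), g in
{0=reference, 1=alternate}.  Likelihoods are defined only up to a positive
per-vector constant; downstream posteriors are invariant to rescaling.
Missing data is the uninformative vector {1,1}.

Sources:

* VCF 4.x with FORMAT GT and PL (phred) or GL (log10) fields.  Both
  haploid 2-value and diploid 3-value PL/GL arrays are accepted; for
  diploid arrays the two homozygous entries are used and the heterozygous
  entry ignored.  Diploid-coded heterozygous GT calls on the Y are treated
  as missing (they indicate mapping artifacts, and the model is strictly
  haploid).
* hard genotype calls (array/TSV): call 0 -> {1,0}, 1 -> {0,1},
  missing -> {1,1}.

A configurable epsilon floor (default 1e-10) replaces zeros so log-space
arithmetic stays finite; it is small enough not to alter MAP calls.

``augment`` joins G onto a marker matrix H by position, producing H*: H
rows copied verbatim (fixed), plus one initially-uninformative {0.5,0.5}
row per site observed in G but absent from H.  Those free rows are the
parameters later learned by EM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam

from .errors import (
    AlleleMismatchError,
    BadGenotypeError,
    EmptyInputError,
    FormatError,
)
from .markers import MarkerMatrix

__all__ = [
    "Site",
    "LikelihoodMatrix",
    "AugmentedMatrix",
    "read_vcf_likelihoods",
    "write_vcf",
    "hard_genotypes_to_likelihoods",
    "read_hard_genotypes",
    "write_hard_genotypes",
    "augment",
]

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-10
_PL_CAP = 255  # phred cap used when writing; reading floors far earlier


class Site(NamedTuple):
    """A bi-allelic SNV site (1-based position, ref base, alt base)."""

    pos: int
    ref: str
    alt: str


def _floor(lik: np.ndarray, epsilon: float) -> np.ndarray:
    """Clamp entries below epsilon (keeps log arithmetic finite)."""
    return np.maximum(lik, epsilon) if epsilon > 0 else lik


@dataclass
class LikelihoodMatrix:
    """N x M matrix of haploid genotype-likelihood 2-vectors."""

    sites: list[Site]
    sample_ids: list[str]
    lik: np.ndarray  # (N, M, 2), non-negative, max of each 2-vector > 0
    stats: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __post_init__(self) -> None:
        if self.lik.shape != (len(self.sites), len(self.sample_ids), 2):
            raise ValueError("lik shape does not match sites x samples x 2")


@dataclass
class AugmentedMatrix:
    """H*: the marker matrix H extended with free rows for G-only sites.

    Rows indexed by ``marker_rows`` are fixed copies of H and are never
    modified by EM; rows in ``free_rows`` start at the uninformative
    {0.5,0.5} and are the EM parameters.
    """

    sites: list[Site]
    node_order: list[str]
    alt_probs: np.ndarray  # (N, L)
    marker_rows: np.ndarray  # indices into sites
    free_rows: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def probs(self) -> np.ndarray:
        return np.stack([1.0 - self.alt_probs, self.alt_probs], axis=-1)

    def copy(self) -> "AugmentedMatrix":
        return AugmentedMatrix(
            list(self.sites),
            list(self.node_order),
            self.alt_probs.copy(),
            self.marker_rows.copy(),
            self.free_rows.copy(),
        )

    # -- TSV serialization (one row per site, one column per node) --------

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.alt_probs, columns=self.node_order)
        df.insert(0, "pos", [s.pos for s in self.sites])
        df.insert(1, "ref", [s.ref for s in self.sites])
        df.insert(2, "alt", [s.alt for s in self.sites])
        is_marker = np.zeros(self.n_sites, dtype=bool)
        is_marker[self.marker_rows] = True
        df.insert(3, "is_marker", is_marker)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AugmentedMatrix":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        sites = [Site(int(p), r, a) for p, r, a in zip(df["pos"], df["ref"], df["alt"])]
        is_marker = df["is_marker"].to_numpy(dtype=bool)
        nodes = [c for c in df.columns if c not in ("pos", "ref", "alt", "is_marker")]
        return cls(
            sites,
            nodes,
            df[nodes].to_numpy(dtype=float),
            np.flatnonzero(is_marker),
            np.flatnonzero(~is_marker),
        )


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf_likelihoods(
    vcf_path: str | Path,
    sample_subset: list[str] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    drop_filtered: bool = True,
) -> LikelihoodMatrix:
    """Extract haploid genotype likelihoods from a VCF.

    Only bi-allelic SNV records are retained (multi-allelic and indel
    records are dropped with a logged count).  Per sample and record, PL
    is preferred, then GL, then a hard GT call; diploid-coded het GT calls
    become missing.  Each 2-vector is normalized to max 1 and floored at
    ``epsilon``.
    """
    vf = pysam.VariantFile(str(vcf_path))
    fmt_keys = set(vf.header.formats.keys())
    if not fmt_keys & {"GT", "PL", "GL"}:
        raise FormatError("VCF FORMAT declares none of GT, PL, GL")
    samples = list(vf.header.samples)
    if sample_subset is not None:
        missing = set(sample_subset) - set(samples)
        if missing:
            raise FormatError(f"samples not in VCF: {sorted(missing)}")
        samples = [s for s in samples if s in set(sample_subset)]

    sites: list[Site] = []
    rows: list[np.ndarray] = []
    stats = {"n_het": 0, "n_multiallelic": 0, "n_filtered": 0, "n_missing_gt": 0, "n_non_snv": 0}

    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            stats["n_multiallelic"] += 1
            continue
        if len(rec.ref) != 1 or len(alts[0]) != 1:
            stats["n_non_snv"] += 1
            continue
        filters = list(rec.filter.keys())
        if drop_filtered and filters and filters != ["PASS"]:
            stats["n_filtered"] += 1
            continue
        row = np.ones((len(samples), 2))
        for k, s in enumerate(samples):
            row[k] = _sample_likelihood(rec.samples[s], stats)
        sites.append(Site(rec.pos, rec.ref, alts[0]))
        rows.append(row)
    vf.close()

    if not sites:
        raise EmptyInputError("no usable bi-allelic SNV records in VCF")
    lik = np.stack(rows)  # (N, M, 2)
    lik /= lik.max(axis=2, keepdims=True)
    lik = _floor(lik, epsilon)
    if stats["n_het"]:
        logger.info("treated %d heterozygous Y calls as missing", stats["n_het"])
    return LikelihoodMatrix(sites, samples, lik, stats)


def _sample_likelihood(fmt, stats: dict) -> np.ndarray:
    """One sample's {ref, alt} likelihood vector from a VCF FORMAT field."""
    pl = fmt.get("PL", None)
    if pl is not None and not all(v is None for v in pl):
        v = [x for x in pl if x is not None]
        if len(v) == 2:
            return np.power(10.0, -np.array(v, dtype=float) / 10.0)
        if len(v) == 3:  # diploid coding: use the homozygous entries
            return np.power(10.0, -np.array([v[0], v[2]], dtype=float) / 10.0)
    gl = fmt.get("GL", None)
    if gl is not None and not all(v is None for v in gl):
        v = [x for x in gl if x is not None]
        if len(v) == 2:
            return np.power(10.0, np.array(v, dtype=float))
        if len(v) == 3:
            return np.power(10.0, np.array([v[0], v[2]], dtype=float))
    gt = fmt.get("GT", None)
    alleles = tuple(a for a in (gt or ()) if a is not None)
    if not alleles:
        stats["n_missing_gt"] += 1
        return np.array([1.0, 1.0])
    if len(set(alleles)) > 1:  # diploid-coded het on the Y
        stats["n_het"] += 1
        return np.array([1.0, 1.0])
    return np.array([1.0, 0.0]) if alleles[0] == 0 else np.array([0.0, 1.0])


def write_vcf(
    G: LikelihoodMatrix,
    path: str | Path,
    contig: str = "Y",
    contig_length: int = 59_373_566,
) -> None:
    """Write a likelihood matrix as an uncompressed VCF with GT and haploid
    2-value PL fields.

    PLs are the phred-scaled, min-normalized likelihoods rounded to
    integers and capped at 255; a {1,1} vector becomes a missing genotype.
    Reading the file back reproduces the matrix up to phred rounding.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">'
    )
    for s in G.sample_ids:
        header.add_sample(s)
    order = np.argsort([s.pos for s in G.sites], kind="stable")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            site = G.sites[i]
            rec = out.new_record(
                contig=contig, start=site.pos - 1, alleles=(site.ref, site.alt)
            )
            rec.qual = None
            for k, s in enumerate(G.sample_ids):
                v = G.lik[i, k]
                if v[0] == v[1]:
                    rec.samples[s]["GT"] = (None,)
                    rec.samples[s]["PL"] = (0, 0)
                else:
                    with np.errstate(divide="ignore"):
                        pl = -10.0 * np.log10(v / v.max())
                    pl = np.minimum(np.rint(pl), _PL_CAP).astype(int)
                    rec.samples[s]["GT"] = (int(np.argmax(v)),)
                    rec.samples[s]["PL"] = (int(pl[0]), int(pl[1]))
            out.write(rec)


# ---------------------------------------------------------------------------
# hard genotype calls
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {".", "", "na", "nan", "none"}


def hard_genotypes_to_likelihoods(
    calls,
    sites: list[Site],
    sample_ids: list[str],
    epsilon: float = DEFAULT_EPSILON,
) -> LikelihoodMatrix:
    """Convert an N x M table of hard haploid calls {0, 1, missing} to
    likelihoods: 0 -> {1,0}, 1 -> {0,1}, missing -> {1,1} (with the usual
    epsilon floor on zeros)."""
    arr = np.asarray(calls, dtype=object)
    if arr.shape != (len(sites), len(sample_ids)):
        raise BadGenotypeError(
            f"call table shape {arr.shape} != (n_sites={len(sites)}, n_samples={len(sample_ids)})"
        )
    lik = np.empty((*arr.shape, 2))
    for (i, j), v in np.ndenumerate(arr):
        if v is None or (isinstance(v, float) and np.isnan(v)) or (
            isinstance(v, str) and v.strip().lower() in _MISSING_TOKENS
        ):
            lik[i, j] = (1.0, 1.0)
        elif v in (0, "0"):
            lik[i, j] = (1.0, 0.0)
        elif v in (1, "1"):
            lik[i, j] = (0.0, 1.0)
        else:
            raise BadGenotypeError(f"bad genotype entry at site {i}, sample {j}: {v!r}")
    return LikelihoodMatrix(list(sites), list(sample_ids), _floor(lik, epsilon))


def read_hard_genotypes(path: str | Path, epsilon: float = DEFAULT_EPSILON) -> LikelihoodMatrix:
    """Read a hard-genotype TSV (columns pos, ref, alt, then one column per
    sample; entries 0/1/.)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("pos", "ref", "alt"):
        if col not in df.columns:
            raise FormatError(f"genotype table missing column {col!r}")
    sample_ids = [c for c in df.columns if c not in ("pos", "ref", "alt")]
    if not sample_ids or df.empty:
        raise EmptyInputError("genotype table has no data")
    sites = [Site(int(p), r, a) for p, r, a in zip(df["pos"], df["ref"], df["alt"])]
    return hard_genotypes_to_likelihoods(
        df[sample_ids].to_numpy(), sites, sample_ids, epsilon=epsilon
    )


def write_hard_genotypes(
    calls: np.ndarray, sites: list[Site], sample_ids: list[str], path: str | Path
) -> None:
    df = pd.DataFrame(np.asarray(calls, dtype=object), columns=sample_ids)
    df = df.map(lambda v: "." if v is None else str(int(v)))
    df.insert(0, "pos", [s.pos for s in sites])
    df.insert(1, "ref", [s.ref for s in sites])
    df.insert(2, "alt", [s.alt for s in sites])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(
    H: MarkerMatrix,
    G: LikelihoodMatrix,
    on_mismatch: str = "error",
) -> tuple[AugmentedMatrix, LikelihoodMatrix]:
    """Join G onto H by position, returning H* and G re-aligned to its rows.

    The H* row set is the union of H and G sites: H rows first (copied
    verbatim, fixed), then G-only rows initialized to {0.5,0.5} for every
    node.  The aligned likelihood matrix covers the same rows; sites in H
    never observed in G get {1,1} for every sample, so the matrix shape is
    stable across cohorts.

    Shared positions must agree on ref/alt; ``on_mismatch="swap"`` instead
    swaps the G vector's alleles (logged), treating the disagreement as an
    allele-order flip.
    """
    if on_mismatch not in ("error", "swap"):
        raise ValueError("on_mismatch must be 'error' or 'swap'")
    g_by_pos = {s.pos: i for i, s in enumerate(G.sites)}

    h_sites = [Site(m.position, m.ref_allele, m.alt_allele) for m in H.sites]
    sites = list(h_sites)
    n_ref, M = len(h_sites), G.n_samples
    lik = np.ones((n_ref, M, 2))
    swapped = 0
    for i, site in enumerate(h_sites):
        gi = g_by_pos.pop(site.pos, None)
        if gi is None:
            continue
        gsite = G.sites[gi]
        if (gsite.ref, gsite.alt) == (site.ref, site.alt):
            lik[i] = G.lik[gi]
        elif (gsite.ref, gsite.alt) == (site.alt, site.ref):
            if on_mismatch == "error":
                raise AlleleMismatchError(
                    f"position {site.pos}: marker table has {site.ref}/{site.alt}, "
                    f"input has {gsite.ref}/{gsite.alt}"
                )
            lik[i] = G.lik[gi, :, ::-1]
            swapped += 1
        else:
            raise AlleleMismatchError(
                f"position {site.pos}: alleles {gsite.ref}/{gsite.alt} do not match "
                f"marker {site.ref}/{site.alt} in any orientation"
            )
    if swapped:
        logger.warning("swapped allele orientation at %d shared positions", swapped)

    free_idx = sorted(g_by_pos.values())  # G-only sites, in G order
    sites.extend(G.sites[i] for i in free_idx)
    lik = np.concatenate([lik, G.lik[free_idx]]) if free_idx else lik

    L = len(H.node_order)
    alt_probs = np.vstack(
        [H.alt_probs, np.full((len(free_idx), L), 0.5)]
    ) if free_idx else H.alt_probs.copy()
    h_star = AugmentedMatrix(
        sites,
        list(H.node_order),
        alt_probs,
        marker_rows=np.arange(n_ref),
        free_rows=np.arange(n_ref, n_ref + len(free_idx)),
    )
    g_aligned = LikelihoodMatrix(list(sites), list(G.sample_ids), lik, dict(G.stats))
    return h_star, g_aligned
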