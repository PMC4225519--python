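"""EM pooling of haplogroup information across a population sample.

A population sample shares haplogroups, so reads from different
individuals of the same haplogroup can be pooled — but the pooling
partition is unknown.  The model treats the allele distributions
{H*_ilg} at sites present in the sequence data but not among the known
markers (the free rows of H*) as parameters, together with the haplogroup
prior, and fits them by expectation-maximization:

E-step
    responsibilities r_jl = posterior P(haplogroup l | sample j) under the
    current parameters — exactly the assignment-module posterior.

M-step
    each free row is updated to the responsibility-weighted average of the
    samples' soft genotypes at that site,

        H*_il1 <- (c + sum_j r_jl q_jil1) / (2c + sum_j r_jl)

    where c is a Dirichlet-style pseudocount per allele and q_jilg is the
    posterior of the latent allele given assignment to l,
    q_jilg ∝ G_ijg H*_ilg (a likelihood-only variant q ∝ G_ijg is
    available for sensitivity analysis).  Marker rows are never touched.
    The prior is updated to the smoothed responsibility proportions,
    P(H*_.l) <- (sum_j r_jl + c/A) / (M + c), so no haplogroup's prior can
    hit an unrecoverable exact zero mid-run.

The observed-data log-likelihood sum_j log sum_l P(G_.j|H*_.l) P(H*_.l)
is tracked each iteration and must be non-decreasing up to numerical
slack; the run stops when the improvement drops below ``tol`` or after
``max_iters`` iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .assign import HaplogroupPrior, _posteriors_from_loglik, cohort_log_likelihoods
from .errors import DegenerateNodeWarning, EMMonotonicityError, UnknownNodeError
from .likelihood import AugmentedMatrix, LikelihoodMatrix

__all__ = ["EMConfig", "EMState", "e_step", "m_step", "observed_log_likelihood", "run_em"]

#: slack allowed on the monotonicity of the log-likelihood trace
MONOTONICITY_SLACK = 1e-8


@dataclass(frozen=True)
class EMConfig:
    """Convergence and smoothing knobs for :func:`run_em`.

    pseudocount is the Dirichlet-style weight added per allele in the
    free-row update (and, scaled by 1/A, to the prior update).  The
    default 0.1 is small enough that a single concordant covered sample
    can push a free row past 0.9 toward the allele it carries, yet keeps
    every probability strictly inside (0,1) so no haplogroup profile is
    poisoned irreversibly by one read.
    """

    max_iters: int = 100
    tol: float = 1e-6
    pseudocount: float = 0.1
    smooth_prior: bool = True
    soft_genotype: str = "posterior"  # or "likelihood"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.soft_genotype not in ("posterior", "likelihood"):
            raise ValueError("soft_genotype must be 'posterior' or 'likelihood'")


@dataclass
class EMState:
    """Fitted parameters plus the per-iteration log-likelihood trace."""

    h_star: AugmentedMatrix
    prior: HaplogroupPrior
    responsibilities: np.ndarray  # (M, A)
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    active_nodes: list[str] = field(default_factory=list)


def _active_columns(h_star: AugmentedMatrix, active_nodes: list[str]) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(h_star.node_order)}
    try:
        return np.array([idx[lab] for lab in active_nodes], dtype=int)
    except KeyError as exc:
        raise UnknownNodeError(f"active node {exc.args[0]!r} not in H*") from None


def e_step(
    G: LikelihoodMatrix,
    h_star: AugmentedMatrix,
    prior: HaplogroupPrior,
    active_nodes: list[str],
) -> np.ndarray:
    """(M, A) responsibility matrix; row j is sample j's haplogroup
    posterior, identical to the assignment-module output."""
    loglik = cohort_log_likelihoods(G, h_star, active_nodes)
    post, _ = _posteriors_from_loglik(loglik, prior)
    return post


def m_step(
    G: LikelihoodMatrix,
    responsibilities: np.ndarray,
    h_star: AugmentedMatrix,
    active_nodes: list[str],
    config: EMConfig = EMConfig(),
) -> tuple[AugmentedMatrix, HaplogroupPrior]:
    """Update free rows of H* and the prior; marker rows stay fixed."""
    cols = _active_columns(h_star, active_nodes)
    r = np.asarray(responsibilities, dtype=float)  # (M, A)
    M, A = r.shape
    if A != cols.size or M != G.n_samples:
        raise ValueError("responsibility matrix shape does not match cohort/active set")
    c = config.pseudocount
    new = h_star.copy()
    free = h_star.free_rows
    if free.size:
        g0 = G.lik[free, :, 0]  # (F, M)
        g1 = G.lik[free, :, 1]
        r_tot = r.sum(axis=0)  # (A,)
        for a, col in enumerate(cols):
            if config.soft_genotype == "posterior":
                p = h_star.alt_probs[free, col][:, None]  # (F, 1)
                w0, w1 = g0 * (1.0 - p), g1 * p
            else:
                w0, w1 = g0, g1
            tot = w0 + w1
            # degenerate 0/0 (impossible data under a hard parameter) falls
            # back to the current parameter value
            q1 = np.where(tot > 0, w1 / np.where(tot > 0, tot, 1.0),
                          h_star.alt_probs[free, col][:, None])
            denom = 2.0 * c + r_tot[a]
            if denom == 0.0:
                warnings.warn(
                    f"node {active_nodes[a]!r} has zero responsibility and no "
                    "smoothing; free rows left unchanged",
                    DegenerateNodeWarning,
                )
                continue
            new.alt_probs[free, col] = (c + q1 @ r[:, a]) / denom
    if config.smooth_prior:
        pr = (r.sum(axis=0) + c / A) / (M + c)
    else:
        pr = r.sum(axis=0) / M
    pr = pr / pr.sum()
    return new, HaplogroupPrior(list(active_nodes), pr)


def observed_log_likelihood(
    G: LikelihoodMatrix,
    h_star: AugmentedMatrix,
    prior: HaplogroupPrior,
    active_nodes: list[str],
) -> float:
    """sum_j log sum_l P(G_.j | H*_.l) P(H*_.l) — the quantity EM ascends."""
    loglik = cohort_log_likelihoods(G, h_star, active_nodes)
    with np.errstate(divide="ignore"):
        log_joint = loglik + np.log(prior.probs)[None, :]
    return float(logsumexp(log_joint, axis=1).sum())


def run_em(
    G: LikelihoodMatrix,
    h_star_init: AugmentedMatrix,
    active_nodes: list[str],
    config: EMConfig = EMConfig(),
    prior_init: HaplogroupPrior | None = None,
    strict: bool = False,
) -> EMState:
    """Alternate E and M steps from H* (free rows at {0.5,0.5}) and a
    uniform prior until the observed-data log-likelihood improves by less
    than ``config.tol`` or ``config.max_iters`` is reached.

    Deterministic given inputs; a decrease of the trace beyond
    MONOTONICITY_SLACK raises :class:`EMMonotonicityError` when
    ``strict`` and warns otherwise.
    """
    h = h_star_init.copy()
    prior = prior_init or HaplogroupPrior.uniform(active_nodes)
    trace: list[float] = []
    resp = None
    converged = False
    marker_snapshot = h.alt_probs[h.marker_rows].copy()

    for it in range(config.max_iters):
        loglik = cohort_log_likelihoods(G, h, active_nodes)
        with np.errstate(divide="ignore"):
            log_joint = loglik + np.log(prior.probs)[None, :]
        obs_ll = float(logsumexp(log_joint, axis=1).sum())
        resp, _ = _posteriors_from_loglik(loglik, prior)
        if trace:
            delta = obs_ll - trace[-1]
            if delta < -MONOTONICITY_SLACK:
                msg = f"log-likelihood decreased by {-delta:.3g} at iteration {it}"
                if strict:
                    raise EMMonotonicityError(msg)
                warnings.warn(msg, RuntimeWarning)
            trace.append(obs_ll)
            if delta < config.tol:
                converged = True
                break
        else:
            trace.append(obs_ll)
        h, prior = m_step(G, resp, h, active_nodes, config)

    assert np.array_equal(h.alt_probs[h.marker_rows], marker_snapshot), \
        "marker rows must never change"
    return EMState(h, prior, resp, trace, converged, len(trace), list(active_nodes))
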