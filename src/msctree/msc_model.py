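"""Multispecies-coalescent density of gene trees and priors on (theta, tau, S).

Units: both ``theta = 4*N*mu`` and node ages are in expected substitutions
per site, so within a population with parameter ``theta`` each pair of
lineages coalesces at rate ``2/theta`` and ``n`` lineages wait with total
rate ``n*(n-1)/theta``.

The density is over *labeled histories* of the gene tree (each coalescence
names the joining pair), so every coalescent event contributes ``2/theta``
with no extra combinatorial factor; the familiar 1/3 probability of each
3-taxon gene-tree topology emerges by integration.

Priors:

* each ``theta`` ~ Gamma(shape, rate) independently (mean = shape/rate);
* the root age ``tau_0`` ~ Gamma(shape, rate) (the density ``g``);
* non-root species ages given ``tau_0``: uniform over the region allowed by
  the topology, with density proportional to ``tau_0**-(s-2)``; the
  topology-dependent normalizing constant is treated as equal across
  topologies, so within-topology ratios are exact and the cross-topology
  factor is carried by the topology prior (see ``topology_mh_log_ratio``);
* species-tree topology: Prior 0 = uniform on labeled histories, Prior 1 =
  uniform on rooted trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees_core import GeneTree, SpeciesTree, count_labeled_histories

__all__ = [
    "PriorConfig",
    "msc_log_density",
    "log_prior_params",
    "species_tree_log_prior",
    "topology_mh_log_ratio",
    "gamma_logpdf",
]

PRIOR_LABELED_HISTORIES = 0   # "Prior 0"
PRIOR_UNIFORM_TREES = 1       # "Prior 1"


@dataclass
class PriorConfig:
    """Gamma priors on theta and the root age, and the topology prior."""

    theta_a: float = 2.0
    theta_b: float = 1000.0        # rate; prior mean = a/b
    tau_a: float = 2.0
    tau_b: float = 200.0
    tree_prior: int = PRIOR_UNIFORM_TREES

    def __post_init__(self) -> None:
        if min(self.theta_a, self.theta_b, self.tau_a, self.tau_b) <= 0:
            raise ValueError("gamma prior parameters must be positive")
        if self.tree_prior not in (0, 1):
            raise ValueError("tree_prior must be 0 or 1")


def gamma_logpdf(x: float, a: float, b: float) -> float:
    """log Gamma(shape a, rate b) density at x."""
    if x <= 0:
        return -math.inf
    return a * math.log(b) - math.lgamma(a) + (a - 1.0) * math.log(x) - b * x


try:
    from numba import njit as _njit
except ImportError:      # pragma: no cover - numba is a hard dependency
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a else a[0]


@_njit(cache=True)
def _stats_kernel(order, children, parent, tau, s, root, n_in, k,
                  sorted_ages, starts, ends):
    nS = tau.shape[0]
    A = np.zeros(nS)
    for oi in range(order.shape[0]):
        j = order[oi]
        if j >= s:
            c0 = children[j, 0]
            c1 = children[j, 1]
            n_in[j] += (n_in[c0] - k[c0]) + (n_in[c1] - k[c1])
        n = n_in[j]
        if j == root:
            if k[j] != n - 1:
                return A, 1
        elif k[j] > max(n - 1, 0):
            return A, 2
        if n < 2:
            continue
        t_prev = tau[j]
        acc = 0.0
        for idx in range(starts[j], ends[j]):
            t = sorted_ages[idx]
            acc += n * (n - 1) * (t - t_prev)
            t_prev = t
            n -= 1
        if j != root and n > 1:
            acc += n * (n - 1) * (tau[parent[j]] - t_prev)
        A[j] = acc
    return A, 0


def coalescent_stats(G: GeneTree, S: SpeciesTree):
    """Sufficient statistics of G per population of S.

    Returns ``(k, A)`` with, for each species node j, ``k[j]`` the number of
    coalescent events inside population j and ``A[j] = sum n(n-1)*dt`` over
    the inter-event intervals (including the final interval up to the
    population's upper bound).  The MSC log density is then
    ``sum_j k[j]*log(2/theta_j) - A[j]/theta_j``.
    """
    if G.pop is None:
        G.recompute_pops(S)
    nS = S.n_nodes
    n_tips = G.n_tips
    pops_int = G.pop[n_tips:]
    ages_int = G.age[n_tips:]
    n_in = np.bincount(G.tip_species, minlength=nS)
    k = np.bincount(pops_int, minlength=nS)
    # event ages grouped by population, ascending within population
    order = np.lexsort((ages_int, pops_int))
    sorted_ages = ages_int[order]
    ends = np.cumsum(k)
    starts = ends - k
    sorder = getattr(S, "_postorder_arr", None)
    if sorder is None:
        sorder = np.asarray(S.postorder(), dtype=np.int64)
        S._postorder_arr = sorder
    A, err = _stats_kernel(sorder, S.children, S.parent, S.tau, S.s, S.root,
                           n_in, k, sorted_ages, starts, ends)
    if err == 1:
        raise ValueError("root population must coalesce to one lineage")
    if err == 2:
        raise ValueError("invalid embedding: too many events in population")
    return k, A


def msc_density_from_stats(k: np.ndarray, A: np.ndarray,
                           theta: np.ndarray) -> float:
    return float(k @ np.log(2.0 / theta) - A @ (1.0 / theta))


def msc_log_density(G: GeneTree, S: SpeciesTree) -> float:
    """Log MSC density of gene tree G (topology and times) given S.

    Requires a compatible embedding; an incompatible gene tree is a caller
    bug and raises.
    """
    k, A = coalescent_stats(G, S)
    return msc_density_from_stats(k, A, S.theta)


def log_prior_params(S: SpeciesTree, config: PriorConfig) -> float:
    """Log prior of all thetas and all taus given the topology.

    Sum of independent gamma terms for every theta, the gamma ``g`` for the
    root age, and ``-(s-2)*log tau_0`` for the conditionally-uniform
    non-root ages (common-constant convention; see module docstring).
    """
    if np.any(S.theta <= 0) or np.any(S.tau[S.s:] <= 0):
        raise ValueError("non-positive parameter")
    logp = 0.0
    for v in range(S.n_nodes):
        logp += gamma_logpdf(float(S.theta[v]), config.theta_a, config.theta_b)
    tau0 = float(S.tau[S.root])
    logp += gamma_logpdf(tau0, config.tau_a, config.tau_b)
    if S.s > 2:
        logp += -(S.s - 2) * math.log(tau0)
    return logp


def total_labeled_histories(s: int) -> int:
    """Sum of labeled-history counts over all rooted topologies on s tips."""
    out = 1
    for k in range(2, s + 1):
        out *= k * (k - 1) // 2
    return out


def species_tree_log_prior(S: SpeciesTree, config: PriorConfig) -> float:
    """Normalized log prior probability of the species-tree topology."""
    s = S.s
    if config.tree_prior == PRIOR_LABELED_HISTORIES:
        return math.log(count_labeled_histories(S)) \
            - math.log(total_labeled_histories(s))
    n_top = 1
    for k in range(3, 2 * s - 2, 2):
        n_top *= k
    return -math.log(n_top)


def topology_mh_log_ratio(S_new: SpeciesTree, S_old: SpeciesTree,
                          config: PriorConfig) -> float:
    """Topology-prior factor entering transmodel acceptance ratios.

    The non-root tau density uses a common normalizing constant across
    topologies, so integrating the taus contributes the labeled-history
    count h(T) per topology; the acceptance factor is therefore
    prior(T*) / h(T*) divided by prior(T) / h(T): zero in log space under
    Prior 0, and log h(T) - log h(T*) under Prior 1.
    """
    if config.tree_prior == PRIOR_LABELED_HISTORIES:
        return 0.0
    return math.log(count_labeled_histories(S_old)) \
        - math.log(count_labeled_histories(S_new))
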