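"""JC69 phylogenetic likelihood via the pruning algorithm.

Each locus alignment is compressed to its unique site patterns with counts
before any likelihood work; the pruning pass is vectorized over patterns.
Gaps and ``N`` are fully ambiguous (partial vector of ones); other IUPAC
codes are indicator vectors over their compatible bases.  Underflow is
handled by per-node log-scaler accumulation, which is deterministic and
independent of traversal order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trees_core import GeneTree, IndividualMap, TreeError

__all__ = ["Locus", "AlignmentSet", "jc69_transition", "phylo_loglik",
           "total_loglik"]

_BASES = "TCAG"

IUPAC = {
    "T": "T", "C": "C", "A": "A", "G": "G", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT", "X": "ACGT",
}


def _partial_row(ch: str) -> np.ndarray:
    try:
        bases = IUPAC[ch.upper()]
    except KeyError:
        raise TreeError(f"unknown nucleotide code {ch!r}") from None
    row = np.zeros(4)
    for b in bases:
        row[_BASES.index(b)] = 1.0
    return row


@dataclass
class Locus:
    """One locus: labels, raw sequences, and compressed site patterns."""

    labels: list[str]
    sequences: list[str]
    tip_partials: np.ndarray = field(init=False)   # (ntips, npat, 4)
    counts: np.ndarray = field(init=False)         # (npat,)

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise TreeError("every locus should have at least two sequences")
        n = len(self.sequences[0])
        if any(len(s) != n for s in self.sequences):
            raise TreeError("ragged alignment")
        self.sequences = [s.upper() for s in self.sequences]
        cols = list(zip(*self.sequences))
        pattern_index: dict[tuple, int] = {}
        counts: list[int] = []
        for col in cols:
            i = pattern_index.setdefault(col, len(pattern_index))
            if i == len(counts):
                counts.append(0)
            counts[i] += 1
        npat = len(pattern_index)
        self.counts = np.asarray(counts, dtype=float)
        self.tip_partials = np.empty((len(self.labels), npat, 4))
        code_cache: dict[str, np.ndarray] = {}
        for col, i in pattern_index.items():
            for tip, ch in enumerate(col):
                row = code_cache.get(ch)
                if row is None:
                    row = code_cache[ch] = _partial_row(ch)
                self.tip_partials[tip, i] = row

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


@dataclass
class AlignmentSet:
    """L independent locus alignments plus the individual-to-species map."""

    loci: list[Locus]
    imap: IndividualMap | None = None

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def jc69_transition(d: float) -> np.ndarray:
    """JC69 transition-probability matrix for branch length d (subst/site)."""
    if d < 0:
        raise ValueError("branch length must be non-negative")
    e = math.exp(-4.0 * d / 3.0)
    off = 0.25 - 0.25 * e
    P = np.full((4, 4), off)
    np.fill_diagonal(P, 0.25 + 0.75 * e)
    return P


try:
    from numba import njit as _njit
except ImportError:      # pragma: no cover - numba is a hard dependency
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a else a[0]


@_njit(cache=True)
def _prune_kernel(order, children, e, tip_partials, counts, n_tips, root):
    n_nodes = 2 * n_tips - 1
    npat = tip_partials.shape[1]
    partials = np.empty((n_nodes, npat, 4))
    partials[:n_tips] = tip_partials
    logscale = np.zeros(npat)
    for oi in range(order.shape[0]):
        v = order[oi]
        if v < n_tips:
            continue
        for p in range(npat):
            for s in range(4):
                partials[v, p, s] = 1.0
        for ci in range(2):
            c = children[v, ci]
            ec = e[c]
            base = 0.25 * (1.0 - ec)
            for p in range(npat):
                tot = (partials[c, p, 0] + partials[c, p, 1]
                       + partials[c, p, 2] + partials[c, p, 3])
                for s in range(4):
                    partials[v, p, s] *= base * tot + ec * partials[c, p, s]
        for p in range(npat):
            m = partials[v, p, 0]
            for s in range(1, 4):
                if partials[v, p, s] > m:
                    m = partials[v, p, s]
            if m <= 0.0:
                return -np.inf
            for s in range(4):
                partials[v, p, s] /= m
            logscale[p] += np.log(m)
    out = 0.0
    for p in range(npat):
        site = 0.25 * (partials[root, p, 0] + partials[root, p, 1]
                       + partials[root, p, 2] + partials[root, p, 3])
        if site <= 0.0:
            return -np.inf
        out += counts[p] * (np.log(site) + logscale[p])
    return out


def phylo_loglik(locus: Locus, G: GeneTree) -> float:
    """Log f(X_i | G_i) under JC69, pruning with per-node rescaling.

    Gene-tree tip ``i`` must correspond to alignment row ``i`` (enforced by
    label identity).
    """
    if G.labels != locus.labels:
        raise TreeError("gene-tree tips do not match alignment labels")
    p = G.parent
    d = np.where(p >= 0, G.age[np.maximum(p, 0)] - G.age, 0.0)
    if np.any(d < -1e-12):
        raise ValueError("negative branch length")
    e = np.exp(-4.0 * np.maximum(d, 0.0) / 3.0)
    order = getattr(G, "_postorder_arr", None)
    if order is None:
        order = np.asarray(G.postorder(), dtype=np.int64)
        G._postorder_arr = order
    return float(_prune_kernel(order, G.children, e, locus.tip_partials,
                               locus.counts, G.n_tips, G.root))


def total_loglik(X: AlignmentSet, gene_trees: list[GeneTree]) -> float:
    """Sum of per-locus log-likelihoods (loci are independent)."""
    return sum(phylo_loglik(loc, G) for loc, G in zip(X.loci, gene_trees))
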