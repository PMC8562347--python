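"""MSC/JC69 simulator: gene trees under the coalescent, sequences under JC69.

All time units are expected substitutions per site; within a population
with parameter ``theta`` the waiting time to the next coalescence among
``n`` lineages is exponential with rate ``n*(n-1)/theta``.  The module also
builds the 16-species symmetric/asymmetric study trees (every internode
interval equal to ``theta``; root age ``4*theta`` and ``15*theta``
respectively) and composes multi-locus datasets, serving as the package's
synthetic-data generator.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .likelihood import AlignmentSet, Locus
from .trees_core import GeneTree, IndividualMap, SpeciesTree, parse_newick

__all__ = ["SimulationDesign", "simulate_gene_tree", "simulate_alignment",
           "build_study_tree", "simulate_dataset"]

_BASES = "TCAG"


@dataclass
class SimulationDesign:
    """One simulation condition: tree shape, theta, sampling and locus sizes."""

    tree: str = "symmetric16"      # 'symmetric16' | 'asymmetric16' | Newick
    theta: float = 0.01
    n_loci: int = 10
    n_sites: int = 1000
    samples_per_species: int = 2
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def species_tree(self) -> SpeciesTree:
        if self.tree in ("symmetric16", "asymmetric16"):
            return build_study_tree(self.tree.replace("16", ""), self.theta)
        return parse_newick(self.tree, theta=self.theta)


def simulate_gene_tree(S: SpeciesTree, samples_per_species,
                       rng: np.random.Generator, locus: int = 0) -> GeneTree:
    """Draw one gene tree from the MSC given (S, tau, theta).

    ``samples_per_species`` is an int (same count for all species) or a
    mapping from species label to count; species with zero samples simply
    contribute no lineages.  Tip labels are ``<species><k>^<species>``.
    """
    if isinstance(samples_per_species, int):
        counts = {lab: samples_per_species for lab in S.labels}
    else:
        counts = {lab: int(samples_per_species.get(lab, 0)) for lab in S.labels}
    n_tips = sum(counts.values())
    if n_tips < 2:
        raise ValueError("need at least two sampled sequences")

    labels: list[str] = []
    tip_species = np.empty(n_tips, dtype=np.int64)
    lineages_in: dict[int, list[int]] = {}
    i = 0
    for sp in range(S.s):
        lab = S.labels[sp]
        lineages_in[sp] = []
        for k in range(counts[lab]):
            labels.append(f"{lab.lower()}{k + 1}^{lab}")
            tip_species[i] = sp
            lineages_in[sp].append(i)
            i += 1

    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    age = np.zeros(n_nodes)
    nxt = n_tips

    for j in S.postorder():
        if S.is_tip(j):
            act = list(lineages_in[j])
        else:
            c0, c1 = (int(c) for c in S.children[j])
            act = lineages_in.pop(c0) + lineages_in.pop(c1)
        t = float(S.tau[j])
        upper = np.inf if j == S.root else float(S.tau[S.parent[j]])
        th = float(S.theta[j])
        while len(act) >= 2:
            n = len(act)
            t = t + rng.exponential(th / (n * (n - 1)))
            if t >= upper:
                break
            a, b = rng.choice(n, size=2, replace=False)
            v = nxt
            nxt += 1
            age[v] = t
            for c in (act[a], act[b]):
                parent[c] = v
                children[v, 0 if children[v, 0] < 0 else 1] = c
            act = [x for idx, x in enumerate(act) if idx not in (a, b)] + [v]
        lineages_in[j] = act

    G = GeneTree(labels, tip_species, parent, children, age, locus=locus)
    G.recompute_pops(S)
    return G


def simulate_alignment(G: GeneTree, n_sites: int,
                       rng: np.random.Generator) -> Locus:
    """Evolve ``n_sites`` iid sites down G under JC69 (root state uniform)."""
    if n_sites < 1:
        raise ValueError("need at least one site")
    states = np.empty((G.n_nodes, n_sites), dtype=np.int8)
    order = list(reversed(G.postorder()))     # preorder: parents first
    states[G.root] = rng.integers(0, 4, size=n_sites)
    for v in order:
        if v == G.root:
            continue
        d = G.age[G.parent[v]] - G.age[v]
        # JC69: with prob e keep the parent state, else draw uniformly
        e = np.exp(-4.0 * d / 3.0)
        keep = rng.random(n_sites) < e
        states[v] = np.where(keep, states[G.parent[v]],
                             rng.integers(0, 4, size=n_sites))
    seqs = ["".join(_BASES[b] for b in states[v]) for v in range(G.n_tips)]
    return Locus(list(G.labels), seqs)


def _caterpillar_newick(labels: list[str], theta: float) -> str:
    s = len(labels)
    nwk = labels[0]
    depth = (s - 1) * theta
    cur = 0.0
    for k, lab in enumerate(labels[1:], start=1):
        h = k * theta
        nwk = f"({nwk}:{h - cur},{lab}:{h})"
        cur = h
    return nwk + ";"


def _balanced_newick(labels: list[str], theta: float) -> str:
    def build(labs, level):
        if len(labs) == 1:
            return labs[0], 0.0
        mid = len(labs) // 2
        l, hl = build(labs[:mid], level - 1)
        r, hr = build(labs[mid:], level - 1)
        h = level * theta
        return f"({l}:{h - hl},{r}:{h - hr})", h

    nwk, _ = build(labels, int(np.log2(len(labels))))
    return nwk + ";"


def build_study_tree(shape: str, theta: float, s: int = 16) -> SpeciesTree:
    """The simulation-study species trees: every internode interval = theta.

    ``asymmetric`` is the pure caterpillar (root age ``(s-1)*theta``);
    ``symmetric`` is the fully balanced tree (root age ``log2(s)*theta``).
    All populations share the same ``theta``.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    labels = [string.ascii_uppercase[i] if s <= 26 else f"S{i + 1}"
              for i in range(s)]
    if shape.startswith("asym"):
        nwk = _caterpillar_newick(labels, theta)
    elif shape.startswith("sym"):
        if s & (s - 1):
            raise ValueError("symmetric tree needs a power-of-2 species count")
        nwk = _balanced_newick(labels, theta)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return parse_newick(nwk, theta=theta)


def simulate_dataset(design: SimulationDesign,
                     rng: np.random.Generator | None = None):
    """Simulate an L-locus dataset; returns (AlignmentSet, gene_trees, S)."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    S = design.species_tree()
    gtrees, loci = [], []
    for i in range(design.n_loci):
        G = simulate_gene_tree(S, design.samples_per_species, rng, locus=i)
        gtrees.append(G)
        loci.append(simulate_alignment(G, design.n_sites, rng))
    imap = IndividualMap({lab: lab.rsplit("^", 1)[1]
                          for loc in loci for lab in loc.labels})
    return AlignmentSet(loci, imap), gtrees, S
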