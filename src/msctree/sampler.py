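"""MCMC driver and posterior summaries.

Two analysis modes mirror the BPP conventions: A00 (species-tree topology
fixed; sample parameters and gene trees) and A01 (species-tree inference:
within-model sweeps plus transmodel SPR/nodeslider proposals with
pre-assigned attempt probabilities, default 0.6/0.4).

One "iteration" is one full sweep updating every parameter in the model
(all thetas, all taus, both gene-tree sub-moves at every locus, one mixing
move), followed in A01 mode by one transmodel attempt.  Iteration counts
are therefore not comparable across programs with thinner iterations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .likelihood import AlignmentSet, phylo_loglik
from .msc_model import PriorConfig, coalescent_stats, log_prior_params, \
    msc_density_from_stats
from .simulator import simulate_gene_tree
from .trees_core import GeneTree, SpeciesTree, parse_newick, \
    random_topology_newick
from .within_moves import TuningState, sweep

__all__ = ["MCMCState", "RunSettings", "Trace", "PosteriorSummary",
           "init_state", "run", "summarize", "simulation_metrics"]


class MCMCState:
    """Full chain state: species tree, per-locus gene trees, caches."""

    def __init__(self, S: SpeciesTree, gtrees: list[GeneTree],
                 data: AlignmentSet | None, prior: PriorConfig,
                 rng: np.random.Generator, beta: float = 1.0):
        self.S = S
        self.gtrees = gtrees
        self.data = data
        self.prior = prior
        self.rng = rng
        self.beta = beta
        self.lnL = np.zeros(len(gtrees))
        self.stats_k: list[np.ndarray] = [None] * len(gtrees)
        self.stats_A: list[np.ndarray] = [None] * len(gtrees)
        self.refresh()

    # ---- caches ----------------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.gtrees)

    def locus_loglik(self, i: int, G: GeneTree) -> float:
        if self.data is None:
            return 0.0
        return phylo_loglik(self.data.loci[i], G)

    def refresh(self) -> None:
        for i, G in enumerate(self.gtrees):
            G.recompute_pops(self.S)
            self.stats_k[i], self.stats_A[i] = coalescent_stats(G, self.S)
            self.lnL[i] = self.locus_loglik(i, G)

    def commit_locus(self, i: int, G: GeneTree, k: np.ndarray,
                     A: np.ndarray, lnl: float) -> None:
        self.gtrees[i] = G
        self.stats_k[i] = k
        self.stats_A[i] = A
        self.lnL[i] = lnl

    def msc_locus(self, i: int) -> float:
        return msc_density_from_stats(self.stats_k[i], self.stats_A[i],
                                      self.S.theta)

    def msc_total(self) -> float:
        return sum(self.msc_locus(i) for i in range(self.n_loci))

    def log_prior(self) -> float:
        return log_prior_params(self.S, self.prior)

    def total_loglik(self) -> float:
        return float(self.lnL.sum())

    def check(self) -> None:
        """Debug assertion: caches equal fresh recomputation."""
        for i, G in enumerate(self.gtrees):
            G.validate(self.S)
            k, A = coalescent_stats(G, self.S)
            assert np.array_equal(k, self.stats_k[i])
            assert np.allclose(A, self.stats_A[i], rtol=1e-8, atol=1e-12)
            assert abs(self.locus_loglik(i, G) - self.lnL[i]) < 1e-6


def _assign_starting_ages(S: SpeciesTree, tau0: float,
                          rng: np.random.Generator) -> None:
    """Valid starting ages: root at tau0, children shrink geometrically."""
    S.tau[S.root] = tau0
    for v in reversed(S.postorder()):
        if S.is_tip(v) or v == S.root:
            continue
        p = int(S.parent[v])
        S.tau[v] = S.tau[p] * (0.5 + 0.45 * rng.random())
    S.tau[:S.s] = 0.0


def init_state(prior: PriorConfig, rng: np.random.Generator,
               data: AlignmentSet | None = None,
               species: list[str] | None = None,
               start_tree: SpeciesTree | None = None,
               n_loci: int | None = None,
               samples_per_species: int = 2,
               beta: float = 1.0) -> MCMCState:
    """Build a starting state.

    The species tree is ``start_tree`` or a uniform-random topology; thetas
    are drawn from their prior, the root age from its prior, and gene trees
    are simulated from the MSC given (S, theta, tau) so the starting
    embedding is compatible by construction.  With ``data`` given, gene
    trees are simulated conditioned on each locus' sampled individuals; a
    locus with fewer than two sequences is rejected at load time.
    """
    if species is None:
        if start_tree is not None:
            species = list(start_tree.labels)
        elif data is not None:
            species = sorted({data.imap.species_of(lab)
                              for loc in data.loci for lab in loc.labels})
        else:
            raise ValueError("need species labels, a tree, or data")
    if start_tree is not None:
        S = start_tree.copy()
    else:
        S = parse_newick(random_topology_newick(species, rng),
                         ages_from_branch_lengths=False)
    tau0 = rng.gamma(prior.tau_a) / prior.tau_b
    _assign_starting_ages(S, tau0, rng)
    S.theta = rng.gamma(prior.theta_a, size=S.n_nodes) / prior.theta_b

    gtrees = []
    if data is not None:
        label_to_tip = {lab: i for i, lab in enumerate(S.labels)}
        for i, loc in enumerate(data.loci):
            tip_species = np.array(
                [label_to_tip[data.imap.species_of(lab)] for lab in loc.labels])
            gtrees.append(_simulate_for_labels(S, list(loc.labels),
                                               tip_species, rng, i))
    else:
        L = n_loci if n_loci is not None else 1
        for i in range(L):
            gtrees.append(simulate_gene_tree(S, samples_per_species, rng,
                                             locus=i))
    return MCMCState(S, gtrees, data, prior, rng, beta=beta)


def _simulate_for_labels(S: SpeciesTree, labels: list[str],
                         tip_species: np.ndarray, rng: np.random.Generator,
                         locus: int) -> GeneTree:
    """Simulate an MSC gene tree over a fixed set of sampled sequences."""
    counts: dict[str, int] = {}
    for sp in tip_species:
        counts[S.labels[int(sp)]] = counts.get(S.labels[int(sp)], 0) + 1
    G = simulate_gene_tree(S, counts, rng, locus=locus)
    # re-label tips to the data's labels, matching within species
    order_by_species: dict[int, list[int]] = {}
    for i in range(G.n_tips):
        order_by_species.setdefault(int(G.tip_species[i]), []).append(i)
    new_labels = list(G.labels)
    for i, lab in enumerate(labels):
        sp = int(tip_species[i])
        j = order_by_species[sp].pop(0)
        new_labels[j] = lab
    # reorder tips so row i of the alignment is tip i
    perm = {old: labels.index(new_labels[old]) for old in range(G.n_tips)}
    return _permute_tips(G, perm, labels, tip_species)


def _permute_tips(G: GeneTree, perm: dict[int, int], labels: list[str],
                  tip_species: np.ndarray) -> GeneTree:
    n = G.n_nodes
    full = np.arange(n)
    for old, new in perm.items():
        full[old] = new
    parent = np.full(n, -1, dtype=np.int64)
    children = np.full((n, 2), -1, dtype=np.int64)
    age = np.zeros(n)
    for v in range(n):
        nv = int(full[v])
        age[nv] = G.age[v]
        if G.parent[v] >= 0:
            parent[nv] = int(full[G.parent[v]])
        for k in range(2):
            if G.children[v, k] >= 0:
                children[nv, k] = int(full[G.children[v, k]])
    return GeneTree(list(labels), np.asarray(tip_species), parent, children,
                    age, locus=G.locus)


@dataclass
class RunSettings:
    """Chain settings (control-file keys burnin/sampfreq/nsample etc.)."""

    mode: str = "a01"            # 'a00' fixes the species-tree topology
    burnin: int = 2000
    nsample: int = 10000
    sampfreq: int = 2
    p_spr: float = 0.6           # probability of attempting SPR vs nodeslider
    expand_ratio: float = 0.1
    shrink_ratio: float = 0.1
    tuning: TuningState | None = None
    record_params: bool = False
    gene_all_ages: bool = False   # resample every coalescent-node age
    debug_check_every: int = 0


@dataclass
class Trace:
    topologies: list[str] = field(default_factory=list)
    tau0: list[float] = field(default_factory=list)
    lnL: list[float] = field(default_factory=list)
    taus: list[np.ndarray] = field(default_factory=list)
    thetas: list[np.ndarray] = field(default_factory=list)
    accept: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.topologies)


def run(state: MCMCState, settings: RunSettings) -> Trace:
    """Run the chain; returns one sample every ``sampfreq`` sweeps."""
    from . import nodeslider_move, spr_move

    tuning = settings.tuning or TuningState()
    transmodel = settings.mode == "a01" and state.S.s >= 3
    trace = Trace()

    def one_iteration() -> None:
        sweep(state, tuning, all_ages=settings.gene_all_ages)
        if transmodel:
            if state.rng.random() < settings.p_spr:
                spr_move.apply_spr(state, tuning)
            else:
                nodeslider_move.apply_nodeslider(
                    state, tuning, expand_ratio=settings.expand_ratio,
                    shrink_ratio=settings.shrink_ratio)

    for it in range(settings.burnin):
        one_iteration()
        if it and it % 200 == 0:
            tuning.tune()
    tuning.frozen = True

    total = settings.nsample * settings.sampfreq
    for it in range(total):
        one_iteration()
        if settings.debug_check_every and it % settings.debug_check_every == 0:
            state.check()
        if (it + 1) % settings.sampfreq == 0:
            trace.topologies.append(state.S.topology_key())
            trace.tau0.append(float(state.S.tau[state.S.root]))
            trace.lnL.append(state.total_loglik())
            if settings.record_params:
                trace.taus.append(state.S.tau.copy())
                trace.thetas.append(state.S.theta.copy())
    trace.accept = {k: v.rate for k, v in tuning.counters.items()}
    return trace


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    topology_probs: list[tuple[str, float]]     # sorted, decreasing
    clade_support: dict[frozenset, float]
    map_tree: str
    consensus: str

    def credible_set(self, level: float) -> list[str]:
        """Smallest prefix of topologies with cumulative probability >= level."""
        out, cum = [], 0.0
        for key, p in self.topology_probs:
            out.append(key)
            cum += p
            if cum >= level - 1e-12:
                break
        return out


def _clades_of(key: str) -> set[frozenset]:
    S = parse_newick(key, ages_from_branch_lengths=False)
    out = set()
    for v in range(S.s, S.n_nodes):
        out.add(frozenset(S.labels[t] for t in S.clade_tips(v)))
    return out


def _consensus_newick(clades: list[frozenset], tips: list[str]) -> str:
    """Build a Newick string from a compatible set of clades."""
    clades = sorted(set(clades) | {frozenset([t]) for t in tips}
                    | {frozenset(tips)}, key=len)

    def build(cl: frozenset) -> str:
        members = [c for c in clades if c < cl]
        # maximal proper sub-clades
        parts = []
        for c in sorted(members, key=len, reverse=True):
            if not any(c < p for p in parts):
                parts.append(c)
        sub = [build(c) if len(c) > 1 else next(iter(c)) for c in parts]
        return "(" + ",".join(sorted(sub)) + ")"

    return build(frozenset(tips)) + ";"


def summarize(trace: Trace) -> PosteriorSummary:
    """Topology probabilities, clade supports, MAP and majority-rule trees."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    n = len(trace)
    counts = Counter(trace.topologies)
    probs = sorted(((k, c / n) for k, c in counts.items()),
                   key=lambda kv: (-kv[1], kv[0]))
    clade_counts: Counter = Counter()
    for key, c in counts.items():
        for cl in _clades_of(key):
            clade_counts[cl] += c
    support = {cl: c / n for cl, c in clade_counts.items()}
    tips = sorted(parse_newick(probs[0][0], ages_from_branch_lengths=False)
                  .labels)
    majority = [cl for cl, p in support.items() if p > 0.5 and 1 < len(cl)]
    consensus = _consensus_newick(majority, tips)
    return PosteriorSummary(probs, support, probs[0][0], consensus)


def simulation_metrics(summaries: list[PosteriorSummary],
                       true_tree: SpeciesTree) -> dict:
    """Replicate-level metrics: node recovery, CST coverage, mean CST size.

    A node of the true tree is recovered in a replicate if its clade has
    posterior support > 0.5 (i.e. it appears in the consensus tree).
    """
    if not summaries:
        raise ValueError("need at least one replicate")
    true_key = true_tree.topology_key()
    true_clades = sorted(_clades_of(true_key), key=len)
    R = len(summaries)
    node_recovery = {}
    for cl in true_clades:
        node_recovery[tuple(sorted(cl))] = \
            sum(s.clade_support.get(cl, 0.0) > 0.5 for s in summaries) / R
    cov95 = sum(true_key in s.credible_set(0.95) for s in summaries) / R
    cov99 = sum(true_key in s.credible_set(0.99) for s in summaries) / R
    mean_cst = float(np.mean([len(s.credible_set(0.99)) for s in summaries]))
    return {"node_recovery": node_recovery, "coverage_95": cov95,
            "coverage_99": cov99, "mean_cst99_size": mean_cst}
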