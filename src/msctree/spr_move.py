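"""Coordinated species-tree SPR proposal.

Prunes a species-tree branch Y-A (clade A included) and regrafts it, at the
unchanged age tau_Y, onto a feasible target branch C (one covering tau_Y,
outside clade A and distinct from A's sibling B).  No node age changes in
the species tree or in any gene tree.  Gene trees are kept compatible by a
coordinated SPR: every gene-tree node residing in a population on the path
Y..Z (Z = MRCA of A and C, Z excluded) that has exactly one daughter whose
descendants are all from clade-A species is pruned (with its all-A subtree)
and regrafted at its unchanged age onto a uniformly chosen skeleton branch
alive at that age in the population the A lineage then occupies (a
population on the path C..Z).  Remaining population labels are rewritten
canonically; with stable node IDs the deleted population AB and the created
population AC share one ID, which carries its theta across the move.

Proposal weights: the internal branch is chosen with probability
proportional to 1/sqrt(branch length) (short branches preferred), and the
target with probability proportional to 1/c_i where c_i counts the nodes on
the path A-Z-C_i (minimum 4, in which case the move reduces to NNI).
"""

from __future__ import annotations

import math

import numpy as np

from .msc_model import coalescent_stats, msc_density_from_stats, \
    topology_mh_log_ratio
from .trees_core import GeneTree, SpeciesTree, mrca

__all__ = ["sample_internal_branch", "feasible_targets", "sample_target",
           "find_moved_nodes", "apply_spr"]

#: floor applied to internal branch lengths before the 1/sqrt(b) weights
MIN_BRANCH = 1e-30


def _branch_weights(S: SpeciesTree, branches: list[int]) -> np.ndarray:
    b = np.array([max(S.branch_length(v), MIN_BRANCH) for v in branches])
    w = b ** -0.5
    return w / w.sum()


def sample_internal_branch(S: SpeciesTree, rng) -> tuple[int, float]:
    """Sample branch X-Y among the s-2 internal branches, w_i ~ b_i^{-1/2}.

    Returns (Y, log selection probability).
    """
    branches = S.internal_branches()
    if not branches:
        raise ValueError("SPR requires at least 3 species")
    p = _branch_weights(S, branches)
    i = int(rng.choice(len(branches), p=p))
    return branches[i], float(np.log(p[i]))


def branch_selection_logprob(S: SpeciesTree, Y: int) -> float:
    """Log Eq.-4 probability of selecting branch parent(Y)-Y on S."""
    branches = S.internal_branches()
    p = _branch_weights(S, branches)
    return float(np.log(p[branches.index(Y)]))


def feasible_targets(S: SpeciesTree, Y: int, A: int) -> list[int]:
    """Branches that remain after pruning Y-A (exclusive of branch B) and
    cover the age tau_Y."""
    B = int(S.children[Y, 0] if S.children[Y, 1] == A else S.children[Y, 1])
    clade_a = set(S.clade_nodes(A))
    tau_y = float(S.tau[Y])
    out = []
    for c in range(S.n_nodes):
        if c in clade_a or c == Y or c == B or S.parent[c] < 0:
            continue
        # candidate parents are never Y (only A and B have parent Y)
        if S.tau[c] <= tau_y < S.tau[S.parent[c]]:
            out.append(c)
    return out


def path_node_count(S: SpeciesTree, A: int, C: int) -> tuple[int, int]:
    """Z = mrca(A, C) and the number of nodes on the path A-Z-C inclusive."""
    Z = mrca(S, A, C)
    c = 1  # Z itself
    u = A
    while u != Z:
        c += 1
        u = int(S.parent[u])
    u = C
    while u != Z:
        c += 1
        u = int(S.parent[u])
    return Z, c


def sample_target(S: SpeciesTree, targets: list[int], A: int, rng
                  ) -> tuple[int, int, float]:
    """Sample a target with v_i ~ 1/c_i; returns (C, c_C, log prob)."""
    cs = np.array([path_node_count(S, A, c)[1] for c in targets], dtype=float)
    w = 1.0 / cs
    p = w / w.sum()
    i = int(rng.choice(len(targets), p=p))
    return targets[i], int(cs[i]), float(np.log(p[i]))


def target_selection_logprob(S: SpeciesTree, targets: list[int], A: int,
                             C: int) -> float:
    cs = np.array([path_node_count(S, A, c)[1] for c in targets], dtype=float)
    w = 1.0 / cs
    return float(np.log(w[targets.index(C)] / w.sum()))


def _all_a_mask(G: GeneTree, a_species: set[int]) -> np.ndarray:
    """allA[v]: all sequence descendants of v belong to clade-A species."""
    mask = np.zeros(G.n_nodes, dtype=bool)
    for v in G.postorder():
        if G.is_tip(v):
            mask[v] = int(G.tip_species[v]) in a_species
        else:
            c0, c1 = G.children[v]
            mask[v] = mask[c0] and mask[c1]
    return mask


def find_moved_nodes(G: GeneTree, S: SpeciesTree, Y: int, Z: int, A: int
                     ) -> list[int]:
    """Gene-tree nodes to be pruned and regrafted by the SPR move.

    A moved node resides in a population on the path Y..Z (Z excluded) and
    has exactly one daughter whose descendants are all in clade A.
    """
    a_species = set(S.clade_tips(A))
    path_pops = set()
    u = Y
    while u != Z:
        path_pops.add(u)
        u = int(S.parent[u])
    all_a = _all_a_mask(G, a_species)
    out = []
    for v in range(G.n_tips, G.n_nodes):
        if int(G.pop[v]) not in path_pops:
            continue
        c0, c1 = (int(c) for c in G.children[v])
        if all_a[c0] != all_a[c1]:
            out.append(v)
    return out


def _build_skeleton(G: GeneTree, moved: list[int], all_a: np.ndarray):
    """Detach each moved node (with its all-A subtree) from the gene tree.

    Moved nodes may be chained (the skeleton-side child of one moved node
    can itself be a moved node); the bypass then skips the whole chain, and
    the effective skeleton child below each moved node is reported in
    ``s_child`` (it is the skeleton branch the node currently sits on).

    Returns (parent, children, skeleton-root, skeleton-node list,
    a_child map, s_child map) on copied arrays.
    """
    parent = G.parent.copy()
    children = G.children.copy()
    moved_set = set(moved)
    a_child, s_child = {}, {}
    for v in moved:
        c0, c1 = (int(c) for c in G.children[v])
        ca, cs = (c0, c1) if all_a[c0] else (c1, c0)
        a_child[v] = ca
        while cs in moved_set:          # skip through chained moved nodes
            cs = (int(G.children[cs, 1])
                  if all_a[G.children[cs, 0]] else int(G.children[cs, 0]))
        s_child[v] = cs
    for v in moved:
        if int(G.parent[v]) in moved_set:
            continue                    # interior of a chain: top handles it
        cs = s_child[v]
        p = int(G.parent[v])
        parent[cs] = p
        if p >= 0:
            children[p, 0 if children[p, 0] == v else 1] = cs
    root = G.root
    while root in moved_set:            # old root was a moved node
        root = s_child[root]
    while parent[root] >= 0:
        root = int(parent[root])
    pruned = set()
    for v in moved:
        pruned.add(v)
        stack = [a_child[v]]
        while stack:
            u = stack.pop()
            pruned.add(u)
            if not G.is_tip(u):
                stack.extend(int(c) for c in G.children[u])
    skel = [u for u in range(G.n_nodes) if u not in pruned]
    return parent, children, root, skel, a_child, s_child


def _skeleton_pops(G: GeneTree, S: SpeciesTree, skel: list[int],
                   children, ages) -> dict[int, int]:
    """Canonical population of every skeleton node under S."""
    pops: dict[int, int] = {}
    order = sorted(skel, key=lambda u: (ages[u], not G.is_tip(u)))
    # bottom-up by age is safe for ultrametric-tips coalescent trees
    for u in order:
        if G.is_tip(u):
            pops[u] = int(G.tip_species[u])
        else:
            c0, c1 = (int(c) for c in children[u])
            base = mrca(S, pops[c0], pops[c1])
            pops[u] = S.pop_at(base, float(ages[u]))
    return pops


def _alive_targets(skel, parent, ages, root, pops, S: SpeciesTree,
                   lineage_pop: int, t: float,
                   exclude_all_a=None) -> list[int]:
    """Skeleton branches alive at t whose lineage is then in the population
    that the regrafted lineage occupies at t.

    ``exclude_all_a`` (a node mask) drops branches whose descendants are
    all from clade-A species: regrafting onto such a branch would merge two
    all-A subtrees and leave the reverse move unable to undo the proposal,
    so those branches are never targets (in either direction).
    """
    P = S.pop_at(lineage_pop, t)
    out = []
    for u in skel:
        if exclude_all_a is not None and exclude_all_a[u]:
            continue
        pu = int(parent[u]) if u != root else -1
        if ages[u] <= t and (pu < 0 or ages[pu] > t):
            if S.pop_at(pops[u], t) == P:
                out.append(u)
    return out


def apply_spr(state, tuning, script: dict | None = None) -> bool:
    """Attempt one coordinated SPR move on the full state (MH accept/reject).

    Ages are never changed; the proposal swaps the species-tree attachment
    of one clade and re-embeds the gene trees, with the Hastings ratio
    assembled from branch selection (on S and on S*), target selection,
    and per-moved-node gene-tree target counts.

    ``script`` overrides individual random choices (testing hook): keys
    'branch', 'daughter', 'target', 'gene_targets', 'force'.  The computed
    log acceptance ratio is exposed as ``state.last_logr``.
    """
    S = state.S
    rng = state.rng
    state.last_logr = None
    if S.s < 3:
        return False
    tuning.record("spr", False)  # provisional; flipped on accept
    script = script or {}

    if "branch" in script:
        Y = script["branch"]
        log_w_fwd = branch_selection_logprob(S, Y)
    else:
        Y, log_w_fwd = sample_internal_branch(S, rng)
    X = int(S.parent[Y])
    if "daughter" in script:
        A = script["daughter"]
    else:
        A = int(S.children[Y, int(rng.integers(2))])
    B = int(S.children[Y, 0] if S.children[Y, 1] == A else S.children[Y, 1])
    tau_y = float(S.tau[Y])

    targets = feasible_targets(S, Y, A)
    if "target" in script:
        C = script["target"]
        log_v_fwd = target_selection_logprob(S, targets, A, C)
    else:
        C, _, log_v_fwd = sample_target(S, targets, A, rng)
    Z, _ = path_node_count(S, A, C)

    # ---- proposed species tree (node Y re-used as the AC population) -----
    S2 = S.copy()
    pc = int(S.parent[C])
    S2.children[X, 0 if S2.children[X, 0] == Y else 1] = B
    S2.parent[B] = X
    S2.children[pc, 0 if S2.children[pc, 0] == C else 1] = Y
    S2.parent[Y] = pc
    S2.children[Y] = (A, C)
    S2.parent[C] = Y
    S2.parent[A] = Y

    # reverse-move bookkeeping on S2
    log_w_rev = branch_selection_logprob(S2, Y)
    rev_targets = feasible_targets(S2, Y, A)
    assert B in rev_targets
    log_v_rev = target_selection_logprob(S2, rev_targets, A, B)

    logr = topology_mh_log_ratio(S2, S, state.prior)
    logr += (log_w_rev - log_w_fwd) + (log_v_rev - log_v_fwd)

    # ---- gene trees ------------------------------------------------------
    new_gtrees: list[GeneTree] = []
    new_stats = []
    new_lnL = np.array(state.lnL)
    for i, G in enumerate(state.gtrees):
        moved = find_moved_nodes(G, S, Y, Z, A)
        if not moved:
            G2 = G.copy()
            G2.recompute_pops(S2)
            k, A_st = coalescent_stats(G2, S2)
            logr += msc_density_from_stats(k, A_st, S2.theta) \
                - state.msc_locus(i)
            new_gtrees.append(G2)
            new_stats.append((k, A_st))
            continue

        a_species = set(S.clade_tips(A))
        all_a = _all_a_mask(G, a_species)
        parent, children, skel_root, skel, a_child, s_child = \
            _build_skeleton(G, moved, all_a)
        pops_old = _skeleton_pops(G, S, skel, children, G.age)
        pops_new = _skeleton_pops(G, S2, skel, children, G.age)

        ok = True
        chosen: dict[int, int] = {}
        gene_script = script.get("gene_targets", {})
        for v in sorted(moved, key=lambda u: G.age[u]):
            t = float(G.age[v])
            fwd = _alive_targets(skel, parent, G.age, skel_root, pops_new,
                                 S2, A, t, exclude_all_a=all_a)
            if not fwd:
                ok = False
                break
            rev = _alive_targets(skel, parent, G.age, skel_root, pops_old,
                                 S, A, t, exclude_all_a=all_a)
            assert s_child[v] in rev
            if (i, v) in gene_script:
                chosen[v] = gene_script[(i, v)]
                assert chosen[v] in fwd
            else:
                chosen[v] = fwd[int(rng.integers(len(fwd)))]
            logr += math.log(len(fwd)) - math.log(len(rev))
        if not ok:
            return False    # a moved node had no feasible regraft branch

        # rebuild: chain moved nodes onto their skeleton target branches
        by_branch: dict[int, list[int]] = {}
        for v, b in chosen.items():
            by_branch.setdefault(b, []).append(v)
        for b, vs in by_branch.items():
            vs.sort(key=lambda u: G.age[u])
            pb = int(parent[b]) if b != skel_root else -1
            low = b
            for v in vs:
                parent[low] = v
                children[v] = (a_child[v], low)
                low = v
            parent[low] = pb
            if pb >= 0:
                children[pb, 0 if children[pb, 0] == b else 1] = low

        G2 = GeneTree(G.labels, G.tip_species, parent, children,
                      G.age.copy(), locus=G.locus, root=-1)
        G2.recompute_pops(S2)
        k, A_st = coalescent_stats(G2, S2)
        logr += msc_density_from_stats(k, A_st, S2.theta) - state.msc_locus(i)
        if state.data is not None:
            lnl = state.locus_loglik(i, G2)
            logr += state.beta * (lnl - state.lnL[i])
            new_lnL[i] = lnl
        new_gtrees.append(G2)
        new_stats.append((k, A_st))

    state.last_logr = logr
    force = script.get("force")
    if force == "reject":
        return False
    if force == "accept" or logr >= 0 \
            or rng.random() < math.exp(max(logr, -745.0)):
        state.S = S2
        state.gtrees = new_gtrees
        for i, (k, A_st) in enumerate(new_stats):
            state.stats_k[i], state.stats_A[i] = k, A_st
        state.lnL = new_lnL
        st = tuning.counters["spr"]
        st.accepts += 1
        return True
    return False
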