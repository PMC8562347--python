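"""Nodeslider (Expand/Shrink) transmodel proposal.

A fair coin picks the direction.  Expand slides an internal node Y (with a
randomly chosen attached clade A) rootward: a new age tau_Y* > tau_X is
drawn from an exponential with mean ``expand_ratio * tau_X`` on the excess,
clade-A ages are rescaled by tau_Y*/tau_Y, and Y-A reattaches on the unique
ancestral branch covering tau_Y* (becoming the new root if tau_Y* exceeds
the old root age).  Shrink slides Y tipward into the clade of its daughter
C: a new age tau_Y < tau_C is drawn from the power density
``f(tau) = (lambda/tau_C)(tau/tau_C)^(lambda-1)`` with
``lambda = log(shrink_ratio)/log(1-shrink_ratio)`` (so 90% of the mass lies
within 10% below tau_C at the 0.1 default), and Y-A reattaches to one of
the G(tau_Y) descendant branches of C alive at that age, chosen uniformly.

Gene trees follow: every node with exactly one all-A daughter is pruned
with its all-A subtree, the subtree ages are rescaled by the same factor,
and the node regrafts at its rescaled age onto a uniformly chosen skeleton
branch then residing in population Y or an ancestor (in the proposed tree).
At an all-A locus every node age is simply rescaled.  The acceptance ratio
combines the species factor (branch/daughter/target selection and the two
age densities, with reverse weights computed on the proposed tree), one
global rescale Jacobian (tau_Y*/tau_Y)^m counting every rescaled age, the
root-age prior terms when the root age changes, the topology prior, and the
MSC-density and likelihood ratios.
"""

from __future__ import annotations

import math

import numpy as np

from .msc_model import coalescent_stats, gamma_logpdf, \
    msc_density_from_stats, topology_mh_log_ratio
from .spr_move import _all_a_mask, _alive_targets, _build_skeleton, \
    _skeleton_pops, branch_selection_logprob, sample_internal_branch
from .trees_core import GeneTree, SpeciesTree

__all__ = ["shrink_lambda", "draw_expand_age", "draw_shrink_age",
           "descendant_branches_at", "apply_nodeslider"]


def shrink_lambda(shrink_ratio: float = 0.1) -> float:
    """lambda = log(q)/log(1-q): puts 1-q of the power-density mass above
    (1-q)*tau_C."""
    return math.log(shrink_ratio) / math.log(1.0 - shrink_ratio)


def draw_expand_age(tau_x: float, expand_ratio: float, rng) -> float:
    """tau_Y* = tau_X + Exponential(mean = expand_ratio * tau_X)."""
    return tau_x + rng.exponential(expand_ratio * tau_x)


def expand_logpdf(tau_new: float, tau_x: float, expand_ratio: float) -> float:
    mu = expand_ratio * tau_x
    return -math.log(mu) - (tau_new - tau_x) / mu


def draw_shrink_age(tau_c: float, lam: float, rng) -> float:
    """Inverse-transform draw from the power density on (0, tau_C)."""
    return tau_c * rng.random() ** (1.0 / lam)


def shrink_logpdf(tau_new: float, tau_c: float, lam: float) -> float:
    return math.log(lam / tau_c) + (lam - 1.0) * math.log(tau_new / tau_c)


def descendant_branches_at(S: SpeciesTree, C: int, t: float) -> list[int]:
    """Branches of clade C (branch C included) alive at time t: G(tau).

    Inside the Shrink move the proposed age is always below tau_C, so
    branch C itself never qualifies there; it can only matter when C is a
    tip, where the sole alive branch is C's own.
    """
    out = []
    for u in S.clade_nodes(C):
        p = S.parent[u]
        if p >= 0 and S.tau[u] <= t < S.tau[p]:
            out.append(u)
    return out


def _regraft_gene_trees(state, S2: SpeciesTree, A: int, r: float,
                        a_species: set[int], gene_script: dict | None = None):
    """Shared Expand/Shrink gene-tree update.

    Returns (gene trees, stats, lnL, m_genes, log target-count ratio) for
    the proposed state, or None if a moved node has no feasible target.
    """
    S = state.S
    rng = state.rng
    logr_targets = 0.0
    m = 0
    new_gtrees, new_stats = [], []
    new_lnL = np.array(state.lnL)

    for i, G in enumerate(state.gtrees):
        species_here = {int(s) for s in G.tip_species}
        changed = bool(species_here & a_species)
        if species_here <= a_species:
            # all-A locus: rescale every age, structure and pops unchanged
            G2 = G.copy()
            G2.age = G.age * r
            m += G.n_tips - 1
            G2.recompute_pops(S2)
        elif not changed:
            G2 = G.copy()
            G2.recompute_pops(S2)
        else:
            all_a = _all_a_mask(G, a_species)
            moved = [v for v in range(G.n_tips, G.n_nodes)
                     if all_a[G.children[v, 0]] != all_a[G.children[v, 1]]]
            parent, children, skel_root, skel, a_child, s_child = \
                _build_skeleton(G, moved, all_a)
            ages = G.age.copy()
            # rescale each pruned piece: the moved node and its all-A subtree
            for v in moved:
                ages[v] *= r
                m += 1
                stack = [a_child[v]]
                while stack:
                    u = stack.pop()
                    if not G.is_tip(u):
                        ages[u] *= r
                        m += 1
                        stack.extend(int(c) for c in G.children[u])
            pops_old = _skeleton_pops(G, S, skel, children, G.age)
            pops_new = _skeleton_pops(G, S2, skel, children, ages)

            chosen: dict[int, int] = {}
            failed = False
            for v in sorted(moved, key=lambda u: ages[u]):
                fwd = _alive_targets(skel, parent, ages, skel_root, pops_new,
                                     S2, A, float(ages[v]))
                if not fwd:
                    failed = True
                    break
                rev = _alive_targets(skel, parent, G.age, skel_root, pops_old,
                                     S, A, float(G.age[v]))
                assert s_child[v] in rev
                if gene_script and (i, v) in gene_script:
                    chosen[v] = gene_script[(i, v)]
                    assert chosen[v] in fwd
                else:
                    chosen[v] = fwd[int(rng.integers(len(fwd)))]
                logr_targets += math.log(len(fwd)) - math.log(len(rev))
            if failed:
                return None

            by_branch: dict[int, list[int]] = {}
            for v, b in chosen.items():
                by_branch.setdefault(b, []).append(v)
            for b, vs in by_branch.items():
                vs.sort(key=lambda u: ages[u])
                pb = int(parent[b]) if b != skel_root else -1
                low = b
                for v in vs:
                    parent[low] = v
                    children[v] = (a_child[v], low)
                    low = v
                parent[low] = pb
                if pb >= 0:
                    children[pb, 0 if children[pb, 0] == b else 1] = low
            G2 = GeneTree(G.labels, G.tip_species, parent, children, ages,
                          locus=G.locus, root=-1)
            G2.recompute_pops(S2)

        k, A_st = coalescent_stats(G2, S2)
        new_gtrees.append(G2)
        new_stats.append((k, A_st))
        if changed and state.data is not None:
            new_lnL[i] = state.locus_loglik(i, G2)
    return new_gtrees, new_stats, new_lnL, m, logr_targets


def apply_nodeslider(state, tuning, expand_ratio: float = 0.1,
                     shrink_ratio: float = 0.1,
                     script: dict | None = None) -> bool:
    """Attempt one nodeslider move (Expand if U >= 0.5, else Shrink).

    ``script`` overrides individual random choices (testing hook): keys
    'expand', 'branch', 'daughter', 'tau_new', 'B', 'gene_targets',
    'force'.  The computed log acceptance ratio is exposed as
    ``state.last_logr``.
    """
    S = state.S
    rng = state.rng
    state.last_logr = None
    if S.s < 3:
        return False
    tuning.record("nodeslider", False)
    script = script or {}
    lam = shrink_lambda(shrink_ratio)
    expand = script["expand"] if "expand" in script \
        else rng.random() >= 0.5

    if expand:
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
        B = int(S.children[Y, 0] if S.children[Y, 1] == A
                else S.children[Y, 1])
        tau_y_old = float(S.tau[Y])
        tau_x = float(S.tau[X])
        tau_y_new = script.get("tau_new") if "tau_new" in script \
            else draw_expand_age(tau_x, expand_ratio, rng)
        r = tau_y_new / tau_y_old
        # unique ancestral branch covering tau_Y* on the pruned tree
        C = X
        while S.parent[C] >= 0 and S.tau[S.parent[C]] <= tau_y_new:
            C = int(S.parent[C])
        log_sel_fwd = log_w_fwd + math.log(0.5) \
            + expand_logpdf(tau_y_new, tau_x, expand_ratio)
    else:
        if "branch" in script:
            C = script["branch"]
            log_w_fwd = branch_selection_logprob(S, C)
        else:
            C, log_w_fwd = sample_internal_branch(S, rng)   # branch Y-C
        Y = int(S.parent[C])
        A = int(S.children[Y, 0] if S.children[Y, 1] == C
                else S.children[Y, 1])
        tau_y_old = float(S.tau[Y])
        tau_c = float(S.tau[C])
        tau_y_new = script.get("tau_new") if "tau_new" in script \
            else draw_shrink_age(tau_c, lam, rng)
        r = tau_y_new / tau_y_old
        g_set = descendant_branches_at(S, C, tau_y_new)
        if "B" in script:
            B = script["B"]
            assert B in g_set
        else:
            B = g_set[int(rng.integers(len(g_set)))]
        log_sel_fwd = log_w_fwd - math.log(len(g_set)) \
            + shrink_logpdf(tau_y_new, tau_c, lam)

    # ---- build proposed species tree (Y keeps its ID) --------------------
    S2 = S.copy()
    if expand:
        detach_sib = B          # B contracts onto X
        attach_on = C
    else:
        detach_sib = C          # C contracts onto Y's old parent (or root)
        attach_on = B
    Xp = int(S.parent[Y])
    if Xp >= 0:
        S2.children[Xp, 0 if S2.children[Xp, 0] == Y else 1] = detach_sib
        S2.parent[detach_sib] = Xp
    else:
        S2.parent[detach_sib] = -1
    pc = int(S.parent[attach_on])   # never Y: the target is not Y's child
    S2.parent[Y] = pc
    if pc >= 0:
        S2.children[pc, 0 if S2.children[pc, 0] == attach_on else 1] = Y
    S2.children[Y] = (A, attach_on)
    S2.parent[attach_on] = Y
    S2.parent[A] = Y
    S2.tau[Y] = tau_y_new
    if pc < 0:
        S2.root = Y
    elif S.root == Y:
        S2.root = detach_sib
    # rescale clade-A internal ages
    m_species = 0
    for v in S.clade_nodes(A):
        if not S.is_tip(v):
            S2.tau[v] = S.tau[v] * r
            m_species += 1
    S2.validate()

    # ---- reverse selection on S2 ----------------------------------------
    if expand:
        # reverse is Shrink selecting branch Y-C on S2
        log_w_rev = branch_selection_logprob(S2, C)
        g_rev = descendant_branches_at(S2, C, tau_y_old)
        assert B in g_rev
        log_sel_rev = log_w_rev - math.log(len(g_rev)) \
            + shrink_logpdf(tau_y_old, float(S2.tau[C]), lam)
    else:
        # reverse is Expand selecting branch X2-Y on S2
        log_w_rev = branch_selection_logprob(S2, Y)
        tau_x2 = float(S2.tau[S2.parent[Y]])
        log_sel_rev = log_w_rev + math.log(0.5) \
            + expand_logpdf(tau_y_old, tau_x2, expand_ratio)

    logr = log_sel_rev - log_sel_fwd
    logr += topology_mh_log_ratio(S2, S, state.prior)
    tau0_old = float(S.tau[S.root])
    tau0_new = float(S2.tau[S2.root])
    if tau0_new != tau0_old:
        cfg = state.prior
        logr += gamma_logpdf(tau0_new, cfg.tau_a, cfg.tau_b) \
            - gamma_logpdf(tau0_old, cfg.tau_a, cfg.tau_b)
        if S.s > 2:
            logr += -(S.s - 2) * (math.log(tau0_new) - math.log(tau0_old))

    # ---- gene trees ------------------------------------------------------
    a_species = set(S.clade_tips(A))
    res = _regraft_gene_trees(state, S2, A, r, a_species,
                              script.get("gene_targets"))
    if res is None:
        return False
    new_gtrees, new_stats, new_lnL, m_genes, logr_targets = res
    logr += logr_targets + (m_species + m_genes) * math.log(r)
    for i, (k, A_st) in enumerate(new_stats):
        logr += msc_density_from_stats(k, A_st, S2.theta) - state.msc_locus(i)
    if state.data is not None:
        logr += state.beta * float(new_lnL.sum() - state.lnL.sum())

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
        tuning.counters["nodeslider"].accepts += 1
        return True
    return False
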