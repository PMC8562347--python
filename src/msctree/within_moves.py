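"""Within-model MCMC moves: theta, tau rubber-band, gene-tree moves, mixing.

These proposals keep the species-tree topology fixed.  Correctness is
defined distributionally — with the likelihood fixed at 1 a full sweep must
sample (theta, tau, G) from prior x MSC density — and is enforced by the
prior-recovery tests.

Kernels:

* ``theta``: sliding window on log theta (one population at a time), with
  the MSC-density ratio from per-population sufficient statistics.
* ``tau`` rubber-band: a species divergence time moves inside its feasible
  window and gene-tree node ages in the three adjacent populations are
  interpolated between the moved boundary and the fixed neighbouring
  boundaries, with the interval-ratio Jacobian; for the root the window is
  one-sided and nodes in the root population shift rigidly.
* gene-tree age resample and gene-tree SPR per locus.
* a global mixing move multiplying all ages and thetas by a common factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .msc_model import coalescent_stats, gamma_logpdf, msc_density_from_stats
from .trees_core import GeneTree

__all__ = ["TuningState", "update_thetas", "update_taus",
           "update_gene_tree", "mixing_move", "sweep"]


@dataclass
class MoveStats:
    attempts: int = 0
    accepts: int = 0

    @property
    def rate(self) -> float:
        return self.accepts / self.attempts if self.attempts else 0.0


@dataclass
class TuningState:
    """Per-move step sizes with burn-in auto-tuning into [0.2, 0.5]."""

    steps: dict = field(default_factory=lambda: {
        "theta": 0.4, "tau": 0.002, "gene_age": 0.002,
        "gene_spr": 0.002, "mixing": 0.3,
    })
    counters: dict = field(default_factory=dict)
    frozen: bool = False
    lo: float = 0.2
    hi: float = 0.5

    def record(self, move: str, accepted: bool) -> None:
        st = self.counters.setdefault(move, MoveStats())
        st.attempts += 1
        st.accepts += int(accepted)

    def tune(self) -> None:
        """Adjust step sizes toward the target window; call during burn-in."""
        if self.frozen:
            return
        for move, st in self.counters.items():
            if move not in self.steps or st.attempts < 50:
                continue
            if st.rate < self.lo:
                self.steps[move] *= 0.7
            elif st.rate > self.hi:
                self.steps[move] *= 1.4
            self.counters[move] = MoveStats()


def _mh_accept(state, logr: float) -> bool:
    return logr >= 0 or state.rng.random() < math.exp(max(logr, -745.0))


# ---------------------------------------------------------------------------
# theta
# ---------------------------------------------------------------------------

def update_thetas(state, tuning: TuningState) -> None:
    """Sliding-window update on log theta, one population at a time."""
    S = state.S
    eps = tuning.steps["theta"]
    cfg = state.prior
    sum_k = np.sum([k for k in state.stats_k], axis=0)
    sum_A = np.sum([A for A in state.stats_A], axis=0)
    for j in range(S.n_nodes):
        th = float(S.theta[j])
        th_new = th * math.exp(eps * (state.rng.random() - 0.5))
        logr = (gamma_logpdf(th_new, cfg.theta_a, cfg.theta_b)
                - gamma_logpdf(th, cfg.theta_a, cfg.theta_b)
                + math.log(th_new / th))
        logr += float(sum_k[j]) * math.log(th / th_new) \
            - float(sum_A[j]) * (1.0 / th_new - 1.0 / th)
        ok = _mh_accept(state, logr)
        if ok:
            S.theta[j] = th_new
        tuning.record("theta", ok)


# ---------------------------------------------------------------------------
# tau rubber-band
# ---------------------------------------------------------------------------

def _reflect(x: float, lo: float, hi: float) -> float:
    if hi < math.inf:
        width = hi - lo
        y = (x - lo) % (2.0 * width)
        return lo + (y if y <= width else 2.0 * width - y)
    # one-sided
    return lo + abs(x - lo)


def update_tau_rubberband(state, j: int, tuning: TuningState) -> None:
    S = state.S
    cfg = state.prior
    c0, c1 = (int(c) for c in S.children[j])
    lo = max(float(S.tau[c0]), float(S.tau[c1]))
    is_root = j == S.root
    up = math.inf if is_root else float(S.tau[S.parent[j]])
    tau_old = float(S.tau[j])
    eps = tuning.steps["tau"] if is_root else \
        min(tuning.steps["tau"], 0.9 * (up - lo))
    tau_new = _reflect(tau_old + eps * (state.rng.random() - 0.5), lo, up)
    if tau_new <= lo or tau_new >= up or tau_new == tau_old:
        tuning.record("tau", False)
        return

    # interpolation factors for ages in the two daughter populations and in
    # population j itself (Jacobian = product of interval ratios)
    fac_child = {c: (tau_new - float(S.tau[c])) / (tau_old - float(S.tau[c]))
                 for c in (c0, c1)}
    logjac_child = {c: math.log(fac_child[c]) for c in (c0, c1)}
    if is_root:
        shift = tau_new - tau_old
    else:
        fac_up = (up - tau_new) / (up - tau_old)
        log_fac_up = math.log(fac_up)

    logjac = 0.0
    new_ages: list[np.ndarray | None] = []
    changed: list[bool] = []
    for G in state.gtrees:
        ages = None
        for v in range(G.n_tips, G.n_nodes):
            p = int(G.pop[v])
            if p == c0 or p == c1:
                if ages is None:
                    ages = G.age.copy()
                tc = float(S.tau[p])
                ages[v] = tc + (G.age[v] - tc) * fac_child[p]
                logjac += logjac_child[p]
            elif p == j:
                if ages is None:
                    ages = G.age.copy()
                if is_root:
                    ages[v] = G.age[v] + shift
                else:
                    ages[v] = up - (up - G.age[v]) * fac_up
                    logjac += log_fac_up
        new_ages.append(ages)
        changed.append(ages is not None)

    logr = logjac
    if is_root:
        logr += (gamma_logpdf(tau_new, cfg.tau_a, cfg.tau_b)
                 - gamma_logpdf(tau_old, cfg.tau_a, cfg.tau_b))
        if S.s > 2:
            logr += -(S.s - 2) * (math.log(tau_new) - math.log(tau_old))

    # recompute MSC stats (interval lengths change even at unchanged loci)
    # and the likelihood at loci whose node ages moved
    S.tau[j] = tau_new
    prop_k, prop_A, prop_L = [], [], []
    try:
        for i, G in enumerate(state.gtrees):
            if changed[i]:
                G2 = G.copy()
                G2.age = new_ages[i]
            else:
                G2 = G
            k, A = coalescent_stats(G2, S)
            prop_k.append(k)
            prop_A.append(A)
            logr += msc_density_from_stats(k, A, S.theta) \
                - msc_density_from_stats(state.stats_k[i], state.stats_A[i],
                                         S.theta)
            if changed[i] and state.data is not None:
                lnl = state.locus_loglik(i, G2)
                logr += state.beta * (lnl - state.lnL[i])
                prop_L.append(lnl)
            else:
                prop_L.append(state.lnL[i])
    finally:
        S.tau[j] = tau_old

    ok = _mh_accept(state, logr)
    if ok:
        S.tau[j] = tau_new
        for i, G in enumerate(state.gtrees):
            if changed[i]:
                G.age = new_ages[i]
            state.stats_k[i] = prop_k[i]
            state.stats_A[i] = prop_A[i]
            state.lnL[i] = prop_L[i]
    tuning.record("tau", ok)


def update_taus(state, tuning: TuningState) -> None:
    for j in range(state.S.s, state.S.n_nodes):
        update_tau_rubberband(state, j, tuning)


# ---------------------------------------------------------------------------
# gene-tree moves
# ---------------------------------------------------------------------------

def _gene_age_move(state, i: int, v: int, tuning: TuningState) -> None:
    S, G = state.S, state.gtrees[i]
    pop = int(G.pop[v])
    c0, c1 = (int(c) for c in G.children[v])
    lo = max(float(G.age[c0]), float(G.age[c1]), float(S.tau[pop]))
    up = math.inf
    if G.parent[v] >= 0:
        up = float(G.age[G.parent[v]])
    ppop = S.parent[pop]
    if ppop >= 0:
        up = min(up, float(S.tau[ppop]))
    t_old = float(G.age[v])
    if up < math.inf:
        t_new = lo + state.rng.random() * (up - lo)
    else:
        t_new = _reflect(t_old + tuning.steps["gene_age"]
                         * (state.rng.random() - 0.5), lo, math.inf)
    if t_new <= lo:
        tuning.record("gene_age", False)
        return
    G2 = G.copy()
    G2.age[v] = t_new
    k, A = coalescent_stats(G2, S)
    logr = msc_density_from_stats(k, A, S.theta) - state.msc_locus(i)
    lnl = state.lnL[i]
    if state.data is not None:
        lnl = state.locus_loglik(i, G2)
        logr += state.beta * (lnl - state.lnL[i])
    ok = _mh_accept(state, logr)
    if ok:
        state.commit_locus(i, G2, k, A, lnl)
    tuning.record("gene_age", ok)


def _gene_spr_move(state, i: int, tuning: TuningState) -> None:
    """Prune a random gene-tree branch and regraft at a new age.

    The pruned branch's parent node is re-inserted at an age proposed by a
    reflected sliding window; the regraft target is uniform among skeleton
    branches alive at that age in the population the pruned lineage then
    occupies.
    """
    S, G = state.S, state.gtrees[i]
    rng = state.rng
    v = int(rng.integers(0, G.n_nodes - 1))
    if v >= G.root:
        v += 1
    p = int(G.parent[v])
    w = G.sibling(v)
    g = int(G.parent[p])

    # subtree of v
    sub = set()
    stack = [v]
    while stack:
        u = stack.pop()
        sub.add(u)
        if not G.is_tip(u):
            stack.extend(int(c) for c in G.children[u])

    skel_parent = G.parent.copy()
    skel_children = G.children.copy()
    if g >= 0:
        skel_children[g, 0 if skel_children[g, 0] == p else 1] = w
        skel_parent[w] = g
        skel_root = G.root
    else:
        skel_parent[w] = -1
        skel_root = w

    # canonical pops on the skeleton (ancestors of p may drop to a smaller
    # population once clade v is detached)
    skel_pop = G.pop.copy()
    chain = []
    u = w if g < 0 else g
    uu = u
    while uu >= 0:
        chain.append(uu)
        uu = int(skel_parent[uu])
    from .trees_core import mrca as _mrca
    for u in chain:
        if G.is_tip(u):
            continue
        c0, c1 = (int(c) for c in skel_children[u])
        base = _mrca(S, int(skel_pop[c0]), int(skel_pop[c1]))
        skel_pop[u] = S.pop_at(base, float(G.age[u]))

    skel_nodes = [u for u in range(G.n_nodes) if u not in sub and u != p]

    def targets(t: float) -> list[int]:
        P = S.pop_at(int(G.pop[v]), t)
        out = []
        for u in skel_nodes:
            pu = int(skel_parent[u])
            if G.age[u] <= t and (pu < 0 or G.age[pu] > t):
                if S.pop_at(int(skel_pop[u]), t) == P:
                    out.append(u)
        return out

    t_old = float(G.age[p])
    lo = float(G.age[v])
    t_new = _reflect(t_old + tuning.steps["gene_spr"]
                     * (rng.random() - 0.5), lo, math.inf)
    fwd = targets(t_new)
    if not fwd:
        tuning.record("gene_spr", False)
        return
    rev = targets(t_old)
    assert w in rev, "current attachment must be a reverse target"
    u_star = fwd[int(rng.integers(len(fwd)))]

    # build proposed tree: insert p on skeleton branch u_star at t_new
    new_parent = skel_parent.copy()
    new_children = skel_children.copy()
    new_age = G.age.copy()
    gp = int(skel_parent[u_star])
    new_parent[p] = gp
    if gp >= 0:
        new_children[gp, 0 if new_children[gp, 0] == u_star else 1] = p
    new_parent[u_star] = p
    new_parent[v] = p
    new_children[p] = (v, u_star)
    new_age[p] = t_new

    G2 = GeneTree(G.labels, G.tip_species, new_parent, new_children, new_age,
                  locus=G.locus, root=-1)
    G2.recompute_pops(S)
    k, A = coalescent_stats(G2, S)
    logr = msc_density_from_stats(k, A, S.theta) - state.msc_locus(i)
    logr += math.log(len(fwd)) - math.log(len(rev))
    lnl = state.lnL[i]
    if state.data is not None:
        lnl = state.locus_loglik(i, G2)
        logr += state.beta * (lnl - state.lnL[i])
    ok = _mh_accept(state, logr)
    if ok:
        state.commit_locus(i, G2, k, A, lnl)
    tuning.record("gene_spr", ok)


def update_gene_tree(state, i: int, tuning: TuningState,
                     all_ages: bool = False) -> None:
    """Per-locus sub-moves: one coalescent-node age resample and one SPR.

    With ``all_ages`` every internal node's age is resampled instead of a
    single random one (useful for prior-only runs where the likelihood is
    free and faster gene-tree mixing is worth the extra proposals).
    """
    G = state.gtrees[i]
    if all_ages:
        for v in range(G.n_tips, G.n_nodes):
            _gene_age_move(state, i, v, tuning)
    else:
        v = int(state.rng.integers(G.n_tips, G.n_nodes))
        _gene_age_move(state, i, v, tuning)
    _gene_spr_move(state, i, tuning)


# ---------------------------------------------------------------------------
# mixing
# ---------------------------------------------------------------------------

def mixing_move(state, tuning: TuningState, scale_theta: bool = True) -> None:
    """Multiply all species and gene-tree ages (and thetas) by a common c."""
    S = state.S
    cfg = state.prior
    eps = tuning.steps["mixing"]
    c = math.exp(eps * (state.rng.random() - 0.5))
    n_sp = S.s - 1
    n_gene = sum(G.n_tips - 1 for G in state.gtrees)
    D = n_sp + n_gene + (S.n_nodes if scale_theta else 0)
    logr = D * math.log(c)

    tau_new = S.tau * c
    theta_new = S.theta * c if scale_theta else S.theta
    # parameter prior ratio
    logp_new = sum(gamma_logpdf(float(t), cfg.theta_a, cfg.theta_b)
                   for t in theta_new)
    logp_old = sum(gamma_logpdf(float(t), cfg.theta_a, cfg.theta_b)
                   for t in S.theta)
    tau0 = float(S.tau[S.root])
    logp_new += gamma_logpdf(tau0 * c, cfg.tau_a, cfg.tau_b)
    logp_old += gamma_logpdf(tau0, cfg.tau_a, cfg.tau_b)
    if S.s > 2:
        logp_new += -(S.s - 2) * math.log(tau0 * c)
        logp_old += -(S.s - 2) * math.log(tau0)
    logr += logp_new - logp_old

    # MSC: k log(2/theta') - c A / theta'; pops invariant under global scaling
    for i in range(state.n_loci):
        k, A = state.stats_k[i], state.stats_A[i]
        logr += msc_density_from_stats(k, c * A, theta_new) \
            - msc_density_from_stats(k, A, S.theta)

    prop_L = state.lnL
    if state.data is not None:
        prop_L = np.empty(state.n_loci)
        for i, G in enumerate(state.gtrees):
            G2 = G.copy()
            G2.age = G.age * c
            prop_L[i] = state.locus_loglik(i, G2)
        logr += state.beta * float(prop_L.sum() - state.lnL.sum())

    ok = _mh_accept(state, logr)
    if ok:
        S.tau[:] = tau_new
        if scale_theta:
            S.theta[:] = theta_new
        for i, G in enumerate(state.gtrees):
            G.age *= c
            state.stats_A[i] = state.stats_A[i] * c
        state.lnL = np.asarray(prop_L, dtype=float)
    tuning.record("mixing", ok)


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------

def sweep(state, tuning: TuningState, all_ages: bool = False) -> None:
    """One iteration: every theta, every tau, both gene-tree sub-moves at
    every locus, one mixing move.  ``all_ages`` requests a full pass over
    coalescent-node ages per locus (always done when the likelihood is 1,
    where it is free; useful for A00 parameter estimation)."""
    update_thetas(state, tuning)
    update_taus(state, tuning)
    all_ages = all_ages or state.data is None
    for i in range(state.n_loci):
        update_gene_tree(state, i, tuning, all_ages=all_ages)
    mixing_move(state, tuning)
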