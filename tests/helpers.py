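"""Shared test utilities: scripted transmodel round-trips and
autocorrelation-adjusted categorical goodness-of-fit."""

import numpy as np
from scipy import stats as sps

from msctree.spr_move import _all_a_mask, _build_skeleton
from msctree import spr_move


def nodeslider_attachments(state, A):
    """Original skeleton attachment of every moved node (nodeslider rule)."""
    S = state.S
    a_species = set(S.clade_tips(A))
    out = {}
    for i, G in enumerate(state.gtrees):
        sp = {int(s) for s in G.tip_species}
        if not (sp & a_species) or sp <= a_species:
            continue
        all_a = _all_a_mask(G, a_species)
        moved = [v for v in range(G.n_tips, G.n_nodes)
                 if all_a[G.children[v, 0]] != all_a[G.children[v, 1]]]
        if not moved:
            continue
        *_, s_child = _build_skeleton(G, moved, all_a)
        for v in moved:
            out[(i, v)] = s_child[v]
    return out


def spr_attachments(state, Y, Z, A):
    """Original skeleton attachment of every moved node (SPR rule)."""
    S = state.S
    a_species = set(S.clade_tips(A))
    out = {}
    for i, G in enumerate(state.gtrees):
        moved = spr_move.find_moved_nodes(G, S, Y, Z, A)
        if not moved:
            continue
        all_a = _all_a_mask(G, a_species)
        *_, s_child = _build_skeleton(G, moved, all_a)
        for v in moved:
            out[(i, v)] = s_child[v]
    return out


def snapshot(state):
    return (state.S.topology_key(), state.S.tau.copy(),
            [(G.parent.copy(), G.age.copy()) for G in state.gtrees])


def state_equals_snapshot(snap, state):
    key, tau, gs = snap
    if key != state.S.topology_key():
        return "species topology"
    if not np.allclose(tau, state.S.tau, rtol=1e-10, atol=0):
        return "species ages"
    for j, ((p, a), G) in enumerate(zip(gs, state.gtrees)):
        if not np.array_equal(p, G.parent):
            return f"gene tree {j} structure"
        if not np.allclose(a, G.age, rtol=1e-10):
            return f"gene tree {j} ages"
    return None


def adjusted_chi2_pvalue(series, expected_probs):
    """Categorical goodness-of-fit for a Markov-chain sample.

    The naive chi-square statistic is deflated by the mean variance
    inflation of the category indicators, estimated by batch means with 40
    batches, so the test remains calibrated under autocorrelation.
    """
    series = np.asarray(series)
    n = len(series)
    ncat = len(expected_probs)
    obs = np.array([(series == j).sum() for j in range(ncat)], dtype=float)
    exp = n * np.asarray(expected_probs)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    nb = 40
    b = n // nb
    inflations = []
    for j in range(ncat):
        ind = (series[:nb * b] == j).astype(float)
        p_hat = ind.mean()
        if p_hat in (0.0, 1.0):
            continue
        bm = ind.reshape(nb, b).mean(axis=1)
        var_bm = bm.var(ddof=1) / nb
        var_iid = p_hat * (1 - p_hat) / n
        inflations.append(var_bm / var_iid)
    factor = max(float(np.mean(inflations)), 1.0) if inflations else 1.0
    return 1.0 - sps.chi2.cdf(chi2 / factor, ncat - 1), factor
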