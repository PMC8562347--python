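"""Rooted-tree data structures for species trees and embedded gene trees.

The species tree is a rooted, binary, ultrametric tree over ``s`` species.
Node ages (``tau``) and per-population sizes (``theta``) are stored in
expected-substitutions-per-site units and node *ages*, not branch lengths,
are the primary representation: every MCMC proposal operates on ages, and
branch lengths are derived views (parent age minus child age).

Nodes carry stable integer IDs: tips are ``0 .. s-1``, internal nodes are
``s .. 2s-2``.  Topology proposals rewire parent/child links in place while
keeping IDs fixed, so gene-tree population labels (which reference species
node IDs) remain meaningful across moves.

Gene trees are embedded in the species tree: each coalescent node resides
in a population (a species-tree node) whose age interval contains the
node's age.  Because coalescent times are always strictly ordered along
each lineage, the population of a node is *uniquely determined* by its age
and by the populations of its children, so population labels are derived
data recomputed canonically rather than tracked through moves.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesTree",
    "GeneTree",
    "IndividualMap",
    "parse_newick",
    "write_newick",
    "mrca",
    "is_compatible",
    "count_labeled_histories",
]

#: relative tolerance for ultrametricity of input trees
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    pass


@dataclass
class SpeciesTree:
    """Rooted binary ultrametric species tree with node ages and thetas.

    Arrays are indexed by stable node ID; tips ``0..s-1`` carry labels,
    internal nodes ``s..2s-2`` carry ages ``tau > 0``.  ``theta`` is defined
    for every node (tip and ancestral populations alike).
    """

    labels: list[str]
    parent: np.ndarray          # int, -1 for root
    children: np.ndarray        # (2s-1, 2) int, -1 for tips
    tau: np.ndarray             # float ages; 0 for tips
    theta: np.ndarray | None = None
    root: int = -1

    def __post_init__(self) -> None:
        if self.root < 0:
            (r,) = np.flatnonzero(self.parent < 0)
            self.root = int(r)
        self.s = len(self.labels)
        self.n_nodes = 2 * self.s - 1

    # ---- basic structure -------------------------------------------------
    def is_tip(self, v: int) -> bool:
        return v < self.s

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(
            list(self.labels),
            self.parent.copy(),
            self.children.copy(),
            self.tau.copy(),
            None if self.theta is None else self.theta.copy(),
            self.root,
        )

    def internal_branches(self) -> list[int]:
        """IDs of internal, non-root nodes; the s-2 internal branches."""
        return [v for v in range(self.s, self.n_nodes)
                if v != self.root and self.parent[v] >= 0]

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        if p < 0:
            return math.inf
        return float(self.tau[p] - self.tau[v])

    def ancestors(self, v: int) -> list[int]:
        """Ancestors of v from parent up to the root (exclusive of v)."""
        out = []
        p = self.parent[v]
        while p >= 0:
            out.append(int(p))
            p = self.parent[p]
        return out

    def clade_tips(self, v: int) -> list[int]:
        """Tip IDs below (and including) node v."""
        stack, out = [v], []
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(u)
            else:
                stack.extend(int(c) for c in self.children[u])
        return out

    def clade_nodes(self, v: int) -> list[int]:
        """All node IDs in clade v (v included), preorder."""
        stack, out = [v], []
        while stack:
            u = stack.pop()
            out.append(u)
            if not self.is_tip(u):
                stack.extend(int(c) for c in self.children[u])
        return out

    def postorder(self) -> list[int]:
        """Postorder node IDs; cached (topology edits must precede queries)."""
        cached = getattr(self, "_postorder", None)
        if cached is not None:
            return cached
        order, stack = [], [self.root]
        while stack:
            u = stack.pop()
            order.append(u)
            if not self.is_tip(u):
                stack.extend(int(c) for c in self.children[u])
        order.reverse()
        self._postorder = order
        return order

    def sibling(self, v: int) -> int:
        p = self.parent[v]
        c0, c1 = self.children[p]
        return int(c1 if c0 == v else c0)

    def pop_at(self, v: int, t: float) -> int:
        """Population (node ID) on v's ancestral path whose interval covers t.

        The interval of node j is [tau_j, tau_parent(j)); the root interval
        is unbounded above.
        """
        u = v
        while self.parent[u] >= 0 and self.tau[self.parent[u]] <= t:
            u = int(self.parent[u])
        return u

    def validate(self) -> None:
        s = self.s
        assert np.count_nonzero(self.parent < 0) == 1
        for v in range(self.n_nodes):
            if self.is_tip(v):
                assert self.tau[v] == 0.0
            else:
                c0, c1 = self.children[v]
                assert self.parent[c0] == v and self.parent[c1] == v
                assert self.tau[v] > self.tau[c0] and self.tau[v] > self.tau[c1]
        assert len(self.internal_branches()) == s - 2

    # ---- identity --------------------------------------------------------
    def topology_key(self) -> str:
        """Canonical topology-only Newick used for hashing/counting."""
        return write_newick(self, lengths=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({write_newick(self)})"


@dataclass
class GeneTree:
    """Rooted coalescent gene tree for one locus, embedded in a species tree.

    ``tip_species[i]`` is the species-tree tip ID of sequence tip ``i``;
    ``pop`` holds the derived population label of every node and is kept in
    sync via :meth:`recompute_pops`.
    """

    labels: list[str]
    tip_species: np.ndarray     # (n_tips,) species-tree tip IDs
    parent: np.ndarray
    children: np.ndarray        # (2n-1, 2), -1 for tips
    age: np.ndarray             # t; 0 for tips
    pop: np.ndarray | None = None
    locus: int = 0
    root: int = -1

    def __post_init__(self) -> None:
        if self.root < 0:
            (r,) = np.flatnonzero(self.parent < 0)
            self.root = int(r)
        self.n_tips = len(self.labels)
        self.n_nodes = 2 * self.n_tips - 1

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def copy(self) -> "GeneTree":
        g = GeneTree(
            self.labels, self.tip_species, self.parent.copy(),
            self.children.copy(), self.age.copy(),
            None if self.pop is None else self.pop.copy(),
            self.locus, self.root,
        )
        # topology is identical: carry traversal caches across
        if getattr(self, "_postorder", None) is not None:
            g._postorder = self._postorder
        if getattr(self, "_postorder_arr", None) is not None:
            g._postorder_arr = self._postorder_arr
        return g

    def postorder(self) -> list[int]:
        """Postorder node IDs; cached (topology edits must precede queries)."""
        cached = getattr(self, "_postorder", None)
        if cached is not None:
            return cached
        order, stack = [], [self.root]
        while stack:
            u = stack.pop()
            order.append(u)
            if not self.is_tip(u):
                stack.extend(int(c) for c in self.children[u])
        order.reverse()
        self._postorder = order
        return order

    def sibling(self, v: int) -> int:
        p = self.parent[v]
        c0, c1 = self.children[p]
        return int(c1 if c0 == v else c0)

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        return math.inf if p < 0 else float(self.age[p] - self.age[v])

    def recompute_pops(self, S: SpeciesTree, strict: bool = True) -> bool:
        """Canonically (re)derive every node's population from its age.

        Returns True on success; False (with ``pop`` unset for the failing
        node left stale) if the embedding is infeasible and ``strict`` is
        False, otherwise raises.
        """
        if self.pop is None:
            self.pop = np.empty(self.n_nodes, dtype=np.int64)
        for v in self.postorder():
            if self.is_tip(v):
                self.pop[v] = self.tip_species[v]
                continue
            c0, c1 = (int(c) for c in self.children[v])
            base = mrca(S, int(self.pop[c0]), int(self.pop[c1]))
            t = float(self.age[v])
            if t < S.tau[base]:
                if strict:
                    raise TreeError(
                        f"gene-tree node {v} at age {t} predates species "
                        f"divergence tau={S.tau[base]}")
                return False
            self.pop[v] = S.pop_at(base, t)
        return True

    def validate(self, S: SpeciesTree) -> None:
        assert is_compatible(self, S)
        pops = self.pop.copy()
        self.recompute_pops(S)
        assert np.array_equal(pops, self.pop), "stale population labels"


@dataclass
class IndividualMap:
    """Mapping from sequence/individual labels to species labels."""

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "IndividualMap":
        m = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) != 2:
                    raise TreeError(f"bad Imap line: {line!r}")
                m[parts[0]] = parts[1]
        return cls(m)

    def species_of(self, label: str) -> str:
        """Resolve a sequence label; 'ind^species' labels resolve directly."""
        if label in self.mapping:
            return self.mapping[label]
        if "^" in label:
            return label.rsplit("^", 1)[1]
        raise TreeError(f"label {label!r} not in individual map")


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*([(),;]|:[^,();\[\]\s]+|[^,();:\[\]\s]+(?:\[[^\]]*\])?)")


def _tokenize(text: str) -> list[str]:
    pos, out = 0, []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if rest:
                raise TreeError(f"cannot tokenize Newick near {rest[:20]!r}")
            break
        out.append(m.group(1))
        pos = m.end()
    return out


def parse_newick(text: str, ages_from_branch_lengths: bool = True,
                 theta: float | None = None) -> SpeciesTree:
    """Parse a rooted binary Newick string into a :class:`SpeciesTree`.

    Node ages are recovered from root-to-tip distances; the tree must be
    ultrametric within relative tolerance ``ULTRAMETRIC_RTOL``.  BPP-style
    ``#theta`` / bracket annotations on labels are ignored.  With
    ``ages_from_branch_lengths=False`` (topology-only input) internal ages
    are assigned as a ladder so the tree is a valid starting point whose
    ages the caller will overwrite.

    Raises :class:`TreeError` on non-binary nodes or ultrametricity
    violations (reporting the offending tip pair).
    """
    tokens = _tokenize(text)
    if not tokens or tokens[-1] != ";":
        raise TreeError("Newick must end with ';'")
    # recursive-descent on the token list
    pos = 0

    children_of: list[list[int]] = []
    blen: list[float | None] = []
    label_of: list[str | None] = []

    def new_node() -> int:
        children_of.append([])
        blen.append(None)
        label_of.append(None)
        return len(children_of) - 1

    def parse_clade() -> int:
        nonlocal pos
        v = new_node()
        if tokens[pos] == "(":
            pos += 1
            while True:
                children_of[v].append(parse_clade())
                if tokens[pos] == ",":
                    pos += 1
                    continue
                if tokens[pos] == ")":
                    pos += 1
                    break
                raise TreeError("malformed Newick")
        # optional label / annotation
        if pos < len(tokens) and tokens[pos] not in "(),;" \
                and not tokens[pos].startswith(":"):
            lab = tokens[pos].split("[")[0].split("#")[0]
            label_of[v] = lab or None
            pos += 1
        if pos < len(tokens) and tokens[pos].startswith(":"):
            blen[v] = float(tokens[pos][1:].split("#")[0].split("[")[0])
            pos += 1
        return v

    top = parse_clade()
    if tokens[pos] != ";":
        raise TreeError("trailing content in Newick")

    for v, ch in enumerate(children_of):
        if len(ch) not in (0, 2):
            raise TreeError(f"non-binary node with {len(ch)} children")

    tips = [v for v in range(len(children_of)) if not children_of[v]]
    for v in tips:
        if label_of[v] is None:
            raise TreeError("unlabeled tip")
    s = len(tips)
    if s < 2:
        raise TreeError("need at least 2 species")

    # depth from root
    depth = {top: 0.0}
    order = [top]
    for v in order:
        for c in children_of[v]:
            depth[c] = depth[v] + (blen[c] if blen[c] is not None else 1.0)
            order.append(c)

    have_lengths = all(blen[v] is not None for v in range(len(blen)) if v != top)
    height = max(depth[v] for v in tips)
    if ages_from_branch_lengths and have_lengths:
        scale = max(height, 1e-300)
        for a in tips:
            for b in tips:
                if a < b and abs(depth[a] - depth[b]) > ULTRAMETRIC_RTOL * scale:
                    raise TreeError(
                        f"non-ultrametric input: tips {label_of[a]!r}/"
                        f"{label_of[b]!r} at depths {depth[a]}, {depth[b]}")
        age = {v: max(height - depth[v], 0.0) for v in depth}
        for v in tips:
            age[v] = 0.0
    else:
        # ladder ages by (max) levels above tips
        lvl: dict[int, int] = {}
        for v in reversed(order):
            lvl[v] = 0 if not children_of[v] else \
                1 + max(lvl[c] for c in children_of[v])
        age = {v: float(lvl[v]) for v in order}

    # map to stable IDs: tips 0..s-1 (input order), internals s..2s-2
    tip_id = {v: i for i, v in enumerate(tips)}
    internals = [v for v in order if children_of[v]]
    for i, v in enumerate(internals):
        tip_id[v] = s + i

    labels = [label_of[v] for v in tips]
    parent = np.full(2 * s - 1, -1, dtype=np.int64)
    children = np.full((2 * s - 1, 2), -1, dtype=np.int64)
    tau = np.zeros(2 * s - 1)
    for v in order:
        i = tip_id[v]
        tau[i] = age[v]
        for k, c in enumerate(children_of[v]):
            children[i, k] = tip_id[c]
            parent[tip_id[c]] = i
    tau[:s] = 0.0

    th = None
    if theta is not None:
        th = np.full(2 * s - 1, float(theta))
    tree = SpeciesTree(labels, parent, children, tau, th, tip_id[top])
    tree.validate()
    return tree


def write_newick(tree: SpeciesTree, lengths: bool = True,
                 fmt: str = "%.10g") -> str:
    """Canonical Newick: children ordered by smallest descendant tip label."""
    def fmt_len(v: int) -> str:
        if not lengths or tree.parent[v] < 0:
            return ""
        return ":" + (fmt % tree.branch_length(v))

    def rec(v: int) -> tuple[str, str]:
        # returns (newick, min tip label) for ordering
        if tree.is_tip(v):
            return tree.labels[v] + fmt_len(v), tree.labels[v]
        parts = sorted((rec(int(c)) for c in tree.children[v]),
                       key=lambda p: p[1])
        nwk = "(" + ",".join(p[0] for p in parts) + ")" + fmt_len(v)
        return nwk, parts[0][1]

    return rec(tree.root)[0] + ";"


def write_gene_newick(G: GeneTree, fmt: str = "%.10g") -> str:
    def rec(v: int) -> tuple[str, str]:
        p = G.parent[v]
        ln = "" if p < 0 else ":" + (fmt % (G.age[p] - G.age[v]))
        if G.is_tip(v):
            return G.labels[v] + ln, G.labels[v]
        parts = sorted((rec(int(c)) for c in G.children[v]), key=lambda x: x[1])
        return "(" + ",".join(x[0] for x in parts) + ")" + ln, parts[0][1]

    return rec(G.root)[0] + ";"


# ---------------------------------------------------------------------------
# relations
# ---------------------------------------------------------------------------

def mrca(S: SpeciesTree, a: int, b: int) -> int:
    """Most recent common ancestor of nodes a and b.

    Walks the younger node upward; valid because ages strictly increase
    along every ancestor path (ties between *different* lineages are fine:
    each step still moves one node strictly rootward).
    """
    tau = S.tau
    parent = S.parent
    while a != b:
        if tau[a] < tau[b]:
            a = int(parent[a])
        else:
            b = int(parent[b])
    return a


def is_compatible(G: GeneTree, S: SpeciesTree) -> bool:
    """True iff G's coalescent times are feasible under S.

    Checks, bottom-up, that every coalescence of lineages from two
    populations is no earlier than the populations' divergence: sequences
    split before species.
    """
    pop = np.empty(G.n_nodes, dtype=np.int64)
    for v in G.postorder():
        if G.is_tip(v):
            if G.age[v] != 0.0:
                return False
            pop[v] = G.tip_species[v]
            continue
        c0, c1 = (int(c) for c in G.children[v])
        if G.age[v] < G.age[c0] or G.age[v] < G.age[c1]:
            return False
        base = mrca(S, int(pop[c0]), int(pop[c1]))
        if G.age[v] < S.tau[base]:
            return False
        pop[v] = S.pop_at(base, float(G.age[v]))
    return True


def count_labeled_histories(S: SpeciesTree) -> int:
    """Number of orderings of internal-node ages consistent with the topology.

    h(T) = (s-1)! / prod_v c_v over internal nodes v, where c_v is the
    number of internal nodes in the clade of v.
    """
    n_int = np.zeros(S.n_nodes, dtype=np.int64)
    for v in S.postorder():
        if not S.is_tip(v):
            c0, c1 = S.children[v]
            n_int[v] = 1 + n_int[c0] + n_int[c1]
    denom = 1
    for v in range(S.s, S.n_nodes):
        denom *= int(n_int[v])
    return math.factorial(S.s - 1) // denom


def n_rooted_topologies(s: int) -> int:
    """(2s-3)!! rooted binary topologies on s labeled tips."""
    out = 1
    for k in range(3, 2 * s - 2, 2):
        out *= k
    return out


def random_topology_newick(labels: list[str], rng) -> str:
    """Uniform draw over the (2s-3)!! rooted binary topologies.

    The root split is sampled with probability proportional to the number of
    topologies it admits, then both sides recurse; this is exact, unlike
    sequential random joins (which are uniform over labeled histories).
    """
    labels = list(labels)

    def build(labs: list[str]) -> str:
        n = len(labs)
        if n == 1:
            return labs[0]
        if n == 2:
            return f"({labs[0]},{labs[1]})"
        weights = [math.comb(n - 1, k - 1) * n_rooted_topologies(max(k, 1))
                   * n_rooted_topologies(max(n - k, 1))
                   for k in range(1, n)]
        w = np.asarray(weights, dtype=float)
        k = 1 + int(rng.choice(n - 1, p=w / w.sum()))
        rest = labs[1:]
        idx = rng.choice(n - 1, size=k - 1, replace=False)
        left = [labs[0]] + [rest[i] for i in sorted(idx)]
        right = [rest[i] for i in range(n - 1) if i not in set(idx)]
        return f"({build(left)},{build(right)})"

    return build(labels) + ";"


def enumerate_topologies(labels: list[str]) -> list[str]:
    """Canonical topology keys of all rooted binary topologies (small s)."""
    labels = list(labels)

    def build(labs: tuple) -> list[str]:
        if len(labs) == 1:
            return [labs[0]]
        out = []
        rest = labs[1:]
        n = len(rest)
        for mask in range(2 ** n // 1):
            left = [labs[0]] + [rest[i] for i in range(n) if mask >> i & 1]
            right = [rest[i] for i in range(n) if not mask >> i & 1]
            if not right:
                continue
            for l in build(tuple(left)):
                for r in build(tuple(right)):
                    out.append(f"({l},{r})")
        return out

    keys = set()
    for nwk in build(tuple(labels)):
        keys.add(parse_newick(nwk + ";", ages_from_branch_lengths=False)
                 .topology_key())
    return sorted(keys)
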