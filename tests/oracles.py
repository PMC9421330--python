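"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, closed
forms, plain-Python arithmetic) and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from noxevo.trees import Node, Tree


# ---------------------------------------------------------------------------
# Tree enumeration and least-squares fitting (NJ oracle)


def enumerate_unrooted_topologies(taxa: list[str]) -> list[Tree]:
    """All unrooted binary topologies over the taxa (3 for n=4, 15 for n=5),
    built by inserting each taxon on every edge of every smaller tree."""
    def clone(n: Node) -> Node:
        m = Node(n.name)
        for c in n.children:
            m.add(clone(c))
        return m

    def edges(root: Node) -> list[Node]:
        out = []
        stack = list(root.children)
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    base = Node()
    for t in taxa[:3]:
        base.add(Node(t))
    trees = [base]
    for taxon in taxa[3:]:
        nxt = []
        for tr in trees:
            for k in range(len(edges(tr))):
                t2 = clone(tr)
                edge_child = edges(t2)[k]
                parent = edge_child.parent
                mid = Node()
                parent.children[parent.children.index(edge_child)] = mid
                mid.parent = parent
                mid.add(edge_child)
                mid.add(Node(taxon))
                nxt.append(t2)
        trees = nxt
    return [Tree(t, rooted=False) for t in trees]


def least_squares_sse(tree: Tree, ids: list[str], D: np.ndarray) -> float:
    """SSE of the ordinary least-squares branch-length fit of a topology."""
    nodes = [n for n in tree.postorder() if n.parent is not None]
    index = {id(n): k for k, n in enumerate(nodes)}
    leaves = {n.name: n for n in tree.leaves()}

    def path_edges(a: str, b: str) -> list[int]:
        pa, pb = [leaves[a]], [leaves[b]]
        while pa[-1].parent is not None:
            pa.append(pa[-1].parent)
        while pb[-1].parent is not None:
            pb.append(pb[-1].parent)
        sa = {id(x) for x in pa}
        lca = next(x for x in pb if id(x) in sa)
        out = []
        for x in pa:
            if x is lca:
                break
            out.append(index[id(x)])
        for x in pb:
            if x is lca:
                break
            out.append(index[id(x)])
        return out

    pairs = list(itertools.combinations(range(len(ids)), 2))
    A = np.zeros((len(pairs), len(nodes)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for e in path_edges(ids[i], ids[j]):
            A[r, e] = 1.0
        y[r] = D[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ x - y
    return float(resid @ resid)


def bipartition_set(tree: Tree) -> set[frozenset[str]]:
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out = set()
    for n in tree.postorder():
        if n.parent is None:
            continue
        below = frozenset(l.name for l in _leaves(n))
        side = below if ref not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def _leaves(n: Node) -> list[Node]:
    out, stack = [], [n]
    while stack:
        m = stack.pop()
        if m.is_leaf:
            out.append(m)
        else:
            stack.extend(m.children)
    return out


def additive_distances(tree: Tree, ids: list[str]) -> np.ndarray:
    d = tree.leaf_path_lengths()
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((ids[i], ids[j])))
            D[i, j] = D[j, i] = d[key]
    return D


# ---------------------------------------------------------------------------
# Transfer distance (TBE oracle)


def transfer_support_oracle(ref_tree: Tree, boot_trees: list[Tree]) -> dict[frozenset, float]:
    """TBE per non-trivial reference bipartition via exhaustive set
    arithmetic over every replicate branch (trivial branches included)."""
    all_leaves = frozenset(ref_tree.leaf_names())
    n = len(all_leaves)
    ref_bips = {}
    for node in ref_tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        below = frozenset(l.name for l in _leaves(node))
        p = min(len(below), n - len(below))
        if p >= 2:
            ref_bips[below] = p
    boot_sides = []
    for bt in boot_trees:
        sides = []
        for node in bt.postorder():
            if node.parent is None:
                continue
            sides.append(frozenset(l.name for l in _leaves(node)))
        boot_sides.append(sides)
    out = {}
    for below, p in ref_bips.items():
        total = 0.0
        for sides in boot_sides:
            dmin = min(
                min(len(below ^ s), n - len(below ^ s)) for s in sides
            )
            total += dmin
        out[below] = 1.0 - (total / len(boot_sides)) / (p - 1)
    return out


# ---------------------------------------------------------------------------
# Exhaustive Fitch parsimony


def fitch_score_oracle(tree: Tree, leaf_states: dict[str, int]) -> int:
    """Minimum number of state changes over all internal assignments of a
    binary character."""
    internal = [n for n in tree.postorder() if not n.is_leaf]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internal)):
        states = {id(n): s for n, s in zip(internal, assign)}
        for name, s in leaf_states.items():
            states[id(tree.find(name))] = s
        changes = 0
        for n in tree.postorder():
            if n.parent is not None:
                changes += states[id(n)] != states[id(n.parent)]
        if best is None or changes < best:
            best = changes
    return best


# ---------------------------------------------------------------------------
# Exhaustive marginal posteriors


def marginal_posterior_oracle(
    tree: Tree, leaf_site: dict[str, int | None], model, target: str
) -> np.ndarray:
    """Posterior over the 20 states at one internal node for a single site,
    by summing the joint density over every assignment of internal states,
    averaging over the gamma categories with equal weights.

    ``leaf_site`` maps leaf name to a state index or None (missing).
    """
    internal = [n for n in tree.postorder() if not n.is_leaf]
    pi = model.frequencies
    post = np.zeros(20)
    total = 0.0
    for rate in model.category_rates:
        P = {}
        for n in tree.postorder():
            if n.parent is not None:
                P[id(n)] = model.transition_matrix(n.length or 0.0, float(rate))
        for assign in itertools.product(range(20), repeat=len(internal)):
            states = {id(n): s for n, s in zip(internal, assign)}
            prob = pi[states[id(tree.root)]]
            ok = True
            for n in tree.postorder():
                if n.parent is None:
                    continue
                parent_state = states[id(n.parent)]
                if n.is_leaf:
                    obs = leaf_site[n.name]
                    if obs is None:
                        continue
                    prob *= P[id(n)][parent_state, obs]
                else:
                    prob *= P[id(n)][parent_state, states[id(n)]]
                if prob == 0.0:
                    ok = False
                    break
            if not ok:
                continue
            tstate = states[id(tree.find(target))]
            post[tstate] += prob
            total += prob
    return post / total
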