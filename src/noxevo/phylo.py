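"""Distance phylogenetics and LG+Gamma likelihood evaluation.

The tree stage of the pipeline is neighbor joining on p- or
Poisson-corrected distances, midpoint rooting, nonparametric bootstrap over
alignment columns, and branch supports as either classical Felsenstein
proportions or transfer bootstrap expectations (TBE). Likelihoods of fixed
trees are evaluated under an empirical amino-acid model (LG by default)
with discrete-gamma rate heterogeneity; maximum-likelihood topology search
is deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from ._lg_data import AA_ORDER, LG_EXCHANGEABILITIES_LOWER, LG_FREQUENCIES
from .sequences import Alignment, GAP
from .trees import Node, Tree, TreeError, _leaves_below

logger = logging.getLogger(__name__)

N_STATES = 20
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


class PhyloError(ValueError):
    """Raised on invalid phylogenetic input."""


# ---------------------------------------------------------------------------
# Distances


def distance_matrix(
    alignment: Alignment, method: str = "p-distance"
) -> tuple[list[str], np.ndarray]:
    """Pairwise distances over columns where both rows are non-gap.

    ``method`` is ``p-distance`` (mismatch fraction) or
    ``Poisson-corrected`` (-ln(1 - p)). A pair with zero comparable columns,
    or p >= 1 under the Poisson correction, raises :class:`PhyloError`.
    """
    if method not in ("p-distance", "Poisson-corrected"):
        raise PhyloError(f"unknown distance method {method!r}")
    ids = list(alignment.ids)
    n = len(ids)
    if n < 2:
        raise PhyloError("need at least 2 rows")
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in alignment.rows]
    gap = np.bytes_(GAP.encode())
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (rows[i] != gap) & (rows[j] != gap)
            m = int(ok.sum())
            if m == 0:
                raise PhyloError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((rows[i][ok] != rows[j][ok]).sum()) / m
            if method == "Poisson-corrected":
                if p >= 1.0:
                    raise PhyloError(
                        f"p-distance {p} >= 1 between {ids[i]!r} and "
                        f"{ids[j]!r}: Poisson correction undefined"
                    )
                p = -np.log1p(-p)
            D[i, j] = D[j, i] = p
    return ids, D


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(ids: list[str], D: np.ndarray) -> Tree:
    """Saitou-Nei neighbor joining with Studier-Keppler updates.

    Ties in the Q criterion are broken by the lexicographically smallest
    taxon pair (clusters are keyed by their smallest member leaf). Negative
    branch lengths are clamped to zero and the deficit logged. Returns an
    unrooted tree (trifurcating root).
    """
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise PhyloError("distance matrix shape does not match ids")
    if not np.allclose(D, D.T, atol=1e-12):
        raise PhyloError("distance matrix is not symmetric")
    if n < 3:
        raise PhyloError("need at least 3 taxa")

    def clamp(v: float, a: str, b: str) -> float:
        if v < 0:
            logger.info("NJ: clamped negative branch %.6g on (%s,%s)", v, a, b)
            return 0.0
        return v

    nodes = [Node(name=i) for i in ids]
    reps = list(ids)  # smallest leaf name of each cluster, for tie-breaks
    Dw = D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = Dw[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((reps[active[a]], reps[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(li, reps[i], reps[j])
        lj = clamp(lj, reps[j], reps[i])
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        # Studier-Keppler distance update; reuse slot i for the new cluster
        newd = 0.5 * (Dw[i, :] + Dw[j, :] - dij)
        Dw[i, :] = newd
        Dw[:, i] = newd
        Dw[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)
    # resolve the final three clusters around a trifurcating root
    i, j, k = active
    dij, dik, djk = Dw[i, j], Dw[i, k], Dw[j, k]
    root = Node()
    for idx, l in (
        (i, 0.5 * (dij + dik - djk)),
        (j, 0.5 * (dij + djk - dik)),
        (k, 0.5 * (dik + djk - dij)),
    ):
        nodes[idx].length = clamp(l, reps[idx], "root")
        root.add(nodes[idx])
    return Tree(root, rooted=False)


# ---------------------------------------------------------------------------
# Rooting


def _reroot_on_edge(tree: Tree, child: Node, dist_below: float) -> Tree:
    """Place a new root on the edge above ``child``, ``dist_below`` away
    from the child's end of the edge.  Returns a new rooted tree."""
    tree = tree.copy()
    # relocate `child` in the copy by path-from-root coordinates
    def path(n: Node) -> list[int]:
        out = []
        while n.parent is not None:
            out.append(n.parent.children.index(n))
            n = n.parent
        return out[::-1]

    p = path(child)
    child = tree.root
    for idx in p:
        child = child.children[idx]
    u = child.parent
    if u is None:
        raise TreeError("cannot reroot above the root")
    L = child.length or 0.0
    if not (-1e-9 <= dist_below <= L + 1e-9):
        raise TreeError("split point outside edge")
    dist_below = min(max(dist_below, 0.0), L)
    new_root = Node()
    u.children.remove(child)
    new_root.add(child)
    child.length = dist_below
    # flip the path from u back to the old root
    prev, prev_len, prev_sup = new_root, L - dist_below, child.support
    cur = u
    while cur is not None:
        nxt = cur.parent
        cur_len, cur_sup = cur.length, cur.support
        if nxt is not None:
            nxt.children.remove(cur)
        prev.add(cur)
        cur.length = prev_len
        cur.support = prev_sup
        prev, prev_len, prev_sup = cur, cur_len, cur_sup
        cur = nxt
    # suppress a unifurcation left at the old root position
    for n in list(new_root.children):
        _suppress_unifurcations(n)
    return Tree(new_root, rooted=True)


def _suppress_unifurcations(n: Node) -> None:
    for c in list(n.children):
        _suppress_unifurcations(c)
    if len(n.children) == 1 and n.parent is not None:
        (c,) = n.children
        c.length = (c.length or 0.0) + (n.length or 0.0)
        if c.support is None:
            c.support = n.support
        p = n.parent
        idx = p.children.index(n)
        p.children[idx] = c
        c.parent = p


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties on the diameter are broken by the lexicographically smallest leaf
    pair. Pairwise leaf path lengths are preserved. All-zero branch lengths
    raise :class:`PhyloError`.
    """
    dists = tree.leaf_path_lengths()
    if not dists:
        raise PhyloError("tree has fewer than 2 leaves")
    diameter = max(dists.values())
    if diameter <= 0:
        raise PhyloError("all branch lengths are zero; midpoint undefined")
    pair = min(k for k, v in dists.items() if v >= diameter - 1e-12)
    a_name, b_name = pair
    a, b = tree.find(a_name), tree.find(b_name)

    def to_root(n: Node) -> list[Node]:
        out = [n]
        while out[-1].parent is not None:
            out.append(out[-1].parent)
        return out

    pa, pb = to_root(a), to_root(b)
    sa, sb = set(id(x) for x in pa), set(id(x) for x in pb)
    lca = next(x for x in pa if id(x) in sb)
    a_edges = [n for n in pa[:pa.index(lca)]]          # child nodes, a -> lca
    b_edges = [n for n in pb[:pb.index(lca)]][::-1]    # child nodes, lca -> b
    half = diameter / 2.0
    cum = 0.0
    for n in a_edges:
        L = n.length or 0.0
        if cum + L >= half - 1e-12:
            return _reroot_on_edge(tree, n, half - cum)
        cum += L
    for n in b_edges:
        L = n.length or 0.0
        if cum + L >= half - 1e-12:
            return _reroot_on_edge(tree, n, L - (half - cum))
        cum += L
    raise PhyloError("midpoint not found on diameter path")  # pragma: no cover


def outgroup_root(tree: Tree, outgroup: list[str]) -> Tree:
    """Root on the edge above the smallest clade containing the outgroup
    leaves, at its midpoint."""
    node = tree.mrca(outgroup)
    if node.parent is None:
        raise PhyloError("outgroup spans the whole tree; cannot root")
    return _reroot_on_edge(tree, node, (node.length or 0.0) / 2.0)


# ---------------------------------------------------------------------------
# Bootstrap and branch support


def bootstrap_alignments(
    alignment: Alignment, n: int, seed: int
) -> list[Alignment]:
    """Draw ``n`` column-resampled replicates (with replacement, original
    length), reproducible from ``seed``."""
    if n < 1:
        raise PhyloError("need at least one replicate")
    rng = np.random.default_rng(seed)
    L = alignment.length
    out = []
    for _ in range(n):
        cols = rng.integers(0, L, size=L)
        rows = ["".join(row[j] for j in cols) for row in alignment.rows]
        out.append(Alignment(ids=list(alignment.ids), rows=rows,
                             descriptions=list(alignment.descriptions)))
    return out


def _leaf_bits(names: list[str]) -> dict[str, int]:
    return {nm: 1 << i for i, nm in enumerate(sorted(names))}


def _edge_bitsets(tree: Tree, bits: dict[str, int]) -> list[int]:
    """Bitset of the leaf set below every non-root node."""
    out = []
    masks: dict[int, int] = {}
    for n in tree.postorder():
        if n.is_leaf:
            masks[id(n)] = bits[n.name]
        else:
            m = 0
            for c in n.children:
                m |= masks[id(c)]
            masks[id(n)] = m
        if n.parent is not None:
            out.append(masks[id(n)])
    return out


def _annotate_support(
    ref_tree: Tree, boot_trees: list[Tree], method: str
) -> Tree:
    names = ref_tree.leaf_names()
    nset = set(names)
    for bt in boot_trees:
        if set(bt.leaf_names()) != nset:
            raise PhyloError("bootstrap tree leaf set differs from reference")
    n = len(names)
    bits = _leaf_bits(names)
    full = (1 << n) - 1
    boot_sets = [_edge_bitsets(bt, bits) for bt in boot_trees]
    out = ref_tree.copy()
    # canonical keys of replicate bipartitions for the Felsenstein count
    if method == "felsenstein":
        canon = []
        for es in boot_sets:
            canon.append({min(e, full ^ e) for e in es})
    for node in out.postorder():
        if node.is_leaf or node.parent is None:
            continue
        below = 0
        for l in _leaves_below(node):
            below |= bits[l.name]
        p = min(bin(below).count("1"), n - bin(below).count("1"))
        if p < 2:
            continue
        if method == "felsenstein":
            key = min(below, full ^ below)
            node.support = sum(1 for cs in canon if key in cs) / len(boot_sets)
        else:  # TBE
            total = 0.0
            for es in boot_sets:
                dmin = p - 1  # attained by trivial splits
                for e in es:
                    d1 = bin(below ^ e).count("1")
                    d = min(d1, n - d1)
                    if d < dmin:
                        dmin = d
                        if d == 0:
                            break
                total += dmin
            node.support = 1.0 - (total / len(boot_sets)) / (p - 1)
    return out


def tbe_support(ref_tree: Tree, boot_trees: list[Tree]) -> Tree:
    """Transfer bootstrap expectation supports on internal branches.

    For a reference bipartition b with smaller side of size p, the support
    is 1 - mean over replicates of (minimum transfer distance of b to any
    replicate branch) / (p - 1); the transfer distance is the Hamming
    distance between leaf-membership indicators, taken up to complement.
    """
    return _annotate_support(ref_tree, boot_trees, "tbe")


def felsenstein_support(ref_tree: Tree, boot_trees: list[Tree]) -> Tree:
    """Classical bootstrap proportions: the fraction of replicate trees
    containing each reference bipartition exactly."""
    return _annotate_support(ref_tree, boot_trees, "felsenstein")


# ---------------------------------------------------------------------------
# Substitution model


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability categories of Gamma(alpha, alpha).

    The category rate is the conditional mean of the distribution within
    each quantile band; the rates average exactly 1.
    """
    if alpha <= 0:
        raise PhyloError("gamma shape alpha must be positive")
    if k < 1:
        raise PhyloError("need at least one category")
    if k == 1:
        return np.array([1.0])
    edges = _gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    # E[X; X in band] for Gamma(a, rate a) uses the CDF of Gamma(a+1, rate a)
    cdf1 = _gamma_dist.cdf(edges, alpha + 1.0, scale=1.0 / alpha)
    rates = k * np.diff(cdf1)
    return rates / rates.mean()


class SubstitutionModel:
    """A reversible amino-acid substitution model with optional +Gamma rates.

    Parameters
    ----------
    name:
        ``"LG"`` (empirical exchangeabilities) or ``"Poisson"`` (equal
        exchangeabilities, uniform frequencies unless overridden).
    frequencies:
        Optional equilibrium frequencies in :data:`AA_ORDER` order
        (empirical "+F" style); defaults to the model's own.
    alpha:
        Gamma shape for among-site rate variation; None disables it.
    k:
        Number of discrete gamma categories (default 4).

    The rate matrix is normalised to one expected substitution per unit
    branch length at the stationary distribution.
    """

    def __init__(
        self,
        name: str = "LG",
        frequencies: np.ndarray | None = None,
        alpha: float | None = None,
        k: int = 4,
    ) -> None:
        if name not in ("LG", "Poisson"):
            raise PhyloError(f"unknown model {name!r}")
        self.name = name
        R = np.zeros((N_STATES, N_STATES))
        if name == "LG":
            # lower triangle in column-major ("dist") order
            it = iter(LG_EXCHANGEABILITIES_LOWER)
            for j in range(N_STATES - 1):
                for i in range(j + 1, N_STATES):
                    R[i, j] = R[j, i] = next(it)
            pi = np.array(LG_FREQUENCIES)
        else:
            R[:] = 1.0
            np.fill_diagonal(R, 0.0)
            pi = np.full(N_STATES, 1.0 / N_STATES)
        if frequencies is not None:
            pi = np.asarray(frequencies, dtype=float)
            if pi.shape != (N_STATES,) or not np.isclose(pi.sum(), 1.0):
                raise PhyloError("frequencies must be 20 values summing to 1")
        self.frequencies = pi / pi.sum()
        Q = R * self.frequencies[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(self.frequencies, np.diag(Q)))
        Q /= mu
        self.rate_matrix = Q
        self.alpha = alpha
        self.k = int(k)
        # symmetric eigendecomposition: B = P^{1/2} Q P^{-1/2}
        sq = np.sqrt(self.frequencies)
        B = (sq[:, None] * Q) / sq[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = w
        self._left = V.T * sq[None, :]        # V^T P^{1/2}
        self._right = V / sq[:, None]         # P^{-1/2} V

    @property
    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.array([1.0])
        return discretize_gamma(self.alpha, self.k)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * rate * t); rows sum to 1."""
        if t < 0:
            raise PhyloError("branch length must be non-negative")
        P = (self._right * np.exp(self._eigval * t * rate)) @ self._left
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Likelihood


def encode_alignment(alignment: Alignment) -> dict[str, np.ndarray]:
    """Per-row (n_sites, 20) leaf partial vectors; gaps and X give ones."""
    out: dict[str, np.ndarray] = {}
    for rid, row in zip(alignment.ids, alignment.rows):
        M = np.zeros((len(row), N_STATES))
        for s, c in enumerate(row):
            if c == GAP or c == "X":
                M[s, :] = 1.0
            else:
                idx = AA_INDEX.get(c)
                if idx is None:
                    raise PhyloError(f"residue {c!r} outside the model alphabet")
                M[s, idx] = 1.0
        out[rid] = M
    return out


def _conditionals(
    tree: Tree,
    leaf_partials: dict[str, np.ndarray],
    model: SubstitutionModel,
    rate: float,
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Felsenstein pruning at one rate: per-node conditional likelihoods and
    per-edge transition matrices (keyed by id(node))."""
    cond: dict[int, np.ndarray] = {}
    pmats: dict[int, np.ndarray] = {}
    for n in tree.postorder():
        if n.parent is not None:
            pmats[id(n)] = model.transition_matrix(n.length or 0.0, rate)
        if n.is_leaf:
            cond[id(n)] = leaf_partials[n.name]
        else:
            acc = None
            for c in n.children:
                msg = cond[id(c)] @ pmats[id(c)].T
                acc = msg if acc is None else acc * msg
            cond[id(n)] = acc
    return cond, pmats


def log_likelihood(
    tree: Tree, alignment: Alignment, model: SubstitutionModel
) -> tuple[float, np.ndarray]:
    """Total and per-site log-likelihood of a fixed tree.

    Per-site likelihoods are averaged over the discrete gamma categories
    with equal weights; gaps are missing data.
    """
    if set(tree.leaf_names()) != set(alignment.ids):
        raise PhyloError("tree leaves do not match alignment ids")
    leaf_partials = encode_alignment(alignment)
    n_sites = alignment.length
    site_lik = np.zeros(n_sites)
    rates = model.category_rates
    for r in rates:
        cond, _ = _conditionals(tree, leaf_partials, model, float(r))
        site_lik += cond[id(tree.root)] @ model.frequencies
    site_lik /= len(rates)
    if np.any(site_lik <= 0):
        raise PhyloError("zero site likelihood (underflow or impossible data)")
    logs = np.log(site_lik)
    return float(logs.sum()), logs
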