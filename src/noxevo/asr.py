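"""Marginal ancestral sequence reconstruction and Fitch gap parsimony.

Ancestral residues at internal nodes are inferred site by site as marginal
posterior distributions under a reversible amino-acid model with
discrete-gamma rates (categories marginalised with equal prior weights).
Ancestor *lengths* are decided separately: each alignment column is treated
as a binary presence/absence character and reconstructed with Fitch
parsimony, and the composed ancestor emits the maximum-a-posteriori residue
only at columns reconstructed as present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import (
    AA_ORDER,
    SubstitutionModel,
    _conditionals,
    encode_alignment,
)
from .sequences import Alignment, GAP, ProteinRecord
from .trees import Tree


class ASRError(ValueError):
    """Raised on invalid reconstruction input."""


@dataclass
class AncestralReconstruction:
    """Per-site posterior residue distributions at one internal node."""

    node_id: str
    posterior: np.ndarray  # (n_sites, 20), rows sum to 1
    map_sequence: str      # argmax residue per column (over all columns)
    mean_posterior: float  # average posterior of the argmax residues

    def __post_init__(self) -> None:
        if not np.allclose(self.posterior.sum(axis=1), 1.0, atol=1e-9):
            raise ASRError("posteriors must sum to 1 per site")


def marginal_asr(
    tree: Tree,
    alignment: Alignment,
    model: SubstitutionModel,
    node_ids: list[str] | None = None,
    *,
    category_weighting: str = "marginal",
) -> dict[str, AncestralReconstruction]:
    """Marginal posteriors of ancestral states at internal nodes.

    The tree must be rooted with leaves matching the alignment rows; gaps
    are missing data. Unlabelled internal nodes are labelled in place
    (N1, N2, ... in preorder). ``node_ids`` restricts the output (default:
    all internal nodes); requesting a leaf raises :class:`ASRError`.

    ``category_weighting="marginal"`` (default) sums the joint density over
    gamma categories in numerator and denominator; ``"map_category"``
    instead conditions each site on its single highest-evidence category.
    """
    if not tree.rooted:
        raise ASRError("marginal reconstruction requires a rooted tree")
    if set(tree.leaf_names()) != set(alignment.ids):
        raise ASRError("tree leaves do not match alignment ids")
    if category_weighting not in ("marginal", "map_category"):
        raise ASRError(f"unknown category weighting {category_weighting!r}")
    tree.label_internal()
    internal = {n.name: n for n in tree.internal_nodes()}
    if node_ids is None:
        node_ids = list(internal)
    for nid in node_ids:
        if nid not in internal:
            raise ASRError(f"node {nid!r} is not an internal node of the tree")

    leaf_partials = encode_alignment(alignment)
    n_sites = alignment.length
    rates = model.category_rates
    pi = model.frequencies
    # joint[node][cat] = cond * up ; summing over states gives the per-site
    # likelihood of that category, identical at every node.
    joint: dict[str, np.ndarray] = {
        nid: np.zeros((len(rates), n_sites, 20)) for nid in node_ids
    }
    site_lik = np.zeros((len(rates), n_sites))
    for ci, r in enumerate(rates):
        cond, pmats = _conditionals(tree, leaf_partials, model, float(r))
        # messages child -> parent, reused for sibling products
        msg = {
            id(n): cond[id(n)] @ pmats[id(n)].T
            for n in tree.postorder() if n.parent is not None
        }
        up: dict[int, np.ndarray] = {
            id(tree.root): np.broadcast_to(pi, (n_sites, 20)).copy()
        }
        for n in tree.preorder():
            for c in n.children:
                if c.is_leaf:
                    continue
                M = up[id(n)].copy()
                for s in n.children:
                    if s is not c:
                        M *= msg[id(s)]
                up[id(c)] = M @ pmats[id(c)]
        site_lik[ci] = cond[id(tree.root)] @ pi
        for nid in node_ids:
            nd = internal[nid]
            joint[nid][ci] = cond[id(nd)] * up[id(nd)]

    out: dict[str, AncestralReconstruction] = {}
    if category_weighting == "map_category":
        best = site_lik.argmax(axis=0)
    for nid in node_ids:
        if category_weighting == "marginal":
            num = joint[nid].sum(axis=0)
            den = site_lik.sum(axis=0)
        else:
            num = joint[nid][best, np.arange(n_sites), :]
            den = site_lik[best, np.arange(n_sites)]
        post = num / den[:, None]
        post /= post.sum(axis=1, keepdims=True)
        amax = post.argmax(axis=1)
        out[nid] = AncestralReconstruction(
            node_id=nid,
            posterior=post,
            map_sequence="".join(AA_ORDER[i] for i in amax),
            mean_posterior=float(post[np.arange(n_sites), amax].mean()),
        )
    return out


# ---------------------------------------------------------------------------
# Fitch parsimony on residue presence/absence

PRESENT, ABSENT, BOTH = 1, 2, 3


def gap_character_matrix(alignment: Alignment) -> dict[str, np.ndarray]:
    """Binary presence (True = residue, False = gap) per leaf per column."""
    return {
        rid: np.frombuffer(row.encode(), dtype="S1") != GAP.encode()
        for rid, row in zip(alignment.ids, alignment.rows)
    }


@dataclass
class FitchStates:
    """Fitch presence/absence reconstruction over all nodes and columns."""

    node_ids: list[str]
    presence: np.ndarray        # (n_nodes, n_cols) bool
    column_score: np.ndarray    # (n_cols,) int, number of union events
    all_absent: np.ndarray      # (n_cols,) bool flag

    @property
    def score(self) -> int:
        return int(self.column_score.sum())

    def node_presence(self, node_id: str) -> np.ndarray:
        return self.presence[self.node_ids.index(node_id)]


def fitch_gap_states(tree: Tree, gap_matrix: dict[str, np.ndarray]) -> FitchStates:
    """Fitch parsimony on the two-state presence/absence character.

    Bottom-up set intersection/union followed by a top-down refinement;
    ambiguity at the root (and unresolvable ambiguity below it) is resolved
    toward "present", so inferred ancestors err toward retaining domains.
    The parsimony score of a column is its number of union events. The tree
    must be rooted and binary.
    """
    if not tree.rooted:
        raise ASRError("Fitch reconstruction requires a rooted tree")
    for n in tree.internal_nodes():
        if len(n.children) != 2:
            raise ASRError("Fitch reconstruction requires a binary tree")
    leaves = set(tree.leaf_names())
    if leaves != set(gap_matrix):
        raise ASRError("gap matrix rows do not match tree leaves")
    n_cols = len(next(iter(gap_matrix.values())))
    tree.label_internal()
    nodes = list(tree.postorder())
    sets: dict[int, np.ndarray] = {}
    score = np.zeros(n_cols, dtype=int)
    for n in nodes:
        if n.is_leaf:
            sets[id(n)] = np.where(gap_matrix[n.name], PRESENT, ABSENT)
        else:
            a, b = (sets[id(c)] for c in n.children)
            inter = a & b
            union = a | b
            empty = inter == 0
            score += empty.astype(int)
            sets[id(n)] = np.where(empty, union, inter)
    # top-down refinement
    final: dict[int, np.ndarray] = {}
    root_set = sets[id(tree.root)]
    final[id(tree.root)] = np.where(root_set == ABSENT, ABSENT, PRESENT)
    for n in tree.preorder():
        if n is tree.root:
            continue
        s = sets[id(n)]
        parent = final[id(n.parent)]
        keep = (s & parent) != 0
        # tie rule: when the parent state is not in the node's set, an
        # ambiguous set resolves toward "present"
        own = np.where(s == ABSENT, ABSENT, np.where(s == PRESENT, PRESENT, PRESENT))
        final[id(n)] = np.where(keep, parent, own)
    node_ids = [n.name for n in nodes]
    presence = np.vstack([final[id(n)] == PRESENT for n in nodes])
    all_absent = ~presence[[i for i, n in enumerate(nodes) if n.is_leaf]].any(axis=0)
    return FitchStates(
        node_ids=node_ids, presence=presence,
        column_score=score, all_absent=all_absent,
    )


# ---------------------------------------------------------------------------
# Ancestor composition


@dataclass
class ComposedAncestor:
    """An inferred ancestral sequence with its per-site confidence track."""

    record: ProteinRecord
    confidence: list[float]     # posterior of each emitted residue
    columns: list[int]          # 0-based alignment column of each residue


def compose_ancestor(
    reconstruction: AncestralReconstruction,
    gap_states: FitchStates,
    node_id: str,
) -> ComposedAncestor:
    """Emit the MAP residue at every column Fitch-present at ``node_id``.

    Fitch-absent columns are skipped, so the ancestor's length equals the
    number of present columns.
    """
    if reconstruction.node_id != node_id:
        raise ASRError("reconstruction does not cover the requested node")
    present = gap_states.node_presence(node_id)
    if len(present) != len(reconstruction.map_sequence):
        raise ASRError("reconstruction and gap states differ in column count")
    cols = [j for j, p in enumerate(present) if p]
    seq = "".join(reconstruction.map_sequence[j] for j in cols)
    conf = [float(reconstruction.posterior[j].max()) for j in cols]
    return ComposedAncestor(
        record=ProteinRecord(id=node_id, seq=seq,
                             description="inferred ancestral sequence"),
        confidence=conf,
        columns=cols,
    )
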