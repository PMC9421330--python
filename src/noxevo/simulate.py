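"""Synthetic NOX families with planted ground truth.

The generator emits protein families that carry the architectural signal the
annotation pipeline looks for — six hydrophobic transmembrane stretches with
heme histidines, diagnostic motifs, 0-4 EF-hands of canonical or
calpain-like geometry, an optional N-terminal extension standing in for the
DUOX peroxidase-like domain, and an E-loop cysteine insertion — and evolves
them along a tree under a reversible amino-acid model with gamma site rates.
Motif anchor spans are "frozen": they evolve at a small fraction of the
site rate so fingerprints stay detectable while still carrying signal.

Indels are modelled as clade-wise span deletions (gaps at and below a
branch) and insertions (residues only at and below a branch), which is the
structure needed to exercise Fitch presence/absence reconstruction and
ancestor-length logic; there is no stochastic indel process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .phylo import AA_INDEX, AA_ORDER, SubstitutionModel
from .sequences import Alignment, GAP, ProteinRecord, write_alignment, write_fasta
from .trees import Node, Tree

# residue pools; the linker pool is hydrophilic and deliberately avoids the
# EF-hand anchor residues (D/E/N/S), glycine and cysteine so that planted
# motifs are the only motifs present at the root
LINKER_POOL = "TQPKRH"
HELIX_POOL = "LKQM"  # helix formers, avoiding the EF-hand anchor residues A/E
TM_POOL = "LIVF"  # strongly hydrophobic so planted helices survive the
# histidine hydropathy penalty and moderate divergence
TAIL_POOL = "ADEGKLNQRSTV"

#: loop templates; each position lists its allowed residues
CANONICAL_LOOP_CHOICES = ["D", "KQA", "DN", "AK", "DS", "G", "TY", "IL", "ST", "AF", "AK", "E"]
CALPAIN_LOOP_CHOICES = ["AV", "K", "WF", "DE", "V", "S", "S", "TN", "IL", "N", "E"]

CYS_INSERT = "NPCSGQTCAT"

CONSERVATION_FACTOR = 0.05


class SimulationError(ValueError):
    """Raised on invalid simulation configuration."""


@dataclass(frozen=True)
class ArchitecturePreset:
    """A NOX subtype architecture: which optional modules are present."""

    name: str
    ef_kinds: tuple[str, ...]          # per EF-hand: "canonical" | "calpain-like"
    nterm_extension: bool = False
    eloop_cys: bool = False
    expected_label: str = ""


PRESETS: dict[str, ArchitecturePreset] = {
    "nox5": ArchitecturePreset(
        "nox5", ("calpain-like", "canonical", "canonical", "canonical"),
        expected_label="NOX5-like"),
    "duox": ArchitecturePreset(
        "duox", ("canonical", "canonical"), nterm_extension=True,
        expected_label="DUOX-like"),
    "rboh": ArchitecturePreset(
        "rboh", ("canonical", "canonical"), expected_label="RBOH-like"),
    "noxc": ArchitecturePreset(
        "noxc", ("canonical",), expected_label="NOXC-like"),
    "ca_independent": ArchitecturePreset(
        "ca_independent", (), eloop_cys=True,
        expected_label="calcium-independent-like"),
    "unclassified": ArchitecturePreset(
        "unclassified", (), expected_label="unclassified-NOX-like"),
    # internal superset used as the evolving master sequence of a family:
    # every optional module present; clade presets are realised by indels
    "master": ArchitecturePreset(
        "master", ("calpain-like", "canonical", "canonical", "canonical"),
        nterm_extension=True, eloop_cys=True, expected_label="NOX5-like"),
}


@dataclass
class GroundTruth:
    """Planted feature coordinates of a generated root sequence.

    User-facing positions are 1-based inclusive; ``segments`` and
    ``frozen_spans`` are 0-based half-open (internal convention).
    """

    tm_spans: list[tuple[int, int]] = field(default_factory=list)
    heme_his: list[int] = field(default_factory=list)
    nonheme_his_h3: int | None = None
    tsg: tuple[int, int] | None = None
    vxgpfyg: tuple[int, int] | None = None
    eloop_cys: list[int] = field(default_factory=list)
    ef_hands: list[tuple[str, int, int]] = field(default_factory=list)  # (kind, loop_start, loop_len)
    extension_span: tuple[int, int] | None = None
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)
    frozen_spans: list[tuple[int, int]] = field(default_factory=list)
    anchor_positions: list[int] = field(default_factory=list)


def _sample(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(pool[i] for i in rng.integers(0, len(pool), size=n))


def build_root_sequence(
    preset: str | ArchitecturePreset, seed: int
) -> tuple[ProteinRecord, GroundTruth]:
    """Build one root sequence realising an architecture preset.

    The sequence concatenates an N-terminal region (optional extension,
    EF-hand helix-loop-helix units with hydrophilic linkers), six 21-residue
    hydrophobic TM stretches with planted histidines (heme pairs on helices
    III and V plus the non-coordinating helix-III histidine), intracellular
    and extracellular loops carrying the (T/S)G motif and, when the preset
    asks for it, the E-loop cysteine insertion, and a dehydrogenase tail
    with the (V/I/L)xGP(F/Y)G motif. Ground truth records every planted
    feature span and the frozen (conservation) spans.
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise SimulationError(f"unknown preset {preset!r}") from None
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    parts: list[str] = []
    pos = 0

    def add(seq: str, *, frozen: bool = False, segment: str | None = None,
            anchors: tuple[int, ...] = ()) -> int:
        nonlocal pos
        start = pos
        parts.append(seq)
        pos += len(seq)
        if frozen and seq:
            truth.frozen_spans.append((start, pos))
        truth.anchor_positions.extend(start + a for a in anchors)
        if segment:
            truth.segments[segment] = (start, pos)
        return start

    add(_sample(rng, LINKER_POOL, 5))
    if preset.nterm_extension:
        s = add(_sample(rng, LINKER_POOL, 280), segment="extension")
        truth.extension_span = (s + 1, pos)
    ef_start = pos
    for k, kind in enumerate(preset.ef_kinds, start=1):
        seg_start = pos
        add(_sample(rng, HELIX_POOL, 8), frozen=True)
        choices = (CANONICAL_LOOP_CHOICES if kind == "canonical"
                   else CALPAIN_LOOP_CHOICES)
        loop = "".join(c[rng.integers(0, len(c))] for c in choices)
        anchors = (0, 2, 4, 5, 8, 11) if kind == "canonical" else (0, 3, 5, 7, 10)
        s = add(loop, frozen=True, anchors=anchors)
        truth.ef_hands.append((kind, s + 1, len(loop)))
        add(_sample(rng, HELIX_POOL, 8), frozen=True)
        truth.segments[f"ef{k}"] = (seg_start, pos)
        if k < len(preset.ef_kinds):
            add(_sample(rng, LINKER_POOL, 6))
    if preset.ef_kinds:
        truth.segments["ef_region"] = (ef_start, pos)
    add(_sample(rng, LINKER_POOL, 12))

    def add_tm(index: int, his_offsets: tuple[int, ...] = ()) -> None:
        tm = list(_sample(rng, TM_POOL, 21))
        for off in his_offsets:
            tm[off] = "H"
        s = add("".join(tm), frozen=True, segment=f"tm{index}",
                anchors=his_offsets)
        truth.tm_spans.append((s + 1, s + 21))
        for off in his_offsets:
            if off == 10:
                truth.nonheme_his_h3 = s + off + 1
            else:
                truth.heme_his.append(s + off + 1)

    add_tm(1)
    # intracellular loop between TM I and II
    add(_sample(rng, LINKER_POOL, 12))
    add_tm(2)
    # intracellular loop between TM II and III carries the (T/S)G motif
    add(_sample(rng, LINKER_POOL, 4))
    s = add("TG", frozen=True, anchors=(0, 1))
    truth.tsg = (s + 1, s + 2)
    add(_sample(rng, LINKER_POOL, 6))
    add_tm(3, his_offsets=(4, 10, 17))
    add(_sample(rng, LINKER_POOL, 12))
    add_tm(4)
    add(_sample(rng, LINKER_POOL, 12))
    add_tm(5, his_offsets=(4, 17))
    # E-loop between TM V and VI; optionally the cysteine insertion
    add(_sample(rng, LINKER_POOL, 8))
    if preset.eloop_cys:
        s = add(CYS_INSERT, frozen=True, segment="cys_insert",
                anchors=tuple(i for i, c in enumerate(CYS_INSERT) if c == "C"))
        truth.eloop_cys = [s + 1 + i for i, c in enumerate(CYS_INSERT) if c == "C"]
    add(_sample(rng, LINKER_POOL, 8))
    add_tm(6)
    # hydrophilic cap so hydropathy windows past the last helix fall below
    # threshold, then the dehydrogenase tail with the beta-strand motif
    add(_sample(rng, LINKER_POOL, 14))
    add(_sample(rng, TAIL_POOL, 20))
    s = add("LAGPFG", frozen=True, anchors=(0, 2, 3, 4, 5))
    truth.vxgpfyg = (s + 1, s + 6)
    add(_sample(rng, TAIL_POOL, 50))

    seq = "".join(parts)
    rec = ProteinRecord(
        id=f"{preset.name}_root", seq=seq,
        description=f"synthetic {preset.name} architecture",
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Evolution along a tree


@dataclass
class SimulatedFamily:
    """Output of :func:`evolve`: the true alignment plus full ground truth."""

    alignment: Alignment                    # leaves, master coordinates, no gaps yet
    tree: Tree
    site_rates: np.ndarray                  # per-column rate actually used
    node_sequences: dict[str, str]          # every node (internal included)


def evolve(
    tree: Tree,
    root: ProteinRecord,
    model: SubstitutionModel,
    seed: int,
    frozen_spans: list[tuple[int, int]] | None = None,
    *,
    conservation: float = CONSERVATION_FACTOR,
    anchor_positions: list[int] | None = None,
    rate_mode: str = "continuous",
) -> SimulatedFamily:
    """Evolve a root sequence along a tree.

    Per-site rates are drawn once at the root from Gamma(alpha, alpha)
    (``rate_mode="continuous"``) or uniformly from the model's discrete
    categories (``"discrete"``); without +Gamma all rates are 1. Sites in
    ``frozen_spans`` (0-based half-open) are scaled by ``conservation``;
    ``anchor_positions`` (0-based) are invariant sites, emulating the
    strict purifying selection on coordination and catalytic residues that
    makes the fingerprint diagnostic in the first place.
    Substitutions are sampled from the model's transition probabilities on
    each branch. The emitted alignment is the true one: no realignment.
    """
    if len(root.seq) == 0:
        raise SimulationError("root sequence must be non-empty")
    rng = np.random.default_rng(seed)
    tree = tree.copy()
    tree.label_internal()
    n_sites = len(root.seq)
    if model.alpha is None:
        rates = np.ones(n_sites)
    elif rate_mode == "continuous":
        rates = rng.gamma(model.alpha, 1.0 / model.alpha, size=n_sites)
    elif rate_mode == "discrete":
        rates = rng.choice(model.category_rates, size=n_sites)
    else:
        raise SimulationError(f"unknown rate mode {rate_mode!r}")
    scale = np.ones(n_sites)
    for s, e in frozen_spans or []:
        scale[s:e] = conservation
    if anchor_positions:
        scale[np.asarray(anchor_positions)] = 0.0
    site_scale = rates * scale

    w = model._eigval
    right, left = model._right, model._left
    states = {id(tree.root): np.array([AA_INDEX[c] for c in root.seq])}
    node_sequences = {tree.root.name or "root": root.seq}
    for n in tree.preorder():
        if n is tree.root:
            continue
        t = n.length or 0.0
        parent_state = states[id(n.parent)]
        if t == 0:
            child = parent_state.copy()
        else:
            ev = np.exp(w[None, :] * (site_scale * t)[:, None])
            P = (right[None, :, :] * ev[:, None, :]) @ left
            probs = np.clip(P[np.arange(n_sites), parent_state, :], 0.0, None)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n_sites)
            child = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        states[id(n)] = child
        node_sequences[n.name] = "".join(AA_ORDER[i] for i in child)
    leaf_ids = tree.leaf_names()
    aln = Alignment(ids=leaf_ids, rows=[node_sequences[l] for l in leaf_ids])
    return SimulatedFamily(
        alignment=aln, tree=tree, site_rates=site_scale,
        node_sequences=node_sequences,
    )


# ---------------------------------------------------------------------------
# Indels


@dataclass(frozen=True)
class IndelEvent:
    """A clade-wise indel: ``branch`` names the node whose subtree is hit.

    A deletion makes ``span`` (0-based half-open alignment columns) absent
    at and below the branch; an insertion makes it present *only* at and
    below the branch.
    """

    branch: str
    span: tuple[int, int]
    kind: str  # "deletion" | "insertion"


def apply_indels(
    alignment: Alignment,
    tree: Tree,
    events: list[IndelEvent],
) -> tuple[Alignment, dict[str, np.ndarray]]:
    """Apply clade-wise indel events, returning the gapped alignment and the
    true per-node presence table (node name -> boolean per column)."""
    tree = tree.copy()
    tree.label_internal()
    names = {n.name for n in tree.postorder()}
    for ev in events:
        if ev.branch not in names:
            raise SimulationError(f"event branch {ev.branch!r} not in tree")
        if ev.kind not in ("deletion", "insertion"):
            raise SimulationError(f"unknown indel kind {ev.kind!r}")
    # contradictory events: overlapping spans of opposite kind on nested branches
    def below(name: str) -> set[str]:
        node = tree.find(name)
        out = set()
        stack = [node]
        while stack:
            m = stack.pop()
            out.add(m.name)
            stack.extend(m.children)
        return out
    subtree = {ev.branch: below(ev.branch) for ev in events}
    for i, a in enumerate(events):
        for b in events[i + 1:]:
            overlap = a.span[0] < b.span[1] and b.span[0] < a.span[1]
            nested = (a.branch in subtree[b.branch]) or (b.branch in subtree[a.branch])
            if overlap and nested and a.kind != b.kind:
                raise SimulationError(
                    f"contradictory overlapping events on {a.branch!r}/{b.branch!r}"
                )
    n_cols = alignment.length
    presence = {n.name: np.ones(n_cols, dtype=bool) for n in tree.postorder()}
    for ev in events:
        s, e = ev.span
        hit = subtree[ev.branch]
        for name, pres in presence.items():
            inside = name in hit
            if (ev.kind == "deletion" and inside) or (
                ev.kind == "insertion" and not inside
            ):
                pres[s:e] = False
    rows = []
    for rid, row in zip(alignment.ids, alignment.rows):
        mask = presence[rid]
        rows.append("".join(c if m else GAP for c, m in zip(row, mask)))
    gapped = Alignment(ids=list(alignment.ids), rows=rows,
                       descriptions=list(alignment.descriptions))
    return gapped, presence


# ---------------------------------------------------------------------------
# Family fixture


@dataclass
class SimulationConfig:
    """Configuration of a synthetic family.

    Defaults emulate the headline scenario: a calcium-dependent (four
    EF-hand) root from which the DUOX/RBOH/NOXC clades arise by EF-hand
    losses and the calcium-independent clade by loss of the whole EF region
    plus gain of the E-loop cysteine insertion.
    """

    clades: tuple[str, ...] = ("nox5", "noxc", "duox", "rboh", "ca_independent")
    leaves_per_clade: int = 4
    height: float = 0.5
    model: str = "LG"
    alpha: float | None = 1.347
    k: int = 4
    rate_mode: str = "continuous"
    conservation: float = CONSERVATION_FACTOR
    seed: int = 0
    tree_newick: str | None = None


@dataclass
class FamilyBundle:
    """End-to-end fixture: sequences, true alignment/tree and truth tables."""

    config: SimulationConfig
    master_truth: GroundTruth
    tree: Tree
    alignment: Alignment                    # gapped true alignment
    leaves: list[ProteinRecord]             # ungapped leaf sequences
    presence: dict[str, np.ndarray]         # per node true presence
    node_sequences: dict[str, str]          # pre-indel states, master coords
    site_rates: np.ndarray
    events: list[IndelEvent]

    def expected_label(self, leaf_id: str) -> str:
        clade = leaf_id.rsplit("_", 1)[0]
        return PRESETS[clade].expected_label

    def leaf_positions(self, leaf_id: str, span: tuple[int, int]) -> tuple[int, int] | None:
        """Translate a master-coordinate 1-based span to the leaf's own
        ungapped 1-based coordinates; None when any column is absent."""
        mask = self.presence[leaf_id]
        s, e = span[0] - 1, span[1] - 1
        if not mask[s:e + 1].all():
            return None
        offset = int(mask[:s].sum())
        return offset + 1, offset + (e - s + 1)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.leaves, out / "leaves.fasta")
        write_alignment(self.alignment, out / "true_alignment.fasta")
        self.tree.write(out / "true_tree.nwk")
        with open(out / "truth_features.tsv", "w") as fh:
            fh.write("feature\tstart\tend\tdetail\n")
            t = self.master_truth
            for i, (s, e) in enumerate(t.tm_spans, 1):
                fh.write(f"tm{i}\t{s}\t{e}\t\n")
            for p in t.heme_his:
                fh.write(f"heme_his\t{p}\t{p}\t\n")
            if t.nonheme_his_h3:
                fh.write(f"nonheme_his_h3\t{t.nonheme_his_h3}\t{t.nonheme_his_h3}\t\n")
            if t.tsg:
                fh.write(f"tsg\t{t.tsg[0]}\t{t.tsg[1]}\t\n")
            if t.vxgpfyg:
                fh.write(f"vxgpfyg\t{t.vxgpfyg[0]}\t{t.vxgpfyg[1]}\t\n")
            for p in t.eloop_cys:
                fh.write(f"eloop_cys\t{p}\t{p}\t\n")
            for kind, s, ln in t.ef_hands:
                fh.write(f"ef_hand\t{s}\t{s + ln - 1}\t{kind}\n")
        with open(out / "truth_presence.tsv", "w") as fh:
            fh.write("node\t" + "\t".join(
                str(j + 1) for j in range(self.alignment.length)) + "\n")
            for name, pres in self.presence.items():
                fh.write(name + "\t" + "\t".join(
                    "1" if p else "0" for p in pres) + "\n")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=False)


def _clade_subtree(name: str, n_leaves: int, stem_len: float,
                   inner_len: float, leaf_len: float) -> Node:
    """Balanced clade of ``n_leaves`` under a stem node named ``{name}_stem``.

    ``inner_len`` is the stem-to-cherry branch and ``leaf_len`` the terminal
    branch, so every leaf sits ``stem_len + inner_len + leaf_len`` below the
    stem's parent.
    """
    stem = Node(name=f"{name}_stem", length=stem_len)
    leaves = [Node(name=f"{name}_{i + 1}", length=leaf_len)
              for i in range(n_leaves)]
    if n_leaves == 1:
        leaves[0].length = inner_len + leaf_len
        stem.add(leaves[0])
        return stem
    units: list[Node] = []
    for i in range(0, n_leaves, 2):
        group = leaves[i:i + 2]
        if len(group) == 1:
            group[0].length = inner_len + leaf_len
            units.append(group[0])
            continue
        inner = Node(length=inner_len)
        for l in group:
            inner.add(l)
        units.append(inner)
    if len(units) == 1:
        # a single cherry: hang its leaves directly off the stem to keep
        # every internal node binary
        (cherry,) = units
        for l in cherry.children:
            l.parent = None
            l.length = (l.length or 0.0) + (cherry.length or 0.0)
            stem.add(l)
        return stem
    while len(units) > 2:
        join = Node(length=0.0)
        join.add(units.pop(0))
        join.add(units.pop(0))
        units.append(join)
    stem.add(units[0])
    stem.add(units[1])
    return stem


def _family_tree(config: SimulationConfig) -> Tree:
    """Rooted backbone mirroring the inferred divergence order: the NOX5-like
    clade splits first, then NOXC, then DUOX, with RBOH sister to the
    calcium-independent clade."""
    if config.tree_newick:
        t = Tree.from_newick(config.tree_newick, rooted=True)
        return t
    h = config.height
    order = list(config.clades)
    if len(order) < 2:
        raise SimulationError("need at least two clades")
    depth_step = 0.45 * h / max(1, len(order) - 2) if len(order) > 2 else 0.0
    stem_depth, inner_depth = 0.5 * h, 0.75 * h

    def clade(name: str, parent_depth: float) -> Node:
        return _clade_subtree(
            name, config.leaves_per_clade,
            stem_len=stem_depth - parent_depth,
            inner_len=inner_depth - stem_depth,
            leaf_len=h - inner_depth,
        )

    root = Node(name="root")
    cur = root
    cur_depth = 0.0
    for i, name in enumerate(order[:-2]):
        cur.add(clade(name, cur_depth))
        nxt_depth = cur_depth + depth_step
        nxt = Node(name=f"B{i + 1}", length=nxt_depth - cur_depth)
        cur.add(nxt)
        cur, cur_depth = nxt, nxt_depth
    cur.add(clade(order[-2], cur_depth))
    cur.add(clade(order[-1], cur_depth))
    return Tree(root, rooted=True)


#: which master EF-hand slots each clade retains (homology to the
#: four-EF-hand reference: DUOX keeps EF2+EF3, RBOH keeps EF3+EF4, the
#: Ascomycota-style NOXC keeps EF3 only)
EF_HOMOLOGY: dict[str, tuple[int, ...]] = {
    "nox5": (1, 2, 3, 4),
    "duox": (2, 3),
    "rboh": (3, 4),
    "noxc": (3,),
    "ca_independent": (),
    "unclassified": (),
}
#: clades whose whole EF region is deleted in one event
_REGION_LOSS = ("ca_independent", "unclassified")


def _covering_events(
    tree: Tree, absent_clades: set[str], present_clades: set[str],
    span: tuple[int, int],
) -> list[IndelEvent]:
    """Minimal set of deletion branches whose subtrees cover the absent
    clades without touching any present clade.

    Walking top-down, a branch is emitted (and not descended) as soon as its
    subtree contains no leaf of a present clade; losses that are convex on
    the tree therefore become single events, which keeps the planted history
    parsimony-recoverable wherever the loss pattern allows it.
    """
    def clade_of(leaf: str) -> str:
        return leaf.rsplit("_", 1)[0]

    events: list[IndelEvent] = []

    def walk(node: Node) -> None:
        leaves = {l.name for l in _leaves_below_sim(node)}
        clades_here = {clade_of(l) for l in leaves}
        if not clades_here & present_clades:
            if clades_here & absent_clades:
                events.append(IndelEvent(node.name, span, "deletion"))
            return
        for c in node.children:
            walk(c)

    walk(tree.root)
    return events


def _leaves_below_sim(node: Node) -> list[Node]:
    out, stack = [], [node]
    while stack:
        m = stack.pop()
        if m.is_leaf:
            out.append(m)
        else:
            stack.extend(m.children)
    return out


def _family_events(
    config: SimulationConfig, truth: GroundTruth, tree: Tree
) -> list[IndelEvent]:
    seg = truth.segments
    events: list[IndelEvent] = []
    clades = list(config.clades)

    def stem(c: str) -> str:
        return f"{c}_stem"

    # clade-specific insertions: the DUOX N-terminal extension and the
    # calcium-independent E-loop cysteine block
    if "duox" in clades:
        events.append(IndelEvent(stem("duox"), seg["extension"], "insertion"))
    else:
        events.append(IndelEvent("root", seg["extension"], "deletion"))
    if "ca_independent" in clades:
        events.append(IndelEvent(
            stem("ca_independent"), seg["cys_insert"], "insertion"))
    else:
        events.append(IndelEvent("root", seg["cys_insert"], "deletion"))
    # whole-EF-region losses
    for c in _REGION_LOSS:
        if c in clades:
            events.append(IndelEvent(stem(c), seg["ef_region"], "deletion"))
    # per-EF-hand losses via minimal covering branches
    for k in (1, 2, 3, 4):
        absent = {c for c in clades
                  if c not in _REGION_LOSS and k not in EF_HOMOLOGY[c]}
        present = {c for c in clades if k in EF_HOMOLOGY[c]}
        if absent:
            events.extend(_covering_events(tree, absent, present, seg[f"ef{k}"]))
    return events


def make_family_fixture(config: SimulationConfig | None = None) -> FamilyBundle:
    """Generate the end-to-end family fixture.

    One clade per architecture preset hangs off a species-like backbone;
    EF-hand-loss deletions sit on the stems of the duox/rboh/noxc/
    calcium-independent clades and the DUOX extension and E-loop cysteine
    insertion are clade-specific insertions, so the root is the
    four-EF-hand (calcium-dependent) state.
    """
    config = config or SimulationConfig()
    for c in config.clades:
        if c not in PRESETS or c == "master":
            raise SimulationError(f"unknown clade preset {c!r}")
    rng = np.random.default_rng(config.seed)
    master, truth = build_root_sequence("master", int(rng.integers(2**31)))
    tree = _family_tree(config)
    model = SubstitutionModel(config.model, alpha=config.alpha, k=config.k)
    fam = evolve(
        tree, master, model, int(rng.integers(2**31)),
        truth.frozen_spans, conservation=config.conservation,
        anchor_positions=truth.anchor_positions,
        rate_mode=config.rate_mode,
    )
    events = _family_events(config, truth, fam.tree)
    gapped, presence = apply_indels(fam.alignment, fam.tree, events)
    leaves = [gapped.ungapped(rid) for rid in gapped.ids]
    return FamilyBundle(
        config=config, master_truth=truth, tree=fam.tree, alignment=gapped,
        leaves=leaves, presence=presence, node_sequences=fam.node_sequences,
        site_rates=fam.site_rates, events=events,
    )
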