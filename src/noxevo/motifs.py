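"""Rule-based annotation of the NOX catalytic core and EF-hand motifs.

The NOX catalytic core is recognised through a sequence fingerprint: six
transmembrane (TM) helices, two pairs of heme-coordinating histidines on TM
helices III and V, a non-coordinating histidine on helix III, a
(V/I/L)xGP(F/Y)G beta-strand motif in the C-terminal dehydrogenase domain and
a (T/S)G motif in an intracellular loop. Calcium-dependent members carry
N-terminal EF-hand motifs; calcium-independent members instead carry
conserved cysteines in the extracellular loop between TM helices V and VI
(the E-loop).

All positions reported by this module are 1-based inclusive, matching the
residue-landmark convention (e.g. a helix-III histidine reported at 119).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

#: Chou-Fasman alpha-helix propensities (P_alpha), used only for the crude
#: helix-context check around EF-hand loops.
HELIX_PROPENSITY: dict[str, float] = {
    "E": 1.51, "M": 1.45, "A": 1.42, "L": 1.21, "K": 1.16, "F": 1.13,
    "Q": 1.11, "W": 1.08, "I": 1.08, "V": 1.06, "D": 1.01, "H": 1.00,
    "R": 0.98, "T": 0.83, "S": 0.77, "C": 0.70, "Y": 0.69, "N": 0.67,
    "P": 0.57, "G": 0.57, "X": 1.00,
}

#: Residues whose side chains carry coordinating oxygens.
OXYGEN_BEARING = frozenset("DENQST")

#: Role-to-loop-position maps. Positions are 1-based within the loop.
CANONICAL_ROLE_POSITIONS: dict[str, int] = {
    "X": 1, "Y": 3, "Z": 5, "-Y": 7, "-X": 9, "-Z": 12,
}
CALPAIN_ROLE_POSITIONS: dict[str, int] = {
    "X": 1, "Z": 4, "-Y": 6, "-X": 8, "-Z": 11,
}
CANONICAL_LOOP_LEN = 12
CALPAIN_LOOP_LEN = 11

VXGPFYG_RE = re.compile(r"[VIL].GP[FY]G")
TSG_RE = re.compile(r"[TS]G")


class MotifError(ValueError):
    """Raised on invalid motif-scanning input."""


@dataclass(frozen=True)
class TMHelix:
    """A predicted transmembrane helix (1-based inclusive span)."""

    start: int
    end: int
    mean_hydropathy: float
    index: int  # ordinal 1..6 from the N-terminus

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class CoreFingerprint:
    """The NOX catalytic-core fingerprint of one sequence."""

    tm_helices: list[TMHelix]
    heme_his: list[int] = field(default_factory=list)
    nonheme_his_h3: int | None = None
    vxgpfyg: tuple[int, int] | None = None  # 1-based inclusive span
    tsg_motif: tuple[int, int] | None = None  # (T/S position, G position)
    eloop_cys: list[int] = field(default_factory=list)
    is_nox_like: bool = False


@dataclass
class EFHandAnnotation:
    """A helix-loop-helix calcium-binding motif call.

    ``roles`` maps coordination roles (X, Y, Z, -Y, -X, -Z) to 1-based loop
    positions; the offsets are fixed per kind (canonical: 1,3,5,7,9,12;
    calpain-like: 1,4,6,8,11).
    """

    kind: str  # "canonical" | "calpain-like"
    loop_start: int  # 1-based sequence position of loop residue 1
    loop_len: int
    roles: dict[str, int]
    score: float
    gly6: bool = False
    bidentate_zminus: bool = False
    flanks_helical: bool = False
    index: int = 0  # 1-based N-to-C numbering set by scan_ef_hands

    @property
    def loop_end(self) -> int:
        return self.loop_start + self.loop_len - 1


@dataclass
class NOXSubtypeCall:
    """Architecture-level subtype assignment for one sequence."""

    label: str
    n_ef_hands: int
    has_calpain_ef1: bool
    has_nterm_extension: bool
    activation_class: str  # "calcium-dependent" | "calcium-independent" | "unknown"
    evidence: list[str] = field(default_factory=list)
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# Transmembrane helix prediction


def predict_tm_helices(
    seq: str,
    window: int = 19,
    threshold: float = 1.6,
    *,
    min_len: int = 15,
    max_len: int = 30,
    merge_gap: int = 3,
) -> list[TMHelix]:
    """Predict TM helices from sliding-window Kyte-Doolittle hydropathy.

    A residue is a seed when the mean hydropathy of the ``window``-wide
    window centred on it is at least ``threshold``. Maximal seed runs are
    extended outwards over residues with positive hydropathy, merged when
    separated by fewer than ``merge_gap`` residues, then filtered/trimmed to
    the [``min_len``, ``max_len``] length bounds.
    """
    n = len(seq)
    if n <= window:
        raise MotifError("sequence must be longer than the hydropathy window")
    values = [KYTE_DOOLITTLE.get(c, 0.0) for c in seq]
    half = window // 2
    # centred window means for positions with a full window
    seeds = []
    csum = [0.0]
    for v in values:
        csum.append(csum[-1] + v)
    for i in range(half, n - half):
        mean = (csum[i + half + 1] - csum[i - half]) / window
        if mean >= threshold:
            seeds.append(i)
    # group seed runs
    runs: list[list[int]] = []
    for i in seeds:
        if runs and i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    # extend over hydrophobic residues, bridging single hydrophilic dips
    # (heme-coordinating histidines sit inside TM helices)
    spans: list[list[int]] = []
    for s, e in runs:
        while True:
            if s > 0 and values[s - 1] > 0:
                s -= 1
            elif s > 1 and values[s - 2] > 0:
                s -= 2
            else:
                break
        while True:
            if e < n - 1 and values[e + 1] > 0:
                e += 1
            elif e < n - 2 and values[e + 2] > 0:
                e += 2
            else:
                break
        spans.append([s, e])
    # merge close/overlapping spans
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    # split over-long regions at their hydropathy minimum (two helices can
    # merge across a short loop that drifted hydrophobic), then filter
    def split(s: int, e: int) -> list[tuple[int, int]]:
        length = e - s + 1
        if length <= max_len:
            return [(s, e)]
        lo = s + min_len - 1
        hi = e - min_len + 1
        if lo >= hi:  # cannot split into two valid helices: trim instead
            excess = length - max_len
            return [(s + excess // 2, s + excess // 2 + max_len - 1)]
        cut = min(range(lo, hi), key=lambda i: values[i])
        return split(s, cut - 1) + split(cut + 1, e)

    helices: list[TMHelix] = []
    for s0, e0 in merged:
        for s, e in split(s0, e0):
            if e - s + 1 < min_len:
                continue
            mean = sum(values[s:e + 1]) / (e - s + 1)
            helices.append(
                TMHelix(start=s + 1, end=e + 1, mean_hydropathy=mean,
                        index=len(helices) + 1)
            )
    helices = [
        TMHelix(h.start, h.end, h.mean_hydropathy, i + 1)
        for i, h in enumerate(sorted(helices, key=lambda h: h.start))
    ]
    return helices


# ---------------------------------------------------------------------------
# Core fingerprint


def _heme_his_pair(
    seq: str, helix: TMHelix, spacing: tuple[int, int], margin: int = 3
) -> tuple[int, int] | None:
    """First histidine pair on a helix with spacing inside the window.

    The strict predicted span is tried first; a small ``margin`` around it
    is used only as a fallback, absorbing boundary error of the hydropathy
    prediction (the histidines themselves depress it).
    """
    lo, hi = spacing

    def search(m: int) -> tuple[int, int] | None:
        lo_bound = max(0, helix.start - 1 - m)
        hi_bound = min(len(seq), helix.end + m)
        his = [i + 1 for i in range(lo_bound, hi_bound) if seq[i] == "H"]
        for i, a in enumerate(his):
            for b in his[i + 1:]:
                if lo <= b - a <= hi:
                    return a, b
        return None

    return search(0) or search(margin)


def scan_core_fingerprint(
    seq: str,
    tm_helices: Sequence[TMHelix],
    *,
    heme_spacing: tuple[int, int] = (10, 18),
) -> CoreFingerprint:
    """Locate the catalytic-core fingerprint relative to predicted helices.

    Heme-coordinating histidine pairs are sought on TM helices III and V; a
    further helix-III histidine not assigned to a heme is reported as the
    non-coordinating histidine. The (V/I/L)xGP(F/Y)G motif is sought
    C-terminal of the last TM helix (dehydrogenase domain), the (T/S)G motif
    in the intracellular loops (between helices II-III and IV-V), and E-loop
    cysteines strictly between helices V and VI.
    """
    fp = CoreFingerprint(tm_helices=list(tm_helices))
    if len(tm_helices) < 3:
        warnings.warn(
            "fewer than 3 TM helices predicted; not a NOX-like topology",
            stacklevel=2,
        )
        return fp
    helices = list(tm_helices)
    h3 = helices[2]
    pair3 = _heme_his_pair(seq, h3, heme_spacing)
    if pair3:
        fp.heme_his.extend(pair3)
    if len(helices) >= 5:
        pair5 = _heme_his_pair(seq, helices[4], heme_spacing)
        if pair5:
            fp.heme_his.extend(pair5)
    heme_set = set(fp.heme_his)
    for i in range(h3.start - 1, h3.end):
        if seq[i] == "H" and (i + 1) not in heme_set:
            fp.nonheme_his_h3 = i + 1
            break
    # dehydrogenase-domain beta-strand motif, C-terminal of the last helix
    tail_start = helices[-1].end  # 0-based index of first residue after helix
    m = VXGPFYG_RE.search(seq, tail_start)
    if m:
        fp.vxgpfyg = (m.start() + 1, m.end())
    # (T/S)G in the intracellular loops
    loop_spans = []
    if len(helices) >= 3:
        loop_spans.append((helices[1].end, helices[2].start - 1))
    if len(helices) >= 5:
        loop_spans.append((helices[3].end, helices[4].start - 1))
    for s, e in loop_spans:
        m = TSG_RE.search(seq, s, e)
        if m:
            fp.tsg_motif = (m.start() + 1, m.start() + 2)
            break
    # E-loop cysteines between helices V and VI
    if len(helices) >= 6:
        fp.eloop_cys = [
            i + 1
            for i in range(helices[4].end, helices[5].start - 1)
            if seq[i] == "C"
        ]
    fp.is_nox_like = (
        len(helices) >= 6 and len(fp.heme_his) >= 4 and fp.vxgpfyg is not None
    )
    return fp


# ---------------------------------------------------------------------------
# EF-hand classification


def _score_canonical(loop: str) -> tuple[float, bool, bool] | None:
    """Score a 12-residue window against the canonical EF-hand rules.

    Mandatory anchors: position 1 in {D,N,S} (D preferred) and a bidentate
    acidic -Z (D/E) at position 12. Positions 3, 5 and 9 are scored for
    oxygen-bearing side chains, glycine at 6 is scored but not required.
    Returns (score fraction of maximum, gly6, bidentate_zminus) or None.
    """
    if loop[0] not in "DNS" or loop[11] not in "DE":
        return None
    score = 0.2 if loop[0] == "D" else 0.1
    score += 0.2  # -Z anchor
    score += 0.15 if loop[2] in OXYGEN_BEARING else (0.05 if loop[2] == "G" else 0.0)
    score += 0.15 if loop[4] in OXYGEN_BEARING else (0.05 if loop[4] == "G" else 0.0)
    score += 0.10 if loop[8] in OXYGEN_BEARING else (0.05 if loop[8] == "G" else 0.0)
    gly6 = loop[5] == "G"
    if gly6:
        score += 0.2
    return score, gly6, True


def _score_calpain(loop: str) -> float | None:
    """Score an 11-residue window against the calpain-like EF-hand rules.

    Mandatory anchors: position 1 in {A,V}, an acidic Z at position 4 and a
    bidentate glutamate -Z at position 11.
    """
    if loop[0] not in "AV" or loop[3] not in "DE" or loop[10] != "E":
        return None
    score = 0.25 + 0.25 + 0.30
    score += 0.10 if loop[5] in OXYGEN_BEARING else 0.0
    score += 0.10 if loop[7] in OXYGEN_BEARING else 0.0
    return score


def classify_ef_loop(
    window: str, *, min_score: float = 0.6, loop_start: int = 1
) -> EFHandAnnotation | None:
    """Classify a candidate loop window as canonical or calpain-like.

    ``window`` must be at least 12 residues; the canonical rules examine its
    first 12 positions and the calpain-like rules its first 11. The
    higher-scoring kind at or above ``min_score`` (fraction of the maximal
    rule score) is returned, with roles mapped to the fixed offsets, or None
    when neither kind is accepted.
    """
    if len(window) < CANONICAL_LOOP_LEN:
        raise MotifError("window must be at least 12 residues")
    window = window.upper()
    canon = _score_canonical(window[:CANONICAL_LOOP_LEN])
    calp = _score_calpain(window[:CALPAIN_LOOP_LEN])
    best: EFHandAnnotation | None = None
    if canon is not None and canon[0] >= min_score:
        score, gly6, bid = canon
        best = EFHandAnnotation(
            kind="canonical", loop_start=loop_start, loop_len=CANONICAL_LOOP_LEN,
            roles=dict(CANONICAL_ROLE_POSITIONS), score=score, gly6=gly6,
            bidentate_zminus=bid,
        )
    if calp is not None and calp >= min_score and (best is None or calp > best.score):
        best = EFHandAnnotation(
            kind="calpain-like", loop_start=loop_start, loop_len=CALPAIN_LOOP_LEN,
            roles=dict(CALPAIN_ROLE_POSITIONS), score=calp, gly6=False,
            bidentate_zminus=True,
        )
    return best


def _flank_helical(seq: str, start0: int, end0: int, flank: int = 8) -> bool:
    """Crude helix-propensity check on the residues flanking a loop span."""
    left = seq[max(0, start0 - flank):start0]
    right = seq[end0:end0 + flank]
    def mean_prop(s: str) -> float:
        if not s:
            return 0.0
        return sum(HELIX_PROPENSITY.get(c, 1.0) for c in s) / len(s)
    return mean_prop(left) >= 1.05 and mean_prop(right) >= 1.05


def scan_ef_hands(
    seq: str,
    region: tuple[int, int] | None = None,
    *,
    min_score: float = 0.6,
    require_helical_flanks: bool = True,
) -> list[EFHandAnnotation]:
    """Scan a sequence region for EF-hand motifs.

    ``region`` is a 0-based half-open span; it defaults to the whole
    sequence (callers annotating a NOX typically pass the N-terminal segment
    preceding TM helix I). Overlapping candidate loops are resolved by score
    then leftmost position. EF-hands are reported N-to-C and numbered from 1.

    By default a call must sit in a helix-loop-helix context (helical
    flanks); disable with ``require_helical_flanks=False``.
    """
    start, stop = region if region is not None else (0, len(seq))
    start, stop = max(0, start), min(len(seq), stop)
    candidates: list[EFHandAnnotation] = []
    for i in range(start, stop - CANONICAL_LOOP_LEN + 1):
        ann = classify_ef_loop(
            seq[i:i + CANONICAL_LOOP_LEN], min_score=min_score, loop_start=i + 1
        )
        if ann is None:
            continue
        ann.flanks_helical = _flank_helical(seq, i, i + ann.loop_len)
        if require_helical_flanks and not ann.flanks_helical:
            continue
        candidates.append(ann)
    # resolve overlaps: best score first, then leftmost
    chosen: list[EFHandAnnotation] = []
    for ann in sorted(candidates, key=lambda a: (-a.score, a.loop_start)):
        if all(
            ann.loop_end < c.loop_start or ann.loop_start > c.loop_end
            for c in chosen
        ):
            chosen.append(ann)
    chosen.sort(key=lambda a: a.loop_start)
    for k, ann in enumerate(chosen, start=1):
        ann.index = k
    return chosen


# ---------------------------------------------------------------------------
# Architecture assignment


def assign_architecture(
    fingerprint: CoreFingerprint,
    ef_hands: Sequence[EFHandAnnotation],
    nterm_extension_len: int = 0,
    *,
    min_extension: int = 250,
) -> NOXSubtypeCall:
    """Assign a NOX subtype label from the core fingerprint and EF-hands.

    Decision table: 4 EF-hands (the first may be calpain-like) -> NOX5-like;
    2 EF-hands with an N-terminal extension of at least ``min_extension``
    residues (peroxidase-like domain stand-in) -> DUOX-like; 2 EF-hands
    without the extension -> RBOH-like; 1 EF-hand -> NOXC-like; none with at
    least one E-loop cysteine -> calcium-independent-like; none and no
    E-loop cysteine -> unclassified-NOX-like. Sequences whose fingerprint is
    not NOX-like are labelled non-NOX. Three EF-hands fall to the nearest
    rule (NOX5-like) with a low-confidence flag.
    """
    n_ef = len(ef_hands)
    evidence: list[str] = []
    has_calpain_ef1 = bool(ef_hands) and ef_hands[0].kind == "calpain-like"
    has_ext = nterm_extension_len >= min_extension
    low_confidence = False
    if not fingerprint.is_nox_like:
        label = "non-NOX"
        evidence.append("core fingerprint incomplete (is_nox_like false)")
    elif n_ef >= 4:
        label = "NOX5-like"
        evidence.append(f"{n_ef} EF-hands" + (", first calpain-like" if has_calpain_ef1 else ""))
    elif n_ef == 3:
        label = "NOX5-like"
        low_confidence = True
        evidence.append("3 EF-hands: nearest rule is NOX5-like (low confidence)")
    elif n_ef == 2 and has_ext:
        label = "DUOX-like"
        evidence.append(
            f"2 EF-hands with {nterm_extension_len}-residue N-terminal extension"
        )
    elif n_ef == 2:
        label = "RBOH-like"
        evidence.append("2 EF-hands, no N-terminal extension")
    elif n_ef == 1:
        label = "NOXC-like"
        evidence.append("single EF-hand")
    elif fingerprint.eloop_cys:
        label = "calcium-independent-like"
        evidence.append(
            "no EF-hands; E-loop cysteine(s) at "
            + ",".join(map(str, fingerprint.eloop_cys))
        )
    else:
        label = "unclassified-NOX-like"
        evidence.append("no EF-hands and no E-loop cysteine")
    if label == "non-NOX":
        activation = "unknown"
    elif n_ef >= 1:
        activation = "calcium-dependent"
    else:
        activation = "calcium-independent"
    return NOXSubtypeCall(
        label=label,
        n_ef_hands=min(n_ef, 4),
        has_calpain_ef1=has_calpain_ef1,
        has_nterm_extension=has_ext,
        activation_class=activation,
        evidence=evidence,
        low_confidence=low_confidence,
    )


# ---------------------------------------------------------------------------
# Whole-sequence annotation and cross-MSA EF-hand homology


@dataclass
class SequenceAnnotation:
    """Bundle of all annotations for one sequence."""

    id: str
    tm_helices: list[TMHelix]
    fingerprint: CoreFingerprint
    ef_hands: list[EFHandAnnotation]
    subtype: NOXSubtypeCall


def annotate_sequence(
    record,
    *,
    window: int = 19,
    threshold: float = 1.6,
    min_score: float = 0.6,
    min_extension: int = 250,
) -> SequenceAnnotation:
    """Annotate one ungapped protein record end to end.

    EF-hands are sought in the N-terminal segment preceding TM helix I; the
    N-terminal extension length is the number of residues preceding the
    first EF-hand loop.
    """
    seq = record.seq
    tms = predict_tm_helices(seq, window=window, threshold=threshold)
    fp = scan_core_fingerprint(seq, tms)
    region = (0, tms[0].start - 1) if tms else (0, len(seq))
    efs = scan_ef_hands(seq, region, min_score=min_score)
    ext_len = efs[0].loop_start - 1 if efs else 0
    call = assign_architecture(fp, efs, ext_len, min_extension=min_extension)
    return SequenceAnnotation(
        id=record.id, tm_helices=tms, fingerprint=fp, ef_hands=efs, subtype=call
    )


def map_ef_hand_homology(
    alignment,
    annotations_by_id: dict[str, Sequence[EFHandAnnotation]],
    reference_id: str,
) -> dict[str, dict[int, int | None]]:
    """Map each sequence's EF-hands onto the reference EF1..EF4 by alignment
    column overlap.

    The reference must carry 4 annotated EF-hands (a NOX5-like sequence).
    Every non-reference EF-hand is assigned the reference EF-hand whose
    alignment-column span overlaps it most (None for zero overlap). Returns
    ``{seq_id: {ef_index: reference_ef_index_or_None}}``.
    """
    ref_anns = list(annotations_by_id.get(reference_id, []))
    if len(ref_anns) != 4:
        raise MotifError(
            f"reference {reference_id!r} must have exactly 4 EF-hands, "
            f"got {len(ref_anns)}"
        )
    def col_span(rid: str, ann: EFHandAnnotation) -> set[int]:
        r2c = alignment.residue_to_column(rid)
        lo = ann.loop_start - 1
        hi = min(ann.loop_end, len(r2c))
        return set(r2c[lo:hi])
    ref_spans = {k + 1: col_span(reference_id, a) for k, a in enumerate(ref_anns)}
    out: dict[str, dict[int, int | None]] = {}
    for rid, anns in annotations_by_id.items():
        mapping: dict[int, int | None] = {}
        for ann in anns:
            cols = col_span(rid, ann)
            best_k, best_ov = None, 0
            for k, rspan in ref_spans.items():
                ov = len(cols & rspan)
                if ov > best_ov:
                    best_k, best_ov = k, ov
            mapping[ann.index] = best_k
        out[rid] = mapping
    return out
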