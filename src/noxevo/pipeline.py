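"""End-to-end orchestration: curate -> annotate -> tree -> ASR -> report.

Every stage writes its artifact plus a JSON provenance record (inputs,
parameters, seed, package version) into the run directory, so a run is
re-derivable from its config and seed alone. Supports are rounded to two
decimals in text reports; full precision lives in the JSON artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .asr import compose_ancestor, fitch_gap_states, gap_character_matrix, marginal_asr
from .motifs import annotate_sequence
from .phylo import (
    PhyloError,
    SubstitutionModel,
    bootstrap_alignments,
    distance_matrix,
    felsenstein_support,
    midpoint_root,
    neighbor_joining,
    tbe_support,
)
from .sequences import (
    CONSERVATIVE_GAP_FRACTION,
    Alignment,
    kept_column_map_tsv,
    read_alignment,
    removal_log_tsv,
    trim_alignment,
    filter_by_identity,
    write_fasta,
)
from .simulate import SimulationConfig, make_family_fixture
from .trees import Tree

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: Exception | str) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are serialized into provenance."""

    alignment: str | None = None             # input MSA path; None -> simulate
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    canonical_refs: list[str] = field(default_factory=list)  # empty -> auto
    identity_threshold: float = 0.20
    trim_gap_fraction: float = 0.5
    asr_trim_gap_fraction: float = CONSERVATIVE_GAP_FRACTION
    hydropathy_window: int = 19
    hydropathy_threshold: float = 1.6
    model: str = "LG"
    alpha: float = 1.347
    k: int = 4
    bootstrap_n: int = 500
    support: str = "tbe"                     # "tbe" | "felsenstein"
    seed: int = 0
    # name -> list of leaf ids (MRCA); None selects the tree root
    ancestor_clades: dict[str, list[str] | None] = field(
        default_factory=lambda: {"root": None})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim:
            cfg.simulate = SimulationConfig(**sim)
        return cfg


def _provenance(out: Path, stage: str, params: dict) -> None:
    rec = {"stage": stage, "version": __version__, **params}
    with open(out / f"provenance_{stage}.json", "w") as fh:
        json.dump(rec, fh, indent=2, default=str)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage in order; any failure aborts with the stage name and
    cause while partial outputs are retained."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- input -------------------------------------------------------------
    stage = "input"
    try:
        if config.alignment:
            aln = read_alignment(config.alignment)
            source = config.alignment
        else:
            bundle = make_family_fixture(config.simulate)
            bundle.write(out / "fixture")
            aln = bundle.alignment
            source = "simulated fixture"
        _provenance(out, stage, {"source": source, "n_rows": len(aln),
                                 "n_columns": aln.length, "seed": config.seed})
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- curate ------------------------------------------------------------
    stage = "curate"
    try:
        refs = config.canonical_refs or _auto_refs(aln)
        curated, removed = filter_by_identity(
            aln, refs, config.identity_threshold)
        for entry in removed:
            logger.info("curate: removed %s (best ref %s, identity %.3f)",
                        entry.id, entry.best_ref, entry.identity)
        (out / "removal_log.tsv").write_text(removal_log_tsv(removed))
        trimmed, kept = trim_alignment(curated, config.trim_gap_fraction)
        logger.info("curate: dropped %d of %d columns",
                    curated.length - len(kept), curated.length)
        (out / "kept_columns.tsv").write_text(kept_column_map_tsv(kept))
        _provenance(out, stage, {
            "canonical_refs": refs, "identity_threshold": config.identity_threshold,
            "removed": [e.id for e in removed],
            "trim_gap_fraction": config.trim_gap_fraction,
            "n_trimmed_columns": len(kept),
        })
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- annotate ----------------------------------------------------------
    stage = "annotate"
    try:
        annotations = {}
        rows = ["id\tlabel\tn_ef_hands\tactivation_class\tevidence"]
        for rid in curated.ids:
            ann = annotate_sequence(
                curated.ungapped(rid),
                window=config.hydropathy_window,
                threshold=config.hydropathy_threshold,
            )
            annotations[rid] = ann
            rows.append("\t".join([
                rid, ann.subtype.label, str(ann.subtype.n_ef_hands),
                ann.subtype.activation_class, "; ".join(ann.subtype.evidence),
            ]))
        (out / "subtype_calls.tsv").write_text("\n".join(rows) + "\n")
        (out / "annotations.tsv").write_text(_annotation_tsv(annotations))
        _provenance(out, stage, {
            "hydropathy_window": config.hydropathy_window,
            "hydropathy_threshold": config.hydropathy_threshold,
            "n_sequences": len(annotations),
        })
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- tree --------------------------------------------------------------
    stage = "tree"
    try:
        if len(trimmed) < 3:
            raise PhyloError("fewer than 3 taxa after curation")
        ids, D = distance_matrix(trimmed, "p-distance")
        nj = neighbor_joining(ids, D)
        rooted = midpoint_root(nj)
        reps = bootstrap_alignments(trimmed, config.bootstrap_n, config.seed)
        boots = []
        for rep in reps:
            rids, RD = distance_matrix(rep, "p-distance")
            boots.append(neighbor_joining(rids, RD))
        supporter = tbe_support if config.support == "tbe" else felsenstein_support
        supported = supporter(rooted, boots)
        supported.write(out / "tree.nwk", support_decimals=2)
        supports = {
            n.name or f"node@{i}": n.support
            for i, n in enumerate(supported.internal_nodes())
            if n.support is not None
        }
        for name, s in supports.items():
            logger.info("tree: support %.2f on %s", s, name)
        with open(out / "supports.json", "w") as fh:
            json.dump(supports, fh, indent=2)
            fh.write("\n")
        _provenance(out, stage, {
            "method": "NJ + midpoint rooting",
            "bootstrap_n": config.bootstrap_n, "support": config.support,
            "seed": config.seed,
        })
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- asr ---------------------------------------------------------------
    stage = "asr"
    try:
        asr_aln, asr_kept = trim_alignment(curated, config.asr_trim_gap_fraction)
        model = SubstitutionModel(config.model, alpha=config.alpha, k=config.k)
        supported.label_internal()
        targets: dict[str, str] = {}
        for name, leaf_set in config.ancestor_clades.items():
            node = supported.root if leaf_set is None else supported.mrca(leaf_set)
            targets[name] = node.name
        recs = marginal_asr(supported, asr_aln, model,
                            node_ids=sorted(set(targets.values())))
        fitch = fitch_gap_states(supported, gap_character_matrix(asr_aln))
        ancestors = []
        conf_rows = ["ancestor\tnode\tposition\tcolumn_raw\tmap_residue\tposterior"]
        raw_cols = asr_kept
        arch_rows = ["ancestor\tlabel\tn_ef_hands\tactivation_class"]
        for name, node_id in targets.items():
            comp = compose_ancestor(recs[node_id], fitch, node_id)
            rec = dataclasses.replace(comp.record, id=name)
            ancestors.append(rec)
            for k, (col, conf) in enumerate(zip(comp.columns, comp.confidence)):
                conf_rows.append(
                    f"{name}\t{node_id}\t{k + 1}\t{raw_cols[col] + 1}\t"
                    f"{rec.seq[k]}\t{conf:.4f}")
            ann = annotate_sequence(rec)
            arch_rows.append("\t".join([
                name, ann.subtype.label, str(ann.subtype.n_ef_hands),
                ann.subtype.activation_class]))
        write_fasta(ancestors, out / "ancestors.fasta")
        (out / "ancestor_posteriors.tsv").write_text("\n".join(conf_rows) + "\n")
        (out / "ancestor_architectures.tsv").write_text("\n".join(arch_rows) + "\n")
        _provenance(out, stage, {
            "model": config.model, "alpha": config.alpha, "k": config.k,
            "asr_trim_gap_fraction": config.asr_trim_gap_fraction,
            "targets": targets,
        })
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- report ------------------------------------------------------------
    stage = "report"
    try:
        by_class: dict[str, list[str]] = {}
        for rid, ann in annotations.items():
            by_class.setdefault(ann.subtype.activation_class, []).append(rid)
        report = {
            "n_sequences": len(annotations),
            "activation_class_summary": {
                k: sorted(v) for k, v in sorted(by_class.items())
            },
            "subtype_labels": {
                rid: annotations[rid].subtype.label for rid in curated.ids
            },
            "ancestors": {r.id: len(r.seq) for r in ancestors},
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")
        _provenance(out, stage, {"config": dataclasses.asdict(config)})
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return out


def _auto_refs(aln: Alignment) -> list[str]:
    """Default canonical reference set: the first row of each leading id
    prefix (clade), mirroring one reference per canonical NOX subtype."""
    seen: dict[str, str] = {}
    for rid in aln.ids:
        prefix = rid.rsplit("_", 1)[0]
        seen.setdefault(prefix, rid)
    return list(seen.values())


def _annotation_tsv(annotations: dict) -> str:
    rows = ["id\tfeature_type\tstart\tend\tkind\tscore\troles"]
    for rid, ann in annotations.items():
        for tm in ann.tm_helices:
            rows.append(f"{rid}\ttm_helix\t{tm.start}\t{tm.end}\ttm{tm.index}\t"
                        f"{tm.mean_hydropathy:.2f}\t")
        fp = ann.fingerprint
        for p in fp.heme_his:
            rows.append(f"{rid}\theme_his\t{p}\t{p}\t\t\t")
        if fp.nonheme_his_h3:
            rows.append(f"{rid}\tnonheme_his_h3\t{fp.nonheme_his_h3}\t"
                        f"{fp.nonheme_his_h3}\t\t\t")
        if fp.tsg_motif:
            rows.append(f"{rid}\ttsg\t{fp.tsg_motif[0]}\t{fp.tsg_motif[1]}\t\t\t")
        if fp.vxgpfyg:
            rows.append(f"{rid}\tvxgpfyg\t{fp.vxgpfyg[0]}\t{fp.vxgpfyg[1]}\t\t\t")
        for p in fp.eloop_cys:
            rows.append(f"{rid}\teloop_cys\t{p}\t{p}\t\t\t")
        for ef in ann.ef_hands:
            roles = ",".join(f"{k}:{v}" for k, v in ef.roles.items())
            rows.append(f"{rid}\tef_hand\t{ef.loop_start}\t{ef.loop_end}\t"
                        f"{ef.kind}\t{ef.score:.2f}\t{roles}")
    return "\n".join(rows) + "\n"
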