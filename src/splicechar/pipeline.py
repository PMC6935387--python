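"""End-to-end orchestration: from genome + GTF + rMATS tables + expression
to feature tables, group comparisons, summary verdicts and motif hits.

Stage order: load genome/annotation -> parse+filter events -> direction
classification -> reference transcripts -> internal controls -> external
pool + controls -> train splice-site models -> feature extraction ->
comparisons/summaries -> motifs -> report.  A single seeded random stream
is handed down to every sampling operation in this fixed order, so
identical (inputs, config, seed) produce byte-identical outputs.

A5SS/A3SS/MXE events are parsed, filtered, direction-classified and counted
but receive no feature extraction; only retained introns and skipped exons
are characterized.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as anno
from . import compare as cmp
from . import controls as ctrl
from . import events as ev
from . import features as feat
from . import splice_scoring as scoring

log = logging.getLogger(__name__)

KINDS = [ev.EventKind.SE, ev.EventKind.RI, ev.EventKind.A5SS,
         ev.EventKind.A3SS, ev.EventKind.MXE]

RI_FEATURES = [
    "donor_score", "acceptor_score", "focal_length", "focal_gc",
    "upstream_exon_len", "downstream_exon_len", "bp_offset",
]
SE_FEATURES = [
    "donor_score", "acceptor_score", "upstream_donor_score",
    "downstream_acceptor_score", "focal_length", "focal_gc",
    "upstream_intron_len", "downstream_intron_len",
    "upstream_intron_gc", "downstream_intron_gc",
    "bp_offset_upstream", "bp_offset_downstream",
]


@dataclass
class RunConfig:
    genome: str
    gtf: str
    rmats_dir: str
    expression: str
    outdir: str
    g1_is_wildtype: bool  # mandatory: sign conventions invert with it
    seed: int
    counting_mode: str = "JCEC"
    alpha: float = 0.05
    adjust_method: str = "bh"
    external_pool_size: int = 1200
    bp_search_min: int = 15
    bp_search_max: int = 500
    bp_ppt_window: int = 25
    bp_ppt_weight: float = 2.0
    kmer_min: int = 5
    kmer_max: int = 8
    n_perm: int = 1000
    kmer_min_fg_frac: float = 0.2
    scorer_mode: str = "trained"  # or "external_tables"
    donor_table: str | None = None
    acceptor_table: str | None = None
    mito_names: tuple = tuple(sorted(anno.MITO_NAMES))
    pseudocount: float = 0.5
    uniform_background: bool = False
    run_motifs: bool = True

    def bp_params(self) -> dict:
        return {
            "search_min": self.bp_search_min,
            "search_max": self.bp_search_max,
            "agez_ppt_window": self.bp_ppt_window,
            "ppt_weight": self.bp_ppt_weight,
        }


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    fingerprint: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "tables": self.tables,
             "fingerprint": self.fingerprint},
            indent=1, sort_keys=True,
        )


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:
                raise StageError(f"stage '{name}': {e}") from e
        return wrapped
    return deco


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _group_of(event: ev.SpliceEvent) -> str:
    inc = event.direction == ev.Direction.INCREASED_IN_MUTANT
    if event.kind == ev.EventKind.RI:
        return "IRI" if inc else "DRI"
    return "ISE" if inc else "DSE"


def _construct_sequence(c: ctrl.ControlConstruct, genome) -> str:
    parts = [
        anno.get_sequence(genome, c.chrom, iv, c.strand)
        for _, iv in c.segments_transcript_order()
    ]
    return "".join(parts)


def _event_region_sequence(event: ev.SpliceEvent, genome) -> str:
    span = event.span()
    return anno.get_sequence(genome, event.chrom, span, event.strand)


def run(config: RunConfig) -> RunReport:
    """Execute the full characterization pipeline; returns the run report
    (also written to ``outdir/report.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report = RunReport()
    counts = report.counts

    genome = _load_genome_stage(config)
    genes = _load_annotation_stage(config)
    genes_by_id = {g.gene_id: g for g in genes}
    counts["genes_annotated"] = len(genes)

    parsed, filtered = _events_stage(config, genes_by_id)
    for kind in KINDS:
        counts[f"events_parsed_{kind.value}"] = len(parsed[kind])
        counts[f"events_filtered_{kind.value}"] = len(filtered[kind])
    summary = ev.multi_event_summary(filtered)
    counts["genes_with_events"] = len(summary.gene_kinds)
    counts["genes_multi_kind"] = summary.n_multi_kind

    reference = {
        gid: anno.select_reference_transcript(g) for gid, g in genes_by_id.items()
    }
    counts["genes_with_reference_transcript"] = sum(
        1 for t in reference.values() if t is not None
    )

    internal_eie, internal_eieie = _internal_controls_stage(
        filtered, genes_by_id, reference, rng
    )
    counts["controls_internal_EIE"] = len(internal_eie)
    counts["controls_internal_EIEIE"] = len(internal_eieie)

    external_eie, external_eieie = _external_controls_stage(
        config, filtered, genes_by_id, reference, rng
    )
    counts["controls_external_EIE"] = len(external_eie)
    counts["controls_external_EIEIE"] = len(external_eieie)

    donor_model, acceptor_model = _scorer_stage(config, genes, genome)
    counts["donor_training_sites"] = getattr(donor_model, "n_training", 0)
    counts["acceptor_training_sites"] = getattr(acceptor_model, "n_training", 0)

    ri_rows, se_rows = _features_stage(
        config, filtered, internal_eie, internal_eieie, external_eie,
        external_eieie, genome, donor_model, acceptor_model, reference,
        genes_by_id,
    )
    counts["features_ri_rows"] = len(ri_rows)
    counts["features_se_rows"] = len(se_rows)
    counts["features_excluded_for_n"] = sum(
        1 for r in ri_rows + se_rows if r.has_n
    )

    ri_df = pd.DataFrame([r.to_dict() for r in ri_rows])
    se_df = pd.DataFrame([r.to_dict() for r in se_rows])

    comp_df, summary_ri, summary_se = _compare_stage(config, ri_rows, se_rows)

    motif_df = pd.DataFrame()
    if config.run_motifs:
        motif_df = _motif_stage(
            config, filtered, internal_eie, internal_eieie, external_eie,
            external_eieie, genome, rng,
        )
    counts["motif_hits"] = len(motif_df)

    # ---- write outputs ----------------------------------------------
    def _write(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        report.tables[name.split(".")[0]] = str(path)

    filt_rows = []
    for kind in KINDS:
        for e in filtered[kind]:
            filt_rows.append(
                {
                    "event_id": e.event_id, "kind": e.kind.value,
                    "gene_id": e.gene_id, "chrom": e.chrom, "strand": e.strand,
                    "p_value": e.p_value, "fdr": e.fdr,
                    "inc_level_diff": e.inc_level_diff,
                    "direction": e.direction.value if e.direction else "",
                    "span_start": e.span()[0], "span_end": e.span()[1],
                }
            )
    _write(pd.DataFrame(filt_rows), "events_filtered.tsv")
    combo_rows = [
        {"kinds": "+".join(combo), "n_genes": n}
        for combo, n in sorted(summary.combination_counts.items())
    ]
    _write(pd.DataFrame(combo_rows), "multi_event_genes.tsv")
    _write(
        ctrl.constructs_to_frame(
            internal_eie + internal_eieie + external_eie + external_eieie
        ),
        "constructs.tsv",
    )
    _write(ri_df, "features_ri.tsv")
    _write(se_df, "features_se.tsv")
    _write(comp_df, "comparisons.tsv")
    _write(summary_ri, "summary_ri.tsv")
    _write(summary_se, "summary_se.tsv")
    _write(motif_df, "motifs.tsv")

    report.fingerprint = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "inputs": {
            "genome": _digest(config.genome),
            "gtf": _digest(config.gtf),
            "expression": _digest(config.expression),
        },
    }
    (outdir / "report.json").write_text(report.to_json() + "\n")
    log.info("pipeline complete: %s", json.dumps(counts, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# stages


@_stage("load genome")
def _load_genome_stage(config):
    return anno.load_genome(config.genome)


@_stage("load annotation")
def _load_annotation_stage(config):
    return anno.load_annotation(config.gtf, mito_names=set(config.mito_names))


@_stage("parse and filter events")
def _events_stage(config, genes_by_id):
    rmats_dir = Path(config.rmats_dir)
    parsed, filtered = {}, {}
    for kind in KINDS:
        path = rmats_dir / f"{kind.value}.MATS.{config.counting_mode}.txt"
        if not path.exists():
            raise FileNotFoundError(f"missing rMATS table {path}")
        evs = ev.parse_rmats_table(path, kind)
        known = [e for e in evs if e.gene_id in genes_by_id]
        if len(known) < len(evs):
            log.warning(
                "%s: dropped %d events with gene_id absent from annotation",
                kind.value, len(evs) - len(known),
            )
        parsed[kind] = known
        filt = ev.filter_events(known)
        ev.classify_all(filt, config.g1_is_wildtype)
        filtered[kind] = filt
    return parsed, filtered


@_stage("internal controls")
def _internal_controls_stage(filtered, genes_by_id, reference, rng):
    by_gene: dict[str, list] = {}
    for kind in KINDS:
        for e in filtered[kind]:
            by_gene.setdefault(e.gene_id, []).append(e)

    internal_eie, internal_eieie = [], []
    for kind, shape, sink in (
        (ev.EventKind.RI, ctrl.SHAPE_EIE, internal_eie),
        (ev.EventKind.SE, ctrl.SHAPE_EIEIE, internal_eieie),
    ):
        for e in filtered[kind]:
            ref = reference.get(e.gene_id)
            if ref is None:
                continue
            footprints = ctrl.event_footprints(by_gene[e.gene_id])
            cands = ctrl.enumerate_internal_candidates(
                ref, footprints, shape, gene_id=e.gene_id
            )
            pick = ctrl.sample_one(cands, rng)
            if pick is None:
                log.info("no internal %s candidate for %s", shape, e.event_id)
                continue
            sink.append(pick)
    return internal_eie, internal_eieie


@_stage("external controls")
def _external_controls_stage(config, filtered, genes_by_id, reference, rng):
    expr = ctrl.load_expression(config.expression)
    excluded = {
        e.gene_id for kind in KINDS for e in filtered[kind]
    }
    out = []
    for shape in (ctrl.SHAPE_EIE, ctrl.SHAPE_EIEIE):
        pool = ctrl.select_external_genes(
            expr, genes_by_id, excluded, shape, n=config.external_pool_size
        )
        out.append(ctrl.build_external_controls(pool, genes_by_id, shape, rng))
    return out[0], out[1]


@_stage("train splice-site models")
def _scorer_stage(config, genes, genome):
    if config.scorer_mode == "external_tables":
        if not (config.donor_table and config.acceptor_table):
            raise ValueError("external_tables mode needs donor_table and acceptor_table")
        return (
            scoring.load_external_score_tables(config.donor_table, "donor"),
            scoring.load_external_score_tables(config.acceptor_table, "acceptor"),
        )
    background = (
        scoring.UNIFORM_BACKGROUND
        if config.uniform_background
        else scoring.genome_background(genome)
    )
    models = []
    for site_kind in ("donor", "acceptor"):
        windows = scoring.collect_training_sites(genes, genome, site_kind)
        models.append(
            scoring.train_model(
                windows, site_kind,
                pseudocount=config.pseudocount, background=background,
            )
        )
    return models[0], models[1]


@_stage("feature extraction")
def _features_stage(config, filtered, internal_eie, internal_eieie,
                    external_eie, external_eieie, genome,
                    donor_model, acceptor_model, reference, genes_by_id):
    bp = config.bp_params()
    ri_rows, se_rows = [], []
    for e in filtered[ev.EventKind.RI]:
        ri_rows.append(
            feat.extract_ri_features(
                e, _group_of(e), genome, donor_model, acceptor_model,
                genes_by_id=genes_by_id, reference_transcripts=reference,
                bp_params=bp,
            )
        )
    for group, items in (("ICI", internal_eie), ("ECI", external_eie)):
        for i, c in enumerate(items):
            ri_rows.append(
                feat.extract_ri_features(
                    c, group, genome, donor_model, acceptor_model,
                    genes_by_id=genes_by_id, bp_params=bp,
                    item_id=f"{group}:{i}",
                )
            )
    for e in filtered[ev.EventKind.SE]:
        se_rows.append(
            feat.extract_se_features(
                e, _group_of(e), genome, donor_model, acceptor_model, bp_params=bp
            )
        )
    for group, items in (("ICE", internal_eieie), ("ECE", external_eieie)):
        for i, c in enumerate(items):
            se_rows.append(
                feat.extract_se_features(
                    c, group, genome, donor_model, acceptor_model,
                    bp_params=bp, item_id=f"{group}:{i}",
                )
            )
    return ri_rows, se_rows


def _grouped_values(rows, features, score_features):
    grouped: dict[str, dict[str, list]] = {f: {} for f in features}
    for r in rows:
        d = r.to_dict()
        for f in features:
            if f in score_features and r.has_n:
                continue  # scores are undefined on N-containing windows
            grouped[f].setdefault(r.group, []).append(d.get(f))
    return grouped


@_stage("comparisons and summaries")
def _compare_stage(config, ri_rows, se_rows):
    score_feats = {
        "donor_score", "acceptor_score", "upstream_donor_score",
        "downstream_acceptor_score",
    }
    all_comparisons: list[cmp.ComparisonResult] = []

    def summarize(rows, features, event_groups, internal, external):
        grouped = _grouped_values(rows, features, score_feats)
        cells, comps = cmp.summarize_feature_table(
            grouped, event_groups, internal, external,
            method=config.adjust_method, alpha=config.alpha,
        )
        all_comparisons.extend(comps)
        return cells, grouped

    ri_cells, ri_grouped = summarize(ri_rows, RI_FEATURES, ["IRI", "DRI"], "ICI", "ECI")
    se_cells, _ = summarize(se_rows, SE_FEATURES, ["ISE", "DSE"], "ICE", "ECE")

    # % of retained introns with an in-frame stop codon, per event group
    stop_rows = []
    for g in ("IRI", "DRI"):
        conseq = [r.ri_consequence for r in ri_rows if r.group == g]
        if conseq:
            stop_rows.append(
                {
                    "feature": "pct_with_in_frame_stop", "group": g,
                    "verdict": f"{100 * cmp.stop_codon_fraction(conseq):.0f}%",
                }
            )
    # short-intron fractions (the <500 bp comparison)
    for g in ("IRI", "DRI", "ICI", "ECI"):
        vals = ri_grouped["focal_length"].get(g)
        if vals:
            stop_rows.append(
                {
                    "feature": "fraction_shorter_than_500bp", "group": g,
                    "verdict": f"{100 * cmp.fraction_below(vals, 500):.0f}%",
                }
            )

    comp_df = pd.DataFrame([asdict(c) for c in all_comparisons])
    summary_ri = pd.DataFrame(ri_cells + stop_rows)
    summary_se = pd.DataFrame(se_cells)
    return comp_df, summary_ri, summary_se


@_stage("motif enrichment")
def _motif_stage(config, filtered, internal_eie, internal_eieie,
                 external_eie, external_eieie, genome, rng):
    ri_by_group: dict[str, list[str]] = {"IRI": [], "DRI": []}
    for e in filtered[ev.EventKind.RI]:
        ri_by_group[_group_of(e)].append(_event_region_sequence(e, genome))
    se_by_group: dict[str, list[str]] = {"ISE": [], "DSE": []}
    for e in filtered[ev.EventKind.SE]:
        se_by_group[_group_of(e)].append(_event_region_sequence(e, genome))
    backgrounds = {
        "internal_EIE": [_construct_sequence(c, genome) for c in internal_eie],
        "external_EIE": [_construct_sequence(c, genome) for c in external_eie],
        "internal_EIEIE": [_construct_sequence(c, genome) for c in internal_eieie],
        "external_EIEIE": [_construct_sequence(c, genome) for c in external_eieie],
    }
    rows = []
    jobs = [
        (g, bg_name)
        for g in ("IRI", "DRI")
        for bg_name in ("internal_EIE", "external_EIE")
    ] + [
        (g, bg_name)
        for g in ("ISE", "DSE")
        for bg_name in ("internal_EIEIE", "external_EIEIE")
    ]
    fg_sets = {**ri_by_group, **se_by_group}
    for group, bg_name in jobs:
        fg = fg_sets[group]
        bg = backgrounds[bg_name]
        if not fg or not bg:
            continue
        hits = cmp.kmer_enrichment(
            fg, bg,
            k_min=config.kmer_min, k_max=config.kmer_max,
            n_perm=config.n_perm, rng=rng,
            min_fg_frac=config.kmer_min_fg_frac, alpha=config.alpha,
        )
        for h in hits:
            rows.append({"group": group, "background": bg_name, **asdict(h)})
    return pd.DataFrame(rows)
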