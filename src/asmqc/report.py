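"""Pipeline orchestration and report emission.

``run_evaluate`` drives the whole evaluation: read references and
assemblies, global statistics on the original contig set, length filter,
map (or ingest PAF), per-replicon metrics with misassembly and gap calls,
consolidation back into the filtered-set global statistics, optional read
mapping and cross-run comparisons.  ``write_report`` emits the
machine-readable tables (TSV/BED/JSON) plus a static self-contained HTML
summary; identical bundles produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .gaps import GapInterval, gap_consistency
from .io import (AlignmentRecord, SequenceRecord, read_fasta, read_fastq,
                 read_paf)
from .mapper import MapperParams, SeedIndex, index_reference, map_query, \
    map_reads
from .metrics import (AssemblyStats, FilterConfig, consolidate,
                      filter_contigs, global_stats)
from .misassembly import ClassifierThresholds
from .reference import PerReferenceReport, build_reports
from .reproducibility import RunComparison, match_by_size

__all__ = ["AssemblyInput", "EvaluationConfig", "AssemblyEvaluation",
           "ReportBundle", "evaluate_assembly", "run_evaluate",
           "write_report"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class AssemblyInput:
    """One assembly FASTA, tagged with an assembler label and a run id."""

    label: str
    path: str
    run: str = "1"
    paf_path: Optional[str] = None


@dataclass
class EvaluationConfig:
    reference_path: str
    assemblies: list[AssemblyInput]
    reads_paths: tuple[str, ...] = ()
    filter: FilterConfig = field(default_factory=FilterConfig)
    thresholds: ClassifierThresholds = field(
        default_factory=ClassifierThresholds)
    mapper: MapperParams = field(default_factory=MapperParams)
    sample_description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.assemblies:
            raise ValueError("at least one assembly is required")
        keys = [(a.label, a.run) for a in self.assemblies]
        if len(keys) != len(set(keys)):
            raise ValueError("assembly (label, run) pairs must be unique")


@dataclass
class AssemblyEvaluation:
    """Everything computed for one assembly against one reference set."""

    label: str
    run: str
    original: AssemblyStats
    filtered: AssemblyStats
    per_reference: list[PerReferenceReport]
    status: str = "ok"  # "ok" or "empty"
    contig_lengths: list[int] = field(default_factory=list)


@dataclass
class ReportBundle:
    global_table: pd.DataFrame
    reference_table: pd.DataFrame
    contig_pls_table: pd.DataFrame
    misassembly_table: pd.DataFrame
    gaps_bed: pd.DataFrame
    gap_consistency_table: pd.DataFrame
    run_consistency_table: pd.DataFrame
    provenance: dict


def _map_contigs(fs_contigs: Sequence[SequenceRecord], idx: SeedIndex,
                 params: MapperParams) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    for contig in fs_contigs:
        out.extend(map_query(contig, idx, params))
    return out


def evaluate_assembly(replicons: Sequence[SequenceRecord],
                      contigs: Sequence[SequenceRecord],
                      label: str = "assembly", run: str = "1",
                      filter_cfg: FilterConfig = FilterConfig(),
                      thresholds: ClassifierThresholds = ClassifierThresholds(),
                      mapper_params: MapperParams = MapperParams(),
                      alignments: Optional[Sequence[AlignmentRecord]] = None,
                      reads: Optional[Sequence[SequenceRecord]] = None,
                      index: Optional[SeedIndex] = None
                      ) -> AssemblyEvaluation:
    """Evaluate one assembly in memory.

    ``alignments`` bypasses the built-in mapper (e.g. external PAF); they
    are restricted to filtered-set contigs either way.
    """
    t0 = time.monotonic()
    original = global_stats(contigs)
    fs = filter_contigs(contigs, filter_cfg)
    filtered = global_stats(fs)

    if not contigs:
        return AssemblyEvaluation(label=label, run=run, original=original,
                                  filtered=filtered, per_reference=[],
                                  status="empty")

    if alignments is None:
        if index is None:
            index = index_reference(replicons, mapper_params)
        alignments = _map_contigs(fs, index, mapper_params)
    else:
        fs_ids = {c.id for c in fs}
        alignments = [a for a in alignments if a.query_id in fs_ids]

    per_ref = build_reports(replicons, fs, alignments, thresholds)
    mis_contigs, mis_events, gap_bp = consolidate(per_ref)
    filtered.misassembled_contigs = mis_contigs
    filtered.misassembly_events = mis_events
    filtered.total_gap_bp = gap_bp

    if reads is not None:
        mapped, total = map_reads(reads, list(contigs), mapper_params)
        frac = mapped / total if total else 0.0
        original.mapped_read_fraction = frac
        filtered.mapped_read_fraction = frac

    logger.info("evaluated %s run %s: %d contigs (%d filtered) in %.1fs",
                label, run, original.n_contigs, filtered.n_contigs,
                time.monotonic() - t0)
    return AssemblyEvaluation(label=label, run=run, original=original,
                              filtered=filtered, per_reference=per_ref,
                              contig_lengths=[c.length for c in contigs])


def _stats_row(ev: AssemblyEvaluation, which: str) -> dict:
    st = ev.original if which == "original" else ev.filtered
    return {
        "assembly": ev.label, "run": ev.run, "contig_set": which,
        "status": ev.status, "n_contigs": st.n_contigs,
        "total_bp": st.total_bp, "largest_contig": st.largest_contig,
        "n50": st.n50, "uncalled": st.uncalled,
        "mapped_read_fraction": st.mapped_read_fraction,
        "misassembled_contigs": st.misassembled_contigs,
        "misassembly_events": st.misassembly_events,
        "total_gap_bp": st.total_gap_bp,
    }


def _bundle_tables(evaluations: Sequence[AssemblyEvaluation]
                   ) -> tuple[pd.DataFrame, ...]:
    global_rows, ref_rows, pls_rows, mis_rows, bed_rows = [], [], [], [], []
    for ev in evaluations:
        global_rows.append(_stats_row(ev, "original"))
        global_rows.append(_stats_row(ev, "filtered"))
        for rep in ev.per_reference:
            ref_rows.append({
                "assembly": ev.label, "run": ev.run,
                "replicon": rep.replicon_id, "replicon_len": rep.replicon_len,
                "gc": rep.gc, "n_contigs_aligned": rep.n_contigs_aligned,
                "aligned_bp": rep.aligned_bp, "breadth": rep.breadth,
                "lsa": rep.lsa, "snps": rep.snps,
                "uncalled_aligned": rep.uncalled_aligned,
                "compass_coverage": rep.compass.coverage,
                "compass_validity": rep.compass.validity,
                "compass_multiplicity": rep.compass.multiplicity,
                "compass_parsimony": rep.compass.parsimony,
                "n_gaps": len(rep.gaps),
                "gap_bp": sum(g.end - g.start for g in rep.gaps),
                "no_alignment": rep.no_alignment,
            })
            for cs in rep.contig_summaries:
                pls_rows.append({
                    "assembly": ev.label, "run": ev.run,
                    "replicon": rep.replicon_id, "contig": cs.contig_id,
                    "contig_len": cs.contig_len, "identity": cs.identity,
                    "pls": cs.pls,
                })
            seen_events = set()
            for call in rep.misassembly_calls:
                for e in call.events:
                    key = (call.contig_id, e.category, e.block_a.q_start)
                    if key in seen_events:
                        continue
                    seen_events.add(key)
                    reps = {e.block_a.replicon_id}
                    if e.block_b is not None:
                        reps.add(e.block_b.replicon_id)
                    # 1-based inclusive, for humans; BED output stays 0-based
                    mis_rows.append({
                        "assembly": ev.label, "run": ev.run,
                        "contig": call.contig_id, "category": e.category,
                        "replicons": ";".join(sorted(reps)),
                        "contig_start_1based": e.block_a.q_start + 1,
                        "contig_end_1based":
                            (e.block_b.q_end if e.block_b is not None
                             else e.block_a.q_end),
                        "magnitude_bp": e.magnitude,
                    })
            for g in rep.gaps:
                bed_rows.append({
                    "chrom": g.replicon_id, "start": g.start, "end": g.end,
                    "name": f"{ev.label}:{ev.run}",
                })
    return (pd.DataFrame(global_rows),
            pd.DataFrame(ref_rows),
            pd.DataFrame(pls_rows),
            pd.DataFrame(mis_rows),
            pd.DataFrame(bed_rows))


def _cross_run_tables(evaluations: Sequence[AssemblyEvaluation],
                      gap_tolerance: int = 0
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    by_label: dict[str, list[AssemblyEvaluation]] = {}
    for ev in evaluations:
        by_label.setdefault(ev.label, []).append(ev)
    run_rows, gap_rows = [], []
    for label in sorted(by_label):
        evs = sorted(by_label[label], key=lambda e: e.run)
        if len(evs) < 2:
            continue
        cmp = match_by_size([e.contig_lengths for e in evs])
        run_rows.append({
            "assembly": label, "n_runs": cmp.n_runs,
            "total_contigs": cmp.total_contigs, "in_all": cmp.in_all,
            "in_two": cmp.in_two, "in_one": cmp.in_one,
            "inconsistent_fraction":
                cmp.inconsistent_fraction if cmp.total_contigs else 0.0,
        })
        runs_gaps = [[g for rep in e.per_reference for g in rep.gaps]
                     for e in evs]
        consistent, partial = gap_consistency(runs_gaps, gap_tolerance)
        for g in sorted(consistent):
            gap_rows.append({"assembly": label, "replicon": g.replicon_id,
                             "start": g.start, "end": g.end,
                             "runs_present": len(evs), "consistent": True})
        for g in sorted(partial):
            gap_rows.append({"assembly": label, "replicon": g.replicon_id,
                             "start": g.start, "end": g.end,
                             "runs_present": partial[g], "consistent": False})
    return pd.DataFrame(run_rows), pd.DataFrame(gap_rows)


def _md5(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def run_evaluate(cfg: EvaluationConfig) -> ReportBundle:
    """Execute the full evaluation described by ``cfg``.

    A single failed (empty) assembly becomes a flagged row; a missing
    reference aborts.
    """
    replicons = read_fasta(cfg.reference_path)
    if not replicons:
        raise ValueError(f"reference file {cfg.reference_path} is empty")
    index = index_reference(replicons, cfg.mapper)

    reads: Optional[list[SequenceRecord]] = None
    if cfg.reads_paths:
        reads = []
        for p in cfg.reads_paths:
            reads.extend(read_fastq(p))

    evaluations = []
    for asm in cfg.assemblies:
        contigs = read_fasta(asm.path)
        alignments = read_paf(asm.paf_path) if asm.paf_path else None
        evaluations.append(evaluate_assembly(
            replicons, contigs, label=asm.label, run=asm.run,
            filter_cfg=cfg.filter, thresholds=cfg.thresholds,
            mapper_params=cfg.mapper, alignments=alignments,
            reads=reads, index=index))

    glob, ref, pls, mis, bed = _bundle_tables(evaluations)
    run_tbl, gap_tbl = _cross_run_tables(evaluations)

    provenance = {
        "tool": "asmqc", "version": __version__,
        "reference": {"path": str(cfg.reference_path),
                      "md5": _md5(cfg.reference_path),
                      "n_replicons": len(replicons)},
        "assemblies": [{"label": a.label, "run": a.run,
                        "path": str(a.path), "md5": _md5(a.path)}
                       for a in cfg.assemblies],
        "reads": [{"path": str(p), "md5": _md5(p)} for p in cfg.reads_paths],
        "config": {
            "min_contig_len": cfg.filter.min_contig_len,
            "thresholds": {
                "block_split_indel": cfg.thresholds.block_split_indel,
                "ins_min": cfg.thresholds.ins_min,
                "del_min": cfg.thresholds.del_min,
                "dup_overlap_min": cfg.thresholds.dup_overlap_min,
                "trans_min": cfg.thresholds.trans_min,
            },
            "mapper": {"k": cfg.mapper.k,
                       "seed_stride": cfg.mapper.seed_stride,
                       "min_chain_seeds": cfg.mapper.min_chain_seeds,
                       "max_seed_gap": cfg.mapper.max_seed_gap,
                       "min_block_len": cfg.mapper.min_block_len},
        },
        "sample_description": cfg.sample_description or "",
    }
    return ReportBundle(global_table=glob, reference_table=ref,
                        contig_pls_table=pls, misassembly_table=mis,
                        gaps_bed=bed, gap_consistency_table=gap_tbl,
                        run_consistency_table=run_tbl, provenance=provenance)


def _write_tsv(df: pd.DataFrame, path: Path, header_note: str = "") -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>asmqc report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 1.5em; }}
th, td {{ border: 1px solid #999; padding: 3px 8px; font-size: 12px; }}
th {{ background: #eee; }}
h2 {{ border-bottom: 2px solid #444; }}
.warn {{ color: #b00; font-weight: bold; }}
</style></head><body>
<h1>Assembly evaluation report</h1>
<h2>Summary</h2>
<p>asmqc version {version}</p>
<p>Reference: <code>{reference}</code> ({n_replicons} replicons,
md5 <code>{ref_md5}</code>)</p>
{description}
{inputs}
<h2>Global metrics</h2>
{global_table}
<h2>Per-reference metrics</h2>
{reference_table}
<h2>Misassemblies</h2>
{misassembly_table}
<h2>Cross-run consistency</h2>
{run_table}
</body></html>
"""


def _df_html(df: pd.DataFrame) -> str:
    if df.empty:
        return "<p><em>no data</em></p>"
    return df.to_html(index=False, border=0, na_rep="",
                      float_format=lambda x: _FLOAT_FMT % x)


def write_report(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write every table plus the static HTML; returns the paths written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    tsvs = [
        ("global_metrics.tsv", bundle.global_table, ""),
        ("reference_metrics.tsv", bundle.reference_table, ""),
        ("contig_pls.tsv", bundle.contig_pls_table, ""),
        ("misassembly.tsv", bundle.misassembly_table,
         "contig coordinates are 1-based inclusive"),
        ("gap_consistency.tsv", bundle.gap_consistency_table,
         "coordinates are 0-based half-open"),
        ("run_consistency.tsv", bundle.run_consistency_table, ""),
    ]
    for name, df, note in tsvs:
        p = out / name
        _write_tsv(df, p, note)
        paths.append(p)

    bed = out / "gaps.bed"
    with open(bed, "w") as fh:
        for _, row in bundle.gaps_bed.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}"
                     f"\t{row['name']}\n")
    paths.append(bed)

    prov = out / "provenance.json"
    prov.write_text(json.dumps(bundle.provenance, indent=1, sort_keys=True))
    paths.append(prov)

    desc = bundle.provenance.get("sample_description", "")
    desc_html = f"<h3>Sample description</h3><pre>{desc}</pre>" if desc else ""
    inputs = "".join(
        f"<li>{a['label']} (run {a['run']}): <code>{a['path']}</code> "
        f"md5 <code>{a['md5']}</code></li>"
        for a in bundle.provenance["assemblies"])
    html = _HTML_TEMPLATE.format(
        version=bundle.provenance["version"],
        reference=bundle.provenance["reference"]["path"],
        n_replicons=bundle.provenance["reference"]["n_replicons"],
        ref_md5=bundle.provenance["reference"]["md5"],
        description=desc_html,
        inputs=f"<h3>Assemblies</h3><ul>{inputs}</ul>",
        global_table=_df_html(bundle.global_table),
        reference_table=_df_html(bundle.reference_table),
        misassembly_table=_df_html(bundle.misassembly_table),
        run_table=_df_html(bundle.run_consistency_table),
    )
    report = out / "report.html"
    report.write_text(html)
    paths.append(report)
    return paths
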