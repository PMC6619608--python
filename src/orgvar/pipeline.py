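"""Stage orchestration: one call runs the whole analysis and writes every
artifact plus a machine-readable JSON report.

Chloroplast mode: alignment -> variant scan -> summary -> VCF + site table
-> coding-effect annotation -> SNP matrix -> pairwise distances ->
diagnostic screen -> complete-case reduction -> haplotype collapse ->
statistical-parsimony network -> exports.

Mitochondrial mode: allele matrix -> paralog flagging -> robustness filter
-> diagnostic screen -> complete-case reduction -> network -> exports.

Every stage logs counts in/out; re-running with the same config reproduces
every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diagnostics, effects, mito, network, scan
from .io import (
    SnpMatrix,
    ValidationError,
    read_alignment,
    read_gff3,
    read_sample_table,
    read_snp_matrix,
    write_snp_matrix,
    write_variants_vcf,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Inputs, mode and thresholds for one pipeline run."""

    mode: str  # "chloroplast" | "mitochondrial"
    alignment: str | None = None
    reference_id: str | None = None
    annotations: str | None = None
    metadata: str | None = None
    mito_matrix: str | None = None
    mito_loci: str | None = None
    outgroup: str | None = None
    group_by: str = "region"
    group_a: str | None = None
    homopolymer_min_run: int = 4
    inversion_min_span: int = 2
    flank_len: int = 20
    amplicon_min_len: int = 60
    amplicon_max_len: int = 150
    min_obs_per_group: int = 2
    confidence: float = 0.95
    outdir: str = "orgvar-out"
    thresholds_doc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("chloroplast", "mitochondrial"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not 0 < self.confidence < 1:
            raise ValidationError("confidence must be in (0, 1)")
        if not 1 <= self.amplicon_min_len <= self.amplicon_max_len:
            raise ValidationError("amplicon length bounds out of order")


def _groups_from_metadata(records, group_by: str, group_a: str | None):
    values = [getattr(r, group_by) for r in records]
    labels = list(dict.fromkeys(values))
    if group_a is None:
        group_a = labels[0]
    if group_a not in labels:
        raise ValidationError(f"group label {group_a!r} not found in column {group_by!r}")
    ids_a = [r.sample_code for r in records if getattr(r, group_by) == group_a]
    ids_b = [r.sample_code for r in records if getattr(r, group_by) != group_a]
    label_b = "+".join(l for l in labels if l != group_a) or "other"
    return {group_a: ids_a, label_b: ids_b}


def _diagnostic_section(matrix: SnpMatrix, groups, config: RunConfig):
    calls = diagnostics.find_diagnostic_snps(
        matrix, groups, min_obs_per_group=config.min_obs_per_group,
        outgroup=config.outgroup,
    )
    return calls, {
        "n_sites_screened": len(calls),
        "n_diagnostic": sum(1 for c in calls if c.diagnostic),
        "diagnostic_sites": [c.site_id for c in calls if c.diagnostic],
    }


def _network_section(matrix: SnpMatrix, records, config: RunConfig,
                     sequence_length: int | None, outdir: Path, tag: str):
    complete = mito.complete_case_sites(matrix)
    report = {"n_sites_in": matrix.n_sites, "n_complete_case_sites": complete.n_sites}
    if complete.n_sites == 0:
        report.update({"n_haplotypes": 0, "n_edges": 0, "n_components": 0})
        return report
    haps = network.collapse_haplotypes(complete)
    limit = (network.connection_limit(sequence_length, config.confidence)
             if sequence_length else None)
    net = network.network_from_matrix(complete, limit=limit,
                                      sequence_length=sequence_length,
                                      confidence=config.confidence)
    region_of = {r.sample_code: r.region for r in records} if records else {
        s: "unknown" for s in matrix.sample_ids}
    for s in matrix.sample_ids:
        region_of.setdefault(s, "unknown")
    network.export_network(net, region_of,
                           outdir / f"{tag}_network.graphml",
                           outdir / f"{tag}_network.nex")
    with open(outdir / f"{tag}_haplotypes.tsv", "w") as fh:
        fh.write("hap_id\tobserved\tmultiplicity\tmembers\tprofile\n")
        for hid in sorted(net.haplotypes):
            h = net.haplotypes[hid]
            fh.write(f"{hid}\t{int(h.observed)}\t{h.multiplicity}\t"
                     f"{','.join(h.members)}\t{h.profile}\n")
    report.update({
        "n_haplotypes": len(haps),
        "n_inferred_nodes": sum(1 for h in net.haplotypes.values() if not h.observed),
        "n_edges": net.graph.number_of_edges(),
        "n_components": len(net.components),
        "connection_limit": net.connection_limit,
    })
    return report


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the JSON report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "mode": config.mode}
    records = read_sample_table(config.metadata) if config.metadata else []
    try:
        if config.mode == "chloroplast":
            _run_chloroplast(config, records, outdir, report)
        else:
            _run_mitochondrial(config, records, outdir, report)
    except Exception:
        logger.exception("pipeline failed; removing partial report")
        raise
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _run_chloroplast(config: RunConfig, records, outdir: Path, report: dict) -> None:
    if not config.alignment or not config.reference_id:
        raise ValidationError("chloroplast mode needs an alignment and reference_id")
    alignment = read_alignment(config.alignment, config.reference_id)
    logger.info("alignment: %d samples x %d columns", alignment.n_samples,
                alignment.length)
    scan_cfg = scan.ScanConfig(homopolymer_min_run=config.homopolymer_min_run,
                               inversion_min_span=config.inversion_min_span)
    events = scan.scan_alignment(alignment, scan_cfg)
    summary = scan.summarize(alignment, events)
    report["variants"] = summary.to_dict()
    logger.info("scan: %d events", len(events))
    if events:
        write_variants_vcf(events, alignment, outdir / "variants.vcf")
    _write_site_table(events, outdir / "sites.tsv")

    if config.annotations:
        features = read_gff3(config.annotations)
        calls = effects.annotate_snps(
            [e for e in events if e.kind == "SNP"], features,
            alignment.reference_sequence())
        report["effects"] = effects.count_effects(calls)
        _write_effect_table(calls, outdir / "effects.tsv")

    snps = [e for e in events if e.kind == "SNP"]
    if not snps:
        report["diagnostics"] = {"n_sites_screened": 0, "n_diagnostic": 0,
                                 "diagnostic_sites": []}
        report["network"] = {"n_sites_in": 0, "n_complete_case_sites": 0,
                             "n_haplotypes": 0, "n_edges": 0, "n_components": 0}
        report["pairwise_differences"] = {"min": 0, "max": 0}
        return
    matrix = scan.snp_matrix_from_events(events, alignment.sample_ids)
    pw = scan.pairwise_differences(matrix)
    iu = np.triu_indices(matrix.n_samples, k=1)
    report["pairwise_differences"] = {"min": int(pw[iu].min()),
                                      "max": int(pw[iu].max())}
    if records:
        groups = _groups_from_metadata(records, config.group_by, config.group_a)
        calls, diag_report = _diagnostic_section(matrix, groups, config)
        conserved = diagnostics._conserved_columns(alignment)
        windows = []
        for c in calls:
            if not c.diagnostic:
                continue
            column = int(c.site_id.split("|")[0].removeprefix("col"))
            windows.append(diagnostics.evaluate_amplicon_window(
                c.site_id, column, alignment, flank_len=config.flank_len,
                min_len=config.amplicon_min_len, max_len=config.amplicon_max_len,
                conserved=conserved))
        diag_report["n_usable_amplicons"] = sum(1 for w in windows if w.usable)
        diagnostics.write_amplicon_bed(windows, alignment.reference_id,
                                       outdir / "amplicons.bed")
        report["diagnostics"] = diag_report
    report["network"] = _network_section(matrix, records, config,
                                         alignment.length, outdir, "cp")


def _run_mitochondrial(config: RunConfig, records, outdir: Path, report: dict) -> None:
    if not config.mito_matrix:
        raise ValidationError("mitochondrial mode needs a mito_matrix TSV")
    matrix = read_snp_matrix(config.mito_matrix, missing_char="-")
    outgroup = config.outgroup
    main_ids = [s for s in matrix.sample_ids if s != outgroup]
    paralog_sites: set[str] = set()
    if config.mito_loci:
        payload = json.loads(Path(config.mito_loci).read_text())
        locus_alignments = payload["loci"] if "loci" in payload else payload
        site_locus = payload.get("site_locus", {}) if isinstance(payload, dict) else {}
        flagged = mito.flag_paralogs(locus_alignments)
        paralog_sites = {s for s, l in site_locus.items() if l in flagged}
        report["paralogs"] = {"n_loci": len(locus_alignments),
                              "n_flagged_loci": len(flagged),
                              "flagged_loci": sorted(flagged)}
    main = _subset_samples(matrix, main_ids)
    verdicts = mito.robustness_filter(main, n_total_samples=len(main_ids),
                                      paralog_sites=paralog_sites)
    _write_verdict_table(verdicts, outdir / "filter_verdicts.tsv")
    kept = mito.apply_verdicts(main, verdicts)
    report["filter"] = {
        "n_sites_in": main.n_sites,
        "n_sites_kept": kept.n_sites,
        "n_sites_rejected": main.n_sites - kept.n_sites,
    }
    logger.info("robustness filter: %d -> %d sites", main.n_sites, kept.n_sites)
    write_snp_matrix(kept, outdir / "filtered_matrix.tsv")

    if records:
        groups = _groups_from_metadata(
            [r for r in records if r.sample_code in set(matrix.sample_ids)],
            config.group_by, config.group_a)
        _, diag_report = _diagnostic_section(matrix, groups, config)
        report["diagnostics"] = diag_report
    report["network"] = _network_section(kept, records, config, None, outdir, "mt")


def _subset_samples(matrix: SnpMatrix, keep: list[str]) -> SnpMatrix:
    idx = [matrix.sample_ids.index(s) for s in keep]
    return SnpMatrix(site_ids=list(matrix.site_ids), sample_ids=list(keep),
                     alleles=matrix.alleles[:, idx])


def _write_site_table(events, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("column_start\tcolumn_end\tref_position\tkind\t"
                 "substitution_class\tis_singleton\talleles\n")
        for e in events:
            alleles = ";".join(f"{s}={a}" for s, a in e.alleles.items())
            fh.write(f"{e.columns[0]}\t{e.columns[1]}\t"
                     f"{e.ref_position if e.ref_position is not None else 'gap'}\t"
                     f"{e.kind}\t{e.substitution_class or 'NA'}\t"
                     f"{e.is_singleton if e.is_singleton is not None else 'NA'}\t"
                     f"{alleles}\n")


def _write_effect_table(calls, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tfeature\tcontext\tcodon_index\tref_aa\talt_aa\t"
                 "synonymous\tref_class\talt_class\tproperty_changed\n")
        for c in calls:
            fh.write("\t".join(str(x if x is not None else "NA") for x in (
                c.site_id, c.feature_name, c.context, c.codon_index, c.ref_aa,
                c.alt_aa, c.synonymous, c.ref_property, c.alt_property,
                c.property_changed)) + "\n")


def _write_verdict_table(verdicts, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tkept\tn_observed\tminor_count\trule_applied\n")
        for v in verdicts:
            fh.write(f"{v.site_id}\t{int(v.kept)}\t{v.n_observed}\t"
                     f"{v.minor_count}\t{v.rule_applied}\n")
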