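"""Core domain types and file I/O for organelle-genome variation analysis.

This module holds the containers the rest of the package operates on — sample
metadata records, whole-genome multiple alignments, feature annotations, the
site-by-sample allele matrix — together with readers and writers for the
standard plain-text formats (TSV metadata, aligned FASTA, GFF3, VCF 4.2).

Coordinates are 1-based and closed in every user-facing structure, matching
GFF3/VCF conventions.  Alignment columns are numbered 1..L; reference
positions are 1-based indices into the ungapped reference row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = "-"
MISSING = "?"
BASES = ("A", "C", "G", "T")
ALPHABET = frozenset("ACGTN-")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

SAMPLE_FIELDS = (
    "sample_code",
    "region",
    "site",
    "latitude",
    "longitude",
    "vegetation_zone",
    "species_range",
    "accession",
)


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced individual: where it was collected and what it is.

    ``region`` is the coarse geographic label used for grouping (e.g.
    Taymyr / Omoloy / Kolyma); ``species_range`` is the published range the
    individual was sampled from; ``accession`` may be empty for synthetic or
    undeposited material.
    """

    sample_code: str
    region: str
    site: str
    latitude: float
    longitude: float
    vegetation_zone: str
    species_range: str
    accession: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"latitude {self.latitude!r} of {self.sample_code} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"longitude {self.longitude!r} of {self.sample_code} outside [-180, 180]"
            )


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read a TSV of sample metadata into :class:`SampleRecord` rows.

    The header must name every field of :class:`SampleRecord`; row order is
    preserved.  Duplicate sample codes and unparseable coordinates raise
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in SAMPLE_FIELDS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"sample table {path} lacks columns: {missing_cols}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        code = row["sample_code"]
        if code in seen:
            raise ValidationError(f"duplicate sample_code {code!r} (row {idx + 2})")
        seen.add(code)
        try:
            lat = float(row["latitude"])
            lon = float(row["longitude"])
        except ValueError as exc:
            raise ValidationError(
                f"unparseable coordinate in row {idx + 2} (sample {code!r}): {exc}"
            ) from None
        records.append(
            SampleRecord(
                sample_code=code,
                region=row["region"],
                site=row["site"],
                latitude=lat,
                longitude=lon,
                vegetation_zone=row["vegetation_zone"],
                species_range=row["species_range"],
                accession=row["accession"],
            )
        )
    return records


def write_sample_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame([[getattr(r, f) for f in SAMPLE_FIELDS] for r in records],
                      columns=list(SAMPLE_FIELDS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class GenomeAlignment:
    """Equal-length aligned organelle genomes keyed by sample.

    One row per individual over the alphabet {A,C,G,T,N,-}; one row is the
    designated reference used for coordinate mapping.  Circularity is carried
    as a flag only — columns are linear and no event may span the origin.
    """

    sample_ids: list[str]
    rows: dict[str, str]
    reference_id: str
    circular: bool = True

    # caches built lazily
    _ref_positions: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValidationError("alignment has no samples")
        lengths = {sid: len(self.rows[sid]) for sid in self.sample_ids}
        if len(set(lengths.values())) != 1:
            raise ValidationError(f"rows of unequal length: {lengths}")
        if self.length < 1:
            raise ValidationError("alignment length must be >= 1")
        if self.reference_id not in self.rows:
            raise ValidationError(f"reference_id {self.reference_id!r} not among samples")
        for sid in self.sample_ids:
            row = self.rows[sid]
            bad = set(row) - ALPHABET
            if bad:
                raise ValidationError(f"row {sid!r} contains invalid symbols {sorted(bad)}")
            if set(row) == {GAP}:
                raise ValidationError(f"row {sid!r} consists only of gaps")

    @property
    def length(self) -> int:
        return len(self.rows[self.sample_ids[0]])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_id]

    def matrix(self) -> np.ndarray:
        """Rows stacked as a (n_samples, length) array of single characters."""
        return np.array([list(self.rows[sid]) for sid in self.sample_ids], dtype="U1")

    def _build_ref_positions(self) -> np.ndarray:
        row = np.frombuffer(self.reference_row.encode("ascii"), dtype=np.uint8)
        nongap = row != ord(GAP)
        pos = np.cumsum(nongap)
        pos[~nongap] = 0  # 0 marks a reference gap
        return pos

    def map_column_to_reference(self, column: int) -> int | None:
        """Map a 1-based alignment column to the 1-based ungapped reference
        position, or ``None`` if the reference row is gapped there."""
        if not 1 <= column <= self.length:
            raise ValidationError(f"column {column} outside 1..{self.length}")
        if self._ref_positions is None:
            self._ref_positions = self._build_ref_positions()
        p = int(self._ref_positions[column - 1])
        return p if p > 0 else None

    def reference_sequence(self) -> str:
        """The reference row with gaps removed."""
        return self.reference_row.replace(GAP, "")


def read_alignment(path: str | Path, reference_id: str, circular: bool = True) -> GenomeAlignment:
    """Read an aligned FASTA into a :class:`GenomeAlignment`.

    Lowercase is normalised to uppercase; IUPAC ambiguity codes other than N
    are demoted to N with a logged warning.  Unequal sequence lengths raise
    an error listing the offending ids.
    """
    sample_ids: list[str] = []
    rows: dict[str, str] = {}
    demoted = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in ALPHABET:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                demoted += 1
        sample_ids.append(rec.id)
        rows[rec.id] = "".join(cleaned)
    if demoted:
        logger.warning("%d ambiguity-code bases demoted to N while reading %s", demoted, path)
    if not sample_ids:
        raise ValidationError(f"no sequences in {path}")
    lengths = {sid: len(rows[sid]) for sid in sample_ids}
    if len(set(lengths.values())) != 1:
        ref_len = lengths[sample_ids[0]]
        offenders = [sid for sid, n in lengths.items() if n != ref_len]
        raise ValidationError(f"unequal sequence lengths; offending ids: {offenders}")
    if reference_id not in rows:
        raise ValidationError(f"reference_id {reference_id!r} absent from {path}")
    return GenomeAlignment(sample_ids=sample_ids, rows=rows,
                           reference_id=reference_id, circular=circular)


def write_alignment(alignment: GenomeAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(alignment.rows[sid]), id=sid, description="")
        for sid in alignment.sample_ids
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Feature annotations (GFF3)
# ---------------------------------------------------------------------------

FEATURE_KINDS = ("gene", "tRNA", "rRNA", "pseudogene", "intron", "IR", "other")


@dataclass
class FeatureAnnotation:
    """One annotated feature on the reference's ungapped coordinate system.

    ``intervals`` are 1-based closed [start, end] spans listed in
    *transcription order* — ascending for '+' strand features, descending for
    '-' strand features.  ``codon_phase`` shifts the reading frame of the
    first exon (0 for complete CDS).
    """

    name: str
    kind: str
    strand: str
    intervals: list[tuple[int, int]]
    codon_phase: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.codon_phase not in (0, 1, 2):
            raise ValidationError(f"codon_phase must be 0/1/2, got {self.codon_phase}")
        if not self.intervals:
            raise ValidationError(f"feature {self.name!r} has no intervals")
        for s, e in self.intervals:
            if s > e or s < 1:
                raise ValidationError(f"bad interval ({s}, {e}) in {self.name!r}")
        # non-overlap + transcription order
        genomic = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValidationError(f"overlapping intervals in {self.name!r}")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if list(self.intervals) != [tuple(iv) for iv in expect]:
            raise ValidationError(
                f"intervals of {self.name!r} not in transcription order for strand {self.strand}"
            )
        if self.kind == "gene":
            if (self.span_length() - self.codon_phase) % 3 != 0:
                raise ValidationError(
                    f"CDS length of {self.name!r} not a codon multiple after phase adjustment"
                )

    def span_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.intervals)


def write_gff3(features: Sequence[FeatureAnnotation], reference_id: str,
               reference_length: int, path: str | Path) -> None:
    """Write features as GFF3.  Multi-interval genes become gene + CDS lines;
    everything else is one line per interval."""
    lines = ["##gff-version 3", f"##sequence-region {reference_id} 1 {reference_length}"]
    for i, feat in enumerate(features):
        genomic = sorted(feat.intervals)
        start, end = genomic[0][0], genomic[-1][1]
        fid = f"f{i:03d}"
        attrs = f"ID={fid};Name={feat.name}"
        if feat.kind == "gene":
            lines.append("\t".join([reference_id, "orgvar", "gene", str(start), str(end),
                                    ".", feat.strand, ".", attrs]))
            # CDS phases accumulate along transcription order
            phase = feat.codon_phase
            for s, e in feat.intervals:
                lines.append("\t".join([reference_id, "orgvar", "CDS", str(s), str(e), ".",
                                        feat.strand, str(phase),
                                        f"ID={fid}.cds;Parent={fid};Name={feat.name}"]))
                phase = (3 - ((e - s + 1) - phase) % 3) % 3
        else:
            gff_type = {"tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "pseudogene",
                        "intron": "intron", "IR": "inverted_repeat",
                        "other": "region"}[feat.kind]
            for s, e in feat.intervals:
                lines.append("\t".join([reference_id, "orgvar", gff_type, str(s), str(e),
                                        ".", feat.strand, ".", attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


_GFF_KIND = {"gene": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "pseudogene",
             "intron": "intron", "inverted_repeat": "IR", "region": "other"}


def read_gff3(path: str | Path) -> list[FeatureAnnotation]:
    """Read GFF3 annotations back into :class:`FeatureAnnotation` objects.

    Gene CDS children are grouped by their Parent attribute and re-ordered
    into transcription order; the phase of the transcription-first CDS line
    becomes ``codon_phase``.
    """
    import gffutils

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    feats: list[FeatureAnnotation] = []
    genes: dict[str, dict] = {}
    order: list[tuple[str, str]] = []  # (kind-tag, key) to preserve file order
    for f in db.all_features(order_by=("start",)):
        if f.featuretype == "gene":
            fid = f.attributes["ID"][0]
            genes[fid] = {"name": f.attributes.get("Name", [fid])[0],
                          "strand": f.strand, "cds": [], "phase": {}}
            order.append(("gene", fid))
        elif f.featuretype == "CDS":
            parent = f.attributes["Parent"][0]
            genes.setdefault(parent, {"name": parent, "strand": f.strand,
                                      "cds": [], "phase": {}})
            genes[parent]["cds"].append((f.start, f.end))
            genes[parent]["phase"][(f.start, f.end)] = (
                0 if f.frame in (None, ".") else int(f.frame)
            )
        elif f.featuretype in _GFF_KIND:
            order.append(("leaf", f.attributes.get("ID", [f.featuretype])[0]))
            feats.append(FeatureAnnotation(
                name=f.attributes.get("Name", [f.featuretype])[0],
                kind=_GFF_KIND[f.featuretype],
                strand=f.strand if f.strand in ("+", "-") else "+",
                intervals=[(f.start, f.end)],
            ))
    for fid, g in genes.items():
        ivs = sorted(g["cds"])
        if g["strand"] == "-":
            ivs = ivs[::-1]
        phase = g["phase"].get(tuple(ivs[0]), 0) if ivs else 0
        feats.append(FeatureAnnotation(name=g["name"], kind="gene",
                                       strand=g["strand"], intervals=ivs,
                                       codon_phase=phase))
    return feats


# ---------------------------------------------------------------------------
# Allele matrix
# ---------------------------------------------------------------------------


@dataclass
class SnpMatrix:
    """Sites x samples single-character allele matrix with '?' for missing."""

    site_ids: list[str]
    sample_ids: list[str]
    alleles: np.ndarray  # shape (n_sites, n_samples), dtype U1

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype="U1")
        if self.alleles.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValidationError(
                f"allele matrix shape {self.alleles.shape} inconsistent with "
                f"{len(self.site_ids)} sites x {len(self.sample_ids)} samples"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("duplicate site ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        for i, sid in enumerate(self.site_ids):
            observed = set(self.alleles[i]) - {MISSING}
            if len(observed) < 2:
                raise ValidationError(
                    f"site {sid!r} has fewer than 2 observed allele states"
                )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.alleles, index=self.site_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.alleles[:, self.sample_ids.index(sample_id)]

    def profile(self, sample_id: str) -> str:
        return "".join(self.column(sample_id))


def read_snp_matrix(path: str | Path, missing_char: str = MISSING) -> SnpMatrix:
    """Read a sites-by-samples TSV (first column ``site_id``) into a matrix.

    ``missing_char`` entries (and empty cells) are converted to '?'.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    alleles = df.to_numpy(dtype="U1")
    alleles[(alleles == missing_char) | (alleles == "")] = MISSING
    return SnpMatrix(site_ids=[str(s) for s in df.index],
                     sample_ids=[str(c) for c in df.columns], alleles=alleles)


def write_snp_matrix(matrix: SnpMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "site_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------


def write_variants_vcf(events: Iterable, alignment: GenomeAlignment,
                       path: str | Path) -> int:
    """Write scanned variant events as VCF 4.2 against the ungapped reference.

    SNPs become single-base records; InDel-type events (plain InDels and
    homopolymer-length differences) are written as left-anchored indel
    records; a reverse-complement inversion is written as a multi-nucleotide
    substitution.  Haploid genotypes: '.', '0', '1', ...  Returns the number
    of data lines written.

    Events at reference-gap columns cannot be anchored and raise
    :class:`ValidationError`.
    """
    ref_seq = alignment.reference_sequence()
    sample_ids = alignment.sample_ids
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={alignment.reference_id},length={len(ref_seq)}>",
        '##INFO=<ID=KIND,Number=1,Type=String,Description="Event kind">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    lines = list(header)
    n = 0
    for ev in sorted(events, key=lambda e: e.columns[0]):
        c1, c2 = ev.columns
        ref_positions = [alignment.map_column_to_reference(c) for c in range(c1, c2 + 1)]
        if any(p is None for p in ref_positions):
            raise ValidationError(
                f"event at columns {ev.columns} overlaps a reference gap; cannot anchor"
            )
        p1 = ref_positions[0]
        ref_span = ref_seq[p1 - 1: ref_positions[-1]]
        sample_allele = {sid: ev.alleles.get(sid, MISSING) for sid in sample_ids}
        if ev.kind == "SNP":
            pos = p1
            ref_allele = ref_span
            alts = sorted({a for a in sample_allele.values()
                           if a not in (MISSING, ref_allele)})
        elif ev.kind == "Inversion":
            pos = p1
            ref_allele = ref_span
            alts = sorted({a for a in sample_allele.values()
                           if a not in (MISSING, ref_allele)})
        else:  # InDel / HomopolymerDiff -> left-anchored indel record
            if p1 < 2:
                raise ValidationError(
                    f"indel event at reference position {p1} has no anchor base"
                )
            anchor = ref_seq[p1 - 2]
            pos = p1 - 1
            ref_allele = anchor + ref_span
            sample_allele = {
                sid: (MISSING if a == MISSING else anchor + a)
                for sid, a in sample_allele.items()
            }
            alts = sorted({a for a in sample_allele.values()
                           if a not in (MISSING, ref_allele)})
        allele_index = {ref_allele: 0, **{a: i + 1 for i, a in enumerate(alts)}}
        gts = []
        for sid in sample_ids:
            a = sample_allele[sid]
            gts.append("." if a == MISSING else str(allele_index[a]))
        lines.append("\t".join([
            alignment.reference_id, str(pos), ".", ref_allele,
            ",".join(alts) if alts else ".", ".", "PASS",
            f"KIND={ev.kind}", "GT", *gts,
        ]))
        n += 1
    Path(path).write_text("\n".join(lines) + "\n")
    return n
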