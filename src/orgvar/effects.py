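"""Coding-context annotation of SNPs under the bacterial/plastid genetic code.

Each SNP with a reference coordinate is located against the feature
annotations (CDS / intron / tRNA / rRNA / pseudogene / intergenic).  For CDS
hits the codon is assembled across exon boundaries in transcription order,
reverse-complemented for minus-strand genes, and translated with codon
translation table 11; the substitution is then classified as synonymous or
non-synonymous, and non-synonymous changes are further classified by
amino-acid property class.

The default property scheme groups the twenty residues into five classes —
basic {R,K,H}, acid/amide {D,E,N,Q}, hydrophilic {S,T,A,P,G}, hydrophobic
{V,I,L,M,F,W,Y} and special {C} (cysteine's disulfide chemistry puts it in a
class of its own).  The scheme is a plain mapping and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io import BASES, FeatureAnnotation, ValidationError, revcomp
from .scan import VariantEvent, _majority_minority

TRANSLATION_TABLE_ID = 11
_TABLE = CodonTable.unambiguous_dna_by_id[TRANSLATION_TABLE_ID]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_PROPERTY_SCHEME: dict[str, str] = {
    **{aa: "basic" for aa in "RKH"},
    **{aa: "acid/amide" for aa in "DENQ"},
    **{aa: "hydrophilic" for aa in "STAPG"},
    **{aa: "hydrophobic" for aa in "VILMFWY"},
    "C": "special",
}

PROPERTY_CLASSES = ("basic", "acid/amide", "hydrophilic", "hydrophobic", "special")

# context precedence when features overlap (introns are annotated inside
# their gene, so they must win over the gene itself)
_KIND_PRIORITY = {"intron": 0, "tRNA": 1, "rRNA": 2, "pseudogene": 3, "gene": 4,
                  "IR": 5, "other": 6}
_KIND_CONTEXT = {"intron": "intron", "tRNA": "tRNA", "rRNA": "rRNA",
                 "pseudogene": "pseudogene", "gene": "CDS", "IR": "intergenic",
                 "other": "intergenic"}


def validate_scheme(scheme: dict[str, str]) -> None:
    """A scheme must map every residue exactly once to a known class."""
    missing = sorted(set(AMINO_ACIDS) - set(scheme))
    if missing:
        raise ValidationError(f"property scheme misses residues {missing}")
    bad = {aa: c for aa, c in scheme.items() if c not in PROPERTY_CLASSES}
    if bad:
        raise ValidationError(f"unknown property classes: {bad}")


def property_change(ref_aa: str, alt_aa: str,
                    scheme: dict[str, str] | None = None) -> tuple[str, str, bool]:
    """Class labels of the two residues and whether the class changed."""
    scheme = scheme if scheme is not None else DEFAULT_PROPERTY_SCHEME
    for aa in (ref_aa, alt_aa):
        if aa not in scheme:
            raise ValidationError(f"unknown residue {aa!r}")
    ref_c, alt_c = scheme[ref_aa], scheme[alt_aa]
    return ref_c, alt_c, ref_c != alt_c


def locate(position: int,
           annotations: Sequence[FeatureAnnotation]) -> tuple[str, FeatureAnnotation | None]:
    """Context and feature at a reference position.

    Deterministic under overlap: intron > tRNA > rRNA > pseudogene > gene.
    A position covered by no feature is intergenic.
    """
    if position is None:
        raise ValidationError("site has no reference coordinate (reference gap)")
    hits = [f for f in annotations if f.contains(position)]
    if not hits:
        return "intergenic", None
    best = min(hits, key=lambda f: _KIND_PRIORITY[f.kind])
    return _KIND_CONTEXT[best.kind], best


@dataclass
class EffectCall:
    """Annotation of one SNP site: where it falls and what it does to the
    protein, if anything."""

    site_id: str
    feature_name: str  # "intergenic" when outside all features
    context: str
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    synonymous: bool | None = None
    ref_property: str | None = None
    alt_property: str | None = None
    property_changed: bool | None = None


def _cds_offset(feature: FeatureAnnotation, position: int) -> int:
    """0-based offset of a genomic position within the spliced CDS, in
    transcription order."""
    off = 0
    for s, e in feature.intervals:
        if s <= position <= e:
            if feature.strand == "+":
                return off + (position - s)
            return off + (e - position)
        off += e - s + 1
    raise ValidationError(
        f"position {position} not inside feature {feature.name!r}"
    )


def spliced_cds(feature: FeatureAnnotation, ref_seq: str) -> str:
    """Assemble the coding sequence across exons in transcription order,
    reverse-complementing minus-strand exons, and trim the phase."""
    parts = []
    for s, e in feature.intervals:
        chunk = ref_seq[s - 1:e]
        parts.append(chunk if feature.strand == "+" else revcomp(chunk))
    cds = "".join(parts)[feature.codon_phase:]
    if len(cds) % 3 != 0:
        raise ValidationError(f"incomplete terminal codon in feature {feature.name!r}")
    return cds


def translate_cds(cds: str) -> str:
    """Translate with table 11; start codons receive no special treatment."""
    return str(Seq(cds).translate(table=TRANSLATION_TABLE_ID))


def call_effect(site_id: str, position: int, ref_base: str, alt_base: str,
                feature: FeatureAnnotation, ref_seq: str,
                scheme: dict[str, str] | None = None) -> EffectCall:
    """Classify a CDS substitution: codon index, residue change, synonymy,
    property change.

    ``ref_base``/``alt_base`` are given on the forward (reference) strand;
    they are complemented internally for minus-strand genes.  An allele that
    introduces a premature stop is reported, not an error.
    """
    if feature.kind != "gene":
        raise ValidationError(f"feature {feature.name!r} is not a protein-coding gene")
    if ref_seq[position - 1] != ref_base:
        raise ValidationError(
            f"reference base at {position} is {ref_seq[position - 1]!r}, not {ref_base!r}"
        )
    off = _cds_offset(feature, position) - feature.codon_phase
    if off < 0:
        raise ValidationError(
            f"position {position} falls in the phase-trimmed start of {feature.name!r}"
        )
    cds = spliced_cds(feature, ref_seq)
    codon_index = off // 3
    within = off % 3
    codon = cds[codon_index * 3: codon_index * 3 + 3]
    ref_b = ref_base if feature.strand == "+" else revcomp(ref_base)
    alt_b = alt_base if feature.strand == "+" else revcomp(alt_base)
    if codon[within] != ref_b:
        raise ValidationError(
            f"codon/reference mismatch at {feature.name!r} position {position}"
        )
    alt_codon = codon[:within] + alt_b + codon[within + 1:]
    ref_aa = translate_cds(codon)
    alt_aa = translate_cds(alt_codon)
    synonymous = ref_aa == alt_aa
    call = EffectCall(
        site_id=site_id, feature_name=feature.name, context="CDS",
        codon_index=codon_index + 1, ref_aa=ref_aa, alt_aa=alt_aa,
        synonymous=synonymous,
    )
    if not synonymous and ref_aa != "*" and alt_aa != "*":
        ref_c, alt_c, changed = property_change(ref_aa, alt_aa, scheme)
        call.ref_property, call.alt_property = ref_c, alt_c
        call.property_changed = changed
    return call


def annotate_snps(events: Sequence[VariantEvent],
                  annotations: Sequence[FeatureAnnotation],
                  ref_seq: str,
                  scheme: dict[str, str] | None = None) -> list[EffectCall]:
    """One :class:`EffectCall` per SNP event.

    The reference allele is the reference row's base; the alternate is the
    most frequent non-reference allele (ties toward the lexicographically
    smaller base).  Pseudogenes and RNA genes are located but never
    translated.
    """
    calls: list[EffectCall] = []
    for e in events:
        if e.kind != "SNP":
            continue
        if e.ref_position is None:
            raise ValidationError(f"SNP at columns {e.columns} sits on a reference gap")
        site_id = f"col{e.columns[0]}|ref{e.ref_position}"
        context, feature = locate(e.ref_position, annotations)
        if context != "CDS":
            calls.append(EffectCall(
                site_id=site_id,
                feature_name=feature.name if feature else "intergenic",
                context=context,
            ))
            continue
        ref_base = ref_seq[e.ref_position - 1]
        counts: dict[str, int] = {}
        for a in e.observed_alleles().values():
            if a != ref_base:
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            # all observed alleles equal the reference: polymorphism is among
            # other samples' missing entries; treat the minority allele of the
            # site as alternate
            obs: dict[str, int] = {}
            for a in e.observed_alleles().values():
                obs[a] = obs.get(a, 0) + 1
            _, alt_base = _majority_minority(obs)
        else:
            alt_base = sorted(counts, key=lambda b: (-counts[b], b))[0]
        calls.append(call_effect(site_id, e.ref_position, ref_base, alt_base,
                                 feature, ref_seq, scheme))
    return calls


def count_effects(calls: Sequence[EffectCall]) -> dict[str, int]:
    """Summary counts over effect calls."""
    n_coding = sum(1 for c in calls if c.context == "CDS")
    n_nonsyn = sum(1 for c in calls if c.context == "CDS" and c.synonymous is False)
    n_prop = sum(1 for c in calls if c.property_changed)
    n_trna = sum(1 for c in calls if c.context == "tRNA")
    return {
        "n_coding": n_coding,
        "n_noncoding": len(calls) - n_coding,
        "n_nonsynonymous": n_nonsyn,
        "n_property_changed": n_prop,
        "n_in_tRNA": n_trna,
    }
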