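"""Variant detection and classification from a whole-genome alignment.

Every polymorphic alignment column is assigned to exactly one event, with
classification precedence Inversion > HomopolymerDiff > InDel > SNP:

* **InDel** — one maximal run of columns in which at least one row is gapped
  counts as a single event (events, not columns, are what gets counted).
* **HomopolymerDiff** — an InDel event whose varying bases are all identical
  to the adjacent reference base and whose mononucleotide run in the
  reference is at least ``homopolymer_min_run`` long.  Chloroplast poly-A/T
  stretches routinely differ in length between individuals and behave
  differently from ordinary InDels in downstream marker design, so they are
  counted apart.
* **Inversion** — a maximal run of >= ``inversion_min_span`` consecutive
  substitution columns whose two observed allele strings are reverse
  complements of each other (the short stem-loop flip seen between organelle
  haplotypes).  Its columns are excluded from the SNP count.
* **SNP** — a single gap-free column with >= 2 distinct bases among
  non-missing entries.

Missing data (N, or a gap inside an otherwise substitution-type column) is
recorded as '?' for that sample; a column with fewer than two observed
states is invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    BASES,
    GAP,
    MISSING,
    GenomeAlignment,
    SnpMatrix,
    ValidationError,
    revcomp,
)

TRANSITIONS = ({"A", "G"}, {"C", "T"})

_GAP_B = ord(GAP)
_N_B = ord("N")
_BASE_BYTES = tuple(ord(b) for b in BASES)


@dataclass
class ScanConfig:
    """Thresholds for event classification.

    homopolymer_min_run
        Minimum length of the reference mononucleotide run for an InDel to
        be reclassified as a homopolymer-length difference (default 4).
    inversion_min_span
        Minimum number of consecutive substitution columns that may form a
        reverse-complement inversion (default 2; a single A<->T column is a
        SNP, not an inversion).
    """

    homopolymer_min_run: int = 4
    inversion_min_span: int = 2


@dataclass
class VariantEvent:
    """One classified variation locus with per-sample alleles.

    ``columns`` is the 1-based closed span of alignment columns;
    ``ref_position`` is the reference coordinate of the first column (None
    when the reference row is gapped there).  Alleles are strings — a single
    base for SNPs, the block content for InDels/inversions ('' for a full
    deletion), '?' for missing.
    """

    kind: str
    columns: tuple[int, int]
    ref_position: int | None
    alleles: dict[str, str]
    is_singleton: bool | None = None
    substitution_class: str | None = None

    def observed_alleles(self) -> dict[str, str]:
        return {s: a for s, a in self.alleles.items() if a != MISSING}


def classify_substitution(base_a: str, base_b: str) -> str:
    """'transition' for purine<->purine / pyrimidine<->pyrimidine pairs,
    'transversion' otherwise.  Symmetric; identical or non-ACGT input is an
    error."""
    if base_a not in BASES or base_b not in BASES:
        raise ValidationError(f"bases must be in {BASES}, got {base_a!r}, {base_b!r}")
    if base_a == base_b:
        raise ValidationError(f"identical bases {base_a!r} do not form a substitution")
    return "transition" if {base_a, base_b} in TRANSITIONS else "transversion"


def _majority_minority(counts: dict[str, int]) -> tuple[str, str]:
    """Majority and minority allele of a site; ties broken toward the
    lexicographically smaller base being *minor*."""
    by_count: dict[int, list[str]] = {}
    for b, c in counts.items():
        by_count.setdefault(c, []).append(b)
    ordered_counts = sorted(by_count, reverse=True)
    top = ordered_counts[0]
    top_bases = sorted(by_count[top])
    if len(top_bases) >= 2:
        # tie at the top: smaller base is minor, larger is major
        major = top_bases[-1]
        minor = top_bases[0]
    else:
        major = top_bases[0]
        rest = sorted((b for b in counts if b != major), key=lambda b: (-counts[b], b))
        minor = rest[0]
    return major, minor


def scan_alignment(alignment: GenomeAlignment,
                   config: ScanConfig | None = None) -> list[VariantEvent]:
    """Detect and classify all variation events, ordered by column."""
    config = config or ScanConfig()
    sample_ids = alignment.sample_ids
    arr = np.frombuffer(
        "".join(alignment.rows[s] for s in sample_ids).encode("ascii"), dtype=np.uint8
    ).reshape(len(sample_ids), alignment.length)

    is_gap = arr == _GAP_B
    gap_col = is_gap.any(axis=0)
    present = np.zeros(alignment.length, dtype=np.int8)
    base_here = {}
    for b in _BASE_BYTES:
        hit = (arr == b).any(axis=0)
        base_here[b] = hit
        present += hit
    poly_sub_col = (present >= 2) & ~gap_col  # substitution-type columns

    events: list[VariantEvent] = []
    events.extend(_gap_run_events(arr, gap_col, alignment, config, sample_ids))
    events.extend(_substitution_events(arr, poly_sub_col, alignment, config, sample_ids))
    events.sort(key=lambda e: e.columns[0])
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True-runs of a boolean vector as 0-based closed (start, end)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _block_alleles(arr: np.ndarray, c1: int, c2: int,
                   sample_ids: list[str]) -> dict[str, str]:
    """Per-sample block content with gaps removed; '?' when N is present."""
    alleles: dict[str, str] = {}
    for i, sid in enumerate(sample_ids):
        chunk = arr[i, c1:c2 + 1]
        if (chunk == _N_B).any():
            alleles[sid] = MISSING
        else:
            alleles[sid] = chunk[chunk != _GAP_B].tobytes().decode("ascii")
    return alleles


def _gap_run_events(arr, gap_col, alignment, config, sample_ids):
    """Each maximal gapped-column run is one InDel-type event."""
    events = []
    ref_idx = sample_ids.index(alignment.reference_id)
    ref = arr[ref_idx]
    for c1, c2 in _runs(gap_col):
        alleles = _block_alleles(arr, c1, c2, sample_ids)
        block = arr[:, c1:c2 + 1]
        bases_in_block = {b for b in _BASE_BYTES if (block == b).any()}
        kind = "InDel"
        if len(bases_in_block) == 1:
            x = next(iter(bases_in_block))
            run = int((block[ref_idx] == x).sum())
            j = c1 - 1
            while j >= 0 and ref[j] == x:
                run += 1
                j -= 1
            j = c2 + 1
            while j < ref.size and ref[j] == x:
                run += 1
                j += 1
            if run >= config.homopolymer_min_run:
                kind = "HomopolymerDiff"
        events.append(VariantEvent(
            kind=kind,
            columns=(c1 + 1, c2 + 1),
            ref_position=alignment.map_column_to_reference(c1 + 1),
            alleles=alleles,
        ))
    return events


def _substitution_events(arr, poly_sub_col, alignment, config, sample_ids):
    events = []
    for c1, c2 in _runs(poly_sub_col):
        span = c2 - c1 + 1
        if span >= config.inversion_min_span:
            alleles = _block_alleles(arr, c1, c2, sample_ids)
            distinct = sorted(set(alleles.values()) - {MISSING})
            if len(distinct) == 2 and distinct[0] == revcomp(distinct[1]):
                events.append(VariantEvent(
                    kind="Inversion",
                    columns=(c1 + 1, c2 + 1),
                    ref_position=alignment.map_column_to_reference(c1 + 1),
                    alleles=alleles,
                ))
                continue
        for c in range(c1, c2 + 1):
            events.append(_snp_event(arr, c, alignment, sample_ids))
    return events


def _snp_event(arr, c, alignment, sample_ids):
    col = arr[:, c]
    alleles: dict[str, str] = {}
    counts: dict[str, int] = {}
    for i, sid in enumerate(sample_ids):
        ch = chr(col[i])
        if ch in ("N", GAP):
            alleles[sid] = MISSING
        else:
            alleles[sid] = ch
            counts[ch] = counts.get(ch, 0) + 1
    major, minor = _majority_minority(counts)
    n_nonmajor = sum(v for b, v in counts.items() if b != major)
    sub_class = classify_substitution(major, minor) if len(counts) == 2 else None
    return VariantEvent(
        kind="SNP",
        columns=(c + 1, c + 1),
        ref_position=alignment.map_column_to_reference(c + 1),
        alleles=alleles,
        is_singleton=(n_nonmajor == 1),
        substitution_class=sub_class,
    )


# ---------------------------------------------------------------------------
# Matrix, distances, summary
# ---------------------------------------------------------------------------


def snp_matrix_from_events(events: list[VariantEvent],
                           sample_ids: list[str] | None = None) -> SnpMatrix:
    """Allele matrix over SNP events only; site ids carry both alignment
    column and reference position (``col<column>`` / ``ref<pos>``)."""
    snps = [e for e in events if e.kind == "SNP"]
    if sample_ids is None:
        if not snps:
            raise ValidationError("no SNP events and no sample_ids given")
        sample_ids = list(snps[0].alleles)
    site_ids = [
        f"col{e.columns[0]}" if e.ref_position is None
        else f"col{e.columns[0]}|ref{e.ref_position}"
        for e in snps
    ]
    alleles = np.full((len(snps), len(sample_ids)), MISSING, dtype="U1")
    for i, e in enumerate(snps):
        for j, sid in enumerate(sample_ids):
            alleles[i, j] = e.alleles.get(sid, MISSING)
    return SnpMatrix(site_ids=site_ids, sample_ids=sample_ids, alleles=alleles)


def pairwise_differences(matrix: SnpMatrix) -> np.ndarray:
    """Symmetric (n_samples x n_samples) count of sites where both samples
    are observed and their alleles differ."""
    a = matrix.alleles
    obs = a != MISSING
    n = matrix.n_samples
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[:, i] & obs[:, j]
            d = int(np.sum(both & (a[:, i] != a[:, j])))
            out[i, j] = out[j, i] = d
    return out


_PAIR_KEYS = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")


@dataclass
class VariantSummary:
    """Aggregate statistics over a scanned alignment."""

    n_snp: int
    n_indel: int
    n_homopolymer: int
    n_inversion: int
    n_singleton: int
    ts_fraction: float
    tv_fraction: float
    pair_fractions: dict[str, float]
    gc_content: float
    unique_snps_per_sample: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_snp": self.n_snp,
            "n_indel": self.n_indel,
            "n_homopolymer": self.n_homopolymer,
            "n_inversion": self.n_inversion,
            "n_singleton": self.n_singleton,
            "ts_fraction": self.ts_fraction,
            "tv_fraction": self.tv_fraction,
            "pair_fractions": dict(self.pair_fractions),
            "gc_content": self.gc_content,
            "unique_snps_per_sample": dict(self.unique_snps_per_sample),
        }


def summarize(alignment: GenomeAlignment,
              events: list[VariantEvent]) -> VariantSummary:
    """Counts, Ts/Tv breakdown, singletons, GC content and per-sample unique
    SNP counts.

    Multi-allelic sites contribute one unordered base pair per minority
    allele, each counted against the site's majority allele.  GC content is
    computed over the reference row's non-gap bases.  A sample's *unique*
    SNPs are the sites where it alone carries a non-majority allele.
    """
    kinds = {"SNP": 0, "InDel": 0, "HomopolymerDiff": 0, "Inversion": 0}
    pair_counts = {k: 0 for k in _PAIR_KEYS}
    n_singleton = 0
    unique: dict[str, int] = {sid: 0 for sid in alignment.sample_ids}
    for e in events:
        kinds[e.kind] += 1
        if e.kind != "SNP":
            continue
        if e.is_singleton:
            n_singleton += 1
        counts: dict[str, int] = {}
        for a in e.observed_alleles().values():
            counts[a] = counts.get(a, 0) + 1
        major, _ = _majority_minority(counts)
        for b in counts:
            if b == major:
                continue
            key = "/".join(sorted((major, b)))
            pair_counts[key] += 1
        carriers = [s for s, a in e.observed_alleles().items() if a != major]
        if len(carriers) == 1:
            unique[carriers[0]] += 1
    total_pairs = sum(pair_counts.values())
    if total_pairs:
        pair_fractions = {k: v / total_pairs for k, v in pair_counts.items()}
        ts = pair_fractions["A/G"] + pair_fractions["C/T"]
        tv = 1.0 - ts
    else:
        pair_fractions = {k: 0.0 for k in _PAIR_KEYS}
        ts = tv = 0.0
    ref = alignment.reference_sequence()
    gc = (ref.count("G") + ref.count("C")) / len(ref) if ref else 0.0
    return VariantSummary(
        n_snp=kinds["SNP"], n_indel=kinds["InDel"],
        n_homopolymer=kinds["HomopolymerDiff"], n_inversion=kinds["Inversion"],
        n_singleton=n_singleton, ts_fraction=ts, tv_fraction=tv,
        pair_fractions=pair_fractions, gc_content=gc,
        unique_snps_per_sample=unique,
    )
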