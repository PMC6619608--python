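"""Synthetic alignment sets and mitochondrial-style matrices with a known
planted truth table.

The generator emulates the study conditions of a small organelle resequencing
survey at desk scale: 19 individuals in three geographic groups (12/4/3), a
~20 kb circular genome with annotated genes (one multi-exon, one on the
reverse strand, plus a tRNA and a pseudogene), and planted variation — SNPs
with a configurable transition:transversion mix, InDels, homopolymer-length
differences, one short reverse-complement (stem-loop) inversion with
inverted-repeat arms, group-diagnostic alleles, missingness and paralog
contamination for the mitochondrial-like matrix.

Planted loci are mutually disjoint, kept away from alignment ends, and
spaced so that no two events merge into one: every planted event is
recoverable exactly (kind, span, per-sample alleles) by the scanner.
Sequence construction uses integer draws only, so a fixed seed reproduces
bit-identical output on any platform.

Deliberate simplifications (see the methods note): InDels and homopolymer
contractions are planted as deletions relative to the reference row, which
therefore stays ungapped and keeps alignment columns identical to reference
coordinates; no event spans the circular origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    BASES,
    GAP,
    MISSING,
    FeatureAnnotation,
    GenomeAlignment,
    SampleRecord,
    SnpMatrix,
    ValidationError,
    revcomp,
    write_alignment,
    write_gff3,
    write_sample_table,
    write_snp_matrix,
)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c for a in BASES for b in BASES for c in BASES if a + b + c not in _STOPS
)

_REGION_GEO = {
    # (lat, lon) anchors per default region, mimicking a west-east transect
    0: (72.3, 103.0),
    1: (70.6, 132.8),
    2: (68.8, 161.2),
}
_ZONES = ("single-tree tundra", "forest-tundra", "closed forest")


@dataclass
class SimConfig:
    """Generator parameters.  Defaults are the study conditions: 19 samples
    in groups of 12/4/3, a 20 kb genome, 84 SNPs / 5 InDels / 17 homopolymer
    differences / 1 three-nucleotide inversion, 44% transitions, 8
    group-diagnostic sites, GC content 0.3874."""

    seed: int = 0
    n_samples: int = 19
    group_sizes: tuple[int, ...] = (12, 4, 3)
    group_names: tuple[str, ...] = ("Taymyr", "Omoloy", "Kolyma")
    species_ranges: tuple[str, ...] = ("L. gmelinii", "L. cajanderi", "L. cajanderi")
    genome_length: int = 20000
    n_snp: int = 84
    n_indel: int = 5
    n_homopolymer: int = 17
    n_inversion: int = 1
    transition_prob: float = 0.44
    n_diagnostic: int = 8
    missing_rate: float = 0.12
    n_paralog_loci: int = 2
    n_genes: int = 6
    gc_content: float = 0.3874
    inversion_span: int = 3
    inversion_arm: int = 5
    n_mito_sites: int = 213
    mito_locus_count: int = 8
    margin: int = 50
    min_spacing: int = 12

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_samples:
            raise ValidationError(
                f"group_sizes {self.group_sizes} do not sum to n_samples {self.n_samples}"
            )
        if len(self.group_sizes) != len(self.group_names):
            raise ValidationError("group_sizes and group_names differ in length")
        if self.n_diagnostic > self.n_snp:
            raise ValidationError("n_diagnostic cannot exceed n_snp")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.transition_prob <= 1.0:
            raise ValidationError("transition_prob must be in [0, 1]")
        if self.inversion_span < 2:
            raise ValidationError("inversion_span must be >= 2")
        if self.n_paralog_loci > self.mito_locus_count:
            raise ValidationError("n_paralog_loci cannot exceed mito_locus_count")
        if self.n_diagnostic > self.n_mito_sites:
            raise ValidationError("n_diagnostic cannot exceed n_mito_sites")


@dataclass
class TruthTable:
    """Planted ground truth: one entry per event, JSON-serialisable."""

    events: list[dict] = field(default_factory=list)
    site_locus: dict[str, str] = field(default_factory=dict)
    paralog_loci: list[str] = field(default_factory=list)
    filter_verdicts: dict[str, bool] = field(default_factory=dict)
    outgroup_id: str | None = None

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e["kind"]] = out.get(e["kind"], 0) + 1
        return out

    def of_kind(self, kind: str) -> list[dict]:
        return [e for e in self.events if e["kind"] == kind]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "events": self.events,
            "site_locus": self.site_locus,
            "paralog_loci": self.paralog_loci,
            "filter_verdicts": self.filter_verdicts,
            "outgroup_id": self.outgroup_id,
        }, indent=1))


def sample_codes(config: SimConfig) -> list[str]:
    codes = []
    for gi, (name, size) in enumerate(zip(config.group_names, config.group_sizes)):
        prefix = "".join(ch for ch in name.upper() if ch.isalpha())[:2] or f"G{gi}"
        codes.extend(f"{prefix}{i + 1:02d}" for i in range(size))
    return codes


def sample_metadata(config: SimConfig, rng: np.random.Generator) -> list[SampleRecord]:
    records = []
    codes = sample_codes(config)
    k = 0
    for gi, (name, size) in enumerate(zip(config.group_names, config.group_sizes)):
        lat0, lon0 = _REGION_GEO.get(gi, (65.0 + 3 * gi, 100.0 + 25 * gi))
        srange = config.species_ranges[gi] if gi < len(config.species_ranges) else ""
        for i in range(size):
            jlat = int(rng.integers(-4000, 4000)) / 10000.0
            jlon = int(rng.integers(-4000, 4000)) / 10000.0
            records.append(SampleRecord(
                sample_code=codes[k],
                region=name,
                site=f"{codes[k][:2]}S{i // 3 + 1}",
                latitude=round(lat0 + jlat, 5),
                longitude=round(lon0 + jlon, 5),
                vegetation_zone=_ZONES[i % len(_ZONES)],
                species_range=srange,
                accession="",
            ))
            k += 1
    return records


# ---------------------------------------------------------------------------
# Reference sequence and gene layout
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Random bases with the given GC proportion; integer draws only."""
    thr = int(round(gc * 1_000_000))
    r = rng.integers(0, 1_000_000, size=n)
    half = rng.integers(0, 2, size=n)
    out = np.empty(n, dtype="U1")
    gcmask = r < thr
    out[gcmask & (half == 0)] = "G"
    out[gcmask & (half == 1)] = "C"
    out[~gcmask & (half == 0)] = "A"
    out[~gcmask & (half == 1)] = "T"
    return out


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + TAA."""
    inner = [
        _SENSE_CODONS[int(i)]
        for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    ]
    return "ATG" + "".join(inner) + "TAA"


def _plant_genes(ref: np.ndarray, config: SimConfig,
                 rng: np.random.Generator) -> list[FeatureAnnotation]:
    """Lay out genes (first multi-exon, second reverse-strand), a tRNA and a
    pseudogene, writing codon-valid content into the reference."""
    L = config.genome_length
    n_slots = config.n_genes + 2
    usable = L - 2 * config.margin
    if usable < n_slots * 450:  # max gene extent is ~417 nt incl. intron
        raise ValidationError("genome_length too small for the gene layout")
    slot = usable // n_slots
    features: list[FeatureAnnotation] = []
    for i in range(config.n_genes):
        start = config.margin + i * slot + 1  # 1-based
        n_codons = 60 + int(rng.integers(0, 60))
        cds = _random_cds(rng, n_codons)
        if i == 0:
            # two exons with an intron between them
            split = (len(cds) // 2) + 1  # deliberately off the codon boundary
            intron_len = 60
            e1 = (start, start + split - 1)
            iv_intron = (e1[1] + 1, e1[1] + intron_len)
            e2 = (iv_intron[1] + 1, iv_intron[1] + (len(cds) - split))
            ref[e1[0] - 1:e1[1]] = list(cds[:split])
            ref[e2[0] - 1:e2[1]] = list(cds[split:])
            features.append(FeatureAnnotation(
                name=f"gene{i + 1}", kind="gene", strand="+",
                intervals=[e1, e2]))
            features.append(FeatureAnnotation(
                name=f"gene{i + 1}-intron", kind="intron", strand="+",
                intervals=[iv_intron]))
        elif i == 1:
            iv = (start, start + len(cds) - 1)
            ref[iv[0] - 1:iv[1]] = list(revcomp(cds))
            features.append(FeatureAnnotation(
                name=f"gene{i + 1}", kind="gene", strand="-", intervals=[iv]))
        else:
            iv = (start, start + len(cds) - 1)
            ref[iv[0] - 1:iv[1]] = list(cds)
            features.append(FeatureAnnotation(
                name=f"gene{i + 1}", kind="gene", strand="+", intervals=[iv]))
    t_start = config.margin + config.n_genes * slot + 1
    features.append(FeatureAnnotation(
        name="trnX", kind="tRNA", strand="+", intervals=[(t_start, t_start + 71)]))
    p_start = config.margin + (config.n_genes + 1) * slot + 1
    features.append(FeatureAnnotation(
        name="psi-gene", kind="pseudogene", strand="+",
        intervals=[(p_start, p_start + 89)]))
    return features


# ---------------------------------------------------------------------------
# Event placement
# ---------------------------------------------------------------------------


def _overlaps(a1: int, a2: int, blocks: list[tuple[int, int]]) -> bool:
    return any(a1 <= e and b1 <= a2 for b1, e in blocks)


def _place(rng: np.random.Generator, span: int, config: SimConfig,
           occupied: list[tuple[int, int]],
           feature_blocks: list[tuple[int, int]] | None) -> int:
    """Draw a 1-based start for an event of ``span`` columns, respecting
    margins, inter-event spacing and (optionally) feature intervals."""
    L = config.genome_length
    lo = config.margin + 1
    hi = L - config.margin - span + 1
    if hi < lo:
        raise ValidationError("genome_length too small for planted events")
    pad = config.min_spacing
    for _ in range(20000):
        s = int(rng.integers(lo, hi + 1))
        e = s + span - 1
        if _overlaps(s - pad, e + pad, occupied):
            continue
        if feature_blocks is not None and _overlaps(s - pad, e + pad, feature_blocks):
            continue
        occupied.append((s, e))
        return s
    raise ValidationError(
        "infeasible config: could not place all events disjointly"
    )


def _pick_carriers(rng: np.random.Generator, n_samples: int,
                   singleton_bias: bool = True) -> np.ndarray:
    """Indices of non-reference samples carrying the variant (1..n-1 of
    them).  Mostly singletons, echoing real organelle data."""
    candidates = np.arange(1, n_samples)  # sample 0 is the reference row
    if singleton_bias and int(rng.integers(0, 100)) < 60:
        k = 1
    else:
        k = 2 + int(rng.integers(0, max(1, n_samples - 3)))
        k = min(k, n_samples - 2)
    return np.sort(rng.choice(candidates, size=k, replace=False))


def _expected_protein_effect(ref: np.ndarray, position: int, alt: str,
                             features: list[FeatureAnnotation]) -> dict | None:
    """Ground-truth coding effect of a SNP, derived by mutating the whole
    reference and diffing the translated proteins (independent of the
    single-codon arithmetic used by the effect annotator)."""
    from .effects import spliced_cds, translate_cds  # local import, no cycle

    gene = next((f for f in features if f.kind == "gene" and f.contains(position)), None)
    if gene is None:
        return None
    ref_seq = "".join(ref)
    prot_ref = translate_cds(spliced_cds(gene, ref_seq))
    mutated = ref_seq[:position - 1] + alt + ref_seq[position:]
    prot_alt = translate_cds(spliced_cds(gene, mutated))
    diff = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    if not diff:
        return {"feature": gene.name, "synonymous": True}
    i = diff[0]
    return {"feature": gene.name, "synonymous": False,
            "codon_index": i + 1, "ref_aa": prot_ref[i], "alt_aa": prot_alt[i]}


def simulate_alignment_set(
    config: SimConfig,
) -> tuple[GenomeAlignment, list[FeatureAnnotation], list[SampleRecord], TruthTable]:
    """Generate an aligned sample set with planted, exactly recoverable
    variation.  Same seed, same bytes."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    ref = _random_bases(rng, L, config.gc_content)
    features = _plant_genes(ref, config, rng)
    feature_blocks = sorted(
        iv for f in features for iv in (sorted(f.intervals))
    )
    occupied: list[tuple[int, int]] = []
    truth = TruthTable()
    codes = sample_codes(config)
    n = config.n_samples
    group_of = np.repeat(np.arange(len(config.group_sizes)),
                         np.array(config.group_sizes))

    # ---- choose loci and realise reference-side content first -------------
    snp_plan = []
    for i in range(config.n_snp):
        diagnostic = i < config.n_diagnostic
        if diagnostic:
            # reserve a conserved 40-nt context either side so that a short
            # amplicon with invariant primer flanks can be designed
            ctx = 40
            s = _place(rng, 2 * ctx + 1, config, occupied, None) + ctx
        else:
            s = _place(rng, 1, config, occupied, None)  # SNPs may fall in genes
        snp_plan.append((s, diagnostic))
    indel_plan = []
    for _ in range(config.n_indel):
        span = 2 + int(rng.integers(0, 5))
        s = _place(rng, span, config, occupied, feature_blocks)
        seg = _random_bases(rng, span, 0.5)
        if len(set(seg)) == 1:  # block must not look homopolymeric
            seg[-1] = _TRANSITION[str(seg[0])]
        ref[s - 1:s - 1 + span] = seg
        indel_plan.append((s, span))
    homopolymer_plan = []
    for _ in range(config.n_homopolymer):
        run = 5 + int(rng.integers(0, 3))
        s = _place(rng, run + 2, config, occupied, feature_blocks)  # incl. guards
        x = BASES[int(rng.integers(0, 4))]
        guard = _TRANSVERSIONS[x][0]
        ref[s - 1] = guard
        ref[s:s + run] = x
        ref[s + run] = guard
        homopolymer_plan.append((s + 1, run, x))  # run starts one past guard
    inversion_plan = []
    for _ in range(config.n_inversion):
        span = config.inversion_span
        arm = config.inversion_arm
        s = _place(rng, span + 2 * arm, config, occupied, feature_blocks)
        arm_seq = _random_bases(rng, arm, 0.5)
        while True:
            block = _random_bases(rng, span, 0.5)
            if all(block[i] != _COMP[str(block[span - 1 - i])] for i in range(span)):
                break
        ref[s - 1:s - 1 + arm] = arm_seq
        b0 = s + arm
        ref[b0 - 1:b0 - 1 + span] = block
        ref[b0 + span - 1:b0 + span - 1 + arm] = np.array(
            list(revcomp("".join(arm_seq))), dtype="U1")
        inversion_plan.append((b0, span))

    # ---- copy rows and apply per-sample changes ---------------------------
    rows = np.tile(ref, (n, 1))

    ts_thr = int(round(config.transition_prob * 1_000_000))
    for s, diagnostic in snp_plan:
        ref_base = str(ref[s - 1])
        if int(rng.integers(0, 1_000_000)) < ts_thr:
            alt = _TRANSITION[ref_base]
            sub_class = "transition"
        else:
            alt = _TRANSVERSIONS[ref_base][int(rng.integers(0, 2))]
            sub_class = "transversion"
        if diagnostic:
            carriers = np.flatnonzero(group_of != 0)  # groups 2+3 carry alt
        else:
            carriers = _pick_carriers(rng, n)
        rows[carriers, s - 1] = alt
        alleles = {codes[i]: (alt if i in set(carriers.tolist()) else ref_base)
                   for i in range(n)}
        n_alt = len(carriers)
        truth.events.append({
            "kind": "SNP", "columns": [s, s], "ref_position": s,
            "alleles": alleles, "substitution_class": sub_class,
            "is_singleton": min(n_alt, n - n_alt) == 1,
            "diagnostic": diagnostic,
            "effect": _expected_protein_effect(ref, s, alt, features),
        })
    for s, span in indel_plan:
        carriers = _pick_carriers(rng, n)
        for c in carriers:
            rows[c, s - 1:s - 1 + span] = GAP
        seg = "".join(ref[s - 1:s - 1 + span])
        alleles = {codes[i]: ("" if i in set(carriers.tolist()) else seg)
                   for i in range(n)}
        truth.events.append({
            "kind": "InDel", "columns": [s, s + span - 1], "ref_position": s,
            "alleles": alleles, "substitution_class": None,
            "is_singleton": None, "diagnostic": False, "effect": None,
        })
    for s, run, x in homopolymer_plan:
        carriers = _pick_carriers(rng, n)
        deltas = 1 + rng.integers(0, 2, size=len(carriers))
        for c, d in zip(carriers, deltas):
            rows[c, s - 1 + run - int(d):s - 1 + run] = GAP
        dmax = int(deltas.max())
        c1 = s + run - dmax  # first gapped column, 1-based
        delta_of = {int(c): int(d) for c, d in zip(carriers, deltas)}
        alleles = {}
        for i in range(n):
            d = delta_of.get(i, 0)
            alleles[codes[i]] = x * (dmax - d)
        truth.events.append({
            "kind": "HomopolymerDiff", "columns": [c1, s + run - 1],
            "ref_position": c1, "alleles": alleles, "substitution_class": None,
            "is_singleton": None, "diagnostic": False, "effect": None,
            "homopolymer_base": x, "reference_run": run,
        })
    for b0, span in inversion_plan:
        carriers = _pick_carriers(rng, n)
        block = "".join(ref[b0 - 1:b0 - 1 + span])
        inv = revcomp(block)
        for c in carriers:
            rows[c, b0 - 1:b0 - 1 + span] = list(inv)
        alleles = {codes[i]: (inv if i in set(carriers.tolist()) else block)
                   for i in range(n)}
        truth.events.append({
            "kind": "Inversion", "columns": [b0, b0 + span - 1],
            "ref_position": b0, "alleles": alleles, "substitution_class": None,
            "is_singleton": None, "diagnostic": False, "effect": None,
        })
    truth.events.sort(key=lambda e: e["columns"][0])

    alignment = GenomeAlignment(
        sample_ids=list(codes),
        rows={codes[i]: "".join(rows[i]) for i in range(n)},
        reference_id=codes[0],
        circular=True,
    )
    metadata = sample_metadata(config, rng)
    return alignment, features, metadata, truth


# ---------------------------------------------------------------------------
# Mitochondrial-style matrix with missingness and paralog contamination
# ---------------------------------------------------------------------------


def simulate_mito_matrix(
    config: SimConfig,
) -> tuple[SnpMatrix, dict[str, dict[str, list[str]]], TruthTable]:
    """Generate a site-by-individual allele matrix with planted diagnostic
    sites, seeded missingness, and paralog-contaminated locus alignments.

    The returned matrix carries one extra outgroup row (id ``OUTG``) whose
    allele at diagnostic sites is a third state, mimicking the use of a
    distant reference genome to polarize variants; exclude it from group
    screens via the ``outgroup`` argument and drop it before filtering.
    """
    rng = np.random.default_rng([config.seed, 9151])
    n = config.n_samples
    codes = sample_codes(config)
    group_of = np.repeat(np.arange(len(config.group_sizes)),
                         np.array(config.group_sizes))
    n_sites = config.n_mito_sites
    truth = TruthTable(outgroup_id="OUTG")

    site_ids = [f"site{i + 1:03d}" for i in range(n_sites)]
    alleles = np.empty((n_sites, n + 1), dtype="U1")
    diag_flags = []
    for i in range(n_sites):
        a = BASES[int(rng.integers(0, 4))]
        b = _TRANSITION[a] if int(rng.integers(0, 2)) else _TRANSVERSIONS[a][0]
        diagnostic = i < config.n_diagnostic
        if diagnostic:
            carriers = np.flatnonzero(group_of != 0)
            third = next(x for x in BASES if x not in (a, b))
            out_allele = third
        else:
            k = 2 + int(rng.integers(0, n - 3))
            carriers = rng.choice(np.arange(n), size=k, replace=False)
            out_allele = a
        row = np.full(n, a, dtype="U1")
        row[carriers] = b
        alleles[i, :n] = row
        alleles[i, n] = out_allele
        diag_flags.append(diagnostic)
        truth.events.append({
            "kind": "MitoSNP", "site_id": site_ids[i],
            "alleles": {codes[j]: str(row[j]) for j in range(n)},
            "group_allele_a": a, "group_allele_b": b,
            "diagnostic": diagnostic, "outgroup_allele": out_allele,
        })

    # missingness on the main samples only, then repair so that every site
    # keeps two observed states
    thr = int(round(config.missing_rate * 1_000_000))
    mask = rng.integers(0, 1_000_000, size=(n_sites, n)) < thr
    for i in range(n_sites):
        planted = np.array([truth.events[i]["alleles"][codes[j]] for j in range(n)])
        for state in sorted(set(planted)):
            idx = np.flatnonzero(planted == state)
            if mask[i, idx].all():
                mask[i, idx[0]] = False
    observed = alleles[:, :n].copy()
    observed[mask] = MISSING
    alleles[:, :n] = observed

    matrix = SnpMatrix(site_ids=site_ids, sample_ids=[*codes, "OUTG"],
                       alleles=alleles)

    # expected robustness verdicts on the main samples
    for i, sid in enumerate(site_ids):
        row = alleles[i, :n]
        obs = row[row != MISSING]
        _, counts = np.unique(obs, return_counts=True)
        minor = int(sorted(counts)[-2]) if len(counts) >= 2 else 0
        n_obs = int(obs.size)
        truth.filter_verdicts[sid] = (
            (n_obs == n and minor >= 2) or (n_obs >= 6 and minor >= 3)
        )

    # locus alignments: sites assigned round-robin; contaminated loci give
    # one individual a second, divergent copy
    loci = [f"locus{j + 1:02d}" for j in range(config.mito_locus_count)]
    for i, sid in enumerate(site_ids):
        truth.site_locus[sid] = loci[i % len(loci)]
    contaminated = [loci[int(j)] for j in
                    rng.choice(len(loci), size=config.n_paralog_loci, replace=False)]
    truth.paralog_loci = sorted(contaminated)
    locus_alignments: dict[str, dict[str, list[str]]] = {}
    for locus in loci:
        base_seq = "".join(_random_bases(rng, 40, 0.45))
        per_ind: dict[str, list[str]] = {c: [base_seq] for c in codes}
        if locus in contaminated:
            victim = codes[int(rng.integers(0, n))]
            pos = rng.choice(40, size=3, replace=False)
            divergent = list(base_seq)
            for p in pos:
                divergent[int(p)] = _TRANSITION[divergent[int(p)]]
            per_ind[victim] = [base_seq, "".join(divergent)]
        locus_alignments[locus] = per_ind
    return matrix, locus_alignments, truth


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------


def write_bundle(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a full synthetic input bundle (FASTA/GFF3/TSV/JSON) to a
    directory and return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alignment, features, metadata, truth = simulate_alignment_set(config)
    matrix, locus_alignments, mito_truth = simulate_mito_matrix(config)
    paths = {
        "alignment": outdir / "alignment.fasta",
        "annotations": outdir / "annotations.gff3",
        "metadata": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
        "mito_matrix": outdir / "mito_matrix.tsv",
        "mito_truth": outdir / "mito_truth.json",
        "loci": outdir / "mito_loci.json",
    }
    write_alignment(alignment, paths["alignment"])
    write_gff3(features, alignment.reference_id,
               len(alignment.reference_sequence()), paths["annotations"])
    write_sample_table(metadata, paths["metadata"])
    truth.to_json(paths["truth"])
    write_snp_matrix(matrix, paths["mito_matrix"])
    mito_truth.to_json(paths["mito_truth"])
    paths["loci"].write_text(json.dumps(
        {"loci": locus_alignments, "site_locus": mito_truth.site_locus}, indent=0))
    return paths
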