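"""Robustness and anti-paralogy filtering of candidate mitochondrial SNPs.

Mitochondrial contig alignments cover each site in only a subset of
individuals, and mis-assembled paralogous copies can masquerade as
polymorphism.  Two defences are applied before any site enters downstream
analyses:

* **Robustness rule** — a site is kept iff it is unambiguously observed in
  at least 6 individuals with the second allele present at least 3 times,
  or — when every individual is observed — with the second allele present at
  least twice.
* **Paralog flagging** — a locus is discarded when any single individual
  contributes two aligned sequence copies that disagree within the locus:
  a haploid, uniparentally inherited genome cannot be heterozygous, so
  intra-individual disagreement indicates falsely aligned paralogs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import MISSING, SnpMatrix, ValidationError

RULE_FULL = "full-coverage-rule"
RULE_PARTIAL = "partial-coverage-rule"
REJ_COVERAGE = "rejected-coverage"
REJ_MINOR = "rejected-minor"
REJ_PARALOG = "rejected-paralog"


@dataclass(frozen=True)
class FilterVerdict:
    site_id: str
    kept: bool
    n_observed: int
    minor_count: int
    rule_applied: str


def _site_counts(alleles: np.ndarray) -> tuple[int, int]:
    """(n_observed, second-most-frequent allele count) for one site row."""
    observed = alleles[alleles != MISSING]
    values, counts = np.unique(observed, return_counts=True)
    if len(values) < 2:
        raise ValidationError("site has fewer than 2 allele states among observed")
    ranked = sorted(counts, reverse=True)
    return int(observed.size), int(ranked[1])


def robustness_filter(matrix: SnpMatrix, n_total_samples: int,
                      paralog_sites: set[str] | None = None) -> list[FilterVerdict]:
    """Apply the robustness rule to every site; one verdict per site.

    ``n_total_samples`` is the number of sequenced individuals (>= the
    matrix sample count).  Sites named in ``paralog_sites`` are rejected
    outright as paralog-contaminated.  At multi-allelic sites the
    second-most-frequent allele's count is tested; third alleles are
    ignored.
    """
    if n_total_samples < matrix.n_samples:
        raise ValidationError(
            f"n_total_samples {n_total_samples} < matrix sample count {matrix.n_samples}"
        )
    paralog_sites = paralog_sites or set()
    verdicts: list[FilterVerdict] = []
    for i, sid in enumerate(matrix.site_ids):
        n_obs, minor = _site_counts(matrix.alleles[i])
        if sid in paralog_sites:
            verdicts.append(FilterVerdict(sid, False, n_obs, minor, REJ_PARALOG))
        elif n_obs == n_total_samples and minor >= 2:
            verdicts.append(FilterVerdict(sid, True, n_obs, minor, RULE_FULL))
        elif n_obs >= 6 and minor >= 3:
            verdicts.append(FilterVerdict(sid, True, n_obs, minor, RULE_PARTIAL))
        elif n_obs < 6:
            verdicts.append(FilterVerdict(sid, False, n_obs, minor, REJ_COVERAGE))
        else:
            verdicts.append(FilterVerdict(sid, False, n_obs, minor, REJ_MINOR))
    return verdicts


def apply_verdicts(matrix: SnpMatrix, verdicts: Sequence[FilterVerdict]) -> SnpMatrix:
    """Restrict a matrix to the kept sites, preserving order."""
    kept = {v.site_id for v in verdicts if v.kept}
    idx = [i for i, s in enumerate(matrix.site_ids) if s in kept]
    return SnpMatrix(
        site_ids=[matrix.site_ids[i] for i in idx],
        sample_ids=list(matrix.sample_ids),
        alleles=matrix.alleles[idx],
    )


def flag_paralogs(locus_alignments: Mapping[str, Mapping[str, Sequence[str]]],
                  min_mismatches: int = 1) -> set[str]:
    """Loci where some individual contributes >= 2 aligned copies that
    disagree at >= ``min_mismatches`` sites.

    ``locus_alignments`` maps locus id -> individual -> list of aligned
    (equal-length) sequences for that individual at that locus.
    """
    flagged: set[str] = set()
    for locus_id, per_ind in locus_alignments.items():
        for ind, seqs in per_ind.items():
            if len(seqs) < 2:
                continue
            for a in range(len(seqs)):
                for b in range(a + 1, len(seqs)):
                    s1, s2 = seqs[a], seqs[b]
                    if len(s1) != len(s2):
                        raise ValidationError(
                            f"unequal aligned copies for {ind!r} at locus {locus_id!r}"
                        )
                    mism = sum(1 for x, y in zip(s1, s2)
                               if x != y and x != MISSING and y != MISSING)
                    if mism >= min_mismatches:
                        flagged.add(locus_id)
        # continue scanning remaining loci
    return flagged


def complete_case_sites(matrix: SnpMatrix) -> SnpMatrix:
    """Sites observed in every sample, in the original order."""
    keep = [i for i in range(matrix.n_sites)
            if not (matrix.alleles[i] == MISSING).any()]
    return SnpMatrix(
        site_ids=[matrix.site_ids[i] for i in keep],
        sample_ids=list(matrix.sample_ids),
        alleles=matrix.alleles[keep],
    )
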