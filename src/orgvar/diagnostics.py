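"""Group-diagnostic SNP screening and ancient-DNA amplicon window checks.

A site is *diagnostic* for a two-group partition when every observed allele
in group A is one base, every observed allele in group B is a different
base, and each group is observed at least ``min_obs_per_group`` times.
Missing entries are ignored — which is why such calls are only *putatively*
diagnostic: an unobserved individual could still violate the partition.
An optional outgroup sample is excluded from the test; its allele is
recorded to polarize the variants (which base is putatively ancestral).

For assay design on degraded (sedimentary ancient) DNA, a diagnostic site
is only usable if it can sit inside a short amplicon — 60–150 bp — whose
terminal primer-landing flanks are invariant across all individuals and
gap-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import GAP, MISSING, GenomeAlignment, SnpMatrix, ValidationError


@dataclass(frozen=True)
class DiagnosticCall:
    site_id: str
    group_a_allele: str | None
    group_b_allele: str | None
    n_observed_a: int
    n_observed_b: int
    outgroup_allele: str | None
    diagnostic: bool


def find_diagnostic_snps(matrix: SnpMatrix,
                         groups: Mapping[str, Sequence[str]],
                         min_obs_per_group: int = 2,
                         outgroup: str | None = None) -> list[DiagnosticCall]:
    """Screen every site for a perfect two-group allele partition.

    ``groups`` maps exactly two group labels to sample-id lists that
    partition the matrix samples (minus the optional ``outgroup``).  One
    call per site is returned; ``diagnostic`` is True only for sites with
    unanimous, distinct alleles in both groups and enough observations.
    """
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {len(groups)}")
    if min_obs_per_group < 1:
        raise ValidationError("min_obs_per_group must be >= 1")
    (label_a, ids_a), (label_b, ids_b) = groups.items()
    known = set(matrix.sample_ids)
    for sid in [*ids_a, *ids_b]:
        if sid not in known:
            raise ValidationError(f"group references unknown sample {sid!r}")
    if outgroup is not None and outgroup not in known:
        raise ValidationError(f"outgroup {outgroup!r} not in matrix")
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValidationError(f"samples in both groups: {sorted(overlap)}")
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    ja = [col[s] for s in ids_a]
    jb = [col[s] for s in ids_b]
    jo = col[outgroup] if outgroup is not None else None

    calls: list[DiagnosticCall] = []
    for i, site in enumerate(matrix.site_ids):
        row = matrix.alleles[i]
        obs_a = [row[j] for j in ja if row[j] != MISSING]
        obs_b = [row[j] for j in jb if row[j] != MISSING]
        set_a, set_b = set(obs_a), set(obs_b)
        allele_a = obs_a[0] if len(set_a) == 1 else None
        allele_b = obs_b[0] if len(set_b) == 1 else None
        diagnostic = (
            allele_a is not None and allele_b is not None
            and allele_a != allele_b
            and len(obs_a) >= min_obs_per_group
            and len(obs_b) >= min_obs_per_group
        )
        out_allele = None
        if jo is not None and row[jo] != MISSING:
            out_allele = str(row[jo])
        calls.append(DiagnosticCall(
            site_id=site,
            group_a_allele=str(allele_a) if allele_a is not None else None,
            group_b_allele=str(allele_b) if allele_b is not None else None,
            n_observed_a=len(obs_a), n_observed_b=len(obs_b),
            outgroup_allele=out_allele, diagnostic=diagnostic,
        ))
    return calls


@dataclass(frozen=True)
class AmpliconWindow:
    site_id: str
    window: tuple[int, int] | None  # 1-based closed reference interval
    length: int
    left_flank_conserved: bool
    right_flank_conserved: bool
    usable: bool
    reason: str = ""


def _conserved_columns(alignment: GenomeAlignment) -> np.ndarray:
    """Columns identical across all samples, gap- and N-free."""
    arr = np.frombuffer(
        "".join(alignment.rows[s] for s in alignment.sample_ids).encode("ascii"),
        dtype=np.uint8,
    ).reshape(alignment.n_samples, alignment.length)
    same = (arr == arr[0]).all(axis=0)
    clean = ((arr != ord(GAP)) & (arr != ord("N"))).all(axis=0)
    return same & clean


def evaluate_amplicon_window(site_id: str, site_column: int,
                             alignment: GenomeAlignment,
                             flank_len: int = 20,
                             min_len: int = 60,
                             max_len: int = 150,
                             conserved: np.ndarray | None = None) -> AmpliconWindow:
    """Find the shortest usable amplicon window around a site.

    Windows of length ``min_len``..``max_len`` (alignment columns) that
    contain the site are tried shortest-first, placements nearest to
    centered first; a window is usable when its two terminal ``flank_len``
    stretches are conserved across all samples.  The returned interval is
    in reference coordinates.
    """
    if flank_len < 1:
        raise ValidationError("flank_len must be >= 1")
    L = alignment.length
    if conserved is None:
        conserved = _conserved_columns(alignment)
    c0 = site_column - 1  # 0-based
    if c0 < flank_len or c0 >= L - flank_len:
        return AmpliconWindow(site_id, None, 0, False, False, False,
                              reason="site within flank_len of alignment end")
    # prefix sums for O(1) conserved-run checks
    csum = np.concatenate(([0], np.cumsum(conserved.astype(int))))

    def run_conserved(a: int, b: int) -> bool:  # 0-based closed
        return csum[b + 1] - csum[a] == b - a + 1

    best = None
    for w in range(min_len, max_len + 1):
        starts = range(max(0, c0 - w + 1), min(c0, L - w) + 1)
        center_target = c0 - (w - 1) / 2
        for s in sorted(starts, key=lambda s: (abs(s - center_target), s)):
            e = s + w - 1
            left_ok = run_conserved(s, s + flank_len - 1)
            right_ok = run_conserved(e - flank_len + 1, e)
            if left_ok and right_ok:
                best = (s, e)
                break
        if best:
            break
    if best is None:
        # report flank status of the centered min_len window for diagnosis
        s = max(0, min(c0 - (min_len - 1) // 2, L - min_len))
        e = s + min_len - 1
        return AmpliconWindow(
            site_id, None, 0,
            run_conserved(s, s + flank_len - 1),
            run_conserved(e - flank_len + 1, e),
            False, reason="no conserved-flank window within length bounds",
        )
    s, e = best
    p1 = alignment.map_column_to_reference(s + 1)
    p2 = alignment.map_column_to_reference(e + 1)
    return AmpliconWindow(site_id, (p1, p2), e - s + 1, True, True, True)


def write_amplicon_bed(windows: Sequence[AmpliconWindow], reference_id: str,
                       path) -> int:
    """Usable windows as BED (0-based half-open).  Returns the line count."""
    lines = []
    for w in windows:
        if w.usable and w.window:
            lines.append(f"{reference_id}\t{w.window[0] - 1}\t{w.window[1]}\t{w.site_id}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return len(lines)
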