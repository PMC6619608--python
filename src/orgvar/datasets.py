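"""Bundled desk-scale reference data from the northern-larch organelle
resequencing survey.

Three small tables ship with the package:

* ``larch_samples.tsv`` — the 19 sequenced individuals with region
  (Taymyr / Omoloy / Kolyma), site, coordinates, vegetation zone, published
  species range and deposited genome accession.
* ``mito_diagnostic_sites.tsv`` — the published genotype matrix of eight
  putatively group-diagnostic mitochondrial SNP positions (site ids are
  ``scf<scaffold>:<position>`` on the Picea glauca reference scaffolds),
  with '-' where an individual's contigs did not cover the site, plus the
  Picea glauca reference row used as outgroup.
* ``nonsyn_substitutions.tsv`` — the eight chloroplast non-synonymous
  substitutions with their published amino-acid property classes.  The
  source table's idiosyncratic label for the cysteine class is normalised
  to ``special``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import SampleRecord, SnpMatrix, read_sample_table, read_snp_matrix

OUTGROUP_ID = "Picea_glauca"


def _data_path(name: str):
    return resources.files("orgvar.data").joinpath(name)


def load_sample_metadata() -> list[SampleRecord]:
    """The 19 sequenced larch individuals."""
    with resources.as_file(_data_path("larch_samples.tsv")) as p:
        return read_sample_table(p)


def load_mito_diagnostic_matrix() -> SnpMatrix:
    """The published mitochondrial genotype matrix (19 individuals plus the
    ``Picea_glauca`` outgroup row; missing entries as '?')."""
    with resources.as_file(_data_path("mito_diagnostic_sites.tsv")) as p:
        return read_snp_matrix(p, missing_char="-")


def load_nonsyn_substitutions() -> pd.DataFrame:
    """The eight published chloroplast amino-acid substitutions with their
    property classes."""
    with resources.as_file(_data_path("nonsyn_substitutions.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"protein_position": int})


def region_groups(records: list[SampleRecord],
                  group_a: str = "Taymyr") -> dict[str, list[str]]:
    """Two-group partition of sample codes by region: ``group_a`` vs the
    union of all other regions."""
    ids_a = [r.sample_code for r in records if r.region == group_a]
    ids_b = [r.sample_code for r in records if r.region != group_a]
    label_b = "+".join(sorted({r.region for r in records if r.region != group_a}))
    return {group_a: ids_a, label_b or "other": ids_b}
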