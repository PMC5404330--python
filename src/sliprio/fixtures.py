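"""Packaged worked-example fixtures.

Three small dialect-conformant variant tables ship with the package, holding
the published worked examples of the cohort analysis:

* ``candidate_shortlist`` — the 11 validated novel/rare candidate-gene
  variants (the multi-carrier ATP2C2 substitution occupies one row with
  three carriers);
* ``stopgain_validated`` — the 7 validated rare stop-gain variants, with a
  companion protein-annotation table (stop codon position, isoform length)
  for truncation reporting;
* ``multivariant_genes`` — the 25 variant records over the 11 genes carrying
  two or more rare/novel variants in one proband;

plus the 19-gene candidate list and the published overall tier tallies for
the common and low-frequency candidate-gene calls (which cannot be
reconstructed from the shortlist, as it holds only novel/rare records).
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

from .io import PathLike, read_gene_list, read_variant_table
from .models import AnnotatedVariant, CarrierMap, FrequencyTier, VariantKey

FIXTURE_FILES = (
    "candidate_shortlist.tsv",
    "stopgain_validated.tsv",
    "stopgain_protein.tsv",
    "multivariant_genes.tsv",
    "candidate_genes.txt",
    "candidate_tier_counts.tsv",
)


def _data_path(name: str) -> Path:
    return Path(resources.files("sliprio").joinpath("data", name))


def load_candidate_genes() -> list[str]:
    return read_gene_list(_data_path("candidate_genes.txt"))


def load_candidate_shortlist() -> tuple[list[AnnotatedVariant], CarrierMap]:
    return read_variant_table(_data_path("candidate_shortlist.tsv"))


def load_stopgain_table() -> tuple[list[AnnotatedVariant], CarrierMap]:
    return read_variant_table(_data_path("stopgain_validated.tsv"))


def load_multivariant_table() -> tuple[list[AnnotatedVariant], CarrierMap]:
    return read_variant_table(_data_path("multivariant_genes.tsv"))


def load_protein_annotations() -> dict[VariantKey, tuple[int, int]]:
    """Stop-codon position and isoform length per truncating variant."""
    annotations: dict[VariantKey, tuple[int, int]] = {}
    with open(_data_path("stopgain_protein.tsv"), "rt", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            chrom, pos, ref, alt, stop_pos, length = line.split()
            annotations[(chrom, int(pos), ref, alt)] = (int(stop_pos), int(length))
    return annotations


def load_reported_tier_counts() -> dict[FrequencyTier, int]:
    """Published common/low-frequency candidate-gene call tallies."""
    counts: dict[FrequencyTier, int] = {}
    with open(_data_path("candidate_tier_counts.tsv"), "rt", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            tier, count = line.split()
            counts[FrequencyTier(tier)] = int(count)
    return counts


def emit_fixture_tables(outdir: PathLike) -> list[Path]:
    """Copy every packaged fixture into ``outdir``; return the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURE_FILES:
        dest = outdir / name
        shutil.copyfile(_data_path(name), dest)
        written.append(dest)
    return written
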