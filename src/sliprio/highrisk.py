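"""High-risk screens: stop-gains, compound-het candidates, multiple-hit probands.

The stop-gain screen retains rare/novel predicted-deleterious truncating
variants.  The compound-het screen groups qualifying rare/novel deleterious
coding variants by (proband, gene) and keeps groups of two or more after
removing proximity-clustered variants (both members of a pair closer than the
proximity cut are dropped — such clusters are typical alignment artefacts).
Phasing of the surviving groups is done by the segregation module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .filters import FilterConfig, frequency_tier, is_deleterious, truncation_fraction
from .models import (
    CODING_CLASSES,
    AnnotatedVariant,
    CarrierMap,
    FrequencyTier,
    FuncClass,
    Genotype,
)
from .segregation import Phase

TRUNCATING_CLASSES = frozenset(
    {FuncClass.stopgain, FuncClass.stoploss, FuncClass.frameshift_ins, FuncClass.frameshift_del}
)

RARE_OR_NOVEL = (FrequencyTier.novel, FrequencyTier.rare)


@dataclass
class StopgainRecord:
    variant: AnnotatedVariant
    tier: FrequencyTier
    carriers: tuple[str, ...]
    truncation_pct: Optional[float] = None


@dataclass
class CompHetCandidate:
    proband: str
    gene: str
    variants: list[AnnotatedVariant]
    phase: Phase = Phase.unknown


@dataclass
class MultiHitReport:
    proband: str
    hits: list[tuple[str, str, tuple]] = field(default_factory=list)
    # (category in {candidate_gene, stopgain, comphet_gene}, gene, variant keys)


def stopgain_screen(
    variants: list[AnnotatedVariant],
    carriers: CarrierMap,
    cfg: FilterConfig | None = None,
    protein_annotations: dict[tuple, tuple[int, int]] | None = None,
) -> list[StopgainRecord]:
    """Retain rare/novel deleterious truncating variants, sorted by position.

    ``protein_annotations`` optionally maps variant keys to
    (stop_aa_pos, protein_length) pairs used to annotate the percent of
    protein missing.
    """
    cfg = cfg or FilterConfig()
    records: list[StopgainRecord] = []
    for v in variants:
        if v.func_class not in TRUNCATING_CLASSES:
            continue
        tier = frequency_tier(v, cfg)
        if tier not in RARE_OR_NOVEL or not is_deleterious(v, cfg):
            continue
        truncation = None
        if protein_annotations and v.key in protein_annotations:
            stop_pos, length = protein_annotations[v.key]
            truncation = truncation_fraction(stop_pos, length)
        records.append(
            StopgainRecord(
                variant=v,
                tier=tier,
                carriers=carriers.get(v.key, ()),
                truncation_pct=truncation,
            )
        )
    records.sort(key=lambda r: (r.variant.chrom, r.variant.pos))
    return records


def comphet_qualifies(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """A variant qualifies for comphet grouping: coding class, rare/novel,
    predicted deleterious, outside segmental duplications."""
    return (
        v.func_class in CODING_CLASSES
        and v.func_class is not FuncClass.nonframeshift_indel
        and not v.segdup
        and frequency_tier(v, cfg) in RARE_OR_NOVEL
        and is_deleterious(v, cfg)
    )


def _prune_proximal(
    group: list[AnnotatedVariant], proximity_bp: int
) -> list[AnnotatedVariant]:
    """Drop *both* members of every same-chromosome pair closer than the cut."""
    too_close: set[tuple] = set()
    for a, b in combinations(group, 2):
        if a.chrom == b.chrom and abs(a.pos - b.pos) <= proximity_bp:
            too_close.add(a.key)
            too_close.add(b.key)
    return [v for v in group if v.key not in too_close]


def comphet_candidates(
    variants: list[AnnotatedVariant],
    carriers: CarrierMap,
    cfg: FilterConfig | None = None,
) -> list[CompHetCandidate]:
    """Group qualifying variants by (proband, gene); keep groups of size >= 2.

    Output order is deterministic (sorted by proband then gene) and invariant
    to input row order; phase is left unknown for the segregation module.
    """
    cfg = cfg or FilterConfig()
    groups: dict[tuple[str, str], dict[tuple, AnnotatedVariant]] = {}
    for v in variants:
        if not comphet_qualifies(v, cfg):
            continue
        for proband in carriers.get(v.key, ()):
            groups.setdefault((proband, v.gene), {})[v.key] = v
    out: list[CompHetCandidate] = []
    for (proband, gene), keyed in sorted(groups.items()):
        group = sorted(keyed.values(), key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        group = _prune_proximal(group, cfg.comphet_proximity_bp)
        if len(group) >= 2:
            out.append(CompHetCandidate(proband=proband, gene=gene, variants=group))
    return out


def hom_alt_rare_deleterious(
    variants: list[AnnotatedVariant],
    genotypes: dict[tuple[str, tuple], Genotype],
    cfg: FilterConfig | None = None,
) -> list[tuple[str, AnnotatedVariant]]:
    """Report homozygous rare deleterious genotypes (a separate category from
    compound heterozygotes: both alleles are the same variant)."""
    cfg = cfg or FilterConfig()
    hits = []
    qualifying = {v.key: v for v in variants if comphet_qualifies(v, cfg)}
    for (iid, key), gt in sorted(genotypes.items()):
        if gt is Genotype.hom_alt and key in qualifying:
            hits.append((iid, qualifying[key]))
    return hits


def multihit_probands(
    candidate_hits: list,
    stopgain_hits: list[StopgainRecord],
    comphet_hits: list[CompHetCandidate],
) -> list[MultiHitReport]:
    """Pool the three screens per proband; report probands with >= 2 distinct
    variants across hits.

    A comphet gene counts as one hit (its variants pooled under one entry);
    the distinct-variant requirement is over the union of all hit variants.
    """
    pooled: dict[str, list[tuple[str, str, tuple]]] = {}
    for entry in candidate_hits:
        for proband in entry.carriers:
            pooled.setdefault(proband, []).append(
                ("candidate_gene", entry.variant.gene, (entry.variant.key,))
            )
    for rec in stopgain_hits:
        for proband in rec.carriers:
            pooled.setdefault(proband, []).append(
                ("stopgain", rec.variant.gene, (rec.variant.key,))
            )
    for cand in comphet_hits:
        pooled.setdefault(cand.proband, []).append(
            ("comphet_gene", cand.gene, tuple(v.key for v in cand.variants))
        )
    reports: list[MultiHitReport] = []
    for proband in sorted(pooled):
        hits = pooled[proband]
        distinct = {key for (_cat, _gene, keys) in hits for key in keys}
        if len(distinct) >= 2:
            reports.append(MultiHitReport(proband=proband, hits=hits))
    return reports
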