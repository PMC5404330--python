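"""Affection status, Mendelian transmission, comphet phasing and co-segregation.

Affection in children is defined from the CELF-R expressive (ELS) or receptive
(RLS) language score: affected when either score falls more than 1.5 SD below
the population mean (scores standardized to mean 100, SD 15, so the cut is a
score strictly below 77.5).  Parents are never classified from scores because
the instruments are child-normed; co-segregation is therefore assessed over
genotyped, phenotyped children only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .models import Affection, Genotype, Pedigree, VariantKey

#: Affection cut: mean 100 minus 1.5 x SD 15.
AFFECTION_CUTOFF = 77.5


class Origin(str, enum.Enum):
    maternal = "maternal"
    paternal = "paternal"
    de_novo = "de_novo"
    unknown = "unknown"
    inferred_paternal = "inferred_paternal"
    inferred_maternal = "inferred_maternal"


class Cosegregation(str, enum.Enum):
    co_segregates = "co_segregates"
    partial = "partial"
    contradicts = "contradicts"
    uninformative = "uninformative"


class Phase(str, enum.Enum):
    trans = "trans"
    cis = "cis"
    unknown = "unknown"


@dataclass
class SegregationVerdict:
    variant_key: VariantKey
    family: str
    origin: Origin
    cosegregation: Cosegregation
    carriers_affected: int
    carriers_unaffected: int
    noncarriers_affected: int


def affection_status(els: Optional[float], rls: Optional[float]) -> Affection:
    """Derive affection from ELS/RLS scores (affected iff either < 77.5)."""
    for score in (els, rls):
        if score is not None and score < 0:
            raise ValueError(f"negative standardized score {score}")
    if els is None and rls is None:
        return Affection.unknown
    if (els is not None and els < AFFECTION_CUTOFF) or (
        rls is not None and rls < AFFECTION_CUTOFF
    ):
        return Affection.affected
    return Affection.unaffected


def _carries(gt: Genotype) -> bool:
    return gt in (Genotype.het, Genotype.hom_alt)


def transmission_check(variant_key: VariantKey, family: Pedigree) -> Origin:
    """Determine the parental origin of the proband's variant allele.

    Both parents homozygous reference with a heterozygous proband is a
    de novo event; a single carrying parent resolves the origin; one missing
    parental genotype with the other homozygous reference yields an inferred
    origin from the missing side.
    """
    proband = family.proband
    gt = family.genotype(proband.iid, variant_key)
    if gt is Genotype.missing:
        raise ValueError(
            f"proband {proband.iid!r} has no genotype for {variant_key} in "
            f"family {family.fid!r}"
        )
    if not _carries(gt):
        return Origin.unknown
    father_gt = (
        family.genotype(proband.father, variant_key)
        if proband.father is not None
        else Genotype.missing
    )
    mother_gt = (
        family.genotype(proband.mother, variant_key)
        if proband.mother is not None
        else Genotype.missing
    )
    father_carries = _carries(father_gt)
    mother_carries = _carries(mother_gt)
    if father_gt is Genotype.hom_ref and mother_gt is Genotype.hom_ref:
        return Origin.de_novo if gt is Genotype.het else Origin.unknown
    if father_carries and not mother_carries and mother_gt is not Genotype.missing:
        return Origin.paternal
    if mother_carries and not father_carries and father_gt is not Genotype.missing:
        return Origin.maternal
    if father_carries and mother_gt is Genotype.missing:
        return Origin.paternal if gt is Genotype.hom_alt else Origin.unknown
    if mother_carries and father_gt is Genotype.missing:
        return Origin.maternal if gt is Genotype.hom_alt else Origin.unknown
    if father_gt is Genotype.missing and mother_gt is Genotype.hom_ref:
        return Origin.inferred_paternal
    if mother_gt is Genotype.missing and father_gt is Genotype.hom_ref:
        return Origin.inferred_maternal
    return Origin.unknown


_PARENT_SIDE = {
    Origin.paternal: "father",
    Origin.inferred_paternal: "father",
    Origin.maternal: "mother",
    Origin.inferred_maternal: "mother",
}


def phase_comphet(variant_keys: list[VariantKey], family: Pedigree) -> Phase:
    """Phase a compound-het candidate's variants as trans / cis / unknown.

    Groups of more than two variants are phased pairwise; the candidate is
    trans if any pair resolves to opposite parents, cis if every resolvable
    pair resolves to the same parent and at least one does.
    """
    sides = []
    for key in variant_keys:
        origin = transmission_check(key, family)
        sides.append(_PARENT_SIDE.get(origin))
    any_cis = False
    for i in range(len(sides)):
        for j in range(i + 1, len(sides)):
            a, b = sides[i], sides[j]
            if a is None or b is None:
                continue
            if a != b:
                return Phase.trans
            any_cis = True
    return Phase.cis if any_cis else Phase.unknown


def cosegregation(variant_key: VariantKey, family: Pedigree) -> Cosegregation:
    """Classify variant/phenotype co-segregation over the family's children.

    Informative children are genotyped with known affection.  The variant
    co-segregates when every affected child carries it and no unaffected child
    does; it contradicts when an affected child lacks it or an unaffected
    child carries it, with no supporting pattern; mixed evidence is partial;
    fewer than two informative children is uninformative.
    """
    support = 0  # affected carrier or unaffected non-carrier
    against = 0  # affected non-carrier or unaffected carrier
    informative = 0
    for child in family.children():
        gt = family.genotype(child.iid, variant_key)
        if gt is Genotype.missing or child.affected is Affection.unknown:
            continue
        informative += 1
        consistent = _carries(gt) == (child.affected is Affection.affected)
        if consistent:
            support += 1
        else:
            against += 1
    if informative < 2:
        return Cosegregation.uninformative
    if against == 0:
        return Cosegregation.co_segregates
    if support == 0:
        return Cosegregation.contradicts
    return Cosegregation.partial


def segregation_verdict(variant_key: VariantKey, family: Pedigree) -> SegregationVerdict:
    """Full per-family verdict: origin, co-segregation and carrier tallies."""
    carriers_affected = carriers_unaffected = noncarriers_affected = 0
    for child in family.children():
        gt = family.genotype(child.iid, variant_key)
        if gt is Genotype.missing:
            continue
        if _carries(gt):
            if child.affected is Affection.affected:
                carriers_affected += 1
            elif child.affected is Affection.unaffected:
                carriers_unaffected += 1
        elif child.affected is Affection.affected:
            noncarriers_affected += 1
    return SegregationVerdict(
        variant_key=variant_key,
        family=family.fid,
        origin=transmission_check(variant_key, family),
        cosegregation=cosegregation(variant_key, family),
        carriers_affected=carriers_affected,
        carriers_unaffected=carriers_unaffected,
        noncarriers_affected=noncarriers_affected,
    )


def mendelian_audit(family: Pedigree) -> list[tuple[str, VariantKey, str]]:
    """Flag child genotypes impossible under Mendelian transmission.

    A het child of two hom-ref parents is the de novo signature and is *not*
    flagged; a hom-alt child with a hom-ref parent, or a hom-ref child with a
    hom-alt parent, is a genotyping inconsistency.
    """
    problems: list[tuple[str, VariantKey, str]] = []
    keys = {key for (_iid, key) in family.genotypes}
    for child in family.children():
        for key in keys:
            gt = family.genotype(child.iid, key)
            if gt is Genotype.missing:
                continue
            for parent_iid in (child.father, child.mother):
                if parent_iid is None:
                    continue
                pgt = family.genotype(parent_iid, key)
                if gt is Genotype.hom_alt and pgt is Genotype.hom_ref:
                    problems.append((child.iid, key, "hom_alt child of hom_ref parent"))
                elif gt is Genotype.hom_ref and pgt is Genotype.hom_alt:
                    problems.append((child.iid, key, "hom_ref child of hom_alt parent"))
    return problems
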