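"""Domain types for annotated exome variants, genotypes, pedigrees and gene sets.

Coordinates are 1-based inclusive (``chr12:1137072`` style, as in VCF).
Reference-panel allele frequencies are stored as fractions in ``[0, 1]``;
the on-disk table dialect carries percent columns (see :mod:`sliprio.io`).
``None`` denotes an absent/unknown value throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class FuncClass(str, enum.Enum):
    """Functional consequence of a variant on its transcript."""

    nonsynonymous_snv = "nonsynonymous_snv"
    stopgain = "stopgain"
    stoploss = "stoploss"
    splice = "splice"
    frameshift_ins = "frameshift_ins"
    frameshift_del = "frameshift_del"
    nonframeshift_indel = "nonframeshift_indel"
    synonymous = "synonymous"
    intronic = "intronic"
    intergenic = "intergenic"
    ncRNA = "ncRNA"
    UTR = "UTR"


#: Classes retained by the post-annotation exclusion filter (protein-affecting).
CODING_CLASSES = frozenset(
    {
        FuncClass.nonsynonymous_snv,
        FuncClass.stopgain,
        FuncClass.stoploss,
        FuncClass.splice,
        FuncClass.frameshift_ins,
        FuncClass.frameshift_del,
        FuncClass.nonframeshift_indel,
    }
)

#: Loss-of-function classes exempt from the SIFT/PolyPhen predicate by default.
LOF_CLASSES = frozenset(
    {
        FuncClass.stopgain,
        FuncClass.stoploss,
        FuncClass.splice,
        FuncClass.frameshift_ins,
        FuncClass.frameshift_del,
    }
)


class FrequencyTier(str, enum.Enum):
    """Reference-panel frequency tier of a variant.

    novel: absent from both panels; rare: < 1%; low_frequency: 1-5%;
    common: > 5% (default thresholds, see :class:`sliprio.filters.FilterConfig`).
    """

    novel = "novel"
    rare = "rare"
    low_frequency = "low_frequency"
    common = "common"


class Genotype(str, enum.Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Affection(str, enum.Enum):
    affected = "affected"
    unaffected = "unaffected"
    unknown = "unknown"


VariantKey = tuple[str, int, str, str]
"""(chrom, pos, ref, alt) — the identity of a variant."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated variant call with panel frequencies and prediction scores."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    func_class: FuncClass
    rsid: Optional[str] = None
    coding_change: str = ""
    freq_kg: Optional[float] = None  # 1000 Genomes allele frequency, fraction
    freq_evs: Optional[float] = None  # Exome Variant Server frequency, fraction
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    phylop: Optional[float] = None
    phastcons: Optional[float] = None
    segdup: bool = False
    min_depth: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for name in ("freq_kg", "freq_evs", "sift", "polyphen", "phastcons"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1] at {self.chrom}:{self.pos}")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    """Diploid genotype of one sample at one variant."""

    sample_id: str
    variant_key: VariantKey
    gt: Genotype


@dataclass
class Individual:
    """A pedigree member with optional standardized phenotype scores.

    Scores (els, rls, nwr, viq, piq) are age-standardized to mean 100, SD 15.
    ``affected`` is derived from els/rls by the child-normed language threshold
    (see :func:`sliprio.segregation.affection_status`); parents are left unknown
    because the language instruments are child-normed.
    """

    iid: str
    fid: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: Sex = Sex.unknown
    role: str = "parent"  # proband | sibling | parent
    els: Optional[float] = None
    rls: Optional[float] = None
    nwr: Optional[float] = None
    viq: Optional[float] = None
    piq: Optional[float] = None
    affected: Affection = Affection.unknown

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """A nuclear family: members plus their genotypes at screened variants."""

    fid: str
    members: list[Individual] = field(default_factory=list)
    genotypes: dict[tuple[str, VariantKey], Genotype] = field(default_factory=dict)

    def member(self, iid: str) -> Individual:
        for ind in self.members:
            if ind.iid == iid:
                return ind
        raise KeyError(f"no individual {iid!r} in family {self.fid!r}")

    @property
    def proband(self) -> Individual:
        probands = [m for m in self.members if m.role == "proband"]
        if len(probands) != 1:
            raise ValueError(
                f"family {self.fid!r} has {len(probands)} probands; expected exactly 1"
            )
        return probands[0]

    def children(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def genotype(self, iid: str, key: VariantKey) -> Genotype:
        return self.genotypes.get((iid, key), Genotype.missing)


@dataclass
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or GO terms) with an optional background universe."""

    sets: list[GeneSet]
    universe: Optional[frozenset[str]] = None

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


CarrierMap = dict[VariantKey, tuple[str, ...]]
"""variant key -> ordered tuple of carrier proband identifiers."""
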