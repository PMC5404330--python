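"""Candidate-gene screen: tier tallies and the rare/novel shortlist.

The default candidate list holds the 19 genes most robustly implicated in
primary speech, language and reading disorders (SLI association, monogenic
speech disorder, dyslexia, epileptic aphasia, and structural-variant reports).
It ships packaged but is user-replaceable; symbol matching is exact and
case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .filters import FilterConfig, frequency_tier
from .models import AnnotatedVariant, CarrierMap, FrequencyTier

#: Literature candidate genes for speech/language/reading disorders.
CANDIDATE_GENES: tuple[str, ...] = (
    "CMIP",
    "ATP2C2",
    "CNTNAP2",
    "NFXL1",
    "FOXP1",
    "FOXP2",
    "DYX1C1",
    "KIAA0319",
    "DCDC2",
    "ROBO1",
    "SRPX2",
    "GRIN2A",
    "GRIN2B",
    "ERC1",
    "SETBP1",
    "CNTNAP5",
    "DOCK4",
    "SEMA6D",
    "AUTS2",
)

TIER_ORDER = (
    FrequencyTier.common,
    FrequencyTier.low_frequency,
    FrequencyTier.rare,
    FrequencyTier.novel,
)


@dataclass
class ShortlistEntry:
    variant: AnnotatedVariant
    tier: FrequencyTier
    carriers: tuple[str, ...]


@dataclass
class CandidateSummary:
    """Per-gene and overall tier tallies over candidate-gene variants.

    Counting is by distinct variant: a variant carried by several probands
    contributes once.
    """

    per_gene_counts: dict[str, dict[FrequencyTier, int]] = field(default_factory=dict)
    overall_counts: dict[FrequencyTier, int] = field(
        default_factory=lambda: {t: 0 for t in TIER_ORDER}
    )

    @property
    def total(self) -> int:
        return sum(self.overall_counts.values())


def screen_candidates(
    variants: list[AnnotatedVariant],
    carriers: CarrierMap,
    genes: tuple[str, ...] = CANDIDATE_GENES,
    cfg: FilterConfig | None = None,
) -> tuple[CandidateSummary, list[ShortlistEntry]]:
    """Tally candidate-gene variants by frequency tier; shortlist novel/rare ones.

    Expects QC-filtered input.  The shortlist is sorted by (chrom, pos) and
    keeps multi-carrier variants as single entries with all carriers attached.
    """
    if not genes:
        raise ValueError("candidate gene list is empty")
    cfg = cfg or FilterConfig()
    wanted = {g.upper() for g in genes}
    summary = CandidateSummary()
    shortlist: list[ShortlistEntry] = []
    for v in variants:
        if v.gene.upper() not in wanted:
            continue
        tier = frequency_tier(v, cfg)
        gene_counts = summary.per_gene_counts.setdefault(
            v.gene, {t: 0 for t in TIER_ORDER}
        )
        gene_counts[tier] += 1
        summary.overall_counts[tier] += 1
        if tier in (FrequencyTier.novel, FrequencyTier.rare):
            shortlist.append(
                ShortlistEntry(variant=v, tier=tier, carriers=carriers.get(v.key, ()))
            )
    shortlist.sort(key=lambda e: (e.variant.chrom, e.variant.pos))
    return summary, shortlist


def tier_percentages(counts: dict[FrequencyTier, int]) -> dict[FrequencyTier, float]:
    """Tier shares of the total as percentages rounded to 1 decimal."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot compute tier percentages of an empty tally")
    return {tier: round(100.0 * n / total, 1) for tier, n in counts.items()}
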