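"""Post-annotation exclusion filters, frequency tiering and deleteriousness.

The exclusion filter retains protein-affecting classes only (nonsynonymous,
stop-gain/loss, splice, frameshift and non-frameshift indels), drops variants
in segmental-duplication regions, and drops variants whose carrier read depth
never reaches the minimum.  Frequency tiers follow the reference-panel
convention: novel (absent from both panels), rare (< 1%), low-frequency
(1-5%), common (> 5%).  A variant is predicted deleterious when SIFT <= 0.05
or PolyPhen-2 >= 0.85; loss-of-function classes are exempt from the score
predicate by default because truncation is damaging irrespective of
substitution scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import CODING_CLASSES, LOF_CLASSES, AnnotatedVariant, FrequencyTier


@dataclass
class FilterConfig:
    """Thresholds for filtering, tiering and deleteriousness prediction.

    Parameters
    ----------
    rare_threshold : float
        Upper (exclusive) allele-frequency bound of the rare tier. Default 0.01.
    low_freq_threshold : float
        Upper (inclusive) bound of the low-frequency tier. Default 0.05.
    sift_max, polyphen_min : float
        Score cut-offs of the deleteriousness predicate (SIFT <= 0.05 or
        PolyPhen-2 >= 0.85).
    min_depth_required : int
        Minimum carrier read depth; variants below it in every carrier are
        excluded. Default 10.
    comphet_proximity_bp : int
        Variants within this many base pairs of each other are excluded from
        compound-heterozygote groups (alignment-artefact guard). Default 10.
    stopgain_exempt_from_scores : bool
        Treat loss-of-function classes as deleterious regardless of scores.
    tier_panel : str
        ``"max"`` tiers by the maximum over available panel frequencies
        (conservative); ``"kg"`` by the 1000 Genomes panel alone.
    depth_mode : str
        ``"any"`` keeps a variant when any carrier reaches the depth cut
        (``min_depth`` is the max over carriers in that reading); ``"all"``
        requires every carrier to reach it.
    """

    rare_threshold: float = 0.01
    low_freq_threshold: float = 0.05
    sift_max: float = 0.05
    polyphen_min: float = 0.85
    min_depth_required: int = 10
    comphet_proximity_bp: int = 10
    stopgain_exempt_from_scores: bool = True
    tier_panel: str = "max"
    depth_mode: str = "any"

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_threshold < self.low_freq_threshold <= 1.0):
            raise ValueError(
                "need 0 < rare_threshold < low_freq_threshold <= 1, got "
                f"{self.rare_threshold} / {self.low_freq_threshold}"
            )
        for name in ("sift_max", "polyphen_min"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.tier_panel not in ("max", "kg"):
            raise ValueError(f"tier_panel must be 'max' or 'kg', got {self.tier_panel!r}")
        if self.depth_mode not in ("any", "all"):
            raise ValueError(f"depth_mode must be 'any' or 'all', got {self.depth_mode!r}")


@dataclass
class ExclusionCounts:
    """Per-rule exclusion tallies, attributed in fixed order (class, segdup, depth)."""

    func_class: int = 0
    segdup: int = 0
    depth: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "class": self.func_class,
            "segdup": self.segdup,
            "depth": self.depth,
            "retained": self.retained,
        }


def qc_filter(
    variants: list[AnnotatedVariant], cfg: FilterConfig | None = None
) -> tuple[list[AnnotatedVariant], ExclusionCounts]:
    """Apply the post-annotation exclusion filters.

    A variant failing several rules is attributed to the first failing rule in
    the fixed order: functional class, segmental duplication, read depth.
    """
    cfg = cfg or FilterConfig()
    counts = ExclusionCounts()
    retained: list[AnnotatedVariant] = []
    for v in variants:
        if v.func_class not in CODING_CLASSES:
            counts.func_class += 1
        elif v.segdup:
            counts.segdup += 1
        elif v.min_depth < cfg.min_depth_required:
            counts.depth += 1
        else:
            retained.append(v)
    counts.retained = len(retained)
    return retained, counts


def frequency_tier(v: AnnotatedVariant, cfg: FilterConfig | None = None) -> FrequencyTier:
    """Classify a variant into novel / rare / low_frequency / common.

    Novel means absent from both reference panels (a bare dbSNP identifier
    without frequency information does not preclude novelty).  Otherwise the
    tier is set by the panel frequency: rare below ``rare_threshold``,
    low-frequency up to ``low_freq_threshold`` inclusive, common above.
    """
    cfg = cfg or FilterConfig()
    if v.freq_kg is None and v.freq_evs is None:
        return FrequencyTier.novel
    if cfg.tier_panel == "kg":
        freq = v.freq_kg if v.freq_kg is not None else v.freq_evs
    else:
        freq = max(f for f in (v.freq_kg, v.freq_evs) if f is not None)
    if freq < cfg.rare_threshold:
        return FrequencyTier.rare
    if freq <= cfg.low_freq_threshold:
        return FrequencyTier.low_frequency
    return FrequencyTier.common


def is_deleterious(v: AnnotatedVariant, cfg: FilterConfig | None = None) -> bool:
    """Predicted-deleterious predicate: SIFT <= 0.05 or PolyPhen-2 >= 0.85.

    Loss-of-function classes (stop-gain/loss, splice, frameshift) return True
    regardless of scores when ``stopgain_exempt_from_scores`` is set.  With
    both scores absent on a substitution the predicate is False.
    """
    cfg = cfg or FilterConfig()
    if cfg.stopgain_exempt_from_scores and v.func_class in LOF_CLASSES:
        return True
    if v.sift is not None and v.sift <= cfg.sift_max:
        return True
    if v.polyphen is not None and v.polyphen >= cfg.polyphen_min:
        return True
    return False


def truncation_fraction(stop_aa_pos: int, protein_length: int) -> float:
    """Percent of the protein lost to a premature stop, to 1 decimal.

    The stop codon replaces residue ``stop_aa_pos``, so the truncated residue
    itself counts as missing: 100 * (L - pos + 1) / L.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    if not (1 <= stop_aa_pos <= protein_length):
        raise ValueError(
            f"stop position {stop_aa_pos} outside protein of length {protein_length}"
        )
    return round(100.0 * (protein_length - stop_aa_pos + 1) / protein_length, 1)
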