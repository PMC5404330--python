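"""Pooled hypergeometric over-representation and frequency-stratified lists.

A pooled gene list (genes with qualifying variants across all probands) is
tested set-by-set against a background universe (all genes with any variant)
with the hypergeometric upper tail, Benjamini-Hochberg corrected across the
tested sets.  The frequency-stratified construction relaxes the
deleteriousness requirement and splits variants at <= 5% population frequency
into novel / reported-rare (< 1%) / low-frequency (1-5%) strata by their
1000 Genomes frequency (novel additionally requires absence from EVS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .filters import FilterConfig
from .models import AnnotatedVariant, FuncClass, GeneSetCollection


def _log_comb(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(
    overlap: int, set_size: int, list_size: int, universe_size: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe_size, set_size, list_size).

    Accumulated in log space from exact log-binomial terms for numerical
    stability far into the tail.
    """
    if not (0 <= set_size <= universe_size and 0 <= list_size <= universe_size):
        raise ValueError("set and list sizes must lie within the universe")
    if not (0 <= overlap <= min(set_size, list_size)):
        raise ValueError(
            f"overlap {overlap} outside [0, min({set_size}, {list_size})]"
        )
    if overlap == 0:
        return 1.0
    lo = max(overlap, set_size + list_size - universe_size)
    hi = min(set_size, list_size)
    k = np.arange(lo, hi + 1, dtype=float)
    log_terms = (
        _log_comb(set_size, k)
        + _log_comb(universe_size - set_size, list_size - k)
        - _log_comb(universe_size, float(list_size))
    )
    peak = log_terms.max()
    return float(min(1.0, np.exp(peak) * np.exp(log_terms - peak).sum()))


@dataclass
class EnrichmentRow:
    set_id: str
    term: str
    exp_count: float
    count: int
    p: float
    fdr: float
    set_size: int


def enrich(
    gene_list: set[str],
    background: set[str],
    sets: GeneSetCollection,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.01,
    min_set_size: int = 10,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``gene_list`` within ``sets``.

    Set memberships are restricted to the background; BH correction runs over
    every tested set, and the report keeps rows with p < ``p_threshold``,
    BH-FDR < ``fdr_threshold`` and set size > ``min_set_size``, sorted by p.
    """
    if not background:
        raise ValueError("background gene universe is empty")
    extra = gene_list - background
    if extra:
        raise ValueError(f"gene list not contained in background: {sorted(extra)[:5]}")
    universe_size = len(background)
    list_size = len(gene_list)
    tested: list[tuple] = []
    for gs in sets.sets:
        members = gs.genes & background
        if not members:
            continue
        count = len(gene_list & members)
        exp_count = len(members) * list_size / universe_size
        p = hypergeom_upper_tail(count, len(members), list_size, universe_size)
        tested.append((gs, len(members), count, exp_count, p))
    if not tested:
        return []
    pvals = [t[4] for t in tested]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    rows = [
        EnrichmentRow(
            set_id=gs.set_id,
            term=gs.name,
            exp_count=round(exp_count, 2),
            count=count,
            p=p,
            fdr=float(fdr),
            set_size=size,
        )
        for (gs, size, count, exp_count, p), fdr in zip(tested, fdrs)
    ]
    rows = [
        r
        for r in rows
        if r.p < p_threshold and r.fdr < fdr_threshold and r.set_size > min_set_size
    ]
    rows.sort(key=lambda r: (r.p, r.set_id))
    return rows


#: Classes entering the relaxed (prediction-free) frequency-stratified lists.
RELAXED_CLASSES = frozenset(
    {FuncClass.nonsynonymous_snv, FuncClass.stopgain, FuncClass.stoploss}
)


def stratify_by_frequency(
    variants: list[AnnotatedVariant], cfg: FilterConfig | None = None
) -> dict[str, set[str]]:
    """Split genes into novel / rare (< 1%) / low-frequency (1-5%) strata.

    Applies the relaxed filter — nonsynonymous and stop-gain/loss variants at
    <= 5% 1000 Genomes frequency, regardless of SIFT/PolyPhen — then assigns
    each variant's gene to exactly one stratum by that variant's frequency.
    A gene may appear in several strata through different variants.
    """
    cfg = cfg or FilterConfig()
    strata: dict[str, set[str]] = {"novel": set(), "rare": set(), "low_frequency": set()}
    for v in variants:
        if v.func_class not in RELAXED_CLASSES:
            continue
        if v.freq_kg is None and v.freq_evs is None:
            strata["novel"].add(v.gene)
            continue
        if v.freq_kg is None:
            continue  # reported in EVS only: no 1000 Genomes frequency to cut on
        if v.freq_kg > cfg.low_freq_threshold:
            continue
        if v.freq_kg < cfg.rare_threshold:
            strata["rare"].add(v.gene)
        else:
            strata["low_frequency"].add(v.gene)
    return strata
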