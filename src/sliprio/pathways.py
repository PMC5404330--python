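"""Within-proband pathway sharing and its permutation tail probability.

Each proband contributes the set of genes carrying qualifying variants
(rare/novel, predicted deleterious, disruptive classes).  For each pathway the
statistic is the number of probands whose gene set intersects it.  The null is
built by re-drawing every proband's gene list uniformly without replacement
from the universe of all genes with variants, keeping the list sizes fixed;
the reported ``fdr`` is the fraction of permutations in which the pathway is
shared by at least as many probands as observed — a per-pathway empirical
permutation tail probability (no cross-pathway correction), named ``fdr``
for continuity with the field's usage.  An optional max-statistic family-wise
correction is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import FilterConfig, frequency_tier, is_deleterious
from .highrisk import RARE_OR_NOVEL
from .models import AnnotatedVariant, CarrierMap, FuncClass, GeneSetCollection

#: Disruptive classes entering the per-proband gene sets.
DISRUPTIVE_CLASSES = frozenset(
    {
        FuncClass.nonsynonymous_snv,
        FuncClass.stopgain,
        FuncClass.stoploss,
        FuncClass.splice,
        FuncClass.frameshift_ins,
        FuncClass.frameshift_del,
    }
)


@dataclass
class SharedPathwayResult:
    set_id: str
    set_name: str
    observed_probands: int
    perm_geq: int
    perm_eq: int
    fdr: float
    n_perm: int
    seed: int
    fwer: float | None = None

    def majority_flag(self, cohort_size: int) -> bool:
        """True when the pathway is shared by more than half of the probands."""
        return self.observed_probands > cohort_size / 2


def proband_gene_sets(
    variants: list[AnnotatedVariant],
    carriers: CarrierMap,
    cfg: FilterConfig | None = None,
    probands: list[str] | None = None,
) -> dict[str, set[str]]:
    """Per-proband deduplicated gene sets of qualifying variants.

    ``probands`` fixes the cohort roster; probands without qualifying variants
    keep an empty set and still count toward the cohort size.
    """
    cfg = cfg or FilterConfig()
    sets: dict[str, set[str]] = {p: set() for p in (probands or [])}
    for v in variants:
        if v.func_class not in DISRUPTIVE_CLASSES:
            continue
        if frequency_tier(v, cfg) not in RARE_OR_NOVEL or not is_deleterious(v, cfg):
            continue
        for proband in carriers.get(v.key, ()):
            sets.setdefault(proband, set()).add(v.gene)
    return sets


def shared_count(gene_sets_by_proband: dict[str, set[str]], pathway: frozenset[str]) -> int:
    """Number of probands whose gene set shares at least one gene with the pathway."""
    return sum(1 for genes in gene_sets_by_proband.values() if genes & pathway)


def permutation_fdr(
    gene_sets_by_proband: dict[str, set[str]],
    pathways: GeneSetCollection,
    universe: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    include_empty: bool = True,
    fwer: bool = False,
) -> list[SharedPathwayResult]:
    """Empirical permutation tail probability of per-pathway sharing.

    For each of ``n_perm`` permutations every proband receives a uniform
    sample without replacement from ``universe`` of the same size as its
    observed gene list; the shared-proband count is recomputed per pathway.
    ``fdr`` = (# permutations with count >= observed) / n_perm.  Results are
    sorted by (fdr, -observed, set_id) and are reproducible from ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cohort = {
        p: genes
        for p, genes in gene_sets_by_proband.items()
        if include_empty or genes
    }
    universe_arr = np.asarray(sorted(set(universe)))
    universe_index = {g: i for i, g in enumerate(universe_arr)}
    n_genes = len(universe_arr)
    sizes = {}
    for proband, genes in cohort.items():
        missing = genes - universe_index.keys()
        if missing:
            raise ValueError(
                f"proband {proband!r} gene list not contained in universe: "
                f"{sorted(missing)[:5]}"
            )
        if len(genes) > n_genes:
            raise ValueError(f"proband {proband!r} gene list larger than universe")
        sizes[proband] = len(genes)

    # gene-by-pathway membership matrix over the universe
    n_sets = len(pathways.sets)
    membership = np.zeros((n_genes, n_sets), dtype=bool)
    for j, gs in enumerate(pathways.sets):
        for g in gs.genes:
            idx = universe_index.get(g)
            if idx is not None:
                membership[idx, j] = True

    observed = [
        shared_count(cohort, frozenset(gs.genes)) for gs in pathways.sets
    ]

    rng = np.random.default_rng(seed)
    perm_geq = np.zeros(n_sets, dtype=int)
    perm_eq = np.zeros(n_sets, dtype=int)
    perm_max_geq = np.zeros(n_sets, dtype=int)
    probands = sorted(cohort)
    size_arr = [sizes[p] for p in probands]
    obs_arr = np.asarray(observed)
    for _ in range(n_perm):
        counts = np.zeros(n_sets, dtype=int)
        for size in size_arr:
            if size == 0:
                continue
            draw = rng.choice(n_genes, size=size, replace=False)
            counts += membership[draw].any(axis=0)
        perm_geq += counts >= obs_arr
        perm_eq += counts == obs_arr
        if fwer:
            perm_max_geq += counts.max(initial=0) >= obs_arr

    results = [
        SharedPathwayResult(
            set_id=gs.set_id,
            set_name=gs.name,
            observed_probands=obs,
            perm_geq=int(geq),
            perm_eq=int(eq),
            fdr=geq / n_perm,
            n_perm=n_perm,
            seed=seed,
            fwer=(float(mgeq / n_perm) if fwer else None),
        )
        for gs, obs, geq, eq, mgeq in zip(
            pathways.sets, observed, perm_geq, perm_eq, perm_max_geq
        )
    ]
    results.sort(key=lambda r: (r.fdr, -r.observed_probands, r.set_id))
    return results


def randomized_null_rank(result: SharedPathwayResult, u: float) -> float:
    """Tie-randomized permutation rank of the observed sharing statistic.

    The reported ``fdr`` is a discrete tail probability, so its null
    distribution is a staircase.  With ``u`` uniform on [0, 1) the quantity

        (#{perm > obs} + u * (#{perm == obs} + 1)) / (n_perm + 1)

    is exactly Uniform(0, 1) under exchangeability of the observed cohort with
    its permutations, which makes calibration testable at any statistic
    granularity.
    """
    strictly_greater = result.perm_geq - result.perm_eq
    return (strictly_greater + u * (result.perm_eq + 1)) / (result.n_perm + 1)
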