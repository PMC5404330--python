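"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-state the screening rules literally and inefficiently,
without importing any predicate from the package, so that agreement is a
meaningful check rather than a tautology.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np

from sliprio.models import AnnotatedVariant, FuncClass

_CODING = {
    "nonsynonymous_snv",
    "stopgain",
    "stoploss",
    "splice",
    "frameshift_ins",
    "frameshift_del",
}
_LOF = {"stopgain", "stoploss", "splice", "frameshift_ins", "frameshift_del"}


def brute_force_comphet(variants, carriers, proximity_bp=10):
    """Literal enumeration of (proband, gene) compound-het groups."""
    probands = sorted({p for ids in carriers.values() for p in ids})
    genes = sorted({v.gene for v in variants})
    found = {}
    for proband in probands:
        for gene in genes:
            group = []
            for v in variants:
                if v.gene != gene or proband not in carriers.get(v.key, ()):
                    continue
                if v.func_class.value not in _CODING or v.segdup:
                    continue
                # tier: novel (absent from both panels) or rare (< 1%)
                freqs = [f for f in (v.freq_kg, v.freq_evs) if f is not None]
                if freqs and max(freqs) >= 0.01:
                    continue
                # deleterious: LoF class, SIFT <= 0.05, or PolyPhen >= 0.85
                deleterious = v.func_class.value in _LOF
                if not deleterious and v.sift is not None and v.sift <= 0.05:
                    deleterious = True
                if not deleterious and v.polyphen is not None and v.polyphen >= 0.85:
                    deleterious = True
                if not deleterious:
                    continue
                group.append(v)
            drop = set()
            for a, b in combinations(group, 2):
                if a.chrom == b.chrom and abs(a.pos - b.pos) <= proximity_bp:
                    drop.add(a.key)
                    drop.add(b.key)
            survivors = [v for v in group if v.key not in drop]
            if len(survivors) >= 2:
                found[(proband, gene)] = frozenset(v.key for v in survivors)
    return found


def exhaustive_hypergeom_tail(overlap: int, set_size: int, list_size: int, universe: int):
    """P(X >= overlap) by enumerating every size-``list_size`` draw from the
    universe with the first ``set_size`` elements marked."""
    total = comb(universe, list_size)
    hits = sum(
        1
        for draw in combinations(range(universe), list_size)
        if sum(1 for x in draw if x < set_size) >= overlap
    )
    return Fraction(hits, total)


_FREQ_CHOICES = (None, 0.0005, 0.004, 0.0099, 0.01, 0.011, 0.02, 0.049, 0.05, 0.2)
_SIFT_CHOICES = (None, 0.0, 0.01, 0.05, 0.051, 0.3, 0.9)
_PP2_CHOICES = (None, 0.0, 0.5, 0.84, 0.85, 0.99)
_CLASSES = (
    FuncClass.nonsynonymous_snv,
    FuncClass.nonsynonymous_snv,
    FuncClass.stopgain,
    FuncClass.splice,
    FuncClass.synonymous,
    FuncClass.nonframeshift_indel,
)


def random_cohort(rng: np.random.Generator, n_probands: int, n_variants: int):
    """Random cohort with values deliberately dense around every threshold."""
    probands = [f"P{i}" for i in range(n_probands)]
    genes = [f"G{i}" for i in range(max(3, n_variants // 8))]
    variants, carriers = [], {}
    used_pos = set()
    for i in range(n_variants):
        gene = genes[int(rng.integers(len(genes)))]
        chrom = f"chr{1 + hash(gene) % 5}"
        # cluster positions so that <=10 bp pairs occur regularly
        pos = int(rng.integers(1, 60)) * 7 + 1
        while (chrom, pos) in used_pos:
            pos += 1
        used_pos.add((chrom, pos))
        v = AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref="A",
            alt="T",
            gene=gene,
            func_class=_CLASSES[int(rng.integers(len(_CLASSES)))],
            freq_kg=_FREQ_CHOICES[int(rng.integers(len(_FREQ_CHOICES)))],
            freq_evs=_FREQ_CHOICES[int(rng.integers(len(_FREQ_CHOICES)))],
            sift=_SIFT_CHOICES[int(rng.integers(len(_SIFT_CHOICES)))],
            polyphen=_PP2_CHOICES[int(rng.integers(len(_PP2_CHOICES)))],
            segdup=bool(rng.random() < 0.1),
            min_depth=int(rng.integers(5, 60)),
        )
        variants.append(v)
        n_car = int(rng.integers(0, min(4, n_probands) + 1))
        ids = tuple(
            probands[j] for j in sorted(rng.choice(n_probands, size=n_car, replace=False))
        )
        carriers[v.key] = ids
    return variants, carriers
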