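"""Seeded generator of synthetic exome-screen cohorts with planted signals.

The generator emulates the study design this package analyzes: ~43 nuclear
families each ascertained through one affected proband, an annotated variant
table with a realistic reference-panel frequency spectrum, Mendelian
transmission from simulated parental haplotypes, child language scores
consistent with derived affection status, and planted signals for every
pipeline stage — candidate-gene rare/novel variants, rare stop-gains, trans
compound-heterozygote pairs, a de novo substitution, and a pathway carrying a
rare-variant excess across probands.  A truth manifest records every planted
signal so screens can be scored for recovery.

Haplotype phase is tracked internally only to place trans pairs and to
transmit within-gene haplotypes consistently; emitted genotypes are unphased.
Planted variants are private to their family (absent from all other
founders), as validated ultra-rare variants effectively are; their printed
panel frequencies still reflect their tier label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .candidates import CANDIDATE_GENES
from .filters import FilterConfig
from .io import PathLike, write_gmt, write_ped, write_variant_table
from .models import (
    Affection,
    AnnotatedVariant,
    CarrierMap,
    FuncClass,
    GeneSet,
    GeneSetCollection,
    Genotype,
    GenotypeCall,
    Individual,
    Pedigree,
    Sex,
    VariantKey,
)

TIER_NAMES = ("common", "low_frequency", "rare", "novel")

#: Allele-frequency ranges per tier (log-uniform draws within).
TIER_FREQ_RANGES = {
    "common": (0.05, 0.5),
    "low_frequency": (0.01, 0.05),
    "rare": (1e-4, 0.01),
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the emulated design: 43 nuclear families, 1-3 genotyped
    siblings each, a mostly-common variant spectrum, and planted signal
    counts on the scale the screens are meant to detect (2 candidate-gene
    variants, 3 rare stop-gains, 4 trans compound-het pairs, 1 de novo, one
    pathway with a rare-variant excess in 70% of probands).
    """

    n_families: int = 43
    sibs_range: tuple[int, int] = (1, 3)
    n_genes: int = 300
    variants_per_gene: float = 2.0
    tier_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "common": 0.55,
            "low_frequency": 0.20,
            "rare": 0.15,
            "novel": 0.10,
        }
    )
    plant_candidate: int = 2
    plant_stopgain: int = 3
    plant_comphet: int = 4
    plant_denovo: int = 1
    plant_pathway: tuple[str, float] = ("SET001", 0.7)
    n_pathways: int = 10
    pathway_size: int = 15
    penetrance: float = 1.0
    sib_background_affection: float = 0.05
    segdup_rate: float = 0.02
    low_depth_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.tier_mixture.get(t, 0.0) for t in TIER_NAMES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tier_mixture proportions sum to {total}, need 1")
        if not (0.0 <= self.penetrance <= 1.0):
            raise ValueError("penetrance must be in [0, 1]")
        for name in ("plant_candidate", "plant_stopgain", "plant_comphet", "plant_denovo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        n_planted_families = (
            self.plant_candidate + self.plant_stopgain + self.plant_comphet + self.plant_denovo
        )
        if n_planted_families > self.n_families:
            raise ValueError(
                f"{n_planted_families} planted signals exceed {self.n_families} families "
                "(one planted family per signal)"
            )
        if self.plant_candidate + self.plant_denovo > len(CANDIDATE_GENES):
            raise ValueError("more candidate-gene plants than candidate genes")


@dataclass
class PlantedVariant:
    category: str  # candidate | stopgain | comphet | denovo | pathway
    family: str
    proband: str
    gene: str
    key: VariantKey
    origin: str  # paternal | maternal | de_novo


@dataclass
class TruthManifest:
    """Ledger of planted signals for recovery scoring."""

    seed: int
    candidate: list[PlantedVariant] = field(default_factory=list)
    stopgain: list[PlantedVariant] = field(default_factory=list)
    comphet: list[dict] = field(default_factory=list)  # family/proband/gene/keys/phase
    denovo: list[PlantedVariant] = field(default_factory=list)
    pathway_set_id: Optional[str] = None
    pathway_probands: list[str] = field(default_factory=list)
    pathway_variants: list[PlantedVariant] = field(default_factory=list)

    def candidate_shortlist_keys(self) -> set[VariantKey]:
        """Variant keys the candidate screen should report (plants in candidate
        genes, including the de novo)."""
        return {p.key for p in self.candidate} | {p.key for p in self.denovo}

    def to_json(self) -> str:
        def enc(p: PlantedVariant) -> dict:
            d = asdict(p)
            d["key"] = list(p.key)
            return d

        payload = {
            "seed": self.seed,
            "candidate": [enc(p) for p in self.candidate],
            "stopgain": [enc(p) for p in self.stopgain],
            "comphet": [
                {**c, "keys": [list(k) for k in c["keys"]]} for c in self.comphet
            ],
            "denovo": [enc(p) for p in self.denovo],
            "pathway": {
                "set_id": self.pathway_set_id,
                "probands": self.pathway_probands,
                "variants": [enc(p) for p in self.pathway_variants],
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimulatedCohort:
    config: SimConfig
    variants: list[AnnotatedVariant]
    carriers: CarrierMap
    pedigrees: list[Pedigree]
    gene_sets: GeneSetCollection
    truth: TruthManifest

    @property
    def probands(self) -> list[str]:
        return [fam.proband.iid for fam in self.pedigrees]


_BASES = ("A", "C", "G", "T")


class _Genome:
    """Deterministic gene coordinates: 22 autosomes, non-overlapping gene loci."""

    def __init__(self, genes: list[str]):
        self.locus = {}
        for i, gene in enumerate(genes):
            chrom = f"chr{(i % 22) + 1}"
            base = 1_000_000 + (i // 22) * 50_000
            self.locus[gene] = (chrom, base)

    def background_positions(self, gene: str, count: int, rng) -> list[int]:
        chrom, base = self.locus[gene]
        offsets = rng.choice(200, size=min(count, 200), replace=False)
        return [base + int(o) * 25 for o in sorted(offsets)]

    def planted_position(self, gene: str, slot: int) -> tuple[str, int]:
        chrom, base = self.locus[gene]
        return chrom, base + 6_000 + slot * 100


def _draw_alleles(rng) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def _tier_frequency(tier: str, rng) -> Optional[float]:
    if tier == "novel":
        return None
    lo, hi = TIER_FREQ_RANGES[tier]
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _benign_scores(rng) -> tuple[float, float]:
    sift = float(0.06 + 0.94 * rng.beta(2.0, 1.2))
    polyphen = float(0.84 * rng.beta(1.2, 3.0))
    return sift, polyphen


def _deleterious_scores(rng) -> tuple[float, float]:
    sift = float(0.05 * rng.beta(1.0, 4.0))
    polyphen = float(0.85 + 0.15 * rng.beta(3.0, 1.0))
    return sift, polyphen


def _score_pair(els_affected: bool, rng) -> tuple[float, float]:
    if els_affected:
        els = float(np.clip(rng.normal(65.0, 8.0), 30.0, 77.0))
        rls = float(np.clip(rng.normal(78.0, 10.0), 40.0, 120.0))
    else:
        els = float(np.clip(rng.normal(96.0, 9.0), 78.0, 130.0))
        rls = float(np.clip(rng.normal(96.0, 9.0), 78.0, 130.0))
    return round(els, 1), round(rls, 1)


def simulate_cohort(cfg: SimConfig | None = None) -> SimulatedCohort:
    """Generate a cohort; reproducible (byte-identical files) from cfg.seed."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    background_genes = [f"GENE{i:04d}" for i in range(1, cfg.n_genes + 1)]
    all_genes = list(CANDIDATE_GENES) + background_genes
    genome = _Genome(all_genes)

    # --- reserve genes for planted signals, then pathway sets, then background
    pool = background_genes.copy()
    rng.shuffle(pool)
    stopgain_genes = [pool.pop() for _ in range(cfg.plant_stopgain)]
    comphet_genes = [pool.pop() for _ in range(cfg.plant_comphet)]
    candidate_pool = list(CANDIDATE_GENES)
    rng.shuffle(candidate_pool)
    candidate_plant_genes = [candidate_pool.pop() for _ in range(cfg.plant_candidate)]
    denovo_genes = [candidate_pool.pop() for _ in range(cfg.plant_denovo)]

    sets = []
    for s in range(cfg.n_pathways):
        members = rng.choice(len(pool), size=min(cfg.pathway_size, len(pool)), replace=False)
        sets.append(
            GeneSet(
                set_id=f"SET{s + 1:03d}",
                name=f"synthetic pathway {s + 1}",
                genes=frozenset(pool[i] for i in members),
            )
        )
    gene_sets = GeneSetCollection(sets=sets)

    # --- families
    pedigrees: list[Pedigree] = []
    for f in range(1, cfg.n_families + 1):
        fid = f"F{f:02d}"
        father = Individual(iid=f"{fid}_D", fid=fid, sex=Sex.male, role="parent")
        mother = Individual(iid=f"{fid}_M", fid=fid, sex=Sex.female, role="parent")
        members = [father, mother]
        n_children = 1 + int(rng.integers(cfg.sibs_range[0], cfg.sibs_range[1] + 1))
        for c in range(n_children):
            iid = f"{fid}_P" if c == 0 else f"{fid}_S{c}"
            members.append(
                Individual(
                    iid=iid,
                    fid=fid,
                    father=father.iid,
                    mother=mother.iid,
                    sex=Sex.male if rng.random() < 0.5 else Sex.female,
                    role="proband" if c == 0 else "sibling",
                )
            )
        pedigrees.append(Pedigree(fid=fid, members=members))

    # families hosting planted signals, one signal per family
    family_order = list(range(cfg.n_families))
    rng.shuffle(family_order)
    cursor = 0

    def next_families(count: int) -> list[Pedigree]:
        nonlocal cursor
        chosen = [pedigrees[family_order[i]] for i in range(cursor, cursor + count)]
        cursor += count
        return chosen

    candidate_fams = next_families(cfg.plant_candidate)
    stopgain_fams = next_families(cfg.plant_stopgain)
    comphet_fams = next_families(cfg.plant_comphet)
    denovo_fams = next_families(cfg.plant_denovo)

    # --- background variants
    variants: list[AnnotatedVariant] = []
    pop_freq: dict[VariantKey, float] = {}  # frequency used for founder draws
    n_background = int(round(cfg.variants_per_gene * cfg.n_genes))
    tier_probs = [cfg.tier_mixture[t] for t in TIER_NAMES]
    per_gene_counts: dict[str, int] = {}
    gene_choices = rng.choice(len(all_genes), size=n_background)
    tier_choices = rng.choice(len(TIER_NAMES), size=n_background, p=tier_probs)
    class_choices = rng.choice(3, size=n_background, p=[0.5, 0.3, 0.2])
    class_map = (FuncClass.nonsynonymous_snv, FuncClass.synonymous, FuncClass.intronic)
    positions: dict[str, list[int]] = {}
    for gi, ti, ci in zip(gene_choices, tier_choices, class_choices):
        gene = all_genes[gi]
        tier = TIER_NAMES[ti]
        if gene in CANDIDATE_GENES and tier in ("rare", "novel"):
            # rare/novel candidate-gene signals are planted, never background
            tier = "common" if rng.random() < 0.7 else "low_frequency"
        if gene not in positions:
            positions[gene] = genome.background_positions(gene, 40, rng)
        slot = per_gene_counts.get(gene, 0)
        if slot >= len(positions[gene]):
            continue
        per_gene_counts[gene] = slot + 1
        chrom = genome.locus[gene][0]
        pos = positions[gene][slot]
        ref, alt = _draw_alleles(rng)
        freq = _tier_frequency(tier, rng)
        func_class = class_map[ci]
        sift, polyphen = (_benign_scores(rng) if func_class is FuncClass.nonsynonymous_snv else (None, None))
        v = AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene,
            func_class=func_class,
            rsid=f"rs9{len(variants):06d}" if freq is not None else None,
            freq_kg=freq,
            freq_evs=(None if freq is None else float(np.clip(freq * rng.uniform(0.7, 1.3), 1e-5, 1.0))),
            sift=sift,
            polyphen=polyphen,
            phylop=float(rng.normal(1.0, 2.0)),
            phastcons=float(rng.beta(1.5, 1.5)),
            segdup=bool(rng.random() < cfg.segdup_rate),
            min_depth=int(8 if rng.random() < cfg.low_depth_rate else rng.integers(12, 80)),
        )
        variants.append(v)
        pop_freq[v.key] = freq if freq is not None else 5e-4

    # --- planted variants (private to their family; founder placement explicit)
    truth = TruthManifest(seed=cfg.seed)
    # founder_hap_plants[(fid, iid)] -> list of (variant_key, hap_index)
    founder_plants: dict[tuple[str, str], list[tuple[VariantKey, int]]] = {}
    # (fid, gene) -> {child_iid or "*proband*": (father_col, mother_col)}
    forced_choice: dict[tuple[str, str], tuple[int, int]] = {}
    denovo_alleles: dict[tuple[str, VariantKey], int] = {}

    def make_planted(
        gene: str, slot: int, func_class: FuncClass, tier: str
    ) -> AnnotatedVariant:
        chrom, pos = genome.planted_position(gene, slot)
        ref, alt = _draw_alleles(rng)
        freq = _tier_frequency("rare", rng) if tier == "rare" else None
        if func_class in (FuncClass.stopgain,):
            sift, polyphen = float(rng.uniform(0.8, 1.0)), None
        else:
            sift, polyphen = _deleterious_scores(rng)
        return AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene,
            func_class=func_class,
            rsid=None if freq is None else f"rs8{pos % 1_000_000:06d}",
            freq_kg=freq,
            freq_evs=None,
            sift=sift,
            polyphen=polyphen,
            phylop=float(rng.uniform(2.0, 7.0)),
            phastcons=float(rng.uniform(0.9, 1.0)),
            segdup=False,
            min_depth=int(rng.integers(20, 80)),
        )

    def plant_inherited(fam: Pedigree, variant: AnnotatedVariant, side: str) -> str:
        parent = fam.member(f"{fam.fid}_D" if side == "paternal" else f"{fam.fid}_M")
        founder_plants.setdefault((fam.fid, parent.iid), []).append((variant.key, 0))
        variants.append(variant)
        pop_freq[variant.key] = 0.0  # private: no population draws
        return side

    for fam, gene in zip(candidate_fams, candidate_plant_genes):
        v = make_planted(gene, 0, FuncClass.nonsynonymous_snv, "rare" if rng.random() < 0.5 else "novel")
        side = plant_inherited(fam, v, "paternal" if rng.random() < 0.5 else "maternal")
        forced_choice[(fam.fid, gene)] = (0, 0)
        truth.candidate.append(
            PlantedVariant("candidate", fam.fid, fam.proband.iid, gene, v.key, side)
        )

    for fam, gene in zip(stopgain_fams, stopgain_genes):
        v = make_planted(gene, 0, FuncClass.stopgain, "rare")
        side = plant_inherited(fam, v, "paternal" if rng.random() < 0.5 else "maternal")
        forced_choice[(fam.fid, gene)] = (0, 0)
        truth.stopgain.append(
            PlantedVariant("stopgain", fam.fid, fam.proband.iid, gene, v.key, side)
        )

    for fam, gene in zip(comphet_fams, comphet_genes):
        v1 = make_planted(gene, 0, FuncClass.nonsynonymous_snv, "rare")
        v2 = make_planted(gene, 3, FuncClass.nonsynonymous_snv, "novel")
        plant_inherited(fam, v1, "paternal")
        plant_inherited(fam, v2, "maternal")
        forced_choice[(fam.fid, gene)] = (0, 0)  # proband takes both carrier haps
        truth.comphet.append(
            {
                "family": fam.fid,
                "proband": fam.proband.iid,
                "gene": gene,
                "keys": [v1.key, v2.key],
                "phase": "trans",
            }
        )

    for fam, gene in zip(denovo_fams, denovo_genes):
        v = make_planted(gene, 0, FuncClass.nonsynonymous_snv, "novel")
        variants.append(v)
        pop_freq[v.key] = 0.0
        denovo_alleles[(fam.fid, v.key)] = 1
        truth.denovo.append(
            PlantedVariant("denovo", fam.fid, fam.proband.iid, gene, v.key, "de_novo")
        )

    # --- pathway excess: one qualifying rare variant per selected proband
    set_id, excess_rate = cfg.plant_pathway
    target_set = next((s for s in gene_sets.sets if s.set_id == set_id), None)
    if target_set is not None and excess_rate > 0:
        n_hit = int(round(excess_rate * cfg.n_families))
        hit_idx = rng.choice(cfg.n_families, size=n_hit, replace=False)
        truth.pathway_set_id = set_id
        set_genes = sorted(target_set.genes)
        for j, fi in enumerate(sorted(hit_idx)):
            fam = pedigrees[fi]
            gene = set_genes[j % len(set_genes)]
            slot = 10 + j // len(set_genes)  # unique position per (gene, reuse)
            v = make_planted(gene, slot, FuncClass.nonsynonymous_snv, "rare")
            side = "paternal" if rng.random() < 0.5 else "maternal"
            plant_inherited(fam, v, side)
            forced_choice.setdefault((fam.fid, gene), (0, 0))
            truth.pathway_probands.append(fam.proband.iid)
            truth.pathway_variants.append(
                PlantedVariant("pathway", fam.fid, fam.proband.iid, gene, v.key, side)
            )

    # --- founder haplotypes and Mendelian transmission
    variants.sort(key=lambda v: (int(v.chrom.removeprefix("chr")), v.pos, v.ref, v.alt))
    key_index = {v.key: i for i, v in enumerate(variants)}
    n_var = len(variants)
    freqs = np.array([pop_freq[v.key] for v in variants])
    gene_of = [v.gene for v in variants]
    genes_in_use = sorted(set(gene_of))
    gene_idx = {g: i for i, g in enumerate(genes_in_use)}
    var_gene = np.array([gene_idx[g] for g in gene_of])

    carriers: CarrierMap = {v.key: () for v in variants}
    for fam in pedigrees:
        founders = [m for m in fam.members if m.is_founder]
        haps: dict[str, np.ndarray] = {}
        for founder in founders:
            hap = (rng.random((n_var, 2)) < freqs[:, None]).astype(np.int8)
            for key, col in founder_plants.get((fam.fid, founder.iid), []):
                hap[key_index[key], :] = 0
                hap[key_index[key], col] = 1
            haps[founder.iid] = hap
        for member in fam.members:
            if member.is_founder:
                alleles = haps[member.iid].sum(axis=1)
            else:
                cf = rng.integers(0, 2, size=len(genes_in_use))
                cm = rng.integers(0, 2, size=len(genes_in_use))
                if member.role == "proband":
                    for (fid, gene), (fcol, mcol) in forced_choice.items():
                        if fid == fam.fid and gene in gene_idx:
                            cf[gene_idx[gene]] = fcol
                            cm[gene_idx[gene]] = mcol
                idx = np.arange(n_var)
                alleles = (
                    haps[member.father][idx, cf[var_gene]]
                    + haps[member.mother][idx, cm[var_gene]]
                ).astype(np.int8)
                if member.role == "proband":
                    for (fid, key), extra in denovo_alleles.items():
                        if fid == fam.fid:
                            vi = key_index[key]
                            alleles[vi] = min(2, alleles[vi] + extra)
            gt_codes = (Genotype.hom_ref, Genotype.het, Genotype.hom_alt)
            for vi in np.nonzero(alleles)[0]:
                fam.genotypes[(member.iid, variants[vi].key)] = gt_codes[alleles[vi]]
            if member.role == "proband":
                for vi in np.nonzero(alleles)[0]:
                    carriers[variants[vi].key] = carriers[variants[vi].key] + (member.iid,)

    # hom_ref genotypes for family members at family-relevant (screened) keys:
    # store explicitly so segregation sees genotyped non-carriers
    screened_keys = (
        {p.key for p in truth.candidate}
        | {p.key for p in truth.stopgain}
        | {p.key for p in truth.denovo}
        | {p.key for p in truth.pathway_variants}
        | {k for c in truth.comphet for k in c["keys"]}
    )
    for fam in pedigrees:
        for member in fam.members:
            for key in screened_keys:
                fam.genotypes.setdefault((member.iid, key), Genotype.hom_ref)

    # --- phenotypes: probands affected (ascertainment); carrier sibs by penetrance
    planted_by_family: dict[str, set[VariantKey]] = {}
    for p in truth.candidate + truth.stopgain + truth.denovo:
        planted_by_family.setdefault(p.family, set()).add(p.key)
    for c in truth.comphet:
        planted_by_family.setdefault(c["family"], set()).update(c["keys"])

    for fam in pedigrees:
        for member in fam.members:
            if member.is_founder:
                continue  # parents: child-normed tests do not apply
            if member.role == "proband":
                affected = True
            else:
                keys = planted_by_family.get(fam.fid, set())
                carries = any(
                    fam.genotypes.get((member.iid, k), Genotype.hom_ref)
                    in (Genotype.het, Genotype.hom_alt)
                    for k in keys
                )
                if carries:
                    affected = bool(rng.random() < cfg.penetrance)
                else:
                    affected = bool(rng.random() < cfg.sib_background_affection)
            member.els, member.rls = _score_pair(affected, rng)
            member.affected = Affection.affected if affected else Affection.unaffected

    return SimulatedCohort(
        config=cfg,
        variants=variants,
        carriers=carriers,
        pedigrees=pedigrees,
        gene_sets=gene_sets,
        truth=truth,
    )


def genotype_calls(cohort: SimulatedCohort) -> list[GenotypeCall]:
    calls = []
    for fam in cohort.pedigrees:
        for (iid, key), gt in sorted(fam.genotypes.items()):
            calls.append(GenotypeCall(sample_id=iid, variant_key=key, gt=gt))
    return calls


def write_vcf(cohort: SimulatedCohort, path: PathLike) -> None:
    """Emit all genotypes as a minimal annotated VCF (unphased)."""
    samples = [m.iid for fam in cohort.pedigrees for m in fam.members]
    gt_code = {Genotype.hom_ref: "0/0", Genotype.het: "0/1", Genotype.hom_alt: "1/1"}
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in range(1, 23):
            fh.write(f"##contig=<ID=chr{chrom}>\n")
        for key, vtype, desc in (
            ("GENE", "String", "Gene symbol"),
            ("FC", "String", "Functional class"),
            ("KG_AF", "Float", "1000 Genomes allele frequency"),
            ("EVS_AF", "Float", "EVS allele frequency"),
            ("SIFT", "Float", "SIFT score"),
            ("PP2", "Float", "PolyPhen-2 score"),
            ("SEGDUP", "Integer", "Segmental duplication flag"),
            ("MIN_DP", "Integer", "Minimum carrier depth"),
        ):
            fh.write(
                f'##INFO=<ID={key},Number=1,Type={vtype},Description="{desc}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        genotype_of = {}
        for fam in cohort.pedigrees:
            genotype_of.update(fam.genotypes)
        for v in cohort.variants:
            info = [f"GENE={v.gene}", f"FC={v.func_class.value}"]
            if v.freq_kg is not None:
                info.append(f"KG_AF={v.freq_kg:.6g}")
            if v.freq_evs is not None:
                info.append(f"EVS_AF={v.freq_evs:.6g}")
            if v.sift is not None:
                info.append(f"SIFT={v.sift:.6g}")
            if v.polyphen is not None:
                info.append(f"PP2={v.polyphen:.6g}")
            info.append(f"SEGDUP={int(v.segdup)}")
            info.append(f"MIN_DP={v.min_depth}")
            gts = [
                gt_code[genotype_of.get((s, v.key), Genotype.hom_ref)] for s in samples
            ]
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.rsid or ".",
                        v.ref,
                        v.alt,
                        ".",
                        "PASS",
                        ";".join(info),
                        "GT",
                        *gts,
                    ]
                )
                + "\n"
            )


def write_cohort(cohort: SimulatedCohort, outdir: PathLike) -> dict[str, Path]:
    """Write the cohort files: variant TSV, PED, GMT, VCF and truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "ped": outdir / "cohort.ped",
        "gmt": outdir / "pathways.gmt",
        "vcf": outdir / "genotypes.vcf",
        "truth": outdir / "truth.json",
    }
    write_variant_table(cohort.variants, cohort.carriers, paths["variants"])
    write_ped(cohort.pedigrees, paths["ped"])
    write_gmt(cohort.gene_sets, paths["gmt"])
    write_vcf(cohort, paths["vcf"])
    paths["truth"].write_text(cohort.truth.to_json() + "\n", encoding="utf-8")
    return paths
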