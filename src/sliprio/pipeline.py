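"""End-to-end orchestration: QC, screens, segregation, pathway and GO stages.

``run_all`` executes the stages in the order the analysis reports them:
candidate screen, stop-gain screen, compound-het grouping, multiple-hit
pooling, per-family segregation of shortlisted variants, within-proband
pathway sharing, and pooled GO enrichment with frequency-stratified lists.
Every stage writes a TSV report; a run log records the effective
configuration, seed, and per-stage record counts, sufficient to reproduce
the run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io
from .candidates import screen_candidates, tier_percentages, TIER_ORDER
from .enrichment import enrich, stratify_by_frequency
from .filters import FilterConfig, qc_filter
from .fixtures import load_candidate_genes
from .highrisk import comphet_candidates, multihit_probands, stopgain_screen
from .models import GenotypeCall, Pedigree
from .pathways import permutation_fdr, proband_gene_sets
from .segregation import Phase, phase_comphet, segregation_verdict


@dataclass
class RunConfig:
    variants: str
    ped: Optional[str] = None
    gmt: Optional[str] = None
    genotypes_vcf: Optional[str] = None
    candidate_list: Optional[str] = None
    outdir: str = "sliprio_out"
    filters: FilterConfig = field(default_factory=FilterConfig)
    n_perm: int = 1000
    seed: int = 0
    p_threshold: float = 0.01
    fdr_threshold: float = 0.01
    min_set_size: int = 10


def attach_genotypes(pedigrees: list[Pedigree], calls: list[GenotypeCall]) -> None:
    """Populate per-family genotype maps from genotype calls by sample id."""
    owner = {m.iid: fam for fam in pedigrees for m in fam.members}
    for call in calls:
        fam = owner.get(call.sample_id)
        if fam is not None:
            fam.genotypes[(call.sample_id, call.variant_key)] = call.gt


def _key_str(key) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; write reports into ``cfg.outdir``; return summaries."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": _config_dict(cfg), "stages": {}}

    variants, carriers = io.read_variant_table(cfg.variants)
    log["stages"]["input"] = {"variants": len(variants)}

    retained, exclusions = qc_filter(variants, cfg.filters)
    log["stages"]["qc_filter"] = exclusions.as_dict()

    genes = (
        io.read_gene_list(cfg.candidate_list)
        if cfg.candidate_list
        else load_candidate_genes()
    )
    summary, shortlist = screen_candidates(retained, carriers, tuple(genes), cfg.filters)
    log["stages"]["candidate_screen"] = {
        "total": summary.total,
        "shortlist": len(shortlist),
    }

    stopgains = stopgain_screen(retained, carriers, cfg.filters)
    log["stages"]["stopgain_screen"] = {"retained": len(stopgains)}

    comphets = comphet_candidates(retained, carriers, cfg.filters)
    log["stages"]["comphet"] = {
        "candidates": len(comphets),
        "genes": len({c.gene for c in comphets}),
    }

    multihit = multihit_probands(shortlist, stopgains, comphets)
    log["stages"]["multihit"] = {"probands": len(multihit)}

    # segregation over shortlisted variants, when pedigrees and genotypes exist
    segregation_rows = []
    pedigrees: list[Pedigree] = []
    if cfg.ped:
        pedigrees = io.read_ped(cfg.ped)
        if cfg.genotypes_vcf:
            _, calls = io.import_vcf(cfg.genotypes_vcf)
            attach_genotypes(pedigrees, calls)
        by_fid = {fam.fid: fam for fam in pedigrees}
        proband_family = {
            fam.proband.iid: fam for fam in pedigrees if any(
                m.role == "proband" for m in fam.members
            )
        }
        followed = [
            (e.variant.key, e.carriers) for e in shortlist
        ] + [(r.variant.key, r.carriers) for r in stopgains]
        for key, carrier_ids in followed:
            for proband in carrier_ids:
                fam = proband_family.get(proband)
                if fam is None or (proband, key) not in fam.genotypes:
                    continue
                verdict = segregation_verdict(key, fam)
                segregation_rows.append(
                    {
                        "fid": fam.fid,
                        "variant": _key_str(key),
                        "origin": verdict.origin.value,
                        "cosegregation": verdict.cosegregation.value,
                        "carriers_affected": verdict.carriers_affected,
                        "carriers_unaffected": verdict.carriers_unaffected,
                        "noncarriers_affected": verdict.noncarriers_affected,
                    }
                )
        for cand in comphets:
            fam = proband_family.get(cand.proband)
            if fam is None:
                continue
            keys = [v.key for v in cand.variants]
            if all((cand.proband, k) in fam.genotypes for k in keys):
                cand.phase = phase_comphet(keys, fam)
        log["stages"]["segregation"] = {"verdicts": len(segregation_rows)}

    # pathway sharing and pooled enrichment
    pathway_rows, enrichment_rows, strata = [], [], {}
    probands = sorted({p for ids in carriers.values() for p in ids})
    if pedigrees:
        probands = sorted({fam.proband.iid for fam in pedigrees})
    gene_sets_by_proband = proband_gene_sets(retained, carriers, cfg.filters, probands)
    universe = sorted({v.gene for v in variants})
    if cfg.gmt:
        pathways = io.read_gmt(cfg.gmt)
        results = permutation_fdr(
            gene_sets_by_proband,
            pathways,
            universe,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
        )
        cohort_size = len(gene_sets_by_proband)
        pathway_rows = [
            {
                "set_id": r.set_id,
                "set_name": r.set_name,
                "observed": r.observed_probands,
                "fdr": r.fdr,
                "majority": int(r.majority_flag(cohort_size)),
                "n_perm": r.n_perm,
                "seed": r.seed,
            }
            for r in results
        ]
        pooled = set().union(*gene_sets_by_proband.values()) if gene_sets_by_proband else set()
        if pooled:
            enrichment_rows = [
                {
                    "set_id": r.set_id,
                    "term": r.term,
                    "exp_count": r.exp_count,
                    "count": r.count,
                    "p": f"{r.p:.6g}",
                    "fdr": f"{r.fdr:.6g}",
                }
                for r in enrich(
                    pooled,
                    set(universe),
                    pathways,
                    p_threshold=cfg.p_threshold,
                    fdr_threshold=cfg.fdr_threshold,
                    min_set_size=cfg.min_set_size,
                )
            ]
        log["stages"]["pathway_share"] = {"pathways": len(pathway_rows)}
        log["stages"]["go_enrichment"] = {"significant": len(enrichment_rows)}
    strata = stratify_by_frequency(retained, cfg.filters)
    log["stages"]["strata"] = {k: len(v) for k, v in strata.items()}

    # reports
    summary_rows = []
    for gene in sorted(summary.per_gene_counts):
        row = {"gene": gene}
        row.update(
            {t.value: summary.per_gene_counts[gene][t] for t in TIER_ORDER}
        )
        summary_rows.append(row)
    overall = {"gene": "ALL"}
    overall.update({t.value: summary.overall_counts[t] for t in TIER_ORDER})
    summary_rows.append(overall)

    reports = {
        "candidate_summary": summary_rows,
        "candidate_shortlist": (
            [e.variant for e in shortlist],
            {e.variant.key: e.carriers for e in shortlist},
        ),
        "stopgain_screen": (
            [r.variant for r in stopgains],
            {r.variant.key: r.carriers for r in stopgains},
        ),
        "comphet_candidates": [
            {
                "proband": c.proband,
                "gene": c.gene,
                "n_variants": len(c.variants),
                "phase": c.phase.value,
                "variants": ";".join(_key_str(v.key) for v in c.variants),
            }
            for c in comphets
        ],
        "multihit": [
            {
                "proband": m.proband,
                "category": cat,
                "gene": gene,
                "variants": ";".join(_key_str(k) for k in keys),
            }
            for m in multihit
            for (cat, gene, keys) in m.hits
        ],
        "segregation": segregation_rows,
        "pathway_share": pathway_rows,
        "go_enrichment": enrichment_rows,
        "strata": [
            {"stratum": name, "gene": gene}
            for name in ("novel", "rare", "low_frequency")
            for gene in sorted(strata.get(name, ()))
        ],
    }
    io.write_report_tables(reports, outdir)
    (outdir / "run_log.json").write_text(
        json.dumps(log, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {
        "log": log,
        "summary": summary,
        "shortlist": shortlist,
        "stopgains": stopgains,
        "comphets": comphets,
        "multihit": multihit,
        "pathway_rows": pathway_rows,
        "enrichment_rows": enrichment_rows,
        "strata": strata,
        "tier_percentages": (
            tier_percentages(summary.overall_counts) if summary.total else None
        ),
    }


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
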