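"""Readers and writers for the annotated-variant TSV dialect, PED, GMT and VCF.

The variant dialect has 17 tab-separated columns with a mandatory header::

    chrom pos rsid ref alt carriers freq_evs_pct freq_kg_pct gene func_class
    coding_change phylop phastcons sift polyphen segdup min_depth

``NA`` is the sole missing-value token (an empty cell is an error, guarding
against silent column drift); ``rsid`` additionally accepts ``.`` for absent,
as is conventional for dbSNP identifiers.  Columns suffixed ``_pct`` hold
percentages and are converted to fractions on read; writing restores the
percent scale.  ``carriers`` is a comma-separated list of proband identifiers
(multi-carrier variants occupy one row).

The extended PED dialect appends five phenotype columns (els, rls, nwr, viq,
piq; standardized scores, ``NA`` for missing) to the standard six.  Within a
family, children are taken in file order and the first-listed child is the
proband.  Affection status is derived from els/rls (never from the standard
phenotype column, which is retained only for interoperability).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Optional, Union

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
from .segregation import affection_status

VARIANT_COLUMNS = (
    "chrom",
    "pos",
    "rsid",
    "ref",
    "alt",
    "carriers",
    "freq_evs_pct",
    "freq_kg_pct",
    "gene",
    "func_class",
    "coding_change",
    "phylop",
    "phastcons",
    "sift",
    "polyphen",
    "segdup",
    "min_depth",
)

MISSING = "NA"

PathLike = Union[str, os.PathLike]


class TableFormatError(ValueError):
    """A malformed row in one of the text dialects, with its line number."""


def _parse_pct(cell: str, column: str, lineno: int) -> Optional[float]:
    if cell == MISSING:
        return None
    try:
        pct = float(cell)
    except ValueError as exc:
        raise TableFormatError(f"line {lineno}: bad number {cell!r} in {column}") from exc
    if not (0.0 <= pct <= 100.0):
        raise TableFormatError(
            f"line {lineno}: {column} value {pct} outside [0, 100] percent"
        )
    # normalize to 10 significant digits so that the same logical frequency
    # yields the same float regardless of the path it arrived by (percent
    # column vs VCF INFO fraction)
    return float(f"{pct / 100.0:.10g}")


def _parse_float(cell: str, column: str, lineno: int) -> Optional[float]:
    if cell == MISSING:
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise TableFormatError(f"line {lineno}: bad number {cell!r} in {column}") from exc


def read_variant_table(path: PathLike) -> tuple[list[AnnotatedVariant], CarrierMap]:
    """Read an annotated-variant TSV; return the variants and the carrier map."""
    variants: list[AnnotatedVariant] = []
    carriers: CarrierMap = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != VARIANT_COLUMNS:
            raise TableFormatError(
                f"line 1: header {header!r} does not match the dialect columns"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(VARIANT_COLUMNS):
                raise TableFormatError(
                    f"line {lineno}: expected {len(VARIANT_COLUMNS)} columns, "
                    f"got {len(cells)}"
                )
            row = dict(zip(VARIANT_COLUMNS, cells))
            if any(cell == "" for cell in cells):
                raise TableFormatError(f"line {lineno}: empty cell (use 'NA')")
            try:
                func_class = FuncClass(row["func_class"])
            except ValueError as exc:
                raise TableFormatError(
                    f"line {lineno}: unknown func_class {row['func_class']!r}"
                ) from exc
            try:
                pos = int(row["pos"])
                depth = int(row["min_depth"])
                segdup = bool(int(row["segdup"]))
            except ValueError as exc:
                raise TableFormatError(f"line {lineno}: {exc}") from exc
            rsid = None if row["rsid"] in (".", MISSING) else row["rsid"]
            try:
                variant = AnnotatedVariant(
                    chrom=row["chrom"],
                    pos=pos,
                    rsid=rsid,
                    ref=row["ref"],
                    alt=row["alt"],
                    gene=row["gene"],
                    func_class=func_class,
                    coding_change="" if row["coding_change"] == MISSING else row["coding_change"],
                    freq_evs=_parse_pct(row["freq_evs_pct"], "freq_evs_pct", lineno),
                    freq_kg=_parse_pct(row["freq_kg_pct"], "freq_kg_pct", lineno),
                    phylop=_parse_float(row["phylop"], "phylop", lineno),
                    phastcons=_parse_float(row["phastcons"], "phastcons", lineno),
                    sift=_parse_float(row["sift"], "sift", lineno),
                    polyphen=_parse_float(row["polyphen"], "polyphen", lineno),
                    segdup=segdup,
                    min_depth=depth,
                )
            except ValueError as exc:
                raise TableFormatError(f"line {lineno}: {exc}") from exc
            variants.append(variant)
            ids = tuple(s for s in row["carriers"].split(",") if s and s != MISSING)
            carriers[variant.key] = ids
    return variants, carriers


def _fmt_pct(value: Optional[float]) -> str:
    if value is None:
        return MISSING
    # exact for percentages with <= 4 decimal digits (fl error << 1e-10)
    text = f"{value * 100:.10f}".rstrip("0").rstrip(".")
    return text or "0"


def _fmt_float(value: Optional[float]) -> str:
    return MISSING if value is None else repr(value)


def variant_row(variant: AnnotatedVariant, carrier_ids: Iterable[str]) -> str:
    cells = (
        variant.chrom,
        str(variant.pos),
        variant.rsid if variant.rsid is not None else ".",
        variant.ref,
        variant.alt,
        ",".join(carrier_ids) or MISSING,
        _fmt_pct(variant.freq_evs),
        _fmt_pct(variant.freq_kg),
        variant.gene,
        variant.func_class.value,
        variant.coding_change or MISSING,
        _fmt_float(variant.phylop),
        _fmt_float(variant.phastcons),
        _fmt_float(variant.sift),
        _fmt_float(variant.polyphen),
        str(int(variant.segdup)),
        str(variant.min_depth),
    )
    return "\t".join(cells)


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    label = chrom.removeprefix("chr")
    return (int(label), "") if label.isdigit() else (1000, label)


def write_variant_table(
    variants: Iterable[AnnotatedVariant], carriers: CarrierMap, path: PathLike
) -> None:
    """Write a dialect-conformant TSV; rows sorted by (chrom, pos, ref, alt)."""
    rows = sorted(variants, key=lambda v: (_chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in rows:
            fh.write(variant_row(v, carriers.get(v.key, ())) + "\n")


def read_ped(path: PathLike) -> list[Pedigree]:
    """Read the extended PED dialect into per-family pedigrees."""
    rows: list[tuple[int, list[str]]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split()
            if len(cells) != 11:
                raise TableFormatError(
                    f"line {lineno}: expected 11 whitespace-separated fields, "
                    f"got {len(cells)}"
                )
            rows.append((lineno, cells))

    sex_map = {"1": Sex.male, "2": Sex.female}
    families: dict[str, Pedigree] = {}
    order: dict[str, list[Individual]] = {}
    for lineno, cells in rows:
        fid, iid, father, mother, sex_code, _pheno = cells[:6]
        if iid in (father, mother):
            raise TableFormatError(f"line {lineno}: individual {iid!r} is its own parent")
        scores = [None if c == MISSING else float(c) for c in cells[6:11]]
        ind = Individual(
            iid=iid,
            fid=fid,
            father=None if father in ("0", MISSING) else father,
            mother=None if mother in ("0", MISSING) else mother,
            sex=sex_map.get(sex_code, Sex.unknown),
            els=scores[0],
            rls=scores[1],
            nwr=scores[2],
            viq=scores[3],
            piq=scores[4],
        )
        ind.affected = affection_status(ind.els, ind.rls)
        fam = families.setdefault(fid, Pedigree(fid=fid))
        if any(m.iid == iid for m in fam.members):
            raise TableFormatError(f"line {lineno}: duplicate individual {iid!r} in {fid!r}")
        fam.members.append(ind)
        order.setdefault(fid, []).append(ind)

    for fam in families.values():
        known = {m.iid for m in fam.members}
        first_child = True
        for ind in fam.members:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in known:
                    raise TableFormatError(
                        f"family {fam.fid!r}: {ind.iid!r} references unknown parent "
                        f"{parent!r}"
                    )
            if ind.is_founder:
                ind.role = "parent"
            elif first_child:
                ind.role, first_child = "proband", False
            else:
                ind.role = "sibling"
    return list(families.values())


def write_ped(pedigrees: Iterable[Pedigree], path: PathLike) -> None:
    def fmt(score: Optional[float]) -> str:
        return MISSING if score is None else f"{score:.10g}"

    sex_code = {Sex.male: "1", Sex.female: "2", Sex.unknown: "0"}
    aff_code = {Affection.affected: "2", Affection.unaffected: "1", Affection.unknown: "0"}
    with open(path, "wt", encoding="utf-8") as fh:
        for fam in pedigrees:
            for ind in fam.members:
                fh.write(
                    " ".join(
                        [
                            fam.fid,
                            ind.iid,
                            ind.father or "0",
                            ind.mother or "0",
                            sex_code[ind.sex],
                            aff_code[ind.affected],
                            fmt(ind.els),
                            fmt(ind.rls),
                            fmt(ind.nwr),
                            fmt(ind.viq),
                            fmt(ind.piq),
                        ]
                    )
                    + "\n"
                )


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a GMT gene-set file (set_id <tab> description <tab> gene...)."""
    sets: list[GeneSet] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise TableFormatError(
                    f"line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            genes = frozenset(g for g in cells[2:] if g)
            sets.append(GeneSet(set_id=cells[0], name=cells[1], genes=genes))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gs in collection.sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.genes)]) + "\n")


def read_gene_list(path: PathLike) -> list[str]:
    """Read a one-symbol-per-line gene list (blank lines and # comments skipped)."""
    genes: list[str] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            symbol = line.strip()
            if not symbol or symbol.startswith("#"):
                continue
            if symbol not in seen:
                seen.add(symbol)
                genes.append(symbol)
    return genes


_VCF_FC = {fc.value: fc for fc in FuncClass}


def import_vcf(path: PathLike) -> tuple[list[AnnotatedVariant], list[GenotypeCall]]:
    """Import a minimal annotated VCF (INFO keys GENE, FC, KG_AF, EVS_AF, SIFT,
    PP2, SEGDUP, optional PHYLOP/PHASTCONS/MIN_DP) with per-sample GT.

    Multi-allelic records are split into one :class:`AnnotatedVariant` per
    alternate allele; per-sample genotypes are recoded against each allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    calls: list[GenotypeCall] = []
    for record in vcf:
        if record.FORMAT is None or "GT" not in record.FORMAT:
            raise TableFormatError(
                f"{record.CHROM}:{record.POS}: record has no GT format field"
            )
        info = dict(record.INFO)
        fc_raw = info.get("FC")
        func_class = _VCF_FC.get(fc_raw, FuncClass.nonsynonymous_snv)

        def _num(key: str) -> Optional[float]:
            val = info.get(key)
            if val is None:
                return None
            # INFO floats come back as float32; restore decimal precision
            return float(f"{float(val):.6g}")

        for alt_index, alt in enumerate(record.ALT, start=1):
            variant = AnnotatedVariant(
                chrom=record.CHROM,
                pos=record.POS,
                rsid=record.ID,
                ref=record.REF,
                alt=alt,
                gene=str(info.get("GENE", "")),
                func_class=func_class,
                freq_kg=_num("KG_AF"),
                freq_evs=_num("EVS_AF"),
                sift=_num("SIFT"),
                polyphen=_num("PP2"),
                phylop=_num("PHYLOP"),
                phastcons=_num("PHASTCONS"),
                segdup=bool(int(info.get("SEGDUP", 0))),
                min_depth=int(info.get("MIN_DP", 0)),
            )
            variants.append(variant)
            for sample, genotype in zip(samples, record.genotypes):
                alleles = [a for a in genotype[:-1]]
                if any(a < 0 for a in alleles):
                    gt = Genotype.missing
                else:
                    dose = sum(1 for a in alleles if a == alt_index)
                    gt = (Genotype.hom_ref, Genotype.het, Genotype.hom_alt)[dose]
                calls.append(GenotypeCall(sample_id=sample, variant_key=variant.key, gt=gt))
    return variants, calls


def write_report_tables(results: dict, outdir: PathLike) -> list[Path]:
    """Write the screen outputs of a run as TSV report files.

    ``results`` maps report names to either ``(variants, carriers)`` pairs
    (written in the variant dialect, round-trippable through
    :func:`read_variant_table`) or lists of flat dict rows (written as plain
    TSVs with the keys of the first row as header).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, payload in results.items():
        path = outdir / f"{name}.tsv"
        if isinstance(payload, tuple):
            variants, carriers = payload
            write_variant_table(variants, carriers, path)
        else:
            with open(path, "wt", encoding="utf-8") as fh:
                rows = list(payload)
                if rows:
                    columns = list(rows[0].keys())
                    fh.write("\t".join(columns) + "\n")
                    for row in rows:
                        fh.write("\t".join(str(row[c]) for c in columns) + "\n")
        written.append(path)
    return written
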