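"""Readers and writers for the pipeline's file formats.

* Pedigree: tab-separated superset of PED — family_id, id, father_id
  (0 = none), mother_id, sex (1 = male, 2 = female), affected (0 unknown /
  1 unaffected / 2 affected), age (integer or NA), carrier (C/N/U),
  proband (0/1).
* Incidence: CSV with columns sex, age_lo, age_hi, events, person_years,
  rate (rate optional when events/person_years are given).
* Genetic map: HapMap-style tab-separated chrom, pos(bp), cM.
* Genotypes: two-sample VCF using FILTER and FORMAT GT:DP:GQ (read through
  cyvcf2; written as plain text).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

_log = logging.getLogger("famseg")

from .errors import DataFormatError
from .ibd import GeneticMap, VariantSite
from .pedigree import (AFFECTED, CARRIER, FEMALE, MALE, NON_CARRIER,
                       UNAFFECTED, UNKNOWN, UNTESTED, Individual, Pedigree)
from .penetrance import IncidenceTable

__all__ = [
    "read_pedigrees", "read_pedigree", "write_pedigree",
    "read_incidence", "write_incidence",
    "read_map", "write_map",
    "read_vcf_pair", "write_vcf_pair",
]

_SEX_CODE = {"1": MALE, "2": FEMALE}
_AFF_CODE = {"0": UNKNOWN, "1": UNAFFECTED, "2": AFFECTED}
_CARRIER_CODE = {"C": CARRIER, "N": NON_CARRIER, "U": UNTESTED}


# ---------------------------------------------------------------------------
# Pedigree files
# ---------------------------------------------------------------------------

def read_pedigrees(path) -> list[Pedigree]:
    """Read every family in a pedigree file (order of first appearance)."""
    families: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DataFormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(parts)}")
            fam, iid, fid, mid, sex, aff, age, car, pro = parts
            try:
                ind = Individual(
                    id=iid,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX_CODE[sex],
                    affected=_AFF_CODE[aff],
                    age=None if age.upper() in ("NA", "") else int(age),
                    carrier_status=_CARRIER_CODE[car.upper()],
                    is_proband=pro == "1",
                )
            except (KeyError, ValueError) as exc:
                raise DataFormatError(f"{path}:{lineno}: {exc}") from exc
            families.setdefault(fam, []).append(ind)
    if not families:
        raise DataFormatError(f"{path}: no pedigree rows")
    return [Pedigree(fam, members) for fam, members in families.items()]


def read_pedigree(path) -> Pedigree:
    """Read a pedigree file that contains exactly one family."""
    peds = read_pedigrees(path)
    if len(peds) != 1:
        raise DataFormatError(
            f"{path}: expected one family, found {len(peds)}")
    return peds[0]


def write_pedigree(peds, path) -> None:
    if isinstance(peds, Pedigree):
        peds = [peds]
    sex_code = {MALE: "1", FEMALE: "2"}
    aff_code = {UNKNOWN: "0", UNAFFECTED: "1", AFFECTED: "2"}
    car_code = {CARRIER: "C", NON_CARRIER: "N", UNTESTED: "U"}
    with open(path, "w") as fh:
        fh.write("#family_id\tid\tfather_id\tmother_id\tsex\taffected"
                 "\tage\tcarrier\tproband\n")
        for ped in peds:
            for m in ped.members:
                fh.write("\t".join([
                    ped.family_id, m.id,
                    m.father_id or "0", m.mother_id or "0",
                    sex_code[m.sex], aff_code[m.affected],
                    "NA" if m.age is None else str(m.age),
                    car_code[m.carrier_status],
                    "1" if m.is_proband else "0"]) + "\n")


# ---------------------------------------------------------------------------
# Incidence CSV
# ---------------------------------------------------------------------------

def read_incidence(path) -> list[IncidenceTable]:
    """Read an incidence CSV; returns one table per sex present."""
    df = pd.read_csv(path)
    if df.empty:
        raise DataFormatError(f"{path}: incidence table has no rows")
    required = {"sex", "age_lo", "age_hi"}
    if not required.issubset(df.columns):
        raise DataFormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")
    has_counts = {"events", "person_years"}.issubset(df.columns)
    if "rate" not in df.columns and not has_counts:
        raise DataFormatError(f"{path}: need rate or events+person_years")
    tables = []
    for sex, sub in df.groupby("sex", sort=False):
        sub = sub.sort_values("age_lo")
        if has_counts:
            events = sub["events"].to_numpy(dtype=float)
            py = sub["person_years"].to_numpy(dtype=float)
            rate = (sub["rate"].to_numpy(dtype=float) if "rate" in sub
                    else events / py)
        else:
            events = py = None
            rate = sub["rate"].to_numpy(dtype=float)
        tables.append(IncidenceTable(
            sex=str(sex),
            age_lo=sub["age_lo"].to_numpy(dtype=float),
            age_hi=sub["age_hi"].to_numpy(dtype=float),
            rate=rate, events=events, person_years=py))
    return tables


def write_incidence(tables, path) -> None:
    if isinstance(tables, IncidenceTable):
        tables = [tables]
    frames = []
    for t in tables:
        frames.append(pd.DataFrame({
            "sex": t.sex, "age_lo": t.age_lo, "age_hi": t.age_hi,
            "events": np.nan if t.events is None else t.events,
            "person_years": np.nan if t.person_years is None else t.person_years,
            "rate": t.rate}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def read_map(path) -> GeneticMap:
    points: dict[str, list] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: expected chrom<TAB>pos<TAB>cM")
            chrom = parts[0]
            try:
                pos, cm = float(parts[1]), float(parts[2])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise DataFormatError(
                    f"{path}:{lineno}: non-numeric map entry") from None
            points.setdefault(chrom, []).append((pos, cm))
    if not points:
        raise DataFormatError(f"{path}: empty genetic map")
    arrays = {}
    for chrom, rows in points.items():
        pos = np.array([r[0] for r in rows])
        cm = np.array([r[1] for r in rows])
        if np.any(np.diff(pos) <= 0):
            raise DataFormatError(
                f"{path}: positions for chromosome {chrom} not ascending")
        arrays[chrom] = (pos, cm)
    return GeneticMap(points=arrays)


def write_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tcM\n")
        for chrom, (pos, cm) in gmap.points.items():
            for p, c in zip(pos, cm):
                fh.write(f"{chrom}\t{int(p)}\t{c:.6f}\n")


# ---------------------------------------------------------------------------
# Two-sample VCF
# ---------------------------------------------------------------------------

def read_vcf_pair(path, sample_a: str, sample_b: str) -> list[VariantSite]:
    """Read the two samples' genotypes from a VCF, in (chrom, pos) order.

    Multiallelic and non-SNV records are excluded (count logged); FILTER,
    FORMAT/DP, FORMAT/GQ and FORMAT/GT are used.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing = [s for s in (sample_a, sample_b) if s not in samples]
    if missing:
        raise DataFormatError(
            f"sample(s) {missing} not in VCF; available: {samples}")
    ia, ib = samples.index(sample_a), samples.index(sample_b)

    sites: list[VariantSite] = []
    n_excluded = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_excluded += 1
            continue
        gts = var.gt_types  # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        g1 = None if gts[ia] == 3 else int(gts[ia])
        g2 = None if gts[ib] == 3 else int(gts[ib])
        dp = var.format("DP")
        gq = var.format("GQ")
        dp_pair = ((int(dp[ia][0]), int(dp[ib][0]))
                   if dp is not None else (0, 0))
        gq_pair = ((int(gq[ia][0]), int(gq[ib][0]))
                   if gq is not None else (0, 0))
        sites.append(VariantSite(
            chrom=str(var.CHROM), pos=int(var.POS),
            genotypes=(g1, g2),
            filter=var.FILTER if var.FILTER is not None else "PASS",
            depth=dp_pair, genotype_quality=gq_pair,
            ref=str(var.REF), alt=str(var.ALT[0])))
    if n_excluded:
        _log.info("excluded %d multiallelic/non-SNV records", n_excluded)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


_GT_STRING = {None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf_pair(sites, path, sample_a: str = "SAMPLE_A",
                   sample_b: str = "SAMPLE_B") -> None:
    """Write sites as an uncompressed two-sample VCF (GT:DP:GQ)."""
    contigs: dict[str, int] = {}
    for s in sites:
        contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos)
    filters = sorted({s.filter for s in sites} - {"PASS"})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famseg\n")
        for chrom, maxpos in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        for flt in filters:
            fh.write(f'##FILTER=<ID={flt},Description="Failed quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 f"\t{sample_a}\t{sample_b}\n")
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
            cols = [s.chrom, str(s.pos), ".", s.ref, s.alt, ".", s.filter,
                    ".", "GT:DP:GQ",
                    f"{_GT_STRING[s.genotypes[0]]}:{s.depth[0]}"
                    f":{s.genotype_quality[0]}",
                    f"{_GT_STRING[s.genotypes[1]]}:{s.depth[1]}"
                    f":{s.genotype_quality[1]}"]
            fh.write("\t".join(cols) + "\n")
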