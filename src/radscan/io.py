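"""Readers and writers for the tabular formats around a RAD SNP analysis.

Formats:

* VCF 4.2 — genotypes (GT only).  The RAD locus id and the SNP's 0-based
  offset within the locus travel in the ID column as ``<locus>_<offset>`` and
  are echoed in INFO (``LOCUS=...;OFFSET=...``).  CHROM is the locus id and
  POS the 1-based offset, so the file is valid for generic VCF tooling.
* Locus catalog TSV — ``locus_id, length_bp, site_ids, covered_individuals``
  (the last two comma-separated).
* Population map TSV — seven named columns (individual, population, species,
  locality, region, climate, soil).
* Sister-pair contrast YAML — list of pairs with the two sides' individual
  ids and which side is the ultramafic one.
* Structure input — two rows per diploid individual, alleles coded
  A/C/G/T -> 1/2/3/4, missing -9.
* Relaxed PHYLIP — one concatenated sequence per individual with IUPAC
  ambiguity codes for heterozygotes and N for missing.
* NEXUS distances block — input for network software (e.g. NeighborNet).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .genotypes import (
    IUPAC_HET,
    MISSING,
    DistanceMatrix,
    GenotypeMatrix,
    LocusCatalog,
    LocusRecord,
    PopulationMap,
    RadscanError,
    SisterPairContrast,
)

_NUC_CODE = {"A": "1", "C": "2", "G": "3", "T": "4"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the genotype matrix as a minimal VCF 4.2 file."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=radscan",
        '##INFO=<ID=LOCUS,Number=1,Type=String,Description="RAD locus id">',
        '##INFO=<ID=OFFSET,Number=1,Type=Integer,Description="0-based offset of the SNP within its locus">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for locus_id in dict.fromkeys(matrix.sites["locus_id"]):
        lines.append(f"##contig=<ID={locus_id}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.individuals)
    )
    for j, row in matrix.sites.iterrows():
        gts = "\t".join(_GT_STRING[int(d)] for d in matrix.calls[:, j])
        lines.append(
            f"{row['locus_id']}\t{int(row['offset']) + 1}\t{row['site_id']}\t"
            f"{row['ref']}\t{row['alt']}\t.\tPASS\t"
            f"LOCUS={row['locus_id']};OFFSET={int(row['offset'])}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    Multi-allelic records are dropped with a count reported via a warning
    attribute on the returned matrix (``n_dropped_multiallelic``); genotypes
    are reduced to alt-allele dosage.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    site_rows = []
    columns = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.REF is None or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        site_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS - 1}"
        offset = var.INFO.get("OFFSET")
        if offset is None:
            offset = var.POS - 1
        site_rows.append(
            {"site_id": site_id, "locus_id": var.CHROM, "offset": int(offset),
             "ref": var.REF, "alt": var.ALT[0]}
        )
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types
        col = np.full(len(individuals), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        columns.append(col)
    vcf.close()
    if not site_rows:
        raise RadscanError(f"no usable biallelic SNP records in {path}")
    sites = pd.DataFrame(site_rows)
    calls = np.column_stack(columns)
    matrix = GenotypeMatrix(individuals, sites, calls)
    matrix.n_dropped_multiallelic = n_multi
    return matrix


# ---------------------------------------------------------------------------
# Locus catalog TSV
# ---------------------------------------------------------------------------

def write_catalog(catalog: LocusCatalog, path: str | os.PathLike) -> None:
    rows = []
    for lid, rec in catalog.loci.items():
        rows.append(
            {
                "locus_id": lid,
                "length_bp": rec.length_bp,
                "site_ids": ",".join(rec.site_ids),
                "covered_individuals": ",".join(sorted(rec.covered_individuals)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | os.PathLike) -> LocusCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    loci = {}
    for _, row in df.iterrows():
        loci[row["locus_id"]] = LocusRecord(
            locus_id=row["locus_id"],
            length_bp=int(row["length_bp"]),
            site_ids=[s for s in row["site_ids"].split(",") if s],
            covered_individuals={s for s in row["covered_individuals"].split(",") if s},
        )
    return LocusCatalog(loci)


# ---------------------------------------------------------------------------
# Population map TSV
# ---------------------------------------------------------------------------

def write_popmap(popmap: PopulationMap, path: str | os.PathLike) -> None:
    popmap.table[PopulationMap.COLUMNS].to_csv(path, sep="\t", index=False)


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    return PopulationMap(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# Sister-pair contrast YAML
# ---------------------------------------------------------------------------

def write_pairs(pairs: list[SisterPairContrast], path: str | os.PathLike) -> None:
    doc = [
        {
            "pair_id": p.pair_id,
            "side_a": sorted(p.side_a),
            "side_b": sorted(p.side_b),
            "ultramafic_side": p.ultramafic_side,
            "label": p.label,
        }
        for p in pairs
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_pairs(path: str | os.PathLike) -> list[SisterPairContrast]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, list):
        raise RadscanError(f"pair contrast file {path} must be a YAML list")
    return [
        SisterPairContrast(
            pair_id=str(d["pair_id"]),
            side_a=set(d["side_a"]),
            side_b=set(d["side_b"]),
            ultramafic_side=d["ultramafic_side"],
            label=d.get("label", ""),
        )
        for d in doc
    ]


# ---------------------------------------------------------------------------
# Structure / PHYLIP / NEXUS exports
# ---------------------------------------------------------------------------

def write_structure(matrix: GenotypeMatrix, path: str | os.PathLike,
                    popmap: PopulationMap | None = None) -> None:
    """Structure input: two rows per individual, -9 for missing alleles."""
    pop_index: dict[str, int] = {}
    if popmap is not None:
        for p in dict.fromkeys(popmap.table["population_id"]):
            pop_index[p] = len(pop_index) + 1
        ind_pop = dict(zip(popmap.table["individual_id"], popmap.table["population_id"]))
    refs = [ _NUC_CODE[r] for r in matrix.sites["ref"] ]
    alts = [ _NUC_CODE[a] for a in matrix.sites["alt"] ]
    lines = ["\t".join(matrix.sites["site_id"])]
    for i, ind in enumerate(matrix.individuals):
        pop = str(pop_index[ind_pop[ind]]) if popmap is not None else "1"
        row1, row2 = [], []
        for j, d in enumerate(matrix.calls[i]):
            if d == MISSING:
                row1.append("-9"); row2.append("-9")
            elif d == 0:
                row1.append(refs[j]); row2.append(refs[j])
            elif d == 2:
                row1.append(alts[j]); row2.append(alts[j])
            else:
                row1.append(refs[j]); row2.append(alts[j])
        lines.append("\t".join([ind, pop] + row1))
        lines.append("\t".join([ind, pop] + row2))
    Path(path).write_text("\n".join(lines) + "\n")


def write_phylip(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Relaxed PHYLIP of concatenated SNPs with IUPAC codes for heterozygotes."""
    refs = list(matrix.sites["ref"])
    alts = list(matrix.sites["alt"])
    het = [IUPAC_HET[frozenset((r, a))] for r, a in zip(refs, alts)]
    lines = [f"{matrix.n_individuals} {matrix.n_sites}"]
    for i, ind in enumerate(matrix.individuals):
        seq = []
        for j, d in enumerate(matrix.calls[i]):
            seq.append("N" if d == MISSING else (refs[j], het[j], alts[j])[d])
        lines.append(f"{ind}  {''.join(seq)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_nexus_distances(dm: DistanceMatrix, path: str | os.PathLike) -> None:
    """NEXUS distances block (lower-triangular), the input NeighborNet expects."""
    n = len(dm.individuals)
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"  DIMENSIONS NTAX={n};",
        "  TAXLABELS " + " ".join(dm.individuals) + ";",
        "END;",
        "BEGIN DISTANCES;",
        f"  DIMENSIONS NTAX={n};",
        "  FORMAT TRIANGLE=LOWER DIAGONAL LABELS=LEFT;",
        "  MATRIX",
    ]
    for i, ind in enumerate(dm.individuals):
        vals = " ".join(f"{dm.distances[i, j]:.6f}" for j in range(i + 1))
        lines.append(f"    {ind} {vals}")
    lines += ["  ;", "END;"]
    Path(path).write_text("\n".join(lines) + "\n")
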