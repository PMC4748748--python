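"""The D1/D2/D3 SNP filtering cascade and the assembly-parameter criterion.

The cascade mirrors a standard RADseq quality workflow for de-novo
assemblies:

1. *Blacklist SNP-rich loci* — loci with more than ``max_snps`` SNPs
   (default 9, i.e. 10 or more SNPs removed) are treated as likely pooled
   paralogs and discarded outright.
2. *Coverage filter* — loci kept only when covered by sequence data in at
   least a threshold number (or fraction) of individuals.
3. *D1* — all SNPs of the retained loci, locus- then offset-ordered, with
   columns monomorphic over the matrix removed.
4. *D2* — one SNP per locus (random with a seed, or lowest offset), to
   minimise linkage between markers.
5. *D3* — D2 minus apomorphic SNPs, i.e. sites whose minor allele is carried
   by exactly one individual.

The same "most polymorphic loci under the SNP cap, covered in >=90% of
individuals" count also serves as the selection criterion for assembly
parameter sweeps (``select_assembly_params``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import (
    MISSING,
    GenotypeMatrix,
    LocusCatalog,
    RadscanError,
    minor_allele_carrier_count,
)


@dataclass
class FilterConfig:
    """Thresholds for the filtering cascade.

    Exactly one of ``min_covered_individuals`` / ``min_coverage_fraction``
    must be set; a fraction converts to an absolute threshold by ceiling.
    """

    max_snps_per_locus: int = 9
    min_covered_individuals: int | None = 75
    min_coverage_fraction: float | None = None
    d2_rule: str = "random"
    d2_seed: int = 0

    def __post_init__(self) -> None:
        if (self.min_covered_individuals is None) == (self.min_coverage_fraction is None):
            raise RadscanError(
                "set exactly one of min_covered_individuals / min_coverage_fraction"
            )
        if self.max_snps_per_locus < 1:
            raise RadscanError("max_snps_per_locus must be >= 1")
        if self.min_covered_individuals is not None and self.min_covered_individuals < 1:
            raise RadscanError("min_covered_individuals must be positive")
        if self.min_coverage_fraction is not None and not (0 < self.min_coverage_fraction <= 1):
            raise RadscanError("min_coverage_fraction must be in (0, 1]")
        if self.d2_rule not in ("random", "first"):
            raise RadscanError("d2_rule must be 'random' or 'first'")

    def coverage_threshold(self, n_individuals: int) -> int:
        if self.min_covered_individuals is not None:
            return self.min_covered_individuals
        return math.ceil(self.min_coverage_fraction * n_individuals)


@dataclass
class AssemblyRunSummary:
    """One row of an assembly-parameter sweep.

    ``criterion_count`` is the number of polymorphic loci that stay under the
    SNP-richness cap and are covered in at least the coverage threshold of
    individuals.
    """

    m: int
    M: int
    n: int
    criterion_count: int

    def __post_init__(self) -> None:
        if self.criterion_count < 0:
            raise RadscanError("criterion_count must be >= 0")

    @property
    def label(self) -> str:
        return f"m={self.m},M={self.M},n={self.n}"


@dataclass
class FilterReport:
    """Per-stage accounting of the cascade."""

    loci_in: int = 0
    loci_blacklisted_snp_rich: int = 0
    loci_failing_coverage: int = 0
    loci_retained: int = 0
    snps_d1: int = 0
    snps_d2: int = 0
    snps_d3: int = 0
    monomorphic_removed: int = 0
    blacklist: list[str] = field(default_factory=list)
    coverage_dropped: list[str] = field(default_factory=list)
    d1_sites: list[str] = field(default_factory=list)
    d2_sites: list[str] = field(default_factory=list)
    d3_sites: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not (self.snps_d3 <= self.snps_d2 <= self.snps_d1):
            raise RadscanError("filter report violates D3 <= D2 <= D1")
        if self.loci_retained != self.loci_in - self.loci_blacklisted_snp_rich - self.loci_failing_coverage:
            raise RadscanError("filter report locus accounting inconsistent")

    def to_dict(self) -> dict:
        return {
            "loci_in": self.loci_in,
            "loci_blacklisted_snp_rich": self.loci_blacklisted_snp_rich,
            "loci_failing_coverage": self.loci_failing_coverage,
            "loci_retained": self.loci_retained,
            "snps_d1": self.snps_d1,
            "snps_d2": self.snps_d2,
            "snps_d3": self.snps_d3,
            "monomorphic_removed": self.monomorphic_removed,
            "blacklist": self.blacklist,
            "coverage_dropped": self.coverage_dropped,
            "d1_sites": self.d1_sites,
            "d2_sites": self.d2_sites,
            "d3_sites": self.d3_sites,
        }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def blacklist_snp_rich_loci(catalog: LocusCatalog, max_snps: int = 9) -> tuple[LocusCatalog, set[str]]:
    """Remove loci with more than ``max_snps`` SNPs (putative pooled paralogs).

    With the default cap of 9, a 10-SNP locus is blacklisted and a 9-SNP
    locus retained.
    """
    if max_snps < 1:
        raise RadscanError("max_snps must be >= 1")
    blacklist = {lid for lid in catalog.loci if catalog.snp_count(lid) > max_snps}
    kept = catalog.subset([lid for lid in catalog.loci if lid not in blacklist])
    return kept, blacklist


def coverage_filter(catalog: LocusCatalog, n_individuals: int,
                    config: FilterConfig) -> tuple[LocusCatalog, set[str]]:
    """Keep loci covered by data in at least the configured number of individuals."""
    threshold = config.coverage_threshold(n_individuals)
    dropped = {
        lid for lid, rec in catalog.loci.items()
        if len(rec.covered_individuals) < threshold
    }
    kept = catalog.subset([lid for lid in catalog.loci if lid not in dropped])
    return kept, dropped


def build_d1(matrix: GenotypeMatrix, catalog: LocusCatalog) -> tuple[GenotypeMatrix, int]:
    """All SNPs of the retained loci, minus monomorphic columns.

    Returns the D1 matrix and the number of monomorphic columns removed
    (possible after locus/individual subsetting).  Sites are ordered by
    catalog locus order, then by offset within the locus.
    """
    ordered: list[str] = []
    known = set(matrix.site_ids())
    for lid, rec in catalog.loci.items():
        in_matrix = [s for s in rec.site_ids if s in known]
        offsets = {s: int(matrix.sites.iloc[matrix.site_index(s)]["offset"]) for s in in_matrix}
        ordered.extend(sorted(in_matrix, key=lambda s: offsets[s]))
    if not ordered:
        raise RadscanError(
            "no SNPs survive locus filtering; relax max_snps or the coverage threshold"
        )
    sub = matrix.subset_sites(ordered)
    poly = []
    n_mono = 0
    for j, sid in enumerate(sub.site_ids()):
        col = sub.calls[:, j]
        vals = np.unique(col[col != MISSING])
        # monomorphic: all called individuals share one homozygous dosage
        if len(vals) <= 1 and (len(vals) == 0 or vals[0] in (0, 2)):
            n_mono += 1
        else:
            poly.append(sid)
    if not poly:
        raise RadscanError(
            "all retained SNP columns are monomorphic; relax the thresholds"
        )
    return sub.subset_sites(poly), n_mono


def build_d2(d1: GenotypeMatrix, catalog: LocusCatalog,
             rule: str = "random", seed: int = 0) -> GenotypeMatrix:
    """One SNP per retained locus, to minimise linkage between markers.

    ``rule='random'`` draws uniformly per locus from a generator seeded with
    ``seed`` (reproducible); ``rule='first'`` keeps the lowest offset.
    """
    if rule not in ("random", "first"):
        raise RadscanError("d2 rule must be 'random' or 'first'")
    rng = np.random.default_rng(seed)
    d1_sites = set(d1.site_ids())
    chosen: list[str] = []
    for lid, rec in catalog.loci.items():
        candidates = [s for s in rec.site_ids if s in d1_sites]
        if not candidates:
            continue
        offsets = {s: int(d1.sites.iloc[d1.site_index(s)]["offset"]) for s in candidates}
        candidates.sort(key=lambda s: offsets[s])
        if rule == "first" or len(candidates) == 1:
            chosen.append(candidates[0])
        else:
            chosen.append(candidates[rng.integers(len(candidates))])
    return d1.subset_sites(chosen)


def build_d3(d2: GenotypeMatrix) -> GenotypeMatrix:
    """Drop apomorphic SNPs: sites whose minor allele sits in one individual."""
    keep = [
        sid for sid in d2.site_ids()
        if minor_allele_carrier_count(d2, sid) != 1
    ]
    return d2.subset_sites(keep)


def select_assembly_params(summaries: list[AssemblyRunSummary]) -> tuple[AssemblyRunSummary, bool]:
    """Pick the sweep row maximising the criterion count.

    Ties break toward smaller (m, M, n) lexicographically; the second return
    value flags that a tie occurred.
    """
    if not summaries:
        raise RadscanError("empty assembly-parameter sweep")
    best_count = max(s.criterion_count for s in summaries)
    top = [s for s in summaries if s.criterion_count == best_count]
    top.sort(key=lambda s: (s.m, s.M, s.n))
    return top[0], len(top) > 1


def run_filter_cascade(matrix: GenotypeMatrix, catalog: LocusCatalog,
                       config: FilterConfig) -> tuple[GenotypeMatrix, GenotypeMatrix, GenotypeMatrix, LocusCatalog, FilterReport]:
    """Run blacklist -> coverage -> D1 -> D2 -> D3 and assemble the report.

    A locus failing both the blacklist and the coverage threshold is
    attributed to the blacklist stage (stage order is fixed).
    """
    report = FilterReport(loci_in=len(catalog))
    cat_b, blacklist = blacklist_snp_rich_loci(catalog, config.max_snps_per_locus)
    report.loci_blacklisted_snp_rich = len(blacklist)
    report.blacklist = sorted(blacklist)
    cat_c, dropped = coverage_filter(cat_b, matrix.n_individuals, config)
    report.loci_failing_coverage = len(dropped)
    report.coverage_dropped = sorted(dropped)
    report.loci_retained = len(cat_c)
    d1, n_mono = build_d1(matrix, cat_c)
    report.monomorphic_removed = n_mono
    d2 = build_d2(d1, cat_c, config.d2_rule, config.d2_seed)
    d3 = build_d3(d2)
    report.snps_d1, report.snps_d2, report.snps_d3 = d1.n_sites, d2.n_sites, d3.n_sites
    report.d1_sites = d1.site_ids()
    report.d2_sites = d2.site_ids()
    report.d3_sites = d3.site_ids()
    report.validate()
    return d1, d2, d3, cat_c, report
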