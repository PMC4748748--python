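"""Replicated sister-pair outlier scan and collateral/parallel classification.

The scan asks, for each RAD locus, whether it contains SNPs strongly
differentiated (FST strictly above a threshold) between the ultramafic and
volcanic sides of at least ``min_pairs`` independent sister pairs.
Qualification is locus-level: a different SNP position may qualify each pair.
A candidate locus with two or more qualifying pairs is then classified:

* ``collateral_shared`` — one and the same SNP qualifies in two or more
  pairs with the same allele elevated on the ultramafic side in each
  (repeated use of a shared variant, through ancestral sorting or
  introgression);
* ``parallel_distinct`` — otherwise (the pairs recruited different variants
  of the same locus, or the same site with opposite polarity).

``fixed_fraction`` summarises how many qualifying SNPs are reciprocal fixed
differences; a low fixed fraction is the signature of soft / polygenic
differentiation rather than complete sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genotypes import GenotypeMatrix, LocusCatalog, RadscanError, SisterPairContrast
from .fst import ESTIMATORS, FstRecord, pairwise_fst_table

logger = logging.getLogger(__name__)


@dataclass
class CandidateLocusReport:
    """Scan output for one candidate RAD locus."""

    locus_id: str
    qualifying_pairs: set[str]
    #: pair_id -> (site_id, fst) for the pair's best qualifying SNP
    #: (maximum fst; ties broken toward the lowest offset).
    best_snp: dict[str, tuple[str, float]]
    classification: str | None
    #: site_id -> set of pair_ids the site qualifies in.
    qualifying_sites: dict[str, set[str]]
    #: site_id -> True when the site is a reciprocal fixed difference in at
    #: least one pair in which it qualifies.
    fixed_sites: dict[str, bool]
    annotations: dict = field(default_factory=dict)


@dataclass
class ScanResult:
    candidates: list[CandidateLocusReport]
    records: list[FstRecord]
    threshold: float
    min_pairs: int
    estimator: str
    skipped_pairs: list[str] = field(default_factory=list)


def scan_replicated_outliers(matrix: GenotypeMatrix, catalog: LocusCatalog,
                             pairs: list[SisterPairContrast],
                             threshold: float = 0.5, min_pairs: int = 2,
                             estimator: str = "wc",
                             min_called: int = 2) -> ScanResult:
    """Find loci with FST > threshold in at least ``min_pairs`` sister pairs.

    The threshold comparison is strict ("over 0.5" means > 0.5, never >=);
    negative and undefined FST values never qualify.  Reports are sorted by
    number of qualifying pairs (descending) then locus id.
    """
    if not (0 < threshold <= 1):
        raise RadscanError("threshold must be in (0, 1]")
    if min_pairs < 2:
        raise RadscanError("min_pairs must be >= 2")
    if len(pairs) < min_pairs:
        raise RadscanError("need at least min_pairs sister-pair contrasts")
    if estimator not in ESTIMATORS:
        raise RadscanError(f"unknown estimator {estimator!r}")

    site_locus = catalog.site_to_locus()
    offsets = dict(zip(matrix.sites["site_id"], matrix.sites["offset"]))
    all_records: list[FstRecord] = []
    skipped: list[str] = []
    # locus -> pair -> list of qualifying (site, fst)
    qual: dict[str, dict[str, list[tuple[str, float]]]] = {}
    fixed_by_site_pair: dict[tuple[str, str], bool] = {}

    for pair in pairs:
        records = pairwise_fst_table(matrix, pair, estimator, min_called)
        all_records.extend(records)
        if all(r.undefined_reason == "below_min_called" for r in records):
            logger.warning("pair %s has no callable sites; skipped", pair.pair_id)
            skipped.append(pair.pair_id)
            continue
        for rec in records:
            if rec.fst is not None and rec.fst > threshold:
                locus = site_locus.get(rec.site_id)
                if locus is None:
                    continue
                qual.setdefault(locus, {}).setdefault(pair.pair_id, []).append(
                    (rec.site_id, rec.fst)
                )
                fixed_by_site_pair[(rec.site_id, rec.pair_id)] = rec.fixed

    elevated = {
        (r.site_id, r.pair_id): r.elevated_allele_ultramafic for r in all_records
    }

    candidates = []
    for locus_id, per_pair in qual.items():
        if len(per_pair) < min_pairs:
            continue
        best: dict[str, tuple[str, float]] = {}
        for pid, hits in per_pair.items():
            hits.sort(key=lambda sf: (-sf[1], offsets[sf[0]]))
            best[pid] = hits[0]
        qualifying_sites: dict[str, set[str]] = {}
        for pid, hits in per_pair.items():
            for sid, _ in hits:
                qualifying_sites.setdefault(sid, set()).add(pid)
        fixed_sites = {
            sid: any(fixed_by_site_pair[(sid, pid)] for pid in pids)
            for sid, pids in qualifying_sites.items()
        }
        candidate = CandidateLocusReport(
            locus_id=locus_id,
            qualifying_pairs=set(per_pair),
            best_snp=best,
            classification=None,
            qualifying_sites=qualifying_sites,
            fixed_sites=fixed_sites,
        )
        candidate.classification = classify_collateral(candidate, elevated)
        candidates.append(candidate)

    candidates.sort(key=lambda c: (-len(c.qualifying_pairs), c.locus_id))
    return ScanResult(candidates, all_records, threshold, min_pairs, estimator, skipped)


def classify_collateral(candidate: CandidateLocusReport,
                        elevated_by_site_pair: dict[tuple[str, str], str | None]) -> str:
    """Collateral vs parallel evolution at a candidate locus.

    ``collateral_shared`` requires a single SNP site qualifying in >= 2 pairs
    with the same (non-None) allele elevated on the ultramafic side in each;
    anything else is ``parallel_distinct``.
    """
    if len(candidate.qualifying_pairs) < 2:
        raise RadscanError("classification requires >= 2 qualifying pairs")
    for sid, pids in candidate.qualifying_sites.items():
        if len(pids) < 2:
            continue
        alleles = {elevated_by_site_pair.get((sid, pid)) for pid in pids}
        if len(alleles) == 1 and None not in alleles:
            return "collateral_shared"
    return "parallel_distinct"


def fixed_fraction(candidates: list[CandidateLocusReport]) -> tuple[float, float]:
    """Fraction of qualifying SNPs that are reciprocal fixed differences.

    The denominator is the set of qualifying sites deduplicated across pairs
    (a site qualifying in several pairs counts once); such a site counts as
    fixed when it is a fixed difference in at least one of its qualifying
    pairs.  Returns ``(fixed, not_fixed)`` fractions.
    """
    site_fixed: dict[str, bool] = {}
    for cand in candidates:
        for sid, fx in cand.fixed_sites.items():
            site_fixed[sid] = site_fixed.get(sid, False) or fx
    if not site_fixed:
        raise RadscanError("no qualifying SNPs to summarise")
    fixed = sum(site_fixed.values()) / len(site_fixed)
    return fixed, 1.0 - fixed
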