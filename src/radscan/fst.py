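"""Per-SNP pairwise FST estimators for two-group contrasts.

Two estimators are provided:

* ``wc`` — Weir & Cockerham's theta from the standard two-population
  variance components (a, b, c) for diploid samples, theta = a/(a+b+c).
  This is the field default for RAD SNP scans.
* ``hudson`` — a Hudson-type ratio with the sampling-bias correction in the
  numerator,

      num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
      den = p1(1-p2) + p2(1-p1)

  with n counted in alleles (2 x called diploids).

Both return exactly 1.0 under reciprocal fixation, can be negative when the
between-group variance falls below its sampling expectation, and are
undefined (None) when either side has fewer called individuals than
``min_called`` or when the denominator vanishes (both sides monomorphic for
the same allele).  Values are never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, RadscanError, SisterPairContrast

ESTIMATORS = ("wc", "hudson")


@dataclass
class FstRecord:
    """Per-site, per-pair differentiation record."""

    site_id: str
    pair_id: str
    estimator: str
    fst: float | None
    undefined_reason: str | None
    n_called_a: int
    n_called_b: int
    alt_freq_a: float | None
    alt_freq_b: float | None
    #: allele (ref/alt symbol) at higher frequency on the ultramafic side,
    #: or None when the two sides' frequencies are equal or undefined.
    elevated_allele_ultramafic: str | None
    #: reciprocal fixed difference among called individuals.
    fixed: bool


def _group_site_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_called, alt_freq, het_freq) for a sub-matrix of dosages."""
    called = calls != MISSING
    n = called.sum(axis=0)
    dose = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, dose / (2 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, (np.where(called, calls, 0) == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
    return n, p, h


def wc_theta_components(n1, p1, h1, n2, p2, h2):
    """Vectorised Weir-Cockerham variance components for two populations.

    Returns (a, b, c) arrays; callers decide definedness from n and a+b+c.
    """
    n1 = np.asarray(n1, dtype=float); n2 = np.asarray(n2, dtype=float)
    nbar = (n1 + n2) / 2.0
    ntot = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = ntot - (n1 ** 2 + n2 ** 2) / ntot
        pbar = (n1 * p1 + n2 * p2) / ntot
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / ntot
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c


def hudson_fst_parts(n1, p1, n2, p2):
    """Vectorised Hudson estimator numerator/denominator (n in alleles)."""
    a1 = 2.0 * np.asarray(n1, dtype=float)
    a2 = 2.0 * np.asarray(n2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (a1 - 1.0) - p2 * (1 - p2) / (a2 - 1.0)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def pairwise_fst_table(matrix: GenotypeMatrix, pair: SisterPairContrast,
                       estimator: str = "wc", min_called: int = 2) -> list[FstRecord]:
    """FST for every site of the matrix between the pair's two sides."""
    if estimator not in ESTIMATORS:
        raise RadscanError(f"unknown estimator {estimator!r}; use one of {ESTIMATORS}")
    overlap = pair.side_a & pair.side_b
    if overlap:
        raise RadscanError(f"pair {pair.pair_id!r}: sides share individuals {overlap}")
    rows_a = [matrix.individual_index(i) for i in sorted(pair.side_a)]
    rows_b = [matrix.individual_index(i) for i in sorted(pair.side_b)]
    n1, p1, h1 = _group_site_stats(matrix.calls[rows_a, :])
    n2, p2, h2 = _group_site_stats(matrix.calls[rows_b, :])

    if estimator == "wc":
        a, b, c = wc_theta_components(n1, p1, h1, n2, p2, h2)
        denom = a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(denom != 0, a / denom, np.nan)
        # under reciprocal fixation b and c vanish algebraically, so theta is
        # exactly 1; avoid the last-bit cancellation error of a/(a+b+c)
        recip = ((p1 == 1.0) & (p2 == 0.0)) | ((p1 == 0.0) & (p2 == 1.0))
        fst = np.where(recip, 1.0, fst)
        defined = (n1 >= max(min_called, 2)) & (n2 >= max(min_called, 2)) & (denom != 0)
    else:
        num, den = hudson_fst_parts(n1, p1, n2, p2)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(den != 0, num / den, np.nan)
        defined = (n1 >= max(min_called, 1)) & (n2 >= max(min_called, 1)) & (den != 0)
        # the correction terms need more than one allele per side
        defined &= (2 * n1 > 1) & (2 * n2 > 1)

    ultra_is_a = pair.ultramafic_side == "a"
    records = []
    site_ids = matrix.site_ids()
    refs = list(matrix.sites["ref"])
    alts = list(matrix.sites["alt"])
    for j, sid in enumerate(site_ids):
        pa = None if n1[j] == 0 else float(p1[j])
        pb = None if n2[j] == 0 else float(p2[j])
        if not defined[j]:
            if n1[j] < min_called or n2[j] < min_called:
                reason = "below_min_called"
            else:
                reason = "zero_denominator"
            value = None
        else:
            reason = None
            value = float(fst[j])
        elevated = None
        if pa is not None and pb is not None:
            pu, pv = (pa, pb) if ultra_is_a else (pb, pa)
            if pu > pv:
                elevated = alts[j]
            elif pu < pv:
                elevated = refs[j]
        fixed = (
            pa is not None and pb is not None
            and n1[j] >= min_called and n2[j] >= min_called
            and ((pa == 1.0 and pb == 0.0) or (pa == 0.0 and pb == 1.0))
        )
        records.append(
            FstRecord(
                site_id=sid, pair_id=pair.pair_id, estimator=estimator,
                fst=value, undefined_reason=reason,
                n_called_a=int(n1[j]), n_called_b=int(n2[j]),
                alt_freq_a=pa, alt_freq_b=pb,
                elevated_allele_ultramafic=elevated, fixed=bool(fixed),
            )
        )
    return records


def _single_site(matrix: GenotypeMatrix, site_id: str, pair: SisterPairContrast,
                 estimator: str, min_called: int) -> FstRecord:
    sub = matrix.subset_sites([site_id])
    return pairwise_fst_table(sub, pair, estimator, min_called)[0]


def fst_wc(matrix: GenotypeMatrix, site_id: str, side_a, side_b,
           ultramafic_side: str = "a", min_called: int = 2,
           pair_id: str = "pair") -> FstRecord:
    """Weir-Cockerham theta at one site between two individual sets."""
    pair = SisterPairContrast(pair_id, set(side_a), set(side_b), ultramafic_side)
    return _single_site(matrix, site_id, pair, "wc", min_called)


def fst_hudson(matrix: GenotypeMatrix, site_id: str, side_a, side_b,
               ultramafic_side: str = "a", min_called: int = 2,
               pair_id: str = "pair") -> FstRecord:
    """Hudson-type FST at one site between two individual sets."""
    pair = SisterPairContrast(pair_id, set(side_a), set(side_b), ultramafic_side)
    return _single_site(matrix, site_id, pair, "hudson", min_called)
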