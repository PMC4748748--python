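"""Core data model for RADseq SNP genotypes.

A RAD data set is a diploid, biallelic genotype matrix (individuals x SNP
sites) together with a locus catalog grouping SNP sites into short RAD loci
(94-bp reads in the study design this package targets).  Genotypes are stored
as alt-allele dosage in {0, 1, 2}; missing calls are ``MISSING`` (-1).
Missingness is typically locus-level (an individual without sequence data for
a locus is missing every SNP of that locus) but site-level missingness is
tolerated throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: IUPAC ambiguity code for each unordered nucleotide pair (heterozygotes).
IUPAC_HET = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}

SITE_COLUMNS = ["site_id", "locus_id", "offset", "ref", "alt"]


class RadscanError(Exception):
    """Base class for data / configuration errors raised by radscan."""


@dataclass
class LocusRecord:
    """One RAD locus: its length, its SNP sites and who has data for it."""

    locus_id: str
    length_bp: int
    site_ids: list[str]
    covered_individuals: set[str]


class LocusCatalog:
    """Grouping of SNP sites into RAD loci, with per-locus coverage.

    Parameters
    ----------
    loci
        Mapping ``locus_id -> LocusRecord`` (insertion order is preserved and
        used as the canonical locus order).
    """

    def __init__(self, loci: dict[str, LocusRecord]):
        self.loci = dict(loci)
        seen: set[str] = set()
        for rec in self.loci.values():
            for sid in rec.site_ids:
                if sid in seen:
                    raise RadscanError(f"site {sid!r} appears in more than one locus")
                seen.add(sid)

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.loci

    def __getitem__(self, locus_id: str) -> LocusRecord:
        return self.loci[locus_id]

    def locus_ids(self) -> list[str]:
        return list(self.loci)

    def snp_count(self, locus_id: str) -> int:
        return len(self.loci[locus_id].site_ids)

    def subset(self, locus_ids) -> "LocusCatalog":
        """Catalog restricted to ``locus_ids`` (kept in catalog order)."""
        keep = set(locus_ids)
        return LocusCatalog({lid: rec for lid, rec in self.loci.items() if lid in keep})

    def site_to_locus(self) -> dict[str, str]:
        return {sid: lid for lid, rec in self.loci.items() for sid in rec.site_ids}


class GenotypeMatrix:
    """Diploid biallelic genotypes for individuals x SNP sites.

    Parameters
    ----------
    individuals
        Ordered individual identifiers (unique).
    sites
        DataFrame with columns ``site_id, locus_id, offset, ref, alt``;
        ``offset`` is the 0-based position of the SNP within its locus.
    calls
        ``(n_individuals, n_sites)`` int8 array of alt-allele dosages in
        {0, 1, 2} or ``MISSING``.
    """

    def __init__(self, individuals: list[str], sites: pd.DataFrame, calls: np.ndarray):
        self.individuals = list(individuals)
        self.sites = sites.reset_index(drop=True)
        self.calls = np.asarray(calls, dtype=np.int8)
        self._validate()
        self._ind_index = {ind: i for i, ind in enumerate(self.individuals)}
        self._site_index = {sid: j for j, sid in enumerate(self.sites["site_id"])}

    def _validate(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise RadscanError("duplicate individual ids")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise RadscanError(f"site table lacks columns {missing_cols}")
        if self.sites["site_id"].duplicated().any():
            dup = self.sites["site_id"][self.sites["site_id"].duplicated()].iloc[0]
            raise RadscanError(f"duplicate site id {dup!r}")
        if (self.sites["ref"] == self.sites["alt"]).any():
            raise RadscanError("ref and alt alleles must differ at every site")
        if self.calls.shape != (len(self.individuals), len(self.sites)):
            raise RadscanError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise RadscanError(f"invalid dosage values: {np.unique(self.calls[bad])}")

    # -- indexing helpers -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_ids(self) -> list[str]:
        return list(self.sites["site_id"])

    def individual_index(self, individual_id: str) -> int:
        try:
            return self._ind_index[individual_id]
        except KeyError:
            raise RadscanError(f"unknown individual {individual_id!r}") from None

    def site_index(self, site_id: str) -> int:
        try:
            return self._site_index[site_id]
        except KeyError:
            raise RadscanError(f"unknown site {site_id!r}") from None

    def column(self, site_id: str) -> np.ndarray:
        return self.calls[:, self.site_index(site_id)]

    def subset_sites(self, site_ids) -> "GenotypeMatrix":
        idx = [self.site_index(s) for s in site_ids]
        return GenotypeMatrix(
            self.individuals, self.sites.iloc[idx], self.calls[:, idx]
        )

    def subset_individuals(self, individual_ids) -> "GenotypeMatrix":
        idx = [self.individual_index(i) for i in individual_ids]
        return GenotypeMatrix(
            [self.individuals[i] for i in idx], self.sites, self.calls[idx, :]
        )

    def attach_catalog_check(self, catalog: LocusCatalog) -> None:
        """Validate mutual consistency with a locus catalog.

        Checks that every site's locus exists, offsets fit in the locus
        length, covered individuals are known, and that an individual absent
        from a locus's coverage is MISSING at all of that locus's sites.
        """
        for _, row in self.sites.iterrows():
            if row["locus_id"] not in catalog:
                raise RadscanError(
                    f"site {row['site_id']!r} references unknown locus "
                    f"{row['locus_id']!r}"
                )
            if row["offset"] >= catalog[row["locus_id"]].length_bp:
                raise RadscanError(
                    f"site {row['site_id']!r} offset {row['offset']} exceeds "
                    f"locus length {catalog[row['locus_id']].length_bp}"
                )
        ind_set = set(self.individuals)
        for lid, rec in catalog.loci.items():
            extra = rec.covered_individuals - ind_set
            if extra:
                raise RadscanError(f"locus {lid!r} covers unknown individuals {extra}")
            uncovered = [i for i in self.individuals if i not in rec.covered_individuals]
            cols = [self._site_index[s] for s in rec.site_ids if s in self._site_index]
            if not cols or not uncovered:
                continue
            rows = [self._ind_index[i] for i in uncovered]
            if (self.calls[np.ix_(rows, cols)] != MISSING).any():
                raise RadscanError(
                    f"individual not covered by locus {lid!r} has a non-missing call"
                )


@dataclass
class PopulationMap:
    """Individual -> population -> species mapping with ecological attributes.

    ``table`` has one row per individual with columns ``individual_id,
    population_id, species, locality, region, climate, soil``.
    """

    table: pd.DataFrame

    COLUMNS = ["individual_id", "population_id", "species", "locality",
               "region", "climate", "soil"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise RadscanError(f"population map lacks columns {missing}")
        if self.table["individual_id"].duplicated().any():
            raise RadscanError("population map has duplicate individuals")
        if (self.table["population_id"].astype(str) == "").any():
            raise RadscanError("empty population id in population map")
        self.table = self.table.reset_index(drop=True)

    def individuals_of_population(self, population_id: str) -> list[str]:
        mask = self.table["population_id"] == population_id
        return list(self.table.loc[mask, "individual_id"])

    def check_covers(self, matrix: GenotypeMatrix) -> None:
        mapped = set(self.table["individual_id"])
        unmapped = [i for i in matrix.individuals if i not in mapped]
        if unmapped:
            raise RadscanError(f"individuals missing from population map: {unmapped}")


@dataclass
class SisterPairContrast:
    """A replicated two-group contrast with a shared edaphic polarity.

    One side grows on ultramafic substrate, the other on volcanic; a side may
    pool individuals from more than one species.
    """

    pair_id: str
    side_a: set[str]
    side_b: set[str]
    ultramafic_side: str  # "a" or "b"
    label: str = ""

    def __post_init__(self) -> None:
        self.side_a = set(self.side_a)
        self.side_b = set(self.side_b)
        if not self.side_a or not self.side_b:
            raise RadscanError(f"pair {self.pair_id!r}: both sides must be nonempty")
        if self.side_a & self.side_b:
            raise RadscanError(f"pair {self.pair_id!r}: sides overlap")
        if self.ultramafic_side not in ("a", "b"):
            raise RadscanError(
                f"pair {self.pair_id!r}: ultramafic_side must be 'a' or 'b'"
            )

    @property
    def ultramafic_individuals(self) -> set[str]:
        return self.side_a if self.ultramafic_side == "a" else self.side_b

    @property
    def volcanic_individuals(self) -> set[str]:
        return self.side_b if self.ultramafic_side == "a" else self.side_a


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair joint-call counts.

    ``undefined`` lists pairs with zero jointly called sites (their distance
    entries are NaN).
    """

    individuals: list[str]
    distances: np.ndarray
    joint_called: np.ndarray
    normalized: bool
    undefined: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Frequency and distance primitives
# ---------------------------------------------------------------------------

def allele_stats(matrix: GenotypeMatrix, site_id: str, group) -> tuple[float | None, int]:
    """Alt-allele frequency and called-individual count within ``group``.

    Returns ``(alt_frequency, n_called)``; the frequency is ``None``
    (undefined) when no individual in the group is called at the site.
    """
    col = matrix.column(site_id)
    rows = [matrix.individual_index(i) for i in group]
    sub = col[rows]
    called = sub != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        return None, 0
    return float(sub[called].sum()) / (2 * n_called), n_called


def minor_allele_carrier_count(matrix: GenotypeMatrix, site_id: str) -> int:
    """Number of distinct individuals carrying >=1 copy of the minor allele.

    The globally minor allele is the rarer of ref/alt over all called
    individuals; an exact 50/50 tie designates the alt allele as minor.  A
    site whose minor-allele carrier count is 1 is an autapomorphy ("apomorphic
    SNP") distinguishing a single individual.
    """
    col = matrix.column(site_id)
    called = col != MISSING
    if not called.any():
        raise RadscanError(f"site {site_id!r} has no called genotypes")
    sub = col[called]
    alt_freq = sub.sum() / (2 * len(sub))
    if alt_freq <= 0.5:  # tie broken toward alt
        carriers = sub >= 1
    else:
        carriers = sub <= 1
    return int(carriers.sum())


def hamming_distance_matrix(matrix: GenotypeMatrix, normalize: bool = True) -> DistanceMatrix:
    """Pairwise Hamming distances between individuals over dosage vectors.

    A site contributes to a pair only when both individuals are called there
    (pairwise deletion, as required for RAD matrices with per-locus dropout);
    a mismatch is any dosage difference (0/1, 1/2 and 0/2 all count once).
    With ``normalize`` the count is divided by the number of jointly called
    sites; a pair with zero jointly called sites is NaN and reported in
    ``undefined``.
    """
    if matrix.n_individuals < 2:
        raise RadscanError("need at least two individuals for a distance matrix")
    calls = matrix.calls
    n = matrix.n_individuals
    dist = np.zeros((n, n), dtype=float)
    joint = np.zeros((n, n), dtype=int)
    called = calls != MISSING
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        both = called[i] & called[i + 1:]
        diff = (calls[i] != calls[i + 1:]) & both
        joint_i = both.sum(axis=1)
        mism = diff.sum(axis=1)
        joint[i, i + 1:] = joint_i
        joint[i + 1:, i] = joint_i
        if normalize:
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(joint_i > 0, mism / np.maximum(joint_i, 1), np.nan)
        else:
            d = np.where(joint_i > 0, mism.astype(float), np.nan)
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
        for k, jc in enumerate(joint_i):
            if jc == 0:
                undefined.append((matrix.individuals[i], matrix.individuals[i + 1 + k]))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(joint, called.sum(axis=1))
    return DistanceMatrix(list(matrix.individuals), dist, joint, normalize, undefined)
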