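"""Shared fixture builders: tiny hand-constructed matrices and catalogs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from radscan import GenotypeMatrix, LocusCatalog, LocusRecord, MISSING


def make_matrix(columns: dict[str, list[int]], individuals: list[str] | None = None,
                locus_of: dict[str, str] | None = None,
                offset_of: dict[str, int] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-site dosage columns.

    Site ids default to ``L<k>_<j>`` style only when ``locus_of`` is given;
    otherwise each site becomes its own single-SNP locus ``<site>_locus``.
    Ref/alt are fixed A/T so allele symbols are predictable in tests.
    """
    site_ids = list(columns)
    n = len(next(iter(columns.values())))
    if individuals is None:
        individuals = [f"ind{i}" for i in range(n)]
    rows = []
    for k, sid in enumerate(site_ids):
        rows.append(
            {
                "site_id": sid,
                "locus_id": locus_of[sid] if locus_of else f"{sid}_locus",
                "offset": offset_of[sid] if offset_of else 0,
                "ref": "A",
                "alt": "T",
            }
        )
    calls = np.array([columns[s] for s in site_ids], dtype=np.int8).T
    return GenotypeMatrix(individuals, pd.DataFrame(rows), calls)


def make_catalog(matrix: GenotypeMatrix, length_bp: int = 94,
                 covered: dict[str, set[str]] | None = None) -> LocusCatalog:
    """Catalog grouping the matrix's sites by their locus_id column."""
    loci: dict[str, LocusRecord] = {}
    for _, row in matrix.sites.iterrows():
        lid = row["locus_id"]
        if lid not in loci:
            cov = covered[lid] if covered else set(matrix.individuals)
            loci[lid] = LocusRecord(lid, length_bp, [], set(cov))
        loci[lid].site_ids.append(row["site_id"])
    return LocusCatalog(loci)


def random_matrix(rng: np.random.Generator, n_ind: int, n_sites: int,
                  missing_rate: float = 0.1) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n_ind, n_sites)).astype(np.int8)
    calls[rng.random((n_ind, n_sites)) < missing_rate] = MISSING
    cols = {f"s{j}": list(calls[:, j]) for j in range(n_sites)}
    return make_matrix(cols)


@pytest.fixture(scope="session")
def small_bundle():
    """A small simulated radiation reused by read-only tests."""
    from radscan import default_config, simulate

    return simulate(
        default_config(seed=7, n_loci=300, n_adaptive_loci=12,
                       snp_rich_locus_count=6, singleton_snp_count=15)
    )
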