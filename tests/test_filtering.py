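"""The D1/D2/D3 cascade and the assembly-parameter selection criterion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radscan import (
    MISSING,
    AssemblyRunSummary,
    FilterConfig,
    RadscanError,
    blacklist_snp_rich_loci,
    build_d1,
    build_d2,
    build_d3,
    coverage_filter,
    minor_allele_carrier_count,
    run_filter_cascade,
    select_assembly_params,
)

from conftest import make_catalog, make_matrix


def _counted_catalog(snp_counts: dict[str, int]):
    """Matrix + catalog with the given number of (polymorphic) SNPs per locus."""
    cols, locus_of, offset_of = {}, {}, {}
    for lid, count in snp_counts.items():
        for j in range(count):
            sid = f"{lid}_{j}"
            cols[sid] = [0, 1, 2, 0]  # polymorphic, >=2 minor carriers
            locus_of[sid] = lid
            offset_of[sid] = j
    m = make_matrix(cols, locus_of=locus_of, offset_of=offset_of)
    return m, make_catalog(m)


# ---------------------------------------------------------------------------
# Blacklist
# ---------------------------------------------------------------------------

def test_blacklist_boundary_9_vs_10_snps():
    _, cat = _counted_catalog({"keep9": 9, "drop10": 10})
    kept, blacklist = blacklist_snp_rich_loci(cat, max_snps=9)
    assert blacklist == {"drop10"}
    assert kept.locus_ids() == ["keep9"]


def test_blacklist_counts_over_a_known_sweep():
    _, cat = _counted_catalog({f"L{k}": k for k in range(1, 13)})
    kept, blacklist = blacklist_snp_rich_loci(cat, max_snps=9)
    assert blacklist == {"L10", "L11", "L12"}
    assert len(kept) == 9


def test_blacklist_idempotent():
    _, cat = _counted_catalog({f"L{k}": k for k in range(1, 13)})
    once, bl1 = blacklist_snp_rich_loci(cat, 9)
    twice, bl2 = blacklist_snp_rich_loci(once, 9)
    assert once.locus_ids() == twice.locus_ids()
    assert bl2 == set()


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def _coverage_fixture(n_ind, coverage_by_locus):
    inds = [f"i{k}" for k in range(n_ind)]
    cols, locus_of, offset_of, covered = {}, {}, {}, {}
    for lid, n_cov in coverage_by_locus.items():
        sid = f"{lid}_0"
        cov = set(inds[:n_cov])
        cols[sid] = [0 if i in cov else MISSING for i in inds]
        cols[sid][0] = 1  # keep polymorphic
        locus_of[sid] = lid
        offset_of[sid] = 0
        covered[lid] = cov
    m = make_matrix(cols, individuals=inds, locus_of=locus_of, offset_of=offset_of)
    return m, make_catalog(m, covered=covered)


def test_absolute_threshold_75_of_84():
    m, cat = _coverage_fixture(84, {"ok": 75, "low": 74})
    config = FilterConfig(min_covered_individuals=75)
    kept, dropped = coverage_filter(cat, 84, config)
    assert kept.locus_ids() == ["ok"]
    assert dropped == {"low"}


def test_fractional_threshold_uses_ceiling():
    m, cat = _coverage_fixture(40, {"c35": 35, "c36": 36, "c37": 37})
    config = FilterConfig(min_covered_individuals=None, min_coverage_fraction=0.9)
    assert config.coverage_threshold(40) == 36
    kept, dropped = coverage_filter(cat, 40, config)
    assert dropped == {"c35"}
    assert set(kept.locus_ids()) == {"c36", "c37"}


def test_config_requires_exactly_one_threshold():
    with pytest.raises(RadscanError):
        FilterConfig(min_covered_individuals=75, min_coverage_fraction=0.9)
    with pytest.raises(RadscanError):
        FilterConfig(min_covered_individuals=None, min_coverage_fraction=None)


# ---------------------------------------------------------------------------
# D1 / D2 / D3
# ---------------------------------------------------------------------------

def test_d1_concatenates_snps_of_retained_loci():
    m, cat = _counted_catalog({"A": 2, "B": 3, "C": 1, "D": 4, "E": 2})
    d1, n_mono = build_d1(m, cat)
    assert d1.n_sites == 12
    assert n_mono == 0
    # locus-ordered then offset-ordered
    assert d1.site_ids()[:5] == ["A_0", "A_1", "B_0", "B_1", "B_2"]


def test_d1_removes_monomorphic_columns():
    cols = {"L1_0": [0, 0, 0, 0], "L1_1": [0, 1, 2, 0]}
    locus_of = {s: "L1" for s in cols}
    offset_of = {"L1_0": 0, "L1_1": 5}
    m = make_matrix(cols, locus_of=locus_of, offset_of=offset_of)
    d1, n_mono = build_d1(m, make_catalog(m))
    assert d1.site_ids() == ["L1_1"]
    assert n_mono == 1


def test_d1_empty_result_raises_advice():
    m, cat = _counted_catalog({"A": 2})
    empty = cat.subset([])
    with pytest.raises(RadscanError, match="relax"):
        build_d1(m, empty)


def test_d2_one_snp_per_locus_and_seed_determinism():
    m, cat = _counted_catalog({"A": 3, "B": 5, "C": 1})
    d1, _ = build_d1(m, cat)
    d2a = build_d2(d1, cat, rule="random", seed=42)
    d2b = build_d2(d1, cat, rule="random", seed=42)
    assert d2a.site_ids() == d2b.site_ids()
    assert d2a.n_sites == 3
    per_locus = {s.rsplit("_", 1)[0] for s in d2a.site_ids()}
    assert per_locus == {"A", "B", "C"}


def test_d2_first_rule_takes_lowest_offset():
    cols = {"L_55": [0, 1, 2, 0], "L_7": [0, 1, 2, 0], "L_31": [0, 1, 2, 0]}
    locus_of = {s: "L" for s in cols}
    offset_of = {"L_7": 7, "L_31": 31, "L_55": 55}
    m = make_matrix(cols, locus_of=locus_of, offset_of=offset_of)
    d1, _ = build_d1(m, make_catalog(m))
    d2 = build_d2(d1, make_catalog(m), rule="first")
    assert d2.site_ids() == ["L_7"]


def test_d3_removes_exactly_the_planted_singletons():
    cols, locus_of, offset_of = {}, {}, {}
    planted = set()
    rng = np.random.default_rng(1)
    for j in range(20):
        sid = f"L{j}_0"
        if j < 6:  # singleton: one heterozygous carrier
            col = [0] * 10
            col[int(rng.integers(10))] = 1
            planted.add(sid)
        else:
            col = [0, 0, 1, 2, 0, 1, 0, 0, 2, 1]
        cols[sid] = col
        locus_of[sid] = f"L{j}"
        offset_of[sid] = 0
    m = make_matrix(cols, locus_of=locus_of, offset_of=offset_of)
    d3 = build_d3(m)
    assert set(m.site_ids()) - set(d3.site_ids()) == planted
    assert d3.n_sites == 14


def test_d3_boundary_two_carriers_kept():
    m = make_matrix({"one": [1, 0, 0, 0], "two": [1, 1, 0, 0]})
    d3 = build_d3(m)
    assert d3.site_ids() == ["two"]


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_d3_output_never_contains_singletons(seed):
    rng = np.random.default_rng(seed)
    calls = rng.integers(-1, 3, size=(8, 12)).astype(np.int8)
    cols = {}
    for j in range(12):
        col = calls[:, j]
        if (col != MISSING).sum() == 0:
            col[0] = 0
        cols[f"s{j}"] = col.tolist()
    d3 = build_d3(make_matrix(cols))
    for sid in d3.site_ids():
        assert minor_allele_carrier_count(d3, sid) != 1


# ---------------------------------------------------------------------------
# Assembly-parameter selection
# ---------------------------------------------------------------------------

def test_select_assembly_params_by_criterion_count():
    sweep = [AssemblyRunSummary(m=m, M=1, n=1, criterion_count=c)
             for m, c in zip(range(5, 16), [10, 40, 60, 80, 95, 105, 118, 125, 131, 120, 96])]
    best, tied = select_assembly_params(sweep)
    assert best.m == 13  # argmax of the sweep table
    assert not tied
    naive = max(sweep, key=lambda s: s.criterion_count)
    assert best.criterion_count == naive.criterion_count


def test_select_assembly_params_tie_breaks_lexicographically():
    sweep = [
        AssemblyRunSummary(m=13, M=2, n=2, criterion_count=50),
        AssemblyRunSummary(m=13, M=1, n=1, criterion_count=50),
        AssemblyRunSummary(m=12, M=4, n=0, criterion_count=50),
    ]
    best, tied = select_assembly_params(sweep)
    assert (best.m, best.M, best.n) == (12, 4, 0)
    assert tied


def test_select_assembly_params_single_and_empty():
    only = AssemblyRunSummary(m=7, M=1, n=1, criterion_count=3)
    assert select_assembly_params([only])[0] is only
    with pytest.raises(RadscanError):
        select_assembly_params([])


@settings(max_examples=25, deadline=None)
@given(st.lists(st.integers(0, 1000), min_size=1, max_size=11))
def test_select_assembly_params_equals_naive_max(counts):
    sweep = [AssemblyRunSummary(m=5 + i, M=1, n=1, criterion_count=c)
             for i, c in enumerate(counts)]
    best, _ = select_assembly_params(sweep)
    assert best.criterion_count == max(counts)


# ---------------------------------------------------------------------------
# Full cascade report
# ---------------------------------------------------------------------------

def test_cascade_report_counts_match_manifest():
    # 3 loci: one SNP-rich (10 SNPs), one low-coverage, one clean with a
    # planted singleton among its 3 SNPs
    inds = [f"i{k}" for k in range(8)]
    cols, locus_of, offset_of, covered = {}, {}, {}, {}
    for j in range(10):
        sid = f"rich_{j}"
        cols[sid] = [0, 1, 2, 0, 1, 2, 0, 1]
        locus_of[sid], offset_of[sid] = "rich", j
    covered["rich"] = set(inds)
    cols["low_0"] = [0, 1, 2, 0, MISSING, MISSING, MISSING, MISSING]
    locus_of["low_0"], offset_of["low_0"] = "low", 0
    covered["low"] = set(inds[:4])
    for j, col in enumerate([[0, 1, 2, 0, 1, 2, 0, 1],
                             [1, 0, 0, 0, 0, 0, 0, 0],   # singleton
                             [2, 2, 0, 0, 1, 1, 2, 0]]):
        sid = f"clean_{j}"
        cols[sid] = col
        locus_of[sid], offset_of[sid] = "clean", j
    covered["clean"] = set(inds)
    m = make_matrix(cols, individuals=inds, locus_of=locus_of, offset_of=offset_of)
    cat = make_catalog(m, covered=covered)

    config = FilterConfig(min_covered_individuals=7, d2_rule="first")
    d1, d2, d3, kept, report = run_filter_cascade(m, cat, config)
    assert report.loci_in == 3
    assert report.blacklist == ["rich"]
    assert report.coverage_dropped == ["low"]
    assert report.loci_retained == 1
    # rule=first keeps clean_0 (offset 0), which has 5 minor-allele carriers
    assert (report.snps_d1, report.snps_d2, report.snps_d3) == (3, 1, 1)
    assert report.d2_sites == ["clean_0"]
    assert report.snps_d3 <= report.snps_d2 <= report.snps_d1
    assert set(d2.site_ids()) <= set(d1.site_ids())
    assert set(d3.site_ids()) <= set(d2.site_ids())


def test_cascade_subset_chain_on_simulated_data(small_bundle):
    config = FilterConfig(min_covered_individuals=None, min_coverage_fraction=0.9)
    d1, d2, d3, kept, report = run_filter_cascade(
        small_bundle.matrix, small_bundle.catalog, config
    )
    assert set(d3.site_ids()) <= set(d2.site_ids()) <= set(d1.site_ids())
    assert report.loci_retained == len(kept)
    # every planted SNP-rich locus is blacklisted
    rich = {l for l, t in small_bundle.manifest.loci.items() if t.kind == "snp_rich"}
    assert rich <= set(report.blacklist)
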