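"""Properties of the Balding-Nichols radiation generator and its fixtures."""

import numpy as np
import pytest

from radscan import MISSING, default_config, read_fixture, simulate, write_fixture
from radscan import io as rio
from radscan.fst import pairwise_fst_table
from radscan.simulate import _beta_drift, simulate_frequencies


# ---------------------------------------------------------------------------
# Frequency model
# ---------------------------------------------------------------------------

def test_beta_drift_small_c_pins_child_to_parent():
    rng = np.random.default_rng(0)
    p = np.full(500, 0.37)
    child = _beta_drift(rng, p, 1e-4)
    assert np.abs(child - p).max() < 0.05
    np.testing.assert_array_equal(_beta_drift(rng, p, 0.0), p)


def test_beta_drift_mean_identity_and_variance_growth():
    rng = np.random.default_rng(1)
    p = np.full(10_000, 0.4)
    child_small = _beta_drift(rng, p, 0.05)
    child_large = _beta_drift(rng, p, 0.4)
    # E[child] = parent; MC error ~ sqrt(p(1-p)c/n)
    assert child_small.mean() == pytest.approx(0.4, abs=0.01)
    assert child_large.mean() == pytest.approx(0.4, abs=0.01)
    # Var[child] = p(1-p)c
    assert child_small.var() == pytest.approx(0.4 * 0.6 * 0.05, rel=0.1)
    assert child_large.var() == pytest.approx(0.4 * 0.6 * 0.4, rel=0.1)


def test_fixed_boundaries_propagate_unchanged():
    rng = np.random.default_rng(2)
    p = np.array([0.0, 1.0, 0.5])
    child = _beta_drift(rng, p, 0.2)
    assert child[0] == 0.0 and child[1] == 1.0


def test_full_delta_drives_sides_toward_reciprocal_fixation():
    cfg = default_config(seed=3, n_loci=60, n_adaptive_loci=20,
                         snp_rich_locus_count=0, singleton_snp_count=0,
                         adaptive_delta=1.0,
                         causal_ancestral_low=0.45, causal_ancestral_high=0.55)
    # low drift so the tips stay near p ~ 0.5 before displacement
    cfg.tree = {n: (p, 0.005 if p is not None else c) for n, (p, c) in cfg.tree.items()}
    freq, manifest, _ = simulate_frequencies(cfg)
    pair_pops = {pid: (u, v) for pid, u, v in cfg.pair_pops}
    diffs = []
    for lid, truth in manifest.loci.items():
        if truth.kind != "adaptive":
            continue
        for pid, causal in truth.causal_sites.items():
            u, v = pair_pops[pid]
            diffs.append(freq.loc[u, causal] - freq.loc[v, causal])
    diffs = np.array(diffs)
    # residual drift noise keeps a few draws below the clipped ideal of ~0.9
    assert diffs.min() > 0.6
    assert diffs.mean() > 0.85


def test_displacement_clipped_to_unit_interval():
    cfg = default_config(seed=4, n_loci=80, n_adaptive_loci=30,
                         snp_rich_locus_count=0, adaptive_delta=1.0)
    freq, _, _ = simulate_frequencies(cfg)
    vals = freq.to_numpy()
    assert vals.min() >= 0.0 and vals.max() <= 1.0


def test_neutral_fst_increases_with_drift():
    """Mean neutral sister-pair FST is rank-ordered by the tip drift c."""
    means = []
    for c in (0.01, 0.05, 0.2):
        cfg = default_config(seed=11, n_loci=150, n_adaptive_loci=0,
                             snp_rich_locus_count=0, singleton_snp_count=0,
                             locus_missing_rate=0.0)
        # vary only the tip-branch drift of the pair populations
        cfg.tree = {n: (p, c if n.startswith("P") else bc)
                    for n, (p, bc) in cfg.tree.items()}
        bundle = simulate(cfg)
        vals = []
        for pair in bundle.pairs:
            for rec in pairwise_fst_table(bundle.matrix, pair, "hudson"):
                if rec.fst is not None:
                    vals.append(rec.fst)
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------

def test_sample_frequencies_track_simulated_frequencies():
    cfg = default_config(seed=5, individuals_per_pop=50, n_loci=40,
                         n_adaptive_loci=0, snp_rich_locus_count=0,
                         singleton_snp_count=0, locus_missing_rate=0.0)
    bundle = simulate(cfg)
    pop0 = cfg.populations[0].pop_id
    rows = [bundle.matrix.individual_index(i)
            for i in bundle.popmap.individuals_of_population(pop0)]
    sample_p = bundle.matrix.calls[rows, :].mean(axis=0) / 2
    sim_p = bundle.freq_table.loc[pop0].to_numpy()
    # binomial SE at n=50 diploids is sqrt(p(1-p)/100) <= 0.05
    assert np.abs(sample_p - sim_p).max() < 5 * 0.05


def test_zero_dropout_means_full_coverage():
    bundle = simulate(default_config(seed=6, n_loci=50, locus_missing_rate=0.0,
                                     n_adaptive_loci=0, snp_rich_locus_count=0))
    n_ind = bundle.matrix.n_individuals
    for rec in bundle.catalog.loci.values():
        assert len(rec.covered_individuals) == n_ind
    assert (bundle.matrix.calls != MISSING).all()


def test_dropout_is_locus_level_and_catalog_consistent(small_bundle):
    small_bundle.matrix.attach_catalog_check(small_bundle.catalog)


def test_planted_singletons_have_single_carrier(small_bundle):
    from radscan import minor_allele_carrier_count

    planted = [s for t in small_bundle.manifest.loci.values()
               for s in t.singleton_sites]
    assert planted
    for sid in planted:
        assert minor_allele_carrier_count(small_bundle.matrix, sid) == 1


def test_planted_snp_rich_loci_exceed_cap(small_bundle):
    rich = [l for l, t in small_bundle.manifest.loci.items() if t.kind == "snp_rich"]
    assert rich
    for lid in rich:
        assert small_bundle.catalog.snp_count(lid) > 9


def test_manifest_covers_every_locus_once(small_bundle):
    assert set(small_bundle.manifest.loci) == set(small_bundle.catalog.locus_ids())
    for lid, truth in small_bundle.manifest.loci.items():
        assert truth.snp_count == small_bundle.catalog.snp_count(lid)
        for causal in truth.causal_sites.values():
            assert causal in small_bundle.catalog[lid].site_ids


def test_independent_mode_assigns_distinct_causal_sites():
    cfg = default_config(seed=8, n_loci=60, n_adaptive_loci=10,
                         snp_rich_locus_count=0,
                         adaptive_mode="independent_allele")
    _, manifest, _ = simulate_frequencies(cfg)
    for truth in manifest.loci.values():
        if truth.kind == "adaptive":
            sites = list(truth.causal_sites.values())
            assert len(set(sites)) == len(sites) == 4


# ---------------------------------------------------------------------------
# Determinism and fixture round-trip
# ---------------------------------------------------------------------------

def test_same_seed_gives_byte_identical_fixture(tmp_path):
    cfg = dict(n_loci=40, n_adaptive_loci=5, snp_rich_locus_count=2,
               singleton_snp_count=5)
    a = simulate(default_config(seed=13, **cfg))
    b = simulate(default_config(seed=13, **cfg))
    pa = write_fixture(a, tmp_path / "a")
    pb = write_fixture(b, tmp_path / "b")
    for key in pa:
        assert pa[key].read_bytes() == pb[key].read_bytes()
    c = simulate(default_config(seed=14, **cfg))
    pc = write_fixture(c, tmp_path / "c")
    assert pc["vcf"].read_bytes() != pa["vcf"].read_bytes()


def test_fixture_round_trip_reproduces_bundle(tmp_path, small_bundle):
    paths = write_fixture(small_bundle, tmp_path / "fx")
    back = read_fixture(tmp_path / "fx")
    np.testing.assert_array_equal(back.matrix.calls, small_bundle.matrix.calls)
    assert back.matrix.individuals == small_bundle.matrix.individuals
    assert back.catalog.locus_ids() == small_bundle.catalog.locus_ids()
    for lid in back.catalog.locus_ids():
        assert (back.catalog[lid].covered_individuals
                == small_bundle.catalog[lid].covered_individuals)
    assert back.pairs == small_bundle.pairs
    assert back.popmap.table.equals(small_bundle.popmap.table)
    assert set(back.manifest.loci) == set(small_bundle.manifest.loci)


def test_default_small_fixture_parses_under_module_readers(tmp_path):
    cfg = default_config(seed=21, individuals_per_pop=6, n_loci=300,
                         n_adaptive_loci=10, snp_rich_locus_count=5)
    # drop to 6 populations by trimming pairs to emulate a compact fixture
    paths = write_fixture(simulate(cfg), tmp_path)
    m = rio.read_vcf(paths["vcf"])
    cat = rio.read_catalog(paths["catalog"])
    pm = rio.read_popmap(paths["popmap"])
    pairs = rio.read_pairs(paths["pairs"])
    pm.check_covers(m)
    m.attach_catalog_check(cat)
    assert len(cat) == 300
    assert len(pairs) == 4
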