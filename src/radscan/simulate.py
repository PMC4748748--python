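"""Synthetic island-radiation generator with planted adaptive loci.

The generator emulates the statistical structure a replicated edaphic
divergence scan assumes: a set of populations related by a rooted topology
with per-branch drift, short multi-SNP RAD loci with locus-level dropout,
several sister pairs whose two sides sit on contrasting substrates
(ultramafic vs volcanic), and a planted subset of loci carrying an adaptive
allele-frequency contrast between the two sides of the target pairs.

Allele frequencies evolve by the hierarchical Balding-Nichols model: a
branch with drift intensity ``c`` draws the child frequency from
``Beta(p(1-c)/c, (1-p)(1-c)/c)``, which keeps the parent mean and inflates
the variance as ``c`` grows.  Selection is modelled as a deterministic
post-drift displacement of the tip frequencies at causal sites: the
ultramafic side moves by +delta/2 toward the alt allele and the volcanic
side by -delta/2 (clipped to [0, 1]).  ``shared_allele`` loci displace the
same causal site in the same direction in every target pair (collateral
evolution); ``independent_allele`` loci displace a different causal site in
each pair (parallel recruitment of distinct variants).

Every planted feature is recorded in a :class:`TruthManifest` so that scan
sensitivity, specificity and classification accuracy can be measured against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .genotypes import (
    MISSING,
    GenotypeMatrix,
    LocusCatalog,
    LocusRecord,
    PopulationMap,
    RadscanError,
    SisterPairContrast,
)

_NUCS = np.array(list("ACGT"))


@dataclass
class PopulationSpec:
    pop_id: str
    species: str
    locality: str
    region: str
    climate: str
    soil: str
    n_individuals: int


@dataclass
class SimulationConfig:
    """All knobs of the generator; see the module docstring for the model.

    ``tree`` maps node id -> (parent id or None for the root, drift c of the
    branch leading to the node); tip nodes must be population ids.
    ``pair_pops`` lists (pair_id, ultramafic population, volcanic population).
    """

    populations: list[PopulationSpec]
    tree: dict[str, tuple[str | None, float]]
    pair_pops: list[tuple[str, str, str]]
    n_loci: int = 2000
    snp_mean: float = 2.0          # zero-truncated Poisson mean, SNPs per locus
    snp_cap: int = 15
    locus_length: int = 94
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    # causal sites model selection on intermediate-frequency standing
    # variation, so their ancestral range is narrower
    causal_ancestral_low: float = 0.2
    causal_ancestral_high: float = 0.8
    locus_missing_rate: float = 0.1
    n_adaptive_loci: int = 50
    adaptive_delta: float = 0.8
    adaptive_mode: str | list[str] = "shared_allele"
    target_pairs: list[str] | None = None   # default: all pairs
    singleton_snp_count: int = 30
    snp_rich_locus_count: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for prob in (self.locus_missing_rate,):
            if not (0 <= prob <= 1):
                raise RadscanError("probabilities must lie in [0, 1]")
        if not (0 < self.adaptive_delta <= 1):
            raise RadscanError("adaptive_delta must be in (0, 1]")
        if self.n_adaptive_loci + self.snp_rich_locus_count > self.n_loci:
            raise RadscanError("planted loci exceed n_loci")
        if self.snp_cap < 1 or self.snp_mean <= 0:
            raise RadscanError("invalid SNPs-per-locus distribution")
        for node, (parent, c) in self.tree.items():
            if parent is not None and not (0 < c < 1):
                raise RadscanError(f"branch to {node!r}: drift c must be in (0, 1)")
        pop_ids = {p.pop_id for p in self.populations}
        for pid, u, v in self.pair_pops:
            if u not in pop_ids or v not in pop_ids:
                raise RadscanError(f"pair {pid!r} references unknown populations")

    def modes(self) -> list[str]:
        if isinstance(self.adaptive_mode, str):
            return [self.adaptive_mode] * self.n_adaptive_loci
        if len(self.adaptive_mode) != self.n_adaptive_loci:
            raise RadscanError("adaptive_mode list must match n_adaptive_loci")
        return list(self.adaptive_mode)


def default_config(seed: int = 0, individuals_per_pop: int = 8, **overrides) -> SimulationConfig:
    """Paired-radiation design: 4 ultramafic/volcanic sister pairs + outgroup.

    Two outgroup populations attach directly to the root (long branches,
    c=0.3); a rapid radiation clade with short internal branches (c=0.02)
    carries four sister pairs whose tip branches drift at c=0.1.  Eight
    diploid individuals per population.
    """
    pops: list[PopulationSpec] = []
    tree: dict[str, tuple[str | None, float]] = {"root": (None, 0.0), "radiation": ("root", 0.02)}
    pair_pops = []
    regions = ["north", "center", "south", "center"]
    climates = ["humid", "dry", "humid", "dry"]
    for k in range(4):
        anc = f"anc_pair{k + 1}"
        tree[anc] = ("radiation", 0.02)
        for soil in ("ultramafic", "volcanic"):
            pop_id = f"P{k + 1}{soil[0]}"
            tree[pop_id] = (anc, 0.1)
            pops.append(
                PopulationSpec(
                    pop_id=pop_id, species=f"sp_pair{k + 1}_{soil[0]}",
                    locality=f"L{k + 1}{soil[0]}", region=regions[k],
                    climate=climates[k], soil=soil, n_individuals=individuals_per_pop,
                )
            )
        pair_pops.append((f"pair{k + 1}", f"P{k + 1}u", f"P{k + 1}v"))
    for k, soil in enumerate(("schist", "limestone")):
        pop_id = f"OUT{k + 1}"
        tree[pop_id] = ("root", 0.3)
        pops.append(
            PopulationSpec(
                pop_id=pop_id, species=f"sp_out{k + 1}", locality=f"LO{k + 1}",
                region="south", climate="dry", soil=soil, n_individuals=individuals_per_pop,
            )
        )
    cfg = dict(populations=pops, tree=tree, pair_pops=pair_pops, seed=seed)
    cfg.update(overrides)
    return SimulationConfig(**cfg)


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class LocusTruth:
    locus_id: str
    kind: str  # neutral | adaptive | snp_rich
    mode: str | None = None  # shared_allele | independent_allele
    target_pairs: list[str] = field(default_factory=list)
    #: pair_id -> causal site id (shared mode repeats one site)
    causal_sites: dict[str, str] = field(default_factory=dict)
    singleton_sites: list[str] = field(default_factory=list)
    snp_count: int = 0


@dataclass
class TruthManifest:
    loci: dict[str, LocusTruth]
    ancestral_freq: dict[str, float]
    #: population id -> {site_id -> simulated (pre-sampling) frequency}
    pop_freq: dict[str, dict[str, float]]

    def to_json(self) -> str:
        doc = {
            "loci": {
                lid: {
                    "kind": t.kind, "mode": t.mode, "target_pairs": t.target_pairs,
                    "causal_sites": t.causal_sites,
                    "singleton_sites": t.singleton_sites, "snp_count": t.snp_count,
                }
                for lid, t in self.loci.items()
            },
            "ancestral_freq": self.ancestral_freq,
            "pop_freq": self.pop_freq,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        doc = json.loads(text)
        loci = {
            lid: LocusTruth(
                locus_id=lid, kind=d["kind"], mode=d["mode"],
                target_pairs=list(d["target_pairs"]),
                causal_sites=dict(d["causal_sites"]),
                singleton_sites=list(d["singleton_sites"]),
                snp_count=int(d["snp_count"]),
            )
            for lid, d in doc["loci"].items()
        }
        return cls(loci, doc["ancestral_freq"], doc["pop_freq"])


@dataclass
class SimulatedBundle:
    matrix: GenotypeMatrix
    catalog: LocusCatalog
    popmap: PopulationMap
    pairs: list[SisterPairContrast]
    manifest: TruthManifest
    freq_table: pd.DataFrame  # populations x sites


# ---------------------------------------------------------------------------
# Frequency simulation
# ---------------------------------------------------------------------------

def _beta_drift(rng: np.random.Generator, p: np.ndarray, c: float) -> np.ndarray:
    """One Balding-Nichols branch: child ~ Beta(p(1-c)/c, (1-p)(1-c)/c)."""
    if c < 1e-9:
        return p.copy()
    out = p.copy()
    inner = (p > 0) & (p < 1)
    scale = (1 - c) / c
    out[inner] = rng.beta(p[inner] * scale, (1 - p[inner]) * scale)
    return out


def _truncated_poisson(rng: np.random.Generator, lam: float, cap: int, size: int) -> np.ndarray:
    draws = rng.poisson(lam, size=size)
    while (draws == 0).any():
        zeros = draws == 0
        draws[zeros] = rng.poisson(lam, size=int(zeros.sum()))
    return np.minimum(draws, cap)


def simulate_frequencies(config: SimulationConfig) -> tuple[pd.DataFrame, TruthManifest, pd.DataFrame]:
    """Simulate per-population allele frequencies and the truth manifest.

    Returns ``(freq_table, manifest, site_table)`` where ``freq_table`` is a
    populations x sites DataFrame of post-displacement frequencies and
    ``site_table`` carries site metadata (site_id, locus_id, offset, ref, alt).
    """
    rng = np.random.default_rng(config.seed)
    n_loci = config.n_loci
    locus_ids = [f"L{k:05d}" for k in range(n_loci)]

    target_pairs = config.target_pairs or [pid for pid, _, _ in config.pair_pops]
    modes = config.modes()

    # choose planted loci
    order = rng.permutation(n_loci)
    adaptive_idx = set(order[: config.n_adaptive_loci].tolist())
    rich_idx = set(order[config.n_adaptive_loci:
                         config.n_adaptive_loci + config.snp_rich_locus_count].tolist())

    snp_counts = _truncated_poisson(rng, config.snp_mean, config.snp_cap, n_loci)
    mode_by_locus: dict[int, str] = {}
    for mode, k in zip(modes, sorted(adaptive_idx)):
        mode_by_locus[k] = mode
        if mode == "independent_allele":
            snp_counts[k] = max(snp_counts[k], len(target_pairs))
        if mode not in ("shared_allele", "independent_allele"):
            raise RadscanError(f"unknown adaptive mode {mode!r}")
    for k in rich_idx:
        snp_counts[k] = rng.integers(10, config.snp_cap + 1)

    # site metadata
    site_rows = []
    loci_truth: dict[str, LocusTruth] = {}
    for k, lid in enumerate(locus_ids):
        n_snp = int(snp_counts[k])
        offsets = np.sort(rng.choice(config.locus_length, size=n_snp, replace=False))
        for off in offsets:
            ref, alt = rng.choice(4, size=2, replace=False)
            site_rows.append(
                {"site_id": f"{lid}_{off}", "locus_id": lid, "offset": int(off),
                 "ref": _NUCS[ref], "alt": _NUCS[alt]}
            )
        kind = "adaptive" if k in adaptive_idx else ("snp_rich" if k in rich_idx else "neutral")
        loci_truth[lid] = LocusTruth(locus_id=lid, kind=kind,
                                     mode=mode_by_locus.get(k), snp_count=n_snp)
    site_table = pd.DataFrame(site_rows)
    n_sites = len(site_table)
    site_ids = list(site_table["site_id"])
    site_pos = {s: j for j, s in enumerate(site_ids)}

    # causal-site assignment
    causal_cols: set[int] = set()
    for k in sorted(adaptive_idx):
        lid = locus_ids[k]
        truth = loci_truth[lid]
        truth.target_pairs = list(target_pairs)
        locus_sites = [s for s in site_ids if s.startswith(lid + "_")]
        if truth.mode == "shared_allele":
            causal = str(rng.choice(locus_sites))
            truth.causal_sites = {pid: causal for pid in target_pairs}
        else:
            picks = rng.choice(len(locus_sites), size=len(target_pairs), replace=False)
            truth.causal_sites = {
                pid: locus_sites[int(i)] for pid, i in zip(target_pairs, picks)
            }
        causal_cols.update(site_pos[s] for s in truth.causal_sites.values())

    # ancestral frequencies
    p_root = rng.uniform(config.ancestral_low, config.ancestral_high, size=n_sites)
    causal_arr = np.fromiter(sorted(causal_cols), dtype=int, count=len(causal_cols))
    if len(causal_arr):
        p_root[causal_arr] = rng.uniform(
            config.causal_ancestral_low, config.causal_ancestral_high, size=len(causal_arr)
        )

    # drift down the tree (parents before children)
    node_freq: dict[str, np.ndarray] = {}
    remaining = dict(config.tree)
    while remaining:
        progressed = False
        for node, (parent, c) in list(remaining.items()):
            if parent is None:
                node_freq[node] = p_root.copy()
            elif parent in node_freq:
                node_freq[node] = _beta_drift(rng, node_freq[parent], c)
            else:
                continue
            del remaining[node]
            progressed = True
        if not progressed:
            raise RadscanError("tree has a cycle or a missing parent")

    pop_ids = [p.pop_id for p in config.populations]
    for pid in pop_ids:
        if pid not in node_freq:
            raise RadscanError(f"population {pid!r} is not a node of the tree")
    freq = pd.DataFrame(
        {pid: node_freq[pid] for pid in pop_ids}, index=site_ids
    ).T  # populations x sites

    # adaptive displacement at causal sites (post-drift, clipped)
    half = config.adaptive_delta / 2.0
    pair_lookup = {pid: (u, v) for pid, u, v in config.pair_pops}
    for k in sorted(adaptive_idx):
        truth = loci_truth[locus_ids[k]]
        for pid, causal in truth.causal_sites.items():
            upop, vpop = pair_lookup[pid]
            freq.loc[upop, causal] = min(1.0, freq.loc[upop, causal] + half)
            freq.loc[vpop, causal] = max(0.0, freq.loc[vpop, causal] - half)

    manifest = TruthManifest(
        loci=loci_truth,
        ancestral_freq={s: float(p) for s, p in zip(site_ids, p_root)},
        pop_freq={pid: {s: float(v) for s, v in freq.loc[pid].items()} for pid in pop_ids},
    )
    return freq, manifest, site_table


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------

def simulate_genotypes(freq: pd.DataFrame, manifest: TruthManifest,
                       site_table: pd.DataFrame, config: SimulationConfig) -> SimulatedBundle:
    """Sample diploid genotypes, apply locus dropout, plant singletons."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    individuals: list[str] = []
    ind_pop: list[str] = []
    pop_rows = []
    for spec in config.populations:
        for i in range(spec.n_individuals):
            ind = f"{spec.pop_id}_i{i}"
            individuals.append(ind)
            ind_pop.append(spec.pop_id)
            pop_rows.append(
                {"individual_id": ind, "population_id": spec.pop_id,
                 "species": spec.species, "locality": spec.locality,
                 "region": spec.region, "climate": spec.climate, "soil": spec.soil}
            )
    popmap = PopulationMap(pd.DataFrame(pop_rows))

    site_ids = list(site_table["site_id"])
    n_ind, n_sites = len(individuals), len(site_ids)
    p_by_ind = freq.loc[ind_pop].to_numpy()  # n_ind x n_sites
    calls = rng.binomial(2, p_by_ind).astype(np.int8)

    # locus-level dropout
    locus_ids = list(dict.fromkeys(site_table["locus_id"]))
    locus_cols = {
        lid: np.flatnonzero((site_table["locus_id"] == lid).to_numpy())
        for lid in locus_ids
    }
    drop = rng.random((n_ind, len(locus_ids))) < config.locus_missing_rate
    covered: dict[str, set[str]] = {}
    for L, lid in enumerate(locus_ids):
        rows = np.flatnonzero(drop[:, L])
        calls[np.ix_(rows, locus_cols[lid])] = MISSING
        covered[lid] = {individuals[i] for i in range(n_ind) if not drop[i, L]}

    # plant singleton SNPs on neutral, non-causal sites
    neutral_sites = [
        s for s in site_ids
        if manifest.loci[s.rsplit("_", 1)[0]].kind == "neutral"
    ]
    n_single = min(config.singleton_snp_count, len(neutral_sites))
    chosen = rng.choice(len(neutral_sites), size=n_single, replace=False)
    col_of = {s: j for j, s in enumerate(site_ids)}
    for idx in chosen:
        sid = neutral_sites[int(idx)]
        j = col_of[sid]
        lid = sid.rsplit("_", 1)[0]
        col = calls[:, j]
        callable_rows = np.flatnonzero(col != MISSING)
        if len(callable_rows) == 0:
            continue
        col[callable_rows] = 0
        carrier = int(rng.choice(callable_rows))
        col[carrier] = 1
        manifest.loci[lid].singleton_sites.append(sid)

    matrix = GenotypeMatrix(individuals, site_table, calls)
    catalog = LocusCatalog(
        {
            lid: LocusRecord(
                locus_id=lid, length_bp=config.locus_length,
                site_ids=[site_ids[j] for j in locus_cols[lid]],
                covered_individuals=covered[lid],
            )
            for lid in locus_ids
        }
    )
    pairs = []
    for pid, upop, vpop in config.pair_pops:
        pairs.append(
            SisterPairContrast(
                pair_id=pid,
                side_a=set(popmap.individuals_of_population(upop)),
                side_b=set(popmap.individuals_of_population(vpop)),
                ultramafic_side="a",
                label=f"{upop} (ultramafic) vs {vpop} (volcanic)",
            )
        )
    return SimulatedBundle(matrix, catalog, popmap, pairs, manifest, freq)


def simulate(config: SimulationConfig) -> SimulatedBundle:
    """Full generator: frequencies, genotypes, catalog, popmap, contrasts."""
    freq, manifest, site_table = simulate_frequencies(config)
    return simulate_genotypes(freq, manifest, site_table, config)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(bundle: SimulatedBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the five fixture files; re-reading reproduces the bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "catalog": out / "catalog.tsv",
        "popmap": out / "popmap.tsv",
        "pairs": out / "pairs.yaml",
        "manifest": out / "truth_manifest.json",
    }
    rio.write_vcf(bundle.matrix, paths["vcf"])
    rio.write_catalog(bundle.catalog, paths["catalog"])
    rio.write_popmap(bundle.popmap, paths["popmap"])
    rio.write_pairs(bundle.pairs, paths["pairs"])
    paths["manifest"].write_text(bundle.manifest.to_json())
    return paths


def read_fixture(in_dir: str | Path) -> SimulatedBundle:
    """Read back a fixture directory written by :func:`write_fixture`."""
    p = Path(in_dir)
    matrix = rio.read_vcf(p / "genotypes.vcf")
    catalog = rio.read_catalog(p / "catalog.tsv")
    popmap = rio.read_popmap(p / "popmap.tsv")
    pairs = rio.read_pairs(p / "pairs.yaml")
    manifest = TruthManifest.from_json((p / "truth_manifest.json").read_text())
    freq = pd.DataFrame(manifest.pop_freq).T
    return SimulatedBundle(matrix, catalog, popmap, pairs, manifest, freq)
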