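"""Pipeline orchestration: simulate -> filter -> scan -> classify -> report.

A run is driven by a :class:`RunConfig` (loadable from YAML).  Inputs are
either file paths (VCF + catalog + popmap + pairs) or a ``simulate`` block;
every stage writes its outputs before the next begins, all randomness flows
through seeds derived from the single run seed, and the summary records the
tool version and a hash of the semantic configuration so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as rio
from .filtering import FilterConfig, FilterReport, run_filter_cascade
from .genotypes import GenotypeMatrix, LocusCatalog, PopulationMap, RadscanError, SisterPairContrast
from .scan import ScanResult, fixed_fraction, scan_replicated_outliers
from .simulate import SimulationConfig, SimulatedBundle, default_config, simulate, write_fixture

logger = logging.getLogger(__name__)


@dataclass
class ScanSettings:
    threshold: float = 0.5
    min_pairs: int = 2
    estimator: str = "wc"
    min_called: int = 2


@dataclass
class RunConfig:
    out_dir: str = "radscan_out"
    seed: int = 0
    # either file inputs ...
    vcf: str | None = None
    catalog: str | None = None
    popmap: str | None = None
    pairs: str | None = None
    # ... or a simulation block (kwargs for simulate.default_config)
    simulate: dict | None = None
    filter: FilterConfig = field(default_factory=lambda: FilterConfig(
        min_covered_individuals=None, min_coverage_fraction=0.9))
    scan: ScanSettings = field(default_factory=ScanSettings)
    log_level: str = "INFO"

    def validate(self) -> None:
        has_files = all(x is not None for x in (self.vcf, self.catalog, self.pairs))
        if has_files == (self.simulate is not None):
            raise RadscanError(
                "provide either vcf+catalog+pairs paths or a simulate block, not both"
            )
        if has_files:
            for p in (self.vcf, self.catalog, self.popmap, self.pairs):
                if p is not None and not Path(p).exists():
                    raise RadscanError(f"input file not found: {p}")

    def semantic_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "vcf": self.vcf, "catalog": self.catalog,
            "popmap": self.popmap, "pairs": self.pairs,
            "simulate": self.simulate,
            "filter": dataclasses.asdict(self.filter),
            "scan": dataclasses.asdict(self.scan),
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        filt = doc.pop("filter", None)
        scan = doc.pop("scan", None)
        cfg = cls(**doc)
        if filt:
            cfg.filter = FilterConfig(**filt)
        if scan:
            cfg.scan = ScanSettings(**scan)
        return cfg


@dataclass
class RunSummary:
    out_dir: str
    seed: int
    config_hash: str
    version: str
    filter_report: FilterReport
    n_candidates: int
    classification_tally: dict[str, int]
    fixed_fraction: float | None
    not_fixed_fraction: float | None
    skipped_pairs: list[str]
    paths: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "filter_report": self.filter_report.to_dict(),
            "n_candidates": self.n_candidates,
            "classification_tally": self.classification_tally,
            "fixed_fraction": self.fixed_fraction,
            "not_fixed_fraction": self.not_fixed_fraction,
            "skipped_pairs": self.skipped_pairs,
            "paths": self.paths,
        }


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        bundle = simulate(default_config(**sim_kwargs))
        fixture_dir = out / "simulated"
        write_fixture(bundle, fixture_dir)
        return bundle.matrix, bundle.catalog, bundle.popmap, bundle.pairs
    matrix = rio.read_vcf(config.vcf)
    catalog = rio.read_catalog(config.catalog)
    popmap = rio.read_popmap(config.popmap) if config.popmap else None
    pairs = rio.read_pairs(config.pairs)
    return matrix, catalog, popmap, pairs


def records_table(result: ScanResult) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in result.records]
    return pd.DataFrame(rows)


def candidates_table(result: ScanResult) -> pd.DataFrame:
    rows = []
    for c in result.candidates:
        best = "; ".join(
            f"{pid}:{sid}={fst:.4f}" for pid, (sid, fst) in sorted(c.best_snp.items())
        )
        rows.append(
            {
                "locus_id": c.locus_id,
                "n_qualifying_pairs": len(c.qualifying_pairs),
                "qualifying_pairs": ",".join(sorted(c.qualifying_pairs)),
                "best_snp_per_pair": best,
                "classification": c.classification,
                "n_fixed_sites": sum(c.fixed_sites.values()),
                "n_qualifying_sites": len(c.qualifying_sites),
            }
        )
    return pd.DataFrame(
        rows, columns=["locus_id", "n_qualifying_pairs", "qualifying_pairs",
                       "best_snp_per_pair", "classification", "n_fixed_sites",
                       "n_qualifying_sites"],
    )


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full pipeline and write all stage outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    matrix, catalog, popmap, pairs = _load_inputs(config, out)
    matrix.attach_catalog_check(catalog)

    # --- filter cascade
    d1, d2, d3, cat_kept, report = run_filter_cascade(matrix, catalog, config.filter)
    for name, mat in (("D1", d1), ("D2", d2), ("D3", d3)):
        path = out / f"{name}.vcf"
        rio.write_vcf(mat, path)
        paths[f"{name.lower()}_vcf"] = str(path)
    rio.write_structure(d3, out / "D3.structure", popmap)
    paths["structure"] = str(out / "D3.structure")
    rio.write_phylip(d1, out / "D1.phy")
    paths["phylip"] = str(out / "D1.phy")
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    paths["filter_report"] = str(out / "filter_report.json")

    # --- scan on D1 (all SNPs of retained loci)
    result = scan_replicated_outliers(
        d1, cat_kept, pairs,
        threshold=config.scan.threshold, min_pairs=config.scan.min_pairs,
        estimator=config.scan.estimator, min_called=config.scan.min_called,
    )
    records_table(result).to_csv(out / "fst_records.tsv", sep="\t", index=False)
    paths["fst_records"] = str(out / "fst_records.tsv")
    cand_df = candidates_table(result)
    cand_df.to_csv(out / "candidates.tsv", sep="\t", index=False)
    paths["candidates_tsv"] = str(out / "candidates.tsv")
    cand_json = [
        {
            "locus_id": c.locus_id,
            "qualifying_pairs": sorted(c.qualifying_pairs),
            "best_snp": {p: list(v) for p, v in c.best_snp.items()},
            "classification": c.classification,
            "qualifying_sites": {s: sorted(p) for s, p in c.qualifying_sites.items()},
            "fixed_sites": c.fixed_sites,
        }
        for c in result.candidates
    ]
    (out / "candidates.json").write_text(json.dumps(cand_json, indent=1))
    paths["candidates_json"] = str(out / "candidates.json")

    # BED-like intervals of candidate loci for downstream annotation
    bed_lines = [
        f"{c.locus_id}\t0\t{catalog[c.locus_id].length_bp}\t{c.classification}"
        for c in result.candidates
    ]
    (out / "candidates.bed").write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    paths["candidates_bed"] = str(out / "candidates.bed")

    tally: dict[str, int] = {"collateral_shared": 0, "parallel_distinct": 0}
    for c in result.candidates:
        tally[c.classification] += 1
    if result.candidates:
        fixed, not_fixed = fixed_fraction(result.candidates)
    else:
        fixed = not_fixed = None

    summary = RunSummary(
        out_dir=str(out), seed=config.seed, config_hash=config.config_hash(),
        version=__version__, filter_report=report,
        n_candidates=len(result.candidates), classification_tally=tally,
        fixed_fraction=fixed, not_fixed_fraction=not_fixed,
        skipped_pairs=result.skipped_pairs, paths=paths,
    )
    (out / "summary.json").write_text(json.dumps(summary.to_dict(), indent=1, sort_keys=True))
    paths["summary"] = str(out / "summary.json")
    return summary


def render_report(summary: RunSummary) -> str:
    """Human-readable markdown report for a finished run."""
    rep = summary.filter_report
    lines = [
        "# radscan run report",
        "",
        f"- version: {summary.version}",
        f"- seed: {summary.seed}",
        f"- config hash: {summary.config_hash}",
        "",
        "## Filter cascade",
        "",
        f"| loci in | blacklisted (SNP-rich) | failing coverage | retained |",
        f"|---|---|---|---|",
        f"| {rep.loci_in} | {rep.loci_blacklisted_snp_rich} | {rep.loci_failing_coverage} | {rep.loci_retained} |",
        "",
        f"SNP counts: D1 = {rep.snps_d1}, D2 = {rep.snps_d2}, D3 = {rep.snps_d3}.",
        "",
        "## Replicated divergence scan",
        "",
    ]
    if summary.n_candidates == 0:
        lines.append("No candidate loci qualified in the required number of sister pairs.")
    else:
        lines.append(f"{summary.n_candidates} candidate loci; "
                     f"{summary.classification_tally['collateral_shared']} collateral (shared variant), "
                     f"{summary.classification_tally['parallel_distinct']} parallel (distinct variants).")
        lines.append("")
        pct = 100.0 * summary.not_fixed_fraction
        lines.append(f"{pct:.1f}% of qualifying SNPs are not reciprocal fixed differences.")
        lines.append("")
        cand_path = summary.paths.get("candidates_tsv")
        if cand_path and Path(cand_path).exists():
            df = pd.read_csv(cand_path, sep="\t")
            lines.append("| locus | pairs | best SNP per pair | class | fixed/qualifying sites |")
            lines.append("|---|---|---|---|---|")
            for _, r in df.iterrows():
                lines.append(
                    f"| {r['locus_id']} | {r['qualifying_pairs']} | {r['best_snp_per_pair']} "
                    f"| {r['classification']} | {r['n_fixed_sites']}/{r['n_qualifying_sites']} |"
                )
    if summary.skipped_pairs:
        lines += ["", f"Skipped pairs (no callable sites): {', '.join(summary.skipped_pairs)}"]
    return "\n".join(lines) + "\n"
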