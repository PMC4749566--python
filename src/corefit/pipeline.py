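"""End-to-end orchestration: signatures → support → calibration → core → downstream.

`run_fit` executes the primary analysis on a corrector compendium: extract
signatures, scan support thresholds against the chosen null, select the
cut-off (optionally refined by gene-set enrichment), and emit the calibrated
core per direction. `run_downstream` then runs overrepresentation, the PPI
overlap test, and the two-tailed GSEA drug re-ranking, as configured.

Every run writes a JSON manifest recording all parameters and derived
per-stage seeds; outputs are deterministic given a config (byte-identical on
rerun — no timestamps are embedded).
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from ._util import spawn_seeds
from .calibrate import (
    CutoffScan,
    CutoffSelection,
    refine_cutoff_by_enrichment,
    scan_cutoffs,
    select_cutoff,
    write_scan,
)
from .enrich import hypergeom_enrich, ppi_overlap_significance, rank_drugs
from .fit import (
    DEFAULT_TAIL_FRACTION,
    FitResult,
    extract_signatures,
    fuzzy_intersect,
    support_counts,
    write_fit_result,
)
from .profiles import (
    Compendium,
    collapse_probes_to_genes,
    read_edges,
    read_gmt,
    read_probe_gene_map,
    read_ranked_profiles,
)

__all__ = ["RunConfig", "FitRun", "run_fit", "run_downstream"]

log = logging.getLogger("corefit")


@dataclass
class RunConfig:
    """Parameters and input paths for a pipeline run.

    Paths may be None when the corresponding stage is disabled or the objects
    are passed in memory. `null_kind` is 'resampling' (needs a background
    compendium) or 'probe_permutation' (single-platform data).
    """

    profiles: str | None = None
    background_profiles: str | None = None
    probe_gene_map: str | None = None
    gmt: str | None = None
    edges: str | None = None
    gene_list: str | None = None  # e.g. proteostasis genes, one symbol per line
    outdir: str = "results/run"

    f: float = DEFAULT_TAIL_FRACTION
    b: int = 1000
    seed: int = 1
    fold_min: float = 3.0
    alpha: float = 0.05
    enrich_alpha: float = 0.05
    conf_min: float = 0.7
    plateau_eps: float = 0.02
    null_kind: str = "resampling"

    refine_enrichment: bool = False
    ppi_test: bool = False
    gsea_rank: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0.0 < self.f <= 0.5:
            raise ValueError(f"tail fraction must be in (0, 0.5], got {self.f}")
        if self.b < 1:
            raise ValueError("b must be ≥ 1")
        if self.null_kind not in ("resampling", "probe_permutation"):
            raise ValueError(f"unknown null_kind {self.null_kind!r}")
        if self.null_kind == "resampling" and self.background_profiles is None:
            raise ValueError("resampling null requires background_profiles")
        if self.refine_enrichment and (self.gmt is None or self.probe_gene_map is None):
            raise ValueError("enrichment refinement requires gmt and probe_gene_map")
        if self.ppi_test and (self.edges is None or self.gene_list is None):
            raise ValueError("ppi test requires edges and gene_list")
        for name in ("profiles", "background_profiles", "probe_gene_map", "gmt",
                     "edges", "gene_list"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


@dataclass
class FitRun:
    """In-memory result of `run_fit`."""

    config: RunConfig
    scan: CutoffScan
    selection: CutoffSelection
    fits: dict[str, FitResult | None]  # per direction, at the selected k
    core_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    manifest: dict[str, Any] = field(default_factory=dict)


def _read_gene_list(path: str | Path) -> frozenset[str]:
    genes = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.split("\t")[0])
    return frozenset(genes)


def run_fit(
    config: RunConfig,
    correctors: Compendium | None = None,
    background: Compendium | None = None,
) -> FitRun:
    """Execute the primary analysis and serialize its outputs.

    Compendia may be passed in memory (tests, simulations) or read from the
    configured paths.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(config.seed, 4)
    t0 = time.perf_counter()

    if correctors is None:
        if config.profiles is None:
            raise ValueError("no corrector profiles given (path or in-memory)")
        correctors = read_ranked_profiles(config.profiles)
    if background is None and config.background_profiles is not None:
        background = read_ranked_profiles(config.background_profiles)

    signatures = extract_signatures(correctors, config.f)
    table = support_counts(signatures)
    log.info("signatures extracted: N=%d, tail=%d", len(signatures),
             len(signatures[0].up_set))

    scan = scan_cutoffs(
        correctors,
        background=background,
        f=config.f,
        b=config.b,
        seed=seeds[0],
        null_kind=config.null_kind,
    )
    selection = select_cutoff(scan, fold_min=config.fold_min, alpha=config.alpha)

    probe_map = (
        read_probe_gene_map(config.probe_gene_map) if config.probe_gene_map else None
    )
    if config.refine_enrichment:
        sets = read_gmt(config.gmt)
        gene_universe = {probe_map.gene(p) for p in correctors.universe} - {None}
        for direction in ("up", "down"):
            if selection.by_direction[direction] is None:
                continue
            candidates = sorted(
                selection.table[
                    (selection.table["direction"] == direction)
                    & selection.table["passes"]
                ]["k"]
            )
            fits_by_k = {k: fuzzy_intersect(table, k) for k in candidates}
            refined = refine_cutoff_by_enrichment(
                scan, fits_by_k, sets, probe_map, gene_universe,
                direction=direction, fold_min=config.fold_min,
                alpha=config.alpha, enrich_alpha=config.enrich_alpha,
            )
            merged = dict(selection.by_direction)
            merged[direction] = refined.by_direction[direction]
            selection = CutoffSelection(
                by_direction=merged,
                fold_min=selection.fold_min,
                alpha=selection.alpha,
                table=selection.table,
                refined=selection.refined or refined.refined,
                rationale=refined.rationale,
            )

    fits: dict[str, FitResult | None] = {}
    core_genes: dict[str, frozenset[str]] = {}
    for direction in ("up", "down"):
        k = selection.by_direction[direction]
        if k is None:
            fits[direction] = None
            continue
        fit = fuzzy_intersect(table, k, theta=k / len(correctors))
        fits[direction] = fit
        if probe_map is not None:
            genes, report = collapse_probes_to_genes(fit.core(direction), probe_map)
            core_genes[direction] = genes
            log.info(
                "%s core: %d probes → %d genes (%d unmapped)",
                direction, len(fit.core(direction)), len(genes), report.n_unmapped,
            )

    write_scan(scan, selection, outdir / "scan.tsv")
    for direction, fit in fits.items():
        if fit is not None:
            write_fit_result(fit, outdir / f"fit_{direction}.tsv")
            pd.Series(sorted(fit.core(direction))).to_csv(
                outdir / f"core_probes_{direction}.tsv",
                sep="\t", index=False, header=["probe"],
            )
    for direction, genes in core_genes.items():
        pd.Series(sorted(genes)).to_csv(
            outdir / f"core_genes_{direction}.tsv",
            sep="\t", index=False, header=["gene"],
        )

    manifest = {
        "stage": "fit",
        "config": asdict(config),
        "derived_seeds": {"scan": seeds[0], "downstream": seeds[1:]},
        "n_profiles": len(correctors),
        "universe_size": correctors.universe_size,
        "selected_k": {d: selection.by_direction[d] for d in ("up", "down")},
        "selection_rationale": selection.rationale,
        "refined": selection.refined,
        "core_sizes": {
            d: (len(f.core(d)) if f is not None else None) for d, f in fits.items()
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("fit stage done in %.2fs", time.perf_counter() - t0)
    return FitRun(
        config=config, scan=scan, selection=selection, fits=fits,
        core_genes=core_genes, manifest=manifest,
    )


def run_downstream(
    config: RunConfig,
    fit_run: FitRun,
    compendium: Compendium | None = None,
) -> dict[str, Any]:
    """Enrichment, PPI overlap and drug re-ranking for a completed fit.

    ``compendium`` (defaults to the background profiles) is the panel ranked
    by the two-tailed GSEA stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(config.seed, 4)
    results: dict[str, Any] = {}

    probe_map = (
        read_probe_gene_map(config.probe_gene_map) if config.probe_gene_map else None
    )

    if config.gmt and probe_map is not None:
        sets = read_gmt(config.gmt)
        gene_universe = {probe_map.gene(p) for p in probe_map.mapping} - {None}
        frames = []
        for direction, genes in fit_run.core_genes.items():
            if not genes:
                continue
            res = hypergeom_enrich(genes & gene_universe, sets, gene_universe)
            frame = res.table.copy()
            frame.insert(0, "direction", direction)
            frames.append(frame)
        if frames:
            enrichment = pd.concat(frames, ignore_index=True)
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                              float_format="%.6g")
            results["enrichment"] = enrichment

    if config.ppi_test:
        net = read_edges(config.edges)
        partners = _read_gene_list(config.gene_list)
        core_all = frozenset().union(
            *(g for g in fit_run.core_genes.values() if g)
        )
        test = ppi_overlap_significance(
            core_all, partners, net, conf_min=config.conf_min,
            b=config.b, seed=seeds[2],
        )
        frame = pd.DataFrame([asdict(test)])
        frame.to_csv(outdir / "ppi_overlap.tsv", sep="\t", index=False,
                     float_format="%.6g")
        results["ppi_overlap"] = test

    if config.gsea_rank:
        if compendium is None:
            if config.background_profiles is None:
                raise ValueError("gsea_rank needs a compendium to rank")
            compendium = read_ranked_profiles(config.background_profiles)
        up = fit_run.fits["up"].up_core if fit_run.fits["up"] else frozenset()
        down = fit_run.fits["down"].down_core if fit_run.fits["down"] else frozenset()
        if not up and not down:
            raise ValueError("no core available for drug ranking")
        # one-sided queries are allowed: score the available direction only
        if up and down:
            ranking = rank_drugs(up, down, compendium)
        else:
            rows = []
            from .enrich import enrichment_score

            for prof in compendium:
                es = enrichment_score(up or down, prof)
                tes = es / 2.0 if up else -es / 2.0
                rows.append({"drug_id": prof.drug_id, "tes": tes})
            ranking = pd.DataFrame(rows).sort_values(
                "tes", ascending=False, ignore_index=True, kind="mergesort"
            )
            ranking["rank"] = range(1, len(ranking) + 1)
        ranking.to_csv(outdir / "drug_ranking.tsv", sep="\t", index=False,
                       float_format="%.6g")
        results["drug_ranking"] = ranking

    manifest = dict(fit_run.manifest)
    manifest["stage"] = "downstream"
    manifest["downstream_outputs"] = sorted(results)
    with open(outdir / "manifest_downstream.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results
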