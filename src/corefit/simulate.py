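"""Synthetic drug-compendium generator with planted ground truth.

The generator reproduces the statistical structure the fuzzy-intersection
analysis assumes: a small panel of "corrector" drugs shares a weakly
penetrant common signature (each planted probe responds in only a fraction
of the correctors) that is buried under much stronger, heterogeneous
primary mode-of-action (MOA) signals, plus a large background panel of
unrelated drugs. Every drug's latent score vector is standard normal noise;
planted effects are additive mean shifts; profiles are emitted by ranking
the latent scores, so only the ordering matters and the latent scale is
irrelevant.

Stated world (defaults): a 5000-probe universe, 11 correctors, 200
background drugs, a 150-probe planted downregulated core with per-drug
response probability 0.85 at shift 2.5, and 3 disjoint corrector MOA
clusters whose 300-probe modules (half up, half down) shift by 4 — strong
enough that naive profile clustering groups correctors by MOA, not by core
membership. Background drugs each carry an idiosyncratic module of the same
size and strength, emulating "every drug has a strong primary MOA". MOA
modules are disjoint from the planted core and from each other, so ground
truth is unambiguous.

Everything is bit-reproducible given the spec seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import as_rng
from .fit import FitResult
from .profiles import (
    Compendium,
    GeneSetCollection,
    InteractionNetwork,
    ProbeGeneMap,
    rank_from_expression,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "RecoveryReport",
    "DirectionRecovery",
    "generate_compendium",
    "score_recovery",
    "generate_gene_sets",
    "generate_network",
    "make_mimic_profile",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted world. Defaults are the stated conditions."""

    universe_size: int = 5000
    n_correctors: int = 11
    n_background: int = 200
    n_core_up: int = 0
    n_core_down: int = 150
    support_prob: float = 0.85
    core_strength: float = 2.5
    n_moa_clusters: int = 3
    moa_strength: float = 4.0
    moa_module_size: int = 300
    background_module_size: int = 300
    background_module_strength: float = 4.0
    seed: int = 1

    def __post_init__(self):
        if not 0.0 < self.support_prob <= 1.0:
            raise ValueError(f"support_prob must be in (0, 1], got {self.support_prob}")
        planted = (
            self.n_core_up
            + self.n_core_down
            + self.n_moa_clusters * self.moa_module_size
        )
        if planted > self.universe_size:
            raise ValueError(
                f"planted structure ({planted} probes) exceeds the universe "
                f"({self.universe_size})"
            )
        if self.n_correctors < 1 or self.n_background < 0:
            raise ValueError("need ≥1 corrector and ≥0 background drugs")
        if self.n_moa_clusters > 0 and self.n_moa_clusters > self.n_correctors:
            raise ValueError("more MOA clusters than correctors")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure, exactly as emitted into the compendium."""

    spec: SyntheticSpec
    core_up: frozenset[str]
    core_down: frozenset[str]
    #: corrector × planted-probe response indicators (True = shift applied)
    response: pd.DataFrame
    moa_cluster: dict[str, int]  # corrector drug_id → cluster index
    corrector_ids: tuple[str, ...]
    background_ids: tuple[str, ...]

    def core(self, direction: str) -> frozenset[str]:
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        return self.core_up if direction == "up" else self.core_down


def _probe_name(i: int, width: int) -> str:
    return f"P{i:0{width}d}"


def generate_compendium(spec: SyntheticSpec) -> tuple[Compendium, SyntheticTruth]:
    """Simulate the compendium and return it with its ground truth.

    Correctors and background drugs are emitted in one compendium
    (corrector ids ``C01``.., background ``B001``..); slice with
    :meth:`Compendium.subset` or the truth's id tuples.
    """
    rng = as_rng(spec.seed)
    u = spec.universe_size
    width = max(4, len(str(u - 1)))
    probes = np.array([_probe_name(i, width) for i in range(u)], dtype=object)

    # disjoint layout for core and MOA modules, randomized placement
    layout = rng.permutation(u)
    pos = 0
    core_up_ix = layout[pos : pos + spec.n_core_up]
    pos += spec.n_core_up
    core_down_ix = layout[pos : pos + spec.n_core_down]
    pos += spec.n_core_down
    moa_modules: list[np.ndarray] = []
    for _ in range(spec.n_moa_clusters):
        moa_modules.append(layout[pos : pos + spec.moa_module_size])
        pos += spec.moa_module_size
    free_ix = layout[pos:]  # pool for background idiosyncratic modules

    corrector_ids = tuple(f"C{i + 1:02d}" for i in range(spec.n_correctors))
    background_ids = tuple(f"B{i + 1:03d}" for i in range(spec.n_background))
    cluster_of = {
        d: (i % spec.n_moa_clusters) if spec.n_moa_clusters else -1
        for i, d in enumerate(corrector_ids)
    }

    planted_ix = np.concatenate([core_up_ix, core_down_ix]).astype(np.int64)
    planted_sign = np.concatenate(
        [np.ones(spec.n_core_up), -np.ones(spec.n_core_down)]
    )
    scores = np.empty((u, spec.n_correctors + spec.n_background))
    response_rows = []

    for j, drug in enumerate(corrector_ids):
        z = rng.standard_normal(u)
        responds = rng.random(len(planted_ix)) < spec.support_prob
        z[planted_ix[responds]] += (
            planted_sign[responds] * spec.core_strength
        )
        if spec.n_moa_clusters:
            module = moa_modules[cluster_of[drug]]
            half = len(module) // 2
            z[module[:half]] += spec.moa_strength
            z[module[half:]] -= spec.moa_strength
        scores[:, j] = z
        response_rows.append(responds)

    for j, drug in enumerate(background_ids):
        z = rng.standard_normal(u)
        if spec.background_module_size and len(free_ix):
            module = rng.choice(
                free_ix, size=min(spec.background_module_size, len(free_ix)), replace=False
            )
            half = len(module) // 2
            z[module[:half]] += spec.background_module_strength
            z[module[half:]] -= spec.background_module_strength
        scores[:, spec.n_correctors + j] = z

    matrix = pd.DataFrame(
        scores, index=probes, columns=list(corrector_ids) + list(background_ids)
    )
    compendium = rank_from_expression(matrix)
    response = pd.DataFrame(
        np.array(response_rows),
        index=list(corrector_ids),
        columns=list(probes[planted_ix]),
    )
    truth = SyntheticTruth(
        spec=spec,
        core_up=frozenset(probes[core_up_ix]),
        core_down=frozenset(probes[core_down_ix]),
        response=response,
        moa_cluster=cluster_of,
        corrector_ids=corrector_ids,
        background_ids=background_ids,
    )
    return compendium, truth


@dataclass(frozen=True)
class DirectionRecovery:
    precision: float
    recall: float
    f1: float
    n_recovered: int
    n_planted: int
    undefined: bool  # empty recovered or planted set: metrics forced to 0


@dataclass(frozen=True)
class RecoveryReport:
    up: DirectionRecovery
    down: DirectionRecovery

    def direction(self, d: str) -> DirectionRecovery:
        if d not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {d!r}")
        return self.up if d == "up" else self.down


def _recovery(recovered: frozenset[str], planted: frozenset[str]) -> DirectionRecovery:
    if not recovered or not planted:
        return DirectionRecovery(0.0, 0.0, 0.0, len(recovered), len(planted), True)
    tp = len(recovered & planted)
    precision = tp / len(recovered)
    recall = tp / len(planted)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return DirectionRecovery(precision, recall, f1, len(recovered), len(planted), False)


def score_recovery(
    fit: FitResult, truth: SyntheticTruth, probe_map: ProbeGeneMap | None = None
) -> RecoveryReport:
    """Precision / recall / F1 of the recovered core vs the planted core.

    Probe-level by default; pass a probe→gene map to score at gene level
    (both sides collapsed through the same map). An empty recovered core has
    undefined precision, reported as 0 with the ``undefined`` flag set.
    """
    def side(direction: str) -> DirectionRecovery:
        recovered = fit.core(direction)
        planted = truth.core(direction)
        if probe_map is not None:
            from .profiles import collapse_probes_to_genes

            recovered, _ = collapse_probes_to_genes(recovered, probe_map)
            planted, _ = collapse_probes_to_genes(planted, probe_map)
        return _recovery(frozenset(recovered), frozenset(planted))

    return RecoveryReport(up=side("up"), down=side("down"))


# ---------------------------------------------------------------------------
# synthetic companions for the downstream stages (all labelled synthetic)


def identity_probe_gene_map(compendium_or_probes) -> ProbeGeneMap:
    """Synthetic 1:1 probe→gene map (P0042 → G0042)."""
    probes = (
        compendium_or_probes.probe_order
        if isinstance(compendium_or_probes, Compendium)
        else sorted(compendium_or_probes)
    )
    return ProbeGeneMap({p: "G" + p[1:] for p in probes})


def generate_gene_sets(
    truth: SyntheticTruth,
    probe_map: ProbeGeneMap,
    n_core_sets: int = 5,
    n_random_sets: int = 200,
    set_size: int = 100,
    seed: int = 0,
) -> GeneSetCollection:
    """Synthetic gene-set collection for the enrichment stages.

    The planted core genes are split across ``n_core_sets`` "pathway" sets
    padded with random genes to ``set_size``; the rest are random sets. This
    is a stand-in for a GO/pathway collection, usable for the cut-off
    refinement demo on synthetic data.
    """
    rng = as_rng(seed)
    all_genes = np.array(sorted({probe_map.gene(p) for p in probe_map.mapping}), dtype=object)
    core_genes = sorted(
        {probe_map.gene(p) for p in (truth.core_up | truth.core_down) if probe_map.gene(p)}
    )
    non_core = np.array([g for g in all_genes if g not in set(core_genes)], dtype=object)
    sets: dict[str, frozenset[str]] = {}
    chunks = np.array_split(np.array(core_genes, dtype=object), max(n_core_sets, 1))
    for i, chunk in enumerate(chunks):
        pad = rng.choice(non_core, size=max(set_size - len(chunk), 0), replace=False)
        sets[f"CORE_PATHWAY_{i + 1}"] = frozenset(chunk) | frozenset(pad)
    for i in range(n_random_sets):
        members = rng.choice(all_genes, size=set_size, replace=False)
        sets[f"RANDOM_SET_{i + 1:03d}"] = frozenset(members)
    return GeneSetCollection(sets, {k: "synthetic" for k in sets})


def generate_network(
    truth: SyntheticTruth,
    probe_map: ProbeGeneMap,
    n_partner_genes: int = 80,
    p_core_partner: float = 0.15,
    p_background: float = 0.002,
    seed: int = 0,
) -> tuple[InteractionNetwork, frozenset[str]]:
    """Synthetic interaction network plus a "proteostasis-like" gene list.

    The partner list is wired to the planted core genes with probability
    ``p_core_partner`` per pair (high confidence), on top of sparse random
    background edges (mixed confidences, some below the 0.7 filter). Returns
    (network, partner gene set).
    """
    rng = as_rng(seed)
    all_genes = np.array(sorted({probe_map.gene(p) for p in probe_map.mapping}), dtype=object)
    core_genes = sorted(
        {probe_map.gene(p) for p in (truth.core_up | truth.core_down) if probe_map.gene(p)}
    )
    partners = rng.choice(
        np.array([g for g in all_genes if g not in set(core_genes)], dtype=object),
        size=n_partner_genes,
        replace=False,
    )
    edges: list[tuple[str, str, float]] = []
    for cg in core_genes:
        hit = rng.random(n_partner_genes) < p_core_partner
        for pg in partners[hit]:
            edges.append((cg, str(pg), float(rng.uniform(0.75, 0.99))))
    n_random = rng.binomial(len(all_genes) * 20, p_background)
    for _ in range(int(n_random)):
        a, b = rng.choice(all_genes, size=2, replace=False)
        edges.append((str(a), str(b), float(rng.uniform(0.1, 0.99))))
    return InteractionNetwork.from_edges(edges), frozenset(str(g) for g in partners)


def make_mimic_profile(
    truth: SyntheticTruth, drug_id: str = "MIMIC", seed: int = 0
):
    """One extra drug that fully carries the planted core signal.

    Useful as a positive control in mimic/reversal re-ranking: the profile is
    noise plus the core shifts at response probability 1 and no MOA module.
    """
    spec = truth.spec
    # Same probe universe and planted positions as the parent world.
    rng = as_rng(seed)
    u = spec.universe_size
    width = max(4, len(str(u - 1)))
    probes = np.array([_probe_name(i, width) for i in range(u)], dtype=object)
    z = rng.standard_normal(u)
    ix = {p: i for i, p in enumerate(probes)}
    for p in truth.core_up:
        z[ix[p]] += spec.core_strength * 2
    for p in truth.core_down:
        z[ix[p]] -= spec.core_strength * 2
    matrix = pd.DataFrame({drug_id: z}, index=probes)
    return rank_from_expression(matrix)[0]


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Planted-core TSV: probe, direction, plus response fractions."""
    rows = []
    for direction in ("up", "down"):
        for probe in sorted(truth.core(direction)):
            frac = (
                float(truth.response[probe].mean())
                if probe in truth.response.columns
                else float("nan")
            )
            rows.append(
                {"probe": probe, "direction": direction, "response_fraction": frac}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
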