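"""Downstream statistics on a calibrated core gene set.

Four independent analyses live here:

* gene-set overrepresentation of the core (one-sided hypergeometric test per
  set, Benjamini–Hochberg across sets) — used both as a standalone report and
  by the cut-off refinement;
* a permutation test for protein–protein-interaction overlap between the core
  and a second gene list (e.g. known proteostasis regulators) on a
  confidence-filtered interaction network;
* the fold-enrichment of core probes in corrector signatures relative to a
  background drug panel;
* two-tailed (symmetric) GSEA of an up/down core pair against every profile
  of a compendium, for mimic / reversal ("anti-corrector") drug re-ranking.

The enrichment score is the classic unweighted Kolmogorov–Smirnov running
sum: walking down the ranked list, +1/|S| at each member of S and −1/(U−|S|)
otherwise; ES is the signed maximum deviation. Consensus ranked lists carry
no expression weights, so the unweighted statistic is the natural choice.
The two-tailed score TES = (ES(up) − ES(down)) / 2 is this package's stated
convention: a drug that mimics the query signature scores near +1 and one
that reverses it near −1.
"""
from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._util import as_rng
from .fit import Signature
from .profiles import Compendium, GeneSetCollection, InteractionNetwork, RankedProfile

__all__ = [
    "EnrichmentResult",
    "OverlapTest",
    "CoreFrequencyFold",
    "TwoTailedScore",
    "hypergeom_enrich",
    "ppi_overlap_significance",
    "core_frequency_fold",
    "enrichment_score",
    "gsea_two_tailed",
    "rank_drugs",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set overrepresentation table (columns: set_id, overlap, set_size,
    query_size, universe_size, p, q), sorted by p ascending."""

    table: pd.DataFrame
    query_size: int
    universe_size: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] <= alpha]


def hypergeom_enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> EnrichmentResult:
    """One-sided hypergeometric overrepresentation with BH correction.

    Equivalent to the upper tail of Fisher's exact test: with a universe of M
    genes, a set of K and a query of n, p = P[overlap ≥ x] =
    hypergeom.sf(x − 1; M, K, n). Sets are intersected with the universe
    before testing; sets with no member in the universe are skipped.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not query:
        raise ValueError("empty query gene set")
    if not universe:
        raise ValueError("empty gene universe")
    if not query <= universe:
        raise ValueError(
            f"query is not a subset of the universe "
            f"(e.g. {sorted(query - universe)[:5]})"
        )
    m = len(universe)
    n_query = len(query)
    rows = []
    for sid, members in sorted(sets.items()):
        members = members & universe
        if not members:
            continue
        overlap = len(query & members)
        p = float(hypergeom.sf(overlap - 1, m, len(members), n_query))
        rows.append(
            {
                "set_id": sid,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": n_query,
                "universe_size": m,
                "p": min(p, 1.0),
            }
        )
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values(["p", "set_id"], ignore_index=True)
    return EnrichmentResult(table=table, query_size=n_query, universe_size=m)


@dataclass(frozen=True)
class OverlapTest:
    """Permutation test for interaction-edge overlap between two gene sets."""

    observed: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    b: int
    seed: int | None
    mode: str
    conf_min: float


def _edge_count(
    edges_u: np.ndarray, edges_v: np.ndarray, in_a: np.ndarray, in_b: np.ndarray, mode: str
) -> int:
    if mode == "between":
        hit = (in_a[edges_u] & in_b[edges_v]) | (in_b[edges_u] & in_a[edges_v])
    elif mode == "union":
        in_u = in_a | in_b
        hit = in_u[edges_u] & in_u[edges_v]
    else:
        raise ValueError(f"mode must be 'between' or 'union', got {mode!r}")
    return int(hit.sum())


def ppi_overlap_significance(
    set_a: Iterable[str],
    set_b: Iterable[str],
    net: InteractionNetwork,
    conf_min: float = 0.7,
    b: int = 1000,
    seed=None,
    mode: str = "between",
    degree_preserving: bool = False,
) -> OverlapTest:
    """Are two gene sets more interconnected than random node sets?

    Edges with confidence strictly greater than ``conf_min`` are kept. The
    observed statistic is the number of such edges with one endpoint in each
    set (``mode='between'``) or with both endpoints in the union
    (``mode='union'``). The default null permutes node labels: B random
    bijections of the node set, preserving both set sizes and their overlap;
    the p-value is add-one empirical. ``degree_preserving=True`` switches to
    a double-edge-swap rewiring null (2|E| swaps per draw) that additionally
    conditions on every node's degree; it is markedly slower and off by
    default since the label permutation is the simpler defensible null.
    """
    filtered = net.filter_confidence(conf_min)
    nodes = np.array(sorted(filtered.graph.nodes), dtype=object)
    node_ix = {g: i for i, g in enumerate(nodes)}
    a_ix = np.array(sorted(node_ix[g] for g in set(set_a) if g in node_ix), dtype=np.int64)
    b_ix = np.array(sorted(node_ix[g] for g in set(set_b) if g in node_ix), dtype=np.int64)
    if len(a_ix) == 0 or len(b_ix) == 0:
        raise ValueError("one of the gene sets has no node in the filtered network")
    n_nodes = len(nodes)
    edge_list = np.array(
        [(node_ix[u], node_ix[v]) for u, v in filtered.graph.edges], dtype=np.int64
    ).reshape(-1, 2)
    eu, ev = edge_list[:, 0], edge_list[:, 1]

    in_a = np.zeros(n_nodes, dtype=bool)
    in_a[a_ix] = True
    in_b = np.zeros(n_nodes, dtype=bool)
    in_b[b_ix] = True
    observed = _edge_count(eu, ev, in_a, in_b, mode)

    rng = as_rng(seed)
    null = np.empty(b, dtype=np.int64)
    if degree_preserving:
        import networkx as nx

        nx_seed = int(rng.integers(2**31))
        for i in range(b):
            g = filtered.graph.copy()
            if g.number_of_edges() > 1:
                nx.double_edge_swap(
                    g, nswap=2 * g.number_of_edges(),
                    max_tries=100 * g.number_of_edges(),
                    seed=nx_seed + i,
                )
            swapped = np.array(
                [(node_ix[u], node_ix[v]) for u, v in g.edges], dtype=np.int64
            ).reshape(-1, 2)
            null[i] = _edge_count(swapped[:, 0], swapped[:, 1], in_a, in_b, mode)
    else:
        for i in range(b):
            perm = rng.permutation(n_nodes)
            null[i] = _edge_count(eu, ev, in_a[perm], in_b[perm], mode)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if b > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else math.nan
    p = (1 + int((null >= observed).sum())) / (b + 1)
    return OverlapTest(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p=p,
        b=b,
        seed=seed if isinstance(seed, int) else None,
        mode=mode,
        conf_min=conf_min,
    )


@dataclass(frozen=True)
class CoreFrequencyFold:
    """Fold-enrichment of core probes in corrector vs background signatures."""

    fold: float
    corrector_mean: float
    background_mean: float
    infinite: bool
    direction: str


def core_frequency_fold(
    core: Iterable[str],
    drug_sigs: Sequence[Signature],
    background_sigs: Sequence[Signature],
    direction: str = "both",
) -> CoreFrequencyFold:
    """Mean per-signature core fraction in correctors over background.

    For each signature, the fraction of the core present in the signature's
    probe tails (``direction`` = 'up', 'down', or 'both' for their union);
    the statistic is the ratio of the corrector mean to the background mean.
    A zero background mean is reported as an infinite fold with a flag, not
    an error.
    """
    core = frozenset(core)
    if not core:
        raise ValueError("empty core set")
    if not drug_sigs or not background_sigs:
        raise ValueError("both signature collections must be non-empty")

    def members(sig: Signature) -> frozenset[str]:
        if direction == "up":
            return sig.up_set
        if direction == "down":
            return sig.down_set
        if direction == "both":
            return sig.up_set | sig.down_set
        raise ValueError(f"direction must be 'up', 'down' or 'both', got {direction!r}")

    def mean_fraction(sigs: Sequence[Signature]) -> float:
        return float(np.mean([len(core & members(s)) / len(core) for s in sigs]))

    corr = mean_fraction(drug_sigs)
    back = mean_fraction(background_sigs)
    if back == 0.0:
        return CoreFrequencyFold(math.inf, corr, back, True, direction)
    return CoreFrequencyFold(corr / back, corr, back, False, direction)


# ---------------------------------------------------------------------------
# two-tailed GSEA


def enrichment_score(gene_set: Iterable[str], profile: RankedProfile) -> float:
    """Unweighted KS enrichment score of a set against one ranked profile.

    Hit step 1/|S|, miss step 1/(U−|S|); ES is the running sum's signed
    maximum deviation from zero (ties in magnitude resolve to the positive
    peak). |S| counts only members present in the profile universe; a set
    covering the whole universe (or none of it) is an error.
    """
    positions = sorted(
        i for i, p in enumerate(profile.probes) if p in frozenset(gene_set)
    )
    u = len(profile)
    nh = len(positions)
    if nh == 0:
        raise ValueError("gene set has no member in the profile universe")
    if nh == u:
        raise ValueError("gene set covers the entire universe")
    hit_step = 1.0 / nh
    miss_step = 1.0 / (u - nh)
    # The running sum is piecewise linear between hits: its extrema occur
    # right after a hit (local max) or right before one (local min).
    best_pos = 0.0
    best_neg = 0.0
    for j, pos in enumerate(positions):
        after = (j + 1) * hit_step - (pos - j) * miss_step
        before = j * hit_step - (pos - j) * miss_step
        best_pos = max(best_pos, after)
        best_neg = min(best_neg, before)
    return best_pos if best_pos >= -best_neg else best_neg


@dataclass(frozen=True)
class TwoTailedScore:
    es_up: float
    es_down: float

    @property
    def tes(self) -> float:
        return (self.es_up - self.es_down) / 2.0


def gsea_two_tailed(
    up: Iterable[str], down: Iterable[str], profile: RankedProfile
) -> TwoTailedScore:
    """Two-tailed symmetric enrichment of an up/down signature pair.

    TES = (ES(up) − ES(down)) / 2 ∈ [−1, 1]: +1 when the profile puts the
    up-set at its very top and the down-set at its very bottom (a mimic),
    −1 for a perfect reversal.
    """
    up = frozenset(up)
    down = frozenset(down)
    if up & down:
        raise ValueError("up and down sets must be disjoint")
    return TwoTailedScore(
        es_up=enrichment_score(up, profile),
        es_down=enrichment_score(down, profile),
    )


def rank_drugs(
    up: Iterable[str],
    down: Iterable[str],
    compendium: Compendium,
    mimic: bool = True,
) -> pd.DataFrame:
    """Score every profile against a query signature and rank.

    Descending TES for mimic search (drugs reproducing the query first);
    ascending for reversal / anti-signature search. Columns: drug_id, es_up,
    es_down, tes, rank (1 = best).
    """
    rows = []
    for prof in compendium:
        score = gsea_two_tailed(up, down, prof)
        rows.append(
            {
                "drug_id": prof.drug_id,
                "es_up": score.es_up,
                "es_down": score.es_down,
                "tes": score.tes,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "tes", ascending=not mimic, ignore_index=True, kind="mergesort"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table
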