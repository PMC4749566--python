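"""Ranked-profile containers and external formats.

A drug's transcriptional response is represented as a *ranked list*: the full
probe-set universe ordered from the most upregulated (rank 1) to the most
downregulated probe. A :class:`Compendium` is a collection of such lists over
one shared probe universe — e.g. a connectivity-map-style panel of drug
response profiles. This module holds the containers and all file I/O
(ranked-profile TSV, GMT gene sets, edge lists, probe→gene maps) plus the
probe→gene collapse; it does no statistics.

All files are UTF-8, tab-separated; lines starting with '#' are ignored.
Ranks are 0-based internally and 1-based in every written report.
"""
from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RankedProfile",
    "Compendium",
    "ProbeGeneMap",
    "GeneSetCollection",
    "InteractionNetwork",
    "CollapseReport",
    "read_ranked_profiles",
    "write_ranked_profiles",
    "rank_from_expression",
    "collapse_probes_to_genes",
    "read_probe_gene_map",
    "read_gmt",
    "read_edges",
]


@dataclass(frozen=True)
class RankedProfile:
    """One drug's fully ordered probe list (index 0 = most upregulated)."""

    drug_id: str
    probes: tuple[str, ...]

    def __post_init__(self):
        seen: set[str] = set()
        for p in self.probes:
            if p in seen:
                raise ValueError(
                    f"duplicate probe {p!r} in profile {self.drug_id!r}"
                )
            seen.add(p)
        if len(self.probes) < 10:
            warnings.warn(
                f"profile {self.drug_id!r} has only {len(self.probes)} probes; "
                "ranked lists are normally genome-scale",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def probe_set(self) -> frozenset[str]:
        return frozenset(self.probes)


class Compendium:
    """Profiles sharing one probe universe.

    Raises on construction if any profile's probe set differs from the
    universe (the symmetric difference is reported, first 10 entries).
    """

    def __init__(self, profiles: Sequence[RankedProfile]):
        if not profiles:
            raise ValueError("a compendium needs at least one profile")
        ids = [p.drug_id for p in profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate drug_id in compendium")
        universe = profiles[0].probe_set
        for p in profiles[1:]:
            if p.probe_set != universe:
                diff = sorted(universe.symmetric_difference(p.probe_set))
                raise ValueError(
                    f"profile {p.drug_id!r} does not share the probe universe; "
                    f"symmetric difference (first 10): {diff[:10]}"
                )
        self.profiles: list[RankedProfile] = list(profiles)
        self.universe: frozenset[str] = universe
        # integer coding for the fast numeric paths
        self.probe_order: list[str] = sorted(universe)
        self.probe_index: dict[str, int] = {
            p: i for i, p in enumerate(self.probe_order)
        }
        self._codes: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, i) -> RankedProfile:
        return self.profiles[i]

    @property
    def drug_ids(self) -> list[str]:
        return [p.drug_id for p in self.profiles]

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def code_matrix(self) -> np.ndarray:
        """(n_profiles, universe_size) int array of probe codes in rank order."""
        if self._codes is None:
            idx = self.probe_index
            self._codes = np.array(
                [[idx[p] for p in prof.probes] for prof in self.profiles],
                dtype=np.int32,
            )
        return self._codes

    def subset(self, drug_ids: Iterable[str]) -> "Compendium":
        wanted = list(drug_ids)
        by_id = {p.drug_id: p for p in self.profiles}
        missing = [d for d in wanted if d not in by_id]
        if missing:
            raise KeyError(f"drugs not in compendium: {missing[:10]}")
        return Compendium([by_id[d] for d in wanted])


@dataclass(frozen=True)
class ProbeGeneMap:
    """Many-to-one probe → gene-symbol mapping; unmapped probes are allowed."""

    mapping: Mapping[str, str]

    def gene(self, probe: str) -> str | None:
        return self.mapping.get(probe)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class CollapseReport:
    n_probes: int
    n_mapped: int
    n_unmapped: int
    unmapped: frozenset[str]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathways, GO terms, ...)."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for sid, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


class InteractionNetwork:
    """Undirected interaction edges with confidence scores in [0, 1]."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "InteractionNetwork":
        g = nx.Graph()
        for a, b, conf in edges:
            conf = float(conf)
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"confidence {conf} outside [0, 1] for edge ({a}, {b})")
            if a == b:
                warnings.warn(f"dropping self-edge on {a!r}", stacklevel=2)
                continue
            # keep the highest confidence if an edge is listed twice
            if g.has_edge(a, b):
                conf = max(conf, g[a][b]["confidence"])
            g.add_edge(a, b, confidence=conf)
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def filter_confidence(self, conf_min: float) -> "InteractionNetwork":
        """Keep edges with confidence strictly greater than conf_min."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for a, b, d in self.graph.edges(data=True):
            if d["confidence"] > conf_min:
                g.add_edge(a, b, **d)
        return InteractionNetwork(g)


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_ranked_profiles(path: str | Path) -> Compendium:
    """Read a compendium of ranked lists.

    ``path`` may be a wide TSV (header row = drug ids, each column a ranked
    probe list, row order = rank) or a directory of per-drug two-column
    (rank, probe) TSV files whose stem is the drug id.
    """
    path = Path(path)
    if path.is_dir():
        profiles = []
        for f in sorted(path.glob("*.tsv")):
            rows = []
            for lineno, line in _data_lines(f):
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{f}:{lineno}: expected 2 columns, got {len(parts)}")
                try:
                    rank = int(parts[0])
                except ValueError as e:
                    raise ValueError(f"{f}:{lineno}: non-integer rank {parts[0]!r}") from e
                rows.append((rank, parts[1]))
            rows.sort(key=lambda r: r[0])
            profiles.append(RankedProfile(f.stem, tuple(p for _, p in rows)))
        if not profiles:
            raise ValueError(f"no .tsv profile files under {path}")
        return Compendium(profiles)

    header: list[str] | None = None
    columns: list[list[str]] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if header is None:
            header = parts
            columns = [[] for _ in header]
            continue
        if len(parts) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
            )
        for col, cell in zip(columns, parts):
            if cell:
                col.append(cell)
    if header is None:
        raise ValueError(f"{path}: empty ranked-profile file")
    return Compendium(
        [RankedProfile(d, tuple(col)) for d, col in zip(header, columns)]
    )


def write_ranked_profiles(compendium: Compendium, path: str | Path) -> None:
    """Write the wide ranked-profile TSV (inverse of :func:`read_ranked_profiles`)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(compendium.drug_ids) + "\n")
        for rank in range(compendium.universe_size):
            fh.write("\t".join(p.probes[rank] for p in compendium.profiles) + "\n")


def rank_from_expression(matrix: pd.DataFrame) -> Compendium:
    """Rank a genes×conditions matrix of signed scores into a compendium.

    Per column, probes are ordered by descending score (most upregulated
    first); ties are broken by ascending probe-id lexicographic order.
    Non-finite entries are a hard error with their coordinates.
    """
    values = matrix.to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite score at probe {matrix.index[r]!r}, "
            f"condition {matrix.columns[c]!r}"
        )
    probe_ids = matrix.index.to_numpy(dtype=object)
    lex = np.argsort(probe_ids, kind="stable")  # secondary key: probe id ascending
    profiles = []
    for j, drug in enumerate(matrix.columns):
        order = lex[np.argsort(-values[lex, j], kind="stable")]
        profiles.append(RankedProfile(str(drug), tuple(probe_ids[order])))
    return Compendium(profiles)


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Two-column probe<TAB>gene TSV; a probe may appear at most once."""
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        probe, gene = parts
        if probe in mapping and mapping[probe] != gene:
            raise ValueError(f"{path}:{lineno}: probe {probe!r} maps to multiple genes")
        mapping[probe] = gene
    return ProbeGeneMap(mapping)


def collapse_probes_to_genes(
    probes: Iterable[str], probe_map: ProbeGeneMap
) -> tuple[frozenset[str], CollapseReport]:
    """Collapse a probe set to distinct gene symbols.

    Unmapped probes are dropped (with a count in the report), never an error:
    the intersection itself is probe-level, and gene identity only matters to
    the downstream enrichment steps.
    """
    probes = set(probes)
    genes = set()
    unmapped = set()
    for p in probes:
        g = probe_map.gene(p)
        if g is None:
            unmapped.add(p)
        else:
            genes.add(g)
    report = CollapseReport(
        n_probes=len(probes),
        n_mapped=len(probes) - len(unmapped),
        n_unmapped=len(unmapped),
        unmapped=frozenset(unmapped),
    )
    return frozenset(genes), report


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Broad-dialect GMT: set_id <TAB> description <TAB> member genes..."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs set_id, description and ≥1 member"
            )
        sid, desc, *members = parts
        members = [m for m in members if m]
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {sid!r} has no members")
        if sid in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set id {sid!r}")
        sets[sid] = frozenset(members)
        descriptions[sid] = desc
    return GeneSetCollection(sets, descriptions)


def read_edges(path: str | Path) -> InteractionNetwork:
    """Three-column gene_a <TAB> gene_b <TAB> confidence TSV."""
    path = Path(path)
    edges = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        a, b, conf_s = parts
        try:
            conf = float(conf_s)
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: bad confidence {conf_s!r}") from e
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"{path}:{lineno}: confidence {conf} outside [0, 1]")
        edges.append((a, b, conf))
    return InteractionNetwork.from_edges(edges)
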