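"""Signature extraction and the fuzzy intersection of ranked profiles.

The consensus statistic is deliberately simple. Each drug's *signature* is the
top and bottom tail of its ranked list (default 20% per tail — with merged
consensus ranked lists no fold-change or p-value threshold is available, so a
rank quantile is the only defensible cut). For each probe and each direction
we count in how many of the N signatures it occurs (its *support*), and the
fuzzy intersection at support threshold k_min keeps the probes with support
≥ k_min. k_min is derived from a fuzzy cut-off theta ∈ (0, 1] — the fraction
of drugs a probe must respond in to count as consistently regulated — as
ceil(theta·N): with 11 profiles and theta = 0.7 a probe must appear in at
least 8 signatures. "Fuzzy" here means a count threshold between union
(k_min = 1) and classical intersection (k_min = N), not fuzzy-set algebra.

Up- and downregulated intersections are computed and reported separately and
never merged.
"""
from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import scaled_ceil, scaled_floor
from .profiles import Compendium, RankedProfile

__all__ = [
    "DEFAULT_TAIL_FRACTION",
    "Signature",
    "SupportTable",
    "FitResult",
    "tail_size",
    "extract_signature",
    "extract_signatures",
    "min_support",
    "support_counts",
    "fuzzy_intersect",
    "write_fit_result",
]

#: Tail fraction used throughout the analysis unless overridden.
DEFAULT_TAIL_FRACTION = 0.2


@dataclass(frozen=True)
class Signature:
    """Up- and down-regulated tails of one ranked profile."""

    drug_id: str
    up_set: frozenset[str]
    down_set: frozenset[str]
    tail_fraction: float

    def __post_init__(self):
        if self.up_set & self.down_set:
            raise ValueError(
                f"signature {self.drug_id!r}: up and down tails overlap"
            )

    @property
    def universe_hint(self) -> frozenset[str]:
        return self.up_set | self.down_set


def tail_size(universe_size: int, f: float) -> int:
    """Number of probes per tail: floor(f * U), with 0 < f ≤ 0.5."""
    if not 0.0 < f <= 0.5:
        raise ValueError(f"tail fraction must be in (0, 0.5], got {f}")
    t = scaled_floor(f, universe_size)
    if t < 1:
        raise ValueError(
            f"tail fraction {f} of universe {universe_size} leaves an empty tail"
        )
    return t


def extract_signature(
    profile: RankedProfile, f: float = DEFAULT_TAIL_FRACTION
) -> Signature:
    """Top floor(f·U) probes → up_set, bottom floor(f·U) → down_set."""
    t = tail_size(len(profile), f)
    return Signature(
        drug_id=profile.drug_id,
        up_set=frozenset(profile.probes[:t]),
        down_set=frozenset(profile.probes[-t:]),
        tail_fraction=f,
    )


def extract_signatures(
    compendium: Compendium, f: float = DEFAULT_TAIL_FRACTION
) -> list[Signature]:
    return [extract_signature(p, f) for p in compendium]


def min_support(n: int, theta: float) -> int:
    """Integer support threshold k_min = ceil(theta·N), clamped to [1, N].

    theta is the fuzzy cut-off: the fraction of the N profiles a probe must
    respond in. ceil is the only rounding consistent with "0.7 of 11 → 8".
    """
    if n < 1:
        raise ValueError(f"need at least one profile, got n={n}")
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"fuzzy cut-off must be in (0, 1], got {theta}")
    return min(max(scaled_ceil(theta, n), 1), n)


@dataclass(frozen=True)
class SupportTable:
    """Per-probe, per-direction signature occurrence counts."""

    up: dict[str, int]
    down: dict[str, int]
    n_signatures: int
    universe: frozenset[str]

    def counts(self, direction: str) -> dict[str, int]:
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        return self.up if direction == "up" else self.down


def support_counts(signatures: Sequence[Signature]) -> SupportTable:
    """Count, per direction, how many signatures contain each probe.

    Directions are counted independently: a probe may have nonzero support in
    both directions across different drugs. All signatures must come from one
    probe universe; since a signature only carries its tails, the check is
    that tail sizes match and no stronger (full-universe checks happen in
    :class:`~corefit.profiles.Compendium`).
    """
    if not signatures:
        raise ValueError("no signatures given")
    sizes = {(len(s.up_set), len(s.down_set)) for s in signatures}
    if len(sizes) != 1:
        raise ValueError(f"signatures have mixed tail sizes: {sorted(sizes)}")
    up: dict[str, int] = {}
    down: dict[str, int] = {}
    universe: set[str] = set()
    for sig in signatures:
        for p in sig.up_set:
            up[p] = up.get(p, 0) + 1
        for p in sig.down_set:
            down[p] = down.get(p, 0) + 1
        universe |= sig.universe_hint
    return SupportTable(
        up=up, down=down, n_signatures=len(signatures), universe=frozenset(universe)
    )


@dataclass(frozen=True)
class FitResult:
    """Direction-specific fuzzy-intersection output."""

    up_core: frozenset[str]
    down_core: frozenset[str]
    k_min: int
    n_signatures: int
    table: SupportTable
    theta: float | None = None

    def core(self, direction: str) -> frozenset[str]:
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        return self.up_core if direction == "up" else self.down_core


def fuzzy_intersect(
    table: SupportTable, k_min: int, theta: float | None = None
) -> FitResult:
    """Threshold the support table at k_min, per direction."""
    n = table.n_signatures
    if not 1 <= k_min <= n:
        raise ValueError(f"k_min must be in [1, {n}], got {k_min}")
    up_core = frozenset(p for p, c in table.up.items() if c >= k_min)
    down_core = frozenset(p for p, c in table.down.items() if c >= k_min)
    both = up_core & down_core
    if both:
        warnings.warn(
            f"{len(both)} probe(s) pass both the up and down thresholds "
            f"(e.g. {sorted(both)[:5]}); reported in both cores",
            stacklevel=2,
        )
    return FitResult(
        up_core=up_core,
        down_core=down_core,
        k_min=k_min,
        n_signatures=n,
        table=table,
        theta=theta,
    )


def write_fit_result(fit: FitResult, path: str | Path) -> None:
    """Serialize as TSV: probe, direction, support, n, k_min, in_core."""
    rows = []
    for direction in ("up", "down"):
        counts = fit.table.counts(direction)
        core = fit.core(direction)
        for probe in sorted(counts):
            rows.append(
                {
                    "probe": probe,
                    "direction": direction,
                    "support": counts[probe],
                    "n": fit.n_signatures,
                    "k_min": fit.k_min,
                    "in_core": int(probe in core),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fast integer-coded support paths used by the null models


def tail_code_arrays(
    compendium: Compendium, f: float = DEFAULT_TAIL_FRACTION
) -> tuple[np.ndarray, np.ndarray]:
    """(up_codes, down_codes): (n_profiles, tail) int arrays of probe codes."""
    t = tail_size(compendium.universe_size, f)
    codes = compendium.code_matrix()
    return np.ascontiguousarray(codes[:, :t]), np.ascontiguousarray(codes[:, -t:])


def support_vector(tail_codes: np.ndarray, rows: np.ndarray | None, universe_size: int) -> np.ndarray:
    """Support counts over the probe universe for the selected profiles."""
    sel = tail_codes if rows is None else tail_codes[rows]
    return np.bincount(sel.ravel(), minlength=universe_size)


def cardinality_by_k(support: np.ndarray, n: int) -> np.ndarray:
    """Vector c with c[k-1] = #{probes with support ≥ k}, k = 1..n."""
    hist = np.bincount(support, minlength=n + 1)
    return hist[::-1].cumsum()[::-1][1 : n + 1].astype(np.int64)
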