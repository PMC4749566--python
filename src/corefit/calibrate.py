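"""Empirical null models and fuzzy cut-off calibration.

Two nulls are implemented for the intersection cardinality, both empirical
(no closed form is attempted):

* **resampling null** — for multi-platform consensus ranked lists backed by a
  large background compendium: each of B iterations draws N distinct
  background profiles (without replacement within a draw), extracts their
  signatures and records the fuzzy-intersection cardinality. This asks "how
  many probes would N *random* drugs share at this threshold?".
* **probe-permutation null** — for single-platform datasets with no external
  background: each iteration independently permutes every profile's probe
  order uniformly at random before extracting signatures, destroying any
  between-drug agreement while preserving tail sizes.

Empirical p-values use the add-one rule p = (1 + #{null ≥ observed}) / (B + 1)
so p is never 0 and is super-uniform under the null. The signal-to-noise
*fold ratio* is observed / mean(null); the cut-off selection rule keeps the
largest support threshold k whose intersection is at least `fold_min` (3 by
default) times the null mean with p < alpha against a non-degenerate null
(mean ≥ 1 probe — the fold criterion is meaningless against a chance
expectation of ~0), and an optional refinement step revises the choice to
the largest significant k whose gene-collapsed core is still enriched in at
least one gene set.

Both nulls are bit-reproducible given a seed.
"""
from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import as_rng
from .fit import (
    DEFAULT_TAIL_FRACTION,
    FitResult,
    cardinality_by_k,
    min_support,
    support_vector,
    tail_code_arrays,
)
from .profiles import Compendium, GeneSetCollection, ProbeGeneMap, collapse_probes_to_genes

__all__ = [
    "NullDistribution",
    "CutoffScan",
    "CutoffSelection",
    "PlateauCurve",
    "resampling_null",
    "probe_permutation_null",
    "empirical_p",
    "fold_ratio",
    "scan_cutoffs",
    "select_cutoff",
    "refine_cutoff_by_enrichment",
    "plateau_scan",
]

DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class NullDistribution:
    """Empirical distribution of intersection cardinalities under a null."""

    cardinalities: np.ndarray
    null_kind: str  # "resampling" | "probe_permutation"
    n: int
    k_min: int
    f: float
    seed: int | None

    def __post_init__(self):
        if len(self.cardinalities) < 1:
            raise ValueError("a null distribution needs at least one draw")
        if (self.cardinalities < 0).any():
            raise ValueError("negative cardinality in null distribution")

    @property
    def b(self) -> int:
        return len(self.cardinalities)

    @property
    def mean(self) -> float:
        return float(self.cardinalities.mean())


def empirical_p(observed: float, null: NullDistribution | np.ndarray) -> float:
    """Add-one empirical p-value: (1 + #{null ≥ observed}) / (B + 1)."""
    draws = null.cardinalities if isinstance(null, NullDistribution) else np.asarray(null)
    b = len(draws)
    return (1 + int((draws >= observed).sum())) / (b + 1)


def fold_ratio(observed: float, null: NullDistribution | np.ndarray) -> float:
    """Signal-to-noise: observed / mean(null); +inf when the null mean is 0.

    Callers that need a finite denominator (the scan tables) use
    max(null_mean, 1/B) — the smallest nonzero mean B draws can produce — so
    any truly nonzero mean is left untouched.
    """
    draws = null.cardinalities if isinstance(null, NullDistribution) else np.asarray(null)
    mean = float(np.asarray(draws).mean())
    if mean == 0.0:
        return math.inf
    return float(observed) / mean


# ---------------------------------------------------------------------------
# null generators


def _null_cardinality_matrix_resampling(
    background: Compendium,
    n: int,
    f: float,
    b: int,
    seed,
) -> dict[str, np.ndarray]:
    """(B, N) cardinality-by-k matrices for both directions from shared draws."""
    if n > len(background):
        raise ValueError(
            f"cannot draw {n} profiles from a background of {len(background)}"
        )
    if b < 1:
        raise ValueError("B must be ≥ 1")
    rng = as_rng(seed)
    up_codes, down_codes = tail_code_arrays(background, f)
    u = background.universe_size
    m = len(background)
    out = {d: np.empty((b, n), dtype=np.int64) for d in DIRECTIONS}
    for i in range(b):
        rows = rng.choice(m, size=n, replace=False)
        out["up"][i] = cardinality_by_k(support_vector(up_codes, rows, u), n)
        out["down"][i] = cardinality_by_k(support_vector(down_codes, rows, u), n)
    return out


def _null_cardinality_matrix_permutation(
    compendium: Compendium,
    f: float,
    b: int,
    seed,
) -> dict[str, np.ndarray]:
    if b < 1:
        raise ValueError("B must be ≥ 1")
    rng = as_rng(seed)
    from .fit import tail_size

    n = len(compendium)
    u = compendium.universe_size
    t = tail_size(u, f)
    out = {d: np.empty((b, n), dtype=np.int64) for d in DIRECTIONS}
    for i in range(b):
        perms = rng.permuted(
            np.broadcast_to(np.arange(u, dtype=np.int32), (n, u)), axis=1
        )
        out["up"][i] = cardinality_by_k(
            np.bincount(perms[:, :t].ravel(), minlength=u), n
        )
        out["down"][i] = cardinality_by_k(
            np.bincount(perms[:, -t:].ravel(), minlength=u), n
        )
    return out


def resampling_null(
    background: Compendium,
    n: int,
    k_min: int,
    f: float = DEFAULT_TAIL_FRACTION,
    b: int = 1000,
    seed=None,
) -> dict[str, NullDistribution]:
    """Background-resampling null; returns one distribution per direction."""
    if not 1 <= k_min <= n:
        raise ValueError(f"k_min must be in [1, {n}], got {k_min}")
    seed_val = seed if isinstance(seed, int) else None
    mats = _null_cardinality_matrix_resampling(background, n, f, b, seed)
    return {
        d: NullDistribution(mats[d][:, k_min - 1], "resampling", n, k_min, f, seed_val)
        for d in DIRECTIONS
    }


def probe_permutation_null(
    compendium: Compendium,
    k_min: int,
    f: float = DEFAULT_TAIL_FRACTION,
    b: int = 1000,
    seed=None,
) -> dict[str, NullDistribution]:
    """Probe-permutation null for single-platform data; per direction."""
    n = len(compendium)
    if not 1 <= k_min <= n:
        raise ValueError(f"k_min must be in [1, {n}], got {k_min}")
    seed_val = seed if isinstance(seed, int) else None
    mats = _null_cardinality_matrix_permutation(compendium, f, b, seed)
    return {
        d: NullDistribution(
            mats[d][:, k_min - 1], "probe_permutation", n, k_min, f, seed_val
        )
        for d in DIRECTIONS
    }


# ---------------------------------------------------------------------------
# cut-off scan and selection


@dataclass(frozen=True)
class CutoffScan:
    """Observed vs null intersection size for every candidate k, per direction.

    ``table`` columns: direction, k, observed, null_mean, fold, p. The fold
    column uses the 1/B guard so it stays finite and printable; ``fold_ratio``
    on the raw null reports +inf for an all-zero null.
    """

    table: pd.DataFrame
    n: int
    f: float
    b: int
    null_kind: str
    seed: int | None

    def rows(self, direction: str) -> pd.DataFrame:
        return self.table[self.table["direction"] == direction]


@dataclass(frozen=True)
class CutoffSelection:
    """Selected support threshold per direction (None = no k passed)."""

    by_direction: Mapping[str, int | None]
    fold_min: float
    alpha: float
    table: pd.DataFrame
    refined: bool = False
    rationale: str = ""

    def k(self, direction: str) -> int | None:
        return self.by_direction[direction]


def scan_cutoffs(
    correctors: Compendium,
    background: Compendium | None = None,
    f: float = DEFAULT_TAIL_FRACTION,
    b: int = 1000,
    seed=None,
    null_kind: str = "resampling",
    k_values: Sequence[int] | None = None,
) -> CutoffScan:
    """Observed and null intersection cardinality at every support threshold.

    One set of B null draws serves every k (a draw's support vector yields the
    cardinality at all thresholds at once), so the scan costs the same as a
    single-k null.
    """
    n = len(correctors)
    ks = list(k_values) if k_values is not None else list(range(1, n + 1))
    if any(not 1 <= k <= n for k in ks):
        raise ValueError(f"k values must lie in [1, {n}]")
    seed_val = seed if isinstance(seed, int) else None

    up_codes, down_codes = tail_code_arrays(correctors, f)
    u = correctors.universe_size
    observed = {
        "up": cardinality_by_k(support_vector(up_codes, None, u), n),
        "down": cardinality_by_k(support_vector(down_codes, None, u), n),
    }

    if null_kind == "resampling":
        if background is None:
            raise ValueError("resampling null needs a background compendium")
        mats = _null_cardinality_matrix_resampling(background, n, f, b, seed)
    elif null_kind == "probe_permutation":
        mats = _null_cardinality_matrix_permutation(correctors, f, b, seed)
    else:
        raise ValueError(f"unknown null_kind {null_kind!r}")

    rows = []
    for direction in DIRECTIONS:
        for k in ks:
            null_draws = mats[direction][:, k - 1]
            obs = int(observed[direction][k - 1])
            null_mean = float(null_draws.mean())
            rows.append(
                {
                    "direction": direction,
                    "k": k,
                    "observed": obs,
                    "null_mean": null_mean,
                    "fold": obs / max(null_mean, 1.0 / b),
                    "p": empirical_p(obs, null_draws),
                }
            )
    return CutoffScan(
        table=pd.DataFrame(rows),
        n=n,
        f=f,
        b=b,
        null_kind=null_kind,
        seed=seed_val,
    )


#: Minimum null-mean cardinality (in probes) for the fold criterion to be
#: evaluable. "At least threefold higher than expected by chance" presumes a
#: measurable chance level: with an expected random intersection of, say,
#: 0.005 probes, any observed probe yields an astronomical and meaningless
#: fold. Analogous to the minimum-expected-count rules of count statistics.
MIN_NULL_MEAN = 1.0


def _passing(
    table: pd.DataFrame, fold_min: float, alpha: float,
    min_null_mean: float = MIN_NULL_MEAN,
) -> pd.DataFrame:
    return table[
        (table["fold"] >= fold_min)
        & (table["p"] < alpha)
        & (table["null_mean"] >= min_null_mean)
    ]


def select_cutoff(
    scan: CutoffScan,
    fold_min: float = 3.0,
    alpha: float = 0.05,
    min_null_mean: float = MIN_NULL_MEAN,
) -> CutoffSelection:
    """Largest evaluable k whose intersection clears the fold and p criteria.

    Per direction, a threshold k passes when observed/null-mean ≥ fold_min,
    p < alpha, and the null mean is at least ``min_null_mean`` probes (the
    fold criterion is undefined against a degenerate null; see
    :data:`MIN_NULL_MEAN`). The maximal passing k is selected — the most
    stringent threshold that is still calibrated — and
    :func:`refine_cutoff_by_enrichment` can revise the choice within the
    passing range. Absence of any passing k is a valid outcome (None), with
    the full scan attached for inspection.
    """
    table = scan.table.copy()
    table["passes"] = (
        (table["fold"] >= fold_min)
        & (table["p"] < alpha)
        & (table["null_mean"] >= min_null_mean)
    )
    by_direction: dict[str, int | None] = {}
    for direction in DIRECTIONS:
        passing = table[(table["direction"] == direction) & table["passes"]]
        by_direction[direction] = int(passing["k"].max()) if len(passing) else None
    return CutoffSelection(
        by_direction=by_direction,
        fold_min=fold_min,
        alpha=alpha,
        table=table,
        rationale=(
            f"maximal k with fold ≥ {fold_min}, p < {alpha} and a "
            f"non-degenerate null (mean ≥ {min_null_mean} probes)"
        ),
    )


def refine_cutoff_by_enrichment(
    scan: CutoffScan,
    fits_by_k: Mapping[int, FitResult],
    sets: GeneSetCollection,
    probe_map: ProbeGeneMap,
    gene_universe: Iterable[str],
    direction: str = "down",
    fold_min: float = 3.0,
    alpha: float = 0.05,
    enrich_alpha: float = 0.05,
) -> CutoffSelection:
    """Maximal significant k whose gene-collapsed core is still set-enriched.

    Among the thresholds passing the fold/p criteria, pick the largest one
    whose collapsed core shows ≥ 1 gene set at BH-adjusted q ≤ enrich_alpha.
    Falls back (flagged in the rationale) to :func:`select_cutoff` when no
    significant k is enriched.
    """
    from .enrich import hypergeom_enrich  # late import: avoids a cycle

    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    base = select_cutoff(scan, fold_min=fold_min, alpha=alpha)
    passing = _passing(scan.rows(direction), fold_min, alpha)["k"].tolist()
    gene_universe = frozenset(gene_universe)
    for k in sorted(passing, reverse=True):
        if k not in fits_by_k:
            raise KeyError(f"no FitResult supplied for candidate k={k}")
        genes, _ = collapse_probes_to_genes(fits_by_k[k].core(direction), probe_map)
        genes = genes & gene_universe
        if not genes:
            continue
        result = hypergeom_enrich(genes, sets, gene_universe)
        if (result.table["q"] <= enrich_alpha).any():
            by_direction = dict(base.by_direction)
            by_direction[direction] = int(k)
            return CutoffSelection(
                by_direction=by_direction,
                fold_min=fold_min,
                alpha=alpha,
                table=base.table,
                refined=True,
                rationale=(
                    f"maximal significant k with ≥1 gene set at q ≤ {enrich_alpha} "
                    f"({direction})"
                ),
            )
    return CutoffSelection(
        by_direction=dict(base.by_direction),
        fold_min=fold_min,
        alpha=alpha,
        table=base.table,
        refined=False,
        rationale="no significant k was set-enriched; fell back to the base rule",
    )


# ---------------------------------------------------------------------------
# drug-number plateau scan


@dataclass(frozen=True)
class PlateauCurve:
    """Mean null-intersection cardinality as the panel size N varies.

    ``plateau_n`` is the smallest scanned N from which every subsequent
    relative step |c(N+1) − c(N)| / max(c(N), 1) stays below ``eps``; None if
    the curve never settles within the scanned range.
    """

    table: pd.DataFrame  # columns: n, mean_cardinality, is_plateau
    theta: float
    f: float
    b: int
    eps: float
    plateau_n: int | None


def plateau_scan(
    background: Compendium,
    theta: float,
    n_range: Sequence[int],
    f: float = DEFAULT_TAIL_FRACTION,
    b: int = 1000,
    seed=None,
    eps: float = 0.02,
    direction: str = "down",
) -> PlateauCurve:
    """Fix the fuzzy cut-off, vary the number of randomly drawn profiles.

    For each N in ``n_range`` the support threshold is ceil(theta·N) and the
    mean fuzzy-intersection cardinality over B background draws is recorded;
    the plateau is where adding one more drug no longer changes that mean by
    more than ``eps`` (relative, floored at 1 probe to keep near-zero tails
    stable).
    """
    ns = list(n_range)
    if not ns or any(n < 1 or n > len(background) for n in ns):
        raise ValueError(f"n_range must lie within [1, {len(background)}]")
    if sorted(ns) != ns:
        raise ValueError("n_range must be increasing")
    rng = as_rng(seed)
    means = []
    for n in ns:
        k = min_support(n, theta)
        mats = _null_cardinality_matrix_resampling(background, n, f, b, rng)
        means.append(float(mats[direction][:, k - 1].mean()))
    plateau_n = _find_plateau(ns, means, eps)
    table = pd.DataFrame({"n": ns, "mean_cardinality": means})
    table["is_plateau"] = [
        plateau_n is not None and n >= plateau_n for n in ns
    ]
    return PlateauCurve(
        table=table,
        theta=theta,
        f=f,
        b=b,
        eps=eps,
        plateau_n=plateau_n,
    )


def _find_plateau(ns: Sequence[int], means: Sequence[float], eps: float) -> int | None:
    """First N of a run of relative steps all below eps, sustained to the end."""
    steps = [
        abs(means[i + 1] - means[i]) / max(means[i], 1.0)
        for i in range(len(means) - 1)
    ]
    for i in range(len(steps)):
        if all(s < eps for s in steps[i:]):
            return ns[i]
    return None


def write_scan(scan: CutoffScan, selection: CutoffSelection, path: str | Path) -> None:
    """Scan TSV: direction, k, observed, null_mean, fold, p, passes, selected."""
    table = selection.table.copy()
    table["selected"] = [
        int(selection.by_direction.get(d) == k)
        for d, k in zip(table["direction"], table["k"])
    ]
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
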