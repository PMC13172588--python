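"""Association tests, set intersections and over-representation analysis.

Covers the statistics linking motif content to translation-efficiency
class: 2x2 contingency tests (chi-square / Fisher), the Mann-Whitney rank
test on PP-motif counts, three-way gene-set intersection, and hypergeometric
over-representation analysis (ORA) on GMT-style gene-set collections with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "contingency_test",
    "rank_test",
    "intersect3",
    "VennResult",
    "ora_test",
    "GeneSetCollection",
    "normalize_ids",
]


def normalize_ids(ids: Iterable[str], case_insensitive: bool = True) -> frozenset[str]:
    """Whitespace-stripped (and by default upper-cased) identifier set.

    Duplicates after normalization collapse with a warning.
    """
    raw = [i.strip() for i in ids]
    norm = [i.upper() for i in raw] if case_insensitive else raw
    out = frozenset(norm)
    if len(out) < len(norm):
        warnings.warn(
            f"{len(norm) - len(out)} duplicate identifiers collapsed after normalization",
            stacklevel=2,
        )
    return out


class GeneSetCollection(dict):
    """Named gene sets (``name -> frozenset`` of identifiers), dict-like."""

    def __init__(self, sets: Mapping[str, Iterable[str]] | None = None):
        super().__init__()
        if sets:
            for name, members in sets.items():
                self[name] = frozenset(members)


# ---------------------------------------------------------------------------
# contingency + rank tests


def contingency_test(
    table: Sequence[Sequence[int]] | np.ndarray, method: str = "chi2"
) -> tuple[float, float]:
    """2x2 association test: ``(statistic, p)``.

    ``method``: ``"chi2"`` (Pearson, no continuity correction), ``"fisher"``
    (exact two-sided; the returned statistic is the odds ratio), or
    ``"auto"`` (chi-square, falling back to Fisher when any expected cell
    is below 5). A zero row or column margin leaves the test undefined and
    raises ``ValueError``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    if (t < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    if t.sum() <= 0:
        raise ValueError("contingency table grand total must be positive")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: association test undefined")

    if method == "auto":
        expected = stats.contingency.expected_freq(t)
        method = "fisher" if (expected < 5).any() else "chi2"
    if method == "chi2":
        res = stats.chi2_contingency(t, correction=False)
        return float(res.statistic), float(res.pvalue)
    if method == "fisher":
        odds, p = stats.fisher_exact(t, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"unknown method {method!r}")


def _mannwhitney_u(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def rank_test(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: ``(U, p)``.

    When both samples have at most ``exact_max_n`` observations the null
    distribution of U is obtained by full enumeration of all
    C(n_a+n_b, n_a) label assignments on the pooled mid-ranks (ties
    handled exactly); otherwise the normal approximation with tie
    correction (scipy) is used. The exact two-sided p is twice the smaller
    tail probability, capped at 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    if a.size <= exact_max_n and b.size <= exact_max_n:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)  # mid-ranks
        n_a = a.size
        u_obs = _mannwhitney_u(ranks[:n_a], n_a)
        us = np.array(
            [
                _mannwhitney_u(ranks[list(idx)], n_a)
                for idx in itertools.combinations(range(pooled.size), n_a)
            ]
        )
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, float(p)

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# set intersection


@dataclass(frozen=True)
class VennResult:
    """Disjoint region sizes of a three-set intersection.

    Region keys are membership patterns over (A, B, C): ``"110"`` is the
    set of elements in A and B but not C. Region sizes sum to ``|A u B u C|``.
    """

    names: tuple[str, str, str]
    regions: dict[str, int] = field(repr=False)
    common: tuple[str, ...] = ()

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def intersect3(
    set_a: Iterable[str],
    set_b: Iterable[str],
    set_c: Iterable[str],
    names: tuple[str, str, str] = ("A", "B", "C"),
    case_insensitive: bool = True,
) -> VennResult:
    """Three-way set intersection with all 7 disjoint region sizes."""
    a = normalize_ids(set_a, case_insensitive)
    b = normalize_ids(set_b, case_insensitive)
    c = normalize_ids(set_c, case_insensitive)
    regions = {f"{i}{j}{k}": 0 for i in "01" for j in "01" for k in "01" if i + j + k != "000"}
    for el in a | b | c:
        key = f"{int(el in a)}{int(el in b)}{int(el in c)}"
        regions[key] += 1
    return VennResult(names=names, regions=regions, common=tuple(sorted(a & b & c)))


# ---------------------------------------------------------------------------
# over-representation analysis


def ora_test(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    case_insensitive: bool = True,
    top: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in gene sets.

    For each set with K members in a universe of N genes and a query of n
    genes overlapping the set in k, the one-sided upper-tail p-value is
    ``P(X >= k)`` with ``X ~ Hypergeom(N, K, n)``. Sets with zero overlap
    are reported with p = 1. BH adjustment runs across all tested sets;
    rows are ranked by (q, p, name). ``top`` truncates the report.

    Query and set members are intersected with the universe first; an
    empty universe is an error.
    """
    uni = normalize_ids(universe, case_insensitive)
    if not uni:
        raise ValueError("empty universe")
    if not collection:
        raise ValueError("empty gene-set collection")
    q = normalize_ids(query, case_insensitive) & uni

    rows = []
    for name, members in collection.items():
        mem = normalize_ids(members, case_insensitive) & uni
        overlap = sorted(q & mem)
        k, big_k, n, big_n = len(overlap), len(mem), len(q), len(uni)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((name, k, big_k, n, big_n, p, ",".join(overlap)))

    df = pd.DataFrame(
        rows, columns=["pathway", "k", "K", "n", "N", "p_value", "overlap_genes"]
    )
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["q_value", "p_value", "pathway"], kind="mergesort").reset_index(
        drop=True
    )
    df = df[["pathway", "k", "K", "n", "N", "p_value", "q_value", "overlap_genes"]]
    return df.head(top) if top else df
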