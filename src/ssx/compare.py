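"""Cross-dataset pattern matching and coefficient statistics.

Two datasets fitted separately (possibly on different time grids) are
compared through their dynamic patterns: patterns are paired by
trajectory class in spectral order, per-gene coefficients of paired
patterns are rank-correlated over the shared genes, and gene sets are
tested for preferential loading on internal versus external patterns by
comparing pooled coefficient ranks.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .patterns import PrincipalDynamicPattern, coefficient_view


@dataclass
class PatternMatch:
    """A pairing of one pattern from each dataset."""

    pattern_a: PrincipalDynamicPattern
    pattern_b: PrincipalDynamicPattern
    match_basis: str = "class-order"


def match_patterns(
    ipdps_a: list[PrincipalDynamicPattern],
    ipdps_b: list[PrincipalDynamicPattern],
    overrides: list[tuple[int, int]] | None = None,
) -> tuple[list[PatternMatch], list[PrincipalDynamicPattern]]:
    """Pair patterns with identical class labels, in spectral order.

    The k-th pattern of a class in A is paired with the k-th of the same
    class in B — a symmetric rule (A vs B and B vs A give the same
    pairs).  ``overrides`` supplies explicit (index_a, index_b) pairs
    instead.  Returns (matches, unmatched patterns from both lists).
    """
    if overrides is not None:
        by_ia = {p.index: p for p in ipdps_a}
        by_ib = {p.index: p for p in ipdps_b}
        matches = [
            PatternMatch(by_ia[i], by_ib[j], match_basis="user")
            for i, j in overrides
        ]
        matched_a = {i for i, _ in overrides}
        matched_b = {j for _, j in overrides}
    else:
        pool_b: dict[str, list[PrincipalDynamicPattern]] = {}
        for p in ipdps_b:
            pool_b.setdefault(p.class_label, []).append(p)
        matches = []
        matched_a, matched_b = set(), set()
        for p in ipdps_a:
            bucket = pool_b.get(p.class_label, [])
            if bucket:
                q = bucket.pop(0)
                matches.append(PatternMatch(p, q))
                matched_a.add(p.index)
                matched_b.add(q.index)
    unmatched = [p for p in ipdps_a if p.index not in matched_a] + [
        p for p in ipdps_b if p.index not in matched_b
    ]
    return matches, unmatched


def coefficient_correlation(
    coeffs_a: pd.Series,
    coeffs_b: pd.Series,
    mode: str = "absolute",
) -> tuple[float, float, int]:
    """Spearman rank correlation of per-gene coefficients of two patterns.

    ``coeffs_a`` / ``coeffs_b`` are gene-indexed coefficient vectors
    (possibly complex for merged oscillatory patterns); the comparison
    runs over the genes shared by both indexes, in the first vector's
    order, after the chosen real-valued view (magnitude or signed real
    part).  Returns ``(r, p, n_shared)`` with the p-value from the
    asymptotic t approximation and ties mid-ranked.
    """
    shared = [g for g in coeffs_a.index if g in set(coeffs_b.index)]
    if len(shared) < 5:
        raise ValidationError(
            f"need >= 5 shared genes for a rank correlation, got {len(shared)}"
        )
    a = coefficient_view(coeffs_a.loc[shared].to_frame(), mode).iloc[:, 0]
    b = coefficient_view(coeffs_b.loc[shared].to_frame(), mode).iloc[:, 0]
    res = stats.spearmanr(a.to_numpy(), b.to_numpy())
    return float(res.statistic), float(res.pvalue), len(shared)


def gene_set_rank_test(
    ipdp_coeffs: pd.DataFrame,
    epdp_coeffs: pd.DataFrame,
    gene_set: set[str],
    mode: str = "absolute",
    per_pattern: bool = False,
):
    """Does a gene set load higher on internal or on external patterns?

    Within every pattern column, all genes are ranked ascending
    (mid-rank ties) on the chosen coefficient view; the set's ranks are
    pooled across internal columns and across external columns and
    compared with Welch's unequal-variance t-test.  Positive t means the
    set ranks higher on internal patterns.  ``per_pattern=True`` returns
    one row per (iPDP, ePDP) column pair instead of the pooled test.
    """
    genes = ipdp_coeffs.index
    in_set = [g for g in genes if g in gene_set]
    if not in_set:
        raise ValidationError("gene set does not intersect the dataset")
    if len(in_set) < 2:
        raise ValidationError("need >= 2 gene-set members present")

    def _ranks(table: pd.DataFrame) -> pd.DataFrame:
        view = coefficient_view(table, mode)
        return view.apply(lambda col: stats.rankdata(col, method="average"))

    ri = pd.DataFrame(
        _ranks(ipdp_coeffs).to_numpy(), index=genes, columns=ipdp_coeffs.columns
    )
    re_ = pd.DataFrame(
        _ranks(epdp_coeffs).to_numpy(), index=genes, columns=epdp_coeffs.columns
    )
    if per_pattern:
        rows = []
        for ci in ri.columns:
            for ce in re_.columns:
                a = ri.loc[in_set, ci].to_numpy()
                b = re_.loc[in_set, ce].to_numpy()
                t, p = stats.ttest_ind(a, b, equal_var=False)
                rows.append(
                    {"ipdp": ci, "epdp": ce, "mean_rank_ipdp": a.mean(),
                     "mean_rank_epdp": b.mean(), "t_stat": float(t),
                     "p_value": float(p)}
                )
        return pd.DataFrame(rows)
    pooled_i = ri.loc[in_set].to_numpy().ravel()
    pooled_e = re_.loc[in_set].to_numpy().ravel()
    if np.ptp(pooled_i) == 0 and np.ptp(pooled_e) == 0 and (
        pooled_i.mean() == pooled_e.mean()
    ):
        # degenerate equal-constant samples: Welch t is 0/0, define t = 0
        return (
            float(pooled_i.mean()), float(pooled_e.mean()), 0.0, 1.0
        )
    t, p = stats.ttest_ind(pooled_i, pooled_e, equal_var=False)
    return (
        float(pooled_i.mean()),
        float(pooled_e.mean()),
        float(t),
        float(p),
    )


def top_gene_extraction(
    coeffs: pd.DataFrame,
    pattern: str | int,
    direction: str = "largest-magnitude",
    k: int = 10,
    mode_signed_real: bool = True,
) -> list[str]:
    """Top-k genes of one pattern column, for export to enrichment tools.

    ``direction`` is one of ``most-positive``, ``most-negative``,
    ``largest-magnitude``.  Ties break by gene-ID lexicographic order, so
    the list is deterministic.
    """
    if isinstance(pattern, int):
        if not 1 <= pattern <= coeffs.shape[1]:
            raise ValidationError(f"pattern index {pattern} out of range")
        col = coeffs.iloc[:, pattern - 1]
    else:
        if pattern not in coeffs.columns:
            raise ValidationError(f"unknown pattern column {pattern!r}")
        col = coeffs[pattern]
    if not 1 <= k <= len(col):
        raise ValidationError(f"k={k} out of range 1..{len(col)}")
    values = col.apply(np.real) if mode_signed_real else col
    if direction == "most-positive":
        key = -values.astype(float)
    elif direction == "most-negative":
        key = values.astype(float)
    elif direction == "largest-magnitude":
        key = -col.abs().astype(float)
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    order = sorted(zip(key.to_numpy(), key.index), key=lambda t: (t[0], t[1]))
    return [g for _, g in order[:k]]
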