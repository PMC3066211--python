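"""Term overrepresentation of a hit list.

Right-tailed Fisher's exact test — implemented as the hypergeometric upper
tail P(X >= k), identical for one-sided 2x2 tables — with Benjamini-Hochberg
FDR adjustment across tested terms, plus the coverage statistic
floor(100 * k / K): the floored percentage of a term's genes present in the
hit list.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .screen_model import AnnotationSet, ValidationError

__all__ = [
    "hypergeom_right_tail",
    "bh_fdr",
    "coverage_percent",
    "enrich",
]


def hypergeom_right_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K annotated, n drawn).

    Computed in log space (logsumexp over log-pmf terms) for numerical
    stability in deep tails.  Bounds: 0 <= k <= min(K, n) <= N.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 1 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric bounds (K={K}, n={n}, N={N})")
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"invalid overlap k={k} for (K={K}, n={n})")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    p = float(np.exp(logsumexp(logp)))
    return min(max(p, np.finfo(float).tiny), 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def coverage_percent(k: int, K: int) -> int:
    """floor(100 * k / K): integer percentage of a term covered by hits."""
    k, K = int(k), int(K)
    if K < 1:
        raise ValidationError("term size K must be >= 1")
    if not 0 <= k <= K:
        raise ValidationError(f"hits-in-term k={k} outside [0, K={K}]")
    return (100 * k) // K


def enrich(
    hits,
    annotation: AnnotationSet,
    min_term_size: int = 1,
) -> pd.DataFrame:
    """Overrepresentation of ``hits`` in every annotation term.

    Hit genes outside the annotation universe are dropped with a warning.
    Every term with K >= ``min_term_size`` is tested against the universe of
    size N; the BH adjustment runs over all tested terms, and the returned
    table keeps rows with at least one hit in the term, sorted by adjusted
    then raw p-value.  Columns: term, k, K, n, N, coverage_percent, genes
    (';'-joined hit symbols in the term), p_raw, p_adjusted.
    """
    universe = set(annotation.universe)
    if not universe:
        raise ValidationError("annotation universe is empty")
    hit_set = set(hits)
    outside = hit_set - universe
    if outside:
        warnings.warn(
            f"{len(outside)} hit gene(s) outside annotation universe dropped",
            stacklevel=2,
        )
    hit_set &= universe
    n, N = len(hit_set), len(universe)

    rows = []
    for term in sorted(annotation.term_map):
        genes = annotation.term_map[term]
        K = len(genes)
        if K < min_term_size or K == 0:
            continue
        overlap = sorted(hit_set & genes)
        k = len(overlap)
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "coverage_percent": coverage_percent(k, K),
                "genes": ";".join(overlap),
                "p_raw": hypergeom_right_tail(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "coverage_percent",
                     "genes", "p_raw", "p_adjusted"]
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_fdr(df["p_raw"].to_numpy())
    df = df[df["k"] >= 1]
    return (
        df.sort_values(["p_adjusted", "p_raw", "term"])
        .reset_index(drop=True)
    )
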