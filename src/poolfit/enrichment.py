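"""Enrichment statistics: hypergeometric tails, t-test gene ranking, XL-mHG.

The hypergeometric tail asks how surprising it is to find ``k`` members of a
category of size ``K`` within a sample of ``n`` drawn from a universe of size
``N``.  The XL-mHG test scans a ranked binary list for the most surprising
prefix, constrained to prefixes of depth at most ``L`` containing at least
``X`` successes, and converts the minimal tail probability into an exact
p-value by a dynamic program over the (rank, successes) lattice — the
null being a uniformly random arrangement of the successes in the list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import ttest_ind

# tolerance on log tail probabilities when testing "<= s" in the DP; ties at
# the observed statistic must count as hits
_LOG_TOL = 1e-10


def log_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """log P(X >= k) for X ~ Hypergeometric(N, K, n), by log-space summation."""
    _check_hypergeom_args(k, K, n, N)
    if k <= max(0, n + K - N):
        return 0.0
    hi = min(K, n)
    if k > hi:
        return -math.inf
    js = np.arange(k, hi + 1)
    log_terms = (
        gammaln(K + 1)
        - gammaln(js + 1)
        - gammaln(K - js + 1)
        + gammaln(N - K + 1)
        - gammaln(n - js + 1)
        - gammaln(N - K - n + js + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    m = log_terms.max()
    return float(m + np.log(np.exp(log_terms - m).sum()))


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    return float(math.exp(log_hypergeom_tail(k, K, n, N)))


def _check_hypergeom_args(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValueError(f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")


# ---------------------------------------------------------------------------
# XL-mHG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class XlmhgResult:
    statistic: float  # minimal hypergeometric tail over qualifying prefixes
    pvalue: float  # exact permutation p-value
    cutoff: int  # prefix depth achieving the statistic (0 if none qualifies)
    X: int
    L: int
    N: int
    K: int


def _prefix_log_tails(flags: np.ndarray, X: int, L: int) -> tuple[np.ndarray, np.ndarray]:
    """log tail probability of every qualifying prefix depth r <= L."""
    N = flags.size
    K = int(flags.sum())
    ks = np.cumsum(flags)
    rs = np.arange(1, N + 1)
    qual = (rs <= L) & (ks >= X)
    logs = np.full(N, np.inf)
    for i in np.nonzero(qual)[0]:
        logs[i] = log_hypergeom_tail(int(ks[i]), K, int(rs[i]), N)
    return logs, rs


def xlmhg_statistic(flags: np.ndarray, X: int = 1, L: int | None = None) -> tuple[float, float, int]:
    """(statistic, log statistic, cutoff rank) of the XL-mHG scan.

    The statistic is the minimum hypergeometric tail over prefix depths
    r <= L whose top-r success count is at least X; 1 when no depth
    qualifies.
    """
    flags = np.asarray(flags, dtype=int)
    N = flags.size
    if L is None:
        L = N
    if not 1 <= X or not 1 <= L <= N:
        raise ValueError(f"require 1 <= X and 1 <= L <= N; got X={X}, L={L}, N={N}")
    logs, _ = _prefix_log_tails(flags, X, L)
    i = int(np.argmin(logs))
    if not np.isfinite(logs[i]):
        return 1.0, 0.0, 0
    return float(math.exp(logs[i])), float(logs[i]), i + 1


def _log_comb(a: np.ndarray | int, b: np.ndarray | int):
    return gammaln(np.add(a, 1)) - gammaln(np.add(b, 1)) - gammaln(np.subtract(a, b) + 1)


def _xlmhg_pvalue_dp(N: int, K: int, X: int, L: int, log_s: float) -> float:
    """Exact P(S <= s) over uniform arrangements, by lattice path counting.

    Paths go from (0,0) to (N,K), stepping (r+1,k) [failure] or (r+1,k+1)
    [success].  A cell (r,k) is a "hit" when r <= L, k >= X and the tail
    probability at that prefix is <= s.  W(r,k) counts paths avoiding all
    hit cells so far; when a path first enters a hit cell its remaining
    completions C(N-r, K-k) are accumulated, so

        p = sum over first-hit cells of W(r,k) * C(N-r, K-k) / C(N,K)

    with no subtractive cancellation (small p stays accurate).  Counts are
    floats with periodic rescaling; the accumulation runs in log space.
    """
    if K == 0 or X > K:
        return 1.0
    # minimal blocked k per prefix depth (tail is monotone decreasing in k)
    kmin = np.full(N + 1, K + 1, dtype=int)
    for r in range(1, min(L, N) + 1):
        lo = max(X, max(0, r + K - N))
        hi = min(K, r)
        blocked = K + 1
        for k in range(lo, hi + 1):
            if log_hypergeom_tail(k, K, r, N) <= log_s + _LOG_TOL:
                blocked = k
                break
        kmin[r] = blocked

    W = np.zeros(K + 1)
    W[0] = 1.0
    log_rescale = 0.0
    log_acc = -math.inf
    for r in range(1, N + 1):
        W[1:] = W[1:] + W[:-1]
        if kmin[r] <= K:
            ks = np.arange(kmin[r], min(K, r) + 1)
            w = W[ks]
            nz = w > 0
            if nz.any():
                feas = (K - ks[nz]) <= (N - r)
                if feas.any():
                    kk = ks[nz][feas]
                    terms = np.log(w[nz][feas]) + log_rescale + _log_comb(N - r, K - kk)
                    m = max(log_acc, float(terms.max()))
                    log_acc = m + math.log(
                        math.exp(log_acc - m) + np.exp(terms - m).sum()
                    )
            W[ks] = 0.0
        m_w = W.max()
        if m_w > 1e280:
            W /= 1e280
            log_rescale += math.log(1e280)
        elif 0 < m_w < 1e-280:
            W /= 1e-280
            log_rescale -= math.log(1e280)
    if log_acc == -math.inf:
        return 0.0
    log_total = float(_log_comb(N, K))
    return float(min(max(math.exp(log_acc - log_total), 0.0), 1.0))


def xlmhg(flags, X: int = 5, L: int | None = None) -> XlmhgResult:
    """Exact XL-mHG test on a ranked binary membership vector.

    Parameters
    ----------
    flags : sequence of 0/1, best rank first.
    X : minimum number of successes a prefix must contain to qualify.
    L : deepest prefix considered (defaults to the list length).

    Returns the minimal-tail statistic and its exact p-value under uniform
    random arrangements of the successes.
    """
    flags = np.asarray(flags, dtype=int)
    if not np.isin(flags, (0, 1)).all():
        raise ValueError("flags must be binary")
    N = flags.size
    if L is None:
        L = N
    K = int(flags.sum())
    stat, log_stat, cutoff = xlmhg_statistic(flags, X=X, L=L)
    if cutoff == 0:
        return XlmhgResult(1.0, 1.0, 0, X, L, N, K)
    p = _xlmhg_pvalue_dp(N, K, X, L, log_stat)
    return XlmhgResult(stat, p, cutoff, X, L, N, K)


# ---------------------------------------------------------------------------
# Expression ranking
# ---------------------------------------------------------------------------


def rank_genes_by_ttest(
    expression: pd.DataFrame,
    hybrid_cols: list[str],
    parent_cols: list[str],
    gene_col: str = "gene",
    method: str = "pooled",
    parent_mode: str = "combined",
) -> pd.DataFrame:
    """Rank genes by a hybrid-vs-parent two-sample t-test on expression.

    Parameters
    ----------
    expression : one row per gene; replicate expression values in
        ``hybrid_cols`` and ``parent_cols``.
    method : 'pooled' (classic Student, default) or 'welch'.
    parent_mode : 'combined' treats every parental replicate as one group;
        'mean' first averages the two parents' matching replicates (both
        readings of comparing "the parental and hybrid gene expression" are
        available).

    Returns a DataFrame sorted by ascending p (ties broken by descending
    |t| then gene id) with columns gene, t, p, rank, degenerate.  Genes with
    zero variance in both groups but different means get p = 0 and the
    degenerate flag (rank lists must be total); genes with fewer than two
    finite values in a group are dropped.
    """
    if method not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test method {method!r}")
    if parent_mode not in ("combined", "mean"):
        raise ValueError(f"unknown parent_mode {parent_mode!r}")

    rows = []
    for _, row in expression.iterrows():
        hyb = pd.to_numeric(row[hybrid_cols], errors="coerce").to_numpy(dtype=float)
        par = pd.to_numeric(row[parent_cols], errors="coerce").to_numpy(dtype=float)
        if parent_mode == "mean":
            half = len(parent_cols) // 2
            par = (par[:half] + par[half : 2 * half]) / 2.0
        hyb = hyb[~np.isnan(hyb)]
        par = par[~np.isnan(par)]
        if len(hyb) < 2 or len(par) < 2:
            continue
        degenerate = hyb.var(ddof=1) == 0 and par.var(ddof=1) == 0
        if degenerate:
            if hyb.mean() == par.mean():
                t, p = 0.0, 1.0
            else:
                t = math.inf if hyb.mean() > par.mean() else -math.inf
                p = 0.0
        else:
            t, p = ttest_ind(hyb, par, equal_var=(method == "pooled"))
        rows.append({gene_col: row[gene_col], "t": float(t), "p": float(p), "degenerate": bool(degenerate)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["_abs_t"] = out["t"].abs()
    out = out.sort_values(["p", "_abs_t", gene_col], ascending=[True, False, True]).drop(columns="_abs_t")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Category enrichment
# ---------------------------------------------------------------------------


def enrich_sets(
    target: set[str],
    annotation: pd.DataFrame,
    universe: set[str],
    gene_col: str = "gene_name",
    category_col: str = "category",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every annotation category in a target set.

    Genes of the universe absent from the annotation fall into category
    'unknown'.  Returns one row per category: category, k, K, n, N, p (and
    p_adj when ``bh_adjust``).
    """
    if not universe:
        raise ValueError("empty universe")
    extra = target - universe
    if extra:
        raise ValueError(f"target genes outside the universe: {sorted(extra)[:5]}")
    ann = annotation.drop_duplicates(subset=gene_col).set_index(gene_col)[category_col]
    cats = pd.Series({g: ann.get(g, "unknown") for g in universe})
    N, n = len(universe), len(target)
    rows = []
    for cat, members in cats.groupby(cats).groups.items():
        K = len(members)
        k = len(target & set(members))
        rows.append(
            {"category": cat, "k": k, "K": K, "n": n, "N": N, "p": hypergeom_tail(k, K, n, N)}
        )
    out = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    if bh_adjust:
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out
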