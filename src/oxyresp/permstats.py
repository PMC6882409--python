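"""Two-factor permutational univariate ANOVA with unrestricted permutations.

Treatment contrasts on per-fish endpoints (SMR, MMR, aerobic scope, P_crit,
loss of equilibrium, condition factor) are tested with a pseudo-F statistic
from the sequential (Type I, order A, B, A:B) two-way ANOVA decomposition of
the raw univariate response. Significance comes from unrestricted
permutation of the observations: the response vector is shuffled whole,
the pseudo-F recomputed, and

    p = (# permuted F >= observed F + 1) / (n_perm + 1)

so the observed assignment always counts among the permutations. On a
balanced design the pseudo-F equals the classical two-way ANOVA F exactly.
Post-hoc pairwise level contrasts use the same permutation scheme on a
t-type statistic with Holm adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "PermAnovaResult",
    "TermResult",
    "permanova_2factor",
    "pairwise_posthoc",
]


@dataclass(frozen=True)
class TermResult:
    pseudo_f: float
    p_value: float
    df: int
    ss: float


@dataclass
class PermAnovaResult:
    terms: dict  # term name -> TermResult
    residual_df: int
    residual_ss: float
    n_permutations: int
    seed: int
    flags: set = field(default_factory=set)


def _dummy(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((codes.size, n_levels))
    out[np.arange(codes.size), codes] = 1.0
    return out


def _sequential_bases(factor_a, factor_b, include_interaction: bool):
    """Orthonormal bases for the sequential (Type I) term subspaces.

    Each term block is residualised against everything fitted before it
    (intercept, then A, then B, then A:B) and reduced to an orthonormal
    basis by SVD, so projections onto a block give that term's incremental
    sum of squares exactly even though the dummy blocks are rank deficient.
    Returns (list of (name, basis), total model rank, n).
    """
    a_codes, a_levels = pd.factorize(np.asarray(factor_a))
    b_codes, b_levels = pd.factorize(np.asarray(factor_b))
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("each factor needs at least 2 levels")
    n = a_codes.size

    blocks = [("A", _dummy(a_codes, len(a_levels))), ("B", _dummy(b_codes, len(b_levels)))]
    if include_interaction:
        ab = (
            _dummy(a_codes, len(a_levels))[:, :, None]
            * _dummy(b_codes, len(b_levels))[:, None, :]
        )
        blocks.append(("A:B", ab.reshape(n, -1)))

    q_all = np.ones((n, 1)) / np.sqrt(n)  # intercept
    bases = []
    for name, x in blocks:
        resid = x - q_all @ (q_all.T @ x)
        resid -= q_all @ (q_all.T @ resid)  # reorthogonalisation pass
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        keep = s > 1e-8 * max(s[0], 1.0) if s.size else np.zeros(0, bool)
        basis = u[:, keep]
        bases.append((name, basis))
        q_all = np.concatenate([q_all, basis], axis=1)
    rank = q_all.shape[1]
    return bases, rank, n


def _term_f_stats(bases, rank, responses: np.ndarray):
    """Pseudo-F per term for each response column (n x m)."""
    n = responses.shape[0]
    centered = responses - responses.mean(axis=0, keepdims=True)
    total_ss = np.einsum("ij,ij->j", centered, centered)

    term_ss = {}
    explained = np.zeros(responses.shape[1])
    for name, q in bases:
        proj = q.T @ responses
        ss = np.einsum("ij,ij->j", proj, proj)
        term_ss[name] = ss
        explained += ss
    resid_df = n - rank
    resid_ss = np.clip(total_ss - explained, 0.0, None)

    fstats = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, q in bases:
            df = q.shape[1]
            ms_term = term_ss[name] / max(df, 1)
            ms_resid = resid_ss / max(resid_df, 1)
            f = np.where(ms_resid > 0, ms_term / np.where(ms_resid > 0, ms_resid, 1.0), 0.0)
            fstats[name] = (f, df, term_ss[name])
    return fstats, resid_df, resid_ss


def permanova_2factor(
    response,
    factor_a,
    factor_b,
    n_perm: int = 999,
    seed: int = 0,
    include_interaction: bool = True,
) -> PermAnovaResult:
    """Two-factor permutational ANOVA on a univariate response.

    Terms are tested in the fixed order A, B, A:B (Type I sums of squares);
    p-values come from `n_perm` unrestricted permutations of the raw
    observations plus the observed arrangement. With zero residual degrees
    of freedom the interaction is dropped and flagged. A response with zero
    variance is reported with pseudo-F 0, p 1 and a ``zero_variance`` flag.
    """
    y = np.asarray(response, dtype=float)
    if y.ndim != 1:
        raise ValueError("response must be one-dimensional")
    if not (len(y) == len(factor_a) == len(factor_b)):
        raise ValueError("response and factor columns must have equal length")

    flags: set = set()
    bases, rank, n = _sequential_bases(factor_a, factor_b, include_interaction)
    if include_interaction and n - rank == 0:
        bases, rank, n = _sequential_bases(factor_a, factor_b, False)
        flags.add("interaction_skipped_zero_residual_df")

    if np.ptp(y) == 0.0:
        flags.add("zero_variance")
        terms = {
            name: TermResult(pseudo_f=0.0, p_value=1.0, df=q.shape[1], ss=0.0)
            for name, q in bases
        }
        return PermAnovaResult(
            terms=terms,
            residual_df=n - rank,
            residual_ss=0.0,
            n_permutations=n_perm,
            seed=seed,
            flags=flags,
        )

    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm + 1))
    perms[:, 0] = y
    for j in range(1, n_perm + 1):
        perms[:, j] = y[rng.permutation(n)]

    fstats, resid_df, resid_ss = _term_f_stats(bases, rank, perms)
    terms = {}
    for name, (f, df, ss) in fstats.items():
        observed = float(f[0])
        # column 0 is the observed arrangement, so it counts itself (the +1)
        p = float(np.sum(f >= observed) / (n_perm + 1))
        terms[name] = TermResult(pseudo_f=observed, p_value=p, df=df, ss=float(ss[0]))
    return PermAnovaResult(
        terms=terms,
        residual_df=resid_df,
        residual_ss=float(resid_ss[0]),
        n_permutations=n_perm,
        seed=seed,
        flags=flags,
    )


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals, kind="stable")
    m = pvals.size
    adjusted = np.empty(m)
    running = 0.0
    for rank_i, idx in enumerate(order):
        running = max(running, (m - rank_i) * pvals[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def pairwise_posthoc(
    response,
    factor,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation pairwise contrasts between factor levels.

    For every level pair the |t|-type statistic (mean difference over its
    pooled standard error) is compared with its unrestricted-permutation
    distribution; raw and Holm-adjusted p-values are returned.
    """
    y = np.asarray(response, dtype=float)
    levels = pd.unique(np.asarray(factor))
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    factor = np.asarray(factor)
    rng = np.random.default_rng(seed)

    rows = []
    for la, lb in combinations(levels, 2):
        ya = y[factor == la]
        yb = y[factor == lb]
        pooled = np.concatenate([ya, yb])
        na = ya.size
        observed = _t_stat(ya, yb)
        count = 1
        for _ in range(n_perm):
            shuffled = pooled[rng.permutation(pooled.size)]
            if _t_stat(shuffled[:na], shuffled[na:]) >= observed - 1e-12:
                count += 1
        rows.append(
            {"level_a": la, "level_b": lb, "statistic": observed,
             "p_raw": count / (n_perm + 1)}
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = _holm(table["p_raw"].to_numpy())
    return table


def _t_stat(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    se = np.sqrt(va / na + vb / nb)
    diff = abs(a.mean() - b.mean())
    if se == 0.0:
        return 0.0 if diff == 0.0 else np.inf
    return float(diff / se)
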