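"""Pathomic-score dichotomization and gene-set enrichment.

The pathomic score of a sample is the median of its selected, z-scored
slide features; samples strictly above the cohort median form the
"high" group.  Per-gene Welch t statistics (high minus low) rank the
genes, and each gene set gets a weighted Kolmogorov–Smirnov enrichment
score: hit increments proportional to |t| (weight exponent 1 by
default; 0 gives the classic unweighted statistic), uniform miss
decrements, ES = the running sum's signed maximum deviation from zero.
Significance comes from permuting the sample labels (add-one
estimator), and Benjamini–Hochberg q-values below the threshold
(default 0.1) classify each set as up- or down-regulated by ES sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "pathomic_score",
    "gene_t_stats",
    "enrichment_score",
    "permutation_test",
    "fdr_classify",
    "run_gsea",
]


@dataclass
class EnrichmentResult:
    """Per-set enrichment: score, nominal p, BH q and the up/down/ns call."""

    name: str
    es: float
    nominal_p: float
    fdr_q: float
    call: str  # "up" | "down" | "ns"


def pathomic_score(X_selected) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample median of the selected features, split at the cohort median.

    Returns ``(scores, groups)`` with groups "high" where the score
    strictly exceeds the median of scores and "low" otherwise.
    """
    X = np.asarray(X_selected, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0 or X.shape[1] == 0:
        raise ValueError("empty feature selection: no pathomic score")
    scores = np.median(X, axis=1)
    med = np.median(scores)
    groups = np.where(scores > med, "high", "low")
    return scores, groups


def gene_t_stats(expr: pd.DataFrame | np.ndarray, groups) -> pd.Series:
    """Welch two-sample t per gene, oriented high minus low."""
    E = expr.to_numpy(dtype=float) if isinstance(expr, pd.DataFrame) else \
        np.asarray(expr, dtype=float)
    g = np.asarray(groups)
    high = (g == "high") | (g == 1)
    low = (g == "low") | (g == 0)
    if high.sum() < 2 or low.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    t = _welch_t(E, high, low)
    index = expr.index if isinstance(expr, pd.DataFrame) else pd.RangeIndex(E.shape[0])
    return pd.Series(t, index=index, name="t")


def _welch_t(E: np.ndarray, high: np.ndarray, low: np.ndarray) -> np.ndarray:
    nh, nl = int(high.sum()), int(low.sum())
    mh = E[:, high].mean(axis=1)
    ml = E[:, low].mean(axis=1)
    vh = E[:, high].var(axis=1, ddof=1)
    vl = E[:, low].var(axis=1, ddof=1)
    se = np.sqrt(vh / nh + vl / nl)
    se[se == 0] = np.inf  # identical constant groups: t = 0
    return (mh - ml) / se


def _es_from_ranked(member_sorted: np.ndarray, abs_sorted: np.ndarray,
                    weight: float) -> float:
    """ES of one set given rank-ordered membership flags and |t| values."""
    n = member_sorted.size
    n_hit = int(member_sorted.sum())
    w = abs_sorted ** weight if weight != 0 else np.ones(n)
    hit_mass = float((w * member_sorted).sum())
    if hit_mass == 0:  # all member stats are zero: fall back to uniform hits
        hit_inc = member_sorted / n_hit
    else:
        hit_inc = w * member_sorted / hit_mass
    miss_dec = (~member_sorted.astype(bool)).astype(float) / (n - n_hit)
    running = np.cumsum(hit_inc - miss_dec)
    return float(running[np.argmax(np.abs(running))])


def enrichment_score(stats: pd.Series, gene_set, weight: float = 1.0) -> float:
    """Weighted KS enrichment score of one gene set.

    ``stats`` maps gene id → ranking statistic (t); genes are ranked by
    descending value (ties broken by position for determinism).  The set
    must intersect the ranked genes and be a strict subset of them.
    """
    genes = np.asarray(stats.index)
    t = stats.to_numpy(dtype=float)
    member = np.isin(genes, np.asarray(list(gene_set)))
    n_hit = int(member.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked genes")
    if n_hit == genes.size:
        raise ValueError("gene set covers every ranked gene: ES undefined")
    order = np.lexsort((np.arange(t.size), -t))
    return _es_from_ranked(member[order], np.abs(t[order]), weight)


def permutation_test(
    expr: pd.DataFrame,
    groups,
    gene_sets: dict,
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
    sign_aware: bool = False,
    block: int = 1000,
) -> pd.DataFrame:
    """Sample-label permutation null for each gene set's ES.

    Labels are permuted ``n_perm`` times; t statistics and ES are
    recomputed per permutation and the nominal p-value uses the add-one
    estimator ``(1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm)`` (or the
    one-sided, sign-aware count when requested).
    Returns a DataFrame indexed by set name with columns ``es``, ``p``.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are unstable",
                      stacklevel=2)
    E = expr.to_numpy(dtype=float)
    genes = np.asarray(expr.index)
    g = np.asarray(groups)
    high = (g == "high") | (g == 1)
    low = (g == "low") | (g == 0)
    if high.sum() < 2 or low.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    n_samples = g.size
    nh = int(high.sum())

    t_obs = _welch_t(E, high, low)
    obs_series = pd.Series(t_obs, index=genes)
    members = {name: np.isin(genes, np.asarray(list(gs)))
               for name, gs in gene_sets.items()}
    for name, m in members.items():
        if m.sum() == 0 or m.sum() == genes.size:
            raise ValueError(f"gene set {name!r} is empty or covers all genes")
    es_obs = {name: enrichment_score(obs_series, gs, weight=weight)
              for name, gs in gene_sets.items()}

    rng = np.random.default_rng(seed)
    exceed = {name: 0 for name in gene_sets}
    E2 = E ** 2
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        # permutation masks: b random assignments of nh "high" labels
        M = np.zeros((b, n_samples), dtype=float)
        for r in range(b):
            M[r, rng.permutation(n_samples)[:nh]] = 1.0
        Mc = 1.0 - M
        nl = n_samples - nh
        S1h, S1l = E @ M.T, E @ Mc.T  # (genes, b)
        S2h, S2l = E2 @ M.T, E2 @ Mc.T
        mh, ml = S1h / nh, S1l / nl
        vh = (S2h - S1h ** 2 / nh) / (nh - 1)
        vl = (S2l - S1l ** 2 / nl) / (nl - 1)
        se = np.sqrt(np.clip(vh / nh + vl / nl, 0, None))
        se[se == 0] = np.inf
        T = (mh - ml) / se  # (genes, b)

        order = np.argsort(-T, axis=0, kind="stable")
        absT = np.take_along_axis(np.abs(T), order, axis=0)
        for name, member in members.items():
            ms = np.take_along_axis(
                np.broadcast_to(member[:, None], T.shape), order, axis=0
            )
            n_hit = int(member.sum())
            w = absT ** weight if weight != 0 else np.ones_like(absT)
            hit_mass = (w * ms).sum(axis=0)
            hit_inc = np.where(hit_mass > 0, w * ms / np.where(hit_mass > 0,
                                                               hit_mass, 1.0),
                               ms / n_hit)
            miss_dec = (~ms) / (genes.size - n_hit)
            running = np.cumsum(hit_inc - miss_dec, axis=0)
            idx = np.argmax(np.abs(running), axis=0)
            es_perm = running[idx, np.arange(b)]
            if sign_aware:
                if es_obs[name] >= 0:
                    exceed[name] += int((es_perm >= es_obs[name]).sum())
                else:
                    exceed[name] += int((es_perm <= es_obs[name]).sum())
            else:
                exceed[name] += int((np.abs(es_perm) >= abs(es_obs[name])).sum())
        done += b

    rows = {name: dict(es=es_obs[name],
                       p=(1.0 + exceed[name]) / (1.0 + n_perm))
            for name in gene_sets}
    return pd.DataFrame.from_dict(rows, orient="index")


def fdr_classify(results: pd.DataFrame, q_threshold: float = 0.1) -> list[EnrichmentResult]:
    """Benjamini–Hochberg q-values and up/down/ns calls.

    ``results`` is indexed by set name with columns ``es`` and ``p``.
    A set is "up" when ES > 0 and q < ``q_threshold``, "down" when
    ES < 0 and q < ``q_threshold``, otherwise "ns".
    """
    if len(results) == 0:
        raise ValueError("no enrichment results to classify")
    _, q, _, _ = multipletests(results["p"].to_numpy(), method="fdr_bh")
    out = []
    for (name, row), qv in zip(results.iterrows(), q):
        es = float(row["es"])
        if qv < q_threshold and es > 0:
            call = "up"
        elif qv < q_threshold and es < 0:
            call = "down"
        else:
            call = "ns"
        out.append(EnrichmentResult(name=name, es=es, nominal_p=float(row["p"]),
                                    fdr_q=float(qv), call=call))
    return out


def run_gsea(
    expr: pd.DataFrame,
    groups,
    gene_sets: dict,
    n_perm: int = 10_000,
    seed: int = 0,
    q_threshold: float = 0.1,
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Convenience wrapper: permutation test then FDR classification."""
    results = permutation_test(expr, groups, gene_sets, n_perm=n_perm,
                               seed=seed, weight=weight)
    return fdr_classify(results, q_threshold=q_threshold)
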