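"""Preranked gene-set enrichment (GSEA-style running-sum statistic).

Genes are ranked by a signed statistic (descending).  For a set S the running
sum adds ``|stat|^p / sum_hits |stat|^p`` at each member ("hit") and
subtracts ``1/(N - |S|)`` at each non-member; the enrichment score ES is the
signed maximum deviation from zero.  Significance comes from a gene-label
permutation null (sets of the same size drawn at random), appropriate for
small-replicate designs where phenotype permutation is degenerate.  NES
normalizes ES by the mean |null ES| of matching sign, and q-values are BH
across sets.
"""
from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .differential import bh_adjust

__all__ = ["rank_genes", "es", "permutation_test"]


def rank_genes(de: pd.DataFrame, stat_col: str = "t") -> pd.Series:
    """Ranked list: signed statistic per gene, descending; ties broken by gene id."""
    if de["feature_id"].duplicated().any():
        dups = de.loc[de["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate genes in DE table: {dups[:5]}")
    stats_ = de.set_index("feature_id")[stat_col].astype(float)
    if not np.isfinite(stats_.to_numpy()).all():
        stats_ = stats_[np.isfinite(stats_)]
    return stats_.sort_index().sort_values(ascending=False, kind="stable")


def _es_from_hits(stats: np.ndarray, hit_mask: np.ndarray, p: float) -> tuple[float, int]:
    n = len(stats)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit some but not all ranked genes")
    w = np.abs(stats) ** p
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit stats are zero: fall back to unweighted
        hit_w = hit_mask.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit_mask) / (n - n_hits)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def es(ranked: pd.Series, gene_set, p: float = 1.0, return_leading_edge: bool = False):
    """Enrichment score of ``gene_set`` along the ranked list.

    ``ranked`` maps gene -> statistic, sorted descending.  ``p`` is the
    weighting exponent (1 = weighted, 0 = classic Kolmogorov–Smirnov-like).
    """
    genes = ranked.index.to_numpy()
    hit_mask = np.isin(genes, list(gene_set))
    if not hit_mask.any():
        raise ValueError("gene set does not intersect the ranked list")
    score, peak = _es_from_hits(ranked.to_numpy(dtype=float), hit_mask, p)
    if not return_leading_edge:
        return score
    if score >= 0:
        le = [g for g, h in zip(genes[: peak + 1], hit_mask[: peak + 1]) if h]
    else:
        le = [g for g, h in zip(genes[peak:], hit_mask[peak:]) if h]
    return score, le


def permutation_test(
    ranked: pd.Series,
    sets: dict[str, set],
    n_perm: int = 1000,
    seed: int = 0,
    p: float = 1.0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Gene-permutation null for each set; returns ES, NES, p and BH q per set.

    With ``exhaustive=True`` every distinct hit configuration of the set's
    size is enumerated (only feasible for small lists) and the p-value is the
    exact fraction of configurations at least as extreme; otherwise
    ``n_perm`` random sets of matching size are drawn and the add-one
    smoothed estimate ``(1 + #extreme) / (1 + n_perm)`` is used, so p is
    never exactly zero.
    """
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    stats_arr = ranked.to_numpy(dtype=float)
    genes = ranked.index.to_numpy()
    n = len(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for name, gene_set in sets.items():
        hit_mask = np.isin(genes, list(gene_set))
        n_hits = int(hit_mask.sum())
        if n_hits == 0 or n_hits == n:
            raise ValueError(f"set {name!r} hits none or all ranked genes")
        obs, _ = _es_from_hits(stats_arr, hit_mask, p)
        _, leading = es(ranked, gene_set, p=p, return_leading_edge=True)

        if exhaustive:
            if comb(n, n_hits) > 200_000:
                raise ValueError("exhaustive enumeration infeasible for this size")
            null = np.empty(comb(n, n_hits))
            for i, idx in enumerate(combinations(range(n), n_hits)):
                mask = np.zeros(n, dtype=bool)
                mask[list(idx)] = True
                null[i], _ = _es_from_hits(stats_arr, mask, p)
            if obs >= 0:
                pval = float(np.mean(null >= obs))
            else:
                pval = float(np.mean(null <= obs))
        else:
            null = np.empty(n_perm)
            for i in range(n_perm):
                mask = np.zeros(n, dtype=bool)
                mask[rng.choice(n, size=n_hits, replace=False)] = True
                null[i], _ = _es_from_hits(stats_arr, mask, p)
            if obs >= 0:
                pval = (1.0 + float((null >= obs).sum())) / (1.0 + n_perm)
            else:
                pval = (1.0 + float((null <= obs).sum())) / (1.0 + n_perm)
        same_sign = null[null >= 0] if obs >= 0 else null[null < 0]
        denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
        nes = obs / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append((name, n_hits, obs, nes, pval, leading))
    out = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p_perm", "leading_edge"])
    out["fdr_q"] = bh_adjust(out["p_perm"].to_numpy())
    return out
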