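"""The miRNA target-integration cascade.

Given differential-expression tables from a miRNA **mimic** (over-expression)
and **inhibitor** contrast, the cascade proceeds:

1. *opposite-direction set* — genes significantly down under the mimic
   (FDR < alpha, log2FC < 0) and significantly up under the inhibitor
   (FDR < alpha, log2FC > 0): the expected signature of direct targets;
2. *disease filter* — keep only genes whose mean signed fold change across
   disease-tissue studies is below a threshold (default < -1.5, i.e.
   down-regulated in diseased tissue);
3. *tiers* — intersect with the union of in-silico prediction databases
   (predicted tier) and of experimentally validated collections (confirmed
   tier).

Prediction databases are themselves validated by hypergeometric overlap with
the experimentally down-regulated genes, with the up-regulated genes serving
as internal negative controls.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, PrioritizationReport

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_p",
    "evaluate_databases",
    "opposite_direction",
    "disease_filter",
    "tier",
    "prioritize",
]


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ Hypergeom(N, K, n).

    ``k`` observed overlap, ``K`` set size, ``n`` draw size, ``N`` universe
    size — the one-tailed Fisher exact test for over-representation.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("need 0 <= k <= min(K, n)")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def evaluate_databases(
    down_set, up_set, dbs: GeneSetCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric validation of each database against DE gene sets.

    A database is flagged ``performant`` iff its overlap with the
    down-regulated genes is significant (p_down < alpha) while its overlap
    with the up-regulated internal-control genes is not (p_up >= alpha).
    """
    down_set, up_set = frozenset(down_set), frozenset(up_set)
    if down_set & up_set:
        raise ValueError("down and up sets must be disjoint")
    stray = (down_set | up_set) - dbs.universe
    if stray:
        raise ValueError(f"genes outside the universe: {sorted(stray)[:10]}")
    N = len(dbs.universe)
    rows = []
    for name, members in dbs.sets.items():
        K = len(members)
        for tag, s in (("down", down_set), ("up", up_set)):
            k = len(members & s)
            p = hypergeom_p(k, K, len(s), N)
            rows.append((name, tag, k, K, len(s), N, p))
    table = pd.DataFrame(rows, columns=["db", "set", "k", "K", "n", "N", "p"])
    wide = table.pivot(index="db", columns="set", values="p").rename(
        columns={"down": "p_down", "up": "p_up"}
    )
    wide["performant"] = (wide["p_down"] < alpha) & (wide["p_up"] >= alpha)
    down_rows = table[table["set"] == "down"].set_index("db")
    up_rows = table[table["set"] == "up"].set_index("db")
    wide["k_down"] = down_rows["k"]
    wide["k_up"] = up_rows["k"]
    wide["K"] = down_rows["K"]
    wide["n_down"] = down_rows["n"]
    wide["n_up"] = up_rows["n"]
    wide["N"] = down_rows["N"]
    return wide.reset_index()


def _require(de: pd.DataFrame, cols=("feature_id", "p_adj")) -> pd.DataFrame:
    for c in cols:
        if c not in de:
            raise KeyError(f"DE table lacks column {c!r}")
    if "log2fc" in de:
        lfc = de["log2fc"]
    elif "fc_linear" in de:
        lfc = np.log2(de["fc_linear"])
    elif "effect" in de:
        lfc = de["effect"]
    else:
        raise KeyError("DE table needs log2fc, fc_linear or effect")
    return pd.DataFrame(
        {"p_adj": de["p_adj"].to_numpy(), "log2fc": np.asarray(lfc, dtype=float)},
        index=de["feature_id"],
    )


def opposite_direction(
    de_mimic: pd.DataFrame, de_inhibitor: pd.DataFrame, alpha: float = 0.05
) -> frozenset:
    """Genes down under the mimic and up under the inhibitor, both at FDR < alpha (strict)."""
    a = _require(de_mimic)
    b = _require(de_inhibitor)
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    hit = (
        (a["p_adj"] < alpha)
        & (a["log2fc"] < 0)
        & (b["p_adj"] < alpha)
        & (b["log2fc"] > 0)
    )
    return frozenset(shared[hit.to_numpy()])


def disease_filter(
    genes,
    disease_fc: pd.DataFrame,
    threshold: float = -1.5,
    require_all: bool = False,
) -> tuple[frozenset, frozenset]:
    """Keep genes down-regulated in disease-tissue studies.

    ``disease_fc`` is long-format (gene, study, fc_signed) with the signed
    linear FC convention (|FC| >= 1; negative = down in disease).  Default
    rule: mean FC across the studies where the gene was measured is below
    ``threshold``.  With ``require_all`` the gene must be below threshold in
    every study where it appears.  Genes absent from all studies are dropped
    and returned separately.
    """
    if threshold >= -1.0:
        raise ValueError("threshold must be below -1 (signed linear FC convention)")
    genes = frozenset(genes)
    sub = disease_fc[disease_fc["gene"].isin(genes)]
    if require_all:
        ok = sub.groupby("gene")["fc_signed"].agg(lambda v: bool((v < threshold).all()))
    else:
        ok = sub.groupby("gene")["fc_signed"].mean() < threshold
    kept = frozenset(ok.index[ok])
    dropped = genes - set(sub["gene"])
    if dropped:
        logger.info("disease_filter: %d genes absent from all studies dropped", len(dropped))
    return kept, frozenset(dropped)


def tier(genes, dbs: GeneSetCollection) -> tuple[frozenset, frozenset]:
    """(predicted, confirmed) tiers: intersection with in-silico / validated unions."""
    genes = frozenset(genes)
    predicted = genes & dbs.union("in_silico")
    confirmed = genes & dbs.union("validated")
    return predicted, confirmed


def prioritize(
    de_mimic: pd.DataFrame,
    de_inhibitor: pd.DataFrame,
    dbs: GeneSetCollection,
    disease_fc: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = -1.5,
    require_all_studies: bool = False,
) -> PrioritizationReport:
    """Run the full cascade and the database validation; returns the tiered report."""
    mim = _require(de_mimic)
    down_set = frozenset(mim.index[(mim["p_adj"] < alpha) & (mim["log2fc"] < 0)]) & dbs.universe
    up_set = frozenset(mim.index[(mim["p_adj"] < alpha) & (mim["log2fc"] > 0)]) & dbs.universe
    db_stats = evaluate_databases(down_set, up_set, dbs, alpha=alpha)

    opposite = opposite_direction(de_mimic, de_inhibitor, alpha=alpha)
    filtered, dropped = disease_filter(
        opposite, disease_fc, threshold=fc_threshold, require_all=require_all_studies
    )
    predicted, confirmed = tier(filtered, dbs)
    return PrioritizationReport(
        opposite_set=opposite,
        disease_filtered=filtered,
        predicted_tier=predicted,
        confirmed_tier=confirmed,
        db_stats=db_stats,
        dropped_no_disease_data=dropped,
    )
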