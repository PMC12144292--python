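"""Differential expression and qPCR relative quantification.

Two engines live here:

* an empirical-Bayes **moderated t** for normalized panel/expression matrices:
  per-feature residual variances are shrunk toward a prior ``s0^2`` with prior
  degrees of freedom ``d0``, both estimated across features by
  method-of-moments on the log residual variances (trigamma inversion);
  the moderated statistic gains ``d0`` degrees of freedom;
* classic ``2^-ddCt`` relative quantification for qPCR plates, with a
  spike-in or endogenous normalizer.

Multiple testing uses the Benjamini–Hochberg step-up procedure.

Sign convention: ``effect`` is on the *expression* scale — positive means
more abundant in the case/treated group.  For Ct input (lower Ct = more
abundant) the Ct-scale mean difference is negated.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "EbParams",
    "estimate_eb_prior",
    "moderated_t",
    "ct_moderated_t",
    "bh_adjust",
    "delta_ct",
    "fold_change",
    "ddct_analysis",
    "t_test",
    "de_counts",
    "log_cpm",
]

DE_COLUMNS = ["feature_id", "effect", "fc_linear", "t", "df", "p_raw", "p_adj", "direction"]


@dataclass(frozen=True)
class EbParams:
    """Empirical-Bayes prior: variance ``s0_sq`` with ``d0`` degrees of freedom."""

    s0_sq: float
    d0: float

    def __post_init__(self) -> None:
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be positive")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone branch)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * x:
            return x_new
        x = x_new
    return x


def estimate_eb_prior(s2: np.ndarray, df: np.ndarray) -> EbParams:
    """Method-of-moments fit of (d0, s0^2) from residual variances.

    Works on ``z = log(s2)``: after removing the known chi-square bias
    (digamma/log terms), the excess variance of ``z`` over the expected
    ``trigamma(df/2)`` identifies ``trigamma(d0/2)``.  If there is no excess
    (variances are homogeneous), ``d0`` is infinite and every feature shares
    ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # homogeneous variances: shrink fully to their mean so that the
        # moderated statistic coincides with the ordinary pooled t
        return EbParams(s0_sq=float(s2.mean()), d0=np.inf)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EbParams(s0_sq=s0_sq, d0=float(d0))


def _squeeze_var(s2: np.ndarray, df: np.ndarray, prior: EbParams) -> np.ndarray:
    if np.isinf(prior.d0):
        return np.full_like(np.asarray(s2, dtype=float), prior.s0_sq)
    return (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)


def _t_sf_two_sided(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    p = np.empty_like(t, dtype=float)
    inf_df = np.isinf(df)
    p[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))
    p[~inf_df] = 2.0 * stats.t.sf(np.abs(t[~inf_df]), df[~inf_df])
    return p


def moderated_t(
    values: pd.DataFrame,
    groups: pd.Series,
    group1: str,
    group2: str,
    flip_sign: bool = False,
    prior: EbParams | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t test per feature.

    Parameters
    ----------
    values
        Features x samples matrix on the analysis scale (NaN allowed).
    groups
        Sample -> label; only ``group1`` (reference) and ``group2`` samples
        are used.
    flip_sign
        Set True for Ct-scale input so that the reported ``effect`` is on the
        expression scale (positive = up in ``group2``).
    prior
        Fixed (d0, s0^2); estimated from the data when omitted.

    Features with fewer than two observed samples in either group are
    reported with NaN statistics ("not testable") rather than dropped.
    """
    groups = groups.reindex(values.columns)
    m1 = (groups == group1).to_numpy()
    m2 = (groups == group2).to_numpy()
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError(f"both groups must be present; got {groups.value_counts().to_dict()}")

    arr = values.to_numpy(dtype=float)
    x1, x2 = arr[:, m1], arr[:, m2]
    n1 = (~np.isnan(x1)).sum(axis=1).astype(float)
    n2 = (~np.isnan(x2)).sum(axis=1).astype(float)
    mean1 = _nanmean(x1, n1)
    mean2 = _nanmean(x2, n2)
    var1 = _nanvar(x1, n1)
    var2 = _nanvar(x2, n2)

    testable = (n1 >= 2) & (n2 >= 2)
    df_resid = np.where(testable, n1 + n2 - 2.0, np.nan)
    s2 = np.where(
        testable,
        ((n1 - 1.0) * var1 + (n2 - 1.0) * var2) / np.where(testable, n1 + n2 - 2.0, 1.0),
        np.nan,
    )
    effect = mean2 - mean1
    if flip_sign:
        effect = -effect

    if prior is None:
        prior = estimate_eb_prior(s2[testable], df_resid[testable])
    s2_post = np.full_like(s2, np.nan)
    s2_post[testable] = _squeeze_var(s2[testable], df_resid[testable], prior)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    df_total = df_resid + prior.d0
    p = np.full_like(t, np.nan)
    ok = testable & np.isfinite(t)
    p[ok] = _t_sf_two_sided(t[ok], df_total[ok])
    n_untestable = int((~testable).sum())
    if n_untestable:
        logger.info("moderated_t: %d features not testable (<2 obs per group)", n_untestable)

    p_adj = np.full_like(p, np.nan)
    p_adj[ok] = bh_adjust(p[ok])
    out = pd.DataFrame(
        {
            "feature_id": values.index,
            "effect": effect,
            "fc_linear": 2.0 ** effect,
            "t": t,
            "df": df_total,
            "p_raw": p,
            "p_adj": p_adj,
            "direction": np.where(effect > 0, "up", "down"),
        }
    )
    out.loc[~testable, "direction"] = "not_testable"
    out.attrs["eb_prior"] = prior
    return out


def ct_moderated_t(matrix, group_col: str = "group", case: str = "case", control: str = "control") -> pd.DataFrame:
    """Moderated t on a (normalized) CtMatrix; effect on the expression scale."""
    return moderated_t(
        matrix.values, matrix.sample_meta[group_col], group1=control, group2=case, flip_sign=True
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(adj_sorted, 0.0, 1.0)
    return adj


def delta_ct(ct_target: pd.Series, ct_normalizer: pd.Series) -> pd.Series:
    """Per-sample dCt = Ct(target) - Ct(normalizer); samples missing either are dropped."""
    ct_target, ct_normalizer = ct_target.align(ct_normalizer, join="outer")
    ok = ct_target.notna() & ct_normalizer.notna()
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("delta_ct: excluded %d samples with missing Ct", n_drop)
    return (ct_target - ct_normalizer)[ok]


def fold_change(dct_group, dct_ref) -> float:
    """Linear fold change of the group vs reference: 2^(mean dCt_ref - mean dCt_group)."""
    dct_group = np.asarray(dct_group, dtype=float)
    dct_ref = np.asarray(dct_ref, dtype=float)
    if len(dct_group) == 0 or len(dct_ref) == 0:
        raise ValueError("fold_change needs at least one dCt per group")
    return float(2.0 ** (dct_ref.mean() - dct_group.mean()))


def ddct_analysis(
    plate: pd.DataFrame,
    target: str,
    normalizer: str,
    ref_group: str,
    tails: int = 2,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-group ddCt fold change vs ``ref_group`` with a t test on dCt.

    ``plate`` is long-format (sample, group, feature, ct).  ``alternative``
    gives the prespecified direction for one-tailed tests: "greater" means
    the non-reference group is hypothesized to express more target
    (lower dCt).
    """
    wide = plate.pivot_table(index="sample", columns="feature", values="ct")
    if target not in wide or normalizer not in wide:
        raise KeyError(f"plate lacks {target!r} or {normalizer!r}")
    dct = delta_ct(wide[target], wide[normalizer])
    grp = plate.drop_duplicates("sample").set_index("sample")["group"].reindex(dct.index)
    ref = dct[grp == ref_group]
    if len(ref) == 0:
        raise ValueError(f"no usable samples in reference group {ref_group!r}")
    rows = []
    for g in grp.unique():
        if g == ref_group:
            continue
        cur = dct[grp == g]
        fc = fold_change(cur, ref)
        # lower dCt = more expression: "greater" expression maps to "less" on dCt
        dct_alt = {"greater": "less", "less": "greater"}[alternative]
        t, p = t_test(cur, ref, tails=tails, alternative=dct_alt)
        rows.append((g, len(cur), len(ref), fc, float(np.log2(fc)), t, p))
    return pd.DataFrame(
        rows, columns=["group", "n_group", "n_ref", "fc_linear", "log2fc", "t", "p"]
    )


def t_test(
    x,
    y,
    paired: bool = False,
    tails: int = 2,
    welch: bool = False,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Student's t test with optional pairing, Welch correction and one tail.

    For ``tails=1`` the one-tailed p equals half the two-tailed p when the
    observed direction matches the prespecified ``alternative`` ("greater":
    mean(x) > mean(y)), and 1 minus half otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal-length samples")
        if len(x) < 2:
            raise ValueError("need n >= 2")
        res = stats.ttest_rel(x, y)
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need n >= 2 per arm")
        res = stats.ttest_ind(x, y, equal_var=not welch)
    t, p2 = float(res.statistic), float(res.pvalue)
    if np.isnan(p2):  # identical constant samples
        p2 = 1.0
        t = 0.0
    if tails == 2:
        return t, p2
    matches = (t >= 0) if alternative == "greater" else (t <= 0)
    return t, p2 / 2.0 if matches else 1.0 - p2 / 2.0


def de_counts(de: pd.DataFrame, alpha: float = 0.05, min_abs_fc: float = 1.5) -> tuple[int, int]:
    """Counts of significantly (p_adj <= alpha, |FC| >= min_abs_fc) down/up features."""
    if "fc_linear" in de:
        log2fc = np.log2(de["fc_linear"].to_numpy(dtype=float))
    elif "log2fc" in de:
        log2fc = de["log2fc"].to_numpy(dtype=float)
    else:
        raise KeyError("DE table needs a fc_linear or log2fc column")
    p_adj = de["p_adj"].to_numpy(dtype=float)
    sig = (p_adj <= alpha) & (np.abs(log2fc) >= np.log2(min_abs_fc))
    n_down = int((sig & (log2fc < 0)).sum())
    n_up = int((sig & (log2fc > 0)).sum())
    return n_down, n_up


def log_cpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a small prior count (count-data DE scale)."""
    lib = counts.sum(axis=0)
    return np.log2((counts + prior_count).div(lib + 2 * prior_count, axis=1) * 1e6)


def _nanmean(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    total = np.nansum(x, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, total / np.maximum(n, 1.0), np.nan)


def _nanvar(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    mean = _nanmean(x, n)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = np.nansum((x - mean) ** 2, axis=1)
        return np.where(n > 1, ss / np.maximum(n - 1.0, 1.0), np.nan)
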