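"""Quality control and normalization of panel Ct matrices.

The canonical stage order is::

    mark_undetermined -> filter_detection -> quantile_normalize -> drop_controls

Validity masking uses the strict rule that Ct below ``low`` or above ``high``
is "undetermined" (exact boundary values are retained).  The detection filter
removes features not detected in over ``max_missing_frac`` of all samples
(cases and controls pooled).  Quantile normalization equalizes the per-sample
value distributions, which removes additive batch offsets and makes
endogenous controls unnecessary — they are removed *after* normalization.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CtMatrix, QcReport

__all__ = [
    "mark_undetermined",
    "filter_detection",
    "drop_controls",
    "quantile_normalize",
    "pca_qc",
    "run_qc",
]


def mark_undetermined(
    m: CtMatrix, low: float = 15.0, high: float = 35.0, report: QcReport | None = None
) -> CtMatrix:
    """Set Ct values strictly below ``low`` or strictly above ``high`` to missing."""
    if low >= high:
        raise ValueError("low must be below high")
    vals = m.values.copy()
    invalid = (vals < low) | (vals > high)
    n_set = int(invalid.to_numpy().sum())
    vals[invalid] = np.nan
    if report is not None:
        report.n_features_in = m.n_features
        report.n_undetermined_set = n_set
        report.add(f"mark_undetermined: {n_set} entries outside ({low}, {high}) set to missing")
    return CtMatrix(vals, m.sample_meta.copy())


def filter_detection(
    m: CtMatrix, max_missing_frac: float = 0.5, report: QcReport | None = None
) -> CtMatrix:
    """Drop features missing in more than ``max_missing_frac`` of samples.

    The boundary is exclusive: a feature missing in exactly half the samples
    is kept ("excluded if not detected in over 50%").
    """
    if m.n_samples < 1:
        raise ValueError("matrix has no samples")
    keep = m.missing_fraction() <= max_missing_frac
    out = CtMatrix(m.values.loc[keep], m.sample_meta.copy())
    if report is not None:
        report.n_features_kept = out.n_features
        report.per_sample_detection = out.values.notna().mean(axis=0)
        report.add(
            f"filter_detection: kept {out.n_features}/{m.n_features} features "
            f"detected in >= {100 * (1 - max_missing_frac):g}% of samples"
        )
    return out


def drop_controls(m: CtMatrix, control_ids, report: QcReport | None = None) -> CtMatrix:
    """Remove endogenous-control features; error on unknown ids (mislabeled panel)."""
    control_ids = list(control_ids)
    unknown = [c for c in control_ids if c not in m.feature_ids]
    if unknown:
        raise KeyError(f"control ids not in matrix: {unknown}")
    out = CtMatrix(m.values.drop(index=control_ids), m.sample_meta.copy())
    if report is not None:
        report.add(f"drop_controls: removed {len(control_ids)} control features")
    return out


def _column_quantiles(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Empirical quantile function of the observed entries of one column,
    evaluated on the common grid (mid-rank plotting positions)."""
    obs = np.sort(x[~np.isnan(x)])
    k = len(obs)
    pos = (np.arange(k) + 0.5) / k
    return np.interp(grid, pos, obs)


def quantile_normalize(
    m: CtMatrix, anchor_max_missing: float = 0.05, exclude=()
) -> CtMatrix:
    """Quantile-normalize samples onto the pooled reference distribution.

    For complete matrices this is the classic rank-mean scheme: rank r in
    every sample is replaced by the mean of all samples' rank-r values (ties
    get the mean of the tied ranks' reference values).

    With missing entries (or an ``exclude`` list), every observed value is
    instead mapped through a smoothed per-sample curve onto the pooled
    reference.  The curve is *anchored* on the consistently detected
    features (missing fraction at most ``anchor_max_missing``); its nodes
    are block means of the sample's sorted anchor values paired with block
    means of the reference, with unit-slope extension beyond the anchor
    range.  Rationale: exact per-sample ranking over whatever happens to be
    observed lets the dropout pattern itself perturb every feature's
    normalized value (the rank/count ratio jitters with the sample's
    missingness), and rank assignment over a sparse anchor set quantizes
    values to the local anchor gap; block-mean nodes average single-feature
    noise out of the curve and keep its local slope stable.  Missing
    entries stay missing.

    ``exclude`` names features left out of the curve estimation (but still
    normalized through it).  Quantile normalization assumes the bulk of
    features is non-differential; a feature with a real group shift that
    helps define the map leaks its shift into rank-neighboring features, so
    callers running differential analysis should exclude first-pass
    candidates and renormalize (see ``biomarker_discovery``).
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least two samples")
    arr = m.values.to_numpy(dtype=float)
    n_feat, n_samp = arr.shape
    n_obs = (~np.isnan(arr)).sum(axis=0)
    if (n_obs == 0).any():
        bad = m.sample_ids[n_obs == 0].tolist()
        raise ValueError(f"samples with no observed values: {bad}")
    exclude = set(exclude)

    if not np.isnan(arr).any() and not exclude:
        # complete matrix: exact classic rank-mean quantile normalization
        ref = np.sort(arr, axis=0).mean(axis=1)
        out = np.empty_like(arr)
        for j in range(n_samp):
            order = np.argsort(arr[:, j], kind="stable")
            mapped = np.empty(n_feat)
            mapped[order] = ref
            # average-tie: equal input values share the mean of their targets
            ser = pd.Series(mapped).groupby(pd.Series(arr[:, j])).transform("mean")
            out[:, j] = ser.to_numpy()
        values = pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids)
        return CtMatrix(values, m.sample_meta.copy())

    miss_frac = np.isnan(arr).mean(axis=1)
    anchors = miss_frac <= anchor_max_missing
    if exclude:
        anchors &= ~np.asarray(m.feature_ids.isin(exclude))
    if anchors.sum() < max(3, int(0.1 * n_feat)):
        anchors = miss_frac <= anchor_max_missing  # exclusion too aggressive
    if anchors.sum() < max(3, int(0.1 * n_feat)):
        anchors = np.ones(n_feat, dtype=bool)  # too few stable features: use all
    sub = arr[anchors]
    n_anchor = sub.shape[0]
    grid = (np.arange(n_anchor) + 0.5) / n_anchor
    ref = np.mean([_column_quantiles(sub[:, j], grid) for j in range(n_samp)], axis=0)

    out = np.full_like(arr, np.nan)
    for j in range(n_samp):
        ax_col = sub[:, j]
        ax = np.sort(ax_col[~np.isnan(ax_col)])
        k = len(ax)
        if k == 0:
            raise ValueError(f"sample {m.sample_ids[j]!r} has no observed anchor values")
        y_sample = np.interp((np.arange(k) + 0.5) / k, grid, ref)
        T = max(2, min(12, k // 4)) if k >= 8 else 1
        blocks = np.array_split(np.arange(k), T)
        xs = np.array([ax[b].mean() for b in blocks])
        ys = np.array([y_sample[b].mean() for b in blocks])
        nodes = pd.Series(ys).groupby(pd.Series(xs)).mean()
        xk = nodes.index.to_numpy(dtype=float)
        yk = nodes.to_numpy(dtype=float)
        obs = ~np.isnan(arr[:, j])
        x = arr[obs, j]
        if len(xk) == 1:
            mapped = yk[0] + (x - xk[0])
        else:
            mapped = np.interp(x, xk, yk)
            below, above = x < xk[0], x > xk[-1]
            mapped[below] = yk[0] + (x[below] - xk[0])
            mapped[above] = yk[-1] + (x[above] - xk[-1])
        out[obs, j] = mapped
    values = pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids)
    return CtMatrix(values, m.sample_meta.copy())


def pca_qc(m: CtMatrix, n_components: int | None = None, report: QcReport | None = None) -> QcReport:
    """Sample-space PCA for quality control.

    Missing entries are feature-mean imputed (imputation is used for this QC
    view only, never for inference).  Features with no observed values are
    dropped.  Returns a QcReport carrying centered scores and the fraction of
    variance explained per component (non-increasing, summing to 1 over all
    components).
    """
    if m.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    vals = m.values.copy()
    vals = vals.loc[vals.notna().any(axis=1)]
    filled = vals.apply(lambda row: row.fillna(row.mean()), axis=1)
    X = filled.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    scores = X @ vt.T
    k = n_components or min(scores.shape)
    rep = report if report is not None else QcReport()
    rep.pca_variance_explained = frac
    rep.pca_scores = pd.DataFrame(
        scores[:, :k], index=m.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    rep.add(
        "pca_qc: variance explained "
        + ", ".join(f"PC{i + 1}={f:.1%}" for i, f in enumerate(frac[: min(3, len(frac))]))
    )
    return rep


def run_qc(
    m: CtMatrix,
    low: float = 15.0,
    high: float = 35.0,
    max_missing_frac: float = 0.5,
    control_ids=(),
) -> tuple[CtMatrix, QcReport]:
    """Full QC + normalization stage in the canonical order."""
    report = QcReport()
    m = mark_undetermined(m, low, high, report)
    m = filter_detection(m, max_missing_frac, report)
    m = quantile_normalize(m)
    if control_ids:
        present = [c for c in control_ids if c in m.feature_ids]
        m = drop_controls(m, present, report)
    pca_qc(m, report=report)
    return m, report
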