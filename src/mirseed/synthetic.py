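"""Synthetic data generators for every pipeline input.

All generators are deterministic given their ``seed`` and emit a
:class:`~mirseed.containers.TruthRecord` alongside the data wherever there is
planted signal, so parameter-recovery tests have ground truth.

The default parameters mirror the discovery-study design this pipeline was
built around: a 754-feature plasma miRNA OpenArray-style panel profiled in
roughly 200 cases and 190 controls, a planted group difference of 0.1 Ct with
group standard deviations of 0.1, and a 3-vs-3 mimic / inhibitor / scramble
RNA-seq experiment with ~60 true targets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import CtMatrix, GeneSetCollection, TruthRecord

__all__ = [
    "CtSimParams",
    "RnaSeqSimParams",
    "gen_ct_matrix",
    "gen_qpcr_plate",
    "gen_rnaseq_counts",
    "gen_nb_counts",
    "gen_target_db",
    "gen_disease_fc",
]


@dataclass(frozen=True)
class CtSimParams:
    """Design of a synthetic panel Ct matrix.

    ``effect_delta`` is the case-vs-control mean shift on the Ct scale for
    planted features (applied with the sign implied by the planted
    direction: an "up"-regulated feature gets a *lower* Ct in cases).
    Missingness is Ct-dependent (logistic in the true Ct) on top of a base
    rate, so high-Ct (low-abundance) features drop out preferentially, and a
    per-sample batch offset emulates the technical variation that quantile
    normalization is there to remove.
    """

    n_features: int = 754
    n_cases: int = 200
    n_controls: int = 190
    n_planted: int = 12
    effect_delta: float = 0.1
    feature_sd: float = 0.1
    missing_rate_base: float = 0.01
    batch_sd: float = 0.5
    ct_low: float = 15.0
    ct_high: float = 35.0
    detectable_frac: float = 0.17
    baseline_low: float = 19.0
    baseline_high: float = 32.0
    undetectable_low: float = 36.0
    undetectable_high: float = 45.0
    dropout_mid: float = 33.0
    dropout_scale: float = 0.7
    n_endogenous_controls: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_features, self.n_cases, self.n_controls) <= 0:
            raise ValueError("n_features, n_cases and n_controls must be positive")
        if not 0 <= self.n_planted <= self.n_features:
            raise ValueError("n_planted must lie in [0, n_features]")
        if not 0.0 <= self.missing_rate_base <= 1.0:
            raise ValueError("missing_rate_base must be a fraction in [0, 1]")
        if self.ct_low >= self.ct_high:
            raise ValueError("ct_low must be below ct_high")
        if self.feature_sd <= 0:
            raise ValueError("feature_sd must be positive")


def gen_ct_matrix(params: CtSimParams) -> tuple[CtMatrix, TruthRecord]:
    """Generate an OpenArray-like Ct matrix with planted differential miRNAs.

    Returns the matrix (features x samples; NaN = not detected) and the truth
    record naming the planted features and their expression direction in
    cases.
    """
    rng = np.random.default_rng(params.seed)
    n_feat = params.n_features + params.n_endogenous_controls
    n_samp = params.n_cases + params.n_controls

    feat_ids = [f"miR-sim-{i + 1:04d}" for i in range(params.n_features)]
    feat_ids += [f"endo-ctrl-{i + 1}" for i in range(params.n_endogenous_controls)]
    sample_ids = [f"case_{i + 1:03d}" for i in range(params.n_cases)]
    sample_ids += [f"ctrl_{i + 1:03d}" for i in range(params.n_controls)]
    is_case = np.array([1] * params.n_cases + [0] * params.n_controls, dtype=bool)

    # plasma panels are bimodal: a minority of miRNAs circulates at
    # quantifiable levels, the rest sits below the detection limit
    detectable = rng.random(n_feat) < params.detectable_frac
    baselines = np.where(
        detectable,
        rng.uniform(params.baseline_low, params.baseline_high, size=n_feat),
        rng.uniform(params.undetectable_low, params.undetectable_high, size=n_feat),
    )
    # endogenous controls sit at a stable, well-detected Ct
    if params.n_endogenous_controls:
        baselines[params.n_features:] = rng.uniform(19.0, 23.0, params.n_endogenous_controls)

    # plant only among features abundant enough to survive the detection filter
    detectable = np.flatnonzero(baselines[: params.n_features] < params.dropout_mid - 3.0)
    if len(detectable) < params.n_planted:
        raise ValueError("too few well-detected features to plant the requested signal")
    planted_idx = rng.choice(detectable, size=params.n_planted, replace=False)
    up_mask = rng.random(params.n_planted) < 0.5
    direction = {
        feat_ids[i]: ("up" if up else "down")
        for i, up in zip(planted_idx, up_mask)
    }

    batch = rng.normal(0.0, params.batch_sd, size=n_samp)
    ct_true = baselines[:, None] + rng.normal(0.0, params.feature_sd, size=(n_feat, n_samp))
    # "up" in cases = lower Ct in cases
    for i, up in zip(planted_idx, up_mask):
        shift = -params.effect_delta if up else params.effect_delta
        ct_true[i, is_case] += shift

    # detection dropout is logistic in the *true* Ct (underlying abundance);
    # the batch offset is a downstream technical shift of the measured value
    p_miss = params.missing_rate_base + (1.0 - params.missing_rate_base) * expit(
        (ct_true - params.dropout_mid) / params.dropout_scale
    )
    ct = ct_true + batch[None, :]
    ct[rng.random(ct.shape) < p_miss] = np.nan

    values = pd.DataFrame(ct, index=pd.Index(feat_ids, name="feature_id"), columns=sample_ids)
    values.attrs["baseline"] = pd.Series(baselines, index=feat_ids)
    diameter = np.where(
        is_case,
        np.clip(rng.normal(54.0, 10.0, n_samp), 30.5, None),
        np.clip(rng.normal(18.0, 3.0, n_samp), 13.0, 29.0),
    )
    meta = pd.DataFrame(
        {
            "group": np.where(is_case, "case", "control"),
            "diameter": np.round(diameter, 1),
            "batch": "b1",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CtMatrix(values, meta), TruthRecord(direction)


def gen_qpcr_plate(
    n_per_group: int = 8,
    groups: tuple[str, ...] = ("control", "case"),
    target_shift: float = 0.0,
    seed: int = 0,
    target: str = "miR-15a",
    endogenous: str = "U6",
    spike_in: str = "cel-miR-39",
    shifted_group: str | None = None,
    target_mean: float = 26.0,
    sample_sd: float = 0.25,
) -> pd.DataFrame:
    """Simulate a qPCR plate in long format.

    Columns: ``sample``, ``group``, ``feature``, ``ct``, ``role``.  The
    spike-in has a group-independent mean (it is added at a fixed amount per
    sample, before extraction), the endogenous control is likewise flat, and
    the target is shifted by ``target_shift`` Ct cycles in ``shifted_group``
    (default: the last listed group).  A negative shift means lower Ct,
    i.e. higher abundance.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if n_per_group < 2:
        raise ValueError("need at least two samples per group")
    shifted_group = shifted_group if shifted_group is not None else groups[-1]
    if shifted_group not in groups:
        raise ValueError(f"shifted_group {shifted_group!r} not among groups")
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for i in range(n_per_group):
            sample = f"{g}_{i + 1:02d}"
            # per-sample pipetting/extraction offset shared by all assays
            offset = rng.normal(0.0, 0.15)
            shift = target_shift if g == shifted_group else 0.0
            rows.append((sample, g, spike_in, 20.0 + offset + rng.normal(0, 0.1), "spike_in"))
            rows.append((sample, g, endogenous, 22.0 + offset + rng.normal(0, 0.1), "endogenous"))
            rows.append(
                (sample, g, target, target_mean + shift + offset + rng.normal(0, sample_sd), "target")
            )
    return pd.DataFrame(rows, columns=["sample", "group", "feature", "ct", "role"])


@dataclass(frozen=True)
class RnaSeqSimParams:
    """Design of a mimic / inhibitor / scramble NB count experiment.

    True targets are repressed under the mimic arm (``repression_lfc`` < 0,
    log2 units) and de-repressed under the inhibitor arm
    (``derepression_lfc`` > 0), both relative to the scramble arm.
    """

    n_genes: int = 15000
    n_reps_per_arm: int = 3
    arms: tuple[str, ...] = ("scramble", "mimic", "inhibitor")
    n_true_targets: int = 60
    repression_lfc: float = -1.5
    derepression_lfc: float = 1.0
    dispersion: float = 0.05
    lib_size_mean: float = 5e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_true_targets <= self.n_genes:
            raise ValueError("n_true_targets must lie in [0, n_genes]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_reps_per_arm < 2:
            raise ValueError("need at least two replicates per arm")
        if "scramble" not in self.arms:
            raise ValueError("arms must include the 'scramble' reference")


def gen_nb_counts(mean, dispersion: float, size, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def gen_rnaseq_counts(
    params: RnaSeqSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate NB counts for the mimic/inhibitor/scramble design.

    Returns (counts genes x samples, sample metadata with ``arm`` column,
    truth record).  Truth directions are on the mimic-arm expression scale:
    every true target is "down" under the mimic.  Targets are planted among
    genes with base mean >= 50 so that the planted effect is measurable at
    the simulated depth.
    """
    rng = np.random.default_rng(params.seed)
    gene_ids = [f"GENE{i + 1:05d}" for i in range(params.n_genes)]

    log_mu = rng.normal(5.5, 2.0, size=params.n_genes)
    base_mean = np.clip(2.0 ** log_mu, 0.5, 2e5)
    expressed = np.flatnonzero(base_mean >= 50.0)
    if len(expressed) < params.n_true_targets:
        raise ValueError("too few adequately expressed genes to plant targets")
    target_idx = rng.choice(expressed, size=params.n_true_targets, replace=False)
    truth = TruthRecord({gene_ids[i]: "down" for i in target_idx})

    fc = {arm: np.ones(params.n_genes) for arm in params.arms}
    if "mimic" in fc:
        fc["mimic"][target_idx] = 2.0 ** params.repression_lfc
    if "inhibitor" in fc:
        fc["inhibitor"][target_idx] = 2.0 ** params.derepression_lfc

    cols, meta_rows, blocks = [], [], []
    depth_scale = params.lib_size_mean / base_mean.sum()
    for arm in params.arms:
        for r in range(params.n_reps_per_arm):
            sf = depth_scale * np.exp(rng.normal(0.0, 0.1))
            mu = base_mean * fc[arm] * sf
            blocks.append(gen_nb_counts(mu, params.dispersion, params.n_genes, rng))
            cols.append(f"{arm}_{r + 1}")
            meta_rows.append(arm)
    counts = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(gene_ids, name="feature_id"), columns=cols
    )
    meta = pd.DataFrame({"arm": meta_rows}, index=pd.Index(cols, name="sample_id"))
    return counts, meta, truth


def gen_target_db(
    universe,
    enriched_in,
    enrichment_factor: float = 10.0,
    db_size: int = 100,
    seed: int = 0,
    name: str = "mock_db",
    provenance: str = "in_silico",
) -> GeneSetCollection:
    """Mock target-prediction database with controlled overlap structure.

    Members are drawn without replacement, with genes in ``enriched_in``
    weighted ``enrichment_factor``-fold; factor 1 gives a uniform draw (the
    null database).
    """
    universe = sorted(set(universe))
    if not universe:
        raise ValueError("gene universe is empty")
    if db_size > len(universe):
        raise ValueError("db_size exceeds the universe")
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be positive")
    enriched = set(enriched_in)
    rng = np.random.default_rng(seed)
    w = np.array([enrichment_factor if g in enriched else 1.0 for g in universe])
    members = rng.choice(universe, size=db_size, replace=False, p=w / w.sum())
    return GeneSetCollection(universe, {name: set(members)}, {name: provenance})


def gen_disease_fc(
    universe,
    down_genes,
    n_studies: int = 3,
    seed: int = 0,
    presence_rate: float = 0.9,
) -> pd.DataFrame:
    """Mock disease-tissue fold-change tables across ``n_studies`` studies.

    Long format: ``gene``, ``study``, ``fc_signed``.  Signed linear FC
    convention: |FC| >= 1, negative = down in disease.  ``down_genes`` draw
    FCs well below -1.5 on average; all other genes sit near +/-1.  Each gene
    appears in each study with probability ``presence_rate``.
    """
    universe = sorted(set(universe))
    down = set(down_genes)
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_studies):
        study = f"study_{s + 1}"
        present = rng.random(len(universe)) < presence_rate
        for g, keep in zip(universe, present):
            if not keep:
                continue
            if g in down:
                fc = -(1.6 + rng.exponential(0.5))
            else:
                mag = 1.0 + abs(rng.normal(0.0, 0.15))
                fc = mag if rng.random() < 0.5 else -mag
            rows.append((g, study, round(float(fc), 4)))
    return pd.DataFrame(rows, columns=["gene", "study", "fc_signed"])
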