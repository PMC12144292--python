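"""Pipeline orchestration: wire the stages into the two end-to-end analyses.

* **biomarker discovery**: simulate (or load) a panel Ct matrix ->
  validity masking -> detection filter -> quantile normalization ->
  moderated-t differential expression -> BH FDR -> association with diameter;
* **target prioritization**: simulate (or load) mimic/inhibitor count data ->
  log-CPM moderated-t contrasts vs scramble -> opposite-direction set ->
  disease filter -> database validation and tiers -> preranked enrichment.

``run_pipeline`` is deterministic given the config (all randomness flows from
the single ``seed`` key) and writes every intermediate plus the fully
resolved config next to the outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, enrichment, io, prioritize, qc, synthetic
from .containers import CtMatrix, GeneSetCollection, TruthRecord

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "biomarker_discovery", "target_prioritization", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "ct": {
        "n_features": 754,
        "n_cases": 200,
        "n_controls": 190,
        "n_planted": 12,
        "effect_delta": 0.1,
        "feature_sd": 0.1,
    },
    "qc": {"ct_low": 15.0, "ct_high": 35.0, "max_missing_frac": 0.5},
    "de": {"alpha": 0.05},
    "rnaseq": {
        "n_genes": 4000,
        "n_true_targets": 60,
        "repression_lfc": -1.5,
        "derepression_lfc": 1.0,
        "dispersion": 0.05,
    },
    "prioritize": {"alpha": 0.05, "fc_threshold": -1.5, "db_size": 300, "enrichment_factor": 12.0},
    "gsea": {"n_perm": 500},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def _merge_config(config: dict | None) -> dict:
    config = config or {}
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {}
    for key, default in DEFAULT_CONFIG.items():
        if isinstance(default, dict):
            sub = dict(default)
            extra = set(config.get(key, {})) - set(default)
            if extra:
                raise ValueError(f"unknown config keys under {key!r}: {sorted(extra)}")
            sub.update(config.get(key, {}))
            merged[key] = sub
        else:
            merged[key] = config.get(key, default)
    return merged


def biomarker_discovery(
    ct: CtMatrix,
    ct_low: float = 15.0,
    ct_high: float = 35.0,
    max_missing_frac: float = 0.5,
    control_ids=(),
    refine_alpha: float = 0.05,
) -> tuple[pd.DataFrame, CtMatrix, "qc.QcReport"]:
    """QC -> robust quantile normalization -> moderated t -> BH on a Ct matrix.

    Quantile normalization is run twice: first-pass differential candidates
    (flagged at BH-adjusted p < ``refine_alpha``) are excluded from
    the second pass's anchor set, so genuinely differential features cannot
    leak their group shift into rank-neighboring features through the
    normalization map.  Set ``refine_alpha=0`` to disable the refinement.
    """
    report = qc.QcReport()
    m = qc.mark_undetermined(ct, ct_low, ct_high, report)
    m = qc.filter_detection(m, max_missing_frac, report)
    norm = qc.quantile_normalize(m)
    if refine_alpha > 0:
        de1 = differential.ct_moderated_t(norm)
        flagged = de1.loc[de1["p_adj"] < refine_alpha, "feature_id"]
        if len(flagged):
            report.add(
                f"quantile_normalize: refined map excluding {len(flagged)} "
                f"first-pass candidates (BH p < {refine_alpha})"
            )
            norm = qc.quantile_normalize(m, exclude=flagged)
    if control_ids:
        present = [c for c in control_ids if c in norm.feature_ids]
        norm = qc.drop_controls(norm, present, report)
    qc.pca_qc(norm, report=report)
    de = differential.ct_moderated_t(norm)
    return de, norm, report


def _rnaseq_contrasts(counts: pd.DataFrame, meta: pd.DataFrame) -> dict[str, pd.DataFrame]:
    lcpm = differential.log_cpm(counts)
    arms = meta["arm"]
    out = {}
    for arm in ("mimic", "inhibitor"):
        out[arm] = differential.moderated_t(lcpm, arms, group1="scramble", group2=arm)
    return out


def target_prioritization(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    dbs: GeneSetCollection,
    disease_fc: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = -1.5,
):
    """Mimic/inhibitor contrasts and the full prioritization cascade."""
    de = _rnaseq_contrasts(counts, meta)
    report = prioritize.prioritize(
        de["mimic"], de["inhibitor"], dbs, disease_fc, alpha=alpha, fc_threshold=fc_threshold
    )
    return report, de


def run_pipeline(config: dict | None, out_dir) -> dict:
    """Run both pipelines on synthetic inputs; write all intermediates to ``out_dir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    cfg = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    seed = int(cfg["seed"])

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # --- biomarker discovery -------------------------------------------------
    ct_params = synthetic.CtSimParams(seed=seed, **cfg["ct"])
    ct, truth = stage("simulate_ct", synthetic.gen_ct_matrix, ct_params)
    io.write_ct_tsv(ct, out / "ct_matrix.tsv", out / "ct_meta.tsv")
    truth.to_frame().to_csv(out / "ct_truth.tsv", sep="\t")

    de, norm, report = stage(
        "qc_de",
        biomarker_discovery,
        ct,
        ct_low=cfg["qc"]["ct_low"],
        ct_high=cfg["qc"]["ct_high"],
        max_missing_frac=cfg["qc"]["max_missing_frac"],
    )
    io.write_matrix_tsv(norm.values, out / "ct_normalized.tsv")
    io.write_de_tsv(de, out / "de_panel.tsv")
    (out / "qc_log.txt").write_text("\n".join(report.log) + "\n")

    alpha = cfg["de"]["alpha"]
    called = set(de.loc[de["p_adj"] < alpha, "feature_id"])
    planted = set(truth.planted_ids)
    tested = set(de.loc[de["p_raw"].notna(), "feature_id"])
    sens = len(called & planted) / len(planted & tested) if planted & tested else float("nan")

    # --- target prioritization ----------------------------------------------
    rs_params = synthetic.RnaSeqSimParams(seed=seed + 1, **cfg["rnaseq"])
    counts, meta, rna_truth = stage("simulate_rnaseq", synthetic.gen_rnaseq_counts, rs_params)
    io.write_matrix_tsv(counts, out / "rnaseq_counts.tsv")
    io.write_meta_tsv(meta, out / "rnaseq_meta.tsv")
    rna_truth.to_frame().to_csv(out / "rnaseq_truth.tsv", sep="\t")

    universe = list(counts.index)
    targets = set(rna_truth.planted_ids)
    pcfg = cfg["prioritize"]
    rng_seeds = np.random.SeedSequence(seed + 2).generate_state(4)
    db_sets, db_prov = {}, {}
    for i, (name, factor, prov) in enumerate(
        [
            ("diana_like", pcfg["enrichment_factor"], "in_silico"),
            ("mirdb_like", pcfg["enrichment_factor"], "in_silico"),
            ("mirtarbase_like", pcfg["enrichment_factor"], "validated"),
            ("uniform_null", 1.0, "in_silico"),
        ]
    ):
        db = synthetic.gen_target_db(
            universe,
            targets,
            enrichment_factor=factor,
            db_size=pcfg["db_size"],
            seed=int(rng_seeds[i]) % (2**31),
            name=name,
            provenance=prov,
        )
        db_sets[name] = set(db.sets[name])
        db_prov[name] = prov
    dbs = GeneSetCollection(universe, db_sets, db_prov)
    io.write_gmt(dbs, out / "target_dbs.gmt")

    disease_fc = synthetic.gen_disease_fc(universe, targets, seed=seed + 3)
    disease_fc.to_csv(out / "disease_fc.tsv", sep="\t", index=False)

    report2, de_contrasts = stage(
        "prioritize",
        target_prioritization,
        counts,
        meta,
        dbs,
        disease_fc,
        alpha=pcfg["alpha"],
        fc_threshold=pcfg["fc_threshold"],
    )
    io.write_de_tsv(de_contrasts["mimic"], out / "de_mimic.tsv")
    io.write_de_tsv(de_contrasts["inhibitor"], out / "de_inhibitor.tsv")
    report2.db_stats.to_csv(out / "db_validation.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene": sorted(report2.opposite_set),
            "disease_filtered": [g in report2.disease_filtered for g in sorted(report2.opposite_set)],
            "predicted": [g in report2.predicted_tier for g in sorted(report2.opposite_set)],
            "confirmed": [g in report2.confirmed_tier for g in sorted(report2.opposite_set)],
        }
    ).to_csv(out / "prioritization.tsv", sep="\t", index=False)

    # --- enrichment on the mimic contrast ------------------------------------
    ranked = enrichment.rank_genes(de_contrasts["mimic"].dropna(subset=["t"]))
    gsea_sets = {"planted_targets": targets & set(ranked.index)}
    gsea = stage(
        "gsea",
        enrichment.permutation_test,
        ranked,
        gsea_sets,
        n_perm=cfg["gsea"]["n_perm"],
        seed=seed + 4,
    )
    gsea.drop(columns="leading_edge").to_csv(out / "gsea.tsv", sep="\t", index=False)

    summary = {
        "panel_features_tested": int(de["p_raw"].notna().sum()),
        "panel_significant": len(called),
        "planted_sensitivity": sens,
        **report2.summary(),
        "planted_set_nes": float(gsea["nes"].iloc[0]),
        "planted_set_fdr": float(gsea["fdr_q"].iloc[0]),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
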