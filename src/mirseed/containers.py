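"""In-memory containers shared across the pipeline stages.

The central object is :class:`CtMatrix`, a features-by-samples table of qPCR
cycle-threshold (Ct) values with per-sample metadata.  Missing entries (not
detected / "undetermined") are encoded as NaN.  Lower Ct means higher
abundance throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "QcReport",
    "TruthRecord",
    "GeneSetCollection",
    "PrioritizationReport",
]


@dataclass
class CtMatrix:
    """Ct values (features x samples) plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns = sample ids, NaN = missing.
    sample_meta
        DataFrame indexed by sample id.  Conventional columns: ``group``
        (case/control label), ``diameter`` (aortic diameter, mm, optional),
        ``batch`` (optional).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not self.values.columns.equals(self.sample_meta.index):
            missing = set(self.values.columns) ^ set(self.sample_meta.index)
            raise ValueError(
                f"sample metadata does not align with matrix columns; offenders: {sorted(missing)}"
            )
        with np.errstate(invalid="ignore"):
            arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("Ct values must be finite where present")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing (undetermined) entries."""
        return self.values.isna().mean(axis=1)

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.values.copy(), self.sample_meta.copy())


@dataclass
class QcReport:
    """Bookkeeping for the QC / normalization stage."""

    n_features_in: int = 0
    n_undetermined_set: int = 0
    n_features_kept: int = 0
    per_sample_detection: pd.Series | None = None
    pca_variance_explained: np.ndarray | None = None
    pca_scores: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.log.append(message)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "n_features_in": self.n_features_in,
            "n_undetermined_set": self.n_undetermined_set,
            "n_features_kept": self.n_features_kept,
        }
        return pd.DataFrame({"value": rows})


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth emitted next to every synthetic fixture.

    ``direction`` maps planted feature/gene id -> "up" or "down" (expression
    scale: "up" = more abundant in the affected group/arm).
    """

    direction: dict[str, str]

    @property
    def planted_ids(self) -> frozenset[str]:
        return frozenset(self.direction)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": list(self.direction), "direction": list(self.direction.values())}
        ).set_index("feature_id")


class GeneSetCollection:
    """Named gene sets over a declared universe.

    ``provenance`` tags each set as one of ``in_silico`` / ``validated`` /
    ``disease`` / ``hallmark`` — mirroring prediction databases,
    experimentally confirmed interaction collections, disease signatures and
    hallmark-style pathway sets.
    """

    VALID_PROVENANCE = frozenset({"in_silico", "validated", "disease", "hallmark"})

    def __init__(
        self,
        universe,
        sets: dict[str, set],
        provenance: dict[str, str] | None = None,
    ) -> None:
        self.universe = frozenset(universe)
        if not self.universe:
            raise ValueError("gene universe is empty")
        self.sets: dict[str, frozenset] = {}
        for name, members in sets.items():
            members = frozenset(members)
            stray = members - self.universe
            if stray:
                raise ValueError(f"set {name!r} has members outside the universe: {sorted(stray)[:5]}")
            if name in self.sets:
                raise ValueError(f"duplicate set name {name!r}")
            self.sets[name] = members
        self.provenance = dict(provenance or {})
        for name, tag in self.provenance.items():
            if tag not in self.VALID_PROVENANCE:
                raise ValueError(f"unknown provenance {tag!r} for set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self, provenance: str | None = None) -> list[str]:
        if provenance is None:
            return list(self.sets)
        return [n for n in self.sets if self.provenance.get(n) == provenance]

    def union(self, provenance: str) -> frozenset:
        out: frozenset = frozenset()
        for name in self.names(provenance):
            out |= self.sets[name]
        return out


@dataclass
class PrioritizationReport:
    """Tiered output of the target-integration cascade.

    Containment invariant: ``confirmed_tier | predicted_tier`` is a subset of
    ``disease_filtered`` which is a subset of ``opposite_set``.
    """

    opposite_set: frozenset
    disease_filtered: frozenset
    predicted_tier: frozenset
    confirmed_tier: frozenset
    db_stats: pd.DataFrame
    dropped_no_disease_data: frozenset = frozenset()

    def __post_init__(self) -> None:
        tiers = self.predicted_tier | self.confirmed_tier
        if not tiers <= self.disease_filtered:
            raise ValueError("tier genes escape the disease-filtered set")
        if not self.disease_filtered <= self.opposite_set:
            raise ValueError("disease-filtered genes escape the opposite-direction set")

    def summary(self) -> dict:
        return {
            "n_opposite": len(self.opposite_set),
            "n_disease_filtered": len(self.disease_filtered),
            "n_predicted": len(self.predicted_tier),
            "n_confirmed": len(self.confirmed_tier),
        }
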