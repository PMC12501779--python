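"""Core domain objects shared across the toolkit.

Conventions:

* expression matrices are genes-in-rows, samples-in-columns;
* gene identifiers are Entrez-style digit strings after mapping;
* the subtype label canon is ``("LumA", "LumB", "Her2", "Basal", "Normal")``;
* biomarker statuses are ``"pos"``, ``"neg"`` or ``"unknown"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SUBTYPES: tuple[str, ...] = ("LumA", "LumB", "Her2", "Basal", "Normal")

#: clinical subgroups for which quantile-based centering parameters may exist
SUBGROUPS: tuple[str, ...] = (
    "ER+",
    "ER-",
    "TN",
    "ER+/HER2-",
    "ER+/HER2+",
    "ER-/HER2+",
    "ER-/HER2-",
)

#: ER/HER2 cross-tab subgroups (both statuses known)
ER_HER2_SUBGROUPS: tuple[str, ...] = (
    "ER+/HER2-",
    "ER+/HER2+",
    "ER-/HER2+",
    "ER-/HER2-",
)

STATUSES = ("pos", "neg", "unknown")

#: platform tag -> (scale, units) as inferred on ingest
PLATFORM_TABLE: dict[str, tuple[str, str]] = {
    "rnaseq_counts": ("linear", "counts"),
    "rnaseq_log2fpkm": ("log2", "fpkm"),
    "microarray": ("log2", "normalized_intensity"),
    "ncounter": ("log2", "normalized_intensity"),
}

#: matrices produced by the normalization pipeline carry this tag
DERIVED_PLATFORM = "derived"

SCALES = ("linear", "log2")
UNITS = ("counts", "cpm", "fpkm", "normalized_intensity")

#: long subtype names accepted in model files, normalized on load
SUBTYPE_ALIASES: dict[str, str] = {
    "luma": "LumA",
    "luminal a": "LumA",
    "luminala": "LumA",
    "lumb": "LumB",
    "luminal b": "LumB",
    "luminalb": "LumB",
    "her2": "Her2",
    "her2-enriched": "Her2",
    "her2 enriched": "Her2",
    "basal": "Basal",
    "basal-like": "Basal",
    "basallike": "Basal",
    "normal": "Normal",
    "normal-like": "Normal",
    "normallike": "Normal",
}


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


def canonical_subtype(label: str) -> str:
    """Normalize a subtype label, accepting common long-form aliases."""
    if label in SUBTYPES:
        return label
    key = label.strip().lower()
    if key in SUBTYPE_ALIASES:
        return SUBTYPE_ALIASES[key]
    raise ValidationError(f"unknown subtype label: {label!r}")


def canonical_subgroup(name: str) -> str:
    """Normalize a clinical subgroup name (unicode minus accepted)."""
    cleaned = name.strip().replace("−", "-").replace("–", "-")
    if cleaned not in SUBGROUPS:
        raise ValidationError(f"unknown subgroup: {name!r}")
    return cleaned


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with declared scale/units/platform."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids
    scale: str
    units: str
    platform: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"bad scale: {self.scale!r}")
        if self.units not in UNITS:
            raise ValidationError(f"bad units: {self.units!r}")
        if self.platform not in PLATFORM_TABLE and self.platform != DERIVED_PLATFORM:
            raise ValidationError(f"bad platform: {self.platform!r}")
        if self.platform == "rnaseq_counts" and (
            self.units != "counts" or self.scale != "linear"
        ):
            raise ValidationError(
                "platform=rnaseq_counts requires units=counts, scale=linear"
            )
        idx = self.data.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        cols = self.data.columns
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must all be finite")
        if self.units == "counts" and self.scale == "linear":
            if (values < 0).any():
                raise ValidationError("negative values not allowed for counts")
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integral")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def replace_data(self, data: pd.DataFrame, *, scale: Optional[str] = None,
                     units: Optional[str] = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            data=data,
            scale=scale if scale is not None else self.scale,
            units=units if units is not None else self.units,
            platform=self.platform,
        )


@dataclass
class GeneLengths:
    """Per-gene transcript lengths in base pairs."""

    lengths: pd.Series  # index gene id -> positive int length

    def __post_init__(self) -> None:
        if self.lengths.index.has_duplicates:
            raise ValidationError("duplicate gene ids in gene lengths")
        vals = self.lengths.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals <= 0).any():
            raise ValidationError("gene lengths must be positive")

    def for_genes(self, gene_ids: Sequence[str]) -> pd.Series:
        missing = [g for g in gene_ids if g not in self.lengths.index]
        if missing:
            raise ValidationError(f"missing gene lengths for: {missing[:10]}")
        return self.lengths.loc[list(gene_ids)]


@dataclass
class ClinicalTable:
    """Per-sample ER/PR/HER2 status plus the explicit triple-negative flag.

    The TN flag is only accepted when ER, PR and HER2 are all negative; a
    declared-TN sample with any positive (or unknown) marker is rejected at
    construction time.
    """

    table: pd.DataFrame  # index sample id; columns er, pr, her2, tn

    def __post_init__(self) -> None:
        required = {"er", "pr", "her2", "tn"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        for col in ("er", "pr", "her2"):
            bad = set(self.table[col]) - set(STATUSES)
            if bad:
                raise ValidationError(f"bad {col} status values: {sorted(bad)}")
        tn_rows = self.table[self.table["tn"].astype(bool)]
        bad_tn = tn_rows[
            (tn_rows["er"] != "neg")
            | (tn_rows["pr"] != "neg")
            | (tn_rows["her2"] != "neg")
        ]
        if len(bad_tn):
            raise ValidationError(
                "declared TN samples must be ER-/PR-/HER2-: "
                f"{list(bad_tn.index)[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples absent from clinical table: {missing[:10]}")
        return ClinicalTable(self.table.loc[list(sample_ids)].copy())

    def er_status(self) -> pd.Series:
        return self.table["er"]

    def all_tn_declared(self) -> bool:
        return bool(self.table["tn"].astype(bool).all())


@dataclass
class CentroidModel:
    """Per-subtype centroid profiles for nearest-centroid classification."""

    centroids: pd.DataFrame  # index gene id, columns = subtype labels
    correlation_kind: str = "spearman"
    min_gene_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.correlation_kind not in ("spearman", "pearson"):
            raise ValidationError(f"bad correlation kind: {self.correlation_kind!r}")
        if not 0 < self.min_gene_fraction <= 1:
            raise ValidationError("min_gene_fraction must be in (0, 1]")
        labels = [canonical_subtype(c) for c in self.centroids.columns]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate subtype columns in centroid model")
        if set(labels) - set(SUBTYPES):
            raise ValidationError("centroid columns outside the subtype canon")
        self.centroids = self.centroids.copy()
        self.centroids.columns = labels
        if self.centroids.index.has_duplicates:
            raise ValidationError("duplicate genes in centroid model")
        if not np.all(np.isfinite(self.centroids.to_numpy(dtype=float))):
            raise ValidationError("centroid values must be finite")

    @property
    def subtype_order(self) -> tuple[str, ...]:
        return tuple(self.centroids.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.centroids.index)


@dataclass
class QuantileTable:
    """Gene- and subgroup-specific quantile probabilities for centering."""

    table: pd.DataFrame  # columns gene_id, subgroup, quantile_prob

    def __post_init__(self) -> None:
        required = {"gene_id", "subgroup", "quantile_prob"}
        if set(self.table.columns) != required:
            raise ValidationError(
                f"quantile table needs columns {sorted(required)}"
            )
        self.table = self.table.copy()
        self.table["subgroup"] = [
            canonical_subgroup(s) for s in self.table["subgroup"]
        ]
        probs = self.table["quantile_prob"].to_numpy(dtype=float)
        if ((probs <= 0) | (probs >= 1)).any() or not np.all(np.isfinite(probs)):
            raise ValidationError("quantile_prob must lie strictly in (0, 1)")
        if self.table.duplicated(["gene_id", "subgroup"]).any():
            raise ValidationError("duplicate (gene, subgroup) pairs")

    def subgroups(self) -> set[str]:
        return set(self.table["subgroup"])

    def probs_for(self, subgroup: str) -> pd.Series:
        subgroup = canonical_subgroup(subgroup)
        sub = self.table[self.table["subgroup"] == subgroup]
        if sub.empty:
            raise ValidationError(f"subgroup {subgroup!r} absent from quantile table")
        return sub.set_index("gene_id")["quantile_prob"]


@dataclass
class RuleSet:
    """Gene-pair rules with per-subtype class-conditional probabilities.

    A rule ``(gene_a, gene_b)`` is *true* on a sample when the linear-scale
    expression of ``gene_a`` is strictly less than that of ``gene_b``.
    """

    rules: list[tuple[str, str]]
    probs: pd.DataFrame  # rows align with rules, columns = subtype labels
    priors: Optional[pd.Series] = None  # per-subtype; default uniform
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValidationError("empty rule set")
        for a, b in self.rules:
            if a == b:
                raise ValidationError(f"rule with identical genes: {a!r}")
        labels = [canonical_subtype(c) for c in self.probs.columns]
        self.probs = self.probs.copy()
        self.probs.columns = labels
        if len(self.probs) != len(self.rules):
            raise ValidationError("probability rows must align with rules")
        vals = self.probs.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or ((vals <= 0) | (vals >= 1)).any():
            raise ValidationError(
                "class-conditional probabilities must lie strictly in (0, 1); "
                "clip at load time"
            )
        if self.priors is None:
            self.priors = pd.Series(1.0 / len(labels), index=labels)
        else:
            self.priors = self.priors.reindex(labels)
            if self.priors.isna().any():
                raise ValidationError("priors must cover every subtype column")
            total = float(self.priors.sum())
            if total <= 0:
                raise ValidationError("priors must be positive")
            self.priors = self.priors / total

    @property
    def subtype_order(self) -> tuple[str, ...]:
        return tuple(self.probs.columns)


@dataclass
class MethodDescriptor:
    """One entry of the method registry."""

    name: str
    family: str  # "NC" | "SSP"
    centering_strategy: Optional[str] = None
    correlation_kind: Optional[str] = None
    model_ref: str = "centroid"
    assumption_tags: frozenset[str] = frozenset()
    gates: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("NC", "SSP"):
            raise ValidationError(f"bad family: {self.family!r}")
        if self.family == "SSP":
            if self.centering_strategy is not None:
                raise ValidationError("SSP methods carry no centering strategy")
            if self.gates:
                raise ValidationError("SSP methods carry no gates (always eligible)")
        self.assumption_tags = frozenset(self.assumption_tags)
        self.gates = dict(self.gates)


@dataclass
class SubtypeCall:
    """One sample's call from one method."""

    sample_id: str
    label: Optional[str]  # None encodes NA
    scores: dict[str, float]
    method: str
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label is not None and self.scores:
            top = max(self.scores.values())
            if self.scores.get(self.label, -np.inf) < top - 1e-12:
                raise ValidationError("label must be an argmax of scores")


@dataclass
class AutoDecision:
    """Audited output of the AUTO method selector."""

    branch: str  # balanced | deviated | subtype_specific | tn
    cohort_type: str
    diagnostics: dict
    enabled: list[str]
    disabled: dict[str, str]  # method name -> reason code
    thresholds: dict
    ssbc_subgroup: Optional[str] = None
    ssbc2_subgroups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.enabled) & set(self.disabled)
        if overlap:
            raise ValidationError(f"methods both enabled and disabled: {sorted(overlap)}")

    def partition(self) -> tuple[frozenset[str], frozenset[str]]:
        return frozenset(self.enabled), frozenset(self.disabled)


@dataclass
class CallMatrix:
    """Samples x methods table of subtype labels (NA allowed, stored as NaN)."""

    labels: pd.DataFrame  # index sample id, columns method names

    def __post_init__(self) -> None:
        if self.labels.columns.has_duplicates:
            raise ValidationError("duplicate method columns")
        seen = set(self.labels.to_numpy().ravel().tolist())
        bad = {
            v for v in seen
            if not (v is None or (isinstance(v, float) and np.isnan(v)))
            and v not in SUBTYPES
        }
        if bad:
            raise ValidationError(f"labels outside the subtype canon: {sorted(map(str, bad))[:5]}")

    @property
    def methods(self) -> list[str]:
        return list(self.labels.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)
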