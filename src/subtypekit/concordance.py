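"""Multi-method execution and agreement statistics.

Runs every enabled classifier through its own normalization route, collects
the per-sample labels into a call matrix, and summarizes agreement with
per-sample Shannon entropy (bits), pairwise unweighted Cohen's kappa and
optional accuracy against a reference column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import nc, ssp
from .preprocess import prepare_matrix
from .types import (
    AutoDecision,
    CallMatrix,
    CentroidModel,
    ClinicalTable,
    ExpressionMatrix,
    GeneLengths,
    MethodDescriptor,
    QuantileTable,
    RuleSet,
    ValidationError,
)
from .registry import get_method

logger = logging.getLogger("subtypekit")


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def shannon_entropy(labels: Sequence) -> float:
    """Entropy (bits) of the label distribution; NA labels are excluded.

    Returns NaN for an all-NA row.
    """
    usable = [v for v in labels if not _is_na(v)]
    if not usable:
        return float("nan")
    counts = pd.Series(usable).value_counts()
    p = counts.to_numpy(dtype=float) / len(usable)
    return float(-(p * np.log2(p)).sum())


def _usable_pairs(a: Sequence, b: Sequence) -> tuple[list, list, int]:
    if len(a) != len(b):
        raise ValidationError("label vectors must have equal length")
    xs, ys, dropped = [], [], 0
    for x, y in zip(a, b):
        if _is_na(x) or _is_na(y):
            dropped += 1
            continue
        xs.append(x)
        ys.append(y)
    return xs, ys, dropped


def cohens_kappa(a: Sequence, b: Sequence) -> float:
    """Unweighted Cohen's kappa; NA pairs are deleted pairwise.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from marginal label
    frequencies. When p_e = 1 (single shared label in both vectors), kappa
    is defined as 1 if the vectors agree everywhere, else 0.
    """
    xs, ys, _ = _usable_pairs(a, b)
    n = len(xs)
    if n < 2:
        raise ValidationError("need at least 2 usable label pairs for kappa")
    labels = sorted(set(xs) | set(ys))
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(xs, ys):
        table[index[x], index[y]] += 1
    p = table / n
    p_o = float(np.trace(p))
    p_e = float(p.sum(axis=1) @ p.sum(axis=0))
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def accuracy(a: Sequence, ref: Sequence) -> float:
    """Percent agreement over usable (non-NA) pairs."""
    xs, ys, _ = _usable_pairs(a, ref)
    if len(xs) < 2:
        raise ValidationError("need at least 2 usable label pairs for accuracy")
    matches = sum(x == y for x, y in zip(xs, ys))
    return 100.0 * matches / len(xs)


@dataclass
class ConcordanceReport:
    """Entropy / kappa summary of a call matrix."""

    entropy: pd.Series  # per sample, bits (NaN for all-NA rows)
    mean_entropy: float
    kappa: pd.DataFrame  # methods x methods
    accuracy_vs_reference: Optional[dict[str, float]] = None
    na_counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "entropy": {k: (None if math.isnan(v) else v)
                        for k, v in self.entropy.items()},
            "mean_entropy": self.mean_entropy,
            "kappa": {
                m: {n: (None if math.isnan(v) else v)
                    for n, v in row.items()}
                for m, row in self.kappa.to_dict(orient="index").items()
            },
            "na_counts": self.na_counts,
        }
        if self.accuracy_vs_reference is not None:
            out["accuracy_vs_reference"] = self.accuracy_vs_reference
        return out


def concordance_report(
    calls: CallMatrix, reference: Optional[Sequence] = None
) -> ConcordanceReport:
    labels = calls.labels
    entropy = labels.apply(lambda row: shannon_entropy(list(row)), axis=1)
    finite = entropy.dropna()
    mean_entropy = float(finite.mean()) if len(finite) else float("nan")
    methods = calls.methods
    kappa = pd.DataFrame(np.nan, index=methods, columns=methods, dtype=float)
    for i, m in enumerate(methods):
        kappa.loc[m, m] = 1.0
        for n_ in methods[i + 1:]:
            try:
                value = cohens_kappa(labels[m], labels[n_])
            except ValidationError:
                value = float("nan")
            kappa.loc[m, n_] = value
            kappa.loc[n_, m] = value
    acc = None
    if reference is not None:
        acc = {}
        for m in methods:
            try:
                acc[m] = accuracy(labels[m], reference)
            except ValidationError:
                acc[m] = float("nan")
    na_counts = {m: int(labels[m].isna().sum()) for m in methods}
    return ConcordanceReport(
        entropy=entropy,
        mean_entropy=mean_entropy,
        kappa=kappa,
        accuracy_vs_reference=acc,
        na_counts=na_counts,
    )


# ---------------------------------------------------------------------------
# multi-method execution
# ---------------------------------------------------------------------------

def _subgroup_mask(clinical: ClinicalTable, subgroup: str) -> pd.Series:
    table = clinical.table
    if subgroup == "TN":
        return table["tn"].astype(bool)
    if subgroup == "ER+":
        return table["er"] == "pos"
    if subgroup == "ER-":
        return table["er"] == "neg"
    er_side, her2_side = subgroup.split("/")
    er_want = "pos" if er_side == "ER+" else "neg"
    her2_want = "pos" if her2_side == "HER2+" else "neg"
    return (table["er"] == er_want) & (table["her2"] == her2_want)


def _models_for(method: str, models: Mapping) -> Mapping:
    per_method = models.get(method)
    if isinstance(per_method, Mapping):
        return per_method
    return models


def run_method(
    descriptor: MethodDescriptor,
    expr: ExpressionMatrix,
    clinical: Optional[ClinicalTable],
    models: Mapping,
    decision: Optional[AutoDecision] = None,
    lengths: Optional[GeneLengths] = None,
    seed: int = 0,
) -> pd.Series:
    """Execute one registry method end to end; returns per-sample labels."""
    bundle = _models_for(descriptor.name, models)
    prepared = prepare_matrix(expr, descriptor.family, lengths=lengths)
    if descriptor.family == "SSP":
        rules = bundle.get("ruleset")
        if not isinstance(rules, RuleSet):
            raise ValidationError(f"{descriptor.name}: ruleset model missing")
        calls = ssp.classify_ssp(prepared, rules)
        return pd.Series({c.sample_id: c.label for c in calls},
                         index=prepared.sample_ids, dtype=object)

    model = bundle.get("centroid")
    if not isinstance(model, CentroidModel):
        raise ValidationError(f"{descriptor.name}: centroid model missing")
    if descriptor.correlation_kind and (
        descriptor.correlation_kind != model.correlation_kind
    ):
        model = CentroidModel(
            centroids=model.centroids,
            correlation_kind=descriptor.correlation_kind,
            min_gene_fraction=model.min_gene_fraction,
        )
    strategy = descriptor.centering_strategy or "median"
    if strategy == "ssbc_quantile":
        quantiles = bundle.get("quantile")
        if not isinstance(quantiles, QuantileTable):
            raise ValidationError(f"{descriptor.name}: quantile table missing")
        if clinical is None or decision is None:
            raise ValidationError(
                f"{descriptor.name}: subgroup centering needs clinical data "
                "and an AUTO decision"
            )
        if descriptor.name == "ssBC.v2":
            subgroups = decision.ssbc2_subgroups
        else:
            subgroups = [decision.ssbc_subgroup] if decision.ssbc_subgroup else []
        if not subgroups:
            raise ValidationError(
                f"{descriptor.name}: no eligible subgroup in the decision"
            )
        labels = pd.Series(np.nan, index=prepared.sample_ids, dtype=object)
        clin = clinical.subset(prepared.sample_ids)
        for subgroup in subgroups:
            mask = _subgroup_mask(clin, subgroup)
            members = [s for s, ok in mask.items() if ok]
            if not members:
                continue
            sub_expr = ExpressionMatrix(
                data=prepared.data[members],
                scale=prepared.scale,
                units=prepared.units,
                platform=prepared.platform,
            )
            spec = nc.CenteringSpec(
                strategy="ssbc_quantile", quantiles=quantiles,
                subgroup=subgroup, seed=seed,
            )
            centered, _ = nc.apply_centering(sub_expr, clin, spec, model)
            for call in nc.classify_nc(centered, model):
                labels[call.sample_id] = call.label
        return labels

    spec = nc.CenteringSpec(strategy=strategy, seed=seed)
    centered, _ = nc.apply_centering(prepared, clinical, spec, model)
    calls = nc.classify_nc(centered, model)
    return pd.Series({c.sample_id: c.label for c in calls},
                     index=prepared.sample_ids, dtype=object)


def run_multi(
    expr: ExpressionMatrix,
    clinical: Optional[ClinicalTable],
    decision: AutoDecision,
    models: Mapping,
    registry: list[MethodDescriptor],
    lengths: Optional[GeneLengths] = None,
    seed: int = 0,
) -> tuple[CallMatrix, dict[str, str]]:
    """Execute every enabled method; a single method's failure degrades to
    an all-NA column with a logged reason instead of aborting the run."""
    if not decision.enabled:
        raise ValidationError("AUTO decision enables zero methods")
    columns: dict[str, pd.Series] = {}
    failures: dict[str, str] = {}
    for name in decision.enabled:
        descriptor = get_method(registry, name)
        try:
            columns[name] = run_method(
                descriptor, expr, clinical, models,
                decision=decision, lengths=lengths, seed=seed,
            )
        except Exception as exc:  # degradation contract: NA column, not abort
            logger.warning("method %s failed: %s", name, exc)
            failures[name] = str(exc)
            columns[name] = pd.Series(
                np.nan, index=expr.sample_ids, dtype=object
            )
    frame = pd.DataFrame(columns)[list(decision.enabled)]
    frame.index.name = "sample_id"
    return CallMatrix(frame), failures
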