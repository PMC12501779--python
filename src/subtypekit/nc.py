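"""Nearest-centroid classification and its family of centering strategies.

The centering step is what differentiates the eight NC registry methods:
cohort-median subtraction, robust 5%/95% rescaling, ER-proportion-balanced
subcohort medians (optionally iterated or PCA-guided), and subgroup-specific
quantile subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import (
    CentroidModel,
    ClinicalTable,
    ExpressionMatrix,
    QuantileTable,
    SubtypeCall,
    ValidationError,
)

#: ER+ fraction of the reference training cohort (54 of 118 samples)
REFERENCE_ER_POS_PROPORTION = 54.0 / 118.0

CENTERING_STRATEGIES = (
    "median",
    "robust_scale",
    "cihc",
    "cihc_iterative",
    "pca_guided",
    "ssbc_quantile",
)


@dataclass
class CenteringSpec:
    """Parameters of a centering strategy."""

    strategy: str
    target_er_pos_proportion: float = REFERENCE_ER_POS_PROPORTION
    quantiles: Optional[QuantileTable] = None
    subgroup: Optional[str] = None
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in CENTERING_STRATEGIES:
            raise ValidationError(f"unknown centering strategy: {self.strategy!r}")
        if not 0 < self.target_er_pos_proportion < 1:
            raise ValidationError("target ER+ proportion must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValidationError("iteration cap must be >= 1")


def apply_centering(
    expr: ExpressionMatrix,
    clinical: Optional[ClinicalTable],
    spec: CenteringSpec,
    model: Optional[CentroidModel] = None,
) -> tuple[ExpressionMatrix, dict]:
    """Center a log2 expression matrix; returns (centered matrix, flags)."""
    if expr.scale != "log2":
        raise ValidationError("centering expects a log2-scale matrix")
    strategy = spec.strategy
    if strategy == "median":
        return _subtract(expr, expr.data.median(axis=1)), {}
    if strategy == "robust_scale":
        return _robust_scale(expr), {}
    if strategy == "ssbc_quantile":
        return _ssbc_quantile(expr, spec), {}
    if clinical is None:
        raise ValidationError(f"{strategy} centering requires clinical ER labels")
    er = clinical.subset(expr.sample_ids).er_status()
    if strategy == "cihc":
        subcohort = _balanced_subcohort(
            er, spec.target_er_pos_proportion, np.random.default_rng(spec.seed)
        )
        medians = expr.data[subcohort].median(axis=1)
        return _subtract(expr, medians), {"subcohort_size": len(subcohort)}
    if strategy == "pca_guided":
        surrogate = _pca_er_surrogate(expr, er)
        subcohort = _balanced_subcohort(
            surrogate, spec.target_er_pos_proportion,
            np.random.default_rng(spec.seed),
        )
        medians = expr.data[subcohort].median(axis=1)
        return _subtract(expr, medians), {"subcohort_size": len(subcohort)}
    if strategy == "cihc_iterative":
        if model is None:
            raise ValidationError("iterative cIHC requires a centroid model")
        return _cihc_iterative(expr, er, spec, model)
    raise AssertionError("unreachable")


def _subtract(expr: ExpressionMatrix, per_gene: pd.Series) -> ExpressionMatrix:
    centered = expr.data.sub(per_gene, axis=0)
    return ExpressionMatrix(
        data=centered, scale="log2", units=expr.units, platform=expr.platform
    )


def _robust_scale(expr: ExpressionMatrix) -> ExpressionMatrix:
    q05 = expr.data.quantile(0.05, axis=1)
    q95 = expr.data.quantile(0.95, axis=1)
    span = (q95 - q05).replace(0.0, np.nan)
    scaled = expr.data.sub(q05, axis=0).div(span, axis=0).fillna(0.0) - 0.5
    return ExpressionMatrix(
        data=scaled, scale="log2", units=expr.units, platform=expr.platform
    )


def _ssbc_quantile(expr: ExpressionMatrix, spec: CenteringSpec) -> ExpressionMatrix:
    if spec.quantiles is None or spec.subgroup is None:
        raise ValidationError("ssbc_quantile requires a quantile table and subgroup")
    probs = spec.quantiles.probs_for(spec.subgroup)
    offsets = pd.Series(index=expr.data.index, dtype=float)
    for gene in expr.data.index:
        p = probs.get(gene, 0.5)  # genes missing from the table fall back to median
        offsets[gene] = float(np.quantile(expr.data.loc[gene].to_numpy(), p))
    return _subtract(expr, offsets)


def _balanced_subcohort(
    er: pd.Series, target: float, rng: np.random.Generator
) -> list[str]:
    """Keep one ER group whole and subsample the other (without replacement)
    so the subcohort ER+ fraction matches the target as closely as possible."""
    pos = sorted(er.index[er == "pos"])
    neg = sorted(er.index[er == "neg"])
    if not pos or not neg:
        raise ValidationError(
            "ER-balanced subcohort unattainable: need both ER+ and ER- samples "
            f"(have {len(pos)} ER+, {len(neg)} ER-)"
        )
    frac = len(pos) / (len(pos) + len(neg))
    if frac > target:
        n_keep = max(1, round(target * len(neg) / (1.0 - target)))
        n_keep = min(n_keep, len(pos))
        kept_pos = list(rng.choice(pos, size=n_keep, replace=False))
        kept_neg = neg
    else:
        n_keep = max(1, round((1.0 - target) * len(pos) / target))
        n_keep = min(n_keep, len(neg))
        kept_pos = pos
        kept_neg = list(rng.choice(neg, size=n_keep, replace=False))
    return sorted(kept_pos + kept_neg)


def _pca_er_surrogate(expr: ExpressionMatrix, er: pd.Series) -> pd.Series:
    """ER labels inferred from the first principal component of expression.

    The PC is sign-oriented to correlate positively with available IHC ER
    labels; with no informative labels the orientation falls back to a
    positive loading on the highest-variance gene.
    """
    mat = expr.data.to_numpy(dtype=float)
    centered = mat - mat.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    scores = vt[0]  # per-sample PC1 scores
    ihc = er.map({"pos": 1.0, "neg": -1.0}).astype(float)
    known = ihc.notna().to_numpy()
    orientation = 0.0
    if known.sum() >= 2 and np.std(scores[known]) > 0 and np.std(ihc[known]) > 0:
        orientation = float(np.corrcoef(scores[known], ihc[known].to_numpy())[0, 1])
    if orientation == 0.0 or np.isnan(orientation):
        # fall back: orient so the highest-variance gene loads positively
        top_gene = int(np.argmax(centered.var(axis=1)))
        loadings = centered @ scores
        orientation = 1.0 if loadings[top_gene] >= 0 else -1.0
    scores = scores * np.sign(orientation)
    labels = np.where(scores > 0, "pos", "neg")
    return pd.Series(labels, index=expr.data.columns)


def _cihc_iterative(
    expr: ExpressionMatrix,
    er: pd.Series,
    spec: CenteringSpec,
    model: CentroidModel,
) -> tuple[ExpressionMatrix, dict]:
    """Iterate {balanced centering -> classification -> ER-surrogate redraw}
    until the label vector stabilizes or the iteration cap is reached."""
    rng = np.random.default_rng(spec.seed)
    current_er = er.copy()
    prev_labels: Optional[list] = None
    centered = None
    iterations = 0
    for iterations in range(1, spec.max_iterations + 1):
        subcohort = _balanced_subcohort(
            current_er, spec.target_er_pos_proportion, rng
        )
        medians = expr.data[subcohort].median(axis=1)
        centered = _subtract(expr, medians)
        calls = classify_nc(centered, model)
        labels = [c.label for c in calls]
        if labels == prev_labels:
            break
        prev_labels = labels
        # luminal calls act as ER+, Basal/Her2 as ER-; Normal keeps IHC status
        surrogate = {}
        for call in calls:
            if call.label in ("LumA", "LumB"):
                surrogate[call.sample_id] = "pos"
            elif call.label in ("Basal", "Her2"):
                surrogate[call.sample_id] = "neg"
            else:
                surrogate[call.sample_id] = er[call.sample_id]
        current_er = pd.Series(surrogate).reindex(er.index)
    assert centered is not None
    return centered, {"iterations": iterations}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _correlation(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    if kind == "spearman":
        x = rankdata(x)
        y = rankdata(y)
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt((sx * sx).sum() * (sy * sy).sum())
    if denom == 0:
        return 0.0
    return float((sx * sy).sum() / denom)


def classify_nc(
    centered: ExpressionMatrix, model: CentroidModel
) -> list[SubtypeCall]:
    """Correlate each sample's centered profile with every centroid.

    The label is the argmax over subtypes; exact ties break by the model's
    subtype order with a tie flag, and a low-coverage flag is set when the
    gene overlap is below 100% of model genes (but at or above
    ``min_gene_fraction``).
    """
    model_genes = model.gene_ids
    shared = [g for g in model_genes if g in centered.data.index]
    overlap = len(shared) / len(model_genes)
    if overlap < model.min_gene_fraction:
        missing = [g for g in model_genes if g not in centered.data.index]
        raise ValidationError(
            f"gene overlap {overlap:.2f} below minimum "
            f"{model.min_gene_fraction:.2f}; missing genes: {missing[:10]}"
        )
    low_coverage = overlap < 1.0
    centroid_mat = model.centroids.loc[shared].to_numpy(dtype=float)
    subtype_order = model.subtype_order
    sample_mat = centered.data.loc[shared].to_numpy(dtype=float)
    if model.correlation_kind == "spearman":
        sample_mat = np.apply_along_axis(rankdata, 0, sample_mat)
        centroid_mat = np.apply_along_axis(rankdata, 0, centroid_mat)
    sx = sample_mat - sample_mat.mean(axis=0, keepdims=True)
    sy = centroid_mat - centroid_mat.mean(axis=0, keepdims=True)
    norm_x = np.sqrt((sx * sx).sum(axis=0))
    norm_y = np.sqrt((sy * sy).sum(axis=0))
    denom = norm_x[:, np.newaxis] * norm_y[np.newaxis, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (sx.T @ sy) / np.where(denom > 0, denom, 1.0), 0.0)
    calls = []
    for j, sample in enumerate(centered.sample_ids):
        scores = {k: float(corr[j, i]) for i, k in enumerate(subtype_order)}
        best = max(scores.values())
        winners = [k for k in subtype_order if scores[k] == best]
        flags: dict = {}
        if len(winners) > 1:
            flags["tie_broken"] = True
        if low_coverage:
            flags["low_gene_coverage"] = True
        calls.append(
            SubtypeCall(
                sample_id=sample,
                label=winners[0],
                scores=scores,
                method="nc",
                flags=flags,
            )
        )
    return calls
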