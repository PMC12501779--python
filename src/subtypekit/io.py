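"""Readers and writers for every on-disk format the tool touches.

All files are UTF-8, tab-delimited, with "." as the decimal separator.
Expression matrices are genes-in-rows, samples-in-columns (use
``transpose=True`` for the other orientation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import (
    AutoDecision,
    CallMatrix,
    CentroidModel,
    ClinicalTable,
    ExpressionMatrix,
    GeneLengths,
    QuantileTable,
    RuleSet,
    PLATFORM_TABLE,
    SUBTYPES,
    ValidationError,
    canonical_subtype,
)

logger = logging.getLogger("subtypekit")

PathLike = Union[str, Path]

#: accepted biomarker synonyms (case-insensitive); anything else -> unknown
_POS_SYNONYMS = {"pos", "positive", "1", "+"}
_NEG_SYNONYMS = {"neg", "negative", "0", "-", "−"}
_TRUE_SYNONYMS = {"true", "t", "1", "yes", "y"}
_FALSE_SYNONYMS = {"false", "f", "0", "no", "n", ""}


def _normalize_status(raw) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    token = str(raw).strip().lower()
    if token in _POS_SYNONYMS:
        return "pos"
    if token in _NEG_SYNONYMS:
        return "neg"
    return "unknown"


def _normalize_bool(raw) -> bool:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return False
    token = str(raw).strip().lower()
    if token in _TRUE_SYNONYMS:
        return True
    if token in _FALSE_SYNONYMS:
        return False
    raise ValidationError(f"cannot parse boolean flag: {raw!r}")


# ---------------------------------------------------------------------------
# expression / clinical / lengths / annotation
# ---------------------------------------------------------------------------

def read_expression(path: PathLike, platform: str,
                    transpose: bool = False) -> ExpressionMatrix:
    """Parse an expression TSV; scale and units are inferred from *platform*."""
    if platform not in PLATFORM_TABLE:
        raise ValidationError(f"unknown platform tag: {platform!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"non-numeric expression cell at gene {row!r}, sample {col!r}"
            )
        numeric[col] = converted
    scale, units = PLATFORM_TABLE[platform]
    return ExpressionMatrix(data=numeric, scale=scale, units=units,
                            platform=platform)


def write_expression(expr: ExpressionMatrix, path: PathLike) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.12g")


def read_clinical(path: PathLike) -> ClinicalTable:
    """Parse a clinical biomarker TSV (sample_id, er, pr, her2, optional tn)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    required = ["sample_id", "er", "pr", "her2"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValidationError(f"clinical TSV missing columns: {missing}")
    extra = set(cols) - set(required) - {"tn"}
    if extra:
        warnings.warn(f"ignoring unknown clinical columns: {sorted(extra)}")
    out = pd.DataFrame(index=pd.Index(df[cols["sample_id"]].astype(str),
                                      name="sample_id"))
    for marker in ("er", "pr", "her2"):
        out[marker] = [_normalize_status(v) for v in df[cols[marker]]]
    if "tn" in cols:
        out["tn"] = [_normalize_bool(v) for v in df[cols["tn"]]]
    else:
        out["tn"] = False
    return ClinicalTable(out)


def write_clinical(clinical: ClinicalTable, path: PathLike) -> None:
    df = clinical.table.copy()
    df["tn"] = df["tn"].astype(bool).map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_lengths(path: PathLike) -> GeneLengths:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError("gene lengths TSV needs gene_id and length columns")
    series = pd.Series(
        pd.to_numeric(df.iloc[:, 1]).to_numpy(),
        index=pd.Index(df.iloc[:, 0].astype(str), name="gene_id"),
        name="length",
    )
    return GeneLengths(series)


def write_gene_lengths(lengths: GeneLengths, path: PathLike) -> None:
    lengths.lengths.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: PathLike) -> pd.Series:
    """Probe -> Entrez annotation table; rows lacking an Entrez id are kept
    as NA so the mapper can report them as unmapped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("annotation TSV needs probe and entrez columns")
    return pd.Series(df.iloc[:, 1].to_numpy(),
                     index=pd.Index(df.iloc[:, 0].astype(str), name="probe"))


# ---------------------------------------------------------------------------
# classifier model files
# ---------------------------------------------------------------------------

def read_model(path: PathLike, kind: str):
    """Load a classifier model file.

    kind: ``centroid`` | ``quantile`` | ``ruleset``.
    """
    if kind == "centroid":
        return read_centroids(path)
    if kind == "quantile":
        return read_quantiles(path)
    if kind == "ruleset":
        return read_ruleset(path)
    raise ValidationError(f"unknown model kind: {kind!r}")


def read_centroids(path: PathLike, correlation_kind: Optional[str] = None,
                   min_gene_fraction: Optional[float] = None) -> CentroidModel:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    kwargs = {}
    kind = correlation_kind or meta.get("correlation")
    if kind:
        kwargs["correlation_kind"] = kind
    frac = min_gene_fraction or meta.get("min_gene_fraction")
    if frac:
        kwargs["min_gene_fraction"] = float(frac)
    return CentroidModel(centroids=df.astype(float), **kwargs)


def write_centroids(model: CentroidModel, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#correlation={model.correlation_kind}\n")
        fh.write(f"#min_gene_fraction={model.min_gene_fraction:.12g}\n")
        model.centroids.to_csv(fh, sep="\t", index_label="gene_id",
                               float_format="%.17g")


def read_quantiles(path: PathLike) -> QuantileTable:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"gene_id": str, "subgroup": str})
    return QuantileTable(df[["gene_id", "subgroup", "quantile_prob"]])


def write_quantiles(qt: QuantileTable, path: PathLike) -> None:
    qt.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ruleset(path: PathLike, epsilon: float = 1e-6) -> RuleSet:
    """Load a gene-pair rule model.

    Probabilities outside ``[epsilon, 1 - epsilon]`` are clipped with a
    warning; the epsilon actually applied is recorded on the object.
    ``#prior=LumA:0.2,...`` and ``#epsilon=...`` header lines are honoured.
    """
    meta = _read_meta(path)
    if "epsilon" in meta:
        epsilon = float(meta["epsilon"])
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"gene_a": str, "gene_b": str})
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValidationError("ruleset TSV needs gene_a and gene_b columns")
    prob_cols = [c for c in df.columns if c not in ("gene_a", "gene_b")]
    if not prob_cols:
        raise ValidationError("ruleset TSV carries no subtype probability columns")
    probs = df[prob_cols].astype(float)
    raw = probs.to_numpy()
    if not np.all(np.isfinite(raw)) or ((raw < 0) | (raw > 1)).any():
        raise ValidationError("rule probabilities must lie within [0, 1]")
    clipped = np.clip(raw, epsilon, 1.0 - epsilon)
    if not np.array_equal(raw, clipped):
        warnings.warn(
            f"rule probabilities clipped into [{epsilon}, {1 - epsilon}]"
        )
    probs = pd.DataFrame(clipped, columns=prob_cols)
    priors = None
    if "prior" in meta:
        entries = dict(
            item.split(":") for item in meta["prior"].split(",") if item
        )
        priors = pd.Series({canonical_subtype(k): float(v)
                            for k, v in entries.items()})
    rules = list(zip(df["gene_a"], df["gene_b"]))
    return RuleSet(rules=rules, probs=probs, priors=priors, epsilon=epsilon)


def write_ruleset(rules: RuleSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#epsilon={rules.epsilon:.12g}\n")
        prior = ",".join(f"{k}:{v:.17g}" for k, v in rules.priors.items())
        fh.write(f"#prior={prior}\n")
        df = pd.DataFrame(rules.rules, columns=["gene_a", "gene_b"])
        for col in rules.probs.columns:
            df[col] = rules.probs[col].to_numpy()
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def _read_meta(path: PathLike) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


# ---------------------------------------------------------------------------
# calls / decisions
# ---------------------------------------------------------------------------

def read_call_matrix(path: PathLike) -> CallMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df = df.where(df.notna() & (df != "NA"), np.nan)
    return CallMatrix(df)


def write_call_matrix(calls: CallMatrix, path: PathLike) -> None:
    calls.labels.fillna("NA").to_csv(path, sep="\t", index_label="sample_id")


def write_decision(decision: AutoDecision, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(decision), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_decision(path: PathLike) -> AutoDecision:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return AutoDecision(**payload)
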