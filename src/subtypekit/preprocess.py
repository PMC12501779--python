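"""Probe-to-gene mapping and method-family-specific normalization.

Raw RNA-seq counts are routed to log2 upper-quartile CPM for the
nearest-centroid family and to unscaled linear FPKM for the single-sample
predictor family; pre-normalized log2 inputs pass through unchanged for NC
and are back-transformed (2**x) for SSP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import DERIVED_PLATFORM, ExpressionMatrix, GeneLengths, ValidationError


@dataclass
class MappingReport:
    """Bookkeeping of the Entrez mapping step.

    Invariant: n_input_probes = n_mapped_genes + dropped + discarded
    duplicates.
    """

    n_input_probes: int
    n_mapped_genes: int
    dropped_unmapped: list[str]
    duplicates_collapsed: list[tuple[str, str, list[str]]]  # (gene, kept, discarded)
    missing_model_genes: list[str] = field(default_factory=list)

    def check(self) -> None:
        discarded = sum(len(d) for _, _, d in self.duplicates_collapsed)
        if self.n_input_probes != (
            self.n_mapped_genes + len(self.dropped_unmapped) + discarded
        ):
            raise ValidationError("mapping report counts do not balance")


def map_to_entrez(
    expr: ExpressionMatrix,
    annotation: pd.Series,
    required_genes: Optional[Sequence[str]] = None,
) -> tuple[ExpressionMatrix, MappingReport]:
    """Relabel a probe-keyed matrix by Entrez gene id.

    Probes without an annotation entry are dropped and reported. When
    several probes map to the same gene, the probe with the largest
    interquartile range across samples is kept (ties broken by larger mean,
    then lexicographically smallest probe id).
    """
    probes = list(expr.data.index)
    mapped = annotation.reindex(probes)
    has_gene = mapped.notna() & (mapped.astype(str).str.strip() != "")
    if not has_gene.any():
        raise ValidationError("no input probe has an Entrez annotation")
    dropped = [p for p, ok in zip(probes, has_gene) if not ok]

    kept_probe_for_gene: dict[str, str] = {}
    duplicates: list[tuple[str, str, list[str]]] = []
    by_gene: dict[str, list[str]] = {}
    for probe in probes:
        if not has_gene[probe]:
            continue
        by_gene.setdefault(str(mapped[probe]).strip(), []).append(probe)

    values = expr.data
    for gene, gene_probes in by_gene.items():
        if len(gene_probes) == 1:
            kept_probe_for_gene[gene] = gene_probes[0]
            continue
        q75 = values.loc[gene_probes].quantile(0.75, axis=1)
        q25 = values.loc[gene_probes].quantile(0.25, axis=1)
        iqr = q75 - q25
        mean = values.loc[gene_probes].mean(axis=1)
        # max IQR, then max mean, then lexicographically smallest probe id
        ranked = sorted(
            gene_probes,
            key=lambda p: (-iqr[p], -mean[p], p),
        )
        kept = ranked[0]
        kept_probe_for_gene[gene] = kept
        duplicates.append((gene, kept, ranked[1:]))

    genes = sorted(kept_probe_for_gene)
    out = values.loc[[kept_probe_for_gene[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene_id")
    mapped_expr = ExpressionMatrix(
        data=out, scale=expr.scale, units=expr.units, platform=expr.platform
    )

    missing_model = []
    if required_genes is not None:
        missing_model = [g for g in required_genes if g not in kept_probe_for_gene]

    report = MappingReport(
        n_input_probes=len(probes),
        n_mapped_genes=len(genes),
        dropped_unmapped=dropped,
        duplicates_collapsed=duplicates,
        missing_model_genes=missing_model,
    )
    report.check()
    return mapped_expr, report


def upper_quartile_log2cpm(
    counts: ExpressionMatrix, offset: float = 1.0
) -> ExpressionMatrix:
    """Upper-quartile normalized log2 CPM.

    Per sample j: q_j is the 75th percentile of counts over genes with
    count > 0; the factor f_j = (q_j / L_j) rescaled to unit geometric mean
    across samples (L_j the raw library size); the effective library is
    E_j = L_j * f_j and output = log2(counts * 1e6 / E_j + offset).
    """
    if counts.units != "counts" or counts.scale != "linear":
        raise ValidationError("upper_quartile_log2cpm expects linear counts")
    mat = counts.data.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    zero_samples = [
        s for s, total in zip(counts.sample_ids, libsize) if total <= 0
    ]
    if zero_samples:
        raise ValidationError(f"all-zero sample(s): {zero_samples}")
    n_samples = mat.shape[1]
    uq = np.empty(n_samples)
    for j in range(n_samples):
        nonzero = mat[:, j][mat[:, j] > 0]
        uq[j] = np.percentile(nonzero, 75)  # linear interpolation
    ratio = uq / libsize
    factors = ratio / np.exp(np.mean(np.log(ratio)))
    effective = libsize * factors
    out = np.log2(mat * 1e6 / effective + offset)
    return ExpressionMatrix(
        data=pd.DataFrame(out, index=counts.data.index,
                          columns=counts.data.columns),
        scale="log2",
        units="cpm",
        platform=DERIVED_PLATFORM,
    )


def linear_fpkm(counts: ExpressionMatrix, lengths: GeneLengths) -> ExpressionMatrix:
    """FPKM_ij = counts_ij * 1e9 / (L_j * len_i); no cross-sample scaling."""
    if counts.units != "counts" or counts.scale != "linear":
        raise ValidationError("linear_fpkm expects linear counts")
    lens = lengths.for_genes(counts.gene_ids).to_numpy(dtype=float)
    mat = counts.data.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    zero_samples = [
        s for s, total in zip(counts.sample_ids, libsize) if total <= 0
    ]
    if zero_samples:
        raise ValidationError(f"all-zero sample(s): {zero_samples}")
    out = mat * 1e9 / (libsize[np.newaxis, :] * lens[:, np.newaxis])
    return ExpressionMatrix(
        data=pd.DataFrame(out, index=counts.data.index,
                          columns=counts.data.columns),
        scale="linear",
        units="fpkm",
        platform=DERIVED_PLATFORM,
    )


def prepare_matrix(
    expr: ExpressionMatrix,
    family: str,
    lengths: Optional[GeneLengths] = None,
    offset: float = 1.0,
) -> ExpressionMatrix:
    """Dispatch the platform-specific normalization route for a method family."""
    if family not in ("NC", "SSP"):
        raise ValidationError(f"unknown method family: {family!r}")
    platform = expr.platform
    if platform == "rnaseq_counts":
        if family == "NC":
            return upper_quartile_log2cpm(expr, offset=offset)
        if lengths is None:
            raise ValidationError(
                "SSP route for raw counts requires gene lengths"
            )
        return linear_fpkm(expr, lengths)
    # pre-normalized log2 inputs (log2-FPKM, microarray, nCounter)
    if family == "NC":
        return expr
    if expr.scale != "log2":
        if expr.scale == "linear":
            return expr  # already on the SSP scale
        raise ValidationError("SSP back-transform expects a log2 matrix")
    back = np.power(2.0, expr.data.to_numpy(dtype=float))
    units = "fpkm" if platform == "rnaseq_log2fpkm" else expr.units
    return ExpressionMatrix(
        data=pd.DataFrame(back, index=expr.data.index,
                          columns=expr.data.columns),
        scale="linear",
        units=units,
        platform=DERIVED_PLATFORM,
    )
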