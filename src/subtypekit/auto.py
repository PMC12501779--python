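"""Cohort-aware method selection (AUTO mode).

The selector inspects the ER/HER2 composition of the cohort and partitions
the method registry into enabled and disabled sets with machine-readable
reasons:

* unselected cohorts with an ER+ percentage at or beyond the deviation
  cutoffs (<= 39% or >= 69%) route to the ER-deviated branch;
* subtype-specific cohorts enable the quantile-based methods, subject to
  minimum subgroup-size gates (15 ER+ / 18 ER- or TN for ssBC; 8/8/9/9 per
  ER/HER2 subgroup for ssBC.v2);
* SSP methods are always enabled regardless of composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

from .types import (
    AutoDecision,
    ClinicalTable,
    ER_HER2_SUBGROUPS,
    MethodDescriptor,
    ValidationError,
)
from .registry import (
    CONVENTIONAL_TAG,
    ER_DEVIATED_TAG,
    SUBTYPE_SPECIFIC_TAG,
)

COHORT_TYPES = (
    "unselected",
    "ER+",
    "ER-",
    "ER+/HER2-",
    "HER2+",
    "ER-/HER2-",
    "TN",
)

#: reason codes for disabling a method
REASON_DEVIATED_ONLY = "requires ER-deviated cohort"
REASON_BALANCE_VIOLATED = "ER-balance assumption violated"
REASON_BROADER_DISTRIBUTION = "assumes broader subtype distribution"
REASON_SUBTYPE_ONLY = "requires subtype-specific cohort"
REASON_GATE = "subgroup below minimum size"


@dataclass(frozen=True)
class AutoThresholds:
    """Quantitative gates of the AUTO selector."""

    er_low_pct: float = 39.0
    er_high_pct: float = 69.0
    reference_er_pct: float = 100.0 * 54.0 / 118.0
    min_er_pos: int = 15
    min_er_neg_or_tn: int = 18
    min_ssbc2: Mapping[str, int] = field(
        default_factory=lambda: {
            "ER+/HER2-": 8,
            "ER+/HER2+": 8,
            "ER-/HER2+": 9,
            "ER-/HER2-": 9,
        }
    )

    def __post_init__(self) -> None:
        if not self.er_low_pct < self.reference_er_pct < self.er_high_pct:
            raise ValidationError(
                "cutoffs must bracket the reference ER+ percentage"
            )
        minima = [self.min_er_pos, self.min_er_neg_or_tn, *self.min_ssbc2.values()]
        if any(int(m) != m or m <= 0 for m in minima):
            raise ValidationError("subgroup minima must be positive integers")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["min_ssbc2"] = dict(self.min_ssbc2)
        return d


@dataclass
class CohortDiagnostics:
    """ER/HER2 composition summary used by the selector."""

    n_samples: int
    n_er_pos: int
    n_er_neg: int
    n_er_known: int
    er_pos_pct: Optional[float]  # over known-status samples; None if none known
    subgroup_counts: dict[str, int]  # ER/HER2 cross-tab, both statuses known
    n_tn_declared: int

    def as_dict(self) -> dict:
        return asdict(self)


def cohort_diagnostics(clinical: ClinicalTable) -> CohortDiagnostics:
    """ER+ percentage (unknowns excluded from the denominator), ER/HER2
    subgroup counts, and declared-TN count."""
    table = clinical.table
    er = table["er"]
    her2 = table["her2"]
    n_pos = int((er == "pos").sum())
    n_neg = int((er == "neg").sum())
    n_known = n_pos + n_neg
    pct = 100.0 * n_pos / n_known if n_known else None
    counts = {}
    for subgroup in ER_HER2_SUBGROUPS:
        er_side, her2_side = subgroup.split("/")
        er_want = "pos" if er_side == "ER+" else "neg"
        her2_want = "pos" if her2_side == "HER2+" else "neg"
        counts[subgroup] = int(((er == er_want) & (her2 == her2_want)).sum())
    n_tn = int(table["tn"].astype(bool).sum())
    diag = CohortDiagnostics(
        n_samples=len(table),
        n_er_pos=n_pos,
        n_er_neg=n_neg,
        n_er_known=n_known,
        er_pos_pct=pct,
        subgroup_counts=counts,
        n_tn_declared=n_tn,
    )
    if n_known == 0 and n_tn == 0:
        raise ValidationError(
            "no sample has a known ER status and no TN declaration is present"
        )
    return diag


def _ssbc_gate(
    diag: CohortDiagnostics, cohort_type: str, thresholds: AutoThresholds
) -> tuple[bool, Optional[str], str]:
    """(passes, quantile subgroup, detail) for the ssBC total-count gates."""
    if cohort_type in ("ER+", "ER+/HER2-"):
        ok = diag.n_er_pos >= thresholds.min_er_pos
        return ok, "ER+", f"ER+ n={diag.n_er_pos} (min {thresholds.min_er_pos})"
    if cohort_type in ("ER-", "ER-/HER2-"):
        ok = diag.n_er_neg >= thresholds.min_er_neg_or_tn
        return ok, "ER-", f"ER- n={diag.n_er_neg} (min {thresholds.min_er_neg_or_tn})"
    if cohort_type == "TN":
        ok = diag.n_tn_declared >= thresholds.min_er_neg_or_tn
        return ok, "TN", f"TN n={diag.n_tn_declared} (min {thresholds.min_er_neg_or_tn})"
    if cohort_type == "HER2+":
        # mixed-ER cohort: either ER side may satisfy its own gate
        if diag.n_er_pos >= thresholds.min_er_pos:
            return True, "ER+", f"ER+ n={diag.n_er_pos}"
        if diag.n_er_neg >= thresholds.min_er_neg_or_tn:
            return True, "ER-", f"ER- n={diag.n_er_neg}"
        return (
            False,
            None,
            f"ER+ n={diag.n_er_pos} < {thresholds.min_er_pos} and "
            f"ER- n={diag.n_er_neg} < {thresholds.min_er_neg_or_tn}",
        )
    raise AssertionError(cohort_type)


def _ssbc2_subgroups(cohort_type: str) -> list[str]:
    return {
        "ER+": ["ER+/HER2-", "ER+/HER2+"],
        "ER-": ["ER-/HER2+", "ER-/HER2-"],
        "ER+/HER2-": ["ER+/HER2-"],
        "HER2+": ["ER+/HER2+", "ER-/HER2+"],
        "ER-/HER2-": ["ER-/HER2-"],
        "TN": ["ER-/HER2-"],
    }[cohort_type]


def select_methods(
    diagnostics: CohortDiagnostics,
    cohort_type: str,
    registry: list[MethodDescriptor],
    thresholds: Optional[AutoThresholds] = None,
) -> AutoDecision:
    """Partition the registry into enabled/disabled methods for this cohort."""
    if thresholds is None:
        thresholds = AutoThresholds()
    if cohort_type not in COHORT_TYPES:
        raise ValidationError(f"unknown cohort type: {cohort_type!r}")

    enabled: list[str] = []
    disabled: dict[str, str] = {}
    ssbc_subgroup: Optional[str] = None
    ssbc2_enabled: list[str] = []

    nc_methods = [d for d in registry if d.family == "NC"]
    for descriptor in registry:
        if descriptor.family == "SSP":
            enabled.append(descriptor.name)  # SSP always eligible

    if cohort_type == "unselected":
        pct = diagnostics.er_pos_pct
        if pct is None:
            raise ValidationError(
                "unselected cohort needs at least one known ER status"
            )
        deviated = pct <= thresholds.er_low_pct or pct >= thresholds.er_high_pct
        branch = "deviated" if deviated else "balanced"
        for descriptor in nc_methods:
            tags = descriptor.assumption_tags
            if SUBTYPE_SPECIFIC_TAG in tags:
                disabled[descriptor.name] = REASON_SUBTYPE_ONLY
            elif CONVENTIONAL_TAG in tags:
                if deviated:
                    disabled[descriptor.name] = REASON_BALANCE_VIOLATED
                else:
                    enabled.append(descriptor.name)
            elif ER_DEVIATED_TAG in tags:
                if deviated:
                    enabled.append(descriptor.name)
                else:
                    disabled[descriptor.name] = REASON_DEVIATED_ONLY
            else:
                disabled[descriptor.name] = REASON_BROADER_DISTRIBUTION
    else:
        if cohort_type == "TN":
            if diagnostics.n_tn_declared < diagnostics.n_samples:
                raise ValidationError(
                    "the TN branch requires every sample to carry an explicit "
                    "IHC-defined TN declaration (ER-/PR-/HER2-)"
                )
            branch = "tn"
        else:
            branch = "subtype_specific"
        for descriptor in nc_methods:
            tags = descriptor.assumption_tags
            if SUBTYPE_SPECIFIC_TAG not in tags:
                disabled[descriptor.name] = REASON_BROADER_DISTRIBUTION
                continue
            if descriptor.name == "ssBC":
                ok, subgroup, detail = _ssbc_gate(
                    diagnostics, cohort_type, thresholds
                )
                if ok:
                    enabled.append(descriptor.name)
                    ssbc_subgroup = subgroup
                else:
                    disabled[descriptor.name] = f"{REASON_GATE}: {detail}"
            elif descriptor.name == "ssBC.v2":
                candidates = _ssbc2_subgroups(cohort_type)
                passing = []
                for subgroup in candidates:
                    if cohort_type == "TN":
                        count = diagnostics.n_tn_declared
                    else:
                        count = diagnostics.subgroup_counts.get(subgroup, 0)
                    if count >= thresholds.min_ssbc2[subgroup]:
                        passing.append(subgroup)
                if passing:
                    enabled.append(descriptor.name)
                    ssbc2_enabled = passing
                else:
                    mins = {s: thresholds.min_ssbc2[s] for s in candidates}
                    disabled[descriptor.name] = (
                        f"{REASON_GATE}: none of {mins} met"
                    )
            else:
                # unknown subtype-specific entries gate like ssBC
                ok, _, detail = _ssbc_gate(diagnostics, cohort_type, thresholds)
                if ok:
                    enabled.append(descriptor.name)
                else:
                    disabled[descriptor.name] = f"{REASON_GATE}: {detail}"

    decision = AutoDecision(
        branch=branch,
        cohort_type=cohort_type,
        diagnostics=diagnostics.as_dict(),
        enabled=enabled,
        disabled=disabled,
        thresholds=thresholds.as_dict(),
        ssbc_subgroup=ssbc_subgroup,
        ssbc2_subgroups=ssbc2_enabled,
    )
    registry_names = {d.name for d in registry}
    if set(decision.enabled) | set(decision.disabled) != registry_names:
        raise ValidationError("decision does not cover the registry")
    return decision
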