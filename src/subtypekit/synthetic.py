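"""Synthetic fixtures and desk-scale simulation studies.

Provides toy classifier models (centroids, subgroup quantile tables,
gene-pair rule sets) that are mutually consistent at zero noise, a cohort
simulator with controlled ER/HER2 composition, the kappa-drop cutoff
derivation procedure, and the AUTO-vs-excluded benchmark harness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import auto, concordance
from .registry import get_method
from .types import (
    AutoDecision,
    CentroidModel,
    ClinicalTable,
    ExpressionMatrix,
    GeneLengths,
    MethodDescriptor,
    QuantileTable,
    RuleSet,
    SUBGROUPS,
    SUBTYPES,
    ValidationError,
)

REFERENCE_ER_FRACTION = 54.0 / 118.0

#: marker prevalences per subtype; chosen so composition gates are
#: exercisable (configurable through SimSpec)
DEFAULT_ER_GIVEN_SUBTYPE = {
    "LumA": 0.95, "LumB": 0.85, "Her2": 0.30, "Basal": 0.10, "Normal": 0.60,
}
DEFAULT_HER2_GIVEN_SUBTYPE = {
    "LumA": 0.10, "LumB": 0.10, "Her2": 0.80, "Basal": 0.10, "Normal": 0.10,
}
DEFAULT_PROPORTIONS = {
    "LumA": 0.35, "LumB": 0.20, "Her2": 0.15, "Basal": 0.20, "Normal": 0.10,
}


@dataclass
class SimSpec:
    """Parameters of the cohort simulator."""

    n_genes: int = 40
    subtype_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    er_given_subtype: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ER_GIVEN_SUBTYPE)
    )
    pr_given_subtype: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ER_GIVEN_SUBTYPE)
    )
    her2_given_subtype: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HER2_GIVEN_SUBTYPE)
    )
    noise_sd: float = 0.3
    n: int = 118
    replicates: int = 25
    seed: int = 0
    declare_tn: bool = False

    def __post_init__(self) -> None:
        props = np.array([self.subtype_proportions[k] for k in SUBTYPES])
        if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValidationError("subtype proportions must be a distribution")
        for mapping in (self.er_given_subtype, self.pr_given_subtype,
                        self.her2_given_subtype):
            vals = np.array([mapping[k] for k in SUBTYPES])
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError("conditional probabilities must be in [0,1]")
        if self.n < 1 or self.replicates < 1:
            raise ValidationError("n and replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")


@dataclass
class ToyModels:
    """Bundle of mutually consistent toy classifier models."""

    centroid: CentroidModel
    quantile: QuantileTable
    rulesets: dict[str, RuleSet]  # one per SSP method name

    def bundle(self) -> dict:
        """Model mapping in the shape ``run_multi`` consumes."""
        out: dict = {
            "centroid": self.centroid,
            "quantile": self.quantile,
            "ruleset": next(iter(self.rulesets.values())),
        }
        for name, rules in self.rulesets.items():
            out[name] = {"ruleset": rules}
        return out


def _draw_centroids(n_genes: int, rng: np.random.Generator, scale: float,
                    max_corr: float = 0.5, attempts: int = 200) -> pd.DataFrame:
    genes = [str(1000 + i) for i in range(n_genes)]
    weights = np.array([DEFAULT_PROPORTIONS[k] for k in SUBTYPES])
    for _ in range(attempts):
        mat = rng.normal(0.0, scale, size=(n_genes, len(SUBTYPES)))
        mat -= (mat @ weights)[:, np.newaxis]  # mixture-mean centered per gene
        corr = np.corrcoef(mat.T)
        off = corr[~np.eye(len(SUBTYPES), dtype=bool)]
        if np.all(off < max_corr):
            return pd.DataFrame(mat, index=genes, columns=list(SUBTYPES))
    raise ValidationError(
        f"could not draw centroids with pairwise correlation < {max_corr} "
        f"at n_genes={n_genes}"
    )


def _ruleset_from_centroids(
    centroids: pd.DataFrame, noise_sd: float, n_rules: int,
    rng: np.random.Generator,
) -> RuleSet:
    """Rules sampled from the centroid orderings; class-conditional
    probabilities are the Gaussian-noise chance that gene_a < gene_b."""
    genes = list(centroids.index)
    total_pairs = len(genes) * (len(genes) - 1)
    if n_rules > total_pairs:
        raise ValidationError(
            f"cannot build {n_rules} distinct rules from {len(genes)} genes"
        )
    sd = max(noise_sd, 0.05) * np.sqrt(2.0)
    seen: set[tuple[int, int]] = set()
    candidates: list[tuple[float, tuple[str, str], np.ndarray]] = []
    n_candidates = min(4 * n_rules, total_pairs)
    while len(candidates) < n_candidates:
        a, b = rng.choice(len(genes), size=2, replace=False)
        if (a, b) in seen:
            continue
        seen.add((int(a), int(b)))
        gene_a, gene_b = genes[a], genes[b]
        diffs = centroids.loc[gene_b] - centroids.loc[gene_a]
        probs = np.clip(stats.norm.cdf(diffs.to_numpy() / sd), 0.02, 0.98)
        # keep the pairs whose truth probability separates the subtypes most
        candidates.append((float(np.std(probs)), (gene_a, gene_b), probs))
    candidates.sort(key=lambda item: (-item[0], item[1]))
    rules = [pair for _, pair, _ in candidates[:n_rules]]
    rows = [probs for _, _, probs in candidates[:n_rules]]
    probs_df = pd.DataFrame(rows, columns=list(centroids.columns))
    return RuleSet(rules=rules, probs=probs_df)


def make_toy_models(
    n_genes: int = 40, seed: int = 0, noise_sd: float = 0.3,
    reference_size: int = 600, n_rules: int = 200,
    centroid_scale: float = 0.25,
) -> ToyModels:
    """Generate centroids, a subgroup quantile table, and two rule sets.

    Centroids are drawn to be mutually separated (pairwise correlation
    < 0.5). Quantile probabilities are trained on a simulated reference
    cohort: for each gene and clinical subgroup, the probability is the
    rank position of the reference cohort's global median inside the
    subgroup's expression distribution, so subgroup centering recovers the
    reference centering. Rules are derived from the centroid orderings so
    the SSP and NC fixtures agree at zero noise.
    """
    if n_genes < 10:
        raise ValidationError("need at least 10 genes for separable centroids")
    rng = np.random.default_rng(seed)
    # centroid_scale relative to noise_sd controls how hard the task is;
    # 0.25 keeps balanced-cohort recovery near-perfect while leaving biased
    # centering visible on composition-deviated cohorts
    centroids = _draw_centroids(n_genes, rng, centroid_scale)
    model = CentroidModel(centroids=centroids, correlation_kind="spearman")

    spec = SimSpec(n_genes=n_genes, noise_sd=noise_sd, n=reference_size,
                   seed=seed, declare_tn=True)
    expr, clinical, _ = simulate_cohort(spec, model, rng=rng)
    global_median = expr.data.median(axis=1)
    rows = []
    for subgroup in SUBGROUPS:
        mask = concordance._subgroup_mask(clinical, subgroup)
        members = [s for s, ok in mask.items() if ok]
        for gene in expr.data.index:
            if members:
                values = expr.data.loc[gene, members].to_numpy()
                p = float((values <= global_median[gene]).mean())
            else:
                p = 0.5
            rows.append((gene, subgroup, float(np.clip(p, 0.02, 0.98))))
    quantile = QuantileTable(
        pd.DataFrame(rows, columns=["gene_id", "subgroup", "quantile_prob"])
    )

    rulesets = {
        "AIMS": _ruleset_from_centroids(centroids, noise_sd, n_rules, rng),
        "sspbc": _ruleset_from_centroids(centroids, noise_sd, n_rules, rng),
    }
    return ToyModels(centroid=model, quantile=quantile, rulesets=rulesets)


def simulate_cohort(
    spec: SimSpec,
    model: CentroidModel,
    rng: Optional[np.random.Generator] = None,
    sample_prefix: str = "S",
) -> tuple[ExpressionMatrix, ClinicalTable, pd.Series]:
    """Draw a cohort: subtype from the proportions, log2 expression =
    centroid + Gaussian noise, biomarker statuses from the conditionals."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    centroids = model.centroids
    if len(centroids) != spec.n_genes:
        centroids = centroids.iloc[: spec.n_genes]
        if len(centroids) < spec.n_genes:
            raise ValidationError("model has fewer genes than spec.n_genes")
    props = np.array([spec.subtype_proportions[k] for k in SUBTYPES])
    labels = rng.choice(len(SUBTYPES), size=spec.n, p=props)
    noise = rng.normal(0.0, spec.noise_sd, size=(len(centroids), spec.n))
    values = centroids.to_numpy()[:, labels] + noise
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(spec.n)]
    expr = ExpressionMatrix(
        data=pd.DataFrame(values, index=centroids.index, columns=sample_ids),
        scale="log2", units="normalized_intensity", platform="microarray",
    )
    truth = pd.Series([SUBTYPES[k] for k in labels], index=sample_ids,
                      name="subtype")
    rows = {}
    for marker, conditional in (
        ("er", spec.er_given_subtype),
        ("pr", spec.pr_given_subtype),
        ("her2", spec.her2_given_subtype),
    ):
        p = np.array([conditional[SUBTYPES[k]] for k in labels])
        rows[marker] = np.where(rng.random(spec.n) < p, "pos", "neg")
    table = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    if spec.declare_tn:
        table["tn"] = (
            (table["er"] == "neg") & (table["pr"] == "neg")
            & (table["her2"] == "neg")
        )
    else:
        table["tn"] = False
    return expr, ClinicalTable(table), truth


def cohort_to_counts(
    expr: ExpressionMatrix, seed: int = 0,
    mean_library_log2: float = 14.0, library_sd_log2: float = 0.25,
) -> tuple[ExpressionMatrix, GeneLengths]:
    """Raw-counts view of a log2 cohort.

    Library-size model: per sample, counts = round(2**(x + l_j)) with
    l_j ~ Normal(mean_library_log2, library_sd_log2); gene lengths drawn
    uniformly in [500, 5000] bp.
    """
    rng = np.random.default_rng(seed)
    lib = rng.normal(mean_library_log2, library_sd_log2, size=expr.n_samples)
    counts = np.round(np.power(2.0, expr.data.to_numpy() + lib[np.newaxis, :]))
    out = ExpressionMatrix(
        data=pd.DataFrame(counts, index=expr.data.index,
                          columns=expr.data.columns),
        scale="linear", units="counts", platform="rnaseq_counts",
    )
    lengths = GeneLengths(pd.Series(
        rng.integers(500, 5001, size=expr.n_genes),
        index=pd.Index(expr.gene_ids, name="gene_id"), name="length",
    ))
    return out, lengths


# ---------------------------------------------------------------------------
# resampling helpers
# ---------------------------------------------------------------------------

def _take_subcohort(
    expr: ExpressionMatrix, clinical: ClinicalTable, truth: pd.Series,
    sample_ids: Sequence[str],
) -> tuple[ExpressionMatrix, ClinicalTable, pd.Series]:
    ids = list(sample_ids)
    sub_expr = ExpressionMatrix(
        data=expr.data[ids], scale=expr.scale, units=expr.units,
        platform=expr.platform,
    )
    return sub_expr, clinical.subset(ids), truth.loc[ids]


def _resample_by_er(
    clinical: ClinicalTable, n: int, er_frac: float, rng: np.random.Generator
) -> list[str]:
    er = clinical.er_status()
    pos = sorted(er.index[er == "pos"])
    neg = sorted(er.index[er == "neg"])
    n_pos = int(round(er_frac * n))
    n_neg = n - n_pos
    if n_pos > len(pos) or n_neg > len(neg):
        raise ValidationError(
            f"mega-cohort too small to draw {n_pos} ER+ / {n_neg} ER- samples"
        )
    chosen = list(rng.choice(pos, size=n_pos, replace=False)) + list(
        rng.choice(neg, size=n_neg, replace=False)
    )
    return sorted(chosen)


# ---------------------------------------------------------------------------
# cutoff derivation
# ---------------------------------------------------------------------------

@dataclass
class CutoffReport:
    """Per-fraction mean kappa with the flagged deviation region."""

    method: str
    er_fracs: list[float]
    mean_kappa: dict[float, float]
    sd_kappa: dict[float, float]
    flagged: dict[float, bool]
    low_boundary: Optional[float]
    high_boundary: Optional[float]
    params: dict

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def derive_cutoffs(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    truth: pd.Series,
    models: Mapping,
    registry: list[MethodDescriptor],
    method: str = "parker.original",
    er_fracs: Optional[Sequence[float]] = None,
    R: int = 100,
    n: int = 118,
    drop_threshold: float = 0.05,
    alpha: float = 0.01,
    seed: int = 0,
    reference_frac: float = REFERENCE_ER_FRACTION,
) -> CutoffReport:
    """Flag ER+ fractions where a method's agreement with truth drops.

    For each fraction f the mega cohort is resampled (R subcohorts of size
    n, without replacement within a replicate), the method is run, and
    Cohen's kappa against the true labels is recorded. A fraction is
    flagged when its mean kappa sits at least ``drop_threshold`` below the
    reference fraction's mean AND a one-sided two-sample t-test gives
    P < alpha.
    """
    if er_fracs is None:
        er_fracs = [round(0.05 * i, 2) for i in range(1, 20)]
        er_fracs.append(reference_frac)
        er_fracs = sorted(set(er_fracs))
    er_fracs = list(er_fracs)
    if not any(abs(f - reference_frac) < 1e-9 for f in er_fracs):
        raise ValidationError("fraction grid must contain the reference fraction")
    rng = np.random.default_rng(seed)
    descriptor = get_method(registry, method)
    kappas: dict[float, np.ndarray] = {}
    for frac in er_fracs:
        vals = np.empty(R)
        for r in range(R):
            ids = _resample_by_er(clinical, n, frac, rng)
            sub_expr, sub_clin, sub_truth = _take_subcohort(
                expr, clinical, truth, ids
            )
            labels = concordance.run_method(
                descriptor, sub_expr, sub_clin, models, seed=seed + r
            )
            vals[r] = concordance.cohens_kappa(list(labels), list(sub_truth))
        kappas[frac] = vals
    ref_key = min(er_fracs, key=lambda f: abs(f - reference_frac))
    ref_vals = kappas[ref_key]
    ref_mean = float(ref_vals.mean())
    flagged = {}
    for frac in er_fracs:
        if frac == ref_key:
            flagged[frac] = False  # never flag the self-comparison
            continue
        mean_f = float(kappas[frac].mean())
        drop_ok = mean_f <= ref_mean - drop_threshold
        if drop_ok:
            p = stats.ttest_ind(
                kappas[frac], ref_vals, alternative="less", equal_var=False
            ).pvalue
            flagged[frac] = bool(p < alpha)
        else:
            flagged[frac] = False
    low_candidates = [f for f in er_fracs if f < ref_key and flagged[f]]
    high_candidates = [f for f in er_fracs if f > ref_key and flagged[f]]
    return CutoffReport(
        method=method,
        er_fracs=er_fracs,
        mean_kappa={f: float(kappas[f].mean()) for f in er_fracs},
        sd_kappa={f: float(kappas[f].std(ddof=1)) for f in er_fracs},
        flagged=flagged,
        low_boundary=max(low_candidates) if low_candidates else None,
        high_boundary=min(high_candidates) if high_candidates else None,
        params={
            "R": R, "n": n, "drop_threshold_pp": drop_threshold * 100,
            "alpha": alpha, "reference_frac": ref_key, "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# AUTO vs excluded benchmark
# ---------------------------------------------------------------------------

SCENARIOS = ("S10", "S90", "pure_ER+", "pure_ER-", "pure_TN")


@dataclass
class ScenarioResult:
    """Per-scenario aggregate accuracy/kappa for AUTO vs excluded sets."""

    scenario: str
    auto_accuracy_mean: float
    auto_accuracy_sd: float
    excluded_accuracy_mean: Optional[float]
    excluded_accuracy_sd: Optional[float]
    delta_accuracy_pp: Optional[float]
    auto_kappa_mean: float
    excluded_kappa_mean: Optional[float]
    per_replicate_delta: list[Optional[float]]
    replicates: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _mean_scores(
    calls, truth: pd.Series
) -> tuple[Optional[float], Optional[float]]:
    accs, kaps = [], []
    for method in calls.methods:
        labels = calls.labels[method]
        if labels.isna().all():
            continue
        try:
            accs.append(concordance.accuracy(list(labels), list(truth)))
            kaps.append(concordance.cohens_kappa(list(labels), list(truth)))
        except ValidationError:
            continue
    if not accs:
        return None, None
    return float(np.mean(accs)), float(np.mean(kaps))


def _scenario_cohort(
    scenario: str,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    truth: pd.Series,
    rng: np.random.Generator,
    n_skewed: int = 118,
    n_pure: int = 100,
    n_tn: int = 60,
) -> tuple[ExpressionMatrix, ClinicalTable, pd.Series, str]:
    table = clinical.table
    if scenario == "S10":
        ids = _resample_by_er(clinical, n_skewed, 0.10, rng)
        cohort_type = "unselected"
    elif scenario == "S90":
        ids = _resample_by_er(clinical, n_skewed, 0.90, rng)
        cohort_type = "unselected"
    elif scenario == "pure_ER+":
        pool = sorted(table.index[table["er"] == "pos"])
        ids = sorted(rng.choice(pool, size=min(n_pure, len(pool)),
                                replace=False))
        cohort_type = "ER+"
    elif scenario == "pure_ER-":
        pool = sorted(table.index[table["er"] == "neg"])
        ids = sorted(rng.choice(pool, size=min(n_pure, len(pool)),
                                replace=False))
        cohort_type = "ER-"
    elif scenario == "pure_TN":
        pool = sorted(table.index[table["tn"].astype(bool)])
        if len(pool) < n_tn:
            raise ValidationError("mega-cohort has too few declared-TN samples")
        ids = sorted(rng.choice(pool, size=n_tn, replace=False))
        cohort_type = "TN"
    else:
        raise ValidationError(f"unknown scenario: {scenario!r}")
    sub = _take_subcohort(expr, clinical, truth, ids)
    return (*sub, cohort_type)


def auto_vs_excluded(
    scenario: str,
    models: Mapping,
    registry: list[MethodDescriptor],
    mega: tuple[ExpressionMatrix, ClinicalTable, pd.Series],
    R: int = 25,
    seed: int = 0,
    thresholds: Optional[auto.AutoThresholds] = None,
) -> ScenarioResult:
    """Benchmark the AUTO-enabled method set against the methods it excludes.

    Per replicate a subcohort of the mega cohort is drawn at the scenario's
    composition, AUTO selects methods, both the enabled and the excluded
    sets are executed, and each method's calls are scored against the true
    labels. The accuracy delta is reported in percentage points.
    """
    expr, clinical, truth = mega
    rng = np.random.default_rng(seed)
    auto_acc, auto_kap = [], []
    excl_acc, excl_kap = [], []
    deltas: list[Optional[float]] = []
    for r in range(R):
        sub_expr, sub_clin, sub_truth, cohort_type = _scenario_cohort(
            scenario, expr, clinical, truth, rng
        )
        diag = auto.cohort_diagnostics(sub_clin)
        decision = auto.select_methods(diag, cohort_type, registry, thresholds)
        calls, _ = concordance.run_multi(
            sub_expr, sub_clin, decision, models, registry, seed=seed + r
        )
        a_acc, a_kap = _mean_scores(calls, sub_truth)
        if a_acc is None:
            raise ValidationError("no AUTO-enabled method produced calls")
        auto_acc.append(a_acc)
        auto_kap.append(a_kap)
        if decision.disabled:
            excluded_decision = AutoDecision(
                branch=decision.branch,
                cohort_type=decision.cohort_type,
                diagnostics=decision.diagnostics,
                enabled=sorted(decision.disabled),
                disabled={},
                thresholds=decision.thresholds,
                ssbc_subgroup=decision.ssbc_subgroup,
                ssbc2_subgroups=decision.ssbc2_subgroups,
            )
            ex_calls, _ = concordance.run_multi(
                sub_expr, sub_clin, excluded_decision, models, registry,
                seed=seed + r,
            )
            e_acc, e_kap = _mean_scores(ex_calls, sub_truth)
        else:
            e_acc = e_kap = None
        if e_acc is not None:
            excl_acc.append(e_acc)
            excl_kap.append(e_kap)
            deltas.append(a_acc - e_acc)
        else:
            deltas.append(None)
    has_excl = bool(excl_acc)
    return ScenarioResult(
        scenario=scenario,
        auto_accuracy_mean=float(np.mean(auto_acc)),
        auto_accuracy_sd=float(np.std(auto_acc, ddof=1)) if R > 1 else 0.0,
        excluded_accuracy_mean=float(np.mean(excl_acc)) if has_excl else None,
        excluded_accuracy_sd=(
            float(np.std(excl_acc, ddof=1)) if len(excl_acc) > 1 else None
        ),
        delta_accuracy_pp=(
            float(np.mean([d for d in deltas if d is not None]))
            if has_excl else None
        ),
        auto_kappa_mean=float(np.mean(auto_kap)),
        excluded_kappa_mean=float(np.mean(excl_kap)) if has_excl else None,
        per_replicate_delta=deltas,
        replicates=R,
    )


def make_mega_cohort(
    models: ToyModels, size: int = 1500, noise_sd: float = 0.3, seed: int = 0,
) -> tuple[ExpressionMatrix, ClinicalTable, pd.Series]:
    """A large declared-TN-aware cohort used as the resampling pool."""
    spec = SimSpec(
        n_genes=len(models.centroid.gene_ids), noise_sd=noise_sd,
        n=size, seed=seed, declare_tn=True,
    )
    return simulate_cohort(spec, models.centroid)
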