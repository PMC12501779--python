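"""Single-sample predictor engine.

Each sample is classified independently from within-sample gene-pair order
rules scored under a naive-Bayes model, so calls do not depend on the rest
of the cohort and are invariant to strictly increasing per-sample
transforms of the linear expression values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, RuleSet, SubtypeCall, ValidationError


def evaluate_rules(
    sample: pd.Series, rules: RuleSet
) -> tuple[np.ndarray, np.ndarray, int]:
    """Evaluate every rule on one sample's linear expression vector.

    Returns (outcomes, evaluated_mask, n_skipped). Rule r is true (1) iff
    expr[gene_a] < expr[gene_b]; exact equality counts as 0. Rules whose
    genes are absent are skipped and counted.
    """
    outcomes = np.zeros(len(rules.rules), dtype=int)
    evaluated = np.zeros(len(rules.rules), dtype=bool)
    index = sample.index
    for r, (gene_a, gene_b) in enumerate(rules.rules):
        if gene_a not in index or gene_b not in index:
            continue
        evaluated[r] = True
        outcomes[r] = 1 if sample[gene_a] < sample[gene_b] else 0
    return outcomes, evaluated, int((~evaluated).sum())


def classify_ssp(expr: ExpressionMatrix, rules: RuleSet) -> list[SubtypeCall]:
    """Naive-Bayes scoring of gene-pair rule outcomes, per sample.

    log-posterior_k = log prior_k + sum over evaluated rules of
    outcome * log P_rk + (1 - outcome) * log(1 - P_rk); scores are the
    softmax-normalized posteriors. A sample with every rule skipped gets an
    NA call with a flag.
    """
    if expr.scale != "linear":
        raise ValidationError("SSP classification expects a linear-scale matrix")
    subtype_order = rules.subtype_order
    log_p = np.log(rules.probs.to_numpy(dtype=float))
    log_q = np.log1p(-rules.probs.to_numpy(dtype=float))
    log_prior = np.log(rules.priors.to_numpy(dtype=float))

    # vectorize rule outcomes across samples for rules whose genes are present
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    present = np.array(
        [a in gene_pos and b in gene_pos for a, b in rules.rules], dtype=bool
    )
    mat = expr.data.to_numpy(dtype=float)
    if present.any():
        a_idx = np.array([gene_pos[a] for (a, b), ok in
                          zip(rules.rules, present) if ok])
        b_idx = np.array([gene_pos[b] for (a, b), ok in
                          zip(rules.rules, present) if ok])
        outcome_mat = (mat[a_idx] < mat[b_idx]).astype(int)  # rules x samples
    else:
        outcome_mat = np.zeros((0, expr.n_samples), dtype=int)
    n_skipped_all = int((~present).sum())

    calls = []
    for j, sample_id in enumerate(expr.sample_ids):
        outcomes = np.zeros(len(rules.rules), dtype=int)
        outcomes[present] = outcome_mat[:, j]
        evaluated, n_skipped = present, n_skipped_all
        flags: dict = {}
        if n_skipped:
            flags["skipped_rules"] = n_skipped
        if not evaluated.any():
            flags["all_rules_skipped"] = True
            calls.append(
                SubtypeCall(
                    sample_id=sample_id,
                    label=None,
                    scores={},
                    method="ssp",
                    flags=flags,
                )
            )
            continue
        hits = outcomes[evaluated][:, np.newaxis]
        log_post = log_prior + (
            hits * log_p[evaluated] + (1 - hits) * log_q[evaluated]
        ).sum(axis=0)
        shifted = log_post - log_post.max()
        posterior = np.exp(shifted)
        posterior = posterior / posterior.sum()
        scores = {k: float(posterior[i]) for i, k in enumerate(subtype_order)}
        best = max(scores.values())
        winners = [k for k in subtype_order if scores[k] == best]
        if len(winners) > 1:
            flags["tie_broken"] = True
        calls.append(
            SubtypeCall(
                sample_id=sample_id,
                label=winners[0],
                scores=scores,
                method="ssp",
                flags=flags,
            )
        )
    return calls
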