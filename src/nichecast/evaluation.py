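"""Replicate splits, AUC/TSS scoring, and replicate aggregation.

Background points stand in for absences throughout (presence-only setting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import DataError, EvaluationError

TRAIN_FRACTION = 0.7
N_REPLICATES = 10


def split_presences(
    n: int, fraction: float = TRAIN_FRACTION, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random train/test split of ``range(n)`` without replacement.

    Train size is ``round(fraction * n)``. Requires ``n >= 5``.
    """
    if n < 5:
        raise DataError(f"need at least 5 presences to split, got {n}")
    n_train = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def roc_auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(presence outscores background), ties count 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise EvaluationError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def tss(presence_scores, background_scores) -> float:
    """Max over thresholds of sensitivity + specificity - 1.

    Candidate thresholds are the distinct observed scores; a point scores
    positive when its score >= threshold. Background is treated as absence.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise EvaluationError("both score sets must be non-empty")
    thresholds = np.unique(np.concatenate([p, b]))
    p_sorted = np.sort(p)
    b_sorted = np.sort(b)
    # count(p >= thr) and count(b < thr) via binary search, all thresholds at once
    sens = (p.size - np.searchsorted(p_sorted, thresholds, side="left")) / p.size
    spec = np.searchsorted(b_sorted, thresholds, side="left") / b.size
    return float(np.max(sens + spec - 1.0))


@dataclass
class ReplicateResult:
    """Outcome of one 70/30 replicate fit."""

    index: int
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    auc: float
    tss: float
    contribution: dict[str, float]
    model: object = None


@dataclass
class AggregateResult:
    auc_mean: float
    auc_sd: float
    tss_mean: float
    tss_sd: float
    contribution_mean: dict[str, float]
    n_replicates: int

    def format_auc(self) -> str:
        return f"{self.auc_mean:.4f} ± {self.auc_sd:.4f}"

    def format_tss(self) -> str:
        return f"{self.tss_mean:.4f} ± {self.tss_sd:.4f}"


def aggregate_replicates(results: list[ReplicateResult]) -> AggregateResult:
    """Mean +- sample sd (n-1 denominator) of AUC/TSS; mean contribution."""
    if len(results) < 2:
        raise DataError("need at least 2 replicates to aggregate")
    aucs = np.array([r.auc for r in results])
    tsss = np.array([r.tss for r in results])
    variables = list(results[0].contribution)
    contrib = {
        v: float(np.mean([r.contribution[v] for r in results])) for v in variables
    }
    return AggregateResult(
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)),
        tss_mean=float(tsss.mean()),
        tss_sd=float(tsss.std(ddof=1)),
        contribution_mean=contrib,
        n_replicates=len(results),
    )


def run_replicates(
    presence_design: np.ndarray,
    background_design: np.ndarray,
    variables: list[str],
    beta_multiplier: float = 1.0,
    n_replicates: int = N_REPLICATES,
    base_seed: int = 0,
    fraction: float = TRAIN_FRACTION,
    with_contribution: bool = True,
    n_permutations: int = 10,
    keep_models: bool = True,
    tol: float = 1e-6,
    **fit_kwargs,
) -> list[ReplicateResult]:
    """Fit *n_replicates* 70/30 replicate models and score each on its
    held-out presences against the background sample.

    Replicate seeds are ``base_seed + index`` (index 1-based), recorded in
    each result.
    """
    from .maxent_core import fit_maxent_on_design, variable_contribution

    presence_design = np.asarray(presence_design, dtype=float)
    n = presence_design.shape[0]
    results = []
    for i in range(1, n_replicates + 1):
        seed = base_seed + i
        train, test = split_presences(n, fraction=fraction, seed=seed)
        model = fit_maxent_on_design(
            presence_design[train],
            background_design,
            variables,
            beta_multiplier=beta_multiplier,
            tol=tol,
            **fit_kwargs,
        )
        test_scores = model.predict(presence_design[test], output="raw")
        bg_scores = model.predict(background_design, output="raw")
        contrib = (
            variable_contribution(
                model,
                presence_design[train],
                background_design,
                n_permutations=n_permutations,
                seed=seed,
            )
            if with_contribution
            else {v: float("nan") for v in variables}
        )
        results.append(
            ReplicateResult(
                index=i,
                seed=seed,
                train_idx=train,
                test_idx=test,
                auc=roc_auc(test_scores, bg_scores),
                tss=tss(test_scores, bg_scores),
                contribution=contrib,
                model=model if keep_models else None,
            )
        )
    return results
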