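"""Variable screening, VIF diagnostics, and beta-multiplier tuning.

Procedure order: (1) contribution + pairwise-correlation loop, (2) beta
sweep over the survivors, (3) VIF gate with iterative removal of the worst
offender (re-screening after any removal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, SelectionError
from .evaluation import aggregate_replicates, run_replicates

CONTRIBUTION_THRESHOLD = 5.0  # percent; strict: < 5 is excluded
CORRELATION_THRESHOLD = 0.7  # |Pearson r| over background cells
VIF_THRESHOLD = 5.0
DEFAULT_BETAS = tuple(np.arange(1.0, 10.0 + 0.25, 0.5))  # 1.0 .. 10.0 step 0.5


@dataclass
class SelectionReport:
    """Audit trail of the screening + tuning run."""

    candidates: list[str]
    retained: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)  # variable -> reason
    contribution: dict[str, float] = field(default_factory=dict)
    vif: dict[str, float] = field(default_factory=dict)
    chosen_beta: float | None = None
    beta_auc: dict[float, float] = field(default_factory=dict)

    def exclude(self, variable: str, reason: str):
        self.excluded[variable] = reason

    def to_rows(self) -> list[dict]:
        rows = []
        for v in self.candidates:
            rows.append(
                {
                    "variable": v,
                    "contribution": self.contribution.get(v, float("nan")),
                    "vif": self.vif.get(v, float("nan")),
                    "status": "retained" if v in self.retained else "excluded",
                    "reason": self.excluded.get(v, ""),
                }
            )
        return rows


def compute_vif(design: np.ndarray, variables: list[str]) -> dict[str, float]:
    """VIF_k = 1/(1-R^2) from OLS of variable k on the others.

    Computed over background cells. Perfect collinearity reports +inf.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(variables):
        raise DataError("design shape does not match variable list")
    if X.shape[1] < 2:
        raise DataError("VIF needs at least 2 variables")
    if X.shape[0] <= X.shape[1]:
        raise DataError("need more background rows than variables")
    out = {}
    for k, name in enumerate(variables):
        y = X[:, k]
        others = np.delete(X, k, axis=1)
        A = np.column_stack([np.ones(X.shape[0]), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _correlated_pairs(background: np.ndarray, variables: list[str], threshold: float):
    corr = np.corrcoef(background, rowvar=False)
    pairs = []
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            if abs(corr[i, j]) > threshold:
                pairs.append((variables[i], variables[j], abs(corr[i, j])))
    return pairs


def screen_variables(
    candidates: list[str],
    presence_design: np.ndarray,
    background_design: np.ndarray,
    contribution_threshold: float = CONTRIBUTION_THRESHOLD,
    corr_threshold: float = CORRELATION_THRESHOLD,
    reps: int = 10,
    base_seed: int = 0,
    beta_multiplier: float = 1.0,
    report: SelectionReport | None = None,
    **rep_kwargs,
) -> SelectionReport:
    """Iterative contribution/correlation screening.

    Each pass fits *reps* replicate models on the surviving variables and
    averages their permutation contributions; variables with mean
    contribution strictly below *contribution_threshold* are dropped, then
    for every surviving pair with |r| > *corr_threshold* over the background
    the lower-contribution member is dropped (ties: lexicographically later
    name). Repeats until a pass removes nothing.
    """
    if len(candidates) < 2:
        raise DataError("need at least 2 candidate variables")
    presence_design = np.asarray(presence_design, dtype=float)
    background_design = np.asarray(background_design, dtype=float)
    col = {v: j for j, v in enumerate(candidates)}
    report = report or SelectionReport(candidates=list(candidates))
    current = list(candidates)

    while True:
        if not current:
            raise SelectionError("all variables were excluded", report=report)
        idx = [col[v] for v in current]
        results = run_replicates(
            presence_design[:, idx],
            background_design[:, idx],
            current,
            beta_multiplier=beta_multiplier,
            n_replicates=reps,
            base_seed=base_seed,
            **rep_kwargs,
        )
        agg = aggregate_replicates(results)
        contrib = agg.contribution_mean
        report.contribution.update(contrib)

        dropped = False
        low = [v for v in current if contrib[v] < contribution_threshold]
        for v in low:
            report.exclude(v, "low-contribution")
            current.remove(v)
            dropped = True
        if current and len(current) >= 2:
            idx = [col[v] for v in current]
            for a, b, _r in _correlated_pairs(
                background_design[:, idx], current, corr_threshold
            ):
                if a not in current or b not in current:
                    continue
                if contrib[a] > contrib[b]:
                    victim = b
                elif contrib[b] > contrib[a]:
                    victim = a
                else:  # tie: drop the lexicographically later name
                    victim = max(a, b)
                report.exclude(victim, "correlated")
                current.remove(victim)
                dropped = True
        if not dropped:
            break
    report.retained = current
    return report


def sweep_beta(
    variables: list[str],
    presence_design: np.ndarray,
    background_design: np.ndarray,
    betas=DEFAULT_BETAS,
    reps: int = 10,
    base_seed: int = 0,
    **rep_kwargs,
) -> tuple[float, dict[float, float]]:
    """Mean test AUC per beta over replicate 70/30 fits; returns the argmax
    beta (ties -> smallest) and the full beta -> AUC table."""
    betas = list(betas)
    if not betas:
        raise DataError("beta grid is empty")
    rep_kwargs.setdefault("with_contribution", False)
    rep_kwargs.setdefault("keep_models", False)
    table: dict[float, float] = {}
    for beta in betas:
        results = run_replicates(
            presence_design,
            background_design,
            variables,
            beta_multiplier=float(beta),
            n_replicates=reps,
            base_seed=base_seed,
            **rep_kwargs,
        )
        table[float(beta)] = float(np.mean([r.auc for r in results]))
    best_auc = max(table.values())
    chosen = min(b for b, a in table.items() if a == best_auc)
    return chosen, table


def select_model(
    candidates: list[str],
    presence_design: np.ndarray,
    background_design: np.ndarray,
    betas=DEFAULT_BETAS,
    reps: int = 10,
    base_seed: int = 0,
    vif_threshold: float = VIF_THRESHOLD,
    **rep_kwargs,
) -> SelectionReport:
    """Full selection loop: screen, tune beta, then enforce the VIF gate.

    If any retained variable reaches the VIF threshold, the worst offender
    is removed and screening + tuning rerun on the survivors.
    """
    col = {v: j for j, v in enumerate(candidates)}
    report = SelectionReport(candidates=list(candidates))
    current = list(candidates)
    while True:
        report = screen_variables(
            current,
            presence_design[:, [col[v] for v in current]],
            background_design[:, [col[v] for v in current]],
            reps=reps,
            base_seed=base_seed,
            report=report,
            **rep_kwargs,
        )
        retained = report.retained
        idx = [col[v] for v in retained]
        chosen, table = sweep_beta(
            retained,
            presence_design[:, idx],
            background_design[:, idx],
            betas=betas,
            reps=reps,
            base_seed=base_seed,
            **rep_kwargs,
        )
        report.chosen_beta = chosen
        report.beta_auc = table
        if len(retained) >= 2:
            vifs = compute_vif(background_design[:, idx], retained)
            report.vif.update(vifs)
            worst = max(retained, key=lambda v: vifs[v])
            if vifs[worst] >= vif_threshold:
                report.exclude(worst, "high-VIF")
                current = [v for v in retained if v != worst]
                if len(current) < 2:
                    report.retained = current
                    break
                continue
        break
    return report
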