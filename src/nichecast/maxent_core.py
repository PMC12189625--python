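"""Presence-background maximum-entropy model, from scratch.

The model is a Gibbs density over background cells,
``P(cell) = exp(lambda . f(cell)) / Z``, fitted by minimizing the convex
L1-penalized objective

    J(lambda) = -(1/m) sum_presence lambda . f(x_i)
                + log Z(lambda)
                + sum_j beta_j |lambda_j|

where ``Z`` sums ``exp(lambda . f)`` over background cells. Optimization is
a monotone accelerated proximal-gradient scheme (backtracking line search,
objective never increases across accepted iterates), so fits are
reproducible bit-for-bit given identical inputs.

Output transforms: ``raw`` is the normalized Gibbs density; with ``c =
exp(H)`` (H the entropy of the fitted background distribution), ``logistic``
is ``c*raw / (1 + c*raw)`` and ``cloglog`` is ``1 - exp(-c*raw)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .errors import ConfigError, ConvergenceError, DataError, ModelStateError

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("linear", "quadratic", "hinge")

#: Class weight applied inside the per-feature penalty.
_CLASS_WEIGHT = {"linear": 1.0, "quadratic": 1.0, "hinge": 0.5}

_PENALTY_SD_FLOOR = 0.01
DEFAULT_N_HINGE_KNOTS = 5
MAX_BACKGROUND_CELLS = 10_000
#: Features live in [0,1]; weights beyond this signal an unbounded objective.
_WEIGHT_DIVERGENCE_BOUND = 200.0


@dataclass(frozen=True)
class FeatureDef:
    """One derived feature of one environmental variable.

    ``lo``/``hi`` are the variable's background min/max (standardization
    constants); hinge features also carry a knot and an orientation
    (``forward`` ramps up above the knot, ``reverse`` ramps up below it).
    """

    kind: str
    variable: str
    lo: float
    hi: float
    knot: float | None = None
    orientation: str | None = None  # 'forward' | 'reverse'

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, self.lo, self.hi)
        span = self.hi - self.lo
        if self.kind == "linear":
            return (x - self.lo) / span
        if self.kind == "quadratic":
            return ((x - self.lo) / span) ** 2
        if self.kind == "hinge":
            if self.orientation == "forward":
                return np.maximum(0.0, (x - self.knot) / (self.hi - self.knot))
            return np.maximum(0.0, (self.knot - x) / (self.knot - self.lo))
        raise ConfigError(f"unknown feature kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "variable": self.variable,
            "lo": self.lo,
            "hi": self.hi,
            "knot": self.knot,
            "orientation": self.orientation,
        }


def make_feature_defs(
    background: np.ndarray,
    variables: list[str],
    kinds=FEATURE_KINDS,
    n_hinge_knots: int = DEFAULT_N_HINGE_KNOTS,
) -> list[FeatureDef]:
    """Feature definitions standardized on the background sample.

    Variables that are constant over the background contribute no features
    (a warning is emitted). Hinge knots are equally spaced strictly inside
    the background range.
    """
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[1] != len(variables):
        raise DataError("background shape does not match variable list")
    unknown = set(kinds) - set(FEATURE_KINDS)
    if unknown:
        raise ConfigError(f"unknown feature kinds: {sorted(unknown)}")
    defs: list[FeatureDef] = []
    for j, var in enumerate(variables):
        lo = float(np.min(background[:, j]))
        hi = float(np.max(background[:, j]))
        if hi <= lo:
            warnings.warn(
                f"variable {var!r} is constant on the background; "
                "no features emitted",
                stacklevel=2,
            )
            continue
        if "linear" in kinds:
            defs.append(FeatureDef("linear", var, lo, hi))
        if "quadratic" in kinds:
            defs.append(FeatureDef("quadratic", var, lo, hi))
        if "hinge" in kinds:
            for i in range(1, n_hinge_knots + 1):
                knot = lo + (hi - lo) * i / (n_hinge_knots + 1)
                defs.append(FeatureDef("hinge", var, lo, hi, knot, "forward"))
                defs.append(FeatureDef("hinge", var, lo, hi, knot, "reverse"))
    return defs


def transform_features(
    design: np.ndarray, defs: list[FeatureDef], variables: list[str]
) -> np.ndarray:
    """Evaluate *defs* on a records x variables design matrix."""
    design = np.atleast_2d(np.asarray(design, dtype=float))
    col = {v: j for j, v in enumerate(variables)}
    out = np.empty((design.shape[0], len(defs)))
    for k, fd in enumerate(defs):
        out[:, k] = fd.evaluate(design[:, col[fd.variable]])
    return out


def expand_features(
    design: np.ndarray,
    background: np.ndarray,
    variables: list[str],
    kinds=FEATURE_KINDS,
    n_hinge_knots: int = DEFAULT_N_HINGE_KNOTS,
) -> tuple[np.ndarray, list[FeatureDef]]:
    """One-shot convenience: build defs on *background*, evaluate on *design*."""
    defs = make_feature_defs(background, variables, kinds, n_hinge_knots)
    return transform_features(design, defs, variables), defs


@dataclass
class MaxEntModel:
    """Fitted presence-background Gibbs model."""

    variables: list[str]
    feature_defs: list[FeatureDef]
    weights: np.ndarray
    penalties: np.ndarray
    beta_multiplier: float
    log_z: float = 0.0
    entropy: float = 0.0
    background_means: np.ndarray | None = None
    objective_history: np.ndarray | None = None
    fitted: bool = False
    n_iter: int = 0
    kkt_residual: float = float("nan")

    # -- prediction ---------------------------------------------------------
    def _check_fitted(self):
        if not self.fitted:
            raise ModelStateError("model is not fitted")

    def log_raw(self, design: np.ndarray) -> np.ndarray:
        self._check_fitted()
        feats = transform_features(design, self.feature_defs, self.variables)
        return feats @ self.weights - self.log_z

    def predict(self, design: np.ndarray, output: str = "logistic") -> np.ndarray:
        """Scores for a records x variables design matrix.

        Values outside the background range are clamped (feature
        standardization performs the clamp).
        """
        lr = self.log_raw(design)
        if output == "raw":
            return np.exp(lr)
        # c * raw in log domain: entropy + log raw
        z = self.entropy + lr
        if output == "logistic":
            return expit(z)
        if output == "cloglog":
            return 1.0 - np.exp(-np.exp(z))
        raise ConfigError(f"unknown output {output!r}")

    def to_json(self) -> str:
        self._check_fitted()
        doc = {
            "format": "nichecast-maxent",
            "version": 1,
            "variables": self.variables,
            "features": [fd.to_dict() for fd in self.feature_defs],
            "weights": self.weights.tolist(),
            "penalties": self.penalties.tolist(),
            "beta_multiplier": self.beta_multiplier,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "background_means": (
                self.background_means.tolist()
                if self.background_means is not None
                else None
            ),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaxEntModel":
        doc = json.loads(text)
        if doc.get("format") != "nichecast-maxent":
            raise DataError("not a serialized model document")
        defs = [
            FeatureDef(
                kind=d["kind"],
                variable=d["variable"],
                lo=d["lo"],
                hi=d["hi"],
                knot=d["knot"],
                orientation=d["orientation"],
            )
            for d in doc["features"]
        ]
        return cls(
            variables=list(doc["variables"]),
            feature_defs=defs,
            weights=np.asarray(doc["weights"], dtype=float),
            penalties=np.asarray(doc["penalties"], dtype=float),
            beta_multiplier=doc["beta_multiplier"],
            log_z=doc["log_z"],
            entropy=doc["entropy"],
            background_means=(
                np.asarray(doc["background_means"], dtype=float)
                if doc["background_means"] is not None
                else None
            ),
            fitted=True,
        )


def feature_penalties(
    presence_features: np.ndarray,
    defs: list[FeatureDef],
    beta_multiplier: float,
) -> np.ndarray:
    """Per-feature L1 penalty: ``beta * c_class * sd_j / sqrt(m)``.

    ``sd_j`` is the feature sample sd over presences, floored at 0.01;
    hinge features get class weight 0.5, linear/quadratic 1.0.
    """
    m = presence_features.shape[0]
    sd = np.maximum(presence_features.std(axis=0, ddof=1), _PENALTY_SD_FLOOR)
    cw = np.array([_CLASS_WEIGHT[fd.kind] for fd in defs])
    return beta_multiplier * cw * sd / np.sqrt(m)


def _objective_parts(lam, pres_mean, bg_feats):
    scores = bg_feats @ lam
    lz = logsumexp(scores)
    smooth = -pres_mean @ lam + lz
    q = np.exp(scores - lz)
    grad = -pres_mean + bg_feats.T @ q
    return smooth, grad, lz, q


def _kkt_residual(lam, grad, beta):
    at_zero = lam == 0
    res = np.abs(grad + beta * np.sign(lam))
    res[at_zero] = np.maximum(np.abs(grad[at_zero]) - beta[at_zero], 0.0)
    return float(res.max(initial=0.0))


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    feature_defs: list[FeatureDef],
    variables: list[str],
    beta_multiplier: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    background_design: np.ndarray | None = None,
) -> MaxEntModel:
    """Fit the penalized objective by monotone accelerated proximal descent.

    Raises :class:`ConvergenceError` (carrying the final KKT residual) if
    the residual has not dropped to *tol* within *max_iter* iterations.
    """
    F_p = np.asarray(presence_features, dtype=float)
    F_b = np.asarray(background_features, dtype=float)
    if F_p.ndim != 2 or F_b.ndim != 2:
        raise DataError("feature matrices must be 2-D")
    if F_p.shape[0] < 5:
        raise DataError(f"need >= 5 presence rows, got {F_p.shape[0]}")
    if F_b.shape[0] < F_p.shape[0]:
        raise DataError("background must have at least as many rows as presence")
    if beta_multiplier < 0:
        raise ConfigError("beta_multiplier must be >= 0")

    beta = feature_penalties(F_p, feature_defs, beta_multiplier)
    pres_mean = F_p.mean(axis=0)
    J = F_p.shape[1]

    lam = np.zeros(J)
    smooth, grad, _, _ = _objective_parts(lam, pres_mean, F_b)
    obj = smooth + beta @ np.abs(lam)
    history = [obj]

    # Monotone FISTA: momentum point y, accepted iterate lam.
    y = lam.copy()
    smooth_y, grad_y = smooth, grad
    t = 1.0
    L = 1.0
    n_iter = 0
    residual = _kkt_residual(lam, grad, beta)

    for n_iter in range(1, max_iter + 1):
        if residual <= tol:
            break
        # Backtracking proximal step from y.
        for _ in range(60):
            step = y - grad_y / L
            z = np.sign(step) * np.maximum(np.abs(step) - beta / L, 0.0)
            dz = z - y
            smooth_z = -pres_mean @ z + logsumexp(F_b @ z)
            if smooth_z <= smooth_y + grad_y @ dz + 0.5 * L * (dz @ dz) + 1e-12:
                break
            L *= 2.0
        obj_z = smooth_z + beta @ np.abs(z)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        if obj_z <= obj:
            lam_next = z
            obj_next = obj_z
        else:  # keep the best iterate; momentum still rides z
            lam_next = lam
            obj_next = obj
        y = lam_next + (t / t_next) * (z - lam_next) + ((t - 1.0) / t_next) * (
            lam_next - lam
        )
        lam, obj = lam_next, obj_next
        t = t_next
        history.append(obj)
        if np.abs(lam).max() > _WEIGHT_DIVERGENCE_BOUND:
            raise ConvergenceError(
                "weights diverging: presences appear separable from the "
                "background under the given penalties (objective unbounded)",
                residual=residual,
            )
        L = max(L * 0.9, 1e-8)  # gentle step growth
        smooth_y, grad_y, _, _ = _objective_parts(y, pres_mean, F_b)
        _, grad_lam, _, _ = _objective_parts(lam, pres_mean, F_b)
        residual = _kkt_residual(lam, grad_lam, beta)

    if residual > tol:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (KKT residual "
            f"{residual:.3e} > tol {tol:.1e})",
            residual=residual,
        )

    scores = F_b @ lam
    lz = float(logsumexp(scores))
    q = np.exp(scores - lz)
    # H = logZ - E_q[score]; exact (H == logZ) for the all-zero-weight model
    entropy = max(0.0, float(lz - q @ scores))
    bg_means = (
        np.asarray(background_design, dtype=float).mean(axis=0)
        if background_design is not None
        else None
    )
    return MaxEntModel(
        variables=list(variables),
        feature_defs=list(feature_defs),
        weights=lam,
        penalties=beta,
        beta_multiplier=beta_multiplier,
        log_z=lz,
        entropy=entropy,
        background_means=bg_means,
        objective_history=np.asarray(history),
        fitted=True,
        n_iter=n_iter,
        kkt_residual=residual,
    )


def fit_maxent_on_design(
    presence_design: np.ndarray,
    background_design: np.ndarray,
    variables: list[str],
    beta_multiplier: float = 1.0,
    kinds=FEATURE_KINDS,
    n_hinge_knots: int = DEFAULT_N_HINGE_KNOTS,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> MaxEntModel:
    """Convenience wrapper: expand features on raw designs, then fit."""
    defs = make_feature_defs(background_design, variables, kinds, n_hinge_knots)
    if not defs:
        raise DataError("no usable features (all variables constant?)")
    F_b = transform_features(background_design, defs, variables)
    F_p = transform_features(presence_design, defs, variables)
    return fit_maxent(
        F_p,
        F_b,
        defs,
        variables,
        beta_multiplier=beta_multiplier,
        tol=tol,
        max_iter=max_iter,
        background_design=background_design,
    )


def sample_background(
    stack,
    seed: int = 0,
    max_cells: int = MAX_BACKGROUND_CELLS,
    variables=None,
) -> np.ndarray:
    """Background design: all unmasked cells, or a seeded uniform subsample
    of *max_cells* when the domain is larger."""
    full = stack.background_matrix(variables)
    if full.shape[0] <= max_cells:
        return full
    rng = np.random.default_rng(seed)
    idx = rng.choice(full.shape[0], size=max_cells, replace=False)
    return full[np.sort(idx)]


def variable_contribution(
    model: MaxEntModel,
    presence_design: np.ndarray,
    background_design: np.ndarray,
    n_permutations: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance as percent contributions summing to 100.

    For each variable, its values are permuted jointly across the pooled
    presence+background rows and the drop in training AUC is averaged over
    permutations; drops are floored at zero and normalized.
    """
    from .evaluation import roc_auc

    model._check_fitted()
    variables = model.variables
    if len(variables) == 1:
        return {variables[0]: 100.0}
    P = np.atleast_2d(np.asarray(presence_design, dtype=float))
    B = np.atleast_2d(np.asarray(background_design, dtype=float))
    m = P.shape[0]
    pooled = np.vstack([P, B])
    base_auc = roc_auc(
        model.predict(P, output="raw"), model.predict(B, output="raw")
    )
    rng = np.random.default_rng(seed)
    drops = np.zeros(len(variables))
    for j in range(len(variables)):
        acc = 0.0
        for _ in range(n_permutations):
            perm = pooled.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            scores = model.predict(perm, output="raw")
            acc += base_auc - roc_auc(scores[:m], scores[m:])
        drops[j] = max(acc / n_permutations, 0.0)
    total = drops.sum()
    if total <= 0:
        pct = np.full(len(variables), 100.0 / len(variables))
    else:
        pct = 100.0 * drops / total
    return dict(zip(variables, pct))


def response_curve(
    model: MaxEntModel,
    variable: str,
    n_points: int = 100,
    output: str = "logistic",
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted score along one variable, others held at background means."""
    model._check_fitted()
    if variable not in model.variables:
        raise ConfigError(f"unknown variable {variable!r}")
    if model.background_means is None:
        raise ModelStateError("model lacks stored background means")
    j = model.variables.index(variable)
    los = [fd.lo for fd in model.feature_defs if fd.variable == variable]
    his = [fd.hi for fd in model.feature_defs if fd.variable == variable]
    lo, hi = min(los), max(his)
    xs = np.linspace(lo, hi, n_points)
    design = np.tile(model.background_means, (n_points, 1))
    design[:, j] = xs
    return xs, model.predict(design, output=output)
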