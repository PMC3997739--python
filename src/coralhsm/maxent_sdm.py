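"""From-scratch maximum-entropy presence-background model.

The model is the Gibbs distribution q(x) = exp(sum_j lambda_j f_j(x)) / Z
over a background sample, fitted by minimising the L1-regularised negative
average presence log-likelihood

    J(lambda) = log Z(lambda) - lambda . fbar_presence + sum_j beta_j |lambda_j|

which is convex; at the optimum the moment condition
|E_q[f_j] - fbar_j| <= beta_j holds, with equality wherever lambda_j != 0.
The optimiser splits lambda into positive and negative parts so the
objective is smooth over a box, and runs L-BFGS-B with an explicit stopping
rule on the objective improvement (the "convergence threshold").

Feature classes follow the usual presence-only defaults: linear always,
quadratic from 10 presences, hinge from 15, product from 80; all features
are rescaled to [0, 1] against the background and clamped outside its range.
The per-feature regularisation is
beta_j = multiplier * c_class(m) * sd_j(presences) / sqrt(m), with c_class
linearly interpolated in the presence count m from a small published table.
The logistic habitat suitability index is e^H q / (1 + e^H q), with H the
entropy of the fitted distribution, so the null model scores exactly 0.5
everywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "FeatureSpec",
    "MaxentModel",
    "build_features",
    "featurize",
    "default_betas",
    "fit_maxent",
    "logistic_output",
    "training_gain",
    "jackknife_importance",
]

# (presence count, multiplier) knots; linear interpolation, clamped
_BETA_KNOTS = {
    "linear": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "quadratic": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "product": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "hinge": [(0, 0.5)],
}


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: a transform of one (or two) variables, rescaled to [0,1]
    against the background with clamping."""

    name: str
    variable: str
    kind: str  # linear | quadratic | product | hinge
    vmin: float
    vmax: float
    knot: float | None = None
    partner: str | None = None

    def raw(self, values: dict[str, np.ndarray]) -> np.ndarray:
        v = np.asarray(values[self.variable], dtype=float)
        if self.kind == "linear":
            return v
        if self.kind == "quadratic":
            return v**2
        if self.kind == "product":
            return v * np.asarray(values[self.partner], dtype=float)
        if self.kind == "hinge":
            return np.maximum(v - self.knot, 0.0)
        raise ValueError(f"unknown feature kind {self.kind!r}")

    def scaled(self, values: dict[str, np.ndarray]) -> np.ndarray:
        raw = self.raw(values)
        span = self.vmax - self.vmin
        if span <= 0:
            return np.zeros_like(raw)
        return np.clip((raw - self.vmin) / span, 0.0, 1.0)


@dataclass
class MaxentModel:
    features: list[FeatureSpec]
    lam: np.ndarray
    beta: np.ndarray
    log_z: float
    entropy: float
    gain: float
    n_background: int
    iterations: int
    converged: bool
    objective_history: list[float] = field(default_factory=list, repr=False)
    seed: int | None = None

    def scores(self, feature_matrix: np.ndarray) -> np.ndarray:
        """log q(x) for rows of a feature matrix."""
        return feature_matrix @ self.lam - self.log_z

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": [vars(f) | {} for f in self.features],
                "lambda": self.lam.tolist(),
                "beta": self.beta.tolist(),
                "log_z": self.log_z,
                "entropy": self.entropy,
                "gain": self.gain,
                "n_background": self.n_background,
                "iterations": self.iterations,
                "converged": self.converged,
                "seed": self.seed,
            },
            indent=2,
        )


def enabled_classes(m: int) -> tuple[str, ...]:
    """Feature classes enabled by the presence sample size."""
    classes = ["linear"]
    if m >= 10:
        classes.append("quadratic")
    if m >= 15:
        classes.append("hinge")
    if m >= 80:
        classes.append("product")
    return tuple(classes)


def build_features(
    background_values: dict[str, np.ndarray] | pd.DataFrame,
    m: int,
    n_hinge_knots: int = 9,
) -> list[FeatureSpec]:
    """Build feature specs from background samples of each variable.

    Constant variables contribute no features (warned).  Hinge knots sit at
    the background deciles.
    """
    if m < 2:
        raise ValueError("need at least two presences")
    if isinstance(background_values, pd.DataFrame):
        background_values = {c: background_values[c].to_numpy() for c in background_values}
    classes = enabled_classes(m)
    variables = list(background_values)
    specs: list[FeatureSpec] = []
    usable = []
    for var in variables:
        v = np.asarray(background_values[var], dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite background values for {var!r}")
        if v.min() == v.max():
            warnings.warn(f"variable {var!r} is constant on the background; dropped")
            continue
        usable.append(var)
        specs.append(FeatureSpec(var, var, "linear", float(v.min()), float(v.max())))
        if "quadratic" in classes:
            sq = v**2
            specs.append(
                FeatureSpec(f"{var}^2", var, "quadratic", float(sq.min()), float(sq.max()))
            )
        if "hinge" in classes:
            qs = np.quantile(v, np.linspace(0.1, 0.9, n_hinge_knots))
            for i, knot in enumerate(dict.fromkeys(qs)):  # dedupe, keep order
                if knot >= v.max():
                    continue
                hi = float(v.max() - knot)
                specs.append(
                    FeatureSpec(f"{var}:hinge{i}", var, "hinge", 0.0, hi, knot=float(knot))
                )
    if "product" in classes:
        for i, a in enumerate(usable):
            va = np.asarray(background_values[a], dtype=float)
            for b in usable[i + 1 :]:
                vb = np.asarray(background_values[b], dtype=float)
                prod = va * vb
                if prod.min() == prod.max():
                    continue
                specs.append(
                    FeatureSpec(
                        f"{a}*{b}", a, "product", float(prod.min()), float(prod.max()), partner=b
                    )
                )
    return specs


def featurize(
    specs: list[FeatureSpec], values: dict[str, np.ndarray] | pd.DataFrame
) -> np.ndarray:
    if isinstance(values, pd.DataFrame):
        values = {c: values[c].to_numpy() for c in values}
    if not specs:
        n = len(next(iter(values.values())))
        return np.zeros((n, 0))
    return np.column_stack([s.scaled(values) for s in specs])


def _interp_beta_multiplier(kind: str, m: int) -> float:
    knots = _BETA_KNOTS[kind]
    ms = np.array([k[0] for k in knots], dtype=float)
    cs = np.array([k[1] for k in knots], dtype=float)
    return float(np.interp(m, ms, cs))


def default_betas(
    specs: list[FeatureSpec],
    presence_features: np.ndarray,
    reg_multiplier: float = 1.0,
) -> np.ndarray:
    """beta_j = multiplier * c_class(m) * sd_j(presences) / sqrt(m), with the
    standard deviation floored so no feature is left unregularised."""
    m = presence_features.shape[0]
    sd = presence_features.std(axis=0, ddof=0)
    sd = np.maximum(sd, 1e-4)
    c = np.array([_interp_beta_multiplier(s.kind, m) for s in specs])
    return reg_multiplier * c * sd / np.sqrt(m)


class _Objective:
    """Smooth objective over (lambda+, lambda-) >= 0."""

    def __init__(self, F_bg: np.ndarray, fbar: np.ndarray, beta: np.ndarray):
        self.F = F_bg
        self.fbar = fbar
        self.beta = beta
        self.j = F_bg.shape[1]

    def split(self, theta: np.ndarray) -> np.ndarray:
        return theta[: self.j] - theta[self.j :]

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam = self.split(theta)
        s = self.F @ lam
        smax = s.max() if len(s) else 0.0
        log_z = smax + np.log(np.exp(s - smax).sum())
        q = np.exp(s - log_z)
        eq = q @ self.F
        value = log_z - lam @ self.fbar + self.beta @ (theta[: self.j] + theta[self.j :])
        grad_plus = eq - self.fbar + self.beta
        grad_minus = -(eq - self.fbar) + self.beta
        return value, np.concatenate([grad_plus, grad_minus])


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    features: list[FeatureSpec] | None = None,
    betas: np.ndarray | None = None,
    reg_multiplier: float = 1.0,
    convergence: float = 1e-5,
    max_iterations: int = 500,
    seed: int | None = None,
) -> MaxentModel:
    """Fit the regularised maxent model.

    ``betas`` overrides the default per-feature regularisation (pass zeros
    for an unregularised fit).  Iteration stops when the objective improves
    by less than ``convergence`` or after ``max_iterations``.
    """
    P = np.asarray(presence_features, dtype=float)
    B = np.asarray(background_features, dtype=float)
    if P.ndim != 2 or B.ndim != 2 or P.shape[1] != B.shape[1]:
        raise ValueError("presence/background feature matrices must share columns")
    if P.shape[0] < 2:
        raise ValueError("need at least two presence cells")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite feature values")
    n_bg, j = B.shape
    fbar = P.mean(axis=0) if j else np.zeros(0)
    if betas is None:
        if features is None:
            raise ValueError("either betas or feature specs required for regularisation")
        betas = default_betas(features, P, reg_multiplier)
    betas = np.asarray(betas, dtype=float)

    if j == 0:  # all features dropped (e.g. constant layers): the null model
        log_z = float(np.log(n_bg))
        return MaxentModel(
            features=features or [], lam=np.zeros(0), beta=betas, log_z=log_z,
            entropy=log_z, gain=0.0, n_background=n_bg, iterations=0,
            converged=True, objective_history=[log_z], seed=seed,
        )

    obj = _Objective(B, fbar, betas)
    history: list[float] = []
    state = {"stopped": False}

    def callback(theta: np.ndarray) -> None:
        value, _ = obj(theta)
        if history and history[-1] - value < convergence:
            history.append(value)
            state["stopped"] = True
            raise StopIteration
        history.append(value)

    theta0 = np.zeros(2 * j)
    history.append(obj(theta0)[0])
    res = minimize(
        obj,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * j),
        callback=callback,
        options={"maxiter": max_iterations, "ftol": 1e-14, "gtol": 1e-12},
    )
    lam = obj.split(res.x)
    s = B @ lam
    smax = s.max() if len(s) else 0.0
    log_z = float(smax + np.log(np.exp(s - smax).sum()))
    q = np.exp(s - log_z)
    entropy = float(-(q * np.log(np.clip(q, 1e-300, None))).sum())
    raw = P @ lam
    gain = float(raw.mean() - log_z + np.log(n_bg) - betas @ np.abs(lam))
    iterations = len(history) - 1
    final_value = obj(res.x)[0]
    if final_value > history[0] + 1e-9:  # divergence: the convex objective rose
        raise RuntimeError(f"maxent optimisation diverged: {res.message}")
    if final_value < history[-1]:
        history.append(final_value)
    tail_improvement = history[-2] - history[-1] if len(history) > 1 else 0.0
    # an abnormal line-search exit at a stationary point still counts as
    # converged when the objective has stopped improving
    converged = state["stopped"] or bool(res.success) or tail_improvement < convergence
    model = MaxentModel(
        features=features or [],
        lam=lam,
        beta=betas,
        log_z=log_z,
        entropy=entropy,
        gain=gain,
        n_background=n_bg,
        iterations=iterations,
        converged=converged,
        objective_history=history,
        seed=seed,
    )
    return model


def logistic_output(model: MaxentModel, feature_matrix: np.ndarray) -> np.ndarray:
    """Habitat suitability index in [0, 1]: e^H q / (1 + e^H q)."""
    from scipy.special import expit

    log_qe = model.scores(np.asarray(feature_matrix, dtype=float)) + model.entropy
    return expit(log_qe)  # stable logistic of log(e^H q)


def training_gain(model: MaxentModel, presence_features: np.ndarray) -> float:
    """Regularised training gain in nats: mean presence log(q N_bg) minus the
    L1 penalty.  The null model scores exactly 0."""
    P = np.asarray(presence_features, dtype=float)
    raw = P @ model.lam  # exactly zero for the null model
    return float(
        raw.mean() - model.log_z + np.log(model.n_background)
        - model.beta @ np.abs(model.lam)
    )


def jackknife_importance(
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    test_values: pd.DataFrame | None = None,
    reg_multiplier: float = 1.0,
    convergence: float = 1e-5,
    max_iterations: int = 500,
) -> pd.DataFrame:
    """Leave-one-out / only-one variable importance.

    For each variable: the regularised training gain of the model without it,
    of the model with it alone, and the evaluation AUC of the single-variable
    model (held-out presences when ``test_values`` is given, else training
    presences).
    """
    from .spatial_cv import auc_presence_background

    variables = list(background_values.columns)
    m = len(presence_values)
    eval_values = test_values if test_values is not None else presence_values

    def _fit(cols: list[str]):
        specs = build_features(background_values[cols], m)
        P = featurize(specs, presence_values[cols])
        B = featurize(specs, background_values[cols])
        model = fit_maxent(
            P, B, features=specs, reg_multiplier=reg_multiplier,
            convergence=convergence, max_iterations=max_iterations,
        )
        return specs, model, P

    rows = []
    for var in variables:
        others = [v for v in variables if v != var]
        if len(others) >= 1:
            _, model_without, P_wo = _fit(others)
            gain_without = training_gain(model_without, P_wo)
        else:
            gain_without = 0.0
        try:
            specs_only, model_only, P_only = _fit([var])
        except Exception:
            rows.append(
                {"variable": var, "gain_without": gain_without,
                 "gain_with_only": np.nan, "auc_with_only": np.nan, "flagged": True}
            )
            continue
        gain_only = training_gain(model_only, P_only)
        eval_F = featurize(specs_only, eval_values[[var]])
        bg_F = featurize(specs_only, background_values[[var]])
        auc = auc_presence_background(
            logistic_output(model_only, eval_F), logistic_output(model_only, bg_F)
        )
        rows.append(
            {"variable": var, "gain_without": gain_without,
             "gain_with_only": gain_only, "auc_with_only": auc, "flagged": False}
        )
    table = pd.DataFrame(rows).set_index("variable")
    return table.sort_values("gain_with_only", ascending=False)
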