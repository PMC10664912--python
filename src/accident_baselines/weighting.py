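"""Strict maximum-entropy representative sample weighting.

Survey samples are biased: propensity to respond differs across demographic
groups. Calibration weighting fixes this by assigning each respondent a
weight such that the weighted per-category shares reproduce known population
marginals exactly, while the weights stay as close to uniform as possible —
formally, maximize the entropy -sum w_s ln w_s subject to Y w = p, w >= 0,
1'w = 1, where Y is the stacked one-hot indicator matrix of the sample and p
the stacked population marginal shares.

The solver works on the dual: the optimum has the product (raking) form
w_s proportional to exp(sum_k lambda_k y_ks), and the dual objective
g(lambda) = log sum_s exp(y_s' lambda) - p' lambda is smooth and convex with
gradient Y w(lambda) - p, so a quasi-Newton method drives the marginal
residuals to zero directly. Per-feature constraint redundancy (each feature's
shares sum to 1 on both sides) only creates flat directions, which gradient
methods traverse harmlessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from scipy.special import logsumexp

from .harmonize import MarginalTargets, SurveySample
from .scheme import FeatureScheme


class InfeasibleTargetsError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, residuals: np.ndarray):
        super().__init__(msg)
        self.residuals = residuals


@dataclass
class IndicatorMatrix:
    """K x S stacked one-hot matrix: row k is the indicator of (feature,
    category) pair k across sample instances."""

    scheme: FeatureScheme
    y: np.ndarray

    @property
    def K(self) -> int:
        return self.y.shape[0]

    @property
    def S(self) -> int:
        return self.y.shape[1]


@dataclass
class SolverSettings:
    """Convergence tolerances for the calibration solve.

    ``eps_rel``/``eps_abs`` bound the marginal residual Yw - p (absolute and
    relative to the target); the regularizer is fixed to entropy and the loss
    to strict equality, so the regularization weight is immaterial and kept
    only for interface stability.
    """

    eps_rel: float = 1e-6
    eps_abs: float = 1e-6
    maxiter: int = 100_000
    regularizer: str = "entropy"
    loss: str = "equality"
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_rel <= 0 or self.eps_abs <= 0 or self.maxiter < 1:
            raise ValueError("tolerances must be positive and maxiter >= 1")


@dataclass
class WeightVector:
    """Nonnegative per-instance weights on the simplex, plus solve diagnostics."""

    w: np.ndarray
    residuals: np.ndarray | None = None
    n_iter: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, float)
        if (self.w < -1e-12).any():
            raise ValueError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {self.w.sum()}, not 1")

    @property
    def S(self) -> int:
        return self.w.size


def build_indicator_matrix(sample: SurveySample, scheme: FeatureScheme) -> IndicatorMatrix:
    """Stack the per-feature one-hot encodings of the sample into one K x S
    binary matrix (column sums all equal the number of features)."""
    S = sample.S
    y = np.zeros((scheme.K, S), dtype=np.int8)
    for s, (_, row) in enumerate(sample.values.iterrows()):
        for f in scheme.features:
            try:
                k = scheme.flat_index(f, row[f])
            except KeyError as e:
                raise ValueError(str(e)) from None
            y[k, s] = 1
    return IndicatorMatrix(scheme=scheme, y=y)


def check_feasibility(Y: IndicatorMatrix, targets: MarginalTargets) -> dict:
    """Report whether the targets can be met by any weighting of this sample.

    A category with positive target share but no sample instance makes the
    equality constraints unsatisfiable; per-feature target shares must also
    each form a distribution.
    """
    scheme = Y.scheme
    p = targets.as_vector(scheme)
    row_counts = Y.y.sum(axis=1)
    empty = [
        {"feature": f, "category": c, "target": float(p[k])}
        for k, (f, c) in enumerate(scheme.flat_pairs())
        if p[k] > 0 and row_counts[k] == 0
    ]
    bad_sums = []
    k = 0
    for f in scheme.features:
        j = len(scheme.categories[f])
        ssum = float(p[k:k + j].sum())
        if abs(ssum - 1.0) > 1e-9:
            bad_sums.append({"feature": f, "sum": ssum})
        k += j
    return {"feasible": not empty and not bad_sums,
            "empty_categories": empty, "bad_feature_sums": bad_sums}


def solve_weights(
    Y: IndicatorMatrix,
    targets: MarginalTargets,
    settings: SolverSettings | None = None,
) -> WeightVector:
    """Solve the strict entropy-calibration program for this sample.

    Returns the unique maximum-entropy weights satisfying every marginal
    constraint. Categories with an exactly-zero target are handled by pinning
    their instances to weight zero before the dual solve (the entropy optimum
    sends them to zero in the limit). Deterministic: no randomness anywhere.
    """
    settings = settings or SolverSettings()
    scheme = Y.scheme
    p = targets.as_vector(scheme)
    feas = check_feasibility(Y, targets)
    if not feas["feasible"]:
        detail = feas["empty_categories"] or feas["bad_feature_sums"]
        raise InfeasibleTargetsError(f"infeasible marginal targets: {detail}")

    y = np.asarray(Y.y, float)
    S = Y.S
    # instances in any zero-target category are forced to weight zero
    zero_rows = np.flatnonzero((p == 0) & (y.sum(axis=1) > 0))
    active = np.ones(S, bool)
    if zero_rows.size:
        active = y[zero_rows].sum(axis=0) == 0
        if not active.any():
            raise InfeasibleTargetsError("every instance lies in a zero-target category")
    ya = y[:, active]

    def dual(lam: np.ndarray):
        eta = ya.T @ lam
        lse = logsumexp(eta)
        w = np.exp(eta - lse)
        return lse - p @ lam, ya @ w - p

    lam0 = np.zeros(scheme.K)
    res = scipy.optimize.minimize(
        dual, lam0, jac=True, method="L-BFGS-B",
        options={"maxiter": settings.maxiter, "maxfun": settings.maxiter,
                 "gtol": min(settings.eps_abs, settings.eps_rel) * 1e-3,
                 "ftol": 1e-15},
    )
    eta = ya.T @ res.x
    wa = np.exp(eta - logsumexp(eta))
    w = np.zeros(S)
    w[active] = wa
    resid = y @ w - p
    ok = (np.abs(resid) <= settings.eps_abs).all() or (
        np.abs(resid) <= settings.eps_rel * np.maximum(np.abs(p), 1e-12)
    ).all()
    if not ok:
        raise ConvergenceError(
            f"calibration did not converge (max residual {np.abs(resid).max():.3e})",
            residuals=resid,
        )
    return WeightVector(
        w=w, residuals=resid, n_iter=int(res.nit),
        diagnostics={
            "max_abs_residual": float(np.abs(resid).max()),
            "entropy": weight_entropy(w),
            "uniform_entropy": uniform_entropy(S),
            "n_pinned_zero": int(S - active.sum()),
        },
    )


def weight_entropy(w) -> float:
    """Shannon entropy -sum w_s ln w_s of a weight vector (natural log,
    reported positive); zero weights contribute 0."""
    w = np.asarray(getattr(w, "w", w), float)
    nz = w[w > 0]
    return float(-(nz * np.log(nz)).sum())


def uniform_entropy(S: int) -> float:
    """Entropy ln S of the uniform distribution over S instances — the upper
    bound any weighting can reach."""
    return float(np.log(S))
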