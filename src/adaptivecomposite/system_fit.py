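"""Scale-factor fitting against reference heats of formation.

Every fit minimizes a smooth quadratic: the squared deviation of the
calculated 298 K heat of formation from its experimental reference, plus an
optional ridge penalty anchored at the unit factors,

    L(theta) = sum_m (dHf_m(theta) - dHf_exp_m)^2 + ridge * ||theta - 1||^2 .

Optimization starts at theta = (1, 1, 1, 1) and uses BFGS with the analytic
gradient.  Because dHf is affine in theta the objective is convex quadratic,
so the optimum also has a ridge least-squares closed form
(:func:`ridge_closed_form`); the iterative and analytic routes agree to
high precision and the closed form doubles as an independent check.

A single system gives one equation in four unknowns.  The default ridge of
1e-8 selects, among the exact-fit solutions, the one nearest the unit
factors — the natural choice for a quasi-Newton iteration started there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .data_model import AtomReferenceTable, ScaleParams, SystemRecord
from .energy_model import dhf_affine_coefficients

__all__ = [
    "FitResult",
    "UnfittableSystemError",
    "DEFAULT_RIDGE",
    "fit_system_params",
    "fit_group_params",
    "build_parameter_matrix",
    "ridge_closed_form",
]

DEFAULT_RIDGE = 1e-8
_START = np.ones(4)


class UnfittableSystemError(ValueError):
    """No scale factor influences the residual, which is nonzero."""


@dataclass(frozen=True)
class FitResult:
    params: ScaleParams
    residual: float  # signed calc - exp at the optimum (kcal/mol); for groups, MAE-bearing rows live in `residuals`
    n_iter: int
    converged: bool
    objective: float
    residuals: np.ndarray | None = None  # per-member signed deviations (group fits)
    rank_deficient: bool = False

    @property
    def mae(self) -> float:
        """Mean absolute deviation over the fitted members (kcal/mol)."""
        if self.residuals is None:
            return abs(self.residual)
        return float(np.mean(np.abs(self.residuals)))


def _design(members, ref) -> tuple[np.ndarray, np.ndarray]:
    """Stack affine coefficients: rows G[i], targets r[i] with
    residual_i(theta) = G[i] . theta + h0_i - dhf_exp_i."""
    G, r = [], []
    for molecule, atoms, dhf_exp in members:
        g, h0 = dhf_affine_coefficients(molecule, atoms, ref)
        G.append(g)
        r.append(h0 - dhf_exp)
    return np.vstack(G), np.asarray(r, dtype=float)


def ridge_closed_form(G: np.ndarray, r: np.ndarray,
                      ridge: float) -> tuple[np.ndarray, bool]:
    """Analytic minimizer of ||G theta_delta + resid(1)||^2 + ridge ||theta_delta||^2.

    ``r`` must already be the residual vector at theta = 1, i.e.
    ``G @ 1 + h0 - dhf_exp``.  Returns (theta, rank_deficient); with
    ridge = 0 and a rank-deficient design the minimum-norm-about-(1,1,1,1)
    solution is used.
    """
    rank = np.linalg.matrix_rank(G, tol=1e-10 * max(float(np.abs(G).max()), 1.0))
    rank_deficient = rank < 4
    if ridge > 0:
        # augmented least squares keeps the conditioning at sqrt of the
        # normal-equation level, which matters for tiny ridges
        A = np.vstack([G, np.sqrt(ridge) * np.eye(4)])
        b = np.concatenate([-r, np.zeros(4)])
        delta = np.linalg.lstsq(A, b, rcond=None)[0]
    else:
        delta = np.linalg.lstsq(G, -r, rcond=None)[0]
    return _START + delta, rank_deficient


def _fit(members, ref, ridge, gtol, maxiter=500) -> FitResult:
    G, h = _design(members, ref)
    r1 = G @ _START + h  # residuals at unit factors

    if np.allclose(G, 0.0):
        if np.any(np.abs(r1) > 1e-9):
            ids = [m[0].id for m in members]
            raise UnfittableSystemError(
                f"no scale factor influences the residual for {ids}"
            )

    def objective(theta):
        res = G @ (theta - _START) + r1
        pen = theta - _START
        val = res @ res + ridge * (pen @ pen)
        grad = 2.0 * G.T @ res + 2.0 * ridge * pen
        return val, grad

    # normalize curvature so the gradient tolerance means the same thing
    # regardless of the kcal-scale magnitude of the coefficients
    scale = max(float(np.sum(G * G)), 1.0)

    def scaled(theta):
        val, grad = objective(theta)
        return val / scale, grad / scale

    sol = minimize(scaled, _START.copy(), jac=True, method="BFGS",
                   options={"gtol": gtol, "maxiter": maxiter})
    # scipy flags "precision loss" when the line search hits float limits on
    # a nearly flat valley; the iterate it returns is still the optimum to
    # the accuracy we verify against the closed form
    theta = sol.x
    _, rank_deficient = ridge_closed_form(G, r1, ridge)
    residuals = G @ (theta - _START) + r1
    return FitResult(
        params=ScaleParams.from_array(theta),
        residual=float(residuals[0]) if len(residuals) == 1 else float(np.mean(residuals)),
        n_iter=int(sol.nit),
        converged=bool(sol.success) or np.linalg.norm(scaled(theta)[1]) <= 1e-8,
        objective=float(objective(theta)[0]),
        residuals=residuals if len(residuals) > 1 else None,
        rank_deficient=rank_deficient,
    )


def fit_system_params(molecule: SystemRecord, atoms: Sequence[SystemRecord],
                      dhf_exp: float, ref: AtomReferenceTable,
                      ridge: float = DEFAULT_RIDGE) -> FitResult:
    """Fit (a, b, c, d) for one system to its reference heat of formation."""
    if dhf_exp is None:
        raise ValueError(f"{molecule.id}: no reference heat of formation")
    return _fit([(molecule, atoms, dhf_exp)], ref, ridge, gtol=1e-12)


def fit_group_params(members: Sequence[tuple[SystemRecord, Sequence[SystemRecord], float]],
                     ref: AtomReferenceTable,
                     ridge: float = 0.0) -> FitResult:
    """Fit one shared (a, b, c, d) over all members of a group."""
    if not members:
        raise ValueError("empty member list")
    return _fit(list(members), ref, ridge, gtol=1e-12)


def build_parameter_matrix(
    systems: Sequence[tuple[SystemRecord, Sequence[SystemRecord], float]],
    ref: AtomReferenceTable,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """Per-system fitted factors stacked into an (n_systems, 4) matrix.

    Row order follows the input order.
    """
    rows = []
    for molecule, atoms, dhf_exp in systems:
        try:
            rows.append(fit_system_params(molecule, atoms, dhf_exp, ref, ridge)
                        .params.as_array())
        except UnfittableSystemError as exc:
            raise UnfittableSystemError(f"system {molecule.id}: {exc}") from exc
    return np.vstack(rows)
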