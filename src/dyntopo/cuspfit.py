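"""Stochastic cusp-catastrophe density: maximum likelihood fit and fit indices.

The stationary density of the stochastic cusp is

    f(x | alpha, beta) = psi(alpha, beta) * exp(alpha*x + beta*x^2/2 - x^4/4)

with normalizing constant ``psi`` obtained by numerical quadrature.  Following
the standard regression formulation of this model, the shape parameters and
the state are linear in observed covariates:

    alpha_i = a0 + a1 * A_i
    beta_i  = b0 + b1 * B_i
    w_i     = w0 + w1 * Y_i        (fitted linear rescaling of the state)

and the log-likelihood (including the Jacobian of the state transformation)

    l = sum_i [ alpha_i w_i + beta_i w_i^2/2 - w_i^4/4 - log Z(alpha_i, beta_i) ]
        + n*log(w1)

is maximized over (a0, a1, b0, b1, w0, w1) by multi-start quasi-Newton
optimization with analytic gradients.

The pseudo-R-square ("Cobb's R2") assigns each observation to the stationary
point of its fitted density nearest to it — the delay convention, which
handles the folded (bimodal) region by allowing observations above and below
the fold to be explained by their own branch — and reports
``1 - Var(residual)/Var(w)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "CuspFit",
    "fit_cusp_mle",
    "linear_r2",
    "cobb_r2",
    "cusp_density",
    "cusp_normalizer",
    "stationary_points",
    "nearest_stationary_points",
    "sample_cusp",
]


# ----------------------------------------------------------------------
# density utilities
# ----------------------------------------------------------------------
def _quad_range(alpha: np.ndarray, beta: np.ndarray, extra: float = 0.0) -> float:
    """Half-width of a quadrature interval outside which the density is
    negligible.  Stationary points satisfy x^3 = alpha + beta*x, bounded by
    max(2, sqrt(2|beta|), (2|alpha|)^(1/3)); add margin for tail mass."""
    a = float(np.max(np.abs(alpha))) if np.size(alpha) else 0.0
    b = float(np.max(np.abs(beta))) if np.size(beta) else 0.0
    bound = max(2.0, np.sqrt(2 * b), (2 * a) ** (1 / 3))
    return max(6.0, 1.2 * bound + 2.0, extra)


def _simpson_grid(R: float, step: float = 0.02) -> Tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes on [-R, R] with composite-Simpson weights."""
    npts = int(np.ceil(2 * R / step))
    if npts % 2 == 1:
        npts += 1
    x = np.linspace(-R, R, npts + 1)
    h = x[1] - x[0]
    w = np.ones(npts + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= h / 3.0
    return x, w


def _exp_family_moments(
    alpha: np.ndarray, beta: np.ndarray, x: np.ndarray, w: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log Z, E[X], E[X^2] of the cusp density for each (alpha, beta) pair."""
    G = (
        alpha[:, None] * x[None, :]
        + beta[:, None] * (x[None, :] ** 2) / 2.0
        - (x[None, :] ** 4) / 4.0
    )
    Gmax = G.max(axis=1, keepdims=True)
    E = np.exp(G - Gmax)
    Z0 = E @ w
    EX = (E @ (w * x)) / Z0
    EX2 = (E @ (w * x**2)) / Z0
    logZ = np.log(Z0) + Gmax[:, 0]
    return logZ, EX, EX2


def cusp_normalizer(alpha: float, beta: float) -> float:
    """psi(alpha, beta): reciprocal of the quadrature integral of the kernel.

    The quadrature interval is widened until the relative tail mass of the
    kernel is below 1e-10.
    """
    R = _quad_range(np.asarray([alpha]), np.asarray([beta]))
    while True:
        x, w = _simpson_grid(R, step=0.01)
        kern = np.exp(alpha * x + beta * x**2 / 2 - x**4 / 4)
        total = float(kern @ w)
        edge = max(kern[0], kern[-1])
        if edge * 2 * R < 1e-10 * total:
            return 1.0 / total
        R *= 1.5


def cusp_density(y, alpha: float, beta: float):
    """Normalized cusp density evaluated at ``y`` (scalar or array)."""
    psi = cusp_normalizer(alpha, beta)
    y = np.asarray(y, dtype=float)
    return psi * np.exp(alpha * y + beta * y**2 / 2 - y**4 / 4)


def stationary_points(alpha: float, beta: float) -> np.ndarray:
    """Real roots of ``alpha + beta*x - x^3 = 0`` (equilibria of the fitted
    surface: the density's modes and, in the bimodal regime, its antimode)."""
    roots = np.roots([-1.0, 0.0, beta, alpha])
    return np.sort(roots[np.abs(roots.imag) < 1e-8].real)


def nearest_stationary_points(
    y: np.ndarray, alpha: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """For each observation, the stationary point of its own density nearest
    to it (delay convention)."""
    y = np.asarray(y, dtype=float)
    out = np.empty(len(y))
    for i in range(len(y)):
        r = stationary_points(float(alpha[i]), float(beta[i]))
        out[i] = r[np.argmin(np.abs(r - y[i]))]
    return out


def sample_cusp(
    alpha: np.ndarray, beta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one observation per (alpha_i, beta_i) pair by rejection sampling
    with a uniform proposal over the effective support."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    R = _quad_range(alpha, beta)
    out = np.full(len(alpha), np.nan)
    pending = np.arange(len(alpha))
    # per-pair kernel maximum: evaluate on a fine grid once
    xg = np.linspace(-R, R, 2001)
    K = np.exp(
        alpha[:, None] * xg[None, :]
        + beta[:, None] * xg[None, :] ** 2 / 2
        - xg[None, :] ** 4 / 4
    )
    Kmax = K.max(axis=1) * 1.05
    while len(pending):
        x = rng.uniform(-R, R, size=len(pending))
        u = rng.uniform(0.0, 1.0, size=len(pending))
        k = np.exp(
            alpha[pending] * x + beta[pending] * x**2 / 2 - x**4 / 4
        )
        accept = u * Kmax[pending] < k
        out[pending[accept]] = x[accept]
        pending = pending[~accept]
    return out


# ----------------------------------------------------------------------
# maximum likelihood fit
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CuspFit:
    """MLE of the cusp density with linear shape and state predictors."""

    alpha_coefs: Tuple[float, float]
    beta_coefs: Tuple[float, float]
    w_coefs: Tuple[float, float]
    loglik: float
    converged: bool

    def transform(self, Y, A, B):
        """Return per-observation (w, alpha, beta) under the fitted model."""
        Y = np.asarray(Y, dtype=float)
        A = np.asarray(A, dtype=float)
        B = np.asarray(B, dtype=float)
        a0, a1 = self.alpha_coefs
        b0, b1 = self.beta_coefs
        w0, w1 = self.w_coefs
        return w0 + w1 * Y, a0 + a1 * A, b0 + b1 * B


def _negll_grad(theta, Y, A, B):
    a0, a1, b0, b1, w0, w1 = theta
    al = a0 + a1 * A
    be = b0 + b1 * B
    w = w0 + w1 * Y
    n = len(Y)
    R = _quad_range(al, be, extra=1.1 * float(np.max(np.abs(w))) if n else 0.0)
    x, wq = _simpson_grid(R, step=max(0.02, 2 * R / 1200))
    logZ, EX, EX2 = _exp_family_moments(al, be, x, wq)
    ll = np.sum(al * w + be * w**2 / 2 - w**4 / 4 - logZ) + n * np.log(abs(w1))
    ga = w - EX
    gb = (w**2 - EX2) / 2
    slope = al + be * w - w**3
    grad = np.array(
        [
            ga.sum(),
            (ga * A).sum(),
            gb.sum(),
            (gb * B).sum(),
            slope.sum(),
            (slope * Y).sum() + n / w1,
        ]
    )
    return -ll, -grad


def fit_cusp_mle(Y, A, B, extra_starts: Sequence[np.ndarray] = ()) -> CuspFit:
    """Fit the cusp density to ``(Y, A, B)`` observations by maximum likelihood.

    Runs L-BFGS-B with analytic gradients from several starting points (the
    canonical identity start, standardized-state variants, and sharper-scale
    variants) and keeps the best local optimum.  ``converged`` is False when
    no start converged or the fit is degenerate (e.g. constant Y).
    """
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if len(Y) < 10:
        raise ValueError(f"need at least 10 observations to fit, got {len(Y)}")
    sY = float(np.std(Y))
    if sY == 0.0:
        return CuspFit((0.0, 0.0), (0.0, 0.0), (float(-np.mean(Y)), 1.0), -np.inf, False)
    mY = float(np.mean(Y))
    starts = [
        np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0]),
        np.array([0.0, 1.0, 0.0, 1.0, -mY / sY, 1.0 / sY]),
        np.array([0.0, 2.0, 0.0, 2.0, -2 * mY / sY, 2.0 / sY]),
        np.array([0.0, 5.0, 1.0, 5.0, 0.0, 3.0]),
    ] + [np.asarray(s, dtype=float) for s in extra_starts]
    bounds = [(None, None)] * 5 + [(1e-6, None)]  # orient the state link upward
    best = None
    any_ok = False
    for s in starts:
        try:
            r = minimize(
                _negll_grad,
                s,
                args=(Y, A, B),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options=dict(maxiter=500),
            )
        except (FloatingPointError, np.linalg.LinAlgError):  # pragma: no cover
            continue
        any_ok = any_ok or bool(r.success)
        if best is None or r.fun < best.fun:
            best = r
    t = best.x
    return CuspFit(
        alpha_coefs=(float(t[0]), float(t[1])),
        beta_coefs=(float(t[2]), float(t[3])),
        w_coefs=(float(t[4]), float(t[5])),
        loglik=-float(best.fun),
        converged=any_ok,
    )


# ----------------------------------------------------------------------
# fit indices
# ----------------------------------------------------------------------
def linear_r2(Y, A, B) -> float:
    """Multiple R-square of OLS predicting ``Y`` from ``A`` and ``B``.

    This is the fold-blind benchmark: a plane fitted through the set-point
    cloud.  Raises on rank-deficient designs (constant A and B)."""
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if len(Y) < 4:
        raise ValueError("need at least 4 points for a two-predictor OLS fit")
    X = np.column_stack([np.ones(len(Y)), A, B])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: A and B do not both vary")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    vy = Y.var()
    if vy == 0.0:
        raise ValueError("constant Y: R-square undefined")
    return float(1.0 - resid.var() / vy)


def cobb_r2(Y, A, B, fit: CuspFit) -> float:
    """Cobb's pseudo-R-square of a fitted cusp density.

    Each observation's prediction is the stationary point of its own fitted
    density nearest to it (delay convention); the statistic is
    ``1 - Var(residual)/Var(state)`` on the fitted state scale.  Values are
    returned as computed (they can be negative for pathological fits)."""
    w, al, be = fit.transform(Y, A, B)
    pred = nearest_stationary_points(w, al, be)
    vw = w.var()
    if vw == 0.0:
        raise ValueError("constant state: pseudo-R-square undefined")
    return float(1.0 - (w - pred).var() / vw)
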