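"""Fixed points of the recursion and their stability.

Equilibria are found by setting p_x(t+1) = p_x(t) in the three free
coordinates (p1, p2, p3), with p4 = 1 - (p1 + p2 + p3) eliminated, and
solving the resulting polynomial system numerically from a deterministic
multistart set covering the simplex.  Solutions are restricted to the
simplex, deduplicated, and classified.

Stability follows the continuous-time criterion: the recursion is
approximated by dp_i/dt = f_i(p) where f_i is the transmission expression
divided by mean fitness minus p_i (i.e. f = step - identity), and an
equilibrium is stable when all eigenvalues of the 3x3 Jacobian of f have
negative real parts, unstable when at least one real part is positive.
Because f is exactly the discrete map minus the identity, the two criteria
agree for this system.  Exact zero eigenvalues (degenerate neutral cases)
receive the label "marginal".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
from scipy import optimize

from .model import (
    AlleleFreqs,
    DegenerateModelError,
    FitnessMatrix,
    RateParams,
    _step_raw,
)

__all__ = [
    "Equilibrium",
    "continuous_rhs",
    "jacobian",
    "classify_stability",
    "find_equilibria",
    "dedup",
    "write_equilibria",
]

RESIDUAL_GATE = 1e-12   # a fixed point must satisfy ||step(p)-p||_inf below this
BOUND_SLACK = 1e-9      # frequencies may overshoot [0,1] by this before rejection
DEDUP_TOL = 1e-6        # L-infinity radius within which two roots are one equilibrium
ZERO_TOL = 1e-9         # eigenvalue real parts within +/- this are "marginal"
_SNAP = 1e-12           # |p_i| below this is snapped to an exact boundary zero


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the recursion with its local stability.

    freqs         : the equilibrium allele frequencies
    residual_norm : L-infinity norm of step(p) - p (quality of the root)
    eigenvalues   : the 3 eigenvalues of the continuous-time Jacobian
    label         : "stable" | "unstable" | "marginal"
    """

    freqs: AlleleFreqs
    residual_norm: float
    eigenvalues: np.ndarray
    label: str

    @property
    def max_re_eigenvalue(self) -> float:
        return float(np.max(self.eigenvalues.real))


def _rhs3(x: np.ndarray, w: np.ndarray, mu: float, eps: float, beta: float) -> np.ndarray:
    """f(p1,p2,p3) = step(p) - p in the three free coordinates.

    Evaluated without simplex validation so that finite differences may
    probe slightly outside the boundary.  Far outside the simplex (or where
    mean fitness collapses) a smooth repelling penalty is returned so the
    root solver is pushed back toward feasibility.
    """
    if np.any(np.abs(x) > 10.0):
        return (1.0 + np.abs(x)) * 1e3
    p = np.array([x[0], x[1], x[2], 1.0 - (x[0] + x[1] + x[2])])
    m = w @ p
    wbar = float(p @ m)
    if wbar <= 1e-9:
        return (1.0 + np.abs(x)) * 1e3
    p1 = (p[0] * m[0] * (1.0 - mu - eps) + beta * p[2] * m[2]) / wbar
    p2 = (p[1] * m[1] * (1.0 - eps) + mu * p[0] * m[0] + beta * p[3] * m[3]) / wbar
    p3 = (p[2] * m[2] * (1.0 - mu - beta) + eps * p[0] * m[0]) / wbar
    return np.array([p1 - p[0], p2 - p[1], p3 - p[2]])


def continuous_rhs(p123: Sequence[float], w: FitnessMatrix, r: RateParams) -> np.ndarray:
    """Right-hand side of the continuous-time approximation dp_i/dt = f_i.

    Takes the three free coordinates (p4 = 1 - p1 - p2 - p3 implied) and
    returns (f1, f2, f3).  Equals step(p) - p on the embedded 3-vector.
    """
    x = np.asarray(p123, dtype=float)
    p = np.array([x[0], x[1], x[2], 1.0 - x.sum()])
    wbar = float(p @ w.w @ p)
    if wbar <= 0.0:
        raise DegenerateModelError(
            "mean fitness is zero: all extant genotypes are lethal"
        )
    return _rhs3(x, w.w, r.mu, r.epsilon, r.beta)


def jacobian(p123: Sequence[float], w: FitnessMatrix, r: RateParams) -> np.ndarray:
    """3x3 Jacobian J[i][j] = df_i/dp_j of the continuous-time system.

    Central finite differences with per-coordinate step
    h_j = max(1e-7, 1e-7*|p_j|); truncation error O(h^2).
    """
    x = np.asarray(p123, dtype=float)
    wm, mu, eps, beta = w.w, r.mu, r.epsilon, r.beta
    J = np.empty((3, 3))
    for j in range(3):
        h = max(1e-7, 1e-7 * abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (_rhs3(xp, wm, mu, eps, beta) - _rhs3(xm, wm, mu, eps, beta)) / (2.0 * h)
    return J


def _full_residual(x: np.ndarray, w: np.ndarray, mu: float, eps: float, beta: float) -> float:
    """L-infinity norm of step(p)-p over all four components."""
    p = np.array([x[0], x[1], x[2], 1.0 - (x[0] + x[1] + x[2])])
    return float(np.max(np.abs(_step_raw(p, w, mu, eps, beta) - p)))


def classify_stability(
    eq_point: Sequence[float],
    w: FitnessMatrix,
    r: RateParams,
    zero_tol: float = ZERO_TOL,
) -> tuple[str, np.ndarray]:
    """Stability label and Jacobian eigenvalues at a fixed point.

    ``eq_point`` is the 3-vector (p1, p2, p3); it must satisfy the fixed-point
    residual gate (1e-12), otherwise a ValueError is raised: classifying a
    non-equilibrium is meaningless.
    """
    x = np.asarray(eq_point, dtype=float)
    res = _full_residual(x, w.w, r.mu, r.epsilon, r.beta)
    if res >= RESIDUAL_GATE:
        raise ValueError(
            f"point has step-residual {res:.3e} >= {RESIDUAL_GATE}; "
            "not a fixed point, refusing to classify"
        )
    eigvals = np.linalg.eigvals(jacobian(x, w, r))
    re = eigvals.real
    if np.all(re < -zero_tol):
        label = "stable"
    elif np.any(re > zero_tol):
        label = "unstable"
    else:
        label = "marginal"
    return label, eigvals


def dedup(points: Sequence[np.ndarray], tol: float = DEDUP_TOL) -> list[np.ndarray]:
    """Greedy first-seen deduplication of points under the L-infinity metric.

    The first representative of each tol-ball is kept, in input order.  Note
    the greedy rule: in a chain a-b-c with d(a,b) < tol < d(a,c) and
    d(b,c) < tol, both a and c are kept (b is absorbed by a, c is not).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    kept: list[np.ndarray] = []
    for pt in points:
        pt = np.asarray(pt, dtype=float)
        if not any(np.max(np.abs(pt - q)) < tol for q in kept):
            kept.append(pt)
    return kept


def _start_points(n_starts: int) -> np.ndarray:
    """Deterministic multistart set in the three free coordinates.

    The 4 simplex vertices, 6 edge midpoints and the centroid (11 structured
    points), then a Halton low-discrepancy sequence mapped into the interior
    of the simplex to fill ``n_starts``.  No RNG is involved, so equilibrium
    counts are reproducible run to run.
    """
    structured = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 0.0],   # p4 = 1 vertex
            [0.5, 0.5, 0.0],
            [0.5, 0.0, 0.5],
            [0.5, 0.0, 0.0],
            [0.0, 0.5, 0.5],
            [0.0, 0.5, 0.0],
            [0.0, 0.0, 0.5],
            [0.25, 0.25, 0.25],
        ]
    )
    n_extra = max(0, n_starts - len(structured))
    if n_extra == 0:
        return structured
    from scipy.stats import qmc

    eng = qmc.Halton(d=4, scramble=False)
    eng.fast_forward(1)  # the first Halton point is all-zero; skip it
    u = eng.random(n_extra)
    # map the unit cube to the simplex interior via normalized exponentials
    e = -np.log1p(-u * (1.0 - 1e-9))
    p = e / e.sum(axis=1, keepdims=True)
    return np.vstack([structured, p[:, :3]])


def _solve_from(
    x0: np.ndarray, w: np.ndarray, mu: float, eps: float, beta: float
) -> np.ndarray | None:
    """One damped-Newton/hybrid root solve; returns the root or None."""
    sol = optimize.root(
        _rhs3, x0, args=(w, mu, eps, beta), method="hybr", options={"xtol": 1e-13}
    )
    if not sol.success and np.max(np.abs(sol.fun)) > 1e-10:
        return None
    return sol.x


def find_equilibria(
    w: FitnessMatrix,
    r: RateParams,
    n_starts: int = 64,
    tol: float = RESIDUAL_GATE,
) -> list[Equilibrium]:
    """All equilibria of the recursion found by deterministic multistart search.

    Roots with ||step(p)-p||_inf < ``tol`` and every frequency within
    [-1e-9, 1+1e-9] are clipped onto the simplex, deduplicated (L-infinity
    radius 1e-6), classified, and returned sorted by p4 descending.  The
    residual gate also excludes pseudo-equilibria where the flow is merely
    slow (|dp/dt| in the 1e-6..1e-4 range) rather than zero.

    At least one equilibrium always exists; an empty return (with a warning)
    indicates the multistart search failed to converge anywhere and should be
    retried with more starts.
    """
    if n_starts < 27:
        raise ValueError("n_starts must be at least 27 to cover the simplex")
    wm, mu, eps, beta = w.w, r.mu, r.epsilon, r.beta

    candidates: list[np.ndarray] = []
    for x0 in _start_points(n_starts):
        x = _solve_from(x0, wm, mu, eps, beta)
        if x is None:
            continue
        # snap near-boundary coordinates (including the implied p4) to exact 0/1
        x = np.where(np.abs(x) < _SNAP, 0.0, x)
        if abs(1.0 - x.sum()) < _SNAP:
            x = x / x.sum()
        p4 = 1.0 - x.sum()
        if np.any(x < -BOUND_SLACK) or np.any(x > 1.0 + BOUND_SLACK) or not (
            -BOUND_SLACK <= p4 <= 1.0 + BOUND_SLACK
        ):
            continue
        x = np.clip(x, 0.0, 1.0)
        res = _full_residual(x, wm, mu, eps, beta)
        if res >= tol:
            x2 = _solve_from(x, wm, mu, eps, beta)  # polish once after snapping
            if x2 is None:
                continue
            x2 = np.clip(np.where(np.abs(x2) < _SNAP, 0.0, x2), 0.0, 1.0)
            if _full_residual(x2, wm, mu, eps, beta) >= tol:
                continue
            x = x2
        candidates.append(x)

    if not candidates:
        warnings.warn(
            "no multistart root converged to a fixed point; "
            "retry with a larger n_starts",
            RuntimeWarning,
        )
        return []

    out: list[Equilibrium] = []
    for x in dedup(candidates, DEDUP_TOL):
        label, eigvals = classify_stability(x, w, r)
        p4 = max(0.0, 1.0 - x.sum())
        freqs = AlleleFreqs.from_array(np.append(x, p4) / (x.sum() + p4))
        out.append(
            Equilibrium(
                freqs=freqs,
                residual_norm=_full_residual(x, wm, mu, eps, beta),
                eigenvalues=eigvals,
                label=label,
            )
        )
    out.sort(key=lambda e: e.freqs.p4, reverse=True)
    return out


def write_equilibria(
    fh: TextIO,
    equilibria: Sequence[Equilibrium],
    epsilon: float,
    beta: float,
    scenario: str = "",
    write_header: bool = True,
    header_comment: str | None = None,
) -> None:
    """Append equilibria as CSV rows.

    Schema: epsilon,beta,scenario,eq_index,p1,p2,p3,p4,label,
    max_re_eigenvalue,residual_norm.  Frequencies use 17 significant digits
    (repr round-trip safe).
    """
    if header_comment:
        fh.write(f"# {header_comment}\n")
    if write_header:
        fh.write(
            "epsilon,beta,scenario,eq_index,p1,p2,p3,p4,label,"
            "max_re_eigenvalue,residual_norm\n"
        )
    for i, eq in enumerate(equilibria):
        arr = eq.freqs.as_array()
        fh.write(
            f"{epsilon:.17g},{beta:.17g},{scenario},{i},"
            + ",".join(f"{x:.17g}" for x in arr)
            + f",{eq.label},{eq.max_re_eigenvalue:.17g},{eq.residual_norm:.3g}\n"
        )
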