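"""One-generation recursion for a diploid locus with four epialleles.

Two genetic alleles (A1, a2) each carry an alternative epigenetic state
(A3 for A1, a4 for a2), giving four heritable alleles at one locus.  Per
generation, in the gametes, A1/A3 mutate irreversibly to a2/a4 at rate
``mu``; the unmodified states A1/a2 epimutate to A3/a4 at rate ``epsilon``;
the modified states revert at the back-epimutation rate ``beta``.  Viability
selection acts on diploids through a symmetric genotype-fitness table
``w[n][k]``.  The population is infinite, randomly mating, with discrete
non-overlapping generations, so allele frequencies evolve deterministically:

    p1' = [p1*m1*(1-mu-eps) + beta*p3*m3] / wbar
    p2' = [p2*m2*(1-eps) + mu*p1*m1 + beta*p4*m4] / wbar
    p3' = [p3*m3*(1-mu-beta) + eps*p1*m1] / wbar
    p4' = 1 - (p1' + p2' + p3')

where m_n = sum_k p_k*w[n][k] is the marginal fitness of allele n and
wbar = sum_n p_n*m_n the population mean fitness.  Selection happens first,
then gametic transmission with at most one transition per generation (a
single gamete cannot both mutate and epimutate); this ordering is fixed.

Rates are whole-allele rates per generation, not per-nucleotide rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

__all__ = [
    "PAIR_LABELS",
    "RateParams",
    "FitnessMatrix",
    "AlleleFreqs",
    "Trajectory",
    "DegenerateModelError",
    "marginal_fitness",
    "mean_fitness",
    "step",
    "residual",
    "iterate",
    "write_trajectory",
]

#: The ten free entries of the symmetric fitness table, in canonical order.
PAIR_LABELS = ("11", "22", "33", "44", "12", "13", "14", "23", "24", "34")

_SIMPLEX_TOL = 1e-12
_NEG_CLIP = -1e-15  # components above this are treated as rounding noise
_NEG_BUG = -1e-9    # components below this signal an implementation bug


class DegenerateModelError(ValueError):
    """Raised when mean fitness is zero: every extant genotype is lethal."""


@dataclass(frozen=True)
class RateParams:
    """Per-allele, per-generation transition rates.

    mu      : mutation rate, A1 -> a2 and A3 -> a4 (no back-mutation)
    epsilon : epimutation rate, A1 -> A3 and a2 -> a4
    beta    : back-epimutation rate, A3 -> A1 and a4 -> a2
    """

    mu: float
    epsilon: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("mu", "epsilon", "beta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        if self.mu + self.epsilon > 1.0:
            raise ValueError(
                f"mu + epsilon = {self.mu + self.epsilon} exceeds 1; the "
                "A1 survivor factor 1-mu-epsilon would be negative"
            )
        if self.mu + self.beta > 1.0:
            raise ValueError(
                f"mu + beta = {self.mu + self.beta} exceeds 1; the "
                "A3 survivor factor 1-mu-beta would be negative"
            )


class FitnessMatrix:
    """Symmetric 4x4 table of relative diploid viabilities w[n][k] in [0, 1].

    Only 10 entries are free; the table is stored symmetrized.  Entries are
    addressed 1-based to match the allele numbering A1, a2, A3, a4.
    """

    __slots__ = ("_w",)

    def __init__(self, w: np.ndarray | Sequence[Sequence[float]]):
        w = np.asarray(w, dtype=float)
        if w.shape != (4, 4):
            raise ValueError(f"fitness table must be 4x4, got {w.shape}")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("fitness table must be symmetric: w[n][k] == w[k][n]")
        if np.any(w < 0.0) or np.any(w > 1.0):
            raise ValueError("all fitness values must lie in [0, 1]")
        w = 0.5 * (w + w.T)
        w.setflags(write=False)
        self._w = w

    @classmethod
    def neutral(cls) -> "FitnessMatrix":
        """All genotypes equally fit (w = 1 everywhere)."""
        return cls(np.ones((4, 4)))

    @classmethod
    def from_selection(cls, s: Mapping[str, float]) -> "FitnessMatrix":
        """Build w = 1 - s from a mapping of pair labels to selection coefficients.

        Labels are the ten unordered pairs "11", "22", ..., "34" (order of the
        two digits is irrelevant); omitted pairs default to s = 0 (neutral).
        """
        w = np.ones((4, 4))
        for label, value in s.items():
            canon = "".join(sorted(label))
            if canon not in PAIR_LABELS:
                raise KeyError(
                    f"unknown pair label {label!r}; expected one of {PAIR_LABELS}"
                )
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"selection coefficient s[{label}]={value} not in [0, 1]")
            n, k = int(canon[0]) - 1, int(canon[1]) - 1
            w[n, k] = w[k, n] = 1.0 - value
        return cls(w)

    @property
    def w(self) -> np.ndarray:
        """The symmetric 4x4 viability table (read-only view)."""
        return self._w

    @property
    def s(self) -> np.ndarray:
        """Selection coefficients s[n][k] = 1 - w[n][k]."""
        return 1.0 - self._w

    def selection_dict(self) -> dict[str, float]:
        """The ten free selection coefficients keyed by pair label."""
        return {
            lab: float(1.0 - self._w[int(lab[0]) - 1, int(lab[1]) - 1])
            for lab in PAIR_LABELS
        }

    def __getitem__(self, nk: tuple[int, int]) -> float:
        n, k = nk
        return float(self._w[n - 1, k - 1])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FitnessMatrix) and np.array_equal(self._w, other._w)

    def __repr__(self) -> str:
        s = {k: v for k, v in self.selection_dict().items() if v != 0.0}
        return f"FitnessMatrix(s={s or 'neutral'})"


@dataclass(frozen=True)
class AlleleFreqs:
    """A point on the 3-simplex: frequencies of A1, a2, A3, a4."""

    p1: float
    p2: float
    p3: float
    p4: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < 0.0):
            raise ValueError(f"allele frequencies must be nonnegative, got {arr}")
        if abs(arr.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(
                f"allele frequencies must sum to 1 within {_SIMPLEX_TOL}, "
                f"got sum={arr.sum()!r}"
            )

    @classmethod
    def from_array(cls, p: Iterable[float]) -> "AlleleFreqs":
        p1, p2, p3, p4 = (float(x) for x in p)
        return cls(p1, p2, p3, p4)

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4])


@dataclass
class Trajectory:
    """A (possibly thinned) forward orbit of the recursion."""

    states: list[tuple[int, AlleleFreqs]]
    converged: bool
    generations_run: int

    @property
    def final(self) -> AlleleFreqs:
        return self.states[-1][1]


# ---------------------------------------------------------------------------
# Array-level kernels.  These operate on raw ndarrays with no validation and
# are shared with the equilibrium solver, where they are called in tight loops.

def _marginal(p: np.ndarray, w: np.ndarray) -> np.ndarray:
    return w @ p


def _mean_fitness(p: np.ndarray, w: np.ndarray) -> float:
    return float(p @ w @ p)


def _step_raw(p: np.ndarray, w: np.ndarray, mu: float, eps: float, beta: float) -> np.ndarray:
    """Apply the recursion to a raw frequency 4-vector; no clipping."""
    m = w @ p
    wbar = float(p @ m)
    if wbar <= 0.0:
        raise DegenerateModelError(
            "mean fitness is zero: all extant genotypes are lethal"
        )
    p1 = (p[0] * m[0] * (1.0 - mu - eps) + beta * p[2] * m[2]) / wbar
    p2 = (p[1] * m[1] * (1.0 - eps) + mu * p[0] * m[0] + beta * p[3] * m[3]) / wbar
    p3 = (p[2] * m[2] * (1.0 - mu - beta) + eps * p[0] * m[0]) / wbar
    return np.array([p1, p2, p3, 1.0 - (p1 + p2 + p3)])


def _clip_simplex(p: np.ndarray) -> np.ndarray:
    """Clip rounding-noise negatives to zero and renormalize onto the simplex."""
    if np.any(p < _NEG_BUG):
        raise AssertionError(
            f"recursion output left the simplex by more than {-_NEG_BUG}: {p}"
        )
    p = np.where(p < 0.0, 0.0, p)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Public operations.

def marginal_fitness(p: AlleleFreqs, w: FitnessMatrix) -> np.ndarray:
    """Marginal fitness m_n = sum_k p_k * w[n][k] of each allele, as a 4-vector."""
    return _marginal(p.as_array(), w.w)


def mean_fitness(p: AlleleFreqs, w: FitnessMatrix) -> float:
    """Population mean fitness wbar = sum_n p_n * m_n.

    Raises DegenerateModelError if wbar is zero (every extant genotype lethal).
    """
    wbar = _mean_fitness(p.as_array(), w.w)
    if wbar <= 0.0:
        raise DegenerateModelError(
            "mean fitness is zero: all extant genotypes are lethal"
        )
    return wbar


def step(p: AlleleFreqs, w: FitnessMatrix, r: RateParams) -> AlleleFreqs:
    """Advance the population one generation.

    Selection acts on diploids first (through the marginal fitnesses), then
    gametes undergo at most one transition: mutation at ``r.mu``, epimutation
    at ``r.epsilon``, or back-epimutation at ``r.beta``.
    """
    out = _step_raw(p.as_array(), w.w, r.mu, r.epsilon, r.beta)
    return AlleleFreqs.from_array(_clip_simplex(out))


def residual(p: AlleleFreqs, w: FitnessMatrix, r: RateParams) -> np.ndarray:
    """One-generation displacement step(p) - p; zero (to 1e-12) at a fixed point."""
    return step(p, w, r).as_array() - p.as_array()


def iterate(
    p0: AlleleFreqs,
    w: FitnessMatrix,
    r: RateParams,
    tol: float = 1e-12,
    max_gen: int = 100_000,
    record_every: int = 1,
) -> Trajectory:
    """Iterate the recursion from ``p0`` until the per-generation change is small.

    Convergence is declared when the L-infinity norm of step(p) - p drops
    below ``tol``.  The trajectory is thinned to every ``record_every``-th
    generation (the initial and final states are always kept).

    Intended for dynamics and basin-of-attraction checks.  Equilibria at
    mutation rates near 1e-7 take ~1e8 generations to reach by iteration;
    use :func:`epibalance.equilibria.find_equilibria` for equilibrium queries.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_gen < 1:
        raise ValueError("max_gen must be at least 1")
    if record_every < 1:
        raise ValueError("record_every must be at least 1")

    p = p0.as_array()
    wm, mu, eps, beta = w.w, r.mu, r.epsilon, r.beta
    states: list[tuple[int, AlleleFreqs]] = [(0, p0)]
    converged = False
    gen = 0
    for gen in range(1, max_gen + 1):
        nxt = _clip_simplex(_step_raw(p, wm, mu, eps, beta))
        delta = float(np.max(np.abs(nxt - p)))
        p = nxt
        if gen % record_every == 0:
            states.append((gen, AlleleFreqs.from_array(p)))
        if delta < tol:
            converged = True
            break
    if states[-1][0] != gen:
        states.append((gen, AlleleFreqs.from_array(p)))
    return Trajectory(states=states, converged=converged, generations_run=gen)


def write_trajectory(
    traj: Trajectory,
    w: FitnessMatrix,
    fh: TextIO,
    header_comment: str | None = None,
) -> None:
    """Write a trajectory as CSV: generation,p1,p2,p3,p4,mean_fitness.

    Frequencies are printed with repr round-trip precision.  An optional
    comment line (prefixed '#') records the parameterization.
    """
    if header_comment:
        fh.write(f"# {header_comment}\n")
    fh.write("generation,p1,p2,p3,p4,mean_fitness\n")
    for gen, state in traj.states:
        arr = state.as_array()
        wbar = _mean_fitness(arr, w.w)
        cols = [str(gen)] + [f"{x:.17g}" for x in arr] + [f"{wbar:.17g}"]
        fh.write(",".join(cols) + "\n")
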