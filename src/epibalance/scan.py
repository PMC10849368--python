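"""Scenario presets and (epsilon, beta) parameter sweeps.

A scenario fixes the ten selection coefficients of the genotype-fitness
table (and the mutation rate, 1e-7 unless overridden); a sweep solves for
all equilibria and their stability at every point of an
(epimutation-rate, back-epimutation-rate) grid.  The default grid is a
deterministic log-spaced lattice over [1e-5, 0.5] on both axes; a seeded
log-uniform random mode is available as well.  A focal mode fixes the
back-epimutation rate at the three focal reversion rates 0.33, 0.1 and
0.01 (epialleles persisting roughly 3, 10 and 100 generations without
selection) and sweeps epimutation only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np

from .equilibria import Equilibrium, find_equilibria, write_equilibria
from .model import PAIR_LABELS, FitnessMatrix, RateParams

__all__ = [
    "Scenario",
    "ScanRecord",
    "ScanSummary",
    "scenario_registry",
    "get_scenario",
    "swap_genotypes",
    "rate_grid",
    "run_scan",
    "summarize",
    "write_scan",
    "FOCAL_BETAS",
    "DEFAULT_MU",
]

logger = logging.getLogger(__name__)

DEFAULT_MU = 1e-7
FOCAL_BETAS = (0.33, 0.1, 0.01)
GRID_LO, GRID_HI = 1e-5, 0.5


@dataclass(frozen=True)
class Scenario:
    """A named selection regime: ten selection coefficients plus mutation rate."""

    name: str
    s: dict[str, float] = field(default_factory=dict)
    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        for label, value in self.s.items():
            if "".join(sorted(label)) not in PAIR_LABELS:
                raise ValueError(f"unknown pair label {label!r} in scenario {self.name!r}")
            if not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"selection coefficient s[{label}]={value} outside [0, 1] "
                    f"in scenario {self.name!r}"
                )

    def fitness(self) -> FitnessMatrix:
        return FitnessMatrix.from_selection(self.s)

    def rates(self, epsilon: float, beta: float) -> RateParams:
        return RateParams(mu=self.mu, epsilon=epsilon, beta=beta)


@dataclass
class ScanRecord:
    """Equilibria found at one (epsilon, beta) point of a sweep."""

    epsilon: float
    beta: float
    scenario: str
    equilibria: list[Equilibrium]

    @property
    def n_stable(self) -> int:
        return sum(1 for e in self.equilibria if e.label == "stable")


@dataclass(frozen=True)
class ScanSummary:
    """Per-scenario summary of a sweep: multistability counts and p4 range."""

    scenario: str
    n_points: int
    max_equilibria: int
    max_stable: int
    frac_multistable: float
    stable_p4_min: float
    stable_p4_max: float


def _fill(value: float, except_pairs: dict[str, float]) -> dict[str, float]:
    s = {lab: value for lab in PAIR_LABELS}
    s.update(except_pairs)
    return s


def scenario_registry() -> dict[str, Scenario]:
    """The named selection regimes used throughout the equilibrium landscapes.

    Naming encodes the biology: which allele is advantaged or deleterious
    and whether the (dis)advantage acts recessively or dominantly.
    """
    presets = [
        # no selection: pure epimutation/back-epimutation dynamics
        Scenario("fig3_neutral", {}),
        # a4 recessively advantageous over an otherwise-neutral background
        Scenario("fig5_recessive_adv", _fill(0.01, {"44": 0.0})),
        Scenario("fig5_recessive_adv_strong", _fill(0.2, {"44": 0.0})),
        # a4 dominantly advantageous
        Scenario(
            "fig5_dominant_adv",
            _fill(0.01, {"44": 0.0, "14": 0.0, "24": 0.0, "34": 0.0}),
        ),
        # a2 recessive deleterious, fully compensated by its epiallele a4
        Scenario("fig6_compensatory", {"22": 0.01}),
        # a2 recessive deleterious, A-genotype combinations mildly deleterious
        Scenario("fig6_c", {"22": 0.02, "11": 0.01, "12": 0.01}),
        # a2 recessive deleterious and a4 dominantly advantageous
        Scenario(
            "fig6_e",
            _fill(0.01, {"22": 0.02, "44": 0.0, "14": 0.0, "24": 0.0, "34": 0.0}),
        ),
        # a2 dominant deleterious, compensated recessively
        Scenario("fig7_a", {"22": 0.01, "12": 0.01, "23": 0.01, "24": 0.01}),
        # a2 dominant deleterious, A1 combinations intermediate
        Scenario(
            "fig7_c",
            {
                "22": 0.02, "12": 0.02, "23": 0.02, "24": 0.02,
                "11": 0.01, "13": 0.01, "14": 0.01,
            },
        ),
        # a2 dominant deleterious and a4 recessively advantageous
        Scenario(
            "fig7_e",
            _fill(0.01, {"22": 0.02, "12": 0.02, "23": 0.02, "24": 0.02, "44": 0.0}),
        ),
    ]
    return {sc.name: sc for sc in presets}


def get_scenario(name: str) -> Scenario:
    reg = scenario_registry()
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(reg))}"
        ) from None


_SWAP = {"1": "2", "2": "1", "3": "4", "4": "3"}


def swap_genotypes(sc: Scenario) -> Scenario:
    """The symmetric scenario with the roles of the two genotypes exchanged.

    Exchanges allele indices 1<->2 and 3<->4 in the selection table, so that
    e.g. an advantage of a4 becomes the same advantage of A3.  Note the
    mutation rate stays unidirectional (A -> a), so swapped scenarios are
    not fully equivalent dynamically — that asymmetry is the point of
    examining them.
    """
    swapped = {
        "".join(sorted(_SWAP[c] for c in label)): v for label, v in sc.s.items()
    }
    return replace(sc, name=sc.name + "_swapped", s=swapped)


def rate_grid(
    n_per_axis: int,
    lo: float = GRID_LO,
    hi: float = GRID_HI,
    spacing: str = "log",
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Cartesian (epsilon, beta) grid, row-major in epsilon then beta.

    ``spacing="log"`` gives a deterministic log-spaced lattice (the default
    used for equilibrium-count scans); ``spacing="linear"`` a linear lattice
    (the only mode in which a zero bound is allowed).  Passing ``seed``
    replaces the lattice axes with ``n_per_axis`` log-uniform random draws
    per axis, reproducibly.
    """
    if n_per_axis < 2:
        raise ValueError("n_per_axis must be at least 2")
    if not (lo < hi):
        raise ValueError("need lo < hi")
    if spacing == "log":
        if lo <= 0:
            raise ValueError("log spacing requires lo > 0")
        if seed is not None:
            rng = np.random.default_rng(seed)
            eps_axis = np.exp(rng.uniform(np.log(lo), np.log(hi), n_per_axis))
            beta_axis = np.exp(rng.uniform(np.log(lo), np.log(hi), n_per_axis))
        else:
            eps_axis = beta_axis = np.geomspace(lo, hi, n_per_axis)
    elif spacing == "linear":
        if lo < 0:
            raise ValueError("bounds must be nonnegative")
        if seed is not None:
            raise ValueError("random sampling is log-uniform; use spacing='log'")
        eps_axis = beta_axis = np.linspace(lo, hi, n_per_axis)
    else:
        raise ValueError(f"spacing must be 'log' or 'linear', got {spacing!r}")
    return [(float(e), float(b)) for e in eps_axis for b in beta_axis]


def run_scan(
    scenario: Scenario,
    grid: Iterable[tuple[float, float]] | None = None,
    focal_betas: Sequence[float] | None = None,
    epsilons: Sequence[float] | None = None,
    n_starts: int = 27,
) -> list[ScanRecord]:
    """Solve for all equilibria at every grid point of a scenario.

    Either pass an explicit ``grid`` of (epsilon, beta) pairs, or use focal
    mode: ``focal_betas`` (default 0.33, 0.1, 0.01) each combined with every
    value in ``epsilons``.  Points where no start converges are retried with
    4x the starts; if that also fails the point is recorded with an empty
    equilibrium list and a logged warning rather than aborting the sweep.
    """
    if grid is None:
        if epsilons is None:
            raise ValueError("provide either an explicit grid or an epsilon sweep")
        betas = FOCAL_BETAS if focal_betas is None else tuple(focal_betas)
        grid = [(float(e), float(b)) for e in epsilons for b in betas]

    w = scenario.fitness()
    records: list[ScanRecord] = []
    for epsilon, beta in grid:
        r = scenario.rates(epsilon, beta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            eqs = find_equilibria(w, r, n_starts=n_starts)
            if not eqs:  # rare: retry harder before giving up on the point
                eqs = find_equilibria(w, r, n_starts=4 * n_starts)
        if not eqs:
            logger.warning(
                "no equilibrium found for scenario=%s epsilon=%g beta=%g "
                "(retried with %d starts)",
                scenario.name, epsilon, beta, 4 * n_starts,
            )
        records.append(ScanRecord(epsilon, beta, scenario.name, eqs))
    return records


def summarize(records: Sequence[ScanRecord]) -> list[ScanSummary]:
    """Per-scenario multistability summary of sweep records."""
    if not records:
        raise ValueError("no scan records to summarize")
    by_scenario: dict[str, list[ScanRecord]] = {}
    for rec in records:
        by_scenario.setdefault(rec.scenario, []).append(rec)

    out = []
    for name, recs in by_scenario.items():
        stable_p4 = [
            e.freqs.p4 for r in recs for e in r.equilibria if e.label == "stable"
        ]
        out.append(
            ScanSummary(
                scenario=name,
                n_points=len(recs),
                max_equilibria=max(len(r.equilibria) for r in recs),
                max_stable=max(r.n_stable for r in recs),
                frac_multistable=sum(r.n_stable > 1 for r in recs) / len(recs),
                stable_p4_min=min(stable_p4) if stable_p4 else float("nan"),
                stable_p4_max=max(stable_p4) if stable_p4 else float("nan"),
            )
        )
    return out


def write_scan(
    fh: TextIO, records: Sequence[ScanRecord], header_comment: str | None = None
) -> None:
    """Write sweep records as CSV (same schema as the equilibrium writer)."""
    if header_comment:
        fh.write(f"# {header_comment}\n")
    first = True
    for rec in records:
        write_equilibria(
            fh,
            rec.equilibria,
            epsilon=rec.epsilon,
            beta=rec.beta,
            scenario=rec.scenario,
            write_header=first,
        )
        first = False
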