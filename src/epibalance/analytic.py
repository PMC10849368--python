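"""Closed-form equilibria and approximations for limiting regimes.

Each function here is an analytic prediction for a reduced or limiting case
of the four-epiallele recursion: the neutral epimutation–back-epimutation
equilibrium (EBE), epimutation–selection and back-epimutation–selection
balance, the classical mutation–selection balance (MSB) limit, and the
compensatory-epiallele equilibria in which a deleterious genetic allele is
masked by its neutral epigenetic state and its genotype-level frequency is
escalated above MSB by the factor (1 + epsilon/beta).

The recursion itself is the single source of truth: every formula exposed
here is pinned by tests against the numerical fixed points of the full
system in its stated validity regime (typically small selection
coefficients and mu << epsilon, beta), and agrees exactly where equality is
exact (EBE; the epsilon = 0 classical reduction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "BalancePrediction",
    "ebe_freq",
    "persistence",
    "expected_duration",
    "epi_selection_balance",
    "back_epi_selection_balance",
    "compensatory_equilibrium",
    "escalation_factor",
    "msb",
]


@dataclass(frozen=True)
class BalancePrediction:
    """A predicted equilibrium frequency for a named quantity.

    quantity : which frequency or genotype-level sum (e.g. "p4", "p2+p4")
    value    : the predicted equilibrium frequency, in [0, 1]
    form     : "exact" if the prediction is an exact solution of the reduced
               system, "approximation" if it holds only to leading order
    """

    quantity: str
    value: float
    form: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"predicted frequency {self.value} outside [0, 1]")
        if self.form not in ("exact", "approximation"):
            raise ValueError(f"form must be 'exact' or 'approximation', got {self.form!r}")


def ebe_freq(epsilon: float, beta: float) -> float:
    """Neutral epimutation–back-epimutation equilibrium frequency of the epiallele.

    Within a genotype, with no mutation and no selection, the modified state
    settles at p4 = epsilon / (beta + epsilon): the balance of forward
    switching at rate epsilon against reversion at rate beta.  Strictly
    increasing in epsilon and decreasing in beta.
    """
    if epsilon < 0 or beta < 0:
        raise ValueError("rates must be nonnegative")
    if epsilon + beta == 0:
        raise ValueError(
            "EBE is undefined when epsilon = beta = 0: every frequency is neutral"
        )
    return epsilon / (beta + epsilon)


def persistence(beta: float, t: float) -> float:
    """Expected frequency (1 - beta)^t of an epiallele after t generations.

    Models the decay of a modified epiallele that starts at frequency 1 with
    no selection, mutation or new epimutation: each generation a fraction
    beta reverts.
    """
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must lie in (0, 1]")
    if t < 0:
        raise ValueError("t must be nonnegative")
    return (1.0 - beta) ** t


def expected_duration(beta: float) -> float:
    """Expected number of generations an epiallele persists without selection.

    Computed as the area under the decay curve p = (1-beta)^t, i.e.
    integral_0^inf (1-beta)^t dt = -1/ln(1-beta).  The continuous area is
    used (rather than the discrete sum (1-beta)/beta) because it is the
    natural "expected maintenance time" of the exponential-decay picture:
    at the focal reversion rates 0.33, 0.1 and 0.01 it gives 2.5, 9.5 and
    99.5 generations respectively, whereas the discrete sum gives 2.0 at
    beta = 0.33.
    """
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must lie in (0, 1]")
    if beta == 1.0:
        return 0.0
    return -1.0 / math.log1p(-beta)


def epi_selection_balance(epsilon: float, s44: float, h: float = 0.0) -> float:
    """Epimutation–selection balance frequency of a deleterious epiallele.

    With back-epimutation off (beta = 0) the modified state a4 behaves like
    an ordinary deleterious mutant replenished at rate epsilon:

    * recessive (h = 0, heterozygote unselected): p4 = sqrt(epsilon/s44)
    * partial dominance (h > 0, s24 = h*s44):     p4 ~= epsilon/(h*s44)

    The dominance form is the leading-order approximation; both are capped
    at 1.  Relevant where epialleles persist long-term (beta ~ 0), as in
    some plants.
    """
    if s44 <= 0:
        raise ValueError("s44 must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if not (0.0 <= h <= 1.0):
        raise ValueError("h must lie in [0, 1]")
    if epsilon == 0:
        return 0.0
    if h == 0.0:
        return min(1.0, math.sqrt(epsilon / s44))
    return min(1.0, epsilon / (h * s44))


def back_epi_selection_balance(beta: float, s22: float) -> float:
    """Back-epimutation–selection balance frequency of an advantageous epiallele.

    With epimutation off (epsilon = 0) and the unmodified allele a2
    deleterious (s22 > 0, a4 and the heterozygote neutral), reversion at
    rate beta erodes the favoured modified state: p4 = 1 - sqrt(beta/s22).
    When beta >= s22 the epiallele cannot be maintained at all (returns 0):
    without regeneration by epimutation, reversion outruns selection unless
    beta is smaller than the selection coefficient.
    """
    if s22 <= 0:
        raise ValueError("s22 must be positive")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    if beta >= s22:
        return 0.0
    return 1.0 - math.sqrt(beta / s22)


def msb(mu: float, s: float, h: float = 0.0) -> float:
    """Classical mutation–selection balance frequency of a deleterious allele.

    * recessive (h = 0):       q = sqrt(mu/s)
    * partial dominance h > 0: q ~= mu/(h*s)

    Capped at 1.  This is the epsilon = beta = 0 limit of the full model,
    to which it reduces exactly.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if s <= 0:
        raise ValueError("s must be positive")
    if not (0.0 <= h <= 1.0):
        raise ValueError("h must lie in [0, 1]")
    if h == 0.0:
        return min(1.0, math.sqrt(mu / s))
    return min(1.0, mu / (h * s))


def escalation_factor(epsilon: float, beta: float) -> float:
    """Factor (1 + epsilon/beta) by which a compensatory epiallele raises MSB.

    A deleterious genetic allele with a fitness-neutral epigenetic state is
    maintained, at the genotype level (p2 + p4), above classical
    mutation–selection balance by exactly this multiplier: each copy lost to
    selection in the unmodified state is sheltered in the modified state in
    proportion epsilon/beta.  Always >= 1; equals 1 when no epigenetic
    variation is generated (epsilon = 0).
    """
    if beta <= 0:
        raise ValueError(
            "escalation factor requires beta > 0; for beta = 0 use "
            "epi_selection_balance"
        )
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    return 1.0 + epsilon / beta


def compensatory_equilibrium(
    mu: float,
    epsilon: float,
    beta: float,
    s22: float,
    h: float = 0.0,
) -> dict[str, BalancePrediction]:
    """Equilibrium predictions when an epiallele compensates a deleterious allele.

    Scenario: A1 mutates to the deleterious a2 (selection s22 against the
    unmodified homozygote, dominance h so that the a2 heterozygous
    combinations carry h*s22), while the modified states A3 and a4 are
    fitness-neutral — the epiallele fully masks the deleterious effect.

    Recessive case (h = 0), to leading order in mu:

        p2      = sqrt(mu/s22)                      (classical MSB)
        p4      = (epsilon/beta) * sqrt(mu/s22)
        p2+p4   = (1 + epsilon/beta) * sqrt(mu/s22)
        p1+p3   = 1 - (1 + epsilon/beta) * sqrt(mu/s22)
        p1+p2   = beta/(epsilon+beta)               (EBE, unperturbed)
        p3+p4   = epsilon/(epsilon+beta)            (EBE, unperturbed)

    General dominance (h > 0): the genotype-level sum is approximated by the
    escalated MSB, p2+p4 ~= (1 + epsilon/beta) * mu/(h*s22).

    Valid in the regime s22 >> mu and beta not << mu; a warning is issued
    (and values are capped at 1) when a predicted frequency leaves [0, 1],
    signalling that the regime is violated.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if s22 <= 0:
        raise ValueError("s22 must be positive")
    if beta <= 0:
        raise ValueError("beta must be positive (beta = 0 has no compensatory cycle)")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if not (0.0 <= h <= 1.0):
        raise ValueError("h must lie in [0, 1]")

    factor = escalation_factor(epsilon, beta)
    q = msb(mu, s22, h)
    genotype_sum = factor * q
    if genotype_sum > 1.0:
        warnings.warn(
            "predicted genotype-level frequency exceeds 1; the asymptotic "
            "regime (s22 >> mu, beta not << mu) is violated",
            RuntimeWarning,
        )

    def _pred(quantity: str, value: float, form: str) -> BalancePrediction:
        return BalancePrediction(quantity, min(1.0, max(0.0, value)), form)

    form = "approximation"
    preds = {
        "p2+p4": _pred("p2+p4", genotype_sum, form),
        "p1+p3": _pred("p1+p3", 1.0 - genotype_sum, form),
        "p1+p2": _pred("p1+p2", beta / (epsilon + beta), form),
        "p3+p4": _pred("p3+p4", epsilon / (epsilon + beta), form),
    }
    if h == 0.0:
        preds.update(
            {
                "p1": _pred("p1", beta / (epsilon + beta) - q, form),
                "p2": _pred("p2", q, form),
                "p3": _pred("p3", epsilon / (epsilon + beta) - (epsilon / beta) * q, form),
                "p4": _pred("p4", (epsilon / beta) * q, form),
            }
        )
    return preds
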