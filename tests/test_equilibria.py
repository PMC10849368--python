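"""Tests for fixed-point finding and stability classification."""

import io

import numpy as np
import pytest

from epibalance import (
    AlleleFreqs,
    FitnessMatrix,
    RateParams,
    classify_stability,
    continuous_rhs,
    dedup,
    find_equilibria,
    jacobian,
    residual,
    step,
    write_equilibria,
)
from conftest import perturbed

# a known point inside the bistable wedge of the recessive-advantage scenario
# (s44 = 0, all other s = 0.01): three equilibria, two stable
WEDGE_SCENARIO = {lab: 0.01 for lab in
                  ("11", "22", "33", "12", "13", "14", "23", "24", "34")}
WEDGE_POINT = (1e-5, 1e-3)  # (epsilon, beta)


# ---------------------------------------------------------------------------
# continuous-time right-hand side

def test_continuous_rhs_matches_discrete_residual(neutral):
    rng = np.random.default_rng(7)
    w = FitnessMatrix.from_selection({"22": 0.02, "14": 0.01})
    r = RateParams(1e-7, 0.01, 0.1)
    for _ in range(20):
        p = rng.dirichlet(np.ones(4))
        f = continuous_rhs(p[:3], w, r)
        res = residual(AlleleFreqs.from_array(p), w, r)
        assert f == pytest.approx(res[:3], abs=1e-12)


def test_continuous_rhs_vertex_example(neutral):
    f = continuous_rhs([1.0, 0.0, 0.0], neutral, RateParams(1e-7, 0.01, 0.0))
    assert f == pytest.approx([-0.0100001, 1e-7, 0.01], abs=1e-15)


def test_continuous_rhs_zero_everywhere_without_forces(neutral, no_rates):
    rng = np.random.default_rng(3)
    for _ in range(10):
        p = rng.dirichlet(np.ones(4))
        assert np.max(np.abs(continuous_rhs(p[:3], neutral, no_rates))) < 1e-14


# ---------------------------------------------------------------------------
# Jacobian

def test_jacobian_zero_without_forces(neutral, no_rates):
    J = jacobian([0.2, 0.3, 0.1], neutral, no_rates)
    assert np.max(np.abs(J)) < 1e-8


def test_jacobian_ebe_modes(neutral):
    # at the neutral EBE point with mu=0 the nonzero modes relax at rate
    # (eps+beta); the A-genotype total is exactly conserved (zero mode)
    eps, beta = 0.01, 0.1
    x = [0.0, beta / (beta + eps), 0.0]
    eigs = np.sort(np.linalg.eigvals(
        jacobian(x, neutral, RateParams(0.0, eps, beta))).real)
    assert eigs[0] == pytest.approx(-(eps + beta), rel=1e-5)
    assert eigs[1] == pytest.approx(-(eps + beta), rel=1e-5)
    assert abs(eigs[2]) < 1e-8


def test_jacobian_agrees_with_discrete_map_linearization():
    # independent finite differences of the full step map: eigenvalues of
    # (J_step - I) must match those of the continuous-time Jacobian
    w = FitnessMatrix.from_selection({"22": 0.01})
    r = RateParams(1e-7, 0.01, 0.1)
    eq = [e for e in find_equilibria(w, r) if e.label == "stable"][0]
    x = eq.freqs.as_array()[:3]

    h = 1e-7
    Jd = np.empty((3, 3))
    for j in range(3):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        fp = step(AlleleFreqs.from_array(np.append(xp, 1 - xp.sum())), w, r)
        fm = step(AlleleFreqs.from_array(np.append(xm, 1 - xm.sum())), w, r)
        Jd[:, j] = (fp.as_array()[:3] - fm.as_array()[:3]) / (2 * h)
    ev_discrete = np.sort((np.linalg.eigvals(Jd) - 1.0).real)
    ev_cont = np.sort(np.linalg.eigvals(jacobian(x, w, r)).real)
    assert ev_discrete == pytest.approx(ev_cont, abs=1e-5)


# ---------------------------------------------------------------------------
# classification

def test_classify_refuses_non_fixed_point(neutral):
    with pytest.raises(ValueError, match="not a fixed point"):
        classify_stability([1.0, 0.0, 0.0], neutral, RateParams(1e-7, 0.01, 0.0))


def test_classify_marginal_without_forces(neutral, no_rates):
    label, eigs = classify_stability([0.2, 0.3, 0.1], neutral, no_rates)
    assert label == "marginal"
    assert np.max(np.abs(eigs.real)) < 1e-9


def test_classify_ebe_marginal_at_zero_mu_stable_with_mutation(neutral):
    eps, beta = 0.01, 0.1
    x = [0.0, beta / (beta + eps), 0.0]
    label, _ = classify_stability(x, neutral, RateParams(0.0, eps, beta))
    assert label == "marginal"  # A-genotype total exactly conserved
    eqs = find_equilibria(neutral, RateParams(1e-7, eps, beta))
    assert [e.label for e in eqs] == ["stable"]


# ---------------------------------------------------------------------------
# dedup

def test_dedup_removes_copies_keeps_distant():
    a = np.zeros(3)
    b = np.zeros(3)
    far = np.full(3, 1e-5)
    kept = dedup([a, b, far], tol=1e-6)
    assert len(kept) == 2


def test_dedup_greedy_first_seen_chain():
    tol = 1e-6
    a = np.zeros(3)
    b = np.full(3, 0.6 * tol)
    c = np.full(3, 1.2 * tol)
    kept = dedup([a, b, c], tol=tol)
    # b absorbed by a; c is beyond tol of a, kept even though near b
    assert len(kept) == 2
    assert np.array_equal(kept[0], a) and np.array_equal(kept[1], c)


# ---------------------------------------------------------------------------
# global search

def test_neutral_mutation_has_unique_stable_equilibrium(neutral):
    eqs = find_equilibria(neutral, RateParams(1e-7, 0.01, 0.1))
    assert len(eqs) == 1
    eq = eqs[0]
    assert eq.label == "stable"
    assert eq.freqs.p1 == 0.0 and eq.freqs.p3 == 0.0
    assert eq.freqs.p2 == pytest.approx(0.1 / 0.11, abs=1e-9)
    assert eq.freqs.p4 == pytest.approx(0.01 / 0.11, abs=1e-9)


def test_all_returned_equilibria_satisfy_residual_gate():
    w = FitnessMatrix.from_selection(WEDGE_SCENARIO | {"44": 0.0})
    r = RateParams(1e-7, *WEDGE_POINT)
    for eq in find_equilibria(w, r):
        assert eq.residual_norm < 1e-12
        res = residual(eq.freqs, w, r)
        assert np.max(np.abs(res)) < 1e-12


def test_classical_mutation_selection_balance_oracle():
    # eps=beta=0 reduces to two-allele mutation-selection balance
    mu, s22 = 1e-7, 0.01
    w = FitnessMatrix.from_selection({"22": s22})
    eqs = find_equilibria(w, RateParams(mu, 0.0, 0.0))
    classical = [
        e for e in eqs if e.freqs.p3 + e.freqs.p4 < 1e-9 and 1e-6 < e.freqs.p2 < 0.1
    ]
    assert len(classical) == 1
    assert classical[0].freqs.p2 == pytest.approx(np.sqrt(mu / s22), rel=0.05)


def test_bistable_wedge_counts_and_dynamics():
    w = FitnessMatrix.from_selection(WEDGE_SCENARIO | {"44": 0.0})
    r = RateParams(1e-7, *WEDGE_POINT)
    eqs = find_equilibria(w, r)
    labels = sorted(e.label for e in eqs)
    assert labels == ["stable", "stable", "unstable"]
    assert eqs == sorted(eqs, key=lambda e: e.freqs.p4, reverse=True)

    # stable equilibria attract a 1e-4 perturbation back to within 1e-6
    for eq in eqs:
        if eq.label != "stable":
            continue
        p = perturbed(eq.freqs, np.array([0.0, 1e-4, 0.0, -1e-4]))
        arr = p.as_array()
        for _ in range(30_000):
            p_next = step(AlleleFreqs.from_array(arr), w, r)
            arr = p_next.as_array()
        assert np.max(np.abs(arr - eq.freqs.as_array())) < 1e-6

    # the unstable equilibrium repels along its leading eigenvector
    saddle = next(e for e in eqs if e.label == "unstable")
    J = jacobian(saddle.freqs.as_array()[:3], w, r)
    vals, vecs = np.linalg.eig(J)
    v3 = vecs[:, np.argmax(vals.real)].real
    v = np.append(v3, -v3.sum())
    v /= np.max(np.abs(v))
    start = perturbed(saddle.freqs, 1e-6 * v)
    arr = start.as_array()
    d0 = np.max(np.abs(arr - saddle.freqs.as_array()))
    for _ in range(30_000):
        arr = step(AlleleFreqs.from_array(arr), w, r).as_array()
    assert np.max(np.abs(arr - saddle.freqs.as_array())) > 50 * d0


def test_find_equilibria_rejects_too_few_starts(neutral):
    with pytest.raises(ValueError):
        find_equilibria(neutral, RateParams(0.0, 0.1, 0.1), n_starts=5)


# ---------------------------------------------------------------------------
# writer

def test_equilibrium_writer_schema(neutral):
    eqs = find_equilibria(neutral, RateParams(1e-7, 0.01, 0.1))
    buf = io.StringIO()
    write_equilibria(buf, eqs, epsilon=0.01, beta=0.1, scenario="fig3_neutral")
    lines = buf.getvalue().splitlines()
    assert lines[0] == (
        "epsilon,beta,scenario,eq_index,p1,p2,p3,p4,label,"
        "max_re_eigenvalue,residual_norm"
    )
    fields = lines[1].split(",")
    assert fields[2] == "fig3_neutral"
    assert fields[8] == "stable"
    assert float(fields[7]) == eqs[0].freqs.p4  # 17-sig-digit round trip
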