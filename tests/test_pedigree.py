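"""Relationship-matrix machinery against tabular and hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfblup.experiments import random_groups, random_pedigree
from mfblup.pedigree import (GammaMatrix, Pedigree, PedigreeError, build_A,
                             build_A22, build_Agamma, build_A_inverse,
                             build_Q, build_QP_Astar, compute_inbreeding)

TRIO_AINV = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])


def test_pedigree_requires_topological_order():
    with pytest.raises(PedigreeError):
        Pedigree(np.array([1, -1]), np.array([-1, -1]))


def test_inbreeding_classical_cases(trio_ped, fullsib_ped):
    assert compute_inbreeding(trio_ped).tolist() == [0.0, 0.0, 0.0]
    F = compute_inbreeding(fullsib_ped)
    assert F[:4].tolist() == [0.0, 0.0, 0.0, 0.0]
    assert F[4] == pytest.approx(0.25)


def test_trio_A_inverse_matches_classical_worked_case(trio_ped):
    np.testing.assert_allclose(build_A_inverse(trio_ped).toarray(),
                               TRIO_AINV, atol=1e-12)


def test_founders_only_inverse_is_identity():
    ped = Pedigree(np.full(4, -1), np.full(4, -1))
    np.testing.assert_allclose(build_A_inverse(ped).toarray(), np.eye(4),
                               atol=1e-14)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_random_pedigrees_match_tabular_oracle(seed):
    """F = diag(A) - 1 and A^-1 A = I on 200-animal random pedigrees."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, 200)
    A = build_A(ped)
    F = compute_inbreeding(ped)
    np.testing.assert_allclose(F, np.diag(A) - 1.0, atol=1e-10)
    Ainv = build_A_inverse(ped, F=F).toarray()
    np.testing.assert_allclose(Ainv @ A, np.eye(200), atol=1e-8)
    assert np.linalg.eigvalsh(A).min() > -1e-8


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_A22_equals_submatrix_of_tabular_A(seed):
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, 120)
    A = build_A(ped)
    ids = rng.choice(120, size=30, replace=False)
    A22 = build_A22(ped, ids)
    np.testing.assert_allclose(A22, A[np.ix_(ids, ids)], atol=1e-10)


def test_A22_consistency_and_trivial_cases():
    rng = np.random.default_rng(9)
    ped = random_pedigree(rng, 50)
    np.testing.assert_allclose(build_A22(ped, np.arange(50)), build_A(ped),
                               atol=1e-12)
    founders = Pedigree(np.array([-1, -1]), np.array([-1, -1]))
    np.testing.assert_allclose(build_A22(founders, np.array([0, 1])),
                               np.eye(2), atol=1e-14)


def test_dense_limit_enforced():
    ped = Pedigree(np.full(20, -1), np.full(20, -1))
    with pytest.raises(PedigreeError, match="dense limit"):
        build_A(ped, dense_limit=10)


# --- group incidence --------------------------------------------------------

def test_Q_simple_cases():
    # animal 0: both parents unknown in group 0 -> unit row
    # animal 1: founder fully in group 1; animal 2: sire = animal 1
    # (group-1 ancestry), dam unknown in group 0 -> (0.5, 0.5)
    ped = Pedigree(np.array([-1, -1, 1]), np.array([-1, -1, -1]))
    sg = np.array([0, 1, -1])
    dg = np.array([0, 1, 0])
    Q = build_Q(ped, sg, dg, 2).values
    np.testing.assert_allclose(Q[0], [1.0, 0.0])
    np.testing.assert_allclose(Q[1], [0.0, 1.0])
    np.testing.assert_allclose(Q[2], [0.5, 0.5])


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_Q_rows_sum_to_one_when_ancestry_terminates_in_groups(seed):
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, 40)
    sg, dg = random_groups(rng, ped, 3)
    Q = build_Q(ped, sg, dg, 3).values
    np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-12)


def test_missing_group_code_rejected():
    ped = Pedigree(np.array([-1]), np.array([-1]))
    with pytest.raises(PedigreeError, match="group"):
        build_Q(ped, np.array([-1]), np.array([0]), 1)


# --- QP transformation ------------------------------------------------------

def test_QP_single_animal_hand_accumulation():
    ped = Pedigree(np.array([-1]), np.array([-1]))
    astar = build_QP_Astar(ped, np.array([0]), np.array([0]), 1).toarray()
    np.testing.assert_allclose(astar, [[1.0, -1.0], [-1.0, 1.0]], atol=1e-14)


def test_QP_animal_block_equals_A_inverse(trio_ped):
    """Group columns only add group rows/cols; the animal block is A^-1
    itself, and an unused group leaves a zero block."""
    sg = np.where(trio_ped.sire == -1, 0, -1)
    dg = np.where(trio_ped.dam == -1, 0, -1)
    astar = build_QP_Astar(trio_ped, sg, dg, 2).toarray()
    assert np.all(astar[:, 4] == 0) and np.all(astar[4, :] == 0)
    np.testing.assert_allclose(astar[:3, :3], TRIO_AINV, atol=1e-12)


# --- metafounders -----------------------------------------------------------

def test_single_metafounder_tabular_example():
    gamma = GammaMatrix(np.array([[0.2]]))
    ped = Pedigree(np.array([-1, -1]), np.array([-1, -1]))
    mf = build_Agamma(ped, gamma, np.array([0, 0]), np.array([0, 0]))
    assert mf.A[0, 0] == pytest.approx(1.1)   # founder diag 1 + gamma/2
    assert mf.A[0, 1] == pytest.approx(0.2)   # founder pair = gamma
    assert mf.F_gamma[0] == pytest.approx(0.1)
    np.testing.assert_allclose(mf.Ainv.toarray() @ mf.A, np.eye(3),
                               atol=1e-10)


def test_small_gamma_limit_recovers_plain_A():
    rng = np.random.default_rng(3)
    ped = random_pedigree(rng, 60)
    sg, dg = random_groups(rng, ped, 2)
    gamma = GammaMatrix(1e-8 * np.eye(2))
    mf = build_Agamma(ped, gamma, sg, dg)
    np.testing.assert_allclose(mf.A[:60, :60], build_A(ped), atol=1e-6)
    # metafounder block of the inverse is dominated by Gamma^-1
    mf_block = mf.Ainv.toarray()[60:, 60:]
    assert np.diag(mf_block).min() > 0.5e8


def test_positive_gamma_shifts_relationships_upward():
    rng = np.random.default_rng(4)
    ped = random_pedigree(rng, 80)
    sg, dg = random_groups(rng, ped, 4)
    gamma = GammaMatrix(0.3 * np.eye(4) + 0.15)
    mf = build_Agamma(ped, gamma, sg, dg)
    A = build_A(ped)
    assert np.diag(mf.A[:80, :80]).mean() > np.diag(A).mean()
    assert mf.A22(np.arange(40)).mean() > A[:40, :40].mean()


def test_singular_gamma_rejected():
    ped = Pedigree(np.array([-1]), np.array([-1]))
    gamma = GammaMatrix(np.zeros((1, 1)))
    with pytest.raises(ValueError, match="singular"):
        build_Agamma(ped, gamma, np.array([0]), np.array([0]))
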