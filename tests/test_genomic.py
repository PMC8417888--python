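"""Genotype QC and genomic relationship matrices."""

import numpy as np
import pytest

from mfblup.experiments import qc_fixture
from mfblup.genomic import (GenomicError, MarkerMatrix, build_G, build_G05,
                            impute_missing_within_matrix, matrix_summary,
                            qc_markers)
from mfblup.pedigree import compute_inbreeding


def test_qc_fixture_removes_exactly_the_planted_violations():
    markers, report = qc_markers(qc_fixture())
    assert (report.removed_position, report.removed_call_rate,
            report.removed_maf, report.removed_hwe) == (1, 1, 1, 1)
    assert report.n_out == 6
    assert report.n_in - report.total_removed == report.n_out


def test_qc_single_rule_examples():
    # p = 0.02 -> removed by MAF
    geno = np.zeros((50, 2), dtype=np.int8)
    geno[:2, 0] = 1
    geno[:, 1] = np.random.default_rng(0).binomial(2, 0.5, 50)
    out, report = qc_markers(MarkerMatrix(geno, np.arange(50)))
    assert report.removed_maf == 1
    # all-heterozygous marker at p = 0.5: |1.0 - 0.5| > 0.15 -> HWE removal
    geno2 = np.column_stack([np.ones(40, dtype=np.int8),
                             np.random.default_rng(1).binomial(2, 0.5, 40)])
    out2, report2 = qc_markers(MarkerMatrix(geno2.astype(np.int8),
                                            np.arange(40)))
    assert report2.removed_hwe == 1


def test_qc_all_removed_raises():
    geno = np.ones((10, 1), dtype=np.int8)
    with pytest.raises(GenomicError):
        qc_markers(MarkerMatrix(geno, np.arange(10)))


def test_impute_missing_preserves_column_means():
    rng = np.random.default_rng(5)
    geno = rng.binomial(2, 0.4, size=(30, 20)).astype(np.int8)
    miss = rng.random((30, 20)) < 0.1
    geno[miss] = 5
    markers = MarkerMatrix(geno, np.arange(30))
    p = markers.allele_frequency()
    out, n_imp = impute_missing_within_matrix(markers)
    assert n_imp == int(miss.sum())
    np.testing.assert_allclose(out.geno.mean(axis=0), 2 * p, atol=1e-12)
    # no missing -> identity transform
    clean = MarkerMatrix(np.abs(geno % 3), np.arange(30))
    same, n0 = impute_missing_within_matrix(clean)
    assert n0 == 0
    np.testing.assert_allclose(same.geno, clean.geno)


def test_impute_single_missing_at_half():
    geno = np.array([[0, 2], [2, 2], [1, 5], [1, 0]], dtype=np.int8)
    out, n = impute_missing_within_matrix(MarkerMatrix(geno, np.arange(4)))
    assert n == 1
    # observed p for marker 2 = (2+2+0)/6 -> fill = 4/3; at p=0.5 fill = 1
    assert out.geno[2, 1] == pytest.approx(2 * (4 / 6))


def test_G_identities():
    rng = np.random.default_rng(2)
    row = rng.binomial(2, 0.5, 50)
    geno = np.tile(row, (5, 1)).astype(float)
    geno[:, 0] = [0, 1, 2, 1, 0]   # keep polymorphism across animals
    G = build_G(MarkerMatrix(geno, np.arange(5)), alpha=1.0)
    assert G.tag == "raw"
    # raw G rows sum to ~0 under observed-frequency centering
    np.testing.assert_allclose(G.values.sum(axis=1), 0.0, atol=1e-8)
    # blending with alpha = 1 returns raw exactly
    G2 = build_G(MarkerMatrix(geno, np.arange(5)), alpha=1.0, A22=np.eye(5))
    np.testing.assert_allclose(G.values, G2.values)


def test_G_blending_against_A22():
    rng = np.random.default_rng(3)
    geno = rng.binomial(2, 0.5, size=(8, 100)).astype(float)
    A22 = np.eye(8)
    raw = build_G(MarkerMatrix(geno, np.arange(8)), alpha=1.0).values
    blended = build_G(MarkerMatrix(geno, np.arange(8)), alpha=0.95,
                      A22=A22).values
    np.testing.assert_allclose(blended, 0.95 * raw + 0.05 * A22, atol=1e-12)
    np.linalg.cholesky(blended)   # blended matrix is positive definite


def test_G05_trivial_evaluations():
    # all animals fully heterozygous -> Z = 0 -> G05 = 0
    het = np.ones((4, 10), dtype=float)
    G05 = build_G05(MarkerMatrix(het, np.arange(4)), alpha=1.0)
    np.testing.assert_allclose(G05.values, 0.0)
    # one animal homozygous-alt at all markers -> diagonal = m/(m/2) = 2
    geno = np.ones((4, 10), dtype=float)
    geno[0] = 2.0
    G05b = build_G05(MarkerMatrix(geno, np.arange(4)), alpha=1.0)
    assert G05b.values[0, 0] == pytest.approx(2.0)


def test_G_diag_tracks_inbreeding(small_config_factory):
    """Centred at the base frequencies, mean(diag G) = 1 + mean(F); with
    observed-frequency centring on non-inbred founders it is ~1."""
    from mfblup.simdata import simulate
    cfg = small_config_factory(n_markers=4000, seed=31,
                               divergence=(0.02,) * 4,
                               genotyped_pools=(),
                               genotype_cross_fraction=0.0,
                               genotype_founder_fraction=1.0)
    data = simulate(cfg)
    G = build_G(MarkerMatrix(data.markers.geno.astype(float),
                             data.markers.animal_ids), alpha=1.0)
    assert np.diag(G.values).mean() == pytest.approx(1.0, abs=0.05)


def test_base_centred_G_estimates_A(small_config_factory):
    """With a homogeneous base and base-frequency centring, E[G] = A:
    the diagonal tracks 1 + F and off-diagonals track pedigree kinship."""
    from mfblup.simdata import simulate
    cfg = small_config_factory(n_markers=2000, seed=37,
                               divergence=(0.02,) * 4)
    data = simulate(cfg)
    from mfblup.pedigree import build_A
    M = data.gene_content.astype(float)
    p = data.state.base_freqs.mean(axis=1)
    Z = M - 2 * p
    G = (Z @ Z.T) / (2 * np.sum(p * (1 - p)))
    A = build_A(data.ped_true)
    F = compute_inbreeding(data.ped_true)
    assert np.diag(G).mean() == pytest.approx(1 + F.mean(), abs=0.05)
    tri = np.triu_indices(A.shape[0], k=1)
    assert np.corrcoef(G[tri], A[tri])[0, 1] > 0.8


def test_G05_diagonal_shifts_upward_on_multibreed_data(small_sim):
    geno = small_sim.markers.geno.astype(float)
    ids = small_sim.markers.animal_ids
    G = build_G(MarkerMatrix(geno, ids), alpha=1.0).values
    G05 = build_G05(MarkerMatrix(geno, ids), alpha=1.0).values
    assert np.diag(G05).mean() > np.diag(G).mean()


def test_matrix_summary_trivial_cases():
    M = np.array([[1.0, 0.2], [0.2, 1.0]])
    out = matrix_summary({"a": M, "b": M.copy()}, pairs=[("a", "b")])
    corr = out[out["matrix"] == "a~b"]
    # identical matrices: off-diagonal part of a 2x2 has a single element,
    # correlation undefined; diagonal correlation also degenerate here
    I = np.eye(3)
    out2 = matrix_summary({"i": I, "j": I})
    offd = out2[(out2["matrix"] == "i") & (out2["part"] == "offdiagonal")]
    assert offd["variance"].iloc[0] == 0.0
    with pytest.raises(GenomicError):
        matrix_summary({"a": M, "c": np.eye(3)})


def test_matrix_summary_identical_matrices_correlate_perfectly():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((6, 6))
    M = X @ X.T
    out = matrix_summary({"a": M, "b": M.copy()}, pairs=[("a", "b")])
    corr = out[out["matrix"] == "a~b"].set_index("part")["correlation"]
    assert corr["diagonal"] == pytest.approx(1.0)
    assert corr["offdiagonal"] == pytest.approx(1.0)
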