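import math

import numpy as np
import pytest

from pseudoevo.sca import (
    SCA,
    PreprocessedMSA,
    background_frequencies,
    conservation,
    coupling_matrix,
    frequencies,
    ica,
    preprocess,
    significant_modes,
    spectral,
    uniform_background,
)
from pseudoevo.synth import PlantedSectorSpec, generate_sector_msa


def _msa_from_rows(rows):
    return {f"s{i}": r for i, r in enumerate(rows)}


class TestPreprocess:
    def test_gap_heavy_column_truncated(self):
        # column 0: 41% gaps in 100 sequences -> removed; 39% -> kept
        rows_removed = ["-AAAA" if i < 41 else "CAAAA" for i in range(100)]
        pre = preprocess(_msa_from_rows(rows_removed))
        assert pre.n_pos == 4
        assert pre.removed_positions == [1]
        rows_kept = ["-AAAA" if i < 39 else "CAAAA" for i in range(100)]
        pre2 = preprocess(_msa_from_rows(rows_kept))
        assert pre2.n_pos == 5

    def test_gappy_sequence_removed(self):
        rows = ["AAAAAAAAAA"] * 30 + ["AA--A-AAAA"]  # 30% gaps in the last
        pre = preprocess(_msa_from_rows(rows))
        assert pre.n_seq == 30
        assert pre.removed_sequences == ["s30"]

    def test_gap_free_identity(self):
        rows = ["ACDEF", "ACDEY", "ACDEF"]
        pre = preprocess(_msa_from_rows(rows))
        assert pre.n_seq == 3 and pre.n_pos == 5
        assert not pre.removed_sequences and not pre.removed_positions
        assert pre.ats == [1, 2, 3, 4, 5]

    def test_reference_gap_columns_have_no_ats(self):
        # the reference (first retained) row has one gap, under the 0.2
        # sequence cutoff, so its gapped column maps to no residue
        rows = ["AAAAA-AAAA"] + ["AAAAACAAAA"] * 9
        pre = preprocess(_msa_from_rows(rows))
        assert pre.ats == [1, 2, 3, 4, 5, None, 6, 7, 8, 9]

    def test_empty_result_rejected(self):
        rows = ["--A", "A--", "-A-"]
        with pytest.raises(ValueError):
            preprocess(_msa_from_rows(rows))

    def test_structure_mapping(self):
        rows = ["ACDEF"] * 5
        pre = preprocess(_msa_from_rows(rows), structure_seq="CDEF")
        assert pre.ats == [None, 1, 2, 3, 4]


class TestConservation:
    def test_zero_at_background(self):
        assert conservation(np.array(0.05), np.array(0.05)) == pytest.approx(0.0)

    def test_half_frequency_value(self):
        d = conservation(np.array(0.5), np.array(0.05))
        assert d == pytest.approx(
            0.5 * math.log(10) + 0.5 * math.log(0.5 / 0.95), abs=1e-9
        )
        assert d == pytest.approx(0.830366, abs=1e-6)

    def test_full_conservation_limit(self):
        assert conservation(np.array(1.0), np.array(0.05)) == pytest.approx(
            math.log(20), abs=1e-9
        )

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            conservation(np.array(0.5), np.array(1.0))

    def test_background_table_normalized(self):
        q = background_frequencies()
        assert q.shape == (20,)
        assert q.sum() == pytest.approx(1.0)
        assert (q > 0).all()


class TestCouplingMatrix:
    def test_symmetric_nonnegative(self):
        msa = generate_sector_msa(PlantedSectorSpec(80, 30, (), seed=1)).msa
        pre = preprocess(msa)
        C, _ = coupling_matrix(pre)
        assert np.allclose(C, C.T)
        assert (C >= 0).all()

    def test_independent_columns_weakly_coupled(self):
        """With independent columns, off-diagonal couplings are tiny
        relative to the diagonal and shrink as sampling noise ~ 1/sqrt(n)."""
        ratios = {}
        for n in (1000, 5000):
            msa = generate_sector_msa(PlantedSectorSpec(n, 40, (), seed=2)).msa
            pre = preprocess(msa)
            C, _ = coupling_matrix(pre)
            off = C[~np.eye(C.shape[0], dtype=bool)]
            ratios[n] = off.mean() / np.median(np.diag(C))
        assert ratios[5000] <= 0.05
        assert ratios[5000] < ratios[1000]

    def test_duplicated_column_fully_coupled(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 20, size=(400, 25)).astype(np.int8)
        codes[:, 10] = codes[:, 4]
        pre = PreprocessedMSA([f"s{i}" for i in range(400)], codes, list(range(25)))
        C, _ = coupling_matrix(pre, uniform_background())
        assert C[4, 10] == pytest.approx(C[4, 4], rel=1e-5)

    def test_planted_sector_block_structure(self, two_sector_msa):
        """Mean within-sector coupling exceeds background coupling 5-fold."""
        pre = preprocess(two_sector_msa.msa)
        C, _ = coupling_matrix(pre)
        sector_pos = [p - 1 for p in two_sector_msa.sector_of_position]
        in_sector = np.zeros(C.shape[0], dtype=bool)
        in_sector[sector_pos] = True
        within = []
        for s_id in (1, 2):
            pos = [p - 1 for p in two_sector_msa.truth_positions(s_id)]
            block = C[np.ix_(pos, pos)]
            within.append(block[~np.eye(len(pos), dtype=bool)].mean())
        bg = C[np.ix_(~in_sector, ~in_sector)]
        bg_mean = bg[~np.eye(bg.shape[0], dtype=bool)].mean()
        assert min(within) >= 5 * bg_mean

    def test_sequence_order_invariance(self):
        msa = generate_sector_msa(PlantedSectorSpec(60, 20, (), seed=4)).msa
        pre1 = preprocess(msa)
        shuffled = dict(reversed(list(msa.items())))
        pre2 = preprocess(shuffled)
        C1, _ = coupling_matrix(pre1)
        C2, _ = coupling_matrix(pre2)
        assert np.allclose(C1, C2, atol=1e-5)

    def test_position_permutation_equivariance(self):
        msa = generate_sector_msa(
            PlantedSectorSpec(100, 15, ((frozenset({2, 9}), 2, 0.95),), seed=5)
        ).msa
        pre = preprocess(msa)
        C, _ = coupling_matrix(pre)
        perm = np.random.default_rng(0).permutation(15)
        permuted = {k: "".join(v[j] for j in perm) for k, v in msa.items()}
        C2, _ = coupling_matrix(preprocess(permuted))
        assert np.allclose(C2, C[np.ix_(perm, perm)], atol=1e-5)


class TestSpectral:
    def test_reconstruction_identity(self, two_sector_msa):
        pre = preprocess(two_sector_msa.msa)
        C, _ = coupling_matrix(pre)
        evals, evecs = spectral(C)
        recon = evecs @ np.diag(evals) @ evecs.T
        assert np.linalg.norm(recon - C) <= 1e-8 * np.linalg.norm(C)

    def test_identity_matrix(self):
        evals, _ = spectral(np.eye(5))
        assert np.allclose(evals, 1.0)

    def test_planted_rank_two(self):
        rng = np.random.default_rng(6)
        u = rng.standard_normal(30)
        v = rng.standard_normal(30)
        C = 3 * np.outer(u, u) + np.outer(v, v)
        evals, _ = spectral(C)
        assert (np.abs(evals) > 1e-8).sum() == 2

    def test_descending_order_and_sign(self):
        C = np.diag([1.0, 5.0, 3.0])
        evals, evecs = spectral(C)
        assert list(evals) == [5.0, 3.0, 1.0]
        for k in range(3):
            assert evecs[np.argmax(np.abs(evecs[:, k])), k] > 0

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            spectral(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestSignificantModes:
    def test_null_msa_keeps_at_most_one_mode(self):
        hits = 0
        for seed in range(4):
            msa = generate_sector_msa(
                PlantedSectorSpec(200, 80, (), seed=100 + seed)
            ).msa
            pre = preprocess(msa)
            k, _, _ = significant_modes(pre, n_trials=10, seed=seed)
            hits += k <= 1
        assert hits >= 3

    def test_planted_sectors_detected(self, two_sector_msa):
        pre = preprocess(two_sector_msa.msa)
        k, lam2, sd = significant_modes(pre, n_trials=10, seed=3)
        assert k >= 2
        assert lam2 > 0 and sd >= 0

    def test_deterministic(self, two_sector_msa):
        pre = preprocess(two_sector_msa.msa)
        r1 = significant_modes(pre, n_trials=4, seed=9)
        r2 = significant_modes(pre, n_trials=4, seed=9)
        assert r1 == r2

    def test_too_few_trials_rejected(self, two_sector_msa):
        pre = preprocess(two_sector_msa.msa)
        with pytest.raises(ValueError):
            significant_modes(pre, n_trials=1, seed=0)


class TestICA:
    def test_single_component_identity(self):
        v = np.linspace(-1, 1, 40)[:, None]
        out, W, converged = ica(v, seed=0)
        assert converged
        assert np.allclose(out, v)
        assert np.allclose(W, np.eye(1))

    def test_unmixes_sparse_planted_pair(self):
        """Two sparse loading vectors mixed by a rotation are recovered
        up to permutation and sign."""
        rng = np.random.default_rng(7)
        L = 200
        a = np.zeros(L)
        b = np.zeros(L)
        a[:12] = rng.uniform(0.5, 1.0, 12)
        b[100:112] = rng.uniform(0.5, 1.0, 12)
        a /= np.linalg.norm(a)
        b /= np.linalg.norm(b)
        theta = 0.7
        mix = np.column_stack(
            [
                math.cos(theta) * a + math.sin(theta) * b,
                -math.sin(theta) * a + math.cos(theta) * b,
            ]
        )
        out, _, _ = ica(mix, seed=1)
        cos = np.abs(out.T @ np.column_stack([a, b]))
        best = max(cos[0, 0] * cos[1, 1], cos[0, 1] * cos[1, 0])
        assert best >= 0.95**2

    def test_output_spans_input_subspace(self, two_sector_msa):
        pre = preprocess(two_sector_msa.msa)
        C, _ = coupling_matrix(pre)
        _, evecs = spectral(C)
        V = evecs[:, :3]
        out, _, _ = ica(V, seed=2)
        proj = V @ (V.T @ out)
        assert np.linalg.norm(proj - out) <= 1e-6

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        V = np.linalg.qr(rng.standard_normal((50, 3)))[0]
        o1, w1, _ = ica(V, seed=5)
        o2, w2, _ = ica(V, seed=5)
        assert np.array_equal(o1, o2)
        assert np.array_equal(w1, w2)


class TestEstimator:
    def test_fit_exposes_state(self, two_sector_msa):
        model = SCA(n_trials=4, seed=1).fit(two_sector_msa.msa)
        L = model.preprocessed_.n_pos
        assert model.Ctilde_.shape == (L, L)
        assert model.k_star_ >= 2
        assert model.V_ica_.shape[1] == max(model.k_star_, 1)
        assert model.f_ia_.shape == (L, 20)

    def test_sklearn_params_roundtrip(self):
        model = SCA(n_trials=5, seed=2)
        params = model.get_params()
        assert params["n_trials"] == 5
        clone = SCA(**params)
        assert clone.get_params() == params
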