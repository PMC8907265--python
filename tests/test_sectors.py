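import math

import numpy as np
import pytest

from pseudoevo.sectors import (
    ICSelection,
    group_sectors,
    ic_membership,
    motif_correlation_profile,
    select_all,
    select_positions,
    selection_distance_map,
)


class TestSelectPositions:
    def test_planted_outliers_recovered(self):
        """Five strong outliers on a standard-normal background are all
        selected with at most 2% background contamination."""
        rng = np.random.default_rng(1)
        loadings = rng.standard_normal(200)
        outliers = [10, 50, 90, 130, 170]
        loadings[outliers] = 10.0
        sel = select_positions(loadings)
        assert set(outliers) <= set(sel.positions)
        # selecting beyond the fitted 95th percentile admits ~5% of the
        # background by construction; require clearly less than that
        background = set(sel.positions) - set(outliers)
        assert len(background) <= 0.03 * 200

    def test_constant_loadings_fallback(self):
        sel = select_positions(np.full(40, 0.5))
        assert sel.used_fallback
        assert len(sel.positions) == math.ceil(0.05 * 40)
        assert sel.positions == [0, 1]  # index-order tie rule

    def test_selection_shrinks_with_quantile(self):
        rng = np.random.default_rng(2)
        loadings = rng.standard_normal(100)
        sizes = [
            len(select_positions(loadings, quantile=q).positions)
            for q in (0.80, 0.90, 0.95, 0.99)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            select_positions(np.zeros(10))

    def test_ats_labels_attached(self):
        rng = np.random.default_rng(3)
        loadings = rng.standard_normal(30)
        loadings[7] = 8.0
        ats = [100 + i for i in range(30)]
        sel = select_positions(loadings, ats=ats)
        assert 107 in sel.ats_positions


def _two_cluster_vica(sep=2.0, n_per=15, seed=4):
    """IC-loading matrix with two well separated position clusters."""
    rng = np.random.default_rng(seed)
    V = rng.normal(0, 0.02, size=(60, 2))
    V[:n_per, 0] = rng.normal(sep, 0.05, n_per)
    V[30 : 30 + n_per, 1] = rng.normal(sep, 0.05, n_per)
    sel_a = ICSelection(1, list(range(n_per)), list(range(n_per)), None)
    sel_b = ICSelection(2, list(range(30, 30 + n_per)), list(range(n_per)), None)
    return V, sel_a, sel_b


class TestDistanceMap:
    def test_self_distance_zero_and_symmetry(self):
        V, a, b = _two_cluster_vica()
        M, labels = selection_distance_map([a, b], V)
        assert np.allclose(np.diag(M), 0)
        assert np.allclose(M, M.T)
        assert len(labels) == 30

    def test_orthogonal_unit_positions_sqrt2(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        a = ICSelection(1, [0], [1], None)
        b = ICSelection(2, [1], [2], None)
        M, _ = selection_distance_map([a, b], V)
        assert M[0, 1] == pytest.approx(math.sqrt(2))

    def test_triangle_inequality(self):
        rng = np.random.default_rng(5)
        V = rng.standard_normal((20, 3))
        a = ICSelection(1, list(range(10)), list(range(10)), None)
        b = ICSelection(2, list(range(10, 20)), list(range(10)), None)
        M, _ = selection_distance_map([a, b], V)
        n = M.shape[0]
        for i in range(0, n, 3):
            for j in range(1, n, 4):
                for k in range(2, n, 5):
                    assert M[i, j] <= M[i, k] + M[k, j] + 1e-12


class TestGroupSectors:
    def test_identical_selections_merge(self):
        V, a, _ = _two_cluster_vica()
        a2 = ICSelection(2, list(a.positions), list(a.positions), None)
        part = group_sectors([a, a2], V)
        assert len(part.sectors) == 1
        assert part.p_matrix[0, 1] >= 0.999

    def test_strongly_separated_selections_split(self):
        """Selections ~ 10 pooled SDs apart in IC space are distinguished."""
        V, a, b = _two_cluster_vica(sep=3.0)
        part = group_sectors([a, b], V, p_cutoff=0.10)
        assert len(part.sectors) == 2
        assert part.p_matrix[0, 1] < 0.10

    def test_transitive_closure(self):
        """A~B and B~C put all three ICs in one sector even though A and
        C on their own are significantly different."""
        from pseudoevo.sectors import selection_pair_pvalue

        rng = np.random.default_rng(6)
        V = rng.normal(0, 0.5, size=(30, 1))
        V[10:20, 0] += 0.8
        V[20:30, 0] += 1.6
        a = ICSelection(1, list(range(10)), list(range(10)), None)
        b = ICSelection(2, list(range(10, 20)), list(range(10)), None)
        c = ICSelection(3, list(range(20, 30)), list(range(10)), None)
        assert selection_pair_pvalue(a, b, V) >= 0.1
        assert selection_pair_pvalue(b, c, V) >= 0.1
        assert selection_pair_pvalue(a, c, V) < 0.1
        part = group_sectors([a, b, c], V, p_cutoff=0.10)
        assert len(part.sectors) == 1

    def test_tiny_selection_becomes_singleton(self):
        V, a, b = _two_cluster_vica()
        tiny = ICSelection(3, [59], [59], None)
        part = group_sectors([a, b, tiny], V)
        assert {3} in [set(s) for s in part.sectors.values()]

    def test_lower_cutoff_never_decreases_sector_count(self):
        V, a, b = _two_cluster_vica(sep=0.5)
        counts = [
            len(group_sectors([a, b], V, p_cutoff=p).sectors)
            for p in (0.5, 0.1, 0.01, 1e-6)
        ]
        assert all(x >= y for x, y in zip(counts, counts[1:]))

    def test_position_unions_cover_selections(self):
        V, a, b = _two_cluster_vica()
        part = group_sectors([a, b], V)
        covered = set().union(*part.sector_positions.values())
        assert covered == set(a.positions) | set(b.positions)


class TestMotifProfile:
    def test_two_position_motif_single_entry(self):
        C = np.array([[1.0, 0.4], [0.4, 1.0]])
        V = np.array([[1.0], [1.0]])
        profiles = motif_correlation_profile(C, [0, 1], V)
        assert [p.couplings for p in profiles] == [[0.4], [0.4]]

    def test_profiles_symmetric(self):
        rng = np.random.default_rng(7)
        A = rng.random((6, 6))
        C = (A + A.T) / 2
        V = rng.standard_normal((6, 2))
        profiles = motif_correlation_profile(C, [0, 2, 5], V)
        by_pos = {p.position: dict(zip(p.others, p.couplings)) for p in profiles}
        assert by_pos[0][2] == by_pos[2][0]

    def test_truncated_position_reported_missing(self):
        C = np.eye(3)
        V = np.ones((3, 1))
        profiles = motif_correlation_profile(C, [1, -1], V)
        assert profiles[1].missing and not profiles[0].missing

    def test_ic_membership_argmax_with_tie_rule(self):
        V = np.array([[0.5, -0.5], [0.1, 0.9]])
        assert list(ic_membership(V)) == [1, 2]

    def test_planted_sector_motif_coupling_dominates(self, two_sector_msa):
        """A motif inside a planted sector couples to itself far more
        strongly than to background positions."""
        from pseudoevo.sca import coupling_matrix, preprocess, spectral

        pre = preprocess(two_sector_msa.msa)
        C, _ = coupling_matrix(pre)
        motif = sorted(p - 1 for p in two_sector_msa.truth_positions(1))
        _, evecs = spectral(C)
        profiles = motif_correlation_profile(C, motif, evecs[:, :2])
        within = np.mean([np.mean(p.couplings) for p in profiles])
        bg_cols = [j for j in range(C.shape[0]) if j + 1 not in two_sector_msa.sector_of_position]
        background = C[np.ix_(motif, bg_cols)].mean()
        assert within >= 5 * background


class TestEndToEndRecovery:
    def test_planted_sectors_recovered(self, two_sector_msa):
        """The full coupling -> modes -> ICA -> selection -> grouping chain
        recovers both planted sectors with high sensitivity."""
        from pseudoevo.sca import (
            coupling_matrix,
            ica,
            preprocess,
            significant_modes,
            spectral,
        )

        pre = preprocess(two_sector_msa.msa)
        C, _ = coupling_matrix(pre)
        evals, evecs = spectral(C)
        k, _, _ = significant_modes(pre, n_trials=10, seed=3, eigenvalues=evals)
        assert k >= 2
        V_ica, _, _ = ica(evecs[:, :k], seed=3)
        selections = select_all(V_ica)
        part = group_sectors(selections, V_ica, p_cutoff=0.10)
        assert len(part.sectors) >= 2
        truth = {p - 1 for p in two_sector_msa.sector_of_position}
        selected = set().union(*(s.positions for s in selections))
        sensitivity = len(selected & truth) / len(truth)
        false_pos = len(selected - truth) / max(1, len(selected))
        assert sensitivity >= 0.8
        assert false_pos <= 0.1
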