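import numpy as np
import pytest
from dataclasses import replace

from phenosig.exceptions import ParameterError, ValidationError
from phenosig.identifiability import (CELL_NODES, LinearNetModel,
                                      compare_input_modes, default_omega_grid,
                                      gen_linear_model, identifiability_report,
                                      state_space, transfer_sensitivities)


def fim_eigen_oracle(H, threshold=0.99):
    """Independent oracle: pairwise eigen-analysis of the standardized H^T H.

    After column standardization, the 2x2 Gram matrix of a parameter pair is
    its correlation matrix [[1, r], [r, 1]] with eigenvalues 1 +/- |r|, so a
    pair is entangled exactly when the smallest eigenvalue falls to
    1 - threshold or below.  Zero-sensitivity columns are unidentifiable.
    """
    H = np.asarray(H, float)
    n = H.shape[1]
    norms = np.linalg.norm(H, axis=0)
    Hc = H - H.mean(axis=0)
    sd = Hc.std(axis=0)
    live = (norms > 1e-12) & (sd > 0)
    Z = np.where(live, 1.0, np.nan) * np.divide(
        Hc, sd, out=np.zeros_like(Hc), where=sd > 0
    )
    ident = np.zeros(n, dtype=bool)
    for j in range(n):
        if not live[j]:
            continue
        ok = True
        for i in range(n):
            if i == j or not live[i]:
                continue
            gram = np.array([
                [1.0, float(Z[:, i] @ Z[:, j]) / H.shape[0]],
                [float(Z[:, i] @ Z[:, j]) / H.shape[0], 1.0],
            ])
            lam_min = np.linalg.eigvalsh(gram)[0]
            if lam_min <= 1.0 - threshold:
                ok = False
                break
        ident[j] = ok
    return ident


class TestModelGeneration:
    def test_same_seed_identical(self):
        a = gen_linear_model(seed=3)
        b = gen_linear_model(seed=3)
        assert a.edges == b.edges
        np.testing.assert_array_equal(a.rates, b.rates)
        assert a.input_rate == b.input_rate

    def test_six_edges_cover_all_ordered_pairs(self):
        m = gen_linear_model(seed=0, n_edges=6)
        assert set(m.edges) == {(a, b) for a in CELL_NODES for b in CELL_NODES
                                if a != b}

    def test_too_many_edges_rejected(self):
        with pytest.raises(ParameterError):
            gen_linear_model(seed=0, n_edges=7)

    def test_mass_conservation_without_input(self):
        # flux form: every column of the constant-mode A sums to zero
        m = gen_linear_model(seed=1, input_mode="constant")
        A, B, _ = state_space(m)
        np.testing.assert_allclose(A.sum(axis=0), 0.0, atol=1e-12)

    def test_json_round_trip(self):
        m = gen_linear_model(seed=5)
        m2 = LinearNetModel.from_json(m.to_json())
        assert m2.edges == m.edges
        np.testing.assert_allclose(m2.rates, m.rates)


class TestSensitivities:
    def test_matches_finite_differences(self):
        """Analytic resolvent derivatives agree with numerical perturbation."""
        m = gen_linear_model(seed=2)
        # moderate frequencies: away from the conserved-mass pole at s = 0,
        # where finite differences themselves lose accuracy to cancellation
        omegas = np.geomspace(0.1, 10.0, 8)
        H = transfer_sensitivities(m, omega_grid=omegas, normalize=False)

        def transfer(model):
            A, B, states = state_space(model)
            C = np.zeros((3, len(states)))
            for r, o in enumerate(CELL_NODES):
                C[r, states.index(o)] = 1.0
            rows = []
            for w in omegas:
                g = C @ np.linalg.inv(1j * w * np.eye(len(states)) - A) @ B
                rows.append(g)
            g = np.vstack(rows)
            return np.concatenate([g.real.ravel(), g.imag.ravel()])

        eps = 1e-6
        for j in range(len(m.rates)):
            e_j = eps * np.eye(len(m.rates))[j]
            col_fd = (transfer(replace(m, rates=m.rates + e_j))
                      - transfer(replace(m, rates=m.rates - e_j))) / (2 * eps)
            np.testing.assert_allclose(H[:, j], col_fd, rtol=1e-6, atol=1e-9)

    def test_observed_nodes_filtered_in_constant_mode(self, caplog):
        m = gen_linear_model(seed=0, input_mode="constant")
        with caplog.at_level("WARNING"):
            H = transfer_sensitivities(m, observed=("N", "Q", "R"))
        # N is not a state under a constant input: 2 channels remain
        assert H.shape[0] == 2 * 2 * len(default_omega_grid())

    def test_information_grows_with_observed_nodes(self):
        """H^T H (raw) of a nested observation set is dominated in the PSD
        order by the larger set: more observed nodes never remove information."""
        for seed in range(10):
            m = gen_linear_model(seed=seed)
            H_small = transfer_sensitivities(m, observed=("Q", "R"), normalize=False)
            H_big = transfer_sensitivities(m, observed=("P", "Q", "R"),
                                           normalize=False)
            diff = H_big.T @ H_big - H_small.T @ H_small
            assert np.linalg.eigvalsh(diff).min() >= -1e-9


class TestReport:
    def test_duplicate_columns_unidentifiable(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(40)
        H = np.column_stack([col, col, rng.standard_normal(40)])
        rep = identifiability_report(H)
        assert not rep.identifiable[0] and not rep.identifiable[1]
        assert rep.identifiable[2]
        assert abs(rep.R[0, 1]) == pytest.approx(1.0)

    def test_orthogonal_columns_all_identifiable(self):
        H = np.eye(6)[:, :4]
        rep = identifiability_report(H)
        assert rep.n_identifiable == 4

    def test_zero_column_flagged(self):
        H = np.column_stack([np.zeros(20), np.random.default_rng(1).normal(size=20)])
        rep = identifiability_report(H)
        assert not rep.identifiable[0]
        assert rep.reasons[0] == "zero sensitivity"

    def test_r_matrix_properties(self):
        rng = np.random.default_rng(3)
        H = rng.standard_normal((50, 7))
        rep = identifiability_report(H)
        np.testing.assert_allclose(rep.R, rep.R.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(rep.R), 1.0)
        assert np.all(np.abs(rep.R) <= 1.0 + 1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_fim_eigen_oracle(self, seed):
        m = gen_linear_model(seed=seed)
        H = transfer_sensitivities(m)
        rep = identifiability_report(H)
        np.testing.assert_array_equal(rep.identifiable, fim_eigen_oracle(H))


class TestModeComparison:
    def test_reproducible(self):
        a = compare_input_modes(n_models=5, seed=11)
        b = compare_input_modes(n_models=5, seed=11)
        np.testing.assert_array_equal(a.deltas, b.deltas)

    def test_cell_coupled_identifies_more(self):
        cmp_ = compare_input_modes(n_models=40, seed=1)
        assert cmp_.deltas.mean() > 0
        assert cmp_.sign_test_pvalue() < 0.05

    def test_histogram_counts_models(self):
        cmp_ = compare_input_modes(n_models=12, seed=2)
        _, counts = cmp_.histogram()
        assert counts.sum() == 12
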