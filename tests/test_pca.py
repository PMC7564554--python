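import numpy as np
import pandas as pd
import pytest

from conftest import make_count_matrix
from lncnet.data_model import CountMatrix, DataModelError
from lncnet.normalization import filter_nonzero, vst_transform
from lncnet.pca import (
    PCASelection,
    confirm_separation,
    extract_features,
    run_pca,
    select_pcs,
)


def _vst_matrix(values, groups=None):
    """Wrap a real-valued matrix as a vst-state CountMatrix."""
    values = np.asarray(values, dtype=float)
    samples = [f"S{i + 1}" for i in range(values.shape[1])]
    groups = groups or (["healthy"] * 3 + ["tumour"] * 3)
    df = pd.DataFrame(values, index=[f"g{i + 1}" for i in range(values.shape[0])],
                      columns=samples)
    return CountMatrix(df, pd.Series(groups, index=samples), "vst")


class TestRunPca:
    def test_single_varying_gene_owns_all_variance(self):
        x = np.vstack([np.arange(6.0), np.full((5, 6), 3.0)])
        sel = run_pca(_vst_matrix(x))
        assert sel.explained_fraction[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        sel = run_pca(_vst_matrix(rng.normal(size=(50, 6))))
        assert sel.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(sel.cumulative_fraction) >= -1e-12)
        assert len(sel.eigenvalues) <= 5  # at most s-1 nonzero components

    def test_score_covariance_reproduces_eigenvalues(self):
        rng = np.random.default_rng(1)
        sel = run_pca(_vst_matrix(rng.normal(size=(40, 6))))
        s = sel.scores.to_numpy()
        gram = s.T @ s / (s.shape[0] - 1)
        np.testing.assert_allclose(gram, np.diag(sel.eigenvalues), atol=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(DataModelError, match="constant"):
            run_pca(_vst_matrix(np.full((5, 6), 2.0)))


class TestSelectPcs:
    def _sel(self, fractions):
        fractions = np.asarray(fractions, dtype=float)
        return PCASelection(
            eigenvalues=fractions,
            explained_fraction=fractions,
            cumulative_fraction=np.cumsum(fractions),
            scores=pd.DataFrame(np.zeros((6, len(fractions)))),
        )

    @pytest.mark.parametrize(
        "fractions, threshold, expected",
        [
            ((0.40, 0.20, 0.15, 0.15, 0.10), 0.6, 2),
            ((0.70, 0.20, 0.10), 0.6, 1),
            ((0.50, 0.30, 0.20), 1.0, 3),
        ],
    )
    def test_smallest_k_reaching_threshold(self, fractions, threshold, expected):
        assert select_pcs(self._sel(fractions), threshold) == expected

    def test_fixed_k_override(self):
        assert select_pcs(self._sel((0.9, 0.1)), fixed_k=2) == 2


class TestExtractFeatures:
    def _structured(self, rng, n_noise=60):
        pattern = np.array([0.0, 1.0, 2.0, 5.0, 6.0, 7.0])
        signal = np.vstack([pattern * s for s in (2.0, -1.5, 1.0)])
        noise = rng.normal(size=(n_noise, 6)) * 0.5
        return _vst_matrix(np.vstack([signal, noise]))

    def test_profile_matching_pc1_is_selected(self):
        rng = np.random.default_rng(2)
        cm = self._structured(rng)
        sel = run_pca(cm)
        select_pcs(sel, 0.6)
        selected = extract_features(sel, cm)
        assert {"g1", "g2", "g3"} <= set(selected.index)
        assert (selected.loc[["g1", "g2", "g3"], "assigned_pc"] == "PC1").all()
        assert selected.loc["g1", "r"] == pytest.approx(1.0, abs=0.02)

    def test_selection_invariant_to_pc_sign_flip(self):
        rng = np.random.default_rng(3)
        cm = self._structured(rng)
        sel = run_pca(cm)
        select_pcs(sel, 0.6)
        before = set(extract_features(sel, cm).index)
        sel.scores = -sel.scores
        after = set(extract_features(sel, cm).index)
        assert before == after

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        cm = self._structured(rng)
        sel = run_pca(cm)
        select_pcs(sel, 0.6)
        strict = set(extract_features(sel, cm, r_min=0.9, q_max=0.01).index)
        loose = set(extract_features(sel, cm, r_min=0.8, q_max=0.05).index)
        looser = set(extract_features(sel, cm, r_min=0.5, q_max=0.2).index)
        assert strict <= loose <= looser

    def test_pearson_p_matches_permutation_null_at_n6(self):
        # the parametric two-sided p should calibrate against the exact
        # permutation distribution of |r| for moderately correlated pairs
        rng = np.random.default_rng(5)
        from itertools import permutations
        for _ in range(5):
            x = rng.normal(size=6)
            y = 0.5 * x + rng.normal(size=6)
            r_obs = np.corrcoef(x, y)[0, 1]
            from scipy import stats
            ab = 2.0
            p_param = 2 * stats.beta.sf(abs(r_obs), ab, ab, loc=-1, scale=2)
            hits = sum(
                abs(np.corrcoef(x, np.array(p))[0, 1]) >= abs(r_obs) - 1e-12
                for p in permutations(y)
            )
            p_perm = hits / 720
            assert p_param == pytest.approx(p_perm, abs=0.06)

    def test_planted_discriminative_lncrnas_recovered(self, default_run):
        sim, report = default_run
        selected = set(report.pca_selection.selected.index)
        planted = set(sim.truth.module_lnc_ids())
        assert len(selected & planted) / len(planted) >= 0.9


class TestConfirmSeparation:
    def test_planted_structure_separates(self, default_run):
        _, report = default_run
        assert report.separation["silhouette"] > 0.5
        assert report.separation["linearly_separable"]

    def test_null_features_do_not_separate(self):
        rng = np.random.default_rng(6)
        cm = _vst_matrix(rng.normal(size=(30, 6)),
                         groups=["healthy", "tumour"] * 3)
        rep = confirm_separation(cm, list(cm.gene_ids))
        assert abs(rep["silhouette"]) < 0.35

    def test_single_perfect_feature_is_separable(self):
        cm = _vst_matrix(np.array([[0.0, 0.2, 0.1, 5.0, 5.2, 5.1]]))
        rep = confirm_separation(cm, ["g1"])
        assert rep["linearly_separable"]
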