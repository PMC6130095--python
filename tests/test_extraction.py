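import numpy as np
import pandas as pd
import pytest

import replisig as rs
from replisig import extraction as ex
from replisig.mutation_types import TYPE96_LABELS, TYPE192_LABELS
from replisig.simulate import strand_spectrum

FAST = dict(n_resamples=6, n_restarts=2, max_iter=2000, tol=1e-7)


@pytest.fixture(scope="module")
def planted_catalog():
    truth = rs.make_truth(n_samples=25, n_signatures=3, seed=50, asymmetry_ratio=3.0)
    X = rs.simulate_catalogs(truth, mutations_per_sample=8_000, seed=51)
    planted = np.stack([strand_spectrum(s, truth.asymmetry_ratio)
                        for s in truth.signatures])
    return X, planted


def _max_cosines(planted, sigs):
    S = sigs.T
    num = planted @ S.T
    den = (np.linalg.norm(planted, axis=1)[:, None] *
           np.linalg.norm(S, axis=1)[None, :])
    return (num / den).max(axis=1)


class TestMultiplicativeNMF:
    def test_error_monotone_and_reconstructs(self):
        rng = np.random.default_rng(0)
        W0 = rng.uniform(size=(30, 2))
        H0 = rng.uniform(size=(2, 10))
        V = W0 @ H0
        W, H, err = ex.multiplicative_nmf(V, 2, np.random.default_rng(1),
                                          max_iter=5000, tol=1e-12)
        assert err < 1e-3 * np.linalg.norm(V)

    def test_comparable_to_sklearn_mu_solver(self):
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(2)
        V = rng.poisson(20.0, size=(40, 15)).astype(float)
        _, _, err = ex.multiplicative_nmf(V, 3, np.random.default_rng(3),
                                          max_iter=5000, tol=1e-10)
        sk = NMF(3, solver="mu", beta_loss="frobenius", init="random",
                 random_state=0, max_iter=5000, tol=1e-10).fit(V)
        sk_err = np.linalg.norm(V - sk.transform(V) @ sk.components_)
        assert err <= sk_err * 1.05

    def test_rank_one_is_proportional_to_mean_spectrum(self, planted_catalog):
        X, _ = planted_catalog
        sigs, _, _ = ex.nmf_extract(X, 1, n_resamples=4, n_restarts=2, seed=0,
                                    max_iter=3000, tol=1e-9)
        mean_spec = X.to_numpy().sum(axis=0)
        mean_spec = mean_spec / mean_spec.sum()
        cos = sigs[:, 0] @ mean_spec / (np.linalg.norm(sigs[:, 0]) *
                                        np.linalg.norm(mean_spec))
        assert cos > 0.999

    def test_fixed_seed_is_bit_identical(self, planted_catalog):
        X, _ = planted_catalog
        a = ex.nmf_extract(X, 2, seed=7, **FAST)
        b = ex.nmf_extract(X, 2, seed=7, **FAST)
        assert (a[0] == b[0]).all()
        assert (a[1] == b[1]).all()

    def test_k_larger_than_samples_rejected(self):
        X = np.zeros((3, 192))
        X[:, 0] = 10
        with pytest.raises(ValueError, match="exceeds"):
            ex.nmf_extract(X, 5, n_resamples=2, n_restarts=1, seed=0)


class TestModelSelection:
    def test_planted_rank_is_selected(self, planted_catalog):
        X, planted = planted_catalog
        best, results = ex.select_K(X, range(2, 5), seed=1, **FAST)
        assert best.K == 3
        assert best.stability > 0.8
        sigs = results[3][0]
        assert _max_cosines(planted, sigs).min() > 0.9

    def test_stability_threshold_overrides_error(self):
        a = ex.ModelSelection(2, error=5.0, stability=0.95)
        b = ex.ModelSelection(3, error=1.0, stability=0.7)
        for ms, max_err in ((a, 5.0), (b, 5.0)):
            ms.objective = ms.error / max_err + (1 - ms.stability)
            ms.meets_stability = ms.stability >= 0.8
        eligible = [ms for ms in (a, b) if ms.meets_stability]
        assert min(eligible, key=lambda m: (m.objective, m.K)).K == 2

    def test_signature_columns_are_normalized(self, planted_catalog):
        X, _ = planted_catalog
        sigs, _, _ = ex.nmf_extract(X, 3, seed=2, **FAST)
        assert np.allclose(sigs.sum(axis=0), 1.0, atol=1e-9)


class TestLowExposureFilter:
    def test_zero_exposure_signature_removed(self):
        sigs = np.eye(192)[:, :3]
        expo = np.array([[100.0, 50.0, 0.0]] * 10)
        kept_sigs, kept_expo, kept = ex.filter_low_exposure(sigs, expo)
        assert kept.tolist() == [True, True, False]
        assert kept_sigs.shape[1] == 2

    def test_ratio_exactly_at_threshold_is_retained(self):
        expo = np.zeros((10, 2))
        expo[:, 0] = 80.0
        expo[:, 1] = 20.0  # p95 = 20, mean total = 100 -> ratio exactly 0.2
        _, _, kept = ex.filter_low_exposure(np.eye(192)[:, :2], expo, threshold=0.2)
        assert kept.tolist() == [True, True]

    def test_decision_matches_percentile_oracle(self):
        rng = np.random.default_rng(5)
        expo = rng.uniform(0, 50, size=(30, 4))
        expo[:, 2] *= 0.05
        _, _, kept = ex.filter_low_exposure(np.eye(192)[:, :4], expo)
        ratios = [np.percentile(expo[:, j], 95) / expo.sum(axis=1).mean()
                  for j in range(4)]
        assert kept.tolist() == [r >= 0.2 for r in ratios]


def _embed(ref96):
    return np.concatenate([ref96 / 2, ref96 / 2])


class TestClustering:
    def _reference(self, n=4, seed=6):
        rng = np.random.default_rng(seed)
        mat = rng.dirichlet(np.ones(96) * 0.2, size=n).T
        return pd.DataFrame(mat, index=list(TYPE96_LABELS),
                            columns=[f"RefSig{j}" for j in range(n)])

    def test_duplicated_reference_co_clusters_at_zero_distance(self):
        ref = self._reference()
        strand = pd.DataFrame({"ext0": _embed(ref["RefSig0"].to_numpy())},
                              index=list(TYPE192_LABELS))
        clusters = rs.cluster_with_reference(strand, ref, n_clusters=4)
        home = next(c for c in clusters if "ext0" in c.strand_members)
        assert "RefSig0" in home.reference_members
        assert home.provenance == "reference:RefSig0"

    def test_orthogonal_signatures_separate(self):
        a = np.zeros(192); a[:10] = 0.1
        b = np.zeros(192); b[100:110] = 0.1
        strand = pd.DataFrame({"a": a, "b": b}, index=list(TYPE192_LABELS))
        clusters = rs.cluster_with_reference(strand, None, n_clusters=2)
        assert len(clusters) == 2
        assert all(len(c.strand_members) == 1 for c in clusters)

    def test_perturbed_copies_cocluster_with_sources(self):
        ref = self._reference(4)
        rng = np.random.default_rng(7)
        cols = {}
        for j in range(4):
            base = ref[f"RefSig{j}"].to_numpy()
            noisy = np.clip(base + rng.normal(0, 0.1 * base.mean(), 96), 0, None)
            cols[f"copy{j}"] = _embed(noisy / noisy.sum())
        strand = pd.DataFrame(cols, index=list(TYPE192_LABELS))
        clusters = rs.cluster_with_reference(strand, ref, n_clusters=4)
        for c in clusters:
            assert len(c.strand_members) == 1 and len(c.reference_members) == 1
            j = list(c.strand_members)[0].removeprefix("copy")
            assert f"RefSig{j}" in c.reference_members

    def test_too_many_clusters_rejected(self):
        strand = pd.DataFrame(np.full((192, 2), 1 / 192),
                              index=list(TYPE192_LABELS), columns=["a", "b"])
        with pytest.raises(ValueError, match="exceeds"):
            rs.cluster_with_reference(strand, None, n_clusters=5)

    def test_input_order_invariance(self):
        ref = self._reference(3)
        rng = np.random.default_rng(8)
        cols = {f"s{j}": rng.dirichlet(np.ones(192) * 0.2) for j in range(4)}
        strand = pd.DataFrame(cols, index=list(TYPE192_LABELS))
        c1 = rs.cluster_with_reference(strand, ref, n_clusters=3)
        c2 = rs.cluster_with_reference(strand[reversed(list(cols))], ref, n_clusters=3)
        sets1 = sorted(frozenset(c.strand_members) | frozenset(c.reference_members)
                       for c in c1)
        sets2 = sorted(frozenset(c.strand_members) | frozenset(c.reference_members)
                       for c in c2)
        assert sets1 == sets2


class TestDirectionAnnotation:
    def _cluster(self, lead, lag, rep=None):
        v = np.concatenate([lead, lag])
        c = ex.SignatureCluster(1, strand_members={"m": v})
        rep = (lead + lag) if rep is None else rep
        c.representative = rep / rep.sum()
        c.representative_name = "novel_m"
        return c

    def test_larger_side_wins(self):
        lead = np.zeros(96); lag = np.zeros(96)
        lead[0], lag[0] = 0.10, 0.02
        lead[5], lag[5] = 0.01, 0.30
        d = rs.annotate_direction(self._cluster(lead, lag))
        assert d.leading_mask[0]
        assert not d.leading_mask[5]

    def test_zero_mass_type_follows_group_majority(self):
        lead = np.zeros(96); lag = np.zeros(96)
        # C>T group (indices 32..47) majority lagging
        lag[33:40] = 0.1
        lead[34] = 0.01
        d = rs.annotate_direction(self._cluster(lead, lag))
        assert not d.leading_mask[32]  # no mass at 32 -> group majority lagging

    def test_tie_at_high_mass_type_falls_back_to_group(self):
        lead = np.zeros(96); lag = np.zeros(96)
        lead[0] = lag[0] = 0.2          # exact tie
        lead[1:8] = 0.05                # rest of C>A group clearly leading
        d = rs.annotate_direction(self._cluster(lead, lag))
        assert d.leading_mask[0]

    def test_reference_only_cluster_is_flagged_no_evidence(self):
        c = ex.SignatureCluster(2, reference_members={"R": np.full(96, 1 / 96)})
        c.representative = np.full(96, 1 / 96)
        c.representative_name = "R"
        c.provenance = "reference:R"
        d = rs.annotate_direction(c)
        assert d.leading_mask.all()
        assert "no-evidence" in d.provenance

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(9)
        lead = rng.uniform(size=96); lag = rng.uniform(size=96)
        d = rs.annotate_direction(self._cluster(lead, lag))
        assert d.weights.sum() == pytest.approx(1.0, abs=1e-9)
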