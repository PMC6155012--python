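"""Suspension pipeline: transform, gating, embedding, nodes, bubbles,
profiles, MDS and the subset dendrogram."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from mzatlas import cytometry, synthetic
from mzatlas.cytometry import EventTable, Gate
from mzatlas.panels import EMBED_MARKERS, default_subset_rules
from tests.conftest import two_cloud_table


class TestTransform:
    def test_zero_maps_to_zero_and_closed_form(self):
        df = pd.DataFrame({"m": [0.0, 5.0]})
        t = cytometry.transform_intensities(EventTable(df, ["m"]), cofactor=5)
        assert t.data["m"].iloc[0] == 0.0
        assert t.data["m"].iloc[1] == pytest.approx(np.arcsinh(1.0))

    def test_monotone_rank_preserving(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"m": rng.uniform(0, 100, 50)})
        t = cytometry.transform_intensities(EventTable(df, ["m"]))
        assert (df["m"].rank() == t.data["m"].rank()).all()

    def test_nonpositive_cofactor_rejected(self):
        df = pd.DataFrame({"m": [1.0]})
        with pytest.raises(ValueError):
            cytometry.transform_intensities(EventTable(df, ["m"]), cofactor=0)


class TestGating:
    def _fixture(self):
        df = pd.DataFrame({
            "CD19": [3.0, 3.0, 0.2, 3.0, 0.1, 2.5],
            "CD3": [0.1, 2.8, 0.2, 0.3, 2.9, 2.7],
        })
        return EventTable(df, ["CD19", "CD3"])

    def test_empty_gate_list_is_identity(self):
        t = self._fixture()
        out = cytometry.gate_events(t, [])
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_threshold_at_minimum_is_identity(self):
        t = self._fixture()
        out = cytometry.gate_events(t, [Gate("CD19", 0.1, "above")])
        assert out.n_events == t.n_events

    def test_six_event_fixture_brute_force(self):
        """CD19-above/CD3-below keeps exactly the events an exhaustive scan
        qualifies."""
        t = self._fixture()
        gates = [Gate("CD19", 1.0, "above"), Gate("CD3", 1.0, "below")]
        out = cytometry.gate_events(t, gates)
        expected = [i for i in range(6)
                    if t.data["CD19"][i] >= 1.0 and t.data["CD3"][i] <= 1.0]
        assert out.n_events == len(expected) == 2
        assert np.allclose(out.data["CD19"].to_numpy(),
                           t.data["CD19"].iloc[expected].to_numpy())

    def test_gating_idempotent(self):
        t = self._fixture()
        gates = [Gate("CD19", 1.0, "above")]
        once = cytometry.gate_events(t, gates)
        twice = cytometry.gate_events(once, gates)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_unknown_marker_rejected(self):
        with pytest.raises(KeyError):
            cytometry.gate_events(self._fixture(), [Gate("CD99", 1.0)])


class TestEmbedding:
    def test_two_clouds_recovered_by_2means(self):
        t = two_cloud_table(n=400, seed=1)
        coords = cytometry.embed_2d(t, t.markers, seed=0)
        from sklearn.cluster import KMeans
        pred = KMeans(2, random_state=0, n_init=4).fit_predict(coords)
        truth = (t.data["truth_subset"] == "b").to_numpy().astype(int)
        agree = max((pred == truth).mean(), (pred != truth).mean())
        assert agree >= 0.95

    def test_deterministic_given_seed(self):
        t = two_cloud_table(n=120, seed=2)
        a = cytometry.embed_2d(t, t.markers, seed=7)
        b = cytometry.embed_2d(t, t.markers, seed=7)
        assert np.array_equal(a, b)

    def test_duplicated_events_stay_mutual_neighbours(self):
        t = two_cloud_table(n=100, seed=3)
        dup = EventTable(pd.concat([t.data, t.data], ignore_index=True),
                         t.markers)
        coords = cytometry.embed_2d(dup, t.markers, seed=0)
        from scipy.spatial import cKDTree
        tree = cKDTree(coords)
        _, nn = tree.query(coords, k=2)
        n = t.n_events
        ok = sum(1 for i in range(n)
                 if nn[i, 1] == i + n or nn[i + n, 1] == i)
        assert ok / n >= 0.90


class TestNodesAndBubbles:
    def test_singleton_nodes_equal_events(self):
        t = two_cloud_table(n=40, seed=4)
        coords = cytometry.embed_2d(t, t.markers, seed=0, method="pca")
        g = cytometry.cluster_nodes(coords, t, k=40, seed=0)
        assert all(len(m) == 1 for m in g.members.values())
        for nid, idx in g.members.items():
            assert np.allclose(g.medians.loc[nid].to_numpy(),
                               t.intensities[idx[0]])

    def test_two_clouds_two_nodes(self):
        t = two_cloud_table(n=300, seed=5)
        coords = cytometry.embed_2d(t, t.markers, seed=0, method="pca")
        g = cytometry.cluster_nodes(coords, t, k=2, seed=0)
        truth = (t.data["truth_subset"] == "b").to_numpy().astype(int)
        agree = max((g.node_of_event == truth).mean(),
                    (g.node_of_event != truth).mean())
        assert agree >= 0.95

    def test_k_out_of_range_rejected(self):
        t = two_cloud_table(n=10, seed=6)
        coords = np.zeros((10, 2))
        with pytest.raises(ValueError):
            cytometry.cluster_nodes(coords, t, k=1)
        with pytest.raises(ValueError):
            cytometry.cluster_nodes(coords, t, k=11)

    def test_cd45rb_marks_precursor_nodes(self, naive_precursor_table):
        """Node medians carry CD45RB even though it is not an embedding
        marker, so precursor-rich nodes stand out inside the naive bubble."""
        t = naive_precursor_table
        coords = cytometry.embed_2d(t, EMBED_MARKERS, seed=0)
        g = cytometry.cluster_nodes(coords, t, k=30, seed=0)
        truth = t.data["truth_subset"].to_numpy()
        prec_nodes = {int(n) for n, idx in g.members.items()
                      if (truth[idx] == "precursor").mean() > 0.5}
        naive_nodes = {int(n) for n, idx in g.members.items()
                       if (truth[idx] == "naive").all()}
        assert prec_nodes and naive_nodes
        assert (g.medians.loc[sorted(prec_nodes), "CD45RB"].min()
                > g.medians.loc[sorted(naive_nodes), "CD45RB"].max())

    def test_twelve_archetype_recovery(self):
        """Rule-based bubbles recover the mixture within 5% absolute per
        subset and ARI >= 0.8 overall."""
        t = synthetic.gen_cytometry_sample(synthetic.default_archetypes(),
                                           3000, seed=1)
        coords = cytometry.embed_2d(t, EMBED_MARKERS, seed=1)
        g = cytometry.cluster_nodes(coords, t, k=60, seed=1)
        _, labels = cytometry.assign_bubbles(g, default_subset_rules())
        truth = t.data["truth_subset"]
        assert adjusted_rand_score(truth, labels) >= 0.8
        tf = truth.value_counts(normalize=True)
        lf = labels.value_counts(normalize=True)
        for s in tf.index:
            assert abs(tf[s] - lf.get(s, 0.0)) <= 0.05

    def test_precursor_rule_captures_truth_precursors(
            self, naive_precursor_table):
        t = naive_precursor_table
        coords = cytometry.embed_2d(t, EMBED_MARKERS, seed=0)
        g = cytometry.cluster_nodes(coords, t, k=30, seed=0)
        _, labels = cytometry.assign_bubbles(g, default_subset_rules())
        truth = t.data["truth_subset"]
        captured = (labels[truth == "precursor"] == "precursor").mean()
        assert captured >= 0.90

    def test_all_cd19_negative_goes_to_other(self):
        df = pd.DataFrame({m: np.full(20, 0.1) for m in
                           ["CD19", "CD3", "CD14", "IgD", "CD27"]})
        t = EventTable(df, list(df.columns))
        g = cytometry.cluster_nodes(np.random.default_rng(0).normal(
            size=(20, 2)), t, k=2, seed=0)
        _, labels = cytometry.assign_bubbles(g, default_subset_rules())
        assert (labels == "other").all()


class TestProfilesAndMds:
    def test_subset_medians_exact(self):
        df = pd.DataFrame({"m": [1.0, 2.0, 9.0, 4.0], "tissue": "galt"})
        t = EventTable(df, ["m"])
        prof = cytometry.subset_medians(t, pd.Series(["a", "a", "a", "b"]))
        assert prof.medians.loc[("galt", "a"), "m"] == 2.0
        assert prof.medians.loc[("galt", "b"), "m"] == 4.0
        assert prof.fractions.loc["galt"].sum() == pytest.approx(1.0)

    def test_mds_exact_for_planar_profiles(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 2))
        lift = rng.normal(size=(2, 7))
        profiles = pd.DataFrame(base @ lift)  # rank-2: exact 2-D embedding
        _, stress = cytometry.mds_samples(profiles)
        assert stress <= 1e-6

    def test_mds_equilateral_symmetry(self):
        profiles = pd.DataFrame(np.eye(3))  # 3 equidistant samples
        coords, _ = cytometry.mds_samples(profiles)
        d = [np.linalg.norm(coords[i] - coords[j])
             for i, j in itertools.combinations(range(3), 2)]
        assert max(d) - min(d) <= 1e-6

    def test_tissue_replicates_cluster_together(self):
        profs = {}
        seed = 100
        for tissue in ["galt", "spleen", "tonsil"]:
            for r in range(2):
                t = synthetic.gen_tissue_sample(tissue, f"{tissue}{r}", 3000,
                                                seed=seed)
                seed += 1
                profs[f"{tissue}{r}"] = cytometry.profile_vector(
                    t, t.data["truth_subset"])
        P = pd.DataFrame(profs).T
        coords, _ = cytometry.mds_samples(P)
        names = list(P.index)
        dist = lambda i, j: np.linalg.norm(coords[i] - coords[j])
        within = [dist(i, j) for i, j in itertools.combinations(range(6), 2)
                  if names[i][:-1] == names[j][:-1]]
        across = [dist(i, j) for i, j in itertools.combinations(range(6), 2)
                  if names[i][:-1] != names[j][:-1]]
        assert max(within) < min(across)

    def test_degenerate_profiles_rejected(self):
        with pytest.raises(ValueError):
            cytometry.mds_samples(pd.DataFrame(np.ones((4, 3))))


class TestSubsetDendrogram:
    def _profiles(self):
        t = synthetic.gen_cytometry_sample(synthetic.default_archetypes(),
                                           4000, seed=3)
        return t.data.groupby("truth_subset")[t.markers].median()

    def test_identical_profiles_merge_at_zero(self):
        p = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]],
                         index=["a", "b", "c"])
        z = cytometry.hcluster_subsets(p)
        assert z[0, 2] == pytest.approx(0.0)

    def test_precursor_aligns_with_mz_before_switched_memory(self):
        """The precursor and MZ subsets are mutual nearest subsets and merge
        before either joins a class-switched memory subset."""
        prof = self._profiles()
        z = cytometry.hcluster_subsets(prof)
        names = list(prof.index)
        coph = squareform(cophenet(z))
        i_pre = names.index("precursor")
        i_mz = names.index("mz")
        d_pm = coph[i_pre, i_mz]
        for sw in ("csm_igg", "csm_iga"):
            i_sw = names.index(sw)
            assert d_pm < coph[i_pre, i_sw]
            assert d_pm < coph[i_mz, i_sw]
        # mutual nearest by raw euclidean distance
        from scipy.spatial.distance import cdist
        d = cdist(prof.to_numpy(), prof.to_numpy())
        np.fill_diagonal(d, np.inf)
        assert d[i_pre].argmin() == i_mz and d[i_mz].argmin() == i_pre

    def test_merge_heights_invariant_to_input_order(self):
        prof = self._profiles()
        z1 = cytometry.hcluster_subsets(prof)
        perm = prof.sample(frac=1.0, random_state=1)
        z2 = cytometry.hcluster_subsets(perm)
        assert np.allclose(np.sort(z1[:, 2]), np.sort(z2[:, 2]))

    def test_missing_values_rejected(self):
        p = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            cytometry.hcluster_subsets(p)

    def test_newick_rendering_has_all_leaves(self):
        prof = self._profiles()
        z = cytometry.hcluster_subsets(prof)
        nwk = cytometry.linkage_to_newick(z, list(prof.index))
        assert nwk.endswith(";")
        for name in prof.index:
            assert name in nwk
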