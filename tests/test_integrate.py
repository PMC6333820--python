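import numpy as np
import pandas as pd
import pytest

from progmir import diffexp, integrate, preprocess, synthetic
from progmir.diffexp import DECallConfig
from conftest import make_study


def de_table(features, logfc, p, contrast="HC_vs_CP", dataset="d1"):
    """Hand-built DE table with the columns meta_signature consumes."""
    tab = pd.DataFrame({
        "logfc": logfc, "p_raw": p, "p_ordinary": p,
        "direction": np.where(np.asarray(logfc) >= 0, "up", "down"),
    }, index=pd.Index(features, name="feature"))
    tab.attrs.update({"contrast": contrast, "dataset_id": dataset,
                      "moderated": False})
    return tab


class TestMetaSignature:
    def test_consistent_down_in_three_datasets_retained(self):
        de = {d: de_table(["m1", "m2"], [-1.0, 0.2], [0.01, 0.8], dataset=d)
              for d in ("d1", "d2", "d3")}
        meta = integrate.meta_signature(de, min_datasets=3)
        assert list(meta.index) == ["m1"]
        assert meta.loc["m1", "direction"] == "down"
        assert meta.loc["m1", "n_called"] == 3

    def test_conflicting_directions_excluded(self):
        de = {"d1": de_table(["m1"], [-1.0], [0.01], dataset="d1"),
              "d2": de_table(["m1"], [+1.0], [0.01], dataset="d2")}
        meta = integrate.meta_signature(de, min_datasets=2)
        assert len(meta) == 0
        relaxed = integrate.meta_signature(de, min_datasets=2,
                                           require_direction_consistency=False)
        assert relaxed.loc["m1", "direction"] == "inconsistent"

    def test_single_dataset_min1_reduces_to_call_de(self, rng):
        x = rng.normal(size=(60, 20))
        x[:5, 10:] += 2.0
        study = make_study(x, ["HC"] * 10 + ["CP"] * 10)
        de = diffexp.moderate(diffexp.fit_contrast(study, "HC", "CP"))
        meta = integrate.meta_signature({"d1": de}, min_datasets=1)
        called = {f for f, _ in diffexp.call_de(de, DECallConfig.mirna())}
        assert set(meta.index) == called

    def test_disjoint_namespaces_rejected(self):
        de = {"d1": de_table(["a"], [1.0], [0.01], dataset="d1"),
              "d2": de_table(["b"], [1.0], [0.01], dataset="d2")}
        with pytest.raises(ValueError, match="disjoint"):
            integrate.meta_signature(de, min_datasets=1)

    def test_planted_recovery_on_synthetic_cohort(self):
        """CP/PDAC intersection finds the planted miRNAs (down), never with
        inconsistent direction; the PDAC-side meta-signature alone recovers
        >=90% of them."""
        joint, pdac_only, inconsistent = [], [], 0
        for seed in range(5):
            cfg = synthetic.SimConfig(seed=seed, n_genes=60, n_mirnas=200,
                                      targets_per_mirna=6, hub_boost=1.0)
            studies, _, truth = synthetic.generate_cohort(cfg)
            mir = [preprocess.z_normalize(s) for s in studies[:3]]
            metas = {}
            for b in ("CP", "PDAC"):
                de = {s.dataset_id: diffexp.moderate(
                    diffexp.fit_contrast(s, "HC", b)) for s in mir}
                metas[b] = integrate.meta_signature(de, 2)
            common = integrate.cross_contrast_intersection(metas["CP"],
                                                           metas["PDAC"])
            planted = set(truth.planted_mirna_ids)
            inconsistent += (metas["PDAC"]["direction"] == "inconsistent").sum()
            joint.append(np.mean([
                m in common.index and common.loc[m, "direction"] == "down"
                for m in planted]))
            pdac_only.append(np.mean([m in metas["PDAC"].index for m in planted]))
        assert np.mean(pdac_only) >= 0.9
        assert np.mean(joint) >= 0.7  # CP power is the binding constraint
        assert inconsistent == 0


class TestProgressiveFilter:
    def test_monotone_means_above_threshold_are_progressive_up(self):
        # per-group means 0, 1, 2 with logfc_min 1.5 -> up (terminal 2)
        vals = [[0, 0, 1, 1, 2, 2], [0, 0, 2, 2, 1, 1]]
        study = make_study(vals, ["HC", "HC", "CP", "CP", "PDAC", "PDAC"])
        up, down = integrate.progressive_filter(study, ("HC", "CP", "PDAC"), 1.5)
        assert up == ["f0"]        # f1 is non-monotone
        assert down == []

    def test_down_is_symmetric_and_lists_disjoint(self):
        vals = [[2, 2, 1, 1, 0, 0]]
        study = make_study(vals, ["HC", "HC", "CP", "CP", "PDAC", "PDAC"])
        up, down = integrate.progressive_filter(study, ("HC", "CP", "PDAC"), 1.5)
        assert down == ["f0"] and up == []

    def test_terminal_change_gate(self):
        vals = [[0, 0, 0.5, 0.5, 1.0, 1.0]]
        study = make_study(vals, ["HC", "HC", "CP", "CP", "PDAC", "PDAC"])
        up, down = integrate.progressive_filter(study, ("HC", "CP", "PDAC"), 1.5)
        assert up == [] and down == []

    def test_missing_stage_rejected(self):
        study = make_study([[1, 2]], ["HC", "CP"])
        with pytest.raises(ValueError, match="absent"):
            integrate.progressive_filter(study, ("HC", "CP", "PDAC"))

    def test_planted_genes_recovered_nulls_excluded(self):
        """Default schedule (1,2,3 z-units): planted targets pass the
        4-stage progressive filter; null features essentially never."""
        sens, fpr = [], []
        for seed in range(5):
            cfg = synthetic.SimConfig(seed=seed, n_genes=300, n_mirnas=40,
                                      targets_per_mirna=10)
            studies, _, truth = synthetic.generate_cohort(cfg)
            z = preprocess.z_normalize(studies[-1])
            up, down = integrate.progressive_filter(
                z, ("HC", "CP", "PDAC", "MPDAC"), 1.5)
            planted = set(truth.planted_gene_ids)
            sens.append(len(set(up) & planted) / len(planted))
            fpr.append(len((set(up) | set(down)) - planted)
                       / len(truth.null_gene_ids))
        assert np.mean(sens) >= 0.9
        assert np.mean(fpr) <= 0.01

    def test_invariant_to_sample_order(self, rng):
        cfg = synthetic.SimConfig(seed=3, n_genes=100, n_mirnas=20,
                                  targets_per_mirna=5)
        studies, _, _ = synthetic.generate_cohort(cfg)
        study = studies[-1]
        perm = rng.permutation(len(study.sample_ids))
        shuffled = study.subset_samples([study.sample_ids[i] for i in perm])
        assert integrate.progressive_filter(study, ("HC", "CP", "PDAC"), 1.5) \
            == integrate.progressive_filter(shuffled, ("HC", "CP", "PDAC"), 1.5)


class TestSomCluster:
    def test_single_node_prototype_is_sample_mean(self, rng):
        study = make_study(rng.normal(size=(6, 30)), ["HC"] * 30)
        som = integrate.som_cluster(study, grid_shape=(1, 1), n_iter=20, seed=0)
        np.testing.assert_allclose(som.prototypes[0],
                                   study.matrix().T.mean(axis=0), atol=1e-6)
        assert set(som.assignment.values()) == {0}

    def test_separated_clusters_partition_exactly(self, rng):
        a = rng.normal(-5, 0.5, size=(4, 15))
        b = rng.normal(+5, 0.5, size=(4, 15))
        study = make_study(np.hstack([a, b]), ["HC"] * 30)
        som = integrate.som_cluster(study, grid_shape=(1, 2), n_iter=50, seed=1)
        left = {som.assignment[f"s{j}"] for j in range(15)}
        right = {som.assignment[f"s{j}"] for j in range(15, 30)}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_quantization_error_non_increasing_at_fixed_radius(self, rng):
        study = make_study(rng.normal(size=(5, 40)), ["HC"] * 40)
        som = integrate.som_cluster(study, grid_shape=(2, 2), n_iter=30,
                                    radius_schedule=(0.05, 0.05), seed=2)
        qe = np.array(som.qe_history)
        assert np.all(np.diff(qe) <= 1e-10)

    def test_deterministic_under_seed(self, rng):
        study = make_study(rng.normal(size=(5, 20)), ["HC"] * 20)
        a = integrate.som_cluster(study, n_iter=30, seed=7)
        b = integrate.som_cluster(study, n_iter=30, seed=7)
        np.testing.assert_array_equal(a.prototypes, b.prototypes)
        assert a.assignment == b.assignment


class TestCounterRegulation:
    def _inputs(self):
        meta = pd.DataFrame({"direction": ["down"], "mean_logfc": [-0.5],
                             "n_called": [3]},
                            index=pd.Index(["m1"], name="feature"))
        meta.attrs["contrast"] = "HC_vs_PDAC"
        gene = de_table(["g1", "g2"], [0.8, -0.9], [0.001, 0.001],
                        contrast="HC_vs_PDAC")
        gene["p_adj"] = [0.001, 0.001]
        inter = pd.DataFrame({"mirna_id": ["m1", "m1"],
                              "gene_id": ["g1", "g3"],
                              "source_tag": ["db", "db"]})
        return meta, gene, inter

    def test_opposite_pair_in_table_emitted(self):
        meta, gene, inter = self._inputs()
        res = integrate.counter_regulation(meta, gene, inter, "HC_vs_PDAC")
        assert res.pairs[["mirna_id", "gene_id"]].values.tolist() == [["m1", "g1"]]
        assert res.targets_per_mirna["m1"] == 1

    def test_pair_absent_from_table_not_emitted(self):
        meta, gene, inter = self._inputs()
        inter = inter[inter["gene_id"] != "g1"]
        res = integrate.counter_regulation(meta, gene, inter, "HC_vs_PDAC")
        assert len(res.pairs) == 0

    def test_same_sign_pairs_never_emitted(self, rng):
        """Hard invariant on random inputs: no emitted pair has same-sign
        fold changes."""
        genes = [f"g{i}" for i in range(50)]
        for _ in range(20):
            lfc = rng.normal(size=50)
            gene = de_table(genes, lfc, np.full(50, 0.001),
                            contrast="HC_vs_PDAC")
            gene["p_adj"] = 0.001
            meta = pd.DataFrame({
                "direction": ["down", "up"], "mean_logfc": [-0.5, 0.4],
                "n_called": [3, 3]}, index=pd.Index(["m1", "m2"], name="feature"))
            meta.attrs["contrast"] = "HC_vs_PDAC"
            inter = pd.DataFrame({
                "mirna_id": rng.choice(["m1", "m2"], size=60),
                "gene_id": rng.choice(genes, size=60),
                "source_tag": "db"}).drop_duplicates()
            res = integrate.counter_regulation(meta, gene, inter, "HC_vs_PDAC")
            assert (np.sign(res.pairs["mirna_logfc"])
                    != np.sign(res.pairs["gene_logfc"])).all()

    def test_contrast_mismatch_rejected(self):
        meta, gene, inter = self._inputs()
        with pytest.raises(ValueError, match="contrast"):
            integrate.counter_regulation(meta, gene, inter, "HC_vs_CP")

    def test_precision_against_truth_with_decoys(self, small_cohort):
        cfg, studies, interactions, truth = small_cohort
        mir = [preprocess.z_normalize(s) for s in studies[:3]]
        de = {s.dataset_id: diffexp.moderate(diffexp.fit_contrast(s, "HC", "PDAC"))
              for s in mir}
        meta = integrate.meta_signature(de, 2)
        gene_de = diffexp.moderate(diffexp.fit_contrast(
            preprocess.z_normalize(studies[-1]), "HC", "PDAC"))
        res = integrate.counter_regulation(meta, gene_de, interactions,
                                           "HC_vs_PDAC")
        assert len(res.pairs) > 0
        tp = sum((m, g) in truth.planted_pairs
                 for m, g in zip(res.pairs["mirna_id"], res.pairs["gene_id"]))
        assert tp / len(res.pairs) >= 0.9
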