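"""Centroid training, subtype calls and the three molecular scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import hadamard

from lumipipe import config
from lumipipe import molecular_scoring as ms
from lumipipe.expression_qc import NormalizedMatrix


def _nm(values: pd.DataFrame) -> NormalizedMatrix:
    return NormalizedMatrix(values=values, log2=values, centering="gene-median",
                            standardized=True)


def _hadamard_model(**kwargs) -> ms.CentroidModel:
    """Four mutually orthogonal, mean-zero centroids over 8 synthetic genes."""
    H = hadamard(8).astype(float)
    genes = [f"g{i}" for i in range(8)]
    centroids = pd.DataFrame(H[1:5], index=list(config.SUBTYPES), columns=genes)
    kwargs.setdefault("correlation_method", "pearson")
    kwargs.setdefault("proliferation_genes", tuple(genes))
    return ms.CentroidModel(centroids=centroids, **kwargs)


class TestTrainCentroids:
    def test_centroids_equal_common_profiles(self):
        rng = np.random.default_rng(0)
        genes = list(config.SUBTYPE_GENES)
        profiles = {k: rng.normal(size=len(genes)) for k in config.SUBTYPES}
        rows, labels = [], []
        for k in config.SUBTYPES:
            rows += [profiles[k], profiles[k]]
            labels += [k, k]
        values = pd.DataFrame(rows, columns=genes,
                              index=[f"s{i}" for i in range(len(rows))])
        model = ms.train_centroids(_nm(values), pd.Series(labels, index=values.index))
        for k in config.SUBTYPES:
            np.testing.assert_allclose(model.centroids.loc[k].to_numpy(), profiles[k])

    def test_thin_subtype_is_named_in_error(self):
        genes = list(config.SUBTYPE_GENES)
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(5, len(genes))), columns=genes,
                              index=list("abcde"))
        labels = pd.Series(["LumA", "LumA", "LumB", "LumB", "Basal"], index=values.index)
        with pytest.raises(ValueError, match="Basal"):
            ms.train_centroids(_nm(values), labels)

    def test_permuted_labels_destroy_classification(self, cohort600, normalized600):
        rng = np.random.default_rng(2)
        train_ids = normalized600.values.index[:400]
        test_ids = normalized600.values.index[400:]
        labels = cohort600.clinical["true_subtype"].loc[train_ids]
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=train_ids)
        sub = NormalizedMatrix(values=normalized600.values.loc[train_ids],
                               log2=normalized600.log2.loc[train_ids])
        model = ms.train_centroids(sub, permuted)
        calls = [ms.classify_subtype(normalized600.values.loc[s], model).subtype
                 for s in test_ids]
        truth = cohort600.clinical["true_subtype"].loc[test_ids]
        assert (np.array(calls) == truth.to_numpy()).mean() < 0.5


class TestClassifySubtype:
    def test_self_correlation_is_one(self):
        model = _hadamard_model()
        call = ms.classify_subtype(model.centroids.loc["Basal"], model)
        assert call.subtype == "Basal"
        assert call.correlations["Basal"] == pytest.approx(1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        model = _hadamard_model(correlation_method="spearman")
        luma = model.centroids.loc["LumA"]
        transformed = np.exp(2.0 * luma) + 5.0  # strictly increasing map
        call = ms.classify_subtype(transformed, model)
        assert call.subtype == "LumA"
        assert call.correlations["LumA"] == pytest.approx(1.0)

    def test_tie_broken_in_fixed_order_with_flag(self):
        H = hadamard(8).astype(float)
        genes = [f"g{i}" for i in range(8)]
        centroids = pd.DataFrame([H[1], H[1], H[2], H[3]],
                                 index=list(config.SUBTYPES), columns=genes)
        model = ms.CentroidModel(centroids=centroids, correlation_method="pearson")
        call = ms.classify_subtype(pd.Series(H[1], index=genes), model)
        assert call.subtype == "LumA"
        assert call.tie

    def test_constant_profile_rejected(self):
        model = _hadamard_model()
        with pytest.raises(ValueError, match="constant"):
            ms.classify_subtype(pd.Series(1.0, index=model.centroids.columns), model)

    def test_held_out_recovery_above_95pct(self, cohort600, normalized600, scores600):
        held_out = normalized600.values.index[400:]
        truth = cohort600.clinical["true_subtype"].loc[held_out]
        acc = (scores600.loc[held_out, "subtype"] == truth).mean()
        assert acc >= 0.95

    def test_knn_variant_agrees_with_truth_on_separated_data(self, cohort600, normalized600):
        train_ids = normalized600.values.index[:400]
        test_ids = normalized600.values.index[400:450]
        labels = cohort600.clinical["true_subtype"]
        calls = [
            ms.classify_subtype_knn(normalized600.values.loc[s],
                                    normalized600.values.loc[train_ids],
                                    labels.loc[train_ids])
            for s in test_ids
        ]
        assert (np.array(calls) == labels.loc[test_ids].to_numpy()).mean() >= 0.9


class TestRorP:
    def test_zero_correlations_and_zero_p_give_offset(self):
        model = _hadamard_model()
        H = hadamard(8).astype(float)
        sample = pd.Series(H[5], index=model.centroids.columns)  # orthogonal to all
        score, cls, call = ms.ror_p(sample, model)
        for k in config.SUBTYPES:
            assert call.correlations[k] == pytest.approx(0.0, abs=1e-12)
        assert score == pytest.approx(model.ror_rescale[0])
        assert cls == "medium"  # offset 50 sits between the 29/53 bounds

    def test_strictly_increasing_in_proliferation(self):
        genes = [f"g{i}" for i in range(8)]
        prolif = ["p0", "p1", "p2"]
        H = hadamard(8).astype(float)
        centroids = pd.DataFrame(H[1:5], index=list(config.SUBTYPES), columns=genes)
        model = ms.CentroidModel(centroids=centroids, correlation_method="pearson",
                                 proliferation_genes=tuple(prolif))
        base = pd.Series(np.r_[H[5], [0.0, 0.0, 0.0]], index=genes + prolif)
        scores = []
        for delta in (0.0, 0.4, 0.8):
            profile = base.copy()
            profile[prolif] += delta
            scores.append(ms.ror_p(profile, model)[0])
        assert scores[0] < scores[1] < scores[2]

    def test_scores_bounded_for_arbitrary_profiles(self):
        model = _hadamard_model()
        rng = np.random.default_rng(3)
        for _ in range(50):
            sample = pd.Series(rng.normal(scale=10, size=8),
                               index=model.centroids.columns)
            if np.ptp(sample.to_numpy()) == 0:
                continue
            score, cls, _ = ms.ror_p(sample, model)
            assert 0.0 <= score <= 100.0
            assert cls in ("low", "medium", "high")

    def test_class_is_step_function_of_score(self, scores600):
        order = {"low": 0, "medium": 1, "high": 2}
        ranked = scores600.sort_values("ror_p")["ror_class"].map(order)
        assert ranked.is_monotonic_increasing

    def test_basal_scores_above_luma(self, cohort600, scores600):
        truth = cohort600.clinical["true_subtype"].loc[scores600.index]
        assert (scores600.loc[truth == "Basal", "ror_p"].mean()
                > scores600.loc[truth == "LumA", "ror_p"].mean())


class TestOncotypeRS:
    def test_neutral_profile_hits_the_affine_map_value(self):
        model = ms.RSModel()
        profile = pd.Series(7.0, index=model.informative_genes + list(model.reference_genes))
        rs, cls, groups = ms.oncotype_rs(profile, model)
        # all reference-normalized values sit at the +10 offset
        for name in groups:
            assert groups[name] == pytest.approx(10.0)
        rs_unscaled = sum(model.coefficients[g] * 10.0 for g in model.coefficients)
        a, b = model.unscaled_map
        assert rs == pytest.approx(float(np.clip(a + b * rs_unscaled, 0, 100)))

    def test_hand_computed_worked_example(self):
        """Spreadsheet-style recomputation of one profile, step by step."""
        model = ms.RSModel()
        values = {
            "GRB7": 6.1, "ERBB2": 8.2, "ESR1": 11.4, "PGR": 9.6, "BCL2": 10.3,
            "SCUBE2": 8.8, "AURKA": 9.1, "BIRC5": 8.4, "CCNB1": 7.9, "MKI67": 8.8,
            "MYBL2": 7.2, "CTSV": 6.6, "MMP11": 9.9, "CD68": 8.5, "GSTM1": 10.1,
            "BAG1": 9.3,
            "ACTB": 9.0, "GAPDH": 9.4, "GUSB": 8.6, "RPLP0": 9.8, "TFRC": 8.2,
        }
        profile = pd.Series(values)
        hk = (9.0 + 9.4 + 8.6 + 9.8 + 8.2) / 5
        n = {g: v - hk + 10.0 for g, v in values.items()}
        her2 = max(0.9 * n["GRB7"] + 0.1 * n["ERBB2"], 8.0)
        er = 0.2 * n["ESR1"] + 0.3 * n["PGR"] + 0.25 * n["BCL2"] + 0.25 * n["SCUBE2"]
        prolif = max((n["AURKA"] + n["BIRC5"] + n["CCNB1"] + n["MKI67"] + n["MYBL2"]) / 5, 6.5)
        invasion = (n["CTSV"] + n["MMP11"]) / 2
        rsu = (0.47 * her2 - 0.34 * er + 1.04 * prolif + 0.10 * invasion
               + 0.05 * n["CD68"] - 0.08 * n["GSTM1"] - 0.07 * n["BAG1"])
        expected = min(max(-134.0 + 20.0 * rsu, 0.0), 100.0)
        rs, _, _ = ms.oncotype_rs(profile, model)
        assert rs == pytest.approx(expected, abs=1e-9)

    def test_raising_proliferation_genes_never_lowers_rs(self):
        model = ms.RSModel()
        profile = pd.Series(8.0, index=model.informative_genes + list(model.reference_genes))
        prev = ms.oncotype_rs(profile, model)[0]
        for delta in (0.5, 1.0, 2.0):
            bumped = profile.copy()
            bumped[list(model.groups["proliferation"])] += delta
            rs = ms.oncotype_rs(bumped, model)[0]
            assert rs >= prev
            prev = rs

    def test_missing_reference_gene_is_fatal(self):
        model = ms.RSModel()
        profile = pd.Series(8.0, index=model.informative_genes + ["ACTB", "GAPDH"])
        with pytest.raises(ValueError, match="reference gene"):
            ms.oncotype_rs(profile, model)

    def test_rs_bounded_on_cohort(self, scores600):
        assert scores600["rs"].between(0, 100).all()


class TestImmuneScore:
    def test_minmax_endpoints(self, normalized600):
        out = ms.immune_scores(normalized600.log2)
        assert out["immune_score"].max() == pytest.approx(100.0)
        assert out["immune_score"].min() == pytest.approx(0.0)
        assert out["immune_score"].between(0, 100).all()

    def test_cutoff_is_inclusive(self):
        genes = list(config.IMMUNE_GENES) + list(config.HOUSEKEEPING_GENES)
        rows = []
        for raw in (0.0, 1.0, 2.0):  # scores 0 / 50 / 100 after min-max
            row = {g: 5.0 for g in config.HOUSEKEEPING_GENES}
            row.update({g: 5.0 + raw for g in config.IMMUNE_GENES})
            rows.append(row)
        log2 = pd.DataFrame(rows, index=["lo", "mid", "hi"])[genes]
        out = ms.immune_scores(log2, cutoff=50.0)
        assert out.loc["mid", "immune_score"] == pytest.approx(50.0)
        assert out.loc["mid", "immune_group"] == "istrong"
        assert out.loc["lo", "immune_group"] == "iweak"

    def test_degenerate_cohort_rejected(self):
        genes = list(config.IMMUNE_GENES) + list(config.HOUSEKEEPING_GENES)
        log2 = pd.DataFrame([[5.0] * len(genes)] * 3, columns=genes,
                            index=["a", "b", "c"])
        with pytest.raises(ValueError, match="degenerate"):
            ms.immune_scores(log2)

    def test_recovers_latent_immune_level(self, cohort600, scores600):
        latent = cohort600.clinical["true_immune_level"].loc[scores600.index]
        assert scores600["immune_score"].corr(latent) > 0.8


class TestModelSerialization:
    def test_centroid_model_round_trip(self, centroid_model600, tmp_path):
        path = tmp_path / "model.yaml"
        ms.save_centroid_model(centroid_model600, path)
        loaded = ms.load_centroid_model(path)
        pd.testing.assert_frame_equal(loaded.centroids, centroid_model600.centroids)
        assert loaded.correlation_method == centroid_model600.correlation_method
        assert loaded.ror_thresholds == centroid_model600.ror_thresholds


class TestSelfTrainedRor:
    def test_cox_refit_recovers_the_hazard_ordering(
        self, cohort600, normalized600, scores600, centroid_model600
    ):
        """Self-trained mode: the fitted linear risk score must track the
        generator's true log-hazard (the individual coefficients are not
        identifiable — the four correlations are mutually collinear)."""
        clin = cohort600.clinical.loc[scores600.index]
        corrs = scores600[[f"corr_{k}" for k in config.SUBTYPES]].copy()
        corrs.columns = list(config.SUBTYPES)
        genes = list(centroid_model600.proliferation_genes)
        prolif = normalized600.values.loc[scores600.index, genes].mean(axis=1)
        weights, w_p = ms.fit_ror_coefficients(
            corrs, prolif, clin["dfs_months"], clin["dfs_event"]
        )
        assert set(weights) == set(config.SUBTYPES)
        fitted = sum(weights[k] * corrs[k] for k in config.SUBTYPES) + w_p * prolif
        from lumipipe.synthetic_cohort import DEFAULT_HAZARD_LOG_HR as HR

        truth = (
            HR["basal"] * (clin["true_subtype"] == "Basal")
            + HR["lumb"] * (clin["true_subtype"] == "LumB")
            + HR["her2e"] * (clin["true_subtype"] == "HER2E")
            + HR["immune_latent"] * clin["true_immune_level"]
            + HR["size_gt_1"] * (clin["tumor_size_cm"] > 1.0)
        )
        from scipy import stats as sstats

        assert sstats.spearmanr(fitted, truth).statistic > 0.3
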