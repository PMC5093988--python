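import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ska2sig as sk
from ska2sig.biosignature import BiosignatureModel
from ska2sig.simulate import CohortBundle


class TestInteractionScreen:
    def test_planted_probes_reach_cutoff(self):
        # power check: effect 0.15, noise 0.02, n=200 -> >=90% below 0.005
        cfg = sk.SimulationConfig(n_probes=1000, n_brain_samples=200,
                                  brain_case_fraction=0.5, seed=17)
        brain = sk.generate_brain_cohort(cfg)
        screen = sk.interaction_screen(brain)
        planted = brain.probe_truth.index[brain.probe_truth.planted_interaction]
        frac = (screen.table.loc[planted, "p"] < 0.005).mean()
        assert frac >= 0.90

    def test_null_cohort_calibrated_at_cutoff(self):
        cfg = sk.SimulationConfig(n_probes=20000, n_brain_samples=200,
                                  brain_case_fraction=0.5,
                                  interaction_effect_size=0.0,
                                  case_main_effect=0.0, ska2_main_effect=0.0,
                                  seed=23)
        brain = sk.generate_brain_cohort(cfg)
        screen = sk.interaction_screen(brain)
        frac = (screen.table["p"] < 0.005).mean()
        se = np.sqrt(0.005 * 0.995 / len(screen.table))
        assert abs(frac - 0.005) < 3 * se

    def test_all_genotype_zero_is_global_error(self):
        cfg = sk.SimulationConfig(n_probes=100, seed=3,
                                  ska2_allele_frequency=0.5)
        brain = sk.generate_brain_cohort(cfg)
        brain.samples["ska2_genotype"] = 0
        brain.samples["ska2_methylation"] = np.nan
        with pytest.raises(sk.MethylationError):
            sk.interaction_screen(brain)

    def test_alternative_orientation_runs(self, small_study):
        screen = sk.interaction_screen(small_study["brain"],
                                       orientation="ska2m_x_genotype")
        assert screen.orientation == "ska2m_x_genotype"
        assert screen.table["defined"].any()

    def test_probe_order_permutation_changes_nothing_but_order(self, small_study):
        brain = small_study["brain"]
        rng = np.random.default_rng(4)
        perm = list(rng.permutation(brain.beta.probe_ids))
        shuffled = CohortBundle(name="brain", beta=sk.BetaMatrix(
            brain.beta.data.loc[perm]), samples=brain.samples,
            probe_truth=brain.probe_truth.loc[perm], latent=brain.latent)
        a = sk.interaction_screen(brain).table.sort_index()
        b = sk.interaction_screen(shuffled).table.sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestSelectCandidates:
    def _screen(self, pvals):
        table = pd.DataFrame({"p": pvals, "defined": True},
                             index=[f"cg{i}" for i in range(len(pvals))])
        return sk.InteractionScreenResult(table, "suicide_x_ska2m")

    def test_strict_cutoff(self):
        sel = sk.select_candidates(self._screen([0.001, 0.004, 0.006]),
                                   p_cutoff=0.005)
        assert sel == ["cg0", "cg1"]

    def test_cutoff_one_keeps_all_defined(self):
        sel = sk.select_candidates(self._screen([0.3, 0.9, 0.0001]),
                                   p_cutoff=0.999999)
        assert len(sel) == 3

    def test_empty_selection_advises(self):
        with pytest.raises(sk.MethylationError, match="relaxing"):
            sk.select_candidates(self._screen([0.5, 0.9]), p_cutoff=0.005)


def _tiny_training(aucs):
    """Training bundle whose four candidate probes have the given
    probe-alone AUCs against 5 cases / 2 controls (constructed pairwise)."""
    labels = np.array([1] * 5 + [0] * 2)
    # controls at 0.30 and 0.60; a case above both counts 2 concordant
    # pairs, between counts 1; (above, between) per target AUC
    layout = {0.6: (3, 0), 0.7: (3, 1), 0.8: (4, 0), 0.9: (4, 1)}
    cols = []
    for auc in aucs:
        above, between = layout[auc]
        below = 5 - above - between
        cases = ([0.7 + 0.02 * i for i in range(above)]
                 + [0.45] * between + [0.1] * below)
        cols.append(cases + [0.30, 0.60])
    vals = np.array(cols)
    sample_ids = [f"s{i}" for i in range(7)]
    beta = sk.BetaMatrix.from_arrays(vals, [f"cg{i}" for i in range(len(aucs))],
                                     sample_ids)
    samples = pd.DataFrame({"sample_id": sample_ids,
                            "suicide_attempt": labels,
                            "ska2_genotype": 1,
                            "ska2_methylation": 0.5}).set_index("sample_id",
                                                                drop=False)
    return CohortBundle(name="tiny", beta=beta, samples=samples,
                        probe_truth=pd.DataFrame(index=beta.probe_ids),
                        latent=pd.Series(0.0, index=sample_ids))


class TestAucFilter:
    def test_interpolated_quantile_threshold(self):
        training = _tiny_training([0.6, 0.7, 0.8, 0.9])
        retained, table = sk.probewise_auc_filter(
            list(training.beta.probe_ids), training, percentile=75,
            probe_alone=True)
        assert np.allclose(sorted(table["auc"]), [0.6, 0.7, 0.8, 0.9])
        assert table.attrs["threshold"] == pytest.approx(0.875)
        assert retained == ["cg3"]

    def test_all_equal_aucs_retain_nothing(self):
        training = _tiny_training([0.8, 0.8, 0.8, 0.8])
        with pytest.warns(UserWarning, match="percentile"):
            retained, _ = sk.probewise_auc_filter(
                list(training.beta.probe_ids), training, probe_alone=True)
        assert retained == []

    def test_planted_probes_rank_higher(self, small_study, discovery):
        table = discovery["auc_table"]
        truth = small_study["train_blood"].probe_truth
        planted = truth.loc[table.index, "planted_biosignature"]
        if planted.sum() and (~planted).sum():
            stat = stats.mannwhitneyu(table.loc[planted.values, "auc"],
                                      table.loc[~planted.values, "auc"],
                                      alternative="greater")
            assert stat.pvalue < 0.01


class TestPcaBiosignature:
    def test_rank_one_matrix_explains_everything(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([0.05, 0.1, 0.03])
        vals = 0.3 + np.outer(v, u)   # probes x samples, rank 1 after centering
        beta = sk.BetaMatrix.from_arrays(vals, ["a", "b", "c"],
                                         [f"s{i}" for i in range(4)])
        model = sk.train_biosignature_pca(beta, ["a", "b", "c"])
        assert model.explained_variance == pytest.approx(1.0, abs=1e-10)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        vals = np.clip(rng.uniform(0.2, 0.8, (10, 25))
                       + rng.normal(0, 0.05, (10, 25)), 0, 1 - 1e-9)
        probes = [f"p{i}" for i in range(10)]
        beta = sk.BetaMatrix.from_arrays(vals, probes,
                                         [f"s{i}" for i in range(25)])
        model = sk.train_biosignature_pca(beta, probes)
        x = vals.T - vals.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(x, rowvar=False))
        lead = evecs[:, -1]
        oracle = x @ lead
        got = model.training_scores.to_numpy()
        sign = np.sign(oracle @ got)
        assert np.allclose(got, sign * oracle, atol=1e-8)

    def test_sign_rule_under_global_negation(self, rng):
        vals = np.clip(0.5 + rng.normal(0, 0.05, (6, 20)), 0.01, 0.99)
        probes = [f"p{i}" for i in range(6)]
        sids = [f"s{i}" for i in range(20)]
        m1 = sk.train_biosignature_pca(
            sk.BetaMatrix.from_arrays(vals, probes, sids), probes)
        m2 = sk.train_biosignature_pca(
            sk.BetaMatrix.from_arrays(1 - vals, probes, sids), probes)
        for m, v in ((m1, vals), (m2, 1 - vals)):
            corr = np.corrcoef(m.training_scores, v.mean(axis=0))[0, 1]
            assert corr >= -1e-12

    def test_zero_variance_submatrix_errors(self):
        vals = np.full((3, 5), 0.4)
        beta = sk.BetaMatrix.from_arrays(vals, ["a", "b", "c"],
                                         [f"s{i}" for i in range(5)])
        with pytest.raises(sk.MethylationError, match="zero-variance"):
            sk.train_biosignature_pca(beta, ["a", "b", "c"])

    def test_json_round_trip(self, discovery, tmp_path):
        model = discovery["model"]
        path = tmp_path / "model.json"
        model.to_json(path)
        back = BiosignatureModel.from_json(path)
        assert back.probes == model.probes
        assert np.allclose(back.loadings, model.loadings)
        assert np.allclose(back.means, model.means)


class TestProjection:
    def test_training_projection_reproduces_scores(self, small_study, discovery):
        model = discovery["model"]
        scores = sk.project_biosignature(model, small_study["train_blood"])
        assert np.allclose(scores.to_numpy(),
                           model.training_scores.to_numpy(), atol=1e-10)

    def test_sample_at_training_means_scores_zero(self, discovery):
        model = discovery["model"]
        beta = sk.BetaMatrix.from_arrays(np.asarray(model.means)[:, None],
                                         model.probes, ["mean_sample"])
        score = sk.project_biosignature(model, beta)
        assert score.loc["mean_sample"] == pytest.approx(0.0, abs=1e-12)

    def test_cross_cohort_score_tracks_latent(self, small_study, discovery):
        scores = sk.project_biosignature(discovery["model"],
                                         small_study["validation_blood"])
        rho, _ = stats.spearmanr(scores, small_study["validation_blood"].latent)
        assert abs(rho) > 0.9

    def test_missing_probes_error_and_mean_fill(self, small_study, discovery):
        model = discovery["model"]
        cohort = small_study["validation_blood"]
        drop = model.probes[0]
        reduced = sk.BetaMatrix(cohort.beta.data.drop(index=drop))
        with pytest.raises(sk.MethylationError, match="mean_fill"):
            sk.project_biosignature(model, reduced)
        with pytest.warns(UserWarning, match="mean-filling"):
            scores = sk.project_biosignature(model, reduced,
                                             missing_probes="mean_fill")
        assert len(scores) == len(cohort.beta.sample_ids)

    def test_too_many_missing_probes_hard_error(self, discovery):
        model = discovery["model"]
        n_keep = max(2, int(0.5 * len(model.probes)))
        vals = np.full((n_keep, 3), 0.5)
        beta = sk.BetaMatrix.from_arrays(vals, model.probes[:n_keep],
                                         ["a", "b", "c"])
        with pytest.raises(sk.MethylationError, match="missing"):
            sk.project_biosignature(model, beta, missing_probes="mean_fill")


class TestDriverProbes:
    def test_probe_equal_to_score_is_consistent(self, rng):
        n = 40
        sids = [f"s{i}" for i in range(n)]
        score_driver = rng.uniform(0.2, 0.8, n)
        probes = ["driver", "noise1", "noise2"]

        def cohort(name, seed):
            r = np.random.default_rng(seed)
            vals = np.vstack([score_driver + 0.0,
                              r.uniform(0.2, 0.8, n), r.uniform(0.2, 0.8, n)])
            beta = sk.BetaMatrix.from_arrays(vals, probes, sids)
            return CohortBundle(name=name, beta=beta,
                                samples=pd.DataFrame(index=sids),
                                probe_truth=pd.DataFrame(index=probes),
                                latent=pd.Series(0.0, index=sids))

        loadings = np.array([1.0, 0.0, 0.0])
        model = BiosignatureModel(probes=probes,
                                  means=np.array([0.5, 0.5, 0.5]),
                                  loadings=loadings, explained_variance=1.0,
                                  sign_flipped=False)
        table, consistent = sk.driver_probe_correlations(
            model, {"a": cohort("a", 1), "b": cohort("b", 2)})
        assert "driver" in consistent
        driver_rows = table[table["probe_id"] == "driver"]
        assert np.allclose(driver_rows["rho"], 1.0)

    def test_null_probe_consistency_rate_near_alpha_power(self):
        """Independent-noise probes are consistent at ~0.05^n_cohorts."""
        rng = np.random.default_rng(9)
        n_probes, n = 1000, 30
        probes = [f"p{i}" for i in range(n_probes)]
        sids = [f"s{i}" for i in range(n)]
        means = np.full(n_probes, 0.5)
        loadings = np.full(n_probes, 1.0 / np.sqrt(n_probes))
        model = BiosignatureModel(probes=probes, means=means,
                                  loadings=loadings, explained_variance=0.5,
                                  sign_flipped=False)
        cohorts = {}
        for name in ("a", "b", "c"):
            vals = np.clip(rng.normal(0.5, 0.1, (n_probes, n)), 0, 1 - 1e-9)
            beta = sk.BetaMatrix.from_arrays(vals, probes, sids)
            cohorts[name] = CohortBundle(name=name, beta=beta,
                                         samples=pd.DataFrame(index=sids),
                                         probe_truth=pd.DataFrame(index=probes),
                                         latent=pd.Series(0.0, index=sids))
        _, consistent = sk.driver_probe_correlations(model, cohorts)
        # expected ~ 1000 * 0.05^3 = 0.125 consistent probes
        assert len(consistent) <= 5

    def test_small_cohort_excluded_with_warning(self, small_study, discovery):
        tiny = small_study["saliva"]
        shrunk = CohortBundle(name="tiny",
                              beta=sk.BetaMatrix(tiny.beta.data.iloc[:, :3]),
                              samples=tiny.samples.iloc[:3],
                              probe_truth=tiny.probe_truth,
                              latent=tiny.latent.iloc[:3])
        cohorts = {"ok1": small_study["train_blood"],
                   "ok2": small_study["validation_blood"], "tiny": shrunk}
        with pytest.warns(UserWarning, match="tiny"):
            table, _ = sk.driver_probe_correlations(discovery["model"], cohorts)
        assert set(table["cohort"]) == {"ok1", "ok2"}


def test_end_to_end_retained_set_enriched_for_planted(small_study, discovery):
    """Discovery retains a probe set enriched for the planted biosignature."""
    truth = small_study["brain"].probe_truth
    retained = set(discovery["retained"])
    n_planted = int(truth["planted_biosignature"].sum())
    n_universe = len(truth)
    hits = sum(1 for p in retained if truth.loc[p, "planted_biosignature"])
    p = stats.hypergeom.sf(hits - 1, n_universe, n_planted, len(retained))
    assert p < 0.01
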