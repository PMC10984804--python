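"""Unit tests for eigengenes and the exercise / trait statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xtissue.communities import (
    eigengene,
    eigengene_matrix,
    interaction_anova,
    paired_community_test,
    trait_correlation,
)


def make_design(y: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eigengene matrix + annotations for a 2x2 within design.

    ``y`` has shape (n_subjects, 4) with columns SM-pre, SM-post, SAT-pre,
    SAT-post.
    """
    n = y.shape[0]
    rows, scores = [], {}
    for i in range(n):
        for j, (tissue, tp) in enumerate(
            [("SM", "pre"), ("SM", "post"), ("SAT", "pre"), ("SAT", "post")]
        ):
            sid = f"S{i}_{tissue}_{tp}"
            rows.append((sid, f"S{i}", tissue, tp, "x"))
            scores[sid] = y[i, j]
    ann = pd.DataFrame(rows, columns=["sample_id", "subject_id", "tissue", "timepoint", "cohort"])
    eig = pd.DataFrame([scores], index=pd.Index([1], name="community"))
    return eig, ann


class TestEigengene:
    def test_rank_one_matrix(self, rng):
        common = rng.normal(size=20)
        expr = pd.DataFrame(
            np.outer(rng.uniform(1, 3, size=5), common) + rng.uniform(-2, 2, size=(5, 1)),
            columns=[f"s{i}" for i in range(20)],
        )
        scores, ve = eigengene(expr)
        assert ve == pytest.approx(1.0)
        z = (common - common.mean()) / common.std(ddof=1)
        assert abs(np.corrcoef(scores, z)[0, 1]) == pytest.approx(1.0)
        assert scores @ z > 0  # sign follows the community mean profile
        assert np.linalg.norm(scores) == pytest.approx(1.0)

    def test_exact_negatives_tie_break(self, rng):
        v = rng.normal(size=10)
        expr = pd.DataFrame([v, -v], index=["g1", "g2"])
        scores, ve = eigengene(expr)
        assert ve == pytest.approx(1.0)
        # mean standardized expression is identically 0: positive loading on g1
        z1 = (v - v.mean()) / v.std(ddof=1)
        assert scores @ z1 > 0

    def test_first_pc_beats_random_directions(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 30)))
        scores, _ = eigengene(expr)
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T.to_numpy()
        var_pc = np.sum((z @ scores.to_numpy()) ** 2)
        for _ in range(1000):
            d = rng.normal(size=30)
            d /= np.linalg.norm(d)
            assert np.sum((z @ d) ** 2) <= var_pc + 1e-9

    def test_gene_permutation_and_scaling_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 15)),
                            index=[f"g{i}" for i in range(10)])
        s1, _ = eigengene(expr)
        scaled = expr.sample(frac=1, random_state=0) * rng.uniform(0.5, 5, size=(10, 1))
        s2, _ = eigengene(scaled)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_constant_gene_dropped_small_community_errors(self, rng):
        expr = pd.DataFrame(rng.normal(size=(2, 10)), index=["a", "b"])
        expr.loc["a"] = 3.0
        with pytest.raises(ValueError, match="fewer than 2"):
            eigengene(expr)


class TestInteractionAnova:
    def test_constant_scores_null(self):
        y = np.full((6, 4), 2.5)
        eig, ann = make_design(y)
        res = interaction_anova(eig, ann)
        row = res.loc[1]
        assert row["F_interaction"] == 0.0 and row["p_interaction"] == 1.0
        assert row["F_time"] == 0.0 and row["p_time"] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_interaction_equals_paired_t_on_difference_of_differences(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(10, 4))
        eig, ann = make_design(y)
        res = interaction_anova(eig, ann).loc[1]
        d = (y[:, 1] - y[:, 0]) - (y[:, 3] - y[:, 2])
        t, p = stats.ttest_1samp(d, 0.0)
        assert res["F_interaction"] == pytest.approx(t**2, abs=1e-8)
        assert res["p_interaction"] == pytest.approx(p, abs=1e-8)

    def test_matches_pingouin_rm_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(99)
        y = rng.normal(size=(12, 4))
        eig, ann = make_design(y)
        res = interaction_anova(eig, ann).loc[1]
        long = []
        for i in range(12):
            for j, (tissue, tp) in enumerate(
                [("SM", "pre"), ("SM", "post"), ("SAT", "pre"), ("SAT", "post")]
            ):
                long.append({"subject": i, "tissue": tissue, "time": tp, "y": y[i, j]})
        table = pg.rm_anova(
            data=pd.DataFrame(long), dv="y", within=["time", "tissue"],
            subject="subject", detailed=True,
        ).set_index("Source")
        assert res["F_time"] == pytest.approx(table.loc["time", "F"], rel=1e-6)
        assert res["F_tissue"] == pytest.approx(table.loc["tissue", "F"], rel=1e-6)
        assert res["F_interaction"] == pytest.approx(table.loc["time * tissue", "F"], rel=1e-6)
        assert res["p_interaction"] == pytest.approx(table.loc["time * tissue", "p_unc"], rel=1e-6)

    def test_ss_decomposition_sums_to_total(self):
        """Effect + error strata SS account for the full within-subject SS."""
        rng = np.random.default_rng(5)
        y = rng.normal(size=(8, 4))
        eig, ann = make_design(y)
        res = interaction_anova(eig, ann).loc[1]
        n = y.shape[0]
        within_ss = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2)
        df_err = n - 1
        sm_pre, sm_post, sat_pre, sat_post = y.T
        grand = y.mean()
        subj = y.mean(axis=1)
        cell = np.array([[sm_pre.mean(), sm_post.mean()], [sat_pre.mean(), sat_post.mean()]])
        tim = cell.mean(axis=0)
        tis = cell.mean(axis=1)
        ss_time = 2 * n * np.sum((tim - grand) ** 2)
        ss_tissue = 2 * n * np.sum((tis - grand) ** 2)
        ss_inter = n * np.sum((cell - tis[:, None] - tim[None, :] + grand) ** 2)
        subj_time = np.stack([(sm_pre + sat_pre) / 2, (sm_post + sat_post) / 2], axis=1)
        subj_tissue = np.stack([(sm_pre + sm_post) / 2, (sat_pre + sat_post) / 2], axis=1)
        ss_e_time = 2 * np.sum((subj_time - subj[:, None] - tim[None, :] + grand) ** 2)
        ss_e_tissue = 2 * np.sum((subj_tissue - subj[:, None] - tis[None, :] + grand) ** 2)
        ss_e_inter = (
            within_ss - ss_time - ss_tissue - ss_inter - ss_e_time - ss_e_tissue
        )
        # the implementation's F statistics imply exactly these strata
        assert res["F_time"] == pytest.approx(ss_time / (ss_e_time / df_err), abs=1e-8)
        assert res["F_tissue"] == pytest.approx(ss_tissue / (ss_e_tissue / df_err), abs=1e-8)
        assert res["F_interaction"] == pytest.approx(ss_inter / (ss_e_inter / df_err), abs=1e-8)

    def test_incomplete_subject_dropped(self):
        y = np.random.default_rng(0).normal(size=(5, 4))
        eig, ann = make_design(y)
        eig = eig.drop(columns=["S4_SAT_post"])
        ann = ann[ann["sample_id"] != "S4_SAT_post"]
        res = interaction_anova(eig, ann)
        assert res.loc[1, "n_subjects"] == 4

    def test_too_few_subjects_error(self):
        y = np.random.default_rng(0).normal(size=(2, 4))
        eig, ann = make_design(y)
        with pytest.raises(ValueError, match="3 complete"):
            interaction_anova(eig, ann)


class TestPairedCommunityTest:
    def test_no_change_is_null(self):
        x = pd.Series([0.1, 0.5, -0.2, 0.4], index=list("abcd"))
        t, p, fc = paired_community_test(x, x.copy())
        assert (t, p, fc) == (0.0, 1.0, 0.0)

    def test_zero_variance_nonzero_shift_flagged(self):
        pre = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        t, p, fc = paired_community_test(pre, pre + 1.0)
        assert p == 0.0 and fc == 1.0 and np.isinf(t)

    def test_matches_textbook_formula(self):
        d = np.array([0.5, -0.2, 0.3, 0.8, 0.1])
        pre = pd.Series(np.zeros(5), index=list("abcde"))
        post = pd.Series(d, index=list("abcde"))
        t, p, fc = paired_community_test(pre, post)
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_exp = 2 * stats.t.sf(abs(t_exp), df=4)
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-12)
        assert fc == pytest.approx(d.mean())

    def test_unmatched_subject_error(self):
        pre = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        post = pd.Series([1.0, 2.0, 3.0], index=list("abd"))
        with pytest.raises(ValueError, match="unmatched"):
            paired_community_test(pre, post)


def _trait_setup(eig_values: np.ndarray, trait_values: np.ndarray):
    n = len(eig_values)
    samples = [f"S{i}_SAT_pre" for i in range(n)]
    ann = pd.DataFrame(
        {
            "sample_id": samples,
            "subject_id": [f"S{i}" for i in range(n)],
            "tissue": "SAT",
            "timepoint": "pre",
            "cohort": "x",
        }
    )
    eig = pd.DataFrame([dict(zip(samples, eig_values))], index=pd.Index([1], name="community"))
    traits = pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)], "tr": trait_values})
    return eig, ann, traits


class TestTraitCorrelation:
    def test_trait_equals_eigengene(self, rng):
        v = rng.normal(size=20)
        eig, ann, traits = _trait_setup(v, v)
        out = trait_correlation(eig, ann, traits)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "n"] == 20

    def test_independent_trait_is_null(self, rng):
        v = rng.normal(size=1000)
        w = rng.normal(size=1000)
        eig, ann, traits = _trait_setup(v, w)
        out = trait_correlation(eig, ann, traits)
        assert abs(out.loc[0, "r"]) < 0.1

    def test_zero_variance_trait_skipped(self, rng):
        eig, ann, traits = _trait_setup(rng.normal(size=10), np.ones(10))
        out = trait_correlation(eig, ann, traits)
        assert len(out) == 0

    def test_missing_traits_dropped_pairwise(self, rng):
        v = rng.normal(size=12)
        w = v + 0.1 * rng.normal(size=12)
        eig, ann, traits = _trait_setup(v, w)
        traits.loc[3, "tr"] = np.nan
        out = trait_correlation(eig, ann, traits)
        assert out.loc[0, "n"] == 11

    def test_planted_slope_sign_recovered(self, small_intervention, small_config):
        """On eigengenes estimated from counts, the planted trait sign comes back."""
        from xtissue.preprocess import log2cpm, tmm_factors

        cohort = small_intervention
        expr = log2cpm(cohort.counts, tmm_factors(cohort.counts))
        membership = pd.Series(cohort.truth["gene_community"])
        membership = membership[membership > 0]
        eig, _ = eigengene_matrix(expr, membership)
        out = trait_correlation(eig, cohort.annotations, cohort.traits,
                                tissue="SAT", timepoint="pre")
        linked = out[(out["community"] == 2) & (out["trait"] == "bmi_like")]
        slope = small_config.trait_links[2][0]
        assert np.sign(linked["r"].iloc[0]) == np.sign(slope)
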