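"""Association statistics: change scores, Spearman, Holm, pipelines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from braintexture.stats import (associate_relevance, change_scores,
                                holm_bonferroni, spearman_rho)
from braintexture.synthetic import SyntheticCohortSpec, generate_cohort


class TestChangeScores:
    def _table(self, t0, t1=None, var="gaf"):
        rows = [{"subject_id": f"s{i}", "timepoint": "T0", var: v}
                for i, v in enumerate(t0)]
        if t1 is not None:
            rows += [{"subject_id": f"s{i}", "timepoint": "T1", var: v}
                     for i, v in enumerate(t1)]
        return pd.DataFrame(rows)

    def test_no_change_gives_zero(self):
        ch = change_scores(self._table([10, 20], [10, 20]), ["gaf"])
        assert list(ch["gaf"]) == [0.0, 0.0]

    def test_single_subject_arithmetic(self):
        ch = change_scores(self._table([10.0], [7.0]), ["gaf"])
        assert ch.loc[0, "gaf"] == -3.0

    def test_subjects_without_followup_omitted(self):
        tab = self._table([10, 20, 30], [11, 21, 31])
        tab = tab[~((tab["subject_id"] == "s2") & (tab["timepoint"] == "T1"))]
        ch = change_scores(tab, ["gaf"])
        assert list(ch["subject_id"]) == ["s0", "s1"]

    def test_variable_absent_everywhere_rejected(self):
        with pytest.raises(ValueError):
            change_scores(self._table([1.0], [2.0]), ["bdi_ii"])

    def test_generated_followup_shift_recovered(self):
        spec = SyntheticCohortSpec(
            n_per_class=100, volume_shape=(16, 16, 16),
            followup_shift={"bdi_ii": -5.0}, followup_noise_sd=1.0, seed=8)
        cohort = generate_cohort(spec, generate_volumes=False)
        ch = change_scores(cohort.clinical, ["bdi_ii"])
        assert np.mean(ch["bdi_ii"]) == pytest.approx(-5.0, abs=0.25)


class TestSpearman:
    def test_perfect_monotone_gives_plus_minus_one(self):
        rho, t, p = spearman_rho([1, 2, 3, 4], [10, 20, 40, 80])
        assert rho == 1.0 and p == 0.0
        rho, t, p = spearman_rho([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == -1.0 and p == 0.0

    def test_matches_scipy_reference(self, rng):
        for _ in range(10):
            x = rng.standard_normal(25)
            y = 0.4 * x + rng.standard_normal(25)
            rho, t, p = spearman_rho(x, y)
            ref = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_t_approximation_close_to_permutation_oracle(self, rng):
        """At n=20 the t-transform p-value agrees with an exact 10,000-
        permutation p-value within 0.02."""
        n = 20
        x = rng.standard_normal(n)
        y = np.zeros(n)
        # moderate dependence, roughly a rank correlation of 0.5
        y = 0.6 * x + 0.8 * rng.standard_normal(n)
        rho, t, p_t = spearman_rho(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean()) / ry.std()
        nperm = 10_000
        perm_rhos = np.empty(nperm)
        prng = np.random.default_rng(99)
        for i in range(nperm):
            perm_rhos[i] = rx @ prng.permutation(ry) / n
        p_perm = (np.abs(perm_rhos) >= abs(rho) - 1e-12).mean()
        assert abs(p_t - p_perm) <= 0.02

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.lognormal(size=30)
        y = rng.standard_normal(30)
        base = spearman_rho(x, y)[0]
        assert spearman_rho(np.log(x), y)[0] == pytest.approx(base)
        assert spearman_rho(x, np.exp(y / 3))[0] == pytest.approx(base)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])


class TestHolm:
    def test_hand_stepdown_example(self):
        adj, rej = holm_bonferroni([0.01, 0.04], alpha=0.05)
        assert np.allclose(adj, [0.02, 0.04])
        assert rej.tolist() == [True, True]

    def test_single_p_unchanged(self):
        adj, rej = holm_bonferroni([0.03])
        assert adj[0] == 0.03 and rej[0]

    def test_all_ones_reject_nothing(self):
        adj, rej = holm_bonferroni([1.0, 1.0, 1.0])
        assert np.all(adj == 1.0) and not rej.any()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_statsmodels_and_bounds(self, ps):
        adj, rej = holm_bonferroni(ps, alpha=0.05)
        _, adj_sm, _, _ = multipletests(ps, alpha=0.05, method="holm")
        assert np.allclose(adj, adj_sm, atol=1e-12)
        ps = np.asarray(ps)
        assert np.all(adj >= ps - 1e-15)  # never below raw
        assert np.all(adj <= np.minimum(1.0, len(ps) * ps) + 1e-15)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone step-down


def _severity_heatmaps(rng, n, shape=(4, 4, 4)):
    severity = rng.standard_normal(n)
    heatmaps = {f"s{i}": np.full(shape, severity[i])
                + rng.normal(0, 0.01, shape) for i in range(n)}
    return severity, heatmaps


def _clinical_from_scores(scores: dict, n):
    rows = []
    for i in range(n):
        row = {"subject_id": f"s{i}", "group": "ROP+",
               "visdys_label": "VisDys+", "timepoint": "T0"}
        row.update({var: vals[i] for var, vals in scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)


class TestAssociateRelevance:
    def test_single_variable_family_equals_raw_p(self, rng):
        n = 15
        severity, heatmaps = _severity_heatmaps(rng, n)
        clin = _clinical_from_scores(
            {"gaf": sps.rankdata(severity).astype(float)}, n)
        res = associate_relevance(heatmaps, np.ones((4, 4, 4), bool), clin,
                                  ["gaf"], timepoint_mode="t0")
        assert len(res) == 1
        assert res[0].rho == pytest.approx(1.0)
        assert res[0].p_corrected == res[0].p_raw

    def test_empty_variable_list_gives_empty_result(self, rng):
        _, heatmaps = _severity_heatmaps(rng, 5)
        assert associate_relevance(heatmaps, np.ones((4, 4, 4), bool),
                                   _clinical_from_scores({}, 5), []) == []

    def test_injected_association_detected_nulls_controlled(self):
        """An injected rho = −0.6 association is flagged while null
        variables mostly are not, over 10 seeds (power-and-specificity)."""
        n = 100
        detected, null_flags = 0, []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            severity, heatmaps = _severity_heatmaps(rng, n)
            r = 2 * np.sin(np.pi * (-0.6) / 6)
            coupled = r * severity + np.sqrt(1 - r**2) * \
                rng.standard_normal(n)
            scores = {"bdi_ii": coupled}
            for var in ("gaf", "panss_positive", "panss_negative", "visdys"):
                scores[var] = rng.standard_normal(n)
            clin = _clinical_from_scores(scores, n)
            res = {r_.variable: r_ for r_ in associate_relevance(
                heatmaps, np.ones((4, 4, 4), bool), clin, list(scores),
                timepoint_mode="t0", alpha=0.05)}
            if res["bdi_ii"].significant and res["bdi_ii"].rho < 0:
                detected += 1
            null_flags.append(sum(res[v].significant for v in scores
                                  if v != "bdi_ii"))
        assert detected >= 8
        # in at least 8 of 10 seeds no more than 1 of 4 nulls is flagged
        assert sum(f <= 1 for f in null_flags) >= 8

    def test_permuted_linkage_false_positive_rate_bounded(self):
        """Breaking the subject↔score linkage keeps the familywise flag
        rate near the nominal level."""
        n = 40
        nsim = 200
        alpha = 0.05
        false_pos = 0
        rng = np.random.default_rng(7)
        severity, heatmaps = _severity_heatmaps(rng, n)
        base_scores = {v: rng.standard_normal(n)
                       for v in ("gaf", "bdi_ii", "visdys")}
        mask = np.ones((4, 4, 4), bool)
        subjects = list(heatmaps)
        for _ in range(nsim):
            perm = rng.permutation(subjects)
            permuted = {s: heatmaps[p] for s, p in zip(subjects, perm)}
            res = associate_relevance(permuted, mask,
                                      _clinical_from_scores(base_scores, n),
                                      list(base_scores), alpha=alpha)
            false_pos += any(r.significant for r in res)
        rate = false_pos / nsim
        assert rate <= alpha + 2 * np.sqrt(alpha / nsim)

    def test_subjects_missing_scores_or_heatmaps_excluded(self, rng):
        n = 12
        severity, heatmaps = _severity_heatmaps(rng, n)
        clin = _clinical_from_scores(
            {"gaf": sps.rankdata(severity).astype(float)}, n)
        del heatmaps["s0"]
        res = associate_relevance(heatmaps, np.ones((4, 4, 4), bool), clin,
                                  ["gaf"], subset=[f"s{i}" for i in range(n)])
        assert res[0].n == n - 1
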