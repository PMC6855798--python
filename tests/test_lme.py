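import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import taskconn as tc
from taskconn.experiments import default_atlas
from taskconn.lme import (THREEWAY_TERM, design_matrix, edge_interaction_tests,
                          fdr_bh, fit_lme)
from taskconn.roi import connectivity_matrix, scan_connectivity_table
from taskconn.synthetic import EffectSpec, make_design, simulate_roi_timeseries


def _study_table(n_per_group=8, n_timepoints=120, seed=5,
                 effects=None, network="PMN"):
    atlas = default_atlas()
    design = make_design(n_per_group, seed=seed)
    series, scans = simulate_roi_timeseries(
        design, atlas, effects or EffectSpec(), n_timepoints, seed=seed + 1)
    matrices = [connectivity_matrix(s, atlas.names) for s in series]
    return (scan_connectivity_table(matrices, scans, atlas, (network,)),
            matrices, scans, atlas)


class TestDesignCoding:
    def test_threeway_beta_is_difference_of_differences(self):
        # noiseless cell means: the 3-way beta must equal the planted
        # difference-of-differences between groups exactly
        design = make_design(2, seed=0)
        table = design.copy()
        delta = 0.25
        table["value"] = 0.3 + delta * ((table["group"] == "PMN")
                                        & (table["condition"] == "stim")
                                        & (table["task"] == "retrieval"))
        X, names = design_matrix(table)
        beta = np.linalg.lstsq(X, table["value"].to_numpy(), rcond=None)[0]
        assert beta[names.index(THREEWAY_TERM)] == pytest.approx(delta, abs=1e-12)

    def test_unknown_level_rejected(self):
        table = pd.DataFrame({"condition": ["on"], "task": ["rest"],
                              "group": ["PMN"]})
        with pytest.raises(ValueError, match="condition"):
            design_matrix(table)


class TestFitLME:
    def test_zero_subject_sd_matches_ols(self):
        effects = EffectSpec(subject_sd=0.0)
        table, _, _, _ = _study_table(effects=effects, seed=21)
        res = fit_lme(table)
        X, names = design_matrix(table)
        beta_ols = np.linalg.lstsq(X, table["value"].to_numpy(), rcond=None)[0]
        got = res.terms.set_index("term")["beta"]
        for name, b in zip(names, beta_ols):
            assert got[name] == pytest.approx(b, abs=1e-6)

    def test_subject_relabeling_invariance(self):
        table, _, _, _ = _study_table(seed=31)
        res_a = fit_lme(table)
        relabeled = table.copy()
        relabeled["subject"] = relabeled["subject"].map(
            lambda s: 1000 - s)
        res_b = fit_lme(relabeled)
        pd.testing.assert_frame_equal(res_a.terms, res_b.terms)

    def test_constant_tsnr_dropped_reproduces_no_covariate_fit(self):
        table, _, _, _ = _study_table(seed=41)
        const = table.copy()
        const["tsnr"] = 50.0
        res_const = fit_lme(const)
        res_none = fit_lme(table.drop(columns="tsnr"))
        assert "tsnr" in res_const.dropped_terms
        pd.testing.assert_frame_equal(res_const.terms, res_none.terms)

    def test_include_order_adds_order_terms(self):
        table, _, _, _ = _study_table(seed=51)
        res = fit_lme(table, include_order=True)
        terms = res.terms["term"].tolist()
        assert "order" in terms and "order:condition" in terms

    def test_single_row_subject_rejected(self):
        table, _, _, _ = _study_table(seed=61)
        broken = pd.concat([table, pd.DataFrame([{
            "subject": 999, "group": "PMN", "condition": "stim",
            "task": "rest", "order": "stim_first", "network": "PMN",
            "value": 0.1, "tsnr": 50.0}])])
        with pytest.raises(ValueError, match=">= 2 rows"):
            fit_lme(broken)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available")
    def test_matches_lmerTest_satterthwaite(self, tmp_path):
        # independent oracle: lme4 + lmerTest REML with Satterthwaite df
        table, _, _, _ = _study_table(seed=5)
        row = fit_lme(table).term(THREEWAY_TERM)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages({{library(lme4); library(lmerTest)}})
            d <- read.csv("{csv}")
            d$cond <- ifelse(d$condition=="stim", 0.5, -0.5)
            d$tk <- ifelse(d$task=="retrieval", 0.5, -0.5)
            d$grp <- ifelse(d$group=="PMN", 0.5, -0.5)
            d$tsnr_c <- d$tsnr - mean(d$tsnr)
            m <- lmer(value ~ cond*tk*grp + tsnr_c + (1|subject), data=d)
            s <- summary(m)$coefficients["cond:tk:grp", ]
            cat(sprintf("%.10f %.6f %.4f", s[1], s[4], s[3]))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        beta_r, t_r, df_r = map(float, out.stdout.split())
        assert row["beta"] == pytest.approx(beta_r, abs=1e-6)
        assert row["t"] == pytest.approx(t_r, rel=1e-3)
        assert row["df"] == pytest.approx(df_r, abs=0.1)


class TestFDR:
    def test_hand_stepup_example(self):
        p_adj, reject = fdr_bh([0.01, 0.02, 0.2], q=0.05)
        assert list(reject) == [True, True, False]
        assert p_adj[0] == pytest.approx(0.03)
        assert p_adj[1] == pytest.approx(0.03)
        assert p_adj[2] == pytest.approx(0.2)

    def test_single_p(self):
        for p, expect in [(0.04, True), (0.06, False)]:
            _, reject = fdr_bh([p], q=0.05)
            assert reject[0] == expect

    def test_equal_ps_all_rejected_unchanged(self):
        p_adj, reject = fdr_bh([0.001] * 10, q=0.05)
        assert reject.all()
        assert np.allclose(p_adj, 0.001)

    def test_adjusted_at_least_raw_and_flags_monotone(self, rng):
        p = rng.random(40)
        p_adj, reject = fdr_bh(p, q=0.05)
        assert np.all(p_adj >= p - 1e-15)
        if reject.any():
            assert p[reject].max() <= p[~reject].min() if (~reject).any() else True

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            fdr_bh([0.1, np.nan])


class TestEdgeTests:
    def test_planted_single_edge_has_smallest_p(self):
        # plant an effect directly on one PMN edge's z values
        atlas = default_atlas()
        pmn = atlas.members("PMN")[:4]
        hits = 0
        n_runs = 20
        for s in range(n_runs):
            rng = np.random.default_rng(1000 + s)
            design = make_design(8, seed=s)
            scans = design.reset_index(drop=True).copy()
            scans["tsnr"] = 50.0 + rng.normal(0, 2, len(scans))
            matrices = []
            planted_cell = ((scans["group"] == "PMN")
                            & (scans["condition"] == "stim")
                            & (scans["task"] == "retrieval")).to_numpy()
            for i in range(len(scans)):
                z = rng.normal(0.3, 0.08, size=(4, 4))
                z = (z + z.T) / 2
                if planted_cell[i]:
                    z[0, 1] += 0.4
                    z[1, 0] += 0.4
                from taskconn.roi import ConnectivityMatrix
                matrices.append(ConnectivityMatrix(values=z, region_names=pmn))
            table = edge_interaction_tests(matrices, scans, pmn)
            best = table.loc[table["p"].idxmin()]
            if {best["region_a"], best["region_b"]} == {pmn[0], pmn[1]}:
                hits += 1
        assert hits >= int(0.9 * n_runs)

    def test_duplicated_scans_shrink_ses_and_flag_via_n_obs(self):
        # feeding every scan twice is a data error the n_obs diagnostic
        # exposes; point estimates barely move while SEs shrink ~1/sqrt(2)
        table, matrices, scans, atlas = _study_table(seed=71, n_per_group=4)
        pmn = atlas.members("PMN")[:3]
        once = edge_interaction_tests(matrices, scans, pmn)
        twice = edge_interaction_tests(matrices + matrices,
                                       pd.concat([scans, scans]), pmn)
        assert np.allclose(once["beta"], twice["beta"], atol=0.02)
        assert (twice["n_obs"] == 2 * once["n_obs"]).all()
        rerun = edge_interaction_tests(matrices, scans, pmn)
        pd.testing.assert_frame_equal(once, rerun)
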