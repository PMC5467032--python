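"""One-step screening, ranking, chunking, and the two-pass pipeline."""

import numpy as np
import pandas as pd
import pytest

import fastassoc as fa


def _phenotype_setup(sim, ph=0):
    y = sim.phenotypes[:, ph].astype(float)
    Xc = np.column_stack([np.ones(len(y)), sim.covariates])
    warm = fa.fit_covariate_only(y, Xc)
    return y, Xc, warm


class TestOneStepScreen:
    def test_tracks_exact_z2(self, small_sim):
        y, Xc, warm = _phenotype_setup(small_sim)
        z2_fast = fa.one_step_screen(small_sim.study, y, Xc, warm)
        exact = fa.exact_scan(small_sim.study, y, Xc, warm=warm)
        z2_exact = np.array([r.z2 for r in exact])
        rel = np.abs(z2_fast - z2_exact) / np.maximum(z2_exact, 1e-300)
        assert (rel <= 0.10).mean() >= 0.95

    def test_monomorphic_marker_scores_zero(self, small_sim):
        study = small_sim.study
        dosage = study.dosage.copy()
        dosage[:, 7] = 2
        mono = fa.GenotypeStudy(dosage=dosage, markers=study.markers, samples=study.samples)
        y, Xc, warm = _phenotype_setup(small_sim)
        z2 = fa.one_step_screen(mono, y, Xc, warm)
        assert z2[7] == 0.0

    def test_strong_marker_ranked_first_both_ways(self, rng):
        cfg = fa.SimConfig(n_subjects=2000, n_markers=300, n_covariates=3,
                           n_pops=4, causal_frac=0.0, seed=5)
        sim = fa.simulate_study(cfg)
        study = sim.study
        # plant one strong causal marker
        g = study.dosage[:, 0].astype(float)
        eta = -0.2 + 1.0 * (g - g.mean())
        y = (rng.random(cfg.n_subjects) < 1 / (1 + np.exp(-eta))).astype(float)
        Xc = np.column_stack([np.ones(cfg.n_subjects), sim.covariates])
        warm = fa.fit_covariate_only(y, Xc)
        z2_fast = fa.one_step_screen(study, y, Xc, warm)
        exact = fa.exact_scan(study, y, Xc, warm=warm)
        z2_exact = np.array([r.z2 for r in exact])
        assert z2_fast.argmax() == 0 and z2_exact.argmax() == 0


class TestRanking:
    def test_descending_order(self):
        ranked = fa.rank_results(np.array([[4.0], [9.0], [1.0]]))
        assert ranked.marker_index.tolist() == [1, 0, 2]
        assert ranked.z2.tolist() == [9.0, 4.0, 1.0]

    def test_tie_rule_preserves_index_order(self):
        ranked = fa.rank_results(np.array([[2.0, 2.0], [2.0, 5.0]]))
        assert ranked.z2.tolist() == [5.0, 2.0, 2.0, 2.0]
        pairs = list(zip(ranked.marker_index[1:], ranked.phenotype_index[1:]))
        assert pairs == [(0, 0), (0, 1), (1, 0)]

    def test_matches_brute_force_sort(self, rng):
        z2 = rng.random((100, 3)) * 30
        ranked = fa.rank_results(z2)
        brute = sorted(
            ((z2[i, j], i, j) for i in range(100) for j in range(3)),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        assert ranked.z2.tolist() == [t[0] for t in brute]
        assert ranked.marker_index.tolist() == [t[1] for t in brute]


class TestChunking:
    @pytest.mark.parametrize(
        "m,n,expected",
        [
            (10, 3, [(0, 4), (4, 7), (7, 10)]),
            (5, 1, [(0, 5)]),
            (3, 5, [(0, 1), (1, 2), (2, 3)]),
        ],
    )
    def test_ranges(self, m, n, expected):
        assert fa.chunk_markers(m, n) == expected

    def test_cover_and_balance_property(self):
        for m in (1, 7, 100, 1001):
            for n in (1, 2, 7, 64):
                chunks = fa.chunk_markers(m, n)
                assert chunks[0][0] == 0 and chunks[-1][1] == m
                assert all(a < b for a, b in chunks)
                assert all(chunks[k][1] == chunks[k + 1][0] for k in range(len(chunks) - 1))
                sizes = [b - a for a, b in chunks]
                assert max(sizes) - min(sizes) <= 1

    def test_results_invariant_to_chunk_count(self, small_sim):
        runs = [
            fa.run_association(
                small_sim.study, small_sim.phenotypes, small_sim.covariates,
                fa.ScreenConfig(mode="two_pass", screen_p_cutoff=0.05, n_chunks=k),
            )
            for k in (1, 3, 17)
        ]
        for other in runs[1:]:
            pd.testing.assert_frame_equal(runs[0].table, other.table)
            pd.testing.assert_frame_equal(runs[0].screen, other.screen)


class TestTwoPass:
    def test_cutoff_one_reports_every_marker(self, small_sim):
        run = fa.two_pass(
            small_sim.study, small_sim.phenotypes, small_sim.covariates,
            fa.ScreenConfig(screen_p_cutoff=1.0),
        )
        assert len(run.table) == small_sim.study.n_markers * small_sim.phenotypes.shape[1]

    def test_vanishing_cutoff_empties_report(self, small_sim):
        run = fa.two_pass(
            small_sim.study, small_sim.phenotypes, small_sim.covariates,
            fa.ScreenConfig(screen_p_cutoff=1e-300, screen_margin=1.0),
        )
        assert len(run.table) == 0
        assert list(run.table.columns)[:12] == fa.screen_pipeline.ASSOC_COLUMNS

    def test_matches_exact_mode_at_cutoff_one(self, small_sim):
        exact = fa.run_association(
            small_sim.study, small_sim.phenotypes, small_sim.covariates,
            fa.ScreenConfig(mode="exact"),
        )
        tp = fa.two_pass(
            small_sim.study, small_sim.phenotypes, small_sim.covariates,
            fa.ScreenConfig(screen_p_cutoff=1.0),
        )
        pd.testing.assert_frame_equal(exact.table, tp.table.drop(columns="FLAG"))

    def test_recall_of_significant_markers(self, small_sim):
        cutoff = 0.01
        run = fa.two_pass(
            small_sim.study, small_sim.phenotypes, small_sim.covariates,
            fa.ScreenConfig(screen_p_cutoff=cutoff, screen_margin=10.0),
        )
        for ph in range(small_sim.phenotypes.shape[1]):
            y, Xc, warm = _phenotype_setup(small_sim, ph)
            exact = fa.exact_scan(small_sim.study, y, Xc, warm=warm)
            wanted = {
                small_sim.study.markers[r.marker_index].id
                for r in exact
                if r.p <= cutoff
            }
            got = set(run.table.loc[run.table["PHENO"] == ph + 1, "SNP"])
            assert wanted <= got

    def test_rows_sorted_by_position(self, small_sim):
        run = fa.two_pass(
            small_sim.study, small_sim.phenotypes, small_sim.covariates,
            fa.ScreenConfig(screen_p_cutoff=0.2),
        )
        for _, grp in run.table.groupby("PHENO"):
            assert grp["BP"].is_monotonic_increasing

    def test_near_cutoff_rows_flagged_not_dropped(self, small_sim):
        run = fa.two_pass(
            small_sim.study, small_sim.phenotypes, small_sim.covariates,
            fa.ScreenConfig(screen_p_cutoff=0.05),
        )
        above = run.table["P"] > 0.05
        assert (run.table.loc[above, "FLAG"] == "ABOVE_CUTOFF").all()
        assert (run.table.loc[~above, "FLAG"] == "PASS").all()

    def test_missing_data_excluded_per_marker_in_second_pass(self, small_sim):
        study = small_sim.study
        dosage = study.dosage.copy()
        dosage[:25, 3] = fa.MISSING
        holed = fa.GenotypeStudy(dosage=dosage, markers=study.markers, samples=study.samples)
        run = fa.two_pass(
            holed, small_sim.phenotypes[:, 0], small_sim.covariates,
            fa.ScreenConfig(screen_p_cutoff=1.0, missing_policy="drop_per_marker"),
        )
        snp3 = study.markers[3].id
        nmiss = run.table.set_index("SNP")["NMISS"]
        assert nmiss[snp3] == study.n_subjects - 25
        assert (nmiss.drop(snp3) == study.n_subjects).all()


class TestOutputFormat:
    def test_assoc_logistic_layout(self, small_sim, tmp_path):
        run = fa.run_association(
            small_sim.study, small_sim.phenotypes[:, 0], small_sim.covariates,
            fa.ScreenConfig(mode="exact"),
        )
        path = tmp_path / "out.assoc.logistic"
        fa.write_assoc_logistic(run.table, path)
        lines = path.read_text().splitlines()
        assert lines[0].split() == fa.screen_pipeline.ASSOC_COLUMNS
        first = lines[1].split()
        assert first[4] == "ADD"
        # OR = exp(beta) and CI bounds consistent with SE
        row = run.table.iloc[0]
        assert float(first[6]) == pytest.approx(row["OR"], rel=1e-3)
        assert row["L95"] < row["OR"] < row["U95"]

    def test_summary_bookkeeping(self, small_sim):
        run = fa.run_association(
            small_sim.study, small_sim.phenotypes, small_sim.covariates,
            fa.ScreenConfig(mode="exact"),
        )
        n, m = small_sim.study.n_subjects, small_sim.study.n_markers
        assert run.summary["n_genotype_observations"] == n * m
        assert run.summary["n_regressions"] == m * 2
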