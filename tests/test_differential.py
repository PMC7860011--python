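"""DMP/DMR detection, BH-FDR, enrichment and heatmap clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster import hierarchy

from pmfmeth import (
    BetaMatrix,
    ProbeAnnotation,
    SimConfig,
    ValidationError,
    benjamini_hochberg,
    cluster_heatmap_order,
    find_dmrs,
    fit_dmp,
    gene_set_enrichment,
    generate_cohort,
)
from pmfmeth.datatypes import logit_clamped
from tests.conftest import PLANTED_DMPS, two_group_frame


class TestBenjaminiHochberg:
    def test_hand_example(self):
        # step-up rule by hand: 0.04*4/4, then min-accumulate from the right
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_trivial_cases(self):
        assert benjamini_hochberg(np.array([])).size == 0
        assert benjamini_hochberg(np.array([0.3]))[0] == pytest.approx(0.3)
        assert np.allclose(benjamini_hochberg(np.ones(5)), 1.0)

    def test_order_invariance_and_monotonicity(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 200)
        q = benjamini_hochberg(p)
        perm = rng.permutation(200)
        assert np.allclose(benjamini_hochberg(p[perm]), q[perm])
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_invariants_hold_for_arbitrary_p_vectors(self, p_list):
        p = np.array(p_list)
        q = benjamini_hochberg(p)
        assert q.shape == p.shape
        assert np.all((q >= 0) & (q <= 1))
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestFitDmp:
    def test_null_p_values_calibrated(self, null_cohort):
        rng = np.random.default_rng(4)
        perm = pd.Series(
            rng.permutation(null_cohort.samples.groups.to_numpy()),
            index=null_cohort.beta.df.index,
        )
        dmps = fit_dmp(null_cohort.beta, perm)
        frac = (dmps["p"] < 0.05).mean()
        mc_sd = np.sqrt(0.05 * 0.95 / len(dmps))
        assert abs(frac - 0.05) < 3 * mc_sd + 0.01

    def test_recovers_planted_dmps(self, planted_cohort):
        dmps = fit_dmp(planted_cohort.beta, planted_cohort.samples.groups)
        planted = {f"cg{i:08d}" for i in PLANTED_DMPS}
        called = set(dmps.loc[dmps["q"] <= 0.1, "probe_id"])
        assert len(called & planted) >= 20

    def test_moderated_t_sign_matches_delta_beta(self, planted_cohort):
        dmps = fit_dmp(planted_cohort.beta, planted_cohort.samples.groups)
        strong = dmps[dmps["delta_beta"].abs() > 0.02]
        assert (np.sign(strong["moderated_t"]) == np.sign(strong["delta_beta"])).all()

    def test_zero_prior_df_equals_ordinary_t(self, null_cohort):
        beta = BetaMatrix(null_cohort.beta.df.iloc[:, :200])
        groups = null_cohort.samples.groups
        dmps = fit_dmp(beta, groups, prior_df=0)
        m = logit_clamped(beta.values)
        fp = (groups == "FP").to_numpy()
        t_ref, p_ref = stats.ttest_ind(m[fp], m[~fp], axis=0, equal_var=True)
        ref = pd.Series(p_ref, index=beta.probe_ids)
        assert np.abs(dmps.set_index("probe_id")["p"] - ref).max() < 1e-6

    def test_zero_variance_probe_floored_and_flagged(self):
        X, y = two_group_frame(np.random.default_rng(1), 5, 5, 10)
        X["cg000000"] = 0.4  # constant probe
        dmps = fit_dmp(BetaMatrix(X), y)
        row = dmps.set_index("probe_id").loc["cg000000"]
        assert bool(row["var_floored"])
        assert np.isfinite(row["moderated_t"])


def _dmr_oracle(coef, chrom, pos, max_gap, cutoff):
    """Independent run enumeration: plain python loop over sorted probes."""
    order = sorted(range(len(pos)), key=lambda i: (chrom[i], pos[i]))
    bumps, run, prev = [], [], None
    for i in order:
        new_cluster = prev is not None and (
            chrom[i] != chrom[prev] or pos[i] - pos[prev] > max_gap
        )
        sign = 0 if abs(coef[i]) < cutoff else (1 if coef[i] > 0 else -1)
        run_sign = 0 if not run else (1 if coef[run[-1]] > 0 else -1)
        if new_cluster or sign == 0 or (run and sign != run_sign):
            if run:
                bumps.append(tuple(run))
            run = []
        if sign != 0:
            run.append(i)
        prev = i
    if run:
        bumps.append(tuple(run))
    return {b: sum(abs(coef[i]) for i in b) for b in bumps}


class TestFindDmrs:
    def test_matches_bruteforce_enumeration_on_small_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = 40
            chrom = np.array(["chr1"] * 25 + ["chr2"] * 15)
            pos = np.concatenate(
                [np.sort(rng.choice(np.arange(100, 20000, 70), 25, replace=False)),
                 np.sort(rng.choice(np.arange(100, 20000, 70), 15, replace=False))]
            )
            X, y = two_group_frame(rng, 6, 6, n, noise=0.08)
            ann = ProbeAnnotation(pd.DataFrame(
                {"chr": chrom, "pos": pos, "design_type": "II",
                 "island_relation": "OpenSea", "gene": ""},
                index=X.columns,
            ))
            beta = BetaMatrix(X)
            records = find_dmrs(beta, y, ann, max_gap=250, cutoff_quantile=0.5,
                                n_perm=20, fdr=1.0, seed=trial)
            fp = (y == "FP").to_numpy()
            coef = X.to_numpy()[fp].mean(0) - X.to_numpy()[~fp].mean(0)
            cutoff = np.quantile(np.abs(coef), 0.5)
            expected = _dmr_oracle(coef, chrom, pos, 250, cutoff)
            got = {
                tuple(sorted(X.columns.get_loc(p) for p in r.probe_ids)): r.area
                for r in records
            }
            assert set(got) == set(expected)
            for k in got:
                assert got[k] == pytest.approx(expected[k])

    def test_detects_planted_region(self, planted_cohort):
        records = find_dmrs(
            planted_cohort.beta,
            planted_cohort.samples.groups,
            planted_cohort.annotation,
            n_perm=100,
            seed=0,
        )
        truth = set(planted_cohort.truth["dmrs"][0]["probes"])
        best_jaccard = 0.0
        for r in records:
            got = {planted_cohort.beta.probe_ids.index(p) for p in r.probe_ids}
            j = len(got & truth) / len(got | truth)
            best_jaccard = max(best_jaccard, j)
        assert best_jaccard >= 0.75

    def test_gap_rule_never_merges_distant_probes(self):
        rng = np.random.default_rng(5)
        X, y = two_group_frame(rng, 6, 6, 10, noise=0.02)
        X.iloc[:6, [3, 4]] += 0.3  # two strong probes, 500 bp apart
        pos = np.array([100, 400, 700, 1000, 1500, 2000, 2300, 2600, 2900, 3200])
        ann = ProbeAnnotation(pd.DataFrame(
            {"chr": "chr1", "pos": pos, "design_type": "II",
             "island_relation": "OpenSea", "gene": ""}, index=X.columns))
        records = find_dmrs(BetaMatrix(X), y, ann, max_gap=250, n_perm=20,
                            fdr=1.0, seed=0)
        for r in records:
            assert not {"cg000003", "cg000004"} <= set(r.probe_ids)

    def test_null_data_yields_no_dmrs(self):
        hits = 0
        for seed in range(10):
            cohort = generate_cohort(
                SimConfig(n_fp=8, n_sd=8, n_probes=800, probe_fail_rate=0.0,
                          seed=500 + seed)
            )
            records = find_dmrs(cohort.beta, cohort.samples.groups,
                                cohort.annotation, n_perm=60, fdr=0.05, seed=seed)
            hits += len(records) > 0
        assert hits <= 1  # >= 90% of runs clean

    def test_unstable_null_rejected(self, planted_cohort):
        with pytest.raises(ValidationError, match="n_perm"):
            find_dmrs(planted_cohort.beta, planted_cohort.samples.groups,
                      planted_cohort.annotation, n_perm=5)


def _uniform_annotation(n_genes, probes_per_gene):
    n = n_genes * probes_per_gene
    return ProbeAnnotation(pd.DataFrame(
        {
            "chr": "chr1",
            "pos": np.arange(n) * 1000 + 1,
            "design_type": "II",
            "island_relation": "OpenSea",
            "gene": [f"G{i // probes_per_gene}" for i in range(n)],
        },
        index=[f"cg{i:06d}" for i in range(n)],
    ))


class TestEnrichment:
    def test_equal_probe_counts_reduce_to_hypergeometric(self):
        ann = _uniform_annotation(60, 4)
        genes = [f"G{i}" for i in range(60)]
        hits = set(genes[:15])
        sets = {"T": genes[:20]}
        out = gene_set_enrichment(hits, ann, sets)
        expected = stats.hypergeom.sf(14, 60, 20, 15)
        assert out["p"].iloc[0] == pytest.approx(expected, abs=1e-3)

    def test_strongly_enriched_term_ranks_first(self):
        rng = np.random.default_rng(0)
        ann = ProbeAnnotation(pd.DataFrame(
            {
                "chr": "chr1",
                "pos": np.arange(250) * 500 + 1,
                "design_type": "II",
                "island_relation": "OpenSea",
                "gene": [f"G{i}" for i in rng.integers(0, 50, 250)],
            },
            index=[f"cg{i:06d}" for i in range(250)],
        ))
        genes = [f"G{i}" for i in range(50)]
        hits = set(genes[:10])
        sets = {
            "planted": genes[:12],
            "other1": genes[20:40],
            "other2": genes[10:30],
        }
        out = gene_set_enrichment(hits, ann, sets)
        assert out["term_id"].iloc[0] == "planted"
        assert out["q"].iloc[0] <= 0.1

    def test_empty_hit_set_finds_nothing(self):
        ann = _uniform_annotation(30, 3)
        out = gene_set_enrichment(set(), ann, {"T": [f"G{i}" for i in range(10)]})
        assert (out["q"] > 0.1).all()

    def test_unknown_hit_gene_dropped_with_warning(self):
        ann = _uniform_annotation(30, 3)
        with pytest.warns(UserWarning, match="absent"):
            gene_set_enrichment({"NOT_A_GENE", "G1"}, ann,
                                {"T": [f"G{i}" for i in range(10)]})

    def test_p_values_not_anticonservative_under_uniform_null(self):
        # discrete exact tests are super-uniform; check the one-sided bound
        ann = _uniform_annotation(200, 3)
        genes = [f"G{i}" for i in range(200)]
        term = {"T": genes[:30]}
        rng = np.random.default_rng(1)
        ps = np.sort([
            gene_set_enrichment(set(rng.choice(genes, 30, replace=False)), ann, term)[
                "p"
            ].iloc[0]
            for _ in range(200)
        ])
        grid = np.linspace(0.02, 1, 50)
        emp = np.searchsorted(ps, grid, side="right") / ps.size
        mc = 3 * np.sqrt(grid * (1 - grid) / ps.size)
        assert np.all(emp <= grid + mc + 0.02)


class TestClusterHeatmapOrder:
    def test_well_separated_groups_split_cleanly(self):
        rng = np.random.default_rng(2)
        X, y = two_group_frame(rng, 8, 8, 60, noise=0.04)
        X.iloc[:8, :25] += 0.25
        beta = BetaMatrix(X.clip(0, 1))
        dmps = fit_dmp(beta, y)
        _, sample_order, link = cluster_heatmap_order(beta, dmps, top_n=25)
        labels = hierarchy.fcluster(link["sample_linkage"], 2, criterion="maxclust")
        split = {tuple(sorted(np.array(beta.sample_ids)[labels == g])) for g in (1, 2)}
        expected = {tuple(sorted(y.index[y == "FP"])), tuple(sorted(y.index[y == "SD"]))}
        assert split == expected

    def test_duplicate_samples_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(3)
        X, y = two_group_frame(rng, 4, 4, 30)
        X.iloc[1] = X.iloc[0]  # exact duplicate
        beta = BetaMatrix(X)
        dmps = fit_dmp(beta, y)
        _, _, link = cluster_heatmap_order(beta, dmps, top_n=10)
        z = link["sample_linkage"]
        assert z[0, 2] == pytest.approx(0.0)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_minimal_probe_tree(self, planted_cohort):
        dmps = fit_dmp(planted_cohort.beta, planted_cohort.samples.groups)
        probe_order, _, link = cluster_heatmap_order(planted_cohort.beta, dmps, top_n=2)
        assert len(probe_order) == 2
        assert link["probe_linkage"].shape == (1, 4)

    def test_top_n_bounds(self, planted_cohort):
        dmps = fit_dmp(planted_cohort.beta, planted_cohort.samples.groups)
        with pytest.raises(ValidationError):
            cluster_heatmap_order(planted_cohort.beta, dmps, top_n=1)
        with pytest.raises(ValidationError):
            cluster_heatmap_order(planted_cohort.beta, dmps, top_n=len(dmps) + 1)
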