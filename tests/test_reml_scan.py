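"""REML variance components, LRT scan, permutation thresholds, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import salmospot as sp
from salmospot.reml import BlockedREML
from salmospot.scan import _threshold_from_maxima, design_matrix


def _block_structure(labels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == labels[None, :]).astype(float)


class TestFitVcModel:
    def test_balanced_half_sib_matches_anova_oracle(self):
        """One-way random-effects REML equals the expected-mean-squares
        ANOVA estimator on balanced data (classical identity)."""
        n_sires, n_off = 50, 20
        rng = np.random.default_rng(5)
        sire = np.repeat(np.arange(n_sires), n_off)
        y = rng.normal(0, 1, n_sires)[sire] * np.sqrt(0.5) + rng.normal(
            0, 1, n_sires * n_off
        )
        S = _block_structure(sire)
        vc = sp.fit_vc_model(y, np.ones((len(y), 1)), {"sire": S}, validate=False)

        groups = y.reshape(n_sires, n_off)
        msb = n_off * groups.mean(axis=1).var(ddof=1)
        msw = groups.var(axis=1, ddof=1).mean() * n_off / (n_off - 1) * (n_off - 1) / n_off
        msw = np.sum((groups - groups.mean(axis=1, keepdims=True)) ** 2) / (
            n_sires * (n_off - 1)
        )
        anova_sire = (msb - msw) / n_off
        assert vc.sigma2["sire"] == pytest.approx(anova_sire, rel=0.02)
        assert vc.sigma2_e == pytest.approx(msw, rel=0.02)

    def test_null_component_boundary_mixture(self):
        """Pure-noise data: the constrained REML estimate of the structured
        variance is a boundary mixture — an atom of roughly half the mass
        exactly at zero, with the remainder small."""
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(20), 10)
        S = _block_structure(labels)
        estimates = []
        for _ in range(40):
            y = rng.normal(size=200)
            vc = sp.fit_vc_model(y, np.ones((200, 1)), {"grp": S}, validate=False)
            estimates.append(vc.sigma2["grp"])
        estimates = np.asarray(estimates)
        # P(atom) ~ 1/2: 14+/40 is a >3-sigma lower band
        assert (estimates < 1e-4).sum() >= 14
        assert np.median(estimates) < 0.05

    def test_zero_structure_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(2)
        labels = np.repeat(np.arange(10), 8)
        S = _block_structure(labels)
        y = rng.normal(size=80) + rng.normal(0, 0.7, 10)[labels]
        one = sp.fit_vc_model(y, np.ones((80, 1)), {"grp": S}, validate=False)
        two = sp.fit_vc_model(
            y, np.ones((80, 1)), {"grp": S, "null": np.zeros((80, 80))}, validate=False
        )
        assert two.log_restricted_likelihood == pytest.approx(
            one.log_restricted_likelihood, abs=1e-6
        )

    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent cross-check: REML variance of a random intercept model
        matches statsmodels MixedLM."""
        import statsmodels.api as smf

        rng = np.random.default_rng(7)
        labels = np.repeat(np.arange(15), 6)
        y = rng.normal(0, 0.8, 15)[labels] + rng.normal(size=90)
        vc = sp.fit_vc_model(
            y, np.ones((90, 1)), {"grp": _block_structure(labels)}, validate=False
        )
        md = smf.MixedLM(y, np.ones((90, 1)), groups=labels).fit(reml=True)
        assert vc.sigma2["grp"] == pytest.approx(
            float(np.asarray(md.cov_re)[0, 0]), rel=1e-3, abs=1e-5
        )
        assert vc.sigma2_e == pytest.approx(float(md.scale), rel=1e-3)
        assert vc.beta[0] == pytest.approx(float(np.asarray(md.params)[0]), abs=1e-5)

    def test_structure_validation(self):
        y = np.zeros(4)
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="symmetric"):
            sp.fit_vc_model(y, X, {"bad": np.triu(np.ones((4, 4)))})
        with pytest.raises(ValueError, match="positive semi-definite"):
            sp.fit_vc_model(y, X, {"bad": np.eye(4) - 0.9 * np.ones((4, 4))})
        with pytest.raises(ValueError, match="rank deficient"):
            sp.fit_vc_model(np.zeros(4), np.ones((4, 2)), {"ok": np.eye(4)})


class TestLrt:
    def test_aliased_structures_give_zero_lrt(self, nuclear_cohort):
        """QTL structure identical to the kinship: the split is not
        identifiable and the likelihood cannot improve."""
        cohort, ped = nuclear_cohort["cohort"], nuclear_cohort["pedigree"]
        ids = cohort["id"].tolist()
        A = sp.additive_relationship(ped, ids=ids).to_numpy()
        X, _ = design_matrix(cohort)
        y = cohort["spot_density"].to_numpy(float)
        assert sp.lrt_at_position(y, X, A, A) < 0.05

    def test_lrt_nonnegative_across_positions(self, nuclear_cohort):
        sc = sp.GenomeScanner(
            nuclear_cohort["cohort"], nuclear_cohort["pedigree"],
            nuclear_cohort["geno"], step_cM=None,
        )
        lrt = sc.scan()["lrt"]
        assert np.all(lrt >= 0)

    def test_null_lrt_below_chi2_1(self):
        """Null LRT distribution is stochastically below chi2(1): the usual
        1/2 chi2(0) + 1/2 chi2(1) boundary mixture."""
        spec = sp.CohortSpec(
            strains=("A", "B"), n_families_per_cross=5, n_offspring_per_family=10,
            variance_fractions=(0.0, 0.3, 0.0, 0.7), seed=77,
        )
        cohort, ped, geno, truth = sp.simulate_cohort(spec)
        sc = sp.GenomeScanner(cohort, ped, geno, step_cM=None)
        # 300 independent null phenotype draws (family structure, no QTL)
        rng = np.random.default_rng(8)
        n = len(cohort)
        fam_idx = pd.factorize(ped.family_of().reindex(cohort["id"]).to_numpy())[0]
        n_fam = fam_idx.max() + 1
        Y = np.stack(
            [
                rng.normal(0, np.sqrt(0.3), n_fam)[fam_idx]
                + rng.normal(0, np.sqrt(0.7), n)
                for _ in range(300)
            ],
            axis=1,
        )
        lrt = sc.scan(Y)["lrt"][:, 0]
        q = np.quantile(lrt, [0.5, 0.75, 0.9, 0.95])
        chi2q = stats.chi2(1).ppf([0.5, 0.75, 0.9, 0.95])
        assert np.all(q <= chi2q + 0.15)
        assert (lrt < 1e-6).mean() > 0.3  # sizeable point mass at zero


class TestScan:
    def test_scan_localises_planted_qtl(self):
        """Across replicates, LRT at the true QTL position dominates the
        unlinked positions (median separation), and the top hit lands on the
        true linkage group in at least half of the replicates.  Individual
        replicates can be weak when the nearby markers happen to be
        homozygous in the key parents (sparse biallelic map)."""
        true_lrt, unlinked_lrt, hits = [], [], 0
        for r in range(10):
            spec = sp.CohortSpec(
                strains=("A", "B"), n_families_per_cross=8, n_offspring_per_family=15,
                variance_fractions=(0.05, 0.15, 0.20, 0.60),
                qtl_group="LG2", qtl_position_cM=50.0, seed=600 + r,
            )
            cohort, ped, geno, truth = sp.simulate_cohort(spec)
            res = sp.scan_genome(cohort, ped, geno, step_cM=None)
            tab = res.table
            true_lrt.append(
                float(tab.query("linkage_group == 'LG2' and position_cM == 50")["lrt"].iloc[0])
            )
            unlinked_lrt.extend(tab.query("linkage_group != 'LG2'")["lrt"].tolist())
            if res.top_linkage_group == "LG2" and abs(res.top_position_cM - 50.0) <= 25:
                hits += 1
        assert np.median(true_lrt) > np.median(unlinked_lrt)
        assert hits >= 5

    def test_single_marker_map(self):
        gmap = sp.GeneticMap(
            pd.DataFrame(
                {
                    "linkage_group": ["LG1", "LG2"],
                    "marker_id": ["m1", "m2"],
                    "position_cM": [0.0, 0.0],
                }
            )
        )
        spec = sp.CohortSpec(
            strains=("A", "B"), n_families_per_cross=3, n_offspring_per_family=8,
            gmap=gmap, qtl_group="LG1", qtl_position_cM=0.0,
            variance_fractions=(0.0, 0.3, 0.1, 0.6), seed=5,
        )
        cohort, ped, geno, truth = sp.simulate_cohort(spec)
        res = sp.scan_genome(cohort, ped, geno, step_cM=5.0)
        assert len(res.table) == 2  # one test per linkage group

    def test_missing_genotypes_reported(self, nuclear_cohort):
        cohort = nuclear_cohort["cohort"].copy()
        cohort.loc[0, "id"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            sp.GenomeScanner(cohort, nuclear_cohort["pedigree"], nuclear_cohort["geno"])

    def test_grid_includes_markers_and_steps(self, nuclear_cohort):
        sc = sp.GenomeScanner(
            nuclear_cohort["cohort"], nuclear_cohort["pedigree"],
            nuclear_cohort["geno"], step_cM=5.0,
        )
        pos_lg1 = [p for lg, p in sc.positions if lg == "LG1"]
        assert set(np.arange(0, 76, 5.0)) <= set(pos_lg1)


class TestPermutation:
    def test_threshold_monotone_in_alpha(self, nuclear_cohort):
        sc = sp.GenomeScanner(
            nuclear_cohort["cohort"], nuclear_cohort["pedigree"],
            nuclear_cohort["geno"], step_cM=None,
        )
        maxima = sc.permutation_maxima(150, seed=3)
        t05 = _threshold_from_maxima(maxima, 0.05)
        t01 = _threshold_from_maxima(maxima, 0.01)
        assert t01 >= t05

    def test_threshold_reproducible(self, nuclear_cohort):
        args = (
            nuclear_cohort["cohort"], nuclear_cohort["pedigree"], nuclear_cohort["geno"]
        )
        t1 = sp.permutation_threshold(*args, n_perm=100, alpha=0.05, seed=11, step_cM=None)
        t2 = sp.permutation_threshold(*args, n_perm=100, alpha=0.05, seed=11, step_cM=None)
        assert t1 == t2

    def test_genomewide_p_uniform_on_nulls(self):
        """Randomised genome-wide permutation p-values are uniform on null
        cohorts (exactness of the within-family randomisation test)."""
        from scipy import stats

        rng = np.random.default_rng(123)
        n_perm = 50
        pvals = []
        for r in range(150):
            spec = sp.CohortSpec(
                strains=("A", "B"), n_families_per_cross=4, n_offspring_per_family=6,
                gmap=sp.GeneticMap.regular(1, 3, 25.0),
                variance_fractions=(0.05, 0.30, 0.0, 0.65), seed=30_000 + r,
            )
            cohort, ped, geno, truth = sp.simulate_cohort(spec)
            sc = sp.GenomeScanner(cohort, ped, geno, step_cM=None)
            obs = sc.scan()["lrt"][0].max()
            maxima = sc.permutation_maxima(n_perm, seed=31_000 + r)
            # tie-randomised rank p: exactly Uniform(0,1) under
            # exchangeability even with the LRT's point mass at zero
            n_gt = int(np.sum(maxima > obs + 1e-9))
            n_eq = int(np.sum(np.abs(maxima - obs) <= 1e-9))
            pvals.append((n_gt + rng.uniform() * (n_eq + 1)) / (n_perm + 1))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_insufficient_permutations_rejected(self, nuclear_cohort):
        args = (
            nuclear_cohort["cohort"], nuclear_cohort["pedigree"], nuclear_cohort["geno"]
        )
        with pytest.raises(ValueError):
            sp.permutation_threshold(*args, n_perm=50, alpha=0.05)
        with pytest.raises(ValueError):
            sp.permutation_threshold(*args, n_perm=100, alpha=0.001)


class TestSummaries:
    def test_heritability_arithmetic(self):
        vc = sp.VarianceComponents(
            beta=np.zeros(1), sigma2={"additive": 1.0}, sigma2_e=1.0,
            log_restricted_likelihood=0.0, converged=True, n=10, n_fixed=1,
        )
        assert sp.heritability(vc) == pytest.approx(0.5)

    def test_qtl_fraction_arithmetic(self):
        vc = sp.VarianceComponents(
            beta=np.zeros(1), sigma2={"additive": 9.0, "qtl": 1.0}, sigma2_e=10.0,
            log_restricted_likelihood=0.0, converged=True, n=10, n_fixed=1,
        )
        assert sp.qtl_variance_fractions(vc) == (
            pytest.approx(0.10), pytest.approx(0.05)
        )
        vc0 = sp.VarianceComponents(
            beta=np.zeros(1), sigma2={"additive": 9.0, "qtl": 0.0}, sigma2_e=10.0,
            log_restricted_likelihood=0.0, converged=True, n=10, n_fixed=1,
        )
        assert sp.qtl_variance_fractions(vc0) == (0.0, 0.0)

    def test_degenerate_components_rejected(self):
        vc = sp.VarianceComponents(
            beta=np.zeros(1), sigma2={"additive": 0.0, "qtl": 0.0}, sigma2_e=0.0,
            log_restricted_likelihood=0.0, converged=True, n=10, n_fixed=1,
        )
        with pytest.raises(ValueError):
            sp.heritability(vc)
        with pytest.raises(ValueError):
            sp.qtl_variance_fractions(vc)


class TestAlleleContrast:
    def test_planted_effect_detected(self):
        spec = sp.CohortSpec(
            strains=("A", "B"), n_families_per_cross=4, n_offspring_per_family=25,
            variance_fractions=(0.0, 0.1, 0.4, 0.5), seed=21,
        )
        cohort, ped, geno, truth = sp.simulate_cohort(spec)
        asn = sp.assignment_from_truth(ped, geno.gmap, truth)
        off = ped.table[ped.table["sire"] != ""]
        sire = off["sire"].iloc[0]
        out = sp.allele_contrast(asn, cohort, ped, sire, "LG1", 25.0)
        assert set(out["haplotype"]) == {0, 1}
        assert out["n"].sum() >= 40
        # balanced transmission: group sizes near half the sibship
        assert abs(out["n"].iloc[0] - out["n"].iloc[1]) < 0.5 * out["n"].sum()

    def test_null_contrast_centres_on_zero(self):
        diffs = []
        for r in range(12):
            spec = sp.CohortSpec(
                strains=("A", "B"), n_families_per_cross=2, n_offspring_per_family=30,
                variance_fractions=(0.0, 0.0, 0.0, 1.0), seed=900 + r,
            )
            cohort, ped, geno, truth = sp.simulate_cohort(spec)
            asn = sp.assignment_from_truth(ped, geno.gmap, truth)
            sire = ped.table[ped.table["sire"] != ""]["sire"].iloc[0]
            out = sp.allele_contrast(asn, cohort, ped, sire, "LG1", 25.0)
            means = out.set_index("haplotype")["mean"]
            diffs.append(means[0] - means[1])
        assert abs(np.mean(diffs)) < 0.2

    def test_stratified_by_mate(self, nuclear_cohort):
        ped, geno, truth = (
            nuclear_cohort["pedigree"], nuclear_cohort["geno"], nuclear_cohort["truth"]
        )
        asn = sp.assignment_from_truth(ped, geno.gmap, truth)
        off = ped.table[ped.table["sire"] != ""]
        by_sire = off.groupby("sire")["dam"].nunique()
        sire = by_sire[by_sire >= 2].index[0]
        out = sp.allele_contrast(
            asn, nuclear_cohort["cohort"], ped, sire, "LG1", 25.0,
            stratify_by_mate_strain=True,
        )
        assert "mate_strain" in out.columns
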