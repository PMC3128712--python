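"""Design coding, IRLS logistic fits, likelihood-ratio tests, and the scan."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, pearsonr

from hladr.alignment import parse_allele_table, translate_cohort
from hladr.association import (
    RankDeficientDesignError,
    dosage_design,
    fit_logistic,
    genotype_design,
    genotype_pair_categories,
    lrt,
    scan,
)
from hladr.simulate import demo_spec, generate_cohort

from conftest import make_cohort


def _dimorphic_matrix(n_gg=3, n_gv=3, n_vv=3, n_cases_first=True):
    """Small matrix over a G/V dimorphic position (position 86-like)."""
    table = parse_allele_table("allele\t5\nZ*01\tG\nZ*02\tV\n")
    recs = []
    i = 0
    for pair, count in (("11", n_gg), ("12", n_gv), ("22", n_vv)):
        for _ in range(count):
            status = i % 2
            recs.append((f"s{i}", status, f"Z*0{pair[0]}", f"Z*0{pair[1]}"))
            i += 1
    return translate_cohort(make_cohort(recs), table)


class TestDosageDesign:
    def test_dimorphic_single_column_counts_minor(self, demo_matrix):
        design = dosage_design(demo_matrix, [86])
        cols = [c for c in design.labels if c != "const"]
        assert len(cols) == 1
        # the column counts the non-reference amino acid, values in {0,1,2}
        assert set(np.unique(design.frame[cols[0]])) <= {0.0, 1.0, 2.0}

    def test_five_amino_acid_residue_gets_four_columns(self, demo_matrix):
        design = dosage_design(demo_matrix, [37])
        cols = [c for c in design.labels if c.startswith("p37:")]
        assert len(cols) == 4  # Phe/Leu/Asn/Ser/Tyr minus the reference

    def test_homozygote_codes_dosage_two(self, demo_table):
        cohort = make_cohort(
            [("s1", 1, "DRB1*03:01", "DRB1*03:01"),
             ("s2", 0, "DRB1*15:01", "DRB1*15:01"),
             ("s3", 0, "DRB1*04:01", "DRB1*15:01")]
        )
        matrix = translate_cohort(cohort, demo_table)
        design = dosage_design(matrix, [37], reference={37: "S"})
        assert design.frame.loc["s1", "p37:N"] == 2.0

    def test_monomorphic_residue_rejected(self, demo_table):
        cohort = make_cohort(
            [("s1", 1, "DRB1*03:01", "DRB1*03:01"),
             ("s2", 0, "DRB1*13:01", "DRB1*13:01"),
             ("s3", 0, "DRB1*04:01", "DRB1*04:01")]
        )
        matrix = translate_cohort(cohort, demo_table)
        # residue 37 is monomorphic (all Asn) once s3 is masked out
        mask = np.array([True, True, False])
        with pytest.raises(ValueError, match="monomorphic"):
            dosage_design(matrix, [37], sample_mask=mask)


class TestGenotypeDesign:
    def test_three_common_pairs_two_indicators(self):
        matrix = _dimorphic_matrix(50, 30, 20)
        design = genotype_design(matrix, [5])
        indicator_cols = [c for c in design.labels if c != "const"]
        assert len(indicator_cols) == 2

    def test_rare_pairs_pooled(self):
        # GG common; GV has 1 case / 2 controls; VV has 2 cases / 1 control:
        # both below the n >= 2 threshold in one arm -> pooled together
        table = parse_allele_table("allele\t5\nZ*01\tG\nZ*02\tV\n")
        recs = []
        sid = 0

        def add(n, status, a, b):
            nonlocal sid
            for _ in range(n):
                recs.append((f"s{sid}", status, a, b))
                sid += 1

        add(10, 1, "Z*01", "Z*01")
        add(10, 0, "Z*01", "Z*01")
        add(1, 1, "Z*01", "Z*02")
        add(2, 0, "Z*01", "Z*02")
        add(2, 1, "Z*02", "Z*02")
        add(1, 0, "Z*02", "Z*02")
        matrix = translate_cohort(make_cohort(recs), table)
        mask = np.ones(len(recs), dtype=bool)
        kept, category = genotype_pair_categories(matrix, 5, mask)
        assert category["GV"] == "rare" and category["VV"] == "rare"
        assert kept == ["GG", "rare"]

    def test_pooling_matches_brute_force_threshold(self, demo_matrix):
        mask = np.ones(demo_matrix.n_samples, dtype=bool)
        kept, category = genotype_pair_categories(demo_matrix, 37, mask)
        status = demo_matrix.status
        case_counts, ctrl_counts = Counter(), Counter()
        for i in range(demo_matrix.n_samples):
            label = "".join(demo_matrix.pair(i, 37))
            (case_counts if status[i] else ctrl_counts)[label] += 1
        rare = {
            p
            for p in set(case_counts) | set(ctrl_counts)
            if case_counts[p] < 2 or ctrl_counts[p] < 2
        }
        common = (set(case_counts) | set(ctrl_counts)) - rare
        # common pairs always stand alone
        for pair in common:
            assert category[pair] == pair
        # rare pairs all land in one shared category: "rare" if the pool
        # itself clears the threshold in both arms, otherwise the most
        # frequent common pair (the reference)
        pool_cases = sum(case_counts[p] for p in rare)
        pool_ctrls = sum(ctrl_counts[p] for p in rare)
        if pool_cases >= 2 and pool_ctrls >= 2:
            expected = "rare"
        else:
            expected = max(
                common, key=lambda p: (case_counts[p] + ctrl_counts[p], p)
            )
        for pair in rare:
            assert category[pair] == expected

    def test_single_pair_rejected(self):
        table = parse_allele_table("allele\t5\nZ*01\tG\nZ*02\tV\n")
        recs = [(f"s{i}", i % 2, "Z*01", "Z*01") for i in range(8)]
        recs.append(("s8", 1, "Z*01", "Z*02"))  # keeps position 5 polymorphic
        matrix = translate_cohort(make_cohort(recs), table)
        # only the GG pair remains once the lone heterozygote is masked out
        mask = np.array([True] * 8 + [False])
        with pytest.raises(ValueError, match="single"):
            genotype_design(matrix, [5], sample_mask=mask)


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        frame = pd.DataFrame({"const": np.ones(20)})
        y = np.array([1] * 10 + [0] * 10)
        fit = fit_logistic(frame, y)
        assert fit.converged
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-8)
        assert fit.loglik == pytest.approx(20 * math.log(0.5), rel=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
        frame = pd.DataFrame({"const": np.ones(60), "x": x})
        fit = fit_logistic(frame, y)
        ref = sm.Logit(y, frame).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, rel=1e-8)

    def test_duplicated_column_raises_rank_error(self):
        x = np.array([0, 1, 0, 1, 1, 0, 1, 0], float)
        frame = pd.DataFrame({"const": np.ones(8), "x": x, "x2": x})
        with pytest.raises(RankDeficientDesignError) as err:
            fit_logistic(frame, [0, 1, 0, 0, 1, 1, 1, 0])
        assert "x2" in str(err.value) or "x" in str(err.value)

    def test_perfect_separation_flagged_not_silent(self):
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = fit_logistic(pd.DataFrame({"const": np.ones(8), "x": x}), y)
        assert not fit.converged
        assert "separation" in fit.message or "not converged" in fit.message

    def test_constant_column_rejected(self):
        frame = pd.DataFrame({"const": np.ones(8), "z": np.full(8, 3.0)})
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(frame, [0, 1] * 4)


class TestLrt:
    def _fit(self, cols, y):
        return fit_logistic(pd.DataFrame(cols), np.asarray(y))

    def test_identical_models_statistic_zero_p_one(self):
        y = [0, 1, 0, 1, 1, 0, 1, 0]
        f = self._fit({"const": np.ones(8)}, y)
        res = lrt(f, f)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_zero_improvement(self):
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        x = np.zeros(8)
        x[:4] = [0, 0, 1, 1]
        x[4:] = [1, 1, 0, 0]  # covariate orthogonal-ish to y
        base = self._fit({"const": np.ones(8)}, y)
        full = self._fit({"const": np.ones(8), "x": x}, y)
        res = lrt(base, full)
        assert res.statistic >= 0
        assert 0 < res.p <= 1

    def test_chi_square_upper_tail(self):
        assert chi2.sf(3.84, 1) == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_rejected(self):
        y = [0, 1, 0, 1, 1, 0, 1, 0]
        a = self._fit({"const": np.ones(8), "a": np.r_[0, 1, 0, 1, 0, 1, 0, 1.0]}, y)
        b = self._fit({"const": np.ones(8), "b": np.r_[1, 1, 0, 0, 1, 1, 0, 0.0]}, y)
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_df_equals_parameter_difference(self, demo_matrix):
        y = demo_matrix.status
        base = fit_logistic(dosage_design(demo_matrix, [86]), y)
        full = fit_logistic(dosage_design(demo_matrix, [86, 37]), y)
        res = lrt(base, full)
        assert res.df == 4  # residue 37 adds 4 dosage columns


class TestScan:
    def test_causal_residue_ranks_first(self, demo_matrix):
        result = scan(demo_matrix, base_residues=(), coding="dosage")
        assert result.top().position == 37
        assert result.top().rank == 1
        assert result.top().p < 1e-10

    def test_conditioning_on_causal_removes_signal(self, demo_matrix):
        result = scan(demo_matrix, base_residues=[37], coding="dosage")
        assert all(r.p > 0.05 / 30 for r in result.results)

    def test_duplicate_coding_candidate_flagged_not_fatal(self, demo_matrix):
        # In the demo pool Glu28 is carried only by DRB1*12:01, which is the
        # only Leu37 allele: conditioned on residue 37, the residue-28 column
        # duplicates the Leu37 column exactly.
        result = scan(demo_matrix, base_residues=[37], coding="dosage")
        failed = {f.position for f in result.failures}
        assert 28 in failed
        reasons = " ".join(f.reason for f in result.failures)
        assert "rank" in reasons or "collinear" in reasons

    def test_genotype_coding_scan_agrees_on_top_residue(self, demo_matrix):
        result = scan(demo_matrix, base_residues=(), coding="genotype")
        assert result.top().position == 37

    def test_ranks_are_ascending_in_p(self, demo_matrix):
        result = scan(demo_matrix, base_residues=(), coding="dosage")
        ps = [r.p for r in result.results]
        assert ps == sorted(ps)
        assert [r.rank for r in result.results] == list(
            range(1, len(ps) + 1)
        )


class TestInvariants:
    def test_lr_invariant_to_reference_choice(self, demo_matrix):
        y = demo_matrix.status

        def stat_with(ref):
            base = fit_logistic(
                pd.DataFrame(
                    {"const": np.ones(demo_matrix.n_samples)},
                    index=demo_matrix.sample_ids,
                ),
                y,
            )
            full = fit_logistic(
                dosage_design(demo_matrix, [37], reference={37: ref}), y
            )
            return lrt(base, full).statistic

        stats = [stat_with(ref) for ref in "NSYF"]
        assert np.ptp(stats) < 1e-6

    def test_genotype_reference_invariance(self, demo_matrix):
        y = demo_matrix.status
        mask = np.ones(demo_matrix.n_samples, dtype=bool)
        kept, _ = genotype_pair_categories(demo_matrix, 86, mask)

        def stat_with(ref):
            base = fit_logistic(
                pd.DataFrame(
                    {"const": np.ones(demo_matrix.n_samples)},
                    index=demo_matrix.sample_ids,
                ),
                y,
            )
            full = fit_logistic(
                genotype_design(demo_matrix, [86], reference={86: ref}), y
            )
            return lrt(base, full).statistic

        stats = [stat_with(ref) for ref in kept]
        assert np.ptp(stats) < 1e-6

    def test_loglik_monotone_in_nesting_chain(self, demo_matrix):
        y = demo_matrix.status
        ll0 = fit_logistic(
            pd.DataFrame(
                {"const": np.ones(demo_matrix.n_samples)},
                index=demo_matrix.sample_ids,
            ),
            y,
        ).loglik
        ll1 = fit_logistic(dosage_design(demo_matrix, [37]), y).loglik
        ll2 = fit_logistic(dosage_design(demo_matrix, [37, 86]), y).loglik
        assert ll0 <= ll1 + 1e-9 <= ll2 + 2e-9
        assert ll2 <= 0

    def test_dimorphic_lr_tracks_armitage_trend(self, rng):
        """For a dimorphic residue the df-1 dosage LR test should agree
        with the Cochran-Armitage trend test (score test) asymptotically."""
        lr_ps, trend_ps = [], []
        for _ in range(200):
            n = 300
            dosage = rng.binomial(2, 0.3, size=n).astype(float)
            logit = -0.4 + 0.5 * dosage
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
            if len(np.unique(dosage)) < 2 or y.std() == 0:
                continue
            frame = pd.DataFrame({"const": np.ones(n), "d": dosage})
            base = fit_logistic(frame[["const"]], y)
            full = fit_logistic(frame, y)
            lr_ps.append(lrt(base, full).p)
            r = pearsonr(dosage, y)[0]
            trend_ps.append(float(chi2.sf(n * r * r, 1)))
        corr = pearsonr(lr_ps, trend_ps)[0]
        assert corr > 0.99

    def test_dosage_log_or_coverage(self):
        """Wald 95% CI of the per-copy Asn37 log-OR covers the truth in
        roughly 95% of study-scale replicates."""
        truth = math.log(3.0)
        covered = 0
        n_reps = 60
        seeds = np.random.SeedSequence(2024).generate_state(n_reps)
        for s in seeds:
            spec = demo_spec(seed=int(s) % (2**31 - 1))
            matrix = translate_cohort(generate_cohort(spec), spec.table)
            design = dosage_design(matrix, [37], reference={37: "S"})
            fit = fit_logistic(design, matrix.status)
            est = fit.params["p37:N"]
            se = math.sqrt(fit.cov_params.loc["p37:N", "p37:N"])
            if abs(est - truth) < 1.96 * se:
                covered += 1
        assert covered / n_reps > 0.85
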