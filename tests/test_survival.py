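import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lrprog.io import CohortDataset, LRPair
from lrprog.survival import (
    DegenerateStratification,
    PairSkipped,
    Untestable,
    classify,
    cox_hr,
    edgington_combine,
    pair_score,
    peto_peto_test,
    screen_pairs,
    storey_qvalues,
    stratify,
)
from oracles import bruteforce_peto_peto, optimizer_cox_coef


def _cohort(expr: pd.DataFrame, time, event) -> CohortDataset:
    patients = expr.columns
    return CohortDataset(
        cohort_id="c0",
        expression=expr,
        survival_time=pd.Series(np.asarray(time, float), index=patients),
        event=pd.Series(np.asarray(event, int), index=patients),
        grade=pd.Series(3, index=patients),
        stage=pd.Series("II", index=patients),
        is_cpm=True,
    )


class TestPairScore:
    def test_sum_of_ligand_and_receptor(self):
        expr = pd.DataFrame([[10, 0], [5, 5]], index=["L", "R"], columns=["p1", "p2"])
        cohort = _cohort(expr, [1, 2], [1, 1])
        np.testing.assert_allclose(pair_score(cohort, LRPair("L", "R")), [15, 5])

    def test_self_pair_doubles(self):
        expr = pd.DataFrame([[7, 3]], index=["G"], columns=["p1", "p2"])
        cohort = _cohort(expr, [1, 2], [1, 1])
        np.testing.assert_allclose(pair_score(cohort, LRPair("G", "G")), [14, 6])

    def test_missing_gene_is_skip_signal(self):
        expr = pd.DataFrame([[1, 2]], index=["L"], columns=["p1", "p2"])
        cohort = _cohort(expr, [1, 2], [1, 1])
        with pytest.raises(PairSkipped, match="missing_receptor"):
            pair_score(cohort, LRPair("L", "NOPE"))


class TestStratify:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([1, 2, 3, 4], [False, False, True, True]),
            ([1, 2, 2, 9], [False, True, True, True]),  # ties at median go high
        ],
    )
    def test_median_split(self, scores, expected):
        assert stratify(np.array(scores, float)).tolist() == expected

    def test_identical_scores_degenerate(self):
        with pytest.raises(DegenerateStratification):
            stratify(np.array([5.0, 5.0, 5.0]))

    @given(st.lists(st.floats(0, 1e6), min_size=3, max_size=30))
    def test_high_means_at_or_above_median(self, scores):
        scores = np.asarray(scores)
        try:
            high = stratify(scores)
        except PairSkipped:
            return
        cut = np.median(scores)
        assert ((scores >= cut) == high).all()
        assert 0 < high.sum() < len(scores)


class TestPetoPeto:
    def test_identical_group_multisets_give_null(self):
        time = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        event = np.ones(8, int)
        group = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        res = peto_peto_test(time, event, group)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_bruteforce_on_simple_case(self):
        time = np.array([1, 2, 3, 4], float)
        event = np.ones(4, int)
        group = np.array([1, 1, 0, 0], bool)
        res = peto_peto_test(time, event, group)
        assert res.chi_square == pytest.approx(
            bruteforce_peto_peto(time, event, group), rel=1e-9
        )

    def test_matches_bruteforce_with_ties_and_censoring(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            time = np.ceil(rng.exponential(10, n))
            event = (rng.random(n) < 0.75).astype(int)
            group = rng.random(n) < 0.5
            if event.sum() == 0 or group.all() or not group.any():
                continue
            res = peto_peto_test(time, event, group)
            assert res.chi_square == pytest.approx(
                bruteforce_peto_peto(time, event, group), rel=1e-9, abs=1e-12
            )

    def test_group_label_exchange_invariance(self, rng):
        time = rng.exponential(10, 40)
        event = (rng.random(40) < 0.8).astype(int)
        group = rng.random(40) < 0.5
        a = peto_peto_test(time, event, group)
        b = peto_peto_test(time, event, ~group)
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-9)

    def test_matches_r_survdiff_rho1(self, rng, tmp_path):
        """Cross-check against the reference survival implementation."""
        n = 30
        time = np.ceil(rng.exponential(10, n)) + 1
        event = (rng.random(n) < 0.8).astype(int)
        group = rng.random(n) < 0.5
        res = peto_peto_test(time, event, group)
        csv = tmp_path / "surv.csv"
        pd.DataFrame({"time": time, "event": event, "group": group.astype(int)}).to_csv(
            csv, index=False
        )
        script = (
            f'library(survival); d <- read.csv("{csv}"); '
            "s <- survdiff(Surv(time, event) ~ group, data=d, rho=1); "
            "cat(sprintf('%.10f', s$chisq))"
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
            )
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        if out.returncode != 0:
            pytest.skip(f"Rscript failed: {out.stderr[:200]}")
        assert res.chi_square == pytest.approx(float(out.stdout), rel=1e-6)

    def test_untestable_signals(self):
        with pytest.raises(Untestable):
            peto_peto_test([1.0, 2.0], [0, 0], [True, False])
        with pytest.raises(Untestable):
            peto_peto_test([1.0, 2.0], [1, 1], [True, True])


class TestCox:
    def test_matches_optimizer_oracle(self, rng):
        for _ in range(5):
            n = 40
            group = rng.random(n) < 0.5
            time = np.ceil(rng.exponential(np.where(group, 5, 10))) + 1
            event = (rng.random(n) < 0.8).astype(int)
            if event[group].sum() == 0 or event[~group].sum() == 0:
                continue
            res = cox_hr(time, event, group)
            assert res.converged
            assert res.coefficient == pytest.approx(
                optimizer_cox_coef(time, event, group), abs=1e-6
            )
            assert res.hazard_ratio == pytest.approx(np.exp(res.coefficient))

    def test_null_permutation_hr_near_one(self, rng):
        n = 2000
        time = rng.exponential(10, n)
        event = np.ones(n, int)
        group = rng.permutation(n) < n // 2
        res = cox_hr(time, event, group)
        assert 0.85 < res.hazard_ratio < 1.18

    def test_complete_separation_flagged(self):
        time = np.array([1, 2, 3, 10, 11, 12], float)
        event = np.array([1, 1, 1, 0, 0, 0])
        group = np.array([1, 1, 1, 0, 0, 0], bool)
        res = cox_hr(time, event, group)
        assert res.diverged


class TestEdgington:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.5, 0.5, 0.5], 0.5),  # symmetry of the Irwin-Hall null at k/2
            ([0.37], 0.37),  # k = 1 identity
            ([0.1, 0.2, 0.3], 0.6**3 / 6),  # closed form for s <= 1
        ],
    )
    def test_known_values(self, pvals, expected):
        assert edgington_combine(pvals) == pytest.approx(expected, rel=1e-9)

    def test_matches_irwin_hall_reference(self, rng):
        from scipy.stats import irwinhall

        for k in (2, 3, 5):
            p = rng.random(k)
            assert edgington_combine(p) == pytest.approx(
                float(irwinhall.cdf(p.sum(), k)), rel=1e-9, abs=1e-12
            )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            edgington_combine([])
        with pytest.raises(ValueError):
            edgington_combine([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_output_is_probability(self, pvals):
        assert 0.0 <= edgington_combine(pvals) <= 1.0


class TestStorey:
    def test_reduces_to_bh_when_pi0_forced(self):
        q, pi0 = storey_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert pi0 == 1.0

    def test_all_ones_boundary(self):
        q, pi0 = storey_qvalues(np.ones(500))
        assert pi0 == pytest.approx(1.0)
        np.testing.assert_allclose(q, 1.0)

    def test_small_m_falls_back_to_bh(self, caplog):
        with caplog.at_level("WARNING", logger="lrprog.survival"):
            q, pi0 = storey_qvalues([0.01, 0.5, 0.9])
        assert pi0 == 1.0
        assert any("pi0" in r.message for r in caplog.records)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_in_p_and_bounded(self, pvals):
        q, _ = storey_qvalues(pvals, pi0=1.0)
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestClassify:
    @pytest.mark.parametrize(
        "q,hrs,expected",
        [
            (0.05, [1.5, 2.0, 1.2], "poor"),
            (0.05, [1.5, 0.8, 1.2], "none"),  # direction inconsistent
            (0.05, [0.5, 0.8, 0.9], "good"),
            (0.10, [1.5, 2.0, 1.2], "none"),  # threshold is strict
        ],
    )
    def test_rule(self, q, hrs, expected):
        assert classify(q, np.array(hrs), q_threshold=0.1) == expected

    @given(
        st.floats(0, 1),
        st.lists(st.floats(0.01, 100.0), min_size=1, max_size=5),
    )
    def test_pure_function_of_q_and_hrs(self, q, hrs):
        hrs = np.array(hrs)
        klass = classify(q, hrs, q_threshold=0.1)
        if klass == "poor":
            assert q < 0.1 and (hrs > 1).all()
        elif klass == "good":
            assert q < 0.1 and (hrs < 1).all()
        else:
            assert not (q < 0.1 and ((hrs > 1).all() or (hrs < 1).all()))


class TestScreenPairs:
    def _mini_cohorts(self, rng, n_pairs=6, n_patients=60, effect=1.2):
        """Two tiny cohorts with the first pair planted as poor."""
        cohorts = []
        genes = [g for i in range(n_pairs) for g in (f"L{i}", f"R{i}")]
        pairs = [LRPair(f"L{i}", f"R{i}") for i in range(n_pairs)]
        for c in range(2):
            expr = pd.DataFrame(
                rng.poisson(50, size=(len(genes), n_patients)).astype(float),
                index=genes,
                columns=[f"c{c}p{i}" for i in range(n_patients)],
            )
            score = expr.loc["L0"].to_numpy() + expr.loc["R0"].to_numpy()
            high = score >= np.median(score)
            hazard = 0.01 * np.exp(effect * high)
            time = rng.exponential(1 / hazard)
            cohorts.append(_cohort(expr, time, np.ones(n_patients)))
        return cohorts, pairs

    def test_recovers_planted_pair_and_reports_skips(self, rng):
        cohorts, pairs = self._mini_cohorts(rng)
        pairs = pairs + [LRPair("L0", "ABSENT")]
        results = screen_pairs(cohorts, pairs, q_threshold=0.1)
        by_pair = {r.pair: r for r in results}
        planted = by_pair[LRPair("L0", "R0")]
        assert planted.prognostic_class == "poor"
        assert all(hr > 1 for _, _, hr in planted.per_cohort)
        skipped = by_pair[LRPair("L0", "ABSENT")]
        assert skipped.n_cohorts_tested == 0
        assert skipped.prognostic_class == "none"
        assert "missing_receptor" in skipped.reason
        assert np.isnan(skipped.q_value)

    def test_mean_hr_is_arithmetic_mean(self, rng):
        cohorts, pairs = self._mini_cohorts(rng)
        results = screen_pairs(cohorts, pairs)
        for r in results:
            if r.per_cohort:
                assert r.mean_hr == pytest.approx(
                    np.mean([hr for _, _, hr in r.per_cohort])
                )

    def test_global_stratification_variant_runs(self, rng):
        cohorts, pairs = self._mini_cohorts(rng)
        results = screen_pairs(cohorts, pairs, stratify_reference="global")
        assert len(results) == len(pairs)
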