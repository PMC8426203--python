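"""Per-pair survival screening across bulk cohorts.

For every ligand-receptor pair, patients are scored by the sum of the
two genes' CPM values, split at the median score into "high" and "low"
strata, and the strata are compared with the Peto-Peto modification of
the Gehan-Wilcoxon test (a weighted log-rank test whose weights are the
left-continuous pooled Kaplan-Meier estimate, i.e. the rho = 1 member
of the G-rho family). The hazard ratio of high vs low comes from a
univariate Cox proportional-hazards fit with Efron tie handling.
Per-cohort p-values are combined with Edgington's sum-of-p method
(Irwin-Hall null), corrected for multiplicity with Storey's q-value,
and each pair is classified as poor-prognostic (q below threshold and
HR > 1 in every cohort), good-prognostic (HR < 1 in every cohort), or
neither.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .io import CohortDataset, LRPair

logger = logging.getLogger(__name__)

DEFAULT_Q_THRESHOLD = 0.1
DEFAULT_SEED = 20210904


class PairSkipped(Exception):
    """A pair cannot be tested in a cohort; carries a reason code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class DegenerateStratification(PairSkipped):
    """All patients share one score; a median split is impossible."""

    def __init__(self, reason: str = "degenerate_stratification"):
        super().__init__(reason)


class Untestable(PairSkipped):
    """The survival test's preconditions fail (no events / empty group)."""


@dataclass
class SurvivalTestResult:
    """Weighted log-rank outcome for one high/low split."""

    chi_square: float
    p_value: float
    n_high: int
    n_low: int
    n_events: int


@dataclass
class CoxResult:
    """Univariate Cox fit for the high-vs-low stratum indicator."""

    coefficient: float
    hazard_ratio: float
    standard_error: float
    converged: bool
    diverged: bool = False  # monotone likelihood / complete separation


@dataclass
class PairScreenResult:
    """Combined multi-cohort screening outcome for one pair."""

    pair: LRPair
    per_cohort: list[tuple[str, float, float]]  # (cohort_id, p, HR)
    combined_p: float
    q_value: float
    mean_hr: float
    prognostic_class: str  # poor | good | none
    n_cohorts_tested: int = 0
    reason: str = ""


def pair_score(cohort: CohortDataset, pair: LRPair) -> np.ndarray:
    """Per-patient score: CPM(ligand) + CPM(receptor).

    A self-pair (ligand == receptor) scores twice the gene's CPM.
    Raises :class:`PairSkipped` if either gene is absent (exact,
    case-sensitive symbol match).
    """
    expr = cohort.expression
    if pair.ligand not in expr.index:
        raise PairSkipped("missing_ligand")
    if pair.receptor not in expr.index:
        raise PairSkipped("missing_receptor")
    return expr.loc[pair.ligand].to_numpy(float) + expr.loc[pair.receptor].to_numpy(float)


def stratify(scores: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Boolean high/low split: high iff score >= median (ties go high).

    ``threshold`` overrides the per-pair median, for the global-median
    stratification variant. Raises :class:`DegenerateStratification`
    when every patient would land in one stratum.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise PairSkipped("too_few_patients")
    cut = float(np.median(scores)) if threshold is None else float(threshold)
    high = scores >= cut
    if high.all() or not high.any():
        raise DegenerateStratification()
    return high


def peto_peto_test(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> SurvivalTestResult:
    """Peto-Peto modification of the Gehan-Wilcoxon test.

    Two-sample weighted log-rank statistic in which the weight at each
    distinct event time is the left-continuous pooled Kaplan-Meier
    survival estimate, S(t-) = prod_{t_j < t} (1 - d_j / n_j). Tied
    deaths are aggregated per distinct time; the statistic is referred
    to chi-square on one degree of freedom.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    n_high = int(group.sum())
    n_low = int((~group).sum())
    if n_high == 0 or n_low == 0:
        raise Untestable("one_group_empty")
    n_events = int(event.sum())
    if n_events == 0:
        raise Untestable("no_events")

    event_times = np.unique(time[event == 1])
    # risk set sizes and death counts at each distinct event time
    n_at_risk = (time[None, :] >= event_times[:, None]).sum(axis=1).astype(float)
    n1_at_risk = (
        (time[None, :] >= event_times[:, None]) & group[None, :]
    ).sum(axis=1).astype(float)
    deaths = ((time[None, :] == event_times[:, None]) & (event[None, :] == 1)).sum(axis=1).astype(float)
    deaths1 = (
        (time[None, :] == event_times[:, None]) & (event[None, :] == 1) & group[None, :]
    ).sum(axis=1).astype(float)

    # left-continuous pooled KM at each event time
    km_factor = 1.0 - deaths / n_at_risk
    weights = np.concatenate(([1.0], np.cumprod(km_factor)[:-1]))

    expected1 = n1_at_risk * deaths / n_at_risk
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (
            deaths
            * (n_at_risk - deaths)
            * n1_at_risk
            * (n_at_risk - n1_at_risk)
            / (n_at_risk**2 * (n_at_risk - 1.0))
        )
    var = np.where(n_at_risk > 1, var, 0.0)

    u = float(np.sum(weights * (deaths1 - expected1)))
    v = float(np.sum(weights**2 * var))
    if v <= 0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = u * u / v
        p = float(stats.chi2.sf(chi2, df=1))
    return SurvivalTestResult(
        chi_square=chi2, p_value=p, n_high=n_high, n_low=n_low, n_events=n_events
    )


def cox_hr(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> CoxResult:
    """Univariate Cox proportional-hazards fit for the stratum indicator.

    The partial likelihood with Efron tie handling is maximized by
    Newton-Raphson (via lifelines). Complete separation of events
    (monotone likelihood) is reported as ``diverged`` with the last
    iterate rather than raised.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise Untestable("one_group_empty")
    if event.sum() == 0:
        raise Untestable("no_events")

    df = pd.DataFrame({"time": time, "event": event, "high": group.astype(float)})
    fitter = CoxPHFitter()
    diverged = bool(event[group].sum() == 0 or event[~group].sum() == 0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(
                df,
                duration_col="time",
                event_col="event",
                fit_options={"precision": 1e-14, "max_steps": 500},
            )
        coef = float(fitter.params_["high"])
        se = float(fitter.standard_errors_["high"])
        converged = True
    except ConvergenceError as err:
        iterate = getattr(err, "original_exception", None)
        coef = float(np.sign(event[group].mean() - event[~group].mean()) * 20.0)
        se = float("inf")
        converged = False
        diverged = True
        logger.debug("cox fit did not converge: %s / %s", err, iterate)
    # extreme but finite coefficients flag monotone likelihood too
    if abs(coef) > 15:
        diverged = True
    return CoxResult(
        coefficient=coef,
        hazard_ratio=math.exp(coef),
        standard_error=se,
        converged=converged,
        diverged=diverged,
    )


def edgington_combine(p_values) -> float:
    """Combine p-values by Edgington's sum-of-p method.

    Under the null the sum S of k independent Uniform(0,1) p-values
    follows the Irwin-Hall distribution; the combined p-value is its
    CDF at the observed sum:

        P(S <= s) = (1/k!) * sum_{j=0}^{floor(s)} (-1)^j C(k, j) (s-j)^k

    clipped to [0, 1]. With k = 1 this is the identity.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    s = float(p.sum())
    total = 0.0
    for j in range(int(math.floor(s)) + 1):
        total += (-1.0) ** j * math.comb(k, j) * (s - j) ** k
    combined = total / math.factorial(k)
    return float(min(1.0, max(0.0, combined)))


def storey_qvalues(
    p_values,
    lambdas: np.ndarray | None = None,
    pi0: float | None = None,
    min_m_for_spline: int = 100,
) -> tuple[np.ndarray, float]:
    """Storey q-values with smoothing-spline pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    grid lambda = 0.05, 0.10, ..., 0.95, smoothed with a cubic smoothing
    spline and read off at the largest lambda, then clipped to (0, 1].
    q_i = pi0 * min_{p_(j) >= p_(i)} m p_(j) / j. Forcing ``pi0=1``
    reduces to Benjamini-Hochberg. Below ``min_m_for_spline`` p-values
    the spline estimate is unstable and pi0 falls back to 1 with a
    logged warning.
    """
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")

    if pi0 is None:
        if m < min_m_for_spline:
            logger.warning(
                "only %d p-values; falling back to pi0 = 1 (Benjamini-Hochberg)", m
            )
            pi0 = 1.0
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.96, 0.05)
            lambdas = np.asarray(lambdas, dtype=float)
            pi0_lambda = np.array(
                [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
            )
            spline = UnivariateSpline(lambdas, pi0_lambda, k=3)
            pi0 = float(spline(lambdas.max()))
            pi0 = min(1.0, max(pi0, 1.0 / m))
    else:
        if not 0 < pi0 <= 1:
            raise ValueError("pi0 must lie in (0, 1]")

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    ranks = np.arange(1, m + 1, dtype=float)
    q_sorted = np.minimum.accumulate((pi0 * m * ranked / ranks)[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def _global_median(cohort: CohortDataset, pairs: list[LRPair]) -> float:
    """Median over all pairs and patients of the pair scores (variant
    stratification reference)."""
    scores = []
    for pair in pairs:
        try:
            scores.append(pair_score(cohort, pair))
        except PairSkipped:
            continue
    if not scores:
        raise ValueError("no testable pairs for global median")
    return float(np.median(np.concatenate(scores)))


def screen_pairs(
    cohorts: list[CohortDataset],
    pairs: list[LRPair],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    stratify_reference: str = "per_pair",
) -> list[PairScreenResult]:
    """Screen every pair for survival association across cohorts.

    Per cohort: score, median split, Peto-Peto p, Cox HR. The combined
    p is Edgington's over the cohorts where the pair was testable;
    q-values are computed once over all pairs' combined p-values.
    Classification requires q < ``q_threshold`` and a consistent HR
    direction (all > 1 for "poor", all < 1 for "good") across the
    testable cohorts; pairs whose Cox fit failed or diverged anywhere
    are left unclassified with a reason code.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    if stratify_reference not in ("per_pair", "global"):
        raise ValueError("stratify_reference must be 'per_pair' or 'global'")
    cohorts = [c.cpm() for c in cohorts]

    global_cut: dict[str, float] = {}
    if stratify_reference == "global":
        global_cut = {c.cohort_id: _global_median(c, pairs) for c in cohorts}

    records: list[dict] = []
    for pair in pairs:
        per_cohort: list[tuple[str, float, float]] = []
        reasons: list[str] = []
        any_fit_problem = False
        for cohort in cohorts:
            try:
                scores = pair_score(cohort, pair)
                high = stratify(scores, threshold=global_cut.get(cohort.cohort_id))
                test = peto_peto_test(
                    cohort.survival_time.to_numpy(),
                    cohort.event.to_numpy(),
                    high,
                )
                cox = cox_hr(
                    cohort.survival_time.to_numpy(),
                    cohort.event.to_numpy(),
                    high,
                )
            except PairSkipped as skip:
                reasons.append(f"{cohort.cohort_id}:{skip.reason}")
                continue
            if not cox.converged or cox.diverged:
                any_fit_problem = True
                reasons.append(f"{cohort.cohort_id}:cox_not_converged")
            per_cohort.append((cohort.cohort_id, test.p_value, cox.hazard_ratio))
        records.append(
            {
                "pair": pair,
                "per_cohort": per_cohort,
                "reasons": reasons,
                "fit_problem": any_fit_problem,
            }
        )

    testable = [r for r in records if r["per_cohort"]]
    combined = {
        id(r): edgington_combine([p for _, p, _ in r["per_cohort"]]) for r in testable
    }
    if testable:
        qvals, pi0 = storey_qvalues([combined[id(r)] for r in testable])
        logger.info("screened %d testable pairs, pi0 = %.3f", len(testable), pi0)
        qmap = {id(r): q for r, q in zip(testable, qvals)}
    else:
        qmap = {}

    results: list[PairScreenResult] = []
    for rec in records:
        per_cohort = rec["per_cohort"]
        if not per_cohort:
            results.append(
                PairScreenResult(
                    pair=rec["pair"],
                    per_cohort=[],
                    combined_p=float("nan"),
                    q_value=float("nan"),
                    mean_hr=float("nan"),
                    prognostic_class="none",
                    n_cohorts_tested=0,
                    reason=";".join(rec["reasons"]) or "untestable",
                )
            )
            continue
        hrs = np.array([hr for _, _, hr in per_cohort])
        q = qmap[id(rec)]
        if rec["fit_problem"]:
            klass = "none"
        else:
            klass = classify(q, hrs, q_threshold)
        results.append(
            PairScreenResult(
                pair=rec["pair"],
                per_cohort=per_cohort,
                combined_p=combined[id(rec)],
                q_value=float(q),
                mean_hr=float(hrs.mean()),
                prognostic_class=klass,
                n_cohorts_tested=len(per_cohort),
                reason=";".join(rec["reasons"]),
            )
        )
    return results


def classify(q_value: float, hazard_ratios: np.ndarray, q_threshold: float) -> str:
    """Prognostic class from (q, per-cohort HRs): a pure function.

    poor: q < threshold and HR > 1 in every cohort; good: q < threshold
    and HR < 1 in every cohort; none otherwise (including any HR == 1).
    """
    hazard_ratios = np.asarray(hazard_ratios, dtype=float)
    if q_value < q_threshold and (hazard_ratios > 1).all():
        return "poor"
    if q_value < q_threshold and (hazard_ratios < 1).all():
        return "good"
    return "none"


def screen_table(results: list[PairScreenResult]) -> pd.DataFrame:
    """Flatten screening results to one row per pair for TSV output."""
    cohort_ids: list[str] = []
    for res in results:
        for cid, _, _ in res.per_cohort:
            if cid not in cohort_ids:
                cohort_ids.append(cid)
    rows = []
    for res in results:
        row: dict = {"ligand": res.pair.ligand, "receptor": res.pair.receptor}
        by_cohort = {cid: (p, hr) for cid, p, hr in res.per_cohort}
        for cid in cohort_ids:
            p, hr = by_cohort.get(cid, (np.nan, np.nan))
            row[f"p_{cid}"] = p
            row[f"hr_{cid}"] = hr
        row.update(
            combined_p=res.combined_p,
            q_value=res.q_value,
            mean_hr=res.mean_hr,
            prognostic_class=res.prognostic_class,
            n_cohorts_tested=res.n_cohorts_tested,
            reason=res.reason,
        )
        rows.append(row)
    return pd.DataFrame(rows)
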