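"""Per-sample CHIP burden stratification and cohort prevalence statistics.

Samples are stratified into three burden categories: ``negative`` (no
passing CHIP call), ``chip`` (>= 1 call, all VAF <= 10%), and
``high_burden`` (largest clone strictly above 10% VAF). Prevalence is
compared between cohort strata (pathology, timepoint, treatment response)
with the conditional exact 2x2 test, optionally age-adjusted by logistic
regression since CHIP burden rises steeply with age. Multiple comparisons
are Benjamini–Hochberg adjusted together.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .chip_filter import ChipCall
from .io import CohortSample

logger = logging.getLogger(__name__)

HIGH_BURDEN_VAF = 0.10  # largest clone strictly above this -> high_burden


@dataclass(frozen=True)
class BurdenProfile:
    sample_id: str
    n_chip: int
    n_chip_pd: int
    max_vaf: float | None
    category: str  # negative | chip | high_burden


@dataclass(frozen=True)
class PrevalenceComparison:
    group_a: str
    group_b: str
    carriers_a: int
    total_a: int
    carriers_b: int
    total_b: int
    odds_ratio: float  # may be inf; nan when undefined (0/0)
    p_exact: float
    p_adjusted: float | None = None  # age-adjusted logistic Wald p
    method: str = "conditional_exact_2x2"


@dataclass(frozen=True)
class LogisticFit:
    """One covariate's estimate from a logistic regression."""

    name: str
    coef: float
    se: float
    wald_p: float
    separation: bool = False


def classify_burden(sample_id: str, calls: Sequence[ChipCall]) -> BurdenProfile:
    """Burden category for one sample from its filtered, classified calls.

    Non-passing calls are ignored. ``high_burden`` requires the largest
    passing-call VAF to exceed 10% strictly; a clone at exactly 10% is
    ``chip``.
    """
    passing = [c for c in calls if c.passed]
    if not passing:
        return BurdenProfile(sample_id, 0, 0, None, "negative")
    max_vaf = max(c.vaf for c in passing)  # exact rational from the cascade
    n_pd = sum(c.classification == "CHIP_PD" for c in passing)
    category = "high_burden" if max_vaf > Fraction(1, 10) else "chip"
    return BurdenProfile(sample_id, len(passing), n_pd, float(max_vaf), category)


def burden_table(profiles: Sequence[BurdenProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles])


def prevalence_table(
    profiles: Sequence[BurdenProfile],
    samples: Sequence[CohortSample],
    stratify_by: str,
) -> pd.DataFrame:
    """CHIP carriers / totals per stratum of a cohort covariate.

    A carrier is any sample not in the ``negative`` category. Strata with
    zero samples are omitted (with a log line).
    """
    by_id = {s.sample_id: s for s in samples}
    unmatched = [p.sample_id for p in profiles if p.sample_id not in by_id]
    if unmatched:
        raise ValueError(f"burden profiles without cohort metadata: {unmatched}")
    df = pd.DataFrame(
        {
            "stratum": [getattr(by_id[p.sample_id], stratify_by) for p in profiles],
            "carrier": [p.category != "negative" for p in profiles],
        }
    )
    out = (
        df.groupby("stratum", observed=True)["carrier"]
        .agg(carriers="sum", total="count")
        .reset_index()
    )
    out["prevalence"] = out["carriers"] / out["total"]
    logger.info("prevalence by %s: %d strata", stratify_by, len(out))
    return out


def exact_2x2_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Conditional exact test on a 2x2 table [[a, b], [c, d]].

    Returns the sample odds ratio (a*d)/(b*c) — ``inf`` when b*c == 0 with
    a*d > 0, ``nan`` when both products are zero — and the two-sided p-value
    under the hypergeometric null with the minimum-likelihood rule (sum of
    all tables with fixed margins whose probability does not exceed the
    observed table's).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    ad, bc = a * d, b * c
    if bc == 0:
        odds_ratio = math.nan if ad == 0 else math.inf
    else:
        odds_ratio = ad / bc
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds_ratio, float(p)


def age_adjusted_logistic(
    outcomes: Sequence[int],
    group: Sequence[int],
    ages: Sequence[float],
) -> dict[str, LogisticFit]:
    """Logistic regression of a binary outcome on group membership and age.

    Plain maximum likelihood (Newton/IRLS, tolerance 1e-8, up to 100
    iterations) with no penalization; complete separation is detected and
    reported through the ``separation`` flag rather than raised.
    """
    y = np.asarray(outcomes, dtype=float)
    g = np.asarray(group, dtype=float)
    age = np.asarray(ages, dtype=float)
    if np.isnan(age).any():
        raise ValueError("missing ages are not allowed")
    if len({int(v) for v in y}) < 2:
        raise ValueError("constant outcome: logistic fit undefined")
    X = sm.add_constant(np.column_stack([g, age]))
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, X).fit(
                method="newton", maxiter=100, tol=1e-8, disp=False, warn_convergence=False
            )
        except (PerfectSeparationWarning, np.linalg.LinAlgError):
            separation = True
            fit = sm.Logit(y, X).fit(
                method="bfgs", maxiter=200, disp=False, warn_convergence=False
            )
    # diverging coefficients are the practical signature of quasi-separation
    if not separation and np.max(np.abs(fit.params[1:])) > 15:
        separation = True
    names = ("intercept", "group", "age")
    return {
        name: LogisticFit(
            name=name,
            coef=float(fit.params[i]),
            se=float(fit.bse[i]),
            wald_p=float(fit.pvalues[i]),
            separation=separation,
        )
        for i, name in enumerate(names)
    }


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_prevalence(
    profiles: Sequence[BurdenProfile],
    samples: Sequence[CohortSample],
    stratify_by: str,
    group_a: str,
    group_b: str,
    age_adjust: bool = True,
) -> PrevalenceComparison:
    """Exact 2x2 comparison of CHIP prevalence between two cohort strata."""
    by_id = {s.sample_id: s for s in samples}
    rows_a = [p for p in profiles if getattr(by_id[p.sample_id], stratify_by) == group_a]
    rows_b = [p for p in profiles if getattr(by_id[p.sample_id], stratify_by) == group_b]
    ca = sum(p.category != "negative" for p in rows_a)
    cb = sum(p.category != "negative" for p in rows_b)
    odds_ratio, p = exact_2x2_test(ca, len(rows_a) - ca, cb, len(rows_b) - cb)
    p_adj = None
    if age_adjust:
        both = rows_a + rows_b
        outcomes = [int(pr.category != "negative") for pr in both]
        group = [1] * len(rows_a) + [0] * len(rows_b)
        ages = [by_id[pr.sample_id].age for pr in both]
        try:
            p_adj = age_adjusted_logistic(outcomes, group, ages)["group"].wald_p
        except ValueError:
            p_adj = None
    return PrevalenceComparison(
        group_a=group_a,
        group_b=group_b,
        carriers_a=ca,
        total_a=len(rows_a),
        carriers_b=cb,
        total_b=len(rows_b),
        odds_ratio=odds_ratio,
        p_exact=p,
        p_adjusted=p_adj,
    )


def vaf_concordance(
    pre_calls: Sequence[ChipCall], post_calls: Sequence[ChipCall]
) -> dict:
    """Match passing calls across timepoints and correlate their VAFs.

    Calls are keyed by (sample, chrom, pos, ref, alt). Variants present at
    only one timepoint are reported as gained/lost and excluded from the
    correlation, never imputed. Correlations are None with < 3 matched
    pairs.
    """

    def keyed(calls):
        return {
            (c.record.sample_id, *c.record.key): c.vaf for c in calls if c.passed
        }

    pre, post = keyed(pre_calls), keyed(post_calls)
    shared = sorted(set(pre) & set(post))
    lost = sorted(set(pre) - set(post))
    gained = sorted(set(post) - set(pre))
    x = np.array([pre[k] for k in shared], dtype=float)
    y = np.array([post[k] for k in shared], dtype=float)
    pearson = spearman = None
    if len(shared) >= 3 and np.std(x) > 0 and np.std(y) > 0:
        pearson = float(stats.pearsonr(x, y).statistic)
        spearman = float(stats.spearmanr(x, y).statistic)
    return {
        "matched": [
            {"key": k, "vaf_pre": pre[k], "vaf_post": post[k]} for k in shared
        ],
        "lost": lost,
        "gained": gained,
        "pearson": pearson,
        "spearman": spearman,
    }
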