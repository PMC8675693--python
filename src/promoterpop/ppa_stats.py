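"""The population promoter activity (PPA) statistic and its comparisons.

Each promoter type carries a relative promoter activity (measured against the
CGC-type); an individual's activity is the mean of its two alleles' activities
and PPA is the population mean of individual activities:

    PPA = sum_i (a1_i + a2_i) / 2 / n

Under random mating PPA reduces exactly to the allele-frequency-weighted mean
activity, which is what the archaic-composition enumeration uses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .haplotypes import PromoterType

#: Relative promoter activities (CGC-referenced).
DEFAULT_ACTIVITIES: dict[PromoterType, float] = {
    PromoterType.TGT: 3.6,
    PromoterType.CGT: 2.9,
    PromoterType.TCT: 2.1,
    PromoterType.CGC: 1.0,
}


def _activity(pt: PromoterType, activities) -> float:
    if pt not in activities:
        raise KeyError(f"promoter type {pt} is unscored")
    a = activities[pt]
    if a <= 0:
        raise ValueError("activities must be positive")
    return a


def individual_activity(
    type1: PromoterType, type2: PromoterType, activities=None
) -> float:
    """(a1 + a2) / 2 for an individual's two promoter-type alleles."""
    activities = DEFAULT_ACTIVITIES if activities is None else activities
    return 0.5 * (_activity(type1, activities) + _activity(type2, activities))


@dataclass
class PPAResult:
    population: str
    n: int
    individual_activities: list[float]
    ppa: float
    n_excluded: int


def population_ppa(
    type_pairs, activities=None, population: str = ""
) -> PPAResult:
    """Mean individual activity over a population of diploid type pairs.

    Individuals carrying an unscored (OTHER or unknown) type are excluded and
    counted in ``n_excluded``.
    """
    activities = DEFAULT_ACTIVITIES if activities is None else activities
    values: list[float] = []
    excluded = 0
    for t1, t2 in type_pairs:
        try:
            values.append(individual_activity(t1, t2, activities))
        except KeyError:
            excluded += 1
    if not values:
        raise ValueError("no scorable individuals")
    return PPAResult(population, len(values), values, float(np.mean(values)), excluded)


def ppa_from_allele_counts(counts: dict[PromoterType, int], activities=None) -> float:
    """PPA of a randomly mating population from scored allele counts: the
    allele-frequency-weighted mean activity."""
    activities = DEFAULT_ACTIVITIES if activities is None else activities
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no alleles")
    return sum(c * _activity(t, activities) for t, c in counts.items()) / total


def hardy_weinberg_ppa(frequencies: dict[PromoterType, float], activities=None) -> float:
    """Expected PPA under random mating; equals sum_i f_i * a_i."""
    activities = DEFAULT_ACTIVITIES if activities is None else activities
    total = sum(frequencies.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"frequencies must sum to 1 (got {total})")
    return float(sum(f * _activity(t, activities) for t, f in frequencies.items()))


@dataclass
class AHCompositionResult:
    """Extremes of the archaic PPA over admissible promoter-type compositions."""

    min_ppa: float
    max_ppa: float
    min_composition: dict[str, float]
    max_composition: dict[str, float]
    reference_ppa: float
    min_fold: float
    max_fold: float


def enumerate_ah_compositions(
    cgt_lower_bound: float,
    grid_step: float = 0.001,
    reference_ppa: float | None = None,
    activities=None,
) -> AHCompositionResult:
    """Grid enumeration of archaic promoter-type compositions.

    Compositions (f_CGT, f_TGT, f_TCT) satisfy f_CGT >= ``cgt_lower_bound``
    and f_TGT >= f_TCT >= 0 (the recombination-tract evidence implies the
    TGT-type outnumbered the TCT-type in archaic populations); each PPA is the
    random-mating expectation. Fold ranges compare against ``reference_ppa``.
    """
    if not 0 < cgt_lower_bound <= 1:
        raise ValueError("cgt_lower_bound must lie in (0, 1]")
    activities = DEFAULT_ACTIVITIES if activities is None else activities
    a_cgt = _activity(PromoterType.CGT, activities)
    a_tgt = _activity(PromoterType.TGT, activities)
    a_tct = _activity(PromoterType.TCT, activities)

    best_min = (np.inf, None)
    best_max = (-np.inf, None)
    n_cgt = int(np.floor((1.0 - cgt_lower_bound) / grid_step)) + 1
    for i in range(n_cgt + 1):
        f_cgt = min(1.0, cgt_lower_bound + i * grid_step)
        rem = 1.0 - f_cgt
        n_t = int(np.floor(rem / grid_step))
        for j in range(n_t + 1):
            f_tct = min(j * grid_step, rem / 2.0)
            f_tgt = rem - f_tct
            if f_tgt < f_tct - 1e-12:
                continue
            ppa = a_cgt * f_cgt + a_tgt * f_tgt + a_tct * f_tct
            comp = {"CGT": f_cgt, "TGT": f_tgt, "TCT": f_tct}
            if ppa < best_min[0]:
                best_min = (ppa, comp)
            if ppa > best_max[0]:
                best_max = (ppa, comp)
            if f_tct >= rem / 2.0:
                break
    ref = reference_ppa if reference_ppa is not None else np.nan
    return AHCompositionResult(
        best_min[0],
        best_max[0],
        best_min[1],
        best_max[1],
        ref,
        best_min[0] / ref if reference_ppa else np.nan,
        best_max[0] / ref if reference_ppa else np.nan,
    )


def compare_activity_distributions(activities_a, activities_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on individual-activity distributions."""
    a, b = np.asarray(activities_a, float), np.asarray(activities_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class FoldComparisonResult:
    bin_window: tuple[float, float]
    snp_ids: list[str]
    folds: np.ndarray
    mean: float
    sd: float
    ci: tuple[float, float]
    ks_p: float
    normal_ok: bool
    focal_fold: float
    flag: str  # inside | outside | degenerate


def panel_fold_comparison(
    panel_table: pd.DataFrame,
    focal_fold: float,
    pop_a: str,
    pop_b: str,
    bin_window: tuple[float, float],
    level: float = 0.99,
) -> FoldComparisonResult:
    """Fold-difference envelope from a panel of index SNPs.

    SNPs whose ``pop_a`` frequency falls in ``bin_window`` define the
    empirical distribution of pop_b/pop_a frequency folds. A *population*
    interval mean +/- z*sd at the given level (normality checked with a
    one-sample KS test) is the envelope; ``focal_fold`` (the focal type's
    pop_b/pop_a frequency fold) is flagged inside or outside it.
    """
    lo, hi = bin_window
    sel = panel_table[(panel_table[pop_a] >= lo) & (panel_table[pop_a] <= hi)]
    if sel.empty:
        raise ValueError("no panel SNPs inside the frequency bin")
    if len(sel) < 5:
        raise ValueError("fewer than 5 panel SNPs inside the frequency bin")
    folds = (sel[pop_b] / sel[pop_a]).to_numpy(float)
    mean, sd = float(folds.mean()), float(folds.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):
        return FoldComparisonResult(
            bin_window, sel["snp_id"].tolist(), folds, mean, 0.0,
            (mean, mean), 1.0, True, float(focal_fold), "degenerate",
        )
    ks_p = float(stats.kstest((folds - mean) / sd, "norm").pvalue)
    z = stats.norm.ppf(0.5 + level / 2.0)
    ci = (float(mean - z * sd), float(mean + z * sd))
    flag = "inside" if ci[0] <= focal_fold <= ci[1] else "outside"
    if ks_p < 0.05:
        flag = f"{flag} (non-normal)"
    return FoldComparisonResult(
        bin_window, sel["snp_id"].tolist(), folds, mean, sd, ci, ks_p,
        ks_p >= 0.05, float(focal_fold), flag,
    )


def infer_ancestral_frequency(focal_freq: float, median_fold: float) -> float:
    """Approximate ancestral frequency as focal_freq * median_fold, capped at 1.

    The multiplicative convention inverts the observed median fold difference
    of neutral index SNPs; the output is a rough point value, not an interval.
    """
    if focal_freq <= 0 or median_fold <= 0:
        raise ValueError("inputs must be positive")
    return float(min(1.0, focal_freq * median_fold))


def correlate_ppa_covariate(
    ppa_by_population: dict[str, float], covariate: dict[str, float]
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between PPA and a covariate."""
    labels = sorted(ppa_by_population)
    if sorted(covariate) != labels:
        raise ValueError("population labels of PPA and covariate differ")
    if len(labels) < 3:
        raise ValueError("need at least three paired values")
    x = np.array([ppa_by_population[k] for k in labels])
    y = np.array([covariate[k] for k in labels])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
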