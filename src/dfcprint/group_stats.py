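"""Group-level DFC analyses: mass-univariate contrasts, blueprints, symmetry.

A cohort is a table of subject metadata (age, sex, clinical group) plus a
profile matrix per frequency band (subjects x DFC coefficients).  The
analyses here are:

* mass two-sample t-tests over all coefficients with Bonferroni control,
  optionally averaged over age-matched Monte-Carlo subsets of the cohort;
* population-average ("blueprint") profiles from repeated age/sex-matched
  resamples;
* hemispheric mirror-symmetry correlations of any coefficient vector;
* percentile tail subsets of a vector and the incidence of scalp regions
  in such a subset;
* case-control comparison restricted to coefficients insensitive to the
  sex contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InsufficientDataError
from .parcellation import Parcellation

#: Default contrast direction per factor: delta = mean(first) - mean(second).
DEFAULT_LEVELS = {"sex": ("F", "M"), "group": ("HC", "PD")}


@dataclass
class ProfileCohort:
    """Subject metadata plus per-band baseline profile matrices."""

    meta: pd.DataFrame  # columns: id, age, sex, group (group optional)
    profiles: dict[str, np.ndarray]  # band -> (n_subjects, n_coefficients)

    def __post_init__(self):
        n = len(self.meta)
        for band, mat in self.profiles.items():
            if mat.shape[0] != n:
                raise AlignmentError(f"band {band}: {mat.shape[0]} rows for {n} subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.meta)


@dataclass
class DifferenceProfile:
    """Per-coefficient group contrast (delta = level1 mean - level2 mean)."""

    delta: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    threshold: float
    levels: tuple[str, str]
    n_significant: int
    n_significant_matched: float | None = None  # mean over matched subsets
    coefficient_indices: np.ndarray | None = None  # when restricted to a mask


@dataclass
class BlueprintProfile:
    mean: np.ndarray
    n_resamples: int
    band: str = ""


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-test significance level controlling the family-wise error rate."""
    if not (0 < alpha < 1) or m < 1:
        raise ValueError("need 0 < alpha < 1 and m >= 1")
    return alpha / m


# ----------------------------------------------------------------------
def age_matched_subsets(meta: pd.DataFrame, factor: str, n_repeats: int = 500,
                        seed: int | None = None, bin_width: float = 5.0) -> list[np.ndarray]:
    """Random subject subsets with the factor's levels count-matched per age bin.

    Ages are binned in ``bin_width``-year bins; within each bin the larger
    level is randomly down-sampled to the smaller level's count.  Bins where
    one level is absent are dropped with a warning.  Returns positional
    index arrays into ``meta``.
    """
    levels = DEFAULT_LEVELS.get(factor) or tuple(sorted(meta[factor].unique()))
    if len(set(meta[factor]) & set(levels)) < 2:
        raise InsufficientDataError(f"both levels of {factor} must be present")
    rng = np.random.default_rng(seed)
    bins = np.floor(meta["age"].to_numpy() / bin_width).astype(int)
    fac = meta[factor].to_numpy()
    subsets = []
    warned = set()
    for _ in range(n_repeats):
        keep: list[np.ndarray] = []
        for b in np.unique(bins):
            idx0 = np.nonzero((bins == b) & (fac == levels[0]))[0]
            idx1 = np.nonzero((bins == b) & (fac == levels[1]))[0]
            if min(idx0.size, idx1.size) == 0:
                if max(idx0.size, idx1.size) > 0 and b not in warned:
                    warnings.warn(f"age bin {b * bin_width:g}-{(b + 1) * bin_width:g}: "
                                  f"one {factor} level empty, bin dropped",
                                  stacklevel=2)
                    warned.add(b)
                continue
            k = min(idx0.size, idx1.size)
            keep.append(rng.choice(idx0, size=k, replace=False))
            keep.append(rng.choice(idx1, size=k, replace=False))
        if not keep:
            raise InsufficientDataError("no age bin contains both levels")
        subsets.append(np.sort(np.concatenate(keep)))
    return subsets


def _welch_or_pooled(a: np.ndarray, b: np.ndarray, equal_var: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    # both-groups-constant coefficients: undefined t, report p = 1
    bad = ~np.isfinite(t)
    t = np.where(bad, 0.0, t)
    p = np.where(~np.isfinite(p), 1.0, p)
    return t, p, bad


def mass_ttest(profiles: np.ndarray, meta: pd.DataFrame, factor: str,
               matched_subsets: list[np.ndarray] | None = None,
               alpha: float = 0.05, n_comparisons: int | None = None,
               equal_var: bool = False,
               levels: tuple[str, str] | None = None) -> DifferenceProfile:
    """Per-coefficient two-sample t-test between the two levels of ``factor``.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled variant).  The Bonferroni threshold is ``alpha / n_comparisons``
    (``n_comparisons`` defaults to the number of coefficients tested).  When
    ``matched_subsets`` is given, the significant count is additionally
    averaged over those subsets; delta/t/p are always full-cohort.
    """
    X = np.asarray(profiles, dtype=np.float64)
    levels = levels or DEFAULT_LEVELS.get(factor) or tuple(sorted(meta[factor].unique()))
    fac = meta[factor].to_numpy()
    i0, i1 = np.nonzero(fac == levels[0])[0], np.nonzero(fac == levels[1])[0]
    if min(i0.size, i1.size) < 2:
        raise InsufficientDataError("need >= 2 subjects per level")
    m = n_comparisons or X.shape[1]
    thr = bonferroni_threshold(alpha, m)
    t, p, _ = _welch_or_pooled(X[i0], X[i1], equal_var)
    delta = X[i0].mean(axis=0) - X[i1].mean(axis=0)
    sig = p < thr
    n_matched = None
    if matched_subsets is not None:
        counts = []
        for sub in matched_subsets:
            f = fac[sub]
            a = X[sub][f == levels[0]]
            b = X[sub][f == levels[1]]
            _, ps, _ = _welch_or_pooled(a, b, equal_var)
            counts.append(int(np.sum(ps < thr)))
        n_matched = float(np.mean(counts))
    return DifferenceProfile(delta, t, p, sig, thr, levels, int(sig.sum()), n_matched)


# ----------------------------------------------------------------------
def blueprint(cohort: ProfileCohort, band: str, n_resamples: int = 500,
              seed: int | None = None, bin_width: float = 5.0) -> BlueprintProfile:
    """Population-average profile from age/sex-matched random resamples.

    ``n_resamples`` subsets are drawn with the sexes count-matched within
    each age bin; the per-subset mean profiles are averaged.
    """
    X = cohort.profiles[band]
    if "sex" in cohort.meta.columns and cohort.meta["sex"].nunique() > 1:
        subsets = age_matched_subsets(cohort.meta, "sex", n_resamples, seed, bin_width)
    else:  # nothing to match on: every resample is the full cohort
        subsets = [np.arange(cohort.n_subjects)] * n_resamples
    acc = np.zeros(X.shape[1])
    for sub in subsets:
        acc += X[sub].mean(axis=0)
    return BlueprintProfile(acc / len(subsets), n_resamples, band)


def mirror_correlation(profile_vector: np.ndarray, parcellation: Parcellation) -> float:
    """Pearson correlation between a coefficient vector and its mirror image."""
    v = np.asarray(profile_vector, dtype=np.float64)
    if v.std() == 0:
        warnings.warn("constant vector: mirror correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(v, parcellation.mirror(v))[0, 1])


def percentile_subsets(profile_vector: np.ndarray, low: float = 1.0,
                       high: float = 99.0) -> tuple[np.ndarray, np.ndarray]:
    """Indices in the bottom-``low``% and top-(100-``high``)% tails.

    Nearest-rank convention: the bottom set holds the smallest
    ``ceil(low * n / 100)`` values and the top set the largest
    ``ceil((100 - high) * n / 100)`` values; ties at the cut are included,
    so a constant vector degenerates to all indices (with a warning).
    """
    if not (0 < low < high < 100):
        raise ValueError("need 0 < low < high < 100")
    v = np.asarray(profile_vector, dtype=np.float64)
    n = v.size
    s = np.sort(v)
    k_low = int(np.ceil(low * n / 100.0))
    k_high = int(np.ceil((100.0 - high) * n / 100.0))
    thr_low, thr_high = s[k_low - 1], s[n - k_high]
    bottom = np.nonzero(v <= thr_low)[0]
    top = np.nonzero(v >= thr_high)[0]
    if bottom.size == n or top.size == n:
        warnings.warn("degenerate percentile subset covers the whole vector",
                      stacklevel=2)
    return bottom, top


def region_incidence(coefficient_subset: np.ndarray, parcellation: Parcellation) -> pd.DataFrame:
    """Per-region-name incidence in a coefficient subset, hemisphere-averaged.

    For each of the bilateral region names, counts how many subset
    coefficients involve that region (left and right occurrences averaged),
    split by 3-region vs 4-region coefficients.
    """
    idx = np.asarray(coefficient_subset, dtype=np.int64)
    n_names = len(parcellation.region_names)
    counts = np.zeros((2, 2 * n_names))  # rows: 3-region, 4-region
    for k in idx:
        ei, ej = parcellation.coef_edges[k]
        regions = set(parcellation.edge_regions[ei]) | set(parcellation.edge_regions[ej])
        row = 0 if parcellation.coef_n_regions[k] == 3 else 1
        for r in regions:
            counts[row, r] += 1
    averaged = (counts[:, :n_names] + counts[:, n_names:]) / 2.0
    return pd.DataFrame(
        {"three_region": averaged[0], "four_region": averaged[1]},
        index=list(parcellation.region_names),
    )


def category_contrast(blueprint_vector: np.ndarray, parcellation: Parcellation,
                      equal_var: bool = False) -> dict:
    """t contrasts of blueprint coefficients between taxonomy categories."""
    v = np.asarray(blueprint_vector, dtype=np.float64)
    three = v[parcellation.coef_n_regions == 3]
    four = v[parcellation.coef_n_regions == 4]
    uw = parcellation.coef_lateral_class == "uni_within"
    t34, p34 = stats.ttest_ind(three, four, equal_var=equal_var)
    tuw, puw = stats.ttest_ind(v[uw], v[~uw], equal_var=equal_var)
    return {
        "three_vs_four": {"t": float(t34), "p": float(p34),
                          "n": (three.size, four.size)},
        "uni_within_vs_rest": {"t": float(tuw), "p": float(puw),
                               "n": (int(uw.sum()), int((~uw).sum()))},
    }


def case_control_comparison(profiles: np.ndarray, meta: pd.DataFrame,
                            gender_p_values: np.ndarray, alpha: float = 0.05,
                            gender_alpha: float = 0.05,
                            equal_var: bool = False) -> DifferenceProfile:
    """Case-control t-tests restricted to sex-insensitive coefficients.

    Coefficients whose sex-contrast p-value exceeds ``gender_alpha`` form
    the tested set; the Bonferroni correction runs over that set's size
    only.  Delta is stored as healthy-minus-patient.
    """
    mask = np.asarray(gender_p_values) > gender_alpha
    m = int(mask.sum())
    if m == 0:
        raise InsufficientDataError("no sex-insensitive coefficients to test")
    sub = mass_ttest(np.asarray(profiles)[:, mask], meta, "group",
                     alpha=alpha, n_comparisons=m, equal_var=equal_var)
    sub.coefficient_indices = np.nonzero(mask)[0]
    return sub
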