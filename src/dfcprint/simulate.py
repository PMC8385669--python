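"""Synthetic cohorts with known ground truth, at three levels of realism.

The pipeline's statistics operate on objects that real data only provides
after heavy processing, so the generator produces each object directly:

* **profile level** -- DFC coefficient vectors drawn around a base profile
  with i.i.d. subject noise and optional planted group effects; the right
  input for mass-univariate and classifier suites, where effect size and
  noise must be exact.
* **edge level** -- per-epoch PLI edge time series drawn from a Gaussian
  copula with a prescribed edge-edge correlation matrix and Beta-distributed
  PLI-like marginals.  Each subject's target matrix is a shared blueprint
  plus a subject-specific deviation held (partially) stable across sessions,
  so fingerprinting has controllable ground truth.
* **channel level** -- narrowband oscillatory EEG whose regions
  intermittently phase-lock to the band's centre frequency, with lock
  states driven by latent factors mixed through a subject-specific loading
  matrix.  Locked region pairs hold their phase difference (high epoch
  PLI); detuned regions sweep it (low PLI), so the realized edge series
  inherit a subject-specific correlation structure and the *entire* chain
  (filter -> phase -> PLI -> region reduction -> DFC) can be exercised
  end to end.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import dfc_profile
from .errors import DimensionError, InsufficientDataError
from .group_stats import ProfileCohort
from .parcellation import Parcellation, build_parcellation
from .preprocessing import BANDS_BY_NAME, BandDefinition, RawRecording


# ----------------------------------------------------------------------
# profile level
# ----------------------------------------------------------------------
def simulate_profile_cohort(n_subjects: int, n_coefficients: int,
                            noise_sd: float = 0.05,
                            base_profile: np.ndarray | None = None,
                            effect_indices: np.ndarray | None = None,
                            effect_size: float = 0.0,
                            factor: str = "sex", levels: tuple[str, str] = ("F", "M"),
                            age_range: tuple[float, float] = (45.0, 85.0),
                            band: str = "alpha1",
                            seed: int | None = None) -> ProfileCohort:
    """Draw per-subject DFC profile vectors around a base profile.

    Subjects alternate between the two factor levels (balanced cohort);
    subjects of the *first* level receive ``effect_size`` added on the
    ``effect_indices`` coefficients.  Ages are uniform over ``age_range``.
    """
    rng = np.random.default_rng(seed)
    if base_profile is None:
        base_profile = np.zeros(n_coefficients)
    base_profile = np.asarray(base_profile, dtype=np.float64)
    if base_profile.size != n_coefficients:
        raise DimensionError("base profile length mismatch")
    X = base_profile + rng.normal(0.0, noise_sd, size=(n_subjects, n_coefficients))
    fac = np.array([levels[i % 2] for i in range(n_subjects)])
    if effect_indices is not None and effect_size != 0.0:
        X[np.ix_(fac == levels[0], np.asarray(effect_indices))] += effect_size
    meta = pd.DataFrame({
        "id": [f"S{i:03d}" for i in range(n_subjects)],
        "age": rng.uniform(*age_range, size=n_subjects),
        factor: fac,
    })
    if factor != "sex":
        meta["sex"] = np.array([("F", "M")[i % 2] for i in range(n_subjects)])
    return ProfileCohort(meta, {band: X})


# ----------------------------------------------------------------------
# edge level
# ----------------------------------------------------------------------
@dataclass
class FingerprintSpec:
    """Population/individual structure of the edge-level generator.

    ``base_correlation`` is the shared blueprint (unit-diagonal PSD matrix);
    ``subject_deviation_scale`` scales each subject's private deviation from
    it; ``session_stability`` is the correlation of that deviation between
    the two sessions; ``noise_scale`` mixes white latent noise into every
    epoch (attenuating all correlations toward 0); ``group_effect`` plants a
    mean shift on chosen coefficients for one factor level.
    """

    base_correlation: np.ndarray
    subject_deviation_scale: float = 0.2
    session_stability: float = 0.9
    noise_scale: float = 0.1
    group_effect: tuple[np.ndarray, float] | None = None
    effect_factor: str = "sex"
    beta_params: tuple[float, float] = (2.0, 5.0)


@dataclass
class SyntheticCohort:
    """Edge-level cohort: metadata, per-session profiles, and ground truth."""

    meta: pd.DataFrame
    edge_series: dict[tuple[int, int], np.ndarray]  # (subject, session) -> (E, N)
    profiles: dict[int, np.ndarray]  # session -> (n_subjects, n_coefficients)
    targets: dict[tuple[int, int], np.ndarray]  # ground-truth correlation matrices
    band: str = "alpha1"

    def profile_cohort(self, session: int = 0) -> ProfileCohort:
        return ProfileCohort(self.meta, {self.band: self.profiles[session]})


def default_blueprint(parcellation: Parcellation,
                      three_region_level: float = 0.35,
                      four_region_level: float = 0.10) -> np.ndarray:
    """Structured blueprint: edge pairs sharing a region correlate more.

    Mimics the empirical regularity that 3-region DFC coefficients are
    stronger than 4-region ones; projected to the nearest valid correlation
    matrix.
    """
    E = parcellation.n_edges
    C = np.full((E, E), four_region_level)
    three = parcellation.coef_n_regions == 3
    i, j = parcellation.coef_edges[:, 0], parcellation.coef_edges[:, 1]
    C[i[three], j[three]] = three_region_level
    C[j[three], i[three]] = three_region_level
    np.fill_diagonal(C, 1.0)
    return nearest_correlation(C)


def nearest_correlation(C: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a valid (PSD, unit-diagonal) correlation."""
    from statsmodels.stats.correlation_tools import corr_clipped

    C = np.asarray(C, dtype=np.float64)
    C = (C + C.T) / 2
    np.fill_diagonal(C, 1.0)
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-10:
        C = corr_clipped(C, threshold=1e-6)
        np.fill_diagonal(C, 1.0)
    return C


def _copula_factor(C: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a correlation matrix, eigenvalue-clipped."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 1e-10, None)
        return V * np.sqrt(w)


def simulate_edge_dynamics(target_corr: np.ndarray, n_epochs: int,
                           seed: int | None = None,
                           noise_scale: float = 0.0,
                           beta_params: tuple[float, float] = (2.0, 5.0),
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Edge time series with a prescribed edge-edge correlation structure.

    Latent multivariate-normal epochs with correlation ``target_corr`` are
    mapped through the Gaussian copula to a Beta marginal on [0, 1] (a
    PLI-like distribution).  The rank correlation of the output converges to
    the target as ``n_epochs`` grows; the monotone transform attenuates the
    *linear* correlation slightly.  ``noise_scale`` nu replaces the latent
    with sqrt(1-nu^2) x + nu eps, scaling all correlations by (1 - nu^2).
    """
    C = np.asarray(target_corr, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DimensionError("target correlation must be square")
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-8:
        warnings.warn("target not PSD; projecting to nearest correlation matrix",
                      stacklevel=2)
        C = nearest_correlation(C)
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = _copula_factor(C)
    z = L @ rng.standard_normal((C.shape[0], n_epochs))
    if noise_scale > 0:
        z = np.sqrt(1 - noise_scale**2) * z + noise_scale * rng.standard_normal(z.shape)
    u = stats.norm.cdf(z)
    return stats.beta.ppf(u, *beta_params)


def simulate_cohort(spec: FingerprintSpec, n_subjects: int, n_sessions: int = 2,
                    n_epochs: int = 400, seed: int | None = None,
                    band: str = "alpha1",
                    age_range: tuple[float, float] = (45.0, 85.0)) -> SyntheticCohort:
    """Edge-level cohort with per-subject targets and per-session data.

    Each subject's deviation from the blueprint is a symmetric random
    matrix; sessions share a fraction ``session_stability`` of its variance
    (``dev = sqrt(rho) W_subject + sqrt(1-rho) W_session``), so the
    between-session correlation of deviations equals ``session_stability``.
    Group effects shift the target entries of first-level subjects; targets
    are clipped/projected back to valid correlation matrices (logged).
    """
    rng = np.random.default_rng(seed)
    C0 = np.asarray(spec.base_correlation)
    E = C0.shape[0]
    iu = np.triu_indices(E, k=1)
    rho = spec.session_stability
    if not (0 <= rho <= 1):
        raise ValueError("session_stability must lie in [0, 1]")
    fac = np.array([("F", "M")[i % 2] for i in range(n_subjects)])
    meta = pd.DataFrame({
        "id": [f"S{i:03d}" for i in range(n_subjects)],
        "age": rng.uniform(*age_range, size=n_subjects),
        "sex": fac if spec.effect_factor == "sex" else
               np.array([("F", "M")[i % 2] for i in range(n_subjects)]),
    })
    if spec.effect_factor == "group":
        meta["group"] = np.where(fac == "F", "PD", "HC")

    def _sym(v):
        M = np.zeros((E, E))
        M[iu] = v
        return M + M.T

    edge_series: dict[tuple[int, int], np.ndarray] = {}
    targets: dict[tuple[int, int], np.ndarray] = {}
    profiles: dict[int, list[np.ndarray]] = {s: [] for s in range(n_sessions)}
    clipped_any = False
    for i in range(n_subjects):
        w_subj = rng.standard_normal(iu[0].size)
        for s in range(n_sessions):
            w_sess = rng.standard_normal(iu[0].size)
            dev = np.sqrt(rho) * w_subj + np.sqrt(1 - rho) * w_sess
            C = C0 + spec.subject_deviation_scale * _sym(dev)
            if spec.group_effect is not None and fac[i] == "F":
                idx, shift = spec.group_effect
                flat = C[iu]
                flat[np.asarray(idx)] += shift
                C = _sym(flat)
            np.fill_diagonal(C, 1.0)
            if np.abs(C[iu]).max() > 1:
                clipped_any = True
                C = np.clip(C, -1.0, 1.0)
                np.fill_diagonal(C, 1.0)
            C = nearest_correlation(C)
            targets[(i, s)] = C
            values = simulate_edge_dynamics(C, n_epochs, rng=rng,
                                            noise_scale=spec.noise_scale,
                                            beta_params=spec.beta_params)
            edge_series[(i, s)] = values
            profiles[s].append(dfc_profile(values, band=band).vector)
    if clipped_any:
        warnings.warn("some target correlations clipped to [-1, 1]", stacklevel=2)
    return SyntheticCohort(meta, edge_series,
                           {s: np.stack(v) for s, v in profiles.items()},
                           targets, band)


# ----------------------------------------------------------------------
# channel level
# ----------------------------------------------------------------------
@dataclass
class SyntheticEEGCohort:
    """Channel-level cohort: raw recordings plus the montage that reads them."""

    meta: pd.DataFrame
    recordings: dict[tuple[int, int], RawRecording]
    electrode_regions: np.ndarray  # region index per channel
    parcellation: Parcellation
    band: str
    mixings: dict[int, np.ndarray] = field(default_factory=dict)


def simulate_eeg_recording(mixing: np.ndarray, duration: float,
                           sampling_rate: float, band: BandDefinition,
                           rng: np.random.Generator,
                           electrodes_per_region: int = 1,
                           dynamics_interval: float = 0.5,
                           detune_range: tuple[float, float] = (0.5, 0.9),
                           sensor_noise: float = 0.3) -> RawRecording:
    """One narrowband multichannel recording with latent-driven FC dynamics.

    Each region oscillates at the band centre frequency while "locked" and
    detunes by a fixed region-specific offset (a ``detune_range`` fraction
    of the band half-width, random sign) while "unlocked".  Lock states flip
    every ``dynamics_interval`` seconds according to the sign of the
    region's mixture of latent factors (``mixing`` is regions x factors).
    A pair of locked regions holds a constant phase difference across an
    analysis epoch (PLI near 1); a detuned region sweeps its phase
    difference through sign changes (PLI low).  Edges therefore fluctuate
    with the lock states, and edges whose regions share latent factors
    produce correlated time series -- a controllable DFC structure.
    Electrode signals are their region's oscillation plus independent
    sensor noise.
    """
    n_regions, n_factors = mixing.shape
    fc = (band.low + band.high) / 2.0
    half_bw = (band.high - band.low) / 2.0
    n = int(round(duration * sampling_rate))
    spi = max(int(round(dynamics_interval * sampling_rate)), 1)
    n_int = int(np.ceil(n / spi))
    z = rng.standard_normal((n_factors, n_int))
    unlocked = (mixing @ z) > 0  # (regions, intervals)
    detune = rng.uniform(detune_range[0] * half_bw, detune_range[1] * half_bw,
                         size=n_regions) * rng.choice([-1.0, 1.0], size=n_regions)
    freq = fc + np.repeat(unlocked * detune[:, None], spi, axis=1)[:, :n]
    phase0 = rng.uniform(0, 2 * np.pi, size=(n_regions, 1))
    theta = phase0 + 2 * np.pi * np.cumsum(freq, axis=1) / sampling_rate
    region_sig = np.cos(theta)
    data = np.repeat(region_sig, electrodes_per_region, axis=0)
    data = data + sensor_noise * rng.standard_normal(data.shape)
    names = [f"E{r}_{k}" for r in range(n_regions) for k in range(electrodes_per_region)]
    return RawRecording(data, sampling_rate, names)


def simulate_eeg_cohort(n_subjects: int, parcellation: Parcellation | None = None,
                        duration: float = 120.0, sampling_rate: float = 250.0,
                        band: str = "beta", n_sessions: int = 2,
                        electrodes_per_region: int = 1, n_factors: int = 6,
                        subject_weight: float = 0.85,
                        seed: int | None = None, **recording_kwargs) -> SyntheticEEGCohort:
    """Channel-level cohort with subject-specific, session-stable dynamics.

    Each subject's latent mixing matrix is ``sqrt(1-w) M_common +
    sqrt(w) M_subject`` with ``w = subject_weight``: the common part gives
    the cohort a shared blueprint, the private part a stable fingerprint
    reused across sessions.
    """
    if duration < 3 * 0.25:
        raise InsufficientDataError("duration must allow at least 3 epochs")
    parcellation = parcellation or build_parcellation()
    rng = np.random.default_rng(seed)
    bd = BANDS_BY_NAME[band]
    R = parcellation.n_regions
    M_common = rng.standard_normal((R, n_factors))
    meta = pd.DataFrame({
        "id": [f"S{i:03d}" for i in range(n_subjects)],
        "age": rng.uniform(45, 85, size=n_subjects),
        "sex": [("F", "M")[i % 2] for i in range(n_subjects)],
    })
    recs: dict[tuple[int, int], RawRecording] = {}
    mixings: dict[int, np.ndarray] = {}
    w = subject_weight
    for i in range(n_subjects):
        M_i = np.sqrt(1 - w) * M_common + np.sqrt(w) * rng.standard_normal((R, n_factors))
        M_i /= np.linalg.norm(M_i, axis=1, keepdims=True)  # unit row power
        mixings[i] = M_i
        for s in range(n_sessions):
            recs[(i, s)] = simulate_eeg_recording(
                M_i, duration, sampling_rate, bd, rng,
                electrodes_per_region=electrodes_per_region, **recording_kwargs)
    electrode_regions = np.repeat(np.arange(R), electrodes_per_region)
    return SyntheticEEGCohort(meta, recs, electrode_regions, parcellation, band, mixings)
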