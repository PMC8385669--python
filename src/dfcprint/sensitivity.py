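"""Epoch-length and recording-duration sensitivity of DFC estimates.

Both sweeps re-run the pipeline downstream of the instantaneous-phase
stage, which is computed once per recording and cached: epoch length only
changes how the phase series is cut, and shorter recording durations are
simulated by truncating the phase series to its first minutes.  Test-retest
reliability is quantified per DFC coefficient as the absolute difference
between the two sessions' values, averaged over subjects (with an RMSE
variant).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .connectivity import (DFCProfile, dfc_profile, edge_series_from_epochs,
                           epoch_connectivity, reduce_to_regions)
from .errors import AlignmentError
from .fingerprint import ProfileDatabase, identify
from .parcellation import Parcellation
from .preprocessing import PhaseSeries, RawRecording, bandpass, hilbert_phase, segment_epochs
from .simulate import SyntheticEEGCohort


def profile_from_phase(phase: PhaseSeries, electrode_regions: np.ndarray,
                       parcellation: Parcellation, epoch_length: float = 0.25,
                       max_samples: int | None = None) -> DFCProfile:
    """Phase series -> epoch PLI -> region edges -> DFC profile."""
    if max_samples is not None and max_samples < phase.n_samples:
        phase = PhaseSeries(phase.phases[:, :max_samples], phase.sampling_rate,
                            phase.band, phase.channel_names)
    epoched = segment_epochs(phase, epoch_length)
    fc = epoch_connectivity(epoched)
    region_fc = reduce_to_regions(fc, electrode_regions, parcellation.n_regions)
    series = edge_series_from_epochs(region_fc, parcellation)
    return dfc_profile(series, band=phase.band.name)


def compute_phases(cohort: SyntheticEEGCohort) -> dict[tuple[int, int], PhaseSeries]:
    """Filter + Hilbert phase for every recording of a cohort (cached input to sweeps)."""
    from .preprocessing import BANDS_BY_NAME

    band = BANDS_BY_NAME[cohort.band]
    return {key: hilbert_phase(bandpass(rec, band), band)
            for key, rec in cohort.recordings.items()}


def test_retest_error(profiles_session1: np.ndarray,
                      profiles_session2: np.ndarray) -> dict:
    """Per-coefficient reliability between two sessions of the same subjects.

    ``mean_abs[k]`` is |session1 - session2| of coefficient k averaged over
    subjects (the primary definition); ``rmse`` is the root-mean-square
    variant.
    """
    a = np.asarray(profiles_session1, dtype=np.float64)
    b = np.asarray(profiles_session2, dtype=np.float64)
    if a.shape != b.shape:
        raise AlignmentError("both sessions must cover the same subjects/coefficients")
    d = np.abs(a - b)
    return {
        "mean_abs": d.mean(axis=0),
        "rmse": np.sqrt((d ** 2).mean(axis=0)),
        "median_mean_abs": float(np.median(d.mean(axis=0))),
    }


def _session_profiles(phases: dict[tuple[int, int], PhaseSeries],
                      cohort: SyntheticEEGCohort, epoch_length: float,
                      max_samples: int | None = None) -> dict[int, np.ndarray]:
    subjects = sorted({k[0] for k in phases})
    sessions = sorted({k[1] for k in phases})
    out = {}
    for s in sessions:
        out[s] = np.stack([
            profile_from_phase(phases[(i, s)], cohort.electrode_regions,
                               cohort.parcellation, epoch_length, max_samples).vector
            for i in subjects
        ])
    return out


def epoch_length_sweep(cohort: SyntheticEEGCohort,
                       lengths: tuple[float, ...] = (0.25, 0.5, 1, 2, 4, 8, 16, 32),
                       phases: dict[tuple[int, int], PhaseSeries] | None = None,
                       downstream: tuple[str, ...] = ("identify",),
                       classify_repeats: int = 20, seed: int | None = None) -> pd.DataFrame:
    """Re-run the downstream analyses for each analysis epoch length.

    ``downstream`` may include ``"identify"`` (cross-session identification
    rates) and ``"classify"`` (Monte-Carlo lasso classification of the
    cohort's sex labels on session-1 profiles; the same split seed is used
    at every setting so settings are paired).  Settings yielding fewer than
    3 epochs are skipped with a warning.  Test-retest error is always
    reported.
    """
    phases = phases or compute_phases(cohort)
    duration = next(iter(phases.values())).duration
    rows = []
    ids = [f"S{i}" for i in sorted({k[0] for k in phases})]
    for L in lengths:
        n_epochs = int(duration // L)
        if n_epochs < 3:
            warnings.warn(f"epoch length {L}s yields {n_epochs} epochs; skipped",
                          stacklevel=2)
            continue
        prof = _session_profiles(phases, cohort, L)
        err = test_retest_error(prof[0], prof[1])
        row = {"epoch_length": L, "n_epochs": n_epochs,
               "median_test_retest": err["median_mean_abs"]}
        if "identify" in downstream:
            res = identify(ProfileDatabase(ids, prof[0], "1"),
                           ProfileDatabase(ids, prof[1], "2"))
            row.update(rate_dir1=res.rate_dir1, rate_dir2=res.rate_dir2,
                       rate_mean=res.rate_mean)
        if "classify" in downstream:
            from .classify import monte_carlo_cv

            run = monte_carlo_cv(prof[0], cohort.meta, n_repeats=classify_repeats,
                                 seed=seed, age_match=False, internal_cv=3)
            row["median_auc"] = run.median_auc
        rows.append(row)
    return pd.DataFrame(rows)


def duration_sweep(cohort: SyntheticEEGCohort,
                   minutes: tuple[float, ...] = tuple(range(1, 11)),
                   epoch_length: float = 0.25,
                   phases: dict[tuple[int, int], PhaseSeries] | None = None) -> pd.DataFrame:
    """Truncate recordings to their first N minutes and re-run DFC.

    Settings longer than the recording are skipped.  Returns per-setting
    epoch counts, identification rates and median test-retest error.
    """
    phases = phases or compute_phases(cohort)
    first = next(iter(phases.values()))
    fs, duration = first.sampling_rate, first.duration
    rows = []
    ids = [f"S{i}" for i in sorted({k[0] for k in phases})]
    for m in minutes:
        seconds = m * 60.0
        if seconds > duration + 1e-9:
            warnings.warn(f"{m} min exceeds the {duration:.0f}s recording; skipped",
                          stacklevel=2)
            continue
        max_samples = int(round(seconds * fs))
        prof = _session_profiles(phases, cohort, epoch_length, max_samples)
        res = identify(ProfileDatabase(ids, prof[0], "1"),
                       ProfileDatabase(ids, prof[1], "2"))
        err = test_retest_error(prof[0], prof[1])
        rows.append({"minutes": m, "n_epochs": int(seconds // epoch_length),
                     "rate_mean": res.rate_mean,
                     "median_test_retest": err["median_mean_abs"]})
    return pd.DataFrame(rows)
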