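"""Subject identification ("fingerprinting") from DFC profiles.

Two sessions of a cohort give two databases of profile vectors.  Similarity
between a session-1 and a session-2 profile is their Pearson correlation;
each profile in one database is assigned the identity of the most similar
profile in the other.  Identification accuracy is the fraction of subjects
matched to themselves, computed in both directions and averaged.  Chance
level is assessed by permuting identities in one database many times.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class ProfileDatabase:
    """One profile vector per subject for a single session."""

    subject_ids: list[str]
    vectors: np.ndarray  # (n_subjects, n_features)
    session: str = ""

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or len(self.subject_ids) != self.vectors.shape[0]:
            raise AlignmentError("one vector per subject required")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise AlignmentError("duplicate subject ids")

    @property
    def n_subjects(self) -> int:
        return self.vectors.shape[0]


@dataclass
class IdentificationResult:
    similarity: np.ndarray  # (n, n): session1 rows x session2 columns
    predicted_dir1: np.ndarray  # argmax over session2 for each session1 profile
    predicted_dir2: np.ndarray
    correct_dir1: np.ndarray
    correct_dir2: np.ndarray
    rate_dir1: float
    rate_dir2: float
    rate_mean: float
    subject_ids: list[str] = field(default_factory=list)


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``.

    Degenerate (zero-variance) rows get similarity 0 against everything.
    """
    def _standardize(x):
        xc = x - x.mean(axis=1, keepdims=True)
        sd = xc.std(axis=1, keepdims=True)
        bad = sd[:, 0] == 0
        sd[bad] = 1.0
        return xc / sd, bad

    za, bad_a = _standardize(a)
    zb, bad_b = _standardize(b)
    if bad_a.any() or bad_b.any():
        warnings.warn("constant profile vector; its similarities set to 0",
                      RuntimeWarning, stacklevel=2)
    sim = za @ zb.T / a.shape[1]
    sim[bad_a, :] = 0.0
    sim[:, bad_b] = 0.0
    return sim


def similarity_matrix(db1: ProfileDatabase, db2: ProfileDatabase) -> np.ndarray:
    """(i, j) = correlation of subject i's session-1 with subject j's session-2."""
    if db1.subject_ids != db2.subject_ids:
        raise AlignmentError("databases must hold the same subjects in the same order")
    if db1.vectors.shape[1] != db2.vectors.shape[1]:
        raise AlignmentError("profile vector lengths differ between sessions")
    return _row_correlations(db1.vectors, db2.vectors)


def identify(db1: ProfileDatabase, db2: ProfileDatabase) -> IdentificationResult:
    """Argmax-similarity identification, both directions, mean rate reported.

    Exact similarity ties are broken toward the lowest subject index (and
    logged); this keeps the assignment deterministic.
    """
    sim = similarity_matrix(db1, db2)
    n = sim.shape[0]
    pred1 = np.argmax(sim, axis=1)  # for each session-1 profile
    pred2 = np.argmax(sim, axis=0)  # for each session-2 profile
    for axis, pred in ((1, pred1), (0, pred2)):
        m = np.max(sim, axis=axis)
        ties = (sim == (m[:, None] if axis == 1 else m[None, :])).sum(axis=axis)
        if np.any(ties > 1):
            logger.info("similarity ties broken toward lowest index for %d profiles",
                        int(np.sum(ties > 1)))
    truth = np.arange(n)
    c1 = pred1 == truth
    c2 = pred2 == truth
    r1, r2 = float(c1.mean()), float(c2.mean())
    return IdentificationResult(sim, pred1, pred2, c1, c2, r1, r2, (r1 + r2) / 2,
                                list(db1.subject_ids))


def permutation_test(db1: ProfileDatabase, db2: ProfileDatabase,
                     n_perm: int = 10_000, seed: int | None = None,
                     observed_rate: float | None = None) -> dict:
    """Identification-rate null distribution under identity relabelling.

    Identities in the second database are permuted uniformly at random
    ``n_perm`` times; the (direction-averaged) rate is recomputed for each.
    Returns the null rates, their max and mean, and an empirical p-value for
    ``observed_rate`` (the cohort's own rate by default).
    """
    if db1.n_subjects < 2:
        raise InsufficientDataError("permutation test needs >= 2 subjects")
    res = identify(db1, db2)
    if observed_rate is None:
        observed_rate = res.rate_mean
    rng = np.random.default_rng(seed)
    n = db1.n_subjects
    rates = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        # relabelling db2 by perm: session-1 profile i is correct iff its
        # argmax column j carries label perm[j] == i, i.e. pred1[i] maps back
        r1 = np.mean(perm[res.predicted_dir1] == np.arange(n))
        r2 = np.mean(res.predicted_dir2 == perm)
        rates[k] = (r1 + r2) / 2
    p = float((np.sum(rates >= observed_rate) + 1) / (n_perm + 1))
    return {
        "null_rates": rates,
        "null_max": float(rates.max()),
        "null_mean": float(rates.mean()),
        "observed_rate": float(observed_rate),
        "p_value": p,
    }


def within_between_correlations(db1: ProfileDatabase, db2: ProfileDatabase) -> dict:
    """Within-subject (diagonal) and between-subject (off-diagonal) similarities."""
    sim = similarity_matrix(db1, db2)
    n = sim.shape[0]
    mask = ~np.eye(n, dtype=bool)
    within = np.diag(sim).copy()
    between = sim[mask]
    return {
        "within": within,
        "between": between,
        "within_mean": float(within.mean()),
        "between_mean": float(between.mean()),
    }
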