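"""Per-epoch phase-lag-index connectivity and DFC profile construction.

The phase-lag index (PLI) of two phase series measures the asymmetry of
their phase-difference distribution,

    PLI = | (1/T) * sum_t sign( sin(phi_a(t) - phi_b(t)) ) |,

and lies in [0, 1]; it is blind to zero-lag (volume-conduction) coupling
because sign(sin 0) = 0.  Computing PLI on every short epoch of a recording
yields, after averaging electrode pairs into region pairs, a
(n_edges x N) matrix of edge time series.  The Pearson correlation between
every pair of edge rows is the dynamic-functional-connectivity (DFC)
matrix; its vectorized upper triangle is the subject's per-band DFC
profile (26,565 values for 22 regions), and the five band profiles
concatenate to a 132,825-long fingerprint vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DimensionError, InsufficientDataError, MontageError
from .parcellation import Parcellation
from .preprocessing import BAND_ORDER, EpochedPhase

__all__ = [
    "pli_epoch", "epoch_connectivity", "reduce_to_regions", "edge_series_from_epochs",
    "dfc_profile", "concatenate_bands", "EdgeSeries", "DFCProfile", "MultibandProfile",
]


def pli_epoch(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase-lag index of one epoch; ``sign(0)`` contributes nothing."""
    a = np.asarray(phase_a, dtype=np.float64)
    b = np.asarray(phase_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise DimensionError("phase series must be equal-length 1-D arrays")
    return float(np.abs(np.mean(np.sign(np.sin(a - b)))))


def epoch_connectivity(epoched: EpochedPhase) -> np.ndarray:
    """All-pairs PLI per epoch: (n_epochs, n_channels, n_channels).

    Matrices are symmetric with a zero diagonal (self-connectivity is
    undefined and stored as 0).
    """
    ph = epoched.phases
    n_epochs, n_ch, _ = ph.shape
    if n_ch < 2:
        raise InsufficientDataError("need at least 2 channels for connectivity")
    out = np.empty((n_epochs, n_ch, n_ch))
    for e in range(n_epochs):
        d = ph[e, :, None, :] - ph[e, None, :, :]
        m = np.mean(np.sign(np.sin(d)), axis=-1)
        pli = np.abs(m)
        np.fill_diagonal(pli, 0.0)
        out[e] = pli
    return out


def reduce_to_regions(epoch_fc: np.ndarray, electrode_regions: np.ndarray,
                      n_regions: int) -> np.ndarray:
    """Average electrode-level PLI into region-level PLI.

    Parameters
    ----------
    epoch_fc
        (..., n_electrodes, n_electrodes) PLI matrices.
    electrode_regions
        Region index (0..n_regions-1) per electrode.
    n_regions
        Number of regions in the parcellation.

    Entry (A, B), A != B, is the unweighted mean PLI over all electrode
    pairs (a in A, b in B); the diagonal is 0.
    """
    reg = np.asarray(electrode_regions)
    fc = np.asarray(epoch_fc, dtype=np.float64)
    if reg.ndim != 1 or fc.shape[-1] != reg.size or fc.shape[-2] != reg.size:
        raise MontageError("one region assignment per electrode required")
    if reg.min() < 0 or reg.max() >= n_regions:
        raise MontageError("electrode mapped outside the parcellation")
    counts = np.bincount(reg, minlength=n_regions)
    if np.any(counts == 0):
        empty = np.nonzero(counts == 0)[0]
        raise MontageError(f"regions with no electrode: {empty.tolist()}")
    # Membership matrix M (n_regions x n_electrodes); block sums via M fc M^T.
    M = np.zeros((n_regions, reg.size))
    M[reg, np.arange(reg.size)] = 1.0
    sums = np.einsum("re,...ef,sf->...rs", M, fc, M)
    pair_counts = np.outer(counts, counts).astype(float)
    out = sums / pair_counts
    idx = np.arange(n_regions)
    out[..., idx, idx] = 0.0
    return out


def edge_series_from_epochs(region_fc: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Stack per-epoch region matrices into the canonical (n_edges, N) matrix."""
    fc = np.asarray(region_fc)
    if fc.ndim != 3 or fc.shape[1] != parcellation.n_regions:
        raise DimensionError("expected (n_epochs, n_regions, n_regions) matrices")
    a, b = parcellation.edge_regions[:, 0], parcellation.edge_regions[:, 1]
    return fc[:, a, b].T.copy()


@dataclass
class EdgeSeries:
    """Per-epoch PLI for every edge: ``values`` is (n_edges, N) in [0, 1]."""

    values: np.ndarray
    band: str
    subject: str = ""
    session: str = ""

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.values.shape[1]


@dataclass
class DFCProfile:
    """Edge-edge correlation matrix and its vectorized upper triangle."""

    matrix: np.ndarray  # (n_edges, n_edges), symmetric, unit diagonal
    vector: np.ndarray  # row-major upper triangle
    band: str
    subject: str = ""
    session: str = ""
    n_epochs: int = 0


@dataclass
class MultibandProfile:
    """Five per-band profiles and their concatenated fingerprint vector."""

    profiles: dict[str, DFCProfile]
    vector: np.ndarray
    subject: str = ""
    session: str = ""


def dfc_profile(edge_series: EdgeSeries | np.ndarray, band: str = "",
                subject: str = "", session: str = "") -> DFCProfile:
    """Pearson-correlate all pairs of edge time series.

    Rows with zero variance have undefined correlations; those entries are
    stored as 0 (diagonal stays 1) and a warning names the edges.  Requires
    N >= 3 epochs.
    """
    if isinstance(edge_series, EdgeSeries):
        values, band = edge_series.values, edge_series.band or band
        subject = edge_series.subject or subject
        session = edge_series.session or session
    else:
        values = np.asarray(edge_series, dtype=np.float64)
    if values.ndim != 2:
        raise DimensionError("edge series must be 2-D (edges x epochs)")
    n_edges, n_epochs = values.shape
    if n_epochs < 3:
        raise InsufficientDataError(f"need >= 3 epochs, got {n_epochs}")
    degenerate = np.nonzero(np.ptp(values, axis=1) == 0)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mat = np.corrcoef(values)
    if degenerate.size:
        warnings.warn(
            f"constant edge time-series (correlation undefined, stored as 0): "
            f"edges {degenerate.tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
        mat[degenerate, :] = 0.0
        mat[:, degenerate] = 0.0
    np.fill_diagonal(mat, 1.0)
    iu = np.triu_indices(n_edges, k=1)
    return DFCProfile(mat, mat[iu], band, subject, session, n_epochs)


def concatenate_bands(profiles: Sequence[DFCProfile] | Mapping[str, DFCProfile]) -> MultibandProfile:
    """Concatenate the five canonical band profiles in fixed band order."""
    if isinstance(profiles, Mapping):
        by_band = dict(profiles)
    else:
        by_band = {p.band: p for p in profiles}
        if len(by_band) != len(profiles):
            raise DimensionError("duplicate band in profile set")
    if set(by_band) != set(BAND_ORDER):
        raise DimensionError(
            f"expected bands {sorted(BAND_ORDER)}, got {sorted(by_band)}"
        )
    vec = np.concatenate([by_band[b].vector for b in BAND_ORDER])
    first = by_band[BAND_ORDER[0]]
    return MultibandProfile(by_band, vec, first.subject, first.session)
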