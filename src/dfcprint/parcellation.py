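"""Scalp parcellation, edge and DFC-coefficient index spaces, and the mirror map.

The analysis operates on a bilateral parcellation of the scalp into named
regions, 11 per hemisphere by default (22 regions total).  Functional
connections ("edges") are unordered region pairs; DFC coefficients are
unordered pairs of edges, i.e. entries of the edge-by-edge correlation
matrix.  Everything downstream indexes into the canonical enumerations
defined here, so the conventions are fixed once:

* regions: left-hemisphere block first, in the canonical name order, then
  the right-hemisphere block in the same name order;
* edges: row-major upper triangle (excluding the diagonal) of the
  ``n_regions x n_regions`` matrix;
* coefficients: row-major upper triangle of the ``n_edges x n_edges``
  matrix.

With 22 regions this yields 231 edges and 26,565 DFC coefficients per
frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, ParcellationError

#: Canonical region names, one per bilateral pair: fronto-polar, frontal-mid,
#: frontal-lateral, central-mid, central-lateral, temporal-anterior,
#: temporal-posterior, parietal-lateral, parietal-mid, parietal-occipital,
#: occipital.
CANONICAL_REGION_NAMES: tuple[str, ...] = (
    "FP", "FM", "FL", "CM", "CL", "TA", "TP", "PL", "PM", "PO", "OC",
)

#: DFC-coefficient lateralization categories.
LATERAL_CLASSES = ("uni_within", "uni_between", "bilat_uni", "bilat_bilat")


@dataclass(frozen=True)
class Region:
    name: str
    hemisphere: str  # "L" or "R"
    index: int

    @property
    def label(self) -> str:
        return f"{self.hemisphere}.{self.name}"


@dataclass(frozen=True)
class Edge:
    region_a: Region
    region_b: Region
    index: int
    laterality: str  # "LL", "RR" or "LR"

    @property
    def label(self) -> str:
        return f"{self.region_a.label}-{self.region_b.label}"


class Parcellation:
    """Bilateral region scheme with canonical edge/coefficient enumerations.

    Parameters
    ----------
    region_names
        Ordered distinct names, one per bilateral region pair.  The default
        is the canonical 11-name scheme.
    """

    def __init__(self, region_names: Sequence[str] = CANONICAL_REGION_NAMES):
        names = list(region_names)
        if len(set(names)) != len(names) or not names:
            raise ParcellationError("region names must be non-empty and distinct")
        self.region_names = tuple(names)
        n = len(names)
        self.n_regions = 2 * n
        self.regions: list[Region] = [
            Region(names[i % n], "L" if i < n else "R", i)
            for i in range(2 * n)
        ]

        # Edge enumeration: row-major upper triangle of the region matrix.
        iu = np.triu_indices(self.n_regions, k=1)
        self.edge_regions = np.stack(iu, axis=1)  # (n_edges, 2), a < b
        self.n_edges = self.edge_regions.shape[0]
        hemi = (np.arange(self.n_regions) >= n).astype(np.int8)  # 0=L, 1=R
        ha, hb = hemi[iu[0]], hemi[iu[1]]
        lat = np.where(ha == hb, np.where(ha == 0, "LL", "RR"), "LR")
        self.edge_laterality = lat.astype("U2")
        self.edges: list[Edge] = [
            Edge(self.regions[a], self.regions[b], e, self.edge_laterality[e])
            for e, (a, b) in enumerate(self.edge_regions)
        ]
        self._edge_index_lut = np.full((self.n_regions, self.n_regions), -1, dtype=np.int64)
        self._edge_index_lut[iu[0], iu[1]] = np.arange(self.n_edges)
        self._edge_index_lut[iu[1], iu[0]] = np.arange(self.n_edges)

        # Coefficient enumeration: upper triangle of the edge matrix.
        cu = np.triu_indices(self.n_edges, k=1)
        self.coef_edges = np.stack(cu, axis=1)  # (n_coefficients, 2)
        self.n_coefficients = self.coef_edges.shape[0]
        self._coef_index_lut = None  # built lazily; E x E int64 is ~427 KB at E=231

        a1 = self.edge_regions[cu[0], 0]
        b1 = self.edge_regions[cu[0], 1]
        a2 = self.edge_regions[cu[1], 0]
        b2 = self.edge_regions[cu[1], 1]
        shared = (
            (a1 == a2).astype(np.int8) + (a1 == b2) + (b1 == a2) + (b1 == b2)
        )
        self.coef_n_regions = (4 - shared).astype(np.int8)

        lat1 = self.edge_laterality[cu[0]]
        lat2 = self.edge_laterality[cu[1]]
        self.coef_lateral_class = np.empty(self.n_coefficients, dtype="U11")
        within = (lat1 == lat2) & (lat1 != "LR")
        between = (lat1 != lat2) & (lat1 != "LR") & (lat2 != "LR")
        one_cross = ((lat1 == "LR") ^ (lat2 == "LR"))
        both_cross = (lat1 == "LR") & (lat2 == "LR")
        self.coef_lateral_class[within] = "uni_within"
        self.coef_lateral_class[between] = "uni_between"
        self.coef_lateral_class[one_cross] = "bilat_uni"
        self.coef_lateral_class[both_cross] = "bilat_bilat"

        self.edge_mirror, self.coefficient_mirror = self._build_mirror()

    # ------------------------------------------------------------------
    def _build_mirror(self) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.region_names)
        region_mirror = (np.arange(self.n_regions) + n) % self.n_regions
        ma = region_mirror[self.edge_regions[:, 0]]
        mb = region_mirror[self.edge_regions[:, 1]]
        lo, hi = np.minimum(ma, mb), np.maximum(ma, mb)
        edge_mirror = self._edge_index_lut[lo, hi]
        if self.n_coefficients:
            ei = edge_mirror[self.coef_edges[:, 0]]
            ej = edge_mirror[self.coef_edges[:, 1]]
            lo, hi = np.minimum(ei, ej), np.maximum(ei, ej)
            coef_mirror = self.coef_index_lut[lo, hi]
        else:
            coef_mirror = np.empty(0, dtype=np.int64)
        return edge_mirror, coef_mirror

    @property
    def coef_index_lut(self) -> np.ndarray:
        if self._coef_index_lut is None:
            lut = np.full((self.n_edges, self.n_edges), -1, dtype=np.int64)
            cu = (self.coef_edges[:, 0], self.coef_edges[:, 1])
            lut[cu[0], cu[1]] = np.arange(self.n_coefficients)
            lut[cu[1], cu[0]] = np.arange(self.n_coefficients)
            self._coef_index_lut = lut
        return self._coef_index_lut

    # ------------------------------------------------------------------
    def edge_index(self, region_a: int, region_b: int) -> int:
        """Canonical edge index of the unordered region pair."""
        if region_a == region_b:
            raise ParcellationError("an edge joins two distinct regions")
        return int(self._edge_index_lut[region_a, region_b])

    def coefficient_index(self, edge_i: int, edge_j: int) -> int:
        """Canonical DFC-coefficient index of the unordered edge pair."""
        if edge_i == edge_j:
            raise ParcellationError("a DFC coefficient joins two distinct edges")
        return int(self.coef_index_lut[edge_i, edge_j])

    def classify_pair(self, edge_i: int, edge_j: int) -> tuple[int, str]:
        """Number of involved regions (3 or 4) and lateralization category."""
        k = self.coefficient_index(edge_i, edge_j)
        return int(self.coef_n_regions[k]), str(self.coef_lateral_class[k])

    def mirror(self, profile_vector: np.ndarray) -> np.ndarray:
        """Apply the hemispheric L<->R swap to a coefficient vector.

        The operation is an involution: ``mirror(mirror(x)) == x``.
        """
        v = np.asarray(profile_vector)
        if v.shape[-1] != self.n_coefficients:
            raise DimensionError(
                f"expected length-{self.n_coefficients} vector, got {v.shape[-1]}"
            )
        return v[..., self.coefficient_mirror]

    def mirror_edges(self, edge_vector: np.ndarray) -> np.ndarray:
        v = np.asarray(edge_vector)
        if v.shape[-1] != self.n_edges:
            raise DimensionError(f"expected length-{self.n_edges} vector")
        return v[..., self.edge_mirror]

    # ------------------------------------------------------------------
    def category_counts(self) -> dict[str, int]:
        """Sizes of the taxonomy categories."""
        out = {
            "edges": self.n_edges,
            "coefficients": self.n_coefficients,
            "three_region": int(np.sum(self.coef_n_regions == 3)),
            "four_region": int(np.sum(self.coef_n_regions == 4)),
        }
        for cls in LATERAL_CLASSES:
            out[cls] = int(np.sum(self.coef_lateral_class == cls))
        return out

    def taxonomy_frame(self) -> pd.DataFrame:
        """Per-coefficient taxonomy table (one row per DFC coefficient)."""
        labels = np.array([e.label for e in self.edges])
        return pd.DataFrame(
            {
                "coefficient_index": np.arange(self.n_coefficients),
                "edge_i": labels[self.coef_edges[:, 0]],
                "edge_j": labels[self.coef_edges[:, 1]],
                "n_regions": self.coef_n_regions,
                "lateral_class": self.coef_lateral_class,
            }
        )

    def to_dict(self) -> dict:
        return {"region_names": list(self.region_names)}

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256(",".join(self.region_names).encode()).hexdigest()[:16]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Parcellation({self.n_regions} regions, {self.n_edges} edges, "
            f"{self.n_coefficients} coefficients)"
        )


def build_parcellation(region_names: Sequence[str] = CANONICAL_REGION_NAMES) -> Parcellation:
    """Build the bilateral parcellation with canonical index spaces."""
    return Parcellation(region_names)
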