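"""Readers and writers: recordings, montages, profiles, tabular outputs.

Native recording storage is a flat little-endian float64 binary matrix plus
a JSON header (channel names, sampling rate, row-major order) — chosen for
cross-language readability.  Profiles are stored as compressed ``.npz``
containers with a JSON metadata sidecar.  EDF files can be read when the
optional ``mne`` dependency is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, MontageError
from .parcellation import Parcellation
from .preprocessing import RawRecording


@dataclass
class Montage:
    """Electrode -> region assignment over a parcellation."""

    assignments: dict[str, str]  # electrode name -> region label like "L.FP"
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.assignments) & set(self.excluded)
        if overlap:
            raise MontageError(f"electrodes both assigned and excluded: {sorted(overlap)}")

    def region_indices(self, parcellation: Parcellation,
                       channel_names: list[str]) -> np.ndarray:
        """Region index per channel, validating coverage of the parcellation."""
        label_to_idx = {r.label: r.index for r in parcellation.regions}
        idx = []
        unknown = []
        for ch in channel_names:
            if ch in self.excluded:
                raise MontageError(f"channel {ch} is on the exclusion list")
            lab = self.assignments.get(ch)
            if lab is None or lab not in label_to_idx:
                unknown.append(ch)
            else:
                idx.append(label_to_idx[lab])
        if unknown:
            raise MontageError(f"channels without a valid region: {unknown}")
        idx = np.asarray(idx, dtype=np.int64)
        missing = set(range(parcellation.n_regions)) - set(idx.tolist())
        if missing:
            labels = [parcellation.regions[r].label for r in sorted(missing)]
            raise MontageError(f"regions without electrodes: {labels}")
        return idx

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"assignments": self.assignments, "excluded": self.excluded}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        d = json.loads(Path(path).read_text())
        return cls(d["assignments"], d.get("excluded", []))


# ----------------------------------------------------------------------
def write_recording(prefix: str | Path, recording: RawRecording) -> None:
    """Write ``<prefix>.bin`` (float64 LE, row-major) and ``<prefix>.json``."""
    prefix = Path(prefix)
    data = np.ascontiguousarray(recording.data, dtype="<f8")
    data.tofile(prefix.with_suffix(".bin"))
    prefix.with_suffix(".json").write_text(json.dumps({
        "channel_names": recording.channel_names,
        "sampling_rate": recording.sampling_rate,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "dtype": "<f8",
        "order": "C",
    }, indent=1))


def read_recording(path: str | Path, fmt: str = "raw") -> RawRecording:
    """Read a recording; ``fmt`` is ``raw`` (native binary+JSON) or ``edf``."""
    path = Path(path)
    if fmt == "edf":
        return _read_edf(path)
    header_path = path.with_suffix(".json")
    if not header_path.exists():
        raise DimensionError(f"missing header {header_path} (sampling rate unknown)")
    hdr = json.loads(header_path.read_text())
    data = np.fromfile(path.with_suffix(".bin"), dtype=hdr.get("dtype", "<f8"))
    data = data.reshape(hdr["n_channels"], hdr["n_samples"])
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise DimensionError(f"non-finite sample at channel {bad[0]}, sample {bad[1]}")
    return RawRecording(data, hdr["sampling_rate"], hdr["channel_names"])


def _read_edf(path: Path) -> RawRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return RawRecording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                        list(raw.ch_names))


# ----------------------------------------------------------------------
def write_profile(prefix: str | Path, vector: np.ndarray, metadata: dict) -> None:
    """Write a profile vector (``.npz``) and its JSON metadata sidecar."""
    prefix = Path(prefix)
    np.savez_compressed(prefix.with_suffix(".npz"), vector=np.asarray(vector))
    prefix.with_suffix(".meta.json").write_text(json.dumps(metadata, indent=1, default=str))


def read_profile(prefix: str | Path) -> tuple[np.ndarray, dict]:
    prefix = Path(prefix)
    vec = np.load(prefix.with_suffix(".npz"))["vector"]
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    return vec, meta


def default_montage(parcellation: Parcellation, electrodes_per_region: int = 1) -> Montage:
    """Synthetic montage with ``electrodes_per_region`` channels per region."""
    assignments = {}
    for r in parcellation.regions:
        for k in range(electrodes_per_region):
            assignments[f"E{r.index}_{k}"] = r.label
    return Montage(assignments)
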