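"""Core containers for multichannel EEG: recordings, epoch sets, electrode pools.

Conventions
-----------
* ``Recording.data`` is ``(n_channels, n_samples)`` float64 in microvolts
  (microvolts per square metre after the surface-Laplacian stage).
* Channel positions are 3-D head-frame coordinates in metres, taken by
  default from the standard 10-20 layout shipped with MNE.
* A recording carries a ``stage`` tag so that the preprocessing operations
  can enforce their fixed order (raw -> filtered -> ocular_corrected -> csd).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "EpochSet",
    "POOLS",
    "POOL_COUPLINGS",
    "ANALYSIS_CHANNELS",
    "DEFAULT_CHANNELS",
    "default_positions",
    "write_brainvision",
    "read_recording",
]

STAGES = ("raw", "filtered", "ocular_corrected", "csd")

#: Electrode pools: three channels per scalp region, border electrodes excluded.
POOLS = {
    "FL": ("FC5", "F3", "FC1"),
    "FR": ("FC6", "F4", "FC2"),
    "PL": ("CP5", "P3", "CP1"),
    "PR": ("CP6", "P4", "CP2"),
}

#: The six region couplings analysed for spectral coherence.
POOL_COUPLINGS = (
    ("FL", "FR"),
    ("FL", "PL"),
    ("FL", "PR"),
    ("FR", "PR"),
    ("FR", "PL"),
    ("PL", "PR"),
)

ANALYSIS_CHANNELS = tuple(ch for pool in POOLS.values() for ch in pool)

#: Default acquisition montage (10-20 cap; superset of the analysis channels).
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)


def default_positions(channels=DEFAULT_CHANNELS):
    """Head-frame electrode positions (metres) from the standard 10-20 table.

    Returns an ``{label: (x, y, z)}`` dict.  Raises ``KeyError`` for labels
    absent from the standard layout.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    table = montage.get_positions()["ch_pos"]
    return {ch: np.asarray(table[ch], dtype=float) for ch in channels}


@dataclasses.dataclass
class Recording:
    """A multichannel EEG time series with montage and provenance tag."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channels: tuple
    positions: dict  # label -> (x, y, z) metres
    stage: str = "raw"
    units: str = "uV"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channels)} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        missing = [ch for ch in self.channels if ch not in self.positions]
        if missing:
            raise ValueError(f"positions missing for channels {missing}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def index(self, label: str) -> int:
        return self.channels.index(label)

    def copy(self, **replace) -> "Recording":
        new = dataclasses.replace(self, **replace)
        if "data" not in replace:
            new.data = self.data.copy()
        return new

    def to_mne_raw(self):
        """Convert to an MNE ``RawArray`` (volts) with montage attached."""
        import mne

        info = mne.create_info(list(self.channels), self.fs, "eeg")
        raw = mne.io.RawArray(self.data * 1e-6, info, verbose="ERROR")
        montage = mne.channels.make_dig_montage(
            ch_pos={ch: self.positions[ch] for ch in self.channels},
            coord_frame="head",
        )
        raw.set_montage(montage, verbose="ERROR")
        return raw


@dataclasses.dataclass
class EpochSet:
    """Fixed-length contiguous epochs with per-epoch accept/reject status."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_times)
    fs: float
    channels: tuple
    epoch_length: float
    accepted: np.ndarray  # bool per epoch
    rejection_reason: list  # "none" | "amplitude" | "peak_to_peak"
    stage: str = "csd"
    units: str = "uV/m^2"

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.channels = tuple(self.channels)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        n_ep = self.epochs.shape[0]
        if len(self.accepted) != n_ep or len(self.rejection_reason) != n_ep:
            raise ValueError("per-epoch metadata length mismatch")
        expected = int(round(self.epoch_length * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch sample count {self.epochs.shape[2]} != "
                f"epoch_length*fs = {expected}"
            )
        for acc, reason in zip(self.accepted, self.rejection_reason):
            if acc != (reason == "none"):
                raise ValueError("accepted flag inconsistent with reason")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    def accepted_data(self) -> np.ndarray:
        return self.epochs[self.accepted]


# ---------------------------------------------------------------------------
# File round-trip: BrainVision triplet writer, MNE-based readers.
# ---------------------------------------------------------------------------

def write_brainvision(rec: Recording, basename) -> Path:
    """Write a recording as a BrainVision triplet (.vhdr/.vmrk/.eeg).

    Data are stored as multiplexed IEEE float32 in microvolts.  Returns the
    path of the ``.vhdr`` header file.
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.fs:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.channels, start=1):
        header.append(f"Ch{i}={ch},,1,µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    marker = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    vmrk.write_text("\n".join(marker) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr


def read_recording(path, positions=None) -> Recording:
    """Read a BrainVision (.vhdr) or EDF (.edf) file into a raw Recording.

    ``positions`` overrides the built-in standard 10-20 coordinate table.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="ERROR")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")
    channels = tuple(raw.ch_names)
    if positions is None:
        positions = default_positions(channels)
    return Recording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channels=channels,
        positions=positions,
        stage="raw",
    )
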