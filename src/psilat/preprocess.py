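"""Referencing, filtering, downsampling and windowing of raw recordings.

Raw multi-channel intracranial EEG (native 2048 Hz in the default
geometry) is turned into referenced, band-passed, downsampled 16 s
windows:

* macro contacts (8 per depth electrode) -> 7 bipolar channels, each the
  difference of neighboring contacts ordered innermost to outermost;
* micro wires (8 recording wires per bundle) -> 8 channels referenced to
  the bundle mean;
* 4th-order Butterworth band-pass 0.5-40 Hz applied forward and backward
  (zero phase), then decimation 2048 -> 256 Hz by keeping every 8th
  sample (the 40 Hz edge already guards the 128 Hz post-decimation
  Nyquist);
* non-overlapping 16 s windows from the recording start, trailing
  remainder discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "SignalWindow",
    "FilterSpec",
    "Electrode",
    "ChannelMap",
    "ChannelMapError",
    "ArtifactMask",
    "bipolar_reference",
    "bundle_reference",
    "filter_downsample",
    "segment_windows",
    "apply_artifact_mask",
]

STAGES = ("W", "REM", "N1", "N2", "N3")
EXCLUDED = "EXCLUDED"


class ChannelMapError(ValueError):
    """Channel topology does not match the hybrid-electrode geometry."""


@dataclass
class Electrode:
    """One hybrid depth electrode.

    ``macro_contacts`` lists the raw channel ids of the 8 macro contacts
    ordered innermost to outermost; ``micro_wires`` lists the 8 recording
    wires of the tip bundle (the low-impedance reference wire is not
    data).  Electrode names end in their hemisphere letter (e.g. AHL /
    AHR), so contralateral homologues share the stripped label.
    """

    name: str
    hemisphere: str
    macro_contacts: list[str] = field(default_factory=list)
    micro_wires: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ChannelMapError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        if self.macro_contacts and len(self.macro_contacts) != 8:
            raise ChannelMapError(
                f"electrode {self.name}: expected 8 macro contacts, got {len(self.macro_contacts)}"
            )
        if self.micro_wires and len(self.micro_wires) != 8:
            raise ChannelMapError(
                f"electrode {self.name}: expected 8 micro wires, got {len(self.micro_wires)}"
            )

    @property
    def label(self) -> str:
        """Anatomical label without the hemisphere letter."""
        if self.name.endswith(self.hemisphere):
            return self.name[: -len(self.hemisphere)]
        return self.name


@dataclass
class ChannelMap:
    """Electrode topology of one implantation plus the ground-truth SOZ
    hemisphere used for validation."""

    electrodes: list[Electrode]
    soz_hemisphere: str

    def __post_init__(self) -> None:
        if self.soz_hemisphere not in ("L", "R"):
            raise ChannelMapError(f"soz_hemisphere must be 'L' or 'R', got {self.soz_hemisphere!r}")
        names = [e.name for e in self.electrodes]
        if len(names) != len(set(names)):
            raise ChannelMapError("duplicate electrode names in channel map")

    def raw_channel_ids(self) -> list[str]:
        ids: list[str] = []
        for e in self.electrodes:
            ids.extend(e.macro_contacts)
            ids.extend(e.micro_wires)
        return ids


@dataclass
class SignalWindow:
    """One referenced, filtered, downsampled channel segment."""

    samples: np.ndarray
    sample_rate: float
    window_index: int
    channel_id: str
    stage: str = EXCLUDED
    artifact: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass followed by integer decimation.

    Two passes (forward and backward) square the single-pass magnitude
    response, so the effective attenuation at frequency f is |H(f)|^2.
    """

    order: int = 4
    band: tuple[float, float] = (0.5, 40.0)
    fs_in: float = 2048.0
    fs_out: float = 256.0

    @property
    def decimation(self) -> int:
        ratio = self.fs_in / self.fs_out
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"input rate {self.fs_in} Hz is not an integer multiple of "
                f"output rate {self.fs_out} Hz"
            )
        return int(round(ratio))

    def sos(self) -> np.ndarray:
        return butter(self.order, self.band, btype="bandpass", fs=self.fs_in, output="sos")


def bipolar_reference(contacts: np.ndarray) -> np.ndarray:
    """Bipolar montage of one macro electrode.

    ``contacts`` is an (8, n) array ordered innermost to outermost;
    channel c of the (7, n) result is contact_c - contact_{c+1}.
    """
    contacts = np.asarray(contacts, dtype=np.float64)
    if contacts.ndim != 2 or contacts.shape[0] != 8:
        raise ChannelMapError(
            f"macro electrode must provide 8 aligned contacts, got shape {contacts.shape}"
        )
    return contacts[:-1] - contacts[1:]


def bundle_reference(wires: np.ndarray) -> np.ndarray:
    """Bundle-mean reference of one micro-wire bundle.

    ``wires`` is an (8, n) array of the high-impedance recording wires
    (the low-impedance acquisition reference wire is not data).  Each
    output is wire_w minus the mean over the 8 recording wires; the
    outputs sum to zero at every sample.
    """
    wires = np.asarray(wires, dtype=np.float64)
    if wires.ndim != 2 or wires.shape[0] != 8:
        raise ChannelMapError(
            f"micro bundle must provide 8 aligned recording wires, got shape {wires.shape}"
        )
    return wires - wires.mean(axis=0, keepdims=True)


def filter_downsample(signal: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase band-pass then keep every ``decimation``-th sample.

    Reflective padding of one settling length of the slow (high-pass)
    filter edge keeps start-up transients out of the first window; the
    default scipy pad is far too short for a 0.5 Hz edge.  Output length
    is ``len(signal) // decimation``.
    """
    if spec is None:
        spec = FilterSpec()
    x = np.asarray(signal, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    dec = spec.decimation
    settle = int(round(3.0 * spec.fs_in / spec.band[0]))
    y = sosfiltfilt(spec.sos(), x, padtype="even", padlen=min(x.size - 1, settle))
    return y[: (y.size // dec) * dec : dec]


def segment_windows(signal: np.ndarray, channel_id: str, sample_rate: float = 256.0,
                    window_seconds: float = 16.0) -> list[SignalWindow]:
    """Cut a referenced 256 Hz signal into non-overlapping 16 s windows.

    Windows are anchored at the recording start; the trailing remainder
    shorter than one window is discarded.
    """
    x = np.asarray(signal, dtype=np.float64)
    wlen = int(round(window_seconds * sample_rate))
    n_win = x.size // wlen
    return [
        SignalWindow(
            samples=x[w * wlen : (w + 1) * wlen],
            sample_rate=sample_rate,
            window_index=w,
            channel_id=channel_id,
        )
        for w in range(n_win)
    ]


@dataclass
class ArtifactMask:
    """Visual-inspection artifact exclusions.

    ``window_entries`` holds (channel_id, window_index) pairs;
    ``channel_entries`` holds channels discarded wholesale.
    """

    window_entries: set = field(default_factory=set)
    channel_entries: set = field(default_factory=set)


def apply_artifact_mask(windows: list[SignalWindow], mask: ArtifactMask | None,
                        known_channels: set[str] | None = None, logger=None) -> list[str]:
    """Flag masked windows/channels as artifacts (in place).

    Entries referring to unknown channels are ignored with a warning.
    Returns the list of ignored channel ids.
    """
    if mask is None:
        return []
    if known_channels is None:
        known_channels = {w.channel_id for w in windows}
    ignored = sorted(
        {c for c in mask.channel_entries if c not in known_channels}
        | {c for c, _ in mask.window_entries if c not in known_channels}
    )
    if ignored and logger is not None:
        logger.warning("artifact mask references unknown channels: %s", ", ".join(ignored))
    for w in windows:
        if w.channel_id in mask.channel_entries or (w.channel_id, w.window_index) in mask.window_entries:
            w.artifact = True
    return ignored
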