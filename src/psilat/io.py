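"""On-disk formats.

A night lives in a directory:

* ``signals/<raw_channel_id>.f32`` -- one little-endian 32-bit float
  vector per raw channel, with ``signals/channels.tsv`` as sidecar
  (columns ``channel_id  rate_hz  n_samples``);
* ``channel_map.yaml`` -- electrode topology and the ground-truth SOZ
  hemisphere;
* ``hypnogram.txt`` -- one 30 s-epoch label per line, optional
  ``start_offset=<seconds>`` header;
* ``mask.tsv`` -- artifact exclusions, two columns ``channel_id`` and
  ``window_index`` ('*' marks a whole channel).

European Data Format (EDF/EDF+) input is supported through ``mne`` when
that package is installed.
"""

from __future__ import annotations

import os

import numpy as np
import yaml

from psilat.preprocess import ArtifactMask, ChannelMap, Electrode

__all__ = [
    "write_signals", "read_signals", "read_edf_signals",
    "write_channel_map", "read_channel_map",
    "write_mask", "read_mask",
    "write_hypnogram", "write_night", "read_night",
]


def write_signals(directory, signals: dict, rate_hz: float) -> None:
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "channels.tsv"), "w") as fh:
        fh.write("channel_id\trate_hz\tn_samples\n")
        for cid, x in signals.items():
            arr = np.asarray(x, dtype="<f4")
            arr.tofile(os.path.join(directory, f"{cid}.f32"))
            fh.write(f"{cid}\t{rate_hz:g}\t{arr.size}\n")


def read_signals(directory) -> tuple[dict, float]:
    """Read a per-channel binary signal directory; returns (signals, rate)."""
    sidecar = os.path.join(directory, "channels.tsv")
    signals: dict[str, np.ndarray] = {}
    rates = set()
    with open(sidecar) as fh:
        header = fh.readline()
        if not header.startswith("channel_id"):
            raise ValueError(f"{sidecar}: malformed sidecar header")
        for line in fh:
            if not line.strip():
                continue
            cid, rate, n = line.rstrip("\n").split("\t")
            x = np.fromfile(os.path.join(directory, f"{cid}.f32"), dtype="<f4")
            if x.size != int(n):
                raise ValueError(f"{cid}: expected {n} samples, found {x.size}")
            signals[cid] = x.astype(np.float64)
            rates.add(float(rate))
    if len(rates) != 1:
        raise ValueError(f"{sidecar}: channels disagree on sampling rate: {sorted(rates)}")
    return signals, rates.pop()


def read_edf_signals(path) -> tuple[dict, float]:
    """Read all channels of an EDF/EDF+ file (requires ``mne``)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    return {name: data[i] for i, name in enumerate(raw.ch_names)}, float(raw.info["sfreq"])


def write_channel_map(path, cmap: ChannelMap) -> None:
    doc = {
        "soz_hemisphere": cmap.soz_hemisphere,
        "electrodes": [
            {"name": e.name, "hemisphere": e.hemisphere,
             "macro_contacts": list(e.macro_contacts), "micro_wires": list(e.micro_wires)}
            for e in cmap.electrodes
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_channel_map(path) -> ChannelMap:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    electrodes = [
        Electrode(name=e["name"], hemisphere=e["hemisphere"],
                  macro_contacts=list(e.get("macro_contacts", [])),
                  micro_wires=list(e.get("micro_wires", [])))
        for e in doc["electrodes"]
    ]
    return ChannelMap(electrodes=electrodes, soz_hemisphere=doc["soz_hemisphere"])


def write_mask(path, mask: ArtifactMask) -> None:
    with open(path, "w") as fh:
        fh.write("channel_id\twindow_index\n")
        for cid in sorted(mask.channel_entries):
            fh.write(f"{cid}\t*\n")
        for cid, w in sorted(mask.window_entries):
            fh.write(f"{cid}\t{w}\n")


def read_mask(path) -> ArtifactMask:
    mask = ArtifactMask()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("channel_id"):
            raise ValueError(f"{path}: malformed mask header")
        for line in fh:
            if not line.strip():
                continue
            cid, w = line.rstrip("\n").split("\t")
            if w == "*":
                mask.channel_entries.add(cid)
            else:
                mask.window_entries.add((cid, int(w)))
    return mask


def write_hypnogram(path, hypnogram) -> None:
    with open(path, "w") as fh:
        if hypnogram.start_offset:
            fh.write(f"start_offset={hypnogram.start_offset:g}\n")
        fh.write("\n".join(hypnogram.labels) + "\n")


def write_night(directory, night) -> None:
    """Persist a :class:`psilat.simulate.NightData` bundle (round-trips
    through :func:`read_night`)."""
    os.makedirs(directory, exist_ok=True)
    write_signals(os.path.join(directory, "signals"), night.signals, night.sample_rate)
    write_channel_map(os.path.join(directory, "channel_map.yaml"), night.channel_map)
    write_hypnogram(os.path.join(directory, "hypnogram.txt"), night.hypnogram)
    write_mask(os.path.join(directory, "mask.tsv"), night.mask)


def read_night(directory):
    """Load the pieces of a night directory.

    Returns (signals, rate, channel_map, hypnogram, mask)."""
    from psilat.hypnogram import load_hypnogram

    signals, rate = read_signals(os.path.join(directory, "signals"))
    cmap = read_channel_map(os.path.join(directory, "channel_map.yaml"))
    hyp = load_hypnogram(os.path.join(directory, "hypnogram.txt"))
    mask_path = os.path.join(directory, "mask.tsv")
    mask = read_mask(mask_path) if os.path.exists(mask_path) else ArtifactMask()
    return signals, rate, cmap, hyp, mask
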