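"""Hypnogram handling and window -> sleep-stage assignment.

Sleep is scored manually in 30 s epochs with AASM labels W, REM, N1, N2,
N3.  Analysis windows (16 s, anchored at recording start) interleave with
the 30 s epoch grid, so a window may overlap one or two epochs: it
inherits their common label, and is EXCLUDED when the overlapped epochs
disagree (a stage transition) or when any overlapped time is unscored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from psilat.preprocess import EXCLUDED, STAGES

__all__ = ["Hypnogram", "HypnogramParseError", "load_hypnogram", "assign_stage", "stage_census"]

UNKNOWN = "UNKNOWN"
_ALIASES = {"R": "REM"}
_VALID = set(STAGES) | {UNKNOWN}


class HypnogramParseError(ValueError):
    """Malformed hypnogram file."""


@dataclass
class Hypnogram:
    """Ordered 30 s epoch labels with an optional start offset (s)."""

    labels: list[str]
    epoch_seconds: float = 30.0
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        bad = [l for l in self.labels if l not in _VALID]
        if bad:
            raise ValueError(f"invalid stage labels: {sorted(set(bad))}")

    @property
    def duration(self) -> float:
        return len(self.labels) * self.epoch_seconds

    def label_at(self, epoch_index: int) -> str:
        if 0 <= epoch_index < len(self.labels):
            return self.labels[epoch_index]
        return UNKNOWN


def load_hypnogram(path) -> Hypnogram:
    """Read a plain-text hypnogram: one label per line, case-insensitive
    ('R' accepted for REM), optional ``start_offset=<seconds>`` header."""
    labels: list[str] = []
    offset = 0.0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().startswith("start_offset"):
                try:
                    offset = float(line.split("=", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise HypnogramParseError(
                        f"{path}:{lineno}: malformed start_offset line {line!r}"
                    ) from exc
                continue
            label = line.upper()
            label = _ALIASES.get(label, label)
            if label not in _VALID:
                raise HypnogramParseError(f"{path}:{lineno}: unknown stage label {line!r}")
            labels.append(label)
    if not labels:
        raise HypnogramParseError(f"{path}: no epoch labels found")
    return Hypnogram(labels=labels, start_offset=offset)


def assign_stage(window_index: int, window_seconds: float, hypnogram: Hypnogram) -> str:
    """Stage of one window, or EXCLUDED.

    The window covers ``[i*T, (i+1)*T)`` seconds from recording start.
    Every epoch with positive-measure overlap must carry the same known
    label; otherwise (transition, UNKNOWN, or uncovered time) the window
    is EXCLUDED.
    """
    t0 = window_index * window_seconds
    t1 = t0 + window_seconds
    ep = hypnogram.epoch_seconds
    if t0 < hypnogram.start_offset:
        return EXCLUDED
    rel0 = t0 - hypnogram.start_offset
    rel1 = t1 - hypnogram.start_offset
    e0 = int(rel0 // ep)
    # last epoch with positive-measure overlap; a window ending exactly on
    # an epoch boundary does not overlap the following epoch
    e1 = int(rel1 // ep)
    if rel1 - e1 * ep == 0.0:
        e1 -= 1
    labels = {hypnogram.label_at(e) for e in range(e0, e1 + 1)}
    if len(labels) == 1:
        label = labels.pop()
        if label in STAGES:
            return label
    return EXCLUDED


def stage_census(windows) -> dict[str, int]:
    """Window counts per stage plus Total; EXCLUDED reported separately.

    ``windows`` is an iterable of objects with ``stage`` and ``artifact``
    attributes (artifact windows count as EXCLUDED) or of plain stage
    labels.  Conservation: Total + EXCLUDED equals the number of windows.
    """
    counts = {s: 0 for s in STAGES}
    excluded = 0
    for w in windows:
        stage = getattr(w, "stage", w)
        artifact = getattr(w, "artifact", False)
        if artifact or stage not in counts:
            excluded += 1
        else:
            counts[stage] += 1
    counts["Total"] = sum(counts[s] for s in STAGES)
    counts[EXCLUDED] = excluded
    return counts
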