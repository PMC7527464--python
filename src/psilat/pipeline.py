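"""End-to-end orchestration: raw night -> windows -> psi profile -> report.

The psi profile is a long-format :class:`pandas.DataFrame` with one row
per (channel, window): columns channel_id, electrode, hemisphere,
modality, window_index, stage, s_original, s_surrogate, psi, excluded.
Windows are independent work units with no shared mutable state, so the
scoring loop can be chunked or distributed freely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from psilat.hypnogram import Hypnogram, assign_stage
from psilat.preprocess import (
    ArtifactMask,
    ChannelMap,
    EXCLUDED,
    FilterSpec,
    STAGES,
    bipolar_reference,
    bundle_reference,
    filter_downsample,
)
from psilat.score import EmbeddingParams, UnscorableWindowError, predictability_score
from psilat.surrogates import SurrogateConfig, iaaft_surrogate, window_seed_sequence

__all__ = ["DerivedChannel", "WindowedNight", "preprocess_night", "score_night",
           "subsample_channels", "run_synthetic_night", "lateralize", "infer_soz_side"]

logger = logging.getLogger(__name__)


@dataclass
class DerivedChannel:
    """One referenced, filtered, downsampled channel of a night."""

    channel_id: str
    electrode: str
    hemisphere: str
    modality: str
    windows: np.ndarray  # (n_windows, window_samples)
    artifact_channel: bool = False


@dataclass
class WindowedNight:
    """All derived channels of one night on a common window grid."""

    channels: list[DerivedChannel]
    stages: list[str]             # stage label per window index
    sample_rate: float
    window_seconds: float
    channel_map: ChannelMap
    artifact_windows: dict = field(default_factory=dict)  # channel_id -> set of window idx

    @property
    def n_windows(self) -> int:
        return len(self.stages)


def preprocess_night(signals: dict, channel_map: ChannelMap, hypnogram: Hypnogram,
                     mask: ArtifactMask | None = None, raw_rate: float = 2048.0,
                     spec: FilterSpec | None = None, window_seconds: float = 16.0) -> WindowedNight:
    """Reference, filter, downsample and window one night.

    ``signals`` maps raw channel ids to equal-length arrays at
    ``raw_rate``.  Macro electrodes yield 7 bipolar channels named
    ``<electrode>-b1..7`` (innermost difference first), micro bundles 8
    bundle-referenced channels ``<electrode>-w1..8``.  Stage labels come
    from the hypnogram; artifact-mask entries flag windows or whole
    channels.
    """
    if spec is None:
        spec = FilterSpec(fs_in=raw_rate)
    mask = mask or ArtifactMask()
    wlen = int(round(window_seconds * spec.fs_out))

    channels: list[DerivedChannel] = []
    for electrode in channel_map.electrodes:
        groups = []
        if electrode.macro_contacts:
            raw = np.stack([np.asarray(signals[c], dtype=np.float64) for c in electrode.macro_contacts])
            groups.append(("macro", "b", bipolar_reference(raw)))
        if electrode.micro_wires:
            raw = np.stack([np.asarray(signals[c], dtype=np.float64) for c in electrode.micro_wires])
            groups.append(("micro", "w", bundle_reference(raw)))
        for modality, tag, referenced in groups:
            for idx in range(referenced.shape[0]):
                y = filter_downsample(referenced[idx], spec)
                n_win = y.size // wlen
                channels.append(DerivedChannel(
                    channel_id=f"{electrode.name}-{tag}{idx + 1}",
                    electrode=electrode.name,
                    hemisphere=electrode.hemisphere,
                    modality=modality,
                    windows=y[: n_win * wlen].reshape(n_win, wlen),
                ))

    n_windows = min(c.windows.shape[0] for c in channels) if channels else 0
    stages = [assign_stage(w, window_seconds, hypnogram) for w in range(n_windows)]

    known = {c.channel_id for c in channels}
    ignored = sorted({cid for cid in mask.channel_entries if cid not in known}
                     | {cid for cid, _ in mask.window_entries if cid not in known})
    if ignored:
        logger.warning("artifact mask references unknown channels (ignored): %s", ", ".join(ignored))
    artifact_windows: dict[str, set] = {}
    for c in channels:
        if c.channel_id in mask.channel_entries:
            c.artifact_channel = True
    for cid, widx in mask.window_entries:
        if cid in known:
            artifact_windows.setdefault(cid, set()).add(widx)

    return WindowedNight(channels=channels, stages=stages, sample_rate=spec.fs_out,
                         window_seconds=window_seconds, channel_map=channel_map,
                         artifact_windows=artifact_windows)


def subsample_channels(night: WindowedNight, per_electrode: int) -> WindowedNight:
    """Keep an evenly spaced subset of channels per (electrode, modality).

    Analogous to displaying every second channel of an electrode:
    electrode means are then taken over the kept channels only.  Returns
    a shallow copy; window arrays are shared, not copied.
    """
    from collections import defaultdict

    groups: dict[tuple, list] = defaultdict(list)
    for ch in night.channels:
        groups[(ch.electrode, ch.modality)].append(ch)
    kept: list[DerivedChannel] = []
    for (_, _), chans in groups.items():
        if len(chans) <= per_electrode:
            kept.extend(chans)
        else:
            pick = np.linspace(0, len(chans) - 1, per_electrode).round().astype(int)
            kept.extend(chans[i] for i in sorted(set(pick)))
    return WindowedNight(channels=kept, stages=night.stages, sample_rate=night.sample_rate,
                         window_seconds=night.window_seconds, channel_map=night.channel_map,
                         artifact_windows=night.artifact_windows)


def _select_windows(stages: list[str], windows_per_stage: int | None) -> list[int]:
    """Window indices to score: all stage-labelled windows, or an evenly
    spaced subset of at most ``windows_per_stage`` per stage."""
    by_stage: dict[str, list[int]] = {s: [] for s in STAGES}
    for w, s in enumerate(stages):
        if s in by_stage:
            by_stage[s].append(w)
    selected: list[int] = []
    for s, idxs in by_stage.items():
        if windows_per_stage is None or len(idxs) <= windows_per_stage:
            selected.extend(idxs)
        else:
            pick = np.linspace(0, len(idxs) - 1, windows_per_stage).round().astype(int)
            selected.extend(idxs[i] for i in sorted(set(pick)))
    return sorted(selected)


def score_night(night: WindowedNight, params: EmbeddingParams | None = None,
                surrogate: SurrogateConfig | None = None, master_seed: int = 0,
                windows_per_stage: int | None = None, modalities=("macro", "micro"),
                progress=None) -> pd.DataFrame:
    """Compute (S_O, S_S, psi) for every eligible channel window.

    Transition/unknown-stage windows and artifact-masked windows are
    excluded up front; windows that turn out unscorable (constant or
    degenerate) are flagged excluded rather than fatal.
    ``windows_per_stage`` caps the number of scored windows per sleep
    stage (evenly spaced over the night) for scaled-down runs.
    Seeds for the per-window surrogates derive from ``master_seed`` and
    the (channel, window) identity, so results are independent of
    iteration order.
    """
    params = params or EmbeddingParams()
    surrogate = surrogate or SurrogateConfig()
    selected = _select_windows(night.stages, windows_per_stage)

    rows = []
    for ch in night.channels:
        if ch.modality not in modalities:
            continue
        if ch.artifact_channel:
            continue
        bad = night.artifact_windows.get(ch.channel_id, ())
        for w in selected:
            stage = night.stages[w]
            rec = {"channel_id": ch.channel_id, "electrode": ch.electrode,
                   "hemisphere": ch.hemisphere, "modality": ch.modality,
                   "window_index": w, "stage": stage,
                   "s_original": np.nan, "s_surrogate": np.nan, "psi": np.nan,
                   "excluded": False}
            if w in bad:
                rec["excluded"] = True
                rec["stage"] = EXCLUDED
                rows.append(rec)
                continue
            x = ch.windows[w]
            seed = window_seed_sequence(master_seed, ch.channel_id, w)
            try:
                s_o = predictability_score(x, params)
                surr = iaaft_surrogate(x, surrogate, seed)
                s_s = predictability_score(surr, params)
            except (UnscorableWindowError, ValueError) as exc:
                # str() immediately: a live exception in log args pins its whole
                # traceback (and the night's arrays) in log-capture buffers
                logger.warning("window %d of %s excluded: %s", w, ch.channel_id, str(exc))
                rec["excluded"] = True
                rows.append(rec)
                continue
            rec.update(s_original=s_o, s_surrogate=s_s, psi=s_o - s_s)
            rows.append(rec)
        if progress is not None:
            progress(ch.channel_id)
    return pd.DataFrame(rows)


def run_synthetic_night(config, windows_per_stage: int | None = 1,
                        channels_per_electrode: int | None = 4,
                        master_seed: int | None = None) -> dict:
    """Generate, preprocess, score and lateralize one synthetic night.

    Convenience wrapper for validation studies: returns the full
    :func:`lateralize` report plus the profile and the ground truth.
    ``channels_per_electrode`` subsamples channels evenly per electrode
    and modality (None keeps all).
    """
    from psilat.simulate import generate_night

    night = generate_night(config)
    windowed = preprocess_night(night.signals, night.channel_map, night.hypnogram,
                                night.mask, raw_rate=config.raw_rate)
    if channels_per_electrode is not None:
        windowed = subsample_channels(windowed, channels_per_electrode)
    profile = score_night(windowed, master_seed=config.master_seed if master_seed is None
                          else master_seed, windows_per_stage=windows_per_stage)
    report = lateralize(profile, night.soz_hemisphere)
    report["profile"] = profile
    report["truth"] = night.soz_hemisphere
    return report


def lateralize(profile: pd.DataFrame, soz_hemisphere: str) -> dict:
    """Full statistical report for one night's psi profile.

    Returns electrode/hemisphere stage means, the two-way ANOVA p-values
    per modality, the per-stage Mann-Whitney post-hoc table, the pooled
    lateralization summaries, and the inferred SOZ side.
    """
    from psilat import stats as st

    report: dict = {"soz_hemisphere": soz_hemisphere, "anova": {}, "posthoc": {}}
    wm_all, sm_all = [], []
    for modality in ("macro", "micro"):
        sub = profile[profile["modality"] == modality]
        if sub.empty:
            continue
        wm = st.electrode_window_means(sub)
        sm = st.electrode_stage_means(sub)
        wm_all.append(wm.assign(modality=modality))
        sm_all.append(sm.assign(modality=modality))
        try:
            report["anova"][modality] = st.two_way_anova(wm, soz_hemisphere)
        except ValueError as exc:
            logger.warning("ANOVA (%s) skipped: %s", modality, str(exc))
        report["posthoc"][modality] = st.mannwhitney_posthoc(wm, soz_hemisphere)
    stage_means = pd.concat(sm_all, ignore_index=True) if sm_all else pd.DataFrame()
    report["stage_means"] = stage_means
    report["hemisphere_means"] = (
        st.hemisphere_stage_means(stage_means) if not stage_means.empty else pd.DataFrame()
    )
    report["summaries"] = st.summarize_lateralization(stage_means, soz_hemisphere)
    report["inferred_soz"] = infer_soz_side(stage_means)
    return report


def infer_soz_side(stage_means: pd.DataFrame) -> str:
    """Majority vote over per-stage (and per-modality) hemisphere-mean
    comparisons: the side with the greater hemisphere mean wins one vote
    per stage x modality.  Returns 'L', 'R' or '?' on a tie."""
    from psilat.stats import hemisphere_stage_means

    if stage_means.empty:
        return "?"
    votes = {"L": 0, "R": 0}
    margin = 0.0  # summed L-minus-R hemisphere-mean difference (tie-break)
    hm = hemisphere_stage_means(stage_means)
    keys = [k for k in ("night", "modality", "stage") if k in hm.columns]
    for _, grp in hm.groupby(keys):
        sides = grp.set_index("hemisphere")["psi"]
        if set(sides.index) != {"L", "R"}:
            continue
        diff = sides["L"] - sides["R"]
        margin += diff
        if diff > 0:
            votes["L"] += 1
        elif diff < 0:
            votes["R"] += 1
    if votes["L"] > votes["R"]:
        return "L"
    if votes["R"] > votes["L"]:
        return "R"
    if margin > 0:
        return "L"
    if margin < 0:
        return "R"
    return "?"
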