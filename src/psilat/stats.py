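"""Spatio-temporal averaging of psi and the accompanying statistics.

The per-window, per-channel psi values are averaged in two spatial steps:
first over the channels of each electrode (7 bipolar channels of a macro
electrode, or the 8 referenced wires of a micro bundle), then over the
electrodes implanted in the same hemisphere.  Temporal averages are taken
separately per sleep stage, over all non-excluded windows of that stage.

Inference follows the study design: a two-way ANOVA of the per-window
electrode means with factors location (SOZ vs. non-SOZ hemisphere) and
sleep stage, Mann-Whitney U post-hoc tests per stage with a Bonferroni
correction for fifty comparisons (alpha 0.05 -> 0.001), and a pooled
lateralization summary whose chance probabilities are exact binomial
upper tails at p0 = 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from psilat.preprocess import STAGES

__all__ = [
    "BONFERRONI_COMPARISONS",
    "POSTHOC_ALPHA",
    "LateralizationSummary",
    "electrode_window_means",
    "electrode_stage_means",
    "hemisphere_stage_means",
    "two_way_anova",
    "mannwhitney_posthoc",
    "count_favorable",
    "binomial_tail",
    "lateralization_percent",
    "summarize_lateralization",
]

logger = logging.getLogger(__name__)

BONFERRONI_COMPARISONS = 50
#: post-hoc significance level: 0.05 Bonferroni-corrected for fifty
#: comparisons (5 stages x 2 modalities x 5 nights)
POSTHOC_ALPHA = 0.05 / BONFERRONI_COMPARISONS

_PROFILE_KEYS = ["night", "modality", "electrode", "hemisphere"]


def _clean(profile: pd.DataFrame) -> pd.DataFrame:
    """Drop excluded windows; excluded entries never enter any mean."""
    df = profile
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    return df[df["stage"].isin(STAGES) & df["psi"].notna()]


def _group_keys(df: pd.DataFrame, extra: list[str]) -> list[str]:
    return [k for k in _PROFILE_KEYS if k in df.columns and k not in extra] + extra


def electrode_window_means(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-window electrode means of psi.

    ``profile`` is a long table with at least columns electrode,
    hemisphere, modality, window_index, stage, psi (optionally night and
    an ``excluded`` flag).  For every electrode and window, psi is
    averaged over that electrode's non-excluded channels.
    """
    df = _clean(profile)
    keys = _group_keys(df, ["stage", "window_index"])
    out = df.groupby(keys, as_index=False)["psi"].mean()
    return out


def electrode_stage_means(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-stage electrode mean psi with the standard error of the mean
    across windows.  Electrodes with all channels excluded are dropped
    (and logged)."""
    wm = electrode_window_means(profile)
    keys = _group_keys(wm, ["stage"])
    grouped = wm.groupby(keys)["psi"]
    out = grouped.agg(psi="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
                      n_windows="size").reset_index()
    all_electrodes = set(profile["electrode"].unique())
    kept = set(out["electrode"].unique())
    for missing in sorted(all_electrodes - kept):
        logger.warning("electrode %s dropped: all channels excluded", missing)
    return out


def hemisphere_stage_means(stage_means: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of electrode means per hemisphere and stage.

    Electrodes enter with equal weight regardless of how many channels or
    windows contributed to their means.
    """
    if stage_means.empty or stage_means["hemisphere"].nunique() == 0:
        raise ValueError("no electrodes available for hemisphere means")
    keys = _group_keys(stage_means, ["stage"])
    keys = [k for k in keys if k != "electrode"]
    return stage_means.groupby(keys, as_index=False)["psi"].mean()


def two_way_anova(window_means: pd.DataFrame, soz_hemisphere: str) -> dict[str, float]:
    """Two-way ANOVA of per-window electrode means.

    Factors: location (SOZ vs. non-SOZ hemisphere) and sleep stage.
    Returns p-values for the two main effects and their interaction.
    The design is generally unbalanced (stage cell sizes differ), handled
    with Type II sums of squares.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = window_means.copy()
    df["location"] = np.where(df["hemisphere"] == soz_hemisphere, "SOZ", "nonSOZ")
    for factor, levels in (("location", {"SOZ", "nonSOZ"}), ("stage", set(df["stage"].unique()))):
        present = set(df[factor].unique())
        missing = levels - present
        if missing or not present:
            raise ValueError(f"empty level(s) {sorted(missing)} for factor {factor!r}")
    counts = df.groupby(["location", "stage"]).size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 observations per nonempty cell; too few in {small}")

    if np.ptp(df["psi"].to_numpy()) == 0.0:
        # all observations identical: every F statistic is 0
        return {"location": 1.0, "stage": 1.0, "interaction": 1.0,
                "F_location": 0.0, "F_stage": 0.0, "F_interaction": 0.0}

    model = smf.ols("psi ~ C(location) * C(stage)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ps = {}
    for key, row in (("location", "C(location)"), ("stage", "C(stage)"),
                     ("interaction", "C(location):C(stage)")):
        p = float(table.loc[row, "PR(>F)"])
        f = float(table.loc[row, "F"])
        ps[key] = 1.0 if np.isnan(p) else p
        ps[f"F_{key}"] = 0.0 if np.isnan(f) else f
    return ps


def mannwhitney_posthoc(window_means: pd.DataFrame, soz_hemisphere: str,
                        alpha: float = POSTHOC_ALPHA) -> pd.DataFrame:
    """Per-stage Mann-Whitney U tests of SOZ vs. non-SOZ psi values.

    The sampling unit is the per-window electrode mean, pooled across the
    electrodes of a hemisphere.  Two-sided p; a comparison is significant
    iff p < ``alpha`` (default 0.001, the Bonferroni-adjusted level).
    Exact enumeration is used for small tie-free groups, the
    tie-corrected normal approximation otherwise.  Comparisons with a
    group of fewer than 2 values are skipped (logged).
    """
    df = window_means.copy()
    df["location"] = np.where(df["hemisphere"] == soz_hemisphere, "SOZ", "nonSOZ")
    rows = []
    for stage in STAGES:
        sub = df[df["stage"] == stage]
        a = sub.loc[sub["location"] == "SOZ", "psi"].to_numpy()
        b = sub.loc[sub["location"] == "nonSOZ", "psi"].to_numpy()
        if a.size < 2 or b.size < 2:
            logger.warning("stage %s skipped: group sizes %d vs %d", stage, a.size, b.size)
            continue
        if max(a.size, b.size) <= 20 and np.unique(np.concatenate([a, b])).size == a.size + b.size:
            method = "exact"
        else:
            method = "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append({"stage": stage, "U": float(res.statistic), "p": float(res.pvalue),
                     "significant": bool(res.pvalue < alpha),
                     "n_soz": int(a.size), "n_nonsoz": int(b.size)})
    return pd.DataFrame(rows)


def count_favorable(stage_means: pd.DataFrame, soz_hemisphere: str,
                    level: str = "electrode") -> tuple[int, int]:
    """Count comparisons in which the SOZ side exceeds the contralateral.

    ``level='electrode'`` pairs electrodes carrying the same anatomical
    label on both sides (unpaired labels are excluded and logged) and
    compares their per-stage means; ``level='hemisphere'`` compares the
    per-stage hemisphere means.  A comparison is favorable iff the
    SOZ-side mean is strictly greater (exact ties count as unfavorable).
    Returns (n_favorable, n_total).
    """
    favorable = 0
    total = 0
    if level == "hemisphere":
        hm = hemisphere_stage_means(stage_means)
        keys = [k for k in _group_keys(hm, ["stage"]) if k != "hemisphere"]
        for _, grp in hm.groupby(keys):
            sides = grp.set_index("hemisphere")["psi"]
            if len(sides) != 2:
                continue
            other = [h for h in sides.index if h != soz_hemisphere]
            total += 1
            if sides[soz_hemisphere] > sides[other[0]]:
                favorable += 1
        return favorable, total
    if level != "electrode":
        raise ValueError(f"unknown level {level!r}")

    df = stage_means.copy()
    # anatomical label: electrode name with its hemisphere designation
    # stripped, e.g. 'AHL'/'AHR' -> 'AH'
    df["label"] = [
        e[: -len(h)] if e.endswith(h) else e
        for e, h in zip(df["electrode"], df["hemisphere"])
    ]
    keys = [k for k in _group_keys(df, ["stage"]) if k not in ("electrode", "hemisphere")]
    for _, grp in df.groupby(keys + ["label"]):
        sides = grp.set_index("hemisphere")["psi"]
        if soz_hemisphere not in sides.index or len(sides) != 2:
            logger.warning("unpaired electrode label %s excluded from comparisons",
                           grp["label"].iloc[0])
            continue
        other = [h for h in sides.index if h != soz_hemisphere]
        total += 1
        if sides[soz_hemisphere] > sides[other[0]]:
            favorable += 1
    return favorable, total


def binomial_tail(s: int, n: int, p0: float = 0.5) -> float:
    """Exact one-sided upper tail P(X >= s) for X ~ Binomial(n, p0).

    For the fair-coin case the sum is evaluated with exact integer
    arithmetic (``sum C(n, i) / 2**n``); otherwise via the survival
    function.
    """
    if not 0 <= s <= n:
        raise ValueError(f"need 0 <= s <= n, got s={s}, n={n}")
    if p0 == 0.5 and n <= 1000:
        return float(Fraction(sum(comb(n, i) for i in range(s, n + 1)), 2**n))
    return float(sps.binom.sf(s - 1, n, p0))


def lateralization_percent(s: int, n: int) -> float:
    """Percentage 100*s/n, half-up rounded to one decimal."""
    if n <= 0:
        raise ValueError("percentage undefined for n = 0")
    exact = Decimal(100 * s) / Decimal(n)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LateralizationSummary:
    """Pooled favorable-comparison bookkeeping at one level x modality."""

    level: str
    modality: str
    n_favorable: int
    n_total: int

    @property
    def percent(self) -> float:
        return lateralization_percent(self.n_favorable, self.n_total)

    @property
    def p_binomial(self) -> float:
        return binomial_tail(self.n_favorable, self.n_total)


def summarize_lateralization(stage_means: pd.DataFrame, soz_hemisphere: str) -> list[LateralizationSummary]:
    """Pooled summary over both levels and both modalities.

    ``stage_means`` may span several nights (a ``night`` column); the
    counts then pool stages x electrode pairs x nights (electrode level)
    and stages x nights (hemisphere level).
    """
    out = []
    for level in ("electrode", "hemisphere"):
        for modality in ("macro", "micro"):
            sub = stage_means[stage_means["modality"] == modality]
            if sub.empty:
                continue
            fav, tot = count_favorable(sub, soz_hemisphere, level=level)
            if tot:
                out.append(LateralizationSummary(level, modality, fav, tot))
    return out
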