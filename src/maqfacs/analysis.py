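"""Downstream statistics on classified AUs and peri-event neural activity.

Once frames carry AU classes (predicted or manually coded), this module
computes AU frequency and co-occurrence summaries, facial-configuration
proportions per behavioral block period with chi-square comparisons,
and peri-AU-onset z-scored firing rates for simultaneously recorded
neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AUClass


@dataclass
class BlockPeriods:
    """Labeled half-open frame intervals of one experimental block.

    Standard period names: ``enter_exit``, ``shutter_open``,
    ``shutter_closed``.  Intervals must not overlap within a video.
    """

    periods: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        spans = sorted(
            iv for ivs in self.periods.values() for iv in ivs
        )
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s0 < 0 or e0 < s0:
                raise ValueError(f"invalid interval ({s0}, {e0})")
            if s1 < e0:
                raise ValueError("periods overlap")


@dataclass(frozen=True)
class NormalizedFR:
    """Z-scored firing rate against a pre-block baseline."""

    values: np.ndarray  # z per bin (or per event x bin)
    baseline_mean: float  # spikes/s
    baseline_sd: float  # spikes/s
    window_ms: float = 300.0


def au_frequency(
    labels: Sequence[AUClass],
) -> dict[AUClass, float]:
    """Proportion of frames per AU class (including neutral/Other)."""
    labels = list(labels)
    if not labels:
        raise ValueError("no frames supplied")
    out: dict[AUClass, float] = {}
    n = len(labels)
    for lab in labels:
        out[lab] = out.get(lab, 0.0) + 1.0
    return {c: v / n for c, v in out.items()}


def cooccurrence_matrix(
    upper_labels: Sequence[AUClass],
    lower_labels: Sequence[AUClass],
    aus: Sequence[AUClass],
) -> pd.DataFrame:
    """AU combination proportions across frames.

    Cell (i, j) = #frames containing both AU_i and AU_j divided by the
    frame count of the rarer of the two; a frame "contains" an AU when
    its region label equals that AU.  Cells involving an AU with zero
    frames are NaN; the diagonal is 1 where the AU occurs.
    """
    if len(upper_labels) != len(lower_labels):
        raise ValueError("upper/lower label lengths differ")

    def present(au: AUClass) -> np.ndarray:
        source = upper_labels if au.region.value == "upper" else lower_labels
        return np.array([lab is au for lab in source])

    masks = {au: present(au) for au in aus}
    counts = {au: int(m.sum()) for au, m in masks.items()}
    mat = np.full((len(aus), len(aus)), np.nan)
    for i, a in enumerate(aus):
        for j, b in enumerate(aus):
            rarer = min(counts[a], counts[b])
            if rarer == 0:
                continue
            both = int((masks[a] & masks[b]).sum())
            mat[i, j] = both / rarer
    names = [au.value for au in aus]
    return pd.DataFrame(mat, index=names, columns=names)


def combination_proportions(
    upper_labels: Sequence[AUClass],
    lower_labels: Sequence[AUClass],
    periods: BlockPeriods,
    combo: tuple[AUClass, AUClass],
) -> dict[str, Optional[float]]:
    """Per-period proportion of frames showing an (upper, lower) combo.

    Zero-length periods yield None (undefined).
    """
    if len(upper_labels) != len(lower_labels):
        raise ValueError("upper/lower label lengths differ")
    upper_c, lower_c = combo
    hit = np.array(
        [u is upper_c and l is lower_c for u, l in zip(upper_labels, lower_labels)]
    )
    out: dict[str, Optional[float]] = {}
    for name, intervals in periods.periods.items():
        total = sum(e - s for s, e in intervals)
        if total == 0:
            out[name] = None
            continue
        if any(e > len(hit) for _, e in intervals):
            raise ValueError(f"period {name} exceeds the labeled frame range")
        count = sum(int(hit[s:e].sum()) for s, e in intervals)
        out[name] = count / total
    return out


def combo_contingency(
    upper_labels: Sequence[AUClass],
    lower_labels: Sequence[AUClass],
    periods: BlockPeriods,
    combo: tuple[AUClass, AUClass],
    period_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """(periods x {combo-present, combo-absent}) frame-count table."""
    upper_c, lower_c = combo
    hit = np.array(
        [u is upper_c and l is lower_c for u, l in zip(upper_labels, lower_labels)]
    )
    names = list(period_names or periods.periods)
    table = []
    for name in names:
        count = sum(
            int(hit[s:e].sum()) for s, e in periods.periods[name]
        )
        total = sum(e - s for s, e in periods.periods[name])
        table.append([count, total - count])
    return np.asarray(table, dtype=int)


def chi_square_test(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on an r x c count table.

    Returns (statistic, degrees of freedom, upper-tail p value); expected
    counts come from the row/column margins; no continuity correction.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def normalize_firing_rate(
    fr: float | np.ndarray, baseline_mean: float, baseline_sd: float
) -> float | np.ndarray:
    """Z-score a firing rate against the baseline mean and SD."""
    if baseline_sd <= 0:
        raise ValueError(f"baseline SD must be positive, got {baseline_sd}")
    return (np.asarray(fr, dtype=float) - baseline_mean) / baseline_sd


def _bin_edges(window: tuple[float, float], bin_s: float) -> np.ndarray:
    """Bin edges anchored at the event onset, fully inside the window."""
    w0, w1 = window
    n_pre = int(np.floor(-w0 / bin_s + 1e-9))
    n_post = int(np.floor(w1 / bin_s + 1e-9))
    if n_pre + n_post == 0:
        raise ValueError("window shorter than one bin")
    return np.arange(-n_pre, n_post + 1) * bin_s


def peri_event_rates(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    window: tuple[float, float] = (-0.7, 0.7),
    bin_ms: float = 300.0,
    baseline_epoch: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray, NormalizedFR]:
    """Peri-event binned firing rates, z-scored against a baseline epoch.

    Bins of ``bin_ms`` are anchored at the event onset and extend while
    they fit fully inside ``window`` (seconds, relative to onset).
    The baseline epoch (absolute seconds, typically the pre-block
    interval) is binned with the same width to get the baseline mean and
    SD of the firing rate.  Returns (bin_centers, per-event rate matrix,
    NormalizedFR with the event-averaged z per bin).
    """
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one event")
    bin_s = bin_ms / 1000.0
    edges = _bin_edges(window, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rates = np.empty((events.size, centers.size))
    for i, t in enumerate(events):
        counts, _ = np.histogram(spikes - t, bins=edges)
        rates[i] = counts / bin_s
    if baseline_epoch is None:
        raise ValueError("a baseline epoch is required for z-scoring")
    b0, b1 = baseline_epoch
    n_base = int(np.floor((b1 - b0) / bin_s + 1e-9))
    if n_base < 2:
        raise ValueError("baseline epoch too short for mean/SD estimation")
    base_edges = b0 + np.arange(n_base + 1) * bin_s
    base_counts, _ = np.histogram(spikes, bins=base_edges)
    base_rates = base_counts / bin_s
    baseline_mean = float(base_rates.mean())
    baseline_sd = float(base_rates.std(ddof=1))
    if baseline_sd <= 0:
        raise ValueError("baseline SD is zero; cannot z-score")
    z = normalize_firing_rate(rates.mean(axis=0), baseline_mean, baseline_sd)
    return centers, rates, NormalizedFR(
        values=np.asarray(z), baseline_mean=baseline_mean,
        baseline_sd=baseline_sd, window_ms=bin_ms,
    )


def au_onsets(labels: Sequence[AUClass], au: AUClass, fps: float) -> np.ndarray:
    """Onset times (s) of AU episodes: first frame after a non-AU frame."""
    onsets = []
    prev_is_au = False
    for i, lab in enumerate(labels):
        is_au = lab is au
        if is_au and not prev_is_au:
            onsets.append(i / fps)
        prev_is_au = is_au
    return np.asarray(onsets)
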