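"""Event-wise copy-number detection from windowed read depth.

Depth is summarized in fixed non-overlapping windows (100 bp by
default).  Windows are normalized against a robust baseline (median /
MAD of unmasked windows) and given upper- and lower-tail Gaussian
p-values.  Maximal runs of same-direction windows, each significant at
the per-window level ``alpha**(1/min_consec)``, are merged into events;
events must span at least ``min_consec`` windows and ``min_bp`` bases
and their Fisher-combined p-value must reach the event-level ``alpha``
(1e-6 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: smallest representable positive double; combined p-values are floored
#: here rather than reported as an exact zero
_TINY = np.nextafter(0, 1)


@dataclass
class WindowDepthTrack:
    """Consecutive fixed-width window counts for one chromosome."""

    chromosome: str
    window_size: int
    counts: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("window counts must be >= 0")
        if self.mask is None:
            self.mask = np.zeros(len(self.counts), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.counts.shape:
            raise ValueError("mask and counts must have the same length")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    def window_start(self, idx: int) -> int:
        return idx * self.window_size


@dataclass(frozen=True)
class CNVCall:
    """One merged read-depth event."""

    chromosome: str
    start_bp: int
    end_bp: int
    type: str  # 'gain' | 'loss'
    n_windows: int
    mean_ratio: float
    event_p: float

    def __post_init__(self):
        if self.type not in ("gain", "loss"):
            raise ValueError(f"type must be gain/loss, got {self.type!r}")


@dataclass
class NormalizedTrack:
    track: WindowDepthTrack
    baseline: float
    sigma: float
    z: np.ndarray
    p_upper: np.ndarray  # gain evidence; NaN on masked windows
    p_lower: np.ndarray  # loss evidence; NaN on masked windows


def normalize_windows(track: WindowDepthTrack) -> NormalizedTrack:
    """Robust per-window z-scores and tail p-values.

    Baseline is the median of unmasked window counts; dispersion is the
    MAD-derived s.d. (1.4826 * MAD).  Requires >= 100 unmasked windows
    for a reliable baseline.  With zero dispersion (all counts equal),
    z is 0 everywhere the count equals the baseline and +/-inf elsewhere.
    """
    counts = track.counts[~track.mask].astype(float)
    if len(counts) < 100:
        raise ValueError(
            f"only {len(counts)} unmasked windows; >= 100 required for a "
            "reliable baseline"
        )
    baseline = float(np.median(counts))
    sigma = float(1.4826 * np.median(np.abs(counts - baseline)))
    dev = track.counts.astype(float) - baseline
    if sigma > 0:
        z = dev / sigma
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(dev == 0, 0.0, np.sign(dev) * np.inf)
    p_upper = stats.norm.sf(z)
    p_lower = stats.norm.cdf(z)
    p_upper[track.mask] = np.nan
    p_lower[track.mask] = np.nan
    return NormalizedTrack(
        track=track, baseline=baseline, sigma=sigma, z=z,
        p_upper=p_upper, p_lower=p_lower,
    )


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]] + 1
    return list(zip(starts.tolist(), ends.tolist()))


def _fisher_p(pvals: np.ndarray) -> float:
    """Fisher's combined p over member windows, floored at _TINY."""
    clipped = np.clip(pvals, _TINY, 1.0)
    x = -2.0 * np.log(clipped).sum()
    return float(max(stats.chi2.sf(x, 2 * len(clipped)), _TINY))


def ewt_scan(
    track: WindowDepthTrack,
    alpha: float = 1e-6,
    min_consec: int = 10,
    min_bp: int = 1000,
    refine_p: float = 0.01,
) -> list[CNVCall]:
    """Detect gain/loss events by event-wise testing of window runs.

    Runs are formed at the per-window tail level ``alpha**(1/min_consec)``
    (so a qualifying run of ``min_consec`` windows meets the event-level
    ``alpha`` by construction), then boundaries are refined by trimming
    terminal windows whose individual tail p exceeds ``refine_p`` —
    without refinement, marginally significant flanking windows join
    strong events by chance and blur the breakpoints.  Events failing
    ``min_consec``, ``min_bp`` or the Fisher-combined event-level
    ``alpha`` are discarded.  Masked windows break runs.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    norm = normalize_windows(track)
    per_window = alpha ** (1.0 / min_consec)
    calls: list[CNVCall] = []
    for direction, tail_p in (("gain", norm.p_upper), ("loss", norm.p_lower)):
        flags = np.where(np.isnan(tail_p), False, tail_p < per_window)
        for start, end in _runs(flags):
            # boundary refinement: drop weak terminal windows
            while start < end and tail_p[start] > refine_p:
                start += 1
            while end > start and tail_p[end - 1] > refine_p:
                end -= 1
            n_win = end - start
            length = n_win * track.window_size
            if n_win < min_consec or length < min_bp:
                continue
            event_p = _fisher_p(tail_p[start:end])
            if event_p > alpha:
                continue
            mean_ratio = float(
                track.counts[start:end].mean() / norm.baseline
            )
            calls.append(
                CNVCall(
                    chromosome=track.chromosome,
                    start_bp=track.window_start(start),
                    end_bp=track.window_start(end),
                    type=classify_gain_loss(mean_ratio),
                    n_windows=n_win,
                    mean_ratio=mean_ratio,
                    event_p=event_p,
                )
            )
            assert calls[-1].type == direction, "direction/ratio disagreement"
    calls.sort(key=lambda c: (c.chromosome, c.start_bp))
    for c in calls:
        assert c.n_windows >= min_consec
        assert c.end_bp - c.start_bp >= min_bp
        assert c.event_p <= alpha
    return calls


def classify_gain_loss(mean_ratio: float) -> str:
    """'gain' when observed/baseline depth > 1, 'loss' when < 1.

    A ratio of exactly 1 cannot survive the significance filter and is
    rejected here.
    """
    if mean_ratio > 1:
        return "gain"
    if mean_ratio < 1:
        return "loss"
    raise ValueError("mean_ratio exactly 1 is not a copy-number event")
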