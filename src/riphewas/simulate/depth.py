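"""Windowed read-depth tracks with planted copy-number events.

Window counts are Poisson with mean ``depth_mean * copy_ratio / 2``;
copy_ratio 2 is the diploid baseline, 8 a four-fold expansion, 0 a
homozygous loss.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from riphewas.cnv import WindowDepthTrack


def simulate_depth_track(
    genome_length: int,
    depth_mean: float,
    cnv_spec: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    window: int = 100,
    chromosome: str = "chr1",
    mask: Sequence[tuple[int, int]] = (),
) -> WindowDepthTrack:
    """Simulate per-window read counts over one chromosome.

    ``cnv_spec`` rows are ``(start_bp, end_bp, copy_ratio)`` in 0-based
    half-open bp coordinates; a window takes a region's ratio when its
    midpoint falls inside the region.  ``mask`` intervals (bp) flag
    windows excluded from analysis (assembly gaps).
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    n_windows = genome_length // window
    mids = np.arange(n_windows) * window + window / 2
    ratio = np.full(n_windows, 2.0)
    for start, end, r in cnv_spec:
        if r < 0:
            raise ValueError("copy_ratio must be >= 0")
        ratio[(mids >= start) & (mids < end)] = r
    rng = np.random.default_rng(seed)
    counts = rng.poisson(depth_mean * ratio / 2.0)
    masked = np.zeros(n_windows, dtype=bool)
    for start, end in mask:
        masked[(mids >= start) & (mids < end)] = True
    return WindowDepthTrack(
        chromosome=chromosome,
        window_size=window,
        counts=counts.astype(np.int64),
        mask=masked,
    )
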