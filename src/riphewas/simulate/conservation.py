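"""Synthetic regulatory-element, conserved-element and conservation tracks.

Intervals are 0-based half-open (BED convention).  The per-base
conservation track deliberately has gaps so the missing-data rule of the
impact score is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConservationTracks:
    regulatory: pd.DataFrame   # chrom, start, end
    conserved: pd.DataFrame    # chrom, start, end, score in [0, 1]
    per_base: pd.DataFrame     # chrom, start, end (=start+1), value
    chromosome: str
    genome_length: int


def _random_intervals(
    rng: np.random.Generator,
    genome_length: int,
    n: int,
    min_len: int,
    max_len: int,
) -> list[tuple[int, int]]:
    """Non-overlapping random intervals, sorted by start."""
    out: list[tuple[int, int]] = []
    tries = 0
    while len(out) < n and tries < 50 * n:
        tries += 1
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, genome_length - length))
        iv = (start, start + length)
        if all(iv[1] <= s or e <= iv[0] for s, e in out):
            out.append(iv)
    if len(out) < n:
        raise ValueError("could not place requested number of elements")
    return sorted(out)


def simulate_conservation_tracks(
    genome_length: int,
    element_density: float = 0.02,
    seed: int = 0,
    chromosome: str = "chr1",
    gap_fraction: float = 0.3,
    element_len: tuple[int, int] = (20, 80),
) -> ConservationTracks:
    """Simulate the three annotation inputs of the impact score.

    ``element_density`` is the approximate fraction of the genome covered
    by each element class; ``gap_fraction`` is the fraction of positions
    with no per-base conservation value.
    """
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mean_len = (element_len[0] + element_len[1]) / 2
    n_elements = max(1, int(round(element_density * genome_length / mean_len)))

    reg = _random_intervals(rng, genome_length, n_elements, *element_len)
    cons = _random_intervals(rng, genome_length, n_elements, *element_len)
    regulatory = pd.DataFrame(
        [(chromosome, s, e) for s, e in reg], columns=["chrom", "start", "end"]
    )
    conserved = pd.DataFrame(
        [
            (chromosome, s, e, float(rng.uniform(0.2, 1.0)))
            for s, e in cons
        ],
        columns=["chrom", "start", "end", "score"],
    )

    has_value = rng.random(genome_length) >= gap_fraction
    pos = np.flatnonzero(has_value)
    values = rng.gamma(shape=2.0, scale=1.0, size=len(pos))
    per_base = pd.DataFrame(
        {
            "chrom": chromosome,
            "start": pos,
            "end": pos + 1,
            "value": values,
        }
    )
    return ConservationTracks(
        regulatory=regulatory,
        conserved=conserved,
        per_base=per_base,
        chromosome=chromosome,
        genome_length=genome_length,
    )
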