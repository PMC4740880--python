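"""Genetic marker maps: one row per marker, genetic and physical position."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ["marker_id", "chromosome", "position_bp", "position_cM"]


@dataclass
class MarkerMap:
    """Marker map with physical (bp) and genetic (cM) coordinates.

    Invariants (checked on construction): within each chromosome bp
    positions are strictly increasing and cM positions are monotone
    non-decreasing in bp order.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        t = self.table.reset_index(drop=True)
        if t["marker_id"].duplicated().any():
            dups = t.loc[t["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicate marker ids: {dups}")
        if (t["position_bp"] < 1).any():
            raise ValueError("position_bp must be >= 1")
        if (t["position_cM"] < 0).any():
            raise ValueError("position_cM must be non-negative")
        for chrom, grp in t.groupby("chromosome", sort=False):
            bp = grp["position_bp"].to_numpy()
            cm = grp["position_cM"].to_numpy()
            order = np.argsort(bp, kind="stable")
            if (np.diff(bp[order]) <= 0).any():
                raise ValueError(
                    f"bp positions not strictly increasing on {chrom}"
                )
            if (np.diff(cm[order]) < 0).any():
                raise ValueError(f"cM positions decrease with bp on {chrom}")
        self.table = t.sort_values(
            ["chromosome", "position_bp"], kind="stable"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    def chromosomes(self) -> list[str]:
        return self.table["chromosome"].unique().tolist()

    def chromosome_view(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]


def random_marker_map(
    n_markers_per_chrom: dict[str, int],
    chrom_length_bp: int = 100_000_000,
    chrom_length_cM: float = 80.0,
    seed: int = 0,
) -> MarkerMap:
    """Random marker map: uniform bp positions, cM proportional to bp.

    A simple linear bp->cM relation keeps the map invariants trivially
    satisfied while exercising variable inter-marker distances.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, n in n_markers_per_chrom.items():
        bp = np.sort(
            rng.choice(np.arange(1, chrom_length_bp), size=n, replace=False)
        )
        cm = bp / chrom_length_bp * chrom_length_cM
        for i, (b, c) in enumerate(zip(bp, cm)):
            rows.append((f"{chrom}_m{i:04d}", chrom, int(b), float(c)))
    return MarkerMap(pd.DataFrame(rows, columns=COLUMNS))
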