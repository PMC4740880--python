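"""Recombinant-inbred genotype simulation.

Each strain is simulated as a fixed homozygous mosaic of two parental
alleles (coded 0 and 2).  Between adjacent markers the probability that
the parental origin switches is the RI-by-sib-mating map expansion

    R = 4r / (1 + 6r)

of the single-meiosis recombination fraction r, itself obtained from the
inter-marker genetic distance via Haldane's map function
r = (1 - exp(-2 d_Morgan)) / 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from riphewas.containers import GenotypeMatrix
from riphewas.markers import MarkerMap


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction from genetic distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def ri_map_expansion(r: np.ndarray | float) -> np.ndarray | float:
    """RI-by-sibling-mating expansion R = 4r/(1+6r) of recombination fraction r."""
    r = np.asarray(r, dtype=float)
    return 4.0 * r / (1.0 + 6.0 * r)


def simulate_ri_genotypes(
    marker_map: MarkerMap, n_strains: int, seed: int
) -> GenotypeMatrix:
    """Simulate a fully inbred two-parent RI panel.

    Per chromosome, the first marker's parental origin is a fair coin per
    strain; each subsequent marker switches origin with probability
    ``R = 4r/(1+6r)`` where ``r`` comes from the cM gap to the previous
    marker.  No heterozygous calls are produced.

    Parameters
    ----------
    marker_map
        Validated marker map (drives marker order and spacing).
    n_strains
        Number of strains (>= 2).
    seed
        Seed for the generator; output is bit-reproducible.
    """
    if n_strains < 2:
        raise ValueError(f"n_strains must be >= 2, got {n_strains}")
    rng = np.random.default_rng(seed)
    blocks = []
    col_order = []
    for chrom in marker_map.chromosomes():
        view = marker_map.chromosome_view(chrom)
        m = len(view)
        origin = np.empty((n_strains, m), dtype=np.int8)
        origin[:, 0] = rng.integers(0, 2, size=n_strains)
        if m > 1:
            d_cm = np.diff(view["position_cM"].to_numpy())
            big_r = ri_map_expansion(haldane_r(d_cm))
            switches = rng.random((n_strains, m - 1)) < big_r[None, :]
            # cumulative parity of switches gives the mosaic
            origin[:, 1:] = (
                origin[:, [0]] + np.cumsum(switches, axis=1)
            ) % 2
        blocks.append(origin)
        col_order.extend(view["marker_id"].tolist())
    codes = np.concatenate(blocks, axis=1) * 2  # 0 / 2 parental codes
    strains = [f"RI{i:03d}" for i in range(1, n_strains + 1)]
    geno = pd.DataFrame(codes.astype(float), index=strains, columns=col_order)
    return GenotypeMatrix(geno, marker_map)
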