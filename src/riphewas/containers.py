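"""Shared tabular containers: genotype matrices and phenome tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from riphewas.markers import MarkerMap


@dataclass
class GenotypeMatrix:
    """Strains x markers genotype codes.

    Codes are 0 (one parental allele), 2 (the other) or NaN (missing);
    fully inbred panels carry no heterozygous calls.  ``genotypes`` is
    indexed by strain id with one column per marker, column order matching
    ``markers``.
    """

    genotypes: pd.DataFrame
    markers: MarkerMap

    def __post_init__(self):
        map_ids = self.markers.marker_ids
        cols = list(self.genotypes.columns)
        if set(cols) != set(map_ids):
            raise ValueError("genotype columns do not match marker map ids")
        # keep map order
        self.genotypes = self.genotypes[map_ids]
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 2)
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"invalid genotype codes: {bad}")
        self.genotypes.index.name = "strain"

    @property
    def strains(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def n_strains(self) -> int:
        return len(self.genotypes)

    def marker_vector(self, marker_id: str) -> np.ndarray:
        return self.genotypes[marker_id].to_numpy(dtype=float)

    def drop_monomorphic(self) -> "GenotypeMatrix":
        """Drop markers with fewer than 2 distinct non-missing codes."""
        keep = []
        for m in self.genotypes.columns:
            v = self.genotypes[m].dropna()
            if v.nunique() >= 2:
                keep.append(m)
        dropped = set(self.genotypes.columns) - set(keep)
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} monomorphic markers", stacklevel=2
            )
        tab = self.markers.table
        return GenotypeMatrix(
            self.genotypes[keep],
            MarkerMap(tab[tab["marker_id"].isin(keep)].reset_index(drop=True)),
        )


@dataclass
class PhenomeTable:
    """Strains x traits phenotype values with per-trait metadata.

    ``values``: DataFrame indexed by strain, one column per trait (NaN =
    missing).  ``traits``: DataFrame indexed by trait id with at least a
    ``category`` column; endophenotype tables also carry ``tissue``.
    """

    values: pd.DataFrame
    traits: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.traits is None:
            self.traits = pd.DataFrame(
                {"category": ["uncategorized"] * self.values.shape[1]},
                index=self.values.columns,
            )
        if set(self.traits.index) != set(self.values.columns):
            raise ValueError("trait metadata does not match value columns")
        self.traits = self.traits.loc[self.values.columns]
        self.values.index.name = "strain"
        self.traits.index.name = "trait_id"

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    def drop_empty_traits(self) -> "PhenomeTable":
        keep = self.values.columns[self.values.notna().any(axis=0)]
        return PhenomeTable(self.values[keep], self.traits.loc[keep])
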