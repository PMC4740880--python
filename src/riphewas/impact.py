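"""Composite impact scores for noncoding SNPs and comparative-genomics calls.

The impact score S of a noncoding position is the product of a
functional-element score F (1 inside a curated regulatory element, else
the overlapped conserved element's score, else missing) and a
mutation-effect score M (the per-base conservation value mapped to
[0, 1] by the track's empirical CDF; missing where the track has a gap).
When exactly one component is missing it is replaced by a non-zero
epsilon below every observed positive value of that component — half the
observed positive minimum — so single-source evidence is never silently
discarded; when both are missing, S = 0.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# annotations


class _IntervalSet:
    """Sorted non-overlapping half-open intervals with O(log n) lookup."""

    def __init__(self, starts, ends, scores=None):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        self.starts, self.ends = starts[order], ends[order]
        self.scores = (
            None if scores is None else np.asarray(scores, dtype=float)[order]
        )
        if (self.ends <= self.starts).any():
            raise ValueError("empty/inverted interval")
        if (self.starts[1:] < self.ends[:-1]).any():
            raise ValueError("intervals overlap")
        if self.scores is not None and (
            (self.scores < 0) | (self.scores > 1)
        ).any():
            raise ValueError("element scores must be in [0, 1]")

    def lookup(self, pos: int) -> Optional[int]:
        """Index of the interval containing pos, or None."""
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        if i >= 0 and pos < self.ends[i]:
            return i
        return None


class FunctionalAnnotations:
    """Regulatory elements, scored conserved elements, per-base track.

    Built from the BED/bedGraph-style frames emitted by
    :func:`riphewas.simulate.simulate_conservation_tracks` or read by
    :mod:`riphewas.io`; all coordinates 0-based half-open.
    """

    def __init__(
        self,
        regulatory: pd.DataFrame,
        conserved: pd.DataFrame,
        per_base: pd.DataFrame,
    ):
        self.regulatory = _IntervalSet(
            regulatory["start"], regulatory["end"]
        )
        self.conserved = _IntervalSet(
            conserved["start"], conserved["end"], conserved["score"]
        )
        pos = per_base["start"].to_numpy(dtype=np.int64)
        val = per_base["value"].to_numpy(dtype=float)
        order = np.argsort(pos, kind="stable")
        self._track_pos = pos[order]
        self._track_val = val[order]
        if len(np.unique(self._track_pos)) != len(self._track_pos):
            raise ValueError("duplicate positions in per-base track")
        self._sorted_vals = np.sort(val)

    def track_value(self, pos: int) -> Optional[float]:
        i = int(np.searchsorted(self._track_pos, pos))
        if i < len(self._track_pos) and self._track_pos[i] == pos:
            return float(self._track_val[i])
        return None

    def track_ecdf(self, value: float) -> float:
        """rank/n over positions with data (max value -> 1.0)."""
        n = len(self._sorted_vals)
        if n == 0:
            raise ValueError("per-base track is empty")
        rank = int(np.searchsorted(self._sorted_vals, value, side="right"))
        return rank / n


# ---------------------------------------------------------------------------
# component scores


def functional_element_score(
    pos: int, ann: FunctionalAnnotations
) -> Optional[float]:
    """F: 1 in a regulatory element, else conserved-element score, else None.

    When a position sits in both element classes the regulatory overlap
    wins (logged).
    """
    in_reg = ann.regulatory.lookup(pos) is not None
    ci = ann.conserved.lookup(pos)
    if in_reg:
        if ci is not None:
            log.debug(
                "position %d in both element classes; regulatory wins", pos
            )
        return 1.0
    if ci is not None:
        return float(ann.conserved.scores[ci])
    return None


def mutation_effect_score(
    pos: int, ann: FunctionalAnnotations
) -> Optional[float]:
    """M: per-base conservation mapped to [0, 1] by the track ECDF."""
    value = ann.track_value(pos)
    if value is None:
        return None
    return ann.track_ecdf(value)


@dataclass(frozen=True)
class ObservedMinima:
    """Smallest positive F and M seen across all scored positions.

    Either attribute may be None when no positive value of that component
    was observed; substituting for a missing component then fails loudly.
    """

    min_f: Optional[float]
    min_m: Optional[float]


def impact_score(
    f: Optional[float],
    m: Optional[float],
    minima: ObservedMinima,
) -> float:
    """S = F*M with the epsilon rule for a single missing component.

    A missing component is replaced by half the corresponding observed
    positive minimum — a deterministic choice of "a non-zero value less
    than the scores observed for all positions with data present".  Both
    missing -> 0.  Requires the two-pass minima; calling with an
    undefined needed minimum raises.
    """
    if f is None and m is None:
        return 0.0
    if f is None:
        if minima.min_f is None:
            raise ValueError(
                "no positive F observed yet; run the two-pass evaluation"
            )
        f = 0.5 * minima.min_f
    if m is None:
        if minima.min_m is None:
            raise ValueError(
                "no positive M observed yet; run the two-pass evaluation"
            )
        m = 0.5 * minima.min_m
    s = f * m
    if not 0.0 <= s <= 1.0:
        raise AssertionError(f"impact score {s} outside [0, 1]")
    return s


def score_positions(
    positions: Sequence[int], ann: FunctionalAnnotations
) -> pd.DataFrame:
    """Two-pass impact scoring of noncoding positions.

    Pass 1 computes F and M everywhere and records the observed positive
    minima; pass 2 applies the epsilon substitution and the product rule.
    Returns a frame with columns position, F, M, S (F/M NaN = missing).
    """
    fs = [functional_element_score(p, ann) for p in positions]
    ms = [mutation_effect_score(p, ann) for p in positions]
    pos_f = [v for v in fs if v is not None and v > 0]
    pos_m = [v for v in ms if v is not None and v > 0]
    # with no positive observations of a component, "below every observed
    # value" is vacuous: fall back to the component's a-priori maximum 1.0
    # so the epsilon becomes 0.5 (logged)
    if not pos_f and any(f is None for f in fs):
        log.info("no positive F observed; epsilon falls back to 0.5")
    if not pos_m and any(m_ is None for m_ in ms):
        log.info("no positive M observed; epsilon falls back to 0.5")
    minima = ObservedMinima(
        min_f=min(pos_f) if pos_f else 1.0,
        min_m=min(pos_m) if pos_m else 1.0,
    )
    s = [impact_score(f, m, minima) for f, m in zip(fs, ms)]
    return pd.DataFrame(
        {
            "position": list(positions),
            "F": [np.nan if v is None else v for v in fs],
            "M": [np.nan if v is None else v for v in ms],
            "S": s,
        }
    )


# ---------------------------------------------------------------------------
# comparative genomics


class ComparativeCall(str, enum.Enum):
    likely_deleterious = "likely_deleterious"
    likely_deleterious_enhanced = "likely_deleterious_enhanced"
    unlikely_deleterious = "unlikely_deleterious"
    no_call = "no_call"


MAMMAL_GROUPS = frozenset({"rodent", "primate", "other_mammal"})
TAXON_GROUPS = MAMMAL_GROUPS | {"non_mammal"}


@dataclass(frozen=True)
class AlignmentColumn:
    """Residues of one alignment column with per-taxon group labels.

    ``residues`` maps taxon name -> (residue, taxon_group); groups are
    'rodent', 'primate', 'other_mammal' or 'non_mammal'.
    """

    residues: Mapping[str, tuple[str, str]]

    def __post_init__(self):
        for taxon, (_, group) in self.residues.items():
            if group not in TAXON_GROUPS:
                raise ValueError(f"unknown taxon group {group!r} for {taxon}")


def comparative_call(
    col: AlignmentColumn, variant_residue: str
) -> ComparativeCall:
    """Rule-based deleteriousness from ortholog-alignment conservation.

    A variant at a position invariable across mammals (and differing from
    the conserved residue) is likely deleterious; invariance extending
    across non-mammals enhances the call.  Positions variable among
    mammals — in particular within rodents or primates — argue against
    deleteriousness.  Fewer than two mammalian taxa -> no call.  The
    result is invariant to taxon ordering.
    """
    mammal = [r for r, g in col.residues.values() if g in MAMMAL_GROUPS]
    non_mammal = [r for r, g in col.residues.values() if g == "non_mammal"]
    if len(mammal) < 2:
        return ComparativeCall.no_call
    if len(set(mammal)) > 1:
        return ComparativeCall.unlikely_deleterious
    conserved = mammal[0]
    if variant_residue == conserved:
        return ComparativeCall.unlikely_deleterious
    if non_mammal and set(non_mammal) == {conserved}:
        return ComparativeCall.likely_deleterious_enhanced
    return ComparativeCall.likely_deleterious
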