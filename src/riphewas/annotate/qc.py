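"""Variant-QC arithmetic for dual-platform call sets."""

from __future__ import annotations

from typing import Mapping


def platform_fpr(
    total_calls: int, shared_calls: int, specific_fpr: float
) -> float:
    """Platform-wide false-positive rate assuming shared calls are valid.

    Calls detected by both platforms are taken as true; only the
    platform-specific remainder carries the resequencing-estimated
    platform-specific FPR.  Returns
    ``(total_calls - shared_calls) * specific_fpr / total_calls``
    as a proportion.
    """
    if total_calls == 0:
        raise ValueError("total_calls must be positive")
    if shared_calls > total_calls:
        raise ValueError("shared_calls cannot exceed total_calls")
    if not 0.0 <= specific_fpr <= 1.0:
        raise ValueError("specific_fpr must be in [0, 1]")
    return (total_calls - shared_calls) * specific_fpr / total_calls


def combine_class_counts(counts: Mapping[str, int]) -> int:
    """Total variant count across per-class tallies (all must be >= 0)."""
    if any(v < 0 for v in counts.values()):
        raise ValueError("class counts must be non-negative")
    return int(sum(counts.values()))
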