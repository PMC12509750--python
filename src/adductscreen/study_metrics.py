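"""Closed-form study metrics: xenograft tumor volume and the two
behavioral indices (Y-maze spontaneous alternation, novel-object
recognition index)."""

from __future__ import annotations

__all__ = ["tumor_volume", "spontaneous_alternation", "recognition_index"]


def tumor_volume(length: float, width: float) -> float:
    """Ellipsoid-approximation tumor volume V = 0.5 x L x W^2 (mm^3).

    ``length`` is the longer caliper axis; both in mm.
    """
    if width <= 0 or length <= 0:
        raise ValueError("length and width must be positive")
    if width > length:
        raise ValueError("width must not exceed length")
    return 0.5 * length * width**2


def spontaneous_alternation(actual_alternations: int, total_entries: int) -> float:
    """Y-maze spontaneous alternation percentage:
    actual alternations / (total arm entries - 2) x 100."""
    if total_entries <= 2:
        raise ValueError("total arm entries must exceed 2")
    if actual_alternations < 0 or actual_alternations > total_entries - 2:
        raise ValueError("alternations must be within [0, total_entries - 2]")
    return actual_alternations / (total_entries - 2) * 100.0


def recognition_index(novel_time: float, familiar_time: float) -> float:
    """Novel-object recognition index: time on the novel object divided by
    total exploration time of both objects."""
    if novel_time < 0 or familiar_time < 0:
        raise ValueError("exploration times must be non-negative")
    total = novel_time + familiar_time
    if total == 0:
        raise ValueError("no exploration time recorded")
    return novel_time / total
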