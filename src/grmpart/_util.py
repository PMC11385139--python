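"""Small shared helpers."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Undefined:
    """Marker for a quantity that cannot be computed, carrying the reason.

    Returned (never raised) wherever a statistic is undefined for a
    legitimate data-dependent reason, e.g. an empty distance stratum or a
    nonpositive variance component under a square root.
    """

    reason: str

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return False

    def __float__(self) -> float:
        return float("nan")


def is_defined(value) -> bool:
    return not isinstance(value, Undefined)
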