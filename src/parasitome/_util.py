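"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float | None, ndigits: int = 1) -> float | None:
    """Round with ties away from zero (half-up), on the decimal repr.

    Python's builtin ``round`` is banker's rounding; reported percentages
    and ratios follow the half-up convention instead.
    """
    if x is None:
        return None
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numer: float, denom: float, ndigits: int = 1) -> float | None:
    """Percentage ``100*numer/denom`` rounded half-up; None when denom is 0."""
    if denom == 0:
        return None
    return round_half_up(100.0 * numer / denom, ndigits)


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage substream seed from one master seed."""
    import hashlib

    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")
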