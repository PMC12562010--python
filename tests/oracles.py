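"""Independent brute-force oracles used by the tests.

The context-window oracle rebuilds each extraction by splicing the variant
into the *full* chromosome string and slicing the result, with window
placement done by clamping (min/max) rather than the implementation's
shift-by-overflow arithmetic.  The two paths share only the contract, not the
code, so coordinate and off-by-one errors in either show up as mismatches.
"""

from __future__ import annotations


def clamp_window(center: int, W: int, L: int) -> tuple[int, int]:
    """Window placement by clamping the nominal start into feasible range."""
    s = min(max(center - W // 2, 1), L - W + 1)
    return s, s + W - 1


def oracle_snv(chrom: str, pos: int, alt: str, W: int) -> str:
    edited = chrom[: pos - 1] + alt + chrom[pos:]
    s, e = clamp_window(pos, W, len(chrom))
    return edited[s - 1 : e]


def oracle_insertion(chrom: str, anchor: int, payload: str, W: int) -> str:
    s, _ = clamp_window(anchor, W, len(chrom))
    mid_abs = s + W // 2  # payload goes before this 1-based position
    edited = chrom[: mid_abs - 1] + payload + chrom[mid_abs - 1 :]
    left = len(payload) // 2
    return edited[s - 1 + left : s - 1 + left + W]


def oracle_deletion(chrom: str, seg_start: int, seg_end: int, W: int) -> str:
    d = seg_end - seg_start + 1
    center = (seg_start + seg_end) // 2
    s, _ = clamp_window(center, W + d, len(chrom))
    edited = chrom[: seg_start - 1] + chrom[seg_end:]
    return edited[s - 1 : s - 1 + W]


def oracle_indel(chrom: str, seg_start: int, seg_end: int, alt: str, W: int) -> str:
    d = seg_end - seg_start + 1
    center = (seg_start + seg_end) // 2
    s, _ = clamp_window(center, W + d, len(chrom))
    edited = chrom[: seg_start - 1] + alt + chrom[seg_end:]
    t = len(alt)
    left = min(max((seg_start - s) - (W // 2 - t // 2), 0), t)
    return edited[s - 1 + left : s - 1 + left + W]
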