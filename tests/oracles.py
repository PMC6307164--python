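"""Independent brute-force oracles for the tract scanner.

Both oracles define a tract the same way the scanner does but by naive
enumeration, kept deliberately separate from the package code path:

* ``char_oracle`` enumerates every (start, end) character interval and
  checks the tract predicate directly — O(n^2), usable only on tiny
  sequences; it validates ``run_oracle``.
* ``run_oracle`` enumerates chains of same-base runs with at most
  ``max_interruptions`` gaps — fast enough for thousands of kb-scale
  sequences.

Both then select non-overlapping maximal tracts by repeatedly taking,
among the remaining valid intervals, the anchor-most one extended as far
as possible: leftmost-start/longest for T (the anchor is the left
edge), rightmost-end/longest for A — the deterministic "maximal tracts
never overlap" rule, mirror-symmetric between the two bases.
"""

from __future__ import annotations

import re

Interval = tuple[int, int, int, int]  # start, end, match_len, n_interruptions


def _select(valid: list[Interval], base: str) -> list[Interval]:
    out: list[Interval] = []
    if base == "T":
        cur_end = -1
        for iv in sorted(valid, key=lambda iv: (iv[0], -iv[1])):
            if iv[0] >= cur_end:
                out.append(iv)
                cur_end = iv[1]
    else:
        cur_start = None
        for iv in sorted(valid, key=lambda iv: (-iv[1], iv[0])):
            if cur_start is None or iv[1] <= cur_start:
                out.append(iv)
                cur_start = iv[0]
        out.reverse()
    return out


def char_oracle(seq: str, base: str, min_matches: int, max_interruptions: int,
                max_gap_len: int) -> list[Interval]:
    seq = seq.upper()
    n = len(seq)
    valid: list[Interval] = []
    for i in range(n):
        if seq[i] != base:
            continue
        for j in range(i + 1, n + 1):
            if seq[j - 1] != base:
                continue
            sub = seq[i:j]
            if any(c not in "ACGT" for c in sub):
                continue
            gaps = re.findall(f"[^{base}]+", sub)
            if len(gaps) > max_interruptions:
                continue
            if any(len(g) > max_gap_len for g in gaps):
                continue
            matches = sub.count(base)
            if matches >= min_matches:
                valid.append((i, j, matches, len(gaps)))
    return _select(valid, base)


def run_oracle(seq: str, base: str, min_matches: int, max_interruptions: int,
               max_gap_len: int) -> list[Interval]:
    seq = seq.upper()
    runs = [m.span() for m in re.finditer(f"{base}+", seq)]
    valid: list[Interval] = []
    for i in range(len(runs)):
        matches = runs[i][1] - runs[i][0]
        for j in range(i, min(i + max_interruptions, len(runs) - 1) + 1):
            if j > i:
                gap = seq[runs[j - 1][1]:runs[j][0]]
                if len(gap) > max_gap_len or not set(gap) <= set("ACGT"):
                    break
                matches += runs[j][1] - runs[j][0]
            if matches >= min_matches:
                valid.append((runs[i][0], runs[j][1], matches, j - i))
    return _select(valid, base)
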