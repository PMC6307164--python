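"""Scan a reference genome for poly(T/A) tracts.

SMART library preparation primes reverse transcription with a poly(dA)
primer that is meant to anneal to enzymatically added 3' T-tails.  The
primer also anneals to genomic runs of T, so every sufficiently long
poly(T) (or, on the opposite strand, poly(A)) tract is a potential
false-priming site.  This module finds those tracts: maximal chains of
same-base runs, optionally bridged by short interruptions, and records
for each one the *anchor* (the primer-proximal boundary: the left edge
of a poly(T) tract, the right edge of a poly(A) tract) and the strand on
which artifact reads accumulate.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from pyfaidx import Fasta

__all__ = [
    "PolySite",
    "scan_sequence",
    "scan_genome",
    "write_sites_bed",
    "read_sites_bed",
]

DEFAULT_MIN_MATCHES = 12
DEFAULT_MAX_INTERRUPTIONS = 2
DEFAULT_MAX_GAP_LEN = 1

_VALID_GAP_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class PolySite:
    """A maximal poly(T) or poly(A) genomic tract.

    Attributes
    ----------
    chrom, start, end:
        Genomic interval, 0-based half-open.  ``sequence[start]`` and
        ``sequence[end - 1]`` always equal ``base`` — tracts never begin
        or end on an interruption.
    base:
        ``"T"`` or ``"A"`` (forward-strand letter of the tract).
    match_len:
        Number of bases inside the interval equal to ``base``;
        ``end - start == match_len + total interruption bases``.
    n_interruptions:
        Number of non-matching gaps bridged inside the tract.
    """

    chrom: str
    start: int
    end: int
    base: str
    match_len: int
    n_interruptions: int

    @property
    def anchor(self) -> int:
        """Primer-proximal boundary: left edge for T, right edge for A."""
        return self.start if self.base == "T" else self.end

    @property
    def affected_strand(self) -> str:
        """Strand on which artifact reads pile up."""
        return "+" if self.base == "T" else "-"

    @property
    def affected_side(self) -> str:
        return "upstream" if self.base == "T" else "downstream"

    @property
    def name(self) -> str:
        return f"{self.base}:{self.match_len}:{self.n_interruptions}"


def _runs(seq: str, base: str) -> list[tuple[int, int]]:
    """Maximal runs of `base` in `seq` as (start, end) pairs."""
    return [m.span() for m in re.finditer(f"{base}+", seq)]


def scan_sequence(
    seq: str,
    chrom: str,
    min_matches: int = DEFAULT_MIN_MATCHES,
    max_interruptions: int = DEFAULT_MAX_INTERRUPTIONS,
    max_gap_len: int = DEFAULT_MAX_GAP_LEN,
) -> list[PolySite]:
    """Find poly(T) and poly(A) tracts on the forward strand of one sequence.

    A tract is a chain of runs of the same base where consecutive runs are
    separated by gaps of 1..max_gap_len A/C/G/T bases, with at most
    max_interruptions gaps per tract and at least min_matches matching
    bases in total.  Chains are extended greedily left to right, so tracts
    of the same base never overlap.  Matching is case-insensitive; bases
    outside A/C/G/T (e.g. N) neither match nor may be bridged as gaps.
    """
    if min_matches < 2:
        raise ValueError(f"min_matches must be >= 2, got {min_matches}")
    if max_interruptions < 0:
        raise ValueError("max_interruptions must be >= 0")
    if max_gap_len < 1:
        raise ValueError("max_gap_len must be >= 1")

    useq = seq.upper()
    out: list[PolySite] = []
    # Chains are extended greedily away from the primer-proximal anchor:
    # left-to-right for T (anchor at the left edge), right-to-left for A
    # (an A tract is a T tract on the minus strand), which keeps scanning
    # exactly symmetric under reverse complement.
    for base in ("T", "A"):
        scan_seq = useq if base == "T" else useq[::-1]
        for start, end, matches, gaps in _greedy_chains(
            scan_seq, base, min_matches, max_interruptions, max_gap_len
        ):
            if base == "A":
                start, end = len(useq) - end, len(useq) - start
            out.append(PolySite(chrom, start, end, base, matches, gaps))
    out.sort(key=lambda s: (s.start, s.end, s.base))
    return out


def _greedy_chains(
    seq: str, base: str, min_matches: int, max_interruptions: int, max_gap_len: int
) -> list[tuple[int, int, int, int]]:
    """Left-greedy maximal run chains: (start, end, match_len, n_gaps)."""
    runs = _runs(seq, base)
    out: list[tuple[int, int, int, int]] = []
    i = 0
    while i < len(runs):
        start, end = runs[i]
        matches = end - start
        gaps = 0
        j = i
        while j + 1 < len(runs) and gaps < max_interruptions:
            gap = seq[runs[j][1]:runs[j + 1][0]]
            if len(gap) > max_gap_len or not set(gap) <= _VALID_GAP_BASES:
                break
            gaps += 1
            j += 1
            end = runs[j][1]
            matches += runs[j][1] - runs[j][0]
        if matches >= min_matches:
            out.append((start, end, matches, gaps))
            i = j + 1
        else:
            i += 1
    return out


def scan_genome(
    fasta_path: str | Path,
    min_matches: int = DEFAULT_MIN_MATCHES,
    max_interruptions: int = DEFAULT_MAX_INTERRUPTIONS,
    max_gap_len: int = DEFAULT_MAX_GAP_LEN,
) -> list[PolySite]:
    """Scan every sequence of a FASTA file for poly(T/A) tracts.

    Returns sites ordered by (FASTA sequence order, start).  All sequences
    are scanned; users subset the FASTA to restrict the assembly.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    sites: list[PolySite] = []
    with Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True) as fa:
        for name in fa.keys():
            seq = str(fa[name][:])
            sites.extend(
                scan_sequence(seq, name, min_matches, max_interruptions, max_gap_len)
            )
    return sites


def write_sites_bed(sites: Iterable[PolySite], path: str | Path) -> None:
    """Write sites as BED6.

    Name column encodes base/match_len/n_interruptions ("T:12:0"), score is
    match_len, strand is the affected strand.  Input must be sorted by
    (chrom, start) within each chromosome block.
    """
    sites = list(sites)
    by_chrom: dict[str, int] = {}
    for s in sites:
        if s.chrom in by_chrom and s.start < by_chrom[s.chrom]:
            raise ValueError("sites must be sorted by (chrom, start)")
        by_chrom[s.chrom] = s.start
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.name}\t"
                f"{s.match_len}\t{s.affected_strand}\n"
            )


def read_sites_bed(path: str | Path) -> list[PolySite]:
    """Read sites written by :func:`write_sites_bed` (lossless round-trip)."""
    sites: list[PolySite] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, _strand = line.split("\t")[:6]
            base, match_len, n_int = name.split(":")
            sites.append(
                PolySite(chrom, int(start), int(end), base, int(match_len), int(n_int))
            )
    return sites


def iter_sites_by_chrom(sites: Iterable[PolySite]) -> Iterator[tuple[str, list[PolySite]]]:
    """Group already-ordered sites by chromosome, preserving order."""
    cur: str | None = None
    block: list[PolySite] = []
    for s in sites:
        if s.chrom != cur:
            if block:
                yield cur, block  # type: ignore[misc]
            cur, block = s.chrom, []
        block.append(s)
    if block:
        yield cur, block  # type: ignore[misc]
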