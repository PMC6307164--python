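"""Paired-end cleaning of poly(dA) false-priming artifacts.

In a paired-end SMART library, Read2 starts at the poly(dA) primer, so
the 5' terminus of Read2 marks the priming position exactly.  Fragments
primed at a genomic poly(T) tract have Read2 on the "-" strand ending at
the tract's left edge; at a poly(A) tract, Read2 on the "+" strand
starting at the right edge.  Independent genuine fragments essentially
never share an identical Read2 terminus inside a tract window, so when
more than ``threshold`` pairs stack at one (site, terminus) coordinate
the whole stack is called artifact and moved to the noise file.

The cleaner streams a coordinate-sorted BAM/SAM twice: pass one collects
terminus stacks, pass two partitions every record into the clean or the
noise output.  Mates of a noise pair always travel together; unmapped,
secondary and supplementary records pass to the clean file unchanged.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pysam

from .sites import PolySite
from .qc import CleanStats, open_alignment_out, check_coordinate_sorted

logger = logging.getLogger(__name__)

__all__ = ["AlignedRead", "ReadPair", "SiteIndex", "classify_pair", "clean_pe"]

DEFAULT_THRESHOLD = 1
DEFAULT_MAX_GAP = 10


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment facts the cleaners need."""

    chrom: str
    start: int  # 0-based leftmost
    end: int  # exclusive rightmost + 1
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class ReadPair:
    name: str
    read2: AlignedRead
    read1: Optional[AlignedRead] = None


class SiteIndex:
    """Look up the poly-site primer window containing a Read2 terminus.

    For a poly(T) site the window is ``[start - max_gap, end]`` and the
    expected Read2 strand is "-" (terminus = exclusive right coordinate);
    for a poly(A) site it is ``[start, end + max_gap]`` with strand "+"
    (terminus = leftmost coordinate).  The window spans the whole tract
    because primer-derived bases may align into it; ``max_gap`` absorbs
    3'-trimming of Read2 (quality/primer trimming can leave a gap between
    the terminus and the tract edge).  When windows of same-base sites
    overlap, the leftmost site in genome order wins.
    """

    def __init__(self, sites: Iterable[PolySite], max_gap: int = DEFAULT_MAX_GAP):
        if max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        self.max_gap = max_gap
        # per (chrom, base): parallel lists of window starts/ends + sites
        self._index: dict[tuple[str, str], tuple[list[int], list[int], list[PolySite]]] = {}
        grouped: dict[tuple[str, str], list[PolySite]] = {}
        for s in sites:
            grouped.setdefault((s.chrom, s.base), []).append(s)
        for key, group in grouped.items():
            group.sort(key=lambda s: (s.start, s.end))
            starts, ends = [], []
            for s in group:
                if s.base == "T":
                    starts.append(s.start - max_gap)
                    ends.append(s.end)
                else:
                    starts.append(s.start)
                    ends.append(s.end + max_gap)
            self._index[key] = (starts, ends, group)
        self._max_window = {
            key: max(e - s for s, e in zip(starts, ends))
            for key, (starts, ends, _) in self._index.items()
        }

    def lookup(self, chrom: str, strand: str, terminus: int) -> Optional[PolySite]:
        """Leftmost site whose primer window (matching strand) contains terminus."""
        base = "T" if strand == "-" else "A"
        entry = self._index.get((chrom, base))
        if entry is None:
            return None
        starts, ends, group = entry
        hi = bisect_right(starts, terminus)
        lo = hi
        floor = terminus - self._max_window[(chrom, base)]
        while lo > 0 and starts[lo - 1] >= floor:
            lo -= 1
        for i in range(lo, hi):
            if terminus <= ends[i]:
                return group[i]
        return None


def classify_pair(
    pair: ReadPair, site_index: SiteIndex, max_gap: int | None = None
) -> Optional[tuple[PolySite, int]]:
    """Return the (site, terminus) stack key for a candidate artifact pair.

    The Read2 5' terminus is the exclusive right coordinate for a "-"
    read and the leftmost coordinate for a "+" read.  Returns None when
    the terminus falls in no primer window (max_gap, if given, must match
    the index it was built with).
    """
    if max_gap is not None and max_gap != site_index.max_gap:
        raise ValueError("max_gap does not match the site index")
    r2 = pair.read2
    terminus = r2.end if r2.strand == "-" else r2.start
    site = site_index.lookup(r2.chrom, r2.strand, terminus)
    if site is None:
        return None
    return (site, terminus)


def _r2_terminus(rec: pysam.AlignedSegment) -> tuple[str, int]:
    if rec.is_reverse:
        return "-", rec.reference_end
    return "+", rec.reference_start


def clean_pe(
    bam_in: str | Path,
    sites: Iterable[PolySite],
    out_clean: str | Path,
    out_noise: str | Path,
    threshold: int = DEFAULT_THRESHOLD,
    max_gap: int = DEFAULT_MAX_GAP,
) -> CleanStats:
    """Partition a coordinate-sorted paired-end alignment file.

    A pair goes to the noise file iff its Read2 terminus stacks at a
    (site, terminus) key shared by strictly more than ``threshold`` pairs.
    Every input record lands in exactly one output; mates are never split.
    """
    bam_in = str(bam_in)
    site_index = SiteIndex(sites, max_gap)

    # pass 1: collect Read2 terminus stacks at poly-site windows
    stacks: dict[tuple[str, int, int, str, int], list[str]] = {}
    site_of_key: dict[tuple, PolySite] = {}
    n_pairs = 0
    n_dup = 0
    n_primary = 0
    with pysam.AlignmentFile(bam_in, require_index=False) as fin:
        check_coordinate_sorted(fin)
        for rec in fin:
            if rec.is_secondary or rec.is_supplementary:
                continue
            n_primary += 1
            if rec.is_duplicate:
                n_dup += 1
            if not rec.is_paired or not rec.is_read2 or rec.is_unmapped:
                continue
            if rec.mate_is_unmapped or rec.reference_id != rec.next_reference_id:
                continue
            n_pairs += 1
            strand, terminus = _r2_terminus(rec)
            site = site_index.lookup(rec.reference_name, strand, terminus)
            if site is None:
                continue
            key = (site.chrom, site.start, site.end, site.base, terminus)
            stacks.setdefault(key, []).append(rec.query_name)
            site_of_key[key] = site

    if n_primary and n_dup / n_primary > 0.2:
        logger.warning(
            "duplicate-flagged fraction %.1f%% > 20%%; consider deduplicating upstream",
            100 * n_dup / n_primary,
        )

    noise_names: set[str] = set()
    per_site_removed: dict[str, int] = {}
    n_candidates = 0
    for key, names in stacks.items():
        n_candidates += len(names)
        if len(names) > threshold:
            noise_names.update(names)
            site = site_of_key[key]
            label = f"{site.chrom}:{site.start}-{site.end}:{site.base}"
            per_site_removed[label] = per_site_removed.get(label, 0) + len(names)

    # pass 2: partition records; track fragment lengths per destination
    params = {"threshold": threshold, "max_gap": max_gap}
    frag_sum = {"clean": 0, "noise": 0}
    frag_n = {"clean": 0, "noise": 0}
    n_records = 0
    with pysam.AlignmentFile(bam_in, require_index=False) as fin:
        with open_alignment_out(out_clean, fin, "cleanpe", params) as fclean, \
             open_alignment_out(out_noise, fin, "cleanpe", params) as fnoise:
            for rec in fin:
                n_records += 1
                to_noise = (
                    not rec.is_secondary
                    and not rec.is_supplementary
                    and not rec.is_unmapped
                    and rec.query_name in noise_names
                )
                dest = "noise" if to_noise else "clean"
                if rec.is_read1 and not rec.is_secondary and not rec.is_supplementary \
                        and rec.template_length != 0:
                    frag_sum[dest] += abs(rec.template_length)
                    frag_n[dest] += 1
                (fnoise if to_noise else fclean).write(rec)

    removed = len(noise_names)
    return CleanStats(
        mode="PE",
        total_records=n_records,
        evaluated=n_pairs,
        candidates=n_candidates,
        removed=removed,
        removed_fraction=removed / n_pairs if n_pairs else 0.0,
        per_site_removed=per_site_removed,
        mean_fragment_length_clean=(
            frag_sum["clean"] / frag_n["clean"] if frag_n["clean"] else None
        ),
        mean_fragment_length_noise=(
            frag_sum["noise"] / frag_n["noise"] if frag_n["noise"] else None
        ),
        parameters=params,
    )
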