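"""Single-end cleaning by strand-balanced resampling around poly sites.

Without Read2 the priming position is unknown, so artifacts are detected
statistically: false priming loads reads onto one strand only (the "+"
strand upstream of a poly(T) tract, the "-" strand downstream of a
poly(A) tract), while genuine coverage is strand-symmetric.  The cleaner
first measures strand-specific read-start distances in the flanks of all
sites to estimate the contaminated window ``w``, builds one resampling
region of width ``w`` per site on its affected side, and then, per
region, downsamples the affected strand to the opposite-strand count
whenever it exceeds ``ratio`` times that count.

Reads are assigned to regions by their 5' end (left end for "+" reads,
right end for "-" reads).  Overlapping regions are processed in genome
order; reads already sent to noise by an earlier region are invisible to
later ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .sites import PolySite
from .qc import CleanStats, open_alignment_out, five_prime, usable

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceProfile",
    "ResampleRegion",
    "distance_profile",
    "estimate_window",
    "build_regions",
    "write_regions_bed",
    "read_regions_bed",
    "clean_se",
]

DEFAULT_FLANK = 2000
DEFAULT_RATIO = 2.0
DEFAULT_RATIO_FLOOR = 1.2
DEFAULT_SMOOTH = 25
DEFAULT_MIN_RUN = 50


@dataclass
class DistanceProfile:
    """Read-5'-end counts by distance from the site anchor, affected side.

    ``affected_counts[d]`` / ``opposite_counts[d]`` hold, for distance
    ``d`` in ``1..flank-1`` toward the affected side, the number of read
    5' ends on the affected / opposite strand, summed over all sites
    (poly(T) and poly(A) merged by mirroring).  Index 0 is unused (a 5'
    end exactly on the anchor belongs to the tract itself).
    """

    flank: int
    affected_counts: np.ndarray
    opposite_counts: np.ndarray

    def total(self) -> int:
        return int(self.affected_counts.sum() + self.opposite_counts.sum())


def distance_profile(
    bam_in: str | Path, sites: Sequence[PolySite], flank: int = DEFAULT_FLANK
) -> DistanceProfile:
    """Measure strand-specific read-start distances in site flanks.

    For a poly(T) site the affected side is upstream: "+"-strand reads
    contribute distance ``anchor - five_prime`` to the affected counts
    and "-"-strand reads the same form to the opposite counts; poly(A)
    sites are mirrored (``five_prime - anchor`` downstream).  Distances
    outside ``(0, flank)`` are ignored.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites supplied")
    if flank <= 0:
        raise ValueError("flank must be > 0")
    affected = np.zeros(flank, dtype=np.int64)
    opposite = np.zeros(flank, dtype=np.int64)
    with pysam.AlignmentFile(str(bam_in)) as fin:
        lengths = dict(zip(fin.references, fin.lengths))
        for s in sites:
            anchor = s.anchor
            if s.base == "T":
                lo, hi = max(0, anchor - flank), min(lengths.get(s.chrom, 0), anchor)
            else:
                lo, hi = max(0, anchor), min(lengths.get(s.chrom, 0), anchor + flank)
            if hi <= lo:
                continue
            for rec in fin.fetch(s.chrom, lo, hi):
                if not usable(rec):
                    continue
                fp = five_prime(rec)
                d = anchor - fp if s.base == "T" else fp - anchor
                if not 0 < d < flank:
                    continue
                strand = "-" if rec.is_reverse else "+"
                if strand == s.affected_strand:
                    affected[d] += 1
                else:
                    opposite[d] += 1
    if affected.sum() + opposite.sum() == 0:
        logger.warning("no read ends counted in site flanks; empty profile")
    return DistanceProfile(flank, affected, opposite)


def _running_mean(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    kernel = np.ones(width) / width
    return np.convolve(x.astype(float), kernel, mode="same")


def estimate_window(
    profile: DistanceProfile,
    ratio_floor: float = DEFAULT_RATIO_FLOOR,
    smooth: int = DEFAULT_SMOOTH,
    min_run: int = DEFAULT_MIN_RUN,
) -> int:
    """Estimate the contaminated window size ``w`` from a distance profile.

    After running-mean smoothing (width ``smooth``), offsets where the
    affected/opposite count ratio reaches ``ratio_floor`` are flagged;
    flagged runs closer than ``min_run`` offsets are merged into blocks,
    blocks whose raw affected excess is within Poisson noise are dropped,
    and ``w`` is the end of the block with the largest excess — the edge
    of the contaminated zone.  A profile with no significant block gives
    ``w = 0`` (no contamination); a block reaching closer than
    ``min_run`` to the flank edge falls back to ``w = flank`` (the
    contamination may extend beyond what was measured).  Deterministic.
    """
    if ratio_floor <= 1:
        raise ValueError("ratio_floor must be > 1")
    if profile.opposite_counts.sum() == 0:
        logger.warning("opposite-strand counts are all zero; falling back to w=flank")
        return profile.flank
    aff = _running_mean(profile.affected_counts, smooth)
    opp = _running_mean(profile.opposite_counts, smooth)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(opp > 0, aff / opp, np.where(aff > 0, np.inf, 1.0))
    exceed = ratio >= ratio_floor
    if not exceed.any():
        return 0

    # merge flagged runs separated by < min_run clean offsets into blocks
    idx = np.nonzero(exceed)[0]
    blocks: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev >= min_run:
            blocks.append((start, prev + 1))
            start = int(i)
        prev = int(i)
    blocks.append((start, prev + 1))

    # keep blocks whose raw excess clears Poisson noise (3 sigma)
    raw_aff = profile.affected_counts
    raw_opp = profile.opposite_counts
    best_end = best_excess = 0.0
    for a, b in blocks:
        excess = float(raw_aff[a:b].sum() - raw_opp[a:b].sum())
        noise = float(np.sqrt(max(raw_aff[a:b].sum() + raw_opp[a:b].sum(), 1)))
        if excess <= 3 * noise:
            continue
        if excess > best_excess:
            best_excess, best_end = excess, b
    if best_excess == 0.0:
        return 0
    w = int(best_end)
    if profile.flank - w < min_run:
        logger.warning(
            "contamination extends to the flank edge; falling back to w=flank"
        )
        return profile.flank
    return w


@dataclass(frozen=True)
class ResampleRegion:
    """Interval adjacent to a site on its affected side.

    poly(T): ``[anchor - w, anchor)`` with affected strand "+";
    poly(A): ``[anchor, anchor + w)`` with affected strand "-";
    truncated at chromosome edges.
    """

    chrom: str
    start: int
    end: int
    affected_strand: str
    site_name: str = "."


def build_regions(
    sites: Sequence[PolySite], w: int, chrom_sizes: dict[str, int]
) -> list[ResampleRegion]:
    """One resampling region per site, in site (genome) order."""
    if w <= 0:
        raise ValueError("window w must be > 0")
    regions: list[ResampleRegion] = []
    for s in sites:
        if s.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {s.chrom!r} in site list")
        size = chrom_sizes[s.chrom]
        if s.base == "T":
            start, end = max(0, s.anchor - w), min(size, s.anchor)
        else:
            start, end = max(0, s.anchor), min(size, s.anchor + w)
        if end <= start:
            continue
        regions.append(ResampleRegion(s.chrom, start, end, s.affected_strand, s.name))
    return regions


def write_regions_bed(regions: Iterable[ResampleRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.site_name}\t0\t{r.affected_strand}\n")


def read_regions_bed(path: str | Path) -> list[ResampleRegion]:
    regions: list[ResampleRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            regions.append(ResampleRegion(chrom, int(start), int(end), strand, name))
    return regions


def _check_region_order(regions: Sequence[ResampleRegion]) -> None:
    cur: str | None = None
    finished: set[str] = set()
    last_start = -1
    for r in regions:
        if r.chrom != cur:
            if r.chrom in finished:
                raise ValueError("regions not grouped by chromosome")
            if cur is not None:
                finished.add(cur)
            cur, last_start = r.chrom, -1
        if r.start < last_start:
            raise ValueError("regions not sorted by start within chromosome")
        last_start = r.start


def clean_se(
    bam_in: str | Path,
    regions: Sequence[ResampleRegion],
    out_clean: str | Path,
    out_noise: str | Path,
    ratio: float = DEFAULT_RATIO,
    seed: int = 0,
) -> CleanStats:
    """Downsample affected-strand reads per region to the opposite count.

    Per region, in genome order: with ``Na`` affected-strand and ``No``
    opposite-strand read 5' ends in the region (reads already sent to
    noise excluded), if ``Na > ratio * No`` a seeded uniform subset of
    exactly ``No`` affected reads is kept and the remaining ``Na - No``
    go to noise; otherwise nothing is removed.  Requires an indexed
    input.  One RNG seeded once drives all regions, so output is
    reproducible for a given seed.
    """
    if ratio <= 1:
        raise ValueError("ratio must be > 1")
    _check_region_order(regions)
    rng = np.random.default_rng(seed)
    noise_names: set[str] = set()
    per_region_removed: dict[str, int] = {}
    evaluated = 0
    with pysam.AlignmentFile(str(bam_in)) as fin:
        if not fin.has_index():
            raise ValueError("clean_se requires a coordinate-sorted, indexed input")
        for r in regions:
            affected: list[tuple[int, str]] = []
            n_opp = 0
            for rec in fin.fetch(r.chrom, r.start, r.end):
                if not usable(rec):
                    continue
                if rec.query_name in noise_names:
                    continue
                fp = five_prime(rec)
                if not r.start <= fp < r.end:
                    continue
                strand = "-" if rec.is_reverse else "+"
                if strand == r.affected_strand:
                    affected.append((fp, rec.query_name))
                else:
                    n_opp += 1
            na = len(affected)
            evaluated += na + n_opp
            if na > ratio * n_opp:
                affected.sort()
                keep = set(rng.choice(na, size=n_opp, replace=False).tolist())
                removed_here = 0
                for i, (_, name) in enumerate(affected):
                    if i not in keep:
                        noise_names.add(name)
                        removed_here += 1
                per_region_removed[f"{r.chrom}:{r.start}-{r.end}:{r.affected_strand}"] = (
                    removed_here
                )

    params = {"ratio": ratio, "seed": seed, "n_regions": len(regions)}
    n_records = 0
    with pysam.AlignmentFile(str(bam_in)) as fin:
        with open_alignment_out(out_clean, fin, "cleanse", params) as fclean, \
             open_alignment_out(out_noise, fin, "cleanse", params) as fnoise:
            for rec in fin:
                n_records += 1
                to_noise = usable(rec) and rec.query_name in noise_names
                (fnoise if to_noise else fclean).write(rec)

    removed = len(noise_names)
    return CleanStats(
        mode="SE",
        total_records=n_records,
        evaluated=evaluated,
        removed=removed,
        removed_fraction=removed / evaluated if evaluated else 0.0,
        per_site_removed=per_region_removed,
        parameters=params,
    )
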