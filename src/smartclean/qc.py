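"""Cleaning reports and aggregated strand-specific read profiles.

The aggregate profile counts read 5' ends per strand at every offset in
``[-flank, +flank)`` around poly-site anchors, summed over sites.  At
genuine-signal-free loci the two strands are symmetric; false priming
shows up as a one-strand excess on the affected side of the anchor
("+" upstream of poly(T) anchors, "-" downstream of poly(A) anchors).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .sites import PolySite

logger = logging.getLogger(__name__)

__all__ = ["CleanStats", "report", "aggregate_profile", "make_control_sites"]

SCHEMA_VERSION = 1


@dataclass
class CleanStats:
    """Counts from one cleaner run.

    ``evaluated`` is pairs (PE) or in-region reads (SE); ``removed`` is
    the number of pairs/reads sent to the noise file; fragment-length
    means are PE-only (from the template-length field) and reported, not
    asserted — artifact fragments tend to run shorter because the primer
    annealed inside the fragment rather than at its tailed end.
    """

    mode: str
    total_records: int
    evaluated: int
    removed: int
    removed_fraction: float
    candidates: int = 0
    per_site_removed: dict[str, int] = field(default_factory=dict)
    mean_fragment_length_clean: Optional[float] = None
    mean_fragment_length_noise: Optional[float] = None
    parameters: dict = field(default_factory=dict)

    @property
    def kept(self) -> int:
        return self.evaluated - self.removed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        d["kept"] = self.kept
        d["removed_fraction"] = round(self.removed_fraction, 6)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CleanStats":
        d = {k: v for k, v in d.items() if k not in ("schema_version", "kept")}
        return cls(**d)


def report(stats: CleanStats, path: str | Path) -> dict:
    """Write a machine-readable JSON cleaning report; returns the dict."""
    d = stats.to_dict()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info(
        "%s cleaning: %d/%d removed (%.4f%%)",
        stats.mode, stats.removed, stats.evaluated, 100 * stats.removed_fraction,
    )
    return d


# --- alignment I/O helpers shared by the cleaners ---

def check_coordinate_sorted(fin: pysam.AlignmentFile) -> None:
    so = fin.header.to_dict().get("HD", {}).get("SO")
    if so is not None and so != "coordinate":
        raise ValueError(f"alignment file must be coordinate-sorted (SO:{so})")


def open_alignment_out(
    path: str | Path, template: pysam.AlignmentFile, tool: str, params: dict
) -> pysam.AlignmentFile:
    """Open a SAM/BAM writer (by extension) with a PG line recording params."""
    header = template.header.to_dict()
    pg = {
        "ID": f"smartclean.{tool}",
        "PN": "smartclean",
        "CL": " ".join(f"{k}={v}" for k, v in params.items()),
    }
    header.setdefault("PG", []).append(pg)
    mode = "w" if str(path).endswith(".sam") else "wb"
    return pysam.AlignmentFile(str(path), mode, header=header)


def five_prime(rec: pysam.AlignedSegment) -> int:
    """0-based coordinate of the read's 5' base (rightmost for "-" reads)."""
    return rec.reference_end - 1 if rec.is_reverse else rec.reference_start


def usable(rec: pysam.AlignedSegment) -> bool:
    return not (rec.is_unmapped or rec.is_secondary or rec.is_supplementary)


# --- aggregate profile ---

def aggregate_profile(
    bam_in: str | Path,
    sites: Sequence[PolySite],
    flank: int = 2000,
    control_sites: Optional[Sequence[tuple[str, int, int]]] = None,
) -> pd.DataFrame:
    """Read-start counts per strand around site anchors, summed over sites.

    Returns a DataFrame indexed by offset in ``[-flank, flank)`` with raw
    per-base-type columns (``T_plus`` ... ``A_minus``, plus
    ``ctrl_plus``/``ctrl_minus`` when control intervals are given, counted
    around interval midpoints) and oriented columns ``affected``/
    ``opposite`` in which poly(A) sites are mirrored so that positive
    offsets always point toward the affected side of the anchor.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("empty site list")
    offsets = np.arange(-flank, flank)
    cols = {name: np.zeros(2 * flank, dtype=np.int64)
            for name in ("T_plus", "T_minus", "A_plus", "A_minus",
                         "affected", "opposite")}
    with pysam.AlignmentFile(str(bam_in)) as fin:
        lengths = dict(zip(fin.references, fin.lengths))
        for s in sites:
            anchor = s.anchor
            lo = max(0, anchor - flank)
            hi = min(lengths.get(s.chrom, 0), anchor + flank)
            if hi <= lo:
                continue
            for rec in fin.fetch(s.chrom, lo, hi):
                if not usable(rec):
                    continue
                off = five_prime(rec) - anchor
                if not -flank <= off < flank:
                    continue
                strand = "-" if rec.is_reverse else "+"
                cols[f"{s.base}_{'plus' if strand == '+' else 'minus'}"][off + flank] += 1
                oriented = -off if s.base == "T" else off
                if -flank <= oriented < flank:
                    which = "affected" if strand == s.affected_strand else "opposite"
                    cols[which][oriented + flank] += 1
        if control_sites:
            for name in ("ctrl_plus", "ctrl_minus"):
                cols[name] = np.zeros(2 * flank, dtype=np.int64)
            for chrom, start, end in control_sites:
                mid = (start + end) // 2
                lo = max(0, mid - flank)
                hi = min(lengths.get(chrom, 0), mid + flank)
                if hi <= lo:
                    continue
                for rec in fin.fetch(chrom, lo, hi):
                    if not usable(rec):
                        continue
                    off = five_prime(rec) - mid
                    if not -flank <= off < flank:
                        continue
                    key = "ctrl_minus" if rec.is_reverse else "ctrl_plus"
                    cols[key][off + flank] += 1
    df = pd.DataFrame(cols, index=pd.Index(offsets, name="offset"))
    return df


def write_profile_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def make_control_sites(
    sites: Sequence[PolySite],
    chrom_sizes: dict[str, int],
    min_region: int = 4000,
    buffer: int = 1000,
    window: int = 2000,
) -> list[tuple[str, int, int]]:
    """Non-poly(T/A) control intervals.

    Takes genomic regions longer than ``min_region`` lying more than
    ``buffer`` away from any site and returns the centered ``window``-bp
    interval of each.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for s in sites:
        if s.chrom in by_chrom:
            by_chrom[s.chrom].append((max(0, s.start - buffer), s.end + buffer))
    out: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        blocked = sorted(by_chrom[chrom])
        merged: list[list[int]] = []
        for a, b in blocked:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        gaps = []
        prev = 0
        for a, b in merged:
            gaps.append((prev, a))
            prev = b
        gaps.append((prev, size))
        for a, b in gaps:
            if b - a > min_region:
                mid = (a + b) // 2
                out.append((chrom, mid - window // 2, mid + window // 2))
    return out
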