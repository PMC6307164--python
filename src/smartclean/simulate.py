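"""Synthetic data: toy genome with planted poly(T/A) tracts and simulated
reads with ground-truth labels.

The generator emulates the false-priming mechanism directly: background
fragments are placed uniformly on both strands; artifact fragments are
anchored so that the primer-side terminus (the Read2 5' end) coincides
with a tract anchor — upstream of a poly(T) tract with Read2 on "-", or
downstream of a poly(A) tract with Read2 on "+" — and identical termini
are repeated to form stacks, because a falsely primed template is PCR-
amplified into many identical fragments.  Reads are written directly as
coordinate-sorted aligned BAM (pure-match CIGAR, constant base quality;
no sequencing-error or duplicate model), with a truth table mapping each
read name to its origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .sites import PolySite

__all__ = [
    "SimConfig",
    "TruthTable",
    "make_genome",
    "simulate_reads",
    "evaluate_cleaning",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Parameters of one simulation.

    Defaults describe a desk-scale input-DNA (control) library: a 1 Mb
    genome in two chromosomes carrying 40 planted tracts of 12-30
    matching bases, 10,000 background fragments placed uniformly on both
    strands, and 500 artifact fragments stacked 2-4 deep at tract
    anchors.  Fragment lengths follow a normal law (mean 200 bp, sd 25)
    truncated to [50, 500]; ``artifact_frag_max`` optionally truncates
    artifact fragments harder, and ``artifact_frag_shift`` shortens their
    mean, mimicking the shorter inserts of falsely primed molecules.
    ``terminus_jitter`` offsets artifact termini from the anchor by up to
    the given number of bases (exercising the cleaner's gap tolerance).
    """

    chrom_length: int = 500_000
    n_chroms: int = 2
    n_tracts: int = 40
    tract_t_fraction: float = 0.5
    tract_len_min: int = 12
    tract_len_max: int = 30
    interruption_prob: float = 0.2
    n_background: int = 10_000
    n_artifact: int = 500
    stack_min: int = 2
    stack_max: int = 4
    peak_regions: Optional[list[tuple[str, int, int]]] = None
    n_peak: int = 0
    frag_mean: float = 200.0
    frag_sd: float = 25.0
    frag_min: int = 50
    frag_max: int = 500
    artifact_frag_max: Optional[int] = None
    artifact_frag_shift: int = 0
    terminus_jitter: int = 0
    read_length: int = 50
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_artifact, self.n_peak, self.n_tracts) < 0:
            raise ValueError("counts must be >= 0")
        if self.read_length > self.frag_max:
            raise ValueError("read_length must not exceed frag_max")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            text = fh.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if data.get("peak_regions"):
            data["peak_regions"] = [tuple(x) for x in data["peak_regions"]]
        return cls(**data)


@dataclass
class TruthTable:
    """Read-name -> origin map with artifact anchoring details."""

    origin: dict[str, str] = field(default_factory=dict)  # background|artifact|peak
    artifact_site: dict[str, str] = field(default_factory=dict)  # name -> site label
    artifact_terminus: dict[str, int] = field(default_factory=dict)

    def add(self, name: str, origin: str,
            site: Optional[PolySite] = None, terminus: Optional[int] = None) -> None:
        self.origin[name] = origin
        if site is not None:
            self.artifact_site[name] = f"{site.chrom}:{site.start}-{site.end}:{site.base}"
            self.artifact_terminus[name] = int(terminus)  # type: ignore[arg-type]

    def names_of(self, origin: str) -> set[str]:
        return {n for n, o in self.origin.items() if o == origin}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\torigin\tsite\tterminus\n")
            for name, origin in sorted(self.origin.items()):
                fh.write(
                    f"{name}\t{origin}\t{self.artifact_site.get(name, '.')}\t"
                    f"{self.artifact_terminus.get(name, '.')}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthTable":
        tt = cls()
        with open(path) as fh:
            next(fh)
            for line in fh:
                name, origin, site, terminus = line.rstrip("\n").split("\t")
                tt.origin[name] = origin
                if site != ".":
                    tt.artifact_site[name] = site
                    tt.artifact_terminus[name] = int(terminus)
        return tt


def make_genome(
    config: SimConfig, fasta_path: str | Path
) -> tuple[Path, list[PolySite]]:
    """Write a random genome with planted poly(T/A) tracts; returns truth sites.

    Background bases are i.i.d. uniform over ACGT.  Planted tracts are
    flanked by C/G so they are maximal, and an interrupted tract carries a
    single C/G gap base at an interior position.  Placements never
    overlap (margin of 2 bp); infeasible placement raises after bounded
    retries.
    """
    rng = np.random.default_rng(config.seed)
    fasta_path = Path(fasta_path)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom = [config.n_tracts // config.n_chroms] * config.n_chroms
    for i in range(config.n_tracts % config.n_chroms):
        per_chrom[i] += 1

    planted: list[PolySite] = []
    with open(fasta_path, "w") as fh:
        for chrom, n_here in zip(chroms, per_chrom):
            seq = rng.choice(_BASES, size=config.chrom_length)
            occupied: list[tuple[int, int]] = []
            for _ in range(n_here):
                match_len = int(rng.integers(config.tract_len_min, config.tract_len_max + 1))
                interrupted = rng.random() < config.interruption_prob
                span = match_len + (1 if interrupted else 0)
                placed = False
                for _attempt in range(1000):
                    start = int(rng.integers(2, config.chrom_length - span - 2))
                    if all(start + span + 3 <= a or start - 3 >= b for a, b in occupied):
                        placed = True
                        break
                if not placed:
                    raise RuntimeError("could not place tract without overlap")
                occupied.append((start, start + span))
                base = "T" if rng.random() < config.tract_t_fraction else "A"
                tract = np.full(span, base.encode(), dtype="S1")
                if interrupted:
                    gap_pos = int(rng.integers(2, span - 2))
                    tract[gap_pos] = rng.choice(np.frombuffer(b"CG", dtype="S1"))
                seq[start:start + span] = tract
                # 2 bp C/G margins: the tract is maximal and cannot chain with
                # a chance-adjacent run at the default gap length of 1
                cg = np.frombuffer(b"CG", dtype="S1")
                seq[start - 2:start] = rng.choice(cg, size=2)
                seq[start + span:start + span + 2] = rng.choice(cg, size=2)
                planted.append(
                    PolySite(chrom, start, start + span, base, match_len,
                             1 if interrupted else 0)
                )
            text = seq.tobytes().decode()
            fh.write(f">{chrom}\n")
            for i in range(0, len(text), 60):
                fh.write(text[i:i + 60] + "\n")
    pysam.faidx(str(fasta_path))
    planted.sort(key=lambda s: (chroms.index(s.chrom), s.start))
    return fasta_path, planted


def _draw_frag_len(rng: np.random.Generator, config: SimConfig,
                   artifact: bool = False) -> int:
    mean = config.frag_mean - (config.artifact_frag_shift if artifact else 0)
    hi = config.frag_max
    if artifact and config.artifact_frag_max is not None:
        hi = config.artifact_frag_max
    lo = max(config.frag_min, config.read_length)
    for _ in range(1000):
        L = int(round(rng.normal(mean, config.frag_sd)))
        if lo <= L <= hi:
            return L
    return lo


def _pair_records(
    name: str, tid: int, frag_start: int, frag_end: int, frag_strand: str,
    read_length: int, paired: bool,
) -> list[pysam.AlignedSegment]:
    """Aligned records for one fragment.

    ``frag_strand`` is the strand of Read1 (the tailed, genuine end of
    the template); Read2 sits at the opposite end on the other strand.
    SE simulations emit Read1 only.
    """
    L = frag_end - frag_start
    rl = min(read_length, L)

    def seg(start: int, reverse: bool, read1: bool, mate_start: int,
            mate_reverse: bool, tlen: int) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment()
        a.query_name = name
        a.reference_id = tid
        a.reference_start = start
        a.mapping_quality = 60
        a.cigarstring = f"{rl}M"
        a.query_sequence = "A" * rl
        a.query_qualities = pysam.qualitystring_to_array("I" * rl)
        a.is_reverse = reverse
        if paired:
            a.is_paired = True
            a.is_proper_pair = True
            a.is_read1 = read1
            a.is_read2 = not read1
            a.next_reference_id = tid
            a.next_reference_start = mate_start
            a.mate_is_reverse = mate_reverse
            a.template_length = tlen
        return a

    if frag_strand == "+":
        r1_start, r1_rev = frag_start, False
        r2_start, r2_rev = frag_end - rl, True
        tlen = L
    else:
        r1_start, r1_rev = frag_end - rl, True
        r2_start, r2_rev = frag_start, False
        tlen = -L
    out = [seg(r1_start, r1_rev, True, r2_start, r2_rev, tlen)]
    if paired:
        out.append(seg(r2_start, r2_rev, False, r1_start, r1_rev, -tlen))
    return out


def simulate_reads(
    fasta_path: str | Path,
    sites: Sequence[PolySite],
    config: SimConfig,
    bam_path: str | Path,
    truth_path: Optional[str | Path] = None,
) -> tuple[Path, TruthTable]:
    """Simulate aligned reads over a genome; returns sorted+indexed BAM and truth.

    Background fragments are uniform in position and strand.  Artifact
    fragments anchor their primer-side terminus at a site anchor: for
    poly(T), the fragment is ``[anchor - L, anchor)`` with Read2 "-" 5'
    at the anchor (Read1 "+"); poly(A) is mirrored.  Stacks repeat one
    terminus ``stack_min..stack_max`` times.  Optional peak fragments are
    placed uniformly inside the configured peak intervals.
    """
    rng = np.random.default_rng(config.seed + 1)
    bam_path = Path(bam_path)
    with pysam.FastaFile(str(fasta_path)) as fa:
        refs = list(fa.references)
        lengths = list(fa.lengths)
    tid_of = {name: i for i, name in enumerate(refs)}
    len_of = dict(zip(refs, lengths))
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": n, "LN": ln} for n, ln in zip(refs, lengths)]}
    )

    truth = TruthTable()
    records: list[pysam.AlignedSegment] = []

    def emit(name: str, chrom: str, fs: int, fe: int, strand: str) -> None:
        records.extend(
            _pair_records(name, tid_of[chrom], fs, fe, strand,
                          config.read_length, config.paired)
        )

    weights = np.asarray(lengths, dtype=float)
    weights /= weights.sum()
    for i in range(config.n_background):
        name = f"bg{i:07d}"
        for _ in range(1000):
            chrom = refs[int(rng.choice(len(refs), p=weights))]
            L = _draw_frag_len(rng, config)
            fs = int(rng.integers(0, len_of[chrom] - L + 1))
            break
        strand = "+" if rng.random() < 0.5 else "-"
        emit(name, chrom, fs, fs + L, strand)
        truth.add(name, "background")

    if config.n_artifact and not sites:
        raise ValueError("artifact fragments requested but no sites supplied")
    k = 0
    while k < config.n_artifact:
        site = sites[int(rng.integers(0, len(sites)))]
        stack = int(rng.integers(config.stack_min, config.stack_max + 1))
        stack = min(stack, config.n_artifact - k)
        jitter = (int(rng.integers(0, config.terminus_jitter + 1))
                  if config.terminus_jitter else 0)
        for _ in range(stack):
            name = f"art{k:07d}"
            L = _draw_frag_len(rng, config, artifact=True)
            if site.base == "T":
                terminus = site.anchor - jitter
                fs, fe, strand = terminus - L, terminus, "+"
            else:
                terminus = site.anchor + jitter
                fs, fe, strand = terminus, terminus + L, "-"
            if fs < 0 or fe > len_of[site.chrom]:
                continue
            emit(name, site.chrom, fs, fe, strand)
            truth.add(name, "artifact", site, terminus)
            k += 1
            if k >= config.n_artifact:
                break

    if config.n_peak and config.peak_regions:
        for i in range(config.n_peak):
            name = f"pk{i:07d}"
            chrom, ps, pe_ = config.peak_regions[
                int(rng.integers(0, len(config.peak_regions)))
            ]
            L = _draw_frag_len(rng, config)
            center = int(rng.integers(ps, pe_))
            fs = max(0, min(center - L // 2, len_of[chrom] - L))
            strand = "+" if rng.random() < 0.5 else "-"
            emit(name, chrom, fs, fs + L, strand)
            truth.add(name, "peak")

    records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name,
                                not a.is_read1))
    unsorted = bam_path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as out:
        for a in records:
            out.write(a)
    pysam.sort("-o", str(bam_path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(bam_path))
    if truth_path is not None:
        truth.write_tsv(truth_path)
    return bam_path, truth


def evaluate_cleaning(
    truth: TruthTable, noise_path: str | Path
) -> dict[str, float]:
    """Score a cleaner's noise output against simulator ground truth.

    Precision / recall / false-removal rate are computed over fragment
    names (a PE pair counts once).  Precision of an empty noise set is
    NaN with ``n_noise = 0``.
    """
    noise_names: set[str] = set()
    with pysam.AlignmentFile(str(noise_path)) as fin:
        for rec in fin:
            noise_names.add(rec.query_name)
    unknown = noise_names - set(truth.origin)
    if unknown:
        raise ValueError(f"{len(unknown)} noise reads absent from truth table")
    artifacts = truth.names_of("artifact")
    non_artifacts = set(truth.origin) - artifacts
    tp = len(noise_names & artifacts)
    fp = len(noise_names - artifacts)
    return {
        "precision": tp / len(noise_names) if noise_names else float("nan"),
        "recall": tp / len(artifacts) if artifacts else float("nan"),
        "false_removal_rate": fp / len(non_artifacts) if non_artifacts else 0.0,
        "n_noise": float(len(noise_names)),
    }
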