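"""Shared fixtures: simulated datasets built once per session in tmp dirs."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

import smartclean as sc


@pytest.fixture(scope="session")
def pe_sim(tmp_path_factory) -> dict:
    """Paired-end simulation under default study conditions.

    1 Mb genome, 40 planted tracts, 10,000 background pairs, 500 artifact
    pairs in stacks of 2-4 at tract anchors.
    """
    d = tmp_path_factory.mktemp("pe_sim")
    cfg = sc.SimConfig(seed=11)
    fasta, planted = sc.make_genome(cfg, d / "sim.fa")
    bam, truth = sc.simulate_reads(fasta, planted, cfg, d / "sim.bam",
                                   d / "sim.truth.tsv")
    return {"dir": d, "config": cfg, "fasta": fasta, "sites": planted,
            "bam": bam, "truth": truth}


@pytest.fixture(scope="session")
def se_sim(tmp_path_factory) -> dict:
    """Single-end simulation with artifact fragments truncated at 300 bp."""
    d = tmp_path_factory.mktemp("se_sim")
    cfg = sc.SimConfig(seed=13, paired=False, artifact_frag_max=300)
    fasta, planted = sc.make_genome(cfg, d / "sim.fa")
    bam, truth = sc.simulate_reads(fasta, planted, cfg, d / "sim.bam",
                                   d / "sim.truth.tsv")
    with pysam.AlignmentFile(str(bam)) as f:
        chrom_sizes = dict(zip(f.references, f.lengths))
    regions = sc.build_regions(planted, 300, chrom_sizes)
    return {"dir": d, "config": cfg, "fasta": fasta, "sites": planted,
            "bam": bam, "truth": truth, "regions": regions,
            "chrom_sizes": chrom_sizes}


@pytest.fixture(scope="session")
def bg_sim(tmp_path_factory) -> dict:
    """Background-only single-end simulation (no artifacts)."""
    d = tmp_path_factory.mktemp("bg_sim")
    cfg = sc.SimConfig(seed=17, paired=False, n_artifact=0)
    fasta, planted = sc.make_genome(cfg, d / "sim.fa")
    bam, truth = sc.simulate_reads(fasta, planted, cfg, d / "sim.bam")
    with pysam.AlignmentFile(str(bam)) as f:
        chrom_sizes = dict(zip(f.references, f.lengths))
    return {"dir": d, "config": cfg, "fasta": fasta, "sites": planted,
            "bam": bam, "truth": truth, "chrom_sizes": chrom_sizes}


def make_sam(path: Path, records: list[dict], chroms: dict[str, int],
             sort_index: bool = False) -> Path:
    """Write a tiny alignment file from dicts of AlignedSegment attributes.

    Keys: name, tid, start, cigar (default '40M'), reverse, paired,
    read1, mate_start, mate_reverse, tlen, flags overrides.
    """
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": n, "LN": ln} for n, ln in chroms.items()]}
    )
    segs = []
    for r in records:
        a = pysam.AlignedSegment(header)
        a.query_name = r["name"]
        a.reference_id = r.get("tid", 0)
        a.reference_start = r["start"]
        a.cigarstring = r.get("cigar", "40M")
        rl = a.infer_query_length()
        a.query_sequence = "A" * rl
        a.query_qualities = pysam.qualitystring_to_array("I" * rl)
        a.mapping_quality = 60
        a.is_reverse = r.get("reverse", False)
        if r.get("paired"):
            a.is_paired = True
            a.is_proper_pair = True
            a.is_read1 = r.get("read1", True)
            a.is_read2 = not r.get("read1", True)
            a.next_reference_id = r.get("tid", 0)
            a.next_reference_start = r.get("mate_start", r["start"])
            a.mate_is_reverse = r.get("mate_reverse", False)
            a.template_length = r.get("tlen", 0)
        segs.append(a)
    segs.sort(key=lambda a: (a.reference_id, a.reference_start))
    if sort_index:
        bam = path.with_suffix(".bam")
        with pysam.AlignmentFile(str(bam), "wb", header=header) as out:
            for a in segs:
                out.write(a)
        pysam.index(str(bam))
        return bam
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in segs:
            out.write(a)
    return path
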