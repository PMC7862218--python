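"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cheatkit.svscan import (
    ALTERNATE,
    AlignmentObservation,
    classify_alignment,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrI,length=100000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Variant allele frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tclone
"""


def write_vcf(path, rows):
    """Write a minimal single-sample VCF; rows are (contig, pos, ref, alt, depth, freq)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for contig, pos, ref, alt, depth, freq in rows:
            ad_alt = round(freq * depth)
            fh.write(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tDP={depth}\t"
                f"DP:AD\t{depth}:{depth - ad_alt},{ad_alt}\n"
            )
    return str(path)


def per_base_coverage_oracle(observations, contig_length, windows):
    """Brute-force per-base depth accumulation, independent of svscan.

    Builds full-length depth arrays base by base and sums them within
    each window; usable for references up to ~10 kb.
    """
    total = np.zeros(contig_length, dtype=np.int64)
    alt = np.zeros(contig_length, dtype=np.int64)
    for obs in observations:
        label = classify_alignment(obs)
        pos = obs.pos
        for op, length in obs.cigar:
            if op in "MDN=X":
                end = min(pos + length, contig_length)
                for b in range(pos, end):
                    total[b] += 1
                    if label == ALTERNATE:
                        alt[b] += 1
                pos += length
    out = []
    for ws, we in windows:
        out.append((int(alt[ws:we].sum()), int(total[ws:we].sum())))
    return out


def random_observations(rng, contig_length, n_reads, contig="chrT"):
    """Random mapped reads with a mix of CIGAR shapes and flags."""
    obs = []
    flag_pool = [99, 147, 83, 163, 97, 145, 81, 161, 0, 16, 113, 177]
    for _ in range(n_reads):
        rl = int(rng.integers(20, 80))
        pos = int(rng.integers(0, max(1, contig_length - rl)))
        shape = rng.integers(0, 4)
        if shape == 0:
            cigar = ((("M", rl)),)
        elif shape == 1:
            clip = int(rng.integers(1, rl))
            cigar = (("M", rl - clip), ("S", clip))
        elif shape == 2:
            d = int(rng.integers(1, 30))
            half = rl // 2
            cigar = (("M", half), ("D", d), ("M", rl - half))
        else:
            ins = int(rng.integers(1, 10))
            half = rl // 2
            cigar = (("M", half), ("I", ins), ("M", rl - half - ins)) if rl - half - ins > 0 else (("M", rl),)
        obs.append(
            AlignmentObservation(
                flag=int(rng.choice(flag_pool)),
                contig=contig,
                pos=pos,
                cigar=cigar,
                mapq=int(rng.integers(0, 61)),
            )
        )
    return obs


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
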