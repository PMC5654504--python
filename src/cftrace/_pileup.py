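"""Vectorised per-position base tallies from SAM/BAM alignments.

A single pass over the reads of one contig produces quality-binned per-base
count arrays; both the error-model estimator and the candidate scanner are
thin consumers of these arrays.  Reads are filtered once (mapping quality,
duplicate / secondary / supplementary flags) and the outermost aligned bases
of each read are trimmed, which suppresses the bulk of end-of-read artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from cftrace._seq import seq_to_codes


def open_alignment(path: str | Path) -> pysam.AlignmentFile:
    mode = "r" if str(path).endswith(".sam") else "rb"
    return pysam.AlignmentFile(str(path), mode)


def reference_dict(reference) -> dict[str, str]:
    """Normalise a reference argument to {contig: sequence}.

    Accepts a dict, a FASTA path, or a pyfaidx.Fasta.
    """
    if isinstance(reference, dict):
        return {c: str(s).upper() for c, s in reference.items()}
    if isinstance(reference, (str, Path)):
        import pyfaidx

        fa = pyfaidx.Fasta(str(reference))
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    # pyfaidx.Fasta or similar mapping-like object
    return {name: str(reference[name][:]).upper() for name in reference.keys()}


def iter_reads(af: pysam.AlignmentFile, chrom: str,
               start: int | None = None, end: int | None = None):
    """Reads of one contig/region; falls back to a full scan without an index."""
    has_index = False
    try:
        has_index = af.has_index()
    except (ValueError, OSError):
        pass
    if has_index:
        yield from af.fetch(chrom, start, end)
        return
    # no index (plain SAM): re-open and scan; reset() mis-seeks on SAM text
    name = af.filename.decode() if isinstance(af.filename, bytes) else af.filename
    with open_alignment(name) as fresh:
        for read in fresh:
            if read.reference_name != chrom:
                continue
            if end is not None and read.reference_start >= end:
                continue
            if start is not None and (read.reference_end or 0) <= start:
                continue
            yield read


def usable(read: pysam.AlignedSegment, min_mapping_quality: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.mapping_quality < min_mapping_quality
    )


def aligned_arrays(read: pysam.AlignedSegment) -> tuple[np.ndarray, np.ndarray]:
    """(query positions, reference positions) of aligned (match) bases."""
    ct = read.cigartuples
    n = read.query_length
    if ct is not None and len(ct) == 1 and ct[0][0] in (0, 7, 8):
        q = np.arange(n, dtype=np.int64)
        return q, read.reference_start + q
    pairs = read.get_aligned_pairs(matches_only=True)
    if not pairs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.asarray(pairs, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


@dataclass
class PiledCounts:
    """Per-position tallies for one contig."""

    chrom: str
    length: int
    quality_bins: tuple[tuple[int, int], ...]
    bin_counts: np.ndarray  # (n_bins, 4, L): interior, mapq-filtered
    hq_counts: np.ndarray   # (4, L): additionally base quality >= hq floor
    depth: np.ndarray       # (L,): all aligned bases of usable reads
    n_reads: int

    def ref_codes(self, refseq: str) -> np.ndarray:
        return seq_to_codes(refseq)

    @property
    def bin_depth(self) -> np.ndarray:
        """(n_bins, L) depth per quality bin (interior, mapq-filtered)."""
        return self.bin_counts.sum(axis=1)


def _qual_to_bin(quality_bins: Sequence[tuple[int, int]]) -> np.ndarray:
    table = np.full(128, -1, dtype=np.int8)
    for i, (lo, hi) in enumerate(quality_bins):
        table[lo: min(hi, 127) + 1] = i
    return table


def accumulate_base_counts(
    alignments: str | Path | pysam.AlignmentFile,
    chrom: str,
    length: int,
    quality_bins: Sequence[tuple[int, int]],
    min_mapping_quality: int = 20,
    min_base_quality: int = 20,
    end_trim: int = 5,
) -> PiledCounts:
    quality_bins = tuple(tuple(b) for b in quality_bins)
    nbins = len(quality_bins)
    bin_counts = np.zeros((nbins, 4, length), dtype=np.int32)
    hq_counts = np.zeros((4, length), dtype=np.int32)
    depth = np.zeros(length, dtype=np.int32)
    qtable = _qual_to_bin(quality_bins)

    owned = not isinstance(alignments, pysam.AlignmentFile)
    af = open_alignment(alignments) if owned else alignments
    n_reads = 0
    try:
        for read in iter_reads(af, chrom):
            if not usable(read, min_mapping_quality):
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            n_reads += 1
            qpos, rpos = aligned_arrays(read)
            if qpos.size == 0:
                continue
            inb = (rpos >= 0) & (rpos < length)
            qpos, rpos = qpos[inb], rpos[inb]
            np.add.at(depth, rpos, 1)

            interior = (qpos >= end_trim) & (qpos < read.query_length - end_trim)
            if not interior.any():
                continue
            qpos, rpos = qpos[interior], rpos[interior]
            codes = seq_to_codes(seq)[qpos]
            quals = np.asarray(read.query_qualities, dtype=np.int16)[qpos]
            known = codes < 4
            codes, rpos, quals = codes[known], rpos[known], quals[known]

            bins = qtable[np.clip(quals, 0, 127)]
            valid = bins >= 0
            np.add.at(bin_counts, (bins[valid], codes[valid], rpos[valid]), 1)
            hq = quals >= min_base_quality
            np.add.at(hq_counts, (codes[hq], rpos[hq]), 1)
    finally:
        if owned:
            af.close()

    return PiledCounts(chrom, length, quality_bins, bin_counts, hq_counts, depth, n_reads)
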