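"""Stage 2 of the somatic caller: haplotype construction and k-mer verification.

For every stage-1 candidate a local variant background haplotype is built by
per-position majority consensus of the alternate-supporting reads, and its
presence in the cfDNA reads / absence in the germline reads is established
with alignment-free k-mer statistics: the haplotype's variant-spanning
k-mers (canonicalised over strand) are looked up in each read, and support
is counted per fragment so overlapping k-mers within one molecule are not
double-counted.

A local de Bruijn assembly of the candidate window guards against artefacts
caused by divergence from the reference: reads that really come from a
diverged paralog carry a whole divergent background, so the candidate
haplotype either fails to appear intact in any assembled contig or the
alternate-read consensus disagrees with the reference at multiple positions
beyond the candidate itself.  Either signal downgrades the verdict to
``assembly_artefact``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from cftrace._seq import canonical_kmer, revcomp

DEFAULT_WINDOW = 30       # haplotype half-width w -> haplotype length 2w+1
DEFAULT_K = 31            # k-mer length
DEFAULT_MIN_KMER_COUNT = 2
DEFAULT_MIN_SUPPORT = 3   # mirrors the 3-read candidate floor
DEFAULT_GERMLINE_TOLERANCE = 0
DEFAULT_MAX_BACKGROUND_MISMATCHES = 2

VERDICTS = ("verified", "germline_contaminated", "assembly_artefact", "insufficient")


@dataclass
class ReadSeq:
    """A read reduced to what verification needs: placement, sequence, molecule."""

    start: int  # 0-based reference start
    seq: str
    fragment: str = ""

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    def base_at(self, pos0: int) -> str | None:
        if self.start <= pos0 < self.end:
            return self.seq[pos0 - self.start]
        return None


def reads_from_bam(bam, chrom: str, start0: int, end0: int,
                   min_mapping_quality: int = 20) -> list[ReadSeq]:
    """Extract ungapped-aligned reads overlapping a window from a BAM."""
    from cftrace import _pileup
    import pysam

    owned = not isinstance(bam, pysam.AlignmentFile)
    af = _pileup.open_alignment(bam) if owned else bam
    out: list[ReadSeq] = []
    try:
        for read in _pileup.iter_reads(af, chrom, max(0, start0), end0):
            if not _pileup.usable(read, min_mapping_quality):
                continue
            seq = read.query_sequence
            ct = read.cigartuples
            if seq is None or ct is None:
                continue
            if len(ct) == 1 and ct[0][0] in (0, 7, 8):
                out.append(ReadSeq(read.reference_start, seq, read.query_name))
            # gapped reads are skipped: indel handling is out of scope
    finally:
        if owned:
            af.close()
    return out


@dataclass
class HaplotypeEvidence:
    """k-mer evidence for one candidate's background haplotype."""

    candidate_key: str
    haplotype: str
    k: int
    spanning_kmers: frozenset[str]
    cfdna_support: int
    germline_support: int
    assembly_confirmed: bool
    verdict: str
    background_mismatches: int = 0
    notes: dict = field(default_factory=dict)


def build_background_haplotype(
    pos0: int,
    alt: str,
    alt_reads: Sequence[ReadSeq],
    reference: str,
    w: int = DEFAULT_WINDOW,
) -> str:
    """Majority-consensus haplotype of the alternate-supporting reads.

    The window is ``[pos0 - w, pos0 + w]`` (clipped at contig ends);
    positions not covered by any alternate read fall back to the reference
    base, ties resolve to the reference base, and the centre is forced to
    the alternate allele.
    """
    if not alt_reads:
        raise ValueError("no alternate-supporting reads to build a haplotype from")
    lo = max(0, pos0 - w)
    hi = min(len(reference), pos0 + w + 1)
    out = []
    for p in range(lo, hi):
        if p == pos0:
            out.append(alt)
            continue
        votes = Counter()
        for read in alt_reads:
            b = read.base_at(p)
            if b is not None and b in "ACGT":
                votes[b] += 1
        refbase = reference[p]
        if not votes:
            out.append(refbase)
            continue
        top = max(votes.values())
        winners = {b for b, c in votes.items() if c == top}
        out.append(refbase if refbase in winners else min(winners))
    return "".join(out)


def consensus_background_mismatches(
    pos0: int,
    alt_reads: Sequence[ReadSeq],
    reference: str,
    ignore_positions: Iterable[int] = (),
) -> int:
    """Non-reference consensus positions across the alternate reads' full span.

    The consensus of the alternate-supporting reads is compared with the
    reference over every position the reads cover (requiring >= 2
    concordant reads away from the candidate, so stray sequencing errors do
    not count); the candidate itself and any supplied positions (known
    germline variants) are ignored.  A true somatic SNV sits on a
    reference-like background (0 extra mismatches); reads imported from a
    diverged paralog disagree at many.
    """
    ignore = set(ignore_positions) | {pos0}
    lo = min(r.start for r in alt_reads)
    hi = max(r.end for r in alt_reads)
    lo, hi = max(0, lo), min(len(reference), hi)
    mismatches = 0
    for p in range(lo, hi):
        if p in ignore:
            continue
        votes = Counter()
        for read in alt_reads:
            b = read.base_at(p)
            if b is not None and b in "ACGT":
                votes[b] += 1
        if not votes:
            continue
        top_base, top = votes.most_common(1)[0]
        if top_base != reference[p] and top >= 2 and top > sum(votes.values()) - top:
            mismatches += 1
    return mismatches


# ---------------------------------------------------------------------------
# local de Bruijn assembly


def local_assemble(
    region_reads: Sequence[ReadSeq | str],
    k: int = DEFAULT_K,
    min_kmer_count: int = DEFAULT_MIN_KMER_COUNT,
) -> set[str]:
    """Assemble a candidate window into unitigs (maximal unbranched paths).

    A de Bruijn graph is built over the k-mers of the reads and their
    reverse complements; nodes below ``min_kmer_count`` abundance are
    dropped, and contigs are read off deterministically.  Contigs are
    deduplicated by canonical orientation.
    """
    if k < 15 or k % 2 == 0:
        raise ValueError("k must be odd and >= 15")
    seqs = [r.seq if isinstance(r, ReadSeq) else r for r in region_reads]

    counts: Counter[str] = Counter()
    edges: set[tuple[str, str]] = set()
    for seq in seqs:
        for oriented in (seq, revcomp(seq)):
            if len(oriented) < k:
                continue
            prev = None
            for i in range(len(oriented) - k + 1):
                kmer = oriented[i: i + k]
                if "N" in kmer:
                    prev = None
                    continue
                counts[kmer] += 1
                if prev is not None:
                    edges.add((prev, kmer))
                prev = kmer

    nodes = {km for km, c in counts.items() if c >= min_kmer_count}
    if not nodes:
        return set()
    succ: dict[str, set[str]] = defaultdict(set)
    pred: dict[str, set[str]] = defaultdict(set)
    for a, b in edges:
        if a in nodes and b in nodes:
            succ[a].add(b)
            pred[b].add(a)

    def is_branchless_extension(a: str, b: str) -> bool:
        return len(succ[a]) == 1 and len(pred[b]) == 1

    contigs: set[str] = set()
    visited: set[str] = set()
    # unitig starts: nodes whose single predecessor edge is not branchless
    for node in sorted(nodes):
        if node in visited:
            continue
        preds = pred[node]
        if len(preds) == 1 and is_branchless_extension(next(iter(preds)), node):
            continue  # interior node; will be reached from its unitig start
        path = [node]
        visited.add(node)
        cur = node
        while len(succ[cur]) == 1:
            nxt = next(iter(succ[cur]))
            if not is_branchless_extension(cur, nxt) or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        contigs.add(path[0] + "".join(p[-1] for p in path[1:]))
    # any remaining nodes are in cycles; emit them deterministically
    for node in sorted(nodes - visited):
        if node in visited:
            continue
        path = [node]
        visited.add(node)
        cur = node
        while len(succ[cur]) == 1:
            nxt = next(iter(succ[cur]))
            if nxt in visited or not is_branchless_extension(cur, nxt):
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        contigs.add(path[0] + "".join(p[-1] for p in path[1:]))
    return {_canonical_contig(c) for c in contigs}


def _canonical_contig(contig: str) -> str:
    rc = revcomp(contig)
    return contig if contig <= rc else rc


def contig_contains(contigs: Iterable[str], haplotype: str) -> bool:
    hap_rc = revcomp(haplotype)
    return any(haplotype in c or hap_rc in c for c in contigs)


def haplotype_core(haplotype: str, centre: int, k: int) -> str:
    """The k-length stretch of the haplotype centred on the variant."""
    half = (k - 1) // 2
    lo = max(0, centre - half)
    hi = min(len(haplotype), lo + k)
    lo = max(0, hi - k)
    return haplotype[lo:hi]


def assembly_supports(contigs: Iterable[str], haplotype: str, centre: int, k: int) -> bool:
    """Whether the assembly reproduces the haplotype around the variant.

    The check anchors on the variant-centred core: it must appear in some
    contig, i.e. the local graph is unbranched across the variant's
    immediate context at assembly abundance.  Demanding the full haplotype
    would punish genuine variants whose flanks are thinly tiled.
    """
    return contig_contains(contigs, haplotype_core(haplotype, centre, k))


# ---------------------------------------------------------------------------
# k-mer verification


def spanning_kmers(haplotype: str, centre: int, k: int) -> frozenset[str]:
    """Canonicalised k-mers of the haplotype overlapping the variant position."""
    if len(haplotype) < k:
        raise ValueError("haplotype shorter than k")
    lo = max(0, centre - k + 1)
    hi = min(len(haplotype) - k, centre)
    return frozenset(canonical_kmer(haplotype[i: i + k]) for i in range(lo, hi + 1))


def _read_support(reads: Sequence[ReadSeq | str], kmers: frozenset[str], k: int) -> int:
    """Number of distinct molecules containing at least one spanning k-mer."""
    supporting: set[str] = set()
    for i, r in enumerate(reads):
        seq = r.seq if isinstance(r, ReadSeq) else r
        frag = (r.fragment or f"#{i}") if isinstance(r, ReadSeq) else f"#{i}"
        if frag in supporting:
            continue
        for j in range(len(seq) - k + 1):
            if canonical_kmer(seq[j: j + k]) in kmers:
                supporting.add(frag)
                break
    return len(supporting)


def kmer_verify(
    haplotype: str,
    cfdna_reads: Sequence[ReadSeq | str],
    germline_reads: Sequence[ReadSeq | str],
    k: int = DEFAULT_K,
    min_support: int = DEFAULT_MIN_SUPPORT,
    germline_tolerance: int = DEFAULT_GERMLINE_TOLERANCE,
    centre: int | None = None,
    contigs: set[str] | None = None,
    candidate_key: str = "",
    background_mismatches: int = 0,
    max_background_mismatches: int = DEFAULT_MAX_BACKGROUND_MISMATCHES,
) -> HaplotypeEvidence:
    """Verify haplotype presence in cfDNA and absence in the germline.

    Support is the number of distinct molecules carrying at least one
    variant-spanning k-mer (canonicalised, so verification is strand
    symmetric).  Verdict precedence: germline contamination, insufficient
    cfDNA support, assembly artefact (haplotype absent from every assembled
    cfDNA contig, or a divergent read background), else verified.
    """
    if centre is None:
        centre = len(haplotype) // 2
    kmers = spanning_kmers(haplotype, centre, k)
    cf = _read_support(cfdna_reads, kmers, k)
    gl = _read_support(germline_reads, kmers, k)

    if contigs is None:
        contigs = local_assemble(cfdna_reads, k=k)
    confirmed = assembly_supports(contigs, haplotype, centre, k)
    if not confirmed:
        # the intact core present in enough reads carries the same evidence
        # as an assembled unitig
        core = haplotype_core(haplotype, centre, k)
        core_rc = revcomp(core)
        core_reads = 0
        for r in cfdna_reads:
            seq = r.seq if isinstance(r, ReadSeq) else r
            if core in seq or core_rc in seq:
                core_reads += 1
        confirmed = core_reads >= DEFAULT_MIN_KMER_COUNT

    # a silent assembly only condemns the candidate when read support was
    # ample enough that an intact core should have assembled; thin support
    # is judged by spanning-k-mer consistency and the background alone
    assembly_condemns = not confirmed and cf >= 2 * min_support

    if gl > germline_tolerance:
        verdict = "germline_contaminated"
    elif cf < min_support:
        verdict = "insufficient"
    elif background_mismatches >= max_background_mismatches or assembly_condemns:
        verdict = "assembly_artefact"
    else:
        verdict = "verified"
    return HaplotypeEvidence(
        candidate_key=candidate_key,
        haplotype=haplotype,
        k=k,
        spanning_kmers=kmers,
        cfdna_support=cf,
        germline_support=gl,
        assembly_confirmed=confirmed,
        verdict=verdict,
        background_mismatches=background_mismatches,
    )


def verify_reads(
    pos0: int,
    alt: str,
    cf_reads: Sequence[ReadSeq],
    gl_reads: Sequence[ReadSeq],
    refseq: str,
    het_positions: Iterable[int] = (),
    w: int = DEFAULT_WINDOW,
    k: int = DEFAULT_K,
    min_kmer_count: int = DEFAULT_MIN_KMER_COUNT,
    min_support: int = DEFAULT_MIN_SUPPORT,
    germline_tolerance: int = DEFAULT_GERMLINE_TOLERANCE,
    max_background_mismatches: int = DEFAULT_MAX_BACKGROUND_MISMATCHES,
    candidate_key: str = "",
) -> HaplotypeEvidence:
    """Verify one candidate from in-memory read sets.

    Builds the background haplotype from the alternate-supporting cfDNA
    reads, assembles the candidate window, measures the divergent-background
    mismatch count and delegates the verdict to :func:`kmer_verify`.
    """
    alt_reads = [r for r in cf_reads if r.base_at(pos0) == alt]
    if not alt_reads:
        return HaplotypeEvidence(
            candidate_key=candidate_key, haplotype="", k=k,
            spanning_kmers=frozenset(), cfdna_support=0, germline_support=0,
            assembly_confirmed=False, verdict="insufficient",
        )
    # the molecule, not the read, carries the background: pull in mates of
    # alternate-carrying fragments so the consensus spans the whole insert
    alt_frags = {r.fragment for r in alt_reads if r.fragment}
    alt_molecule_reads = [
        r for r in cf_reads if r.fragment and r.fragment in alt_frags
    ] or alt_reads
    haplotype = build_background_haplotype(pos0, alt, alt_molecule_reads, refseq, w)
    centre = pos0 - max(0, pos0 - w)
    mismatches = consensus_background_mismatches(
        pos0, alt_molecule_reads, refseq, het_positions
    )
    window_reads = [r for r in cf_reads if r.start < pos0 + w + 1 and r.end > pos0 - w]
    contigs = local_assemble(window_reads, k=k, min_kmer_count=min_kmer_count)
    return kmer_verify(
        haplotype, cf_reads, gl_reads, k=k,
        min_support=min_support, germline_tolerance=germline_tolerance,
        centre=centre, contigs=contigs, candidate_key=candidate_key,
        background_mismatches=mismatches,
        max_background_mismatches=max_background_mismatches,
    )


def verify_candidate(
    candidate,
    cfdna_bam,
    germline_bam,
    reference,
    germline_genotypes: Mapping[tuple[str, int], frozenset[str]] | None = None,
    w: int = DEFAULT_WINDOW,
    k: int = DEFAULT_K,
    min_kmer_count: int = DEFAULT_MIN_KMER_COUNT,
    min_support: int = DEFAULT_MIN_SUPPORT,
    germline_tolerance: int = DEFAULT_GERMLINE_TOLERANCE,
    max_background_mismatches: int = DEFAULT_MAX_BACKGROUND_MISMATCHES,
) -> HaplotypeEvidence:
    """End-to-end verification of one stage-1 candidate against BAMs."""
    from cftrace._pileup import reference_dict

    refdict = reference_dict(reference)
    refseq = refdict[candidate.chrom]
    pos0 = candidate.pos - 1
    fetch_lo, fetch_hi = pos0 - w - 200, pos0 + w + 201
    cf_reads = reads_from_bam(cfdna_bam, candidate.chrom, fetch_lo, fetch_hi)
    gl_reads = reads_from_bam(germline_bam, candidate.chrom, fetch_lo, fetch_hi)
    het_positions = set()
    if germline_genotypes:
        het_positions = {
            p - 1 for (c, p) in germline_genotypes if c == candidate.chrom
        }
    return verify_reads(
        pos0, candidate.alt, cf_reads, gl_reads, refseq, het_positions,
        w=w, k=k, min_kmer_count=min_kmer_count, min_support=min_support,
        germline_tolerance=germline_tolerance,
        max_background_mismatches=max_background_mismatches,
        candidate_key=candidate.key,
    )
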