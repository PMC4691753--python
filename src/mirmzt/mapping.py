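"""Deterministic short-read alignment and multi-map-corrected microRNA counting.

The mapper reproduces the report-all-best-stratum policy of classic short
read aligners run with ``-v <mm> -a --best --strata -m <cap>``: all hits at
the lowest observed mismatch level are reported, reads hitting more than
``max_loci`` genomic positions are discarded, and a retained read mapping to
n positions contributes 1/n of its collapsed count to each mature microRNA
it overlaps. Expression is normalised as reads per million genome-mapped
reads (RPM).

A read is assigned to a mature microRNA when its alignment is on the mature's
strand, starts (5') within +/-3 nt of the annotated mature 5' end, and is
contained in the hairpin; microRNA 5' ends are homogeneous, so the 5' anchor
is the robust assignment key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirmzt.catalog import MatureMirna, MirnaLocus
from mirmzt.sequtils import revcomp, to_dna

MIN_READ_LENGTH = 16  # shorter reads are dropped before mapping


@dataclass(frozen=True)
class CollapsedRead:
    """A collapsed (unique-sequence) small-RNA read with its multiplicity."""

    id: str
    seq: str
    count: int

    def __post_init__(self):
        object.__setattr__(self, "seq", to_dna(self.seq))
        if self.count < 1:
            raise ValueError(f"read {self.id}: count must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    chrom: str
    strand: str
    start: int  # 0-based
    end: int  # half-open
    mismatches: int


class GenomeRef:
    """In-memory reference genome: chromosome name -> uppercase DNA string."""

    def __init__(self, chroms: dict[str, str]):
        if len(set(chroms)) != len(chroms):
            raise ValueError("duplicate chromosome names")
        self.chroms: dict[str, str] = {}
        for name, seq in chroms.items():
            self.chroms[name] = to_dna(seq)
        self._arrays: dict[str, np.ndarray] = {}
        # memo of map_read results; collapsed libraries and iterative
        # 3'-trimming re-query the same sequences heavily
        self._hit_cache: dict[tuple[str, int], tuple] = {}

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end]

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def array(self, chrom: str) -> np.ndarray:
        """Chromosome as a uint8 byte array (cached; used for mismatch scans)."""
        if chrom not in self._arrays:
            self._arrays[chrom] = np.frombuffer(
                self.chroms[chrom].encode("ascii"), dtype=np.uint8
            )
        return self._arrays[chrom]

    def contains_substring(self, seq: str) -> bool:
        """True if ``seq`` occurs verbatim on either strand (exact match)."""
        s = to_dna(seq)
        rc = revcomp(s)
        return any(s in c or rc in c for c in self.chroms.values())


def _exact_hits(genome: GenomeRef, seq: str) -> list[AlignmentHit]:
    hits = []
    rc = revcomp(seq)
    n = len(seq)
    for chrom, chromseq in genome.chroms.items():
        for query, strand in ((seq, "+"), (rc, "-")):
            pos = chromseq.find(query)
            while pos != -1:
                hits.append(AlignmentHit(chrom, strand, pos, pos + n, 0))
                pos = chromseq.find(query, pos + 1)
    return hits


_N_BYTE = ord("N")


def _mismatch_hits(genome: GenomeRef, seq: str, max_mismatches: int) -> list[AlignmentHit]:
    # Exhaustive sliding-window scan; N in genome or read never matches.
    hits = []
    n = len(seq)
    for chrom in genome.chroms:
        arr = genome.array(chrom)
        if len(arr) < n:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, n)
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
            mm = ((windows != q) | (windows == _N_BYTE) | (q == _N_BYTE)).sum(axis=1)
            for pos in np.flatnonzero(mm <= max_mismatches):
                hits.append(AlignmentHit(chrom, strand, int(pos), int(pos) + n, int(mm[pos])))
    return hits


def map_read(genome: GenomeRef, seq: str, max_mismatches: int = 1) -> list[AlignmentHit]:
    """Align a read against both strands, reporting the best stratum only.

    If any 0-mismatch hit exists, only 0-mismatch hits are returned; otherwise
    only hits at the lowest observed mismatch count <= ``max_mismatches``.
    Reverse-strand hits report the genomic interval matched by the read's
    reverse complement. U is treated as T; other non-ACGTN characters raise.
    """
    s = to_dna(seq)
    if len(s) < MIN_READ_LENGTH:
        raise ValueError(
            f"read of length {len(s)} below the {MIN_READ_LENGTH} nt minimum"
        )
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    key = (s, max_mismatches)
    cached = genome._hit_cache.get(key)
    if cached is not None:
        return list(cached)
    if max_mismatches == 0:
        hits = _exact_hits(genome, s)
    else:
        hits = _mismatch_hits(genome, s, max_mismatches)
        if hits:
            best = min(h.mismatches for h in hits)
            hits = [h for h in hits if h.mismatches == best]
    hits = sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))
    genome._hit_cache[key] = tuple(hits)
    return hits


@dataclass
class CountMatrix:
    """Mature microRNA x library fractional counts with per-library totals.

    ``counts`` rows are mature ids, columns library ids; ``totals`` holds the
    genome-mapped read count per library (denominator for RPM).
    """

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self):
        self.totals = self.totals.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


@dataclass
class LibraryMapping:
    """Per-library counting result: one CountMatrix column plus a summary."""

    column: pd.Series  # mature id -> fractional count
    mapped_total: float  # genome-mapped read count (multimapper cap applied)
    discarded_multimapper: float
    unmapped: float


def _mature_index(loci: list[MirnaLocus]) -> list[tuple[str, str, str, int, int, int]]:
    # (mature_id, chrom, strand, hairpin_start, hairpin_end, mature_5p_pos)
    index = []
    for locus in loci:
        for m in locus.matures:
            index.append(
                (m.id, locus.chrom, locus.strand, locus.start, locus.end,
                 locus.mature_5p_position(m))
            )
    return index


def assign_matures(
    hit: AlignmentHit,
    loci: list[MirnaLocus],
    anchor_tolerance: int = 3,
    _index=None,
) -> list[str]:
    """Mature microRNAs a hit is assigned to under the 5'-anchor rule."""
    index = _index if _index is not None else _mature_index(loci)
    read_5p = hit.start if hit.strand == "+" else hit.end - 1
    assigned = []
    for mid, chrom, strand, hstart, hend, m5p in index:
        if (
            hit.chrom == chrom
            and hit.strand == strand
            and hstart <= hit.start
            and hit.end <= hend
            and abs(read_5p - m5p) <= anchor_tolerance
        ):
            assigned.append(mid)
    return assigned


def quantify_library(
    reads: list[CollapsedRead],
    genome: GenomeRef,
    loci: list[MirnaLocus],
    max_loci: int = 5,
    max_mismatches: int = 1,
    exclude: list[tuple[str, int, int]] | None = None,
) -> LibraryMapping:
    """Count reads per mature microRNA with multi-mapping correction.

    Reads with more than ``max_loci`` best-stratum hits are discarded; a read
    with n <= max_loci hits contributes count/n to each mature microRNA
    overlapped by each hit (5'-anchor rule). ``exclude`` optionally lists
    genomic intervals (chrom, start, end) whose hits disqualify a read
    entirely — a stand-in for upstream filtering of reads from abundant
    non-microRNA loci such as tRNA genes.
    """
    mature_ids = [mid for mid, *_ in _mature_index(loci)]
    column = pd.Series(0.0, index=pd.Index(mature_ids, name="mature"), dtype=float)
    index = _mature_index(loci)
    mapped = discarded = unmapped = 0.0
    for read in reads:
        if len(read.seq) < MIN_READ_LENGTH:
            unmapped += read.count
            continue
        hits = map_read(genome, read.seq, max_mismatches)
        if not hits:
            unmapped += read.count
            continue
        if exclude and any(
            h.chrom == c and h.start < e and s < h.end
            for h in hits
            for (c, s, e) in exclude
        ):
            unmapped += read.count
            continue
        if len(hits) > max_loci:
            discarded += read.count
            continue
        mapped += read.count
        share = read.count / len(hits)
        for hit in hits:
            for mid in assign_matures(hit, loci, _index=index):
                column[mid] += share
    return LibraryMapping(
        column=column,
        mapped_total=mapped,
        discarded_multimapper=discarded,
        unmapped=unmapped,
    )


def build_count_matrix(per_library: dict[str, LibraryMapping]) -> CountMatrix:
    """Assemble per-library counting results into one CountMatrix."""
    counts = pd.DataFrame({lib: lm.column for lib, lm in per_library.items()})
    totals = pd.Series({lib: lm.mapped_total for lib, lm in per_library.items()})
    return CountMatrix(counts=counts, totals=totals)


def rpm(matrix: CountMatrix) -> CountMatrix:
    """Reads-per-million normalisation against per-library mapped totals."""
    zero = matrix.totals[matrix.totals <= 0]
    if len(zero):
        raise ValueError(
            f"zero genome-mapped total for libraries: {list(zero.index)}"
        )
    normalised = matrix.counts * 1e6 / matrix.totals
    return CountMatrix(counts=normalised, totals=matrix.totals.copy())
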