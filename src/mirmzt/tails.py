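"""Nontemplated 3'-end addition ("tailing") detection by iterative 3' trimming.

Mature microRNAs are frequently extended post-transcriptionally by one or a
few nontemplated nucleotides at the 3' end — in early insect eggs this
modification is dominated by oligoadenylation of maternally deposited
microRNAs. The caller detects such tails from genome alignment alone: a read
that fails to map perfectly is trimmed by 1 nt from its 3' end and remapped,
repeatedly, until a perfect hit is found or the remaining prefix falls below
a minimum length. On success the read is decomposed into the longest
perfectly templated prefix and the remaining nontemplated tail.

Only tails that differ from the genomic continuation are visible this way:
an appended nucleotide identical to the base immediately 3' of the cleavage
site is absorbed into the templated prefix, so any estimate of the modified
fraction is conservative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirmzt.catalog import MirnaLocus
from mirmzt.mapping import (
    AlignmentHit,
    CollapsedRead,
    GenomeRef,
    _mature_index,
    assign_matures,
    map_read,
)

NUCLEOTIDES = ("A", "C", "G", "T")
COMPOSITION_POSITIONS = 5  # tail positions summarised in the composition matrix

UNTAILED = "untailed"
TAILED = "tailed"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class TailCall:
    """Decomposition of one read into templated prefix + nontemplated tail.

    ``hits`` are the perfect alignments of the prefix (best stratum is the
    0-mismatch stratum by construction). Invariant: prefix + tail = read;
    at every hit the genomic base immediately 3' of the prefix differs from
    the first tail base — otherwise a longer prefix would have mapped.
    """

    read_id: str
    seq: str
    prefix_len: int
    tail: str
    hits: tuple[AlignmentHit, ...]
    count: int
    matures: tuple[str, ...] = field(default_factory=tuple)

    @property
    def prefix(self) -> str:
        return self.seq[: self.prefix_len]


@dataclass(frozen=True)
class TailResult:
    """Three-way outcome of tail calling for one read."""

    status: str  # UNTAILED | TAILED | UNMAPPED
    call: TailCall | None = None
    hits: tuple[AlignmentHit, ...] = ()  # full-read hits when untailed


def call_tail(genome: GenomeRef, read: CollapsedRead, min_prefix: int = 16) -> TailResult:
    """Call a nontemplated 3' tail on one read by iterative 3' trimming.

    If the full read maps with 0 mismatches the read is untailed. Otherwise
    one base at a time is removed from the 3' end and the prefix remapped;
    the first (longest) perfectly mapping prefix defines the tail. If no
    prefix of length >= ``min_prefix`` maps, the read is unmapped.
    """
    from mirmzt.mapping import MIN_READ_LENGTH

    min_prefix = max(min_prefix, MIN_READ_LENGTH)
    seq = read.seq
    if len(seq) < min_prefix:
        return TailResult(status=UNMAPPED)
    full_hits = map_read(genome, seq, max_mismatches=0)
    if full_hits:
        return TailResult(status=UNTAILED, hits=tuple(full_hits))
    for prefix_len in range(len(seq) - 1, min_prefix - 1, -1):
        hits = map_read(genome, seq[:prefix_len], max_mismatches=0)
        if hits:
            call = TailCall(
                read_id=read.id,
                seq=seq,
                prefix_len=prefix_len,
                tail=seq[prefix_len:],
                hits=tuple(hits),
                count=read.count,
            )
            return TailResult(status=TAILED, call=call)
    return TailResult(status=UNMAPPED)


@dataclass
class LibraryTailCalls:
    """Tail calls for one library, with mature assignment attached."""

    tailed: list[TailCall]
    untailed: list[tuple[CollapsedRead, tuple[AlignmentHit, ...]]]
    unmapped: list[CollapsedRead]


def call_library(
    genome: GenomeRef,
    reads: list[CollapsedRead],
    loci: list[MirnaLocus],
    min_prefix: int = 16,
    anchor_tolerance: int = 3,
) -> LibraryTailCalls:
    """Run the tail caller over a collapsed library and assign matures.

    Mature assignment uses the same 5'-anchor rule as read counting, applied
    to the prefix alignment for tailed reads and the full-read alignment for
    untailed reads.
    """
    index = _mature_index(loci)
    tailed: list[TailCall] = []
    untailed: list[tuple[CollapsedRead, tuple[AlignmentHit, ...]]] = []
    unmapped: list[CollapsedRead] = []
    for read in reads:
        result = call_tail(genome, read, min_prefix=min_prefix)
        if result.status == UNMAPPED:
            unmapped.append(read)
        elif result.status == UNTAILED:
            untailed.append((read, result.hits))
        else:
            call = result.call
            matures: list[str] = []
            for hit in call.hits:
                matures.extend(
                    assign_matures(hit, loci, anchor_tolerance, _index=index)
                )
            tailed.append(
                TailCall(
                    read_id=call.read_id,
                    seq=call.seq,
                    prefix_len=call.prefix_len,
                    tail=call.tail,
                    hits=call.hits,
                    count=call.count,
                    matures=tuple(sorted(set(matures))),
                )
            )
    return LibraryTailCalls(tailed=tailed, untailed=untailed, unmapped=unmapped)


@dataclass
class TailSummary:
    """Library-level tailing summary.

    ``composition`` rows are tail positions 1..5, columns A/C/G/T; each row
    is normalised over the (count-weighted) nucleotides observed at that
    position, NaN where no tail reaches the position. Tails longer than 5 nt
    contribute only their first five positions to the matrix but their full
    length to the histogram.
    """

    modified_proportion: float
    per_mature: pd.DataFrame  # columns: modified, unmodified, proportion
    length_histogram: dict[int, float]
    composition: pd.DataFrame
    total_reads: float  # modified + unmodified (count-weighted)


def summarize_tails(
    calls: LibraryTailCalls,
    loci: list[MirnaLocus],
    anchor_tolerance: int = 3,
) -> TailSummary:
    """Summarise tail calls: modified fractions, lengths, composition.

    The modified proportion is modified / (modified + unmodified) read
    counts; unmapped reads are excluded from the denominator. Per-mature
    proportions use fractional (1/n) assignment when a read's alignments
    touch several matures. All statistics are weighted by collapsed counts.
    """
    index = _mature_index(loci)
    mature_ids = [mid for mid, *_ in index]
    per = pd.DataFrame(
        0.0, index=pd.Index(mature_ids, name="mature"), columns=["modified", "unmodified"]
    )

    modified_total = float(sum(c.count for c in calls.tailed))
    unmodified_total = float(sum(r.count for r, _ in calls.untailed))

    for call in calls.tailed:
        if call.matures:
            share = call.count / len(call.matures)
            for mid in call.matures:
                per.loc[mid, "modified"] += share
    for read, hits in calls.untailed:
        assigned = sorted(
            {m for h in hits for m in assign_matures(h, loci, anchor_tolerance, _index=index)}
        )
        if assigned:
            share = read.count / len(assigned)
            for mid in assigned:
                per.loc[mid, "unmodified"] += share

    totals = per["modified"] + per["unmodified"]
    with np.errstate(invalid="ignore", divide="ignore"):
        per["proportion"] = np.where(totals > 0, per["modified"] / totals, np.nan)

    hist: dict[int, float] = {}
    comp = np.zeros((COMPOSITION_POSITIONS, len(NUCLEOTIDES)))
    for call in calls.tailed:
        hist[len(call.tail)] = hist.get(len(call.tail), 0.0) + call.count
        for pos, base in enumerate(call.tail[:COMPOSITION_POSITIONS]):
            comp[pos, NUCLEOTIDES.index(base)] += call.count
    row_sums = comp.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        comp_freq = np.where(row_sums > 0, comp / row_sums, np.nan)
    composition = pd.DataFrame(
        comp_freq,
        index=pd.Index(range(1, COMPOSITION_POSITIONS + 1), name="tail_position"),
        columns=list(NUCLEOTIDES),
    )

    denominator = modified_total + unmodified_total
    proportion = modified_total / denominator if denominator > 0 else float("nan")
    return TailSummary(
        modified_proportion=proportion,
        per_mature=per,
        length_histogram=dict(sorted(hist.items())),
        composition=composition,
        total_reads=denominator,
    )
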