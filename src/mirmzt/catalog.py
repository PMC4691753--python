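"""MicroRNA locus records, genomic clustering, and seed-family grouping.

MicroRNA genes frequently occur in genomic clusters that are transcribed
together; here loci are chained into clusters whenever consecutive hairpins
on the same chromosome lie within a fixed distance (10 kb by default) of
each other. Mature microRNAs are additionally grouped into "seed families":
sets of matures sharing an identical seed (nucleotides 2-7, optionally
extended to 8, of the mature 5' end), the primary determinant of canonical
target recognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mirmzt.sequtils import to_rna


@dataclass(frozen=True)
class MatureMirna:
    """A mature microRNA arm excised from a hairpin precursor.

    Coordinates are 0-based half-open on the chromosome of the parent
    hairpin. ``seq`` is the mature sequence in RNA alphabet, 5'->3'.
    """

    id: str
    arm: str  # "5p" | "3p"
    start: int
    end: int
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", to_rna(self.seq))
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be '5p' or '3p', got {self.arm!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid mature interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class MirnaLocus:
    """A hairpin precursor locus with its annotated mature arms."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    matures: tuple[MatureMirna, ...] = field(default_factory=tuple)
    family: str | None = None  # supplied from annotation, never computed

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid hairpin interval [{self.start}, {self.end})")
        object.__setattr__(self, "matures", tuple(self.matures))
        for m in self.matures:
            if not (self.start <= m.start and m.end <= self.end):
                raise ValueError(
                    f"mature {m.id} interval [{m.start}, {m.end}) outside "
                    f"hairpin {self.id} [{self.start}, {self.end})"
                )

    def mature_5p_position(self, mature: MatureMirna) -> int:
        """Genomic coordinate of the mature 5' end (strand-aware).

        For a minus-strand locus the 5'-most base of the mature is the last
        base of its genomic interval.
        """
        return mature.start if self.strand == "+" else mature.end - 1


@dataclass(frozen=True)
class SeedFamily:
    """Mature microRNAs sharing an identical 6/7/8-mer seed."""

    seed: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.seed) not in (6, 7, 8):
            raise ValueError("seed length must be 6, 7 or 8")


def cluster_loci(loci: list[MirnaLocus], max_gap: int = 10_000) -> list[list[MirnaLocus]]:
    """Chain microRNA loci into genomic clusters (single linkage).

    Two consecutive loci on the same chromosome join a cluster when the gap
    between their nearest hairpin boundaries (end of one to start of the
    next) is at most ``max_gap`` bases; clustering ignores strand. Returns
    clusters ordered by (chromosome, start), each cluster's members ordered
    by start. The result is a partition and is invariant to input order.
    """
    clusters: list[list[MirnaLocus]] = []
    by_chrom: dict[str, list[MirnaLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.id))
        current = [ordered[0]]
        max_end = ordered[0].end
        for locus in ordered[1:]:
            if locus.start - max_end <= max_gap:
                current.append(locus)
            else:
                clusters.append(current)
                current = [locus]
            max_end = max(max_end, locus.end)
        clusters.append(current)
    return clusters


def extract_seed(mature_seq: str, k: int = 6) -> str:
    """Seed of a mature microRNA: nucleotides 2..k+1 (1-based) from the 5' end.

    ``k`` must be 6, 7 or 8; the mature must be at least ``k + 1`` nt long.
    """
    if k not in (6, 7, 8):
        raise ValueError(f"seed length k must be 6, 7 or 8, got {k}")
    seq = to_rna(mature_seq)
    if len(seq) < k + 1:
        raise ValueError(
            f"mature sequence of length {len(seq)} too short for a {k}-mer seed"
        )
    return seq[1 : k + 1]


def seed_families(matures: list[MatureMirna], k: int = 6) -> list[SeedFamily]:
    """Partition matures by exact seed identity.

    Families are returned sorted by seed; member ids are sorted
    lexicographically, so the output is deterministic.
    """
    groups: dict[str, list[str]] = {}
    for m in matures:
        groups.setdefault(extract_seed(m.seq, k), []).append(m.id)
    return [
        SeedFamily(seed=seed, members=tuple(sorted(ids)))
        for seed, ids in sorted(groups.items())
    ]
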