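"""Canonical seed-match microRNA target prediction over merged 3' UTRs.

Canonical animal microRNA targeting is driven by Watson-Crick pairing of the
seed (mature nucleotides 2-7) to the 3' UTR, graded into four site classes
of increasing efficacy:

    6mer     perfect match to the seed (positions 2-7)
    7mer-A1  seed match plus an adenosine opposite mature position 1
    7mer-m8  match to positions 2-8
    8mer     match to positions 2-8 plus the position-1 adenosine

A UTR occurrence is reported once, under its highest class. Genes with
several annotated transcripts are represented by a merged UTR record:
unique transcript UTRs joined by an 8-N spacer so no site can span the
junction (N never matches).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from mirmzt.catalog import MatureMirna
from mirmzt.sequtils import revcomp, to_dna

SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")  # ascending efficacy
_CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}
UTR_SPACER = "N" * 8


@dataclass(frozen=True)
class UtrRecord:
    """Merged 3' UTR for one gene (DNA, 5'->3')."""

    gene: str
    seq: str
    transcripts: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "seq", to_dna(self.seq))
        if not self.seq:
            raise ValueError(f"gene {self.gene}: empty UTR sequence")


@dataclass(frozen=True)
class TargetSite:
    gene: str
    mirna: str
    site_class: str
    offset: int  # 0-based position of the site string's 5' end in the UTR

    def __post_init__(self):
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")


def merge_utrs(gene: str, utr_seqs: list[str], transcripts: list[str] | None = None) -> UtrRecord:
    """Merge per-transcript UTRs into one per-gene record.

    Identical sequences are deduplicated (first occurrence kept); distinct
    sequences are concatenated with an 8-N spacer. All-empty input raises —
    the caller should exclude such genes with a diagnostic.
    """
    if not utr_seqs:
        raise ValueError(f"gene {gene}: no transcript UTRs supplied")
    unique: list[str] = []
    for s in utr_seqs:
        s = to_dna(s)
        if s and s not in unique:
            unique.append(s)
    if not unique:
        raise ValueError(f"gene {gene}: all transcript UTRs empty")
    return UtrRecord(
        gene=gene,
        seq=UTR_SPACER.join(unique),
        transcripts=tuple(transcripts or ()),
    )


def site_strings(mature_seq: str) -> dict[str, str]:
    """The four class-defining UTR match strings for a mature microRNA.

    With seed s = mature positions 2-7 and m8 = position 8 (U == T):
    6mer = rc(s); 7mer-m8 = rc(positions 2-8); 7mer-A1 = rc(s) + "A";
    8mer = rc(positions 2-8) + "A".
    """
    m = to_dna(mature_seq)
    if len(m) < 9:
        raise ValueError("mature sequence must be >= 9 nt for site classes")
    core = revcomp(m[1:7])
    core8 = revcomp(m[1:8])
    return {
        "6mer": core,
        "7mer-A1": core + "A",
        "7mer-m8": core8,
        "8mer": core8 + "A",
    }


def find_sites(mature: MatureMirna | str, utr: UtrRecord) -> list[TargetSite]:
    """Scan a UTR 5'->3' for canonical sites of one mature microRNA.

    Each seed-core occurrence is reported once at its highest class; the
    offset is the 5' end of the full site string (one base left of the core
    for m8-extended classes).
    """
    if isinstance(mature, MatureMirna):
        mirna_id, mseq = mature.id, mature.seq
    else:
        raise TypeError("find_sites expects a MatureMirna")
    patterns = site_strings(mseq)
    core = patterns["6mer"]
    m8_base = patterns["7mer-m8"][0]  # complement of mature position 8
    seq = utr.seq
    sites: list[TargetSite] = []
    pos = seq.find(core)
    while pos != -1:
        has_m8 = pos > 0 and seq[pos - 1] == m8_base and m8_base != "N"
        has_a1 = pos + 6 < len(seq) and seq[pos + 6] == "A"
        if has_m8 and has_a1:
            cls, offset = "8mer", pos - 1
        elif has_m8:
            cls, offset = "7mer-m8", pos - 1
        elif has_a1:
            cls, offset = "7mer-A1", pos
        else:
            cls, offset = "6mer", pos
        sites.append(TargetSite(gene=utr.gene, mirna=mirna_id, site_class=cls, offset=offset))
        pos = seq.find(core, pos + 1)
    return sites


def class_at_least(site_class: str, min_class: str) -> bool:
    return _CLASS_RANK[site_class] >= _CLASS_RANK[min_class]


def predict_targets(
    matures: list[MatureMirna],
    utrs: list[UtrRecord],
    min_class: str = "7mer-A1",
) -> pd.DataFrame:
    """Gene-level microRNA-target pairs from canonical site scanning.

    A gene is a target of a mature when its merged UTR carries at least one
    site of class >= ``min_class``. Returns one row per (mirna, gene) pair
    with per-class site counts and the best class, ordered by (mirna, gene).
    """
    if min_class not in SITE_CLASSES:
        raise ValueError(f"unknown min_class {min_class!r}")
    rows = []
    for mature in matures:
        for utr in utrs:
            sites = find_sites(mature, utr)
            kept = [s for s in sites if class_at_least(s.site_class, min_class)]
            if not kept:
                continue
            counts = {c: 0 for c in SITE_CLASSES}
            for s in kept:
                counts[s.site_class] += 1
            best = max((s.site_class for s in kept), key=lambda c: _CLASS_RANK[c])
            rows.append({"mirna": mature.id, "gene": utr.gene, "best_class": best,
                         **{f"n_{c}": counts[c] for c in SITE_CLASSES}})
    columns = ["mirna", "gene", "best_class"] + [f"n_{c}" for c in SITE_CLASSES]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values(["mirna", "gene"], ignore_index=True)


def pairs_by_mirna(pair_table: pd.DataFrame) -> dict[str, set[str]]:
    """Target gene set per mature microRNA from a pair table."""
    return {
        mirna: set(group["gene"]) for mirna, group in pair_table.groupby("mirna")
    }


def pair_overlap(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame) -> dict[str, int]:
    """Bookkeeping of pair-level agreement between two predictors."""
    a = set(zip(pairs_a["mirna"], pairs_a["gene"]))
    b = set(zip(pairs_b["mirna"], pairs_b["gene"]))
    return {
        "overlap": len(a & b),
        "unique_a": len(a - b),
        "unique_b": len(b - a),
    }
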