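"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: FASTA (genome, UTRs, collapsed reads with the
``id_xN`` count dialect), GFF3 for microRNA loci (``pre_miRNA`` features with
child ``miRNA`` features), TSV for spike-ins, count matrices, DE tables and
summaries, BED for locus clusters, JSON for truth and reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mirmzt.catalog import MatureMirna, MirnaLocus
from mirmzt.mapping import CollapsedRead, CountMatrix, GenomeRef
from mirmzt.quantify import SpikeIn
from mirmzt.targets import UtrRecord

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


# -- FASTA ------------------------------------------------------------------

def write_genome_fasta(genome: GenomeRef, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path) -> GenomeRef:
    return GenomeRef(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_collapsed_fasta(reads: list[CollapsedRead], path) -> None:
    """Collapsed reads: one record per unique sequence, count in the id."""
    records = [
        SeqRecord(Seq(r.seq), id=f"{r.id}_x{r.count}", description="") for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def read_collapsed_fasta(path) -> list[CollapsedRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, _, count = rec.id.rpartition("_x")
        if not rid or not count.isdigit():
            raise ValueError(f"read id {rec.id!r} lacks the _xN count suffix")
        reads.append(CollapsedRead(id=rid, seq=str(rec.seq), count=int(count)))
    return reads


def write_utr_fasta(utrs: list[UtrRecord], path) -> None:
    records = [
        SeqRecord(
            Seq(u.seq), id=u.gene,
            description=f"transcripts={','.join(u.transcripts)}" if u.transcripts else "",
        )
        for u in utrs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_utr_fasta(path) -> list[UtrRecord]:
    return [
        UtrRecord(gene=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# -- GFF3 loci --------------------------------------------------------------

def write_loci_gff3(loci: list[MirnaLocus], path) -> None:
    lines = ["##gff-version 3"]
    for locus in loci:
        attrs = f"ID={locus.id}"
        if locus.family:
            attrs += f";family={locus.family}"
        lines.append(
            "\t".join(
                [locus.chrom, "mirmzt", "pre_miRNA", str(locus.start + 1),
                 str(locus.end), ".", locus.strand, ".", attrs]
            )
        )
        for m in locus.matures:
            lines.append(
                "\t".join(
                    [locus.chrom, "mirmzt", "miRNA", str(m.start + 1), str(m.end),
                     ".", locus.strand, ".",
                     f"ID={m.id};Parent={locus.id};arm={m.arm};seq={m.seq}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for piece in attrs.split(";"):
        if "=" in piece:
            key, value = piece.split("=", 1)
            out[key] = value
    return out


def read_loci_gff3(path) -> list[MirnaLocus]:
    table = pd.read_csv(
        path, sep="\t", comment="#", names=GFF3_COLUMNS, dtype=str, header=None
    )
    hairpins: dict[str, dict] = {}
    matures: dict[str, list[MatureMirna]] = {}
    for _, row in table.iterrows():
        attrs = _parse_attributes(row["attributes"])
        start, end = int(row["start"]) - 1, int(row["end"])
        if row["type"] == "pre_miRNA":
            hairpins[attrs["ID"]] = {
                "chrom": row["seqid"], "strand": row["strand"],
                "start": start, "end": end, "family": attrs.get("family"),
            }
        elif row["type"] == "miRNA":
            matures.setdefault(attrs["Parent"], []).append(
                MatureMirna(
                    id=attrs["ID"], arm=attrs["arm"], start=start, end=end,
                    seq=attrs["seq"],
                )
            )
    return [
        MirnaLocus(
            id=lid, chrom=info["chrom"], strand=info["strand"], start=info["start"],
            end=info["end"], matures=tuple(matures.get(lid, [])), family=info["family"],
        )
        for lid, info in hairpins.items()
    ]


# -- TSV tables -------------------------------------------------------------

def write_spikes_tsv(spikes: list[SpikeIn], path) -> None:
    pd.DataFrame(
        [{"sequence": s.sequence, "fmol": s.fmol, "observed_count": s.observed_count}
         for s in spikes]
    ).to_csv(path, sep="\t", index=False)


def read_spikes_tsv(path) -> list[SpikeIn]:
    table = pd.read_csv(path, sep="\t")
    return [
        SpikeIn(
            sequence=row["sequence"], fmol=float(row["fmol"]),
            observed_count=float(row.get("observed_count", 0.0)),
        )
        for _, row in table.iterrows()
    ]


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_count_matrix(matrix: CountMatrix, path) -> None:
    """Counts with the per-library mapped totals as a leading '#total' row."""
    out = Path(path)
    with out.open("w") as fh:
        fh.write("#total\t" + "\t".join(str(t) for t in matrix.totals) + "\n")
        matrix.counts.rename_axis("mature").to_csv(fh, sep="\t")


def read_count_matrix(path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#total":
            raise ValueError("count matrix missing the '#total' header row")
        totals = [float(x) for x in header[1:]]
        counts = pd.read_csv(fh, sep="\t", index_col="mature")
    return CountMatrix(counts=counts, totals=pd.Series(totals, index=counts.columns))


def write_clusters_bed(clusters: list[list[MirnaLocus]], path) -> None:
    """Cluster spans as BED4: name field lists member locus ids."""
    lines = []
    for cluster in clusters:
        chrom = cluster[0].chrom
        start = min(l.start for l in cluster)
        end = max(l.end for l in cluster)
        lines.append(f"{chrom}\t{start}\t{end}\t{','.join(l.id for l in cluster)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
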