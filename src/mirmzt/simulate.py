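"""Synthetic small-RNA study generator with a machine-readable truth record.

Emits a complete toy dataset — genome, microRNA loci, stage-resolved
collapsed read libraries, spike-ins of known molarity, per-gene 3' UTRs with
planted canonical target sites, and differential-expression tables — so that
every downstream stage (mapping, tail calling, quantification, clustering,
target prediction, enrichment) can be validated against known ground truth.

The default configuration emulates the structure of an early-development
small-RNA study in an insect egg: a handful of "clearance" microRNA families
(members sharing a seed, encoded in genomic clusters) switch on sharply after
zygotic genome activation and target a set of maternally deposited
transcripts that are down-regulated in every embryonic interval; reads carry
nontemplated 3' tails dominated by short adenosine runs; spike-ins anchor
absolute quantification at ~0.2 fmol of microRNA per egg.

Two bookkeeping subtleties, both recorded per read in the truth record:

* a planted tail whose first base equals the genomic base immediately 3' of
  the mature end is (at least partly) invisible to alignment-based tail
  calling (``first_base_detectable`` is False);
* more generally a tail is recoverable only if the full read is not a
  verbatim genomic substring (``recoverable``, established by an independent
  substring scan, never by the tail caller itself).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from mirmzt.catalog import MatureMirna, MirnaLocus, extract_seed
from mirmzt.mapping import CollapsedRead, GenomeRef
from mirmzt.quantify import SpikeIn
from mirmzt.sequtils import revcomp, to_dna, to_rna
from mirmzt.targets import UtrRecord, site_strings

NUCLEOTIDES = "ACGT"

STAGES = ("oocyte", "e08_16", "e16_24", "e24_48")
COMPARISONS = ("e08_16", "e16_24", "e24_48")  # each versus oocyte

HAIRPIN_LENGTH = 90
MATURE_LENGTH = 22
MATURE_5P_OFFSET = 8
MATURE_3P_OFFSET = 58


@dataclass(frozen=True)
class TailModel:
    """Nontemplated 3'-tail model: P(modified), length law, per-position bases.

    ``length_probs`` is a distribution over tail lengths 1..5 (additions are
    concentrated at 1-3 nt in real oocyte data); ``position_probs`` gives a
    nucleotide distribution for each of the five tail positions, strongly
    adenosine-biased by default (maternal microRNA tails are near-exclusively
    oligoadenylation).
    """

    probability: float = 0.2
    length_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.30, 3: 0.12, 4: 0.05, 5: 0.03}
    )
    position_probs: tuple[dict[str, float], ...] = field(
        default_factory=lambda: (
            {"A": 0.98, "C": 0.005, "G": 0.005, "T": 0.01},
            {"A": 0.95, "C": 0.015, "G": 0.015, "T": 0.02},
            {"A": 0.95, "C": 0.015, "G": 0.015, "T": 0.02},
            {"A": 0.95, "C": 0.015, "G": 0.015, "T": 0.02},
            {"A": 0.95, "C": 0.015, "G": 0.015, "T": 0.02},
        )
    )

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("modification probability must be in [0, 1]")
        if set(self.length_probs) - {1, 2, 3, 4, 5}:
            raise ValueError("tail lengths must be in 1..5")
        for dist in (self.length_probs, *self.position_probs):
            values = np.array(list(dist.values()), dtype=float)
            if (values < 0).any() or not np.isclose(values.sum(), 1.0):
                raise ValueError("distributions must be nonnegative and sum to 1")
        if len(self.position_probs) != 5:
            raise ValueError("position_probs must cover tail positions 1..5")


@dataclass
class SimConfig:
    """Full specification of one synthetic study.

    ``expression`` maps stage -> mature id -> expected collapsed read count
    (counts are emitted exactly; only the modified/unmodified split and tail
    sequences are stochastic). ``targeting_plan`` maps mature id -> list of
    (gene id, site class) plantings. ``de_plan`` maps comparison ->
    {"down": [...], "up": [...]}; unlisted genes are unregulated.
    ``cluster_plan`` entries are (chromosome, start, n_members, start-to-start
    spacing); members are consumed from the front of the locus id list.
    ``family_plan`` maps an RNA seed (mature positions 2-7) -> locus ids whose
    3p arms receive that seed (plus a shared position-8 base, so all seed-
    dependent site classes coincide within the family).
    """

    rng_seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 150_000
    n_loci: int = 24
    cluster_plan: list[tuple[str, int, int, int]] = field(default_factory=list)
    family_plan: dict[str, list[str]] = field(default_factory=dict)
    expression: dict[str, dict[str, int]] = field(default_factory=dict)
    tail_model: TailModel | dict[str, TailModel] = field(default_factory=TailModel)
    end_variation_prob: float = 0.0  # optional +/-1 nt templated 3'-offset
    spike_plan: list[tuple[str | None, float, int | None]] = field(default_factory=list)
    total_mirna_fmol: float = 0.2  # per egg, in the spiked (oocyte) library
    n_eggs: int = 1
    n_genes: int = 300
    utr_length: int = 1000
    targeting_plan: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    de_plan: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    reference_mature: str | None = None  # endogenous quantification reference
    clearance_matures: list[str] = field(default_factory=list)
    min_locus_separation: int = 11_000  # keeps unplanned loci out of clusters

    def locus_ids(self) -> list[str]:
        return [f"mir-sim-{i:02d}" for i in range(1, self.n_loci + 1)]

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SimTruth:
    """Ground truth for every planted quantity of one simulated dataset."""

    # lib -> read id -> {mature, count, tail, first_base_detectable, recoverable}
    read_tails: dict[str, dict[str, dict]]
    # lib -> mature -> {total, modified, recoverable_modified, first_base_detectable}
    per_mature_tails: dict[str, dict[str, dict[str, int]]]
    expected_counts: dict[str, dict[str, int]]  # lib -> mature -> planted count
    target_pairs: list[tuple[str, str]]  # (mature id, gene id)
    gene_classes: dict[str, dict[str, str]]  # comparison -> gene -> class
    always_down: list[str]
    always_up: list[str]
    spike_fmol: list[float]
    reads_per_fmol: float
    total_mirna_fmol: float
    reference_mature: str | None
    reference_fmol: float | None
    clearance_matures: list[str]
    family_seeds: dict[str, list[str]]  # seed -> member mature ids

    def detectable_rate(self, lib: str, mature: str) -> float:
        """Recoverable-modified fraction of a mature's reads in one library."""
        row = self.per_mature_tails[lib][mature]
        return row["recoverable_modified"] / row["total"] if row["total"] else float("nan")

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["target_pairs"] = [list(p) for p in self.target_pairs]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["target_pairs"] = [tuple(p) for p in payload["target_pairs"]]
        return cls(**payload)


@dataclass
class SimDataset:
    """Everything :func:`generate_dataset` emits, in memory."""

    config: SimConfig
    genome: GenomeRef
    loci: list[MirnaLocus]
    libraries: dict[str, list[CollapsedRead]]
    spikes: list[SpikeIn]
    utrs: list[UtrRecord]
    de_tables: dict[str, pd.DataFrame]
    truth: SimTruth

    @property
    def matures(self) -> list[MatureMirna]:
        return [m for locus in self.loci for m in locus.matures]


def default_config(rng_seed: int = 0) -> SimConfig:
    """The study conditions: clustered clearance families, staged expression.

    Loci 01-04 form a 4-member cluster carrying the AGUACG seed family on
    their 3p arms; loci 05-06 a 2-member cluster with the CACUGG family.
    These six 3p matures are the planted "clearance" microRNAs: nearly silent
    in the oocyte, sharply up after zygotic genome activation, and their
    targets are planted in the genes down-regulated in every embryonic
    interval. Locus 07's 3p arm is the abundant constitutive endogenous
    reference (a miR-184-like product). Remaining loci are constitutively
    expressed background.
    """
    cfg = SimConfig(rng_seed=rng_seed)
    lids = cfg.locus_ids()
    cfg.cluster_plan = [("chr3", 10_000, 4, 2_000), ("chr3", 60_000, 2, 3_000)]
    cfg.family_plan = {
        "AGUACG": lids[0:4],
        "CACUGG": lids[4:6],
    }
    clearance = [f"{lid}-3p" for lid in lids[0:6]]
    cfg.clearance_matures = clearance
    cfg.reference_mature = f"{lids[6]}-3p"

    expression: dict[str, dict[str, int]] = {stage: {} for stage in STAGES}
    clearance_by_stage = {"oocyte": 20, "e08_16": 2000, "e16_24": 800, "e24_48": 400}
    for lid in lids:
        m3, m5 = f"{lid}-3p", f"{lid}-5p"
        for stage in STAGES:
            if m3 in clearance:
                expression[stage][m3] = clearance_by_stage[stage]
            elif m3 == cfg.reference_mature:
                expression[stage][m3] = 5000
            else:
                expression[stage][m3] = 300
            expression[stage][m5] = 30
    cfg.expression = expression

    cfg.spike_plan = [(None, 0.01, None), (None, 0.005, None), (None, 0.002, None)]

    genes = cfg.gene_ids()
    always_down = genes[0:40]
    always_up = genes[40:75]
    extra_down = {c: genes[75 + 5 * i : 80 + 5 * i] for i, c in enumerate(COMPARISONS)}
    extra_up = {c: genes[90 + 5 * i : 95 + 5 * i] for i, c in enumerate(COMPARISONS)}
    cfg.de_plan = {
        c: {"down": always_down + extra_down[c], "up": always_up + extra_up[c]}
        for c in COMPARISONS
    }

    targeting: dict[str, list[tuple[str, str]]] = {}
    # family targets: one representative mature per family plants the sites;
    # seed identity makes them targets of every family member
    rep_agu = f"{lids[0]}-3p"
    targeting[rep_agu] = [
        (g, cls) for g in genes[0:30] for cls in ("8mer", "7mer-m8")
    ]
    rep_cac = f"{lids[4]}-3p"
    targeting[rep_cac] = [
        (g, cls) for g in genes[10:35] for cls in ("7mer-A1", "8mer")
    ]
    # background matures target a thin uniform scatter of genes (no enrichment)
    rng = np.random.default_rng(rng_seed + 104729)
    classes = ("7mer-A1", "7mer-m8", "8mer")
    for i, lid in enumerate(lids[6:], start=6):
        m3 = f"{lid}-3p"
        picked = rng.choice(cfg.n_genes, size=8, replace=False)
        targeting[m3] = [
            (genes[int(g)], classes[(i + j) % 3]) for j, g in enumerate(sorted(picked))
        ]
    cfg.targeting_plan = targeting
    return cfg


def simulate_tail(mature_seq: str, tail_model: TailModel, rng: np.random.Generator) -> str:
    """Append a (possibly empty) nontemplated tail to a mature sequence.

    Returns the read in DNA alphabet. With modification probability p the
    tail length is drawn from the model's length law and each tail base from
    the per-position nucleotide law.
    """
    if not mature_seq:
        raise ValueError("mature_seq must be nonempty")
    read = to_dna(mature_seq)
    if rng.random() >= tail_model.probability:
        return read
    lengths = sorted(tail_model.length_probs)
    probs = [tail_model.length_probs[l] for l in lengths]
    length = int(rng.choice(lengths, p=probs))
    tail = []
    for pos in range(length):
        dist = tail_model.position_probs[pos]
        bases = sorted(dist)
        tail.append(str(rng.choice(bases, p=[dist[b] for b in bases])))
    return read + "".join(tail)


def plant_sites(
    utr: str,
    mature: MatureMirna,
    site_class: str,
    positions: list[int],
    occupied: list[tuple[int, int]] | None = None,
) -> str:
    """Substitute canonical sites for ``mature`` into a UTR at given offsets.

    Each position is the 0-based offset of the site string's 5' end. The
    substitution preserves UTR length. The two bases flanking the seed core
    are adjusted when needed so the realized class equals the requested one
    (no accidental upgrade by a chance m8 match or A1 adenosine). Collisions
    between planted intervals — within this call or with the ``occupied``
    registry, which is extended in place — raise ValueError.
    """
    patterns = site_strings(mature.seq)
    if site_class not in patterns:
        raise ValueError(f"unknown site class {site_class!r}")
    site = patterns[site_class]
    m8_base = patterns["7mer-m8"][0]
    has_m8 = site_class in ("7mer-m8", "8mer")
    has_a1 = site_class in ("7mer-A1", "8mer")
    chars = list(to_dna(utr))
    registry = occupied if occupied is not None else []
    for pos in positions:
        # reserve one flank base on each side so classes stay exact
        start, end = pos - (0 if has_m8 else 1), pos + len(site) + (0 if has_a1 else 1)
        if start < 0 or end > len(chars):
            raise ValueError(
                f"site at {pos} (with flanks) does not fit in UTR of length {len(chars)}"
            )
        for a, b in registry:
            if start < b and a < end:
                raise ValueError(f"planted site at {pos} collides with [{a}, {b})")
        chars[pos : pos + len(site)] = site
        if not has_m8 and chars[start] == m8_base:
            chars[start] = "C" if m8_base != "C" else "G"
        if not has_a1 and chars[end - 1] == "A":
            chars[end - 1] = "C"
        registry.append((start, end))
    return "".join(chars)


# ---------------------------------------------------------------------------
# generation internals


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=length)])


def _place_loci(cfg: SimConfig, rng: np.random.Generator) -> dict[str, tuple[str, int]]:
    """Decide (chromosome, hairpin start) per locus id; clusters first."""
    chrom_names = [f"chr{i}" for i in range(1, cfg.n_chromosomes + 1)]
    lids = cfg.locus_ids()
    placement: dict[str, tuple[str, int]] = {}
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    cursor = 0
    for chrom, start, n_members, spacing in cfg.cluster_plan:
        if chrom not in taken:
            raise ValueError(f"cluster plan names unknown chromosome {chrom!r}")
        if spacing < HAIRPIN_LENGTH:
            raise ValueError("cluster spacing smaller than hairpin length")
        last_end = start + (n_members - 1) * spacing + HAIRPIN_LENGTH
        if start < 0 or last_end > cfg.chrom_length:
            raise ValueError(
                f"cluster plan exceeds chromosome length: [{start}, {last_end}) "
                f"on {chrom} of length {cfg.chrom_length}"
            )
        for j in range(n_members):
            s = start + j * spacing
            for a, b in taken[chrom]:
                if s < b and a < s + HAIRPIN_LENGTH:
                    raise ValueError(f"planted loci overlap on {chrom} at {s}")
            placement[lids[cursor]] = (chrom, s)
            taken[chrom].append((s, s + HAIRPIN_LENGTH))
            cursor += 1
    sep = cfg.min_locus_separation
    for lid in lids[cursor:]:
        for _ in range(20_000):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            s = int(rng.integers(0, cfg.chrom_length - HAIRPIN_LENGTH))
            if all(s >= b + sep or s + HAIRPIN_LENGTH + sep <= a for a, b in taken[chrom]):
                placement[lid] = (chrom, s)
                taken[chrom].append((s, s + HAIRPIN_LENGTH))
                break
        else:
            raise ValueError(
                "could not place all loci with the required separation; "
                "increase chrom_length or reduce n_loci"
            )
    return placement


def _write_family_seeds(
    chroms: dict[str, list[str]],
    placement: dict[str, tuple[str, int]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Write seeds (positions 2-8) into mature arms; keep target sets disjoint.

    Family members receive their family seed plus one shared position-8 base;
    every other mature gets its own seed. Seed choice enforces more than
    uniqueness: no mature's seed core (the reverse complement of positions
    2-7, the string a UTR site contains) may occur as a substring of another
    mature's possible site strings (core extended by the m8 complement on the
    left or the A1 adenosine on the right) — otherwise every planted site for
    one mature would systematically carry a site for the other and truth
    target pairs could never be exact. Returns the 6-mer RNA seed per mature.
    """
    lids = cfg.locus_ids()
    family_of: dict[str, str] = {}
    for seed, members in cfg.family_plan.items():
        for lid in members:
            if lid in family_of:
                raise ValueError(f"locus {lid} assigned to two families")
            family_of[lid] = seed

    assigned: list[tuple[str, str]] = []  # (core, m8 complement) per seed group
    used_cores: set[str] = set()

    def compatible(core: str, m8c: str) -> bool:
        if core in used_cores:
            return False
        own_subs = {m8c + core[:5], core[1:] + "A"}
        for core_y, m8c_y in assigned:
            if core in {m8c_y + core_y[:5], core_y[1:] + "A"}:
                return False
            if core_y in own_subs:
                return False
        return True

    # families first: seed fixed by config, position-8 base redrawable
    family_pos8: dict[str, str] = {}
    for fam_seed in cfg.family_plan:
        core = revcomp(to_dna(fam_seed))
        for base in [NUCLEOTIDES[int(rng.integers(0, 4))]] + list(NUCLEOTIDES):
            m8c = revcomp(base)
            if compatible(core, m8c):
                family_pos8[fam_seed] = base
                assigned.append((core, m8c))
                used_cores.add(core)
                break
        else:
            raise ValueError(f"family seeds are mutually incompatible: {fam_seed}")

    seeds: dict[str, str] = {}

    def place_arm(lid: str, arm: str, arm_offset: int) -> None:
        chrom, start = placement[lid]
        pos = start + arm_offset + 1  # mature position 2
        if arm == "3p" and lid in family_of:
            fam = family_of[lid]
            chroms[chrom][pos : pos + 6] = to_dna(fam)
            chroms[chrom][pos + 6] = family_pos8[fam]
            seeds[f"{lid}-{arm}"] = fam
            return
        m8c = revcomp(chroms[chrom][pos + 6])
        current = "".join(chroms[chrom][pos : pos + 6])
        for _ in range(10_000):
            if compatible(revcomp(current), m8c):
                break
            current = _random_seq(rng, 6)
        else:
            raise RuntimeError("could not draw a compatible seed")
        chroms[chrom][pos : pos + 6] = current
        assigned.append((revcomp(current), m8c))
        used_cores.add(revcomp(current))
        seeds[f"{lid}-{arm}"] = to_rna(current)

    for lid in lids:
        place_arm(lid, "3p", MATURE_3P_OFFSET)
        place_arm(lid, "5p", MATURE_5P_OFFSET)
    return seeds


def _build_loci(
    genome: GenomeRef, placement: dict[str, tuple[str, int]], cfg: SimConfig
) -> list[MirnaLocus]:
    loci = []
    for lid in cfg.locus_ids():
        chrom, start = placement[lid]
        matures = []
        for arm, offset in (("5p", MATURE_5P_OFFSET), ("3p", MATURE_3P_OFFSET)):
            a = start + offset
            matures.append(
                MatureMirna(
                    id=f"{lid}-{arm}",
                    arm=arm,
                    start=a,
                    end=a + MATURE_LENGTH,
                    seq=to_rna(genome.fetch(chrom, a, a + MATURE_LENGTH)),
                )
            )
        loci.append(
            MirnaLocus(
                id=lid, chrom=chrom, strand="+", start=start,
                end=start + HAIRPIN_LENGTH, matures=tuple(matures),
            )
        )
    return loci


def _tail_model_for(cfg: SimConfig, mature_id: str) -> TailModel:
    if isinstance(cfg.tail_model, TailModel):
        return cfg.tail_model
    return cfg.tail_model[mature_id]


def _emit_library(
    stage: str,
    cfg: SimConfig,
    genome: GenomeRef,
    loci: list[MirnaLocus],
    rng: np.random.Generator,
) -> tuple[list[CollapsedRead], dict[str, dict], dict[str, dict[str, int]]]:
    """Emit one stage library plus its per-read and per-mature truth."""
    mature_lookup = {m.id: (locus, m) for locus in loci for m in locus.matures}
    reads: list[CollapsedRead] = []
    read_truth: dict[str, dict] = {}
    per_mature: dict[str, dict[str, int]] = {}
    for mature_id in sorted(cfg.expression.get(stage, {})):
        n = cfg.expression[stage][mature_id]
        if n <= 0:
            continue
        locus, mature = mature_lookup[mature_id]
        model = _tail_model_for(cfg, mature_id)
        stats = {"total": n, "modified": 0, "recoverable_modified": 0,
                 "first_base_detectable": 0}

        # templated portion: mature sequence, optionally +/-1 nt at the 3' end
        def templated(offset: int) -> tuple[str, int]:
            end = mature.end + offset
            return genome.fetch(locus.chrom, mature.start, end), end

        molecules: Counter[tuple[str, int, str]] = Counter()  # (prefix, end, tail)
        offsets = np.zeros(n, dtype=int)
        if cfg.end_variation_prob > 0:
            varied = rng.random(n) < cfg.end_variation_prob
            offsets[varied] = rng.choice([-1, 1], size=int(varied.sum()))
        for i in range(n):
            prefix, end = templated(int(offsets[i]))
            full = simulate_tail(prefix, model, rng)
            molecules[(prefix, end, full[len(prefix):])] += 1

        for (prefix, end, tail), count in sorted(molecules.items()):
            seq = prefix + tail
            rid = f"{stage}_{mature_id}_{'t' + tail if tail else 'u'}_e{end - mature.end}"
            reads.append(CollapsedRead(id=rid, seq=seq, count=count))
            continuation = genome.fetch(locus.chrom, end, end + 1)
            first_detectable = bool(tail) and tail[0] != continuation
            recoverable = bool(tail) and not genome.contains_substring(seq)
            read_truth[rid] = {
                "mature": mature_id, "count": count, "tail": tail,
                "first_base_detectable": first_detectable,
                "recoverable": recoverable,
            }
            if tail:
                stats["modified"] += count
                if recoverable:
                    stats["recoverable_modified"] += count
                if first_detectable:
                    stats["first_base_detectable"] += count
        per_mature[mature_id] = stats
    return reads, read_truth, per_mature


def _scrub_cores(utr: str, cores: set[str], rng: np.random.Generator) -> str:
    """Remove all chance seed-core occurrences from a random UTR.

    Mutates the middle base of each occurrence; repeats until clean (a
    mutation can itself create a new core). Scrubbing keeps planted sites as
    the only canonical sites of the simulated matures, so truth target pairs
    are exact rather than contaminated by background matches.
    """
    chars = list(utr)
    for _ in range(200):
        dirty = False
        s = "".join(chars)
        for core in cores:
            pos = s.find(core)
            while pos != -1:
                dirty = True
                old = chars[pos + 3]
                choices = [b for b in NUCLEOTIDES if b != old]
                chars[pos + 3] = choices[int(rng.integers(0, 3))]
                s = "".join(chars)
                pos = s.find(core, pos + 1)
        if not dirty:
            return s
    raise RuntimeError("UTR scrubbing did not converge")


def _build_utrs(
    cfg: SimConfig,
    matures: dict[str, MatureMirna],
    rng: np.random.Generator,
) -> tuple[list[UtrRecord], set[tuple[str, str]]]:
    """Random UTRs, scrubbed of chance sites, with planted canonical sites.

    Returns the records and the truth pair set: a planted site for one
    mature is a site for every mature sharing its seed core.
    """
    cores = {mid: site_strings(m.seq)["6mer"] for mid, m in matures.items()}
    core_members: dict[str, list[str]] = {}
    for mid, core in cores.items():
        core_members.setdefault(core, []).append(mid)

    plan_by_gene: dict[str, list[tuple[str, str]]] = {}
    for mid, entries in cfg.targeting_plan.items():
        if mid not in matures:
            raise ValueError(f"targeting plan names unknown mature {mid!r}")
        for gene, cls in entries:
            plan_by_gene.setdefault(gene, []).append((mid, cls))

    gene_ids = cfg.gene_ids()
    unknown = set(plan_by_gene) - set(gene_ids)
    if unknown:
        raise ValueError(f"targeting plan names unknown genes: {sorted(unknown)}")

    records: list[UtrRecord] = []
    pairs: set[tuple[str, str]] = set()
    all_cores = set(cores.values())
    for gene in gene_ids:
        plantings = plan_by_gene.get(gene, [])
        for attempt in range(50):
            utr = _scrub_cores(_random_seq(rng, cfg.utr_length), all_cores, rng)
            occupied: list[tuple[int, int]] = []
            position = 100
            try:
                for mid, cls in plantings:
                    utr = plant_sites(utr, matures[mid], cls, [position], occupied)
                    position += 60
            except ValueError:
                continue  # geometry failure: redraw
            # post-hoc: planting must not have created sites for other matures
            realized = {c for c in all_cores if c in utr}
            intended = {cores[mid] for mid, _ in plantings}
            if realized == intended:
                break
        else:
            raise RuntimeError(f"could not plant sites cleanly in gene {gene}")
        records.append(UtrRecord(gene=gene, seq=utr, transcripts=(f"{gene}.t1",)))
        for mid, _cls in plantings:
            for member in core_members[cores[mid]]:
                pairs.add((member, gene))
    return records, pairs


def _build_de_tables(cfg: SimConfig, rng: np.random.Generator):
    tables = {}
    classes: dict[str, dict[str, str]] = {}
    for comparison in COMPARISONS:
        plan = cfg.de_plan.get(comparison, {"down": [], "up": []})
        down, up = set(plan.get("down", [])), set(plan.get("up", []))
        if down & up:
            raise ValueError(f"{comparison}: genes assigned both down and up")
        rows = []
        cls: dict[str, str] = {}
        for gene in cfg.gene_ids():
            if gene in down:
                log2fc = float(rng.uniform(-4.0, -1.2))
                padj = float(10 ** rng.uniform(-6, -2))
                cls[gene] = "down"
            elif gene in up:
                log2fc = float(rng.uniform(1.2, 4.0))
                padj = float(10 ** rng.uniform(-6, -2))
                cls[gene] = "up"
            else:
                log2fc = float(rng.uniform(-0.9, 0.9))
                padj = float(rng.uniform(0.06, 0.95))
                cls[gene] = "none"
            rows.append({"gene": gene, "log2fc": log2fc, "padj": padj})
        tables[comparison] = pd.DataFrame(rows)
        classes[comparison] = cls
    return tables, classes


def generate_dataset(config: SimConfig) -> SimDataset:
    """Generate the full synthetic study. Deterministic given ``rng_seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)

    placement = _place_loci(cfg, rng)
    chroms = {
        f"chr{i}": list(_random_seq(rng, cfg.chrom_length))
        for i in range(1, cfg.n_chromosomes + 1)
    }
    _write_family_seeds(chroms, placement, cfg, rng)
    genome = GenomeRef({name: "".join(seq) for name, seq in chroms.items()})
    loci = _build_loci(genome, placement, cfg)
    matures = {m.id: m for locus in loci for m in locus.matures}

    libraries: dict[str, list[CollapsedRead]] = {}
    read_tails: dict[str, dict[str, dict]] = {}
    per_mature_tails: dict[str, dict[str, dict[str, int]]] = {}
    for stage in STAGES:
        reads, rt, pm = _emit_library(stage, cfg, genome, loci, rng)
        libraries[stage] = reads
        read_tails[stage] = rt
        per_mature_tails[stage] = pm

    # spike-ins: absent from the genome, amounts coherent with the planted
    # total microRNA content of the spiked (oocyte) library
    oocyte_total = sum(cfg.expression.get("oocyte", {}).values())
    reads_per_fmol = oocyte_total / (cfg.total_mirna_fmol * cfg.n_eggs)
    spikes: list[SpikeIn] = []
    for seq, fmol, count in cfg.spike_plan:
        if seq is None:
            seq = _random_seq(rng, MATURE_LENGTH)
            while genome.contains_substring(seq):
                seq = _random_seq(rng, MATURE_LENGTH)
        elif genome.contains_substring(seq):
            raise ValueError("configured spike-in sequence occurs in the genome")
        if count is None:
            count = max(1, round(fmol * reads_per_fmol * cfg.n_eggs))
        spikes.append(SpikeIn(sequence=seq, fmol=fmol, observed_count=float(count)))
    for i, sp in enumerate(spikes):
        libraries["oocyte"].append(
            CollapsedRead(id=f"oocyte_spike{i}", seq=sp.sequence, count=int(sp.observed_count))
        )

    utrs, pairs = _build_utrs(cfg, matures, rng)
    de_tables, gene_classes = _build_de_tables(cfg, rng)

    always_down = sorted(
        set.intersection(*(set(cfg.de_plan[c]["down"]) for c in COMPARISONS))
    ) if cfg.de_plan else []
    always_up = sorted(
        set.intersection(*(set(cfg.de_plan[c]["up"]) for c in COMPARISONS))
    ) if cfg.de_plan else []

    reference_fmol = None
    if cfg.reference_mature is not None:
        ref_reads = cfg.expression.get("oocyte", {}).get(cfg.reference_mature, 0)
        reference_fmol = ref_reads / reads_per_fmol if ref_reads else None

    family_seeds = {
        seed: sorted(f"{lid}-3p" for lid in members)
        for seed, members in cfg.family_plan.items()
    }

    truth = SimTruth(
        read_tails=read_tails,
        per_mature_tails=per_mature_tails,
        expected_counts={
            stage: dict(sorted(cfg.expression.get(stage, {}).items())) for stage in STAGES
        },
        target_pairs=sorted(pairs),
        gene_classes=gene_classes,
        always_down=always_down,
        always_up=always_up,
        spike_fmol=[s.fmol for s in spikes],
        reads_per_fmol=reads_per_fmol,
        total_mirna_fmol=cfg.total_mirna_fmol,
        reference_mature=cfg.reference_mature,
        reference_fmol=reference_fmol,
        clearance_matures=sorted(cfg.clearance_matures),
        family_seeds=family_seeds,
    )
    return SimDataset(
        config=cfg, genome=genome, loci=loci, libraries=libraries,
        spikes=spikes, utrs=utrs, de_tables=de_tables, truth=truth,
    )
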