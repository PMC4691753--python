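"""Synthetic-data generator: determinism, truth consistency, tail sampling
statistics, site planting, and configuration validation."""

import dataclasses
import json

import numpy as np
import pytest

from mirmzt.catalog import MatureMirna, extract_seed
from mirmzt.sequtils import revcomp, to_dna
from mirmzt.simulate import (
    SimConfig,
    TailModel,
    default_config,
    generate_dataset,
    plant_sites,
    simulate_tail,
)
from mirmzt.targets import find_sites, site_strings, UtrRecord

from helpers import random_seq


class TestSimulateTail:
    def test_forced_degenerate_distributions(self):
        model = TailModel(
            probability=1.0,
            length_probs={2: 1.0},
            position_probs=tuple({"A": 1.0} for _ in range(5)),
        )
        rng = np.random.default_rng(0)
        assert simulate_tail("UGAGGUAG", model, rng) == "TGAGGTAG" + "AA"

    def test_zero_probability_leaves_sequence_unchanged(self):
        model = TailModel(probability=0.0)
        rng = np.random.default_rng(0)
        assert simulate_tail("UGAGGUAG", model, rng) == "TGAGGTAG"

    def test_modified_fraction_matches_binomial_sampling(self):
        model = TailModel(probability=0.2)
        rng = np.random.default_rng(12)
        n = 10_000
        modified = sum(
            1 for _ in range(n) if len(simulate_tail("UGAGGUAGGU", model, rng)) > 10
        )
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(modified / n - 0.2) < 3 * se

    def test_tail_composition_approaches_position_probs(self):
        model = TailModel(probability=1.0, length_probs={1: 1.0})
        rng = np.random.default_rng(3)
        n = 5000
        first = [simulate_tail("UGAGGUAGGU", model, rng)[10] for _ in range(n)]
        p_a = model.position_probs[0]["A"]
        se = np.sqrt(p_a * (1 - p_a) / n)
        assert abs(first.count("A") / n - p_a) < 4 * se

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            TailModel(probability=1.5)
        with pytest.raises(ValueError):
            TailModel(length_probs={1: 0.5, 2: 0.2})  # does not sum to 1
        with pytest.raises(ValueError):
            TailModel(length_probs={6: 1.0})  # length above the cap


class TestPlantSites:
    MATURE = MatureMirna("m", "3p", 0, 20, "UAGUACGUUAUCGAUGGCAA")

    def test_planted_site_found_by_scan_exactly_once(self, rng):
        utr = random_seq(rng, 400).replace(site_strings(self.MATURE.seq)["6mer"], "TTTTTT")
        planted = plant_sites(utr, self.MATURE, "7mer-A1", [150])
        sites = find_sites(self.MATURE, UtrRecord("g", planted))
        assert [(s.site_class, s.offset) for s in sites] == [("7mer-A1", 150)]
        assert len(planted) == len(utr)  # substitution, not insertion

    def test_empty_positions_identity(self):
        utr = "ACGT" * 50
        assert plant_sites(utr, self.MATURE, "8mer", []) == utr

    def test_requested_class_is_realized_not_upgraded(self, rng):
        # plant every class on adversarial all-A backgrounds: flank repair
        # must prevent upgrades (m8 match, A1 adenosine) and downgrades
        for cls in ("6mer", "7mer-A1", "7mer-m8", "8mer"):
            utr = "A" * 200
            planted = plant_sites(utr, self.MATURE, cls, [100])
            sites = find_sites(self.MATURE, UtrRecord("g", planted))
            assert [s.site_class for s in sites] == [cls], cls

    def test_collision_raises(self):
        utr = "C" * 200
        occupied = []
        plant_sites(utr, self.MATURE, "8mer", [100], occupied)
        with pytest.raises(ValueError, match="collides"):
            plant_sites(utr, self.MATURE, "8mer", [104], occupied)

    def test_site_must_fit(self):
        with pytest.raises(ValueError):
            plant_sites("ACGT" * 3, self.MATURE, "8mer", [8])


class TestGenerateDataset:
    def test_deterministic_given_seed(self):
        a = generate_dataset(default_config(3))
        b = generate_dataset(default_config(3))
        assert a.genome.chroms == b.genome.chroms
        assert a.loci == b.loci
        for lib in a.libraries:
            assert a.libraries[lib] == b.libraries[lib]
        assert json.dumps(dataclasses.asdict(a.truth), default=str) == json.dumps(
            dataclasses.asdict(b.truth), default=str
        )
        for comp in a.de_tables:
            assert a.de_tables[comp].equals(b.de_tables[comp])

    def test_zero_tail_probability_gives_empty_tails(self):
        cfg = default_config(4)
        cfg.tail_model = TailModel(probability=0.0)
        cfg.expression = {"oocyte": cfg.expression["oocyte"]}
        ds = generate_dataset(cfg)
        assert all(
            info["tail"] == "" for info in ds.truth.read_tails["oocyte"].values()
        )

    def test_reads_are_templated_prefix_plus_planted_tail(self, dataset):
        """Every emitted microRNA read is a genomic substring of its locus
        extended by its recorded tail."""
        by_id = {m.id: m for locus in dataset.loci for m in locus.matures}
        locus_of = {m.id: locus for locus in dataset.loci for m in locus.matures}
        reads = {r.id: r for r in dataset.libraries["oocyte"]}
        for rid, info in dataset.truth.read_tails["oocyte"].items():
            read = reads[rid]
            mature = by_id[info["mature"]]
            locus = locus_of[info["mature"]]
            tail = info["tail"]
            prefix = read.seq[: len(read.seq) - len(tail)] if tail else read.seq
            genomic = dataset.genome.fetch(locus.chrom, mature.start,
                                           mature.start + len(prefix))
            assert prefix == genomic
            assert read.seq == prefix + tail

    def test_detectability_flags_consistent_with_genome(self, dataset):
        """first_base_detectable is re-derivable from the genome; recoverable
        implies first-base-or-later deviation and never exceeds modified."""
        by_id = {m.id: (locus, m) for locus in dataset.loci for m in locus.matures}
        for rid, info in dataset.truth.read_tails["oocyte"].items():
            locus, mature = by_id[info["mature"]]
            tail = info["tail"]
            if not tail:
                assert not info["first_base_detectable"]
                assert not info["recoverable"]
                continue
            continuation = dataset.genome.fetch(locus.chrom, mature.end, mature.end + 1)
            assert info["first_base_detectable"] == (tail[0] != continuation)
            if info["first_base_detectable"]:
                assert info["recoverable"]
        for per_mature in dataset.truth.per_mature_tails.values():
            for row in per_mature.values():
                assert row["first_base_detectable"] <= row["recoverable_modified"]
                assert row["recoverable_modified"] <= row["modified"]
                assert row["modified"] <= row["total"]

    def test_planted_site_counts_by_substring_scan(self, dataset):
        """Counting planted 8mer site strings directly in the emitted UTRs
        reproduces the targeting plan (independent substring scan)."""
        cfg = dataset.config
        by_id = {m.id: m for m in dataset.matures}
        utr_by_gene = {u.gene: u for u in dataset.utrs}
        for mature_id, entries in cfg.targeting_plan.items():
            per_gene = {}
            for gene, cls in entries:
                per_gene.setdefault(gene, []).append(cls)
            strings = site_strings(by_id[mature_id].seq)
            for gene, classes in per_gene.items():
                seq = utr_by_gene[gene].seq
                core = strings["6mer"]
                occurrences = seq.count(core)
                assert occurrences == len(classes), (mature_id, gene)

    def test_truth_pair_invariants(self, dataset):
        genes = set(dataset.config.gene_ids())
        matures = {m.id for m in dataset.matures}
        for mirna, gene in dataset.truth.target_pairs:
            assert mirna in matures and gene in genes
        # family members appear pairwise with identical gene sets
        pairs = set(dataset.truth.target_pairs)
        for members in dataset.truth.family_seeds.values():
            sets = [{g for m2, g in pairs if m2 == m} for m in members]
            assert all(s == sets[0] for s in sets)

    def test_family_seed_written_into_matures(self, dataset):
        by_id = {m.id: m for m in dataset.matures}
        for seed, members in dataset.truth.family_seeds.items():
            for mid in members:
                assert extract_seed(by_id[mid].seq, 6) == seed

    def test_spikes_absent_from_genome(self, dataset):
        for spike in dataset.spikes:
            assert not dataset.genome.contains_substring(spike.sequence)

    def test_overlapping_cluster_plan_rejected(self):
        cfg = default_config(0)
        cfg.cluster_plan = [("chr1", 100, 3, 50)]  # spacing < hairpin length
        with pytest.raises(ValueError):
            generate_dataset(cfg)

    def test_cluster_plan_beyond_chromosome_rejected(self):
        cfg = default_config(0)
        cfg.cluster_plan = [("chr1", cfg.chrom_length - 500, 4, 2000)]
        with pytest.raises(ValueError, match="exceeds"):
            generate_dataset(cfg)
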