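"""Find the microRNAs whose targets are enriched in down-regulated genes.

Genes are classified from the DE table (more than twofold, adjusted
P < 0.05); each microRNA's predicted targets are tested for
over-representation in the down- and up-regulated sets (hypergeometric +
permutation, Bonferroni-corrected). MicroRNAs significant in "down" but
quiet in "up" are the maternal-clearance candidates, and a 6-mer word
enrichment over the down-set UTRs recovers their seed complements.
"""

from mirmzt import (
    classify_genes,
    default_config,
    enrichment_table,
    generate_dataset,
    predict_targets,
    rank_mirnas,
    word_enrich,
)
from mirmzt.sequtils import revcomp
from mirmzt.targets import pairs_by_mirna

dataset = generate_dataset(default_config(rng_seed=1))
comparison = "e08_16"  # right after zygotic genome activation

classified = classify_genes(dataset.de_tables[comparison])
universe = {u.gene for u in dataset.utrs} & set(classified["gene"])
gene_sets = {
    cls: set(classified.loc[classified["class"] == cls, "gene"]) & universe
    for cls in ("down", "up", "none")
}
print({k: len(v) for k, v in gene_sets.items()}, "of", len(universe), "genes")

pairs = predict_targets(dataset.matures, dataset.utrs)
table = enrichment_table(
    pairs_by_mirna(pairs), gene_sets, universe, n_perm=1000, rng_seed=1
)
expression = {m: dataset.truth.expected_counts[comparison].get(m, 0) for m in table["mirna"]}
import pandas as pd

ranking = rank_mirnas(table, pd.Series(expression))
flagged = ranking[ranking["flagged"]]
print("\nflagged clearance candidates (Bonferroni p_down < 1e-3, up quiet):")
print(flagged[["mirna", "expression", "p_down_adjusted"]].to_string(index=False))
print(f"\nmatches planted clearance set: "
      f"{sorted(flagged['mirna']) == dataset.truth.clearance_matures}")

words = word_enrich(dataset.utrs, gene_sets["down"], universe, k=6)
print("\ntop 5 enriched 6-mer words in down-regulated UTRs:")
print(words.head(5)[["word", "k", "K", "p_bonferroni"]].to_string(index=False))
for seed in dataset.truth.family_seeds:
    word = revcomp(seed)
    rank = int(words.index[words["word"] == word][0]) + 1
    print(f"seed {seed} complement {word}: rank {rank}")
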