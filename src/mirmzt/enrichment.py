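"""Target-set enrichment statistics for microRNA-driven transcript clearance.

Genes are classified from a differential-expression table into down-, up-
and not-regulated sets (more than twofold change at adjusted P < 0.05).
For each mature microRNA, over-representation of its predicted targets in a
gene set is scored by the hypergeometric upper tail and, independently, by a
permutation test drawing size-matched random gene sets without replacement.
P-values are corrected for multiple testing (Bonferroni by default). A
complementary k-mer word-enrichment test asks which of the 4^k words are
over-represented in the UTRs of a gene set — the word complementary to a
clearance microRNA's seed should surface near the top.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirmzt.targets import UtrRecord


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap statistics of one target set against one classified gene set."""

    mirna: str
    gene_set: str
    universe_size: int  # N
    targets_in_universe: int  # K
    set_size: int  # n
    overlap: int  # k
    p_hyper: float
    p_perm: float | None = None
    p_adjusted: float | None = None

    def __post_init__(self):
        if self.overlap > min(self.targets_in_universe, self.set_size):
            raise ValueError("overlap exceeds min(K, n)")


def classify_genes(
    de_table: pd.DataFrame,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign down/up/none classes from a DE table (gene, log2fc, padj).

    down: log2fc <= -log2(fold_threshold) and padj < alpha; up symmetric;
    everything else none. Genes with missing padj are excluded; the number
    excluded is recorded in ``result.attrs["n_excluded"]``.
    """
    required = {"gene", "log2fc", "padj"}
    missing = required - set(de_table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    table = de_table.copy()
    n_before = len(table)
    table = table.dropna(subset=["padj"])
    cut = np.log2(fold_threshold)
    significant = table["padj"] < alpha
    table["class"] = "none"
    table.loc[significant & (table["log2fc"] <= -cut), "class"] = "down"
    table.loc[significant & (table["log2fc"] >= cut), "class"] = "up"
    table = table.reset_index(drop=True)
    table.attrs["n_excluded"] = n_before - len(table)
    return table


def intersect_classes(classified: dict[str, pd.DataFrame]) -> dict[str, set[str]]:
    """Genes down (resp. up) in every supplied comparison."""
    out: dict[str, set[str]] = {}
    for cls in ("down", "up"):
        sets = [
            set(t.loc[t["class"] == cls, "gene"]) for t in classified.values()
        ]
        out[cls] = set.intersection(*sets) if sets else set()
    return out


def enrich_hyper(
    target_genes: set[str],
    gene_set: set[str],
    universe: set[str],
    mirna: str = "",
    gene_set_label: str = "",
) -> EnrichmentResult:
    """Hypergeometric upper-tail P(X >= k) for target overlap with a gene set.

    Targets are intersected with the universe first; ``gene_set`` must be a
    subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set is not a subset of the universe")
    targets = target_genes & universe
    N, K, n = len(universe), len(targets), len(gene_set)
    k = len(targets & gene_set)
    # P(X >= k) = sf(k - 1) under Hypergeometric(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        mirna=mirna,
        gene_set=gene_set_label,
        universe_size=N,
        targets_in_universe=K,
        set_size=n,
        overlap=k,
        p_hyper=min(p, 1.0),
    )


def enrich_perm(
    target_genes: set[str],
    set_size: int,
    universe: set[str],
    observed_overlap: int,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value: size-matched random sets drawn without replacement.

    p = (1 + #{permutation overlap >= observed}) / (n_perm + 1); the +1
    pseudocount keeps p strictly positive. Deterministic under a fixed seed.
    """
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ordered = sorted(universe)
    is_target = np.fromiter((g in target_genes for g in ordered), dtype=bool)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(len(ordered), size=set_size, replace=False)
        if int(is_target[draw].sum()) >= observed_overlap:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def adjust(pvals, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni or Benjamini-Hochberg."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "benjamini_hochberg":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


def enrichment_table(
    targets_by_mirna: dict[str, set[str]],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    n_perm: int = 1000,
    rng_seed: int | None = None,
    adjust_method: str = "bonferroni",
) -> pd.DataFrame:
    """Per-(microRNA, gene set) enrichment with hypergeometric + permutation p.

    The correction family is all tested (microRNA, gene set) combinations;
    its size is recorded in ``result.attrs["correction_family_size"]``.
    MicroRNAs absent from ``targets_by_mirna`` simply have no rows.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for mirna in sorted(targets_by_mirna):
        targets = targets_by_mirna[mirna] & universe
        for label in sorted(gene_sets):
            gene_set = gene_sets[label] & universe
            res = enrich_hyper(targets, gene_set, universe, mirna, label)
            p_perm = enrich_perm(
                targets, len(gene_set), universe, res.overlap, n_perm=n_perm, rng=rng
            )
            rows.append(
                {"mirna": mirna, "gene_set": label, "N": res.universe_size,
                 "K": res.targets_in_universe, "n": res.set_size, "k": res.overlap,
                 "p_hyper": res.p_hyper, "p_perm": p_perm}
            )
    table = pd.DataFrame(
        rows, columns=["mirna", "gene_set", "N", "K", "n", "k", "p_hyper", "p_perm"]
    )
    if len(table):
        table["p_adjusted"] = adjust(table["p_hyper"].to_numpy(), adjust_method)
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
    table.attrs["correction_family_size"] = len(table)
    table.attrs["adjust_method"] = adjust_method
    return table


def word_enrich(
    utrs: list[UtrRecord],
    gene_set: set[str],
    universe: set[str],
    k: int = 6,
) -> pd.DataFrame:
    """Hypergeometric word enrichment over all 4^k words in UTRs of a gene set.

    For each word, the genes whose UTR contains it form the "target" set and
    enrichment in ``gene_set`` versus the universe is scored as in
    :func:`enrich_hyper`; Bonferroni correction is over all 4^k words. This
    is a set-based simplification of ranked-landscape word enrichment
    ("sylamer-like"), trading the expression ranking for a fixed gene set.
    """
    if not 4 <= k <= 8:
        raise ValueError("word length k must be in 4..8")
    by_gene = {u.gene: u for u in utrs}
    missing = universe - set(by_gene)
    if missing:
        raise ValueError(f"UTRs missing for {len(missing)} universe genes")
    if not gene_set <= universe:
        raise ValueError("gene_set is not a subset of the universe")
    genes_with_word: dict[str, set[str]] = {}
    for gene in universe:
        seq = by_gene[gene].seq
        seen = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        for word in seen:
            if "N" not in word:
                genes_with_word.setdefault(word, set()).add(gene)
    words = ["".join(w) for w in itertools.product("ACGT", repeat=k)]
    N, n = len(universe), len(gene_set)
    rows = []
    for word in words:
        carriers = genes_with_word.get(word, set())
        K = len(carriers)
        kk = len(carriers & gene_set)
        p = float(stats.hypergeom.sf(kk - 1, N, K, n))
        rows.append({"word": word, "K": K, "k": kk, "p_hyper": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = np.minimum(table["p_hyper"] * len(words), 1.0)
    table = table.sort_values(
        ["p_hyper", "word"], ascending=[True, True], ignore_index=True
    )
    table.attrs["method"] = "sylamer-like set-based hypergeometric"
    return table


def rank_mirnas(
    table: pd.DataFrame,
    expression: pd.Series,
    down_label: str = "down",
    up_label: str = "up",
    p_threshold: float = 1e-3,
    up_alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag candidate clearance microRNAs and emit plotting coordinates.

    A microRNA is flagged when its Bonferroni-corrected enrichment p in the
    down-regulated set is below ``p_threshold`` while its corrected p in the
    up-regulated set is not significant (>= ``up_alpha``). The returned frame
    carries (expression, -log10 p_down) pairs for an expression-versus-
    enrichment scatter.
    """
    down = table[table["gene_set"] == down_label].set_index("mirna")
    up = table[table["gene_set"] == up_label].set_index("mirna")
    rows = []
    for mirna in down.index:
        p_down = float(down.loc[mirna, "p_adjusted"])
        p_up = float(up.loc[mirna, "p_adjusted"]) if mirna in up.index else 1.0
        has_targets = int(down.loc[mirna, "K"]) > 0
        flagged = has_targets and p_down < p_threshold and p_up >= up_alpha
        rows.append(
            {"mirna": mirna,
             "expression": float(expression.get(mirna, 0.0)),
             "p_down_adjusted": p_down,
             "p_up_adjusted": p_up,
             "neg_log10_p_down": -np.log10(p_down),
             "flagged": bool(flagged)}
        )
    return pd.DataFrame(rows).sort_values("mirna", ignore_index=True)
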