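"""Absolute microRNA quantification and stage-to-stage expression correlation.

Absolute amounts are estimated by rescaling microRNA read counts against a
reference of known molarity: either a synthetic 5'-phosphorylated spike-in
oligonucleotide added at a known fmol amount before library preparation, or
an abundant endogenous microRNA whose cellular amount was measured
independently. Treating all microRNA reads as equimolar per read,

    fmol/egg = (total microRNA reads / reference reads) * reference fmol / n eggs

and molecule numbers follow from Avogadro's constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.constants import Avogadro

from mirmzt.mapping import CollapsedRead, CountMatrix, GenomeRef
from mirmzt.sequtils import to_dna


@dataclass(frozen=True)
class SpikeIn:
    """A spiked-in synthetic oligonucleotide of known molar amount."""

    sequence: str
    fmol: float
    observed_count: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "sequence", to_dna(self.sequence))
        if self.fmol <= 0:
            raise ValueError("spike-in amount must be > 0 fmol")


@dataclass(frozen=True)
class AbsoluteEstimate:
    fmol_per_egg: float
    reference: str  # "spike-in" | "endogenous"
    n_eggs: int

    def __post_init__(self):
        if self.fmol_per_egg < 0:
            raise ValueError("estimate must be >= 0")


def absolute_quantify(
    total_mirna_reads: float,
    reference_reads: float,
    reference_fmol: float,
    n_eggs: int = 1,
    reference: str = "spike-in",
) -> AbsoluteEstimate:
    """Absolute microRNA content from read counts relative to one reference."""
    if reference_reads <= 0:
        raise ValueError("reference below detection: zero reference reads")
    if n_eggs <= 0:
        raise ValueError("n_eggs must be a positive integer")
    fmol = (total_mirna_reads / reference_reads) * reference_fmol / n_eggs
    return AbsoluteEstimate(fmol_per_egg=fmol, reference=reference, n_eggs=n_eggs)


def combine_spike_estimates(
    total_mirna_reads: float,
    spikes: list[SpikeIn],
    n_eggs: int = 1,
) -> tuple[AbsoluteEstimate, pd.DataFrame]:
    """Average per-spike estimates; report the per-spike spread alongside.

    Each spike-in yields an independent estimate; the combined value is their
    mean. The returned frame lists the individual estimates so the spread is
    never hidden behind the average.
    """
    if not spikes:
        raise ValueError("no spike-ins supplied")
    rows = []
    for i, sp in enumerate(spikes):
        est = absolute_quantify(
            total_mirna_reads, sp.observed_count, sp.fmol, n_eggs, reference="spike-in"
        )
        rows.append(
            {"spike": i, "fmol": sp.fmol, "observed_count": sp.observed_count,
             "estimate_fmol_per_egg": est.fmol_per_egg}
        )
    table = pd.DataFrame(rows)
    mean = float(table["estimate_fmol_per_egg"].mean())
    return AbsoluteEstimate(fmol_per_egg=mean, reference="spike-in", n_eggs=n_eggs), table


def count_spike_reads(reads: list[CollapsedRead], spike: SpikeIn) -> float:
    """Collapsed count of reads exactly matching a spike-in sequence."""
    return float(sum(r.count for r in reads if r.seq == spike.sequence))


def check_spikes_absent(genome: GenomeRef, spikes: list[SpikeIn]) -> None:
    """Spike-in sequences must not occur in the genome (either strand)."""
    present = [s.sequence for s in spikes if genome.contains_substring(s.sequence)]
    if present:
        raise ValueError(f"spike-in sequences present in genome: {present}")


def fmol_to_molecules(amount_fmol: float) -> float:
    """Convert femtomoles to molecule count via Avogadro's constant."""
    if amount_fmol < 0:
        raise ValueError("amount must be >= 0 fmol")
    return amount_fmol * 1e-15 * Avogadro


def stage_correlation(matrix: CountMatrix, transform: str | None = None) -> pd.DataFrame:
    """All-versus-all Spearman correlation between library expression profiles.

    ``transform`` may be ``"log1p"``; rank correlation is invariant to any
    monotone transform, so this is cosmetic but mirrors common practice.
    Constant libraries give an undefined correlation: their entries are NaN
    and their names are recorded in ``result.attrs["constant_libraries"]``.
    """
    if matrix.counts.shape[1] < 2:
        raise ValueError("at least 2 libraries required")
    values = matrix.counts.to_numpy(dtype=float)
    if transform == "log1p":
        values = np.log1p(values)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    libs = list(matrix.counts.columns)
    constant = [lib for j, lib in enumerate(libs) if np.ptp(values[:, j]) == 0]
    corr = pd.DataFrame(np.eye(len(libs)), index=libs, columns=libs)
    for i in range(len(libs)):
        for j in range(i + 1, len(libs)):
            if libs[i] in constant or libs[j] in constant:
                rho = np.nan
            else:
                rho = stats.spearmanr(values[:, i], values[:, j]).statistic
            corr.iloc[i, j] = corr.iloc[j, i] = rho
    for lib in constant:
        corr.loc[lib, lib] = np.nan
    corr.attrs["constant_libraries"] = constant
    return corr
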