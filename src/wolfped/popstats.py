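"""Allele-frequency based diversity and identity statistics.

Per-locus and multilocus summaries for any collection of consensus
genotypes: observed/effective allele numbers, observed and unbiased expected
heterozygosity, rarefied allelic richness, polymorphism information content,
probabilities of identity and a permutation test of Hardy-Weinberg
proportions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MicrosatGenotype

log = logging.getLogger(__name__)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele counts and relative frequencies (2 gene copies per
    typed diploid genotype)."""

    counts: dict[str, dict[int, int]] = field(default_factory=dict)

    @property
    def loci(self) -> list[str]:
        return list(self.counts)

    def n_genes(self, locus: str) -> int:
        return sum(self.counts[locus].values())

    def frequencies(self, locus: str) -> dict[int, float]:
        n = self.n_genes(locus)
        return {a: c / n for a, c in self.counts[locus].items()}

    def homozygosity(self, locus: str) -> float:
        """Sum of squared allele frequencies."""
        return sum(p * p for p in self.frequencies(locus).values())


def allele_frequencies(genotypes: list[MicrosatGenotype],
                       loci: list[str] | None = None) -> AlleleFrequencyTable:
    if not genotypes:
        raise ValueError("no genotypes supplied")
    if loci is None:
        seen: list[str] = []
        for g in genotypes:
            for locus in g.loci:
                if locus not in seen:
                    seen.append(locus)
        loci = seen
    counts: dict[str, dict[int, int]] = {}
    for locus in loci:
        c: dict[int, int] = {}
        for g in genotypes:
            pair = g.loci.get(locus)
            if pair is None:
                continue
            for allele in pair:
                c[allele] = c.get(allele, 0) + 1
        if c:
            counts[locus] = dict(sorted(c.items()))
        else:
            log.warning("locus %s has zero typed copies; excluded", locus)
    return AlleleFrequencyTable(counts)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def rarefied_richness(counts: dict[int, int], g: int) -> float:
    """Expected allele count in a subsample of ``g`` gene copies.

    E[A(g)] = sum_i [1 - C(n - n_i, g) / C(n, g)] over alleles i with copy
    count n_i, n total copies (exact combinatorial rarefaction).
    """
    n = sum(counts.values())
    if g < 2:
        raise ValueError("rarefaction requires g >= 2")
    if g > n:
        raise ValueError(f"rarefaction g={g} exceeds {n} gene copies")
    denom = math.comb(n, g)
    return float(sum(1 - math.comb(n - ni, g) / denom for ni in counts.values()))


@dataclass
class DiversitySummary:
    per_locus: pd.DataFrame           # index locus; Na, Ne, Ho, He, Ar, PIC
    rarefaction_g: int

    def mean(self, stat: str) -> float:
        return float(self.per_locus[stat].mean())

    @property
    def means(self) -> dict[str, float]:
        return {c: self.mean(c) for c in self.per_locus.columns}


def diversity_summary(genotypes: list[MicrosatGenotype],
                      rarefaction_g: int | None = None,
                      loci: list[str] | None = None) -> DiversitySummary:
    """Per-locus Na, Ne, Ho, He (Nei unbiased), Ar(g) and PIC plus unweighted
    means over loci.

    ``rarefaction_g`` defaults to the smallest per-locus gene-copy count so
    every locus can be rarefied; it must be >= 2.
    """
    table = allele_frequencies(genotypes, loci)
    if not table.counts:
        raise ValueError("no typed loci")
    if rarefaction_g is None:
        rarefaction_g = min(table.n_genes(locus) for locus in table.loci)
    if rarefaction_g < 2:
        raise ValueError("rarefaction_g must be >= 2")

    rows = {}
    for locus in table.loci:
        counts = table.counts[locus]
        n = table.n_genes(locus)
        freqs = table.frequencies(locus)
        sum_p2 = sum(p * p for p in freqs.values())
        na = len(counts)
        ne = 1.0 / sum_p2
        typed = [g.loci[locus] for g in genotypes if g.loci.get(locus) is not None]
        ho = sum(1 for a, b in typed if a != b) / len(typed)
        he = np.nan if n <= 2 else (n / (n - 1)) * (1 - sum_p2)
        ps = list(freqs.values())
        pic = (1 - sum_p2
               - sum(2 * ps[i] ** 2 * ps[j] ** 2
                     for i in range(len(ps)) for j in range(i + 1, len(ps))))
        ar = rarefied_richness(counts, min(rarefaction_g, n))
        rows[locus] = {"Na": na, "Ne": ne, "Ho": ho, "He": he,
                       "Ar": ar, "PIC": pic}
    return DiversitySummary(pd.DataFrame.from_dict(rows, orient="index"),
                            rarefaction_g)


# ---------------------------------------------------------------------------
# identity
# ---------------------------------------------------------------------------

@dataclass
class IdentityStats:
    per_locus: pd.DataFrame           # index locus; PID, PIDsib
    pid: float                        # multilocus products
    pidsib: float


def probability_of_identity(freqs: AlleleFrequencyTable) -> IdentityStats:
    """Probability that two random individuals (PID) or two full siblings
    (PIDsib) share a multilocus genotype by chance.

    Per locus: PID = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2 and
    PIDsib = 0.25 + 0.5 s2 + 0.5 s2^2 - 0.25 s4 with s2 = sum p_i^2,
    s4 = sum p_i^4.  Multilocus values are products over loci.
    """
    if not freqs.counts:
        raise ValueError("empty frequency table")
    rows = {}
    for locus in freqs.loci:
        ps = list(freqs.frequencies(locus).values())
        s2 = sum(p * p for p in ps)
        s4 = sum(p ** 4 for p in ps)
        pid = s4 + sum((2 * ps[i] * ps[j]) ** 2
                       for i in range(len(ps)) for j in range(i + 1, len(ps)))
        pidsib = 0.25 + 0.5 * s2 + 0.5 * s2 * s2 - 0.25 * s4
        rows[locus] = {"PID": pid, "PIDsib": pidsib}
    df = pd.DataFrame.from_dict(rows, orient="index")
    return IdentityStats(df, float(df["PID"].prod()), float(df["PIDsib"].prod()))


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_test(genotypes: list[MicrosatGenotype], locus: str,
             n_permutations: int = 10_000, seed: int | None = None) -> float:
    """Monte-Carlo test of Hardy-Weinberg proportions at one locus.

    Alleles are permuted among individuals; the statistic is the absolute
    deviation of the heterozygote count from its expectation under random
    pairing of gene copies.  Two-sided add-one p-value; deterministic for a
    given seed.  Monomorphic loci return 1.0 by convention.
    """
    pairs = [g.loci[locus] for g in genotypes if g.loci.get(locus) is not None]
    if len(pairs) < 5:
        raise ValueError(f"need >=5 typed individuals at {locus}")
    if n_permutations < 1000:
        raise ValueError("n_permutations must be >= 1000")
    copies = np.array([a for p in pairs for a in p])
    if len(np.unique(copies)) == 1:
        return 1.0
    n_ind = len(pairs)
    n = 2 * n_ind
    _, allele_counts = np.unique(copies, return_counts=True)
    # expected heterozygote count under random pairing without replacement
    expected = n_ind * (1 - np.sum(allele_counts * (allele_counts - 1))
                        / (n * (n - 1)))
    obs = sum(1 for a, b in pairs if a != b)
    t_obs = abs(obs - expected)

    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(copies)
        het = np.count_nonzero(perm[0::2] != perm[1::2])
        if abs(het - expected) >= t_obs - 1e-12:
            extreme += 1
    return (extreme + 1) / (n_permutations + 1)
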