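"""Breeder dispersal distances, sex-ratio / rank-sum tests and the
corrected-assignment-index (mAIc) permutation test of sex-biased dispersal."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genodata import FEMALE, MALE, MicrosatGenotype
from .geo import vincenty_km
from .popstats import AlleleFrequencyTable, allele_frequencies

log = logging.getLogger(__name__)


@dataclass
class DispersalRecord:
    individual_id: str
    sex: str
    natal_territory: str
    breeding_territory: str
    distance_km: float

    @property
    def philopatric(self) -> bool:
        return self.natal_territory == self.breeding_territory

    def __post_init__(self):
        if self.distance_km < 0:
            raise ValueError("negative distance")


@dataclass
class Breeder:
    """First-reproduction record of one breeding individual."""
    individual_id: str
    sex: str
    natal_territory: str | None
    breeding_territory: str
    first_breeding_year: int


def dispersal_distances(breeders: list[Breeder],
                        territories: dict[str, tuple[float, float]],
                        include_philopatric: bool = True,
                        ) -> list[DispersalRecord]:
    """Geodesic distance (km) from natal to first-breeding territory centroid.

    Breeders with unknown natal territory are excluded with a log entry;
    a missing centroid is an error.  Only the first reproduction of each
    breeder must be supplied (one record per individual).
    """
    records = []
    seen: set[str] = set()
    for b in breeders:
        if b.individual_id in seen:
            raise ValueError(f"duplicate breeder {b.individual_id}; supply "
                             "first reproduction only")
        seen.add(b.individual_id)
        if b.natal_territory is None:
            log.info("breeder %s has unknown natal territory; excluded",
                     b.individual_id)
            continue
        for code in (b.natal_territory, b.breeding_territory):
            if code not in territories:
                raise ValueError(f"missing centroid for territory {code}")
        if b.natal_territory == b.breeding_territory:
            d = 0.0
        else:
            d = vincenty_km(*territories[b.natal_territory],
                            *territories[b.breeding_territory])
        rec = DispersalRecord(b.individual_id, b.sex, b.natal_territory,
                              b.breeding_territory, d)
        if not include_philopatric and rec.philopatric:
            continue
        records.append(rec)
    return records


@dataclass
class SexRatioResult:
    chi2: float
    df: int
    p_value: float


def sex_ratio_test(n_females: int, n_males: int) -> SexRatioResult:
    """Chi-square goodness of fit of the breeder sex counts against 1:1
    (no continuity correction, df = 1)."""
    if n_females < 0 or n_males < 0 or n_females + n_males == 0:
        raise ValueError("counts must be non-negative and not both zero")
    chi2, p = stats.chisquare([n_females, n_males])
    return SexRatioResult(float(chi2), 1, float(p))


@dataclass
class RankSumResult:
    w: float
    p_value: float


def distance_test(distances_f, distances_m) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of the two distance samples.

    W is the rank sum of the first group minus n1(n1+1)/2 (the Mann-Whitney
    U of the first group, the convention of R's ``wilcox.test``); p uses the
    normal approximation with midranks, tie correction and continuity
    correction.
    """
    x, y = np.asarray(distances_f, float), np.asarray(distances_m, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one value")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             use_continuity=True, method="asymptotic")
    return RankSumResult(float(res.statistic), float(min(res.pvalue, 1.0)))


# ---------------------------------------------------------------------------
# mAIc sex-biased dispersal test
# ---------------------------------------------------------------------------

@dataclass
class MaicResult:
    maic_female: float
    maic_male: float
    statistic: float          # mAIc(F) - mAIc(M)
    p_value: float
    aic: dict[str, float]     # corrected assignment index per individual


def assignment_index(genotype: MicrosatGenotype,
                     freqs: AlleleFrequencyTable,
                     pseudocount: float = 0.0) -> float:
    """AI = sum over typed loci of log10 of the expected Hardy-Weinberg
    genotype frequency (p^2 for homozygotes, 2pq for heterozygotes)."""
    ai = 0.0
    for locus, pair in genotype.loci.items():
        if pair is None or locus not in freqs.counts:
            continue
        f = freqs.frequencies(locus)
        n = freqs.n_genes(locus)
        def p_of(allele):
            if allele in f:
                return f[allele]
            if pseudocount > 0:
                return pseudocount / n
            raise ValueError(f"allele {allele} at {locus} absent from "
                             "frequency table")
        a, b = pair
        pa, pb = p_of(a), p_of(b)
        freq = pa * pa if a == b else 2 * pa * pb
        ai += math.log10(freq)
    return ai


def maic_test(genotypes: list[MicrosatGenotype],
              n_permutations: int = 10_000, seed: int | None = None,
              freqs: AlleleFrequencyTable | None = None) -> MaicResult:
    """Permutation test for sex-biased dispersal via corrected assignment
    indices.

    AIc centres each individual's AI on the overall mean; the statistic is
    mAIc(F) - mAIc(M), with a two-sided p-value from random permutations of
    the sex labels (add-one estimator).  The more dispersing sex carries
    immigrant-like genotypes and shows the lower mAIc.
    """
    sexed = [g for g in genotypes if g.sex in (MALE, FEMALE)]
    nf = sum(1 for g in sexed if g.sex == FEMALE)
    nm = len(sexed) - nf
    if nf < 5 or nm < 5:
        raise ValueError("need at least 5 individuals of each sex")
    pseudocount = 0.0
    if freqs is None:
        freqs = allele_frequencies(sexed)
    else:
        pseudocount = 0.5  # guard against alleles absent from external table

    ai = np.array([assignment_index(g, freqs, pseudocount) for g in sexed])
    aic = ai - ai.mean()
    is_f = np.array([g.sex == FEMALE for g in sexed])
    maic_f = float(aic[is_f].mean())
    maic_m = float(aic[~is_f].mean())
    observed = maic_f - maic_m

    rng = np.random.default_rng(seed)
    count = 0
    labels = is_f.copy()
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        stat = aic[perm].mean() - aic[~perm].mean()
        if abs(stat) >= abs(observed) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MaicResult(maic_f, maic_m, observed, p,
                      {g.individual_id: float(v) for g, v in zip(sexed, aic)})
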