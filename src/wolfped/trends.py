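"""Yearly breeder-cohort series, Mann-Kendall/Sen trend tests and the
exponential growth fit of breeding-pair counts."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .genodata import MicrosatGenotype
from .pedigree import BreedingPair, Pedigree, is_genotyped_id
from .popstats import diversity_summary

VALID_STATISTICS = ("breeding_pair_count", "Na", "Ar", "Ho", "He", "mean_Fp",
                    "haplotype_freq", "unknown_origin_freq")


@dataclass
class YearlySeries:
    years: tuple[int, ...]
    values: tuple[float, ...]
    label: str = ""

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if len(self.years) != len(self.values):
            raise ValueError("years and values differ in length")

    def dropna(self) -> "YearlySeries":
        keep = [(y, v) for y, v in zip(self.years, self.values)
                if not (v is None or (isinstance(v, float) and math.isnan(v)))]
        return YearlySeries(tuple(y for y, _ in keep),
                            tuple(float(v) for _, v in keep), self.label)


def yearly_series(pairs: list[BreedingPair],
                  statistic: str = "breeding_pair_count",
                  ped: Pedigree | None = None,
                  genotypes: dict[str, MicrosatGenotype] | None = None,
                  haplotype: str | None = None,
                  years: range = range(2005, 2016)) -> YearlySeries:
    """One value per monitoring year for the cohort of pairs active that year.

    Diversity statistics need ``genotypes`` (breeder id -> genotype),
    ``mean_Fp`` needs the pedigree, ``haplotype_freq`` needs ``haplotype``.
    Breeder-level frequencies (haplotype, unknown origin) are per distinct
    genotyped breeder active that year, not per pair.
    """
    if statistic not in VALID_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    values = []
    for year in years:
        active = [p for p in pairs if year in p.years]
        if not active:
            values.append(math.nan)
            continue
        if statistic == "breeding_pair_count":
            values.append(float(len(active)))
            continue
        if statistic == "mean_Fp":
            fps = [float(ped.kinship(p.male, p.female)) for p in active]
            values.append(sum(fps) / len(fps))
            continue
        # per-breeder statistics
        breeders: dict[str, BreedingPair] = {}
        natal: dict[str, str | None] = {}
        for p in active:
            for ind, nat in ((p.male, p.male_natal), (p.female, p.female_natal)):
                if is_genotyped_id(ind):
                    breeders[ind] = p
                    natal[ind] = nat
        if statistic == "unknown_origin_freq":
            unk = sum(1 for ind in breeders
                      if natal[ind] is None
                      or str(natal[ind]).lower() in ("", "unk.", "unk", "unknown"))
            values.append(unk / len(breeders))
            continue
        gts = [genotypes[i] for i in breeders if i in genotypes]
        if statistic == "haplotype_freq":
            with_hap = [g for g in gts if g.mtdna_haplotype != "UNKNOWN"]
            if not with_hap:
                values.append(math.nan)
                continue
            values.append(sum(1 for g in with_hap
                              if g.mtdna_haplotype == haplotype) / len(with_hap))
            continue
        if not gts:
            values.append(math.nan)
            continue
        summ = diversity_summary(gts)
        values.append(summ.mean(statistic))
    return YearlySeries(tuple(years), tuple(values), label=statistic)


# ---------------------------------------------------------------------------
# Mann-Kendall / Sen
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    s: int
    var_s: float
    z: float
    p_value: float
    tau: float
    sen_slope: float
    n: int


def trend_test(series: YearlySeries) -> TrendResult:
    """Mann-Kendall trend test with tie-corrected variance and continuity
    correction, plus Sen's slope (median of all pairwise slopes over time)."""
    clean = series.dropna()
    x = np.asarray(clean.values, float)
    t = np.asarray(clean.years, float)
    n = len(x)
    if n < 3:
        raise ValueError("need >=3 non-missing points for a trend test")

    s = 0
    slopes = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            s += int(np.sign(x[j] - x[i]))
            slopes.append((x[j] - x[i]) / (t[j] - t[i]))
    sen = float(np.median(slopes))

    _, tie_counts = np.unique(x, return_counts=True)
    var_s = (n * (n - 1) * (2 * n + 5)
             - sum(tc * (tc - 1) * (2 * tc + 5) for tc in tie_counts)) / 18.0

    d = n * (n - 1) / 2.0
    u = sum(tc * (tc - 1) / 2.0 for tc in tie_counts)
    tau = s / math.sqrt(d * (d - u)) if d > u else 0.0

    if s == 0 or var_s == 0:
        return TrendResult(s, var_s, 0.0, 1.0, tau, sen, n)
    z = (s - 1) / math.sqrt(var_s) if s > 0 else (s + 1) / math.sqrt(var_s)
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(int(s), float(var_s), float(z), float(p), float(tau),
                       sen, n)


# ---------------------------------------------------------------------------
# exponential growth
# ---------------------------------------------------------------------------

@dataclass
class GrowthFit:
    n0: float
    r: float                       # per-year instantaneous rate
    rss: float
    r_loglinear: float
    fitted: tuple[float, ...] = field(default_factory=tuple)

    @property
    def annual_growth(self) -> float:
        """e^r - 1 (nonlinear least-squares estimate)."""
        return math.exp(self.r) - 1.0

    @property
    def annual_growth_loglinear(self) -> float:
        return math.exp(self.r_loglinear) - 1.0


def growth_fit(series: YearlySeries) -> GrowthFit:
    """Fit N(t) = N0 * exp(r t) to yearly counts.

    Nonlinear least squares on the counts is the primary estimate; the
    log-linear OLS estimate is reported alongside for comparison.
    """
    clean = series.dropna()
    y = np.asarray(clean.values, float)
    if len(y) < 3:
        raise ValueError("need >=3 points")
    if np.any(y <= 0):
        raise ValueError("non-positive counts: exclude them or add an offset "
                         "before fitting")
    t = np.asarray(clean.years, float) - clean.years[0]

    slope, intercept = np.polyfit(t, np.log(y), 1)
    (n0, r), _ = optimize.curve_fit(lambda tt, n0, r: n0 * np.exp(r * tt),
                                    t, y, p0=[math.exp(intercept), slope],
                                    maxfev=20_000)
    fitted = n0 * np.exp(r * t)
    return GrowthFit(float(n0), float(r), float(np.sum((y - fitted) ** 2)),
                     float(slope), tuple(float(v) for v in fitted))
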