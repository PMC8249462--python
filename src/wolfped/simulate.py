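"""Synthetic recolonization generator.

Simulates a territorial population recolonizing a region: founder
immigrants arrive with genotypes drawn from founder allele frequencies,
pairs claim territories, breed yearly litters with Mendelian inheritance and
maternal mtDNA, vacant breeding slots are refilled with a male-biased
among-pack dispersal process, and non-invasive sampling with allelic dropout
and false alleles is layered on top.  Every run carries full ground truth
(pedigree, genotypes, injected errors) so that each pipeline stage can be
validated against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .genodata import (DEFAULT_LOCI, FEMALE, MALE, MicrosatGenotype,
                       SampleRecord, canonical_pair)
from .pedigree import Pedigree, PedigreeMember


@dataclass
class SimConfig:
    seed: int
    n_years: int = 30
    n_founder_immigrants_per_year: int = 3
    loci: tuple[str, ...] = DEFAULT_LOCI
    alleles_per_locus: tuple[int, int] = (4, 8)
    founder_allele_freqs: dict[str, dict[int, float]] | None = None
    lat_range: tuple[float, float] = (51.0, 54.0)
    lon_range: tuple[float, float] = (6.0, 15.0)
    pack_founding_prob: float = 0.3
    max_packs: int = 20                # carrying capacity of the region
    litter_mean: float = 4.0
    dispersal_mean_km: float = 70.0
    male_fill_bias: float = 0.8
    breeder_mortality: float = 0.15
    disperser_mortality: float = 0.45  # non-breeding adults (roaming risk)
    min_breeding_age: int = 2
    dropout_rate: float = 0.1
    false_allele_rate: float = 0.02
    replicates_per_sample: int = 4
    samples_per_individual_year: int = 1
    haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: {"HT01": 0.8, "HT02": 0.2})

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("pack_founding_prob", "male_fill_bias",
                     "breeder_mortality", "disperser_mortality",
                     "dropout_rate", "false_allele_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.replicates_per_sample < 1 or self.litter_mean <= 0:
            raise ValueError("invalid replicate count or litter mean")
        if abs(sum(self.haplotype_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    # -- flat key=value config files --------------------------------------

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        kwargs = {}
        ftypes = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in ftypes:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = _parse_value(value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, dict) or v is None:
                    continue
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")


def _parse_value(value: str):
    if "," in value:
        return tuple(_parse_value(v.strip()) for v in value.split(","))
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def default_allele_freqs(config: SimConfig,
                         rng: np.random.Generator) -> dict[str, dict[int, float]]:
    """Uniform frequencies over 4-8 alleles per locus (2 bp repeat ladder)."""
    lo, hi = config.alleles_per_locus
    freqs = {}
    for i, locus in enumerate(config.loci):
        k = int(rng.integers(lo, hi + 1))
        alleles = [100 + 10 * i + 2 * j for j in range(k)]
        freqs[locus] = {a: 1.0 / k for a in alleles}
    return freqs


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimIndividual:
    id: str
    sex: str
    genotype: dict[str, tuple[int, int]]
    mtdna: str
    sire: str | None
    dam: str | None
    natal_pack: str | None
    birth_year: int
    alive: bool = True
    breeding_pack: str | None = None
    death_year: int | None = None


@dataclass
class SimPack:
    code: str
    lat: float
    lon: float
    founding_year: int
    male: str | None = None
    female: str | None = None
    active: bool = True


@dataclass
class SimTruth:
    config: SimConfig
    individuals: dict[str, SimIndividual]
    packs: dict[str, SimPack]
    pack_breeders: dict[tuple[str, int], tuple[str, str]]
    litters: list[tuple[str, int, tuple[str, ...]]]
    founder_freqs: dict[str, dict[int, float]]
    extinct: bool = False

    @property
    def pedigree(self) -> Pedigree:
        ped = Pedigree()
        for ind in self.individuals.values():
            ped.add(PedigreeMember(ind.id, ind.sire, ind.dam, ind.sex,
                                   ind.natal_pack, ind.birth_year))
        return ped

    @property
    def genotypes(self) -> dict[str, MicrosatGenotype]:
        return {
            ind.id: MicrosatGenotype(ind.id, dict(ind.genotype), sex=ind.sex,
                                     mtdna_haplotype=ind.mtdna)
            for ind in self.individuals.values()
        }


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def simulate_recolonization(config: SimConfig) -> SimTruth:
    """Year-stepped recolonization with known pedigree; deterministic for a
    given seed."""
    rng = np.random.default_rng(config.seed)
    freqs = config.founder_allele_freqs or default_allele_freqs(config, rng)
    allele_arrays = {locus: (np.array(list(f)),
                             np.array([f[a] for a in f]))
                     for locus, f in freqs.items()}
    hap_names = list(config.haplotype_freqs)
    hap_p = np.array([config.haplotype_freqs[h] for h in hap_names])

    individuals: dict[str, SimIndividual] = {}
    packs: dict[str, SimPack] = {}
    pack_breeders: dict[tuple[str, int], tuple[str, str]] = {}
    litters: list[tuple[str, int, tuple[str, ...]]] = []
    counter = {"ind": 0, "pack": 0}

    def new_id(sex: str) -> str:
        counter["ind"] += 1
        return f"W{counter['ind']:04d}{'m' if sex == MALE else 'f'}"

    def founder_genotype() -> dict[str, tuple[int, int]]:
        gt = {}
        for locus, (alleles, p) in allele_arrays.items():
            pick = rng.choice(alleles, size=2, p=p)
            gt[locus] = canonical_pair(int(pick[0]), int(pick[1]))
        return gt

    def add_immigrant(year: int) -> SimIndividual:
        sex = MALE if rng.random() < 0.5 else FEMALE
        ind = SimIndividual(
            new_id(sex), sex, founder_genotype(),
            hap_names[int(rng.choice(len(hap_names), p=hap_p))],
            None, None, None, year - config.min_breeding_age)
        individuals[ind.id] = ind
        return ind

    def natal_location(ind: SimIndividual) -> tuple[float, float]:
        if ind.natal_pack and ind.natal_pack in packs:
            p = packs[ind.natal_pack]
            return p.lat, p.lon
        return (float(rng.uniform(*config.lat_range)),
                float(rng.uniform(*config.lon_range)))

    def disperse_from(lat: float, lon: float) -> tuple[float, float]:
        d_km = float(rng.exponential(config.dispersal_mean_km))
        theta = float(rng.uniform(0, 2 * math.pi))
        dlat = d_km * math.cos(theta) / 111.32
        dlon = d_km * math.sin(theta) / (111.32 * math.cos(math.radians(lat)))
        return (min(max(lat + dlat, config.lat_range[0]), config.lat_range[1]),
                min(max(lon + dlon, config.lon_range[0]), config.lon_range[1]))

    def unpaired(sex: str, year: int) -> list[SimIndividual]:
        out = [i for i in individuals.values()
               if i.alive and i.sex == sex and i.breeding_pack is None
               and year - i.birth_year >= config.min_breeding_age]
        out.sort(key=lambda i: i.id)
        return out

    for year in range(config.n_years):
        # founder immigration
        for _ in range(config.n_founder_immigrants_per_year):
            add_immigrant(year)

        # mortality (every adult, breeders included)
        for ind in individuals.values():
            if ind.alive and year - ind.birth_year >= 1:
                rate = (config.breeder_mortality if ind.breeding_pack
                        else config.disperser_mortality)
                if rng.random() < rate:
                    ind.alive = False
                    ind.death_year = year
                    if ind.breeding_pack:
                        pack = packs[ind.breeding_pack]
                        if pack.male == ind.id:
                            pack.male = None
                        if pack.female == ind.id:
                            pack.female = None
                        ind.breeding_pack = None

        # refill vacant slots: males immigrate from other packs, females
        # mostly inherit their natal territory (male-biased among-pack flow)
        for pack in sorted(packs.values(), key=lambda p: p.code):
            if not pack.active or (pack.male is None and pack.female is None):
                pack.active = False
                continue
            if pack.male is None:
                if rng.random() < config.male_fill_bias:
                    cands = [m for m in unpaired(MALE, year)
                             if m.natal_pack != pack.code]
                    if cands:
                        chosen = cands[int(rng.integers(len(cands)))]
                        chosen.breeding_pack = pack.code
                        pack.male = chosen.id
            if pack.female is None:
                outsiders = rng.random() < (1.0 - config.male_fill_bias)
                cands = [f for f in unpaired(FEMALE, year)
                         if (f.natal_pack != pack.code) == outsiders]
                if not cands:  # fall back to any available female
                    cands = unpaired(FEMALE, year)
                if cands:
                    chosen = cands[int(rng.integers(len(cands)))]
                    chosen.breeding_pack = pack.code
                    pack.female = chosen.id

        # new pack founding by unpaired dispersers
        males, females = unpaired(MALE, year), unpaired(FEMALE, year)
        rng.shuffle(males), rng.shuffle(females)
        for male, female in zip(males, females):
            n_active = sum(1 for p in packs.values()
                           if p.male is not None or p.female is not None)
            if n_active >= config.max_packs:
                break
            if rng.random() >= config.pack_founding_prob:
                continue
            if (male.natal_pack is not None
                    and male.natal_pack == female.natal_pack):
                # packmates rarely found a territory together; sib pairings
                # still arise through breeder turnover in existing packs
                continue
            counter["pack"] += 1
            lat, lon = disperse_from(*natal_location(female))
            code = f"T{counter['pack']:03d}"
            packs[code] = SimPack(code, lat, lon, year, male.id, female.id)
            male.breeding_pack = female.breeding_pack = code

        # litters
        for pack in sorted(packs.values(), key=lambda p: p.code):
            if pack.male is None or pack.female is None:
                continue
            sire, dam = individuals[pack.male], individuals[pack.female]
            pack_breeders[(pack.code, year)] = (sire.id, dam.id)
            size = max(1, int(rng.poisson(config.litter_mean)))
            pup_ids = []
            for _ in range(size):
                sex = MALE if rng.random() < 0.5 else FEMALE
                gt = {}
                for locus in config.loci:
                    pa = sire.genotype[locus][int(rng.integers(2))]
                    pb = dam.genotype[locus][int(rng.integers(2))]
                    gt[locus] = canonical_pair(pa, pb)
                pup = SimIndividual(new_id(sex), sex, gt, dam.mtdna,
                                    sire.id, dam.id, pack.code, year)
                individuals[pup.id] = pup
                pup_ids.append(pup.id)
            litters.append((pack.code, year, tuple(pup_ids)))

    extinct = not any(p.male and p.female for p in packs.values())
    return SimTruth(config, individuals, packs, pack_breeders, litters,
                    freqs, extinct=extinct)


# ---------------------------------------------------------------------------
# sampling with genotyping error
# ---------------------------------------------------------------------------

@dataclass
class SampleSet:
    samples: list[SampleRecord]
    sample_to_individual: dict[str, str]
    error_events: list[tuple[str, str, int, str]]   # sample, locus, rep, kind


def simulate_sampling(truth: SimTruth, config: SimConfig | None = None,
                      ) -> SampleSet:
    """Draw replicated non-invasive samples from the simulated population.

    Per replicate and locus a heterozygote loses one random allele with the
    dropout probability, and with the false-allele probability one allele is
    shifted by one repeat unit (2 bp).  Seeded independently of the
    population run (seed + 1) so truth and sampling can be regenerated
    separately.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    samples: list[SampleRecord] = []
    mapping: dict[str, str] = {}
    events: list[tuple[str, str, int, str]] = []
    n = 0
    for ind in sorted(truth.individuals.values(), key=lambda i: i.id):
        last = ind.death_year if ind.death_year is not None else config.n_years
        for year in range(ind.birth_year, last):
            if year < 0 or year >= config.n_years:
                continue
            for _ in range(config.samples_per_individual_year):
                n += 1
                sid = f"S{n:05d}"
                calls: dict[str, list] = {locus: [] for locus in config.loci}
                for rep in range(config.replicates_per_sample):
                    for locus in config.loci:
                        a, b = ind.genotype[locus]
                        if a != b and rng.random() < config.dropout_rate:
                            keep = a if rng.random() < 0.5 else b
                            a = b = keep
                            events.append((sid, locus, rep, "dropout"))
                        if rng.random() < config.false_allele_rate:
                            shift = 2 if rng.random() < 0.5 else -2
                            if rng.random() < 0.5:
                                a += shift
                            else:
                                b += shift
                            events.append((sid, locus, rep, "false_allele"))
                        calls[locus].append(canonical_pair(a, b))
                flags = [(True, ind.sex == MALE)
                         for _ in range(config.replicates_per_sample)]
                pack = ind.breeding_pack or ind.natal_pack
                if pack and pack in truth.packs:
                    lat, lon = truth.packs[pack].lat, truth.packs[pack].lon
                else:
                    lat = lon = None
                samples.append(SampleRecord(
                    sample_id=sid, date=f"{2000 + year}-06-01",
                    lat=lat, lon=lon, sample_type="scat",
                    calls=calls, sex_flags=flags))
                mapping[sid] = ind.id
    return SampleSet(samples, mapping, events)


def write_sample_csv(sample_set: SampleSet, path,
                     loci: tuple[str, ...] = DEFAULT_LOCI) -> None:
    """Emit the replicate-level sample table consumed by genodata."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["sample_id", "date", "lat", "lon", "type", "dbx6", "dby7"]
        for locus in loci:
            header += [f"{locus}_a", f"{locus}_b"]
        w.writerow(header)
        for s in sample_set.samples:
            for rep in range(s.n_replicates):
                dbx6, dby7 = s.sex_flags[rep]
                row = [s.sample_id, s.date,
                       "" if s.lat is None else s.lat,
                       "" if s.lon is None else s.lon,
                       s.sample_type, int(dbx6), int(dby7)]
                for locus in loci:
                    pair = s.calls.get(locus, [None] * (rep + 1))[rep]
                    row += ["", ""] if pair is None else [pair[0], pair[1]]
                w.writerow(row)
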