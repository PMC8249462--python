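"""Pedigree representation, kinship/inbreeding and breeding-pair summaries.

Kinship is computed by the classical tabular recursion (equivalent to the
Meuwissen-Luo algorithm for inbreeding coefficients): founders are mutually
unrelated and non-inbred, unknown parents contribute nothing, and the
inbreeding coefficient of a litter equals the kinship of its parents.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction

from .genodata import FEMALE, MALE, UNKNOWN, MicrosatGenotype


class PedigreeCycleError(ValueError):
    def __init__(self, cycle):
        self.cycle = cycle
        super().__init__(f"pedigree contains a cycle: {' -> '.join(cycle)}")


@dataclass
class PedigreeMember:
    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = UNKNOWN
    natal_pack: str | None = None
    birth_year: int | None = None

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """Directed acyclic genealogy with memoised kinship.

    Unknown parents are treated as distinct unrelated founders, one per
    individual; they are never merged, so pedigree inbreeding is a lower
    bound on true inbreeding.
    """

    def __init__(self, members: list[PedigreeMember] | None = None):
        self.members: dict[str, PedigreeMember] = {}
        self._depth: dict[str, int] = {}
        self._kin_cache: dict = {}
        for m in members or []:
            self.add(m)

    def add(self, member: PedigreeMember) -> None:
        if member.id in self.members:
            raise ValueError(f"duplicate individual {member.id}")
        self.members[member.id] = member
        self._depth.clear()
        self._kin_cache.clear()

    def add_individual(self, id, sire=None, dam=None, sex=UNKNOWN,
                       natal_pack=None, birth_year=None) -> None:
        self.add(PedigreeMember(id, sire, dam, sex, natal_pack, birth_year))

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.members

    def __len__(self) -> int:
        return len(self.members)

    @property
    def founders(self) -> list[str]:
        return [m.id for m in self.members.values() if m.is_founder]

    def validate(self) -> None:
        """Check acyclicity, parent presence and parent-sex consistency."""
        for m in self.members.values():
            for parent, want in ((m.sire, MALE), (m.dam, FEMALE)):
                if parent is None:
                    continue
                p = self.members.get(parent)
                if p is None:
                    raise ValueError(f"{m.id}: parent {parent} not in pedigree")
                if p.sex not in (want, UNKNOWN):
                    raise ValueError(f"{m.id}: parent {parent} has sex {p.sex}, "
                                     f"expected {want}")
        for ind in self.members:
            self.depth(ind)  # raises on cycles

    def depth(self, ind_id: str) -> int:
        """Generation number: 0 for founders, else 1 + max parental depth."""
        if ind_id in self._depth:
            return self._depth[ind_id]
        # iterative DFS with grey-marking for cycle detection
        GREY, DONE = 1, 2
        state: dict[str, int] = {}
        stack = [ind_id]
        path: list[str] = []
        while stack:
            cur = stack[-1]
            if cur in self._depth or state.get(cur) == DONE:
                stack.pop()
                if path and path[-1] == cur:
                    path.pop()
                continue
            if state.get(cur) == GREY:
                m = self.members[cur]
                parents = [p for p in (m.sire, m.dam) if p is not None]
                self._depth[cur] = 1 + max((self._depth[p] for p in parents),
                                           default=-1)
                state[cur] = DONE
                stack.pop()
                path.pop()
                continue
            state[cur] = GREY
            path.append(cur)
            m = self.members.get(cur)
            if m is None:
                raise ValueError(f"individual {cur} not in pedigree")
            for p in (m.sire, m.dam):
                if p is None:
                    continue
                if state.get(p) == GREY:
                    raise PedigreeCycleError(path[path.index(p):] + [p])
                if p not in self._depth and state.get(p) != DONE:
                    stack.append(p)
        return self._depth[ind_id]

    def kinship(self, i: str, j: str, exact: bool = False) -> float | Fraction:
        """Kinship coefficient f(i, j): probability that random alleles drawn
        from i and from j are identical by descent.

        f(i, i) = (1 + f(sire_i, dam_i)) / 2; otherwise the recursion descends
        through the individual with the larger generation number, so an
        ancestor is never expanded through its own descendant.  With
        ``exact=True`` all arithmetic uses rationals.
        """
        for ind in (i, j):
            if ind not in self.members:
                raise ValueError(f"individual {ind} not in pedigree")
        half = Fraction(1, 2) if exact else 0.5
        zero = Fraction(0) if exact else 0.0

        def f(a: str | None, b: str | None):
            if a is None or b is None:
                return zero
            key = (a, b, exact) if a <= b else (b, a, exact)
            if key in self._kin_cache:
                return self._kin_cache[key]
            if a == b:
                m = self.members[a]
                val = half * (1 + f(m.sire, m.dam))
            else:
                # expand the deeper individual (ties broken arbitrarily)
                x, y = (a, b) if self.depth(a) >= self.depth(b) else (b, a)
                m = self.members[x]
                if m.is_founder:
                    val = zero
                else:
                    val = half * (f(m.sire, y) + f(m.dam, y))
            self._kin_cache[key] = val
            return val

        self.depth(i), self.depth(j)
        return f(i, j)

    def inbreeding(self, ind_id: str, exact: bool = False) -> float | Fraction:
        m = self.members[ind_id]
        if m.is_founder:
            return Fraction(0) if exact else 0.0
        if m.sire is None or m.dam is None:
            return Fraction(0) if exact else 0.0
        return self.kinship(m.sire, m.dam, exact=exact)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read(cls, path) -> "Pedigree":
        """Read a pedigree text file: id, sire, dam, sex, natal_pack,
        birth_year ('0' or empty = unknown)."""
        ped = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                def clean(v):
                    v = (v or "").strip()
                    return None if v in ("", "0") else v
                year = clean(row.get("birth_year"))
                ped.add_individual(
                    row["id"].strip(), clean(row.get("sire")),
                    clean(row.get("dam")), (row.get("sex") or UNKNOWN).strip(),
                    clean(row.get("natal_pack")),
                    int(year) if year else None)
        ped.validate()
        return ped

    def write(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "sire", "dam", "sex", "natal_pack", "birth_year"])
            for m in self.members.values():
                w.writerow([m.id, m.sire or "0", m.dam or "0", m.sex,
                            m.natal_pack or "0", m.birth_year or "0"])


# ---------------------------------------------------------------------------
# breeding pairs and litters
# ---------------------------------------------------------------------------

def expand_years(first: int, last: int) -> tuple[int, ...]:
    """A breeding-year range X..Y counts one litter per monitoring year."""
    if last < first:
        raise ValueError(f"year range {first}-{last} reversed")
    return tuple(range(first, last + 1))


@dataclass
class BreedingPair:
    """One territory's reproducing pair over a run of monitoring years."""

    territory: str
    male: str
    female: str
    years: tuple[int, ...]
    male_natal: str | None = None
    female_natal: str | None = None
    fp_printed: float | None = None

    def __post_init__(self):
        if not self.years:
            raise ValueError("breeding pair requires at least one year")
        self.years = tuple(sorted(self.years))

    @property
    def n_litters(self) -> int:
        return len(self.years)

    @property
    def bond_years(self) -> int:
        return len(self.years)


def inbreeding_coefficient(ped: Pedigree, pair: BreedingPair,
                           exact: bool = False) -> float | Fraction:
    """Pedigree inbreeding coefficient of the pair's offspring = parental
    kinship."""
    for breeder in (pair.male, pair.female):
        if breeder not in ped:
            raise ValueError(f"breeder {breeder} missing from pedigree")
    return ped.kinship(pair.male, pair.female, exact=exact)


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Display rounding used for inbreeding tables (0.0005 -> 0.001)."""
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LitterSummary:
    n_pairs: int
    n_litters: int
    mean_bond_years: float
    min_bond_years: int
    max_bond_years: int
    n_litters_inbred: int               # Fp > 0
    n_litters_high_inbreeding: int      # Fp >= threshold
    fp_threshold: float
    per_litter_fp: list[tuple[str, int, float]]    # (territory, year, Fp)
    breeder_origin: dict[str, int]

    @property
    def fraction_inbred(self) -> float:
        return self.n_litters_inbred / self.n_litters

    @property
    def fraction_high_inbreeding(self) -> float:
        return self.n_litters_high_inbreeding / self.n_litters


def is_genotyped_id(ind_id: str) -> bool:
    """Monitoring convention: genotyped wolves carry GW-prefixed ids,
    ungenotyped pedigree placeholders are Roman numerals."""
    return ind_id.upper().startswith("GW")


def litter_summary(pairs: list[BreedingPair], ped: Pedigree,
                   fp_threshold: float = 0.156) -> LitterSummary:
    """Litter counts, bond durations, inbreeding tallies and breeder-origin
    composition for a set of breeding pairs."""
    per_litter = []
    for pair in pairs:
        fp = float(inbreeding_coefficient(ped, pair))
        for year in pair.years:
            per_litter.append((pair.territory, year, fp))
    bonds = [p.bond_years for p in pairs]

    origin = {"males_known": 0, "males_unknown": 0,
              "females_known": 0, "females_unknown": 0}
    seen: set[str] = set()
    for pair in pairs:
        for breeder, natal, sex in ((pair.male, pair.male_natal, "males"),
                                    (pair.female, pair.female_natal, "females")):
            if breeder in seen or not is_genotyped_id(breeder):
                continue
            seen.add(breeder)
            known = natal is not None and natal.lower() not in ("", "unk.", "unk", "unknown")
            origin[f"{sex}_known" if known else f"{sex}_unknown"] += 1

    return LitterSummary(
        n_pairs=len(pairs),
        n_litters=len(per_litter),
        mean_bond_years=sum(bonds) / len(bonds),
        min_bond_years=min(bonds),
        max_bond_years=max(bonds),
        n_litters_inbred=sum(1 for _, _, fp in per_litter if fp > 0),
        n_litters_high_inbreeding=sum(1 for _, _, fp in per_litter
                                      if fp >= fp_threshold - 1e-12),
        fp_threshold=fp_threshold,
        per_litter_fp=per_litter,
        breeder_origin=origin,
    )


# ---------------------------------------------------------------------------
# parentage assignment
# ---------------------------------------------------------------------------

@dataclass
class CandidatePair:
    pair: BreedingPair
    male_genotype: MicrosatGenotype
    female_genotype: MicrosatGenotype
    territory_lat: float | None = None
    territory_lon: float | None = None


@dataclass
class ParentageResult:
    assigned: CandidatePair | None
    candidates_surviving: list[str] = field(default_factory=list)
    untestable: list[str] = field(default_factory=list)

    @property
    def is_assigned(self) -> bool:
        return self.assigned is not None


def mendelian_mismatches(offspring: MicrosatGenotype,
                         sire: MicrosatGenotype,
                         dam: MicrosatGenotype) -> tuple[int, int]:
    """Count loci typed in all three where no allele assignment lets the
    offspring inherit one allele from each parent.

    Returns ``(n_comparable, n_mismatch)``.
    """
    comparable = mismatch = 0
    for locus, pair in offspring.loci.items():
        sp, dp = sire.loci.get(locus), dam.loci.get(locus)
        if pair is None or sp is None or dp is None:
            continue
        comparable += 1
        a, b = pair
        ok = ((a in sp and b in dp) or (b in sp and a in dp))
        if not ok:
            mismatch += 1
    return comparable, mismatch


def assign_parentage(offspring: MicrosatGenotype,
                     candidates: list[CandidatePair],
                     year: int | None = None,
                     location: tuple[float, float] | None = None,
                     max_mendelian_mismatches: int = 1,
                     min_comparable_loci: int = 8,
                     max_distance_km: float | None = None) -> ParentageResult:
    """Exclusion-based parentage with spatio-temporal constraints.

    A candidate pair survives when it was active no later than the
    offspring's observation year, lies within ``max_distance_km`` of the
    sampling location (when both are given) and is Mendelian-compatible at
    all but at most ``max_mendelian_mismatches`` loci.  The offspring is
    assigned only when exactly one candidate survives.
    """
    from .geo import vincenty_km

    surviving: list[CandidatePair] = []
    untestable: list[str] = []
    for cand in candidates:
        if year is not None and min(cand.pair.years) > year:
            continue
        if (max_distance_km is not None and location is not None
                and cand.territory_lat is not None):
            d = vincenty_km(location[0], location[1],
                            cand.territory_lat, cand.territory_lon)
            if d > max_distance_km:
                continue
        comparable, mismatch = mendelian_mismatches(
            offspring, cand.male_genotype, cand.female_genotype)
        if comparable < min_comparable_loci:
            untestable.append(cand.pair.territory)
            continue
        if mismatch <= max_mendelian_mismatches:
            surviving.append(cand)

    if len(surviving) == 1:
        return ParentageResult(surviving[0],
                               [surviving[0].pair.territory], untestable)
    return ParentageResult(None, [c.pair.territory for c in surviving],
                           untestable)
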