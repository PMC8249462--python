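"""Sample records, replicate PCR calls, consensus genotypes and individual identification.

The multiple-tube workflow modelled here: every non-invasive sample is
amplified in several PCR replicates per locus; a consensus genotype is
accepted only when allele pairs are seen often enough to rule out allelic
dropout and false alleles.  Consensus genotypes are then clustered into
individuals by near-exact multilocus matching.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

log = logging.getLogger(__name__)

#: default 13 autosomal microsatellite loci of the monitoring panel
DEFAULT_LOCI = (
    "CPH5", "FH2001", "FH2010", "FH2017", "FH2054", "FH2087L", "FH2088",
    "FH2096", "FH2137", "FH2140", "FH2161", "vWF", "PEZ17",
)

MALE = "M"
FEMALE = "F"
UNKNOWN = "UNKNOWN"

#: returned by :func:`assign_mtdna_haplotype` when no reference matches
NO_MATCH = "NO_MATCH"

SAMPLE_TYPES = {"scat", "hair", "urine", "saliva", "tissue", "blood", "tooth"}


class ConsensusRejected:
    """Sentinel result for a sample whose consensus typed too few loci."""

    def __init__(self, sample_id: str, n_loci_typed: int, min_loci: int):
        self.sample_id = sample_id
        self.n_loci_typed = n_loci_typed
        self.min_loci = min_loci

    def __repr__(self):  # pragma: no cover
        return (f"ConsensusRejected({self.sample_id!r}: "
                f"{self.n_loci_typed} < {self.min_loci} loci)")

    def __bool__(self):
        return False


def canonical_pair(a: int, b: int) -> tuple[int, int]:
    """Order an allele pair ascending (storage canonical form)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class LocusCall:
    """One replicate PCR call at one locus; ``None`` alleles = no amplification."""

    locus: str
    allele_a: int | None
    allele_b: int | None
    replicate_id: int = 0

    def __post_init__(self):
        if (self.allele_a is None) != (self.allele_b is None):
            raise ValueError("partial allele call: both alleles or neither")
        if self.allele_a is not None and self.allele_a > self.allele_b:
            object.__setattr__(self, "allele_a", self.allele_b)
            object.__setattr__(self, "allele_b", self.allele_a)

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def pair(self) -> tuple[int, int] | None:
        return None if self.is_missing else (self.allele_a, self.allele_b)


@dataclass
class SampleRecord:
    """A collected sample with its replicate calls and sex-marker flags.

    ``calls`` maps locus -> one entry per replicate, each an ascending
    ``(a, b)`` tuple or ``None`` (no amplification).  ``sex_flags`` holds one
    ``(dbx6, dby7)`` boolean tuple per replicate.
    """

    sample_id: str
    date: str = ""
    lat: float | None = None
    lon: float | None = None
    sample_type: str = "scat"
    calls: dict[str, list[tuple[int, int] | None]] = field(default_factory=dict)
    sex_flags: list[tuple[bool, bool]] = field(default_factory=list)

    def __post_init__(self):
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        self.calls = {
            locus: [canonical_pair(*c) if c is not None else None for c in reps]
            for locus, reps in self.calls.items()
        }

    @property
    def n_replicates(self) -> int:
        return max((len(v) for v in self.calls.values()), default=len(self.sex_flags))


@dataclass
class MicrosatGenotype:
    """Consensus multilocus genotype of one sample or individual."""

    individual_id: str
    loci: dict[str, tuple[int, int] | None] = field(default_factory=dict)
    sex: str = UNKNOWN
    mtdna_haplotype: str = UNKNOWN
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.loci = {
            locus: canonical_pair(*pair) if pair is not None else None
            for locus, pair in self.loci.items()
        }
        suffix_sex = _sex_from_suffix(self.individual_id)
        if suffix_sex is not None:
            if self.sex == UNKNOWN:
                self.sex = suffix_sex
            elif self.sex != suffix_sex:
                # marker-based call wins over the advisory id suffix
                msg = (f"{self.individual_id}: id suffix disagrees with "
                       f"marker-based sex {self.sex}")
                self.warnings.append(msg)
                log.warning(msg)

    @property
    def n_loci_typed(self) -> int:
        return sum(1 for p in self.loci.values() if p is not None)

    def typed_loci(self) -> list[str]:
        return [k for k, v in self.loci.items() if v is not None]

    def mismatches(self, other: "MicrosatGenotype") -> tuple[int, int, int]:
        """Compare with another genotype over loci typed in both.

        Returns ``(n_comparable, n_mismatch, n_conflict)`` where a mismatch is
        any differing pair and a conflict is a differing pair whose allele
        union exceeds two alleles (cannot be explained by a single dropout).
        """
        comparable = mismatch = conflict = 0
        for locus, pair in self.loci.items():
            o = other.loci.get(locus)
            if pair is None or o is None:
                continue
            comparable += 1
            if pair != o:
                mismatch += 1
                if len(set(pair) | set(o)) > 2:
                    conflict += 1
        return comparable, mismatch, conflict


def _sex_from_suffix(individual_id: str) -> str | None:
    if individual_id.endswith("m"):
        return MALE
    if individual_id.endswith("f"):
        return FEMALE
    return None


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

def call_consensus(sample: SampleRecord, min_loci: int = 10,
                   het_min: int = 2, hom_min: int = 3,
                   ) -> MicrosatGenotype | ConsensusRejected:
    """Derive a consensus genotype from replicate calls.

    A heterozygote pair is accepted when observed in >= ``het_min``
    replicates; a homozygote when observed in >= ``hom_min`` replicates and
    no heterozygote was accepted at that locus.  The genotype is rejected
    when fewer than ``min_loci`` loci reach consensus.
    """
    if het_min < 1 or hom_min < het_min:
        raise ValueError("require het_min >= 1 and hom_min >= het_min")
    if not sample.calls or all(len(v) == 0 for v in sample.calls.values()):
        raise ValueError(f"sample {sample.sample_id} has no replicate calls")

    loci: dict[str, tuple[int, int] | None] = {}
    warns: list[str] = []
    for locus, reps in sample.calls.items():
        counts = Counter(p for p in reps if p is not None)
        hets = [p for p, n in counts.items() if p[0] != p[1] and n >= het_min]
        homs = [p for p, n in counts.items() if p[0] == p[1] and n >= hom_min]
        if len(hets) > 1:
            loci[locus] = None
            warns.append(f"{locus}: conflicting heterozygote consensus {sorted(hets)}")
        elif len(hets) == 1:
            loci[locus] = hets[0]
        elif len(homs) > 1:  # cannot happen with >2 replicate agreement rules relaxed, keep safe
            loci[locus] = None
            warns.append(f"{locus}: conflicting homozygote consensus {sorted(homs)}")
        elif len(homs) == 1:
            loci[locus] = homs[0]
        else:
            loci[locus] = None

    genotype = MicrosatGenotype(sample.sample_id, loci)
    genotype.warnings.extend(warns)
    genotype.sex = assign_sex(sample)
    if genotype.n_loci_typed < min_loci:
        return ConsensusRejected(sample.sample_id, genotype.n_loci_typed, min_loci)
    return genotype


# ---------------------------------------------------------------------------
# sex and mtDNA assignment
# ---------------------------------------------------------------------------

def assign_sex(sample: SampleRecord) -> str:
    """Call sex from replicate DBX6/DBY7 amplification flags.

    Male when the Y marker amplifies consistently (>=2 replicates and a
    majority of amplifying replicates); female when the X marker amplifies in
    >=2 replicates with the Y marker never seen.  Anything weaker (single
    replicate, contradictory replicates with equal support) is UNKNOWN.
    """
    amplified = [(x, y) for x, y in sample.sex_flags if x or y]
    if not amplified:
        return UNKNOWN
    n = len(amplified)
    y = sum(1 for _, dby7 in amplified if dby7)
    x = sum(1 for dbx6, _ in amplified if dbx6)
    if y == 0:
        return FEMALE if x >= 2 else UNKNOWN
    if y >= 2 and y > n - y:
        return MALE
    return UNKNOWN


@dataclass
class ReferenceHaplotypeSet:
    """Named mtDNA control-region reference fragments (uppercase ACGT)."""

    sequences: dict[str, str]

    def __post_init__(self):
        clean = {}
        for name, seq in self.sequences.items():
            s = str(seq).upper()
            if not set(s) <= set("ACGT"):
                raise ValueError(f"reference {name}: non-ACGT characters")
            clean[name] = s
        if len(clean) != len(self.sequences):
            raise ValueError("duplicate reference haplotype names")
        self.sequences = clean

    @classmethod
    def from_fasta(cls, path) -> "ReferenceHaplotypeSet":
        from Bio import SeqIO
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


class AmbiguousHaplotypeError(ValueError):
    def __init__(self, candidates):
        self.candidates = sorted(candidates)
        super().__init__(f"query matches multiple references: {self.candidates}")


def assign_mtdna_haplotype(query: str, refs: ReferenceHaplotypeSet,
                           min_length: int = 200) -> str:
    """Exact-match a query control-region sequence against the references.

    The query matches a reference when, after trimming terminal Ns, either
    sequence contains the other (the two primer systems yield 250 and 390 bp
    windows of the same region).  Exactly one match is required.
    """
    q = str(query).upper().strip().strip("N")
    if not set(q) <= set("ACGTN"):
        raise ValueError("query contains non-ACGTN characters")
    if len(q) < min_length:
        raise ValueError(f"query shorter than {min_length} bp after trimming")
    hits = [name for name, seq in refs.sequences.items() if q in seq or seq in q]
    if not hits:
        return NO_MATCH
    if len(hits) > 1:
        raise AmbiguousHaplotypeError(hits)
    return hits[0]


# ---------------------------------------------------------------------------
# individual identification
# ---------------------------------------------------------------------------

@dataclass
class IdentifiedIndividual:
    individual_id: str
    genotype: MicrosatGenotype
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class IdentificationResult:
    individuals: list[IdentifiedIndividual]
    sample_to_individual: dict[str, str]
    flagged_pairs: list[tuple[str, str, str]]

    @property
    def mean_samples_per_individual(self) -> float:
        return len(self.sample_to_individual) / len(self.individuals)

    @property
    def fraction_seen_once(self) -> float:
        ones = sum(1 for ind in self.individuals if ind.n_samples == 1)
        return ones / len(self.individuals)


def identify_individuals(genotypes: list[MicrosatGenotype],
                         max_mismatch_loci: int = 1,
                         min_comparable_loci: int = 8,
                         ) -> IdentificationResult:
    """Partition consensus genotypes into individuals.

    Two genotypes match when they share >= ``min_comparable_loci`` typed loci
    and differ at <= ``max_mismatch_loci`` of them, every difference being
    explicable by a single allelic dropout (allele union of two per locus).
    Matching is transitive: individuals are connected components of the
    pairwise match graph, which makes the result independent of input order.
    A candidate merge that would imply three distinct alleles at a locus is
    refused and the pair flagged for review.
    """
    n = len(genotypes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    flagged: list[tuple[str, str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            comparable, mismatch, conflict = genotypes[i].mismatches(genotypes[j])
            if comparable < min_comparable_loci:
                continue
            if mismatch <= max_mismatch_loci:
                if conflict:
                    flagged.append((genotypes[i].individual_id,
                                    genotypes[j].individual_id,
                                    "merge refused: >2 alleles at a locus"))
                    continue
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    individuals = []
    sample_to_individual = {}
    for k, members in enumerate(sorted(groups.values(), key=lambda m: m[0])):
        gts = [genotypes[i] for i in members]
        merged = _merge_consensus(gts)
        ind_id = f"IND{k + 1:04d}"
        merged = replace(merged, individual_id=ind_id)
        individuals.append(IdentifiedIndividual(ind_id, merged,
                                                [g.individual_id for g in gts]))
        for g in gts:
            sample_to_individual[g.individual_id] = ind_id
    return IdentificationResult(individuals, sample_to_individual, flagged)


def _merge_consensus(gts: list[MicrosatGenotype]) -> MicrosatGenotype:
    """Merge matched genotypes locus-wise, preferring heterozygote calls."""
    loci_names: list[str] = []
    for g in gts:
        for locus in g.loci:
            if locus not in loci_names:
                loci_names.append(locus)
    loci: dict[str, tuple[int, int] | None] = {}
    for locus in loci_names:
        pairs = [g.loci[locus] for g in gts
                 if g.loci.get(locus) is not None]
        if not pairs:
            loci[locus] = None
            continue
        hets = Counter(p for p in pairs if p[0] != p[1])
        homs = Counter(p for p in pairs if p[0] == p[1])
        loci[locus] = hets.most_common(1)[0][0] if hets else homs.most_common(1)[0][0]
    sexes = {g.sex for g in gts} - {UNKNOWN}
    haps = {g.mtdna_haplotype for g in gts} - {UNKNOWN, NO_MATCH}
    merged = MicrosatGenotype(
        gts[0].individual_id, loci,
        sex=sexes.pop() if len(sexes) == 1 else UNKNOWN,
        mtdna_haplotype=haps.pop() if len(haps) == 1 else UNKNOWN)
    return merged


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "t", "yes", "+", "y"}


def _parse_flag(v) -> bool:
    if isinstance(v, bool):
        return v
    if pd.isna(v):
        return False
    return str(v).strip().lower() in _TRUTHY


def read_sample_table(path, loci: tuple[str, ...] = DEFAULT_LOCI) -> list[SampleRecord]:
    """Read a replicate-level sample table (CSV/TSV, one row per replicate).

    Expected columns: sample_id, date, lat, lon, type, dbx6, dby7 and one
    ``<locus>_a`` / ``<locus>_b`` pair per locus (empty = no amplification).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    records = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        first = grp.iloc[0]
        calls: dict[str, list] = {locus: [] for locus in loci
                                  if f"{locus}_a" in df.columns}
        sex_flags = []
        for _, row in grp.iterrows():
            for locus in calls:
                a, b = row.get(f"{locus}_a"), row.get(f"{locus}_b")
                if pd.isna(a) or pd.isna(b):
                    calls[locus].append(None)
                else:
                    calls[locus].append(canonical_pair(int(a), int(b)))
            sex_flags.append((_parse_flag(row.get("dbx6")),
                              _parse_flag(row.get("dby7"))))
        records.append(SampleRecord(
            sample_id=str(sample_id),
            date=str(first.get("date", "")),
            lat=None if pd.isna(first.get("lat")) else float(first["lat"]),
            lon=None if pd.isna(first.get("lon")) else float(first["lon"]),
            sample_type=str(first.get("type", "scat")),
            calls=calls, sex_flags=sex_flags))
    return records


def write_individual_table(result: IdentificationResult, path,
                           loci: tuple[str, ...] = DEFAULT_LOCI) -> None:
    rows = []
    for ind in result.individuals:
        row = {"individual_id": ind.individual_id, "sex": ind.genotype.sex,
               "haplotype": ind.genotype.mtdna_haplotype,
               "n_samples": ind.n_samples}
        for locus in loci:
            pair = ind.genotype.loci.get(locus)
            row[f"{locus}_a"] = pair[0] if pair else ""
            row[f"{locus}_b"] = pair[1] if pair else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def to_genepop(genotypes: list[MicrosatGenotype], path,
               loci: tuple[str, ...] = DEFAULT_LOCI,
               title: str = "wolfped export") -> None:
    """Write genotypes as a one-population GenePop file (3-digit alleles)."""
    for g in genotypes:
        for pair in g.loci.values():
            if pair is not None and max(pair) > 999:
                raise ValueError("allele too large for 3-digit GenePop coding")
    lines = [title]
    lines.extend(loci)
    lines.append("Pop")
    for g in genotypes:
        codes = []
        for locus in loci:
            pair = g.loci.get(locus)
            codes.append("000000" if pair is None else f"{pair[0]:03d}{pair[1]:03d}")
        lines.append(f"{g.individual_id} , " + " ".join(codes))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path) -> list[MicrosatGenotype]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    genotypes = []
    for line in lines[i + 1:]:
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            warnings.warn("multiple Pop blocks collapsed into one")
            continue
        ident, _, rest = line.partition(",")
        codes = rest.split()
        pairs: dict[str, tuple[int, int] | None] = {}
        for locus, code in zip(loci, codes):
            a, b = int(code[:len(code) // 2]), int(code[len(code) // 2:])
            pairs[locus] = None if a == 0 or b == 0 else canonical_pair(a, b)
        genotypes.append(MicrosatGenotype(ident.strip(), pairs))
    return genotypes
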