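"""Packaged worked-example fixture: the published breeding-pair table of the
German recolonization (76 pairs, 2005-2015) plus the founder genealogy.

The parentage links in ``data/pedigree.csv`` follow each breeder's natal
pack; where a pack had several successive breeding pairs, the natal litter
was fixed by requiring consistency between the recursion's kinship values
and the printed inbreeding coefficients (a unique solution except for a few
coefficient-neutral choices, which were resolved by breeding-year
plausibility).  Breeders with unknown source packs are unrelated founders;
Roman-numeral ids are ungenotyped breeders, also treated as distinct
founders.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .pedigree import BreedingPair, Pedigree, expand_years


@dataclass
class ReferenceFixture:
    pairs: list[BreedingPair]          # the 76 study pairs
    all_pairs: list[BreedingPair]      # including the two pre-study founder pairs
    pedigree: Pedigree


def _data_path(name: str):
    return resources.files("wolfped").joinpath("data", name)


def load_fixture() -> ReferenceFixture:
    pedigree = Pedigree.read(_data_path("pedigree.csv"))
    study, all_pairs = [], []
    with _data_path("breeding_pairs.csv").open(newline="") as fh:
        for row in csv.DictReader(fh):
            fp = row["fp_printed"].strip()
            pair = BreedingPair(
                territory=row["territory"],
                male=row["male"], female=row["female"],
                years=expand_years(int(row["first_year"]),
                                   int(row["last_year"])),
                male_natal=None if row["male_natal"] == "unk" else row["male_natal"],
                female_natal=None if row["female_natal"] == "unk" else row["female_natal"],
                fp_printed=float(fp) if fp else None)
            all_pairs.append(pair)
            if row["in_study"].strip() == "1":
                study.append(pair)
    return ReferenceFixture(study, all_pairs, pedigree)
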