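"""Family-size accounting and the inbreeding effective number of breeders.

From a resolved pedigree, offspring counts are tallied per contributing
parent (a parent with at least one assigned offspring) separately for each
sex, optionally excluding every offspring sired by sneaker males from BOTH
the male and female tallies, and optionally restricted to an origin
stratum.  With ``N`` contributing parents, mean family size ``k̄`` and
family-size variance ``Vk`` (population variance over contributors), the
per-sex effective number of breeders is

    Nb_sex = (k̄·N − 2) / (k̄ − 1 + Vk / k̄)

and the two sexes combine harmonically:

    Nb = 4·Nb_f·Nb_m / (Nb_f + Nb_m).

Unequal family sizes (Vk above the Poisson expectation) and skewed sex
contributions both depress Nb below the census of contributors.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_data import Individual, Origin, Tactic
from .parentage import PedigreeAssignment

__all__ = [
    "FamilyStats",
    "NbEstimate",
    "family_stats",
    "nb_per_sex",
    "nb_combined",
    "nb_report",
    "round_half_up",
]


@dataclass(frozen=True)
class FamilyStats:
    """Contributor census and family-size moments for one sex stratum."""

    sex: str  # "male" | "female"
    origin: str  # "south" | "west" | "all"
    sneakers_included: bool
    N: int
    k_bar: float
    Vk: float
    counts: Mapping[str, int]  # parent id -> offspring count

    @property
    def total_offspring(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class NbEstimate:
    Nb_male: float
    Nb_female: float
    Nb_combined: float
    male_inputs: tuple[int, float, float]
    female_inputs: tuple[int, float, float]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding for report tables (Python's round is
    half-even)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _moments(counts: Mapping[str, int]) -> tuple[int, float, float]:
    n = len(counts)
    if n == 0:
        return 0, float("nan"), float("nan")
    k = np.array(list(counts.values()), dtype=float)
    return n, float(k.mean()), float(k.var())  # population variance


def family_stats(
    assignments: Sequence[PedigreeAssignment],
    registry: Mapping[str, Individual],
    include_sneakers: bool = True,
    origin: str = "all",
) -> tuple[FamilyStats, FamilyStats]:
    """(male, female) contributor statistics from resolved assignments.

    Excluding sneakers removes every sneaker-sired offspring from both
    parental tallies; an origin filter keeps only parents of that origin
    (each sex filtered by its own parent's origin).
    """
    male_counts: dict[str, int] = {}
    female_counts: dict[str, int] = {}
    for a in assignments:
        if a.status != "assigned":
            continue
        father = registry[a.father_id]
        mother = registry[a.mother_id]
        if not include_sneakers and father.tactic is Tactic.SNEAKER_MALE:
            continue
        if origin == "all" or father.origin.value == origin:
            male_counts[a.father_id] = male_counts.get(a.father_id, 0) + 1
        if origin == "all" or mother.origin.value == origin:
            female_counts[a.mother_id] = female_counts.get(a.mother_id, 0) + 1
    nm, km, vm = _moments(male_counts)
    nf, kf, vf = _moments(female_counts)
    return (
        FamilyStats("male", origin, include_sneakers, nm, km, vm, male_counts),
        FamilyStats("female", origin, include_sneakers, nf, kf, vf, female_counts),
    )


def nb_per_sex(N: int, k_bar: float, Vk: float) -> float:
    """Single-sex inbreeding effective number of breeders
    (k̄N − 2) / (k̄ − 1 + Vk/k̄)."""
    if k_bar <= 0:
        raise ValueError("mean family size must be positive")
    if Vk < 0:
        raise ValueError("family-size variance must be non-negative")
    denom = (k_bar - 1.0) + Vk / k_bar
    if denom <= 0:
        return float("nan")
    return (k_bar * N - 2.0) / denom


def nb_combined(nb_f: float, nb_m: float) -> float:
    """Two-sex harmonic combination 4·Nb_f·Nb_m / (Nb_f + Nb_m)."""
    if nb_f <= 0 or nb_m <= 0:
        raise ValueError("per-sex Nb must be positive")
    return 4.0 * nb_f * nb_m / (nb_f + nb_m)


def nb_estimate(male: FamilyStats, female: FamilyStats) -> NbEstimate:
    nb_m = nb_per_sex(male.N, male.k_bar, male.Vk)
    nb_f = nb_per_sex(female.N, female.k_bar, female.Vk)
    return NbEstimate(
        Nb_male=nb_m,
        Nb_female=nb_f,
        Nb_combined=nb_combined(nb_f, nb_m),
        male_inputs=(male.N, male.k_bar, male.Vk),
        female_inputs=(female.N, female.k_bar, female.Vk),
    )


def nb_report(
    assignments: Sequence[PedigreeAssignment],
    registry: Mapping[str, Individual],
    origins: Iterable[str] = ("south", "west", "all"),
) -> pd.DataFrame:
    """Strata x sneaker-inclusion Nb table (census, k̄, Vk, per-sex Nb,
    combined Nb), full precision; round for presentation with
    :func:`round_half_up`."""
    rows = []
    for include in (True, False):
        for origin in origins:
            male, female = family_stats(assignments, registry, include, origin)
            for fs in (male, female):
                row = {
                    "sneakers_included": include,
                    "origin": fs.origin,
                    "sex": fs.sex,
                    "N": fs.N,
                    "k_bar": fs.k_bar,
                    "Vk": fs.Vk,
                }
                try:
                    row["Nb_sex"] = nb_per_sex(fs.N, fs.k_bar, fs.Vk)
                except ValueError:
                    row["Nb_sex"] = float("nan")
                rows.append(row)
            try:
                est = nb_estimate(male, female)
                rows[-1]["Nb_combined"] = est.Nb_combined
                rows[-2]["Nb_combined"] = est.Nb_combined
            except ValueError:
                rows[-1]["Nb_combined"] = float("nan")
                rows[-2]["Nb_combined"] = float("nan")
    return pd.DataFrame(rows)
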