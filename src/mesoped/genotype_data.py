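"""Genotype and breeder-metadata containers plus GenePop / phenotype-TSV I/O.

The data model is deliberately small: a diploid microsatellite panel
(:class:`Locus`), individuals with origin / reproductive-tactic metadata
(:class:`Individual`), and a :class:`GenotypeTable` holding an
``(n_individuals, n_loci, 2)`` array of integer allele codes with ``0``
marking a missing allele.  Allele codes are opaque positive integers below
1000 (fragment sizes or arbitrary 3-digit codes); no repeat-unit conversion
is attempted.

GenePop is the exchange format: both the 2-digit and 3-digit concatenated
dialects are read (auto-detected per file) and the 3-digit dialect is
written.  Individual metadata (origin, sex/tactic, length, weight, tag)
lives in a sidecar TSV keyed on the individual id, because GenePop has no
metadata slots.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Origin",
    "Tactic",
    "Locus",
    "Individual",
    "GenotypeTable",
    "GenePopError",
    "PhenotypeError",
    "read_genepop",
    "write_genepop",
    "read_phenotypes",
    "attach_phenotypes",
]

MISSING = 0


class GenePopError(ValueError):
    """Malformed GenePop input or an un-encodable table."""


class PhenotypeError(ValueError):
    """Schema or validation failure in the phenotype TSV."""


class Origin(str, enum.Enum):
    SOUTH = "south"
    WEST = "west"
    OFFSPRING = "offspring"


class Tactic(str, enum.Enum):
    FEMALE = "female"
    NESTING_MALE = "nesting_male"
    SNEAKER_MALE = "sneaker_male"
    IMMATURE = "immature"


#: males eligible as candidate fathers
MALE_TACTICS = (Tactic.NESTING_MALE, Tactic.SNEAKER_MALE)


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker: a name, its allele registry, and a flag for
    null-allele-bearing loci that are kept in the table but excluded from
    the main statistics."""

    name: str
    alleles: frozenset[int] = frozenset()
    flagged_null: bool = False

    def __post_init__(self) -> None:
        for a in self.alleles:
            if not (0 < a < 1000):
                raise ValueError(
                    f"locus {self.name}: allele code {a} outside (0, 1000)"
                )


@dataclass(frozen=True)
class Individual:
    """One fish.  Adults (origin south/west) carry a reproductive tactic and
    body measurements; offspring are immature.  ``tactic`` may be ``None``
    for genotype-only records awaiting a phenotype join."""

    id: str
    origin: Origin
    tactic: Tactic | None = None
    total_length: float | None = None
    body_weight: float | None = None
    tag: str = ""

    def __post_init__(self) -> None:
        if self.total_length is not None and self.total_length <= 0:
            raise PhenotypeError(f"{self.id}: non-positive total_length")
        if self.body_weight is not None and self.body_weight <= 0:
            raise PhenotypeError(f"{self.id}: non-positive body_weight")
        if self.origin in (Origin.SOUTH, Origin.WEST) and self.tactic is not None:
            if self.tactic is Tactic.IMMATURE:
                raise PhenotypeError(f"{self.id}: adult with tactic 'immature'")
            if self.total_length is None or self.body_weight is None:
                raise PhenotypeError(f"{self.id}: adult missing length/weight")
        if self.origin is Origin.OFFSPRING and self.tactic not in (
            None,
            Tactic.IMMATURE,
        ):
            raise PhenotypeError(f"{self.id}: offspring must be immature")

    @property
    def is_adult(self) -> bool:
        return self.origin in (Origin.SOUTH, Origin.WEST)


class GenotypeTable:
    """Individuals x loci diploid calls.

    ``calls[i, l]`` is the unordered allele pair of individual ``i`` at
    locus ``l``, stored sorted ascending; ``(0, 0)`` means missing.
    """

    def __init__(
        self,
        panel: Sequence[Locus],
        individuals: Sequence[Individual],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(individuals), len(panel), 2):
            raise ValueError(
                f"calls shape {calls.shape} != "
                f"({len(individuals)}, {len(panel)}, 2)"
            )
        names = [loc.name for loc in panel]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in panel")
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        calls = np.sort(calls, axis=2)
        # register every observed allele in its locus allele set
        panel = list(panel)
        for l, loc in enumerate(panel):
            observed = set(int(a) for a in calls[:, l, :].ravel()) - {MISSING}
            if not observed <= loc.alleles:
                panel[l] = replace(loc, alleles=loc.alleles | frozenset(observed))
        self.panel: list[Locus] = panel
        self.individuals: list[Individual] = list(individuals)
        self.calls = calls

    # -- basic protocol ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.panel]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def locus_index(self, name: str) -> int:
        return self.locus_names.index(name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.locus_names == other.locus_names
            and [i.id for i in self.individuals] == [i.id for i in other.individuals]
            and [i.origin for i in self.individuals]
            == [i.origin for i in other.individuals]
            and np.array_equal(self.calls, other.calls)
        )

    # -- selection --------------------------------------------------------
    def subset(
        self,
        *,
        origin: Origin | Iterable[Origin] | None = None,
        ids: Iterable[str] | None = None,
    ) -> "GenotypeTable":
        """Rows restricted by origin and/or explicit id list (table order kept)."""
        mask = np.ones(self.n_individuals, dtype=bool)
        if origin is not None:
            origins = {origin} if isinstance(origin, Origin) else set(origin)
            mask &= np.array([ind.origin in origins for ind in self.individuals])
        if ids is not None:
            wanted = set(ids)
            mask &= np.array([ind.id in wanted for ind in self.individuals])
        idx = np.flatnonzero(mask)
        return GenotypeTable(
            self.panel,
            [self.individuals[i] for i in idx],
            self.calls[idx],
        )

    def drop_flagged_loci(self) -> "GenotypeTable":
        keep = [l for l, loc in enumerate(self.panel) if not loc.flagged_null]
        return GenotypeTable(
            [self.panel[l] for l in keep], self.individuals, self.calls[:, keep]
        )

    def flag_locus(self, name: str) -> None:
        l = self.locus_index(name)
        self.panel[l] = replace(self.panel[l], flagged_null=True)


# ---------------------------------------------------------------------------
# GenePop I/O
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)

DEFAULT_BLOCK_ORIGINS = (Origin.SOUTH, Origin.WEST, Origin.OFFSPRING)


def _decode_call(token: str, width: int, lineno: int) -> tuple[int, int]:
    if len(token) != 2 * width or not token.isdigit():
        raise GenePopError(
            f"line {lineno}: genotype token '{token}' is not {2 * width} digits"
        )
    return int(token[:width]), int(token[width:])


def read_genepop(
    path: str | Path,
    block_origins: Sequence[Origin] = DEFAULT_BLOCK_ORIGINS,
) -> GenotypeTable:
    """Parse a GenePop file into a :class:`GenotypeTable`.

    POP blocks map onto origins via ``block_origins`` (default: block 1 =
    south, block 2 = west, block 3 = offspring).  The 2- vs 3-digit dialect
    is auto-detected from the first genotype token and must be consistent
    across the file.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise GenePopError("empty file")
    # locus names: one per line until first POP, possibly comma-separated
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenePopError("no POP separator found")
    ids: list[str] = []
    origins: list[Origin] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    block = -1
    for lineno0, raw in enumerate(lines[i:], start=i + 1):
        if _POP_RE.match(raw):
            block += 1
            continue
        if not raw.strip():
            continue
        if "," not in raw:
            raise GenePopError(f"line {lineno0}: expected 'id , genotypes...'")
        ind_id, _, geno_part = raw.partition(",")
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise GenePopError(
                f"line {lineno0}: {len(tokens)} genotypes for "
                f"{len(locus_names)} loci"
            )
        if width is None and tokens:
            if len(tokens[0]) not in (4, 6):
                raise GenePopError(
                    f"line {lineno0}: genotype token '{tokens[0]}' has "
                    "unsupported width"
                )
            width = len(tokens[0]) // 2
        row = [_decode_call(t, width, lineno0) for t in tokens]
        ids.append(ind_id.strip())
        if block < 0 or block >= len(block_origins):
            raise GenePopError(f"line {lineno0}: POP block {block + 1} has no origin")
        origins.append(block_origins[block])
        rows.append(row)
    panel = [Locus(name) for name in locus_names]
    individuals = [Individual(i_, o) for i_, o in zip(ids, origins)]
    calls = np.array(rows, dtype=np.int64).reshape(len(rows), len(panel), 2)
    return GenotypeTable(panel, individuals, calls)


def write_genepop(
    table: GenotypeTable, path: str | Path, title: str = "mesoped export"
) -> None:
    """Emit the 3-digit GenePop dialect, one POP block per origin in
    south/west/offspring order, preserving input row order within blocks."""
    for loc in table.panel:
        if any(a >= 1000 for a in loc.alleles):
            raise GenePopError(f"locus {loc.name}: allele code >= 1000")
    out = [title]
    out.extend(table.locus_names)
    for origin in DEFAULT_BLOCK_ORIGINS:
        idx = [
            i for i, ind in enumerate(table.individuals) if ind.origin is origin
        ]
        if not idx and origin is not Origin.OFFSPRING:
            # keep block structure only for populated origins
            continue
        if not idx:
            continue
        out.append("POP")
        for i in idx:
            genos = " ".join(
                f"{a:03d}{b:03d}" for a, b in table.calls[i]
            )
            out.append(f"{table.individuals[i].id} , {genos}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Phenotype TSV
# ---------------------------------------------------------------------------

_PHENO_COLUMNS = ["id", "origin", "tactic", "total_length_cm", "body_weight_g", "tag"]


def read_phenotypes(path: str | Path) -> list[Individual]:
    """Read the sidecar phenotype TSV (columns id, origin, tactic,
    total_length_cm, body_weight_g, tag) into typed records."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "tag": str})
    missing = [c for c in _PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise PhenotypeError(f"phenotype file missing columns: {missing}")
    individuals = []
    for _, row in df.iterrows():
        try:
            origin = Origin(row["origin"])
            tactic = Tactic(row["tactic"])
        except ValueError as exc:
            raise PhenotypeError(f"{row['id']}: {exc}") from exc
        length = row["total_length_cm"]
        weight = row["body_weight_g"]
        individuals.append(
            Individual(
                id=str(row["id"]),
                origin=origin,
                tactic=tactic,
                total_length=None if pd.isna(length) else float(length),
                body_weight=None if pd.isna(weight) else float(weight),
                tag="" if pd.isna(row["tag"]) else str(row["tag"]),
            )
        )
    return individuals


def write_phenotypes(individuals: Sequence[Individual], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [i.id for i in individuals],
            "origin": [i.origin.value for i in individuals],
            "tactic": [
                "" if i.tactic is None else i.tactic.value for i in individuals
            ],
            "total_length_cm": [i.total_length for i in individuals],
            "body_weight_g": [i.body_weight for i in individuals],
            "tag": [i.tag for i in individuals],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def attach_phenotypes(
    table: GenotypeTable, phenotypes: Iterable[Individual]
) -> GenotypeTable:
    """Join phenotype records onto a genotype table by individual id.

    Genotype rows without a phenotype record keep their existing metadata.
    """
    by_id: Mapping[str, Individual] = {p.id: p for p in phenotypes}
    merged = [by_id.get(ind.id, ind) for ind in table.individuals]
    return GenotypeTable(table.panel, merged, table.calls)
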