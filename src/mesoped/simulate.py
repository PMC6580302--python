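"""Generative model of the mesocosm experiment with known truth.

The simulator emulates the full study design: two source populations of
adults diverged at a configurable multilocus F_ST (Balding–Nichols
construction around Dirichlet ancestral frequencies), sex/tactic structure
and truncated-normal length/weight distributions per origin x tactic,
mating over every male x female pair governed by the logistic success
model and a zero-truncated Poisson offspring-count model, Mendelian
transmission with per-locus genotype-replacement error, and one
null-allele-bearing locus whose null is shared by both populations
(heterozygote-with-null recorded as a visible homozygote, null homozygote
recorded as missing).

Every stochastic step is driven by a single seeded generator; the same
configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_data import (
    GenotypeTable,
    Individual,
    Locus,
    Origin,
    Tactic,
    write_genepop,
    write_phenotypes,
)
from .mating import COEF_NAMES

__all__ = [
    "PhenotypeDist",
    "SimulationConfig",
    "TruthPedigree",
    "SimulationResult",
    "draw_population_freqs",
    "sample_adults",
    "simulate_mating",
    "transmit_genotypes",
    "simulate_mesocosm",
]

#: internal allele code for the non-amplifying (null) allele
NULL_ALLELE = 995


@dataclass(frozen=True)
class PhenotypeDist:
    """Truncated-normal length (cm) and weight (g) for one origin x tactic."""

    length_mean: float
    length_sd: float
    length_lo: float
    length_hi: float
    weight_mean: float
    weight_sd: float
    weight_lo: float
    weight_hi: float


# Adult censuses and phenotype distributions of the two source samples:
# south 64 nesting + 9 sneaker + 76 female, west 59 + 24 + 86.
DEFAULT_CENSUS: dict[tuple[str, str], int] = {
    ("south", "nesting_male"): 64,
    ("south", "sneaker_male"): 9,
    ("south", "female"): 76,
    ("west", "nesting_male"): 59,
    ("west", "sneaker_male"): 24,
    ("west", "female"): 86,
}

DEFAULT_PHENOTYPES: dict[tuple[str, str], PhenotypeDist] = {
    ("south", "nesting_male"): PhenotypeDist(14.0, 2.6, 10.5, 20.5, 39.8, 22.6, 16.2, 108.0),
    ("south", "sneaker_male"): PhenotypeDist(11.8, 0.3, 11.5, 12.5, 21.1, 2.6, 18.2, 27.0),
    ("south", "female"): PhenotypeDist(14.4, 2.4, 10.5, 20.0, 44.5, 22.0, 14.6, 103.8),
    ("west", "nesting_male"): PhenotypeDist(12.8, 1.3, 10.5, 17.0, 30.1, 8.6, 16.4, 59.3),
    ("west", "sneaker_male"): PhenotypeDist(12.3, 0.9, 10.5, 14.5, 25.7, 5.0, 17.1, 37.2),
    ("west", "female"): PhenotypeDist(12.9, 1.3, 10.5, 19.5, 30.0, 11.2, 16.5, 101.7),
}

# Mating-model coefficients (success logit; count log) in COEF_NAMES order.
DEFAULT_SUCCESS_COEFS = (-5.361, 1.133, 1.083, -0.167, -0.026, -0.029, 0.372)
DEFAULT_COUNT_COEFS = (-2.620, 0.270, 0.599, 0.009, 0.180, 0.055, -0.753)


@dataclass
class SimulationConfig:
    n_loci: int = 11
    alleles_per_locus: tuple[int, int] = (4, 30)
    ancestral_freq_concentration: float = 0.5
    target_fst: float = 0.094
    census: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_CENSUS)
    )
    phenotypes: Mapping[tuple[str, str], PhenotypeDist] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPES)
    )
    success_coefs: Sequence[float] = DEFAULT_SUCCESS_COEFS
    count_coefs: Sequence[float] = DEFAULT_COUNT_COEFS
    covariate_mode: str = "length"
    genotyping_error_rate: float = 0.02
    null_allele_rate: float = 0.073
    null_locus: int | None = 10  # 0-based index of the flagged locus
    n_offspring_sampled: int = 651
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_fst < 1):
            raise ValueError("target_fst must lie in (0, 1)")
        for rate in (self.genotyping_error_rate, self.null_allele_rate):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if len(self.success_coefs) != 7 or len(self.count_coefs) != 7:
            raise ValueError("coefficient vectors must have length 7")
        for ph in self.phenotypes.values():
            if ph.length_lo > ph.length_hi or ph.weight_lo > ph.weight_hi:
                raise ValueError("inverted truncation bounds")


@dataclass
class TruthPedigree:
    """Ground truth: one row per produced offspring."""

    frame: pd.DataFrame  # offspring_id, mother_id, father_id, origin_class

    def origin_counts(self) -> pd.Series:
        return self.frame["origin_class"].value_counts()


@dataclass
class SimulationResult:
    config: SimulationConfig
    freqs: dict[str, dict[str, dict[int, float]]]  # origin -> locus -> allele -> p
    adults: GenotypeTable  # recorded (null-masked) adult genotypes
    adults_true: GenotypeTable  # latent true genotypes incl. null alleles
    registry: dict[str, Individual]
    offspring: GenotypeTable  # recorded genotypes of the sampled offspring
    truth: TruthPedigree  # sampled offspring only
    truth_all: TruthPedigree  # every offspring produced
    seed: int

    def write(self, outdir: str | Path) -> None:
        """GenePop + phenotype TSV + truth TSV + config echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        combined = GenotypeTable(
            self.adults.panel,
            self.adults.individuals + self.offspring.individuals,
            np.concatenate([self.adults.calls, self.offspring.calls]),
        )
        write_genepop(combined, outdir / "genotypes.gen")
        write_phenotypes(
            list(self.registry.values()), outdir / "phenotypes.tsv"
        )
        self.truth.frame.to_csv(
            outdir / "truth_pedigree.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
        cfg = {k: v for k, v in asdict(self.config).items()
               if k not in ("census", "phenotypes")}
        lines = [f"{k}: {v}" for k, v in cfg.items()]
        (outdir / "simulation_config.txt").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def draw_population_freqs(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, dict[str, dict[int, float]]]:
    """Balding–Nichols population frequencies for south and west.

    Ancestral frequencies per locus come from a symmetric Dirichlet; each
    population then draws Dirichlet(p_anc · (1 − F)/F) with
    F = ``target_fst``, so each population's allele frequency has variance
    F·p(1 − p) about the ancestral value — the variance model whose
    among-population component the Weir–Cockerham theta estimates.  The
    flagged locus carries an extra (null) allele at ``null_allele_rate`` in
    the ancestral pool, shared by both populations.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = cfg.alleles_per_locus
    out: dict[str, dict[str, dict[int, float]]] = {"south": {}, "west": {}}
    scale = (1.0 - cfg.target_fst) / cfg.target_fst
    for l in range(cfg.n_loci):
        k = int(rng.integers(lo, hi + 1))
        codes = [100 + 2 * i for i in range(k)]
        anc = rng.dirichlet(np.full(k, cfg.ancestral_freq_concentration))
        anc = np.maximum(anc, 1e-4)
        if cfg.null_locus is not None and l == cfg.null_locus:
            anc = np.append(anc * (1 - cfg.null_allele_rate), cfg.null_allele_rate)
            codes = codes + [NULL_ALLELE]
        anc = anc / anc.sum()
        name = f"L{l + 1:02d}"
        for pop in ("south", "west"):
            p = rng.dirichlet(anc * scale)
            out[pop][name] = {c: float(v) for c, v in zip(codes, p)}
    return out


# ---------------------------------------------------------------------------
# adults
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def sample_adults(
    cfg: SimulationConfig,
    freqs: dict[str, dict[str, dict[int, float]]],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, Individual], GenotypeTable, GenotypeTable]:
    """Draw the adult censuses: registry, recorded table, true table.

    Genotypes are Hardy–Weinberg random unions within each origin; lengths
    and weights are truncated normals per origin x tactic.  The recorded
    table hides null alleles (visible homozygote / missing).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    loci = list(next(iter(freqs.values())).keys())
    panel = [
        Locus(name, flagged_null=(cfg.null_locus is not None
                                  and i == cfg.null_locus))
        for i, name in enumerate(loci)
    ]
    individuals: list[Individual] = []
    true_rows: list[np.ndarray] = []
    counter = 1
    prefix = {"nesting_male": "M", "sneaker_male": "S", "female": "F"}
    for (origin, tactic), n in cfg.census.items():
        ph = cfg.phenotypes[(origin, tactic)]
        lengths = _truncnorm(rng, ph.length_mean, ph.length_sd,
                             ph.length_lo, ph.length_hi, n)
        weights = _truncnorm(rng, ph.weight_mean, ph.weight_sd,
                             ph.weight_lo, ph.weight_hi, n)
        calls = np.zeros((n, len(loci), 2), dtype=np.int64)
        for l, name in enumerate(loci):
            fmap = freqs[origin][name]
            alleles = np.array(sorted(fmap))
            p = np.array([fmap[a] for a in alleles])
            p = p / p.sum()
            calls[:, l, :] = rng.choice(alleles, size=(n, 2), p=p)
        for i in range(n):
            individuals.append(
                Individual(
                    id=f"{prefix[tactic]}{counter:03d}",
                    origin=Origin(origin),
                    tactic=Tactic(tactic),
                    total_length=round(float(lengths[i]), 1),
                    body_weight=round(float(weights[i]), 1),
                    tag="yellow" if origin == "south" else "pink",
                )
            )
            counter += 1
        true_rows.append(calls)
    true_calls = np.concatenate(true_rows)
    true_table = GenotypeTable(panel, individuals, true_calls)
    recorded = GenotypeTable(panel, individuals, _mask_nulls(true_calls))
    registry = {ind.id: ind for ind in individuals}
    return registry, recorded, true_table


def _mask_nulls(calls: np.ndarray) -> np.ndarray:
    """Null-aware recording: het-with-null becomes a visible homozygote,
    null homozygote becomes missing."""
    rec = calls.copy()
    is_null = rec == NULL_ALLELE
    one_null = is_null.sum(axis=2) == 1
    both_null = is_null.sum(axis=2) == 2
    visible = np.where(is_null[..., 0], rec[..., 1], rec[..., 0])
    for s in (0, 1):
        rec[..., s] = np.where(one_null, visible, rec[..., s])
        rec[..., s] = np.where(both_null, 0, rec[..., s])
    return rec


# ---------------------------------------------------------------------------
# mating
# ---------------------------------------------------------------------------

def _covariate(ind: Individual, mode: str) -> float:
    if mode == "length":
        return float(ind.total_length)
    if mode == "weight_length":
        return float(ind.body_weight / ind.total_length)
    raise ValueError(f"unknown covariate_mode {mode!r}")


def simulate_mating(
    cfg: SimulationConfig,
    registry: Mapping[str, Individual],
    rng: np.random.Generator | None = None,
) -> TruthPedigree:
    """Bernoulli success per pair from the logistic model, zero-truncated
    Poisson offspring counts for successful pairs."""
    rng = rng or np.random.default_rng(cfg.seed)
    beta = np.asarray(cfg.success_coefs, dtype=float)
    gamma = np.asarray(cfg.count_coefs, dtype=float)
    males = [i for i in registry.values()
             if i.tactic in (Tactic.NESTING_MALE, Tactic.SNEAKER_MALE)]
    females = [i for i in registry.values() if i.tactic is Tactic.FEMALE]
    if not males or not females:
        raise ValueError("registry must contain both sexes")
    rows = []
    counter = 1
    for m in males:
        o_i = 1.0 if m.origin is Origin.WEST else 0.0
        s_i = 1.0 if m.tactic is Tactic.SNEAKER_MALE else 0.0
        l_i = _covariate(m, cfg.covariate_mode)
        for f in females:
            o_j = 1.0 if f.origin is Origin.WEST else 0.0
            x = np.array([1.0, o_i, o_j, 1.0 if o_i == o_j else 0.0,
                          l_i, _covariate(f, cfg.covariate_mode), s_i])
            p = 1.0 / (1.0 + np.exp(-float(beta @ x)))
            if rng.random() >= p:
                continue
            lam = float(np.exp(gamma @ x))
            n_kids = _zero_truncated_poisson(rng, lam)
            for _ in range(n_kids):
                rows.append(
                    {
                        "offspring_id": f"O{counter:05d}",
                        "mother_id": f.id,
                        "father_id": m.id,
                        "origin_class": (
                            m.origin.value if m.origin is f.origin else "hybrid"
                        ),
                    }
                )
                counter += 1
    return TruthPedigree(pd.DataFrame(
        rows, columns=["offspring_id", "mother_id", "father_id", "origin_class"]
    ))


def _zero_truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    """Poisson conditioned on >= 1 by inverse transform."""
    u = rng.random()
    p0 = np.exp(-lam)
    return int(sps.poisson.ppf(p0 + u * (1.0 - p0), lam))


# ---------------------------------------------------------------------------
# transmission
# ---------------------------------------------------------------------------

def transmit_genotypes(
    pedigree: TruthPedigree,
    adults_true: GenotypeTable,
    cfg: SimulationConfig,
    freqs: dict[str, dict[str, dict[int, float]]] | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeTable:
    """Mendelian offspring genotypes with genotyping error and null-allele
    recording.

    Each offspring receives one random allele per parent per locus; with
    probability ``genotyping_error_rate`` the recorded genotype at a locus
    is replaced by a random Hardy–Weinberg draw from the mean of the two
    population frequency sets; null alleles follow the recording rule of
    :func:`sample_adults`.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    frame = pedigree.frame
    idx = {ind.id: i for i, ind in enumerate(adults_true.individuals)}
    n = len(frame)
    loci = adults_true.locus_names
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    mi = frame["mother_id"].map(idx).to_numpy()
    fi = frame["father_id"].map(idx).to_numpy()
    for l in range(len(loci)):
        pick_m = rng.integers(0, 2, n)
        pick_f = rng.integers(0, 2, n)
        calls[:, l, 0] = adults_true.calls[mi, l, pick_m]
        calls[:, l, 1] = adults_true.calls[fi, l, pick_f]
        if cfg.genotyping_error_rate > 0 and freqs is not None:
            err = rng.random(n) < cfg.genotyping_error_rate
            if err.any():
                name = loci[l]
                merged: dict[int, float] = {}
                for pop in freqs.values():
                    for a, p in pop[name].items():
                        merged[a] = merged.get(a, 0.0) + p
                alleles = np.array(sorted(merged))
                p = np.array([merged[a] for a in alleles])
                p /= p.sum()
                draw = rng.choice(alleles, size=(int(err.sum()), 2), p=p)
                calls[err, l, :] = draw
    recorded = _mask_nulls(calls)
    individuals = [
        Individual(oid, Origin.OFFSPRING, Tactic.IMMATURE)
        for oid in frame["offspring_id"]
    ]
    return GenotypeTable(adults_true.panel, individuals, recorded)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def simulate_mesocosm(cfg: SimulationConfig | None = None) -> SimulationResult:
    """Run the full generative model under one seed."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    freqs = draw_population_freqs(cfg, rng)
    registry, adults_rec, adults_true = sample_adults(cfg, freqs, rng)
    truth_all = simulate_mating(cfg, registry, rng)
    offspring_all = transmit_genotypes(truth_all, adults_true, cfg, freqs, rng)
    n_total = offspring_all.n_individuals
    n_keep = min(cfg.n_offspring_sampled, n_total)
    keep = np.sort(rng.choice(n_total, size=n_keep, replace=False))
    sampled = GenotypeTable(
        offspring_all.panel,
        [offspring_all.individuals[i] for i in keep],
        offspring_all.calls[keep],
    )
    truth = TruthPedigree(truth_all.frame.iloc[keep].reset_index(drop=True))
    registry = dict(registry)
    for ind in sampled.individuals:
        registry[ind.id] = ind
    return SimulationResult(
        config=cfg,
        freqs=freqs,
        adults=adults_rec,
        adults_true=adults_true,
        registry=registry,
        offspring=sampled,
        truth=truth,
        truth_all=truth_all,
        seed=cfg.seed,
    )
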