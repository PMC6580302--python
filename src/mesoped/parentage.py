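"""Marker power and trio parentage assignment for a closed breeding system.

Marker informativeness
----------------------
For a locus with allele frequencies ``p``:

* PIC (Botstein): ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``;
* probability of identity: ``I = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2``,
  multiplied across loci;
* exclusion probability Q in three configurations — P1 (random candidate
  vs offspring alone), P2 (candidate second parent with one true parent
  known), PP (random candidate parent pair) — each derived by exact
  expectation over Hardy–Weinberg genotype combinations, combined across
  loci as ``1 - prod(1 - Q_l)``.

Assignment engine
-----------------
Every mother x father trio is scored per offspring with a log-likelihood
ratio (LOD): the likelihood of the offspring genotype given the pair under
a per-locus genotype-replacement error model with rate ``e`` (the observed
genotype is the true Mendelian draw with probability ``1 - e``, otherwise a
random Hardy–Weinberg genotype), over the likelihood of a random draw from
the population allele frequencies.  Round 1 accepts the highest-LOD trio
with zero Mendelian mismatches; offspring unresolved in round 1 are
re-scored allowing up to two mismatching loci.  Loci flagged as
null-bearing are excluded from scoring and used only to break round-2 LOD
ties.  Ties never become arbitrary assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotype_data import (
    MALE_TACTICS,
    MISSING,
    GenotypeTable,
    Individual,
    Origin,
    Tactic,
)

__all__ = [
    "MarkerPower",
    "TrioScore",
    "PedigreeAssignment",
    "pic",
    "probability_of_identity",
    "exclusion_probability",
    "combined_exclusion",
    "combined_identity",
    "marker_power_table",
    "trio_lod",
    "assign_parentage",
    "classify_origin",
    "simulate_assignment_success",
]

FreqMap = Mapping[int, float]


@dataclass(frozen=True)
class MarkerPower:
    locus: str
    PIC: float
    Q_P1: float
    Q_P2: float
    Q_PP: float
    I: float


@dataclass(frozen=True)
class TrioScore:
    offspring_id: str
    mother_id: str
    father_id: str
    lod: float
    mismatches: int


@dataclass
class PedigreeAssignment:
    offspring_id: str
    mother_id: str | None
    father_id: str | None
    lod: float
    mismatches: int
    origin_class: str  # south | west | hybrid | unresolved
    mismatch_budget_used: int
    status: str  # assigned | ambiguous | unassigned


def _freq_array(freqs: FreqMap) -> np.ndarray:
    p = np.array(list(freqs.values()), dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency map")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValueError(f"frequencies sum to {p.sum():.6f}, not 1")
    return p


# ---------------------------------------------------------------------------
# marker power indices
# ---------------------------------------------------------------------------

def pic(freqs: FreqMap) -> float:
    """Polymorphic information content (Botstein form)."""
    p = _freq_array(freqs)
    s2 = float(np.sum(p**2))
    cross = float(np.sum(np.outer(p**2, p**2))) - float(np.sum(p**4))
    return 1.0 - s2 - cross  # cross = sum_{i != j} p_i^2 p_j^2 = 2 sum_{i<j}


def probability_of_identity(freqs: FreqMap) -> float:
    """Per-locus probability that two random individuals share a genotype."""
    p = _freq_array(freqs)
    s4 = float(np.sum(p**4))
    het = float(np.sum(np.outer(2 * p, p) ** 2)) / 2 - 2 * s4
    # sum over i<j of (2 p_i p_j)^2 = (sum_{i,j} (2 p_i p_j)^2 - sum_ii)/2
    return s4 + het


def exclusion_probability(freqs: FreqMap, variant: str = "P2") -> float:
    """Exclusion power of one locus.

    ``P1``: probability a random non-parent is excluded against the
    offspring genotype alone; ``P2``: against offspring plus one known true
    parent; ``PP``: probability a random non-parental pair is excluded
    jointly.  All are exact expectations under Hardy–Weinberg.
    """
    p = _freq_array(freqs)
    if variant == "P1":
        return _exclusion_p1(p)
    if variant == "P2":
        return _exclusion_p2(p)
    if variant == "PP":
        return _exclusion_pp(p)
    raise ValueError(f"unknown exclusion variant {variant!r}")


def _exclusion_p1(p: np.ndarray) -> float:
    k = len(p)
    q = 0.0
    for i in range(k):
        q += p[i] ** 2 * (1 - p[i]) ** 2
        for j in range(i + 1, k):
            q += 2 * p[i] * p[j] * (1 - p[i] - p[j]) ** 2
    return float(q)


def _exclusion_p2(p: np.ndarray) -> float:
    """Expectation over (known mother, transmitted allele, paternal allele)
    of the probability that a random male carries no allele that could be
    the paternal contribution."""
    k = len(p)
    q = 0.0
    for m1 in range(k):
        for m2 in range(k):
            pm = p[m1] * p[m2]  # ordered maternal genotype
            for mt in (m1, m2):
                for f in range(k):
                    w = pm * 0.5 * p[f]
                    # offspring {mt, f}; paternal-candidate allele set S
                    a, b = mt, f
                    s: set[int] = set()
                    if b in (m1, m2):
                        s.add(a)
                    if a in (m1, m2):
                        s.add(b)
                    ps = float(np.sum(p[list(s)])) if s else 0.0
                    q += w * (1 - ps) ** 2
    return float(q)


def _exclusion_pp(p: np.ndarray) -> float:
    k = len(p)
    carry = 1 - (1 - p) ** 2  # q_i = P(genotype contains allele i)
    q = 0.0
    for i in range(k):
        q += p[i] ** 2 * (1 - carry[i] ** 2)
        for j in range(i + 1, k):
            qij = (
                1
                - (1 - p[i]) ** 2
                - (1 - p[j]) ** 2
                + (1 - p[i] - p[j]) ** 2
            )
            compat = 2 * carry[i] * carry[j] - qij**2
            q += 2 * p[i] * p[j] * (1 - compat)
    return float(q)


def combined_exclusion(per_locus_q: Sequence[float]) -> float:
    """Panel-level exclusion: non-exclusion multiplies across loci."""
    non_excl = np.prod([1.0 - q for q in per_locus_q])
    return float(1.0 - non_excl)


def combined_identity(per_locus_i: Sequence[float]) -> float:
    return float(np.prod(list(per_locus_i)))


def marker_power_table(freqs_by_locus: Mapping[str, FreqMap]):
    """PIC, Q (all variants), and I for every locus plus the panel row."""
    import pandas as pd

    rows = []
    for name, f in freqs_by_locus.items():
        if not f:
            continue
        rows.append(
            MarkerPower(
                locus=name,
                PIC=pic(f),
                Q_P1=exclusion_probability(f, "P1"),
                Q_P2=exclusion_probability(f, "P2"),
                Q_PP=exclusion_probability(f, "PP"),
                I=probability_of_identity(f),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("locus")
    combined = {
        "PIC": float("nan"),
        "Q_P1": combined_exclusion(df["Q_P1"]),
        "Q_P2": combined_exclusion(df["Q_P2"]),
        "Q_PP": combined_exclusion(df["Q_PP"]),
        "I": combined_identity(df["I"]),
    }
    df.loc["combined"] = combined
    return df


# ---------------------------------------------------------------------------
# trio LOD
# ---------------------------------------------------------------------------

def _transmission(genotype: tuple[int, int], allele: int) -> float:
    a, b = genotype
    return 0.5 * (a == allele) + 0.5 * (b == allele)


def _hw_prob(freqs: FreqMap, genotype: tuple[int, int]) -> float:
    a, b = genotype
    pa, pb = freqs.get(a, 0.0), freqs.get(b, 0.0)
    return pa * pb * (1 if a == b else 2)


def trio_lod(
    offspring: Mapping[str, tuple[int, int]],
    mother: Mapping[str, tuple[int, int]],
    father: Mapping[str, tuple[int, int]],
    freqs: Mapping[str, FreqMap],
    error_rate: float = 0.02,
) -> TrioScore:
    """LOD and mismatch count for a single trio over per-locus genotype
    maps (convenience scalar form of the vectorized engine)."""
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    lod = 0.0
    mismatches = 0
    for locus, og in offspring.items():
        if MISSING in og:
            continue
        mg, fg = mother.get(locus), father.get(locus)
        if mg is None or fg is None or MISSING in mg or MISSING in fg:
            continue
        a, b = og
        t = (
            _transmission(mg, a) * _transmission(fg, b)
            + (_transmission(mg, b) * _transmission(fg, a) if a != b else 0.0)
        )
        p0 = _hw_prob(freqs[locus], og)
        if p0 == 0:
            continue
        if t == 0:
            mismatches += 1
        l1 = (1 - error_rate) * t + error_rate * p0
        lod += math.log(l1 / p0) if l1 > 0 else -math.inf
    return TrioScore("", "", "", lod, mismatches)


# ---------------------------------------------------------------------------
# vectorized assignment engine
# ---------------------------------------------------------------------------

class _LocusCache:
    """Per-locus transmission-probability matrices for a candidate set."""

    def __init__(
        self,
        table: GenotypeTable,
        locus_cols: Sequence[int],
        allele_index: Sequence[Mapping[int, int]],
        freq_vectors: Sequence[np.ndarray],
    ):
        self.trans: list[np.ndarray] = []  # (n_candidates, K_l)
        for l, col in enumerate(locus_cols):
            idx = allele_index[l]
            k = len(idx)
            t = np.zeros((table.n_individuals, k))
            calls = table.calls[:, col, :]
            for i, (a, b) in enumerate(calls):
                if a == MISSING or b == MISSING:
                    t[i] = freq_vectors[l]  # uninformative parent call
                    continue
                t[i, idx[int(a)]] += 0.5
                t[i, idx[int(b)]] += 0.5
            self.trans.append(t)


def _prepare(freqs, loci):
    allele_index = []
    freq_vectors = []
    for name in loci:
        f = freqs[name]
        idx = {a: i for i, a in enumerate(sorted(f))}
        allele_index.append(idx)
        vec = np.zeros(len(idx))
        for a, i in idx.items():
            vec[i] = f[a]
        freq_vectors.append(vec)
    return allele_index, freq_vectors


def _score_all(
    offspring: GenotypeTable,
    mothers: GenotypeTable,
    fathers: GenotypeTable,
    freqs: Mapping[str, FreqMap],
    loci: Sequence[str],
    error_rate: float,
):
    """LOD and mismatch matrices, shape (n_offspring, n_mothers, n_fathers)
    returned one offspring at a time as a generator of (lod, mism)."""
    cols = [offspring.locus_index(n) for n in loci]
    allele_index, freq_vectors = _prepare(freqs, loci)
    m_cache = _LocusCache(mothers, [mothers.locus_index(n) for n in loci],
                          allele_index, freq_vectors)
    f_cache = _LocusCache(fathers, [fathers.locus_index(n) for n in loci],
                          allele_index, freq_vectors)
    n_m, n_f = mothers.n_individuals, fathers.n_individuals
    for o in range(offspring.n_individuals):
        lod = np.zeros((n_m, n_f))
        mism = np.zeros((n_m, n_f), dtype=np.int32)
        for l, col in enumerate(cols):
            a, b = offspring.calls[o, col]
            if a == MISSING or b == MISSING:
                continue
            idx = allele_index[l]
            if int(a) not in idx or int(b) not in idx:
                continue  # allele unseen in the frequency base
            ia, ib = idx[int(a)], idx[int(b)]
            tm, tf = m_cache.trans[l], f_cache.trans[l]
            if ia == ib:
                t = np.outer(tm[:, ia], tf[:, ia])
            else:
                t = np.outer(tm[:, ia], tf[:, ib]) + np.outer(
                    tm[:, ib], tf[:, ia]
                )
            pa, pb = freq_vectors[l][ia], freq_vectors[l][ib]
            p0 = pa * pb * (1 if ia == ib else 2)
            mism += t <= 1e-300
            l1 = (1 - error_rate) * t + error_rate * p0
            with np.errstate(divide="ignore"):
                lod += np.log(l1) - math.log(p0)
        yield lod, mism


def _classify(mother: Individual, father: Individual) -> str:
    if mother.origin is father.origin:
        return mother.origin.value
    return "hybrid"


def classify_origin(
    mother: Individual | None, father: Individual | None
) -> str:
    """south / west / hybrid from the two parental origins; unresolved when
    either parent is unassigned."""
    if mother is None or father is None:
        return "unresolved"
    return _classify(mother, father)


def assign_parentage(
    offspring: GenotypeTable,
    mothers: GenotypeTable,
    fathers: GenotypeTable,
    freqs: Mapping[str, FreqMap],
    error_rate: float = 0.02,
    max_mismatch_round2: int = 2,
    lod_tie_tol: float = 1e-9,
) -> list[PedigreeAssignment]:
    """Two-round trio assignment over all mother x father pairs.

    Round 1 requires zero Mendelian mismatches on the unflagged loci and
    takes the highest-LOD compatible pair; unresolved offspring enter
    round 2 with up to ``max_mismatch_round2`` mismatching loci allowed.
    LOD ties are broken in round 2 by the flagged (null-bearing) loci when
    available, otherwise reported as ambiguous.
    """
    loci_main = [loc.name for loc in offspring.panel if not loc.flagged_null]
    loci_flagged = [loc.name for loc in offspring.panel if loc.flagged_null]
    results: list[PedigreeAssignment] = []
    if mothers.n_individuals == 0 or fathers.n_individuals == 0:
        return [
            PedigreeAssignment(ind.id, None, None, float("nan"), -1,
                               "unresolved", 0, "unassigned")
            for ind in offspring.individuals
        ]
    flagged_scores = None
    scores = _score_all(offspring, mothers, fathers, freqs, loci_main, error_rate)
    pending: list[tuple[int, np.ndarray, np.ndarray]] = []
    for o, (lod, mism) in enumerate(scores):
        res = _pick(lod, mism, max_mismatch=0, tol=lod_tie_tol)
        if res is not None:
            mi, fi, used = res
            results.append(_make_assignment(
                offspring.individuals[o], mothers.individuals[mi],
                fathers.individuals[fi], lod[mi, fi], int(mism[mi, fi]), 0))
        else:
            pending.append((o, lod, mism))
            results.append(None)  # placeholder, filled in round 2
    if pending:
        if loci_flagged:
            flagged_iter = _score_all(
                offspring.subset(ids=[offspring.individuals[o].id for o, _, _ in pending]),
                mothers, fathers, freqs, loci_flagged, error_rate,
            )
            flagged_scores = list(flagged_iter)
        for j, (o, lod, mism) in enumerate(pending):
            tie_lod = flagged_scores[j][0] if flagged_scores else None
            res = _pick(lod, mism, max_mismatch=max_mismatch_round2,
                        tol=lod_tie_tol, tie_breaker=tie_lod)
            ind = offspring.individuals[o]
            if res is None:
                results[o] = PedigreeAssignment(
                    ind.id, None, None, float("nan"), -1, "unresolved",
                    max_mismatch_round2, "ambiguous")
            else:
                mi, fi, _ = res
                results[o] = _make_assignment(
                    ind, mothers.individuals[mi], fathers.individuals[fi],
                    lod[mi, fi], int(mism[mi, fi]), max_mismatch_round2)
    return results


def _pick(lod, mism, max_mismatch, tol, tie_breaker=None):
    """Best pair under the mismatch budget, or None on no candidate / tie."""
    ok = mism <= max_mismatch
    if not ok.any():
        return None
    masked = np.where(ok, lod, -np.inf)
    best = masked.max()
    if not np.isfinite(best):
        return None
    ties = np.argwhere(masked >= best - tol)
    if len(ties) == 1:
        mi, fi = ties[0]
        return int(mi), int(fi), max_mismatch
    if tie_breaker is not None:
        tb = np.array([tie_breaker[mi, fi] for mi, fi in ties])
        order = np.argsort(-tb)
        if tb[order[0]] > tb[order[1]] + tol:
            mi, fi = ties[order[0]]
            return int(mi), int(fi), max_mismatch
    return None


def _make_assignment(ind, mother, father, lod, mism, budget):
    return PedigreeAssignment(
        offspring_id=ind.id,
        mother_id=mother.id,
        father_id=father.id,
        lod=float(lod),
        mismatches=mism,
        origin_class=_classify(mother, father),
        mismatch_budget_used=budget,
        status="assigned",
    )


def split_candidates(
    adults: GenotypeTable,
) -> tuple[GenotypeTable, GenotypeTable]:
    """Sex-aware candidate lists: mothers = females, fathers = nesting and
    sneaker males."""
    mother_ids = [
        ind.id for ind in adults.individuals if ind.tactic is Tactic.FEMALE
    ]
    father_ids = [
        ind.id for ind in adults.individuals if ind.tactic in MALE_TACTICS
    ]
    return adults.subset(ids=mother_ids), adults.subset(ids=father_ids)


# ---------------------------------------------------------------------------
# assignment-power simulation
# ---------------------------------------------------------------------------

def simulate_assignment_success(
    freqs: Mapping[str, FreqMap],
    n_offspring: int = 1000,
    n_mothers: int = 162,
    n_fathers: int = 156,
    error_rate: float = 0.0,
    seed: int = 0,
):
    """Cumulative parentage-allocation success as loci are added in
    descending second-parent exclusion power Q(P2).

    Candidate parents are Hardy–Weinberg draws from ``freqs``; each
    simulated offspring has a uniformly chosen true mother and father and a
    Mendelian genotype.  For k = 1..L the top-k loci are used; success is
    the fraction assigned to the true pair.  Returns a list of
    (k, success_fraction) with the k = 0 entry fixed at 0.
    """
    import pandas as pd

    from .genotype_data import GenotypeTable, Individual, Locus

    rng = np.random.default_rng(seed)
    ranked = sorted(
        (name for name, f in freqs.items() if f),
        key=lambda name: -exclusion_probability(freqs[name], "P2"),
    )

    def hw_table(n, prefix, origin):
        panel = [Locus(name) for name in ranked]
        calls = np.zeros((n, len(ranked), 2), dtype=np.int64)
        for l, name in enumerate(ranked):
            alleles = np.array(sorted(freqs[name]))
            p = np.array([freqs[name][a] for a in alleles])
            calls[:, l, :] = rng.choice(alleles, size=(n, 2), p=p)
        inds = [Individual(f"{prefix}{i}", origin) for i in range(n)]
        return GenotypeTable(panel, inds, calls)

    mothers = hw_table(n_mothers, "SM", Origin.SOUTH)
    fathers = hw_table(n_fathers, "SF", Origin.WEST)
    true_m = rng.integers(0, n_mothers, n_offspring)
    true_f = rng.integers(0, n_fathers, n_offspring)
    child_calls = np.zeros((n_offspring, len(ranked), 2), dtype=np.int64)
    for l in range(len(ranked)):
        pick_m = rng.integers(0, 2, n_offspring)
        pick_f = rng.integers(0, 2, n_offspring)
        child_calls[:, l, 0] = mothers.calls[true_m, l, pick_m]
        child_calls[:, l, 1] = fathers.calls[true_f, l, pick_f]
    kids_inds = [
        Individual(f"K{i}", Origin.OFFSPRING) for i in range(n_offspring)
    ]
    curve = [(0, 0.0)]
    for k in range(1, len(ranked) + 1):
        loci_k = ranked[:k]
        cols = [i for i, name in enumerate(ranked) if name in loci_k]
        kids = GenotypeTable(
            [Locus(n) for n in loci_k], kids_inds, child_calls[:, cols]
        )
        m_k = GenotypeTable([Locus(n) for n in loci_k],
                            mothers.individuals, mothers.calls[:, cols])
        f_k = GenotypeTable([Locus(n) for n in loci_k],
                            fathers.individuals, fathers.calls[:, cols])
        assigned = assign_parentage(
            kids, m_k, f_k, freqs, error_rate=max(error_rate, 1e-4)
        )
        hits = sum(
            1
            for i, a in enumerate(assigned)
            if a.status == "assigned"
            and a.mother_id == mothers.individuals[true_m[i]].id
            and a.father_id == fathers.individuals[true_f[i]].id
        )
        curve.append((k, hits / n_offspring))
    return pd.DataFrame(curve, columns=["k_loci", "success"])
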