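"""Diversity and differentiation statistics for diploid microsatellite panels.

Implements the classical single-breeding-study toolkit:

* allele frequencies and observed heterozygosity by direct counting;
* unbiased expected heterozygosity (Nei & Chesser small-sample form,
  including the observed-heterozygosity correction term);
* allelic richness by hypergeometric rarefaction to a standardized number
  of gene copies (exact rational arithmetic);
* Weir–Cockerham variance-component F-statistics: within-population f
  (F_IS) and among-population theta (F_ST), multilocus values always as
  ratio-of-sums over loci and alleles, never means of per-locus ratios;
* the Hardy–Weinberg exact conditional test estimated by a Guo–Thompson
  style Markov chain over genotype arrays with fixed allele counts;
* a Monte-Carlo genotypic-association (linkage disequilibrium) G-test by
  permutation of one locus's genotypes among individuals;
* a heterozygote-deficit null-allele frequency estimate
  fn = (He - Ho) / (He + Ho), signed (negative under heterozygote excess);
* Benjamini–Hochberg / Benjamini–Yekutieli FDR step-up corrections.

Loci flagged as null-bearing are excluded from multilocus summaries unless
explicitly requested, mirroring the practice of dropping a
null-allele-compromised marker from the headline statistics while keeping
it genotyped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genotype_data import MISSING, GenotypeTable, Origin

__all__ = [
    "McTestConfig",
    "LocusSummary",
    "DifferentiationResult",
    "HWTestResult",
    "LDTestResult",
    "allele_freqs",
    "genotype_counts",
    "observed_expected_het",
    "allelic_richness",
    "total_gene_diversity",
    "fis_weir_cockerham",
    "fst_weir_cockerham",
    "hw_exact_test",
    "ld_exact_test",
    "null_allele_freq",
    "fdr_adjust",
    "locus_summary_table",
    "pairwise_fst_table",
]


@dataclass(frozen=True)
class McTestConfig:
    """Markov-chain settings for the exact tests.

    Defaults are the conventional heavy chain (1e5 dememorization steps,
    1000 batches of 5e4 iterations); analyses on small tables can run far
    shorter chains, controlled here.
    """

    dememorization: int = 100_000
    batches: int = 1_000
    iterations_per_batch: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dememorization, self.batches, self.iterations_per_batch) <= 0:
            raise ValueError("chain parameters must be positive")


@dataclass
class LocusSummary:
    locus: str
    n: int
    A: int
    Ar: float
    Ho: float
    He: float
    Fis: float
    fn: float


@dataclass
class DifferentiationResult:
    theta: float
    per_locus_theta: dict[str, float]
    p_value: float


@dataclass
class HWTestResult:
    p_value: float
    mc_se: float
    monomorphic: bool = False


@dataclass
class LDTestResult:
    p_value: float
    g_statistic: float
    n_permutations: int
    monomorphic: bool = False


# ---------------------------------------------------------------------------
# counting substrate
# ---------------------------------------------------------------------------

def _group_calls(table: GenotypeTable, group) -> np.ndarray:
    """Calls array for an origin filter (Origin, iterable of Origin, or None
    for everyone)."""
    if group is None:
        return table.calls
    sub = table.subset(origin=group)
    if sub.n_individuals == 0:
        raise ValueError("empty group")
    return sub.calls


def allele_freqs(table: GenotypeTable, group=None) -> dict[str, dict[int, float]]:
    """Per-locus allele relative frequencies over non-missing calls."""
    calls = _group_calls(table, group)
    out: dict[str, dict[int, float]] = {}
    for l, loc in enumerate(table.panel):
        col = calls[:, l, :].ravel()
        col = col[col != MISSING]
        if col.size == 0:
            out[loc.name] = {}
            continue
        alleles, counts = np.unique(col, return_counts=True)
        total = counts.sum()
        out[loc.name] = {int(a): c / total for a, c in zip(alleles, counts)}
    return out


def genotype_counts(
    table: GenotypeTable, group, locus: str
) -> dict[tuple[int, int], int]:
    """Unordered-genotype counts at one locus (missing calls dropped)."""
    calls = _group_calls(table, group)
    l = table.locus_index(locus)
    out: dict[tuple[int, int], int] = {}
    for a, b in calls[:, l, :]:
        if a == MISSING or b == MISSING:
            continue
        key = (int(a), int(b))
        out[key] = out.get(key, 0) + 1
    return out


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def observed_expected_het(
    table: GenotypeTable, group=None
) -> pd.DataFrame:
    """Observed and unbiased expected heterozygosity per locus.

    He follows the Nei & Chesser small-sample estimator
    ``He = n/(n-1) * (1 - sum p_i^2 - Ho/(2n))`` with n the number of
    individuals with non-missing calls.  Loci with n < 2 get NaN.
    """
    calls = _group_calls(table, group)
    rows = []
    for l, loc in enumerate(table.panel):
        pair = calls[:, l, :]
        ok = (pair[:, 0] != MISSING) & (pair[:, 1] != MISSING)
        pair = pair[ok]
        n = len(pair)
        if n < 2:
            rows.append((loc.name, n, np.nan, np.nan))
            continue
        ho = float(np.mean(pair[:, 0] != pair[:, 1]))
        _, counts = np.unique(pair.ravel(), return_counts=True)
        p = counts / (2 * n)
        he = n / (n - 1) * (1.0 - float(np.sum(p**2)) - ho / (2 * n))
        rows.append((loc.name, n, ho, he))
    return pd.DataFrame(rows, columns=["locus", "n", "Ho", "He"]).set_index("locus")


def allelic_richness(
    table: GenotypeTable, group=None, g: int | None = None
) -> pd.Series:
    """Hypergeometric-rarefaction allelic richness at ``g`` gene copies.

    ``Ar = sum_a [1 - C(2N - N_a, g) / C(2N, g)]`` where ``N_a`` is the
    copy count of allele ``a``; equals the expected number of distinct
    alleles in a random subsample of ``g`` copies.  Exact rational
    arithmetic; ``g`` defaults to the smallest per-locus copy count.
    """
    calls = _group_calls(table, group)
    copy_counts = []
    for l in range(table.n_loci):
        col = calls[:, l, :].ravel()
        copy_counts.append(int(np.sum(col != MISSING)))
    if g is None:
        g = min(c for c in copy_counts if c > 0)
    vals = {}
    for l, loc in enumerate(table.panel):
        col = calls[:, l, :].ravel()
        col = col[col != MISSING]
        two_n = col.size
        if two_n == 0:
            vals[loc.name] = np.nan
            continue
        if g > two_n:
            raise ValueError(
                f"locus {loc.name}: rarefaction size {g} exceeds {two_n} copies"
            )
        _, counts = np.unique(col, return_counts=True)
        denom = math.comb(two_n, g)
        ar = sum(
            1 - Fraction(math.comb(two_n - int(na), g), denom) for na in counts
        )
        vals[loc.name] = float(ar)
    return pd.Series(vals, name="Ar")


def total_gene_diversity(
    table: GenotypeTable, groups: Iterable[Origin] | None = None
) -> pd.DataFrame:
    """Gene diversity H_T of the pooled material: He on the concatenation of
    the requested groups (default: everyone)."""
    if groups is None:
        return observed_expected_het(table, None)
    return observed_expected_het(table, list(groups))


def null_allele_freq(table: GenotypeTable, group, locus: str) -> float:
    """Heterozygote-deficit null-allele estimate fn = (He - Ho)/(He + Ho)."""
    het = observed_expected_het(table, group)
    ho, he = het.loc[locus, "Ho"], het.loc[locus, "He"]
    if not np.isfinite(ho) or he + ho == 0:
        return float("nan")
    return float((he - ho) / (he + ho))


# ---------------------------------------------------------------------------
# Weir–Cockerham variance components
# ---------------------------------------------------------------------------

def _wc_components(pop_calls: Sequence[np.ndarray], locus_col: int):
    """Per-allele Weir–Cockerham (a, b, c) components at one locus.

    ``pop_calls``: one ``(n_i, n_loci, 2)`` array per population.  Returns
    the summed-over-alleles (a, b, c); NaN-free, or None when fewer than
    two populations have data / the locus is globally monomorphic.
    """
    pops = []
    for calls in pop_calls:
        pair = calls[:, locus_col, :]
        ok = (pair[:, 0] != MISSING) & (pair[:, 1] != MISSING)
        pair = pair[ok]
        if len(pair) > 0:
            pops.append(pair)
    r = len(pops)
    if r == 0:
        return None
    alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
    if alleles.size < 2:
        return None
    n = np.array([len(p) for p in pops], dtype=float)
    nbar = n.mean()
    total_a = total_b = total_c = 0.0
    if r >= 2:
        nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    else:
        nc = nbar  # unused for within-population f
    for allele in alleles:
        p_i = np.array([np.mean(p == allele) for p in pops])
        h_i = np.array(
            [np.mean((p[:, 0] == allele) ^ (p[:, 1] == allele)) for p in pops]
        )
        pbar = float(np.sum(n * p_i) / (r * nbar))
        hbar = float(np.sum(n * h_i) / (r * nbar))
        if r >= 2:
            s2 = float(np.sum(n * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        else:
            s2 = 0.0
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        total_a += a
        total_b += b
        total_c += c
    return total_a, total_b, total_c


def fis_weir_cockerham(table: GenotypeTable, group=None, include_flagged=False):
    """Weir–Cockerham within-population f (F_IS) per locus and multilocus.

    Per locus f = 1 - c/(b + c); multilocus f = 1 - sum(c)/sum(b + c) over
    polymorphic, unflagged loci.
    """
    calls = _group_calls(table, group)
    per_locus: dict[str, float] = {}
    sum_c = sum_bc = 0.0
    for l, loc in enumerate(table.panel):
        comp = _wc_components([calls], l)
        if comp is None:
            per_locus[loc.name] = float("nan")
            continue
        _, b, c = comp
        per_locus[loc.name] = 1.0 - c / (b + c) if b + c != 0 else float("nan")
        if loc.flagged_null and not include_flagged:
            continue
        sum_c += c
        sum_bc += b + c
    multi = 1.0 - sum_c / sum_bc if sum_bc != 0 else float("nan")
    return per_locus, multi


def fst_weir_cockerham(
    table: GenotypeTable,
    groups: Sequence = (Origin.SOUTH, Origin.WEST),
    include_flagged: bool = False,
    g_test: bool = False,
    cfg: McTestConfig | None = None,
) -> DifferentiationResult:
    """Weir–Cockerham theta between/among the given origin groups.

    Per-locus theta = a / (a + b + c); multilocus = ratio of summed
    components over polymorphic unflagged loci.  Negative estimates are
    retained.  With ``g_test=True`` a permutation G-test of genotypic
    differentiation supplies the p-value (individuals permuted among
    groups), otherwise p is NaN.
    """
    pop_calls = [_group_calls(table, g) for g in groups]
    per_locus: dict[str, float] = {}
    num = den = 0.0
    for l, loc in enumerate(table.panel):
        comp = _wc_components(pop_calls, l)
        if comp is None:
            per_locus[loc.name] = float("nan")
            continue
        a, b, c = comp
        tot = a + b + c
        per_locus[loc.name] = a / tot if tot != 0 else float("nan")
        if loc.flagged_null and not include_flagged:
            continue
        num += a
        den += tot
    theta = num / den if den != 0 else float("nan")
    p = float("nan")
    if g_test:
        p = _differentiation_g_test_p(table, groups, include_flagged, cfg)
    return DifferentiationResult(theta, per_locus, p)


def _allele_count_g(pop_calls: list[np.ndarray], include: list[bool]) -> float:
    """Summed-over-loci G statistic of the population x allele-count tables."""
    g_total = 0.0
    n_loci = pop_calls[0].shape[1]
    for l in range(n_loci):
        if not include[l]:
            continue
        cols = []
        for calls in pop_calls:
            col = calls[:, l, :].ravel()
            cols.append(col[col != MISSING])
        alleles = np.unique(np.concatenate(cols))
        if alleles.size < 2:
            continue
        tab = np.array(
            [[np.sum(c == a) for a in alleles] for c in cols], dtype=float
        )
        row = tab.sum(axis=1, keepdims=True)
        colsum = tab.sum(axis=0, keepdims=True)
        e = row @ colsum / tab.sum()
        nz = tab > 0
        g_total += 2.0 * float(np.sum(tab[nz] * np.log(tab[nz] / e[nz])))
    return g_total


def _differentiation_g_test_p(table, groups, include_flagged, cfg):
    """Monte-Carlo G-test of genic differentiation: individuals permuted
    among groups, statistic = summed-over-loci allele-count G."""
    cfg = cfg or McTestConfig()
    rng = np.random.default_rng(cfg.seed)
    n_perm = min(cfg.batches * cfg.iterations_per_batch, 2_000)
    subs = [table.subset(origin=g) for g in groups]
    sizes = [s.n_individuals for s in subs]
    pooled = np.concatenate([s.calls for s in subs], axis=0)
    include = [
        include_flagged or not loc.flagged_null for loc in table.panel
    ]
    g_obs = _allele_count_g([s.calls for s in subs], include)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        start, pop_calls = 0, []
        for sz in sizes:
            pop_calls.append(pooled[perm[start : start + sz]])
            start += sz
        if _allele_count_g(pop_calls, include) >= g_obs - 1e-9:
            count += 1
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (Guo–Thompson Markov chain)
# ---------------------------------------------------------------------------

def _hw_log_weight(geno_counts: dict[tuple[int, int], int]) -> float:
    """log of the non-constant part of the conditional probability of a
    genotype array given allele counts: H*log2 - sum log f_ij!"""
    h = sum(c for (a, b), c in geno_counts.items() if a != b)
    return h * math.log(2.0) - sum(
        math.lgamma(c + 1) for c in geno_counts.values()
    )


def hw_exact_test(
    table: GenotypeTable, group, locus: str, cfg: McTestConfig | None = None
) -> HWTestResult:
    """Markov-chain estimate of the Hardy–Weinberg exact conditional test.

    The chain state is the assignment of the fixed multiset of gene copies
    to individuals; a step swaps the contents of two random allele slots,
    which leaves allele counts invariant and has the exact conditional
    distribution of genotype arrays as its stationary law.  The p-value is
    the visited-state fraction whose conditional probability is <= that of
    the observed array, with a Monte-Carlo standard error from batch means.
    """
    cfg = cfg or McTestConfig()
    counts = genotype_counts(table, group, locus)
    alleles = sorted({a for g in counts for a in g})
    if len(alleles) < 2:
        return HWTestResult(1.0, 0.0, monomorphic=True)
    rng = np.random.default_rng(cfg.seed)
    # slot representation: n individuals x 2 gene copies
    genos = []
    for g, c in counts.items():
        genos.extend([g] * c)
    slots = np.array(genos, dtype=np.int64)  # (n, 2)
    n = len(slots)
    obs_weight = _hw_log_weight(counts)
    cur = dict(counts)
    cur_weight = obs_weight

    def step() -> None:
        nonlocal cur_weight
        i, j = rng.integers(0, n, 2)
        if i == j:
            return
        si, sj = rng.integers(0, 2, 2)
        ai, aj = slots[i, si], slots[j, sj]
        if ai == aj:
            return
        old_i = (min(slots[i]), max(slots[i]))
        old_j = (min(slots[j]), max(slots[j]))
        slots[i, si], slots[j, sj] = aj, ai
        new_i = (min(slots[i]), max(slots[i]))
        new_j = (min(slots[j]), max(slots[j]))
        for old in (old_i, old_j):
            cur_weight += math.lgamma(cur[old] + 1)
            cur[old] -= 1
            cur_weight -= math.lgamma(cur[old] + 1)
            if old[0] != old[1]:
                cur_weight -= math.log(2.0)
            if cur[old] == 0:
                del cur[old]
        for new in (new_i, new_j):
            prev = cur.get(new, 0)
            cur_weight += math.lgamma(prev + 1)
            cur[new] = prev + 1
            cur_weight -= math.lgamma(prev + 2)
            if new[0] != new[1]:
                cur_weight += math.log(2.0)

    for _ in range(cfg.dememorization):
        step()
    batch_means = np.empty(cfg.batches)
    for b in range(cfg.batches):
        hits = 0
        for _ in range(cfg.iterations_per_batch):
            step()
            if cur_weight <= obs_weight + 1e-9:
                hits += 1
        batch_means[b] = hits / cfg.iterations_per_batch
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(cfg.batches))
    return HWTestResult(p, se)


def hw_exact_p_enumerated(geno_counts: dict[tuple[int, int], int]) -> float:
    """Full-enumeration exact conditional p for a TWO-allele sample (used as
    the oracle for the Markov-chain test on small data).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums exact rational probabilities <= the observed array's.
    """
    alleles = sorted({a for g in geno_counts for a in g})
    if len(alleles) != 2:
        raise ValueError("enumeration oracle is for two-allele samples")
    a1, a2 = alleles
    n = sum(geno_counts.values())
    n1 = sum(
        c * ((g[0] == a1) + (g[1] == a1)) for g, c in geno_counts.items()
    )
    obs_het = geno_counts.get((a1, a2), 0)

    def weight(het: int) -> Fraction:
        h11 = (n1 - het) // 2
        h22 = n - het - h11
        return Fraction(
            2**het,
            math.factorial(h11) * math.factorial(het) * math.factorial(h22),
        )

    feasible = [
        h
        for h in range(min(n1, 2 * n - n1) + 1)
        if (n1 - h) % 2 == 0 and (n - h - (n1 - h) // 2) >= 0
    ]
    weights = {h: weight(h) for h in feasible}
    total = sum(weights.values())
    w_obs = weights[obs_het]
    p = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(p, total))


# ---------------------------------------------------------------------------
# linkage-disequilibrium permutation G-test
# ---------------------------------------------------------------------------

def ld_exact_test(
    table: GenotypeTable,
    group,
    locus_a: str,
    locus_b: str,
    cfg: McTestConfig | None = None,
) -> LDTestResult:
    """Monte-Carlo genotypic-association test between two loci.

    Builds the genotype-by-genotype contingency table over individuals,
    computes the log-likelihood-ratio G statistic, and permutes one locus's
    genotypes among individuals to obtain the null distribution.  The
    number of permutations is ``min(batches * iterations_per_batch, 10^4)``.
    """
    cfg = cfg or McTestConfig()
    calls = _group_calls(table, group)
    ia, ib = table.locus_index(locus_a), table.locus_index(locus_b)
    pa, pb = calls[:, ia, :], calls[:, ib, :]
    ok = (pa != MISSING).all(axis=1) & (pb != MISSING).all(axis=1)
    pa, pb = pa[ok], pb[ok]
    ga = _genotype_codes(pa)
    gb = _genotype_codes(pb)
    if ga.max() == 0 or gb.max() == 0:
        return LDTestResult(1.0, 0.0, 0, monomorphic=True)
    ka, kb = ga.max() + 1, gb.max() + 1
    n = len(ga)
    row = np.bincount(ga, minlength=ka).astype(float)
    col = np.bincount(gb, minlength=kb).astype(float)
    log_e = np.log(np.outer(row, col) / n).ravel()

    def g_stat(gb_vec: np.ndarray) -> float:
        counts = np.bincount(ga * kb + gb_vec, minlength=ka * kb).astype(float)
        nz = counts > 0
        return 2.0 * float(
            np.sum(counts[nz] * (np.log(counts[nz]) - log_e[nz]))
        )

    g_obs = g_stat(gb)
    n_perm = min(cfg.batches * cfg.iterations_per_batch, 10_000)
    rng = np.random.default_rng(cfg.seed)
    hits = 0
    work = gb.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if g_stat(work) >= g_obs - 1e-9:
            hits += 1
    return LDTestResult((hits + 1) / (n_perm + 1), g_obs, n_perm)


def _genotype_codes(pairs: np.ndarray) -> np.ndarray:
    """Dense integer codes for unordered genotype pairs."""
    uniq, codes = np.unique(pairs, axis=0, return_inverse=True)
    return codes.astype(np.int64)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_adjust(
    pvalues: Sequence[float], method: str = "bh", alpha: float = 0.05
) -> pd.DataFrame:
    """Benjamini–Hochberg ('bh') or Benjamini–Yekutieli ('by') step-up.

    Returns a frame aligned with the input order: raw p, adjusted p
    (monotone in rank), and the reject decision at ``alpha``.
    """
    if method not in ("bh", "by"):
        raise ValueError(f"unknown FDR method {method!r}")
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return pd.DataFrame(columns=["p", "p_adjusted", "reject"])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(
        p, alpha=alpha, method="fdr_bh" if method == "bh" else "fdr_by"
    )
    return pd.DataFrame({"p": p, "p_adjusted": p_adj, "reject": reject})


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def locus_summary_table(
    table: GenotypeTable,
    group=None,
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """Per-locus summary (A, Ar, Ho, He, Fis, fn) for one origin group —
    the diversity-table layout of a standard microsatellite study."""
    freqs = allele_freqs(table, group)
    het = observed_expected_het(table, group)
    ar = allelic_richness(table, group, rarefaction_g)
    fis, _ = fis_weir_cockerham(table, group)
    rows = []
    for loc in table.panel:
        name = loc.name
        ho = het.loc[name, "Ho"]
        he = het.loc[name, "He"]
        fn = (
            (he - ho) / (he + ho)
            if np.isfinite(ho) and (he + ho) != 0
            else float("nan")
        )
        rows.append(
            LocusSummary(
                locus=name,
                n=int(het.loc[name, "n"]),
                A=len(freqs[name]),
                Ar=float(ar[name]),
                Ho=float(ho),
                He=float(he),
                Fis=float(fis[name]),
                fn=float(fn),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("locus")


def pairwise_fst_table(
    table: GenotypeTable,
    groups: Sequence[Origin] = (Origin.SOUTH, Origin.WEST, Origin.OFFSPRING),
    **kwargs,
) -> pd.DataFrame:
    """All pairwise multilocus theta estimates among the given groups."""
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            try:
                res = fst_weir_cockerham(table, (groups[i], groups[j]), **kwargs)
            except ValueError:
                continue
            rows.append(
                {
                    "group_a": groups[i].value,
                    "group_b": groups[j].value,
                    "theta": res.theta,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
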