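"""Independent oracles, coded from first principles in exact rational
arithmetic, for cross-checking the package's statistics.

Nothing here imports from mesoped: the oracles enumerate or evaluate the
defining expectation of each quantity directly so that agreement is a real
two-route check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


# ---------------------------------------------------------------------------
# Weir–Cockerham variance components (textbook ANOVA, Fractions)
# ---------------------------------------------------------------------------

def wc_components(pops: list[list[tuple[int, int]]]):
    """Summed-over-alleles (a, b, c) for one locus.

    ``pops``: per population, the list of diploid genotypes.  Exact
    Fractions throughout.  Returns None if the locus is monomorphic.
    """
    r = len(pops)
    n = [len(p) for p in pops]
    alleles = sorted({x for p in pops for g in p for x in g})
    if len(alleles) < 2:
        return None
    nbar = Fraction(sum(n), r)
    sum_a = sum_b = sum_c = Fraction(0)
    if r >= 2:
        nc = (r * nbar - Fraction(sum(ni * ni for ni in n)) / (r * nbar)) / (r - 1)
    else:
        nc = nbar
    for allele in alleles:
        p_i = [
            Fraction(sum(g.count(allele) for g in pop), 2 * ni)
            for pop, ni in zip(pops, n)
        ]
        h_i = [
            Fraction(
                sum(1 for g in pop if (allele in g) and g[0] != g[1]), ni
            )
            for pop, ni in zip(pops, n)
        ]
        pbar = sum(ni * pi for ni, pi in zip(n, p_i)) / (r * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h_i)) / (r * nbar)
        if r >= 2:
            s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_i)) / (
                (r - 1) * nbar
            )
        else:
            s2 = Fraction(0)
        a = (nbar / nc) * (
            s2
            - Fraction(1, 1) / (nbar - 1)
            * (pbar * (1 - pbar) - s2 * Fraction(r - 1, r) - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * Fraction(r - 1, r)
            - Fraction(2 * nbar - 1, 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_b += b
        sum_c += c
    return sum_a, sum_b, sum_c


def theta_oracle(pops_by_locus: list[list[list[tuple[int, int]]]]) -> float:
    """Multilocus Weir–Cockerham theta: ratio of summed components."""
    num = den = Fraction(0)
    for pops in pops_by_locus:
        comp = wc_components(pops)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
    return float(num / den)


def fis_oracle(pop_by_locus: list[list[tuple[int, int]]]) -> float:
    """Multilocus within-population f = 1 - sum(c)/sum(b + c)."""
    sum_c = sum_bc = Fraction(0)
    for pop in pop_by_locus:
        comp = wc_components([pop])
        if comp is None:
            continue
        _, b, c = comp
        sum_c += c
        sum_bc += b + c
    return float(1 - sum_c / sum_bc)


# ---------------------------------------------------------------------------
# rarefaction by exhaustive subsampling
# ---------------------------------------------------------------------------

def allelic_richness_exhaustive(copies: list[int], g: int) -> Fraction:
    """Mean number of distinct alleles over ALL g-subsets of the gene
    copies (exact)."""
    total = Fraction(0)
    subsets = list(itertools.combinations(range(len(copies)), g))
    for idx in subsets:
        total += len({copies[i] for i in idx})
    return total / len(subsets)


# ---------------------------------------------------------------------------
# Nei & Chesser unbiased expected heterozygosity
# ---------------------------------------------------------------------------

def unbiased_he(genotypes: list[tuple[int, int]]) -> Fraction:
    """n/(n-1) * (1 - sum p^2 - Ho/(2n)) evaluated directly."""
    n = len(genotypes)
    alleles = [a for g in genotypes for a in g]
    counts: dict[int, int] = {}
    for a in alleles:
        counts[a] = counts.get(a, 0) + 1
    sum_p2 = sum(Fraction(c, 2 * n) ** 2 for c in counts.values())
    ho = Fraction(sum(1 for g in genotypes if g[0] != g[1]), n)
    return Fraction(n, n - 1) * (1 - sum_p2 - ho / (2 * n))


# ---------------------------------------------------------------------------
# marker-power enumeration oracles
# ---------------------------------------------------------------------------

def _genotype_space(freqs: dict[int, Fraction]):
    alleles = sorted(freqs)
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            p = freqs[a] * freqs[b] * (1 if a == b else 2)
            yield (a, b), p


def _mendel_compatible(m: tuple[int, int], f: tuple[int, int],
                       o: tuple[int, int]) -> bool:
    a, b = o
    return (a in m and b in f) or (b in m and a in f)


def pic_oracle(freqs: dict[int, Fraction]) -> Fraction:
    alleles = sorted(freqs)
    s = 1 - sum(freqs[a] ** 2 for a in alleles)
    for i, a in enumerate(alleles):
        for b in alleles[i + 1:]:
            s -= 2 * freqs[a] ** 2 * freqs[b] ** 2
    return s


def identity_oracle(freqs: dict[int, Fraction]) -> Fraction:
    """P(two independent HW genotypes identical) by enumeration."""
    return sum(p * p for _, p in _genotype_space(freqs))


def exclusion_oracle(freqs: dict[int, Fraction], variant: str) -> Fraction:
    """Exclusion probability by exhaustive enumeration of all parent /
    offspring / candidate genotype combinations under Hardy–Weinberg."""
    total = Fraction(0)
    space = list(_genotype_space(freqs))
    alleles = sorted(freqs)
    if variant == "P1":
        for og, po in _offspring_distribution(freqs):
            excl = sum(
                pc for cg, pc in space
                if not (cg[0] in og or cg[1] in og)
            )
            total += po * excl
        return total
    if variant == "P2":
        for mg, pm in space:
            for trans_m in mg:
                for f_allele in alleles:
                    w = pm * Fraction(1, 2) * freqs[f_allele]
                    og = tuple(sorted((trans_m, f_allele)))
                    excl = sum(
                        pc for cg, pc in space
                        if not _mendel_compatible(mg, cg, og)
                    )
                    total += w * excl
        return total
    if variant == "PP":
        for og, po in _offspring_distribution(freqs):
            excl = sum(
                p1 * p2
                for g1, p1 in space
                for g2, p2 in space
                if not _mendel_compatible(g1, g2, og)
            )
            total += po * excl
        return total
    raise ValueError(variant)


def _offspring_distribution(freqs: dict[int, Fraction]):
    """Offspring genotype distribution from two HW parents with random
    transmission (equals HW, but derived by enumeration)."""
    space = list(_genotype_space(freqs))
    dist: dict[tuple[int, int], Fraction] = {}
    for mg, pm in space:
        for fg, pf in space:
            for a in mg:
                for b in fg:
                    og = tuple(sorted((a, b)))
                    dist[og] = dist.get(og, 0) + pm * pf * Fraction(1, 4)
    return sorted(dist.items())


# ---------------------------------------------------------------------------
# GLM log-likelihoods for numerical-ML cross fits
# ---------------------------------------------------------------------------

def logistic_negll(beta, x, y):
    import numpy as np

    eta = x @ beta
    return float(np.sum(np.log1p(np.exp(eta)) - y * eta))


def poisson_negll(beta, x, y):
    import numpy as np

    eta = x @ beta
    return float(np.sum(np.exp(eta) - y * eta + [math.lgamma(v + 1) for v in y]))
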