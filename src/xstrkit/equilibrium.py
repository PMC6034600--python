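"""Exact Hardy-Weinberg and linkage-disequilibrium tests for female X genotypes.

Males carry a single X and contribute nothing to genotype-proportion tests,
so both tests run on females only.

The HWE test is the conditional exact probability test: given the observed
allele counts, every genotype table has probability

    P(table) = n! * 2^h * prod_i a_i! / ( (2n)! * prod_{i<=j} n_ij! )

(h = number of heterozygotes), and the p-value is the total probability of
tables no more probable than the observed one.  ``enumerate`` mode walks all
tables with the observed allele margins (feasible for few alleles);
``monte-carlo`` mode samples tables *independently* by randomly pairing the
2n chromosomes, which draws exactly from the conditional distribution.

The LD test scores the genotype x genotype contingency table of a locus pair
with the G statistic and permutes one locus's genotype column for the null;
it is a test of genotypic association, not an estimator of D'/r^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "TestResult",
    "hwe_exact_test",
    "ld_exact_test",
    "bonferroni_threshold",
    "n_locus_pairs",
]


@dataclass(frozen=True)
class TestResult:
    kind: str  # "exact-probability" | "G-permutation"
    p_value: float
    n_reps: int  # 0 for full enumeration
    seed: int | None = None


def _log_factorial(x) -> np.ndarray:
    return gammaln(np.asarray(x, dtype=float) + 1.0)


def _genotype_counts(
    genotypes: Sequence[tuple[Hashable, Hashable]]
) -> tuple[np.ndarray, list]:
    """Upper-triangular genotype count matrix and the sorted allele list."""
    alleles = sorted({a for g in genotypes for a in g})
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in genotypes:
        i, j = sorted((index[a], index[b]))
        counts[i, j] += 1
    return counts, alleles


def _log_table_prob(counts: np.ndarray) -> float:
    """log P(table | allele counts) under the conditional null."""
    k = counts.shape[0]
    n = int(counts.sum())
    # a_i = row i + column i of the upper triangle; the diagonal counts twice
    allele_counts = counts.sum(axis=0) + counts.sum(axis=1)
    h = n - int(np.trace(counts))
    return float(
        _log_factorial(n)
        + h * math.log(2.0)
        + _log_factorial(allele_counts).sum()
        - _log_factorial(2 * n)
        - _log_factorial(counts[np.triu_indices(k)]).sum()
    )


def _enumerate_tables(allele_counts: np.ndarray):
    """Yield every upper-triangular genotype table with the given margins."""
    k = len(allele_counts)
    counts = np.zeros((k, k), dtype=np.int64)
    remaining = allele_counts.copy()

    def fill_row(i: int):
        if i == k:
            yield counts.copy()
            return
        yield from fill_cell(i, i)

    def fill_cell(i: int, j: int):
        if j == k - 1:
            # last cell of row i: count forced by the remaining a_i
            if i == j:
                if remaining[i] % 2:
                    return
                c = remaining[i] // 2
                counts[i, j] = c
                remaining[i] = 0
                yield from fill_row(i + 1)
                remaining[i] = 2 * c
            else:
                c = remaining[i]
                if c > remaining[j]:
                    counts[i, j] = 0
                    return
                counts[i, j] = c
                remaining[i] = 0
                remaining[j] -= c
                yield from fill_row(i + 1)
                remaining[i] = c
                remaining[j] += c
            counts[i, j] = 0
            return
        if i == j:
            cmax = remaining[i] // 2
            for c in range(cmax + 1):
                counts[i, j] = c
                remaining[i] -= 2 * c
                yield from fill_cell(i, j + 1)
                remaining[i] += 2 * c
            counts[i, j] = 0
        else:
            cmax = min(remaining[i], remaining[j])
            for c in range(cmax + 1):
                counts[i, j] = c
                remaining[i] -= c
                remaining[j] -= c
                yield from fill_cell(i, j + 1)
                remaining[i] += c
                remaining[j] += c
            counts[i, j] = 0

    yield from fill_row(0)


_LOG_TOL = 1e-9


def hwe_exact_test(
    genotypes: Sequence[tuple[Hashable, Hashable]],
    mode: str = "monte-carlo",
    n_reps: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Conditional exact test of Hardy-Weinberg proportions.

    Parameters
    ----------
    genotypes : sequence of unordered allele pairs (one per female)
    mode : {"enumerate", "monte-carlo"}
        ``enumerate`` sums probabilities over every table with the observed
        allele counts (use for few alleles); ``monte-carlo`` samples tables by
        random chromosome pairing, with add-one correction
        ``p = (b + 1) / (n_reps + 1)``.
    """
    if len(genotypes) < 1:
        raise ValueError("need at least one female genotype")
    counts, alleles = _genotype_counts(genotypes)
    k = len(alleles)
    if k < 2:
        warnings.warn("monomorphic locus: HWE test undefined, p = 1", stacklevel=2)
        return TestResult("exact-probability", 1.0, 0, seed)
    log_obs = _log_table_prob(counts)
    allele_counts = counts.sum(axis=0) + counts.sum(axis=1)

    if mode == "enumerate":
        total = 0.0
        for table in _enumerate_tables(allele_counts):
            lp = _log_table_prob(table)
            if lp <= log_obs + _LOG_TOL:
                total += math.exp(lp)
        return TestResult("exact-probability", min(total, 1.0), 0, seed)

    if mode != "monte-carlo":
        raise ValueError(f"unknown mode {mode!r}")
    if n_reps < 1000:
        raise ValueError("monte-carlo mode needs n_reps >= 1000")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(k), allele_counts)
    n = len(genotypes)
    # sample tables by pairing a shuffled chromosome pool, in batches
    log2 = math.log(2.0)
    b = 0
    batch = max(1, min(n_reps, int(5e6 // max(2 * n, 1))))
    done = 0
    while done < n_reps:
        m = min(batch, n_reps - done)
        mat = rng.permuted(np.broadcast_to(pool, (m, 2 * n)), axis=1)
        a1, a2 = mat[:, ::2], mat[:, 1::2]
        lo, hi = np.minimum(a1, a2), np.maximum(a1, a2)
        codes = lo * k + hi
        h = (lo != hi).sum(axis=1)
        codes.sort(axis=1)
        # sum log(count!) per row via within-run occurrence indices:
        # log(c!) = sum_{r=1..c} log r, and r is each element's position
        # inside its run of equal codes
        run = np.zeros((m, n), dtype=bool)
        run[:, 1:] = codes[:, 1:] == codes[:, :-1]
        idx = np.arange(n)
        start = np.maximum.accumulate(np.where(run, 0, idx), axis=1)
        occ = idx - start + 1
        sum_lf = np.log(occ).sum(axis=1)
        # log P up to the table-independent constant:
        rel_sim = h * log2 - sum_lf
        h_obs = int(counts.sum()) - int(np.trace(counts))
        rel_obs = h_obs * log2 - float(
            _log_factorial(counts[np.triu_indices(k)]).sum()
        )
        b += int(np.sum(rel_sim <= rel_obs + _LOG_TOL))
        done += m
    return TestResult(
        "exact-probability", (b + 1) / (n_reps + 1), n_reps, seed
    )


def _g_from_counts(obs: np.ndarray, log_e: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = obs * (np.log(obs) - log_e)
    return 2.0 * np.nansum(t, axis=tuple(range(1, obs.ndim)))


def ld_exact_test(
    genotype_pairs: Sequence[tuple[Hashable, Hashable]],
    n_reps: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Permutation G-test of genotypic association between two loci.

    ``genotype_pairs`` holds, per female with complete calls at both loci,
    the (genotype at locus A, genotype at locus B) pair; genotypes may be any
    hashable (typically sorted allele tuples).  One column is permuted
    ``n_reps`` times; p = (b + 1) / (n_reps + 1).  The input is canonically
    sorted first, so the p-value is invariant to sample order for a fixed
    seed.
    """
    if len(genotype_pairs) < 2:
        raise ValueError("need at least two females with complete calls")
    ga = sorted({g for g, _ in genotype_pairs})
    gb = sorted({g for _, g in genotype_pairs})
    if len(ga) < 2 or len(gb) < 2:
        warnings.warn(
            "fewer than 2 distinct genotypes at a locus: LD test undefined, p = 1",
            stacklevel=2,
        )
        return TestResult("G-permutation", 1.0, 0, seed)
    ia = {g: i for i, g in enumerate(ga)}
    ib = {g: i for i, g in enumerate(gb)}
    coded = sorted((ia[a], ib[b]) for a, b in genotype_pairs)
    a = np.array([c[0] for c in coded])
    b_col = np.array([c[1] for c in coded])
    ka, kb = len(ga), len(gb)
    n = len(coded)

    obs = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(obs, (a, b_col), 1)
    row = obs.sum(axis=1).astype(float)
    col = obs.sum(axis=0).astype(float)
    with np.errstate(divide="ignore"):
        log_e = np.log(np.outer(row, col) / n)
    g_obs = float(_g_from_counts(obs[None], log_e[None])[0])

    rng = np.random.default_rng(seed)
    ncells = ka * kb
    batch = max(1, int(2e7 // max(ncells, n)))
    exceed = 0
    done = 0
    while done < n_reps:
        m = min(batch, n_reps - done)
        perm = rng.permuted(np.broadcast_to(b_col, (m, n)), axis=1)
        flat = (a[None, :] * kb + perm) + np.arange(m)[:, None] * ncells
        tables = np.bincount(flat.ravel(), minlength=m * ncells).reshape(
            m, ka, kb
        )
        g_sim = _g_from_counts(tables, log_e[None])
        exceed += int(np.sum(g_sim >= g_obs - 1e-9))
        done += m
    return TestResult("G-permutation", (exceed + 1) / (n_reps + 1), n_reps, seed)


def n_locus_pairs(n_loci: int) -> int:
    """C(L, 2) pairwise comparisons among L loci."""
    if n_loci < 1:
        raise ValueError("need at least one locus")
    return n_loci * (n_loci - 1) // 2


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Familywise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m
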