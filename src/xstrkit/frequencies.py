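"""Sex-stratified allele counting, frequency pooling, and homogeneity testing.

On the X chromosome a male contributes one chromosome per locus and a female
two, so frequencies are estimated separately per sex stratum and then pooled.
The conventional forensic pooling weights the female vector twice:
``p = (2*p_f + p_m) / 3`` — exact when the sample holds equal numbers of male
and female individuals, an approximation otherwise; the chromosome-weighted
alternative ``p = (2 n_f p_f + n_m p_m) / (2 n_f + n_m)`` is also offered.

Male/female frequency homogeneity ("no gender bias") is assessed with a 2 x k
contingency G-test whose null distribution is obtained by permuting stratum
labels over the pooled chromosomes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import AlleleLabel, GenotypeTable

__all__ = [
    "count_alleles",
    "pool_frequencies",
    "sex_homogeneity_test",
    "AlleleFrequencyTable",
    "build_frequency_table",
]

_FREQ_TOL = 1e-6


def count_alleles(
    table: GenotypeTable, locus: str
) -> tuple[Counter[AlleleLabel], Counter[AlleleLabel]]:
    """Chromosome counts of every observed allele at *locus*, by sex.

    Males contribute one chromosome, females two.  Alleles absent from both
    strata are not listed.  Individuals missing the call are excluded from
    this locus only.
    """
    counts_male = Counter(table.male_alleles(locus))
    counts_female: Counter[AlleleLabel] = Counter()
    for a, b in table.female_genotypes(locus):
        counts_female[a] += 1
        counts_female[b] += 1
    if not counts_male and not counts_female:
        warnings.warn(f"no calls at locus {locus!r}", stacklevel=2)
    return counts_male, counts_female


def _as_freq(counts: Mapping[AlleleLabel, int]) -> dict[AlleleLabel, float]:
    total = sum(counts.values())
    if total == 0:
        return {}
    return {a: c / total for a, c in counts.items()}


def pool_frequencies(
    freq_female: Mapping,
    freq_male: Mapping,
    method: str = "paper",
    n_female: int | None = None,
    n_male: int | None = None,
) -> dict:
    """Pool female and male allele-frequency vectors into one.

    method "paper": p = (2 p_f + p_m) / 3 per allele.
    method "chromosome-weighted": p = (2 n_f p_f + n_m p_m) / (2 n_f + n_m);
    requires ``n_female`` and ``n_male`` (individuals with calls).
    Absent alleles enter with frequency 0; the result sums to 1.
    """
    for name, vec in (("female", freq_female), ("male", freq_male)):
        s = sum(vec.values())
        if vec and abs(s - 1.0) > _FREQ_TOL:
            raise ValueError(f"{name} frequencies sum to {s}, not 1")
    alleles = sorted(set(freq_female) | set(freq_male))
    if method == "paper":
        wf, wm = 2.0 / 3.0, 1.0 / 3.0
    elif method == "chromosome-weighted":
        if n_female is None or n_male is None:
            raise ValueError("chromosome-weighted pooling needs n_female, n_male")
        total = 2 * n_female + n_male
        wf, wm = 2 * n_female / total, n_male / total
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    return {
        a: wf * freq_female.get(a, 0.0) + wm * freq_male.get(a, 0.0)
        for a in alleles
    }


def _g_statistic(obs: np.ndarray) -> float:
    """G (log-likelihood-ratio) statistic of an r x c contingency table."""
    obs = np.asarray(obs, dtype=float)
    n = obs.sum()
    if n == 0:
        return 0.0
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = obs * np.log(obs / exp)
    return 2.0 * np.nansum(terms)


def sex_homogeneity_test(
    counts_male: Mapping[AlleleLabel, int],
    counts_female: Mapping[AlleleLabel, int],
    n_reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo p-value for allele-count homogeneity between the sexes.

    The observed 2 x k table (strata x alleles) is scored with the G
    statistic; the null is generated by permuting stratum labels over the
    pooled chromosomes (equivalently, drawing the male row from the
    multivariate hypergeometric with fixed margins).  Add-one corrected:
    p = (b + 1) / (n_reps + 1).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if not counts_male or not counts_female:
        raise ValueError("both strata must observe at least one allele")
    rng = np.random.default_rng(seed)
    alleles = sorted(set(counts_male) | set(counts_female))
    m = np.array([counts_male.get(a, 0) for a in alleles])
    f = np.array([counts_female.get(a, 0) for a in alleles])
    obs_g = _g_statistic(np.stack([m, f]))
    pooled = np.repeat(np.arange(len(alleles)), m + f)
    n_m = int(m.sum())
    k = len(alleles)
    # permute stratum labels: the male row is the first n_m of a shuffle
    reps_mat = np.broadcast_to(pooled, (n_reps, pooled.size))
    perm = rng.permuted(reps_mat, axis=1)[:, :n_m]
    sim_m = np.zeros((n_reps, k), dtype=np.int64)
    flat = perm + np.arange(n_reps)[:, None] * k
    sim_m.reshape(-1)[:] = np.bincount(flat.ravel(), minlength=n_reps * k)
    sim_f = (m + f)[None, :] - sim_m
    g_sim = _g_mat(sim_m, sim_f)
    b = int(np.sum(g_sim >= obs_g - 1e-12))
    return (b + 1) / (n_reps + 1)


def _g_mat(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """Vectorized G over many 2 x k tables (one per row pair)."""
    tot = rows_a + rows_b  # column margins, constant across reps here
    n = tot.sum(axis=1, keepdims=True).astype(float)
    na = rows_a.sum(axis=1, keepdims=True).astype(float)
    nb = n - na
    with np.errstate(divide="ignore", invalid="ignore"):
        ea = na * tot / n
        eb = nb * tot / n
        ta = rows_a * np.log(rows_a / ea)
        tb = rows_b * np.log(rows_b / eb)
    return 2.0 * (np.nansum(ta, axis=1) + np.nansum(tb, axis=1))


@dataclass
class AlleleFrequencyTable:
    """Per-locus sex-stratified counts and frequencies plus the pooled vector."""

    loci: list[str]
    counts_male: dict[str, dict[AlleleLabel, int]]
    counts_female: dict[str, dict[AlleleLabel, int]]
    freq_male: dict[str, dict[AlleleLabel, float]]
    freq_female: dict[str, dict[AlleleLabel, float]]
    freq_pooled: dict[str, dict[AlleleLabel, float]]
    n_male: dict[str, int]
    n_female: dict[str, int]
    pooling: str = "paper"

    def alleles(self, locus: str) -> list[AlleleLabel]:
        return sorted(set(self.counts_male[locus]) | set(self.counts_female[locus]))

    @property
    def total_alleles(self) -> int:
        """Number of distinct alleles observed over all loci."""
        return sum(len(self.alleles(locus)) for locus in self.loci)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for locus in self.loci:
            for a in self.alleles(locus):
                rows.append(
                    {
                        "locus": locus,
                        "allele": str(a),
                        "count_m": self.counts_male[locus].get(a, 0),
                        "count_f": self.counts_female[locus].get(a, 0),
                        "freq_m": self.freq_male[locus].get(a, 0.0),
                        "freq_f": self.freq_female[locus].get(a, 0.0),
                        "freq_pooled": self.freq_pooled[locus].get(a, 0.0),
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        for col in ("freq_m", "freq_f", "freq_pooled"):
            df[col] = df[col].map(lambda v: f"{v:.4f}")
        df.to_csv(path, sep="\t", index=False)


def build_frequency_table(
    table: GenotypeTable, pooling: str = "paper"
) -> AlleleFrequencyTable:
    """Count, estimate, and pool allele frequencies for every locus."""
    cm, cf, fm, ff, fp, nm, nf = {}, {}, {}, {}, {}, {}, {}
    for locus in table.loci:
        counts_m, counts_f = count_alleles(table, locus)
        cm[locus], cf[locus] = dict(counts_m), dict(counts_f)
        nm[locus] = sum(counts_m.values())
        nf[locus] = sum(counts_f.values()) // 2
        fm[locus] = _as_freq(counts_m)
        ff[locus] = _as_freq(counts_f)
        if not fm[locus] and not ff[locus]:
            fp[locus] = {}
        elif not fm[locus]:
            fp[locus] = dict(ff[locus])
        elif not ff[locus]:
            fp[locus] = dict(fm[locus])
        else:
            fp[locus] = pool_frequencies(
                ff[locus], fm[locus], method=pooling,
                n_female=nf[locus], n_male=nm[locus],
            )
    return AlleleFrequencyTable(
        loci=list(table.loci),
        counts_male=cm, counts_female=cf,
        freq_male=fm, freq_female=ff, freq_pooled=fp,
        n_male=nm, n_female=nf, pooling=pooling,
    )
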