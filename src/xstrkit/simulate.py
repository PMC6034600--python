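"""Synthetic X-STR populations with the statistical structure the pipeline assumes.

The generator emulates the study design the package targets: a 19-locus
X-STR panel typed in 156 males and 111 females, 5-26 alleles per locus with
microvariant labels, Hardy-Weinberg female genotypes (with an optional
inbreeding coefficient ``f`` to spike violations), seven linkage groups that
may carry haplotype-level association, and random missing calls.  Allele
frequencies are Dirichlet draws; inter-population divergence uses the
Balding-Nichols construction (offspring frequencies Dirichlet-distributed
around an ancestral vector with concentration ``(1 - d) / d``).

A single integer seed drives one root generator; every sub-draw derives from
it, so one number reproduces any fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import AlleleLabel, GenotypeTable, Sample
from .haplotypes import LinkageGroupSpec, default_linkage_groups
from .popcompare import PopulationFrequencySet
from .reference import LOCI

__all__ = [
    "SimSpec",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_table",
    "simulate_population_set",
    "simulate_clustered_population_set",
    "haplotype_marginals",
]

Haplotype = tuple[AlleleLabel, ...]


@dataclass(frozen=True)
class SimSpec:
    """Study-design parameters for the generator.

    Defaults mirror the target study: 19 loci in seven linkage groups,
    156 males and 111 females, 5-26 alleles per locus, flat Dirichlet
    frequencies, no inbreeding, no missingness.
    """

    n_loci: int = 19
    min_alleles: int = 5
    max_alleles: int = 26
    concentration: float = 1.0
    n_males: int = 156
    n_females: int = 111
    inbreeding: float = 0.0
    microvariant_prob: float = 0.1
    missing_rate: float = 0.0
    linkage_groups: tuple[LinkageGroupSpec, ...] = field(
        default_factory=lambda: tuple(default_linkage_groups())
    )
    #: group_id -> {haplotype tuple -> probability}; groups listed here get
    #: haplotype-level association, all other loci segregate independently
    haplotype_distributions: Mapping[int, Mapping[Haplotype, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        for name, rate in (
            ("inbreeding", self.inbreeding),
            ("microvariant_prob", self.microvariant_prob),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {rate}")

    @property
    def locus_names(self) -> list[str]:
        if self.n_loci == 19:
            return list(LOCI)
        return [f"L{i + 1:02d}" for i in range(self.n_loci)]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_frequencies(
    spec: SimSpec, seed: int | np.random.Generator | None = None
) -> dict[str, dict[AlleleLabel, float]]:
    """Dirichlet allele-frequency vectors with repeat-number labels.

    Labels are consecutive repeat numbers from a random start; each label
    independently acquires a microvariant suffix with
    ``spec.microvariant_prob``.
    """
    rng = _rng(seed)
    freqs: dict[str, dict[AlleleLabel, float]] = {}
    for locus in spec.locus_names:
        k = int(rng.integers(spec.min_alleles, spec.max_alleles + 1))
        start = int(rng.integers(6, 21))
        labels = []
        for r in range(start, start + k):
            if rng.random() < spec.microvariant_prob:
                labels.append(AlleleLabel(r, int(rng.integers(1, 4))))
            else:
                labels.append(AlleleLabel(r))
        p = rng.dirichlet(np.full(k, spec.concentration))
        freqs[locus] = dict(zip(labels, p.tolist()))
    return freqs


def haplotype_marginals(
    distribution: Mapping[Haplotype, float], loci: Sequence[str]
) -> dict[str, dict[AlleleLabel, float]]:
    """Per-locus allele frequencies implied by a haplotype distribution."""
    out: dict[str, dict[AlleleLabel, float]] = {locus: {} for locus in loci}
    for hap, prob in distribution.items():
        for locus, allele in zip(loci, hap):
            out[locus][allele] = out[locus].get(allele, 0.0) + prob
    return out


def _draw_pair(rng, items, probs, f):
    """Two draws with inbreeding f: identical with prob f + (1-f) p_i."""
    first = items[rng.choice(len(items), p=probs)]
    if f > 0 and rng.random() < f:
        return first, first
    second = items[rng.choice(len(items), p=probs)]
    return first, second


def simulate_genotypes(
    freqs: Mapping[str, Mapping[AlleleLabel, float]],
    spec: SimSpec,
    seed: int | np.random.Generator | None = None,
) -> GenotypeTable:
    """Draw a sex-annotated genotype table from per-locus frequencies.

    Males receive one i.i.d. allele per locus; females a genotype with
    inbreeding ``f``: ``P(homozygote i) = f p_i + (1-f) p_i^2``,
    ``P(heterozygote ij) = (1-f) 2 p_i p_j``.  For linkage groups with a
    configured haplotype distribution, whole haplotypes are drawn instead
    (two per female, inbreeding applied at the haplotype level), which
    induces the within-group association the LD test should detect.
    Calls are masked at ``spec.missing_rate``.
    """
    rng = _rng(seed)
    f = spec.inbreeding
    loci = [l for l in spec.locus_names if l in freqs]
    if len(loci) != spec.n_loci:
        missing = set(spec.locus_names) - set(freqs)
        raise ValueError(f"frequencies missing for loci: {sorted(missing)}")

    hap_groups: dict[int, tuple[tuple[str, ...], list, np.ndarray]] = {}
    hap_loci: set[str] = set()
    if spec.haplotype_distributions:
        for gid, dist in spec.haplotype_distributions.items():
            group = next(
                (g for g in spec.linkage_groups if g.group_id == gid), None
            )
            if group is None:
                raise KeyError(f"haplotype distribution for unknown group {gid}")
            haps = list(dist)
            probs = np.array([dist[h] for h in haps], dtype=float)
            probs = probs / probs.sum()
            hap_groups[gid] = (group.loci, haps, probs)
            hap_loci.update(group.loci)

    samples = [Sample(f"M{i + 1:04d}", "male") for i in range(spec.n_males)] + [
        Sample(f"F{i + 1:04d}", "female") for i in range(spec.n_females)
    ]
    calls: dict[tuple[str, str], tuple[AlleleLabel, ...]] = {}

    indep = [l for l in loci if l not in hap_loci]
    per_locus = {
        locus: (list(freqs[locus]), np.array(list(freqs[locus].values())))
        for locus in indep
    }
    for s in samples:
        for locus in indep:
            alleles, probs = per_locus[locus]
            if s.sex == "male":
                call = (alleles[rng.choice(len(alleles), p=probs)],)
            else:
                call = tuple(sorted(_draw_pair(rng, alleles, probs, f)))
            calls[(s.sample_id, locus)] = call
        for gloci, haps, probs in hap_groups.values():
            if s.sex == "male":
                hap = haps[rng.choice(len(haps), p=probs)]
                for locus, allele in zip(gloci, hap):
                    calls[(s.sample_id, locus)] = (allele,)
            else:
                h1, h2 = _draw_pair(rng, haps, probs, f)
                for locus, a1, a2 in zip(gloci, h1, h2):
                    calls[(s.sample_id, locus)] = tuple(sorted((a1, a2)))

    if spec.missing_rate > 0:
        for key in list(calls):
            if rng.random() < spec.missing_rate:
                del calls[key]

    return GenotypeTable(samples=samples, loci=list(loci), calls=calls)


def simulate_table(
    spec: SimSpec, seed: int | np.random.Generator | None = None
) -> tuple[GenotypeTable, dict[str, dict[AlleleLabel, float]]]:
    """Frequencies + genotype table from one seed; returns (table, truth).

    Truth frequencies for loci inside haplotype-configured groups are the
    marginals of the configured haplotype distribution.
    """
    rng = _rng(seed)
    freqs = simulate_frequencies(spec, rng)
    if spec.haplotype_distributions:
        for gid, dist in spec.haplotype_distributions.items():
            group = next(g for g in spec.linkage_groups if g.group_id == gid)
            freqs.update(haplotype_marginals(dist, group.loci))
    table = simulate_genotypes(freqs, spec, rng)
    return table, freqs


def _perturb(
    freqs: Mapping[str, Mapping[AlleleLabel, float]],
    divergence: float,
    rng: np.random.Generator,
) -> dict[str, dict[AlleleLabel, float]]:
    """Balding-Nichols drift: Dirichlet(p (1-d)/d) around the ancestor."""
    if divergence == 0:
        return {locus: dict(vec) for locus, vec in freqs.items()}
    scale = (1.0 - divergence) / divergence
    out = {}
    for locus, vec in freqs.items():
        alleles = list(vec)
        alpha = np.maximum(np.array(list(vec.values())) * scale, 1e-9)
        out[locus] = dict(zip(alleles, rng.dirichlet(alpha).tolist()))
    return out


def simulate_population_set(
    n_pops: int,
    divergence: float,
    spec: SimSpec | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[PopulationFrequencySet]:
    """Populations drifted from a common ancestral frequency set.

    ``divergence`` in [0, 1): 0 yields identical copies; expected pairwise
    D_A increases with it.
    """
    if n_pops < 2:
        raise ValueError("need at least two populations")
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = _rng(seed)
    spec = spec or SimSpec()
    ancestral = simulate_frequencies(spec, rng)
    pops = []
    for i in range(n_pops):
        drifted = _perturb(ancestral, divergence, rng)
        pops.append(
            PopulationFrequencySet(
                f"pop{i + 1:02d}",
                {
                    locus: {str(a): p for a, p in vec.items()}
                    for locus, vec in drifted.items()
                },
            )
        )
    return pops


def simulate_clustered_population_set(
    n_per_cluster: int,
    n_clusters: int = 2,
    between: float = 0.3,
    within: float = 0.05,
    spec: SimSpec | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[PopulationFrequencySet], dict[str, int]]:
    """Population sets drifted from ``n_clusters`` diverged ancestors.

    Returns the populations plus a name->cluster assignment, for testing
    that tree building separates the planted clusters.
    """
    rng = _rng(seed)
    spec = spec or SimSpec()
    root = simulate_frequencies(spec, rng)
    pops, assignment = [], {}
    for c in range(n_clusters):
        ancestor = _perturb(root, between, rng)
        for i in range(n_per_cluster):
            drifted = _perturb(ancestor, within, rng)
            name = f"c{c + 1}p{i + 1:02d}"
            assignment[name] = c
            pops.append(
                PopulationFrequencySet(
                    name,
                    {
                        locus: {str(a): p for a, p in vec.items()}
                        for locus, vec in drifted.items()
                    },
                )
            )
    return pops, assignment
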