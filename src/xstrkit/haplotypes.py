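"""Male haplotype tables for linked X-STR groups.

Physically close X-STR loci are inherited as blocks; male samples read those
haplotypes directly (one X, no phase ambiguity), so haplotype counting uses
males only.  Diversity is the bias-corrected gene diversity
``HD = n (1 - sum f_i^2) / (n - 1)`` — the probability that two random male
haplotypes differ.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genotypes import AlleleLabel, GenotypeTable
from .reference import DEFAULT_LINKAGE_GROUPS

__all__ = [
    "LinkageGroupSpec",
    "HaplotypeTable",
    "male_haplotypes",
    "haplotype_diversity",
    "read_linkage_groups",
    "default_linkage_groups",
]


@dataclass(frozen=True)
class LinkageGroupSpec:
    group_id: int
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("linkage group needs at least one locus")


def default_linkage_groups() -> list[LinkageGroupSpec]:
    """The panel's seven disjoint linkage groups covering all 19 loci."""
    return [
        LinkageGroupSpec(gid, tuple(loci))
        for gid, loci in DEFAULT_LINKAGE_GROUPS.items()
    ]


def read_linkage_groups(path: str | Path) -> list[LinkageGroupSpec]:
    """Parse a plain-text group file: one ``id: locus,locus,...`` per line."""
    specs = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        gid, _, rest = line.partition(":")
        loci = tuple(l.strip() for l in rest.replace(",", " ").split())
        specs.append(LinkageGroupSpec(int(gid), loci))
    return specs


Haplotype = tuple[AlleleLabel, ...]


@dataclass
class HaplotypeTable:
    group: LinkageGroupSpec
    counts: dict[Haplotype, int]
    n: int          # males with complete calls across the group
    n_excluded: int  # males dropped for a missing member-locus call

    @property
    def frequencies(self) -> dict[Haplotype, float]:
        return {h: c / self.n for h, c in self.counts.items()}

    @property
    def n_haplotypes(self) -> int:
        return len(self.counts)

    @property
    def diversity(self) -> float:
        return haplotype_diversity(list(self.counts.values()), self.n)

    @staticmethod
    def name(h: Haplotype) -> str:
        """Hyphen-joined report name, e.g. ``H 33-20``."""
        return "H " + "-".join(str(a) for a in h)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "haplotype": self.name(h),
                "count": c,
                "frequency": c / self.n,
            }
            for h, c in sorted(
                self.counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df["frequency"] = df["frequency"].map(lambda v: f"{v:.4f}")
        with Path(path).open("w", encoding="utf-8") as fh:
            df.to_csv(fh, sep="\t", index=False)
            fh.write(f"# n={self.n}\thaplotypes={self.n_haplotypes}\t"
                     f"diversity={self.diversity:.4f}\n")


def male_haplotypes(table: GenotypeTable, spec: LinkageGroupSpec) -> HaplotypeTable:
    """Count male haplotypes (allele tuples across the group's loci).

    Males missing any member-locus call are excluded from the group and
    tallied in ``n_excluded``.
    """
    for locus in spec.loci:
        if locus not in table.loci:
            raise KeyError(f"linkage group {spec.group_id}: unknown locus {locus!r}")
    counts: Counter[Haplotype] = Counter()
    excluded = 0
    for s in table.males:
        calls = [table.call(s.sample_id, locus) for locus in spec.loci]
        if any(c is None for c in calls):
            excluded += 1
            continue
        counts[tuple(c[0] for c in calls)] += 1
    return HaplotypeTable(
        group=spec, counts=dict(counts), n=sum(counts.values()),
        n_excluded=excluded,
    )


def haplotype_diversity(counts: Sequence[int] | Mapping, n: int | None = None) -> float:
    """Unbiased haplotype diversity ``HD = n (1 - sum f_i^2) / (n - 1)``."""
    if isinstance(counts, Mapping):
        counts = list(counts.values())
    total = sum(counts)
    if n is None:
        n = total
    if n != total:
        raise ValueError(f"counts sum to {total}, not n={n}")
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    sum_f2 = sum((c / n) ** 2 for c in counts)
    return n * (1.0 - sum_f2) / (n - 1)
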