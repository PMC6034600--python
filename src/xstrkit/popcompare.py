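"""Inter-population comparison: Nei's D_A distance, UPGMA, classical MDS.

Populations are compared through allele frequencies at shared loci.  Nei's
D_A distance averages, over loci, one minus the Bhattacharyya affinity
``sum_i sqrt(x_i y_i)`` — a measure well suited to microsatellite tree
building.  The distance matrix feeds a UPGMA dendrogram (size-weighted
average linkage, ultrametric by construction, deterministic lexicographic
tie-breaking) and a classical (Torgerson) metric MDS embedding.  Published
frequency tables are rounded, so vectors are renormalized over the allele
union before the square-root sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationFrequencySet",
    "read_population_frequencies",
    "da_distance",
    "da_matrix",
    "upgma",
    "classical_mds",
]


@dataclass
class PopulationFrequencySet:
    """Per-locus allele->frequency maps for one population."""

    name: str
    frequencies: dict[str, dict]  # locus -> {allele label -> freq}

    def __post_init__(self) -> None:
        for locus, vec in self.frequencies.items():
            s = sum(vec.values())
            if abs(s - 1.0) > 1e-4:  # published tables round to 4 decimals
                raise ValueError(
                    f"{self.name}/{locus}: frequencies sum to {s}, not 1"
                )

    @property
    def loci(self) -> list[str]:
        return list(self.frequencies)


def read_population_frequencies(path: str | Path, name: str | None = None
                                ) -> PopulationFrequencySet:
    """Read a per-population TSV/CSV with columns locus, allele, frequency."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={"allele": str})
    required = {"locus", "allele", "frequency"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    freqs: dict[str, dict] = {}
    for locus, sub in df.groupby("locus", sort=False):
        freqs[str(locus)] = dict(zip(sub["allele"], sub["frequency"].astype(float)))
    return PopulationFrequencySet(name or path.stem, freqs)


def _renormalized(vec: Mapping, alleles: Sequence) -> np.ndarray:
    v = np.array([float(vec.get(a, 0.0)) for a in alleles])
    s = v.sum()
    if s <= 0:
        raise ValueError("empty frequency vector")
    return v / s


def da_distance(
    pop_a: PopulationFrequencySet,
    pop_b: PopulationFrequencySet,
    loci: Sequence[str] | None = None,
) -> float:
    """Nei's D_A = 1 - (1/L) sum_loci sum_alleles sqrt(x_i y_i)."""
    if loci is None:
        loci = [l for l in pop_a.loci if l in set(pop_b.loci)]
    if not loci:
        raise ValueError(
            f"no shared loci between {pop_a.name!r} and {pop_b.name!r}"
        )
    affinity = 0.0
    for locus in loci:
        if locus not in pop_a.frequencies or locus not in pop_b.frequencies:
            raise KeyError(f"locus {locus!r} missing from one population")
        union = sorted(
            set(pop_a.frequencies[locus]) | set(pop_b.frequencies[locus]),
            key=str,
        )
        x = _renormalized(pop_a.frequencies[locus], union)
        y = _renormalized(pop_b.frequencies[locus], union)
        affinity += float(np.sqrt(x * y).sum())
    return 1.0 - affinity / len(loci)


def da_matrix(
    populations: Sequence[PopulationFrequencySet],
    loci: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Symmetric D_A distance matrix over populations (shared loci only)."""
    if loci is None:
        shared = set(populations[0].loci)
        for pop in populations[1:]:
            shared &= set(pop.loci)
        loci = [l for l in populations[0].loci if l in shared]
    names = [p.name for p in populations]
    n = len(populations)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = da_distance(populations[i], populations[j], loci)
    return pd.DataFrame(d, index=names, columns=names)


# -- UPGMA -----------------------------------------------------------------


@dataclass
class _Cluster:
    label: str          # lexicographically smallest member leaf
    members: frozenset
    size: int
    height: float
    newick: str


def upgma(distances: pd.DataFrame) -> str:
    """UPGMA tree of a distance matrix, returned as a rooted Newick string.

    Size-weighted average linkage; merge heights are half the inter-cluster
    distance, so the tree is ultrametric.  Ties are broken by the
    lexicographic order of the pair of cluster labels (each cluster labelled
    by its smallest leaf name).
    """
    d = distances.to_numpy(dtype=float)
    names = [str(n) for n in distances.index]
    if d.shape[0] != d.shape[1] or list(distances.columns) != list(distances.index):
        raise ValueError("distance matrix must be square with matching labels")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = len(names)
    if n < 2:
        raise ValueError("need at least two taxa")

    clusters: dict[int, _Cluster] = {
        i: _Cluster(names[i], frozenset([names[i]]), 1, 0.0, names[i])
        for i in range(n)
    }
    dist: dict[frozenset, float] = {
        frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        # nearest pair; ties by (min label, max label)
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                *sorted(
                    (clusters[i].label for i in kv[0])
                ),
            ),
        )
        (i, j), dij = best
        i, j = sorted(best[0], key=lambda c: clusters[c].label)
        a, b = clusters.pop(i), clusters.pop(j)
        height = dij / 2.0
        merged = _Cluster(
            label=min(a.label, b.label),
            members=a.members | b.members,
            size=a.size + b.size,
            height=height,
            newick=(
                f"({a.newick}:{height - a.height:.10g},"
                f"{b.newick}:{height - b.height:.10g})"
            ),
        )
        new_dist = {}
        for k in clusters:
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            new_dist[frozenset((next_id, k))] = (
                a.size * dik + b.size * djk
            ) / (a.size + b.size)
        dist.pop(frozenset((i, j)))
        dist.update(new_dist)
        clusters[next_id] = merged
        next_id += 1
    root = next(iter(clusters.values()))
    return root.newick + ";"


# -- classical MDS ---------------------------------------------------------


def classical_mds(distances: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS coordinates.

    Double-centers the squared distance matrix, eigendecomposes, and returns
    the top-``dims`` coordinates scaled by the square roots of the (positive)
    eigenvalues.  Orientation is fixed by making the first nonzero loading of
    each axis positive; coordinates are otherwise defined only up to
    rotation/reflection.
    """
    d = distances.to_numpy(dtype=float)
    names = list(distances.index)
    n = d.shape[0]
    if n < dims + 1:
        raise ValueError("need at least dims + 1 populations")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-9 * max(vals.max(), 1.0), 0.0)
    rank = int(np.sum(vals > tol))
    if np.allclose(d, 0.0):
        coords = np.zeros((n, dims))
    else:
        if dims > rank:
            raise ValueError(f"dims={dims} exceeds configuration rank {rank}")
        coords = vecs[:, :dims] * np.sqrt(vals[:dims])
        for c in range(dims):
            col = coords[:, c]
            nz = np.nonzero(np.abs(col) > 1e-12)[0]
            if nz.size and col[nz[0]] < 0:
                coords[:, c] = -col
    return pd.DataFrame(
        coords, index=names, columns=[f"dim{k + 1}" for k in range(dims)]
    )
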