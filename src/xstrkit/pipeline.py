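"""One-command orchestration of the full study pipeline.

Runs, in the order of the underlying study design: allele frequencies ->
forensic-efficiency panel -> HWE exact tests -> pairwise LD tests ->
linkage-group haplotype tables, writing a plain-text report bundle.  Every
threshold, replicate count and seed is echoed into the run log so any number
in the bundle can be regenerated from (input, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import equilibrium, forensic, frequencies, haplotypes
from .genotypes import read_genotype_table

__all__ = ["RunConfig", "run_study", "compare_populations"]


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    pooling: str = "paper"          # "paper" | "chromosome-weighted"
    alpha: float = 0.05
    bonferroni_scope: str = "family"  # "family" (per test family) | "none"
    n_reps: int = 10_000
    seed: int = 0
    linkage_group_file: str | None = None


def _linkage_specs(config: RunConfig) -> list[haplotypes.LinkageGroupSpec]:
    if config.linkage_group_file:
        return haplotypes.read_linkage_groups(config.linkage_group_file)
    return haplotypes.default_linkage_groups()


def run_study(config: RunConfig) -> dict[str, Path]:
    """Execute the pipeline; returns the paths of the written artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_genotype_table(config.input_path)
    artifacts: dict[str, Path] = {}

    # allele frequencies
    freq_table = frequencies.build_frequency_table(table, pooling=config.pooling)
    artifacts["frequencies"] = out / "frequencies.tsv"
    freq_table.write_tsv(artifacts["frequencies"])

    # forensic parameters + cumulatives
    per_locus = {
        locus: forensic.locus_params(freq_table.freq_pooled[locus])
        for locus in table.loci
        if freq_table.freq_pooled[locus]
    }
    report, cumulatives = forensic.panel_report(per_locus)
    artifacts["forensic"] = out / "forensic.tsv"
    report.to_csv(artifacts["forensic"], sep="\t", index=False)
    artifacts["cumulatives"] = out / "cumulatives.json"
    artifacts["cumulatives"].write_text(json.dumps(cumulatives, indent=2))

    # HWE per locus (females)
    m_hwe = len(table.loci)
    hwe_threshold = (
        equilibrium.bonferroni_threshold(config.alpha, m_hwe)
        if config.bonferroni_scope == "family"
        else config.alpha
    )
    hwe_rows = []
    for i, locus in enumerate(table.loci):
        res = equilibrium.hwe_exact_test(
            table.female_genotypes(locus),
            mode="monte-carlo",
            n_reps=config.n_reps,
            seed=config.seed + i,
        )
        hwe_rows.append(
            {
                "locus": locus,
                "p_value": res.p_value,
                "n_reps": res.n_reps,
                "threshold": hwe_threshold,
                "significant": res.p_value < hwe_threshold,
            }
        )
    artifacts["hwe"] = out / "hwe.tsv"
    pd.DataFrame(hwe_rows).to_csv(artifacts["hwe"], sep="\t", index=False)

    # pairwise LD (females)
    pairs = [
        (table.loci[i], table.loci[j])
        for i in range(len(table.loci))
        for j in range(i + 1, len(table.loci))
    ]
    m_ld = len(pairs)
    ld_threshold = (
        equilibrium.bonferroni_threshold(config.alpha, m_ld)
        if config.bonferroni_scope == "family"
        else config.alpha
    )
    ld_rows = []
    for i, (la, lb) in enumerate(pairs):
        ga = {s.sample_id: table.call(s.sample_id, la) for s in table.females}
        gb = {s.sample_id: table.call(s.sample_id, lb) for s in table.females}
        joint = [
            (ga[sid], gb[sid])
            for sid in ga
            if ga[sid] is not None and gb[sid] is not None
        ]
        res = equilibrium.ld_exact_test(
            joint, n_reps=config.n_reps, seed=config.seed + 1000 + i
        )
        ld_rows.append(
            {
                "locus_a": la,
                "locus_b": lb,
                "p_value": res.p_value,
                "n_reps": res.n_reps,
                "threshold": ld_threshold,
                "significant": res.p_value < ld_threshold,
            }
        )
    artifacts["ld"] = out / "ld.tsv"
    pd.DataFrame(ld_rows).to_csv(artifacts["ld"], sep="\t", index=False)

    # haplotype tables per linkage group (males)
    for spec in _linkage_specs(config):
        ht = haplotypes.male_haplotypes(table, spec)
        key = f"haplotypes_lg{spec.group_id}"
        artifacts[key] = out / f"{key}.tsv"
        ht.write_tsv(artifacts[key])

    log = {
        "config": asdict(config),
        "n_males": table.n_males,
        "n_females": table.n_females,
        "n_loci": len(table.loci),
        "hwe_threshold": hwe_threshold,
        "ld_threshold": ld_threshold,
        "n_locus_pairs": m_ld,
    }
    artifacts["run_log"] = out / "run_log.json"
    artifacts["run_log"].write_text(json.dumps(log, indent=2))
    return artifacts


def compare_populations(
    freq_files: list[str], output_dir: str
) -> dict[str, Path]:
    """D_A matrix, UPGMA Newick tree, and 2-D MDS coordinates from
    per-population frequency tables (restricted to the shared locus set)."""
    from . import popcompare

    if len(freq_files) < 2:
        raise ValueError("need at least two population frequency files")
    pops = [popcompare.read_population_frequencies(f) for f in freq_files]
    shared = set(pops[0].loci)
    for p in pops[1:]:
        shared &= set(p.loci)
    if not shared:
        raise ValueError("no shared loci across populations")
    loci = [l for l in pops[0].loci if l in shared]

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    dmat = popcompare.da_matrix(pops, loci)
    artifacts["distances"] = out / "da_distances.tsv"
    dmat.to_csv(artifacts["distances"], sep="\t")
    artifacts["tree"] = out / "upgma.nwk"
    artifacts["tree"].write_text(popcompare.upgma(dmat) + "\n")
    if len(pops) >= 3:
        coords = popcompare.classical_mds(dmat, dims=2)
        artifacts["mds"] = out / "mds_coordinates.tsv"
        coords.to_csv(artifacts["mds"], sep="\t")
    artifacts["shared_loci"] = out / "shared_loci.txt"
    artifacts["shared_loci"].write_text("\n".join(loci) + "\n")
    return artifacts
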