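"""End-to-end orchestration: simulate -> metrics -> composition -> elements
-> functional -> phylo -> habitat -> stats, from one config.

Every stage writes a TSV under the output directory; a master genome-level
table joins the per-genome panels, and a JSON manifest records the seed,
parameter hashes and per-stage row counts so a run can be audited and
reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, codons, elements, functional, genome_metrics, habitat
from . import phylo as phylo_mod
from . import stats as stats_mod
from . import synthetic
from .core_io import write_matrix
from .elements import RESIDUE_ATOMS

ALL_STAGES = (
    "simulate", "genome_metrics", "codons", "aa", "elements",
    "functional", "pd", "habitat", "stats",
)

#: genome-level columns contrasted across lineages in the stats stage
_STAT_METRICS = (
    "corrected_size_bp", "gc_overall_pct", "gc_genic_pct",
    "gc_intergenic_pct", "coding_density_fraction", "median_spacer_bp",
    "sigma_per_1000_genes", "mean_c_per_aa", "mean_n_per_aa", "frr",
)


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    seed: int = 0
    out_dir: str = "limnoscope_out"
    stages: tuple[str, ...] = ALL_STAGES
    n_genomes_per_lineage: int = 10
    genes_reference: int = 200
    n_abundance_samples: int = 1000
    abundance_threshold_pct: float = 0.5
    alpha: float = 0.05
    n_perm: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> list[str]:
        """Schema check without computation; returns collected errors."""
        errors = []
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            errors.append(f"unknown stage(s): {bad}")
        deps = {s: ("simulate",) for s in ALL_STAGES if s != "simulate"}
        deps["stats"] = ("simulate", "genome_metrics", "elements", "functional")
        for stage in self.stages:
            missing = [d for d in deps.get(stage, ()) if d not in self.stages]
            if missing:
                errors.append(f"stage {stage!r} requires {missing}")
        if not (0 < self.alpha < 1):
            errors.append(f"alpha must be in (0, 1), got {self.alpha}")
        if self.abundance_threshold_pct < 0 or self.abundance_threshold_pct > 100:
            errors.append(
                f"abundance threshold outside [0, 100]: "
                f"{self.abundance_threshold_pct}"
            )
        if self.n_perm < 1:
            errors.append(f"n_perm must be >= 1, got {self.n_perm}")
        if self.n_genomes_per_lineage < 1:
            errors.append("n_genomes_per_lineage must be >= 1")
        return errors


def _residue_table_hash() -> str:
    blob = json.dumps(RESIDUE_ATOMS, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "residue_atom_table_sha256_16": _residue_table_hash(),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "stages": {},
    }

    sim_cfg = synthetic.study_config(
        seed=config.seed,
        n_genomes=config.n_genomes_per_lineage,
        genes_reference=config.genes_reference,
        n_abundance_samples=config.n_abundance_samples,
    )
    bundle = synthetic.simulate(sim_cfg)
    lineage_of = {g.genome_id: g.lineage for g in bundle.genomes}
    lineage_order = [spec.name for spec in sim_cfg.lineages]

    if "simulate" in config.stages:
        sim_manifest = synthetic.write_bundle(bundle, str(out / "bundle"))
        manifest["stages"]["simulate"] = {
            "rows": sim_manifest["n_genomes_total"],
            "outputs": ["bundle/"],
        }

    master = pd.DataFrame({"genome_id": [g.genome_id for g in bundle.genomes]})

    if "genome_metrics" in config.stages:
        mtab = genome_metrics.metrics_table(bundle.genomes)
        mtab.to_csv(out / "metrics.tsv", sep="\t", index=False)
        master = master.merge(mtab, on="genome_id", how="left")
        manifest["stages"]["genome_metrics"] = {
            "rows": len(mtab), "outputs": ["metrics.tsv"],
        }

    codon_profiles = {}
    if "codons" in config.stages:
        codon_profiles = {
            gid: codons.codon_frequencies(list(cds.values()), genome_id=gid)
            for gid, cds in bundle.cds.items()
        }
        cmat = codons.codon_matrix(list(codon_profiles.values()))
        write_matrix(
            cmat.to_numpy(), list(cmat.index), list(cmat.columns),
            out / "codons.tsv",
        )
        gc3 = pd.DataFrame(
            {
                "genome_id": list(codon_profiles),
                "gc1_pct": [p.gc_by_position[0] for p in codon_profiles.values()],
                "gc2_pct": [p.gc_by_position[1] for p in codon_profiles.values()],
                "gc3_pct": [p.gc_by_position[2] for p in codon_profiles.values()],
            }
        )
        gc3.to_csv(out / "gc_by_position.tsv", sep="\t", index=False)
        master = master.merge(gc3, on="genome_id", how="left")

        trend = codons.synonymous_family_trend(
            [
                (
                    name,
                    [
                        codon_profiles[g.genome_id]
                        for g in bundle.genomes
                        if g.lineage == name
                    ],
                )
                for name in lineage_order
            ]
        )
        trend.to_csv(out / "codon_family_trend.tsv", sep="\t", index=False)
        manifest["stages"]["codons"] = {
            "rows": len(cmat.columns),
            "fraction_families_decreasing": trend.attrs["fraction_decreasing"],
            "outputs": ["codons.tsv", "gc_by_position.tsv",
                        "codon_family_trend.tsv"],
        }

    if "aa" in config.stages:
        aa_profiles = [
            codons.aa_composition(list(prot.values()), sequence_id=gid)
            for gid, prot in bundle.proteins.items()
        ]
        amat = codons.aa_matrix(aa_profiles)
        write_matrix(
            amat.to_numpy(), list(amat.index), list(amat.columns),
            out / "aa.tsv",
        )
        manifest["stages"]["aa"] = {
            "rows": len(amat.columns), "outputs": ["aa.tsv"],
        }

    if "elements" in config.stages:
        eprofiles = [
            elements.proteome_cn(prot, genome_id=gid)
            for gid, prot in bundle.proteins.items()
        ]
        etab = elements.elements_table(eprofiles, lineages=lineage_of)
        etab.to_csv(out / "elements.tsv", sep="\t", index=False)
        master = master.merge(
            etab[["genome_id", "mean_c_per_aa", "mean_n_per_aa"]],
            on="genome_id", how="left",
        )
        rel = elements.cn_relationship(
            eprofiles, group_labels=[lineage_of[p.genome_id] for p in eprofiles]
        )
        manifest["stages"]["elements"] = {
            "rows": len(etab),
            "cn_spearman_rho": rel["rho"],
            "cn_spearman_p": rel["p_value"],
            "outputs": ["elements.tsv"],
        }

    if "functional" in config.stages:
        habitat_of = {g.genome_id: g.habitat for g in bundle.genomes}
        pools = functional.pool_by_group(
            bundle.annotations.values(), habitat_of
        )
        jmat = functional.jaccard_matrix(pools)
        write_matrix(
            jmat.to_numpy(), list(jmat.index), list(jmat.columns),
            out / "jaccard.tsv",
        )
        ftab = functional.frr_table(
            bundle.annotations.values(), lineages=lineage_of
        )
        ftab.to_csv(out / "frr.tsv", sep="\t", index=False)
        master = master.merge(
            ftab[["genome_id", "frr"]], on="genome_id", how="left"
        )
        manifest["stages"]["functional"] = {
            "rows": len(ftab), "outputs": ["jaccard.tsv", "frr.tsv"],
        }

    if "pd" in config.stages:
        # reference: the three older lineages; added: the newest (reduced)
        added_lineage = lineage_order[-1]
        reference = [
            g.genome_id for g in bundle.genomes if g.lineage != added_lineage
        ]
        added = [
            g.genome_id for g in bundle.genomes if g.lineage == added_lineage
        ]
        pd_ref = phylo_mod.pd(bundle.tree, reference)
        gain, pct = phylo_mod.pd_gain(bundle.tree, reference, added)
        pd_report = pd.DataFrame(
            [
                {
                    "reference_lineages": "+".join(lineage_order[:-1]),
                    "added_lineage": added_lineage,
                    "pd_reference": pd_ref,
                    "pd_total": pd_ref + gain,
                    "pd_gain": gain,
                    "pct_gain": pct,
                }
            ]
        )
        pd_report.to_csv(out / "pd_gain.tsv", sep="\t", index=False)
        manifest["stages"]["pd"] = {
            "rows": 1, "pct_gain": pct, "outputs": ["pd_gain.tsv"],
        }

    if "habitat" in config.stages:
        valid = habitat.filter_valid_matches(
            bundle.abundance, config.abundance_threshold_pct
        )
        summary = habitat.summarize_all(valid)
        summary.to_csv(out / "habitat_summary.tsv", sep="\t", index=False)
        manifest["stages"]["habitat"] = {
            "rows": len(summary),
            "n_valid_matches": int(len(valid)),
            "outputs": ["habitat_summary.tsv"],
        }

    if "stats" in config.stages:
        rows = []
        master_lineage = master.merge(
            pd.DataFrame(
                {
                    "genome_id": list(lineage_of),
                    "lineage_": list(lineage_of.values()),
                }
            ),
            on="genome_id",
        )
        for metric in _STAT_METRICS:
            if metric not in master_lineage.columns:
                continue
            groups = {
                name: master_lineage.loc[
                    master_lineage["lineage_"] == name, metric
                ].dropna().to_numpy()
                for name in lineage_order
            }
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            try:
                report = stats_mod.compare_groups(groups, alpha=config.alpha)
            except ValueError as exc:
                rows.append(
                    {"metric": metric, "test_used": f"skipped ({exc})",
                     "global_p": float("nan")}
                )
                continue
            rows.append(
                {
                    "metric": metric,
                    "test_used": report.test_used,
                    "global_p": report.global_p,
                    **{
                        f"letter[{g}]": report.letters.get(g, "")
                        for g in lineage_order
                    },
                }
            )
        stats_df = pd.DataFrame(rows)
        stats_df.to_csv(out / "comparisons.tsv", sep="\t", index=False)
        manifest["stages"]["stats"] = {
            "rows": len(stats_df), "outputs": ["comparisons.tsv"],
        }

    master.to_csv(out / "master.tsv", sep="\t", index=False)
    manifest["master_rows"] = len(master)
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
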