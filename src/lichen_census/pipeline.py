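"""Pipeline orchestration: dedup → occurrence → LFS → cascade → census →
modules → trophy → complementarity.

Consumes a directory of TSV input tables (as produced upstream by read
mapping, quality estimation, taxonomy and KO annotation — or by the
bundled simulator), runs every census stage in order, and writes
deterministic, sorted outputs plus a machine-readable run manifest carrying
the dataset cascade counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import census as census_mod
from . import kegg, occurrence as occ_mod, qc, trophy as trophy_mod
from .tables import read_table, write_table

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "infer_roles"]

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    rules_path: str | None = None
    modules_path: str | None = None
    breadth_min: float = 0.5
    ani_min: float = 95.0
    af_min_bacteria: float = 30.0
    af_min_eukaryota: float = 40.0
    near_complete_min_completeness: float = 95.0
    near_complete_max_contamination: float = 10.0
    min_group_size: int = 4
    top_k_genera: int = 13
    census_levels: tuple[str, ...] = ("species", "genus", "family", "order")
    detection_level: str = "family"
    dataset: int = 1
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if not 0 < self.breadth_min <= 1:
            raise ValueError("breadth_min must be in (0, 1]")
        if self.dataset not in (1, 2):
            raise ValueError("dataset selector must be 1 or 2")
        for level in tuple(self.census_levels) + (self.detection_level,):
            if level not in census_mod.RANKS:
                raise ValueError(f"unknown taxonomic level {level!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        if "census_levels" in raw:
            raw["census_levels"] = tuple(raw["census_levels"])
        return cls(**raw)


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict[str, str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    cascade: dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "input_checksums": self.input_checksums,
                    "stage_counts": self.stage_counts,
                    "cascade": self.cascade,
                },
                handle,
                indent=2,
                sort_keys=True,
            )
            handle.write("\n")


def _checksum(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def infer_roles(quality: pd.DataFrame, taxonomy: pd.DataFrame) -> dict[str, str]:
    """Role of each MAG: alga, cyanobacterium, bacterium or fungus.

    An explicit ``role`` column in the quality table wins; otherwise algae
    come from the algae domain, cyanobacteria from the Cyanobacteria phylum,
    the remaining bacteria are plain bacteria and the rest fungi. (Which
    fungal MAG is the LFS is a per-sample call, not a per-MAG role.)
    """
    tax = taxonomy.set_index("mag_id")
    roles = {}
    for row in quality.itertuples():
        explicit = getattr(row, "role", None)
        if explicit in ("alga", "cyanobacterium", "bacterium", "yeast", "LFS"):
            roles[row.mag_id] = {"yeast": "fungus", "LFS": "fungus"}.get(explicit, explicit)
            continue
        if row.domain == "algae":
            roles[row.mag_id] = "alga"
        elif row.domain == "bacteria":
            phylum = tax.loc[row.mag_id, "phylum"] if row.mag_id in tax.index else ""
            roles[row.mag_id] = "cyanobacterium" if phylum == "Cyanobacteria" else "bacterium"
        else:
            roles[row.mag_id] = "fungus"
    return roles


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all census stages and write the outputs.

    Outputs are byte-stable under rerun: rows sorted on primary keys, fixed
    float formatting via pandas defaults, cascade counts recorded in the
    run manifest. A stage failure aborts with the stage name; outputs
    written so far are removed.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(frame: pd.DataFrame, name: str, sort_by: list[str]) -> None:
        path = outdir / name
        write_table(frame, path, sort_by=sort_by)
        written.append(path)

    stage = "read inputs"
    try:
        input_paths = {
            name: indir / f"{name}.tsv"
            for name in ("coverage", "quality", "taxonomy", "ko", "rrna", "manifest")
        }
        tables = {name: read_table(path, name) for name, path in input_paths.items()}
        checksums = {name: _checksum(path) for name, path in input_paths.items()}
        manifest = tables["manifest"]
        coverage = tables["coverage"]
        quality = tables["quality"]
        taxonomy = tables["taxonomy"]
        tax_indexed = taxonomy.set_index("mag_id")

        stage = "dedup"
        pairs = [
            (row.duplicate_of, row.sample_id)
            for row in manifest.itertuples()
            if getattr(row, "duplicate_of", "") not in ("", None)
        ]
        keep = [a for a, _ in pairs]
        retained_ids, removal_log = qc.deduplicate_samples(
            list(manifest["sample_id"]), pairs, keep=keep
        )
        retained = manifest[manifest["sample_id"].isin(retained_ids)]
        emit(retained, "retained_manifest.tsv", ["sample_id"])
        emit(
            pd.DataFrame(removal_log, columns=["kept", "removed"]),
            "dedup_log.tsv",
            ["kept", "removed"],
        )

        stage = "occurrence"
        cov = coverage[coverage["sample_id"].isin(retained_ids)]
        occ = occ_mod.call_occurrence(
            cov,
            breadth_min=config.breadth_min,
            samples=sorted(retained_ids),
            species=sorted(quality["mag_id"]),
        )
        emit(occ.to_long(), "occurrence.tsv", ["sample_id", "species"])

        stage = "lfs"
        fungal = set(quality.loc[quality["domain"] == "fungi", "mag_id"])
        depth_col = "depth" if "depth" in cov.columns else None
        depths_by_sample: dict[str, dict[str, float]] = {}
        for row in cov.itertuples():
            d = (
                float(row.depth)
                if depth_col
                else occ_mod.depth_of_coverage(row.n_reads, row.read_length, row.mag_length)
            )
            depths_by_sample.setdefault(row.sample_id, {})[row.mag_id] = d
        lineage_of = {
            m: ";".join(str(tax_indexed.loc[m, r]) for r in census_mod.RANKS)
            for m in tax_indexed.index
        }
        fungal_genera = {
            str(tax_indexed.loc[m, "genus"]) for m in fungal if m in tax_indexed.index
        }
        name_to_lineage = {g: g for g in fungal_genera if g}
        declared = dict(zip(manifest["sample_id"], manifest["declared_lfs_name"]))
        lfs_calls: dict[str, occ_mod.LFSCall] = {}
        for sample_id in sorted(retained_ids):
            present = occ.present_species(sample_id)
            fungal_present = [m for m in present if m in fungal]
            call = occ_mod.assign_lfs(
                sample_id,
                fungal_present,
                depths_by_sample.get(sample_id, {}),
                lineage_of,
            )
            call = occ_mod.verify_lfs(
                call,
                declared.get(sample_id, ""),
                name_to_lineage,
                fungal_candidates=fungal_present,
                taxonomy=lineage_of,
            )
            lfs_calls[sample_id] = call
        emit(
            pd.DataFrame(
                [
                    {
                        "sample_id": c.sample_id,
                        "lfs_mag_id": c.lfs_mag_id or "",
                        "status": c.status,
                        "reason": c.reason,
                    }
                    for c in lfs_calls.values()
                ]
            ),
            "lfs_calls.tsv",
            ["sample_id"],
        )

        stage = "cascade"
        labels, cascade = occ_mod.build_dataset_cascade(sorted(retained_ids), occ, lfs_calls)
        emit(labels, "datasets.tsv", ["sample_id"])
        ds1 = list(labels.loc[labels["in_dataset1"] == 1, "sample_id"])
        ds2 = list(labels.loc[labels["in_dataset2"] == 1, "sample_id"])
        census_samples = ds1 if config.dataset == 1 else ds2

        stage = "census"
        for level in config.census_levels:
            freq = census_mod.tabulate_frequency(
                occ, tax_indexed, level, sample_subset=census_samples
            )
            emit(freq, f"frequency_{level}.tsv", ["taxon"])
        rrna = tables["rrna"][tables["rrna"]["sample_id"].isin(census_samples)]
        occ_census = occ.subset_samples(sorted(census_samples)) if census_samples else occ
        detection = census_mod.merge_detection_tiers(
            occ_census, rrna, tax_indexed, config.detection_level
        )
        # heatmap-style reporting keeps only groups seen in enough metagenomes
        group_sizes = detection.groupby("taxon")[["mag", "assembly_rrna", "read_rrna"]].sum()
        visible = group_sizes[(group_sizes.max(axis=1) >= config.min_group_size)].index
        emit(
            detection[detection["taxon"].isin(visible)],
            "detection.tsv",
            ["taxon", "sample_id"],
        )
        sample_depths = dict(zip(manifest["sample_id"], manifest["total_depth_bp"]))
        outcomes = census_mod.outcome_table(
            detection[detection["taxon"].isin(visible)], sample_depths
        )
        emit(outcomes, "outcomes.tsv", ["taxon", "outcome_rank", "sample_id"])

        bact_freq = census_mod.tabulate_frequency(
            occ_census if census_samples else occ,
            tax_indexed,
            "genus",
            sample_subset=census_samples,
            domain="Bacteria",
        )
        top, shares = census_mod.rank_and_select_top(
            bact_freq, min(config.top_k_genera, len(bact_freq)) or 1
        )
        emit(top, "top_genera.tsv", ["taxon"])

        roles = infer_roles(quality, taxonomy)
        focal_genera = set(top["taxon"])
        focal_lineages = [
            m
            for m in occ.species
            if roles.get(m) != "bacterium"
            or str(tax_indexed.loc[m, "genus"]) in focal_genera
        ]
        occ_ds2 = occ.subset_samples(sorted(ds2)) if ds2 else occ
        network = census_mod.build_cooccurrence(
            occ_ds2,
            focal_lineages,
            node_classes=roles,
        )
        edge_rows = [
            {"lineage_a": a, "lineage_b": b, "n_shared_samples": d["weight"]}
            for a, b, d in network.edges(data=True)
        ]
        emit(
            pd.DataFrame(edge_rows, columns=["lineage_a", "lineage_b", "n_shared_samples"]),
            "network_edges.tsv",
            ["lineage_a", "lineage_b"],
        )
        nx.write_graphml(network, outdir / "network.graphml")
        written.append(outdir / "network.graphml")

        stage = "modules"
        from .simulate import synthetic_definitions, synthetic_rules_path

        if config.modules_path:
            module_table = read_table(config.modules_path, "modules")
            definitions = {
                row.module_id: kegg.parse_definition(
                    row.definition, module_id=row.module_id, name=row.name
                )
                for row in module_table.itertuples()
            }
        else:
            definitions = synthetic_definitions()
        ko_sets = {
            genome: frozenset(group["ko"])
            for genome, group in tables["ko"].groupby("genome_id")
        }
        completeness_rows = []
        for genome_id in sorted(ko_sets):
            for module_id in sorted(definitions):
                result = kegg.completeness(
                    definitions[module_id], ko_sets[genome_id], genome_id=genome_id
                )
                completeness_rows.append(
                    {
                        "genome_id": genome_id,
                        "module_id": module_id,
                        "n_blocks": result.n_blocks,
                        "n_present_blocks": result.n_present_blocks,
                        "fraction": round(result.fraction, 4),
                        "complete": int(result.complete),
                        "partial_one_missing": int(result.partial_one_missing),
                    }
                )
        emit(pd.DataFrame(completeness_rows), "completeness.tsv", ["genome_id", "module_id"])

        stage = "trophy"
        rules_path = config.rules_path or synthetic_rules_path()
        rules, genes = trophy_mod.load_rules(rules_path)
        quality_by_id = {
            row.mag_id: qc.GenomeQuality(
                mag_id=row.mag_id,
                completeness=row.completeness,
                contamination=row.contamination,
                domain=row.domain,
            )
            for row in quality.itertuples()
        }
        profiles = {
            genome_id: trophy_mod.classify_trophy(
                genome_id,
                ko_sets.get(genome_id, frozenset()),
                rules,
                definitions,
                genes=genes,
                role=roles.get(genome_id, "bacterium"),
            )
            for genome_id in sorted(quality["mag_id"])
        }
        trophy_rows = []
        for genome_id, profile in profiles.items():
            q = quality_by_id[genome_id]
            row = {
                "genome_id": genome_id,
                "role": profile.role,
                "near_complete": int(
                    qc.is_near_complete(
                        q,
                        config.near_complete_min_completeness,
                        config.near_complete_max_contamination,
                    )
                ),
                "mete_present": int(profile.mete_present),
                "meth_present": int(profile.meth_present),
                "cobalamin_dependence": profile.cobalamin_dependence,
            }
            for vitamin in sorted(profile.status):
                row[f"{vitamin}_status"] = profile.status[vitamin]
                row[f"{vitamin}_status_relaxed"] = profile.status_relaxed[vitamin]
                row[f"{vitamin}_fraction"] = round(profile.fraction[vitamin], 4)
            trophy_rows.append(row)
        emit(pd.DataFrame(trophy_rows), "trophy.tsv", ["genome_id"])

        stage = "complementarity"
        focal_bacteria = [
            m
            for m in occ.species
            if roles.get(m) == "bacterium" and str(tax_indexed.loc[m, "genus"]) in focal_genera
        ]
        qualifying = trophy_mod.select_highly_complete_metagenomes(
            occ_ds2,
            lfs_calls,
            roles,
            quality_by_id,
            focal_bacteria=focal_bacteria,
            min_completeness=config.near_complete_min_completeness,
            max_contamination=config.near_complete_max_contamination,
        )
        comp_rows = []
        for sample_id in qualifying:
            call = lfs_calls[sample_id]
            present = set(occ.present_species(sample_id))
            near_present = {
                m: profiles[m]
                for m in present
                if qc.is_near_complete(
                    quality_by_id[m],
                    config.near_complete_min_completeness,
                    config.near_complete_max_contamination,
                )
            }
            report = trophy_mod.assess_complementarity(
                sample_id, call.lfs_mag_id, near_present
            )
            for vitamin, detail in sorted(report.vitamins.items()):
                comp_rows.append(
                    {
                        "sample_id": sample_id,
                        "vitamin": vitamin,
                        "lfs_mag_id": call.lfs_mag_id,
                        "lfs_status": detail["lfs_status"],
                        "complemented": int(detail["complemented"]),
                        "providers": ";".join(m for m, _ in detail["providers"]),
                        "provider_roles": ";".join(r for _, r in detail["providers"]),
                        "partial_providers": ";".join(
                            m for m, _ in detail["partial_providers"]
                        ),
                    }
                )
        emit(
            pd.DataFrame(
                comp_rows,
                columns=[
                    "sample_id",
                    "vitamin",
                    "lfs_mag_id",
                    "lfs_status",
                    "complemented",
                    "providers",
                    "provider_roles",
                    "partial_providers",
                ],
            ),
            "complementarity.tsv",
            ["sample_id", "vitamin"],
        )

    except Exception as exc:  # pragma: no cover - exercised via stage failure test
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run_manifest = RunManifest(
        version=VERSION,
        config={
            f.name: (list(v) if isinstance(v := getattr(config, f.name), tuple) else v)
            for f in fields(config)
        },
        input_checksums=checksums,
        stage_counts={
            "retained_samples": len(retained_ids),
            "occurrence_pairs": int(occ.incidence.sum()),
            "qualifying_metagenomes": len(qualifying),
            "top_genera_pct_lineages": shares["pct_lineages"],
            "top_genera_pct_occurrences": shares["pct_occurrences"],
        },
        cascade=cascade,
    )
    run_manifest.write(outdir / "run_manifest.json")
    return run_manifest
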