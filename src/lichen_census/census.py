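"""Frequency ranking, prevalence, detection tiers and co-occurrence networks.

Frequency of a taxon is the total number of occurrences of its member
species-level lineages across the dataset; prevalence is the integer
percentage of metagenomes in which the taxon is detected (rounded half away
from zero, which reproduces the printed integer percentages from their
count pairs). Detection is tracked in three tiers — recovered MAG, SSU
rRNA in the assembly, SSU rRNA in raw reads — and each sample × taxon row
classifies into a categorical screening outcome. Co-occurrence networks
connect two lineages with an edge weighted by the number of metagenomes in
which both are present.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .occurrence import OccurrenceMatrix

__all__ = [
    "RANKS",
    "round_half_away",
    "taxon_label",
    "tabulate_frequency",
    "rank_and_select_top",
    "prevalence",
    "prevalence_counts",
    "merge_detection_tiers",
    "classify_detection_outcome",
    "build_cooccurrence",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
OUTCOMES = ("mag_and_rrna", "mag_only", "rrna_only", "not_detected")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def taxon_label(row: Mapping[str, str], level: str) -> str:
    """Group label of a lineage at a rank; empty genus falls back to the family.

    A MAG without a genus-level assignment is labeled by its family as
    "<Family> gen. sp." so that genus-level tabulations keep it distinct.
    """
    if level not in RANKS:
        raise KeyError(f"unknown taxonomic level {level!r}")
    label = (row.get(level) or "").strip()
    if label:
        return label
    if level == "genus":
        family = (row.get("family") or "").strip()
        if family:
            return f"{family} gen. sp."
    return f"unclassified {level}"


def tabulate_frequency(
    occ: OccurrenceMatrix,
    taxonomy: pd.DataFrame,
    level: str,
    sample_subset: Sequence[str] | None = None,
    domain: str | None = None,
) -> pd.DataFrame:
    """Sum occurrences of all species-level lineages assigned to each group.

    ``taxonomy`` is indexed by MAG/species id with the seven rank columns.
    Returns one row per group with n_occurrences (summed occurrences),
    n_lineages (member species with ≥1 occurrence), n_samples_detected,
    prevalence_pct and the denominator used for it.
    """
    if level not in RANKS:
        raise KeyError(f"unknown taxonomic level {level!r}")
    missing = [sp for sp in occ.species if sp not in taxonomy.index]
    if missing:
        raise KeyError(f"species missing from taxonomy table: {missing[:5]}")
    matrix = occ if sample_subset is None else occ.subset_samples(list(sample_subset))
    denominator = len(matrix.samples)
    frame = matrix.to_frame()
    rows: dict[str, dict[str, float]] = {}
    for species in matrix.species:
        tax_row = taxonomy.loc[species]
        if domain is not None and (tax_row.get("domain") or "").strip() != domain:
            continue
        label = taxon_label(tax_row, level)
        entry = rows.setdefault(
            label, {"n_occurrences": 0, "n_lineages": 0, "detected": np.zeros(denominator, bool)}
        )
        counts = frame[species].to_numpy()
        n_occ = int(counts.sum())
        entry["n_occurrences"] += n_occ
        entry["n_lineages"] += int(n_occ > 0)
        entry["detected"] = entry["detected"] | counts
    out = []
    for label, entry in rows.items():
        n_detected = int(entry["detected"].sum())
        out.append(
            {
                "taxon": label,
                "level": level,
                "n_occurrences": int(entry["n_occurrences"]),
                "n_lineages": int(entry["n_lineages"]),
                "n_samples_detected": n_detected,
                "prevalence_pct": round_half_away(100.0 * n_detected / denominator)
                if denominator
                else 0,
                "denominator": denominator,
            }
        )
    freq = pd.DataFrame(out)
    return freq.sort_values(
        ["n_occurrences", "taxon"], ascending=[False, True]
    ).reset_index(drop=True)


def rank_and_select_top(
    freq: pd.DataFrame, k: int
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Top-k groups by occurrences, with the share of lineages/occurrences covered.

    Ties are broken alphabetically; shares are integer percentages of the
    whole table's totals. Asking for more groups than exist returns all.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    ranked = freq.sort_values(
        ["n_occurrences", "taxon"], ascending=[False, True]
    ).reset_index(drop=True)
    top = ranked.head(k)
    total_lineages = int(ranked["n_lineages"].sum())
    total_occurrences = int(ranked["n_occurrences"].sum())
    share = {
        "n_selected": len(top),
        "pct_lineages": round_half_away(100.0 * top["n_lineages"].sum() / total_lineages)
        if total_lineages
        else 0,
        "pct_occurrences": round_half_away(
            100.0 * top["n_occurrences"].sum() / total_occurrences
        )
        if total_occurrences
        else 0,
    }
    return top, share


def prevalence_counts(n_detected: int, denominator: int) -> int:
    """Integer percent, rounded half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(100.0 * n_detected / denominator)


def prevalence(
    detection: pd.DataFrame,
    taxon: str,
    tier: str,
    dataset_subset: Sequence[str],
) -> tuple[int, int, int]:
    """Percent of subset samples in which a taxon is detected at a tier.

    ``detection`` is the long table from :func:`merge_detection_tiers`.
    Returns (percent, n_detected, denominator).
    """
    subset = list(dataset_subset)
    if not subset:
        raise ValueError("empty dataset subset")
    mask = (detection["taxon"] == taxon) & detection["sample_id"].isin(subset)
    hits = detection.loc[mask, tier]
    n_detected = int(hits.astype(bool).sum())
    return prevalence_counts(n_detected, len(subset)), n_detected, len(subset)


def merge_detection_tiers(
    occ: OccurrenceMatrix,
    rrna: pd.DataFrame,
    taxonomy: pd.DataFrame,
    level: str,
    taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Combine MAG occurrence with two-tier rRNA screening per sample × taxon.

    The MAG tier of a taxon is the occurrence of any member species rolled up
    to ``level``; rRNA tiers come from the screening table (columns
    sample_id, taxon or mag_id, assembly_rrna, read_rrna). No inference is
    made across tiers.
    """
    if level not in RANKS:
        raise KeyError(f"unknown taxonomic level {level!r}")
    labels = {sp: taxon_label(taxonomy.loc[sp], level) for sp in occ.species}
    if rrna.empty:
        rrna = pd.DataFrame(columns=["sample_id", "taxon", "assembly_rrna", "read_rrna"])
    elif "taxon" not in rrna.columns:
        if "mag_id" not in rrna.columns:
            raise KeyError("rRNA table needs a 'taxon' or 'mag_id' column")
        unknown = set(rrna["mag_id"]) - set(taxonomy.index)
        if unknown:
            raise KeyError(f"rRNA table references taxa missing from taxonomy: {sorted(unknown)[:5]}")
        rrna = rrna.assign(
            taxon=[taxon_label(taxonomy.loc[m], level) for m in rrna["mag_id"]]
        )
    all_taxa = sorted(set(labels.values()) | set(rrna["taxon"])) if taxa is None else list(taxa)
    frame = occ.to_frame()
    rows = []
    rrna_grouped = rrna.groupby(["sample_id", "taxon"])[["assembly_rrna", "read_rrna"]].any()
    for sample_id in occ.samples:
        for taxon in all_taxa:
            member_cols = [sp for sp, lab in labels.items() if lab == taxon]
            mag = bool(frame.loc[sample_id, member_cols].any()) if member_cols else False
            try:
                tier_row = rrna_grouped.loc[(sample_id, taxon)]
                assembly = bool(tier_row["assembly_rrna"])
                read = bool(tier_row["read_rrna"])
            except KeyError:
                assembly = read = False
            rows.append(
                {
                    "sample_id": sample_id,
                    "taxon": taxon,
                    "mag": int(mag),
                    "assembly_rrna": int(assembly),
                    "read_rrna": int(read),
                }
            )
    return pd.DataFrame(rows)


def classify_detection_outcome(mag: bool, read_rrna: bool) -> str:
    """Screening outcome of one sample × taxon from the MAG and read-rRNA tiers."""
    if mag and read_rrna:
        return "mag_and_rrna"
    if mag:
        return "mag_only"
    if read_rrna:
        return "rrna_only"
    return "not_detected"


def outcome_table(detection: pd.DataFrame, depths: Mapping[str, float]) -> pd.DataFrame:
    """Attach outcomes and the (outcome order, depth descending) sort key."""
    out = detection.copy()
    out["outcome"] = [
        classify_detection_outcome(bool(m), bool(r))
        for m, r in zip(out["mag"], out["read_rrna"])
    ]
    out["sequencing_depth_bp"] = out["sample_id"].map(depths)
    order = {o: i for i, o in enumerate(OUTCOMES)}
    out["outcome_rank"] = out["outcome"].map(order)
    return out.sort_values(
        ["taxon", "outcome_rank", "sequencing_depth_bp"],
        ascending=[True, True, False],
    ).reset_index(drop=True)


def build_cooccurrence(
    occ: OccurrenceMatrix,
    focal_lineages: Sequence[str],
    node_classes: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Undirected network of lineages weighted by shared-sample counts.

    An edge joins two focal lineages with weight = number of metagenomes in
    which both are present; zero-weight pairs and lineages present in no
    sample are omitted. Node attribute ``node_class`` carries the role label
    used for coloring (the LFS anchors the network).
    """
    focal = list(focal_lineages)
    if not focal:
        raise ValueError("focal lineage set is empty")
    frame = occ.to_frame()
    missing = [l for l in focal if l not in frame.columns]
    if missing:
        raise KeyError(f"focal lineages absent from occurrence matrix: {missing[:5]}")
    graph = nx.Graph()
    classes = node_classes or {}
    present_counts = frame[focal].sum()
    for lineage in focal:
        if present_counts[lineage] > 0:
            graph.add_node(lineage, node_class=classes.get(lineage, "other"))
    nodes = list(graph.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            weight = int((frame[a] & frame[b]).sum())
            if weight >= 1:
                graph.add_edge(a, b, weight=weight)
    return graph
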