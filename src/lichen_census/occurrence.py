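"""Presence calling from read-mapping coverage and the dataset cascade.

A species-representative MAG is counted as present in a metagenome when at
least 50% of its bases are covered by mapped reads (breadth-of-coverage
rule, inclusive at the boundary). Depth of coverage is the number of mapped
reads × read length / MAG length.

Each metagenome's lichen fungal symbiont (LFS) MAG is identified among the
fungal MAGs present (the deepest one when several are present) and verified
against the sample's declared lichen name; unresolvable mismatches mark the
sample as potentially misidentified. The cascade then defines Dataset 1
(samples with ≥1 recovered MAG) and Dataset 2 (Dataset 1 samples with a
verified LFS MAG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceMatrix",
    "LFSCall",
    "depth_of_coverage",
    "call_occurrence",
    "relative_abundance",
    "assign_lfs",
    "verify_lfs",
    "build_dataset_cascade",
]

VERIFIED_STATUSES = frozenset({"verified", "reassigned", "name_corrected"})


@dataclass
class OccurrenceMatrix:
    """Binary sample × species incidence."""

    samples: list[str]
    species: list[str]
    incidence: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.incidence.shape != (len(self.samples), len(self.species)):
            raise ValueError("incidence shape does not match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=self.samples, columns=self.species)

    def to_long(self) -> pd.DataFrame:
        frame = self.to_frame().rename_axis("sample_id").reset_index()
        long = frame.melt(id_vars="sample_id", var_name="species", value_name="present")
        long["present"] = long["present"].astype(int)
        return long.sort_values(["sample_id", "species"]).reset_index(drop=True)

    def present_species(self, sample_id: str) -> list[str]:
        row = self.incidence[self.samples.index(sample_id)]
        return [sp for sp, flag in zip(self.species, row) if flag]

    def n_present(self) -> pd.Series:
        return pd.Series(self.incidence.sum(axis=1), index=self.samples, name="n_present")

    def subset_samples(self, keep: Sequence[str]) -> "OccurrenceMatrix":
        index = [self.samples.index(s) for s in keep]
        return OccurrenceMatrix(list(keep), list(self.species), self.incidence[index])


@dataclass
class LFSCall:
    sample_id: str
    lfs_mag_id: str | None
    status: str  # verified | reassigned | name_corrected | misassigned | none_found
    reason: str = ""

    def __post_init__(self):
        if self.status in VERIFIED_STATUSES and self.lfs_mag_id is None:
            raise ValueError(f"status {self.status!r} requires an LFS MAG id")


def depth_of_coverage(n_reads: float, read_length: float, mag_length: float) -> float:
    """Mapped reads × read length / MAG length."""
    if mag_length <= 0:
        raise ValueError("mag_length must be positive")
    return n_reads * read_length / mag_length


def call_occurrence(
    coverage: pd.DataFrame,
    breadth_min: float = 0.5,
    samples: Sequence[str] | None = None,
    species: Sequence[str] | None = None,
) -> OccurrenceMatrix:
    """Threshold breadth of coverage into a binary occurrence matrix.

    ``coverage`` is a long table with columns sample_id, mag_id, breadth.
    Pairs absent from the table are absent; breadth ≥ ``breadth_min`` counts
    as present (inclusive, "at least 50% covered").
    """
    if not 0 < breadth_min <= 1:
        raise ValueError("breadth_min must be in (0, 1]")
    breadth = coverage["breadth"].to_numpy(dtype=float)
    if breadth.size and (breadth.min() < 0 or breadth.max() > 1):
        bad = coverage.loc[(breadth < 0) | (breadth > 1)].iloc[0]
        raise ValueError(
            f"breadth {bad['breadth']} outside [0, 1] for sample {bad['sample_id']!r}, "
            f"MAG {bad['mag_id']!r}"
        )
    sample_ids = list(samples) if samples is not None else sorted(coverage["sample_id"].unique())
    species_ids = list(species) if species is not None else sorted(coverage["mag_id"].unique())
    incidence = np.zeros((len(sample_ids), len(species_ids)), dtype=bool)
    s_index = {s: i for i, s in enumerate(sample_ids)}
    m_index = {m: j for j, m in enumerate(species_ids)}
    hits = coverage.loc[breadth >= breadth_min]
    for sample_id, mag_id in zip(hits["sample_id"], hits["mag_id"]):
        if sample_id in s_index and mag_id in m_index:
            incidence[s_index[sample_id], m_index[mag_id]] = True
    return OccurrenceMatrix(sample_ids, species_ids, incidence)


def relative_abundance(depth_symbiont: float, depth_lfs: float) -> float | None:
    """Symbiont depth / LFS depth; None (missing) when the LFS depth is zero."""
    if depth_lfs <= 0:
        return None
    return depth_symbiont / depth_lfs


def _lineage_matches(expected: str, lineage: str) -> bool:
    """Expected name (typically a genus) consistent with a 7-rank lineage."""
    ranks = [r.strip() for r in lineage.split(";")]
    return expected in ranks or expected == lineage


def assign_lfs(
    sample_id: str,
    fungal_mags_present: Sequence[str],
    depths: Mapping[str, float],
    taxonomy: Mapping[str, str],
) -> LFSCall:
    """Pick the putative LFS MAG among fungal MAGs present in a sample.

    A single fungal MAG is taken as is; among several, the one with the
    highest depth of coverage wins (the dominant symbiont is expected to be
    the deepest), ties broken by lexicographic MAG id.
    """
    candidates = list(fungal_mags_present)
    if not candidates:
        return LFSCall(sample_id, None, "none_found", reason="no fungal MAG present")
    best = min(candidates, key=lambda m: (-depths.get(m, 0.0), m))
    return LFSCall(sample_id, best, "verified")


def verify_lfs(
    call: LFSCall,
    declared_name: str,
    name_to_lineage: Mapping[str, str],
    fungal_candidates: Sequence[str] = (),
    taxonomy: Mapping[str, str] | None = None,
    alternate_declared_name: str | None = None,
) -> LFSCall:
    """Check the putative LFS against the sample's declared lichen name.

    The declared name resolves (via ``name_to_lineage``) to an expected
    lineage; a match verifies the call. On mismatch, another present fungal
    MAG whose lineage matches takes over the assignment (``reassigned``); a
    matching alternate declared name (library name) yields
    ``name_corrected``; otherwise the sample is flagged ``misassigned``.
    """
    if call.status == "none_found":
        return call
    taxonomy = taxonomy or {}
    expected = name_to_lineage.get(declared_name)
    if expected is None:
        return LFSCall(
            call.sample_id, call.lfs_mag_id, "misassigned",
            reason=f"declared name {declared_name!r} unresolvable",
        )
    if _lineage_matches(expected, taxonomy.get(call.lfs_mag_id, "")):
        return LFSCall(call.sample_id, call.lfs_mag_id, "verified")
    for other in sorted(fungal_candidates):
        if other == call.lfs_mag_id:
            continue
        if _lineage_matches(expected, taxonomy.get(other, "")):
            return LFSCall(
                call.sample_id, other, "reassigned",
                reason=f"declared {declared_name!r} matched {other!r}, not {call.lfs_mag_id!r}",
            )
    if alternate_declared_name is not None:
        alt_expected = name_to_lineage.get(alternate_declared_name)
        if alt_expected is not None and _lineage_matches(
            alt_expected, taxonomy.get(call.lfs_mag_id, "")
        ):
            return LFSCall(
                call.sample_id, call.lfs_mag_id, "name_corrected",
                reason=f"library name {alternate_declared_name!r} matches; "
                f"organism field {declared_name!r} does not",
            )
    return LFSCall(
        call.sample_id, call.lfs_mag_id, "misassigned",
        reason=f"no present fungal MAG matches declared {declared_name!r}",
    )


def build_dataset_cascade(
    sample_ids: Sequence[str],
    occ: OccurrenceMatrix,
    lfs_calls: Mapping[str, LFSCall],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label each sample with Dataset 1/2 membership and summarize counts.

    Dataset 1: samples with at least one present MAG. Dataset 2: Dataset 1
    samples whose LFS call is verified, reassigned or name-corrected.
    """
    n_present = occ.n_present()
    rows = []
    for sample_id in sample_ids:
        has_mag = bool(n_present.get(sample_id, 0) > 0)
        call = lfs_calls.get(sample_id)
        status = call.status if call is not None else "none_found"
        in_ds2 = has_mag and status in VERIFIED_STATUSES
        rows.append(
            {
                "sample_id": sample_id,
                "in_dataset1": int(has_mag),
                "in_dataset2": int(in_ds2),
                "lfs_status": status,
            }
        )
    labels = pd.DataFrame(rows)
    has_fungal = labels["lfs_status"].isin(VERIFIED_STATUSES | {"misassigned"})
    summary = {
        "n_total": len(labels),
        "n_no_mag": int((labels["in_dataset1"] == 0).sum()),
        "n_dataset1": int(labels["in_dataset1"].sum()),
        "n_with_fungal_mag": int((has_fungal & (labels["in_dataset1"] == 1)).sum()),
        "n_misassigned": int(
            ((labels["lfs_status"] == "misassigned") & (labels["in_dataset1"] == 1)).sum()
        ),
        "n_dataset2": int(labels["in_dataset2"].sum()),
    }
    return labels, summary
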