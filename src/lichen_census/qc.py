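"""MAG quality scoring, sample deduplication and ANI/AF dereplication.

Quality of a genome bin is summarized as completeness − 5 × contamination
(the standard MIMAG-style quality score); bins with a score ≥ 50 pass the
QS50 threshold, and bins at ≥95% completeness and ≤10% contamination are
"near complete" and eligible for functional annotation.

Dereplication collapses genome bins into species-level representatives at
an average nucleotide identity (ANI) / alignment fraction (AF) threshold
(95% ANI with 30% AF for prokaryotes, 40% AF for eukaryotes). The
clustering is greedy and centroid-based, mirroring dRep's score-ranked
representative choice: bins are visited in order of decreasing quality
score and either join the first established representative they match or
found a new cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "GenomeQuality",
    "ANIRecord",
    "DereplicationResult",
    "quality_score",
    "passes_qs50",
    "is_near_complete",
    "deduplicate_samples",
    "dereplicate",
]

DOMAINS = ("bacteria", "fungi", "algae")


@dataclass(frozen=True)
class GenomeQuality:
    mag_id: str
    completeness: float
    contamination: float
    domain: str = "bacteria"

    def __post_init__(self):
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"completeness {self.completeness} outside [0, 100] for {self.mag_id}")
        if self.contamination < 0:
            raise ValueError(f"negative contamination for {self.mag_id}")


@dataclass(frozen=True)
class ANIRecord:
    mag_a: str
    mag_b: str
    ani: float
    af: float

    def __post_init__(self):
        if not 0 <= self.ani <= 100:
            raise ValueError(f"ANI {self.ani} outside [0, 100] for ({self.mag_a}, {self.mag_b})")
        if not 0 <= self.af <= 100:
            raise ValueError(f"AF {self.af} outside [0, 100] for ({self.mag_a}, {self.mag_b})")


@dataclass
class DereplicationResult:
    clusters: dict[str, list[str]]  # representative -> members (incl. itself)
    species_table: pd.DataFrame = field(repr=False)

    @property
    def representatives(self) -> list[str]:
        return list(self.clusters)

    def member_to_representative(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters.items() for m in members}


def quality_score(q: GenomeQuality) -> float:
    """completeness − 5 × contamination."""
    return q.completeness - 5.0 * q.contamination


def passes_qs50(q: GenomeQuality) -> bool:
    """Quality score at or above 50 (inclusive)."""
    return quality_score(q) >= 50.0


def is_near_complete(
    q: GenomeQuality, min_completeness: float = 95.0, max_contamination: float = 10.0
) -> bool:
    """Completeness ≥ 95% and contamination ≤ 10% (bounds inclusive, configurable)."""
    return q.completeness >= min_completeness and q.contamination <= max_contamination


def deduplicate_samples(
    sample_ids: Sequence[str],
    duplicate_pairs: Iterable[tuple[str, str]],
    keep: Iterable[str] | None = None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Remove one sample of each identical pair from a manifest.

    Pairs that overlap (A=B, B=C) are resolved transitively: one sample is
    retained per connected component. Within a component the retained sample
    is the one flagged in ``keep`` (if exactly one member is flagged), else
    the lexicographically smallest id.

    Returns the retained ids (original manifest order) and a removal log of
    ``(kept, removed)`` tuples.
    """
    ids = list(sample_ids)
    id_set = set(ids)
    keep_set = set(keep or ())
    graph = nx.Graph()
    for a, b in duplicate_pairs:
        if a not in id_set or b not in id_set:
            missing = a if a not in id_set else b
            raise KeyError(f"duplicate pair references unknown sample id {missing!r}")
        graph.add_edge(a, b)
    removed: dict[str, str] = {}
    for component in nx.connected_components(graph):
        flagged = sorted(component & keep_set)
        kept = flagged[0] if len(flagged) == 1 else min(component)
        for member in component:
            if member != kept:
                removed[member] = kept
    retained = [s for s in ids if s not in removed]
    log = sorted((kept, gone) for gone, kept in removed.items())
    return retained, log


def _ani_lookup(records: Iterable[ANIRecord]) -> dict[frozenset[str], tuple[float, float]]:
    table: dict[frozenset[str], tuple[float, float]] = {}
    for rec in records:
        key = frozenset((rec.mag_a, rec.mag_b))
        if key in table:  # symmetric storage: keep max AF of the two directions
            ani, af = table[key]
            table[key] = (max(ani, rec.ani), max(af, rec.af))
        else:
            table[key] = (rec.ani, rec.af)
    return table


def dereplicate(
    mags: Sequence[GenomeQuality],
    ani: Iterable[ANIRecord],
    ani_min: float = 95.0,
    af_min: float = 30.0,
) -> DereplicationResult:
    """Greedy score-ranked clustering into species-level representatives.

    MAGs are sorted by descending quality score (ties broken by id); each MAG
    joins the first established representative with ANI ≥ ``ani_min`` and AF
    ≥ ``af_min``, else founds a new cluster. Missing pairs are treated as
    below threshold.
    """
    lookup = _ani_lookup(ani)
    order = sorted(mags, key=lambda q: (-quality_score(q), q.mag_id))
    clusters: dict[str, list[str]] = {}
    domains = {q.mag_id: q.domain for q in mags}
    for mag in order:
        assigned = False
        for rep in clusters:
            pair = lookup.get(frozenset((mag.mag_id, rep)))
            if pair is not None and pair[0] >= ani_min and pair[1] >= af_min:
                clusters[rep].append(mag.mag_id)
                assigned = True
                break
        if not assigned:
            clusters[mag.mag_id] = [mag.mag_id]
    rows = [
        {
            "representative": rep,
            "n_members": len(members),
            "domain": domains[rep],
        }
        for rep, members in clusters.items()
    ]
    species_table = pd.DataFrame(rows).sort_values("representative").reset_index(drop=True)
    return DereplicationResult(clusters=clusters, species_table=species_table)
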