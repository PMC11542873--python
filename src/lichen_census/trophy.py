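"""Vitamin prototrophy/auxotrophy classification and cross-feeding reports.

An organism is a *prototroph* for a B vitamin when at least one de novo
synthesis route is complete in its genome annotation — for biotin the ring
assembly module M00123 or its alternative M00950; for cobalamin M00122
(prokaryotic) or M00925 (eukaryotic). An organism with no complete synthesis
route but a complete salvage route (thiamine salvage M00899 or the thiMDE
gene trio) is *salvage-only*; a best route fraction strictly between 0 and
1 is *partial*; all routes absent is *auxotroph*. Because whether "complete"
tolerates a single missing gene is a judgment call, both the strict status
and the relaxed one-missing-gene status are computed side by side.

Cobalamin dependence is read off the methionine synthase genes: metE only →
independent, metE+metH → facultative, metH only → dependent.

Cross-feeding complementarity is assessed inside "highly complete"
metagenomes — those containing near-complete (≥95% complete, ≤10%
contaminated) MAGs of the lichen fungal symbiont, a photobiont and at least
one focal bacterium — by listing, for each vitamin the LFS cannot
synthesize, the co-occurring prototrophs that could provide it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .kegg import ModuleDefinition, completeness, partial_one_missing
from .occurrence import LFSCall, OccurrenceMatrix, VERIFIED_STATUSES
from .qc import GenomeQuality, is_near_complete

__all__ = [
    "VitaminRule",
    "GeneAlternative",
    "TrophyProfile",
    "ComplementarityReport",
    "load_rules",
    "classify_trophy",
    "classify_cobalamin_dependence",
    "select_highly_complete_metagenomes",
    "assess_complementarity",
    "trophy_prevalence",
]

STATUS_ORDER = ("auxotroph", "partial", "salvage_only", "prototroph")
PHOTOBIONT_ROLES = frozenset({"alga", "cyanobacterium"})


@dataclass(frozen=True)
class GeneAlternative:
    """A named KO conjunction standing in for a module (e.g. thiMDE)."""

    name: str
    route: str  # "synthesis" | "salvage"
    kos: tuple[str, ...]

    def fraction(self, ko_set: set[str]) -> float:
        if not self.kos:
            return 0.0
        return sum(k in ko_set for k in self.kos) / len(self.kos)


@dataclass(frozen=True)
class VitaminRule:
    vitamin: str
    synthesis_modules: tuple[str, ...] = ()
    salvage_modules: tuple[str, ...] = ()
    gene_alternatives: tuple[GeneAlternative, ...] = ()

    def __post_init__(self):
        if not (self.synthesis_modules or self.salvage_modules or self.gene_alternatives):
            raise ValueError(f"vitamin rule {self.vitamin!r} has no qualifying route")


@dataclass
class TrophyProfile:
    genome_id: str
    role: str = "bacterium"
    status: dict[str, str] = field(default_factory=dict)
    status_relaxed: dict[str, str] = field(default_factory=dict)
    fraction: dict[str, float] = field(default_factory=dict)
    mete_present: bool = False
    meth_present: bool = False
    cobalamin_dependence: str = "unknown"


@dataclass
class ComplementarityReport:
    sample_id: str
    qualifying: bool
    lfs_mag_id: str | None = None
    vitamins: dict[str, dict] = field(default_factory=dict)
    # per vitamin: lfs_status, providers [(mag, role)], partial_providers, complemented


def load_rules(path) -> tuple[list[VitaminRule], dict[str, str]]:
    """Read vitamin rules and screening genes from a YAML file.

    Returns the rule list and a mapping of screening gene name (metE, metH)
    to KO id.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    rules = []
    for vitamin, spec in raw.get("vitamins", {}).items():
        alternatives = tuple(
            GeneAlternative(name=name, route=alt["route"], kos=tuple(alt["kos"]))
            for name, alt in (spec.get("gene_alternatives") or {}).items()
        )
        rules.append(
            VitaminRule(
                vitamin=vitamin,
                synthesis_modules=tuple(spec.get("synthesis_modules") or ()),
                salvage_modules=tuple(spec.get("salvage_modules") or ()),
                gene_alternatives=alternatives,
            )
        )
    genes = dict(raw.get("genes", {}))
    return rules, genes


def _route_stats(
    module_ids: Sequence[str],
    alternatives: Sequence[GeneAlternative],
    ko_set: set[str],
    definitions: Mapping[str, ModuleDefinition],
) -> tuple[bool, bool, float]:
    """(any complete, any complete allowing one missing KO, best fraction)."""
    complete = relaxed = False
    best = 0.0
    for module_id in module_ids:
        if module_id not in definitions:
            raise KeyError(f"module definition {module_id} is missing")
        result = completeness(definitions[module_id], ko_set)
        best = max(best, result.fraction)
        complete = complete or result.complete
        relaxed = relaxed or result.complete or result.partial_one_missing
    for alt in alternatives:
        frac = alt.fraction(ko_set)
        best = max(best, frac)
        complete = complete or frac == 1.0
        relaxed = relaxed or frac == 1.0 or (
            len(alt.kos) > 1 and frac >= (len(alt.kos) - 1) / len(alt.kos)
        )
    return complete, relaxed, best


def _status(
    synth_complete: bool, salvage_complete: bool, best_fraction: float
) -> str:
    if synth_complete:
        return "prototroph"
    if salvage_complete:
        return "salvage_only"
    if 0.0 < best_fraction < 1.0:
        return "partial"
    return "auxotroph"


def classify_trophy(
    genome_id: str,
    ko_set: set[str] | frozenset[str],
    rules: Sequence[VitaminRule],
    definitions: Mapping[str, ModuleDefinition],
    genes: Mapping[str, str] | None = None,
    role: str = "bacterium",
) -> TrophyProfile:
    """Per-vitamin trophy status of one genome from its KO annotations."""
    ko_set = set(ko_set)
    profile = TrophyProfile(genome_id=genome_id, role=role)
    for rule in rules:
        synth_alts = [a for a in rule.gene_alternatives if a.route == "synthesis"]
        salv_alts = [a for a in rule.gene_alternatives if a.route == "salvage"]
        s_complete, s_relaxed, s_best = _route_stats(
            rule.synthesis_modules, synth_alts, ko_set, definitions
        )
        v_complete, v_relaxed, v_best = _route_stats(
            rule.salvage_modules, salv_alts, ko_set, definitions
        )
        best = max(s_best, v_best)
        profile.status[rule.vitamin] = _status(s_complete, v_complete, best)
        profile.status_relaxed[rule.vitamin] = _status(s_relaxed, v_relaxed, best)
        profile.fraction[rule.vitamin] = best
    genes = genes or {}
    if "metE" in genes:
        profile.mete_present = genes["metE"] in ko_set
    if "metH" in genes:
        profile.meth_present = genes["metH"] in ko_set
    profile.cobalamin_dependence = classify_cobalamin_dependence(
        profile.mete_present, profile.meth_present
    )
    return profile


def classify_cobalamin_dependence(mete: bool, meth: bool) -> str:
    """metE only → independent; both → facultative; metH only → dependent."""
    if mete and meth:
        return "facultative"
    if mete:
        return "independent"
    if meth:
        return "dependent"
    return "unknown"


def select_highly_complete_metagenomes(
    occ: OccurrenceMatrix,
    lfs_calls: Mapping[str, LFSCall],
    roles: Mapping[str, str],
    quality: Mapping[str, GenomeQuality],
    focal_bacteria: Sequence[str] | None = None,
    min_completeness: float = 95.0,
    max_contamination: float = 10.0,
) -> list[str]:
    """Samples containing near-complete MAGs of LFS, photobiont and a bacterium.

    The LFS must be the sample's verified LFS call; the photobiont may be an
    alga or a cyanobacterium; the bacterium must come from ``focal_bacteria``
    when a focal list is given. All three MAGs must be present (occurrence)
    and near complete.
    """
    focal = set(focal_bacteria) if focal_bacteria is not None else None

    def near(mag_id: str) -> bool:
        q = quality.get(mag_id)
        return q is not None and is_near_complete(q, min_completeness, max_contamination)

    qualifying = []
    for sample_id in occ.samples:
        call = lfs_calls.get(sample_id)
        if call is None or call.status not in VERIFIED_STATUSES:
            continue
        present = set(occ.present_species(sample_id))
        if call.lfs_mag_id not in present or not near(call.lfs_mag_id):
            continue
        has_photobiont = any(
            roles.get(m) in PHOTOBIONT_ROLES and near(m) for m in present
        )
        has_bacterium = any(
            roles.get(m) == "bacterium" and (focal is None or m in focal) and near(m)
            for m in present
        )
        if has_photobiont and has_bacterium:
            qualifying.append(sample_id)
    return qualifying


def assess_complementarity(
    sample_id: str,
    lfs_mag_id: str,
    profiles: Mapping[str, TrophyProfile],
    relaxed: bool = False,
) -> ComplementarityReport:
    """Who could feed the fungus: providers for each vitamin the LFS lacks.

    ``profiles`` covers the present near-complete MAGs of the sample. For
    each vitamin where the LFS is auxotrophic or salvage-only, co-occurring
    prototrophs are listed as providers (partial-pathway organisms are
    reported separately and never count as complementing).
    """
    if lfs_mag_id not in profiles:
        raise KeyError(f"no trophy profile for LFS MAG {lfs_mag_id!r} in sample {sample_id!r}")
    lfs = profiles[lfs_mag_id]
    status_of = (lambda p: p.status_relaxed) if relaxed else (lambda p: p.status)
    report = ComplementarityReport(sample_id=sample_id, qualifying=True, lfs_mag_id=lfs_mag_id)
    for vitamin, lfs_status in status_of(lfs).items():
        if lfs_status not in ("auxotroph", "salvage_only"):
            continue
        providers = []
        partial_providers = []
        for mag_id, profile in sorted(profiles.items()):
            if mag_id == lfs_mag_id:
                continue
            status = status_of(profile).get(vitamin)
            if status == "prototroph":
                providers.append((mag_id, profile.role))
            elif status in ("partial", "salvage_only"):
                partial_providers.append((mag_id, profile.role))
        report.vitamins[vitamin] = {
            "lfs_status": lfs_status,
            "providers": providers,
            "partial_providers": partial_providers,
            "complemented": bool(providers),
        }
    return report


def trophy_prevalence(
    profiles: Sequence[TrophyProfile],
    vitamin: str,
    status: str = "prototroph",
    relaxed: bool = False,
) -> tuple[int, int, int]:
    """Percent of profiles with the given status for a vitamin.

    Returns (integer percent rounded half away from zero, count, total).
    """
    pool = list(profiles)
    if not pool:
        raise ValueError("empty profile subset")
    getter = (lambda p: p.status_relaxed) if relaxed else (lambda p: p.status)
    count = sum(getter(p).get(vitamin) == status for p in pool)
    from .census import prevalence_counts

    return prevalence_counts(count, len(pool)), count, len(pool)
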