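"""Synthetic lichen-metagenome communities with known ground truth.

The generator emulates the statistical structure the downstream census
assumes: each sample is a community of one dominant lichen fungal symbiont
(LFS), a photobiont (green alga and/or cyanobacterium), an occasional
low-abundance basidiomycete yeast, and a handful of bacteria, sequenced to
a total depth drawn log-uniformly across six decades. Per-organism coverage
follows the Lander–Waterman model: with per-base depth

    c = total_depth_bp × mass_fraction / genome_size,

breadth of coverage is 1 − exp(−c_eff) where effective depth
c_eff = c / strain_multiplicity^penalty discounts the assembly ambiguity
introduced by mixtures of closely related strains. SSU rRNA detection in
raw reads is a Poisson draw over reads overlapping the multicopy rRNA loci;
detection in the assembly additionally requires the rRNA locus to be
assemblable (effective locus depth ≥ 1). Because rRNA loci are multicopy,
rRNA screening detects organisms well below the depth needed to recover
their MAG — the ordering the census is designed to expose.

The emitted bundle carries every input table the pipeline consumes plus a
ground-truth table, and is byte-identical under a fixed seed.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OrganismSpec",
    "SampleSpec",
    "SimulationConfig",
    "SimulatedBundle",
    "depth_for_organism",
    "breadth_from_depth",
    "rrna_detected",
    "default_roster",
    "generate_bundle",
    "write_bundle",
    "load_bundle",
    "synthetic_definitions",
    "synthetic_rules_path",
]

ROLES = ("LFS", "alga", "cyanobacterium", "yeast", "bacterium")
VITAMINS = ("biotin", "thiamine", "cobalamin")

BUNDLE_TABLES = (
    "coverage",
    "quality",
    "taxonomy",
    "ko",
    "rrna",
    "manifest",
    "ani",
    "truth",
)


@dataclass(frozen=True)
class OrganismSpec:
    organism_id: str
    role: str
    lineage: str  # 7-rank, semicolon-separated
    genome_size: float  # bp
    rrna_copies: int
    rrna_length: float  # bp
    mass_fraction: float
    strain_multiplicity: int = 1
    ko_set: frozenset[str] = frozenset()
    completeness_pct: float = 95.0
    contamination_pct: float = 1.0
    trophy: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.organism_id}")
        if self.genome_size <= 0:
            raise ValueError(f"genome_size must be positive for {self.organism_id}")
        if not 0 <= self.mass_fraction <= 1:
            raise ValueError(f"mass_fraction outside [0, 1] for {self.organism_id}")
        if self.strain_multiplicity < 1:
            raise ValueError(f"strain_multiplicity < 1 for {self.organism_id}")
        if self.rrna_copies < 0:
            raise ValueError(f"negative rrna_copies for {self.organism_id}")
        if self.rrna_length >= self.genome_size:
            raise ValueError(f"rrna_length must be below genome_size for {self.organism_id}")

    @property
    def genus(self) -> str:
        return self.lineage.split(";")[5].strip()


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    declared_lfs_name: str
    total_depth_bp: float
    read_length: float
    organisms: tuple[OrganismSpec, ...]
    duplicate_of: str | None = None
    misidentified: bool = False

    def __post_init__(self):
        if self.total_depth_bp <= 0:
            raise ValueError(f"total_depth_bp must be positive for {self.sample_id}")
        n_lfs = sum(o.role == "LFS" for o in self.organisms)
        if n_lfs != 1:
            raise ValueError(f"sample {self.sample_id} has {n_lfs} LFS organisms, expected 1")
        ids = [o.organism_id for o in self.organisms]
        if len(ids) != len(set(ids)):
            raise ValueError(f"conflicting organism ids in sample {self.sample_id}")
        total = sum(o.mass_fraction for o in self.organisms)
        if total > 1 + 1e-9:
            raise ValueError(f"mass fractions sum to {total:.3f} > 1 in sample {self.sample_id}")

    @property
    def lfs(self) -> OrganismSpec:
        return next(o for o in self.organisms if o.role == "LFS")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_samples: int = 100
    depth_range: tuple[float, float] = (1e6, 1e12)  # six decades, skewed coverage
    read_length: float = 150.0
    strain_penalty_exponent: float = 1.0
    min_rrna_reads: int = 1
    breadth_threshold: float = 0.5
    n_duplicate_pairs: int = 5
    n_misidentified: int = 4

    def __post_init__(self):
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must satisfy 0 < min ≤ max")
        if self.min_rrna_reads < 1:
            raise ValueError("min_rrna_reads must be ≥ 1")
        if self.strain_penalty_exponent < 0:
            raise ValueError("strain_penalty_exponent must be ≥ 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be ≥ 1")
        if self.n_duplicate_pairs * 2 > self.n_samples:
            raise ValueError("too many duplicate pairs for n_samples")


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    coverage: pd.DataFrame
    quality: pd.DataFrame
    taxonomy: pd.DataFrame
    ko: pd.DataFrame
    rrna: pd.DataFrame
    manifest: pd.DataFrame
    ani: pd.DataFrame
    truth: pd.DataFrame
    roster: tuple[SampleSpec, ...] = ()

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in BUNDLE_TABLES}


# ---------------------------------------------------------------------------
# coverage model
# ---------------------------------------------------------------------------


def depth_for_organism(sample: SampleSpec, org: OrganismSpec) -> float:
    """Per-base depth c = total_depth_bp × mass_fraction / genome_size."""
    if org not in sample.organisms:
        raise ValueError(f"{org.organism_id} does not belong to sample {sample.sample_id}")
    if org.genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return sample.total_depth_bp * org.mass_fraction / org.genome_size


def breadth_from_depth(
    c: float, strain_multiplicity: int = 1, penalty: float = 1.0
) -> float:
    """Lander–Waterman expected breadth 1 − exp(−c_eff).

    Strain mixtures divide the effective depth: c_eff = c / m^penalty.
    Monotone non-decreasing in c, non-increasing in multiplicity, in [0, 1].
    """
    if c < 0:
        raise ValueError("depth must be ≥ 0")
    c_eff = c / float(strain_multiplicity) ** penalty
    return float(-np.expm1(-c_eff))


def rrna_detected(
    c: float,
    org: OrganismSpec,
    read_length: float,
    min_reads: int,
    rng: np.random.Generator,
    penalty: float = 1.0,
) -> tuple[bool, bool]:
    """Draw SSU-rRNA detection flags for the read tier and the assembly tier.

    The number of reads overlapping an rRNA locus is Poisson with mean

        λ = (c × G / L) × copies × (rrna_length + L − 1) / G,

    i.e. reads from the organism times the chance each overlaps one of the
    ``copies`` rRNA loci. Read-tier detection requires ≥ ``min_reads`` such
    reads. Assembly-tier detection additionally requires the multicopy rRNA
    locus to be assemblable, gated at effective locus depth
    c_eff × copies ≥ 1 — so assembly-tier implies read-tier, and for
    multicopy loci the assembly tier remains more sensitive than whole-MAG
    recovery.
    """
    if c < 0:
        raise ValueError("depth must be ≥ 0")
    if org.rrna_copies == 0 or c == 0:
        return False, False
    lam = c * org.rrna_copies * (org.rrna_length + read_length - 1.0) / read_length
    n = int(rng.poisson(min(lam, 1e12)))
    read_tier = n >= min_reads
    c_eff = c / float(org.strain_multiplicity) ** penalty
    assembly_tier = read_tier and (c_eff * org.rrna_copies >= 1.0)
    return read_tier, assembly_tier


# ---------------------------------------------------------------------------
# organism pool (the study conditions)
# ---------------------------------------------------------------------------

_MB = 1e6

# genus, family, order, class, phylum for the fixed species pool
_LFS_GENERA = [
    ("Cladonia", "Cladoniaceae", "Lecanorales", "Lecanoromycetes"),
    ("Lecanora", "Lecanoraceae", "Lecanorales", "Lecanoromycetes"),
    ("Rhizoplaca", "Lecanoraceae", "Lecanorales", "Lecanoromycetes"),
    ("Usnea", "Parmeliaceae", "Lecanorales", "Lecanoromycetes"),
    ("Letharia", "Parmeliaceae", "Lecanorales", "Lecanoromycetes"),
    ("Peltigera", "Peltigeraceae", "Peltigerales", "Lecanoromycetes"),
    ("Lobaria", "Lobariaceae", "Peltigerales", "Lecanoromycetes"),
    ("Umbilicaria", "Umbilicariaceae", "Umbilicariales", "Lecanoromycetes"),
]

_BACTERIA = [
    # genus, family, phylum, weight (sampling propensity per sample)
    ("Lichenihabitans", "Beijerinckiaceae", "Proteobacteria", 0.75),
    ("RH-AL1", "Beijerinckiaceae", "Proteobacteria", 0.35),
    ("LMUY01", "Acetobacteraceae", "Proteobacteria", 0.55),
    ("CAHJXG01", "Acetobacteraceae", "Proteobacteria", 0.55),
    ("Lichenicoccus", "Acetobacteraceae", "Proteobacteria", 0.40),
    ("Lichenicola", "Acetobacteraceae", "Proteobacteria", 0.35),
    ("Acidisphaera", "Acetobacteraceae", "Proteobacteria", 0.30),
    ("Sphingomonas", "Sphingomonadaceae", "Proteobacteria", 0.45),
    ("Novosphingobium", "Sphingomonadaceae", "Proteobacteria", 0.25),
    ("Terriglobus", "Acidobacteriaceae", "Acidobacteriota", 0.45),
    ("Granulicella", "Acidobacteriaceae", "Acidobacteriota", 0.40),
    ("Edaphobacter", "Acidobacteriaceae", "Acidobacteriota", 0.30),
    ("CAHJWO01", "Verrucomicrobiota fam.", "Verrucomicrobiota", 0.25),
    ("Jatrophihabitans", "Frankiaceae", "Actinobacteriota", 0.15),
    ("Hymenobacter", "Hymenobacteraceae", "Bacteroidota", 0.15),
    ("Deinococcus", "Deinococcaceae", "Deinococcota", 0.10),
]


def _lineage(domain, phylum, klass, order, family, genus, species) -> str:
    return ";".join([domain, phylum, klass, order, family, genus, species])


def _synthetic_routes() -> dict[str, dict[str, list[list[list[str]]]]]:
    """Per-vitamin routes of the synthetic rules as ordered per-block KO lists.

    Synthesis and salvage routes use disjoint KO pools (and vitamins do not
    share KOs), so a planted status for one vitamin never disturbs another.
    """
    return {
        "biotin": {
            "synthesis": [
                [["K90101"], ["K90102"], ["K90103"], ["K90104"]],  # M00123
                [["K90111"], ["K90112"], ["K90114"]],  # M00950 (one alternative arm)
            ],
            "salvage": [],
        },
        "thiamine": {
            "synthesis": [[["K90211"], ["K90212", "K90213"], ["K90214"], ["K90215"]]],
            "salvage": [
                [["K90201"], ["K90202"], ["K90203"]],  # M00899 (one alternative arm)
                [["K90221"], ["K90222"], ["K90223"]],  # thiMDE
            ],
        },
        "cobalamin": {
            "synthesis": [
                [[f"K903{i:02d}"] for i in range(1, 8)],  # M00122
                [[f"K903{i:02d}"] for i in range(11, 22)],  # M00925
            ],
            "salvage": [],
        },
    }


def _ko_set_for(statuses: dict[str, str], mete: bool, meth: bool) -> frozenset[str]:
    routes = _synthetic_routes()
    kos: set[str] = set()
    for vitamin, status in statuses.items():
        spec = routes[vitamin]
        if status == "prototroph":
            kos |= {k for block in spec["synthesis"][0] for k in block}
        elif status == "salvage_only":
            kos |= {k for block in spec["salvage"][0] for k in block}
        elif status == "partial":
            route = spec["synthesis"][0] if spec["synthesis"] else spec["salvage"][0]
            n = max(1, len(route) // 2)
            if n == len(route):
                n -= 1
            kos |= {k for block in route[:n] for k in block}
        elif status != "auxotroph":
            raise ValueError(f"unknown planted status {status!r}")
    if mete:
        kos.add("K90401")
    if meth:
        kos.add("K90402")
    return frozenset(kos)


def _build_pool(rng: np.random.Generator) -> dict[str, list[OrganismSpec]]:
    """Fixed species pool: LFS fungi, algae, cyanobacteria, yeasts, bacteria.

    mass_fraction on pool entries is a per-sample template re-drawn at
    sample-assembly time; here it is left at 0.
    """
    pool: dict[str, list[OrganismSpec]] = {r: [] for r in ROLES}
    for i, (genus, family, order, klass) in enumerate(_LFS_GENERA):
        # most LFSs: biotin auxotrophs; thiamine salvage-only in a third,
        # partial otherwise; cobalamin absent throughout
        thi = "salvage_only" if i % 3 == 0 else ("partial" if i % 3 == 1 else "auxotroph")
        statuses = {"biotin": "auxotroph", "thiamine": thi, "cobalamin": "auxotroph"}
        pool["LFS"].append(
            OrganismSpec(
                organism_id=f"LFS_{genus}",
                role="LFS",
                lineage=_lineage("Fungi", "Ascomycota", klass, order, family, genus, f"{genus} sp{i}"),
                genome_size=float(rng.uniform(28, 45)) * _MB,
                rrna_copies=int(rng.integers(40, 120)),
                rrna_length=1800.0,
                mass_fraction=0.0,
                strain_multiplicity=1,
                ko_set=_ko_set_for(statuses, mete=False, meth=True),
                completeness_pct=float(rng.uniform(95.5, 99.5)) if i < 6 else float(rng.uniform(85, 94)),
                contamination_pct=float(rng.uniform(0.2, 4.0)),
                trophy=statuses,
            )
        )
    algal = [
        ("Trebouxia", "partial", "prototroph", 2),
        ("Coccomyxa", "prototroph", "prototroph", 1),
        ("Elliptochloris", "partial", "salvage_only", 2),
    ]
    for i, (genus, biotin, thiamine, mult) in enumerate(algal):
        statuses = {"biotin": biotin, "thiamine": thiamine, "cobalamin": "partial"}
        both = i % 2 == 0  # metE+metH (facultative) vs metE only
        pool["alga"].append(
            OrganismSpec(
                organism_id=f"ALG_{genus}",
                role="alga",
                lineage=_lineage(
                    "Eukaryota", "Chlorophyta", "Trebouxiophyceae", "Trebouxiales",
                    f"{genus}ceae", genus, f"{genus} sp{i}",
                ),
                genome_size=float(rng.uniform(50, 70)) * _MB,
                rrna_copies=int(rng.integers(100, 400)),
                rrna_length=1800.0,
                mass_fraction=0.0,
                strain_multiplicity=mult,
                ko_set=_ko_set_for(statuses, mete=True, meth=both),
                completeness_pct=float(rng.uniform(95.5, 99.0)),
                contamination_pct=float(rng.uniform(0.5, 5.0)),
                trophy=statuses,
            )
        )
    for i, genus in enumerate(["Nostoc", "Scytonema"]):
        statuses = {"biotin": "prototroph", "thiamine": "prototroph", "cobalamin": "prototroph"}
        pool["cyanobacterium"].append(
            OrganismSpec(
                organism_id=f"CYA_{genus}",
                role="cyanobacterium",
                lineage=_lineage(
                    "Bacteria", "Cyanobacteria", "Cyanophyceae", "Nostocales",
                    "Nostocaceae", genus, f"{genus} sp{i}",
                ),
                genome_size=float(rng.uniform(6, 9)) * _MB,
                rrna_copies=int(rng.integers(3, 6)),
                rrna_length=1550.0,
                mass_fraction=0.0,
                strain_multiplicity=1,
                ko_set=_ko_set_for(statuses, mete=False, meth=True),
                completeness_pct=float(rng.uniform(95.5, 99.5)),
                contamination_pct=float(rng.uniform(0.2, 3.0)),
                trophy=statuses,
            )
        )
    yeasts = [
        ("Tremella", "Tremellomycetes", "Tremellales", "Tremellaceae"),
        ("Cyphobasidium", "Cystobasidiomycetes", "Cystobasidiales", "Cystobasidiaceae"),
    ]
    for i, (genus, klass, order, family) in enumerate(yeasts):
        statuses = {"biotin": "partial", "thiamine": "salvage_only", "cobalamin": "auxotroph"}
        pool["yeast"].append(
            OrganismSpec(
                organism_id=f"YST_{genus}",
                role="yeast",
                lineage=_lineage("Fungi", "Basidiomycota", klass, order, family, genus, f"{genus} sp{i}"),
                genome_size=float(rng.uniform(18, 25)) * _MB,
                rrna_copies=int(rng.integers(40, 80)),
                rrna_length=1800.0,
                mass_fraction=0.0,
                strain_multiplicity=1,
                ko_set=_ko_set_for(statuses, mete=False, meth=False),
                completeness_pct=float(rng.uniform(88, 97)),
                contamination_pct=float(rng.uniform(0.5, 6.0)),
                trophy=statuses,
            )
        )
    n_bact = len(_BACTERIA)
    # plant biotin prototrophy in ~43% of bacteria, thiamine salvage in the
    # acetic-acid/beijerinckia fraction, cobalamin synthesis in a few
    biotin_proto = set(rng.choice(n_bact, size=round(0.43 * n_bact), replace=False).tolist())
    for i, (genus, family, phylum, _w) in enumerate(_BACTERIA):
        thi = "salvage_only" if family in ("Acetobacteraceae", "Beijerinckiaceae") and i % 2 == 0 else "auxotroph"
        statuses = {
            "biotin": "prototroph" if i in biotin_proto else ("partial" if i % 4 == 0 else "auxotroph"),
            "thiamine": thi,
            "cobalamin": "prototroph" if genus in ("LMUY01", "Sphingomonas", "CAHJXG01") else "auxotroph",
        }
        pool["bacterium"].append(
            OrganismSpec(
                organism_id=f"BAC_{genus}",
                role="bacterium",
                lineage=_lineage(
                    "Bacteria", phylum, f"{phylum} class", f"{family} order", family, genus, f"{genus} sp{i}",
                ),
                genome_size=float(rng.uniform(3, 7)) * _MB,
                rrna_copies=int(rng.integers(2, 6)),
                rrna_length=1550.0,
                mass_fraction=0.0,
                strain_multiplicity=1,
                ko_set=_ko_set_for(statuses, mete=False, meth=i % 3 == 0),
                completeness_pct=float(rng.uniform(95.5, 99.8)) if i % 4 != 3 else float(rng.uniform(70, 94)),
                contamination_pct=float(rng.uniform(0.1, 3.5)),
                trophy=statuses,
            )
        )
    return pool


def default_roster(config: SimulationConfig) -> tuple[SampleSpec, ...]:
    """Assemble the default study-condition roster for a configuration.

    Each sample holds one LFS (≈45–70% of sample DNA), a green alga in most
    samples and/or a cyanobacterium in a minority, a basidiomycete yeast at
    ≈1:100 of the LFS depth in half the samples, and 4–10 bacteria sharing
    5–25% of the DNA. Sequencing depths are log-uniform over the configured
    range. A configured number of duplicate pairs and misidentified samples
    (declared lichen name inconsistent with the LFS lineage) are planted.
    """
    rng = np.random.default_rng(config.seed)
    pool = _build_pool(rng)
    bact_weights = np.array([w for *_x, w in _BACTERIA])
    n_unique = config.n_samples - config.n_duplicate_pairs
    samples: list[SampleSpec] = []
    lfs_genera = [o.genus for o in pool["LFS"]]
    for i in range(n_unique):
        sample_id = f"S{i:04d}"
        depth = float(
            10 ** rng.uniform(np.log10(config.depth_range[0]), np.log10(config.depth_range[1]))
        )
        lfs = pool["LFS"][int(rng.integers(len(pool["LFS"])))]
        organisms: list[OrganismSpec] = []
        f_lfs = float(rng.uniform(0.45, 0.70))
        organisms.append(replace(lfs, mass_fraction=f_lfs))
        cyano_lichen = rng.random() < 0.15
        if not cyano_lichen:
            alga = pool["alga"][int(rng.integers(len(pool["alga"])))]
            organisms.append(replace(alga, mass_fraction=float(rng.uniform(0.02, 0.10))))
            if rng.random() < 0.15:  # tripartite
                cyano = pool["cyanobacterium"][int(rng.integers(2))]
                organisms.append(replace(cyano, mass_fraction=float(rng.uniform(0.005, 0.03))))
        else:
            cyano = pool["cyanobacterium"][int(rng.integers(2))]
            organisms.append(replace(cyano, mass_fraction=float(rng.uniform(0.03, 0.12))))
        if rng.random() < 0.5:
            yeast = pool["yeast"][int(rng.integers(2))]
            # ≈1:100 depth-of-coverage ratio to the LFS
            f_yeast = 0.01 * f_lfs * yeast.genome_size / lfs.genome_size
            organisms.append(replace(yeast, mass_fraction=float(f_yeast)))
        n_bact = int(rng.integers(4, 11))
        chosen = rng.choice(
            len(_BACTERIA), size=n_bact, replace=False, p=bact_weights / bact_weights.sum()
        )
        f_bact_total = float(rng.uniform(0.05, 0.25))
        shares = rng.dirichlet(np.ones(n_bact) * 0.8) * f_bact_total
        for j, idx in enumerate(sorted(chosen.tolist())):
            organisms.append(replace(pool["bacterium"][idx], mass_fraction=float(shares[j])))
        total = sum(o.mass_fraction for o in organisms)
        if total > 0.98:
            organisms = [replace(o, mass_fraction=o.mass_fraction * 0.98 / total) for o in organisms]
        samples.append(
            SampleSpec(
                sample_id=sample_id,
                declared_lfs_name=lfs.genus,
                total_depth_bp=depth,
                read_length=config.read_length,
                organisms=tuple(organisms),
            )
        )
    # misidentify: declared name points at a different LFS genus
    mis_idx = rng.choice(n_unique, size=min(config.n_misidentified, n_unique), replace=False)
    for idx in sorted(mis_idx.tolist()):
        s = samples[idx]
        wrong = [g for g in lfs_genera if g != s.lfs.genus]
        name = wrong[int(rng.integers(len(wrong)))]
        samples[idx] = replace(s, declared_lfs_name=name, misidentified=True)
    # duplicates: re-deposited copies of existing samples
    dup_sources = rng.choice(n_unique, size=config.n_duplicate_pairs, replace=False)
    for k, src in enumerate(sorted(dup_sources.tolist())):
        original = samples[src]
        samples.append(
            replace(original, sample_id=f"S{n_unique + k:04d}_dup", duplicate_of=original.sample_id)
        )
    return tuple(samples)


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------


def generate_bundle(
    config: SimulationConfig, roster: tuple[SampleSpec, ...] | None = None
) -> SimulatedBundle:
    """Emit the full set of synthetic input tables plus ground truth.

    Deterministic under the config seed; duplicate samples carry coverage
    and rRNA rows identical to their originals (only the sample id differs).
    """
    if roster is None:
        roster = default_roster(config)
    if not roster:
        raise ValueError("roster is empty")
    rng = np.random.default_rng(config.seed + 1)
    coverage_rows: dict[str, list[dict]] = {}
    rrna_rows: dict[str, list[dict]] = {}
    truth_rows: dict[str, list[dict]] = {}
    organisms: dict[str, OrganismSpec] = {}
    for sample in roster:
        for org in sample.organisms:
            prev = organisms.get(org.organism_id)
            if prev is not None and prev.lineage != org.lineage:
                raise ValueError(f"conflicting organism id {org.organism_id}")
            organisms[org.organism_id] = org
        if sample.duplicate_of is not None:
            continue
        cov, rrn, tru = [], [], []
        for org in sample.organisms:
            c = depth_for_organism(sample, org)
            breadth = breadth_from_depth(
                c, org.strain_multiplicity, config.strain_penalty_exponent
            )
            n_reads = int(round(c * org.genome_size / sample.read_length))
            read_tier, assembly_tier = rrna_detected(
                c, org, sample.read_length, config.min_rrna_reads, rng,
                penalty=config.strain_penalty_exponent,
            )
            if n_reads > 0:
                cov.append(
                    {
                        "sample_id": sample.sample_id,
                        "mag_id": org.organism_id,
                        "breadth": round(breadth, 6),
                        "n_reads": n_reads,
                        "read_length": sample.read_length,
                        "mag_length": org.genome_size,
                        "depth": round(n_reads * sample.read_length / org.genome_size, 6),
                    }
                )
            if read_tier:
                rrn.append(
                    {
                        "sample_id": sample.sample_id,
                        "mag_id": org.organism_id,
                        "assembly_rrna": int(assembly_tier),
                        "read_rrna": int(read_tier),
                    }
                )
            tru.append(
                {
                    "sample_id": sample.sample_id,
                    "organism_id": org.organism_id,
                    "role": org.role,
                    "mass_fraction": org.mass_fraction,
                    "depth": c,
                    "breadth": breadth,
                    "present": int(breadth >= config.breadth_threshold),
                    "rrna_read": int(read_tier),
                    "rrna_assembly": int(assembly_tier),
                    "misidentified": int(sample.misidentified),
                }
            )
        coverage_rows[sample.sample_id] = cov
        rrna_rows[sample.sample_id] = rrn
        truth_rows[sample.sample_id] = tru
    # duplicates copy their original's rows byte-identically
    for sample in roster:
        if sample.duplicate_of is None:
            continue
        for store in (coverage_rows, rrna_rows, truth_rows):
            copied = [dict(row, sample_id=sample.sample_id) for row in store[sample.duplicate_of]]
            store[sample.sample_id] = copied
    coverage = pd.DataFrame(
        [r for s in roster for r in coverage_rows[s.sample_id]],
        columns=["sample_id", "mag_id", "breadth", "n_reads", "read_length", "mag_length", "depth"],
    )
    rrna = pd.DataFrame(
        [r for s in roster for r in rrna_rows[s.sample_id]],
        columns=["sample_id", "mag_id", "assembly_rrna", "read_rrna"],
    )
    truth = pd.DataFrame([r for s in roster for r in truth_rows[s.sample_id]])
    org_list = sorted(organisms.values(), key=lambda o: o.organism_id)
    quality = pd.DataFrame(
        {
            "mag_id": [o.organism_id for o in org_list],
            "completeness": [round(o.completeness_pct, 2) for o in org_list],
            "contamination": [round(o.contamination_pct, 2) for o in org_list],
            "domain": [
                "bacteria" if o.role in ("bacterium", "cyanobacterium")
                else ("algae" if o.role == "alga" else "fungi")
                for o in org_list
            ],
            "role": [o.role for o in org_list],
        }
    )
    taxonomy = pd.DataFrame(
        [
            dict(
                mag_id=o.organism_id,
                **dict(zip(("domain", "phylum", "class", "order", "family", "genus", "species"),
                           [r.strip() for r in o.lineage.split(";")])),
            )
            for o in org_list
        ]
    )
    ko = pd.DataFrame(
        [
            {"genome_id": o.organism_id, "ko": k}
            for o in org_list
            for k in sorted(o.ko_set)
        ],
        columns=["genome_id", "ko"],
    )
    manifest = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in roster],
            "declared_lfs_name": [s.declared_lfs_name for s in roster],
            "total_depth_bp": [s.total_depth_bp for s in roster],
            "read_length": [s.read_length for s in roster],
            "duplicate_of": [s.duplicate_of or "" for s in roster],
            "misidentified": [int(s.misidentified) for s in roster],
        }
    )
    ani = _pool_ani(org_list, rng)
    trophy_cols = pd.DataFrame(
        [
            {
                "organism_id": o.organism_id,
                "biotin_status": o.trophy.get("biotin", "auxotroph"),
                "thiamine_status": o.trophy.get("thiamine", "auxotroph"),
                "cobalamin_status": o.trophy.get("cobalamin", "auxotroph"),
                "mete": int("K90401" in o.ko_set),
                "meth": int("K90402" in o.ko_set),
            }
            for o in org_list
        ]
    )
    truth = truth.merge(trophy_cols, on="organism_id", how="left")
    return SimulatedBundle(
        config=config,
        coverage=coverage,
        quality=quality,
        taxonomy=taxonomy,
        ko=ko,
        rrna=rrna,
        manifest=manifest,
        ani=ani,
        truth=truth,
        roster=tuple(roster),
    )


def _pool_ani(org_list, rng: np.random.Generator) -> pd.DataFrame:
    """Pairwise ANI/AF for same-family organisms (all below species threshold:
    pool members are species representatives by construction)."""
    rows = []
    for i, a in enumerate(org_list):
        fam_a = a.lineage.split(";")[4]
        for b in org_list[i + 1 :]:
            if b.lineage.split(";")[4] != fam_a:
                continue
            same_genus = a.genus == b.genus
            ani = float(rng.uniform(88, 94)) if same_genus else float(rng.uniform(78, 86))
            af = float(rng.uniform(20, 60))
            rows.append(
                {
                    "mag_a": a.organism_id,
                    "mag_b": b.organism_id,
                    "ani": round(ani, 2),
                    "af": round(af, 2),
                }
            )
    return pd.DataFrame(rows, columns=["mag_a", "mag_b", "ani", "af"])


# ---------------------------------------------------------------------------
# bundle IO and packaged synthetic content
# ---------------------------------------------------------------------------


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> None:
    """Write all bundle tables as TSV files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in bundle.tables().items():
        frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


def load_bundle(indir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the TSV tables of a written bundle back into DataFrames."""
    indir = Path(indir)
    return {
        name: pd.read_csv(indir / f"{name}.tsv", sep="\t", keep_default_na=False,
                          na_values=[], dtype={"duplicate_of": str} if name == "manifest" else None)
        for name in BUNDLE_TABLES
    }


def synthetic_rules_path() -> Path:
    """Path of the packaged synthetic vitamin-rules file."""
    return Path(resources.files("lichen_census") / "data" / "synthetic_rules.yaml")


def synthetic_definitions():
    """Parsed synthetic module definitions shipped with the package."""
    from .kegg import parse_definition

    path = Path(resources.files("lichen_census") / "data" / "synthetic_modules.tsv")
    table = pd.read_csv(path, sep="\t")
    return {
        row.module_id: parse_definition(row.definition, module_id=row.module_id, name=row.name)
        for row in table.itertuples()
    }
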