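"""Frequency tabulation, prevalence rounding, detection tiers and networks."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from lichen_census.census import (
    build_cooccurrence,
    classify_detection_outcome,
    merge_detection_tiers,
    prevalence_counts,
    rank_and_select_top,
    round_half_away,
    tabulate_frequency,
    taxon_label,
)
from lichen_census.occurrence import OccurrenceMatrix
from lichen_census.simulate import SimulationConfig, OrganismSpec, rrna_detected

TAX = pd.DataFrame(
    {
        "domain": ["Bacteria"] * 4 + ["Eukaryota"],
        "phylum": ["Proteobacteria", "Proteobacteria", "Acidobacteriota", "Proteobacteria", "Chlorophyta"],
        "class": ["Alpha", "Alpha", "Acido", "Alpha", "Trebouxiophyceae"],
        "order": ["Rhizobiales", "Rhizobiales", "Acidobacteriales", "Acetobacterales", "Trebouxiales"],
        "family": ["Beijerinckiaceae", "Beijerinckiaceae", "Acidobacteriaceae", "Acetobacteraceae", "Trebouxiaceae"],
        "genus": ["Lichenihabitans", "Lichenihabitans", "Terriglobus", "", "Trebouxia"],
        "species": [f"sp{i}" for i in range(5)],
    },
    index=["m1", "m2", "m3", "m4", "m5"],
)


def _occ(incidence, samples=None, species=None):
    incidence = np.asarray(incidence, dtype=bool)
    samples = samples or [f"s{i}" for i in range(incidence.shape[0])]
    species = species or list(TAX.index[: incidence.shape[1]])
    return OccurrenceMatrix(samples, species, incidence)


# ---------------------------------------------------------------------------
# rounding and prevalence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n,d,pct",
    [
        (282, 674, 42),  # Proteobacteria share of bacterial lineages
        (153, 674, 23),  # Acidobacteriota share
        (59, 278, 21),   # Ulvophyceae in trebouxioid lichens
        (10, 23, 43),    # Ulvophyceae in cyanobacterial lichens
        (250, 674, 37),  # top-13 genera lineage share
        (62, 437, 14),   # metagenomes without a recoverable MAG
        (27, 63, 43),    # biotin prototrophy among annotated bacteria
        (374, 375, 100),
        (1, 375, 0),
    ],
)
def test_prevalence_reproduces_printed_percentages(n, d, pct):
    assert prevalence_counts(n, d) == pct


def test_round_half_away_convention():
    assert round_half_away(0.5) == 1
    assert round_half_away(2.5) == 3
    assert round_half_away(-0.5) == -1
    assert round_half_away(0.49) == 0


def test_prevalence_requires_positive_denominator():
    with pytest.raises(ValueError):
        prevalence_counts(1, 0)


# ---------------------------------------------------------------------------
# frequency tabulation
# ---------------------------------------------------------------------------


def test_genus_fallback_label():
    assert taxon_label(TAX.loc["m4"], "genus") == "Acetobacteraceae gen. sp."
    assert taxon_label(TAX.loc["m1"], "genus") == "Lichenihabitans"


def test_genus_occurrences_sum_over_member_species():
    # m1 occurs 3 times, m2 occurs 4 → genus total 7
    incidence = np.zeros((5, 5), dtype=bool)
    incidence[:3, 0] = True
    incidence[:4, 1] = True
    freq = tabulate_frequency(_occ(incidence), TAX, "genus")
    row = freq.set_index("taxon").loc["Lichenihabitans"]
    assert row["n_occurrences"] == 7
    assert row["n_lineages"] == 2


def test_family_conserves_species_occurrences():
    rng = np.random.default_rng(2)
    incidence = rng.random((6, 5)) < 0.4
    occ = _occ(incidence)
    species_freq = tabulate_frequency(occ, TAX, "species")
    family_freq = tabulate_frequency(occ, TAX, "family")
    per_family = {}
    for sp in occ.species:
        fam = TAX.loc[sp, "family"]
        n = int(species_freq.set_index("taxon").loc[TAX.loc[sp, "species"], "n_occurrences"])
        per_family[fam] = per_family.get(fam, 0) + n
    for fam, total in per_family.items():
        assert int(family_freq.set_index("taxon").loc[fam, "n_occurrences"]) == total


def test_unknown_level_errors():
    with pytest.raises(KeyError):
        tabulate_frequency(_occ(np.ones((1, 1))), TAX, "tribe")


def test_prevalence_invariant_to_permutation():
    rng = np.random.default_rng(4)
    incidence = rng.random((6, 5)) < 0.5
    occ = _occ(incidence)
    freq = tabulate_frequency(occ, TAX, "family").set_index("taxon")
    perm = rng.permutation(6)
    occ_perm = OccurrenceMatrix(
        [occ.samples[i] for i in perm], occ.species, occ.incidence[perm]
    )
    freq_perm = tabulate_frequency(occ_perm, TAX, "family").set_index("taxon")
    pd.testing.assert_frame_equal(freq, freq_perm)


def test_rank_and_select_top_shares_and_ties():
    freq = pd.DataFrame(
        {
            "taxon": ["b", "a", "c"],
            "level": "genus",
            "n_occurrences": [5, 5, 2],
            "n_lineages": [2, 1, 1],
        }
    )
    top, share = rank_and_select_top(freq, 2)
    assert list(top["taxon"]) == ["a", "b"]  # tie broken alphabetically
    assert share["pct_lineages"] == 75
    assert share["pct_occurrences"] == 83
    _all, share_all = rank_and_select_top(freq, 3)
    assert share_all["pct_lineages"] == share_all["pct_occurrences"] == 100


# ---------------------------------------------------------------------------
# detection tiers and outcomes
# ---------------------------------------------------------------------------


def test_merge_tiers_no_cross_tier_inference():
    occ = _occ([[True, False, False, False, False]])
    rrna = pd.DataFrame(columns=["sample_id", "taxon", "assembly_rrna", "read_rrna"])
    det = merge_detection_tiers(occ, rrna, TAX, "family").set_index(["sample_id", "taxon"])
    row = det.loc[("s0", "Beijerinckiaceae")]
    assert (row["mag"], row["assembly_rrna"], row["read_rrna"]) == (1, 0, 0)


def test_species_occurrence_rolls_up_to_family():
    """Roll-up oracle: family MAG tier = OR over member species occurrences."""
    rng = np.random.default_rng(9)
    incidence = rng.random((4, 5)) < 0.5
    occ = _occ(incidence)
    rrna = pd.DataFrame(columns=["sample_id", "taxon", "assembly_rrna", "read_rrna"])
    det = merge_detection_tiers(occ, rrna, TAX, "family").set_index(["sample_id", "taxon"])
    frame = occ.to_frame()
    for sample in occ.samples:
        for family in TAX["family"].unique():
            members = [m for m in occ.species if TAX.loc[m, "family"] == family]
            expected = bool(frame.loc[sample, members].any())
            assert bool(det.loc[(sample, family), "mag"]) == expected


def test_empty_rrna_table_gives_all_false_tiers():
    occ = _occ(np.ones((2, 5)))
    det = merge_detection_tiers(occ, pd.DataFrame(), TAX, "family")
    assert det["read_rrna"].sum() == 0 and det["assembly_rrna"].sum() == 0


@pytest.mark.parametrize(
    "mag,rrna,expected",
    [
        (True, True, "mag_and_rrna"),
        (True, False, "mag_only"),
        (False, True, "rrna_only"),
        (False, False, "not_detected"),
    ],
)
def test_classify_detection_outcome(mag, rrna, expected):
    assert classify_detection_outcome(mag, rrna) == expected


def test_rrna_only_share_falls_with_depth():
    """Among read-tier detections, the share lacking a MAG is non-increasing
    across depth deciles (the depth-dependence the census is built to show)."""
    rng = np.random.default_rng(21)
    org = OrganismSpec(
        organism_id="b",
        role="bacterium",
        lineage="Bacteria;p;c;o;f;g;s",
        genome_size=5e6,
        rrna_copies=3,
        rrna_length=1550,
        mass_fraction=0.02,
        strain_multiplicity=1,
    )
    depths = np.logspace(6.5, 10.5, 40)
    shares = []
    for depth in depths:
        c = depth * org.mass_fraction / org.genome_size
        mag = (1 - np.exp(-c)) >= 0.5
        detected = rrna_only = 0
        for _ in range(100):
            read, _asm = rrna_detected(c, org, 150, 1, rng)
            detected += read
            rrna_only += read and not mag
        if detected:
            shares.append(rrna_only / detected)
    deciles = np.array_split(np.array(shares), 5)
    means = [d.mean() for d in deciles if len(d)]
    assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# co-occurrence networks
# ---------------------------------------------------------------------------


def test_network_matches_pair_count_oracle():
    incidence = np.array(
        [
            [1, 1, 0, 1, 0],
            [1, 1, 1, 0, 0],
            [0, 1, 1, 1, 1],
        ],
        dtype=bool,
    )
    occ = _occ(incidence)
    graph = build_cooccurrence(occ, occ.species)
    frame = occ.to_frame()
    for a, b in itertools.combinations(occ.species, 2):
        expected = int((frame[a] & frame[b]).sum())
        if expected:
            assert graph[a][b]["weight"] == expected
        else:
            assert not graph.has_edge(a, b)
    assert all(not graph.has_edge(n, n) for n in graph.nodes)


def test_network_edge_weight_counts_shared_samples():
    incidence = np.zeros((6, 5), dtype=bool)
    incidence[:5, 0] = True
    incidence[:5, 1] = True
    graph = build_cooccurrence(_occ(incidence), ["m1", "m2"])
    assert graph["m1"]["m2"]["weight"] == 5


def test_network_omits_never_present_lineages():
    incidence = np.zeros((3, 5), dtype=bool)
    incidence[:, 0] = True
    graph = build_cooccurrence(_occ(incidence), ["m1", "m2"])
    assert "m2" not in graph.nodes
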