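"""Module-definition grammar and completeness engine, checked against an
independent string-splitting truth-table oracle."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from lichen_census.kegg import (
    ParseError,
    UnresolvedModuleError,
    block_present,
    completeness,
    parse_definition,
    partial_one_missing,
)

# ---------------------------------------------------------------------------
# independent oracle: recursive top-level splitting, no shared code with the
# parser
# ---------------------------------------------------------------------------


def _split_top(text: str, separators: str) -> list[str]:
    parts, depth, current = [], 0, ""
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch in separators and depth == 0:
            parts.append(current)
            current = ""
        else:
            current += ch
    parts.append(current)
    return parts


def _strip_parens(text: str) -> str:
    while text.startswith("(") and text.endswith(")"):
        depth = 0
        for i, ch in enumerate(text):
            depth += ch == "("
            depth -= ch == ")"
            if depth == 0 and i < len(text) - 1:
                return text
        text = text[1:-1]
    return text


def oracle_eval(text: str, kos: set[str]) -> bool:
    text = _strip_parens(text.strip())
    blocks = _split_top(text, " ")
    if len(blocks) > 1:
        return all(oracle_eval(b, kos) for b in blocks)
    alts = _split_top(text, ",")
    if len(alts) > 1:
        return any(oracle_eval(a, kos) for a in alts)
    # complex: '+' required, '-' optional; '--' is a literal gap
    if text == "--":
        return False
    units: list[tuple[str, str]] = []  # (sign, unit)
    depth, sign, current = 0, "+", ""
    i = 0
    while i < len(text):
        ch = text[i]
        depth += ch == "("
        depth -= ch == ")"
        if ch in "+-" and depth == 0:
            if ch == "-" and i + 1 < len(text) and text[i + 1] == "-" and not current:
                current = "--"  # the gap literal
                i += 2
                continue
            if current:
                units.append((sign, current))
            sign, current = ch, ""
        else:
            current += ch
        i += 1
    units.append((sign, current))
    if len(units) > 1 or units[0][0] == "-":
        required = [u for s, u in units if s == "+" and u != "--"]
        if not required:
            return True
        return all(oracle_eval(u, kos) for u in required)
    unit = units[0][1]
    if unit == "--":
        return False
    if unit.startswith("("):
        return oracle_eval(unit, kos)
    return unit in kos


def oracle_block_count(text: str) -> int:
    """Top-level blocks, excluding optional-only (leading '-', not '--') blocks."""
    blocks = _split_top(text.strip(), " ")
    return sum(1 for b in blocks if not (b.startswith("-") and not b.startswith("--")))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,n_blocks",
    [
        ("K00001 K00002", 2),
        ("(K00001,K00002) K00003", 2),
        ("K00001+K00002-K00003", 1),
        ("K00001", 1),
        ("(K00001 K00002) K00003", 2),
        ("-- K00001", 2),
    ],
)
def test_block_counts(text, n_blocks):
    module = parse_definition(text, "M99999")
    assert completeness(module, set()).n_blocks == oracle_block_count(text) == n_blocks


@pytest.mark.parametrize(
    "text",
    ["(K00001 K00002", "K00001+", "K00001,,K00002", "K00001 + K00002", "", "K1"],
)
def test_parse_errors_carry_position(text):
    with pytest.raises(ParseError) as err:
        parse_definition(text)
    assert "position" in str(err.value)


@pytest.mark.parametrize(
    "text",
    [
        "K00001 K00002",
        "(K00001,K00002) K00003",
        "K00001+K00002-K00003",
        "((K00001 K00002),K00003) K00004+K00005",
        "K00001 -K00002 (K00003,K00004+K00005)",
        "-- K00001",
        "M00001 K00002",
    ],
)
def test_serialization_round_trip_is_fixed_point(text):
    once = parse_definition(text).serialize()
    twice = parse_definition(once).serialize()
    assert once == twice
    assert parse_definition(once).root == parse_definition(twice).root


def test_optional_complex_semantics():
    module = parse_definition("K00001+K00002-K00003")
    assert not block_present(module.root, {"K00001"})
    assert block_present(module.root, {"K00001", "K00002"})
    assert block_present(module.root, {"K00001", "K00002", "K00003"})


def test_nested_module_reference_requires_expansion():
    module = parse_definition("M00001 K00002")
    with pytest.raises(UnresolvedModuleError):
        completeness(module, {"K00002"})
    result = completeness(module, {"K00002", "K11111"},
                          module_expansion={"M00001": {"K11111"}})
    assert result.complete


# ---------------------------------------------------------------------------
# evaluation vs the oracle
# ---------------------------------------------------------------------------

ORACLE_DEFINITIONS = [
    "K00001 K00002",
    "(K00001,K00002) K00003",
    "K00001+K00002-K00003",
    "K00001,K00002+K00003",
    "(K00001 K00002),K00003",
    "((K00001,K00002) K00003) K00004",
    "K00001+K00002 K00003,K00004",
    "K00001 -K00002 K00003",
    "-- K00001",
    "(K00001,K00002,K00003) (K00004,K00001)",
]


@pytest.mark.parametrize("text", ORACLE_DEFINITIONS)
def test_block_evaluation_matches_truth_table_oracle(text):
    """Every definition with ≤4 distinct KOs agrees with the oracle on all subsets."""
    module = parse_definition(text)
    kos = sorted(module.kos())
    assert len(kos) <= 4
    for r in range(len(kos) + 1):
        for subset in itertools.combinations(kos, r):
            subset = set(subset)
            got = all(
                block_present(b, subset) for b in module.blocks
            )
            assert got == oracle_eval(text, subset), (text, subset)


@pytest.mark.parametrize(
    "text,kos,fraction",
    [
        ("K00001 K00002", {"K00001"}, 0.5),
        ("(K00001,K00002) (K00003,K00004)", {"K00002", "K00003"}, 1.0),
        ("K00001 K00002 K00003 K00004", set(), 0.0),
    ],
)
def test_completeness_fraction(text, kos, fraction):
    assert completeness(parse_definition(text), kos).fraction == fraction


def test_zero_countable_blocks_is_an_error():
    with pytest.raises(ValueError):
        completeness(parse_definition("-K00001"), set())


@pytest.mark.parametrize(
    "text,kos,expected_flag,expected_ko",
    [
        ("K00001 K00002 K00003", {"K00001", "K00002"}, True, "K00003"),
        ("K00001+K00002 K00003", {"K00003"}, False, None),
        ("K00001 K00002", {"K00001", "K00002"}, False, None),
        ("(K00001,K00002) K00003", set(), False, None),
    ],
)
def test_partial_one_missing_single_ko_rescue(text, kos, expected_flag, expected_ko):
    flag, rescuer = partial_one_missing(parse_definition(text), kos)
    assert flag is expected_flag
    assert rescuer == expected_ko


def test_partial_one_missing_agrees_with_exhaustive_augmentation():
    for text in ORACLE_DEFINITIONS:
        module = parse_definition(text)
        kos = sorted(module.kos())
        for r in range(len(kos) + 1):
            for subset in map(set, itertools.combinations(kos, r)):
                flag, _ = partial_one_missing(module, subset)
                complete_now = oracle_eval(text, subset)
                rescuable = any(
                    oracle_eval(text, subset | {k}) for k in set(kos) - subset
                )
                assert flag == ((not complete_now) and rescuable), (text, subset)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

_ko_pool = [f"K{i:05d}" for i in range(1, 7)]


@settings(max_examples=150, deadline=None)
@given(
    text=st.sampled_from(ORACLE_DEFINITIONS),
    chain=st.lists(st.sampled_from(_ko_pool), max_size=6),
)
def test_completeness_monotone_under_ko_growth(text, chain):
    """Adding KOs never decreases the completeness fraction."""
    module = parse_definition(text)
    acc: set[str] = set()
    previous = completeness(module, acc).fraction
    for ko in chain:
        acc.add(ko)
        current = completeness(module, acc).fraction
        assert current >= previous
        previous = current
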