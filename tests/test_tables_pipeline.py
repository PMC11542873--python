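"""Table IO validation, CLI entry points and end-to-end pipeline behavior."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner

from lichen_census.cli import main
from lichen_census.pipeline import PipelineConfig, run_pipeline
from lichen_census.simulate import SimulationConfig, generate_bundle, write_bundle
from lichen_census.tables import TableValidationError, read_table, write_table


@pytest.fixture(scope="module")
def bundle_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig(seed=11, n_samples=40, n_duplicate_pairs=3, n_misidentified=3)
    write_bundle(generate_bundle(config), outdir)
    return outdir


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------


def test_round_trip_is_identity(bundle_dir, tmp_path):
    for name in ("coverage", "quality", "taxonomy", "ko", "rrna", "manifest", "ani"):
        frame = read_table(bundle_dir / f"{name}.tsv", name)
        out = tmp_path / f"{name}.tsv"
        write_table(frame, out)
        again = read_table(out, name)
        pd.testing.assert_frame_equal(frame, again)


def test_malformed_breadth_names_the_cell(tmp_path):
    path = tmp_path / "coverage.tsv"
    path.write_text(
        "sample_id\tmag_id\tbreadth\tn_reads\tread_length\tmag_length\n"
        "s1\tm1\t1.2\t10\t150\t1000\n"
    )
    with pytest.raises(TableValidationError, match=r"row 1.*breadth"):
        read_table(path, "coverage")


def test_missing_column_reported(tmp_path):
    path = tmp_path / "quality.tsv"
    path.write_text("mag_id\tcompleteness\nm1\t90\n")
    with pytest.raises(TableValidationError, match="missing column"):
        read_table(path, "quality")


def test_duplicate_primary_key_reported(tmp_path):
    path = tmp_path / "quality.tsv"
    path.write_text(
        "mag_id\tcompleteness\tcontamination\tdomain\nm1\t90\t1\tbacteria\nm1\t80\t2\tbacteria\n"
    )
    with pytest.raises(TableValidationError, match="duplicate primary key"):
        read_table(path, "quality")


def test_unparseable_number_reported(tmp_path):
    path = tmp_path / "quality.tsv"
    path.write_text("mag_id\tcompleteness\tcontamination\tdomain\nm1\tninety\t1\tbacteria\n")
    with pytest.raises(TableValidationError, match="malformed number"):
        read_table(path, "quality")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _run(bundle_dir, outdir, **kwargs) -> tuple:
    config = PipelineConfig(input_dir=str(bundle_dir), output_dir=str(outdir), **kwargs)
    manifest = run_pipeline(config)
    return config, manifest


def test_pipeline_outputs_and_cascade_order(bundle_dir, tmp_path):
    _config, manifest = _run(bundle_dir, tmp_path / "out")
    cascade = manifest.cascade
    assert cascade["n_dataset2"] <= cascade["n_dataset1"] <= cascade["n_total"]
    expected = {
        "retained_manifest.tsv", "dedup_log.tsv", "occurrence.tsv", "lfs_calls.tsv",
        "datasets.tsv", "detection.tsv", "outcomes.tsv", "top_genera.tsv",
        "network_edges.tsv", "network.graphml", "completeness.tsv", "trophy.tsv",
        "complementarity.tsv", "run_manifest.json",
    }
    produced = {p.name for p in (tmp_path / "out").iterdir()}
    assert expected <= produced
    assert {f"frequency_{l}.tsv" for l in ("species", "genus", "family", "order")} <= produced


def test_pipeline_rerun_is_byte_identical(bundle_dir, tmp_path):
    _run(bundle_dir, tmp_path / "a")
    _run(bundle_dir, tmp_path / "b")
    for path_a in sorted((tmp_path / "a").iterdir()):
        path_b = tmp_path / "b" / path_a.name
        if path_a.name == "run_manifest.json":
            a = json.loads(path_a.read_text())
            b = json.loads(path_b.read_text())
            a["config"].pop("output_dir"), b["config"].pop("output_dir")
            assert a == b
        else:
            assert path_a.read_bytes() == path_b.read_bytes(), path_a.name


def test_pipeline_recovers_planted_truth(bundle_dir, tmp_path):
    """Occurrences equal planted presence; misassignment flags match the
    planted misidentified samples; dedup removes exactly the planted pairs."""
    _config, manifest = _run(bundle_dir, tmp_path / "out")
    outdir = tmp_path / "out"
    truth = pd.read_csv(bundle_dir / "truth.tsv", sep="\t")
    sim_manifest = pd.read_csv(
        bundle_dir / "manifest.tsv", sep="\t", keep_default_na=False
    )
    duplicates = set(sim_manifest.loc[sim_manifest["duplicate_of"] != "", "sample_id"])
    retained = set(pd.read_csv(outdir / "retained_manifest.tsv", sep="\t")["sample_id"])
    assert retained == set(sim_manifest["sample_id"]) - duplicates

    occurrence = pd.read_csv(outdir / "occurrence.tsv", sep="\t")
    occ_map = {
        (r.sample_id, r.species): r.present for r in occurrence.itertuples()
    }
    planted = truth[truth["sample_id"].isin(retained)]
    for row in planted.itertuples():
        assert occ_map.get((row.sample_id, row.organism_id), 0) == row.present, (
            row.sample_id, row.organism_id,
        )
    # no false positives: every called occurrence has a planted counterpart
    planted_present = {
        (r.sample_id, r.organism_id) for r in planted.itertuples() if r.present
    }
    called = {
        (r.sample_id, r.species) for r in occurrence.itertuples() if r.present
    }
    assert called == planted_present

    lfs = pd.read_csv(outdir / "lfs_calls.tsv", sep="\t").set_index("sample_id")
    mis_planted = set(
        sim_manifest.loc[sim_manifest["misidentified"] == 1, "sample_id"]
    ) & retained
    fungal_recovered = {
        s for (s, o) in planted_present
        if truth.loc[
            (truth["sample_id"] == s) & (truth["organism_id"] == o), "role"
        ].iloc[0] in ("LFS", "yeast")
    }
    for sample_id in sorted(fungal_recovered):
        status = lfs.loc[sample_id, "status"]
        assert (status == "misassigned") == (sample_id in mis_planted), sample_id


def test_pipeline_dataset2_restricts_denominators(bundle_dir, tmp_path):
    _c1, m1 = _run(bundle_dir, tmp_path / "d1", dataset=1)
    _c2, m2 = _run(bundle_dir, tmp_path / "d2", dataset=2)
    f1 = pd.read_csv(tmp_path / "d1" / "frequency_genus.tsv", sep="\t")
    f2 = pd.read_csv(tmp_path / "d2" / "frequency_genus.tsv", sep="\t")
    assert f1["denominator"].iloc[0] == m1.cascade["n_dataset1"]
    assert f2["denominator"].iloc[0] == m2.cascade["n_dataset2"]


def test_pipeline_stage_failure_names_stage(tmp_path):
    (tmp_path / "empty").mkdir()
    with pytest.raises(RuntimeError, match="stage 'read inputs'"):
        run_pipeline(PipelineConfig(input_dir=str(tmp_path / "empty"),
                                    output_dir=str(tmp_path / "out")))


def test_pipeline_config_rejects_unknown_keys(tmp_path):
    path = tmp_path / "config.yaml"
    path.write_text("input_dir: x\noutput_dir: y\nmystery_knob: 3\n")
    with pytest.raises(ValueError, match="mystery_knob"):
        PipelineConfig.from_yaml(path)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def test_cli_simulate_and_run_all(tmp_path):
    runner = CliRunner()
    bundle = tmp_path / "bundle"
    result = runner.invoke(
        main, ["simulate", "--seed", "5", "--n-samples", "20", "--out", str(bundle)]
    )
    assert result.exit_code == 0, result.output
    result = runner.invoke(
        main, ["run-all", "--input-dir", str(bundle), "--out", str(tmp_path / "out")]
    )
    assert result.exit_code == 0, result.output
    run_manifest = json.loads((tmp_path / "out" / "run_manifest.json").read_text())
    assert run_manifest["cascade"]["n_total"] > 0


def test_cli_derep_and_occurrence(tmp_path):
    runner = CliRunner()
    bundle = tmp_path / "bundle"
    assert runner.invoke(
        main, ["simulate", "--seed", "5", "--n-samples", "15", "--out", str(bundle)]
    ).exit_code == 0
    result = runner.invoke(
        main,
        ["derep", "--quality", str(bundle / "quality.tsv"), "--ani", str(bundle / "ani.tsv"),
         "--out", str(tmp_path / "derep.tsv")],
    )
    assert result.exit_code == 0, result.output
    clusters = pd.read_csv(tmp_path / "derep.tsv", sep="\t")
    quality = pd.read_csv(bundle / "quality.tsv", sep="\t")
    assert set(clusters["member"]) == set(quality["mag_id"])
    result = runner.invoke(
        main,
        ["occurrence", "--coverage", str(bundle / "coverage.tsv"),
         "--out", str(tmp_path / "occ.tsv")],
    )
    assert result.exit_code == 0, result.output
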