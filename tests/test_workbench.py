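"""Pipeline orchestration, fixture generation, report I/O, CLI."""

import json

import pytest
from click.testing import CliRunner

from plexprimer.cli import main as cli_main
from plexprimer.design import DesignConstraints
from plexprimer.fixtures import (
    FixtureError,
    FixtureSpec,
    generate_fixture,
    write_fixture,
)
from plexprimer.interaction import build_index, is_dimer
from plexprimer.pipeline import (
    RunConfig,
    panel_to_primer_sets,
    read_fasta,
    read_regions,
    run,
    run_files,
)
from plexprimer.report import build_report, write_report
from plexprimer.search import validate_psc
from plexprimer.thermo import revcomp


class TestFixtureGeneration:
    def test_same_seed_reproduces_identical_sequences(self, clean3):
        again = generate_fixture(FixtureSpec(
            n_templates=3, purine_bias=0.8, ensure_clean=True, seed=7,
            background_pad=1000))
        assert again.templates == clean3.templates
        assert again.background == clean3.background
        assert again.manifest == clean3.manifest

    def test_manifest_decoy_count_matches_planted_segments(self, decoy3):
        assert len(decoy3.manifest["decoys"]) == decoy3.spec.n_decoys == 2
        bg = decoy3.background["BG1"]
        for d in decoy3.manifest["decoys"]:
            a = decoy3.spec.anchor_length
            assert bg[d["start"] : d["start"] + a] == d["forward_primer"][-a:]
            assert bg[d["end"] - a : d["end"]] == revcomp(d["reverse_primer"][-a:])

    def test_full_candidate_pool_per_template(self, clean5):
        c = clean5.spec.constraints
        for tid in clean5.template_ids:
            assert len(clean5.candidate_sets[tid]) == c.candidates_per_template

    def test_contradictory_spec_rejected(self):
        with pytest.raises(FixtureError, match="product size"):
            generate_fixture(FixtureSpec(n_templates=2, amplicon_targets=[50, 300]))
        with pytest.raises(FixtureError, match="background_pad"):
            generate_fixture(FixtureSpec(n_templates=2, n_decoys=3, background_pad=100))

    def test_dimer_plant_records_a_true_dimer_pair(self):
        fx = generate_fixture(FixtureSpec(
            n_templates=3, purine_bias=0.8, ensure_clean=True, seed=7,
            background_pad=1000, n_dimer_plants=1))
        (plant,) = fx.manifest["dimer_plants"]
        assert plant["expected_dimer_dg"] <= -7.0
        assert is_dimer(plant["donor_primer"], plant["engineered_primer"])
        host = fx.templates[plant["template"]]
        assert host[plant["start"] : plant["end"]] == plant["anchor"]

    def test_written_fixture_round_trips(self, clean3, tmp_path):
        paths = write_fixture(clean3, tmp_path)
        assert read_fasta(paths["templates"]) == clean3.templates
        assert read_fasta(paths["background"]) == clean3.background
        regions = read_regions(paths["regions"])
        assert regions == {tid: (0, len(seq)) for tid, seq in clean3.templates.items()}
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["n_templates"] == 3


class TestPipeline:
    def test_five_plex_clean_fixture_yields_full_coverage_psc(self, clean5):
        result = run(clean5.templates, clean5.background)
        assert result.pscs
        best = result.pscs[0]
        assert sorted(best.covered_templates) == sorted(clean5.template_ids)
        ok, reasons = validate_psc(best, result.matrix, result.minbs, result.gel)
        assert ok, reasons

    def test_decoy_blocked_pair_never_cooccurs_in_any_psc(self, decoy3):
        result = run(decoy3.templates, decoy3.background)
        blocked = {
            (d["template_i"], d["rank_i"], d["template_j"], d["rank_j"])
            for d in decoy3.manifest["decoys"]
        }
        for psc in result.pscs:
            chosen = {ps.template_id: ps.rank for ps in psc.members}
            for ti, ri, tj, rj in blocked:
                assert not (chosen.get(ti) == ri and chosen.get(tj) == rj)

    def test_rerun_produces_byte_identical_machine_outputs(self, clean3, tmp_path):
        fx_paths = write_fixture(clean3, tmp_path / "fx")
        outs = []
        for name in ("out1", "out2"):
            cfg = RunConfig(
                str(fx_paths["templates"]), str(fx_paths["background"]),
                str(tmp_path / name), render_png=False,
            )
            _, paths = run_files(cfg)
            outs.append(paths)
        for key in ("json", "tsv", "report", "matrix", "matrix_reasons", "bed", "gel_txt"):
            assert outs[0][key].read_bytes() == outs[1][key].read_bytes()

    def test_duplicate_fasta_ids_rejected(self, tmp_path):
        bad = tmp_path / "bad.fa"
        bad.write_text(">A\nACGT\n>A\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(bad)

    def test_empty_template_set_rejected(self, clean3):
        with pytest.raises(ValueError, match="empty template set"):
            run({}, clean3.background)

    def test_infeasible_template_logged_and_skipped(self, clean3):
        templates = dict(clean3.templates)
        templates["BAD"] = "AT" * 120
        background = dict(clean3.background)
        background["BAD"] = templates["BAD"]
        result = run(templates, background)
        assert any("BAD" in d for d in result.diagnostics)
        assert result.pscs  # the remaining templates still combine
        for psc in result.pscs:
            assert "BAD" not in psc.covered_templates

    def test_panel_check_roundtrip(self, clean3):
        panel = [
            (tid, clean3.candidate_sets[tid][0].forward.sequence,
             clean3.candidate_sets[tid][0].reverse.sequence)
            for tid in clean3.template_ids
        ]
        sets = panel_to_primer_sets(panel, clean3.templates)
        for ps, tid in zip(sets, clean3.template_ids):
            designed = clean3.candidate_sets[tid][0]
            assert ps.forward.sequence == designed.forward.sequence
            assert ps.forward.start == designed.forward.start
            assert ps.amplicon_size == designed.amplicon_size


class TestReport:
    def test_primer_sequences_match_their_templates(self, clean5):
        result = run(clean5.templates, clean5.background)
        rep = build_report(result)
        for psc in rep["pscs"]:
            for m in psc["members"]:
                template = clean5.templates[m["template"]]
                f, r = m["forward"], m["reverse"]
                fs = f["start"]
                assert template[fs : fs + f["length"]] == f["sequence_5to3"]
                rs = r["start"]
                sub = template[rs - r["length"] + 1 : rs + 1]
                assert revcomp(sub) == r["sequence_5to3"]

    def test_json_twin_round_trips(self, clean3, tmp_path):
        result = run(clean3.templates, clean3.background)
        paths = write_report(result, tmp_path, render_png=False)
        loaded = json.loads(paths["json"].read_text())
        assert loaded == json.loads(json.dumps(build_report(result)))
        assert len(loaded["pscs"]) == min(15, len(result.pscs))

    def test_psc_section_count_matches_report(self, clean3, tmp_path):
        result = run(clean3.templates, clean3.background, report_k=4)
        paths = write_report(result, tmp_path, render_png=False)
        text = paths["report"].read_text()
        assert text.count("## PSC ") == len(result.pscs) == 4


class TestCli:
    def test_fixture_design_and_check_verbs(self, tmp_path):
        runner = CliRunner()
        fxdir = tmp_path / "fx"
        r = runner.invoke(cli_main, [
            "fixture", "--out", str(fxdir), "-k", "2", "--seed", "5",
            "--pad", "800",
        ])
        assert r.exit_code == 0, r.output
        outdir = tmp_path / "out"
        r = runner.invoke(cli_main, [
            "design", "--templates", str(fxdir / "templates.fa"),
            "--background", str(fxdir / "background.fa"),
            "--out", str(outdir), "--no-png",
        ])
        assert r.exit_code == 0, r.output
        assert (outdir / "pscs.json").exists()
        rep = json.loads((outdir / "pscs.json").read_text())
        assert rep["pscs"], "expected at least one PSC"
        panel = tmp_path / "panel.tsv"
        lines = []
        for psc_member in rep["pscs"][0]["members"]:
            lines.append("\t".join([
                psc_member["template"],
                psc_member["forward"]["sequence_5to3"],
                psc_member["reverse"]["sequence_5to3"],
            ]))
        panel.write_text("\n".join(lines) + "\n")
        r = runner.invoke(cli_main, [
            "check", "--panel", str(panel),
            "--background", str(fxdir / "background.fa"),
            "--out", str(tmp_path / "check.tsv"),
        ])
        assert r.exit_code == 0, r.output
        assert "0 incompatible pair(s)" in r.output

    def test_gel_verb_renders_bands(self):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["gel", "--sizes", "120,260,410"])
        assert r.exit_code == 0, r.output
        for s in ("120", "260", "410"):
            assert s in r.output
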