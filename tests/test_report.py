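"""Per-image reports, CSV export, batch driver and the CLI surface."""

import csv

import numpy as np
import pytest
import tifffile
from click.testing import CliRunner

from lipidquant.cli import main as cli_main
from lipidquant.report import (
    AnalysisReport,
    analyze_pair,
    find_pairs,
    run_batch,
    write_csv,
)
from lipidquant.synthetic import SceneSpec, UniformDiameters, generate_scene, write_scene

from conftest import as_gray


def small_scene(seed=1, n_droplets=10, n_nuclei=2):
    spec = SceneSpec(
        height_px=384,
        width_px=384,
        n_droplets=n_droplets,
        n_nuclei=n_nuclei,
        diameter_distribution=UniformDiameters(1.0, 6.0),
        noise_sd=0.0,
        seed=seed,
    )
    return generate_scene(spec)


class TestAnalyzePair:
    def test_recovers_truth_counts_and_ratio(self):
        droplet_img, nuclei_img, truth = small_scene()
        report = analyze_pair(droplet_img, nuclei_img, image_id="pair0")
        assert report.n_droplets == len(truth.droplets) == 10
        assert report.n_cells == len(truth.nuclei) == 2
        assert report.droplets_per_cell == pytest.approx(5.0)
        assert report.pct_small + report.pct_medium + report.pct_large == pytest.approx(100.0)

    def test_blank_droplet_channel_gives_zero_ratio(self):
        _droplets, nuclei_img, _truth = small_scene(n_nuclei=3)
        blank = as_gray(np.zeros((384, 384)))
        report = analyze_pair(blank, nuclei_img)
        assert report.n_droplets == 0
        assert report.droplets_per_cell == 0.0
        assert report.mean_diameter_um is None

    def test_blank_nuclei_channel_flags_ratio_undefined(self):
        droplet_img, _nuclei, _truth = small_scene()
        blank = as_gray(np.zeros((384, 384)))
        with pytest.warns(UserWarning, match="no cells"):
            report = analyze_pair(droplet_img, blank)
        assert report.n_cells == 0
        assert report.droplets_per_cell is None

    def test_calibration_mismatch_rejected(self):
        a = as_gray(np.zeros((32, 32)), mpp=0.2)
        b = as_gray(np.zeros((32, 32)), mpp=0.3)
        with pytest.raises(ValueError, match="calibration"):
            analyze_pair(a, b)


class TestWriteCsv:
    def reports(self):
        return [
            AnalysisReport("img_a", 3, 2, 1.5, 2.1234567, 0.5, 23.809, 33.3333, 33.3333, 33.3334),
            AnalysisReport("img_b", 0, 0, None, None, None, None, None, None, None),
        ]

    def test_empty_list_writes_header_only(self, tmp_path):
        path = write_csv([], tmp_path / "out.csv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("image_id,n_droplets,n_cells,droplets_per_cell")

    def test_roundtrip_to_four_decimals(self, tmp_path):
        path = write_csv(self.reports(), tmp_path / "out.csv")
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        assert rows[0]["image_id"] == "img_a"
        assert float(rows[0]["mean_diameter_um"]) == pytest.approx(2.1234567, abs=5e-5)
        assert float(rows[0]["droplets_per_cell"]) == 1.5
        assert rows[1]["droplets_per_cell"] == ""  # undefined -> empty field
        assert rows[1]["n_droplets"] == "0"

    def test_unwritable_path_raises(self, tmp_path):
        with pytest.raises(OSError):
            write_csv([], tmp_path / "nope" / "out.csv")


class TestRunBatch:
    def write_pair(self, directory, stem, seed):
        droplet_img, nuclei_img, _ = small_scene(seed=seed)
        tifffile.imwrite(
            directory / f"{stem}_droplets.tif",
            np.round(droplet_img.pixels * 65535).astype(np.uint16),
        )
        tifffile.imwrite(
            directory / f"{stem}_nuclei.tif",
            np.round(nuclei_img.pixels * 65535).astype(np.uint16),
        )

    def test_three_pairs_give_three_rows(self, tmp_path):
        for i in range(3):
            self.write_pair(tmp_path, f"img{i}", seed=i + 1)
        summary = run_batch(tmp_path, tmp_path / "out.csv", 0.2)
        assert summary.n_analyzed == 3 and summary.n_failed == 0
        lines = (tmp_path / "out.csv").read_text().splitlines()
        assert len(lines) == 4

    def test_corrupt_file_logged_and_skipped(self, tmp_path):
        for i in range(2):
            self.write_pair(tmp_path, f"img{i}", seed=i + 1)
        (tmp_path / "bad_droplets.tif").write_bytes(b"garbage")
        (tmp_path / "bad_nuclei.tif").write_bytes(b"garbage")
        summary = run_batch(tmp_path, tmp_path / "out.csv", 0.2)
        assert summary.n_analyzed == 2
        assert summary.n_failed == 1

    def test_rerun_is_byte_identical(self, tmp_path):
        self.write_pair(tmp_path, "img0", seed=7)
        run_batch(tmp_path, tmp_path / "a.csv", 0.2)
        run_batch(tmp_path, tmp_path / "b.csv", 0.2)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_empty_directory_raises(self, tmp_path):
        with pytest.raises(OSError, match="no channel pairs"):
            run_batch(tmp_path, tmp_path / "out.csv", 0.2)

    def test_find_pairs_reports_unmatched(self, tmp_path):
        self.write_pair(tmp_path, "img0", seed=1)
        (tmp_path / "lonely_droplets.tif").write_bytes(b"x")
        pairs, unmatched = find_pairs(tmp_path, "_droplets", "_nuclei")
        assert list(pairs) == ["img0"]
        assert [p.name for p in unmatched] == ["lonely_droplets.tif"]


class TestCli:
    def test_analyze_and_simulate_subcommands(self, tmp_path):
        runner = CliRunner()
        scene_dir = tmp_path / "scenes"
        result = runner.invoke(
            cli_main,
            [
                "simulate", "--out", str(scene_dir), "--stem", "demo", "--seed", "3",
                "--n-droplets", "12", "--n-nuclei", "3", "--noise-sd", "0.0",
                "--diameters", "uniform:1.0:6.0", "--height", "384", "--width", "384",
            ],
        )
        assert result.exit_code == 0, result.output
        assert (scene_dir / "demo_truth.csv").exists()

        out_csv = tmp_path / "report.csv"
        result = runner.invoke(
            cli_main,
            [
                "analyze", str(scene_dir), "--microns-per-pixel", "0.2",
                "--out", str(out_csv),
            ],
        )
        assert result.exit_code == 0, result.output
        with open(out_csv, newline="") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 1
        assert rows[0]["n_droplets"] == "12"
        assert rows[0]["n_cells"] == "3"

    def test_evaluate_closes_loop_with_analyze(self, tmp_path):
        """simulate → analyze (per-droplet records) → evaluate scores the
        pipeline's own detections against the scene truth."""
        import json

        runner = CliRunner()
        scene_dir = tmp_path / "scenes"
        records_dir = tmp_path / "records"
        result = runner.invoke(
            cli_main,
            [
                "simulate", "--out", str(scene_dir), "--stem", "s", "--seed", "11",
                "--n-droplets", "15", "--n-nuclei", "2", "--noise-sd", "0.0",
                "--diameters", "uniform:1.0:6.0", "--height", "384", "--width", "384",
            ],
        )
        assert result.exit_code == 0, result.output
        result = runner.invoke(
            cli_main,
            [
                "analyze", str(scene_dir), "--microns-per-pixel", "0.2",
                "--out", str(tmp_path / "r.csv"),
                "--droplet-records-dir", str(records_dir),
            ],
        )
        assert result.exit_code == 0, result.output
        result = runner.invoke(
            cli_main,
            [
                "evaluate", "--truth", str(scene_dir / "s_truth.csv"),
                "--detections", str(records_dir / "s_droplets.csv"),
            ],
        )
        assert result.exit_code == 0, result.output
        rep = json.loads(result.output)
        assert rep["precision"] == 1.0
        assert rep["recall"] == 1.0
        assert rep["mean_abs_diameter_error_px"] < 1.0

    def test_count_nuclei_subcommand(self, tmp_path):
        _droplets, nuclei_img, truth = small_scene(seed=9, n_nuclei=4)
        path = tmp_path / "nuc.tif"
        tifffile.imwrite(path, np.round(nuclei_img.pixels * 65535).astype(np.uint16))
        runner = CliRunner()
        result = runner.invoke(cli_main, ["count-nuclei", str(path)])
        assert result.exit_code == 0, result.output
        assert "4 cell(s)" in result.output

    def test_config_file_overridden_by_flags(self, tmp_path):
        scene_dir = tmp_path / "scenes"
        scene_dir.mkdir()
        droplet_img, nuclei_img, _ = small_scene(seed=4)
        tifffile.imwrite(
            scene_dir / "a_droplets.tif",
            np.round(droplet_img.pixels * 65535).astype(np.uint16),
        )
        tifffile.imwrite(
            scene_dir / "a_nuclei.tif",
            np.round(nuclei_img.pixels * 65535).astype(np.uint16),
        )
        config = tmp_path / "cfg.toml"
        config.write_text('small_max_um = 0.5\nlarge_min_um = 0.6\n')
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "analyze", str(scene_dir), "--microns-per-pixel", "0.2",
                "--out", str(tmp_path / "o.csv"), "--config", str(config),
                "--small-max", "2.0", "--large-min", "3.0",
            ],
        )
        assert result.exit_code == 0, result.output
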