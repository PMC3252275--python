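"""Tests for the sliding-window pipeline, loaders and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from plicrit import cli
from plicrit import ecog_pipeline as ep
from plicrit import synth


def _write_text_rec(tmp_path, data, fs=200.0, name="rec.tsv"):
    path = tmp_path / name
    np.savetxt(path, data, delimiter="\t", fmt="%.6g")
    (tmp_path / f"{name}.json").write_text(json.dumps({"fs": fs}))
    return path


class TestLoadRecording:
    def test_text_with_sidecar(self, tmp_path, rng):
        path = _write_text_rec(tmp_path, rng.standard_normal((1000, 4)))
        rec = ep.load_recording(path)
        assert rec.data.shape == (1000, 4)
        assert rec.fs == 200.0
        assert rec.duration_s == pytest.approx(5.0)

    def test_missing_fs_errors(self, tmp_path, rng):
        path = tmp_path / "nofs.tsv"
        np.savetxt(path, rng.standard_normal((100, 3)))
        with pytest.raises(ValueError, match="sampling rate missing"):
            ep.load_recording(path)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.touch()
        with pytest.raises(ValueError, match="empty"):
            ep.load_recording(path, fs=200.0)

    def test_nan_rejected(self, tmp_path, rng):
        data = rng.standard_normal((100, 3))
        data[5, 1] = np.nan
        path = _write_text_rec(tmp_path, data, name="bad.tsv")
        with pytest.raises(ValueError, match="non-finite"):
            ep.load_recording(path)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            ep.load_recording("/does/not/exist.tsv")

    def test_single_channel_rejected(self, tmp_path, rng):
        path = _write_text_rec(tmp_path, rng.standard_normal((100, 1)), name="one.tsv")
        with pytest.raises(ValueError, match="2 channels"):
            ep.load_recording(path)


def _recording(n_samples, n_channels=4, fs=200.0, seed=0):
    rng = np.random.default_rng(seed)
    return ep.MultichannelRecording(
        data=rng.standard_normal((n_samples, n_channels)), fs=fs
    )


class TestMakeWindows:
    def test_window_sizes_at_canonical_rates(self):
        w200 = ep.make_windows(_recording(30_000, fs=200.0))
        assert w200 == [(0, 30_000)]
        w256 = ep.make_windows(_recording(38_400, fs=256.0))
        assert w256 == [(0, 38_400)]

    def test_ten_windows_over_600s(self):
        rec = _recording(120_000, fs=200.0)  # 600 s
        wins = ep.make_windows(rec)
        assert len(wins) == 10
        starts_s = [a / rec.fs for a, _ in wins]
        assert starts_s == [50.0 * k for k in range(10)]
        assert all(b - a == 30_000 for a, b in wins)

    def test_short_recording_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            ep.make_windows(_recording(1_000, fs=200.0))

    def test_count_formula_against_enumeration(self, rng):
        for _ in range(100):
            length_s = float(rng.uniform(5, 60))
            overlap_s = float(rng.uniform(0, length_s - 1e-3))
            fs = float(rng.choice([100.0, 200.0, 256.0]))
            dur_s = float(rng.uniform(length_s, 600))
            rec = _recording(int(round(dur_s * fs)), n_channels=2, fs=fs)
            spec = ep.WindowSpec(length_s, overlap_s)
            wins = ep.make_windows(rec, spec)
            win = int(round(length_s * fs))
            step = int(round((length_s - overlap_s) * fs))
            expected = [
                (s, s + win) for s in range(0, rec.n_samples - win + 1, step)
            ]
            assert wins == expected

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ep.WindowSpec(length_s=100.0, overlap_s=100.0)


class TestWindowPli:
    def test_pair_count_pooling(self, rng):
        data = rng.standard_normal((4096, 5))
        out = ep.window_pli(data, 200.0, ep.PLIParams(scales=(2,)))
        assert set(out) == {2}
        # 5 channels -> 10 unordered pairs feed the pool; check via two
        # identical channels which always contribute one full-span interval
        data[:, 1] = data[:, 0]
        out2 = ep.window_pli(data, 200.0, ep.PLIParams(scales=(2,)))
        assert out2[2].n >= 1

    def test_identical_channels_span_window(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(8192)
        data = np.stack([base, base], axis=1)
        out = ep.window_pli(data, 200.0, ep.PLIParams(scales=(2, 3)))
        for j in (2, 3):
            assert out[j].n == 1  # one interval spanning the trimmed window

    def test_channel_permutation_invariance(self, rng):
        data = rng.standard_normal((4096, 4))
        params = ep.PLIParams(scales=(2,))
        a = np.sort(ep.window_pli(data, 200.0, params)[2].durations)
        b = np.sort(ep.window_pli(data[:, ::-1], 200.0, params)[2].durations)
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def short_recording():
    cfg = synth.SynthConfig(
        n_channels=4,
        regimes=[synth.RegimeSpec("baseline", 160.0)],
        seed=6,
    )
    return synth.generate_recording(cfg)


class TestDeltaTimecourse:
    def test_single_window_self_delta(self, short_recording):
        tc = ep.delta_timecourse(
            short_recording,
            spec=ep.WindowSpec(150.0, 100.0),
            params=ep.PLIParams(scales=(2,)),
        )
        assert len(tc.window_starts_s) == 1
        n = tc.n_eval[2][0]
        assert abs(tc.delta[2][0]) < 3.0 / np.sqrt(n)

    def test_deterministic_tsv_output(self, short_recording, tmp_path):
        outs = []
        for k in range(2):
            tc = ep.delta_timecourse(
                short_recording,
                spec=ep.WindowSpec(150.0, 100.0),
                params=ep.PLIParams(scales=(2,)),
            )
            p = tmp_path / f"delta{k}.tsv"
            ep.write_delta_tsv(tc, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]


class TestCli:
    def test_synth_pli_delta_round_trip(self, tmp_path):
        runner = CliRunner()
        cfg = {
            "n_channels": 3,
            "fs": 200.0,
            "seed": 5,
            "regimes": [{"name": "baseline", "duration_s": 160.0}],
        }
        cfg_path = tmp_path / "synth.json"
        cfg_path.write_text(json.dumps(cfg))
        rec_path = tmp_path / "rec.tsv"
        r = runner.invoke(cli.main, ["synth", "--config", str(cfg_path), "--out", str(rec_path)])
        assert r.exit_code == 0, r.output
        pli_path = tmp_path / "pli.tsv"
        r = runner.invoke(cli.main, [
            "pli", "--input", str(rec_path), "--scales", "2",
            "--window", "150", "--overlap", "100", "--out", str(pli_path),
        ])
        assert r.exit_code == 0, r.output
        delta_path = tmp_path / "delta.tsv"
        r = runner.invoke(cli.main, [
            "delta", "--pli", str(pli_path), "--window", "150",
            "--overlap", "100", "--out", str(delta_path),
        ])
        assert r.exit_code == 0, r.output
        lines = delta_path.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["window_start_s", "scale", "delta"]
        assert len(lines) == 2  # one window, one scale

    def test_soc_run_writes_trajectory(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "traj.json"
        r = runner.invoke(cli.main, [
            "soc-run", "--n", "64", "--k-init", "1.0", "--epoch", "50",
            "--iterations", "20", "--seed", "3", "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        payload = json.loads(out.read_text())
        assert len(payload["K_series"]) == 20
        assert payload["final_K"] == payload["K_series"][-1]
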