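"""Orchestration: determinism, checkpoint/resume, I/O round trips, analysis."""

import json
import pathlib

import numpy as np
import pytest

from ratchetsim.runner import (RunConfig, run, analyze, load_bundle,
                               write_frame, read_frames, _rle_encode,
                               _rle_decode, simulate, save_checkpoint,
                               load_checkpoint, ReplicaResult)
from ratchetsim.topology import build_system, add_cluster_to_state, cluster_coords
from ratchetsim.chemostat import ChemostatSpec, generate_reservoir
from ratchetsim.dynamics import DynamicsParams
from ratchetsim.events import EventDetector, CycleCounts, EventRecord

KT = 0.5


def _tiny_config(tmp_path, **kw):
    defaults = dict(n_steps=2000, seed=5, reservoir_size=100,
                    pre_equilibration_steps=500, outdir=str(tmp_path / "out"))
    defaults.update(kw)
    return RunConfig(**defaults)


class TestConfig:
    def test_defaults_are_model_standard_values(self):
        cfg = RunConfig()
        assert cfg.dt == 5e-3 and cfg.kT == 0.5 and cfg.gamma == 0.5
        assert cfg.move_period == 100
        assert cfg.L_inner == 30.0 and cfg.L_outer == 34.0
        assert cfg.mu_prime == {"FTC": 0.5, "ETC": -10.0, "C": -10.0}

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("""
run: {n_steps: 5000, seed: 3}
dynamics: {gamma: 10.0}
chemostat: {mu_prime_ftc: -0.25, move_period: 50}
pairs:
  - {i: SHUTTLE, j: BIND, eps_A: 0.9}
""")
        cfg = RunConfig.from_yaml(p)
        assert cfg.n_steps == 5000 and cfg.gamma == 10.0
        assert cfg.mu_prime["FTC"] == -0.25 and cfg.move_period == 50
        tab = cfg.make_tables()
        from ratchetsim.forcefield import ParticleType
        assert tab.eps_A[ParticleType.SHUTTLE, ParticleType.BIND] == 0.9

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(move_period=0)
        with pytest.raises(ValueError):
            RunConfig(mu_prime={"FTC": 0.0})


class TestTrajectoryIO:
    def test_lossless_round_trip(self, tmp_path, rng):
        state, tables = build_system()
        add_cluster_to_state(state, tables, "C", np.array([[16.0, 0.1, -2.0]]))
        state.positions += rng.standard_normal(state.positions.shape) * 0.01
        state.momenta += rng.standard_normal(state.momenta.shape)
        state.time = 1.23456789
        p = tmp_path / "t.extxyz"
        with open(p, "w") as fh:
            write_frame(fh, state, 34.0, 30.0)
        frames = read_frames(p)
        assert len(frames) == 1
        assert np.array_equal(frames[0]["positions"], state.positions)
        assert np.array_equal(frames[0]["momenta"], state.momenta)
        assert np.array_equal(frames[0]["types"], state.types)

    def test_variable_particle_counts_across_frames(self, tmp_path):
        p = tmp_path / "t.extxyz"
        with open(p, "w") as fh:
            s1, t1 = build_system(include_motor=False)
            add_cluster_to_state(s1, t1, "C", np.array([[16.0, 0, 0]]))
            write_frame(fh, s1, 34.0, 30.0)
            s2, t2 = build_system()
            write_frame(fh, s2, 34.0, 30.0)
        frames = read_frames(p)
        assert [len(f["positions"]) for f in frames] == [1, 42]

    def test_malformed_frame_reports_line(self, tmp_path):
        p = tmp_path / "bad.extxyz"
        p.write_text("2\ncomment\nINERT 0 0 0 0 0 0 0\nINERT 1 2\n")
        from ratchetsim.runner import FrameParseError
        with pytest.raises(FrameParseError, match="line 4"):
            read_frames(p)

    def test_rle_round_trip(self, rng):
        s = rng.integers(1, 9, 500)
        assert np.array_equal(_rle_decode(_rle_encode(s)), s)
        assert _rle_encode(np.zeros(0, dtype=np.int64)) == ""


class TestRun:
    def test_zero_steps_outputs_initial_frame_only(self, tmp_path):
        cfg = _tiny_config(tmp_path, n_steps=0, pre_equilibration_steps=0)
        run(cfg)
        frames = read_frames(tmp_path / "out" / "traj_r0.extxyz")
        assert len(frames) == 1
        assert (tmp_path / "out" / "events_r0.jsonl").read_text() == ""

    def test_same_seed_byte_identical_logs(self, tmp_path):
        texts = []
        for sub in ("a", "b"):
            cfg = _tiny_config(tmp_path / sub)
            run(cfg)
            d = tmp_path / sub / "out"
            texts.append((d / "moves_r0.jsonl").read_text()
                         + (d / "events_r0.jsonl").read_text()
                         + (d / "coarse_r0.rle").read_text())
        assert texts[0] == texts[1]

    def test_replicas_differ(self, tmp_path):
        cfg = _tiny_config(tmp_path, replicas=2, n_steps=3000)
        res = run(cfg)
        assert not np.array_equal(res[0].state.positions[:42],
                                  res[1].state.positions[:42])


class TestCheckpoint:
    def test_resume_is_bit_exact(self, tmp_path, rng):
        from ratchetsim.forcefield import default_tables
        base = default_tables()
        res = {sp: generate_reservoir(sp, 50, KT, np.random.default_rng(1))
               for sp in ("FTC", "ETC")}
        spec = ChemostatSpec(mu_prime={"FTC": 0.5, "ETC": -10.0, "C": -10.0},
                             reservoirs=res)
        params = DynamicsParams()

        def fresh():
            state, tables = build_system(tables=default_tables())
            det = EventDetector()
            return (state, tables, det, np.random.default_rng(77),
                    np.random.default_rng(88))

        # uninterrupted: 12 segments
        s1, t1, d1, m1, g1 = fresh()
        t1, _ = simulate(s1, t1, spec, params, d1, m1, g1, 12)

        # interrupted at segment 6
        s2, t2, d2, m2, g2 = fresh()
        t2, _ = simulate(s2, t2, spec, params, d2, m2, g2, 6)
        ckpt = tmp_path / "ck.json"
        save_checkpoint(ckpt, s2, m2, g2, d2)
        s3, t3, m3, g3, d3 = load_checkpoint(ckpt, base)
        t3, _ = simulate(s3, t3, spec, params, d3, m3, g3, 6)

        assert np.array_equal(s1.positions, s3.positions)
        assert np.array_equal(s1.momenta, s3.momenta)
        assert s1.step == s3.step
        assert len(d1.events) == len(d3.events)
        assert d1.counts == d3.counts


class TestAnalyze:
    def _replica(self, n_cw, n_ccw, n_cat, t_obs=100.0):
        counts = CycleCounts(n_CW=n_cw, n_CCW=n_ccw, n_cat=n_cat, t_obs=t_obs)
        return ReplicaResult(counts=counts, events=[], moves=[],
                             coarse=np.zeros(0, dtype=np.int64), state=None,
                             diagnostics={})

    def test_exact_observables_from_known_counts(self):
        rep = analyze([self._replica(10, 4, 7)], dt=5e-3)
        assert rep["bias"]["mean"] == pytest.approx(10 / 14)
        assert rep["current"]["mean"] == pytest.approx(0.06)
        assert rep["coupling"]["mean"] == pytest.approx(6 / 7)

    def test_identical_replicas_zero_se(self):
        rep = analyze([self._replica(5, 1, 2), self._replica(5, 1, 2)], dt=5e-3)
        assert rep["bias"]["se"] == 0.0
        assert rep["current"]["se"] == 0.0

    def test_undefined_observables_excluded(self):
        rep = analyze([self._replica(0, 0, 0), self._replica(3, 1, 2)], dt=5e-3)
        assert rep["excluded"]["bias"] == 1
        assert rep["bias"]["mean"] == pytest.approx(0.75)

    def test_bundle_round_trip(self, tmp_path):
        cfg = _tiny_config(tmp_path, n_steps=3000)
        results = run(cfg)
        rep_disk = analyze(str(tmp_path / "out"), dt=cfg.dt)
        rep_mem = analyze(results, dt=cfg.dt)
        assert rep_disk["n_replicas"] == rep_mem["n_replicas"] == 1
        assert rep_disk["decompositions"] == rep_mem["decompositions"]


class TestCLI:
    def test_fixtures_and_analyze_subcommands(self, tmp_path):
        from click.testing import CliRunner
        from ratchetsim.cli import main
        runner = CliRunner()
        out = tmp_path / "walk.txt"
        res = runner.invoke(main, ["fixtures", "--kind", "walk", "--seed", "3",
                                   "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert out.exists() and "true winding" in res.output

        cfg = _tiny_config(tmp_path, n_steps=2000)
        run(cfg)
        res = runner.invoke(main, ["analyze", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        assert '"n_replicas": 1' in res.output


class TestRLEProperties:
    def test_round_trip_arbitrary_series(self):
        from hypothesis import given, settings, strategies as st
        from ratchetsim.runner import _rle_encode, _rle_decode

        @settings(derandomize=True, deadline=None, max_examples=100)
        @given(st.lists(st.integers(min_value=1, max_value=8), max_size=200))
        def check(vals):
            s = np.array(vals, dtype=np.int64)
            assert np.array_equal(_rle_decode(_rle_encode(s)), s)

        check()
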