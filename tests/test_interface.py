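import numpy as np
import pytest
from click.testing import CliRunner

from prevoid.alarm import Event, EventLog
from prevoid.cli import main
from prevoid.echo_sim import SimulationConfig, simulate_ascan
from prevoid.features import extract_feature_table
from prevoid.interface import (
    FeatureTableError,
    load_config,
    load_feature_table,
    read_event_log,
    read_trace,
    save_feature_table,
    write_event_log,
    write_trace,
)
from prevoid.states import BladderState


@pytest.fixture()
def table(noiseless_config, gates, volunteers):
    fills = (0.0, 0.5, 0.75, 1.0)  # includes a silent-gate-B (empty) row
    traces = [simulate_ascan(noiseless_config, f, volunteers[0], seed=i) for i, f in enumerate(fills)]
    return extract_feature_table(traces, gates, volunteers[0])


def test_feature_table_round_trip(tmp_path, table):
    path = tmp_path / "features.csv"
    save_feature_table(table, path)
    # the empty-bladder row is written with empty posterior fields
    lines = path.read_text().splitlines()
    assert ",,," in lines[1]
    features, labels = load_feature_table(path)
    assert len(features) == len(table)
    assert list(labels) == [BladderState.from_label(s) for s in table["state"]]
    np.testing.assert_allclose(features["ds"], table["ds"], atol=1e-9)
    assert features.loc[0, "t_b"] == 0.0 and features.loc[0, "v_b"] == -120.0


def test_malformed_tables_raise_named_errors(tmp_path):
    bad_header = tmp_path / "bad1.csv"
    bad_header.write_text("a,b,c\n1,2,3\n")
    with pytest.raises(FeatureTableError, match="header"):
        load_feature_table(bad_header)
    bad_cell = tmp_path / "bad2.csv"
    header = "t_a,t_b,s_a,s_b,dt,ds,h_a,h_b,v_a,v_b,dv,bmi,sex,age,state"
    bad_cell.write_text(header + "\n1,2,3,4,1,1,5,6,0,0,0,oops,M,6,full\n")
    with pytest.raises(FeatureTableError, match=r"row 0.*'bmi'"):
        load_feature_table(bad_cell)


def test_trace_record_round_trip(tmp_path, noiseless_config, volunteers):
    tr = simulate_ascan(noiseless_config, 0.75, volunteers[0], seed=5)
    path = tmp_path / "trace.txt"
    write_trace(tr, path)
    back = read_trace(path)
    np.testing.assert_allclose(back.samples, tr.samples, rtol=1e-8)
    assert back.truth.state is BladderState.THREE_QUARTERS
    assert back.sample_rate == tr.sample_rate and back.subject_ref == tr.subject_ref


def test_event_log_round_trip(tmp_path):
    log = EventLog(
        [
            Event(0.0, "state_estimate", {"state": "empty"}),
            Event(5.0, "prevoid_alarm", {"modality": "sound"}),
            Event(6.0, "moisture", {}),
        ]
    )
    path = tmp_path / "events.log"
    write_event_log(log, path)
    back = read_event_log(path)
    assert [(e.time_min, e.kind, e.payload) for e in back] == [
        (e.time_min, e.kind, e.payload) for e in log
    ]


def test_config_loads_and_validates(tmp_path):
    cfg_path = tmp_path / "config.yaml"
    cfg_path.write_text(
        """
seed: 9
personal: {age: 8, sex: M, height_cm: 128, weight_kg: 27}
simulation: {noise_sd: 0.01}
gates: {threshold_a: 0.04}
cv: {kind: k_fold, k: 5}
policy: {trigger_state: "1/2"}
"""
    )
    cfg = load_config(cfg_path)
    assert cfg.seed == 9
    assert cfg.personal.bmi == pytest.approx(27 / 1.28**2)
    assert cfg.simulation.noise_sd == 0.01
    assert cfg.gates.threshold_a == 0.04
    assert cfg.cv.k == 5
    assert cfg.policy.trigger_state is BladderState.HALF

    (tmp_path / "bad.yaml").write_text("personal: {age: 8, sex: M, height_cm: 128, weight_kg: 27, bmi: 20}\n")
    with pytest.raises(ValueError, match="BMI"):
        load_config(tmp_path / "bad.yaml")
    (tmp_path / "bad2.yaml").write_text("frobnicate: 1\n")
    with pytest.raises(ValueError, match="unknown config keys"):
        load_config(tmp_path / "bad2.yaml")


def test_cli_evaluate_fixtures_prints_voting_rates():
    result = CliRunner().invoke(main, ["evaluate", "--fixtures", "--trigger", "3/4", "--scheme", "voting"])
    assert result.exit_code == 0
    assert "Se 0.89 Sp 0.93" in result.output


def test_cli_unknown_subcommand_exits_2():
    result = CliRunner().invoke(main, ["frobnicate"])
    assert result.exit_code == 2


def test_cli_simulate_is_deterministic(tmp_path):
    runner = CliRunner()
    out1, out2 = tmp_path / "a.csv", tmp_path / "b.csv"
    for out in (out1, out2):
        res = runner.invoke(main, ["simulate", "--days", "1", "--seed", "7", "--out", str(out)])
        assert res.exit_code == 0, res.output
    assert out1.read_bytes() == out2.read_bytes()


def test_cli_train_then_monitor_ends_in_alarm(tmp_path, noiseless_config, volunteers):
    runner = CliRunner()
    feats = tmp_path / "features.csv"
    res = runner.invoke(main, ["simulate", "--days", "1", "--seed", "3", "--noise-sd", "0.02", "--out", str(feats)])
    assert res.exit_code == 0, res.output
    model = tmp_path / "models.joblib"
    res = runner.invoke(main, ["train", "--features", str(feats), "--out", str(model)])
    assert res.exit_code == 0, res.output

    night = tmp_path / "night"
    night.mkdir()
    cfg = SimulationConfig(noise_sd=0.02, speckle_sd=0.02)
    for i, fill in enumerate(np.linspace(0, 1, 8)):
        write_trace(simulate_ascan(cfg, float(fill), volunteers[0], seed=50 + i), night / f"t{i:02d}.txt")
    log_path = tmp_path / "events.log"
    res = runner.invoke(
        main, ["monitor", "--traces", str(night), "--model", str(model), "--out", str(log_path)]
    )
    assert res.exit_code == 0, res.output
    log = read_event_log(log_path)
    assert log.of_kind("prevoid_alarm")
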