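"""Trajectory preprocessing: steps, turns, transforms, truncation, lags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangeshift import (
    PhaseSchedule,
    SimConfig,
    TrajectoryError,
    compute_steps,
    detect_resettlement,
    lag_features,
    read_fixes,
    simulate_experiment,
    transform_movement,
    truncate_phases,
    write_fixes,
)

from conftest import hourly_trajectory


def make_schedule(start="2018-01-01", pre=14, closure=14, post=14, ay="ay1"):
    t0 = pd.Timestamp(start, tz="UTC")
    return PhaseSchedule(
        animal_year_id=ay,
        pre_start=t0,
        closure_start=t0 + pd.Timedelta(days=pre),
        post_start=t0 + pd.Timedelta(days=pre + closure),
        post_end=t0 + pd.Timedelta(days=pre + closure + post),
    )


# ---------------------------------------------------------------------------
# steps and turning angles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "coords, exp_steps, exp_turns",
    [
        ([(0, 0), (3, 4)], [5.0], [np.nan]),
        ([(0, 0), (1, 0), (2, 0)], [1.0, 1.0], [np.nan, 0.0]),
        # left turn is counterclockwise positive
        ([(0, 0), (1, 0), (1, 1)], [1.0, 1.0], [np.nan, np.pi / 2]),
        ([(0, 0), (1, 0), (1, -1)], [1.0, 1.0], [np.nan, -np.pi / 2]),
    ],
)
def test_step_and_turn_geometry(coords, exp_steps, exp_turns):
    steps = compute_steps(hourly_trajectory(coords))
    assert np.allclose(steps["step"], exp_steps)
    assert np.allclose(steps["turn"], exp_turns, equal_nan=True)


def test_step_count_conservation():
    traj = hourly_trajectory(np.random.default_rng(0).normal(size=(50, 2)))
    assert len(compute_steps(traj)) == traj.n_fixes - 1


def test_zero_length_step_carries_heading():
    # stationary fix: the turn at the zero step is missing, the next turn
    # uses the carried heading
    steps = compute_steps(hourly_trajectory([(0, 0), (1, 0), (1, 0), (2, 0)]))
    assert steps["step"].tolist() == [1.0, 0.0, 1.0]
    assert np.isnan(steps["turn"].iloc[1])
    assert steps["turn"].iloc[2] == pytest.approx(0.0)


def test_gap_steps_flagged_and_turns_suppressed():
    ts = pd.to_datetime(
        ["2018-01-01 00:00", "2018-01-01 01:00", "2018-01-01 03:00",
         "2018-01-01 04:00"], utc=True)
    from rangeshift import Trajectory
    traj = Trajectory("ay1", "a1", "F", 2018,
                      pd.DataFrame({"timestamp": ts,
                                    "x": [0.0, 1.0, 2.0, 3.0],
                                    "y": [0.0] * 4}))
    steps = compute_steps(traj)
    assert steps["gap"].tolist() == [False, True, False]
    # turns bounded by the gap step are undefined
    assert np.isnan(steps["turn"].iloc[1]) and np.isnan(steps["turn"].iloc[2])


@settings(max_examples=25, deadline=None)
@given(
    angle=st.floats(0, 2 * np.pi),
    dx=st.floats(-1e4, 1e4),
    dy=st.floats(-1e4, 1e4),
)
def test_rigid_motion_invariance(angle, dx, dy):
    """Translation and rotation leave step lengths and |turns| unchanged."""
    rng = np.random.default_rng(42)
    xy = np.cumsum(rng.normal(0, 50, size=(40, 2)), axis=0)
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    moved = xy @ rot.T + np.array([dx, dy])
    s0 = compute_steps(hourly_trajectory(xy))
    s1 = compute_steps(hourly_trajectory(moved))
    np.testing.assert_allclose(s0["step"], s1["step"], rtol=1e-9, atol=1e-6)
    np.testing.assert_allclose(np.abs(s0["turn"]), np.abs(s1["turn"]),
                               rtol=1e-6, atol=1e-6, equal_nan=True)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "theta, eps, expected",
    [
        (np.pi / 2, 1e-6, 0.0),                       # |theta|/pi = 1/2, logit midpoint
        (np.pi / 4, 1e-6, np.log(1 / 3)),             # logit(1/4)
        (0.0, 1e-6, np.log(1e-6 / (1 - 1e-6))),       # clamped at eps
        (np.pi, 1e-6, np.log((1 - 1e-6) / 1e-6)),     # clamped at 1 - eps
    ],
)
def test_turn_logit_transform(theta, eps, expected):
    steps = pd.DataFrame({"step": [10.0], "turn": [theta], "gap": [False]})
    out = transform_movement(steps, eps=eps)
    assert out["phi"].iloc[0] == pytest.approx(expected, rel=1e-9)


def test_log_step_floor():
    steps = pd.DataFrame({"step": [0.0, 0.5, 20.0], "turn": np.nan, "gap": False})
    out = transform_movement(steps)
    assert np.allclose(out["log_step"], [0.0, 0.0, np.log(20.0)])


def test_transform_rejects_bad_eps():
    steps = pd.DataFrame({"step": [1.0], "turn": [0.1], "gap": [False]})
    with pytest.raises(ValueError):
        transform_movement(steps, eps=0.7)


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------

def _complete_traj_for(schedule):
    n = int((schedule.post_end - schedule.pre_start) / pd.Timedelta(hours=1))
    ts = pd.date_range(schedule.pre_start, periods=n, freq="1h", tz="UTC")
    from rangeshift import Trajectory
    return Trajectory("ay1", "a1", "F", 2018,
                      pd.DataFrame({"timestamp": ts,
                                    "x": np.arange(n, dtype=float),
                                    "y": 0.0}))


def test_truncation_keeps_final_closure_window():
    # a 15.5-day raw closure keeps its last 14 days, ending at post_start
    sched = make_schedule(pre=14, closure=15.5, post=14)
    traj = _complete_traj_for(sched)
    out = truncate_phases(traj, sched)
    clo = out.fixes[out.fixes["phase"] == "closure"]
    assert clo["timestamp"].max() == sched.post_start - pd.Timedelta(hours=1)
    span = clo["timestamp"].max() - clo["timestamp"].min()
    assert span == pd.Timedelta(days=14) - pd.Timedelta(hours=1)


def test_truncation_exact_phase_unchanged():
    sched = make_schedule()
    traj = _complete_traj_for(sched)
    out = truncate_phases(traj, sched)
    assert out.n_fixes == traj.n_fixes
    assert (out.fixes["phase"].value_counts() == 14 * 24).all()


def test_truncation_removes_leading_pre_excess():
    # 16-day pre-closure with complete hourly fixes: 48 leading fixes removed
    sched = make_schedule(pre=16)
    traj = _complete_traj_for(sched)
    out = truncate_phases(traj, sched)
    pre = out.fixes[out.fixes["phase"] == "pre"]
    assert len(pre) == 14 * 24
    assert pre["timestamp"].min() == traj.fixes["timestamp"].iloc[48]


def test_truncation_idempotent():
    sched = make_schedule(pre=15, closure=16, post=18)
    traj = _complete_traj_for(sched)
    once = truncate_phases(traj, sched)
    twice = truncate_phases(once, sched)
    pd.testing.assert_frame_equal(once.fixes, twice.fixes)


def test_truncation_rejects_short_phase():
    sched = make_schedule(closure=10)
    with pytest.raises(TrajectoryError, match="closure"):
        truncate_phases(_complete_traj_for(sched), sched)


# ---------------------------------------------------------------------------
# resettlement
# ---------------------------------------------------------------------------

def test_resettlement_scan():
    # distances from capture: 10, 200, 300, 40 -> first return is the 4th fix
    traj = hourly_trajectory([(10, 0), (200, 0), (300, 0), (40, 0)])
    t = detect_resettlement(traj, (0.0, 0.0), radius=61.2)
    assert t == traj.fixes["timestamp"].iloc[3]


def test_resettlement_never_leaves_is_first_fix():
    traj = hourly_trajectory([(5, 0), (10, 0), (3, 0)])
    t = detect_resettlement(traj, (0.0, 0.0), radius=61.2)
    assert t == traj.fixes["timestamp"].iloc[0]


def test_resettlement_never_returns_raises():
    traj = hourly_trajectory([(10, 0), (500, 0), (900, 0)])
    with pytest.raises(TrajectoryError, match="re-visitation"):
        detect_resettlement(traj, (0.0, 0.0), radius=61.2)


# ---------------------------------------------------------------------------
# lags
# ---------------------------------------------------------------------------

def test_lagged_columns_are_exact_shifts():
    traj = hourly_trajectory(np.random.default_rng(1).normal(0, 50, (200, 2)))
    steps = transform_movement(compute_steps(traj))
    out = lag_features(steps)
    for k in (1, 2, 24):
        expect = steps["log_step"].shift(k)
        got = out[f"log_step_lag{k}"]
        np.testing.assert_allclose(got[k:], expect[k:], rtol=1e-12)
        assert got[:k].isna().all()


def test_lag24_model_table_size_complete_series():
    # 1008 hourly fixes -> 1007 steps; all three lags exist once 24 earlier
    # steps are available, leaving 1007 - 24 usable rows
    traj = hourly_trajectory(np.random.default_rng(2).normal(0, 50, (1008, 2)))
    steps = transform_movement(compute_steps(traj))
    out = lag_features(steps)
    usable = out.dropna(subset=[f"log_step_lag{k}" for k in (1, 2, 24)])
    assert len(usable) == 1007 - 24


def test_short_series_has_empty_lag_table():
    traj = hourly_trajectory(np.random.default_rng(3).normal(0, 50, (10, 2)))
    steps = transform_movement(compute_steps(traj))
    out = lag_features(steps)
    assert out["log_step_lag24"].isna().all()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_read_fixes_small_file(tmp_path):
    p = tmp_path / "fixes.csv"
    p.write_text(
        "animal_year_id,animal_id,sex,timestamp,x,y\n"
        "a1-2018,a1,F,2018-01-01T00:00:00Z,0,0\n"
        "a1-2018,a1,F,2018-01-01T01:00:00Z,10,0\n"
        "a1-2018,a1,F,2018-01-01T02:00:00Z,20,5\n"
    )
    trajs = read_fixes(p)
    assert len(trajs) == 1 and trajs[0].n_fixes == 3
    assert trajs[0].sex == "F"


def test_read_fixes_duplicate_timestamp_names_animal_year(tmp_path):
    p = tmp_path / "fixes.csv"
    p.write_text(
        "animal_year_id,animal_id,sex,timestamp,x,y\n"
        "a1-2018,a1,F,2018-01-01T00:00:00Z,0,0\n"
        "a1-2018,a1,F,2018-01-01T00:00:00Z,10,0\n"
    )
    with pytest.raises(TrajectoryError, match="a1-2018"):
        read_fixes(p)


def test_read_fixes_unknown_sex(tmp_path):
    p = tmp_path / "fixes.csv"
    p.write_text(
        "animal_year_id,animal_id,sex,timestamp,x,y\n"
        "a1-2018,a1,X,2018-01-01T00:00:00Z,0,0\n"
        "a1-2018,a1,X,2018-01-01T01:00:00Z,1,0\n"
    )
    with pytest.raises(TrajectoryError, match="sex"):
        read_fixes(p)


def test_fixes_roundtrip_synthetic_bundle(tmp_path, small_bundle):
    path = tmp_path / "fixes.csv"
    write_fixes(small_bundle.trajectories, path)
    back = read_fixes(path)
    assert len(back) == len(small_bundle.trajectories)
    orig = {t.animal_year_id: t for t in small_bundle.trajectories}
    for t in back:
        o = orig[t.animal_year_id]
        assert (t.fixes["timestamp"] == o.fixes["timestamp"]).all()
        np.testing.assert_allclose(t.fixes[["x", "y"]], o.fixes[["x", "y"]])
        assert (t.animal_id, t.sex) == (o.animal_id, o.sex)
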