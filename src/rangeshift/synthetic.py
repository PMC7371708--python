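"""Synthetic resource-manipulation experiments on home-ranging herbivores.

Emulates the design of a feeding-site closure experiment: a winter
population of GPS-collared animals (default 25 animal-years over three
years, with some individuals manipulated in two consecutive winters) moves
hourly over a featureless plane containing point feeding sites. Each
animal-year has one *manipulated* site M — its most familiar feeder, close
to its home-range centre — and a handful of *alternate* sites A roughly
700 m away. Food access at M is withdrawn during a middle ~14-day closure
phase and restored afterwards; A sites stay open throughout.

Movement is a three-mode, hourly Markov mover (the field experiment
specifies no generative model; this is the simplest mechanism that
produces the expected response directions):

ATTEND
    small steps (gamma, mean ~10 m) scattered around the current target
    feeding site; attendance ends per hour with probability 1/dwell.
FORAGE
    a biased correlated random walk: gamma step lengths (mean ~60 m),
    wrapped-Cauchy turning angles (concentration ~0.3), plus a linear
    drift toward the home-range centre that keeps the range bounded.
RELOCATE
    directed travel toward a chosen feeding site (gamma mean ~200 m,
    truncated at the remaining distance); the heading is the circular
    weighted mean of the previous heading and the bearing to the target.

While foraging, an animal initiates a feeding-site visit with per-hour
probability p_i / (dwell * (1 - p_i)), so the long-run fraction of time
spent attending approximates its latent preference p_i (drawn from a Beta
with mean ~0.34). The target site is drawn with weight proportional to
familiarity * exp(-distance / delta) * availability, familiarity being
maximal for M; closure therefore diverts high-preference animals to A
sites or the matrix, and the restored availability plus familiarity pulls
them back to M post-closure.

All randomness flows from a single integer seed through independent
per-animal-year streams, so identical configurations reproduce byte-
identical output bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .resource_states import FeedingSiteSet, write_sites
from .trajectories import (
    PhaseSchedule,
    Trajectory,
    write_fixes,
    write_schedules,
)

__all__ = ["SimConfig", "GroundTruth", "ExperimentBundle",
           "generate_landscape", "simulate_animal_year", "simulate_experiment"]


@dataclass(frozen=True)
class SimConfig:
    """Design constants and movement parameters of a synthetic experiment.

    Defaults reproduce the study regime: 25 animal-years, three 14-day
    phases at hourly fixes, ~4 alternate sites per animal at mean 700 m
    (sd 300 m) from M, latent preference Beta-distributed with mean 0.34,
    and a population mean hourly displacement around 60 m.
    """

    n_animal_years: int = 25
    phase_length_days: float = 14.0
    fix_interval_hours: float = 1.0
    n_alt_sites_mean: float = 4.0
    n_alt_sites_fixed: int | None = None
    site_spacing_mean: float = 700.0
    site_spacing_sd: float = 300.0
    min_site_spacing: float = 100.0
    preference_alpha: float = 1.7
    preference_beta: float = 3.3  # Beta(1.7, 3.3): mean 0.34
    # movement: per-mode gamma step means (m), shape, and turn concentration
    attend_step_mean: float = 10.0
    forage_step_mean: float = 60.0
    relocate_step_mean: float = 200.0
    step_shape: float = 2.0
    forage_turn_rho: float = 0.3
    home_bias: float = 0.15
    # attendance dynamics
    dwell_mean_hours: float = 4.0
    attend_rate_scale: float = 0.7
    attend_gate: float = 0.25  # weight scale gating initiation when sites are poor
    target_decay: float = 400.0  # delta (m) in the site-choice weight
    familiarity_m: float = 1.0
    familiarity_a: float = 0.1
    arrive_radius: float = 50.0
    heading_weight_target: float = 0.7
    home_offset: float = 250.0  # home centre distance from M (m)
    closure_effect: float = 0.0  # availability of M during closure
    dropout: float = 0.0  # per-slot fix loss probability
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_length_days < 1:
            raise ValueError("phase_length must be at least one day")
        for name in ("site_spacing_mean", "min_site_spacing", "target_decay",
                     "attend_step_mean", "forage_step_mean", "relocate_step_mean"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 <= self.closure_effect <= 1:
            raise ValueError("closure_effect is an availability in [0, 1]")

    @property
    def slots_per_phase(self) -> int:
        return int(round(self.phase_length_days * 24 / self.fix_interval_hours))


@dataclass
class GroundTruth:
    """Latent quantities behind one simulated animal-year."""

    animal_year_id: str
    p_i: float
    home_centre: tuple[float, float]
    manipulated_site_id: str
    mode_counts: dict[str, int]
    availability: dict[str, dict[str, float]]  # phase -> site role -> availability
    modes: np.ndarray | None = None  # per-fix mode labels


@dataclass
class ExperimentBundle:
    """In-memory result of :func:`simulate_experiment`."""

    config: SimConfig
    trajectories: list[Trajectory]
    sites: FeedingSiteSet
    schedules: dict[str, PhaseSchedule]
    ground_truth: dict[str, GroundTruth]


# ---------------------------------------------------------------------------
# Roster and landscape
# ---------------------------------------------------------------------------

#: Share of individuals manipulated in a second consecutive winter, and the
#: female share of the population (21 adults + 4 yearlings: 17 F, 8 M).
REPEAT_PROB = 0.28
FEMALE_PROB = 0.68
STUDY_YEARS = (2017, 2018, 2019)
NEIGHBOURHOOD_SPACING = 10_000.0  # m between individual neighbourhoods


def _build_roster(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Animal-year roster: individuals, sexes, years, neighbourhood index."""
    rows = []
    ind = 0
    while len(rows) < config.n_animal_years:
        ind += 1
        sex = "F" if rng.random() < FEMALE_PROB else "M"
        animal_id = f"{sex}{ind:02d}"
        year = int(rng.choice(STUDY_YEARS[:-1]))
        n_years = 2 if rng.random() < REPEAT_PROB else 1
        for k in range(n_years):
            if len(rows) >= config.n_animal_years:
                break
            rows.append(
                {
                    "animal_id": animal_id,
                    "sex": sex,
                    "year": year + k,
                    "animal_year_id": f"{animal_id}-{year + k}",
                    "neighbourhood": ind - 1,
                }
            )
    return pd.DataFrame(rows)


def _place_neighbourhood_sites(
    config: SimConfig, rng: np.random.Generator, origin: np.ndarray, prefix: str
) -> pd.DataFrame:
    """One M candidate plus alternates around a neighbourhood origin."""
    if config.n_alt_sites_fixed is not None:
        n_alt = int(config.n_alt_sites_fixed)
    else:
        n_alt = max(1, int(rng.poisson(config.n_alt_sites_mean)))
    if config.n_alt_sites_mean < 1:
        raise ValueError("need at least one alternate site on average")
    pts = [origin]
    ids = [f"{prefix}M"]
    for j in range(n_alt):
        for _ in range(200):
            dist = rng.normal(config.site_spacing_mean, config.site_spacing_sd)
            if dist < config.min_site_spacing:
                continue
            ang = rng.uniform(0, 2 * np.pi)
            cand = origin + dist * np.array([np.cos(ang), np.sin(ang)])
            if all(np.hypot(*(cand - p)) >= config.min_site_spacing for p in pts):
                break
        else:
            raise ValueError(
                "could not place feeding sites at the requested spacing"
            )
        pts.append(cand)
        ids.append(f"{prefix}A{j + 1}")
    return pd.DataFrame(
        {
            "site_id": ids,
            "x": [p[0] for p in pts],
            "y": [p[1] for p in pts],
            "managed": True,
        }
    )


def generate_landscape(
    config: SimConfig, roster: pd.DataFrame | None = None
) -> FeedingSiteSet:
    """Feeding-site landscape for every individual neighbourhood.

    Each individual gets a well-separated neighbourhood containing one M
    candidate and its alternate sites at the configured spacing (mean
    700 m). Roles are pre-assigned from the design (the analysis pipeline
    re-derives them from the data as a cross-check). Repeat individuals
    reuse their neighbourhood in the second winter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    if roster is None:
        roster = _build_roster(
            config, np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0]))
        )
    frames = []
    roles: dict[str, str] = {}
    for nb in sorted(roster["neighbourhood"].unique()):
        origin = np.array([float(nb) * NEIGHBOURHOOD_SPACING, 0.0])
        frame = _place_neighbourhood_sites(config, rng, origin, prefix=f"N{nb:02d}")
        frames.append(frame)
        for ay in roster.loc[roster["neighbourhood"] == nb, "animal_year_id"]:
            roles[ay] = frame["site_id"].iloc[0]
    return FeedingSiteSet(sites=pd.concat(frames, ignore_index=True), roles=roles)


# ---------------------------------------------------------------------------
# The three-mode mover
# ---------------------------------------------------------------------------

def _wrapped_cauchy(rng: np.random.Generator, rho: float) -> float:
    """Draw a turning angle from a wrapped Cauchy with mean 0."""
    u = rng.random()
    return 2.0 * np.arctan((1 - rho) / (1 + rho) * np.tan(np.pi * (u - 0.5)))


def _circ_weighted_mean(a: float, b: float, w_b: float) -> float:
    return float(
        np.arctan2(
            (1 - w_b) * np.sin(a) + w_b * np.sin(b),
            (1 - w_b) * np.cos(a) + w_b * np.cos(b),
        )
    )


def simulate_animal_year(
    sites: FeedingSiteSet,
    p_i: float,
    schedule: PhaseSchedule,
    config: SimConfig,
    seed: int,
    animal_year_id: str = "sim-ay",
    animal_id: str = "sim",
    sex: str = "F",
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one animal-year's hourly trajectory through the experiment.

    The animal's home-range centre sits a fixed distance from its
    manipulated site; availability of M follows the phase schedule
    (``config.closure_effect`` during closure, 1 otherwise), alternates are
    always available. Returns the trajectory plus the latent ground truth
    (preference, centre, per-fix modes).
    """
    if not 0 <= p_i <= 1:
        raise ValueError("p_i must lie in [0, 1]")
    if schedule.raw_length("pre") <= pd.Timedelta(0):
        raise ValueError("schedule phases must be contiguous and ordered")
    rng = np.random.default_rng(seed)
    role_key = (schedule.animal_year_id
                if schedule.animal_year_id in sites.roles else animal_year_id)
    mg = sites.role_frame(role_key)
    site_xy = mg[["x", "y"]].to_numpy(float)
    site_ids = mg["site_id"].to_numpy()
    fam = np.where(mg["role"].to_numpy() == "M", config.familiarity_m,
                   config.familiarity_a)
    m_idx = int(np.flatnonzero(mg["role"].to_numpy() == "M")[0])

    ang = rng.uniform(0, 2 * np.pi)
    centre = site_xy[m_idx] + config.home_offset * np.array([np.cos(ang), np.sin(ang)])

    dt = pd.Timedelta(hours=config.fix_interval_hours)
    times = pd.date_range(schedule.pre_start, schedule.post_end - dt, freq=dt, tz="UTC")
    n = len(times)
    closure_mask = (times >= schedule.closure_start) & (times < schedule.post_start)

    k = config.step_shape
    p_start = min(0.95, p_i / (config.dwell_mean_hours * max(1e-12, 1 - p_i))) \
        if p_i < 1 else 0.95
    p_start *= config.attend_rate_scale

    pos = centre + rng.normal(0, 30, size=2)
    heading = rng.uniform(-np.pi, np.pi)
    mode = "FORAGE"
    target: int | None = None

    xs = np.empty(n)
    ys = np.empty(n)
    modes = np.empty(n, dtype=object)
    xs[0], ys[0] = pos
    modes[0] = mode

    for t in range(1, n):
        avail = np.ones(len(site_ids))
        if closure_mask[t]:
            avail[m_idx] = config.closure_effect
        if mode == "ATTEND":
            assert target is not None
            if avail[target] <= 0 or rng.random() < 1 / config.dwell_mean_hours:
                mode, target = "FORAGE", None
        if mode == "FORAGE":
            d = np.hypot(*(site_xy - pos).T)
            w = fam * np.exp(-d / config.target_decay) * avail
            # poor prospects (all sites far or closed) damp the urge to visit
            gate = min(1.0, w.sum() / config.attend_gate)
            if w.sum() > 0 and rng.random() < p_start * gate:
                target = int(rng.choice(len(w), p=w / w.sum()))
                mode = "RELOCATE"

        if mode == "ATTEND":
            r = rng.gamma(k, config.attend_step_mean / k)
            a = rng.uniform(-np.pi, np.pi)
            new = site_xy[target] + r * np.array([np.cos(a), np.sin(a)])
        elif mode == "RELOCATE":
            to_t = site_xy[target] - pos
            dist = np.hypot(*to_t)
            bearing = np.arctan2(to_t[1], to_t[0])
            heading = _circ_weighted_mean(heading, bearing,
                                          config.heading_weight_target)
            r = min(rng.gamma(k, config.relocate_step_mean / k), dist)
            new = pos + r * np.array([np.cos(heading), np.sin(heading)])
            if np.hypot(*(site_xy[target] - new)) <= config.arrive_radius:
                mode = "ATTEND"
        else:  # FORAGE
            heading = heading + _wrapped_cauchy(rng, config.forage_turn_rho)
            r = rng.gamma(k, config.forage_step_mean / k)
            new = (
                pos
                + r * np.array([np.cos(heading), np.sin(heading)])
                + config.home_bias * (centre - pos)
            )
        # headings follow realized displacement (bias shifts forage headings)
        d_real = new - pos
        if np.hypot(*d_real) > 0:
            heading = float(np.arctan2(d_real[1], d_real[0]))
        pos = new
        xs[t], ys[t] = pos
        modes[t] = mode

    keep = np.ones(n, dtype=bool)
    if config.dropout > 0:
        keep = rng.random(n) >= config.dropout
        keep[:2] = True  # a trajectory needs at least two fixes
    fixes = pd.DataFrame({"timestamp": times[keep], "x": xs[keep], "y": ys[keep]})
    traj = Trajectory(
        animal_year_id=animal_year_id,
        animal_id=animal_id,
        sex=sex,
        year=int(schedule.pre_start.year),
        fixes=fixes,
    )
    phase = np.where(closure_mask, "closure",
                     np.where(times < schedule.closure_start, "pre", "post"))
    truth = GroundTruth(
        animal_year_id=animal_year_id,
        p_i=float(p_i),
        home_centre=(float(centre[0]), float(centre[1])),
        manipulated_site_id=str(site_ids[m_idx]),
        mode_counts={m: int((modes[keep] == m).sum())
                     for m in ("ATTEND", "FORAGE", "RELOCATE")},
        availability={
            "pre": {"M": 1.0, "A": 1.0},
            "closure": {"M": float(config.closure_effect), "A": 1.0},
            "post": {"M": 1.0, "A": 1.0},
        },
        modes=modes[keep],
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Whole experiments
# ---------------------------------------------------------------------------

def _schedule_for(ay: pd.Series, config: SimConfig,
                  rng: np.random.Generator) -> PhaseSchedule:
    start = pd.Timestamp(f"{int(ay['year'])}-01-15", tz="UTC") + pd.Timedelta(
        days=int(rng.integers(0, 21))
    )
    span = pd.Timedelta(days=config.phase_length_days)
    return PhaseSchedule(
        animal_year_id=ay["animal_year_id"],
        pre_start=start,
        closure_start=start + span,
        post_start=start + 2 * span,
        post_end=start + 3 * span,
    )


def simulate_experiment(
    config: SimConfig, out_dir: str | Path | None = None
) -> ExperimentBundle:
    """Simulate a complete experiment; optionally write the input bundle.

    Builds the roster, landscape and phase schedules, draws each
    animal-year's preference from the configured Beta, and simulates every
    trajectory. When ``out_dir`` is given, writes ``fixes.csv``,
    ``sites.csv``, ``schedule.csv`` (pipeline input formats),
    ``ground_truth.json`` and a ``manifest.json`` with the full
    configuration and seed; identical configurations produce byte-identical
    files.
    """
    root = np.random.SeedSequence([config.rng_seed])
    rng_roster = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0]))
    roster = _build_roster(config, rng_roster)
    sites = generate_landscape(config, roster)
    rng_design = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))

    trajs: list[Trajectory] = []
    schedules: dict[str, PhaseSchedule] = {}
    truths: dict[str, GroundTruth] = {}
    for i, (_, ay) in enumerate(roster.iterrows()):
        sched = _schedule_for(ay, config, rng_design)
        p_i = float(rng_design.beta(config.preference_alpha, config.preference_beta))
        traj, truth = simulate_animal_year(
            sites,
            p_i,
            sched,
            config,
            seed=int(np.random.default_rng(
                np.random.SeedSequence([config.rng_seed, 3, i])).integers(2**31)),
            animal_year_id=ay["animal_year_id"],
            animal_id=ay["animal_id"],
            sex=ay["sex"],
        )
        trajs.append(traj)
        schedules[ay["animal_year_id"]] = dataclasses.replace(
            sched,
            capture_location=(float(traj.fixes["x"].iloc[0]),
                              float(traj.fixes["y"].iloc[0])),
            manipulated_site_id=truth.manipulated_site_id,
        )
        truths[ay["animal_year_id"]] = truth

    bundle = ExperimentBundle(
        config=config, trajectories=trajs, sites=sites,
        schedules=schedules, ground_truth=truths,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fixes(trajs, out / "fixes.csv")
        write_sites(sites, out / "sites.csv")
        write_schedules(schedules.values(), out / "schedule.csv")
        gt = {
            ay: {
                "p_i": t.p_i,
                "home_centre": list(t.home_centre),
                "manipulated_site_id": t.manipulated_site_id,
                "mode_counts": t.mode_counts,
                "availability": t.availability,
            }
            for ay, t in truths.items()
        }
        (out / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))
        manifest = {"config": dataclasses.asdict(config), "seed": config.rng_seed}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return bundle
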