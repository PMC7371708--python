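"""End-to-end analysis: from raw fixes to model tables and fitted models.

The order of operations mirrors the experimental workflow: truncate each
animal-year's phases to a common 14-day window; compute steps and the
population scale l (mean hourly displacement); identify each animal-year's
manipulated feeding site from its pre-closure fixes; classify fixes into
M/A/V at a buffer of l; score feeding-site preference h_FS; estimate
per-phase utilization distributions (bandwidth l/2), isopleth areas and
between-phase overlaps; and fit the mixed-model battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import inference, resource_states, space_use, trajectories
from .resource_states import FeedingSiteSet
from .trajectories import PhaseSchedule, Trajectory

__all__ = ["AnalysisResult", "prepare", "run_analysis",
           "CONTRASTS", "logit_clamped"]

#: Phase-pair contrasts for space-use overlap, reference first.
CONTRASTS = (("pre", "closure"), ("closure", "post"), ("pre", "post"))


def logit_clamped(p: np.ndarray | float, eps: float = trajectories.LOGIT_EPS):
    q = np.clip(p, eps, 1 - eps)
    return np.log(q / (1 - q))


@dataclass
class AnalysisResult:
    """Everything the pipeline computes, ready for reporting."""

    l: float
    preferences: pd.DataFrame          # animal_year_id, h_fs, sex, animal_id
    buffer_sensitivity: pd.DataFrame
    areas: pd.DataFrame                # animal_year_id, phase, level, area_ha
    overlaps: pd.DataFrame             # animal_year_id, contrast, vi
    steps: pd.DataFrame                # per-step table with transforms + lags
    states: pd.DataFrame               # per-fix state table at the working buffer
    resource_usability: pd.DataFrame
    model_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    fits: dict[str, inference.ModelFit] = field(default_factory=dict)

    def phase_summary(self) -> pd.DataFrame:
        """Per-phase means of the headline observables."""
        a95 = (self.areas[self.areas["level"] == 0.95]
               .groupby("phase", observed=True)["area_ha"].agg(["mean", "std"]))
        a50 = (self.areas[self.areas["level"] == 0.50]
               .groupby("phase", observed=True)["area_ha"].agg(["mean", "std"]))
        st = (self.steps[~self.steps["gap"]]
              .groupby("phase", observed=True)["step"].agg(["mean", "std"]))
        use = (self.states.groupby("phase", observed=True)[["u_M", "u_A", "u_V"]]
               .mean())
        out = pd.concat(
            {"home_range_ha": a95, "core_area_ha": a50, "step_m": st,
             "resource_use": use}, axis=1
        )
        return out


def prepare(
    trajs: Sequence[Trajectory],
    schedules: Mapping[str, PhaseSchedule],
    target_days: float = 14.0,
) -> tuple[list[Trajectory], float, dict[str, pd.DataFrame]]:
    """Truncate phases, compute step tables, and the population scale l."""
    target = pd.Timedelta(days=target_days)
    trunc = [trajectories.truncate_phases(t, schedules[t.animal_year_id], target)
             for t in trajs]
    steps = {t.animal_year_id: trajectories.compute_steps(t) for t in trunc}
    l = trajectories.population_mean_step(steps.values())
    return trunc, l, steps


def run_analysis(
    trajs: Sequence[Trajectory],
    sites: FeedingSiteSet,
    schedules: Mapping[str, PhaseSchedule],
    target_days: float = 14.0,
    resolution: float = space_use.DEFAULT_RESOLUTION,
    buffer_scale: float = 1.0,
    auto_scale: bool = False,
    alpha: float = 0.05,
    fit_models: bool = True,
    lrt_pvalues: bool = True,
    drop_terms: bool = False,
    exclude_unusable: bool = True,
) -> AnalysisResult:
    """Run the full analysis on one experiment's inputs.

    ``buffer_scale`` fixes the working feeding-site buffer at that multiple
    of l (1 by default, for comparability); with ``auto_scale`` the
    IQR-maximizing scale from the sensitivity analysis is used instead.
    ``drop_terms`` additionally runs backward elimination on every model
    (slower); otherwise the full fixed-effect structures are reported.
    """
    trunc, l, step_tables = prepare(trajs, schedules, target_days)
    meta = {t.animal_year_id: t for t in trunc}

    # --- manipulated-site identification (from the data, per animal-year)
    roles = dict(sites.roles)
    for t in trunc:
        pre = t.fixes[t.fixes["phase"] == "pre"]
        mg = sites.managed
        roles[t.animal_year_id] = resource_states.assign_manipulated_site(
            pre, mg, radius=l
        )
    sites = FeedingSiteSet(sites=sites.sites.copy(), roles=roles)

    # --- buffer sensitivity and working scale
    sens = resource_states.buffer_sensitivity(trunc, sites, l)
    if auto_scale:
        working_scale = float(
            sens.loc[sens["best"], "buffer_scale"].iloc[0]
        )
    else:
        working_scale = buffer_scale

    # --- states and preference at the working buffer
    states_list, pref_rows, usable_rows = [], [], []
    for t in trunc:
        st = resource_states.classify_states(
            t, sites, buffer=working_scale * l, buffer_scale=working_scale
        )
        states_list.append(st)
        pref_rows.append({
            "animal_year_id": t.animal_year_id,
            "animal_id": t.animal_id,
            "sex": t.sex,
            "h_fs": resource_states.compute_h_fs(st),
        })
        ok, reason = resource_states.usable_for_resource_models(
            t.animal_year_id, st)
        usable_rows.append({"animal_year_id": t.animal_year_id,
                            "usable": ok, "reason": reason})
    states = pd.concat(states_list, ignore_index=True)
    prefs = pd.DataFrame(pref_rows)
    usable = pd.DataFrame(usable_rows)

    # --- space use: per-phase UDs, areas, overlaps
    bandwidth = l / 2
    area_rows, ov_rows = [], []
    for t in trunc:
        uds = {}
        for ph in trajectories.PHASES:
            fx = t.fixes[t.fixes["phase"] == ph]
            if len(fx) == 0:
                continue
            uds[ph] = space_use.estimate_ud(fx, resolution=resolution,
                                            bandwidth=bandwidth)
            for level in (0.95, 0.50):
                iso = space_use.isopleth_area(uds[ph], level)
                area_rows.append({"animal_year_id": t.animal_year_id,
                                  "phase": ph, "level": level,
                                  "area_ha": iso["area_ha"]})
        for a, b in CONTRASTS:
            if a in uds and b in uds:
                ov_rows.append({
                    "animal_year_id": t.animal_year_id,
                    "contrast": f"{a}/{b}",
                    "vi": space_use.vi_overlap(uds[a], uds[b]),
                })
    areas = pd.DataFrame(area_rows)
    areas["phase"] = pd.Categorical(areas["phase"],
                                    categories=list(trajectories.PHASES))
    overlaps = pd.DataFrame(ov_rows)
    overlaps["contrast"] = pd.Categorical(
        overlaps["contrast"], categories=[f"{a}/{b}" for a, b in CONTRASTS])

    # --- movement table
    steps = pd.concat(
        [trajectories.transform_movement(s) for s in step_tables.values()],
        ignore_index=True,
    )
    steps = trajectories.lag_features(steps, columns=("log_step",))

    result = AnalysisResult(
        l=l, preferences=prefs, buffer_sensitivity=sens, areas=areas,
        overlaps=overlaps, steps=steps, states=states,
        resource_usability=usable,
    )
    if not fit_models:
        return result

    # --- model tables
    key = prefs.set_index("animal_year_id")
    sex_cat = lambda s: pd.Categorical(s, categories=["F", "M"])

    def attach(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["ind"] = df["animal_year_id"]
        df["animal_id"] = df["animal_year_id"].map(key["animal_id"])
        df["h_fs"] = df["animal_year_id"].map(key["h_fs"]).astype(float)
        df["sex"] = sex_cat(df["animal_year_id"].map(key["sex"]))
        return df

    tables: dict[str, pd.DataFrame] = {}
    for level, name in ((0.95, "home_range"), (0.50, "core_area")):
        tb = attach(areas[areas["level"] == level])
        tb["log_area"] = np.log(tb["area_ha"])
        tables[name] = tb
    tb = attach(overlaps)
    tb["logit_vi"] = logit_clamped(tb["vi"].to_numpy())
    tables["overlap"] = tb

    mv = attach(steps)
    mv = mv[mv["phase"].notna()]
    lag_cols = [f"log_step_lag{k}" for k in (1, 2, 24)]
    tables["step_length"] = mv.dropna(subset=["log_step"] + lag_cols)
    tables["turning_angle"] = mv.dropna(subset=["phi"])

    rs = attach(states)
    if exclude_unusable:
        ok_ids = set(usable.loc[usable["usable"], "animal_year_id"])
        rs = rs[rs["animal_year_id"].isin(ok_ids)]
    for u in ("u_M", "u_A", "u_V"):
        rs = rs.sort_values(["animal_year_id", "timestamp"])
        lagged = rs.groupby("animal_year_id", observed=True)[u]
        for k in (1, 2, 24):
            rs[f"{u}_lag{k}"] = lagged.shift(k)
    tables["resource"] = rs

    # --- fits
    fits: dict[str, inference.ModelFit] = {}
    phase_terms = ["phase", "h_fs", "phase:h_fs", "sex", "phase:sex"]
    contrast_terms = ["contrast", "h_fs", "contrast:h_fs", "sex",
                      "contrast:sex"]

    def run(name, table, response, terms, fitter):
        if drop_terms:
            fits[name] = inference.drop_nonsignificant(
                table, response, terms, alpha=alpha, fitter=fitter)
        else:
            fits[name] = fitter(table, response, terms, pvalues=lrt_pvalues)

    run("home_range", tables["home_range"], "log_area", phase_terms,
        inference.fit_lmm)
    run("core_area", tables["core_area"], "log_area", phase_terms,
        inference.fit_lmm)
    run("overlap", tables["overlap"], "logit_vi", contrast_terms,
        inference.fit_lmm)
    run("step_length", tables["step_length"], "log_step",
        phase_terms + lag_cols, inference.fit_lmm)
    run("turning_angle", tables["turning_angle"], "phi", phase_terms,
        inference.fit_lmm)

    for state in ("M", "A"):
        resp = f"u_{state}"
        lag_terms = [f"{resp}_lag{k}" for k in (1, 2, 24)]
        tbl = tables["resource"].dropna(subset=lag_terms)
        run(f"use_{state}", tbl, resp, phase_terms + lag_terms,
            inference.fit_resource_glmm)
    # V: the pre-closure level is dropped (h_FS is defined from pre-closure
    # V use, so including it would be circular); closure is the reference.
    vt = tables["resource"]
    vt = vt[vt["phase"].isin(["closure", "post"])].copy()
    vt["phase"] = pd.Categorical(vt["phase"], categories=["closure", "post"])
    lag_terms = [f"u_V_lag{k}" for k in (1, 2, 24)]
    vt = vt.dropna(subset=lag_terms)
    run("use_V", vt, "u_V", phase_terms + lag_terms,
        inference.fit_resource_glmm)

    result.model_tables = tables
    result.fits = fits
    return result
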