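"""End-to-end study analogue on synthetic cohorts.

Simulates two (or more) arms of cells — e.g. a wild-type-like arm and a
disease-like arm with the large-sIPSC component reduced — and runs the full
analysis chain per cell: event detection, per-cell summaries over an
event-count quota, cumulative-normal mixture split (A_th), rise-rate
statistics, burstiness/memory per event class, all-point-histogram phasic
charges with E/I matrices, then between-arm statistics (Mann–Whitney on
per-cell summaries, two-level nested ANOVA on phasic charges, three-level
nested ANOVA on E/I ratios).

Per-cell heterogeneity is drawn from arm-level hyper-distributions
(log-normal multipliers applied per animal and per cell) so the nested
ANOVA's among-animal and among-cell variance structure is non-trivial.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anova import NestedAnova, mann_whitney
from .detection import detect_events, summarize_cell
from .mixture import AmplitudeMixtureModel, split_by_threshold
from .phasic import ei_matrix, fractional_deviation, measure_segment, sample_segments
from .synthetic import (
    AmplitudeMixtureSpec,
    IEIProcessSpec,
    KernelSpec,
    SimConfig,
    synthesize_trace,
)
from .temporal import bm_table

__all__ = ["ArmConfig", "StudyConfig", "run_study"]


@dataclass(frozen=True)
class ArmConfig:
    """One study arm: cell counts and arm-level synthesis hyper-parameters."""

    name: str
    n_cells: int = 12
    n_animals: int = 4
    epsc_rate: float = 7.0  # Hz
    ipsc_rate: float = 10.0  # Hz
    epsc_amps: AmplitudeMixtureSpec = field(
        default_factory=lambda: AmplitudeMixtureSpec(0.8, 18.0, 5.0, 38.0, 10.0)
    )
    ipsc_amps: AmplitudeMixtureSpec = field(
        default_factory=lambda: AmplitudeMixtureSpec(0.8, 28.0, 8.0, 95.0, 25.0)
    )
    animal_log_sd: float = 0.15  # log-normal multiplier SD at the animal level
    cell_log_sd: float = 0.10  # ... at the cell level


@dataclass(frozen=True)
class StudyConfig:
    """Whole-study configuration (defaults mirror the study conditions)."""

    arms: tuple[ArmConfig, ...] = (
        ArmConfig("WT"),
        ArmConfig(
            "AD",
            ipsc_amps=AmplitudeMixtureSpec(0.8, 24.0, 8.0, 57.0, 20.0),
        ),
    )
    duration: float = 240.0  # s per trace (4 min recordings)
    fs: float = 10_000.0
    noise_sigma: float = 7.0
    n_epsc_events: int = 161  # per-cell event quota for summaries
    n_ipsc_events: int = 626
    m_segments: int = 10  # E segments per cell
    n_segments: int = 10  # I segments per cell
    segment_duration: float = 15.0
    seed: int = 0

    def scaled(self, **kw) -> "StudyConfig":
        return replace(self, **kw)


def _simulate_cell_traces(study, arm, rate_mult, amp_mult, rng):
    """Synthesize one cell's sEPSC and sIPSC traces with jittered parameters."""
    def jitter_amps(spec):
        return AmplitudeMixtureSpec(
            spec.w1,
            spec.mu1 * amp_mult,
            spec.sigma1 * amp_mult,
            spec.mu2 * amp_mult,
            spec.sigma2 * amp_mult,
        )

    traces = {}
    for kind, rate, amps, pol, vh in (
        ("epsc", arm.epsc_rate, arm.epsc_amps, "inward", -60.0),
        ("ipsc", arm.ipsc_rate, arm.ipsc_amps, "outward", 0.0),
    ):
        cfg = SimConfig(
            duration=study.duration,
            fs=study.fs,
            noise_sigma=study.noise_sigma,
            iei=IEIProcessSpec("gamma", rate * rate_mult, shape=2.0),
            amps=jitter_amps(amps),
            kernel=KernelSpec(0.5, 6.0, pol),
            v_hold=vh,
        )
        traces[kind] = synthesize_trace(cfg, rng)
    return traces


def _analyze_cell(study, cell_id, traces, rng):
    """Run detection → mixture split → kinetics → B/M → phasic E/I for one cell."""
    out = {"cell_id": cell_id}
    ieis_by_class = {}
    for kind, quota, pol in (
        ("epsc", study.n_epsc_events, "inward"),
        ("ipsc", study.n_ipsc_events, "outward"),
    ):
        trace, _truth = traces[kind]
        table = detect_events(trace, polarity=pol)
        if len(table) < 10:
            warnings.warn(f"cell {cell_id}: too few {kind} events detected")
            out[f"{kind}_status"] = "failed"
            continue
        summ = summarize_cell(table, quota, rng)
        run = summ["events"]
        out[f"{kind}_frequency_hz"] = summ["frequency_hz"]
        out[f"{kind}_amplitude_pA"] = summ["mean_amplitude_pA"]
        out[f"{kind}_rr_pA_per_ms"] = summ["mean_rate_of_rise_pA_per_ms"]
        out[f"{kind}_status"] = "ok"

        # objective small/large split on the summarized run
        model = AmplitudeMixtureModel(run.amplitudes)
        fit1, fit2 = model.fit(1), model.fit(2)
        ftest = fit1.compare_to(fit2)
        out[f"{kind}_f_p"] = ftest.p_value
        thr = fit2.amplitude_threshold()
        out[f"{kind}_a_th_pA"] = thr.a_th
        labelled = split_by_threshold(run, thr.a_th)
        small = labelled.subset(labelled.amplitudes <= thr.a_th)
        large = labelled.subset(labelled.amplitudes > thr.a_th)
        out[f"{kind}_small_amp_pA"] = small.mean_amplitude
        out[f"{kind}_large_amp_pA"] = large.mean_amplitude
        out[f"{kind}_small_rr"] = (
            float(np.mean(small.rates_of_rise)) if len(small) else float("nan")
        )
        out[f"{kind}_large_rr"] = (
            float(np.mean(large.rates_of_rise)) if len(large) else float("nan")
        )
        ieis_by_class[kind] = {
            "all": summ["ieis_s"],
            "small": np.diff(small.peak_times) if len(small) > 2 else np.empty(0),
            "large": np.diff(large.peak_times) if len(large) > 2 else np.empty(0),
        }

    out["_ieis"] = ieis_by_class

    # phasic charges and E/I
    try:
        e_windows = sample_segments(
            traces["epsc"][0], study.m_segments, study.segment_duration, rng
        )
        i_windows = sample_segments(
            traces["ipsc"][0], study.n_segments, study.segment_duration, rng
        )
        e_meas = [
            measure_segment(traces["epsc"][0], w, j) for j, w in enumerate(e_windows)
        ]
        i_meas = [
            measure_segment(traces["ipsc"][0], w, j) for j, w in enumerate(i_windows)
        ]
        mat = ei_matrix(e_meas, i_meas)
        ratios = mat.flat
        out["_e_charges"] = [m.charge for m in e_meas]
        out["_i_charges"] = [m.charge for m in i_meas]
        out["_ei_ratios"] = ratios.tolist()
        out["e_charge_pC"] = float(np.mean(out["_e_charges"]))
        out["i_charge_pC"] = float(np.mean(out["_i_charges"]))
        out["ei_mean"] = mat.mean
        out["ei_fractional_dev_100"] = fractional_deviation(ratios, len(ratios))
        out["phasic_status"] = "ok"
    except (RuntimeError, ValueError) as exc:
        warnings.warn(f"cell {cell_id}: phasic stage failed: {exc}")
        out["phasic_status"] = f"failed: {exc}"
    return out


def _group_tests(cells: pd.DataFrame, arms) -> dict:
    """Between-arm Mann–Whitney tests on per-cell summaries."""
    if len(arms) != 2:
        return {}
    a, b = arms[0].name, arms[1].name
    tests = {}
    metrics = [
        "epsc_frequency_hz", "ipsc_frequency_hz",
        "epsc_amplitude_pA", "ipsc_amplitude_pA",
        "epsc_rr_pA_per_ms", "ipsc_rr_pA_per_ms",
        "epsc_a_th_pA", "ipsc_a_th_pA",
        "ipsc_small_amp_pA", "ipsc_large_amp_pA",
        "ipsc_large_rr",
    ]
    for mcol in metrics:
        if mcol not in cells.columns:
            continue
        xa = cells.loc[cells.arm == a, mcol].dropna().to_numpy()
        xb = cells.loc[cells.arm == b, mcol].dropna().to_numpy()
        if len(xa) and len(xb):
            u, p = mann_whitney(xa, xb)
            tests[mcol] = {
                "U": u, "p": p,
                f"mean_{a}": float(np.mean(xa)),
                f"mean_{b}": float(np.mean(xb)),
            }
    return tests


def run_study(cfg: StudyConfig, out_dir: str | os.PathLike | None = None) -> dict:
    """Run the full synthetic-study analogue; deterministic given ``cfg.seed``.

    Returns a report dict with per-cell summaries, per-class (B, M) tables,
    between-arm rank tests, nested-ANOVA results on phasic charges (two
    levels: arm/animal) and on E/I ratios (three levels: arm/animal/cell),
    and a per-stage status.  When ``out_dir`` is given, CSV/JSON artifacts
    are written there.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    bm_cells: dict = {}
    ei_long = []
    status: dict = {}

    for arm in cfg.arms:
        animal_mults = np.exp(
            rng.normal(0.0, arm.animal_log_sd, size=arm.n_animals)
        )
        for c in range(arm.n_cells):
            animal = c % arm.n_animals
            cell_mult = float(np.exp(rng.normal(0.0, arm.cell_log_sd)))
            amp_mult = animal_mults[animal] * cell_mult
            rate_mult = float(
                np.exp(rng.normal(0.0, arm.cell_log_sd))
            ) * animal_mults[animal]
            cell_id = f"{arm.name}_a{animal}_c{c}"
            traces = _simulate_cell_traces(cfg, arm, rate_mult, amp_mult, rng)
            res = _analyze_cell(cfg, cell_id, traces, rng)
            res["arm"] = arm.name
            res["animal"] = f"{arm.name}_a{animal}"
            ieis = res.pop("_ieis", {})
            for kind, by_class in ieis.items():
                bm_cells[f"{cell_id}_{kind}"] = {
                    k: v for k, v in by_class.items() if len(v) >= 2
                }
            for r in res.pop("_ei_ratios", []):
                ei_long.append(
                    {
                        "group": arm.name,
                        "animal": res["animal"],
                        "cell": cell_id,
                        "value": r,
                    }
                )
            res.pop("_e_charges", None)
            res.pop("_i_charges", None)
            rows.append(res)

    cells = pd.DataFrame(rows)
    report: dict = {"config_seed": cfg.seed, "cells": cells}
    status["simulate_detect"] = "ok"

    report["bm"] = bm_table(bm_cells)
    status["bm"] = "ok"

    report["group_tests"] = _group_tests(cells, cfg.arms)
    status["group_tests"] = "ok"

    # nested ANOVAs on phasic measures
    ei_df = pd.DataFrame(ei_long)
    try:
        for charge_col, label in (("e_charge_pC", "E"), ("i_charge_pC", "I")):
            sub = cells.dropna(subset=[charge_col])
            res2 = NestedAnova(
                sub[charge_col].to_numpy(),
                [sub["arm"].to_numpy(), sub["animal"].to_numpy()],
            ).fit()
            report[f"nested_anova_{label}"] = res2
        if len(ei_df):
            res3 = NestedAnova.from_dataframe(
                ei_df, "value", ["group", "animal", "cell"]
            ).fit()
            report["nested_anova_EI"] = res3
        status["nested_anova"] = "ok"
    except (ValueError, RuntimeError) as exc:
        status["nested_anova"] = f"failed: {exc}"

    report["status"] = status

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        cells.to_csv(os.path.join(out_dir, "cells.csv"), index=False)
        report["bm"].to_csv(os.path.join(out_dir, "bm.csv"), index=False)
        if len(ei_df):
            ei_df.to_csv(os.path.join(out_dir, "ei_ratios.csv"), index=False)
        blob = {
            "seed": cfg.seed,
            "arms": [dataclasses.asdict(a) for a in cfg.arms],
            "group_tests": report["group_tests"],
            "status": status,
        }
        for key in ("nested_anova_E", "nested_anova_I", "nested_anova_EI"):
            if key in report:
                blob[key] = report[key].to_dict()
        with open(os.path.join(out_dir, "report.json"), "w") as f:
            json.dump(blob, f, indent=2, default=float)
    return report
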