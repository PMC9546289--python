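"""Study orchestration: simulate or load curves, run the per-modality
analyses, and assemble group comparisons into reproducible result bundles.

Every run is deterministic given its seed; outputs are per-curve CSV
tables, a JSON comparison report and a run log echoing the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adhesion import AdhesionConfig, analyze_adhesion
from .curves import ForceCurve
from .elasticity import (
    IndenterGeometry,
    MaxForceNotReachedError,
    ShallowCurveError,
    fit_modulus,
    indentation_at_force,
)
from .io import Manifest, iter_manifest_curves
from .preprocess import QCThresholds, process_curve
from .simulate import (
    AdhesionSimConfig,
    IndentationSimConfig,
    UnfoldingSimConfig,
    simulate_adhesion_population,
    simulate_indentation_population,
    simulate_unfolding_population,
)
from .stats import compare_groups
from .unfolding import SawtoothConfig, analyze_trace, summarize_unfolding

log = logging.getLogger("forcespec")


@dataclass
class PipelineError(RuntimeError):
    message: str

    def __str__(self) -> str:
        return self.message


# ---------------------------------------------------------------------------
# per-modality batch analyses (in-memory API used by CLI and acceptance)


def analyze_indentation_batch(
    curves: list[ForceCurve],
    geometry: IndenterGeometry | None = None,
    fit_depth_nm: float = 500.0,
    fraction_noncontact: float = 0.5,
    qc_thresholds: QCThresholds | None = None,
    target_force_pn: float = 1000.0,
) -> pd.DataFrame:
    """Preprocess + Hertz-Sneddon fit per curve; QC failures yield NaN rows."""
    geometry = geometry or IndenterGeometry()
    rows = []
    for curve in curves:
        row = {
            "curve_id": curve.curve_id,
            "cell_id": curve.cell_id,
            "group": curve.group_label,
            "E_kPa": np.nan,
            "delta_at_1nN_nm": np.nan,
            "rss_pN2": np.nan,
            "contact_point_nm": np.nan,
            "qc_passed": False,
            "qc_reasons": "",
        }
        processed = process_curve(
            curve, fraction_noncontact=fraction_noncontact, qc_thresholds=qc_thresholds
        )
        row["qc_passed"] = processed.qc.passed
        row["qc_reasons"] = ";".join(processed.qc.reasons)
        row["contact_point_nm"] = processed.contact_point
        if processed.qc.passed:
            try:
                fit = fit_modulus(processed, geometry, fit_depth_nm)
                row["E_kPa"] = fit.youngs_modulus_kpa
                row["rss_pN2"] = fit.rss_pn2
            except ShallowCurveError as exc:
                row["qc_passed"] = False
                row["qc_reasons"] = f"shallow_curve:{exc}"
            try:
                row["delta_at_1nN_nm"] = indentation_at_force(processed, target_force_pn)
            except MaxForceNotReachedError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_adhesion_batch(
    curves: list[ForceCurve], config: AdhesionConfig | None = None
) -> pd.DataFrame:
    rows = []
    for curve in curves:
        r = analyze_adhesion(curve, config)
        rows.append(
            {
                "curve_id": curve.curve_id,
                "cell_id": curve.cell_id,
                "group": curve.group_label,
                "work_fJ": r.work_fj,
                "max_adhesion_pN": r.max_adhesion_force_pn,
                "rupture_count": r.rupture_count,
                "detachment_nm": r.detachment_point_nm,
                "zero_force_nm": r.zero_force_point_nm,
                "qc_passed": r.qc.passed,
            }
        )
    return pd.DataFrame(rows)


def analyze_unfolding_batch(
    curves: list[ForceCurve], config: SawtoothConfig | None = None
) -> tuple[pd.DataFrame, list]:
    """Event table plus the raw TraceResult list (for acceptance filtering)."""
    traces = [analyze_trace(c, config) for c in curves]
    frames = [t.to_frame() for t in traces if t.events]
    events = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "curve_id",
                "order_index",
                "label",
                "peak_force_pN",
                "Lc_nm",
                "dLc_nm",
                "extension_nm",
                "rss",
                "pulling_speed_nm_s",
                "accepted",
            ]
        )
    )
    groups = {c.curve_id: c.group_label for c in curves}
    if len(events):
        events["group"] = events["curve_id"].map(groups)
    return events, traces


# ---------------------------------------------------------------------------
# two-group synthetic studies (the demo mirrors the published figure designs)


def run_stiffness_study(
    seed: int,
    out_dir: Path | None = None,
    mode_kpa: tuple[float, float] = (1.88, 2.72),
    sigma: float = 0.5,
    n_cells: int = 50,
    curves_per_cell: int = 10,
    labels: tuple[str, str] = ("Q", "R"),
    noise_sd_pn: float = 5.0,
) -> dict:
    """Two-group indentation study: simulate, fit, compare E and delta(1 nN)."""
    per_curve = []
    # both groups share one seed (common random numbers): the same standard
    # normal draws scale to either group's lognormal, so recovered group
    # deltas isolate measurement error from finite-sample drawing error
    for label, mode in zip(labels, mode_kpa):
        cfg = IndentationSimConfig(
            modulus_mode_kpa=mode,
            modulus_sigma=sigma,
            n_cells=n_cells,
            curves_per_cell=curves_per_cell,
            noise_sd_pn=noise_sd_pn,
            group_label=label,
            seed=seed,
        )
        curves, _truth = simulate_indentation_population(cfg)
        df = analyze_indentation_batch(curves, cfg.geometry)
        df["true_E_kPa"] = [float(c.annotations["true_E_kPa"]) for c in curves]
        per_curve.append(df)
    table = pd.concat(per_curve, ignore_index=True)
    ok = table[table["qc_passed"] & table["E_kPa"].notna()]
    groups_E = {lab: ok.loc[ok["group"] == lab, "E_kPa"].to_numpy() for lab in labels}
    comparison = compare_groups(groups_E, metric_name="youngs_modulus_kPa")
    ok_d = table[table["delta_at_1nN_nm"].notna()]
    groups_d = {
        lab: ok_d.loc[ok_d["group"] == lab, "delta_at_1nN_nm"].to_numpy() for lab in labels
    }
    comparison_delta = compare_groups(groups_d, metric_name="delta_at_1nN_nm")
    bundle = {
        "per_curve": table,
        "comparison": comparison,
        "comparison_delta": comparison_delta,
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "stiffness_per_curve.csv", index=False)
        _write_json(out_dir / "stiffness_comparison.json", comparison.to_dict())
        _write_json(out_dir / "indentation_comparison.json", comparison_delta.to_dict())
    return bundle


def run_adhesion_study(
    seed: int,
    out_dir: Path | None = None,
    median_work_fj: tuple[float, float] = (1.0, 2.5),
    work_sigma: float = 0.5,
    n_per_group: int = 90,
    labels: tuple[str, str] = ("Q", "R"),
    noise_sd_pn: float = 5.0,
) -> dict:
    """Two-group adhesion study with a configurable true median-work ratio."""
    per_curve = []
    # common random numbers across groups (see run_stiffness_study)
    for label, med in zip(labels, median_work_fj):
        cfg = AdhesionSimConfig(
            work_target_fj=med,
            noise_sd_pn=noise_sd_pn,
            group_label=label,
            seed=seed + 100,
        )
        curves, _truth = simulate_adhesion_population(cfg, n_per_group, work_sigma)
        per_curve.append(analyze_adhesion_batch(curves))
    table = pd.concat(per_curve, ignore_index=True)
    groups = {lab: table.loc[table["group"] == lab, "work_fJ"].to_numpy() for lab in labels}
    comparison = compare_groups(groups, metric_name="work_of_adhesion_fJ")
    bundle = {"per_curve": table, "comparison": comparison}
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "adhesion_per_curve.csv", index=False)
        _write_json(out_dir / "adhesion_comparison.json", comparison.to_dict())
    return bundle


def run_unfolding_study(
    seed: int,
    out_dir: Path | None = None,
    speeds: tuple[float, ...] = (400.0, 1600.0),
    n_traces_per_speed: int = 50,
    variant: str = "Q",
    noise_sd_pn: float = 5.0,
) -> dict:
    """Two-speed sawtooth study for one FLNA variant: simulate, detect, fit,
    classify, summarize."""
    from .simulate import FLNA_Q_BELL_EVANS, FLNA_R_BELL_EVANS, default_domain_layout

    be = {"Q": FLNA_Q_BELL_EVANS, "R": FLNA_R_BELL_EVANS}[variant]
    all_events, all_traces = [], []
    for offset, speed in enumerate(speeds):
        cfg = UnfoldingSimConfig(
            domain_layout=default_domain_layout(be),
            pulling_speed_nm_s=speed,
            sampling_rate_hz=4096.0 if speed >= 1000 else 1024.0,
            noise_sd_pn=noise_sd_pn,
            n_traces=n_traces_per_speed,
            group_label=f"{variant}-{int(speed)}",
            seed=seed + 200 + offset,
        )
        curves, _truth = simulate_unfolding_population(cfg)
        events, traces = analyze_unfolding_batch(curves)
        all_events.append(events)
        all_traces.extend(traces)
    events = pd.concat(all_events, ignore_index=True)
    summary_accepted = summarize_unfolding(all_traces, accepted_only=True)
    summary_all = summarize_unfolding(all_traces, accepted_only=False)
    bundle = {
        "events": events,
        "traces": all_traces,
        "summary_accepted": summary_accepted,
        "summary_all": summary_all,
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        events.to_csv(out_dir / f"unfolding_events_{variant}.csv", index=False)
        summary_accepted.to_csv(out_dir / f"unfolding_summary_{variant}.csv", index=False)
        summary_all.to_csv(out_dir / f"unfolding_summary_unfiltered_{variant}.csv", index=False)
    return bundle


# ---------------------------------------------------------------------------
# RunConfig-driven entry point


@dataclass
class RunConfig:
    """One reproducible pipeline run: mode, input source, parameters, seed."""

    mode: str  # indentation | adhesion | unfolding | demo
    seed: int = 0
    out_dir: str = "results"
    manifest: str | None = None
    simulation: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("indentation", "adhesion", "unfolding", "demo"):
            raise PipelineError(f"unknown run mode {self.mode!r}")
        if self.manifest is not None and self.simulation:
            raise PipelineError("exactly one input source: manifest OR simulation")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _load_manifest_curves(manifest_path: str) -> list[ForceCurve]:
    from .io import read_manifest

    manifest = read_manifest(manifest_path)
    curves = []
    for entry, curve, error in iter_manifest_curves(manifest):
        if error is not None:
            log.error("manifest entry %s failed: %s", entry.path, error)
            continue
        curves.append(curve)
    return curves


def run(config: RunConfig) -> dict:
    """Execute one configured run; deterministic given the seed.

    Writes per-curve tables, comparison JSON and a run log into the output
    directory; QC failures never abort, module errors name the curve.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    meta = {
        "forcespec_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config": asdict(config),
    }
    if config.mode == "demo":
        bundle = run_demo(config.seed, out)
    elif config.mode == "indentation":
        if config.manifest:
            curves = _load_manifest_curves(config.manifest)
            table = analyze_indentation_batch(curves, **config.parameters)
        else:
            sim = IndentationSimConfig(**config.simulation, seed=config.seed)
            curves, _ = simulate_indentation_population(sim)
            table = analyze_indentation_batch(curves, sim.geometry)
        if not len(table) or not table["qc_passed"].any():
            raise PipelineError("no curves passed QC")
        table.to_csv(out / "indentation_per_curve.csv", index=False)
        bundle = {"per_curve": table}
    elif config.mode == "adhesion":
        if config.manifest:
            curves = _load_manifest_curves(config.manifest)
        else:
            sim = AdhesionSimConfig(**config.simulation, seed=config.seed)
            curves, _ = simulate_adhesion_population(sim, int(config.parameters.get("n_curves", 90)))
        table = analyze_adhesion_batch(curves)
        if not len(table):
            raise PipelineError("no adhesion curves analysed")
        table.to_csv(out / "adhesion_per_curve.csv", index=False)
        bundle = {"per_curve": table}
    else:  # unfolding
        if config.manifest:
            curves = _load_manifest_curves(config.manifest)
        else:
            sim = UnfoldingSimConfig(**config.simulation, seed=config.seed)
            curves, _ = simulate_unfolding_population(sim)
        events, traces = analyze_unfolding_batch(curves)
        if not len(events):
            raise PipelineError("no unfolding events detected")
        events.to_csv(out / "unfolding_events.csv", index=False)
        summarize_unfolding(traces).to_csv(out / "unfolding_summary.csv", index=False)
        bundle = {"events": events, "traces": traces}
    _write_json(out / "run_log.json", meta)
    return bundle


def run_demo(seed: int, out_dir: Path | None = None, scale: float = 1.0) -> dict:
    """Full synthetic study mirroring the three figure-style analyses.

    ``scale`` < 1 shrinks the sample sizes proportionally (floor of 10
    curves or traces per group) for quick smoke runs.
    """
    n_cells = max(int(50 * scale), 5)
    n_adh = max(int(90 * scale), 10)
    n_unf = max(int(50 * scale), 10)
    stiffness = run_stiffness_study(seed, out_dir, n_cells=n_cells)
    adhesion = run_adhesion_study(seed, out_dir, n_per_group=n_adh)
    unfolding_q = run_unfolding_study(seed, out_dir, n_traces_per_speed=n_unf, variant="Q")
    unfolding_r = run_unfolding_study(seed + 1000, out_dir, n_traces_per_speed=n_unf, variant="R")
    return {
        "stiffness": stiffness,
        "adhesion": adhesion,
        "unfolding_Q": unfolding_q,
        "unfolding_R": unfolding_r,
    }
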