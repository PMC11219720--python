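"""Table formats, run configuration and the end-to-end orchestrator.

All tables are plain RFC-4180 CSV.  Missing vitals are empty fields, never
sentinel numbers.  A run writes a machine-readable manifest with the
configuration, seed and SHA-256 hashes of every output, so identical
config + seed yields identical hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .protocol import Group, standard_protocol
from .simulator import (
    FREQUENCIES_KHZ,
    SEGMENTS,
    SubjectParams,
    generate_dataset,
)
from . import pipeline as pl
from . import hemostats as hs

__all__ = [
    "IOError_",
    "RunConfig",
    "read_impedance_table",
    "write_impedance_table",
    "read_vitals_table",
    "write_vitals_table",
    "load_config",
    "run_pipeline",
    "analyze_group",
]

IMPEDANCE_COLUMNS = ["subject_id", "t_min", "segment", "frequency_khz", "z_ohm"]
VITALS_COLUMNS = ["subject_id", "t_min", "pr", "map", "sv", "svv"]


class IOError_(ValueError):
    """Malformed table or configuration."""


@dataclass
class RunConfig:
    """Configuration of a full simulate-and-analyze run."""

    groups: tuple[str, ...] = (
        "crystalloid",
        "crystalloid_dextrose",
        "crystalloid_albumin",
    )
    n_subjects: int = 5
    seed: int = 0
    noise_cv: float = 0.005
    segment: str = "torso"
    low_freq_khz: float = 5.0
    high_freq_khz: float = 1000.0
    spline_degree: int = 3
    curvature_threshold: float = 0.0015
    alpha: float = 0.05
    trajectory_window: tuple[float, float] = (0.0, 180.0)
    out_dir: str = "results"
    impedance_path: str | None = None  # analyze-only mode inputs
    vitals_path: str | None = None

    def __post_init__(self) -> None:
        if self.low_freq_khz >= self.high_freq_khz:
            raise IOError_("low_freq_khz must be below high_freq_khz")
        for f in (self.low_freq_khz, self.high_freq_khz):
            if f not in FREQUENCIES_KHZ:
                raise IOError_(f"frequency {f} kHz not in the measured set")


def load_config(path) -> RunConfig:
    """Read a RunConfig from JSON or YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise IOError_(f"config file {path} does not hold a mapping")
    if "groups" in data:
        data["groups"] = tuple(data["groups"])
    if "trajectory_window" in data:
        data["trajectory_window"] = tuple(data["trajectory_window"])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise IOError_(f"bad config key: {exc}") from None


# -- impedance tables ------------------------------------------------------


def read_impedance_table(path) -> pd.DataFrame:
    """Read and validate an impedance CSV.

    Rejects missing columns, unknown segments or frequencies, non-positive
    impedances and duplicate (subject, time, segment, frequency) keys,
    naming the offending rows (1-based data row numbers).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise IOError_(f"{path}: empty impedance table")
    missing = [c for c in IMPEDANCE_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    df = df[IMPEDANCE_COLUMNS].copy()
    df["t_min"] = df["t_min"].astype(float)
    df["frequency_khz"] = df["frequency_khz"].astype(float)
    df["z_ohm"] = df["z_ohm"].astype(float)

    bad_seg = ~df["segment"].isin(SEGMENTS)
    if bad_seg.any():
        rows = (df.index[bad_seg] + 1).tolist()[:5]
        raise IOError_(f"{path}: unknown segment in rows {rows}")
    bad_freq = ~df["frequency_khz"].isin(FREQUENCIES_KHZ)
    if bad_freq.any():
        rows = (df.index[bad_freq] + 1).tolist()[:5]
        raise IOError_(f"{path}: unknown frequency in rows {rows}")
    bad_z = ~(df["z_ohm"] > 0)
    if bad_z.any():
        rows = (df.index[bad_z] + 1).tolist()[:5]
        raise IOError_(f"{path}: non-positive impedance in rows {rows}")
    dup = df.duplicated(subset=["subject_id", "t_min", "segment", "frequency_khz"])
    if dup.any():
        rows = (df.index[dup] + 1).tolist()[:5]
        raise IOError_(f"{path}: duplicate measurement keys in rows {rows}")
    return df


def write_impedance_table(df: pd.DataFrame, path) -> None:
    df[IMPEDANCE_COLUMNS].to_csv(path, index=False)


def read_vitals_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise IOError_(f"{path}: empty vitals table")
    missing = [c for c in VITALS_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    df = df[VITALS_COLUMNS].copy()
    for c in VITALS_COLUMNS[1:]:
        df[c] = df[c].astype(float)
    return df


def write_vitals_table(df: pd.DataFrame, path) -> None:
    # NaN -> empty field for undetectable MAP/SV/SVV
    df[VITALS_COLUMNS].to_csv(path, index=False, na_rep="")


# -- orchestration ---------------------------------------------------------


def _subject_matrix(std: pd.DataFrame, freq: float) -> tuple[np.ndarray, np.ndarray, list]:
    """Pivot standardized long table to (subjects x times) for one frequency."""
    sub = std[std["frequency_khz"] == freq]
    pivot = sub.pivot_table(
        index="subject_id", columns="t_min", values="zscore", sort=True
    )
    if pivot.isna().any().any():
        raise IOError_("subjects do not share the measurement schedule")
    return pivot.columns.to_numpy(dtype=float), pivot.to_numpy(), list(pivot.index)


def analyze_group(
    impedance: pd.DataFrame,
    vitals: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Full analysis chain for one group's tables.

    Standardize -> group curves at the low and high frequency -> 1 MHz
    recovery time -> group-median trajectory over the analysis window ->
    curvature classification -> endpoint extraction -> comparisons.
    """
    protocol = standard_protocol(Group(impedance["subject_id"].iloc[0].rsplit("_", 1)[0]))
    std = pl.standardize_impedance(
        impedance,
        segment=config.segment,
        frequencies=(config.low_freq_khz, config.high_freq_khz),
    )

    curves = {}
    for freq in (config.low_freq_khz, config.high_freq_khz):
        times, mat, _ = _subject_matrix(std, freq)
        curves[freq] = pl.group_curve(times, mat, baseline_align=True)

    rec = pl.recovery_time(curves[config.high_freq_khz], infusion_start=60.0)

    # Per-subject trajectories (axes z-scored per subject over the window),
    # then the pointwise group median of x and y, re-standardized so the
    # group trajectory lives on the same z-score axes.
    sub = impedance[impedance["segment"] == config.segment]
    piv = {
        freq: sub[sub["frequency_khz"] == freq].pivot_table(
            index="subject_id", columns="t_min", values="z_ohm", sort=True
        )
        for freq in (config.low_freq_khz, config.high_freq_khz)
    }
    times_traj = piv[config.low_freq_khz].columns.to_numpy(dtype=float)
    xs, ys = [], []
    for sid in piv[config.low_freq_khz].index:
        tr = pl.build_trajectory(
            times_traj,
            piv[config.low_freq_khz].loc[sid].to_numpy(),
            piv[config.high_freq_khz].loc[sid].to_numpy(),
            window=config.trajectory_window,
        )
        xs.append(tr["x"].to_numpy())
        ys.append(tr["y"].to_numpy())
        t_window = tr["t_min"].to_numpy()
    xs, ys = np.array(xs), np.array(ys)
    if xs.shape[0] > 1:
        med_x = np.array([pl.mle_group_median(xs[:, j]) for j in range(xs.shape[1])])
        med_y = np.array([pl.mle_group_median(ys[:, j]) for j in range(ys.shape[1])])
    else:
        med_x, med_y = xs[0], ys[0]
    # Coarse-knot least-squares spline suppresses measurement noise before
    # the curvature fit; the bends of interest are slower than the knots.
    traj = pd.DataFrame(
        {
            "t_min": t_window,
            "x": pl.zscore_standardize(pl.lsq_spline_smooth(t_window, med_x)),
            "y": pl.zscore_standardize(pl.lsq_spline_smooth(t_window, med_y)),
        }
    )
    curv = pl.curvature_statistic(
        traj["x"], traj["y"], threshold=config.curvature_threshold
    )

    endpoints = hs.extract_endpoints(vitals, protocol, rec)
    comparisons, flags = hs.endpoint_comparison_report(endpoints, alpha=config.alpha)

    sv_means = {
        tp: grp["value"].mean()
        for tp, grp in endpoints[endpoints["variable"] == "sv"].groupby("timepoint")
    }
    responsiveness = None
    if "recovery_1M" in sv_means and sv_means["start_resus2"] > 0:
        responsiveness = hs.delta_sv_responsiveness(
            sv_means["recovery_1M"], sv_means["end_infusion"]
        )

    return {
        "curves": curves,
        "recovery_min": rec,
        "trajectory": traj,
        "curvature": curv,
        "endpoints": endpoints,
        "comparisons": comparisons,
        "flags": flags,
        "responsiveness": responsiveness,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, params: SubjectParams | None = None) -> dict:
    """Simulate (unless input tables are given), analyze all groups, write outputs.

    Writes per-group and pooled CSV/JSON artifacts plus ``manifest.json``
    under ``config.out_dir`` and returns the in-memory results keyed by
    group.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = SubjectParams(noise_cv=config.noise_cv)
    else:
        params = dc_replace(params, noise_cv=config.noise_cv)

    results: dict[str, dict] = {}
    imp_all, vit_all = [], []
    curve_rows, traj_rows = [], []
    endpoints_all, comparisons_all = [], []
    recovery_json, curvature_json, report_json = {}, {}, {}

    for gi, group in enumerate(config.groups):
        if config.impedance_path is not None:
            stage = "read-input"
            pattern = rf"^{group}_\d+$"
            imp = read_impedance_table(config.impedance_path)
            imp = imp[imp["subject_id"].str.fullmatch(pattern)]
            if imp.empty:
                raise IOError_(f"[{stage}] no rows for group {group} in input")
            vit = read_vitals_table(config.vitals_path)
            vit = vit[vit["subject_id"].str.fullmatch(pattern)]
        else:
            imp, vit, _truth = generate_dataset(
                config.n_subjects,
                group,
                params_template=params,
                seed=config.seed + 1000 * gi,
            )
        try:
            res = analyze_group(imp, vit, config)
        except Exception as exc:
            raise RuntimeError(f"[analyze:{group}] {exc}") from exc
        results[group] = res
        imp_all.append(imp)
        vit_all.append(vit)

        for freq, curve in res["curves"].items():
            for j in range(curve.times.size):
                curve_rows.append(
                    (
                        group,
                        freq,
                        curve.times[j],
                        curve.median[j],
                        curve.p25[j],
                        curve.p75[j],
                    )
                )
        for _, r in res["trajectory"].iterrows():
            traj_rows.append((group, r["t_min"], r["x"], r["y"]))
        ep = res["endpoints"].copy()
        ep.insert(0, "group", group)
        endpoints_all.append(ep)
        cmp_ = res["comparisons"].copy()
        cmp_.insert(0, "group", group)
        comparisons_all.append(cmp_)
        recovery_json[group] = res["recovery_min"]
        curvature_json[group] = res["curvature"]
        report_json[group] = {
            "restored": res["flags"]["restored"],
            "recovery_min": res["recovery_min"],
            "curvature": res["curvature"],
            "responsiveness": res["responsiveness"],
        }

    write_impedance_table(pd.concat(imp_all, ignore_index=True), out / "impedance.csv")
    write_vitals_table(pd.concat(vit_all, ignore_index=True), out / "vitals.csv")
    pd.DataFrame(
        curve_rows, columns=["group", "frequency_khz", "t_min", "median", "p25", "p75"]
    ).to_csv(out / "group_curves.csv", index=False)
    pd.DataFrame(traj_rows, columns=["group", "t_min", "x", "y"]).to_csv(
        out / "trajectory.csv", index=False
    )
    pd.concat(endpoints_all, ignore_index=True).to_csv(
        out / "endpoints.csv", index=False
    )
    pd.concat(comparisons_all, ignore_index=True).to_csv(
        out / "comparisons.csv", index=False
    )
    for name, payload in [
        ("recovery.json", recovery_json),
        ("curvature.json", curvature_json),
        ("report.json", report_json),
    ]:
        (out / name).write_text(json.dumps(payload, indent=2, sort_keys=True))

    artifacts = sorted(
        p.name
        for p in out.iterdir()
        if p.suffix in (".csv", ".json") and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {**config.__dict__, "groups": list(config.groups),
                   "trajectory_window": list(config.trajectory_window)},
        "outputs": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results

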