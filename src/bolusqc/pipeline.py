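"""End-to-end orchestration: simulate/load -> clean -> fit -> statistics.

The pipeline is a pure function of (study design, simulation config,
seed): identical inputs produce identical numeric outputs.  Each stage
writes plain CSV/JSON intermediates so a run can be restarted or
inspected at any point.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .boxcar import BoxcarFit, QualityResult, boxcar_series, score_recording
from .io import (
    InjectionProtocol,
    ProtocolGroup,
    StudyDesign,
    TCRecording,
    default_design,
    expected_injection_time,
    protocol_in_group,
    read_recording,
    read_study_design,
    write_recording,
)
from .preprocess import clean_recording
from .simulate import SimulationConfig, generate_study
from .stats import (
    AncovaRankError,
    ancova,
    compliance_odds_ratio,
    dtk_pairwise,
    kruskal_wallis,
    rank_summary,
)

log = logging.getLogger("bolusqc")

__all__ = [
    "RunConfig",
    "score_study",
    "run_group_stats",
    "run_pipeline",
    "render_curve_report",
    "ANCOVA_FLOW_ML_S",
    "ANCOVA_VOLUME_RANGE_ML",
]

# Protocol subset for the covariate analysis: constant 5 ml/s flow,
# injection volumes from the micro (2 ml) to the largest (15 ml) grid.
ANCOVA_FLOW_ML_S = 5.0
ANCOVA_VOLUME_RANGE_ML = (2.0, 15.0)

GROUP_KEYS = ("all", "vVol", "cVol", "mVol")


@dataclass
class RunConfig:
    out_dir: Path
    design_path: Path | None = None
    recordings_dir: Path | None = None
    sim_config: SimulationConfig | None = None
    seed: int = 0
    alpha: float = 0.05
    cbcf_min: float | None = None
    dbit_max: float | None = None
    groups: Sequence[str] = GROUP_KEYS
    include_experimental: bool = True
    make_figures: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        bad = set(self.groups) - set(GROUP_KEYS)
        if bad:
            raise ValueError(f"unknown protocol groups: {sorted(bad)}")


def score_study(
    recordings: Iterable[TCRecording],
    design: StudyDesign,
    force: bool = False,
) -> pd.DataFrame:
    """Clean, fit and score every recording into a flat quality table."""
    rows = []
    for rec in recordings:
        protocol = design.protocol(rec.protocol_id)
        injector = design.injector(rec.injector_id)
        curve = clean_recording(rec, window_s=protocol.injection_delay_s)
        result = score_recording(curve, protocol, force=force)
        rows.append(
            {
                "recording_id": rec.recording_id,
                "injector_id": injector.injector_id,
                "pump_type": injector.pump_type.value,
                "line_volume_ml": injector.line_volume_ml,
                "max_pressure": injector.max_pressure,
                "line_config": injector.line_config.value,
                "protocol_id": protocol.protocol_id,
                "group": protocol.group.value,
                "cm_type": protocol.cm_type.value,
                "cm_volume_ml": protocol.cm_volume_ml,
                "flow_rate_ml_s": protocol.flow_rate_ml_s,
                "day": rec.day,
                "cbcf": result.cbcf,
                "dbit_signed": result.dbit_signed,
                "dbit_abs": result.dbit_abs,
                "expected_time_s": result.expected_time_s,
                "valid": result.valid,
                "notes": ";".join(result.notes),
            }
        )
    return pd.DataFrame(rows)


def _subset_for_group(table: pd.DataFrame, design: StudyDesign, group: str) -> pd.DataFrame:
    if group == "all":
        return table
    keep = [
        pid
        for pid in table["protocol_id"].unique()
        if protocol_in_group(design.protocol(pid), group)
    ]
    return table[table["protocol_id"].isin(keep)]


def _metric_groups(table: pd.DataFrame, metric: str) -> dict[str, np.ndarray]:
    valid = table[table["valid"].astype(bool)]
    return {
        str(inj): sub[metric].to_numpy()
        for inj, sub in valid.groupby("injector_id")
        if len(sub) >= 2
    }


def run_group_stats(
    table: pd.DataFrame,
    design: StudyDesign,
    alpha: float = 0.05,
    cbcf_min: float | None = None,
    dbit_max: float | None = None,
    groups: Sequence[str] = GROUP_KEYS,
) -> dict:
    """The full statistics battery on a quality table.

    Per protocol group and metric: rank summary, Kruskal-Wallis omnibus
    test and DTK pairwise comparisons; plus the covariate ANCOVA (on the
    constant-flow protocol subset) and the contrast-medium compliance
    odds ratio, each computed once on the full table.
    """
    out: dict = {"alpha": alpha, "groups": {}}
    for group in groups:
        sub = _subset_for_group(table, design, group)
        gout: dict = {}
        for metric in ("cbcf", "dbit_abs"):
            m: dict = {}
            try:
                m["rank_summary"] = rank_summary(sub, metric)
            except Exception as exc:  # pragma: no cover - tiny studies
                m["rank_summary"] = None
                m["error"] = str(exc)
            grps = _metric_groups(sub, metric)
            if len(grps) >= 2:
                h, p = kruskal_wallis(grps)
                m["kruskal_wallis"] = {"H": h, "p": round(p, 4)}
                m["pairwise"] = dtk_pairwise(grps, alpha=alpha)
            gout[metric] = m
        out["groups"][group] = gout

    lo, hi = ANCOVA_VOLUME_RANGE_ML
    subset = table[
        np.isclose(table["flow_rate_ml_s"], ANCOVA_FLOW_ML_S)
        & table["cm_volume_ml"].between(lo, hi)
        & table["valid"].astype(bool)
    ]
    out["ancova"] = {}
    for metric in ("cbcf", "dbit_abs"):
        try:
            out["ancova"][metric] = ancova(subset, metric)
        except (AncovaRankError, Exception) as exc:
            out["ancova"][metric] = None
            out.setdefault("ancova_errors", {})[metric] = str(exc)
            log.warning("ANCOVA for %s failed: %s", metric, exc)
    try:
        out["odds_ratio"] = compliance_odds_ratio(
            table, cbcf_min=cbcf_min, dbit_abs_max=dbit_max
        )
    except Exception as exc:
        out["odds_ratio"] = None
        out["odds_ratio_error"] = str(exc)
        log.warning("odds-ratio test failed: %s", exc)
    return out


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(_jsonify(dataclasses.asdict(cfg)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """simulate/load -> score -> statistics -> report bundle on disk.

    Returns the manifest dict.  Output files: ``recordings/*.csv`` (when
    simulating), ``quality_results.csv``, ``rank_summary_*.csv``,
    ``pairwise_*.csv``, ``stats_summary.json`` and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.design_path is not None:
        design = read_study_design(config.design_path)
    else:
        design = default_design(experimental=config.include_experimental)

    if config.recordings_dir is not None:
        recordings = _load_recordings(Path(config.recordings_dir), design)
        log.info("loaded %d recordings", len(recordings))
    else:
        sim = config.sim_config or SimulationConfig(seed=config.seed)
        if sim.seed != config.seed:
            sim = dataclasses.replace(sim, seed=config.seed)
        recordings = generate_study(design, sim)
        log.info("simulated %d recordings", len(recordings))
        rec_dir = out / "recordings"
        manifest_rows = []
        for rec in recordings:
            write_recording(rec, rec_dir / f"{rec.recording_id}.csv")
            manifest_rows.append(
                {
                    "recording_id": rec.recording_id,
                    "injector_id": rec.injector_id,
                    "protocol_id": rec.protocol_id,
                    "day": rec.day,
                    "cm_type": rec.cm_type.value if rec.cm_type else "",
                }
            )
        pd.DataFrame(manifest_rows).to_csv(
            rec_dir / "manifest.csv", index=False
        )

    table = score_study(recordings, design)
    table.to_csv(out / "quality_results.csv", index=False)

    stats = run_group_stats(
        table,
        design,
        alpha=config.alpha,
        cbcf_min=config.cbcf_min,
        dbit_max=config.dbit_max,
        groups=config.groups,
    )
    for group, gout in stats["groups"].items():
        for metric, m in gout.items():
            rs = m.get("rank_summary")
            if rs is not None:
                rs.to_csv(out / f"rank_summary_{group}_{metric}.csv", index=False)
            pw = m.get("pairwise")
            if pw:
                pd.DataFrame([dataclasses.asdict(p) for p in pw]).to_csv(
                    out / f"pairwise_{group}_{metric}.csv", index=False
                )
    with open(out / "stats_summary.json", "w") as fh:
        json.dump(_jsonify(stats), fh, indent=2)

    if config.make_figures:
        fig_dir = out / "figures"
        for rec in recordings:
            protocol = design.protocol(rec.protocol_id)
            curve = clean_recording(rec, window_s=protocol.injection_delay_s)
            result = score_recording(curve, protocol, force=True)
            render_curve_report(
                curve, result, protocol, fig_dir / f"{rec.recording_id}.png"
            )

    manifest = {
        "bolusqc_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_recordings": len(recordings),
        "n_valid": int(table["valid"].sum()),
        "design": {
            "injectors": [i.injector_id for i in design.injectors],
            "n_protocols": len(design.protocols),
            "days": design.days,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonify(manifest), fh, indent=2)
    return manifest


def _load_recordings(rec_dir: Path, design: StudyDesign) -> list[TCRecording]:
    """Load recordings listed in ``manifest.csv`` (or every CSV, parsing
    metadata from ``<injector>__<protocol>__d<day>.csv`` file names)."""
    manifest = rec_dir / "manifest.csv"
    recordings = []
    if manifest.exists():
        rows = pd.read_csv(manifest)
        for _, row in rows.iterrows():
            rec = read_recording(
                rec_dir / f"{row['recording_id']}.csv",
                metadata={
                    "recording_id": row["recording_id"],
                    "injector_id": row["injector_id"],
                    "protocol_id": row["protocol_id"],
                    "day": int(row["day"]),
                    "cm_type": row["cm_type"] or None,
                },
            )
            recordings.append(rec)
        return recordings
    for path in sorted(rec_dir.glob("*.csv")):
        parts = path.stem.split("__")
        if len(parts) != 3 or not parts[2].startswith("d"):
            raise ValueError(
                f"{path.name}: cannot infer metadata; provide manifest.csv "
                "or name files <injector>__<protocol>__d<day>.csv"
            )
        injector_id, protocol_id, day = parts[0], parts[1], int(parts[2][1:])
        protocol = design.protocol(protocol_id)
        recordings.append(
            read_recording(
                path,
                metadata={
                    "injector_id": injector_id,
                    "protocol_id": protocol_id,
                    "day": day,
                    "cm_type": protocol.cm_type.value,
                },
            )
        )
    return recordings


def render_curve_report(
    curve,
    result: QualityResult,
    protocol: InjectionProtocol,
    path: str | Path,
) -> Path:
    """Plot a TC-curve with its fitted and protocol-nominal boxcars.

    The nominal boxcar has width = expected injection time (volume/flow)
    and is aligned at the fitted onset; for degenerate fits only the
    curve is drawn and a warning logged.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(curve.time_s, curve.deflection, color="tab:blue", lw=1.2,
            label="TC-curve")
    fit = result.fit
    if fit is not None and not fit.degenerate:
        b = boxcar_series(fit, curve.n_samples)
        ax.plot(curve.time_s, b, color="tab:red", lw=1.5,
                label=f"fitted boxcar (cBCF={result.cbcf:.3f})")
        expected = expected_injection_time(protocol)
        nominal = np.full(curve.n_samples, fit.baseline_level)
        nominal[
            (curve.time_s >= fit.t_on)
            & (curve.time_s < fit.t_on + expected)
        ] = fit.plateau_level
        ax.plot(curve.time_s, nominal, color="tab:green", lw=1.2, ls="--",
                label=f"nominal boxcar ({expected:.1f} s)")
    else:
        log.warning("%s: degenerate fit, plotting curve only",
                    curve.recording_id)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("deflection (absorbance units)")
    ax.set_title(curve.recording_id)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
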