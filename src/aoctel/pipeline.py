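"""End-to-end orchestration: scan analysis and multi-scan studies.

``run_scan`` takes one stack + pressure trace to a one-row compliance result
with all intermediate artifacts on disk; ``run_study`` aggregates many scans,
joins metadata, and fits the ANOVA/regression models. Outputs are
deterministic for a fixed (config, seed) pair and a manifest records both.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, elasto, io, segment
from .errors import AoctelError
from .stats import DEFAULT_ANOVA_TERMS, anova_ncsc, encode, regress

__all__ = ["ScanConfig", "StudyConfig", "run_scan", "run_study"]


@dataclass
class ScanConfig:
    """Configuration of a single-scan analysis."""

    stack: str
    geometry: str
    pressure: str
    out_dir: str
    scan_id: str = "scan"
    seed: int = 0
    seed_depths: str | None = None
    breaths_per_min: float = 20.0
    sd_window_frames: int = 5
    sd_rule: str = "rss"
    segmentation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)


def _config_hash(cfg) -> str:
    payload = json.dumps(cfg.__dict__, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _write_manifest(out: Path, cfg, extra: dict | None = None) -> None:
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.__dict__,
        "config_sha256": _config_hash(cfg),
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_scan(cfg: ScanConfig) -> elasto.ComplianceResult:
    """Segment, calibrate, and estimate compliance for one scan.

    Writes ``boundary.csv``, ``csa.csv``, ``result.csv`` and
    ``manifest.json`` under ``cfg.out_dir``. Stage failures are re-raised
    with the stage name and scan id attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        stack, geom, frame_times = io.read_stack(cfg.stack, cfg.geometry)
        t_p, p = io.read_pressure(cfg.pressure)
        seeds = io.read_seed_depths(cfg.seed_depths, geom) if cfg.seed_depths else None
        stage = "segment"
        boundary, csa = segment.segment_stack(
            stack, geom, frame_times=frame_times, seed_depths=seeds, **cfg.segmentation
        )
        io.write_boundary_csv(out / "boundary.csv", boundary, geom)
        io.write_csa_csv(out / "csa.csv", csa)
        stage = "elasto"
        result = elasto.analyze_scan(
            csa.csa_mm2,
            csa.time_s,
            t_p,
            p,
            geom.frame_rate,
            breaths_per_min=cfg.breaths_per_min,
            sd_window_frames=cfg.sd_window_frames,
            sd_rule=cfg.sd_rule,
        )
    except AoctelError as exc:
        raise type(exc)(f"[{cfg.scan_id} / {stage}] {exc}") from exc
    pd.DataFrame([result.to_row(cfg.scan_id)]).to_csv(out / "result.csv", index=False)
    _write_manifest(out, cfg, {"n_frames": int(geom.n_frames)})
    return result


@dataclass
class StudyConfig:
    """Configuration of a multi-scan study.

    ``scans`` maps scan ids to ScanConfig-style dicts (out_dir defaults to a
    per-scan subdirectory); ``metadata`` is a CSV with columns
    ``scan_id,intensity,time_label,position``.
    """

    scans: dict
    metadata: str
    out_dir: str
    seed: int = 0
    anova_terms: tuple = DEFAULT_ANOVA_TERMS
    regression_predictors: tuple = ("intensity", "time", "position")
    ss_type: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        if "anova_terms" in cfg:
            cfg["anova_terms"] = tuple(cfg["anova_terms"])
        if "regression_predictors" in cfg:
            cfg["regression_predictors"] = tuple(cfg["regression_predictors"])
        return cls(**cfg)


def run_study(cfg: StudyConfig) -> dict[str, pd.DataFrame]:
    """Analyze all scans, join metadata, and fit the study models.

    Returns (and writes) ``study_results``, ``anova`` and ``regression``
    tables, plus a summary figure of nCsC versus time by intensity and
    position bin.
    """
    if len(cfg.scans) < 2:
        raise ValueError("a study needs at least 2 scans")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan_id in sorted(cfg.scans):
        scan_cfg = dict(cfg.scans[scan_id])
        scan_cfg.setdefault("out_dir", str(out / scan_id))
        scan_cfg.setdefault("seed", cfg.seed)
        result = run_scan(ScanConfig(scan_id=scan_id, **scan_cfg))
        rows.append(result.to_row(scan_id))
    results = pd.DataFrame(rows)

    meta = pd.read_csv(cfg.metadata)
    missing = sorted(set(results["scan_id"]) ^ set(meta["scan_id"]))
    if missing:
        raise ValueError(f"metadata/scan id mismatch; unmatched ids: {missing}")
    meta = meta.sort_values("scan_id").reset_index(drop=True)
    coded = encode(meta)
    table = coded.merge(results, on="scan_id")
    table = table.rename(columns={"ncsc_pct_per_cmH2O": "ncsc"})

    aov = anova_ncsc(table, terms=cfg.anova_terms, ss_type=cfg.ss_type)
    reg = regress(table, "ncsc", cfg.regression_predictors)

    table.to_csv(out / "study_results.csv", index=False)
    aov.to_csv(out / "anova.csv", index=False)
    reg.to_csv(out / "regression.csv", index=False)
    _plot_summary(table, out / "summary.png")
    _write_manifest(out, cfg, {"n_scans": len(cfg.scans)})
    return {"study_results": table, "anova": aov, "regression": reg}


def _plot_summary(table: pd.DataFrame, path: Path) -> None:
    """nCsC versus time, one panel per position bin, colored by intensity."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = [(-0.01, 1.0 / 3), (1.0 / 3, 2.0 / 3), (2.0 / 3, 1.01)]
    names = ["distal (carina)", "mid-trachea", "proximal (larynx)"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, (lo, hi), name in zip(axes, bins, names):
        sub = table[(table["position"] > lo) & (table["position"] <= hi)]
        for level, grp in sub.groupby("intensity"):
            g = grp.sort_values("time")
            ax.plot(g["time"], g["ncsc"], "o-", label=f"intensity {level}")
        ax.set_title(name)
        ax.set_xlabel("time (h)")
    axes[0].set_ylabel("nCsC (%/cmH2O)")
    if table["intensity"].nunique() > 1:
        axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
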