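"""End-to-end orchestration: decompose -> peaks -> filter -> quantify ->
cluster -> stats, from a config object, with plain-file intermediates.

`analyze_cells` is the pure in-memory pipeline; `run_pipeline` wraps it with
file input/output so each stage can be re-run and inspected independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decomposition, multivariate, peak_analysis, quantification
from .group_stats import compare_groups
from .spectra_io import (
    Spectrum,
    TimeSeriesSpectra,
    append_jsonl,
    read_frames,
    write_delimited,
    write_records_csv,
)
from .quantification import CellRecord

logger = logging.getLogger("scraman")

__all__ = ["RunConfig", "PipelineResult", "analyze_cells", "run_pipeline"]


@dataclass
class RunConfig:
    """All tunables of one pipeline run; serialized into every output."""

    input_dir: str | None = None
    output_dir: str = "scraman_out"
    excitation_nm: float = 632.8
    baseline_method: str = "iterpoly"
    baseline_order: int = 12
    baseline_presmooth: int = 20
    baseline_tol: float = 1e-4
    baseline_max_iter: int = 100
    nu1_window: tuple[float, float] = peak_analysis.NU1_WINDOW
    nu2_window: tuple[float, float] = peak_analysis.NU2_WINDOW
    n_signal_points: int = 5
    signal_stat: str = "mean"
    snr_threshold: float = 2.0
    ch_region: tuple[float, float] = quantification.CH_REGION
    af_window_nm: tuple[float, float] = quantification.AF_WINDOW_NM
    af_shape_window_nm: tuple[float, float] = quantification.AF_SHAPE_WINDOW_NM
    n_components: int = 7
    k_init: int = 2
    k_max: int = 20
    cluster_tolerance: float = 1e-4
    alpha: float = 0.05
    seed: int = 0

    def baseline_params(self) -> dict:
        if self.baseline_method == "iterpoly":
            return {
                "order": self.baseline_order,
                "presmooth": self.baseline_presmooth,
                "tol": self.baseline_tol,
                "max_iter": self.baseline_max_iter,
            }
        return {}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


@dataclass
class PipelineResult:
    records: pd.DataFrame
    decompositions: dict[str, decomposition.DecompositionResult]
    cell_records: list[CellRecord]
    cluster: multivariate.ClusterResult | None
    cluster_cell_ids: list[str]
    stats: dict
    af_threshold: float | None
    rejections: list[dict] = field(default_factory=list)


def _analyze_one(
    ts: TimeSeriesSpectra, config: RunConfig
) -> tuple[CellRecord, decomposition.DecompositionResult, Spectrum | None]:
    dec = decomposition.decompose(
        ts, method=config.baseline_method, **config.baseline_params()
    )
    rec = CellRecord(cell_id=ts.cell_id)
    fit1 = peak_analysis.fit_lorentzian_peak(dec.raman, config.nu1_window, mode="nu1")
    fit2 = peak_analysis.fit_lorentzian_peak(dec.raman, config.nu2_window, mode="nu2")
    ch = None
    try:
        ch = quantification.ch_norm(ts.frames[2], region=config.ch_region)
    except ValueError as exc:
        logger.warning("cell %s: C-H norm failed (%s)", ts.cell_id, exc)
    if fit1.success:
        rec.nu1_center = fit1.center
        rec.snr_nu1 = peak_analysis.compute_snr(
            dec.raman, fit1.center,
            n_signal_points=config.n_signal_points,
            signal_stat=config.signal_stat,
        ).value
        if ch:
            rec.nu1_intensity = quantification.normalized_peak_intensity(
                dec.raman, fit1, ch, n_points=config.n_signal_points
            )
    if fit2.success:
        rec.nu2_center = fit2.center
        rec.snr_nu2 = peak_analysis.compute_snr(
            dec.raman, fit2.center,
            n_signal_points=config.n_signal_points,
            signal_stat=config.signal_stat,
        ).value
        if ch:
            rec.nu2_intensity = quantification.normalized_peak_intensity(
                dec.raman, fit2, ch, n_points=config.n_signal_points
            )
    if ch:
        rec.af_intensity = quantification.af_intensity(
            dec.autofluorescence, ch, window_nm=config.af_window_nm
        )
    rec.carotenoid_positive = bool(
        fit1.success and np.isfinite(rec.snr_nu1) and rec.snr_nu1 >= config.snr_threshold
    )
    return rec, dec, dec.autofluorescence


def analyze_cells(
    cells: list[TimeSeriesSpectra],
    config: RunConfig | None = None,
    groups: dict[str, str] | None = None,
    control_cells: list[TimeSeriesSpectra] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory time series.

    ``groups`` maps cell_id to a group/species label for the statistics
    stage; ``control_cells`` (nonphototrophic controls) define the
    autofluorescence-positivity threshold.  Per-cell fit failures are logged
    and excluded, never fatal.
    """
    if config is None:
        config = RunConfig()
    if not cells:
        raise ValueError("no input cells")
    records: list[CellRecord] = []
    decs: dict[str, decomposition.DecompositionResult] = {}
    af_spectra: dict[str, Spectrum] = {}
    rejections: list[dict] = []
    for ts in cells:
        try:
            rec, dec, af = _analyze_one(ts, config)
        except (ValueError, RuntimeError) as exc:
            rejections.append({"cell_id": ts.cell_id, "reason": str(exc)})
            logger.warning("cell %s rejected: %s", ts.cell_id, exc)
            continue
        if groups:
            rec.group = groups.get(ts.cell_id, "")
        records.append(rec)
        decs[ts.cell_id] = dec
        if af is not None:
            af_spectra[ts.cell_id] = af

    kept, snr_rejected = peak_analysis.apply_snr_filter(
        [r for r in records if np.isfinite(r.snr_nu1)], config.snr_threshold
    )
    for entry in snr_rejected:
        rejections.append({
            "cell_id": entry["record"].cell_id,
            "reason": entry["reason"],
        })

    threshold = None
    if control_cells:
        control_vals = []
        for ts in control_cells:
            try:
                rec, _, _ = _analyze_one(ts, config)
            except (ValueError, RuntimeError):
                continue
            if np.isfinite(rec.af_intensity):
                control_vals.append(rec.af_intensity)
        if control_vals:
            threshold = quantification.af_threshold(control_vals)
            for rec in records:
                if np.isfinite(rec.af_intensity):
                    rec.af_positive = quantification.flag_af_positive(
                        rec.af_intensity, threshold
                    )

    cluster = None
    cluster_ids: list[str] = []
    cluster_candidates = [
        r for r in kept
        if r.cell_id in af_spectra and (threshold is None or r.af_positive)
    ]
    if len(cluster_candidates) >= max(2, config.k_init):
        spectra = [af_spectra[r.cell_id] for r in cluster_candidates]
        try:
            cluster, kept_idx, _ = multivariate.classify_af_shapes(
                spectra,
                window_nm=config.af_shape_window_nm,
                n_components=config.n_components,
                k_init=config.k_init,
                k_max=config.k_max,
                tolerance=config.cluster_tolerance,
                seed=config.seed,
            )
            cluster_ids = [cluster_candidates[i].cell_id for i in kept_idx]
        except ValueError as exc:
            logger.warning("clustering skipped: %s", exc)

    stats: dict = {}
    if groups:
        for score in ("nu1_intensity", "nu2_intensity", "af_intensity"):
            by_group: dict[str, list[float]] = {}
            for rec in kept:
                val = getattr(rec, score)
                if rec.group and np.isfinite(val):
                    by_group.setdefault(rec.group, []).append(val)
            by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
            if len(by_group) >= 2:
                cmp = compare_groups(by_group, alpha=config.alpha)
                stats[score] = {
                    "H": cmp.h_statistic,
                    "p": cmp.omnibus_p,
                    "letters": cmp.letters,
                    "groups": {g: len(v) for g, v in by_group.items()},
                }

    df = pd.DataFrame([r.to_dict() for r in records])
    if not df.empty:
        df["snr_pass"] = df["cell_id"].isin([r.cell_id for r in kept])
        if cluster is not None:
            label_map = dict(zip(cluster_ids, cluster.labels))
            df["af_cluster"] = df["cell_id"].map(
                lambda c: label_map.get(c, -1)
            )
    return PipelineResult(
        records=df,
        decompositions=decs,
        cell_records=records,
        cluster=cluster,
        cluster_cell_ids=cluster_ids,
        stats=stats,
        af_threshold=threshold,
        rejections=rejections,
    )


def load_cells(input_dir: str | Path, pattern: str = "*.tsv") -> list[TimeSeriesSpectra]:
    paths = sorted(Path(input_dir).glob(pattern))
    return [read_frames(p) for p in paths]


def run_pipeline(
    config: RunConfig,
    cells: list[TimeSeriesSpectra] | None = None,
    groups: dict[str, str] | None = None,
    control_cells: list[TimeSeriesSpectra] | None = None,
) -> PipelineResult:
    """File-level pipeline: read multi-frame spectra, analyze, write outputs.

    Outputs in ``config.output_dir``: cell_records.csv, component spectra
    (per-cell Raman and autofluorescence), cluster_labels.csv, stats.json,
    run_log.jsonl, and a config.yaml provenance snapshot.
    """
    if cells is None:
        if not config.input_dir:
            raise ValueError("config.input_dir is required when no cells are passed")
        if not Path(config.input_dir).is_dir():
            raise ValueError(f"input_dir does not exist: {config.input_dir}")
        cells = load_cells(config.input_dir)
        if not cells:
            raise ValueError(f"no spectra found in {config.input_dir}")
    out = Path(config.output_dir)
    result = analyze_cells(cells, config, groups=groups, control_cells=control_cells)

    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    write_records_csv(result.records, out / "cell_records.csv")
    comp_dir = out / "components"
    comp_dir.mkdir(exist_ok=True)
    for cell_id, dec in result.decompositions.items():
        write_delimited(dec.raman, comp_dir / f"{cell_id}_raman.tsv")
        write_delimited(dec.autofluorescence, comp_dir / f"{cell_id}_af.tsv")
    if result.cluster is not None:
        pd.DataFrame({
            "cell_id": result.cluster_cell_ids,
            "cluster": result.cluster.labels,
        }).to_csv(out / "cluster_labels.csv", index=False)
    (out / "stats.json").write_text(json.dumps(
        {
            "af_threshold": result.af_threshold,
            "scores": result.stats,
            "n_cells": len(cells),
            "n_rejected": len(result.rejections),
        },
        indent=2,
    ))
    log_path = out / "run_log.jsonl"
    log_path.unlink(missing_ok=True)
    for entry in result.rejections:
        append_jsonl(entry, log_path)
    return result
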