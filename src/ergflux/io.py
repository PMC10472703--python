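"""Readers, writers, run configuration and the end-to-end pipeline.

Interchange format is plain CSV (UTF-8, header row, "." decimal): no
public binary standard exists for rodent full-field ERG exports. Epoch
tables are long-format with columns ``epoch_id, time_ms, voltage_uv,
intensity_log``; derived results are written as tidy CSV or JSON. A run
manifest (config hash, package version, seed) makes pipeline runs
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from ergflux.epoch import ERGEpoch
from ergflux.features import FeatureWindows, baseline_correct, measure_ab_waves, measure_pstr
from ergflux.nakarushton import fit_naka_rushton
from ergflux.ops import detect_op_wavelets, spectral_bandpass
from ergflux.stats import GroupSummary, pooled_t_from_summary, reproduce_reference_tests
from ergflux.synth import ERGSimParams, simulate_intensity_series

log = logging.getLogger("ergflux")

EPOCH_COLUMNS = ("epoch_id", "time_ms", "voltage_uv", "intensity_log")


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "results"
    # simulation
    intensities_log: list[float] = [-4.32, -3.3, -2.3, -1.3, -0.8, 0.3, 1.3]
    noise_sd: float = 20.0
    # feature windows
    a_window: tuple[float, float] = (3.0, 50.0)
    b_window: tuple[float, float] = (20.0, 150.0)
    pstr_window: tuple[float, float] = (80.0, 200.0)
    # OP band and detection
    op_lo_hz: float = 65.0
    op_hi_hz: float = 300.0
    op_window_ms: tuple[float, float] = (10.0, 100.0)
    op_k: int = 4
    op_intensity_log: float = 0.3
    # Naka-Rushton
    fix_n: float | None = None
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        fs = ERGSimParams(noise_sd=self.noise_sd).fs_hz
        if not (0 < self.op_lo_hz < self.op_hi_hz <= fs / 2):
            raise ValueError(
                f"OP band ({self.op_lo_hz}, {self.op_hi_hz}) invalid for fs {fs}"
            )
        return self

    def semantic_hash(self) -> str:
        payload = self.model_dump()
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig(**(data or {}))


# --------------------------------------------------------------------------
# Epoch tables
# --------------------------------------------------------------------------

def write_epochs(epochs: Sequence[ERGEpoch], path: str | Path) -> None:
    """Write epochs to a long-format CSV (one row per sample)."""
    frames = []
    for i, e in enumerate(epochs):
        frames.append(
            pd.DataFrame(
                {
                    "epoch_id": e.meta.get("epoch_id", f"epoch{i:03d}"),
                    "time_ms": e.time_ms,
                    "voltage_uv": e.voltage_uv,
                    "intensity_log": e.intensity_log,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epochs(path: str | Path) -> list[ERGEpoch]:
    """Read epochs from a long-format CSV; enforces a uniform grid.

    Rows may arrive in any order (sorted by time within epoch). A
    duplicated timestamp or a non-uniform grid raises an error naming
    the offending epoch; an empty file returns [] with a warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty epoch file", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path}: empty epoch file", stacklevel=2)
        return []
    missing = set(EPOCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    epochs = []
    for eid, sub in df.groupby("epoch_id", sort=False):
        sub = sub.sort_values("time_ms", kind="stable")
        t = sub["time_ms"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            raise ValueError(
                f"epoch {eid!r}: duplicated timestamp at t = {t[dup[0]]} ms"
            )
        steps = np.diff(t)
        if np.any(np.abs(steps - steps[0]) > 1e-9 * max(abs(steps[0]), 1.0)):
            raise ValueError(f"epoch {eid!r}: non-uniform time grid")
        fs = 1000.0 / steps[0]
        epochs.append(
            ERGEpoch(
                time_ms=t,
                voltage_uv=sub["voltage_uv"].to_numpy(dtype=float),
                intensity_log=float(sub["intensity_log"].iloc[0]),
                fs_hz=fs,
                meta={"epoch_id": str(eid)},
            )
        )
    return epochs


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig, sim_params: ERGSimParams | None = None) -> dict:
    """Simulate -> features -> OPs -> Naka-Rushton fit -> reference stats.

    Writes features, OP measurements, the intensity-response fit, the
    reference-comparison report and a manifest under ``config.out_dir``
    and returns them in-memory as a result bundle.
    """
    logging.basicConfig(level=config.log_level, format="[%(name)s] %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = sim_params or ERGSimParams(noise_sd=config.noise_sd)
    windows = FeatureWindows(
        a_window=config.a_window,
        b_window=config.b_window,
        pstr_window=config.pstr_window,
    )

    log.info("simulate: %d intensities", len(config.intensities_log))
    epochs = simulate_intensity_series(params, config.intensities_log, config.seed)
    for i, e in enumerate(epochs):
        e.meta["epoch_id"] = f"epoch{i:03d}"
    write_epochs(epochs, out / "epochs.csv")

    log.info("features: extracting a/b waves and pSTR")
    rows = []
    for e in epochs:
        corrected = baseline_correct(e)
        feats = measure_ab_waves(corrected, windows)
        row = {
            "epoch_id": e.meta["epoch_id"],
            "intensity_log": e.intensity_log,
            "a_amp": feats.a_amp,
            "a_implicit_ms": feats.a_implicit_ms,
            "b_amp": feats.b_amp,
            "b_implicit_ms": feats.b_implicit_ms,
        }
        if e.meta.get("zone") == 1:
            pstr = measure_pstr(corrected, windows)
            row["pstr_amp"] = pstr.pstr_amp
            row["pstr_implicit_ms"] = pstr.pstr_implicit_ms
        rows.append(row)
    features = pd.DataFrame(rows)
    features.to_csv(out / "features.csv", index=False)

    log.info("ops: band-pass %s-%s Hz", config.op_lo_hz, config.op_hi_hz)
    op_epoch = min(
        epochs, key=lambda e: abs(e.intensity_log - config.op_intensity_log)
    )
    filtered = spectral_bandpass(
        baseline_correct(op_epoch), config.op_lo_hz, config.op_hi_hz
    )
    op_result = detect_op_wavelets(filtered, config.op_window_ms, config.op_k)
    pd.DataFrame(
        {
            "peak_time_ms": op_result.peak_times_ms,
            "implicit_ms": op_result.implicit_ms,
            "amplitude_uv": op_result.amplitudes_uv,
        }
    ).to_csv(out / "ops.csv", index=False)

    log.info("fit-nr: rod-range Naka-Rushton fit")
    fit = fit_naka_rushton(
        features["intensity_log"].to_numpy(),
        features["b_amp"].to_numpy(),
        fix_n=config.fix_n,
    )
    fit_payload = {
        "bmax": fit.bmax,
        "semisat": fit.semisat,
        "slope_n": fit.slope_n,
        "rss": fit.rss,
        "n_points": fit.n_points,
        "converged": fit.converged,
    }
    (out / "naka_rushton.json").write_text(json.dumps(fit_payload, indent=2))

    log.info("stats: reproducing reference comparisons")
    report = reproduce_reference_tests()
    report.to_csv(out / "reference_report.csv", index=False)

    import ergflux

    manifest = {
        "config": config.model_dump(),
        "config_hash": config.semantic_hash(),
        "package_version": ergflux.__version__,
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "epochs": epochs,
        "features": features,
        "op_result": op_result,
        "fit": fit,
        "report": report,
        "manifest": manifest,
    }
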