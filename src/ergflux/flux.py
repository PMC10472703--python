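"""Mitochondrial respiration parameters from oxygen-consumption traces.

The extracellular-flux assay on retinal punches measures the oxygen
consumption rate (OCR) in three phases: basal, after injection of the
uncoupler FCCP (maximal electron-transport flux), and after rotenone +
antimycin A (complex I/III blockade, leaving only non-mitochondrial
oxygen consumption). The derived parameters follow the standard flux-
analyzer report:

    non-mitochondrial = mean OCR in the rotenone/antimycin phase
    basal             = last basal-phase OCR  - non-mitochondrial
    maximal           = max  FCCP-phase OCR   - non-mitochondrial
    spare capacity    = maximal - basal

No oligomycin phase exists in this protocol (FCCP is injected first),
so ATP-linked respiration and proton leak are not computable and are
deliberately absent. OCR values may be normalized by punch protein
content (pmol/min/mg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASE_ORDER = ("basal", "fccp", "rotaa")


class PhaseError(ValueError):
    """Raised when the injection phases are missing or out of order."""


@dataclass
class OCRTrace:
    """One well's OCR trace with injection-phase labels."""

    well_id: str
    time_min: np.ndarray
    ocr: np.ndarray
    phase: np.ndarray
    protein_mg: float | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.time_min.size == self.ocr.size == self.phase.size):
            raise PhaseError("time, OCR and phase vectors differ in length")
        if not np.all(np.isfinite(self.ocr)):
            raise PhaseError("OCR contains non-finite values")
        labels = [p for i, p in enumerate(self.phase) if i == 0 or p != self.phase[i - 1]]
        if tuple(labels) != PHASE_ORDER:
            raise PhaseError(
                f"phases must run basal -> fccp -> rotaa, got {labels}"
            )

    def values(self, phase: str) -> np.ndarray:
        return self.ocr[self.phase == phase]


@dataclass
class BioenergeticsParams:
    """Respiration parameters in pmol O2/min (and per mg protein)."""

    basal: float
    maximal: float
    spare: float
    nonmito: float
    normalized: dict[str, float] | None = None
    flags: set[str] = field(default_factory=set)


def segment_phases(rows: pd.DataFrame, well_id: str | None = None) -> OCRTrace:
    """Build a validated OCRTrace from annotated trace rows.

    Expects columns ``time_min``, ``ocr_pmol_min``, ``phase`` (values
    basal/fccp/rotaa) and optionally ``well_id`` / ``protein_mg``. Rows
    are sorted by time, so input row order is irrelevant; missing or
    out-of-order phases raise.
    """
    required = {"time_min", "ocr_pmol_min", "phase"}
    missing = required - set(rows.columns)
    if missing:
        raise PhaseError(f"missing columns: {sorted(missing)}")
    rows = rows.sort_values("time_min", kind="stable")
    unknown = set(rows["phase"]) - set(PHASE_ORDER)
    if unknown:
        raise PhaseError(f"unknown phase labels: {sorted(unknown)}")
    if well_id is None:
        well_id = str(rows["well_id"].iloc[0]) if "well_id" in rows else "well"
    protein = None
    if "protein_mg" in rows.columns:
        protein = float(rows["protein_mg"].iloc[0])
    return OCRTrace(
        well_id=well_id,
        time_min=rows["time_min"].to_numpy(),
        ocr=rows["ocr_pmol_min"].to_numpy(),
        phase=rows["phase"].to_numpy(),
        protein_mg=protein,
    )


def compute_respiration_params(
    trace: OCRTrace,
    basal_stat: str = "last",
    maximal_stat: str = "max",
) -> BioenergeticsParams:
    """Derive basal, maximal, spare and non-mitochondrial respiration.

    ``basal_stat`` ("last" or "mean") picks the basal-phase statistic
    and ``maximal_stat`` ("max" or "mean") the FCCP-phase statistic;
    defaults follow the flux-analyzer vendor report. Negative derived
    values are flagged, not clamped.
    """
    for phase in PHASE_ORDER:
        if trace.values(phase).size == 0:
            raise PhaseError(f"phase {phase!r} is empty")
    if basal_stat not in ("last", "mean") or maximal_stat not in ("max", "mean"):
        raise ValueError("basal_stat in {'last','mean'}, maximal_stat in {'max','mean'}")

    nonmito = float(trace.values("rotaa").mean())
    basal_raw = (
        float(trace.values("basal")[-1])
        if basal_stat == "last"
        else float(trace.values("basal").mean())
    )
    maximal_raw = (
        float(trace.values("fccp").max())
        if maximal_stat == "max"
        else float(trace.values("fccp").mean())
    )
    basal = basal_raw - nonmito
    maximal = maximal_raw - nonmito
    spare = maximal - basal

    flags = set()
    for name, value in (("basal", basal), ("maximal", maximal), ("spare", spare)):
        if value < 0:
            flags.add(f"negative-{name}")
    params = BioenergeticsParams(
        basal=basal, maximal=maximal, spare=spare, nonmito=nonmito, flags=flags
    )
    if trace.protein_mg is not None:
        params = normalize_by_protein(params, trace.protein_mg)
    return params


def normalize_by_protein(
    params: BioenergeticsParams, protein_mg: float
) -> BioenergeticsParams:
    """Protein-normalize all four parameters (pmol/min/mg)."""
    if not (protein_mg > 0):
        raise ValueError("protein_mg must be > 0")
    normalized = {
        "basal": params.basal / protein_mg,
        "maximal": params.maximal / protein_mg,
        "spare": params.spare / protein_mg,
        "nonmito": params.nonmito / protein_mg,
    }
    return BioenergeticsParams(
        basal=params.basal,
        maximal=params.maximal,
        spare=params.spare,
        nonmito=params.nonmito,
        normalized=normalized,
        flags=set(params.flags),
    )
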