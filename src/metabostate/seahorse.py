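"""Extracellular-flux (Seahorse-style) stress-test analysis.

Mito Stress Test (OCR, pmol O2/min): sequential injection phases
baseline -> oligomycin -> FCCP -> rotenone+antimycin A yield
non-mitochondrial respiration, basal respiration, ATP-linked
respiration, maximal respiration and spare capacity.

Glyco Stress Test (ECAR, mpH/min): no-glucose baseline -> glucose ->
oligomycin -> 2-DG yield non-glycolytic acidification, glycolysis,
glycolytic capacity and glycolytic reserve.

Each phase is summarized as the mean of its last three measurements per
well (the plateau after an injection; manufacturer convention), averaged
across wells, normalized to cell count.  Derived parameters follow the
standard arithmetic; the two identities

    glycolytic_reserve = glycolytic_capacity - glycolysis
    spare_capacity     = maximal_respiration - basal_respiration

hold exactly by construction.  Conditions can be aggregated into a 2-D
(glycolysis, OXPHOS) metabolic space (mean of z-scored parameters per
arm) and both arms converted to a common ATP-rate unit (JATP,
pmol ATP/min) using configurable bioenergetic constants.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MITO_PHASES = ("baseline", "oligomycin", "FCCP", "rotenone_antimycinA")
GLYCO_PHASES = ("no_glucose", "glucose", "oligomycin", "2DG")

GLYCO_PARAMS = ("non_glycolytic_acidification", "glycolysis",
                "glycolytic_capacity", "glycolytic_reserve")
MITO_PARAMS = ("non_mito_respiration", "basal_respiration", "atp_linked",
               "maximal_respiration", "spare_capacity")

#: parameters entering the 2-D aggregation (non-mito respiration is a
#: background term, not an OXPHOS read-out, and is excluded)
GLYCO_AXIS_PARAMS = GLYCO_PARAMS
MITO_AXIS_PARAMS = ("basal_respiration", "atp_linked",
                    "maximal_respiration", "spare_capacity")


class PhaseError(ValueError):
    """A required injection phase is missing from the trace."""


@dataclass
class FluxAssay:
    """One stress-test run: per-well time series with phase annotations.

    ``measurements`` columns: well, time_min, phase, value, cell_count.
    ``modality`` is ``"OCR"`` (Mito Stress Test) or ``"ECAR"`` (Glyco
    Stress Test); ``condition`` names the biological condition.
    """

    modality: str
    measurements: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        if self.modality not in ("OCR", "ECAR"):
            raise ValueError("modality must be 'OCR' or 'ECAR'")
        required = {"well", "time_min", "phase", "value", "cell_count"}
        missing = required - set(self.measurements.columns)
        if missing:
            raise ValueError(f"measurements missing columns: {sorted(missing)}")

    @property
    def phases(self) -> tuple[str, ...]:
        return MITO_PHASES if self.modality == "OCR" else GLYCO_PHASES


def read_flux_csv(path) -> list[FluxAssay]:
    """Read the long-format flux CSV (columns well, time_min, phase,
    value, cell_count, condition, modality) into one assay per
    (condition, modality)."""
    df = pd.read_csv(path)
    assays = []
    for (condition, modality), grp in df.groupby(["condition", "modality"], sort=True):
        assays.append(FluxAssay(
            modality=str(modality),
            measurements=grp.drop(columns=["condition", "modality"]).reset_index(drop=True),
            condition=str(condition),
        ))
    return assays


@dataclass
class MetabolicParameterSet:
    """The eight stress-test parameters (plus non-mito respiration),
    per cell-count unit."""

    glyco: dict[str, float] = field(default_factory=dict)
    mito: dict[str, float] = field(default_factory=dict)
    negative_flags: tuple[str, ...] = ()

    def validate_identities(self, atol: float = 0.0) -> None:
        if self.glyco:
            lhs = self.glyco["glycolytic_reserve"]
            rhs = self.glyco["glycolytic_capacity"] - self.glyco["glycolysis"]
            if abs(lhs - rhs) > atol:
                raise ValueError("glycolytic_reserve != capacity - glycolysis")
        if self.mito:
            lhs = self.mito["spare_capacity"]
            rhs = self.mito["maximal_respiration"] - self.mito["basal_respiration"]
            if abs(lhs - rhs) > atol:
                raise ValueError("spare_capacity != maximal - basal")

    def merged(self) -> dict[str, float]:
        return {**self.glyco, **self.mito}


def _phase_means(assay: FluxAssay, last_n: int = 3) -> dict[str, float]:
    """Per-phase summary: mean of the last ``last_n`` measurements of
    each well (all if fewer), normalized per cell, averaged over wells."""
    out = {}
    df = assay.measurements
    for phase in assay.phases:
        sub = df[df["phase"] == phase]
        if sub.empty:
            raise PhaseError(f"required phase {phase!r} missing from "
                             f"{assay.modality} trace")
        per_well = []
        for _, grp in sub.groupby("well"):
            grp = grp.sort_values("time_min")
            tail = grp.tail(last_n)
            per_well.append((tail["value"] / tail["cell_count"]).mean())
        out[phase] = float(np.mean(per_well))
    return out


def extract_stress_test(assay: FluxAssay) -> MetabolicParameterSet:
    """Derive the stress-test parameters for one arm from a trace.

    Negative derived parameters (possible with noisy traces) are
    returned as-is but flagged.
    """
    means = _phase_means(assay)
    if assay.modality == "OCR":
        non_mito = means["rotenone_antimycinA"]
        mito = {
            "non_mito_respiration": non_mito,
            "basal_respiration": means["baseline"] - non_mito,
            "atp_linked": means["baseline"] - means["oligomycin"],
            "maximal_respiration": means["FCCP"] - non_mito,
        }
        mito["spare_capacity"] = mito["maximal_respiration"] - mito["basal_respiration"]
        params = MetabolicParameterSet(mito=mito)
        values = mito
    else:
        non_glyc = means["no_glucose"]
        glyco = {
            "non_glycolytic_acidification": non_glyc,
            "glycolysis": means["glucose"] - non_glyc,
            "glycolytic_capacity": means["oligomycin"] - non_glyc,
        }
        glyco["glycolytic_reserve"] = glyco["glycolytic_capacity"] - glyco["glycolysis"]
        params = MetabolicParameterSet(glyco=glyco)
        values = glyco
    flags = tuple(name for name, v in values.items() if v < 0)
    if flags:
        logger.warning("negative derived parameter(s) in %s/%s: %s",
                       assay.condition, assay.modality, flags)
        params.negative_flags = flags
    return params


def combine_arms(glyco: MetabolicParameterSet,
                 mito: MetabolicParameterSet) -> MetabolicParameterSet:
    return MetabolicParameterSet(
        glyco=dict(glyco.glyco), mito=dict(mito.mito),
        negative_flags=glyco.negative_flags + mito.negative_flags,
    )


def aggregate_2d(params_by_condition: Mapping[str, MetabolicParameterSet]) -> pd.DataFrame:
    """Project conditions into 2-D metabolic space.

    Each stress-test parameter is z-scored across conditions; the
    glycolysis axis is the mean of the four glycolytic parameters'
    z-scores and the OXPHOS axis the mean of the four mitochondrial
    parameters' z-scores.  Coordinates are centred (sum to zero on each
    axis).  Returns a DataFrame indexed by condition with columns
    ``glycolysis_axis`` and ``oxphos_axis``.
    """
    if len(params_by_condition) < 2:
        raise ValueError("need at least 2 conditions to z-score parameters")
    table = pd.DataFrame(
        {cond: p.merged() for cond, p in params_by_condition.items()}
    ).T
    z = (table - table.mean(axis=0)) / table.std(axis=0, ddof=1)
    z = z.fillna(0.0)     # zero-variance parameter: no information, no push
    return pd.DataFrame({
        "glycolysis_axis": z[list(GLYCO_AXIS_PARAMS)].mean(axis=1),
        "oxphos_axis": z[list(MITO_AXIS_PARAMS)].mean(axis=1),
    })


def displacement(coords: pd.DataFrame, baseline: str, treated: str) -> np.ndarray:
    """Vector baseline -> treated in the 2-D metabolic space."""
    return (coords.loc[treated] - coords.loc[baseline]).to_numpy()


@dataclass(frozen=True)
class JatpConstants:
    """Bioenergetic conversion constants (configurable defaults follow
    the published ATP-rate accounting framework).

    p_o_ratio
        ATP per O atom for oxidative phosphorylation; OCR counts O2
        molecules, hence the factor 2 in the conversion.
    mph_to_pmol_h
        Buffering conversion from mpH/min to pmol H+/min (assay-medium
        and plate dependent).
    atp_per_lactate
        Glycolytic ATP per lactate (= per extruded H+) exported.
    """

    p_o_ratio: float = 2.45
    mph_to_pmol_h: float = 10.0
    atp_per_lactate: float = 1.0

    def __post_init__(self) -> None:
        if min(self.p_o_ratio, self.mph_to_pmol_h, self.atp_per_lactate) <= 0:
            raise ValueError("all JATP constants must be positive")

    @classmethod
    def from_yaml(cls, path=None) -> "JatpConstants":
        if path is None:
            res = importlib.resources.files("metabostate.data").joinpath("jatp.yaml")
            cfg = yaml.safe_load(res.read_text())
        else:
            with open(path) as fh:
                cfg = yaml.safe_load(fh)
        try:
            return cls(**{k: float(v) for k, v in cfg.items()})
        except TypeError as exc:
            raise ValueError(f"malformed JATP constants config: {exc}") from exc


def to_jatp(
    mito: MetabolicParameterSet,
    glyco: MetabolicParameterSet,
    constants: JatpConstants | None = None,
) -> dict[str, float]:
    """Convert both arms to ATP production rates (pmol ATP/min).

    ``jatp_ox = atp_linked_OCR * 2 * P/O`` and ``jatp_glyc =
    glycolysis_ECAR * buffering * ATP-per-lactate``; ``total`` is the
    bioenergetic capacity, their sum.
    """
    constants = constants or JatpConstants.from_yaml()
    jatp_ox = mito.mito["atp_linked"] * 2.0 * constants.p_o_ratio
    jatp_glyc = (glyco.glyco["glycolysis"] * constants.mph_to_pmol_h
                 * constants.atp_per_lactate)
    return {"jatp_ox": jatp_ox, "jatp_glyc": jatp_glyc,
            "total": jatp_ox + jatp_glyc}
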