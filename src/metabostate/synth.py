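"""Synthetic-data generators with known ground truth.

Every analysis stage in the package has a forward generator here that
emits its input format with the latent truth attached, so recovery can
be verified without any external download:

* expression cohorts in which downstream-target genes report latent
  AMPK / HIF-1 activity and enzyme genes report pathway activity
  (Gaussian noise on log-scale expression; effect sizes in sd units,
  i.e. Cohen's d per unit latent activity);
* longitudinal "patient" cohorts with a planted number of subjects whose
  AMPK and HIF-1 activities both decrease under treatment;
* stress-test flux traces that invert exactly through
  :func:`metabostate.seahorse.extract_stress_test` at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import GeneSets
from .seahorse import (
    FluxAssay,
    GLYCO_PHASES,
    MITO_PHASES,
    MetabolicParameterSet,
)


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic expression cohort.

    ``beta_*`` are log-scale effect sizes per unit latent activity, in
    units of the noise sd (so ``beta / noise_sd`` is the per-gene
    signal-to-noise ratio).  TCA and FAO enzyme genes are driven by the
    AMPK axis, glycolytic enzymes by the HIF-1 axis, matching the
    regulatory logic of the circuit model.
    """

    n_subjects: int = 30
    timepoints: tuple[float, ...] = (0.0,)
    beta_ampk: float = 2.0
    beta_hif1: float = 2.0
    beta_enzyme: float = 2.0
    noise_sd: float = 1.0
    n_background_genes: int = 50
    baseline_mean: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or len(self.timepoints) < 1:
            raise ValueError("need at least one subject and one time point")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _sample_ids(design: CohortDesign) -> tuple[list[str], list[str], list[float]]:
    samples, subjects, times = [], [], []
    for i in range(design.n_subjects):
        for t in design.timepoints:
            samples.append(f"S{i:02d}_t{t:g}")
            subjects.append(f"S{i:02d}")
            times.append(float(t))
    return samples, subjects, times


def generate_expression(
    design: CohortDesign,
    gene_sets: GeneSets,
    latent_ampk: np.ndarray | None = None,
    latent_hif1: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples log-expression matrix.

    Latent activities default to independent standard normals per
    subject/time point; pass ``(n_subjects, n_timepoints)`` arrays to
    plant trajectories.  Returns ``(expr, truth)`` where ``truth`` has
    one row per sample with columns subject, time, ampk_activity,
    hif1_activity.
    """
    for name in ("ampk_targets", "hif1_targets", "tca_enzymes",
                 "glycolysis_enzymes", "fao_enzymes"):
        if not getattr(gene_sets, name):
            raise ValueError(f"empty gene set: {name}")
    rng = rng or np.random.default_rng(design.seed)
    nT = len(design.timepoints)
    shape = (design.n_subjects, nT)
    a = rng.standard_normal(shape) if latent_ampk is None else np.asarray(latent_ampk, float)
    h = rng.standard_normal(shape) if latent_hif1 is None else np.asarray(latent_hif1, float)
    if a.shape != shape or h.shape != shape:
        raise ValueError(f"latent arrays must have shape {shape}")

    samples, subjects, times = _sample_ids(design)
    a_flat, h_flat = a.ravel(), h.ravel()

    blocks: list[tuple[Sequence[str], float, np.ndarray]] = [
        (gene_sets.ampk_targets, design.beta_ampk, a_flat),
        (gene_sets.hif1_targets, design.beta_hif1, h_flat),
        (gene_sets.tca_enzymes, design.beta_enzyme, a_flat),
        (gene_sets.fao_enzymes, design.beta_enzyme, a_flat),
        (gene_sets.glycolysis_enzymes, design.beta_enzyme, h_flat),
    ]
    rows, index = [], []
    for genes, beta, latent in blocks:
        base = rng.normal(design.baseline_mean, 1.0, size=len(genes))
        for g, b0 in zip(genes, base):
            rows.append(b0 + beta * latent
                        + rng.normal(0.0, design.noise_sd, size=len(samples)))
            index.append(g)
    for j in range(design.n_background_genes):
        rows.append(rng.normal(design.baseline_mean, 1.0)
                    + rng.normal(0.0, design.noise_sd, size=len(samples)))
        index.append(f"BG{j:03d}")
    expr = pd.DataFrame(np.asarray(rows), index=index, columns=samples)
    truth = pd.DataFrame({
        "subject": subjects, "time": times,
        "ampk_activity": a_flat, "hif1_activity": h_flat,
    }, index=samples)
    return expr, truth


def generate_patient_course(
    n_subjects: int = 7,
    n_decreasing: int = 6,
    design: CohortDesign | None = None,
    gene_sets: GeneSets | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal treated cohort with a planted both-axes-decreasing
    subject count.

    The first ``n_decreasing`` subjects have strictly decreasing latent
    AMPK *and* HIF-1 activity across the time course; the remaining
    subjects decrease on the HIF-1 axis only (their AMPK activity
    rises), so feeding the output through signature scoring should
    recover exactly ``n_decreasing`` subjects decreasing on both axes.
    """
    if n_decreasing > n_subjects:
        raise ValueError("n_decreasing cannot exceed n_subjects")
    gene_sets = gene_sets or GeneSets.from_gmt()
    design = design or CohortDesign(
        n_subjects=n_subjects, timepoints=(0.0, 21.0, 90.0), noise_sd=0.5
    )
    if design.n_subjects != n_subjects or len(design.timepoints) < 2:
        raise ValueError("design must carry n_subjects and >= 2 time points")
    rng = rng or np.random.default_rng(design.seed)
    nT = len(design.timepoints)
    down = np.linspace(1.5, -1.5, nT)          # strictly decreasing course
    up = np.linspace(-1.0, 1.0, nT)
    a = np.empty((n_subjects, nT))
    h = np.empty((n_subjects, nT))
    for i in range(n_subjects):
        offset = rng.normal(0.0, 0.3)
        if i < n_decreasing:
            a[i] = down + offset
            h[i] = down + offset
        else:
            a[i] = up + offset                 # AMPK axis non-decreasing
            h[i] = down + offset
    expr, truth = generate_expression(design, gene_sets, latent_ampk=a,
                                      latent_hif1=h, rng=rng)
    return expr, truth


def generate_flux_fixture(
    true_params: MetabolicParameterSet,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    condition: str = "fixture",
    n_wells: int = 5,
    n_per_phase: int = 3,
    cell_count: float = 25000.0,
) -> tuple[FluxAssay, FluxAssay]:
    """Phase-wise constant OCR/ECAR traces realizing the given
    stress-test parameters, plus Gaussian measurement noise.

    At ``noise_sd=0`` the traces invert exactly:
    ``extract_stress_test(mito/glyco)`` reproduces ``true_params``.
    """
    true_params.validate_identities(atol=1e-9)
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = rng or np.random.default_rng()
    m, g = true_params.mito, true_params.glyco
    if not m or not g:
        raise ValueError("true_params must carry both mito and glyco arms")
    mito_levels = {
        "baseline": m["non_mito_respiration"] + m["basal_respiration"],
        "oligomycin": (m["non_mito_respiration"] + m["basal_respiration"]
                       - m["atp_linked"]),
        "FCCP": m["non_mito_respiration"] + m["maximal_respiration"],
        "rotenone_antimycinA": m["non_mito_respiration"],
    }
    glyco_levels = {
        "no_glucose": g["non_glycolytic_acidification"],
        "glucose": g["non_glycolytic_acidification"] + g["glycolysis"],
        "oligomycin": (g["non_glycolytic_acidification"]
                       + g["glycolytic_capacity"]),
        "2DG": g["non_glycolytic_acidification"],
    }

    def build(levels: dict, phases: tuple, modality: str) -> FluxAssay:
        rows = []
        t = 0.0
        for phase in phases:
            for _ in range(n_per_phase):
                for w in range(n_wells):
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append({
                        "well": f"W{w:02d}", "time_min": t, "phase": phase,
                        "value": levels[phase] * cell_count + noise,
                        "cell_count": cell_count,
                    })
                t += 6.0
        return FluxAssay(modality=modality, measurements=pd.DataFrame(rows),
                         condition=condition)

    mito_assay = build(mito_levels, MITO_PHASES, "OCR")
    glyco_assay = build(glyco_levels, GLYCO_PHASES, "ECAR")
    return mito_assay, glyco_assay


def example_flux_parameters(scale: float = 1.0) -> MetabolicParameterSet:
    """A consistent stress-test parameter set (identities hold exactly);
    ``scale < 1`` emulates a treated / metabolically repressed condition
    with both arms reduced."""
    return MetabolicParameterSet(
        mito={
            "non_mito_respiration": 10.0 * scale,
            "basal_respiration": 90.0 * scale,
            "atp_linked": 60.0 * scale,
            "maximal_respiration": 150.0 * scale,
            "spare_capacity": 60.0 * scale,
        },
        glyco={
            "non_glycolytic_acidification": 10.0 * scale,
            "glycolysis": 40.0 * scale,
            "glycolytic_capacity": 70.0 * scale,
            "glycolytic_reserve": 30.0 * scale,
        },
    )
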