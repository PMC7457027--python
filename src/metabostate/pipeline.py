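"""End-to-end reproduction workflow.

``run_all`` chains the four analysis demonstrations -- the 2x2-scenario
circuit ensemble, metabolic scoring of a synthetic longitudinal cohort,
stress-test extraction of a synthetic flux fixture, and the three
population-dynamics presets -- into one output directory with CSV
tables, figures and a machine-readable summary.  One global seed fans
out deterministically to per-stage sub-seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import population as pop
from .params import baseline_parameters, default_solver, load_parameters
from .scoring import GeneSets, pathway_score, signature_trajectory
from .seahorse import aggregate_2d, combine_arms, extract_stress_test, to_jatp
from .synth import example_flux_parameters, generate_flux_fixture, generate_patient_course

logger = logging.getLogger(__name__)

STAGES = ("ensemble", "scoring", "seahorse", "population")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of the full workflow (one global seed)."""

    seed: int = 0
    outdir: str = "metabostate_run"
    params_file: str | None = None      # None = shipped baseline
    n_sets: int = 500
    n_repeats: int = 3
    fraction: float = 0.25
    n_patients: int = 7
    n_decreasing: int = 6
    population_horizon: float = pop.DEFAULT_HORIZON_HOURS
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


def _stage_ensemble(config: RunConfig, out: Path, rng: np.random.Generator) -> dict:
    if config.params_file:
        params, settings = load_parameters(config.params_file)
    else:
        params, settings = baseline_parameters(), default_solver()
    summary = ens.scenario_fractions(
        params, ens.CANONICAL_SCENARIOS, n_sets=config.n_sets,
        n_repeats=config.n_repeats, rng=rng, fraction=config.fraction,
        settings=settings,
    )
    summary.mean.to_csv(out / "fractions_mean.csv")
    summary.sd.to_csv(out / "fractions_sd.csv")

    # one labelled reference ensemble for records + PC coordinates
    ref_res = ens.run_ensemble(params, ens.REFERENCE_SCENARIO, config.n_sets,
                               rng, fraction=config.fraction, settings=settings)
    reference = ens.fit_reference(ref_res)
    Z, pcs = ens.normalize_and_project(ref_res.records, reference)
    labels = ens.cluster_and_label(Z)
    records = ref_res.records.copy()
    records["cluster"] = labels
    records["PC1"], records["PC2"] = pcs[:, 0], pcs[:, 1]
    records.to_csv(out / "reference_records.csv", index=False)
    if config.make_figures:
        _scatter_figure(records, out / "reference_pca.png")
    ll = summary.mean["L/L"]
    return {
        "n_state_clusters": int(len(set(labels))),
        "ll_fraction_by_scenario": {k: float(v) for k, v in ll.items()},
        "reference_state_fractions":
            {k: float(v) for k, v in ens.state_fractions(labels).items()},
    }


def _stage_scoring(config: RunConfig, out: Path, rng: np.random.Generator) -> dict:
    gene_sets = GeneSets.from_gmt()
    expr, truth = generate_patient_course(
        n_subjects=config.n_patients, n_decreasing=config.n_decreasing,
        gene_sets=gene_sets, rng=rng,
    )
    expr.to_csv(out / "synthetic_patients_expression.csv")
    traj = signature_trajectory(expr, truth[["subject", "time"]], gene_sets)
    traj.table.to_csv(out / "patient_signatures.csv")
    scores = pd.DataFrame({
        "tca": pathway_score(expr, gene_sets.tca_enzymes),
        "glycolysis": pathway_score(expr, gene_sets.glycolysis_enzymes),
        "fao": pathway_score(expr, gene_sets.fao_enzymes),
    })
    scores.to_csv(out / "pathway_scores.csv")
    if config.make_figures:
        _trajectory_figure(traj.table, out / "patient_trajectories.png")
    return {"both_decrease_count": traj.both_decrease_count,
            "n_patients": int(config.n_patients)}


def _stage_seahorse(config: RunConfig, out: Path, rng: np.random.Generator) -> dict:
    conditions = {"basal": 1.0, "idling": 0.5}
    coords_in = {}
    jatp = {}
    for cond, scale in conditions.items():
        true = example_flux_parameters(scale)
        mito_assay, glyco_assay = generate_flux_fixture(true, noise_sd=0.0,
                                                        rng=rng, condition=cond)
        mito = extract_stress_test(mito_assay)
        glyco = extract_stress_test(glyco_assay)
        coords_in[cond] = combine_arms(glyco, mito)
        jatp[cond] = to_jatp(mito, glyco)
    coords = aggregate_2d(coords_in)
    coords.to_csv(out / "metabolic_space.csv")
    pd.DataFrame(jatp).T.to_csv(out / "jatp.csv")
    disp = coords.loc["idling"] - coords.loc["basal"]
    return {
        "idling_displacement": [float(disp["glycolysis_axis"]),
                                float(disp["oxphos_axis"])],
        "jatp_total_basal": float(jatp["basal"]["total"]),
        "jatp_total_idling": float(jatp["idling"]["total"]),
    }


def _stage_population(config: RunConfig, out: Path, rng: np.random.Generator) -> dict:
    rows = {}
    horizon = config.population_horizon
    trajs = {}
    for name, preset in pop.subclone_presets().items():
        tr = pop.simulate(preset, pop.DEFAULT_INITIAL_FRACTIONS, horizon)
        trajs[name] = tr
        rows[name] = {
            "early_dip": pop.dip_rate(tr, (0.0, 48.0)),
            "late_dip": pop.dip_rate(tr, (0.75 * horizon, horizon)),
            "asymptotic_dip": preset.asymptotic_dip(),
            "idling": pop.is_idling(tr),
        }
    table = pd.DataFrame(rows).T
    table.to_csv(out / "population_dip.csv")
    if config.make_figures:
        _population_figure(trajs, out / "population_growth.png")
    return {
        "preset_early_dip_signs": {
            name: int(np.sign(r["early_dip"])) if abs(r["early_dip"]) >= pop.IDLING_EPSILON else 0
            for name, r in rows.items()
        },
        "all_presets_idle": bool(table["idling"].all()),
    }


_STAGE_FUNCS = {
    "ensemble": _stage_ensemble,
    "scoring": _stage_scoring,
    "seahorse": _stage_seahorse,
    "population": _stage_population,
}


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the summary dict.

    Any stage failure raises :class:`StageError` naming the stage; all
    outputs stay under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    stage_rngs = dict(zip(STAGES, root.spawn(len(STAGES))))
    summary: dict = {"seed": config.seed}
    for stage in STAGES:
        logger.info("running stage %s", stage)
        try:
            summary[stage] = _STAGE_FUNCS[stage](config, out, stage_rngs[stage])
        except Exception as exc:       # noqa: BLE001 - rewrap with stage name
            raise StageError(stage, exc) from exc
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
# figures


def _scatter_figure(records: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for state, grp in records.groupby("cluster"):
        ax.scatter(grp["PC1"], grp["PC2"], s=8, alpha=0.6, label=state)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(title="state", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _trajectory_figure(table: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for subject, grp in table.groupby("subject"):
        grp = grp.sort_values("time")
        ax.plot(grp["ampk"], grp["hif1"], "-o", ms=3, alpha=0.7)
        ax.annotate("", xy=(grp["ampk"].iloc[-1], grp["hif1"].iloc[-1]),
                    xytext=(grp["ampk"].iloc[0], grp["hif1"].iloc[0]),
                    arrowprops=dict(arrowstyle="->", color="red", alpha=0.6))
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("AMPK signature")
    ax.set_ylabel("HIF-1 signature")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _population_figure(trajs: dict, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, tr in trajs.items():
        ax.plot(tr.times / 24.0, np.log2(tr.total / tr.total.iloc[0]), label=name)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("log2 population doublings")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
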