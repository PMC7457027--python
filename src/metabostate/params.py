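"""Parameters and circuit topology of the AMPK:HIF-1:ROS metabolic model.

The regulatory layer has four dynamical variables -- pAMPK (``A``, nM),
HIF-1 (``H``, nM), mitochondrial ROS (``Rmt``, mM) and NOX-derived ROS
(``Rnox``, mM).  Three metabolic pathway rates -- glucose oxidation
(``G1``), glycolysis (``G2``) and fatty-acid oxidation (``F``), in mM/min
-- are treated as quasi-steady-state algebraic functions of A and H,
because enzyme kinetics relax much faster than gene regulation.

Every interaction is a shifted-Hill edge, and the circuit is an explicit
edge list: topology is configuration, not code.  The special source
``"OX"`` denotes the combined oxidative flux G1 + F, which feeds back on
mtROS production.

All basal production/degradation rates are stored internally in per-hour
units; the shipped config file declares ROS production in mM/min (the
customary unit for those rates) and the loader converts on read.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Mapping

import yaml

REGULATORS = ("A", "H", "Rmt", "Rnox")
RATE_NAMES = ("G1", "G2", "F")
#: pseudo-regulator: total oxidative flux G1 + F (mM/min)
COMPOSITE_SOURCES = ("OX",)

PRODUCTION = "production"
DEGRADATION = "degradation"


class ParameterError(ValueError):
    """Invalid model parameter or override."""


class ConfigError(ValueError):
    """Malformed configuration input."""


@dataclass(frozen=True)
class HillEdge:
    """One shifted-Hill regulatory interaction.

    ``lam > 1`` is activation, ``lam < 1`` inhibition.  ``arm`` selects
    whether the edge multiplies the production or the degradation term of
    a regulatory target; edges onto metabolic rates always multiply the
    basal rate (``arm == "production"``).
    """

    source: str
    target: str
    arm: str
    x0: float
    n: int
    lam: float

    def __post_init__(self) -> None:
        if self.source not in REGULATORS + COMPOSITE_SOURCES:
            raise ConfigError(f"unknown edge source {self.source!r}")
        if self.target not in REGULATORS + tuple(RATE_NAMES):
            raise ConfigError(f"unknown edge target {self.target!r}")
        if self.target in RATE_NAMES and self.source in COMPOSITE_SOURCES:
            raise ConfigError("metabolic rates may not depend on OX (circular)")
        if self.arm not in (PRODUCTION, DEGRADATION):
            raise ConfigError(f"unknown edge arm {self.arm!r}")
        if self.target in RATE_NAMES and self.arm != PRODUCTION:
            raise ConfigError("rate edges act multiplicatively on the basal rate")
        if not (self.x0 > 0 and self.lam > 0):
            raise ParameterError("Hill threshold x0 and fold-change lam must be > 0")
        if int(self.n) != self.n or self.n < 1:
            raise ParameterError("Hill coefficient n must be an integer >= 1")

    @property
    def key(self) -> str:
        return f"{self.source}_{self.target}"


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for steady-state search and stability calls."""

    n_starts: int = 100
    tol: float = 1e-9           # scaled (dimensionless) residual
    dedup_rtol: float = 1e-3
    stability_eig_threshold: float = -1e-8  # 1/hour
    max_iter: int = 80
    box_lo: float = 1e-3        # start box, in units of g/k per variable
    box_hi: float = 1e2


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameterization of circuit + metabolic rate functions.

    Attributes
    ----------
    g, k
        Basal production (units of the variable per hour) and degradation
        (1/hour) for each regulator.
    rate_basal
        Basal metabolic pathway rates, mM/min.
    atp_yield
        ATP yield constants (mol ATP per mol substrate flux unit) for
        G1, G2, F.
    edges
        The shifted-Hill interaction list.
    """

    g: Mapping[str, float]
    k: Mapping[str, float]
    rate_basal: Mapping[str, float]
    atp_yield: Mapping[str, float]
    edges: tuple[HillEdge, ...]

    def __post_init__(self) -> None:
        for v in REGULATORS:
            if v not in self.g or v not in self.k:
                raise ConfigError(f"missing basal rates for regulator {v}")
            if not (self.g[v] > 0 and self.k[v] > 0):
                raise ParameterError(f"g_{v} and k_{v} must be > 0")
        for r in RATE_NAMES:
            if not (self.rate_basal.get(r, 0) > 0 and self.atp_yield.get(r, 0) > 0):
                raise ParameterError(f"basal rate and ATP yield for {r} must be > 0")
        keys = [e.key for e in self.edges]
        if len(set(keys)) != len(keys):
            raise ConfigError("duplicate (source, target) edge; keys must be unique")

    # -- flat scalar view (used by RACIPE-style sampling and overrides) ----

    def flatten(self) -> dict[str, float]:
        """All scalar parameters under stable names.

        Names: ``g_X``/``k_X`` per regulator (per-hour units),
        ``basal_R``/``y_R`` per pathway, and ``lam_S_T``/``x0_S_T``/
        ``n_S_T`` per edge.
        """
        out: dict[str, float] = {}
        for v in REGULATORS:
            out[f"g_{v}"] = float(self.g[v])
            out[f"k_{v}"] = float(self.k[v])
        for r in RATE_NAMES:
            out[f"basal_{r}"] = float(self.rate_basal[r])
            out[f"y_{r}"] = float(self.atp_yield[r])
        for e in self.edges:
            out[f"lam_{e.key}"] = float(e.lam)
            out[f"x0_{e.key}"] = float(e.x0)
            out[f"n_{e.key}"] = float(e.n)
        return out

    def with_values(self, values: Mapping[str, float]) -> "ModelParameters":
        """Return a copy with the named flat parameters replaced."""
        known = set(self.flatten())
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown parameter name(s): {sorted(unknown)}")
        g = dict(self.g)
        k = dict(self.k)
        basal = dict(self.rate_basal)
        yields_ = dict(self.atp_yield)
        by_key = {e.key: e for e in self.edges}
        for name, val in values.items():
            head, _, rest = name.partition("_")
            if head == "g" and rest in REGULATORS:
                g[rest] = float(val)
            elif head == "k" and rest in REGULATORS:
                k[rest] = float(val)
            elif head == "basal":
                basal[rest] = float(val)
            elif head == "y":
                yields_[rest] = float(val)
            else:
                edge = by_key[rest]
                if head == "lam":
                    by_key[rest] = replace(edge, lam=float(val))
                elif head == "x0":
                    by_key[rest] = replace(edge, x0=float(val))
                elif head == "n":
                    by_key[rest] = replace(edge, n=int(round(val)))
        edges = tuple(by_key[e.key] for e in self.edges)
        return ModelParameters(g=g, k=k, rate_basal=basal, atp_yield=yields_, edges=edges)

    def edges_onto(self, target: str, arm: str | None = None) -> tuple[HillEdge, ...]:
        return tuple(
            e for e in self.edges
            if e.target == target and (arm is None or e.arm == arm)
        )


# ---------------------------------------------------------------------------
# config I/O


def _params_from_config(cfg: Mapping) -> ModelParameters:
    base = cfg["baseline"]
    g, k = {}, {}
    for v in REGULATORS:
        entry = base[v]
        if "g_mm_per_min" in entry:
            g[v] = float(entry["g_mm_per_min"]) * 60.0  # harmonize to per-hour
        else:
            g[v] = float(entry["g"])
        k[v] = float(entry["k"])
    rates = base["rates"]
    rate_basal = {r: float(rates[r]["basal"]) for r in RATE_NAMES}
    atp_yield = {r: float(rates[r]["atp_yield"]) for r in RATE_NAMES}
    edges = tuple(
        HillEdge(
            source=str(e["source"]), target=str(e["target"]),
            arm=str(e.get("arm", PRODUCTION)),
            x0=float(e["x0"]), n=int(e["n"]), lam=float(e["lam"]),
        )
        for e in cfg["topology"]
    )
    return ModelParameters(g=g, k=k, rate_basal=rate_basal,
                           atp_yield=atp_yield, edges=edges)


def _solver_from_config(cfg: Mapping) -> SolverSettings:
    sol = cfg.get("solver", {})
    coerced = {
        key: (int(val) if key in ("n_starts", "max_iter") else float(val))
        for key, val in sol.items()
    }
    return SolverSettings(**coerced)


def load_parameters(path=None) -> tuple[ModelParameters, SolverSettings]:
    """Load (parameters, solver settings) from a YAML config.

    With ``path=None`` the versioned baseline shipped with the package is
    used.  The file has three sections: ``baseline`` (basal rates; ROS
    production may be given as ``g_mm_per_min``), ``topology`` (edge
    list) and ``solver``.
    """
    if path is None:
        res = importlib.resources.files("metabostate.data").joinpath("baseline.yaml")
        cfg = yaml.safe_load(res.read_text())
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    try:
        return _params_from_config(cfg), _solver_from_config(cfg)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed parameter config: {exc}") from exc


def baseline_parameters() -> ModelParameters:
    """The shipped, frozen baseline parameter set."""
    return load_parameters()[0]


def default_solver() -> SolverSettings:
    return load_parameters()[1]
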