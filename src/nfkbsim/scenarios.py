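"""Hsp72 regulatory hypotheses as declarative model perturbations.

Constant Hsp72 overexpression is represented as constant multiplicative
changes to specific rate constants and/or initial protein pools — Hsp72 is
never an explicit reacting species.  Each scenario is applied before
equilibration, so the perturbed cell reaches its own resting state first.

A scenario is judged plausible when it simultaneously reproduces the four
key experimental observations from Hsp72-overexpressing cells: reduced
resting total IκBα, reduced peak IKK activity, reduced peak nuclear NF-κB,
and essentially unchanged resting NF-κB activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import InitialPools, ParameterSet
from .readouts import observable, peak
from .simulate import Trajectory

__all__ = [
    "Scenario",
    "ScenarioVerdict",
    "REDUCTION_MARGIN",
    "BASAL_BAND",
    "build_catalog",
    "apply_scenario",
    "evaluate_scenario",
]

#: A feature counts as "reduced" when scenario/nominal <= 1 - margin.
REDUCTION_MARGIN = 0.05
#: Basal NF-κB activity counts as preserved within +/- this relative band.
BASAL_BAND = 0.15


@dataclass(frozen=True)
class Scenario:
    """Named multiplicative perturbation of rates and/or initial pools."""

    name: str
    rate_factors: Mapping[str, float] = field(default_factory=dict)
    pool_factors: Mapping[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        for label, factors in (("rate", self.rate_factors),
                               ("pool", self.pool_factors)):
            for k, f in factors.items():
                if not (f > 0 and np.isfinite(f)):
                    raise ValueError(
                        f"{label} factor for {k!r} must be finite and > 0, got {f}"
                    )
        object.__setattr__(self, "rate_factors", dict(self.rate_factors))
        object.__setattr__(self, "pool_factors", dict(self.pool_factors))

    @property
    def is_nominal(self) -> bool:
        return not self.rate_factors and not self.pool_factors

    def apply(self, params: ParameterSet,
              pools: InitialPools) -> tuple[ParameterSet, InitialPools]:
        return (params.with_factors(self.rate_factors),
                pools.with_factors(self.pool_factors))

    def inverse(self) -> "Scenario":
        """Scenario undoing this one: apply then apply-inverse restores nominal."""
        return Scenario(
            name=f"{self.name}__inverse",
            rate_factors={k: 1.0 / f for k, f in self.rate_factors.items()},
            pool_factors={k: 1.0 / f for k, f in self.pool_factors.items()},
            provenance=f"algebraic inverse of {self.name}",
        )

    def to_dict(self) -> dict:
        return {"name": self.name, "rate_factors": dict(self.rate_factors),
                "pool_factors": dict(self.pool_factors),
                "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        return cls(name=d["name"], rate_factors=d.get("rate_factors", {}),
                   pool_factors=d.get("pool_factors", {}),
                   provenance=d.get("provenance", ""))


def apply_scenario(params: ParameterSet, pools: InitialPools,
                   scenario: Scenario) -> tuple[ParameterSet, InitialPools]:
    """Functional form of :meth:`Scenario.apply`."""
    return scenario.apply(params, pools)


def _scan(prefix: str, rate: str, factors, provenance: str) -> list[Scenario]:
    out = []
    for f in factors:
        tag = f"{f:g}".replace("/", "_")
        out.append(Scenario(name=f"{prefix}_{rate}_x{tag}",
                            rate_factors={rate: f}, provenance=provenance))
    return out


def build_catalog() -> dict[str, Scenario]:
    """Every cataloged Hsp72 regulation hypothesis, keyed by name.

    Names carry the figure each scenario reproduces.  Hypothetical
    kp/ki/kiA20 scans use dyadic factors over [1/16, 16]; the published
    ka scan uses the dyadic factors down to 1/16.
    """
    halvings = [0.5, 0.25, 0.125, 1 / 16]
    doublings = [2.0, 4.0, 8.0, 16.0]
    cat: list[Scenario] = [Scenario(name="nominal", provenance="control model")]

    # --- upstream single-mechanism scans -------------------------------
    cat += _scan("Fig3A", "ka", [1.0] + halvings,
                 "Fig 3A: inhibition of TNF-induced IKK activation")
    cat += _scan("FigS2B", "kp", halvings,
                 "Fig S2B: reduced recovery of inactivated IKK (hypothetical)")
    cat += _scan("FigS2C", "ki", doublings,
                 "Fig S2C: enhanced IKK auto-inactivation (hypothetical)")
    cat += _scan("FigS2D", "kiA20", doublings,
                 "Fig S2D: enhanced A20-dependent IKK inactivation (hypothetical)")

    # --- downstream single-mechanism scans -----------------------------
    cat += _scan("Fig3B", "kc2a", [0.2, 1 / 6, 0.1, 1 / 32],
                 "Fig 3B / S3A / S6B: inhibition of IκBα phosphorylation")
    for rate, fig in (("kua1", "FigS3C"), ("kuc1", "FigS3D"), ("kupd", "FigS3B")):
        cat += _scan(fig, rate, halvings + [1 / 32],
                     f"{fig}: inhibition of IκBα degradation step {rate}")

    # --- steady-state protein-level scenarios --------------------------
    cat.append(Scenario("Fig4A_c2a_30th", rate_factors={"c2a": 1 / 30},
                        provenance="Fig 4A: direct inhibition of IκBα translation"))
    cat.append(Scenario("Fig5A_pool70", pool_factors={"NFkB_pool": 0.70},
                        provenance="Fig 5A / S7A: total p65 reduced to 70%"))
    for f, tag in ((0.055, "5p5pct"), (0.125, "8th"), (1 / 18, "18th")):
        cat.append(Scenario(f"FigS4A_IKKn_{tag}", pool_factors={"IKKn_pool": f},
                            provenance="Fig S4A: reduction of total IKK only"))

    # --- combined scenarios --------------------------------------------
    cat += [
        Scenario("Fig5B_pool70_IKKn5p5",
                 pool_factors={"NFkB_pool": 0.70, "IKKn_pool": 0.055},
                 provenance="Fig 5B: p65 at 70% plus total IKK at 5.5%"),
        Scenario("Fig6A_combined",
                 rate_factors={"kiA20": 10.0, "kc2a": 1 / 6},
                 pool_factors={"NFkB_pool": 0.70},
                 provenance="Fig 5C / 6A / S7C: p65 70%, kiA20 x10, kc2a /6"),
        Scenario("FigS5_pool70_kiA20x10",
                 rate_factors={"kiA20": 10.0}, pool_factors={"NFkB_pool": 0.70},
                 provenance="Fig S5: p65 70% plus upstream inhibition only"),
        Scenario("FigS4C_pool70_kc2a10th",
                 rate_factors={"kc2a": 0.1}, pool_factors={"NFkB_pool": 0.70},
                 provenance="Fig S4C: p65 70% plus downstream inhibition only"),
        Scenario("FigS4B_IKKn8th_kc2a5th",
                 rate_factors={"kc2a": 0.2}, pool_factors={"IKKn_pool": 0.125},
                 provenance="Fig S4B: IKK pool 1/8 plus downstream inhibition"),
        Scenario("FigS7B_IKKn18th_pool70",
                 pool_factors={"NFkB_pool": 0.70, "IKKn_pool": 1 / 18},
                 provenance="Fig S7B: p65 70% plus IKK pool 1/18"),
        Scenario("FigS6A_ka_16th", rate_factors={"ka": 1 / 16},
                 provenance="Fig S6A: ka at 1/16 under parameter uncertainty"),
        Scenario("FigS6B_kc2a_32nd", rate_factors={"kc2a": 1 / 32},
                 provenance="Fig S6B: kc2a at 1/32 under parameter uncertainty"),
    ]
    return {s.name: s for s in cat}


@dataclass(frozen=True)
class ScenarioVerdict:
    """Plausibility classification of one scenario against the key observations."""

    scenario: str
    reduces_basal_total_IkBa: bool
    reduces_peak_IKKa: bool
    reduces_peak_nuclear_NFkB: bool
    preserves_basal_NFkB_activity: bool
    basal_total_IkBa_ratio: float
    peak_IKKa_ratio: float
    peak_nuclear_NFkB_ratio: float
    basal_NFkB_ratio: float
    reduction_margin: float
    basal_band: float

    @property
    def plausible(self) -> bool:
        return (self.reduces_basal_total_IkBa and self.reduces_peak_IKKa
                and self.reduces_peak_nuclear_NFkB
                and self.preserves_basal_NFkB_activity)

    @property
    def failed_criteria(self) -> tuple[str, ...]:
        checks = {
            "reduces_basal_total_IkBa": self.reduces_basal_total_IkBa,
            "reduces_peak_IKKa": self.reduces_peak_IKKa,
            "reduces_peak_nuclear_NFkB": self.reduces_peak_nuclear_NFkB,
            "preserves_basal_NFkB_activity": self.preserves_basal_NFkB_activity,
        }
        return tuple(k for k, ok in checks.items() if not ok)

    def to_dict(self) -> dict:
        d = {
            "scenario": self.scenario,
            "label": "plausible" if self.plausible else "implausible",
            "failed_criteria": list(self.failed_criteria),
            "reduction_margin": self.reduction_margin,
            "basal_band": self.basal_band,
        }
        for k in ("reduces_basal_total_IkBa", "reduces_peak_IKKa",
                  "reduces_peak_nuclear_NFkB", "preserves_basal_NFkB_activity",
                  "basal_total_IkBa_ratio", "peak_IKKa_ratio",
                  "peak_nuclear_NFkB_ratio", "basal_NFkB_ratio"):
            d[k] = getattr(self, k)
        return d


def evaluate_scenario(
    scenario: Scenario,
    nominal_run: Trajectory,
    scenario_run: Trajectory,
    reduction_margin: float = REDUCTION_MARGIN,
    basal_band: float = BASAL_BAND,
) -> ScenarioVerdict:
    """Classify a scenario by comparing its stimulated run against the nominal run.

    Both trajectories must start from their respective equilibria (first row)
    and share the same time grid.
    """
    if nominal_run.t.shape != scenario_run.t.shape or not np.allclose(
            nominal_run.t, scenario_run.t, rtol=0, atol=1e-9):
        raise ValueError("nominal and scenario runs must share the same time grid")

    def _ratio(name: str, basal: bool) -> float:
        nom = observable(nominal_run, name)
        sce = observable(scenario_run, name)
        if basal:
            num, den = sce.values[0], nom.values[0]
        else:
            num, den = peak(sce)[0], peak(nom)[0]
        return float("nan") if den == 0 else num / den

    r_ikba = _ratio("total_ikba", basal=True)
    r_ikka = _ratio("ikk_active", basal=False)
    r_nfkb = _ratio("nuclear_nfkb", basal=False)
    r_basal = _ratio("nuclear_nfkb", basal=True)

    cut = 1.0 - reduction_margin
    return ScenarioVerdict(
        scenario=scenario.name,
        reduces_basal_total_IkBa=bool(r_ikba <= cut),
        reduces_peak_IKKa=bool(r_ikka <= cut),
        reduces_peak_nuclear_NFkB=bool(r_nfkb <= cut),
        preserves_basal_NFkB_activity=bool(abs(r_basal - 1.0) <= basal_band),
        basal_total_IkBa_ratio=r_ikba,
        peak_IKKa_ratio=r_ikka,
        peak_nuclear_NFkB_ratio=r_nfkb,
        basal_NFkB_ratio=r_basal,
        reduction_margin=reduction_margin,
        basal_band=basal_band,
    )
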