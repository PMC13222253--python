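"""Synthetic inputs: parametric life tables, ground-truth bundles, PSA fixtures.

Everything the pipeline consumes can be generated here without any external
download. The life table is a Gompertz–Makeham stand-in for a national
annual life table (the published analysis used the Turkish one, which is
not redistributed here); ground-truth bundles drive the calibration
recovery tests; PSA fixtures assign Beta/Gamma uncertainty to every
sampled parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .parameters import LifeTable, ParameterBundle, TransitionParams, get_param
from .states import HealthState, Perspective

__all__ = [
    "GompertzMakehamSpec",
    "make_life_table",
    "make_ground_truth_bundle",
    "make_psa_fixture",
]


@dataclass(frozen=True)
class GompertzMakehamSpec:
    """Adult mortality law: hazard(age) = makeham + gompertz_a * exp(gompertz_b * age).

    Defaults give a remaining life expectancy at age 40 in the high-30s to
    mid-40s — a realistic band for a middle-income general population —
    with the modal age at death in the mid-80s.
    """

    makeham: float = 0.0005   # age-independent annual hazard
    gompertz_a: float = 2e-5  # senescent hazard scale
    gompertz_b: float = 0.1   # log-hazard slope per year of age
    age_lo: int = 40
    age_hi: int = 99

    def __post_init__(self):
        if self.makeham < 0 or self.gompertz_a < 0 or self.gompertz_b < 0:
            raise ValidationError("Gompertz-Makeham parameters must be >= 0",
                                  field="gompertz_makeham")
        if self.age_hi < self.age_lo:
            raise ValidationError("age range is empty", field="gompertz_makeham")


def make_life_table(spec: GompertzMakehamSpec) -> LifeTable:
    """Annual death probabilities ``qx = 1 - exp(-hazard(age))`` over the range.

    The exponential form keeps every qx inside [0, 1] by construction and
    qx is non-decreasing in age whenever ``gompertz_b > 0``.
    """
    ages = np.arange(spec.age_lo, spec.age_hi + 1)
    hazard = spec.makeham + spec.gompertz_a * np.exp(spec.gompertz_b * ages)
    lt = LifeTable(ages=ages, qx=1.0 - np.exp(-hazard))
    lt.validate()
    return lt


def make_ground_truth_bundle(seed: int) -> tuple[ParameterBundle, dict[str, float]]:
    """Draw a plausible, fully valid parameter bundle plus its hidden truth.

    Remission entry is drawn high for sleeve gastrectomy and low for
    pharmacotherapy (overall box [0.05, 0.6]); relapse in [0, 0.15]; an
    excess T2DM mortality hazard ratio in [1.3, 2.0] applies while on
    glucose-lowering treatment, with remission back at background mortality.
    The state-dependent mortality makes lifetime discounted cost and QALY
    jointly informative about (p_remission, p_relapse), so the pair is
    recoverable from noiseless lifetime targets.

    Returns ``(bundle, truth)`` where ``truth`` maps dot paths
    (e.g. ``transitions.SG.p_remission``) to the drawn values. The truth
    record is deliberately separate from the bundle so recovery tests can
    start calibration elsewhere without leaking the answer.
    """
    from .basecase import base_case_bundle  # deferred: basecase also uses us

    rng = np.random.default_rng(seed)
    spec = GompertzMakehamSpec(
        makeham=float(rng.uniform(3e-4, 8e-4)),
        gompertz_a=float(np.exp(rng.uniform(np.log(1e-5), np.log(4e-5)))),
        gompertz_b=float(rng.uniform(0.09, 0.11)),
    )
    bundle = base_case_bundle(life_table=make_life_table(spec))
    hr = float(rng.uniform(1.3, 2.0))
    bundle.transitions = {
        "PT": TransitionParams(
            p_remission=float(rng.uniform(0.05, 0.20)),
            p_relapse=float(rng.uniform(0.02, 0.15)),
            mortality_hr_t2dm=hr),
        "SG": TransitionParams(
            p_remission=float(rng.uniform(0.25, 0.60)),
            p_relapse=float(rng.uniform(0.0, 0.10)),
            mortality_hr_t2dm=hr),
    }
    bundle.validate()
    truth = {
        "transitions.PT.p_remission": bundle.transitions["PT"].p_remission,
        "transitions.PT.p_relapse": bundle.transitions["PT"].p_relapse,
        "transitions.SG.p_remission": bundle.transitions["SG"].p_remission,
        "transitions.SG.p_relapse": bundle.transitions["SG"].p_relapse,
        "transitions.*.mortality_hr_t2dm": hr,
    }
    return bundle, truth


def make_psa_fixture(bundle: ParameterBundle, se_fraction: float = 0.10):
    """Distribution specs for every sampled parameter of ``bundle``.

    Beta for probabilities and utilities, Gamma for every non-zero cost
    component of the bundle's run perspective; standard error defaults to
    ``se_fraction`` of the mean (10%, the usual convention when only point
    estimates are published). Zero-valued quantities become ``fixed``.
    """
    from .psa import DistributionSpec  # deferred: psa imports parameters only

    specs: list[DistributionSpec] = []

    def add(path: str, value: float, kind: str) -> None:
        if value == 0.0:
            specs.append(DistributionSpec(path, "fixed", value, 0.0))
        elif kind == "prob":
            specs.append(DistributionSpec(path, "beta", value,
                                          se_fraction * value))
        else:
            specs.append(DistributionSpec(path, "gamma", value,
                                          se_fraction * value))

    add("utilities.u_t2dm", bundle.utilities.u_t2dm, "prob")
    add("utilities.u_remission", bundle.utilities.u_remission, "prob")
    for sid in bundle.strategies:
        tp = bundle.transitions[sid]
        add(f"transitions.{sid}.p_remission", tp.p_remission, "prob")
        add(f"transitions.{sid}.p_relapse", tp.p_relapse, "prob")
    from .parameters import iter_cost_paths
    for path in iter_cost_paths(bundle):
        add(path, get_param(bundle, path), "cost")
    return specs
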