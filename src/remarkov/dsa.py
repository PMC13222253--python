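"""Deterministic sensitivity analysis: one-way tornado and scenario re-runs.

Default ranges follow the usual convention when a source publishes only
point estimates: costs and utilities varied +/-20% (utilities clamped to
[0, 1]), transition probabilities varied +/-20% on a relative scale
clamped to [0, 1], and the discount rate swept from 0 to 5%. The default
outcome metric is the incremental net monetary benefit at the 3x-GDP
willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .economics import CEResult, evaluate
from .errors import ValidationError
from .parameters import (
    ParameterBundle,
    get_param,
    iter_cost_paths,
    with_params,
)
from .states import Perspective

__all__ = ["ParamRange", "TornadoEntry", "default_ranges", "one_way",
           "scenario", "best_worst"]

METRICS = ("inmb", "icer")


@dataclass(frozen=True)
class ParamRange:
    """Low/base/high values for one dot-path parameter."""

    path: str
    low: float
    base: float
    high: float

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValidationError(
                f"require low <= base <= high, got ({self.low}, {self.base}, "
                f"{self.high})", field=self.path)


@dataclass(frozen=True)
class TornadoEntry:
    path: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float
    error: str = ""

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def default_ranges(bundle: ParameterBundle, rel: float = 0.20,
                   perspective: Perspective | None = None) -> list[ParamRange]:
    """The package's default one-way ranges for a bundle."""
    ranges: list[ParamRange] = []

    def clamp01(x: float) -> float:
        return min(max(x, 0.0), 1.0)

    for path in ("utilities.u_t2dm", "utilities.u_remission"):
        base = get_param(bundle, path)
        ranges.append(ParamRange(path, clamp01(base * (1 - rel)), base,
                                 clamp01(base * (1 + rel))))
    for sid in bundle.strategies:
        for name in ("p_remission", "p_relapse"):
            path = f"transitions.{sid}.{name}"
            base = get_param(bundle, path)
            ranges.append(ParamRange(path, clamp01(base * (1 - rel)), base,
                                     clamp01(base * (1 + rel))))
    for path in iter_cost_paths(bundle, perspective):
        base = get_param(bundle, path)
        ranges.append(ParamRange(path, base * (1 - rel), base, base * (1 + rel)))
    base_dr = get_param(bundle, "config.discount_rate")
    ranges.append(ParamRange("config.discount_rate", 0.0, base_dr, 0.05))
    return ranges


def _metric_value(result: CEResult, metric: str, wtp: float) -> float:
    if metric == "inmb":
        return wtp * result.delta_qaly - result.delta_cost
    if metric == "icer":
        if result.icer is None:
            raise ValidationError("ICER undefined (zero QALY difference)",
                                  field="metric")
        return result.icer
    raise ValidationError(f"metric must be one of {METRICS}", field="metric")


def one_way(bundle: ParameterBundle, ranges: list[ParamRange],
            metric: str = "inmb", wtp: float = 39330.0,
            perspective: Perspective | None = None,
            ) -> tuple[list[TornadoEntry], float]:
    """Re-run the full model at each range end, all else held at base.

    Returns the tornado entries sorted by width descending (ties broken by
    parameter path) together with the base-case metric value. A range that
    produces an invalid bundle is returned flagged in ``error`` with NaN
    outcomes rather than aborting the sweep.
    """
    base_result = evaluate(bundle, perspective)
    base_value = _metric_value(base_result, metric, wtp)

    entries: list[TornadoEntry] = []
    for r in ranges:
        outs = {}
        err = ""
        for end, value in (("low", r.low), ("high", r.high)):
            try:
                b = with_params(bundle, {r.path: value})
                b.validate()
                outs[end] = _metric_value(evaluate(b, perspective), metric, wtp)
            except Exception as exc:  # flagged, sweep continues
                outs[end] = float("nan")
                err = f"{type(exc).__name__}: {exc}"
        entries.append(TornadoEntry(r.path, r.low, r.high,
                                    outs["low"], outs["high"], error=err))
    entries.sort(key=lambda e: (-(e.width if e.width == e.width else -1.0), e.path))
    return entries, base_value


def scenario(bundle: ParameterBundle, overrides: dict[str, float],
             perspective: Perspective | None = None) -> CEResult:
    """One re-run with all overrides applied simultaneously."""
    b = with_params(bundle, overrides) if overrides else bundle.copy()
    b.validate()
    return evaluate(b, perspective)


def best_worst(bundle: ParameterBundle, ranges: list[ParamRange],
               wtp: float = 39330.0, perspective: Perspective | None = None,
               ) -> tuple[CEResult, CEResult]:
    """Best-case / worst-case scenarios for the intervention.

    The intervention-favourable end of each range is read off the one-way
    sweep (the end with the larger incremental NMB); the best case applies
    every favourable end simultaneously, the worst case every unfavourable
    end.
    """
    entries, _ = one_way(bundle, ranges, metric="inmb", wtp=wtp,
                         perspective=perspective)
    best: dict[str, float] = {}
    worst: dict[str, float] = {}
    for e in entries:
        if e.error or e.outcome_low != e.outcome_low:
            continue
        if e.outcome_high >= e.outcome_low:
            best[e.path], worst[e.path] = e.high, e.low
        else:
            best[e.path], worst[e.path] = e.low, e.high
    return (scenario(bundle, best, perspective),
            scenario(bundle, worst, perspective))
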