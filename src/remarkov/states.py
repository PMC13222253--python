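"""Health states, payer perspectives and strategy identifiers.

The model is a three-state Markov structure for people with obesity and
type 2 diabetes: ``T2DM`` (on glucose-lowering treatment), ``REMISSION``
(normal glycaemic control off glucose-lowering drugs) and ``DEAD``
(absorbing). Two treatment strategies are compared — pharmacological
therapy (``PT``) and sleeve gastrectomy (``SG``) — under two payer
perspectives: the Turkish Social Security Institution tariff (``SUT``)
and the Public Health Service Price Schedule (``PHSP``).
"""

from __future__ import annotations

from enum import Enum


class HealthState(str, Enum):
    """One of the three Markov health states."""

    T2DM = "T2DM"
    REMISSION = "REMISSION"
    DEAD = "DEAD"


class Perspective(str, Enum):
    """Payer perspective used to price resource use."""

    SUT = "SUT"
    PHSP = "PHSP"


#: Column order used everywhere a state axis appears (traces, matrices).
STATE_ORDER: tuple[HealthState, ...] = (
    HealthState.T2DM,
    HealthState.REMISSION,
    HealthState.DEAD,
)

#: Index of each state along the shared state axis.
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATE_ORDER)}

#: Strategy identifiers. PT is the comparator, SG the intervention.
STRATEGIES: tuple[str, str] = ("PT", "SG")
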