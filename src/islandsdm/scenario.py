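"""Scenario addressing: one (GCM, RCP, time-slice) triple per projected climate."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScenarioSpec:
    """Addresses one projected climate stack.

    gcm
        Circulation-model label, e.g. ``"ccsm4-like"`` or ``"ensemble-like"``.
    rcp
        Emissions-pathway label, ``"4.5"`` (mild) or ``"8.5"`` (severe).
    slice
        Time-slice label, one of ``"2020s"``, ``"2050s"``, ``"2080s"``.
    """

    gcm: str
    rcp: str
    slice: str

    @property
    def label(self) -> str:
        return f"{self.gcm}_rcp{self.rcp}_{self.slice}"


#: Label used wherever a ScenarioSpec slot refers to the baseline climate.
BASELINE = ScenarioSpec("baseline", "none", "current")
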