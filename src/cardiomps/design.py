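"""Dose-escalation study designs.

A design mirrors the acute dose-escalation protocol of a 4-plex cardiac MPS
pharmacology study: one or more drug arms, each with a dose ladder given
either directly in µM or as multiples of the drug's clinical Cmax (resolved
to µM at load time so that a single canonical unit flows downstream), seven
tissues per arm by default, four tissue chambers per chip, and a fixed
per-dose recording protocol (spontaneous 6-s and 30-s calcium, 6-s voltage,
plus 6-s paced recordings of both channels) with a 30-min incubation per
dose step.  Polytherapy arms carry several components whose per-step doses
are listed in lockstep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import yaml

from .traces import Channel, Rhythm

__all__ = [
    "DrugComponent",
    "DrugArm",
    "DoseEscalationDesign",
    "DEFAULT_RECORDING_PROTOCOL",
    "table1_design",
    "load_design",
    "save_design",
]

#: (channel, rhythm, length_s) triplets recorded per tissue x dose step
DEFAULT_RECORDING_PROTOCOL: Tuple[Tuple[str, str, float], ...] = (
    ("calcium", "spontaneous", 30.0),
    ("calcium", "spontaneous", 6.0),
    ("voltage", "spontaneous", 6.0),
    ("calcium", "paced", 6.0),
    ("voltage", "paced", 6.0),
)


@dataclass(frozen=True)
class DrugComponent:
    """One compound within an arm, with its ladder resolved to µM."""

    name: str
    cmax_uM: float
    doses: Tuple[float, ...]  # per dose step
    unit: str = "xcmax"  # "xcmax" (multiples of Cmax) or "uM"

    def __post_init__(self) -> None:
        if self.unit not in ("xcmax", "uM"):
            raise ValueError("unit must be 'xcmax' or 'uM'")
        if self.unit == "xcmax" and not self.cmax_uM > 0:
            raise ValueError("xcmax ladders require a positive cmax_uM")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))

    @property
    def doses_uM(self) -> Tuple[float, ...]:
        if self.unit == "uM":
            return self.doses
        return tuple(d * self.cmax_uM for d in self.doses)


@dataclass(frozen=True)
class DrugArm:
    """One escalation arm: a drug (or fixed-ratio combination) and its ladder."""

    name: str
    components: Tuple[DrugComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("an arm needs at least one component")
        lengths = {len(c.doses) for c in self.components}
        if len(lengths) != 1:
            raise ValueError("all components must list one dose per step")
        totals = self.total_uM
        if totals[0] != 0.0:
            raise ValueError(f"arm {self.name!r}: dose ladder must start at 0")
        if any(b <= a for a, b in zip(totals, totals[1:])):
            raise ValueError(
                f"arm {self.name!r}: total dose must be strictly increasing"
            )

    @classmethod
    def single(
        cls, name: str, cmax_uM: float, ladder: Sequence[float], unit: str = "xcmax"
    ) -> "DrugArm":
        return cls(name, (DrugComponent(name, cmax_uM, tuple(ladder), unit),))

    @property
    def n_steps(self) -> int:
        return len(self.components[0].doses)

    @property
    def doses_uM(self) -> List[Dict[str, float]]:
        """Per step, the µM dose of every component."""
        return [
            {c.name: c.doses_uM[i] for c in self.components}
            for i in range(self.n_steps)
        ]

    @property
    def total_uM(self) -> Tuple[float, ...]:
        """Summed µM per step — the scalar dose recorded in trace metadata."""
        return tuple(sum(step.values()) for step in self.doses_uM)


@dataclass(frozen=True)
class DoseEscalationDesign:
    drugs: Tuple[DrugArm, ...]
    n_tissues: int = 7
    chambers_per_chip: int = 4
    pacing_frequency_hz: float = 1.0
    recording_protocol: Tuple[Tuple[str, str, float], ...] = DEFAULT_RECORDING_PROTOCOL
    incubation_min_per_dose: int = 30

    def __post_init__(self) -> None:
        if isinstance(self.drugs, DrugArm):
            object.__setattr__(self, "drugs", (self.drugs,))
        else:
            object.__setattr__(self, "drugs", tuple(self.drugs))
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be >= 1")
        if self.chambers_per_chip != 4:
            raise ValueError("the 4-plex chip houses exactly 4 chambers")
        if self.pacing_frequency_hz not in (1.0, 1.5):
            raise ValueError("pacing frequency must be 1.0 or 1.5 Hz")
        for ch, rhythm, length in self.recording_protocol:
            Channel(ch), Rhythm(rhythm)
            if length <= 0:
                raise ValueError("recording length must be positive")


def table1_design(n_tissues: int = 7) -> DoseEscalationDesign:
    """The acute HCQ / AZM / polytherapy escalation design.

    Ladders are in multiples of the clinical Cmax (HCQ 1 µM, AZM 0.67 µM);
    the polytherapy arm holds HCQ at Cmax while AZM escalates.
    """
    hcq = DrugArm.single("HCQ", 1.0, (0, 0.1, 1, 10, 100, 1000))
    azm = DrugArm.single("AZM", 0.67, (0, 0.1, 1, 10, 100))
    combo = DrugArm(
        "HCQ+AZM",
        (
            DrugComponent("HCQ", 1.0, (0, 1, 1, 1, 1, 1, 1)),
            DrugComponent("AZM", 0.67, (0, 0, 0.1, 0.3, 1, 3, 10)),
        ),
    )
    return DoseEscalationDesign(drugs=(hcq, azm, combo), n_tissues=n_tissues)


# ---------------------------------------------------------------------------
# YAML round trip

def save_design(design: DoseEscalationDesign, path) -> None:
    data = {
        "n_tissues": design.n_tissues,
        "chambers_per_chip": design.chambers_per_chip,
        "pacing_frequency_hz": design.pacing_frequency_hz,
        "incubation_min_per_dose": design.incubation_min_per_dose,
        "recording_protocol": [list(r) for r in design.recording_protocol],
        "drugs": [
            {
                "name": arm.name,
                "components": [
                    {
                        "name": c.name,
                        "cmax_uM": c.cmax_uM,
                        "unit": c.unit,
                        "doses": list(c.doses),
                    }
                    for c in arm.components
                ],
            }
            for arm in design.drugs
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_design(path) -> DoseEscalationDesign:
    data = yaml.safe_load(Path(path).read_text())
    arms = []
    for arm in data["drugs"]:
        comps = tuple(
            DrugComponent(
                name=c["name"],
                cmax_uM=float(c["cmax_uM"]),
                doses=tuple(c["doses"]),
                unit=c.get("unit", "xcmax"),
            )
            for c in arm["components"]
        )
        arms.append(DrugArm(arm["name"], comps))
    return DoseEscalationDesign(
        drugs=tuple(arms),
        n_tissues=int(data.get("n_tissues", 7)),
        chambers_per_chip=int(data.get("chambers_per_chip", 4)),
        pacing_frequency_hz=float(data.get("pacing_frequency_hz", 1.0)),
        recording_protocol=tuple(
            tuple(r) for r in data.get(
                "recording_protocol", [list(r) for r in DEFAULT_RECORDING_PROTOCOL]
            )
        ),
        incubation_min_per_dose=int(data.get("incubation_min_per_dose", 30)),
    )
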