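"""Core data model for patch-clamp sweeps, protocols, and cells.

Unit and sign conventions used throughout the package:

* voltages in mV, currents in pA, conductances in nS, capacitance in pF,
  times on sweep axes in seconds, latencies/kinetic constants in ms;
* inward membrane currents are negative (hyperpolarization-activated
  currents are reported with negative sign), depolarizing injected
  current is positive;
* current-clamp sweeps carry a voltage response (mV) and a current
  command (pA); voltage-clamp sweeps carry a current response (pA) and a
  voltage command (mV).

All analysis operates on junction-corrected voltages; see
:func:`correct_junction_potential`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

CURRENT_CLAMP = "cc"
VOLTAGE_CLAMP = "vc"

#: Nominal acquisition rate of the recordings this package models (Hz).
DEFAULT_SAMPLING_RATE = 10_000.0

#: Empirically determined liquid-junction potential (mV), subtracted from
#: recorded voltages.
DEFAULT_JUNCTION_POTENTIAL = 11.0

PROTOCOL_KINDS = (
    "rest",
    "rheobase_coarse",
    "rheobase_fine",
    "firing_steps",
    "vc_hyperpol_steps",
    "cc_hyperpol_steps",
    "evoked_single",
    "evoked_train_20Hz",
    "optogenetic",
)

GROUPS = ("CC", "medial", "lateral", "other")

DRUG_CONDITIONS = ("none", "ZD7288", "picrotoxin+strychnine", "QX314-internal")


class SpinephysError(Exception):
    """Base class for package errors."""


class FormatError(SpinephysError):
    """A sweep bundle on disk is malformed or incomplete."""


class ValidationError(SpinephysError):
    """Data violates a structural invariant."""


class ProtocolError(SpinephysError):
    """An operation was applied to the wrong protocol or battery shape."""


class ModeError(SpinephysError):
    """An operation was applied to a sweep in the wrong clamp mode."""


class IntegrationError(SpinephysError):
    """The simulator state became non-finite."""


class InsufficientDataError(SpinephysError):
    """Too few sweeps/observations for the requested statistic."""


@dataclass
class StimEvent:
    """A stimulus delivered during a sweep.

    time_s is the onset relative to the sweep start; intensity is in µA
    for electrical dorsal-root stimulation and is None for light pulses.
    """

    time_s: float
    intensity: float | None = None
    kind: str = "electrical"  # "electrical" | "light" | "step"


@dataclass
class Sweep:
    """One acquisition trace: response samples plus the command waveform."""

    sampling_rate: float
    response: np.ndarray
    command: np.ndarray
    mode: str
    t0_events: list[StimEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=np.float64)
        self.command = np.asarray(self.command, dtype=np.float64)
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValidationError(f"unknown clamp mode {self.mode!r}")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.response.ndim != 1 or self.command.ndim != 1:
            raise ValidationError("response and command must be 1-D")
        if self.response.shape != self.command.shape:
            raise ValidationError(
                "response and command must have equal length "
                f"({self.response.size} vs {self.command.size})"
            )

    @property
    def n_samples(self) -> int:
        return int(self.response.size)

    @property
    def duration(self) -> float:
        """Sweep duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def copy(self) -> "Sweep":
        return Sweep(
            sampling_rate=self.sampling_rate,
            response=self.response.copy(),
            command=self.command.copy(),
            mode=self.mode,
            t0_events=[replace(ev) for ev in self.t0_events],
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class ProtocolSpec:
    """Definition of one stimulation protocol.

    ``step_amplitudes`` are in pA for current-clamp kinds and mV for
    voltage-clamp kinds; ``holding_level`` likewise (mV holding for
    voltage clamp, pA bias for current clamp). ``step_onset`` is the time
    of step/stimulus onset within each sweep (s).
    """

    kind: str
    holding_level: float = 0.0
    step_amplitudes: tuple[float, ...] = ()
    step_duration: float = 0.0
    n_sweeps: int = 1
    step_onset: float = 0.1
    sweep_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValidationError(f"unknown protocol kind {self.kind!r}")
        if self.step_amplitudes and len(self.step_amplitudes) != self.n_sweeps:
            raise ValidationError(
                f"{self.kind}: {len(self.step_amplitudes)} step amplitudes "
                f"for {self.n_sweeps} sweeps"
            )

    @property
    def mode(self) -> str:
        return VOLTAGE_CLAMP if self.kind in (
            "vc_hyperpol_steps", "evoked_single", "evoked_train_20Hz",
            "optogenetic",
        ) else CURRENT_CLAMP


def standard_protocols(
    n_cc_hyperpol: int = 10,
    rest_sweeps: int = 5,
) -> dict[str, ProtocolSpec]:
    """The protocol battery applied to every characterized cell.

    * ``rest`` — five 2 s sweeps with no holding current;
    * ``firing_steps`` — ten Δ+50 pA / 1 s steps (50–500 pA) from −70 mV;
    * ``vc_hyperpol_steps`` — nine Δ−10 mV / 1 s steps from −70 mV;
    * ``cc_hyperpol_steps`` — up to twenty Δ−50 pA / 200 ms steps from −70 mV
      (default battery stops at ``n_cc_hyperpol`` steps).
    """
    return {
        "rest": ProtocolSpec(
            kind="rest", n_sweeps=rest_sweeps, sweep_duration=2.0,
            step_onset=0.0,
        ),
        "firing_steps": ProtocolSpec(
            kind="firing_steps",
            holding_level=-70.0,
            step_amplitudes=tuple(50.0 * k for k in range(1, 11)),
            step_duration=1.0,
            n_sweeps=10,
            step_onset=0.1,
            sweep_duration=1.4,
        ),
        "vc_hyperpol_steps": ProtocolSpec(
            kind="vc_hyperpol_steps",
            holding_level=-70.0,
            step_amplitudes=tuple(-10.0 * k for k in range(1, 10)),
            step_duration=1.0,
            n_sweeps=9,
            step_onset=0.1,
            sweep_duration=1.3,
        ),
        "cc_hyperpol_steps": ProtocolSpec(
            kind="cc_hyperpol_steps",
            holding_level=-70.0,
            step_amplitudes=tuple(-50.0 * k for k in range(1, n_cc_hyperpol + 1)),
            step_duration=0.2,
            n_sweeps=n_cc_hyperpol,
            step_onset=0.1,
            sweep_duration=0.6,
        ),
    }


@dataclass
class CellRecording:
    """All protocol sweep sets recorded from one cell."""

    cell_id: str
    group: str
    sweep_sets: dict[str, list[Sweep]] = field(default_factory=dict)
    protocols: dict[str, ProtocolSpec] = field(default_factory=dict)
    junction_potential: float = DEFAULT_JUNCTION_POTENTIAL
    drug_condition: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.junction_potential < 0:
            raise ValidationError("junction_potential must be >= 0")
        if self.drug_condition not in DRUG_CONDITIONS:
            raise ValidationError(f"unknown drug condition {self.drug_condition!r}")
        for kind, sweeps in self.sweep_sets.items():
            spec = self.protocols.get(kind)
            for i, sw in enumerate(sweeps):
                if spec is not None and sw.mode != spec.mode:
                    raise ValidationError(
                        f"sweep {kind}[{i}] mode {sw.mode!r} inconsistent "
                        f"with protocol mode {spec.mode!r}"
                    )

    def get(self, kind: str) -> list[Sweep]:
        if kind not in self.sweep_sets:
            raise ProtocolError(
                f"cell {self.cell_id!r} has no {kind!r} protocol"
            )
        return self.sweep_sets[kind]


def correct_junction_potential(sweep: Sweep, jp: float = DEFAULT_JUNCTION_POTENTIAL) -> Sweep:
    """Subtract the liquid-junction potential from the voltage channel.

    In current clamp the response (mV) is shifted by −jp; in voltage
    clamp the command channel is shifted. Current samples are untouched.
    The correction is recorded in sweep metadata and applying it twice
    raises :class:`ValidationError`.
    """
    if sweep.meta.get("junction_corrected", False):
        raise ValidationError("junction potential already subtracted")
    out = sweep.copy()
    if sweep.mode == CURRENT_CLAMP:
        out.response = out.response - jp
    else:
        out.command = out.command - jp
    out.meta["junction_corrected"] = True
    out.meta["junction_potential_mV"] = float(jp)
    return out


def correct_recording(rec: CellRecording) -> CellRecording:
    """Apply the cell's junction-potential correction to every sweep."""
    corrected = {
        kind: [correct_junction_potential(sw, rec.junction_potential) for sw in sweeps]
        for kind, sweeps in rec.sweep_sets.items()
    }
    return CellRecording(
        cell_id=rec.cell_id,
        group=rec.group,
        sweep_sets=corrected,
        protocols=dict(rec.protocols),
        junction_potential=rec.junction_potential,
        drug_condition=rec.drug_condition,
        meta=dict(rec.meta),
    )
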