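"""High-level cell object: morphology + channels + synapse bank + noise.

``CellModel`` ties the pieces together and runs input scenarios end to end
(realize the drive, integrate, extract features, score the IVL metric).
Calibration (leak to the variant's input-resistance target, noise to the
0.22 mV resting sigma_Vm) happens once per variant via
:meth:`CellModel.calibrated`; a pre-calibrated cell can be rebuilt cheaply
from its two fitted numbers with :meth:`CellModel.from_parameters`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibrate import calibrate_noise, calibrate_passive
from .channels import ChannelDensities, assign_channels
from .input_gen import (
    InputAssignment,
    InputScenario,
    ThetaProtocol,
    events_from_assignment,
    merge_events,
    realize_scenario,
    scenario_streams,
    theta_events,
)
from .morphology import FixtureConfig, Morphology, build_fixture_morphology
from .solver import CableModel, CurrentStep, NoiseConfig, SolverConfig, VoltageTrace
from .synapses import SynapseBank, build_synapse_bank
from .trace_metrics import IvlAssessment, TraceMeasurements, ivl_metric, summarize

__all__ = ["CellModel", "ScenarioResult"]


@dataclass
class ScenarioResult:
    scenario: InputScenario
    trace: VoltageTrace
    assignment: InputAssignment
    measurements: TraceMeasurements
    ivl: IvlAssessment

    @property
    def mean_rate_hz(self) -> float:
        """Output spike rate over the 9 s analysis window."""
        return self.measurements.n_spikes / 9.0


class CellModel:
    """One calibrated IS3 model variant ready to run input scenarios."""

    def __init__(
        self,
        variant: str,
        morphology: Morphology,
        channels: ChannelDensities,
        noise: NoiseConfig,
        solver: SolverConfig | None = None,
    ):
        self.variant = variant
        self.morphology = morphology
        self.channels = channels
        self.noise = noise
        self.solver = solver or SolverConfig()
        self.bank: SynapseBank = build_synapse_bank(morphology)
        self.model = CableModel(morphology, channels)

    # -- construction ------------------------------------------------------
    @classmethod
    def calibrated(
        cls,
        variant: str = "AType+",
        fixture: FixtureConfig | None = None,
        solver: SolverConfig | None = None,
    ) -> "CellModel":
        """Build the fixture morphology and run both calibrations."""
        m = build_fixture_morphology(fixture)
        chan = assign_channels(m, variant)
        chan = calibrate_passive(m, chan, variant, solver=solver)
        noise = calibrate_noise(m, chan, solver=solver)
        return cls(variant, m, chan, noise, solver)

    @classmethod
    def from_parameters(
        cls,
        variant: str,
        g_leak: float,
        sigma_current: float,
        fixture: FixtureConfig | None = None,
        solver: SolverConfig | None = None,
    ) -> "CellModel":
        """Rebuild a calibrated cell from its fitted leak and noise values."""
        m = build_fixture_morphology(fixture)
        chan = replace(assign_channels(m, variant), g_leak=g_leak)
        return cls(variant, m, chan, NoiseConfig(sigma_current=sigma_current), solver)

    # -- running -----------------------------------------------------------
    def run_scenario(
        self,
        scenario: InputScenario,
        duration: float = 10_000.0,
        theta: ThetaProtocol | None = None,
        noise_on: bool = True,
        injections: tuple[CurrentStep, ...] = (),
    ) -> ScenarioResult:
        """Realize the scenario's drive, integrate, and score the outcome.

        The scenario seed fans out into independent placement, spike-time and
        noise streams, so toggling ``noise_on`` or adding the deterministic
        theta protocol leaves the background drive bit-identical.
        """
        streams = scenario_streams(scenario.seed)
        assignment = realize_scenario(self.bank, scenario, duration)
        events = events_from_assignment(assignment, self.bank)
        if theta is not None:
            events = merge_events(events, theta_events(theta, self.bank, duration))
        noise = replace(self.noise, seed=streams["noise_seed"]) if noise_on else None
        cfg = replace(self.solver, duration=duration) if duration != self.solver.duration else self.solver
        trace = self.model.run(
            solver=cfg, events=events, noise=noise, injections=injections
        )
        meas = summarize(trace)
        return ScenarioResult(scenario, trace, assignment, meas, ivl_metric(meas))
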