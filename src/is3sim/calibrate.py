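"""Closing the loop on the two printed physiological anchors.

The gating kinetics in :mod:`is3sim.kinetics` are stand-ins, so two knobs are
calibrated against measured IS3 properties:

* ``g_leak`` (uniform, mS/cm^2) is tuned by a bracketing root search until
  the no-input somatic input resistance, measured with the -100 pA /
  4.5-5.5 s step protocol, hits the variant's target (388.71 MOhm for
  AType+, 406.57 MOhm for AType-) within 0.5 MOhm;
* the somatic noise amplitude ``sigma_current`` (pA) is scaled until the
  subthreshold sigma_Vm of a 10 s no-synapse run averages 0.22 mV over
  several seeds (sigma_Vm is linear in sigma_current to good accuracy, so a
  measure-rescale-verify loop converges in a couple of passes).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.optimize import brentq

from .channels import ChannelDensities
from .morphology import Morphology
from .solver import CableModel, NoiseConfig, SolverConfig
from .trace_metrics import input_resistance, summarize

__all__ = ["RI_TARGETS_MOHM", "SIGMA_VM_TARGET_MV", "calibrate_passive",
           "calibrate_noise", "build_model"]

RI_TARGETS_MOHM = {"AType+": 388.71, "AType-": 406.57}
RI_TOL_MOHM = 0.5
SIGMA_VM_TARGET_MV = 0.22
SIGMA_VM_TOL_MV = 0.02


def build_model(m: Morphology, channels: ChannelDensities) -> CableModel:
    return CableModel(m, channels)


def calibrate_passive(
    m: Morphology,
    channels: ChannelDensities,
    variant: str,
    solver: SolverConfig | None = None,
    bracket: tuple[float, float] = (0.004, 0.2),
) -> ChannelDensities:
    """Scale ``g_leak`` so the measured no-input Ri matches the variant target.

    Noise must be disabled (it is: no NoiseConfig enters the measurement).
    Raises ``ValueError`` if the bracket does not straddle the target.
    """
    target = RI_TARGETS_MOHM[variant]
    cfg = solver or SolverConfig()

    def ri_minus_target(g_leak: float) -> float:
        chan = replace(channels, g_leak=g_leak)
        res = input_resistance(CableModel(m, chan), solver=cfg)
        return res.r_in - target

    lo, hi = bracket
    f_lo, f_hi = ri_minus_target(lo), ri_minus_target(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"bracket {bracket} mS/cm^2 does not straddle Ri={target} MOhm "
            f"(endpoints give {f_lo + target:.1f}, {f_hi + target:.1f} MOhm)"
        )
    # Ri tolerance 0.5 MOhm; |dRi/dg| ~ Ri/g so convert to an xtol on g
    g_star = brentq(ri_minus_target, lo, hi, xtol=1e-5, rtol=1e-4)
    return replace(channels, g_leak=float(g_star))


def calibrate_noise(
    m: Morphology,
    channels: ChannelDensities,
    noise: NoiseConfig | None = None,
    solver: SolverConfig | None = None,
    n_seeds: int = 5,
    max_iter: int = 4,
) -> NoiseConfig:
    """Set ``sigma_current`` so the mean no-synapse subthreshold sigma_Vm
    over ``n_seeds`` fresh seeds equals 0.22 mV within 0.02 mV.

    Requires passive calibration to have been done first. Raises
    ``RuntimeError`` if the target is not reached within ``max_iter``
    rescaling passes.
    """
    base = noise or NoiseConfig()
    cfg = solver or SolverConfig()
    model = CableModel(m, channels)

    def mean_sigma(sigma_pa: float, seeds: range) -> float:
        vals = []
        for s in seeds:
            nc = replace(base, sigma_current=sigma_pa, seed=int(s), enabled=True)
            trace = model.run(solver=cfg, noise=nc)
            vals.append(summarize(trace).sigma_sub_vm)
        return float(np.mean(vals))

    sigma = base.sigma_current if base.sigma_current > 0 else 10.0
    for _ in range(max_iter):
        probe = mean_sigma(sigma, range(3))
        if probe == 0:
            raise RuntimeError("noise produced zero sigma_Vm; cannot calibrate")
        sigma *= SIGMA_VM_TARGET_MV / probe
        achieved = mean_sigma(sigma, range(100, 100 + n_seeds))
        if abs(achieved - SIGMA_VM_TARGET_MV) <= SIGMA_VM_TOL_MV:
            return replace(base, sigma_current=float(sigma))
    raise RuntimeError(
        f"noise calibration did not reach {SIGMA_VM_TARGET_MV} mV "
        f"(last achieved {achieved:.3f} mV at sigma={sigma:.2f} pA)"
    )
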