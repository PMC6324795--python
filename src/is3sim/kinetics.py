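"""Hodgkin–Huxley-style gating kinetics for the four active conductances.

The exact channel kinetics of reconstructed IS3 cell models are not part of
this package's contract; what is calibrated against data are the passive
input resistance and the intrinsic-noise voltage fluctuation. The gating
curves here are sigmoid steady states with voltage-dependent time constants,
shaped for a fast-spiking interneuron profile and collected in this single
file so they can be swapped wholesale:

* transient Na (``na_t``): instantaneous activation ``m_inf(V)**3`` and a
  first-order inactivation gate ``h`` (inactivation under sustained
  depolarization is what produces depolarization block);
* fast delayed-rectifier K (``kdrf``): ``n**4``, steep and relatively
  depolarized so the (high) maximal density contributes almost nothing at
  subthreshold voltages;
* A-type K (``ka``): ``a**3 * b`` with fast activation and slow
  inactivation, damping onset excitability;
* persistent Na (``na_p``): single non-inactivating activation gate ``p``.

All rates in 1/ms, voltages in mV, time constants in ms. No temperature/q10
correction is applied. Every function is numba-compiled so the integration
engine can call it inside its step loop.
"""

from __future__ import annotations

import math

from numba import njit

__all__ = [
    "E_NA", "E_K",
    "na_t_m_inf", "na_t_h_inf", "na_t_h_tau",
    "kdrf_n_inf", "kdrf_n_tau",
    "ka_a_inf", "ka_a_tau", "ka_b_inf", "ka_b_tau",
    "na_p_p_inf", "na_p_p_tau",
]

E_NA = 55.0  # mV
E_K = -90.0  # mV


@njit(cache=True, inline="always")
def _sig(v: float, half: float, slope: float) -> float:
    # rising sigmoid for slope > 0, falling for slope < 0
    return 1.0 / (1.0 + math.exp(-(v - half) / slope))


@njit(cache=True, inline="always")
def na_t_m_inf(v: float) -> float:
    return _sig(v, -35.0, 7.0)


@njit(cache=True, inline="always")
def na_t_h_inf(v: float) -> float:
    return _sig(v, -58.0, -7.0)


@njit(cache=True, inline="always")
def na_t_h_tau(v: float) -> float:
    # slow recovery from inactivation at subthreshold voltages: sustained
    # high-rate firing depletes h cumulatively, shrinking spikes toward
    # depolarization block
    return 0.5 + 100.0 * _sig(v, -52.0, -8.0)


@njit(cache=True, inline="always")
def kdrf_n_inf(v: float) -> float:
    return _sig(v, -25.0, 6.0)


@njit(cache=True, inline="always")
def kdrf_n_tau(v: float) -> float:
    return 0.5 + 2.0 * _sig(v, -30.0, -10.0)


@njit(cache=True, inline="always")
def ka_a_inf(v: float) -> float:
    return _sig(v, -35.0, 8.0)


@njit(cache=True, inline="always")
def ka_a_tau(v: float) -> float:
    return 1.0


@njit(cache=True, inline="always")
def ka_b_inf(v: float) -> float:
    return _sig(v, -68.0, -6.0)


@njit(cache=True, inline="always")
def ka_b_tau(v: float) -> float:
    return 15.0


@njit(cache=True, inline="always")
def na_p_p_inf(v: float) -> float:
    return _sig(v, -48.0, 5.0)


@njit(cache=True, inline="always")
def na_p_p_tau(v: float) -> float:
    return 1.0
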