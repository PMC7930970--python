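"""Analytic model of the capacitive coupling and bootstrapped-varistor front end.

The electrode and the skin form a coupling capacitor ``C = eps * S / d``
(permittivity ``eps``, coupling area ``S``, pillowcase thickness ``d``)
whose reactance ``X_C = 1 / (2 pi f C)`` sits in series with the input
impedance of the front-end voltage follower (FVF).  The source
biopotential ``e_s`` is divided:

    v_in = e_s / (Z_cap / Z_in + 1)

so the follower must present an input impedance far above ``X_C`` to pass
~100 uV biopotentials undiminished.  The FVF bootstraps a varistor:
below the varistor threshold the network ``Z = R1 + Rbv + R1*Rbv/R3``
multiplies the apparent impedance to the teraohm range; above threshold
the varistor collapses to a short and the input impedance drops to
``R1``, discharging static quickly (the system time constant is
``Z_in * C``).

All impedances here are real magnitudes evaluated at a stated frequency,
which is how the design arithmetic is done; a complex-phasor treatment is
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import SignalError

__all__ = [
    "CouplingSpec",
    "FVFSpec",
    "coupling_capacitance",
    "capacitive_reactance",
    "varistor_resistance",
    "bootstrap_input_impedance",
    "synthesized_input_impedance",
    "divider_gain",
    "effective_clamp_threshold",
    "frontend_report",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Skin-insulator-electrode coupling geometry.

    epsilon : permittivity, F/m (default: vacuum/design value 8.85e-12)
    area_s : coupling area, m^2 (default 2.00e-3, the electrode patch)
    distance_d : insulator thickness, m (default 3.08e-4, the pillowcase)
    """

    epsilon: float = 8.85e-12
    area_s: float = 2.00e-3
    distance_d: float = 3.08e-4

    def __post_init__(self) -> None:
        if min(self.epsilon, self.area_s, self.distance_d) <= 0:
            raise SignalError("coupling parameters must all be positive")


@dataclass(frozen=True)
class FVFSpec:
    """Bootstrapped-varistor voltage-follower components.

    r1, r3 : bootstrap network resistances, ohm (99 Mohm, 10 kohm)
    rh : varistor high-state (below-threshold) resistance, ohm (250 Mohm)
    v_thr : varistor threshold voltage, V (8 V)
    opamp_zin : op-amp input impedance, ohm (10 Tohm)
    """

    r1: float = 99e6
    r3: float = 10e3
    rh: float = 250e6
    v_thr: float = 8.0
    opamp_zin: float = 10e12

    def __post_init__(self) -> None:
        if min(self.r1, self.r3, self.rh, self.v_thr, self.opamp_zin) <= 0:
            raise SignalError("FVF parameters must all be positive")


def coupling_capacitance(spec: CouplingSpec = CouplingSpec()) -> float:
    """Parallel-plate coupling capacitance ``C = eps * S / d`` in farads."""
    return spec.epsilon * spec.area_s / spec.distance_d


def capacitive_reactance(c: float, f: float) -> float:
    """Reactance magnitude ``X_C = 1 / (2 pi f C)`` in ohms."""
    if c <= 0 or f <= 0:
        raise SignalError("capacitance and frequency must be positive")
    return 1.0 / (2.0 * np.pi * f * c)


def varistor_resistance(v_applied: float, spec: FVFSpec = FVFSpec()) -> float:
    """Ideal varistor: ``rh`` strictly below threshold, 0 otherwise.

    The boundary ``|v| == v_thr`` is assigned to the clamped (zero) branch.
    """
    return spec.rh if abs(v_applied) < spec.v_thr else 0.0


def bootstrap_input_impedance(spec: FVFSpec = FVFSpec(),
                              v_applied: float = 0.0) -> float:
    """Input impedance of the bootstrapped network in ohms.

    ``Z = R1 + Rbv + R1 * Rbv / R3`` with ``Rbv`` the varistor state at
    the applied voltage.  Below threshold this is dominated by
    ``R1 * Rh / R3`` (teraohms); above threshold it collapses to ``R1``.
    """
    r_bv = varistor_resistance(v_applied, spec)
    return spec.r1 + r_bv + spec.r1 * r_bv / spec.r3


def synthesized_input_impedance(z_bt: float, opamp_zin: float) -> float:
    """Parallel combination of the bootstrap network and the op-amp input."""
    if z_bt <= 0 or opamp_zin <= 0:
        raise SignalError("impedances must be positive")
    if np.isinf(opamp_zin):
        return z_bt
    return z_bt * opamp_zin / (z_bt + opamp_zin)


def divider_gain(z_cap: float, z_in: float) -> float:
    """Source-to-input voltage gain ``1 / (Z_cap / Z_in + 1)``."""
    if z_cap <= 0 or z_in <= 0:
        raise SignalError("impedances must be positive")
    return 1.0 / (z_cap / z_in + 1.0)


def effective_clamp_threshold(spec: FVFSpec = FVFSpec()) -> float:
    """Input voltage at which the clamp engages: ``v_thr * (1 + R3/Rh)``.

    The varistor sees the input through the R3/Rh divider, so the input
    threshold is slightly above the varistor's own threshold.
    """
    return spec.v_thr * (1.0 + spec.r3 / spec.rh)


def frontend_report(coupling: CouplingSpec = CouplingSpec(),
                    fvf: FVFSpec = FVFSpec(),
                    frequencies: tuple[float, ...] = (10.0, 15.0, 20.0),
                    ) -> dict:
    """Design summary: capacitance, reactances, impedances, gain, clamp."""
    c = coupling_capacitance(coupling)
    z_bt = bootstrap_input_impedance(fvf, 0.0)
    z_syn = synthesized_input_impedance(z_bt, fvf.opamp_zin)
    report = {
        "coupling_capacitance_pF": c * 1e12,
        "bootstrap_impedance_Tohm": z_bt / 1e12,
        "bootstrap_impedance_clamped_Mohm": bootstrap_input_impedance(
            fvf, 2 * effective_clamp_threshold(fvf)) / 1e6,
        "synthesized_impedance_Tohm": z_syn / 1e12,
        "effective_clamp_threshold_V": effective_clamp_threshold(fvf),
        "reactance_Mohm": {},
        "divider_gain": {},
    }
    for f in frequencies:
        xc = capacitive_reactance(c, f)
        report["reactance_Mohm"][f"{f:g}Hz"] = xc / 1e6
        report["divider_gain"][f"{f:g}Hz"] = divider_gain(xc, z_syn)
    return report
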