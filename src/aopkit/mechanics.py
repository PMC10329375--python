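"""Passive single-compartment mechanics of the ventilated respiratory system.

Units are fixed throughout the package: pressures in cmH2O, volumes in mL,
resistances in cmH2O/(L/s), compliances in mL/cmH2O.  Flow *settings* are
expressed in L/min (the ventilator convention) while sampled flow signals are
in L/s; :class:`VentSettings` exposes both.

The respiratory system is modelled as a single compartment behind a resistive
airway.  Its static pressure-volume relation is either linear (constant
compliance ``Crs``) or bilinear with a lower inflection point (LIP): a low
compliance below the LIP and a higher one above it, as described in some ARDS
patients.  Airway closure is represented by a single opening-pressure
threshold ``aop``: the airway conducts no flow while the pressure upstream of
the closure is below ``aop``, and gas trapped behind a closed airway holds
the alveolar pressure at ``aop``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

__all__ = [
    "LinearCompliance",
    "BilinearCompliance",
    "Compliance",
    "RespiratorySystem",
    "VentCircuit",
    "VentSettings",
    "SimOptions",
]


@dataclass(frozen=True)
class LinearCompliance:
    """Constant-compliance static PV relation, ``V = crs * P``.

    Parameters
    ----------
    crs:
        Respiratory-system compliance, mL/cmH2O.  Must be positive.
    """

    crs: float

    def __post_init__(self) -> None:
        if not self.crs > 0:
            raise ValueError(f"crs must be > 0, got {self.crs}")

    def volume(self, p: float) -> float:
        """Static volume (mL above relaxation volume) at recoil pressure ``p``."""
        return self.crs * p

    def pressure(self, v: float) -> float:
        """Static recoil pressure at volume ``v`` (mL above relaxation volume)."""
        return v / self.crs


@dataclass(frozen=True)
class BilinearCompliance:
    """Two-segment static PV curve with a lower inflection point.

    Below the LIP the chord compliance is ``c_below``; above it, ``c_above``.
    The curve is continuous at the LIP.  This is the classic shape reported
    for ARDS lungs that are poorly recruited at low pressure.

    Parameters
    ----------
    c_below, c_above:
        Compliances below/above the inflection point, mL/cmH2O.
    lip:
        Lower inflection point, cmH2O (recoil pressure at which the
        compliance switches).
    """

    c_below: float
    c_above: float
    lip: float

    def __post_init__(self) -> None:
        if not self.c_below > 0 or not self.c_above > 0:
            raise ValueError("compliances must be > 0")
        if not self.lip > 0:
            raise ValueError(f"lip must be > 0, got {self.lip}")

    @property
    def v_lip(self) -> float:
        """Volume at the inflection point, mL above relaxation volume."""
        return self.c_below * self.lip

    def volume(self, p: float) -> float:
        if p <= self.lip:
            return self.c_below * p
        return self.v_lip + self.c_above * (p - self.lip)

    def pressure(self, v: float) -> float:
        if v <= self.v_lip:
            return v / self.c_below
        return self.lip + (v - self.v_lip) / self.c_above


Compliance = Union[LinearCompliance, BilinearCompliance]


@dataclass(frozen=True)
class RespiratorySystem:
    """A passive single-compartment respiratory system.

    Parameters
    ----------
    rrs:
        Airway (respiratory system) resistance, cmH2O/(L/s).
    compliance:
        Static PV relation, :class:`LinearCompliance` or
        :class:`BilinearCompliance`.
    aop:
        Airway opening pressure, cmH2O (absolute airway pressure), or
        ``None`` for a system without airway closure.  The airway opens when
        the pressure at its entrance reaches ``aop`` and re-closes during
        expiration once the alveolar pressure has decayed to ``aop``,
        trapping gas at that pressure.
    relax_volume:
        Lung volume at zero elastic recoil, mL.  Acts as a constant offset of
        the static curve; defaults to 0.
    """

    rrs: float
    compliance: Compliance
    aop: Optional[float] = None
    relax_volume: float = 0.0

    def __post_init__(self) -> None:
        if not self.rrs > 0:
            raise ValueError(f"rrs must be > 0, got {self.rrs}")
        if self.aop is not None and not self.aop > 0:
            raise ValueError(f"aop must be > 0 when present, got {self.aop}")
        if not isinstance(self.compliance, (LinearCompliance, BilinearCompliance)):
            raise TypeError("compliance must be LinearCompliance or BilinearCompliance")

    def static_volume(self, p: float) -> float:
        """Absolute static lung volume (mL) at recoil pressure ``p``."""
        return self.relax_volume + self.compliance.volume(p)

    def static_pressure(self, v: float) -> float:
        """Static recoil pressure (cmH2O) at absolute lung volume ``v``."""
        return self.compliance.pressure(v - self.relax_volume)


@dataclass(frozen=True)
class VentCircuit:
    """Ventilator circuit seen from the Y-piece.

    ``ccirc`` is the compressible-volume compliance of the tubing
    (mL/cmH2O): while the airway is closed, all delivered gas charges this
    compliance and sets the first slope of the pressure waveform.  ``rcirc``
    is an optional series circuit resistance (cmH2O/(L/s)), 0 by default.
    """

    ccirc: float = 2.0
    rcirc: float = 0.0

    def __post_init__(self) -> None:
        if not self.ccirc > 0:
            raise ValueError(f"ccirc must be > 0, got {self.ccirc}")
        if self.rcirc < 0:
            raise ValueError(f"rcirc must be >= 0, got {self.rcirc}")


@dataclass(frozen=True)
class VentSettings:
    """Volume assist control settings for one simulated breath.

    Parameters
    ----------
    insp_flow:
        Constant inspiratory flow, L/min.
    tidal_volume:
        Set tidal volume, mL (volume delivered at the Y-piece).
    peep:
        Set PEEP, cmH2O.
    rr:
        Respiratory rate, breaths/min; fixes the cycle length ``60/rr``.
    pause_s:
        End-inspiratory occlusion duration, s (0 disables the pause).
    exp_resistance:
        Resistance of the expiratory pathway (exhalation valve and tubing),
        cmH2O/(L/s).  ``None`` means "same as the airway resistance".
    """

    insp_flow: float
    tidal_volume: float
    peep: float = 5.0
    rr: float = 12.0
    pause_s: float = 0.4
    exp_resistance: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.insp_flow > 0:
            raise ValueError(f"insp_flow must be > 0, got {self.insp_flow}")
        if not self.tidal_volume > 0:
            raise ValueError(f"tidal_volume must be > 0, got {self.tidal_volume}")
        if self.peep < 0:
            raise ValueError(f"peep must be >= 0, got {self.peep}")
        if self.pause_s < 0:
            raise ValueError(f"pause_s must be >= 0, got {self.pause_s}")
        if not self.rr > 0:
            raise ValueError(f"rr must be > 0, got {self.rr}")
        if self.exp_resistance is not None and not self.exp_resistance > 0:
            raise ValueError("exp_resistance must be > 0 when given")
        if self.t_insp + self.pause_s >= self.t_cycle:
            raise ValueError(
                "tidal volume unreachable before the inspiratory window ends: "
                f"tidal_volume {self.tidal_volume} mL at insp_flow "
                f"{self.insp_flow} L/min needs {self.t_insp:.2f} s insufflation "
                f"plus {self.pause_s:.2f} s pause, but rr {self.rr}/min allows "
                f"only {self.t_cycle:.2f} s per cycle"
            )

    @property
    def flow_lps(self) -> float:
        """Inspiratory flow in L/s."""
        return self.insp_flow / 60.0

    @property
    def t_insp(self) -> float:
        """Insufflation duration, s (tidal volume over constant flow)."""
        return self.tidal_volume / (self.flow_lps * 1000.0)

    @property
    def t_cycle(self) -> float:
        """Cycle duration, s."""
        return 60.0 / self.rr


@dataclass(frozen=True)
class SimOptions:
    """Sampling, noise and integration options for the simulator.

    ``fs`` is the output sampling rate (Hz), emulating the rate at which a
    ventilator logs or displays its waveforms.  ``noise_sd`` is the standard
    deviation of additive Gaussian pressure-sensor noise (cmH2O) applied to
    the sampled airway pressure only; flow is left noise-free.
    ``integrator_step`` is the internal fixed step of the integrator (s) and
    must divide the sampling interval.
    """

    fs: float = 100.0
    noise_sd: float = 0.0
    seed: Optional[int] = None
    integrator_step: float = 1e-3

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not self.integrator_step > 0:
            raise ValueError("integrator_step must be > 0")
        if self.integrator_step > 1.0 / self.fs + 1e-12:
            raise ValueError("integrator_step must not exceed the sampling interval")

    @property
    def stride(self) -> int:
        """Number of integrator steps per output sample."""
        ratio = 1.0 / (self.fs * self.integrator_step)
        stride = round(ratio)
        if abs(ratio - stride) > 1e-6 or stride < 1:
            raise ValueError(
                "integrator_step must divide the sampling interval "
                f"(1/fs = {1.0 / self.fs} s, step = {self.integrator_step} s)"
            )
        return stride
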