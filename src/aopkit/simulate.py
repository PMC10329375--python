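"""Mechanistic simulation of passive constant-flow ventilation.

One breath is integrated through four phases:

A. *Closed airway* (only when the opening pressure lies above PEEP): the
   delivered flow charges the circuit compliance, so airway pressure climbs
   linearly at ``insp_flow / ccirc`` until it reaches the opening pressure.
B. *Open-airway insufflation*: the delivered flow splits between the circuit
   compliance and the lung; airway pressure at the Y-piece equals alveolar
   pressure plus the resistive drop ``Rrs * lung_flow``, with alveolar
   pressure following the static (bi)linear PV relation.
C. *End-inspiratory occlusion*: flow stops; circuit and lung equilibrate and
   the pressure settles onto the plateau (total PEEP plus elastic recoil of
   the insufflated volume).
D. *Passive expiration* through the expiratory pathway resistance toward set
   PEEP.  With airway closure, the airway re-closes once alveolar pressure
   decays to the opening pressure, trapping gas at that pressure — which is
   why the next insufflation re-opens the airway exactly at ``aop``.

The integrator advances with a fixed step (1 kHz by default) using an
exponential update of the Y-piece pressure node: within a step the alveolar
pressure is frozen, the pressure relaxes analytically toward its
instantaneous asymptote, and the lung volume increment is taken as the
residual of the volume balance.  This keeps gas volume conserved to machine
precision at every step and remains stable for arbitrarily small circuit
compliances (the stiff limit used when comparing against the closed form).

Gaussian sensor noise, when requested, is added to the *sampled* airway
pressure only, after integration and decimation.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .mechanics import (
    LinearCompliance,
    RespiratorySystem,
    SimOptions,
    VentCircuit,
    VentSettings,
)
from .waveform import BreathWaveform

__all__ = [
    "simulate_breath",
    "simulate_low_flow_maneuver",
    "closed_form_linear",
    "low_flow_settings",
    "vacv_settings",
]


def vacv_settings(peep: float, insp_flow: float = 60.0, tidal_volume: float = 420.0,
                  rr: float = 12.0, pause_s: float = 0.4) -> VentSettings:
    """Usual volume assist control settings for the conductive-pressure method.

    60 L/min constant flow with an end-inspiratory occlusion long enough
    (>= 0.3 s) to read the plateau.  The default rate leaves a long
    expiratory window so that expiratory flow reaches zero even for long
    time constants, mirroring the clinical practice of lowering the rate
    until no intrinsic PEEP is visible on the expiratory flow trace.
    """
    return VentSettings(insp_flow=insp_flow, tidal_volume=tidal_volume,
                        peep=peep, rr=rr, pause_s=pause_s)


def low_flow_settings(peep: float, insp_flow: float = 5.0, tidal_volume: float = 420.0,
                      rr: float = 5.0, pause_s: float = 0.0) -> VentSettings:
    """Low-flow insufflation settings for the standard (reference) method."""
    return VentSettings(insp_flow=insp_flow, tidal_volume=tidal_volume,
                        peep=peep, rr=rr, pause_s=pause_s)


def _simulate_fine(system: RespiratorySystem, circuit: VentCircuit,
                   settings: VentSettings, dt: float):
    """Integrate one cycle on the fine grid.

    Returns fine-grid arrays ``(t, flow, paw, v_alv, v_delivered)`` where
    ``flow`` is the Y-piece flow over ``[t_k, t_k + dt)`` and the state
    arrays are instantaneous values at ``t_k``.
    """
    rrs = system.rrs
    ccirc = circuit.ccirc
    peep = settings.peep
    rexp = settings.exp_resistance if settings.exp_resistance is not None else rrs
    qy_insp = settings.flow_lps

    # airway closure is only in play when the opening pressure exceeds PEEP
    aop = system.aop if (system.aop is not None and system.aop > peep) else None
    airway_open = aop is None
    # steady cycling: a closed airway has trapped gas at alveolar pressure aop
    p_alv = aop if not airway_open else peep
    v_alv = system.static_volume(p_alv)
    paw = peep
    v_delivered = 0.0

    n = int(round(settings.t_cycle / dt))
    k_insp = int(round(settings.t_insp / dt))
    k_pause = k_insp + int(round(settings.pause_s / dt))

    t = np.arange(n) * dt
    flow = np.empty(n)
    paw_arr = np.empty(n)
    v_alv_arr = np.empty(n)
    v_del_arr = np.empty(n)

    def step_inflow(qy: float, h: float) -> None:
        """Advance one step with known inflow ``qy`` (L/s) at the Y-piece."""
        nonlocal paw, v_alv, p_alv, airway_open
        remaining = h
        if not airway_open:
            slope = qy * 1000.0 / ccirc  # cmH2O/s while charging the circuit
            if slope > 0 and paw + slope * remaining >= aop:
                remaining -= (aop - paw) / slope
                paw = aop
                airway_open = True
            else:
                paw += slope * remaining
                return
        # open airway: exponential relaxation of paw toward its asymptote
        tau = rrs * ccirc / 1000.0
        paw_inf = p_alv + rrs * qy
        paw_new = paw_inf + (paw - paw_inf) * math.exp(-remaining / tau)
        dv_circ = ccirc * (paw_new - paw)
        dv_lung = qy * 1000.0 * remaining - dv_circ
        v_alv += dv_lung
        p_alv = system.static_pressure(v_alv)
        paw = paw_new

    def step_exp(h: float) -> float:
        """Advance one expiratory step; return gas volume (L) out the valve."""
        nonlocal paw, v_alv, p_alv, airway_open
        if airway_open:
            g = 1.0 / rrs + 1.0 / rexp
            paw_inf = (p_alv / rrs + peep / rexp) / g
            tau = ccirc / (1000.0 * g)
            e = math.exp(-h / tau)
            paw_new = paw_inf + (paw - paw_inf) * e
            ipaw = paw_inf * h + (paw - paw_inf) * tau * (1.0 - e)
            qv_int = (ipaw - peep * h) / rexp          # through the valve
            ql_out = (p_alv * h - ipaw) / rrs          # out of the lung
            v_alv -= ql_out * 1000.0
            p_alv = system.static_pressure(v_alv)
            paw = paw_new
            if aop is not None and p_alv <= aop:
                # airway re-closes; gas is trapped at the opening pressure
                v_alv = system.static_volume(aop)
                p_alv = aop
                airway_open = False
            return qv_int
        tau = ccirc * rexp / 1000.0
        paw_new = peep + (paw - peep) * math.exp(-h / tau)
        qv_int = ccirc * (paw - paw_new) / 1000.0      # circuit discharge only
        paw = paw_new
        return qv_int

    for k in range(n):
        paw_arr[k] = paw
        v_alv_arr[k] = v_alv
        v_del_arr[k] = v_delivered
        if k < k_insp:
            flow[k] = qy_insp
            step_inflow(qy_insp, dt)
            v_delivered += qy_insp * 1000.0 * dt
        elif k < k_pause:
            flow[k] = 0.0
            step_inflow(0.0, dt)
        else:
            flow[k] = -(paw - peep) / rexp
            qv = step_exp(dt)
            v_delivered -= qv * 1000.0

    return t, flow, paw_arr, v_alv_arr, v_del_arr


def simulate_breath(system: RespiratorySystem, circuit: VentCircuit,
                    settings: VentSettings, opts: SimOptions = SimOptions(),
                    *, return_internals: bool = False):
    """Simulate one full volume assist control cycle.

    Parameters mirror the domain types; see :mod:`aopkit.mechanics`.  An
    opening pressure at or below PEEP is legal and simply means the airway
    never closes at that PEEP: the resulting waveform is identical to the
    same system without closure.

    Returns
    -------
    BreathWaveform, or ``(BreathWaveform, dict)`` when ``return_internals``
    is set.  The internals dictionary carries the fine-grid state (time,
    pressure, lung volume relative to the start of the breath, circuit
    stored volume and delivered volume) for conservation checks.
    """
    dt = opts.integrator_step
    stride = opts.stride
    tf, flow_f, paw_f, v_alv_f, v_del_f = _simulate_fine(system, circuit, settings, dt)

    sl = slice(0, None, stride)
    t = tf[sl].copy()
    flow = flow_f[sl].copy()
    paw = paw_f[sl].copy()
    if opts.noise_sd > 0:
        rng = np.random.default_rng(opts.seed)
        paw = paw + rng.normal(0.0, opts.noise_sd, size=paw.size)

    meta = {
        "fs": opts.fs,
        "peep": settings.peep,
        "flow_setting": settings.insp_flow,
        "tidal_volume": settings.tidal_volume,
        "rr": settings.rr,
        "pause_s": settings.pause_s,
        "rrs": system.rrs,
        "aop": system.aop if system.aop is not None else "none",
        "noise_sd": opts.noise_sd,
        "seed": opts.seed if opts.seed is not None else "none",
        "maneuver": "low_flow" if settings.insp_flow <= 10.0 else "vacv",
    }
    if isinstance(system.compliance, LinearCompliance):
        meta["crs"] = system.compliance.crs
    else:
        meta.update(c_below=system.compliance.c_below,
                    c_above=system.compliance.c_above,
                    lip=system.compliance.lip)

    w = BreathWaveform.from_samples(t, flow, paw, meta=meta)
    if not return_internals:
        return w
    internals = {
        "t": tf,
        "paw": paw_f,
        "v_lung": v_alv_f - v_alv_f[0],
        "v_circuit": circuit.ccirc * (paw_f - paw_f[0]),
        "v_delivered": v_del_f,
    }
    return w, internals


def simulate_low_flow_maneuver(system: RespiratorySystem, circuit: VentCircuit,
                               settings: Optional[VentSettings] = None,
                               opts: SimOptions = SimOptions(), *,
                               peep: float = 5.0, **kwargs):
    """Simulate the low-flow (5 L/min) reference maneuver.

    Same physics as :func:`simulate_breath`; with closure and PEEP below the
    opening pressure the time-pressure curve shows two slopes, the first set
    by the circuit compliance, breaking near ``aop + Rrs * flow``.
    """
    if settings is None:
        settings = low_flow_settings(peep=peep)
    return simulate_breath(system, circuit, settings, opts, **kwargs)


def closed_form_linear(system: RespiratorySystem, settings: VentSettings,
                       t_grid: np.ndarray) -> BreathWaveform:
    """Analytic airway pressure for a linear, closure-free system.

    During constant-flow insufflation (circuit compliance neglected) the
    equation of motion gives ``paw(t) = peep + Rrs*flow + flow*t/Crs``,
    exact to machine precision.  Serves as the independent oracle for the
    numerical simulator.

    ``t_grid`` must lie within the insufflation ``[0, t_insp]``.
    """
    if system.aop is not None:
        raise ValueError("closed form requires a system without airway closure")
    if not isinstance(system.compliance, LinearCompliance):
        raise ValueError("closed form requires linear compliance")
    t = np.asarray(t_grid, dtype=float)
    if t.size < 2:
        raise ValueError("t_grid needs at least 2 points")
    if t.min() < 0 or t.max() > settings.t_insp + 1e-12:
        raise ValueError("t_grid must lie within the insufflation window")
    q = settings.flow_lps
    crs = system.compliance.crs
    paw = settings.peep + system.rrs * q + (q * 1000.0 * t) / crs
    flow = np.full_like(t, q)
    meta = {"fs": 1.0 / (t[1] - t[0]), "peep": settings.peep,
            "flow_setting": settings.insp_flow, "analytic": True}
    return BreathWaveform.from_samples(t, flow, paw, meta=meta)
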