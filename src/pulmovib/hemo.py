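"""Lumped-parameter (Windkessel) model of the pulmonary circulation.

The circulation is represented by the electrical analogy: pressure is
voltage, flow is current, vessel segments are RC(L) elements, heart valves
are diodes and the right ventricle is a time-varying elastance source.
Blood leaves the right ventricle (RV) through the pulmonary valve, crosses
the proximal pulmonary artery (pap), the distal pulmonary artery (pad) and
the pulmonary veins (pv), and returns to the RV through a minimal lumped
systemic path (reservoir + tricuspid valve).  Progressive distal pulmonary
artery stenosis (DPAS) is modelled by shrinking the pad radius over time,
with Poiseuille's law converting radius to flow resistance.

Units are mmHg, mL and s throughout the circuit model; the stand-alone
physical formulas (`resistance_from_radius`, `compliance_value`) are
evaluated in whatever consistent unit system the caller supplies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import yaml

__all__ = [
    "VesselSegment",
    "ValveElement",
    "ChamberDrive",
    "StenosisSchedule",
    "CircuitModel",
    "SimResult",
    "InstabilityError",
    "resistance_from_radius",
    "radius_at_time",
    "compliance_value",
    "derivatives",
    "simulate",
    "pv_loop",
    "summarize_pressures",
    "classify_ph",
    "load_model",
    "normal_model",
]


class InstabilityError(RuntimeError):
    """Raised when the integration blows up (|P| > 1000 mmHg at a node)."""


# ---------------------------------------------------------------------------
# element types
# ---------------------------------------------------------------------------


@dataclass
class VesselSegment:
    """One vessel segment: flow resistance R [mmHg·s/mL], compliance
    C [mL/mmHg] and (optionally) inertance L [mmHg·s²/mL]."""

    name: str
    R: float
    C: float
    L: float = 0.0

    def __post_init__(self) -> None:
        if self.R < 0 or self.C <= 0 or self.L < 0:
            raise ValueError(
                f"segment {self.name!r}: need R >= 0, C > 0, L >= 0"
            )


@dataclass
class ValveElement:
    """Piecewise-linear diode: small forward resistance, large reverse
    (leak) resistance."""

    name: str
    R_forward: float = 1e-3
    R_reverse: float = 1e3

    def __post_init__(self) -> None:
        if not (0 < self.R_forward < self.R_reverse):
            raise ValueError(f"valve {self.name!r}: need 0 < R_forward < R_reverse")

    def flow(self, dp: float) -> float:
        """Flow [mL/s] through the valve for pressure drop ``dp`` [mmHg]."""
        return dp / self.R_forward if dp > 0.0 else dp / self.R_reverse


def _double_hill(phi: float, a1: float, n1: float, a2: float, n2: float) -> float:
    """Product-of-Hill activation, the standard normalized elastance shape."""
    x1 = (phi / a1) ** n1
    x2 = (phi / a2) ** n2
    return (x1 / (1.0 + x1)) * (1.0 / (1.0 + x2))


@dataclass
class ChamberDrive:
    """Time-varying elastance chamber: P(t, V) = E(t)·(V − V0).

    E(t) swings between the diastolic stiffness ``Emin`` and the end-systolic
    stiffness ``Emax`` following a double-Hill activation curve, the usual
    smooth approximation of the normalized human elastance waveform.
    """

    name: str
    Emin: float
    Emax: float
    V0: float
    period: float
    hill_a1: float = 0.303
    hill_n1: float = 1.32
    hill_a2: float = 0.508
    hill_n2: float = 21.9

    _norm: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.Emin <= 0 or self.Emax < self.Emin or self.period <= 0:
            raise ValueError("need 0 < Emin <= Emax and period > 0")
        grid = np.linspace(0.0, 1.0, 2001)[1:]
        self._norm = max(
            _double_hill(p, self.hill_a1, self.hill_n1, self.hill_a2, self.hill_n2)
            for p in grid
        )

    def elastance(self, t: float) -> float:
        """Instantaneous elastance E(t) [mmHg/mL]; periodic in ``period``."""
        phi = (t / self.period) % 1.0
        if phi == 0.0:
            act = 0.0
        else:
            act = (
                _double_hill(phi, self.hill_a1, self.hill_n1, self.hill_a2, self.hill_n2)
                / self._norm
            )
        return self.Emin + (self.Emax - self.Emin) * act

    def pressure(self, t: float, V: float) -> float:
        return self.elastance(t) * (V - self.V0)


@dataclass
class StenosisSchedule:
    """Progressive narrowing of the distal pulmonary artery.

    The vessel radius shrinks as r(t) = r0·(1 + gr·t)^(−1/4), so by
    Poiseuille's law the resistance grows exactly linearly:
    R(t) = R(0)·(1 + gr·t).
    """

    r0: float
    gr: float
    eta: float = 1.0
    pipe_len: float = 1.0

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.gr < 0 or self.eta <= 0 or self.pipe_len <= 0:
            raise ValueError("need r0, eta, pipe_len > 0 and gr >= 0")

    def radius_at(self, t: float) -> float:
        return radius_at_time(t, self)

    def resistance_at(self, t: float) -> float:
        return resistance_from_radius(self.radius_at(t), self.eta, self.pipe_len)

    @classmethod
    def for_resistance(
        cls, R0: float, gr: float, eta: float = 1.0, pipe_len: float = 1.0
    ) -> "StenosisSchedule":
        """Schedule whose t=0 resistance equals ``R0`` (radius solved from
        Poiseuille's law)."""
        r0 = (8.0 * eta * pipe_len / (math.pi * R0)) ** 0.25
        return cls(r0=r0, gr=gr, eta=eta, pipe_len=pipe_len)


# ---------------------------------------------------------------------------
# physical formulas
# ---------------------------------------------------------------------------


def resistance_from_radius(r: float, eta: float, pipe_len: float) -> float:
    """Poiseuille flow resistance of a cylindrical pipe: R = 8ηL/(πr⁴)."""
    if r <= 0 or eta <= 0 or pipe_len <= 0:
        raise ValueError("radius, viscosity and pipe length must be positive")
    return 8.0 * eta * pipe_len / (math.pi * r ** 4)


def radius_at_time(t: float, sched: StenosisSchedule) -> float:
    """Stenosed radius r(t) = r0·(1 + gr·t)^(−1/4) for t ≥ 0."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    return sched.r0 * (1.0 + sched.gr * t) ** -0.25


def compliance_value(
    hfluid: float, hcan: float, Acan: float, Patom: float, rho_g: float
) -> float:
    """Compliance of an air-spring chamber partially filled with liquid.

    A sealed vertical can of height ``hcan`` and cross-section ``Acan``
    holds liquid up to ``hfluid``; the gas column above acts as a spring.
    From the ideal-gas law,

        C = hfluid·(hcan − hfluid)·Acan
            / [Patom·hcan + (ρg·hfluid − Patom)·(hcan − hfluid)]

    where ``Patom`` is atmospheric pressure and ``rho_g`` the liquid's
    density times gravity.  A full (hfluid = hcan) or empty (hfluid = 0)
    can has zero compliance.
    """
    if Acan <= 0 or Patom <= 0:
        raise ValueError("Acan and Patom must be positive")
    if hfluid < 0 or hfluid > hcan:
        raise ValueError("need 0 <= hfluid <= hcan")
    num = hfluid * (hcan - hfluid) * Acan
    if num == 0.0:
        # full or empty can: no compressible gas spring (the empty-can
        # denominator is also 0, so take the limit explicitly)
        return 0.0
    den = Patom * hcan + (rho_g * hfluid - Patom) * (hcan - hfluid)
    return num / den


def classify_ph(mPAP: float) -> bool:
    """Pulmonary hypertension by the hemodynamic definition: mPAP > 25 mmHg
    (strict)."""
    if not math.isfinite(mPAP):
        raise ValueError("mPAP must be finite")
    return mPAP > 25.0


# ---------------------------------------------------------------------------
# circuit model
# ---------------------------------------------------------------------------

#: state vector layout: volumes of the five compartments, then the
#: inertance-branch flow from pap to pad
STATE_NAMES = ("V_rv", "V_pap", "V_pad", "V_pv", "V_res", "Q_pp")


@dataclass
class CircuitModel:
    """Closed-loop pulmonary circulation circuit.

    Topology (flows in parentheses)::

        reservoir --tricuspid--> RV --p-valve--> pap --R,L--> pad
             ^                                               |
             |___________ R_ret _________ pv <---- R_pad ----|

    The reservoir is a large-compliance node standing in for the systemic
    side (left heart + veins); the model's focus is the pulmonary loop.
    """

    rv: ChamberDrive
    pap: VesselSegment
    pad: VesselSegment
    pv: VesselSegment
    valve_p: ValveElement
    valve_tri: ValveElement
    C_res: float
    R_ret: float
    init_state: np.ndarray

    @property
    def period(self) -> float:
        return self.rv.period

    def pressures(self, t: float, y: np.ndarray) -> dict[str, float]:
        """Node pressures for a state vector."""
        return {
            "P_rv": self.rv.pressure(t, y[0]),
            "P_pap": y[1] / self.pap.C,
            "P_pad": y[2] / self.pad.C,
            "P_pv": y[3] / self.pv.C,
            "P_res": y[4] / self.C_res,
        }


def derivatives(
    state: np.ndarray, t: float, model: CircuitModel, R_pad: float | None = None
) -> np.ndarray:
    """Right-hand side of the circuit ODEs.

    dV/dt at each compliance node is the net in/out flow; dQ/dt on the
    inertance branch is (ΔP − R·Q)/L; valve branches follow the diode law.
    ``R_pad`` overrides the distal resistance (used during stenosis runs).
    """
    if state.shape != (6,):
        raise ValueError(f"state must have shape (6,), got {state.shape}")
    V_rv, V_pap, V_pad, V_pv, V_res, Q_pp = state
    m = model
    P_rv = m.rv.pressure(t, V_rv)
    P_pap = V_pap / m.pap.C
    P_pad = V_pad / m.pad.C
    P_pv = V_pv / m.pv.C
    P_res = V_res / m.C_res

    Q_tri = m.valve_tri.flow(P_res - P_rv)
    Q_pval = m.valve_p.flow(P_rv - P_pap)
    Rd = m.pad.R if R_pad is None else R_pad
    Q_pd = (P_pad - P_pv) / Rd
    Q_ret = (P_pv - P_res) / m.R_ret
    dQ_pp = (P_pap - P_pad - m.pap.R * Q_pp) / m.pap.L

    return np.array(
        [
            Q_tri - Q_pval,
            Q_pval - Q_pp,
            Q_pp - Q_pd,
            Q_pd - Q_ret,
            Q_ret - Q_tri,
            dQ_pp,
        ]
    )


@dataclass
class SimResult:
    """Uniformly sampled simulation output.

    ``pressures``/``flows``/``volumes`` map channel names to arrays on the
    time grid ``t``.  ``cycle_starts`` are the sample indices at which new
    cardiac cycles begin; ``steady_cycle_starts`` marks the cycles that
    satisfied the steady-state criterion.
    """

    t: np.ndarray
    pressures: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    volumes: dict[str, np.ndarray]
    dt: float
    period: float
    cycle_starts: np.ndarray
    steady: bool

    @property
    def steady_cycle_starts(self) -> np.ndarray:
        # the last cycles are the converged ones; keep the final 3 complete
        return self.cycle_starts[-4:-1] if self.steady else self.cycle_starts[:-1]

    def total_volume(self) -> np.ndarray:
        return sum(self.volumes.values())


def simulate(
    model: CircuitModel,
    dt: float = 1e-4,
    n_cycles: int = 40,
    stenosis: StenosisSchedule | None = None,
    save_every: int = 10,
    steady_rtol: float = 1e-3,
    steady_run: int = 3,
    stop_at_steady: bool = True,
) -> SimResult:
    """Fixed-step RK4 integration of the circuit over up to ``n_cycles``.

    Steady state is declared when the cycle-over-cycle relative change of
    PASP stays below ``steady_rtol`` for ``steady_run`` consecutive cycles
    (no stenosis progressing); with ``stop_at_steady`` the run ends there.
    A stenosis schedule, when given, rescales the distal resistance each
    step via the radius law.

    Raises :class:`InstabilityError` if any node pressure exceeds
    1000 mmHg in magnitude.
    """
    if dt <= 0 or n_cycles < 1:
        raise ValueError("need dt > 0 and n_cycles >= 1")
    m = model
    period = m.period
    steps_per_cycle = int(round(period / dt))
    y = np.asarray(m.init_state, dtype=float).copy()

    ts: list[float] = []
    rows: list[tuple] = []
    cycle_starts = [0]
    pasp_hist: list[float] = []
    steady = False
    n_saved = 0

    def record(t: float, y: np.ndarray, R_pad: float) -> float:
        V_rv, V_pap, V_pad_, V_pv, V_res, Q_pp = y
        P_rv = m.rv.pressure(t, V_rv)
        P_pap = V_pap / m.pap.C
        P_pad = V_pad_ / m.pad.C
        P_pv = V_pv / m.pv.C
        P_res = V_res / m.C_res
        for name, p in (
            ("P_rv", P_rv), ("P_pap", P_pap), ("P_pad", P_pad),
            ("P_pv", P_pv), ("P_res", P_res),
        ):
            if not math.isfinite(p) or abs(p) > 1e3:
                raise InstabilityError(
                    f"pressure at node {name} reached {p:.1f} mmHg at t={t:.4f} s"
                )
        Q_tri = m.valve_tri.flow(P_res - P_rv)
        Q_pval = m.valve_p.flow(P_rv - P_pap)
        Q_pd = (P_pad - P_pv) / R_pad
        Q_ret = (P_pv - P_res) / m.R_ret
        ts.append(t)
        rows.append(
            (P_rv, P_pap, P_pad, P_pv, P_res,
             Q_tri, Q_pval, Q_pp, Q_pd, Q_ret,
             V_rv, V_pap, V_pad_, V_pv, V_res)
        )
        return P_pap

    t = 0.0
    step = 0
    done = False
    for cyc in range(n_cycles):
        cycle_pasp = -np.inf
        for _ in range(steps_per_cycle):
            Rd = stenosis.resistance_at(t) if stenosis is not None else m.pad.R
            if step % save_every == 0:
                p_pap = record(t, y, Rd)
                n_saved += 1
            else:
                p_pap = y[1] / m.pap.C
            cycle_pasp = max(cycle_pasp, p_pap)
            # classic RK4 step
            k1 = derivatives(y, t, m, Rd)
            k2 = derivatives(y + 0.5 * dt * k1, t + 0.5 * dt, m, Rd)
            k3 = derivatives(y + 0.5 * dt * k2, t + 0.5 * dt, m, Rd)
            k4 = derivatives(y + dt * k3, t + dt, m, Rd)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += dt
            step += 1
        pasp_hist.append(cycle_pasp)
        cycle_starts.append(step // save_every)
        if stenosis is None or stenosis.gr == 0.0:
            tail = pasp_hist[-(steady_run + 1):]
            if len(tail) == steady_run + 1 and all(
                abs(tail[i + 1] - tail[i]) < steady_rtol * abs(tail[i])
                for i in range(steady_run)
            ):
                steady = True
                if stop_at_steady:
                    done = True
        if done:
            break

    arr = np.array(rows)
    names_p = ("P_rv", "P_pap", "P_pad", "P_pv", "P_res")
    names_q = ("Q_tri", "Q_pval", "Q_pp", "Q_pd", "Q_ret")
    names_v = ("V_rv", "V_pap", "V_pad", "V_pv", "V_res")
    return SimResult(
        t=np.array(ts),
        pressures={n: arr[:, i] for i, n in enumerate(names_p)},
        flows={n: arr[:, 5 + i] for i, n in enumerate(names_q)},
        volumes={n: arr[:, 10 + i] for i, n in enumerate(names_v)},
        dt=dt * save_every,
        period=period,
        cycle_starts=np.array(cycle_starts[:-1] + [n_saved]),
        steady=steady,
    )


# ---------------------------------------------------------------------------
# result analysis
# ---------------------------------------------------------------------------


def _cycle_slices(result: SimResult, steady_only: bool = True):
    starts = (
        result.steady_cycle_starts if steady_only else result.cycle_starts[:-1]
    )
    n_per = int(round(result.period / result.dt))
    for s in starts:
        e = min(s + n_per, len(result.t))
        if e - s >= n_per // 2:
            yield slice(int(s), int(e))


def pv_loop(
    result: SimResult, chamber: str = "rv", steady_only: bool = True
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-cycle pressure–volume loops (V, P) of a chamber.

    Returns one (volume, pressure) pair of arrays per cycle; for a
    steady-state result the loops close on themselves.
    """
    vkey, pkey = f"V_{chamber}", f"P_{chamber}"
    if vkey not in result.volumes:
        raise KeyError(f"no chamber {chamber!r} in result")
    loops = []
    for sl in _cycle_slices(result, steady_only):
        loops.append((result.volumes[vkey][sl], result.pressures[pkey][sl]))
    if not loops:
        raise ValueError("no complete cycles in result")
    return loops


def loop_area(V: np.ndarray, P: np.ndarray) -> float:
    """Signed area ∮P dV of one pressure–volume loop (trapezoid rule on the
    closed polygon)."""
    Vc = np.append(V, V[0])
    Pc = np.append(P, P[0])
    return float(np.trapezoid(Pc, Vc))


def summarize_pressures(result: SimResult, steady_only: bool = True) -> dict:
    """Per-cycle PASP (max pulmonary-artery pressure), mPAP (cycle mean) and
    RV systolic pressure, plus their across-cycle means."""
    slices = list(_cycle_slices(result, steady_only))
    if not slices:
        raise ValueError("empty result: no complete cycles")
    pasp = [float(result.pressures["P_pap"][sl].max()) for sl in slices]
    mpap = [float(result.pressures["P_pap"][sl].mean()) for sl in slices]
    rvs = [float(result.pressures["P_rv"][sl].max()) for sl in slices]
    return {
        "PASP": float(np.mean(pasp)),
        "mPAP": float(np.mean(mpap)),
        "RV_systolic": float(np.mean(rvs)),
        "per_cycle": {"PASP": pasp, "mPAP": mpap, "RV_systolic": rvs},
    }


# ---------------------------------------------------------------------------
# packaged parameter set
# ---------------------------------------------------------------------------


def load_model(config: dict | str | None = None) -> CircuitModel:
    """Build a :class:`CircuitModel` from a YAML file path, a dict, or the
    packaged normal-state parameter set (``config=None``)."""
    if config is None:
        text = (
            resources.files("pulmovib").joinpath("data/normal_circuit.yaml")
        ).read_text()
        cfg = yaml.safe_load(text)
    elif isinstance(config, str):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = config
    seg = {s["name"]: VesselSegment(**s) for s in cfg["segments"]}
    valves = {v["name"]: ValveElement(**v) for v in cfg["valves"]}
    rv = ChamberDrive(name="RV", **cfg["rv"])
    init = np.array([cfg["init"][k] for k in STATE_NAMES], dtype=float)
    return CircuitModel(
        rv=rv,
        pap=seg["pap"],
        pad=seg["pad"],
        pv=seg["pv"],
        valve_p=valves["p-valve"],
        valve_tri=valves["tricuspid"],
        C_res=cfg["reservoir"]["C"],
        R_ret=cfg["reservoir"]["R_ret"],
        init_state=init,
    )


def normal_model() -> CircuitModel:
    """The packaged normal-state pulmonary circulation model."""
    return load_model(None)
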