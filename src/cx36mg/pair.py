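"""Coupled two-cell gap-junction simulator.

Two hemichannels in series (one per cell) each follow the 3-state gating
chain from :mod:`cx36mg.schemes`, driven by their own cell's cytosolic Mg2+
concentration.  The junction is closed whenever either hemichannel is
closed, so the normalised junctional conductance is the product of the two
open fractions, ``gj = o1 * o2``.  Cytosolic Mg2+ in an unclamped cell
evolves by Fickian exchange through the junction, ``+P * gj * (mg_other -
mg_self)``, minus a pipette leak ``P_leak * mg_self``; a cell whose pipette
clamps the cytosol has zero Mg2+ derivative.

Experimental protocols covered: asymmetric pipette Mg2+ (donor cell clamped
at 5 or 10 mM, recipient starting near zero, with simultaneous conductance
and fluorescence-proxy readout), symmetric clamped Mg2+, transjunctional
voltage (Vj) pulses with exponential modulation of the gating rates, and a
"deep-closed" trapping variant in which Mg2+ unbinding is slowed once both
hemichannels are Mg2+-bound closed (a 9-state joint master equation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .schemes import (
    KineticScheme,
    RateParams,
    open_fraction,
    rate_matrix,
    steady_state,
)

__all__ = [
    "Protocol",
    "PairState",
    "TraceSet",
    "VjModulation",
    "VjPulse",
    "SimulationError",
    "asymmetric_protocol",
    "symmetric_protocol",
    "vj_pulse_protocol",
    "mg_flux_rhs",
    "modulate_rates",
    "simulate_pair",
    "simulate_pair_joint_trap",
    "vj_ramp_experiment",
    "trace_summary",
]


class SimulationError(RuntimeError):
    """Integration failed or produced an unphysical trajectory."""


@dataclass(frozen=True)
class VjPulse:
    """Piecewise-constant Vj waveform: ``amplitude_mv`` during
    [t_start, t_end], zero elsewhere."""

    t_start: float
    t_end: float
    amplitude_mv: float

    def __call__(self, t: float) -> float:
        return self.amplitude_mv if self.t_start <= t <= self.t_end else 0.0


@dataclass(frozen=True)
class VjModulation:
    """Exponential modulation of the gating rates by transjunctional voltage.

    For the hemichannel with polarity ``s`` seeing voltage ``v`` (mV),
    ``k1' = k1 * exp(z_open * s * v)`` and ``k2' = k2 * exp(-z_close * s * v)``.
    The junctional voltage splits equally across the two hemichannels, which
    carry opposite polarities.
    """

    z_open: float = 0.1
    z_close: float = 0.1
    polarity1: float = 1.0
    polarity2: float = -1.0

    def __post_init__(self) -> None:
        for name in ("z_open", "z_close", "polarity1", "polarity2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class Protocol:
    """One experimental protocol for a cell pair.

    ``pipette_mg`` are the pipette Mg2+ concentrations (mM); a clamped cell
    has its cytosol held at the pipette value.  ``initial_mg`` are the
    cytosolic concentrations at t = 0 (default: pipette value for clamped
    cells, 0 for unclamped).  Hemichannel states start at the equilibrium
    for ``initial_state_mg`` (default 0: the ligand-free equilibrium, since
    the initial conductance is recorded before the channels respond to
    pipette dialysis).
    """

    duration: float
    pipette_mg: tuple[float, float]
    clamp: tuple[bool, bool] = (True, True)
    initial_mg: tuple[float, float] | None = None
    initial_state_mg: tuple[float, float] = (0.0, 0.0)
    sample_interval: float = 0.05
    vj_waveform: Callable[[float], float] | None = None
    trap_factor: float | None = None
    protocol_id: str = "custom"

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if any(c < 0 for c in self.pipette_mg):
            raise ValueError("pipette Mg2+ concentrations must be >= 0")
        if self.trap_factor is not None and not 0.0 <= self.trap_factor <= 1.0:
            raise ValueError("trap factor must lie in [0, 1]")

    def resolved_initial_mg(self) -> tuple[float, float]:
        if self.initial_mg is not None:
            return self.initial_mg
        return tuple(
            self.pipette_mg[i] if self.clamp[i] else 0.0 for i in range(2)
        )

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.sample_interval))
        return np.linspace(0.0, n * self.sample_interval, n + 1)

    def without_vj(self) -> "Protocol":
        return replace(self, vj_waveform=None, protocol_id=self.protocol_id + "_novj")


def asymmetric_protocol(
    donor_mg: float, duration: float = 5.0, sample_interval: float = 0.05
) -> Protocol:
    """Donor cell (cell 2) clamped at ``donor_mg``; recipient (cell 1)
    unclamped, starting Mg2+-free, read out by conductance and fluorescence."""
    return Protocol(
        duration=duration,
        pipette_mg=(0.0, donor_mg),
        clamp=(False, True),
        sample_interval=sample_interval,
        protocol_id=f"asym_{donor_mg:g}mM",
    )


def symmetric_protocol(
    mg: float, duration: float = 5.0, sample_interval: float = 0.05
) -> Protocol:
    """Both cells clamped at the same pipette Mg2+ concentration."""
    return Protocol(
        duration=duration,
        pipette_mg=(mg, mg),
        clamp=(True, True),
        sample_interval=sample_interval,
        protocol_id=f"sym_{mg:g}mM",
    )


def vj_pulse_protocol(
    mg: float = 5.0,
    duration: float = 11.0,
    pulse_start: float = 5.0,
    pulse_length: float = 0.1,
    amplitude_mv: float = 60.0,
    sample_interval: float = 0.05,
) -> Protocol:
    """Symmetric clamped Mg2+ with a brief Vj pulse, then recovery at Vj=0."""
    return Protocol(
        duration=duration,
        pipette_mg=(mg, mg),
        clamp=(True, True),
        sample_interval=sample_interval,
        vj_waveform=VjPulse(pulse_start, pulse_start + pulse_length, amplitude_mv),
        protocol_id=f"vjramp_{mg:g}mM_{amplitude_mv:g}mV",
    )


@dataclass
class PairState:
    """State of the coupled system: two hemichannel probability vectors and
    the two cytosolic Mg2+ concentrations (mM)."""

    hc1: np.ndarray
    hc2: np.ndarray
    mg1: float
    mg2: float

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.hc1, self.hc2, [self.mg1, self.mg2]])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "PairState":
        return cls(hc1=y[0:3].copy(), hc2=y[3:6].copy(), mg1=float(y[6]), mg2=float(y[7]))


@dataclass
class TraceSet:
    """Observed or simulated time series for one protocol.

    ``gj_norm`` is junctional conductance normalised to its initial value;
    ``fi_norm`` the fluorescence proxy for recipient-cell Mg2+ (affine in
    mg1, unity at t = 0).  ``states`` optionally stores the six state
    probabilities per sample; ``extras`` holds auxiliary series such as
    double-closed probabilities or the Vj waveform.
    """

    time: np.ndarray
    gj_norm: np.ndarray
    fi_norm: np.ndarray | None = None
    mg1: np.ndarray | None = None
    mg2: np.ndarray | None = None
    states: np.ndarray | None = None
    variant: str = ""
    protocol_id: str = ""
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.gj_norm = np.asarray(self.gj_norm, dtype=float)
        if len(self.time) != len(self.gj_norm):
            raise ValueError("time and gj_norm must have equal length")
        for name in ("fi_norm", "mg1", "mg2"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if len(val) != len(self.time):
                    raise ValueError(f"{name} length does not match time grid")
                setattr(self, name, val)

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_min": self.time, "gj_norm": self.gj_norm}
        if self.fi_norm is not None:
            data["fi_norm"] = self.fi_norm
        if self.mg1 is not None:
            data["mg1_mM"] = self.mg1
        if self.mg2 is not None:
            data["mg2_mM"] = self.mg2
        for key, val in self.extras.items():
            data[key] = val
        frame = pd.DataFrame(data)
        frame["variant"] = self.variant
        frame["protocol_id"] = self.protocol_id
        return frame

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TraceSet":
        def col(name):
            return frame[name].to_numpy(dtype=float) if name in frame else None

        variant = str(frame["variant"].iloc[0]) if "variant" in frame else ""
        protocol_id = str(frame["protocol_id"].iloc[0]) if "protocol_id" in frame else ""
        known = {"time_min", "gj_norm", "fi_norm", "mg1_mM", "mg2_mM", "variant", "protocol_id"}
        extras = {
            name: frame[name].to_numpy(dtype=float)
            for name in frame.columns
            if name not in known
        }
        return cls(
            time=frame["time_min"].to_numpy(dtype=float),
            gj_norm=frame["gj_norm"].to_numpy(dtype=float),
            fi_norm=col("fi_norm"),
            mg1=col("mg1_mM"),
            mg2=col("mg2_mM"),
            variant=variant,
            protocol_id=protocol_id,
            extras=extras,
        )

    @classmethod
    def read_csv(cls, path) -> "TraceSet":
        return cls.from_frame(pd.read_csv(path))


def mg_flux_rhs(
    pair: PairState,
    params: RateParams,
    gj: float,
    protocol: Protocol,
) -> tuple[float, float]:
    """Cytosolic Mg2+ derivatives (mM/min) for both cells.

    Unclamped cell i: +P * gj * (mg_other - mg_i) - P_leak * mg_i.
    Clamped cell: 0.
    """
    if not 0.0 <= gj <= 1.0 + 1e-9:
        raise ValueError("gj must lie in [0, 1]")
    if pair.mg1 < 0 or pair.mg2 < 0:
        raise SimulationError("negative Mg2+ concentration in integration state")
    d1 = 0.0
    d2 = 0.0
    if not protocol.clamp[0]:
        d1 = params.p * gj * (pair.mg2 - pair.mg1) - params.p_leak * pair.mg1
    if not protocol.clamp[1]:
        d2 = params.p * gj * (pair.mg1 - pair.mg2) - params.p_leak * pair.mg2
    return d1, d2


def modulate_rates(
    params: RateParams,
    vj: float,
    mod: VjModulation,
    polarity: float = 1.0,
) -> tuple[float, float]:
    """Effective (k1', k2') of one hemichannel at voltage ``vj`` (mV)."""
    k1 = params.k1 * math.exp(mod.z_open * polarity * vj)
    k2 = params.k2 * math.exp(-mod.z_close * polarity * vj)
    return k1, k2


def _rate_scales(
    vj: float, mod: VjModulation | None
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Multipliers on (k1, k2) for each hemichannel; Vj splits equally."""
    if mod is None or vj == 0.0:
        return (1.0, 1.0), (1.0, 1.0)
    half = vj / 2.0
    scales = []
    for pol in (mod.polarity1, mod.polarity2):
        scales.append(
            (
                math.exp(mod.z_open * pol * half),
                math.exp(-mod.z_close * pol * half),
            )
        )
    return scales[0], scales[1]


def _initial_pair_state(
    scheme: KineticScheme,
    params1: RateParams,
    params2: RateParams,
    protocol: Protocol,
) -> np.ndarray:
    mg0 = protocol.resolved_initial_mg()
    s1 = steady_state(params1, protocol.initial_state_mg[0], scheme)
    s2 = steady_state(params2, protocol.initial_state_mg[1], scheme)
    return np.concatenate([s1, s2, mg0])


def _check_conservation(states: np.ndarray, tol: float = 1e-6) -> None:
    # states: (..., 3) blocks already split by caller
    err = np.max(np.abs(states.sum(axis=-1) - 1.0))
    if not np.isfinite(err) or err > tol:
        raise SimulationError(
            f"state-probability conservation violated (max |sum p - 1| = {err:.3g})"
        )


def simulate_pair(
    scheme: KineticScheme,
    params: RateParams,
    protocol: Protocol,
    *,
    params2: RateParams | None = None,
    mod: VjModulation | None = None,
    method: str = "LSODA",
    euler_step: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    variant: str = "",
    record_states: bool = True,
) -> TraceSet:
    """Integrate the coupled cell-pair system and return normalised traces.

    Hemichannel i binds its own cell's Mg2+; junctional permeability is
    taken from ``params`` (the two cells of a pair express the same
    variant).  ``method`` is any stiff-capable ``solve_ivp`` method, or
    ``"euler"`` for fixed-step explicit Euler with step ``euler_step``.
    """
    p1 = params
    p2 = params2 if params2 is not None else params
    y0 = _initial_pair_state(scheme, p1, p2, protocol)
    times = protocol.time_grid()
    vj_fun = protocol.vj_waveform

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        vj = vj_fun(t) if vj_fun is not None else 0.0
        scale1, scale2 = _rate_scales(vj, mod)
        s1, s2 = y[0:3], y[3:6]
        mg1 = max(y[6], 0.0)
        mg2 = max(y[7], 0.0)
        q1 = rate_matrix(p1, mg1, scheme, scale1)
        q2 = rate_matrix(p2, mg2, scheme, scale2)
        gj = open_fraction(s1, scheme) * open_fraction(s2, scheme)
        gj = min(max(gj, 0.0), 1.0)
        dmg1 = 0.0 if protocol.clamp[0] else (
            p1.p * gj * (mg2 - mg1) - p1.p_leak * mg1
        )
        dmg2 = 0.0 if protocol.clamp[1] else (
            p1.p * gj * (mg1 - mg2) - p1.p_leak * mg2
        )
        return np.concatenate([q1 @ s1, q2 @ s2, [dmg1, dmg2]])

    if method.lower() == "euler":
        ys = _euler_path(rhs, y0, times, euler_step)
    elif all(protocol.clamp) and (
        vj_fun is None or isinstance(vj_fun, VjPulse) or mod is None
    ):
        # both cytosols clamped: per-hemichannel dynamics are linear and
        # (piecewise) time-invariant, so propagate exactly through the
        # generator spectrum, segment by segment around the Vj pulse
        mg0 = protocol.resolved_initial_mg()
        pulse = vj_fun if (isinstance(vj_fun, VjPulse) and mod is not None) else None
        s1, s2 = _piecewise_clamped_path(
            scheme, p1, p2, mg0, y0, times, pulse, mod
        )
        ys = np.hstack(
            [s1, s2, np.full((len(times), 1), mg0[0]), np.full((len(times), 1), mg0[1])]
        )
    else:
        max_step = np.inf
        if vj_fun is not None:
            # do not step over the narrow Vj pulse
            max_step = protocol.sample_interval / 2.0
        sol = solve_ivp(
            rhs,
            (times[0], times[-1]),
            y0,
            method=method,
            t_eval=times,
            rtol=rtol,
            atol=atol,
            max_step=max_step,
        )
        if not sol.success:
            raise SimulationError(f"ODE integration failed: {sol.message}")
        ys = sol.y.T

    states = ys[:, 0:6]
    _check_conservation(states[:, 0:3])
    _check_conservation(states[:, 3:6])
    o1 = states[:, sorted(scheme.conducting)].sum(axis=1)
    o2 = states[:, [3 + i for i in sorted(scheme.conducting)]].sum(axis=1)
    gj = o1 * o2
    if gj[0] <= 0:
        raise SimulationError("initial junctional conductance is zero")
    mg1 = ys[:, 6]
    mg2 = ys[:, 7]
    return TraceSet(
        time=times,
        gj_norm=gj / gj[0],
        fi_norm=1.0 + (mg1 - mg1[0]),
        mg1=mg1,
        mg2=mg2,
        states=states if record_states else None,
        variant=variant,
        protocol_id=protocol.protocol_id,
    )


def _piecewise_clamped_path(
    scheme: KineticScheme,
    p1: RateParams,
    p2: RateParams,
    mg0: tuple[float, float],
    y0: np.ndarray,
    times: np.ndarray,
    pulse: "VjPulse | None",
    mod: "VjModulation | None",
) -> tuple[np.ndarray, np.ndarray]:
    """Exact hemichannel trajectories under clamped Mg2+ and an optional
    rectangular Vj pulse (constant generator within each segment)."""
    if pulse is None:
        edges = [times[0], times[-1]]
        vjs = [0.0]
    else:
        edges = sorted({times[0], pulse.t_start, pulse.t_end, times[-1]})
        edges = [e for e in edges if times[0] <= e <= times[-1]]
        vjs = [
            pulse(0.5 * (a + b)) for a, b in zip(edges[:-1], edges[1:])
        ]
    out1 = np.empty((len(times), 3))
    out2 = np.empty((len(times), 3))
    s1 = y0[0:3].copy()
    s2 = y0[3:6].copy()
    for (a, b), vj in zip(zip(edges[:-1], edges[1:]), vjs):
        scale1, scale2 = _rate_scales(vj, mod)
        q1 = rate_matrix(p1, mg0[0], scheme, scale1)
        q2 = rate_matrix(p2, mg0[1], scheme, scale2)
        last = b == edges[-1]
        mask = (times >= a - 1e-12) & ((times <= b + 1e-12) if last else (times < b - 1e-12))
        local = times[mask] - a
        out1[mask] = _propagate_linear(q1, s1, local)
        out2[mask] = _propagate_linear(q2, s2, local)
        s1 = _propagate_linear(q1, s1, np.array([b - a]))[0]
        s2 = _propagate_linear(q2, s2, np.array([b - a]))[0]
    return out1, out2


def _propagate_linear(q: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Exact solution of dp/dt = Q p via eigendecomposition, with a matrix-
    exponential fallback when the eigenbasis is ill-conditioned."""
    lam, vecs = np.linalg.eig(q)
    if np.linalg.cond(vecs) < 1e10:
        coeffs = np.linalg.solve(vecs, p0)
        sol = (vecs @ (coeffs[:, None] * np.exp(np.outer(lam, times)))).T
        return np.real(sol)
    return np.stack([expm(q * float(t)) @ p0 for t in times])


def _euler_path(rhs, y0: np.ndarray, times: np.ndarray, step: float) -> np.ndarray:
    """Fixed-step explicit Euler sampled onto ``times``."""
    out = np.empty((len(times), len(y0)))
    out[0] = y0
    y = y0.copy()
    t = times[0]
    for k in range(1, len(times)):
        t_target = times[k]
        while t < t_target - 1e-12:
            h = min(step, t_target - t)
            y = y + h * rhs(t, y)
            t += h
        out[k] = y
    return out


def _joint_generator(
    q1: np.ndarray, q2: np.ndarray, k4: float, eps: float
) -> np.ndarray:
    """9-state generator of the hemichannel pair with the deep-closed trap.

    The chains are independent except that Mg2+ unbinding (rate k4) out of
    the joint doubly-bound state (C-Mg, C-Mg) is multiplied by ``eps``.
    """
    eye = np.eye(3)
    q = np.kron(q1, eye) + np.kron(eye, q2)
    trap = 3 * 2 + 2  # joint index of (C-Mg, C-Mg)
    for target in (3 * 1 + 2, 3 * 2 + 1):  # (C, C-Mg) and (C-Mg, C)
        q[target, trap] -= (1.0 - eps) * k4
    off_diagonal_outflow = q[:, trap].sum() - q[trap, trap]
    q[trap, trap] = -off_diagonal_outflow
    return q


def simulate_pair_joint_trap(
    scheme: KineticScheme,
    params: RateParams,
    protocol: Protocol,
    *,
    eps: float | None = None,
    variant: str = "",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TraceSet:
    """Joint 9-state master equation of the hemichannel pair with trapping.

    ``eps`` (default from ``protocol.trap_factor``, else 0 = absorbing)
    multiplies the unbinding rate k4 only in the joint state where both
    hemichannels are Mg2+-bound closed.  Only the terminal-binding scheme
    family ("Model 5") supports a Mg2+-bound closed state to trap.
    Reports P(double-closed) and P(double-open) alongside the usual traces.
    """
    if not scheme.label.startswith("Model 5"):
        raise ValueError(
            f"joint trapping requires a 'Model 5'-family scheme, got {scheme.label!r}"
        )
    if eps is None:
        eps = protocol.trap_factor if protocol.trap_factor is not None else 0.0
    if not 0.0 <= eps <= 1.0:
        raise ValueError("trap factor must lie in [0, 1]")
    times = protocol.time_grid()
    mg0 = protocol.resolved_initial_mg()
    s1 = steady_state(params, protocol.initial_state_mg[0], scheme)
    s2 = steady_state(params, protocol.initial_state_mg[1], scheme)
    p0 = np.kron(s1, s2)

    if all(protocol.clamp):
        # time-invariant generator: exact matrix-exponential solution
        q = _joint_generator(
            rate_matrix(params, mg0[0], scheme),
            rate_matrix(params, mg0[1], scheme),
            params.k4,
            eps,
        )
        ps = np.stack([expm(q * float(t)) @ p0 for t in times])
        mg1 = np.full_like(times, mg0[0])
        mg2 = np.full_like(times, mg0[1])
    else:
        y0 = np.concatenate([p0, mg0])

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            p = y[0:9]
            mg1 = max(y[9], 0.0)
            mg2 = max(y[10], 0.0)
            q = _joint_generator(
                rate_matrix(params, mg1, scheme),
                rate_matrix(params, mg2, scheme),
                params.k4,
                eps,
            )
            gj = min(max(p[0], 0.0), 1.0)
            dmg1 = 0.0 if protocol.clamp[0] else (
                params.p * gj * (mg2 - mg1) - params.p_leak * mg1
            )
            dmg2 = 0.0 if protocol.clamp[1] else (
                params.p * gj * (mg1 - mg2) - params.p_leak * mg2
            )
            return np.concatenate([q @ p, [dmg1, dmg2]])

        sol = solve_ivp(
            rhs, (times[0], times[-1]), y0, method="LSODA",
            t_eval=times, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"ODE integration failed: {sol.message}")
        ps = sol.y[0:9].T
        mg1 = sol.y[9]
        mg2 = sol.y[10]

    _check_conservation(ps)
    gj = ps[:, 0]  # P(both open): only state O conducts in this family
    if gj[0] <= 0:
        raise SimulationError("initial junctional conductance is zero")
    return TraceSet(
        time=times,
        gj_norm=gj / gj[0],
        fi_norm=1.0 + (mg1 - mg1[0]),
        mg1=mg1,
        mg2=mg2,
        variant=variant,
        protocol_id=protocol.protocol_id,
        extras={
            "p_double_open": ps[:, 0],
            "p_double_closed": ps[:, 8],
            "joint_p": ps,
        },
    )


def vj_ramp_experiment(
    scheme: KineticScheme,
    params: RateParams,
    protocol: Protocol,
    mod: VjModulation,
    *,
    variant: str = "",
    with_baseline: bool = False,
    **solver_kwargs,
):
    """Simulate a Vj closure/recovery protocol.

    Rate modulation is active while the waveform is nonzero; gating rates
    revert to baseline afterwards.  With ``with_baseline=True`` also returns
    the counterfactual trace with no Vj perturbation (constant k1, k2).
    """
    if protocol.vj_waveform is None:
        trace = simulate_pair(
            scheme, params, protocol, mod=None, variant=variant, **solver_kwargs
        )
    else:
        trace = simulate_pair(
            scheme, params, protocol, mod=mod, variant=variant, **solver_kwargs
        )
        trace.extras["vj_mV"] = np.array(
            [protocol.vj_waveform(t) for t in trace.time]
        )
    if not with_baseline:
        return trace
    baseline = simulate_pair(
        scheme, params, protocol.without_vj(), mod=None, variant=variant,
        **solver_kwargs,
    )
    return trace, baseline


def trace_summary(trace: TraceSet, plateau_fraction: float = 0.1) -> dict[str, float]:
    """Ratios of steady-state/final to initial values.

    The steady-state level is estimated as the mean over the trailing
    ``plateau_fraction`` of the trace.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    g0 = trace.gj_norm[0]
    if g0 == 0:
        raise ZeroDivisionError("initial gj is zero; ratios undefined")
    tail = max(1, int(round(plateau_fraction * len(trace))))
    out = {
        "gj_ss_over_init": float(trace.gj_norm[-tail:].mean() / g0),
        "gj_final_over_init": float(trace.gj_norm[-1] / g0),
    }
    if trace.fi_norm is not None:
        f0 = trace.fi_norm[0]
        if f0 == 0:
            raise ZeroDivisionError("initial fluorescence is zero; ratio undefined")
        out["fi_final_over_init"] = float(trace.fi_norm[-1] / f0)
    return out
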