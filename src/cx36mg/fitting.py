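"""Simultaneous least-squares fitting of conductance and fluorescence traces.

A candidate gating scheme is fitted to a multi-protocol dataset by
minimising the pooled sum of squared errors (SSE) over all traces and both
measurement channels: normalised junctional conductance, and the
fluorescence proxy for recipient-cell Mg2+.  Global search is a seeded
multi-start: Latin-hypercube starting points inside box bounds, each refined
by trust-region least squares, with rates and permeability searched on a
log10 scale.  The pipette-leak rate ``p_leak`` is never fitted (it is
determined by the recording configuration, not the channel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .pair import Protocol, SimulationError, TraceSet, VjModulation, simulate_pair
from .schemes import KineticScheme, RateParams, get_scheme

__all__ = [
    "FitDataset",
    "FitEntry",
    "FitResult",
    "FitFailureError",
    "sse",
    "objective",
    "GatingModelFitter",
    "fit_global",
    "DEFAULT_BOUNDS",
]

logger = logging.getLogger(__name__)

#: Default box bounds per free parameter (rates in min^-1, p in min^-1,
#: n dimensionless); wide enough to span all plausible variant values.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k1": (1e-6, 1e4),
    "k2": (1e-6, 1e4),
    "k3": (1e-6, 1e4),
    "k4": (1e-6, 1e4),
    "p": (1e-6, 1.0),
    "n": (0.01, 5.0),
}

#: Parameters searched on a log10 scale.
_LOG_PARAMS = frozenset({"k1", "k2", "k3", "k4", "p"})

_PENALTY = 1e3  # per-residual penalty when the simulator fails


class FitFailureError(RuntimeError):
    """Every restart of a global fit failed."""


@dataclass(frozen=True)
class FitEntry:
    """One trace with its protocol and the data channels to fit."""

    trace: TraceSet
    protocol: Protocol
    channels: tuple[str, ...] = ("gj", "fi")

    def __post_init__(self) -> None:
        valid = {"gj", "fi"}
        if not self.channels or not set(self.channels) <= valid:
            raise ValueError(f"channels must be a non-empty subset of {valid}")
        if "fi" in self.channels and self.trace.fi_norm is None:
            object.__setattr__(self, "channels", ("gj",))


@dataclass
class FitDataset:
    """A collection of traces to be fitted jointly for one variant."""

    entries: list[FitEntry]
    variant: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("dataset must contain at least one trace")

    def __len__(self) -> int:
        return len(self.entries)

    def n_points(self) -> int:
        total = 0
        for e in self.entries:
            if "gj" in e.channels:
                total += len(e.trace)
            if "fi" in e.channels and e.trace.fi_norm is not None:
                total += len(e.trace)
        return total


@dataclass
class FitResult:
    """Best-of-restarts outcome of a global fit."""

    scheme_label: str
    params: RateParams
    sse: float
    n_points: int
    k_params: int
    seed: int
    n_restarts: int
    restart_sse: np.ndarray
    n_failed_restarts: int = 0
    residuals: dict[int, np.ndarray] = field(default_factory=dict)


def sse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Sum of squared errors between two equal-length series."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: observed {observed.shape}, predicted {predicted.shape}"
        )
    return float(np.sum((observed - predicted) ** 2))


def _predict_traces(
    params: RateParams,
    scheme: KineticScheme,
    dataset: FitDataset,
    solver_kwargs: dict,
) -> dict[int, TraceSet]:
    """Simulate each unique protocol once (replicates share predictions)."""
    cache: dict[int, TraceSet] = {}
    out: dict[int, TraceSet] = {}
    for i, entry in enumerate(dataset.entries):
        key = id(entry.protocol)
        if key not in cache:
            kwargs = dict(solver_kwargs)
            if entry.protocol.vj_waveform is None:
                kwargs.pop("mod", None)
            cache[key] = simulate_pair(
                scheme, params, entry.protocol, record_states=False, **kwargs
            )
        out[i] = cache[key]
    return out


def _residual_vector(
    params: RateParams,
    scheme: KineticScheme,
    dataset: FitDataset,
    solver_kwargs: dict,
) -> np.ndarray:
    preds = _predict_traces(params, scheme, dataset, solver_kwargs)
    chunks = []
    for i, entry in enumerate(dataset.entries):
        pred = preds[i]
        if len(pred) != len(entry.trace):
            raise ValueError("trace and protocol time grids disagree")
        if "gj" in entry.channels:
            chunks.append(entry.trace.gj_norm - pred.gj_norm)
        if "fi" in entry.channels and entry.trace.fi_norm is not None:
            chunks.append(entry.trace.fi_norm - pred.fi_norm)
    return np.concatenate(chunks)


def objective(
    params: RateParams,
    scheme: KineticScheme | str,
    dataset: FitDataset,
    **solver_kwargs,
) -> float:
    """Pooled SSE of a parameter set over all traces and enabled channels.

    A simulator failure yields a large finite penalty (logged) rather than
    an exception, so global search can continue past pathological points.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    try:
        r = _residual_vector(params, scheme, dataset, solver_kwargs)
    except (SimulationError, ValueError, FloatingPointError) as exc:
        logger.warning("objective penalised at %s: %s", params, exc)
        return _PENALTY**2 * dataset.n_points()
    return float(np.dot(r, r))


class GatingModelFitter(BaseEstimator):
    """Multi-start least-squares estimator for one gating scheme.

    Parameters
    ----------
    scheme :
        Catalogue label (e.g. ``"Model 5, Hill"``) or a ``KineticScheme``.
    bounds :
        Mapping parameter name -> (lower, upper); defaults to
        ``DEFAULT_BOUNDS`` entries.  The Hill exponent is only free for
        Hill-law schemes.
    n_restarts :
        Number of Latin-hypercube starting points.
    random_state :
        Seed for the starting-point design; the fit is reproducible given
        (seed, n_restarts, dataset).
    p_leak :
        Fixed pipette-leak rate (min^-1), not fitted.
    max_nfev :
        Residual-evaluation budget per local refinement.

    Attributes
    ----------
    params_ : RateParams
        Best-fit parameter set.
    sse_ : float
        Pooled SSE at the optimum.
    result_ : FitResult
        Full record including every restart's terminal SSE.
    """

    def __init__(
        self,
        scheme: str | KineticScheme = "Model 5, Hill",
        bounds: dict[str, tuple[float, float]] | None = None,
        n_restarts: int = 20,
        random_state: int = 0,
        p_leak: float = 0.0,
        max_nfev: int = 120,
        solver_method: str = "LSODA",
        rtol: float = 1e-7,
        atol: float = 1e-9,
        vj_modulation: VjModulation | None = None,
    ):
        self.scheme = scheme
        self.bounds = bounds
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.p_leak = p_leak
        self.max_nfev = max_nfev
        self.solver_method = solver_method
        self.rtol = rtol
        self.atol = atol
        self.vj_modulation = vj_modulation

    # -- parameter-space transforms -------------------------------------

    def _scheme(self) -> KineticScheme:
        return get_scheme(self.scheme) if isinstance(self.scheme, str) else self.scheme

    def _free_names(self, scheme: KineticScheme) -> list[str]:
        names = ["k1", "k2", "k3", "k4", "p"]
        if scheme.is_hill:
            names.append("n")
        return names

    def _resolved_bounds(self, names: list[str]) -> list[tuple[float, float]]:
        user = self.bounds or {}
        out = []
        for name in names:
            lo, hi = user.get(name, DEFAULT_BOUNDS[name])
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
            out.append((float(lo), float(hi)))
        return out

    def _to_params(self, theta: np.ndarray, names: list[str]) -> RateParams:
        values = {}
        for name, x in zip(names, theta):
            values[name] = 10.0**x if name in _LOG_PARAMS else x
        values.setdefault("n", 1.0)
        return RateParams(p_leak=self.p_leak, **values)

    def _transform_bounds(
        self, names: list[str], bounds: list[tuple[float, float]]
    ) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name, (a, b) in zip(names, bounds):
            if name in _LOG_PARAMS:
                a, b = np.log10(a), np.log10(b)
            lo.append(a)
            hi.append(b)
        return np.array(lo), np.array(hi)

    # -- fitting ---------------------------------------------------------

    def fit(self, X: FitDataset, y=None) -> "GatingModelFitter":
        """Fit the scheme to a :class:`FitDataset` (``y`` is ignored)."""
        dataset = X
        scheme = self._scheme()
        names = self._free_names(scheme)
        lo, hi = self._transform_bounds(names, self._resolved_bounds(names))
        solver_kwargs = dict(
            method=self.solver_method,
            rtol=self.rtol,
            atol=self.atol,
            # Vj-modulation slopes are protocol constants shared with the
            # generator, not fitted parameters
            mod=self.vj_modulation if self.vj_modulation is not None else VjModulation(),
        )
        m = dataset.n_points()

        def residuals(theta: np.ndarray) -> np.ndarray:
            try:
                params = self._to_params(theta, names)
                return _residual_vector(params, scheme, dataset, solver_kwargs)
            except (SimulationError, ValueError, FloatingPointError) as exc:
                logger.warning("restart penalised at theta=%s: %s", theta, exc)
                return np.full(m, _PENALTY)

        sampler = qmc.LatinHypercube(d=len(names), seed=self.random_state)
        starts = lo + sampler.random(self.n_restarts) * (hi - lo)

        best = None
        restart_sse = np.full(self.n_restarts, np.inf)
        n_failed = 0
        for i, x0 in enumerate(starts):
            try:
                res = least_squares(
                    residuals,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    max_nfev=self.max_nfev,
                    xtol=1e-10,
                    ftol=1e-10,
                    gtol=1e-10,
                )
            except Exception as exc:  # optimiser-internal failure
                logger.warning("restart %d failed: %s", i, exc)
                n_failed += 1
                continue
            value = float(np.dot(res.fun, res.fun))
            restart_sse[i] = value
            if value >= _PENALTY**2 * m * 0.99:
                n_failed += 1
                continue
            if best is None or value < best[0]:
                best = (value, res.x)
        if best is None:
            raise FitFailureError(
                f"all {self.n_restarts} restarts failed; terminal SSEs: {restart_sse}"
            )

        self.scheme_ = scheme
        self.params_ = self._to_params(best[1], names)
        self.sse_ = best[0]
        self.n_points_ = m
        self.k_params_ = scheme.n_free_params
        self.restart_sse_ = restart_sse
        self.result_ = FitResult(
            scheme_label=scheme.label,
            params=self.params_,
            sse=self.sse_,
            n_points=m,
            k_params=self.k_params_,
            seed=self.random_state,
            n_restarts=self.n_restarts,
            restart_sse=restart_sse,
            n_failed_restarts=n_failed,
        )
        return self

    def predict(self, protocol: Protocol) -> TraceSet:
        """Simulate the fitted model under a protocol."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fitter is not fitted")
        kwargs = {}
        if protocol.vj_waveform is not None:
            kwargs["mod"] = (
                self.vj_modulation if self.vj_modulation is not None else VjModulation()
            )
        return simulate_pair(
            self.scheme_,
            self.params_,
            protocol,
            method=self.solver_method,
            rtol=self.rtol,
            atol=self.atol,
            **kwargs,
        )

    def score(self, X: FitDataset, y=None) -> float:
        """Negative pooled SSE on a dataset (higher is better)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fitter is not fitted")
        return -objective(
            self.params_, self.scheme_, X,
            method=self.solver_method, rtol=self.rtol, atol=self.atol,
            mod=self.vj_modulation if self.vj_modulation is not None else VjModulation(),
        )


def fit_global(
    scheme: str | KineticScheme,
    dataset: FitDataset,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_restarts: int = 20,
    **kwargs,
) -> FitResult:
    """Functional wrapper over :class:`GatingModelFitter`."""
    fitter = GatingModelFitter(
        scheme=scheme, bounds=bounds, n_restarts=n_restarts,
        random_state=seed, **kwargs,
    )
    fitter.fit(dataset)
    return fitter.result_
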