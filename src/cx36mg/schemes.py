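"""Candidate 3-state kinetic schemes for Mg2+-mediated gating of Cx36 hemichannels.

Each hemichannel is described by a linear chain of three conformational
states, ``S0 <-> S1 <-> S2``, where the first state is open, the terminal
state is closed, and the intermediate state may be either open or closed.
Either of the two transitions may represent binding of cytosolic Mg2+
(forward rate scaling as ``k * [Mg2+]**n``) or a ligand-independent gating
event.  Enumerating the binding assumptions and the conductance of the
intermediate state, and discarding the schemes with no Mg2+ dependence plus
the one with a redundant ligand-independent transition between two open
states, leaves five basic schemes; each is paired with either mass-action
(``n = 1``, fixed) or Hill binding, giving a catalogue of ten candidate
models.

The preferred scheme for Cx36 ("Model 5, Hill") reads

    O  <-k1/k2->  C  <-k3*[Mg]^n / k4->  C-Mg

i.e. a ligand-independent open/closed gating step followed by Mg2+ binding
to - and stabilisation of - the closed conformation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "BindingLaw",
    "SchemeSpec",
    "KineticScheme",
    "RateParams",
    "SchemeError",
    "NoMgBindingError",
    "RedundantSchemeError",
    "DegenerateChainError",
    "build_scheme",
    "scheme_catalogue",
    "get_scheme",
    "rate_matrix",
    "hemichannel_rhs",
    "steady_state",
    "open_fraction",
    "propagate_constant_mg",
    "VARIANT_PARAMS",
]


class BindingLaw(str, enum.Enum):
    MASS_ACTION = "mass_action"
    HILL = "hill"


class SchemeError(ValueError):
    """Invalid kinetic-scheme specification."""

    code = "invalid_scheme"


class NoMgBindingError(SchemeError):
    """Scheme contains no Mg2+-dependent transition."""

    code = "no_mg_binding"


class RedundantSchemeError(SchemeError):
    """Ligand-independent transition between two open states is redundant."""

    code = "redundant_open_open"


class DegenerateChainError(ValueError):
    """Equilibrium undefined: forward flux with no return path."""


@dataclass(frozen=True)
class SchemeSpec:
    """Declarative description of one candidate scheme.

    Parameters
    ----------
    o_to_x_binding :
        Whether the first transition (open state to intermediate) is a
        Mg2+-binding step.
    x_is_open :
        Whether the intermediate state conducts.
    x_to_c_binding :
        Whether the second transition (intermediate to terminal closed
        state) is a Mg2+-binding step.
    binding_law :
        Mass-action (Hill exponent frozen at 1) or Hill binding.
    """

    o_to_x_binding: bool
    x_is_open: bool
    x_to_c_binding: bool
    binding_law: BindingLaw = BindingLaw.MASS_ACTION


#: (o_to_x_binding, x_is_open, x_to_c_binding) -> basic model number
_MODEL_GRID = {
    (True, True, True): 1,
    (True, True, False): 2,
    (True, False, True): 3,
    (True, False, False): 4,
    (False, False, True): 5,
}


@dataclass(frozen=True)
class KineticScheme:
    """Validated scheme descriptor.

    Attributes
    ----------
    states :
        Names of the three chain states, first to last.
    conducting :
        Indices of conducting states ({0} if the intermediate is closed,
        {0, 1} if it is open).
    mg_dependent :
        Pair of flags: whether the forward rate of transition 1 (k1) and
        transition 2 (k3) carries the ``[Mg2+]**n`` factor.
    """

    spec: SchemeSpec
    label: str
    states: tuple[str, str, str]
    conducting: frozenset[int]
    mg_dependent: tuple[bool, bool]

    @property
    def is_hill(self) -> bool:
        return self.spec.binding_law is BindingLaw.HILL

    @property
    def n_free_params(self) -> int:
        """Free parameters fitted for this scheme: k1..k4 and P, plus the
        Hill exponent when it is not frozen at 1."""
        return 6 if self.is_hill else 5


def build_scheme(spec: SchemeSpec) -> KineticScheme:
    """Validate a scheme specification and return its descriptor.

    Raises
    ------
    NoMgBindingError
        If neither transition binds Mg2+ (no ligand dependence at all).
    RedundantSchemeError
        If the first transition is ligand-independent and the intermediate
        state is open: an open-open gating step adds an indistinguishable
        state.
    """
    if not (spec.o_to_x_binding or spec.x_to_c_binding):
        raise NoMgBindingError("scheme has no Mg2+-dependent transition")
    if not spec.o_to_x_binding and spec.x_is_open:
        raise RedundantSchemeError(
            "ligand-independent transition between two open states is redundant"
        )
    number = _MODEL_GRID[(spec.o_to_x_binding, spec.x_is_open, spec.x_to_c_binding)]
    label = f"Model {number}"
    if spec.binding_law is BindingLaw.HILL:
        label += ", Hill"
    if number == 5:
        states = ("O", "C", "C-Mg")
    else:
        states = ("O", "X", "C")
    conducting = frozenset({0, 1}) if spec.x_is_open else frozenset({0})
    return KineticScheme(
        spec=spec,
        label=label,
        states=states,
        conducting=conducting,
        mg_dependent=(spec.o_to_x_binding, spec.x_to_c_binding),
    )


def scheme_catalogue() -> dict[str, KineticScheme]:
    """The ten retained candidate schemes, addressable by label."""
    catalogue: dict[str, KineticScheme] = {}
    for key in _MODEL_GRID:
        for law in (BindingLaw.MASS_ACTION, BindingLaw.HILL):
            scheme = build_scheme(SchemeSpec(*key, binding_law=law))
            catalogue[scheme.label] = scheme
    return catalogue


def get_scheme(label: str) -> KineticScheme:
    try:
        return scheme_catalogue()[label]
    except KeyError:
        raise KeyError(
            f"unknown scheme label {label!r}; valid labels: "
            f"{sorted(scheme_catalogue())}"
        ) from None


@dataclass(frozen=True)
class RateParams:
    """Kinetic and transport parameters of one hemichannel variant.

    Rates are per minute; concentrations in mM.  ``k3`` carries units
    min^-1 mM^-n so that ``k3 * mg**n`` is a rate.  ``p`` is the junctional
    Mg2+ permeability per unit normalised conductance (min^-1); ``p_leak``
    the leak rate of Mg2+ from an unclamped cell into its pipette (min^-1,
    fixed during fitting).
    """

    k1: float
    k2: float
    k3: float
    k4: float
    n: float = 1.0
    p: float = 0.0
    p_leak: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "p", "p_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.n > 0:
            raise ValueError("Hill exponent n must be > 0")

    def replace(self, **kwargs) -> "RateParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {
            "k1": self.k1, "k2": self.k2, "k3": self.k3, "k4": self.k4,
            "n": self.n, "p": self.p, "p_leak": self.p_leak,
        }


#: Published point estimates for wild-type Cx36 and N-terminal variants
#: (Model 5, Hill), used as generator defaults and simulation presets.
VARIANT_PARAMS: dict[str, RateParams] = {
    "WT": RateParams(k1=5.35, k2=386.57, k3=3.2770, k4=0.1802, n=1.12, p=0.0135),
    "E3Q": RateParams(k1=3.52, k2=392.28, k3=3.2366, k4=0.0417, n=1.08, p=0.0258),
    "E8Q": RateParams(k1=5.88, k2=271.07, k3=0.7168, k4=0.0197, n=1.07, p=0.0076),
    "A13K": RateParams(k1=3.05, k2=179.34, k3=0.0026, k4=0.0637, n=2.84, p=0.0011),
    "H18K": RateParams(k1=9.80, k2=337.60, k3=3.2391, k4=0.2008, n=0.11, p=0.0072),
}


def _effective_n(params: RateParams, scheme: KineticScheme) -> float:
    return params.n if scheme.is_hill else 1.0


def transition_rates(
    params: RateParams,
    mg: float,
    scheme: KineticScheme,
    rate_scale: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float, float, float]:
    """Forward/backward rates (f1, r1, f2, r2) of the chain at ligand
    concentration ``mg``.  ``rate_scale`` multiplies (k1, k2) to express
    transjunctional-voltage modulation of the gating step."""
    if mg < 0:
        raise ValueError("mg concentration must be >= 0")
    n = _effective_n(params, scheme)
    mg_factor = mg**n
    f1 = params.k1 * rate_scale[0] * (mg_factor if scheme.mg_dependent[0] else 1.0)
    r1 = params.k2 * rate_scale[1]
    f2 = params.k3 * (mg_factor if scheme.mg_dependent[1] else 1.0)
    r2 = params.k4
    return f1, r1, f2, r2


def rate_matrix(
    params: RateParams,
    mg: float,
    scheme: KineticScheme,
    rate_scale: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Generator matrix Q of the chain such that dp/dt = Q @ p."""
    f1, r1, f2, r2 = transition_rates(params, mg, scheme, rate_scale)
    return np.array(
        [
            [-f1, r1, 0.0],
            [f1, -(r1 + f2), r2],
            [0.0, f2, -r2],
        ]
    )


def hemichannel_rhs(
    state: np.ndarray,
    params: RateParams,
    mg: float,
    scheme: KineticScheme,
    rate_scale: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Time derivative (min^-1) of the state-probability vector."""
    state = np.asarray(state, dtype=float)
    if state.shape != (3,):
        raise ValueError("state must be a length-3 probability vector")
    if np.any(state < -1e-9) or abs(state.sum() - 1.0) > 1e-6:
        raise ValueError("state is not a normalised probability vector")
    return rate_matrix(params, mg, scheme, rate_scale) @ state


def steady_state(
    params: RateParams,
    mg: float,
    scheme: KineticScheme,
    rate_scale: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Detailed-balance equilibrium of the linear chain.

    The chain is a reversible birth-death process, so the stationary
    distribution follows from the products of forward/backward rate ratios:
    p1/p0 = f1/r1, p2/p1 = f2/r2.
    """
    f1, r1, f2, r2 = transition_rates(params, mg, scheme, rate_scale)
    if r1 == 0.0:
        if f1 > 0.0:
            raise DegenerateChainError("k2 = 0 with k1 > 0: no return path from state 1")
        # chain never leaves state 0
        return np.array([1.0, 0.0, 0.0])
    w1 = f1 / r1
    if f2 == 0.0:
        w2 = 0.0
    elif r2 == 0.0:
        if w1 > 0.0:
            raise DegenerateChainError("k4 = 0 with flux into the terminal state")
        w2 = 0.0
    else:
        w2 = f2 / r2
    weights = np.array([1.0, w1, w1 * w2])
    return weights / weights.sum()


def open_fraction(state: np.ndarray, scheme: KineticScheme) -> float:
    """Conductance fraction: total probability of the conducting states."""
    state = np.asarray(state, dtype=float)
    return float(state[sorted(scheme.conducting)].sum())


def propagate_constant_mg(
    state0: np.ndarray,
    params: RateParams,
    mg: float,
    scheme: KineticScheme,
    times: np.ndarray,
) -> np.ndarray:
    """Exact solution p(t) = expm(Q t) p(0) at constant ligand concentration.

    Serves as the closed-form oracle for the ODE integrators; returns an
    array of shape (len(times), 3).
    """
    q = rate_matrix(params, mg, scheme)
    state0 = np.asarray(state0, dtype=float)
    return np.stack([expm(q * float(t)) @ state0 for t in np.atleast_1d(times)])
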