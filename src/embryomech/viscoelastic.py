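"""Lumped-parameter viscoelastic creep models for micropipette aspiration.

A one-cell embryo held at a micropipette and subjected to a suction pressure
step deforms with three characteristic phases: an instantaneous elongation,
an exponential settling, and a late constant-rate flow.  The four-parameter
model that reproduces all three phases is a Zener (standard linear solid)
body — an equilibrium spring ``k0`` in parallel with a Maxwell arm
(spring ``k1`` in series with dashpot ``eta1``) — placed in series with an
extra dashpot ``eta0``.  We call this the *modified Zener* model.  Springs
carry units of N·m⁻¹ and dashpots N·s·m⁻¹ because the model maps applied
force to aspiration depth (a bulk, not continuum, description).

This module provides the closed-form creep response of that model and of the
simpler textbook models it is compared against (Maxwell, Kelvin–Voigt,
Zener) plus a five-parameter two-arm generalisation, a numerical ODE oracle
for verification, nonlinear least-squares fitting of measured traces, and
model comparison by residual error.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

PSI_TO_PA = 6894.757

__all__ = [
    "PSI_TO_PA",
    "ModelKind",
    "ViscoParams",
    "PressureProtocol",
    "AspirationTrace",
    "FitResult",
    "step_force",
    "creep",
    "creep_ode_oracle",
    "fit_trace",
    "compare_models",
    "HUMAN_PROTOCOL",
    "MOUSE_PROTOCOL",
]


class ModelKind(str, enum.Enum):
    """The five candidate spring–dashpot networks."""

    MAXWELL = "maxwell"
    KELVIN_VOIGT = "kelvin_voigt"
    ZENER = "zener"
    MODIFIED_ZENER = "modified_zener"
    FIVE_PARAM = "five_param"


# parameter names used by each model, in fit order
MODEL_PARAM_NAMES = {
    ModelKind.MAXWELL: ("k1", "eta1"),
    ModelKind.KELVIN_VOIGT: ("k0", "eta1"),
    ModelKind.ZENER: ("k0", "k1", "eta1"),
    ModelKind.MODIFIED_ZENER: ("k0", "k1", "eta1", "eta0"),
    ModelKind.FIVE_PARAM: ("k0", "k1", "eta1", "k2", "eta2"),
}


@dataclass(frozen=True)
class ViscoParams:
    """Mechanical parameters of one embryo.

    k0 : equilibrium (parallel) spring, N·m⁻¹
    k1 : Maxwell-arm spring, N·m⁻¹
    eta1 : Maxwell-arm dashpot, N·s·m⁻¹
    eta0 : series dashpot, N·s·m⁻¹
    k2, eta2 : optional second Maxwell arm (five-parameter model only)
    """

    k0: float | None = None
    k1: float | None = None
    eta1: float | None = None
    eta0: float | None = None
    k2: float | None = None
    eta2: float | None = None

    def validate_for(self, model: ModelKind) -> None:
        for name in MODEL_PARAM_NAMES[model]:
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0.0:
                raise ValueError(
                    f"parameter {name!r} must be a positive finite number "
                    f"for model {model.value!r}, got {v!r}"
                )

    def as_vector(self, model: ModelKind) -> np.ndarray:
        return np.array([getattr(self, n) for n in MODEL_PARAM_NAMES[model]], float)

    @classmethod
    def from_vector(cls, model: ModelKind, vec) -> "ViscoParams":
        return cls(**dict(zip(MODEL_PARAM_NAMES[model], (float(v) for v in vec))))


@dataclass(frozen=True)
class PressureProtocol:
    """Suction protocol and pipette geometry of one aspiration measurement.

    Pressures are in Pa (suction negative).  The defaults below follow the
    measurement protocol for this instrument class: a holding pressure of
    −0.03 psi to seal the embryo to the pipette opening, then a step to
    −0.345 psi; pipettes of 40 μm (mouse) or 70 μm (human) inner diameter.
    """

    holding_pressure_pa: float
    step_pressure_pa: float
    pipette_inner_diameter_m: float
    step_onset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.pipette_inner_diameter_m <= 0:
            raise ValueError("pipette_inner_diameter_m must be positive")
        if abs(self.step_pressure_pa) < abs(self.holding_pressure_pa):
            raise ValueError("step pressure must exceed holding pressure in magnitude")


MOUSE_PROTOCOL = PressureProtocol(
    holding_pressure_pa=-0.03 * PSI_TO_PA,
    step_pressure_pa=-0.345 * PSI_TO_PA,
    pipette_inner_diameter_m=40e-6,
)
HUMAN_PROTOCOL = PressureProtocol(
    holding_pressure_pa=-0.03 * PSI_TO_PA,
    step_pressure_pa=-0.345 * PSI_TO_PA,
    pipette_inner_diameter_m=70e-6,
)


@dataclass
class AspirationTrace:
    """Time series of one aspiration measurement.

    times_s is zeroed at the pressure-step onset and strictly increasing;
    depths_m is aspiration depth into the pipette (positive into the
    pipette regardless of the sign of the suction).
    """

    times_s: np.ndarray
    depths_m: np.ndarray
    rate_hz: float = 75.0
    pressure_pa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.depths_m = np.asarray(self.depths_m, float)
        if self.times_s.shape != self.depths_m.shape:
            raise ValueError("times and depths must have equal length")
        if self.times_s.size < 8:
            raise ValueError("a trace needs at least 8 samples for fitting")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class FitResult:
    model: ModelKind
    params: ViscoParams
    rms_residual_m: float
    converged: bool
    n_iter: int


def step_force(protocol: PressureProtocol) -> float:
    """Net aspiration force of the pressure step, in N.

    The force is the pressure change across the pipette opening (step minus
    holding, i.e. the net change the embryo experiences at onset) times the
    opening area: F0 = |Δp|·π·(d/2)².
    """
    dp = abs(protocol.step_pressure_pa - protocol.holding_pressure_pa)
    r = protocol.pipette_inner_diameter_m / 2.0
    return dp * math.pi * r * r


def creep(t, model: ModelKind, params: ViscoParams, f0: float):
    """Closed-form aspiration depth (m) under a force step of amplitude f0.

    For the modified Zener model the response is

        x(t) = F0/k0 − [F0·k1 / (k0·(k0+k1))]·exp(−t/τ) + F0·t/η0,
        τ = η1·(k0+k1)/(k0·k1),

    i.e. an instantaneous jump to F0/(k0+k1), an exponential approach toward
    F0/k0, and a constant-rate tail of slope F0/η0 from the series dashpot.
    The five-parameter (two-arm Wiechert) form uses the same per-arm
    constants: x(t) = F0/k0 − Σᵢ Aᵢ·exp(−t/τᵢ) with
    Aᵢ = F0·kᵢ/(k0·(k0+kᵢ)) and τᵢ = ηᵢ·(k0+kᵢ)/(k0·kᵢ).
    """
    model = ModelKind(model)
    params.validate_for(model)
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("creep is defined for t >= 0 (time since step onset)")

    if model is ModelKind.MAXWELL:
        return f0 * (1.0 / params.k1 + t / params.eta1)
    if model is ModelKind.KELVIN_VOIGT:
        return (f0 / params.k0) * (1.0 - np.exp(-params.k0 * t / params.eta1))
    if model is ModelKind.ZENER:
        return _zener_terms(t, params.k0, params.k1, params.eta1, f0)
    if model is ModelKind.MODIFIED_ZENER:
        return (
            _zener_terms(t, params.k0, params.k1, params.eta1, f0)
            + f0 * t / params.eta0
        )
    # five_param
    x = np.full_like(t, f0 / params.k0, dtype=float)
    for k, eta in ((params.k1, params.eta1), (params.k2, params.eta2)):
        amp = f0 * k / (params.k0 * (params.k0 + k))
        tau = eta * (params.k0 + k) / (params.k0 * k)
        x -= amp * np.exp(-t / tau)
    return x


def _zener_terms(t, k0, k1, eta1, f0):
    amp = f0 * k1 / (k0 * (k0 + k1))
    tau = eta1 * (k0 + k1) / (k0 * k1)
    return f0 / k0 - amp * np.exp(-t / tau)


def creep_ode_oracle(
    t_grid, model: ModelKind, params: ViscoParams, f0: float, rtol: float = 1e-12
) -> np.ndarray:
    """Creep response by stiff numerical integration of the network ODEs.

    Independent verification path for :func:`creep`: the governing force
    balances of the spring–dashpot network are integrated directly with
    ``scipy.integrate.solve_ivp`` (Radau), never the closed forms.  For the
    Zener body (force F on spring k0 parallel to arm k1–η1, displacement y):

        F0 = k0·y + η1·(k0+k1)/k1 · dy/dt,     y(0⁺) = F0/(k0+k1)

    and the series dashpot adds an independent state with dz/dt = F0/η0.
    """
    model = ModelKind(model)
    params.validate_for(model)
    t_grid = np.asarray(t_grid, float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if model is ModelKind.FIVE_PARAM:
        raise NotImplementedError(
            "the two-arm model's compliance is defined constructively; "
            "the ODE oracle covers the four classical networks"
        )

    k0, k1, eta1, eta0 = params.k0, params.k1, params.eta1, params.eta0

    if model is ModelKind.MAXWELL:
        y0 = [f0 / k1]
        rhs = lambda t, y: [f0 / eta1]
    elif model is ModelKind.KELVIN_VOIGT:
        y0 = [0.0]
        rhs = lambda t, y: [(f0 - k0 * y[0]) / eta1]
    elif model is ModelKind.ZENER:
        c = eta1 * (k0 + k1) / k1
        y0 = [f0 / (k0 + k1)]
        rhs = lambda t, y: [(f0 - k0 * y[0]) / c]
    else:  # modified zener: zener displacement + series dashpot displacement
        c = eta1 * (k0 + k1) / k1
        y0 = [f0 / (k0 + k1), 0.0]
        rhs = lambda t, y: [(f0 - k0 * y[0]) / c, f0 / eta0]

    t0 = float(t_grid[0])
    sol = solve_ivp(
        rhs,
        (t0, float(t_grid[-1])),
        y0 if t0 == 0.0 else _warm_start(rhs, y0, t0, rtol),
        t_eval=t_grid,
        method="Radau",
        rtol=rtol,
        atol=1e-18,
    )
    if not sol.success:
        raise RuntimeError(f"ODE oracle failed to converge: {sol.message}")
    return sol.y.sum(axis=0)


def _warm_start(rhs, y0, t0, rtol):
    sol = solve_ivp(rhs, (0.0, t0), y0, method="Radau", rtol=rtol, atol=1e-18)
    if not sol.success:
        raise RuntimeError(f"ODE oracle failed to converge: {sol.message}")
    return sol.y[:, -1]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_LOG_LO, _LOG_HI = math.log(1e-9), math.log(1e9)


@dataclass
class FitOptions:
    """Solver settings for :func:`fit_trace`.

    Parameters are optimized in log space, which enforces positivity and
    makes the step tolerance relative.  ``multistart`` extra starting points
    (log-spaced around the heuristic start) guard against local minima.
    """

    xtol: float = 1e-12
    ftol: float = 1e-14
    max_nfev: int = 2000
    multistart: int = 4
    weights: np.ndarray | None = None


def _heuristic_start(trace: AspirationTrace, f0: float, model: ModelKind) -> np.ndarray:
    """Data-driven initial parameter guess.

    eta0 from the late-time slope, k0 from the late-time linear intercept,
    k1 from the initial jump after removing the k0 contribution, eta1 from
    the decay timescale read off the detrended transient.
    """
    t, x = trace.times_s, trace.depths_m
    n = t.size
    tail = slice(max(n - max(n // 4, 4), 0), n)
    slope, intercept = np.polyfit(t[tail], x[tail], 1)
    slope = max(slope, f0 / 1e6)
    eta0 = f0 / slope
    k0 = f0 / max(intercept, f0 / 1e6)
    jump = max(x[0], f0 / 1e6)
    k1 = max(f0 / jump - k0, k0 * 1e-3)
    # timescale: time to cover ~63% of the detrended transient
    detr = x - slope * t
    span = detr[tail].mean() - detr[0]
    if span > 0:
        target = detr[0] + 0.632 * span
        idx = np.argmax(detr >= target)
        tau = t[idx] if idx > 0 else (t[-1] - t[0]) / 10.0
    else:
        tau = (t[-1] - t[0]) / 10.0
    eta1 = tau * (k0 * k1) / (k0 + k1)
    full = ViscoParams(k0=k0, k1=k1, eta1=eta1, eta0=eta0, k2=k1 / 10, eta2=eta1 * 10)
    return full.as_vector(model)


def _fit_from(theta0, t, x, model, f0, opts):
    w = np.ones_like(x) if opts.weights is None else np.asarray(opts.weights, float)

    def resid(theta):
        p = ViscoParams.from_vector(model, np.exp(theta))
        return w * (creep(t, model, p, f0) - x)

    theta0 = np.clip(np.log(theta0), _LOG_LO, _LOG_HI)
    return least_squares(
        resid,
        theta0,
        bounds=(_LOG_LO, _LOG_HI),
        xtol=opts.xtol,
        ftol=opts.ftol,
        gtol=None,
        max_nfev=opts.max_nfev,
        method="trf",
    )


def fit_trace(
    trace: AspirationTrace,
    protocol: PressureProtocol,
    model: ModelKind = ModelKind.MODIFIED_ZENER,
    options: FitOptions | None = None,
    starts: list | None = None,
) -> FitResult:
    """Least-squares fit of a creep model to an aspiration trace.

    Positivity of the parameters is enforced by optimizing in log space; the
    heuristic start is refined from up to ``options.multistart`` additional
    log-spaced starting points and the best converged solution is returned.
    ``starts`` may supply extra parameter vectors (used by
    :func:`compare_models` to warm-start richer models from nested fits).
    """
    model = ModelKind(model)
    opts = options or FitOptions()
    f0 = step_force(protocol)
    t, x = trace.times_s, trace.depths_m

    theta0 = _heuristic_start(trace, f0, model)
    start_list = [theta0]
    for i in range(opts.multistart):
        start_list.append(theta0 * 10.0 ** ((-1) ** i * (0.5 + i // 2)))
    if starts:
        start_list.extend(np.asarray(s, float) for s in starts)

    best = None
    for s in start_list:
        try:
            res = _fit_from(s, t, x, model, f0, opts)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"all fit starts failed for model {model.value}")

    params = ViscoParams.from_vector(model, np.exp(best.x))
    rms = float(np.sqrt(np.mean((creep(t, model, params, f0) - x) ** 2)))
    return FitResult(
        model=model,
        params=params,
        rms_residual_m=rms,
        converged=bool(best.status > 0),
        n_iter=int(best.nfev),
    )


def _embed_nested(model: ModelKind, fitted: dict) -> list:
    """Starting vectors for `model` that reproduce already-fitted nested models.

    A richer model can always emulate its nested special case (Kelvin–Voigt
    is the k1→∞ limit of Zener; Zener the η0→∞ limit of the modified Zener;
    a slow second arm emulates the series dashpot), so warm-starting from the
    nested solution guarantees the residual ordering up to solver tolerance.
    """
    starts = []
    big = 1e8
    if model is ModelKind.ZENER and ModelKind.KELVIN_VOIGT in fitted:
        p = fitted[ModelKind.KELVIN_VOIGT].params
        starts.append([p.k0, big, p.eta1])  # tau -> eta1/k0 as k1 -> inf
    if model is ModelKind.MODIFIED_ZENER and ModelKind.ZENER in fitted:
        p = fitted[ModelKind.ZENER].params
        starts.append([p.k0, p.k1, p.eta1, big])
    if model is ModelKind.FIVE_PARAM and ModelKind.MODIFIED_ZENER in fitted:
        p = fitted[ModelKind.MODIFIED_ZENER].params
        # slow arm with early-time slope F0/eta0: k2 = k0*eta2/eta0
        eta2 = 1000.0 * p.k0  # tau2 ≈ eta2/k0 = 1000 s >> trace duration
        k2 = p.k0 * eta2 / p.eta0
        starts.append([p.k0, p.k1, p.eta1, k2, eta2])
    return starts


def compare_models(
    trace: AspirationTrace,
    protocol: PressureProtocol,
    models: tuple = tuple(ModelKind),
    options: FitOptions | None = None,
) -> list[FitResult]:
    """Fit every candidate model and rank them by RMS residual (ascending).

    Models are fitted simplest-first and each richer model is warm-started
    from the solutions of the models nested within it, so the reported
    residuals respect model nesting up to solver tolerance.
    """
    order = [
        ModelKind.MAXWELL,
        ModelKind.KELVIN_VOIGT,
        ModelKind.ZENER,
        ModelKind.MODIFIED_ZENER,
        ModelKind.FIVE_PARAM,
    ]
    fitted: dict[ModelKind, FitResult] = {}
    for m in order:
        if m not in models:
            continue
        starts = [fitted[m].params.as_vector(m)] if m in fitted else []
        starts += _embed_nested(m, fitted)
        fitted[m] = fit_trace(trace, protocol, m, options, starts=starts)
    return sorted(fitted.values(), key=lambda r: r.rms_residual_m)
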