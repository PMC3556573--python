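"""Synthetic ¹³C turnover-curve generation.

Emulates the standard in vivo protocol used to benchmark flux estimation:
a 160-min substrate infusion sampled at 32 time points per measurable curve,
with additive Gaussian noise of known standard deviation (in concentration
units, μmol/g) on every sample.  The generator is the fixture source for the
whole test suite — there is no external dataset.

The default flux/pool configuration is a literature-plausible resting-brain
set for glucose infusion: vcyc = 0.32, n_vtca = 0.60, a_vtca = 0.10,
vana = 0.04, vdil_lac = 0.05, vdil_gln = 0.14 μmol/g/min, with pools
nGlu = 10.0, aGlu = 0.8, aGln = 3.7, Lac = 1.0 μmol/g and a step precursor
enrichment of 0.35.  Only the dilution fluxes and the astroglial TCA bound
are pinned by the benchmark protocol; the remainder are tunable configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .isotope_model import (
    FluxSet,
    LabelingStrategy,
    ModelVariant,
    PoolSizes,
    Strategy,
    diluted_precursor_fe,
    system_matrices,
    validate_fluxes,
)

__all__ = [
    "InputFunction",
    "Protocol",
    "TurnoverCurves",
    "make_input",
    "simulate_turnover",
    "add_noise",
    "default_fluxes",
    "default_pools",
    "default_protocol",
]

#: integration tolerances (solver contract for the stiff/general path)
RTOL = 1e-8
ATOL = 1e-10


@dataclass(frozen=True)
class InputFunction:
    """Precursor fractional-enrichment input vs. time.

    shape: "step" (plateau_fe for all t >= 0), "exp_rise"
    (plateau_fe·(1 − exp(−t/rise_time_constant))), or "table"
    (piecewise-linear interpolation of (times, values) knots).
    """

    shape: str = "step"
    plateau_fe: float = 0.35
    rise_time_constant: float = 5.0
    table: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("step", "exp_rise", "table"):
            raise ValueError(f"unknown input shape {self.shape!r}")
        if not 0.0 <= self.plateau_fe <= 1.0:
            raise ValueError(
                f"plateau_fe = {self.plateau_fe:g} outside [0, 1]"
            )
        if self.shape == "exp_rise" and self.rise_time_constant <= 0:
            raise ValueError("rise_time_constant must be > 0")
        if self.shape == "table":
            if self.table is None:
                raise ValueError("table shape requires knots")
            times, values = self.table
            if len(times) != len(values) or len(times) < 2:
                raise ValueError("table requires >= 2 (time, value) knots")
            if any(not 0.0 <= v <= 1.0 for v in values):
                raise ValueError("table enrichment values must lie in [0, 1]")


def make_input(spec: InputFunction) -> Callable[[float], float]:
    """Build the enrichment-of-time callable for an input specification.

    The returned function accepts scalars or arrays and maps into [0, 1].
    """
    if spec.shape == "step":
        plateau = spec.plateau_fe

        def fe(t):
            return np.where(np.asarray(t) >= 0, plateau, 0.0)[()]

    elif spec.shape == "exp_rise":
        plateau, tau = spec.plateau_fe, spec.rise_time_constant

        def fe(t):
            t = np.asarray(t, dtype=float)
            return (plateau * (1.0 - np.exp(-np.clip(t, 0, None) / tau)))[()]

    else:
        times = np.asarray(spec.table[0], dtype=float)
        values = np.asarray(spec.table[1], dtype=float)

        def fe(t):
            return np.interp(np.asarray(t, dtype=float), times, values)[()]

    return fe


@dataclass(frozen=True)
class Protocol:
    """Acquisition protocol for a synthetic infusion experiment."""

    duration: float = 160.0  # min
    n_points_per_curve: int = 32
    noise_sigma: float = 0.1  # μmol/g
    seed: int = 0
    observables: tuple[str, ...] = ("nGlu4", "aGln4")
    input_spec: InputFunction = field(default_factory=InputFunction)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_points_per_curve < 2:
            raise ValueError("need at least 2 points per curve")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_points_per_curve)


@dataclass(frozen=True)
class TurnoverCurves:
    """Time-gridded labeled-concentration curves per observable pool.

    ``values`` holds the working (possibly noisy) curves; ``noiseless`` the
    underlying model curves, retained so residual diagnostics stay exact.
    """

    time: np.ndarray
    values: Mapping[str, np.ndarray]
    noiseless: Mapping[str, np.ndarray]
    sigma: float = 0.0

    @property
    def observables(self) -> tuple[str, ...]:
        return tuple(self.values)

    @property
    def n_points(self) -> int:
        return len(self.time) * len(self.values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for obs in self.observables:
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.time,
                        "observable": obs,
                        "value_umol_g": self.values[obs],
                        "noiseless_umol_g": self.noiseless[obs],
                        "sigma": self.sigma,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TurnoverCurves":
        required = {"time_min", "observable", "value_umol_g"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"turnover CSV is missing columns: {sorted(missing)}")
        values, noiseless = {}, {}
        time = None
        for obs, grp in frame.groupby("observable", sort=False):
            grp = grp.sort_values("time_min")
            t = grp["time_min"].to_numpy(dtype=float)
            if time is None:
                time = t
            elif not np.array_equal(time, t):
                raise ValueError(f"observable {obs!r} is on a different time grid")
            values[obs] = grp["value_umol_g"].to_numpy(dtype=float)
            if "noiseless_umol_g" in grp:
                noiseless[obs] = grp["noiseless_umol_g"].to_numpy(dtype=float)
            else:
                noiseless[obs] = values[obs]
        sigma = float(frame["sigma"].iloc[0]) if "sigma" in frame else 0.0
        return cls(time=time, values=values, noiseless=noiseless, sigma=sigma)

    @classmethod
    def from_csv(cls, path) -> "TurnoverCurves":
        # round_trip parsing keeps write->read->write bit-identical
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


# ---------------------------------------------------------------------------
# reference configuration


def default_fluxes(**overrides) -> FluxSet:
    """Reference resting-brain flux set (μmol/g/min), see module docstring."""
    params = dict(
        vcyc=0.32, n_vtca=0.60, a_vtca=0.10, vana=0.04,
        vdil_gln=0.14, vdil_lac=0.05,
    )
    params.update(overrides)
    return validate_fluxes(FluxSet(**params))


def default_pools(**overrides) -> PoolSizes:
    """Reference pool sizes (μmol/g)."""
    params = dict(n_glu=10.0, a_glu=0.8, a_gln=3.7, n_gln=0.5, lac=1.0)
    params.update(overrides)
    return PoolSizes(**params)


def default_protocol(seed: int = 0, **overrides) -> Protocol:
    """Reference 160-min, 32-point, σ = 0.1 μmol/g glucose-infusion protocol."""
    params = dict(
        duration=160.0, n_points_per_curve=32, noise_sigma=0.1, seed=seed,
        observables=("nGlu4", "aGln4"), input_spec=InputFunction(),
    )
    params.update(overrides)
    return Protocol(**params)


# ---------------------------------------------------------------------------
# simulation


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a solution."""


def _effective_input(
    strategy: LabelingStrategy,
    fluxes: FluxSet,
    input_spec: InputFunction,
    k_feed: float | None,
):
    """Compose the raw input with the lactate-level dilution factor.

    The acetate route feeds astroglial acetyl-CoA directly, bypassing the
    lactate pool, so no lactate dilution applies there.
    """
    raw = make_input(input_spec)
    if strategy.name is Strategy.ACETATE_C2:
        return raw
    k = fluxes.n_vtca if k_feed is None else k_feed
    factor = diluted_precursor_fe(1.0, fluxes.vdil_lac, k)
    return lambda t: factor * raw(t)


def simulate_turnover(
    strategy: LabelingStrategy,
    fluxes: FluxSet,
    pools: PoolSizes,
    protocol: Protocol,
    *,
    k_feed: float | None = None,
    method: str = "auto",
    times: np.ndarray | None = None,
    fe_gln_feed: Callable[[float], float] | None = None,
    validate: bool = True,
) -> TurnoverCurves:
    """Solve the labeling kinetics and sample noiseless turnover curves.

    Parameters
    ----------
    method
        "auto" uses the exact linear-system propagator for step inputs and
        LSODA (rtol 1e-8, atol 1e-10) otherwise; "ivp" forces the numerical
        solver; "analytic" forces the propagator (step inputs only).
    times
        Optional explicit sampling grid (overrides the protocol grid).
    fe_gln_feed
        For the acetate strategy only: a forcing astroglial glutamine C4
        enrichment curve (mode A).  When omitted, the acetate strategy runs
        with a dynamic astroglial glutamine pool fed by the astroglial TCA
        cycle (mode B).
    """
    if validate:
        fluxes = validate_fluxes(fluxes)
    t_eval = protocol.time_grid if times is None else np.asarray(times, float)
    fe_in = _effective_input(strategy, fluxes, protocol.input_spec, k_feed)

    if strategy.name is Strategy.ACETATE_C2 and fe_gln_feed is not None:
        return _simulate_acetate_forced(
            fluxes, pools, protocol, t_eval, fe_gln_feed
        )

    A, b, keys = system_matrices(strategy, fluxes, pools)
    x0 = np.zeros(2)

    is_step = protocol.input_spec.shape == "step"
    if method == "analytic" and not is_step:
        raise ValueError("analytic propagation requires a step input")
    use_analytic = method == "analytic" or (method == "auto" and is_step)

    if use_analytic:
        x = _propagate_lti(A, b * float(fe_in(0.0)), t_eval, x0)
    elif method in ("auto", "ivp"):
        def rhs(t, x):
            return A @ x + b * fe_in(t)

        sol = solve_ivp(
            rhs, (0.0, float(t_eval[-1])), x0, t_eval=t_eval,
            method="LSODA", rtol=RTOL, atol=ATOL,
        )
        if not sol.success:
            raise IntegrationError(
                f"labeling ODE integration failed: {sol.message}"
            )
        x = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r}")

    curves = {keys[0]: x[:, 0], keys[1]: x[:, 1]}
    selected = {
        obs: curves[obs] for obs in protocol.observables if obs in curves
    }
    missing = set(protocol.observables) - set(selected)
    if missing:
        raise KeyError(
            f"protocol requests observables {sorted(missing)} that strategy "
            f"{strategy.name.value} does not produce (has {list(curves)})"
        )
    return TurnoverCurves(
        time=t_eval,
        values={k: v.copy() for k, v in selected.items()},
        noiseless=selected,
        sigma=0.0,
    )


def _simulate_acetate_forced(fluxes, pools, protocol, t_eval, fe_gln_feed):
    """Acetate mode A: neuronal Glu C4 driven by a forcing Gln C4 curve."""
    from .isotope_model import rhs_acetate_c4

    def rhs(t, x):
        d = rhs_acetate_c4(
            {"nGlu4": x[0]}, fluxes, pools, fe_gln_feed=float(fe_gln_feed(t))
        )
        return [d["nGlu4"]]

    sol = solve_ivp(
        rhs, (0.0, float(t_eval[-1])), [0.0], t_eval=t_eval,
        method="LSODA", rtol=RTOL, atol=ATOL,
    )
    if not sol.success:
        raise IntegrationError(f"labeling ODE integration failed: {sol.message}")
    curves = {"nGlu4": sol.y[0]}
    feed = np.asarray([float(fe_gln_feed(t)) for t in t_eval]) * pools.a_gln
    curves["aGln4"] = feed
    selected = {o: curves[o] for o in protocol.observables if o in curves}
    missing = set(protocol.observables) - set(selected)
    if missing:
        raise KeyError(f"unavailable observables for forced acetate run: {sorted(missing)}")
    return TurnoverCurves(
        time=t_eval,
        values={k: v.copy() for k, v in selected.items()},
        noiseless=selected,
        sigma=0.0,
    )


def _propagate_lti(A, b, times, x0):
    """Exact solution of x' = A x + b (constant b) at the given times."""
    w, V = np.linalg.eig(A)
    xp = -np.linalg.solve(A, b)  # particular (steady-state) solution
    c = np.linalg.solve(V, x0 - xp)
    E = np.exp(np.multiply.outer(np.asarray(times, float), w))
    return (np.real((E * c) @ V.T) + xp)


def add_noise(
    curves: TurnoverCurves, sigma: float, seed: int | np.random.Generator
) -> TurnoverCurves:
    """Add i.i.d. Gaussian noise N(0, σ²) to every sample of every curve.

    Noise is applied to labeled concentrations (μmol/g).  The noiseless
    curves are carried along unchanged; the operation is deterministic for a
    fixed seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    noisy = {
        obs: vals + rng.normal(0.0, sigma, size=vals.shape)
        for obs, vals in curves.noiseless.items()
    }
    if sigma == 0:
        noisy = {obs: vals.copy() for obs, vals in curves.noiseless.items()}
    return TurnoverCurves(
        time=curves.time, values=noisy, noiseless=curves.noiseless, sigma=sigma
    )
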