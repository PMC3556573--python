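"""Two-compartment (neuron/astroglia) model of ¹³C label flow through the
glutamate–glutamine cycle.

The model tracks labeled concentrations (μmol/g) of the measurable carbon
positions — neuronal glutamate C4/C3 and astroglial glutamine C4/C3 — during
infusion of a ¹³C-labeled substrate.  Label enters via pyruvate/lactate (or
acetate), passes through the neuronal and astroglial TCA cycles, and is
exchanged between compartments by the glutamate–glutamine cycling flux
``vcyc``.  Two small pools, astroglial glutamate and neuronal glutamine, are
treated algebraically: they are assumed to reach isotopic steady state
instantaneously with the fluxes passing through them (the standard small-pool
approximation), so the dynamic state is two-dimensional per labeling strategy.

Fractional enrichments (labeled concentration / total pool size) are derived
quantities; the state variables themselves are labeled concentrations, which
is what an MRS experiment measures and what the noise level σ refers to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

__all__ = [
    "FluxValidationError",
    "MassBalanceError",
    "UndefinedStateError",
    "SmallPoolWarning",
    "FluxSet",
    "PoolSizes",
    "Strategy",
    "ModelVariant",
    "LabelingStrategy",
    "EnrichmentState",
    "validate_fluxes",
    "astroglial_glu_fe",
    "diluted_precursor_fe",
    "rhs_full_glc",
    "rhs_simplified_glc",
    "rhs_glc2_c3",
    "rhs_acetate_c4",
    "system_matrices",
]


class FluxValidationError(ValueError):
    """A flux value violates its domain constraint (e.g. negative)."""


class MassBalanceError(ValueError):
    """A flux configuration violates a steady-state mass balance."""


class UndefinedStateError(ValueError):
    """An algebraic pool state is undefined (zero total throughput)."""


class SmallPoolWarning(UserWarning):
    """The small-pool approximation is questionable for these pool sizes."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FluxSet:
    """Metabolic fluxes of the two-compartment model, in μmol/g/min.

    Attributes
    ----------
    vcyc : glutamate–glutamine neurotransmitter cycling flux.
    n_vtca : neuronal TCA cycle flux.
    a_vtca : astroglial TCA cycle flux.
    vana : astroglial anaplerotic flux (pyruvate carboxylase).
    vgln : total glutamine synthesis rate; vgln = vcyc + vana at steady state.
    vefflux : net glutamine efflux to blood; vefflux = vana at steady state.
    vdil_gln : lumped glutamine-level isotopic dilution flux.
    vdil_lac : lumped lactate/pyruvate-level isotopic dilution flux.
    """

    vcyc: float
    n_vtca: float
    a_vtca: float
    vana: float = 0.0
    vgln: float = None  # type: ignore[assignment]
    vefflux: float = None  # type: ignore[assignment]
    vdil_gln: float = 0.0
    vdil_lac: float = 0.0

    def replace(self, **kwargs) -> "FluxSet":
        """Return a copy with the given fields replaced and balances refilled."""
        new = replace(self, **kwargs)
        vgln = new.vgln if "vgln" in kwargs else None
        vefflux = new.vefflux if "vefflux" in kwargs else None
        return validate_fluxes(replace(new, vgln=vgln, vefflux=vefflux))


@dataclass(frozen=True)
class PoolSizes:
    """Total (labeled + unlabeled) metabolite concentrations, μmol/g.

    ``a_glu`` must be much smaller than ``a_gln`` for the small-pool
    treatment of astroglial glutamate to be defensible; the validator warns
    when a_glu/a_gln exceeds 0.2.
    """

    n_glu: float
    a_glu: float
    a_gln: float
    n_gln: float = 0.5
    lac: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_glu", "a_glu", "a_gln", "n_gln", "lac"):
            if not getattr(self, name) > 0:
                raise FluxValidationError(f"pool size {name!r} must be > 0")
        if self.a_glu / self.a_gln > 0.2:
            warnings.warn(
                "astroglial glutamate pool is not small relative to glutamine "
                f"(a_glu/a_gln = {self.a_glu / self.a_gln:.2f} > 0.2); the "
                "small-pool approximation may be inaccurate",
                SmallPoolWarning,
                stacklevel=2,
            )


class Strategy(str, Enum):
    """Labeling strategy: which substrate is infused and which carbon
    positions carry the signal."""

    #: [1-¹³C]/[1,6-¹³C₂] glucose → neuronal Glu C4 → astroglial Gln C4
    GLC_C1 = "GLC_C1"
    #: [2-¹³C]/[2,5-¹³C₂] glucose via anaplerosis → Gln C3 → Glu C3
    GLC_C2_VIA_PC = "GLC_C2_VIA_PC"
    #: [2-¹³C] acetate → astroglial Gln C4 → neuronal Glu C4
    ACETATE_C2 = "ACETATE_C2"


class ModelVariant(str, Enum):
    FULL = "FULL"
    SIMPLIFIED = "SIMPLIFIED"


@dataclass(frozen=True)
class LabelingStrategy:
    name: Strategy = Strategy.GLC_C1
    model_variant: ModelVariant = ModelVariant.FULL

    def __post_init__(self) -> None:
        name = Strategy(self.name)
        variant = ModelVariant(self.model_variant)
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "model_variant", variant)
        if name is not Strategy.GLC_C1 and variant is ModelVariant.FULL:
            raise FluxValidationError(
                f"strategy {name.value} is defined only for the SIMPLIFIED "
                "model variant"
            )

    @property
    def observables(self) -> tuple[str, str]:
        """Pool-position labels of the two measurable curves."""
        if self.name is Strategy.GLC_C2_VIA_PC:
            return ("nGlu3", "aGln3")
        return ("nGlu4", "aGln4")


@dataclass(frozen=True)
class EnrichmentState:
    """Labeled concentrations (μmol/g) of the dynamic pools at one instant.

    Keys are pool-position labels: ``nGlu4``, ``aGln4``, ``nGlu3``, ``aGln3``.
    """

    labeled_conc: Mapping[str, float]
    time: float = 0.0

    def fe(self, key: str, pools: PoolSizes) -> float:
        """Fractional enrichment of one pool position, in [0, 1]."""
        return self.labeled_conc[key] / _pool_of(key, pools)

    def validate(self, pools: PoolSizes) -> "EnrichmentState":
        for key, conc in self.labeled_conc.items():
            total = _pool_of(key, pools)
            if not (0.0 <= conc <= total):
                raise FluxValidationError(
                    f"labeled concentration of {key} ({conc:g} μmol/g) outside "
                    f"[0, {total:g}]"
                )
        return self


_POOL_FIELD = {"nGlu": "n_glu", "aGlu": "a_glu", "aGln": "a_gln", "nGln": "n_gln"}


def _pool_of(key: str, pools: PoolSizes) -> float:
    base = key.rstrip("0123456789")
    try:
        return getattr(pools, _POOL_FIELD[base])
    except KeyError:  # pragma: no cover
        raise KeyError(f"unknown pool-position label {key!r}") from None


def _require(state: Mapping[str, float], *keys: str) -> None:
    missing = [k for k in keys if k not in state]
    if missing:
        raise KeyError(f"state is missing required labeled pools: {missing}")


# ---------------------------------------------------------------------------
# flux validation


def validate_fluxes(fluxes: FluxSet) -> FluxSet:
    """Complete and validate a flux set against the steady-state balances.

    ``vgln`` and ``vefflux`` may be omitted (None): they are then filled from
    the mass balances vgln = vcyc + vana and vefflux = vana.  Raises
    :class:`FluxValidationError` for negative fluxes, and
    :class:`MassBalanceError` if a balance is violated or a_vtca < vana
    (the astroglial TCA cycle must at least carry the anaplerotic inflow).
    """
    vgln = fluxes.vgln if fluxes.vgln is not None else fluxes.vcyc + fluxes.vana
    vefflux = fluxes.vefflux if fluxes.vefflux is not None else fluxes.vana
    out = replace(fluxes, vgln=vgln, vefflux=vefflux)

    for name in ("vcyc", "n_vtca", "a_vtca", "vana", "vgln", "vefflux",
                 "vdil_gln", "vdil_lac"):
        value = getattr(out, name)
        if value < 0:
            raise FluxValidationError(f"negative flux: {name} = {value:g}")
    tol = 1e-9
    if abs(out.vgln - (out.vcyc + out.vana)) > tol:
        raise MassBalanceError(
            f"vgln ({out.vgln:g}) != vcyc + vana ({out.vcyc + out.vana:g})"
        )
    if abs(out.vefflux - out.vana) > tol:
        raise MassBalanceError(
            f"vefflux ({out.vefflux:g}) != vana ({out.vana:g})"
        )
    if out.a_vtca < out.vana - tol:
        raise MassBalanceError(
            f"a_vtca ({out.a_vtca:g}) < vana ({out.vana:g}): astroglial TCA "
            "flux cannot be smaller than the anaplerotic flux"
        )
    return out


# ---------------------------------------------------------------------------
# algebraic small pools and precursor dilution


def astroglial_glu_fe(fluxes: FluxSet, fe_lac: float, fe_nglu4: float) -> float:
    """Small-pool steady-state fractional enrichment of astroglial Glu C4.

    Setting the astroglial glutamate balance to zero gives

        fe = (a_vtca·fe_lac + vcyc·fe_nglu4) / (a_vtca + vcyc)

    since the outgoing terms (vcyc + vana) + (a_vtca − vana) sum to
    vcyc + a_vtca.  Note the anaplerotic flux cancels.
    """
    denom = fluxes.a_vtca + fluxes.vcyc
    if denom <= 0:
        raise UndefinedStateError(
            "astroglial glutamate enrichment undefined: a_vtca + vcyc = 0"
        )
    return (fluxes.a_vtca * fe_lac + fluxes.vcyc * fe_nglu4) / denom


def diluted_precursor_fe(
    fe_input: float, vdil_lac: float, k_feed: float
) -> float:
    """Lactate/pyruvate enrichment after lactate-level isotopic dilution.

    The lumped dilution flux ``vdil_lac`` exchanges the precursor pool with
    unlabeled carbon sources; at the lactate pool's fast steady state the
    enrichment reaching pyruvate dehydrogenase is scaled by
    k_feed / (k_feed + vdil_lac), where ``k_feed`` is the label-feeding rate
    (defaulting to the neuronal TCA flux in the simulator).
    """
    if k_feed <= 0:
        raise UndefinedStateError("label-feeding rate k_feed must be > 0")
    return fe_input * k_feed / (k_feed + vdil_lac)


# ---------------------------------------------------------------------------
# right-hand sides (labeled-concentration derivatives, μmol/g/min)


def rhs_full_glc(
    state: Mapping[str, float],
    fluxes: FluxSet,
    pools: PoolSizes,
    fe_lac: float,
) -> dict[str, float]:
    """Full-model derivatives for [1-¹³C]/[1,6-¹³C₂] glucose infusion.

    Dynamic states: astroglial Gln C4 and neuronal Glu C4.  Astroglial Glu C4
    is algebraic (see :func:`astroglial_glu_fe`) and neuronal Gln C4 tracks
    astroglial Gln C4 enrichment (its own small-pool balance).
    """
    _require(state, "aGln4", "nGlu4")
    fe_agln = state["aGln4"] / pools.a_gln
    fe_nglu = state["nGlu4"] / pools.n_glu
    fe_aglu = astroglial_glu_fe(fluxes, fe_lac, fe_nglu)
    fe_ngln = fe_agln  # neuronal glutamine small-pool steady state

    d_agln = (
        fluxes.vgln * fe_aglu
        - fluxes.vcyc * fe_agln
        - (fluxes.vefflux + fluxes.vdil_gln) * fe_agln
    )
    d_nglu = (
        fluxes.n_vtca * fe_lac
        + fluxes.vcyc * fe_ngln
        - (fluxes.vcyc + fluxes.n_vtca) * fe_nglu
    )
    return {"aGln4": d_agln, "nGlu4": d_nglu}


def rhs_simplified_glc(
    state: Mapping[str, float],
    fluxes: FluxSet,
    pools: PoolSizes,
    fe_lac: float,
) -> dict[str, float]:
    """Simplified-model derivatives for glucose infusion (C4 pathway).

    Astroglial glutamine exchanges directly with neuronal glutamate; the
    astroglial TCA/anaplerotic feed and the glutamine efflux term are dropped.
    """
    _require(state, "aGln4", "nGlu4")
    fe_agln = state["aGln4"] / pools.a_gln
    fe_nglu = state["nGlu4"] / pools.n_glu

    d_agln = (
        fluxes.vcyc * fe_nglu
        - fluxes.vcyc * fe_agln
        - fluxes.vdil_gln * fe_agln
    )
    d_nglu = (
        fluxes.n_vtca * fe_lac
        + fluxes.vcyc * fe_agln
        - (fluxes.vcyc + fluxes.n_vtca) * fe_nglu
    )
    return {"aGln4": d_agln, "nGlu4": d_nglu}


def rhs_glc2_c3(
    state: Mapping[str, float],
    fluxes: FluxSet,
    pools: PoolSizes,
    fe_lac2: float,
) -> dict[str, float]:
    """Simplified-model derivatives for [2-¹³C]/[2,5-¹³C₂] glucose, C3 route.

    Label reaches glutamine C3 through the astroglial anaplerotic pathway
    (source term vana·fe_lac2) and is exchanged with neuronal glutamate C3 by
    cycling.  Half of the neuronal glutamate C3 label is lost per TCA turn to
    C2 by symmetric scrambling at fumarate, hence the 0.5 factor.
    """
    _require(state, "aGln3", "nGlu3")
    fe_agln = state["aGln3"] / pools.a_gln
    fe_nglu = state["nGlu3"] / pools.n_glu

    d_nglu = (
        -0.5 * fluxes.n_vtca * fe_nglu
        + fluxes.vcyc * (fe_agln - fe_nglu)
    )
    d_agln = (
        fluxes.vana * fe_lac2
        + fluxes.vcyc * (fe_nglu - fe_agln)
        - fluxes.vdil_gln * fe_agln
    )
    return {"aGln3": d_agln, "nGlu3": d_nglu}


def rhs_acetate_c4(
    state: Mapping[str, float],
    fluxes: FluxSet,
    pools: PoolSizes,
    fe_gln_feed: float | None = None,
    *,
    mode: str = "A",
    fe_acetyl: float | None = None,
) -> dict[str, float]:
    """Simplified-model derivatives for [2-¹³C] acetate infusion.

    Label flows astroglia → neuron: glutamine C4 feeds neuronal glutamate C4
    through the cycle while the neuronal TCA cycle clears it.

    mode "A" (default): the astroglial Gln C4 enrichment is an externally
    supplied forcing value ``fe_gln_feed``; only the neuronal Glu C4
    derivative is returned.

    mode "B": astroglial Gln C4 is a dynamic state fed by the astroglial TCA
    cycle at acetyl-CoA enrichment ``fe_acetyl``, with total outflow
    a_vtca + vcyc + vdil_gln keeping the enrichment bounded.
    """
    _require(state, "nGlu4")
    fe_nglu = state["nGlu4"] / pools.n_glu

    if mode == "A":
        if fe_gln_feed is None:
            raise UndefinedStateError(
                "acetate mode A requires a forcing glutamine C4 enrichment "
                "(fe_gln_feed)"
            )
        fe_agln = fe_gln_feed
        d_nglu = (
            -fluxes.n_vtca * fe_nglu + fluxes.vcyc * (fe_agln - fe_nglu)
        )
        return {"nGlu4": d_nglu}

    if mode == "B":
        if fe_acetyl is None:
            raise UndefinedStateError(
                "acetate mode B requires the acetyl-CoA enrichment fe_acetyl"
            )
        _require(state, "aGln4")
        fe_agln = state["aGln4"] / pools.a_gln
        d_nglu = (
            -fluxes.n_vtca * fe_nglu + fluxes.vcyc * (fe_agln - fe_nglu)
        )
        d_agln = (
            fluxes.a_vtca * fe_acetyl
            + fluxes.vcyc * fe_nglu
            - (fluxes.a_vtca + fluxes.vcyc + fluxes.vdil_gln) * fe_agln
        )
        return {"nGlu4": d_nglu, "aGln4": d_agln}

    raise ValueError(f"unknown acetate mode {mode!r} (expected 'A' or 'B')")


# ---------------------------------------------------------------------------
# linear-system form (used by the simulator's exact propagator)


def system_matrices(
    strategy: LabelingStrategy,
    fluxes: FluxSet,
    pools: PoolSizes,
    *,
    acetate_mode: str = "B",
):
    """Return (A, b, state_keys) such that x' = A x + b·fe_in(t).

    x holds the labeled concentrations of ``state_keys`` in order
    (astroglial glutamine first, neuronal glutamate second) and fe_in is the
    already-diluted precursor enrichment (lactate C3, lactate C2, or
    acetyl-CoA C2 depending on the strategy).  The labeling kinetics are
    linear in the labeled concentrations, so this is exact.
    """
    import numpy as np

    vc, nv, av = fluxes.vcyc, fluxes.n_vtca, fluxes.a_vtca
    agln, nglu = pools.a_gln, pools.n_glu

    if strategy.name is Strategy.GLC_C1:
        keys = ("aGln4", "nGlu4")
        if strategy.model_variant is ModelVariant.FULL:
            # astroglial Glu algebraic: fe = (av·L + vc·u/nglu)/(av+vc)
            mix = fluxes.vgln / (av + vc)
            a11 = -(vc + fluxes.vefflux + fluxes.vdil_gln) / agln
            a12 = mix * vc / nglu
            b1 = mix * av
        else:
            a11 = -(vc + fluxes.vdil_gln) / agln
            a12 = vc / nglu
            b1 = 0.0
        a21 = vc / agln
        a22 = -(vc + nv) / nglu
        b2 = nv
    elif strategy.name is Strategy.GLC_C2_VIA_PC:
        keys = ("aGln3", "nGlu3")
        a11 = -(vc + fluxes.vdil_gln) / agln
        a12 = vc / nglu
        b1 = fluxes.vana
        a21 = vc / agln
        a22 = -(0.5 * nv + vc) / nglu
        b2 = 0.0
    elif strategy.name is Strategy.ACETATE_C2:
        if acetate_mode != "B":
            raise UndefinedStateError(
                "only acetate mode B has an autonomous linear form; mode A "
                "is integrated against its forcing curve"
            )
        keys = ("aGln4", "nGlu4")
        a11 = -(av + vc + fluxes.vdil_gln) / agln
        a12 = vc / nglu
        b1 = av
        a21 = vc / agln
        a22 = -(vc + nv) / nglu
        b2 = 0.0
    else:  # pragma: no cover
        raise ValueError(strategy)

    A = np.array([[a11, a12], [a21, a22]], dtype=float)
    b = np.array([b1, b2], dtype=float)
    return A, b, keys
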