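"""Closed-form isotopic steady-state relations.

At metabolic and isotopic steady state the labeling balances reduce to
algebraic relations between measured fractional enrichments and flux ratios.
These are the relations practitioners use to read flux ratios directly off
steady-state spectra, without fitting full turnover curves:

* glucose C4 route: fe(Gln C4) = fe(Glu C4) · vcyc / (vcyc + vdil_gln) —
  the glutamine dilution flux depresses glutamine C4 below glutamate C4.
* glucose C2→C3 anaplerotic route:
  vcyc/n_vtca = 0.5 · fe(Glu C3) / (fe(Gln C3) − fe(Glu C3)).
* acetate C4 route:
  vcyc/n_vtca = fe(Glu C4) / (fe(Gln C4) − fe(Glu C4)).

The C3 and acetate ratios come from balances on the *neuronal* signal, so
the astroglial glutamine dilution flux does not enter them at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .isotope_model import UndefinedStateError

__all__ = [
    "InfeasibleEnrichmentError",
    "SteadyEnrichments",
    "gln4_fe_steady",
    "vcyc_over_nvtca_from_c3",
    "vdil_over_vcyc_from_c3",
    "vcyc_over_nvtca_from_acetate",
]


class InfeasibleEnrichmentError(ValueError):
    """Enrichment values incompatible with a physical steady state."""


@dataclass(frozen=True)
class SteadyEnrichments:
    """Steady-state fractional enrichments (each in [0, 1] when present)."""

    fe_nglu4: float | None = None
    fe_agln4: float | None = None
    fe_nglu3: float | None = None
    fe_agln3: float | None = None
    fe_lac2: float | None = None

    def __post_init__(self) -> None:
        for name in ("fe_nglu4", "fe_agln4", "fe_nglu3", "fe_agln3", "fe_lac2"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise InfeasibleEnrichmentError(
                    f"{name} = {value:g} outside [0, 1]"
                )


def gln4_fe_steady(vcyc: float, vdil_gln: float, fe_nglu4: float) -> float:
    """Steady-state glutamine C4 enrichment under glucose infusion.

    Returns fe_nglu4 · vcyc / (vcyc + vdil_gln).  With vdil_gln = 0 the
    glutamine and glutamate C4 enrichments coincide; any positive dilution
    holds glutamine C4 strictly below glutamate C4.
    """
    denom = vcyc + vdil_gln
    if denom <= 0:
        raise UndefinedStateError(
            "glutamine C4 steady state undefined: vcyc + vdil_gln = 0"
        )
    return fe_nglu4 * vcyc / denom


def vcyc_over_nvtca_from_c3(fe_nglu3: float, fe_agln3: float) -> float:
    """Cycle-to-neuronal-TCA flux ratio from steady-state C3 enrichments.

    vcyc/n_vtca = 0.5 · fe_nglu3 / (fe_agln3 − fe_nglu3).  The 0.5 factor
    reflects symmetric label scrambling at the fumarate step.  Requires
    fe_agln3 > fe_nglu3 (glutamine C3 is upstream of glutamate C3 on the
    anaplerotic route); anything else is infeasible.
    """
    if fe_nglu3 == 0:
        return 0.0
    if not fe_agln3 > fe_nglu3 > 0:
        raise InfeasibleEnrichmentError(
            "steady state requires fe_agln3 > fe_nglu3 > 0 "
            f"(got fe_agln3 = {fe_agln3:g}, fe_nglu3 = {fe_nglu3:g})"
        )
    return 0.5 * fe_nglu3 / (fe_agln3 - fe_nglu3)


def vdil_over_vcyc_from_c3(
    vana_over_vcyc: float,
    fe_lac2: float,
    fe_nglu3: float,
    fe_agln3: float,
) -> float:
    """Glutamine-dilution-to-cycle flux ratio from steady-state C3 data.

    vdil_gln/vcyc = (vana/vcyc)·(fe_lac2/fe_agln3) + fe_nglu3/fe_agln3 − 1.

    The anaplerotic fraction vana/vcyc must be supplied externally.  A
    negative result implies mutually inconsistent inputs and is returned
    with a warning rather than raised, since measurement noise can push a
    near-zero ratio below zero.
    """
    if fe_agln3 <= 0:
        raise UndefinedStateError("fe_agln3 must be > 0")
    ratio = vana_over_vcyc * (fe_lac2 / fe_agln3) + fe_nglu3 / fe_agln3 - 1.0
    if ratio < -1e-9:  # tolerate floating-point zero
        warnings.warn(
            f"vdil_gln/vcyc = {ratio:.4g} < 0: the supplied enrichments and "
            "vana/vcyc are not mutually consistent with this steady state",
            UserWarning,
            stacklevel=2,
        )
    return ratio


def vcyc_over_nvtca_from_acetate(fe_nglu4: float, fe_agln4: float) -> float:
    """Cycle-to-neuronal-TCA flux ratio from steady-state acetate C4 data.

    vcyc/n_vtca = fe_nglu4 / (fe_agln4 − fe_nglu4).  Requires
    fe_agln4 > fe_nglu4 (glutamine is upstream of glutamate under acetate).
    """
    if fe_nglu4 == 0:
        return 0.0
    if not fe_agln4 > fe_nglu4 > 0:
        raise InfeasibleEnrichmentError(
            "steady state requires fe_agln4 > fe_nglu4 > 0 "
            f"(got fe_agln4 = {fe_agln4:g}, fe_nglu4 = {fe_nglu4:g})"
        )
    return fe_nglu4 / (fe_agln4 - fe_nglu4)
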