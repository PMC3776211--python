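"""Population doubling time, G1 duration and rapamycin-response ratios.

PHA-stimulated lymphocytes grow roughly exponentially over the 72 h culture,
so the population doubling time (PDT) follows from seed and harvest cell
numbers.  The G1 duration is apportioned from the PDT by the G0/G1 occupancy
among cycling cells (proportional-occupancy convention; the exponential
age-distribution correction is available as an option).  The rapamycin
response of a subject is the treated/untreated lengthening of PDT and G1
time; a blunted response is the Alzheimer phenotype the diagnostic exploits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .cellcycle import PhaseFractions

__all__ = [
    "GrowthKinetics",
    "RapaResponse",
    "population_doubling_time",
    "g1_duration",
    "rapamycin_response",
    "DEFAULT_RATIO_CAP",
]

#: Cap applied to response ratios when the treated culture stopped growing.
DEFAULT_RATIO_CAP = 10.0


@dataclass
class GrowthKinetics:
    """Growth summary of one culture (one subject x one condition)."""

    n_seed: float
    n_end: float
    elapsed: float  # hours
    fractions: PhaseFractions | None = None
    pdt: float = field(init=False)
    g1_time: float | None = field(init=False, default=None)
    no_growth: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.pdt = population_doubling_time(self.n_seed, self.n_end, self.elapsed)
        self.no_growth = math.isinf(self.pdt)
        if self.fractions is not None and not self.no_growth:
            self.g1_time = g1_duration(self.pdt, self.fractions)


@dataclass(frozen=True)
class RapaResponse:
    """Treated/untreated response ratios for one subject."""

    pdt_baseline: float
    pdt_ratio: float
    g1_ratio: float
    apoptotic_shift: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pdt_ratio <= 0 or self.g1_ratio <= 0:
            raise ValueError("response ratios must be positive")


def population_doubling_time(n_seed: float, n_end: float, elapsed: float) -> float:
    """PDT under exponential growth: ``elapsed * ln 2 / ln(n_end / n_seed)``.

    A culture that did not grow (``n_end <= n_seed``) has no finite doubling
    time and returns ``+inf`` (callers should treat this as a no-growth flag).
    """
    if n_seed <= 0 or elapsed <= 0:
        raise ValueError("n_seed and elapsed must be positive")
    if n_end <= 0:
        raise ValueError("n_end must be positive")
    if n_end <= n_seed:
        return math.inf
    return elapsed * math.log(2.0) / math.log(n_end / n_seed)


def g1_duration(pdt: float, fractions: PhaseFractions, *,
                age_corrected: bool = False) -> float:
    """G1 duration from PDT and the G0/G1 occupancy among cycling cells.

    The sub-G1 (apoptotic) fraction is excluded from the denominator, so only
    cycling occupancy matters:  ``occ = g0g1 / (g0g1 + s + g2m)``.

    With ``age_corrected=False`` (default) the phase time is proportional
    occupancy: ``g1_time = pdt * occ``.  With ``age_corrected=True`` the
    exponential age-distribution correction is applied: in steady exponential
    growth the cell-age density is ``2^(1 - a/pdt) * ln2 / pdt``, so an
    initial phase holding occupancy ``occ`` lasts
    ``g1_time = -pdt * log2(1 - occ/2)``.
    """
    if not math.isfinite(pdt) or pdt <= 0:
        raise ValueError("pdt must be finite and positive")
    cycling = fractions.g0g1 + fractions.s + fractions.g2m
    if cycling <= 0:
        raise ValueError("no cycling cells: g0g1 + s + g2m is zero")
    occ = fractions.g0g1 / cycling
    if age_corrected:
        return -pdt * math.log2(1.0 - occ / 2.0)
    return pdt * occ


def rapamycin_response(untreated: GrowthKinetics, treated: GrowthKinetics, *,
                       ratio_cap: float = DEFAULT_RATIO_CAP) -> RapaResponse:
    """Relative rapamycin response: treated/untreated PDT and G1-time ratios.

    A treated culture that stopped growing while the untreated one grew gets
    its ratios capped at ``ratio_cap`` (flagged) so downstream logistic
    fitting stays finite.  A non-proliferating *untreated* culture leaves the
    response undefined and raises.
    """
    if untreated.no_growth:
        raise ValueError("baseline non-proliferative: untreated PDT is infinite, "
                         "response undefined")
    flags: list[str] = []
    if treated.no_growth:
        pdt_ratio = g1_ratio = ratio_cap
        flags.append("treated_no_growth_ratio_capped")
    else:
        pdt_ratio = treated.pdt / untreated.pdt
        if untreated.g1_time is not None and treated.g1_time is not None:
            g1_ratio = treated.g1_time / untreated.g1_time
        else:
            g1_ratio = pdt_ratio
            flags.append("g1_ratio_fallback_to_pdt_ratio")
        if pdt_ratio > ratio_cap:
            pdt_ratio = ratio_cap
            flags.append("pdt_ratio_capped")
        if g1_ratio > ratio_cap:
            g1_ratio = ratio_cap
            flags.append("g1_ratio_capped")
    shift = 0.0
    if untreated.fractions is not None and treated.fractions is not None:
        shift = treated.fractions.sub_g1 - untreated.fractions.sub_g1
    return RapaResponse(pdt_baseline=untreated.pdt, pdt_ratio=pdt_ratio,
                        g1_ratio=g1_ratio, apoptotic_shift=shift,
                        flags=tuple(flags))
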