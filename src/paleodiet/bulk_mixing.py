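"""Two-component marine/terrestrial mixing on bulk collagen delta-13C.

Collagen delta-13C of a consumer eating a binary marine/terrestrial diet is
modelled as a linear mixture of a terrestrial and a marine end member, both
expressed on the collagen scale.  Plant-tissue end members are shifted by the
diet-to-collagen 13C enrichment (default +5 permil) before mixing.  End-member
uncertainty enters only the propagated SD, not the point estimate, and
fractions outside [0, 1] are returned and flagged infeasible rather than
silently clamped: an infeasible fraction is diagnostic evidence against the
chosen end members (it violates isotope mass balance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from paleodiet._mixing import two_source_fraction, two_source_sd
from paleodiet.data_model import SampleRecord, ValidationError

#: Conventional 13C enrichment of consumer collagen over plant diet (permil).
DIET_TO_COLLAGEN_OFFSET = 5.0

BASES = ("collagen", "plant_tissue")


@dataclass(frozen=True)
class EndMember:
    """A (mean, sd) isotope end member on a stated tissue basis."""

    mean: float
    sd: float = 0.0
    basis: str = "collagen"
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"end member sd must be >= 0, got {self.sd!r}")
        if self.basis not in BASES:
            raise ValidationError(f"unknown end member basis {self.basis!r}")


#: Archaeological totora reed, the only measured terrestrial sample that
#: satisfies isotope mass balance for all known humans in the study region.
TERRESTRIAL_TOTORA = EndMember(-26.6, 2.0, "plant_tissue", "archaeological totora reed")
#: Literature global C3 value (rejected scenario: yields infeasible fractions).
TERRESTRIAL_LITERATURE = EndMember(-20.0, 1.0, "collagen", "global C3 literature")
#: Uncorrected mean of archaeological fish and marine mammal collagen.
MARINE_COLLAGEN = EndMember(-12.4, 1.5, "collagen", "fish + marine mammal collagen")


@dataclass(frozen=True)
class MixResult:
    """Marine fraction with propagated SD and a mass-balance feasibility flag."""

    f_marine: float
    sd: float
    feasible: bool


def to_collagen_basis(em: EndMember, offset: float = DIET_TO_COLLAGEN_OFFSET) -> EndMember:
    """Shift a plant-tissue end member onto the collagen scale.

    The mean moves by ``+offset`` (diet-to-collagen 13C enrichment); the SD is
    unchanged because the offset is treated as a constant.
    """
    if em.basis != "plant_tissue":
        raise ValidationError(f"end member {em.label!r} is already on collagen basis")
    return replace(em, mean=em.mean + offset, basis="collagen")


def _check_collagen(terr: EndMember, mar: EndMember) -> None:
    if terr.basis != "collagen" or mar.basis != "collagen":
        raise ValidationError("both end members must be on collagen basis")
    if terr.mean == mar.mean:
        raise ValidationError("degenerate mixing model: equal end-member means")


def f_marine_bulk(d13c: float, terr: EndMember, mar: EndMember) -> MixResult:
    """Marine fraction from bulk collagen delta-13C by linear two-source mixing."""
    _check_collagen(terr, mar)
    f = two_source_fraction(d13c, terr.mean, mar.mean)
    sd = two_source_sd(0.0, terr.sd, mar.sd, f, mar.mean - terr.mean)
    return MixResult(f_marine=f, sd=sd, feasible=0.0 <= f <= 1.0)


def f_marine_bulk_sd(
    d13c: float, d13c_sd: float, terr: EndMember, mar: EndMember
) -> float:
    """First-order propagated SD of the bulk marine fraction.

    ``sqrt(sd_mix^2 + f^2 sd_mar^2 + (1 - f)^2 sd_terr^2) / |mar - terr|``.
    """
    _check_collagen(terr, mar)
    if d13c_sd < 0:
        raise ValidationError(f"negative measurement sd {d13c_sd!r}")
    f = two_source_fraction(d13c, terr.mean, mar.mean)
    return two_source_sd(d13c_sd, terr.sd, mar.sd, f, mar.mean - terr.mean)


@dataclass(frozen=True)
class PopulationSummary:
    """Per-sample marine fractions plus feasible-population statistics."""

    table: pd.DataFrame
    mean_f: float
    min_f: float
    max_f: float
    infeasible: list[str]


def population_summary(
    samples: Iterable[SampleRecord], terr: EndMember, mar: EndMember
) -> PopulationSummary:
    """Per-sample marine fractions and population mean / min / max.

    Samples without bulk delta-13C are ignored; samples whose fraction falls
    outside [0, 1] are listed separately and excluded from the statistics.
    """
    _check_collagen(terr, mar)
    rows = []
    for s in samples:
        if s.bulk_d13c is None:
            continue
        res = f_marine_bulk(s.bulk_d13c, terr, mar)
        rows.append(
            {
                "sample_id": s.sample_id,
                "bulk_d13c": s.bulk_d13c,
                "f_marine": res.f_marine,
                "sd": res.sd,
                "feasible": res.feasible,
            }
        )
    if not rows:
        raise ValidationError("no samples with bulk delta-13C values")
    table = pd.DataFrame(rows)
    feasible = table[table["feasible"]]
    if len(feasible):
        mean_f = float(feasible["f_marine"].mean())
        min_f = float(feasible["f_marine"].min())
        max_f = float(feasible["f_marine"].max())
    else:
        mean_f = min_f = max_f = math.nan
    infeasible = list(table.loc[~table["feasible"], "sample_id"])
    return PopulationSummary(table, mean_f, min_f, max_f, infeasible)
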