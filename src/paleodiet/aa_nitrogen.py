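"""Trophic position and marine-protein fraction from amino acid delta-15N.

The "trophic" amino acid glutamic acid (Glx after hydrolysis) is enriched in
15N by Delta_glu-phe permil per trophic transfer, while the "source" amino
acid phenylalanine retains the baseline value of the food web.  With beta the
producer-level Glu-Phe difference (distinct for aquatic photoautotrophs and
C3 vascular plants), a consumer's trophic position under each baseline
assumption is

    TP_marine      = (d15N_glu - d15N_phe + beta_marine) / Delta + 1
    TP_terrestrial = (d15N_glu - d15N_phe + beta_terrestrial) / Delta + 1
    TP_mixed       = (d15N_glu - d15N_phe
                      + (1 - f) beta_terrestrial + f beta_marine) / Delta + 1

where f is the fraction of marine dietary protein.  Two estimators of f are
provided: inverting TP_mixed at an assumed human trophic level (HTL), and
phenylalanine two-source mass balance between terrestrial and marine
baseline end members.  All SDs are first-order (delta-method) propagation
over independent inputs, validated elsewhere against Monte Carlo.

Note on printed averages: the consumer-average d15N_phe for the humans in
the motivating dataset rounds to 11.5 permil in the full-suite table and
11.6 permil in the mass-balance discussion; both are exposed as constants
and used where each applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from paleodiet._mixing import two_source_fraction, two_source_sd
from paleodiet.bulk_mixing import EndMember
from paleodiet.data_model import ValidationError


@dataclass(frozen=True)
class NitrogenParams:
    """Constants parameterizing the Glu/Phe trophic-position equations.

    ``beta_marine``/``beta_terrestrial`` are the producer-level 15N
    differences between glutamic acid and phenylalanine for aquatic
    photoautotrophs and C3 vascular plants; ``delta_glu_phe`` is the
    per-trophic-step enrichment for mammals.  Constant uncertainties default
    to zero and may be supplied when known.
    """

    beta_marine: float = -3.4
    beta_terrestrial: float = 8.4
    delta_glu_phe: float = 7.6
    sd_beta_marine: float = 0.0
    sd_beta_terrestrial: float = 0.0
    sd_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_glu_phe <= 0:
            raise ValidationError("delta_glu_phe must be positive")
        if min(self.sd_beta_marine, self.sd_beta_terrestrial, self.sd_delta) < 0:
            raise ValidationError("constant SDs must be >= 0")


DEFAULT_PARAMS = NitrogenParams()


@dataclass(frozen=True)
class PairedDelta:
    """Measured d15N of glutamic acid and phenylalanine in one consumer."""

    d15n_glu: float
    d15n_phe: float
    sd_glu: float = 0.0
    sd_phe: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sd_glu, self.sd_phe) < 0:
            raise ValidationError("measurement SDs must be >= 0")


@dataclass(frozen=True)
class TPResult:
    tp: float
    sd: float
    assumption: str  # "marine" | "terrestrial" | "mixed"


@dataclass(frozen=True)
class HTLSpec:
    """Global human trophic level: food-supply-derived mean and range."""

    level: float = 2.21
    lo: float = 2.04
    hi: float = 2.76
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lo <= self.level <= self.hi):
            raise ValidationError("require lo <= level <= hi")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


@dataclass(frozen=True)
class FMarineResult:
    f: float
    sd: float
    method: str  # "htl" | "phe"
    feasible: bool


#: Terrestrial d15N_phe end member: archaeological totora reed.
TERRESTRIAL_PHE = EndMember(22.7, 0.9, "collagen", "archaeological totora phe")
#: Marine d15N_phe end member used in the phe mass balance: lowest fish.
MARINE_PHE_LOWEST_FISH = EndMember(0.4, 0.6, "collagen", "lowest measured fish phe")
#: Marine d15N_phe end member used in the end-member inversion: fish average.
MARINE_PHE_FISH_AVG = EndMember(1.0, 0.9, "collagen", "average measured fish phe")

#: Consumer-average human d15N_phe as printed with the full amino acid suite.
HUMAN_PHE_SUITE_AVG = 11.5
#: Consumer-average human d15N_phe as used in the mass-balance estimators.
HUMAN_PHE_MASSBALANCE_AVG = 11.6


# ---------------------------------------------------------------------------
# trophic position estimators


def _tp(p: PairedDelta, beta: float, sd_beta: float, k: NitrogenParams) -> tuple[float, float]:
    num = p.d15n_glu - p.d15n_phe + beta
    tp = num / k.delta_glu_phe + 1.0
    var = (p.sd_glu**2 + p.sd_phe**2 + sd_beta**2) / k.delta_glu_phe**2
    var += num**2 * k.sd_delta**2 / k.delta_glu_phe**4
    return tp, math.sqrt(var)


def tp_marine(p: PairedDelta, k: NitrogenParams = DEFAULT_PARAMS) -> TPResult:
    """Trophic position assuming a fully marine food web baseline."""
    tp, sd = _tp(p, k.beta_marine, k.sd_beta_marine, k)
    return TPResult(tp=tp, sd=sd, assumption="marine")


def tp_terrestrial(p: PairedDelta, k: NitrogenParams = DEFAULT_PARAMS) -> TPResult:
    """Trophic position assuming a fully terrestrial (C3) baseline."""
    tp, sd = _tp(p, k.beta_terrestrial, k.sd_beta_terrestrial, k)
    return TPResult(tp=tp, sd=sd, assumption="terrestrial")


def tp_mixed(
    p: PairedDelta,
    f: float,
    k: NitrogenParams = DEFAULT_PARAMS,
    f_sd: float = 0.0,
) -> TPResult:
    """Trophic position under a mixed diet with marine protein fraction ``f``.

    Reduces exactly to :func:`tp_terrestrial` at ``f = 0`` and to
    :func:`tp_marine` at ``f = 1``.  The SD includes the uncertainty of the
    estimated ``f`` when ``f_sd`` is given.
    """
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"marine fraction must be in [0, 1], got {f!r}")
    if f_sd < 0:
        raise ValidationError("f_sd must be >= 0")
    beta_mix = (1.0 - f) * k.beta_terrestrial + f * k.beta_marine
    num = p.d15n_glu - p.d15n_phe + beta_mix
    tp = num / k.delta_glu_phe + 1.0
    var = (
        p.sd_glu**2
        + p.sd_phe**2
        + (1.0 - f) ** 2 * k.sd_beta_terrestrial**2
        + f**2 * k.sd_beta_marine**2
        + (k.beta_marine - k.beta_terrestrial) ** 2 * f_sd**2
    ) / k.delta_glu_phe**2
    var += num**2 * k.sd_delta**2 / k.delta_glu_phe**4
    return TPResult(tp=tp, sd=math.sqrt(var), assumption="mixed")


# ---------------------------------------------------------------------------
# marine fraction estimators


def f_marine_htl(
    p: PairedDelta,
    htl: HTLSpec = HTLSpec(),
    k: NitrogenParams = DEFAULT_PARAMS,
) -> FMarineResult:
    """Marine fraction from the assumed human trophic level.

    Inverts the mixed-diet trophic position equation at ``TP = htl.level``::

        f = (Delta (TP - 1) + d15N_phe - d15N_glu - beta_terr)
            / (beta_mar - beta_terr)
    """
    denom = k.beta_marine - k.beta_terrestrial
    if denom == 0:
        raise ValidationError("degenerate model: beta_marine == beta_terrestrial")
    num = (
        k.delta_glu_phe * (htl.level - 1.0)
        + p.d15n_phe
        - p.d15n_glu
        - k.beta_terrestrial
    )
    f = num / denom
    var = (
        (htl.level - 1.0) ** 2 * k.sd_delta**2
        + k.delta_glu_phe**2 * htl.sd**2
        + p.sd_phe**2
        + p.sd_glu**2
        + (f - 1.0) ** 2 * k.sd_beta_terrestrial**2
        + f**2 * k.sd_beta_marine**2
    ) / denom**2
    return FMarineResult(f=f, sd=math.sqrt(var), method="htl", feasible=0.0 <= f <= 1.0)


def infer_terrestrial_endmember(
    phe_consumer: float, f: float, phe_marine: float
) -> float:
    """Terrestrial d15N_phe end member implied by a consumer value and f.

    Inverts the phenylalanine two-source mass balance::

        terr = (phe_consumer - f * phe_marine) / (1 - f)
    """
    if f >= 1.0:
        raise ValidationError("f must be < 1 to invert for the terrestrial end member")
    return (phe_consumer - f * phe_marine) / (1.0 - f)


def f_marine_phe(
    phe_consumer: float,
    phe_sd: float = 0.0,
    terr_em: EndMember = TERRESTRIAL_PHE,
    mar_em: EndMember = MARINE_PHE_LOWEST_FISH,
) -> FMarineResult:
    """Marine fraction from phenylalanine d15N two-source mass balance.

    ``f = (phe_consumer - terr) / (mar - terr)`` with the two-source
    first-order SD.  Does not assume a trophic level for the consumer.
    """
    if terr_em.mean == mar_em.mean:
        raise ValidationError("degenerate model: equal end-member means")
    f = two_source_fraction(phe_consumer, terr_em.mean, mar_em.mean)
    sd = two_source_sd(phe_sd, terr_em.sd, mar_em.sd, f, mar_em.mean - terr_em.mean)
    return FMarineResult(f=f, sd=sd, method="phe", feasible=0.0 <= f <= 1.0)


# ---------------------------------------------------------------------------
# error propagation dispatch

_ESTIMATORS = ("tp_marine", "tp_terrestrial", "tp_mixed", "f_marine_htl", "f_marine_phe")


def propagate_sd(estimator: str, **kwargs) -> float:
    """First-order propagated SD for one of the five named estimators.

    A convenience dispatcher: ``propagate_sd("tp_mixed", p=..., f=..., k=...,
    f_sd=...)`` returns the same SD as the estimator itself.  All inputs are
    treated as independent; partial derivatives are documented in each
    estimator.
    """
    if estimator == "tp_marine":
        return tp_marine(**kwargs).sd
    if estimator == "tp_terrestrial":
        return tp_terrestrial(**kwargs).sd
    if estimator == "tp_mixed":
        return tp_mixed(**kwargs).sd
    if estimator == "f_marine_htl":
        return f_marine_htl(**kwargs).sd
    if estimator == "f_marine_phe":
        return f_marine_phe(**kwargs).sd
    raise ValidationError(f"unknown estimator {estimator!r}; expected one of {_ESTIMATORS}")


# ---------------------------------------------------------------------------
# sensitivity sweep over terrestrial end members


def sensitivity_sweep(
    p_human: PairedDelta,
    p_rat: PairedDelta,
    terr_grid: Sequence[float],
    mar_em: EndMember = MARINE_PHE_FISH_AVG,
    k: NitrogenParams = DEFAULT_PARAMS,
    terr_sd: float = 0.0,
    min_rat_tp: float = 2.0,
) -> pd.DataFrame:
    """Effect of candidate terrestrial d15N_phe end members on f and TP_mixed.

    For every grid value the phe mass-balance marine fraction and the
    resulting mixed-diet trophic position are computed for humans and rats.
    Rows where a fraction violates mass balance (outside [0, 1]) are flagged
    and the corresponding TP left undefined; rows where the rat trophic
    position falls below ``min_rat_tp`` are flagged for elimination, because
    rats are at least partly faunivorous (gut-content evidence) and cannot
    sit below the herbivore level.
    """
    terr_grid = list(terr_grid)
    if not terr_grid:
        raise ValidationError("empty terrestrial end-member grid")
    if any(t <= mar_em.mean for t in terr_grid):
        raise ValidationError("grid values must exceed the marine end-member mean")

    rows = []
    for t in terr_grid:
        terr_em = EndMember(t, terr_sd, "collagen", "sweep")
        row: dict[str, object] = {"terr_phe": t}
        for species, p in (("human", p_human), ("rat", p_rat)):
            res = f_marine_phe(p.d15n_phe, p.sd_phe, terr_em, mar_em)
            row[f"f_{species}"] = res.f
            row[f"f_{species}_sd"] = res.sd
            row[f"feasible_{species}"] = res.feasible
            if res.feasible:
                tp = tp_mixed(p, res.f, k, f_sd=res.sd)
                row[f"tp_{species}"] = tp.tp
                row[f"tp_{species}_sd"] = tp.sd
            else:
                row[f"tp_{species}"] = math.nan
                row[f"tp_{species}_sd"] = math.nan
        tp_rat = row["tp_rat"]
        row["rat_tp_eliminated"] = bool(
            isinstance(tp_rat, float) and not math.isnan(tp_rat) and tp_rat < min_rat_tp
        )
        rows.append(row)
    return pd.DataFrame(rows)
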