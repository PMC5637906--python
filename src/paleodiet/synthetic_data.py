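"""Synthetic food-web generator with the statistical structure the estimators assume.

The raw specimen tables behind the motivating study are not redistributable,
so every stage of the pipeline is exercised on synthetic data that emulates
the study conditions: a marine phenylalanine baseline near 0-1 permil, a
manipulated-soil terrestrial baseline near 18-23 permil, a 7.6 permil
per-step trophic enrichment of glutamic acid over phenylalanine, analytical
replicate SDs of ~0.4 permil, and four well-separated EAA delta-13C source
clusters (two marine, two plant).  Consumers are generated by running the
forward model (two-source phenylalanine mass balance plus the mixed-diet
trophic-position equation) at known f_true and tp_true, then adding
independent Gaussian analytical noise, so noiseless simulations invert
exactly through every estimator.

Nothing here attempts to simulate soil biogeochemistry; only the isotopic
end-member consequences of soil manipulation are represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from paleodiet.bulk_mixing import (
    EndMember,
    MARINE_COLLAGEN,
    TERRESTRIAL_TOTORA,
    to_collagen_basis,
)
from paleodiet.data_model import IsotopeValue, SampleRecord, ValidationError, write_samples
from paleodiet.eaa_fingerprinting import EAA_SET, EAAPattern, center_pattern

#: Centered per-EAA delta-13C group means (permil) for the four synthetic
#: source clusters; separations are several times the analytical SD.
DEFAULT_EAA_GROUP_MEANS: dict[str, dict[str, float]] = {
    "Marine-I": {"Leu": 2.0, "Lys": 1.0, "Phe": -1.5, "Val": -1.5},
    "Marine-II": {"Leu": -1.0, "Lys": 2.5, "Phe": -0.5, "Val": -1.0},
    "Plant-I": {"Leu": -2.0, "Lys": -1.0, "Phe": 3.0, "Val": 0.0},
    "Plant-II": {"Leu": 1.0, "Lys": -2.5, "Phe": 0.5, "Val": 1.0},
}

#: Default consumer source mixture (marine-leaning omnivore).
DEFAULT_CONSUMER_MIXTURE = {
    "Marine-I": 0.381,
    "Marine-II": 0.163,
    "Plant-I": 0.25,
    "Plant-II": 0.206,
}


@dataclass(frozen=True)
class FoodWebSpec:
    """Parameters of the synthetic food web.

    Defaults are the study conditions: end members, trophic constants and
    analytical noise as observed in the motivating dataset.
    """

    seed: int = 0
    marine_phe_em: tuple[float, float] = (0.4, 0.6)
    terr_phe_em: tuple[float, float] = (22.7, 0.9)
    trophic_step: float = 7.6
    beta_mar: float = -3.4
    beta_terr: float = 8.4
    analytical_sd_n: float = 0.41
    analytical_sd_c: float = 0.38
    n_per_group: int = 10
    #: true marine protein fraction per consumer; None draws the trophic
    #: position range uniformly with f fixed at the study-level 0.5
    consumer_f_true: tuple[float, ...] | None = None
    #: true trophic position per consumer; None samples Uniform(htl_lo, htl_hi)
    consumer_tp_true: tuple[float, ...] | None = None
    htl_lo: float = 2.04
    htl_hi: float = 2.76
    eaa_group_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_EAA_GROUP_MEANS
    )
    eaa_sd: float = 0.38
    #: bulk collagen generation: delta-13C/delta-15N end members and noise
    bulk_terr_d13c: float = TERRESTRIAL_TOTORA.mean + 5.0
    bulk_mar_d13c: float = MARINE_COLLAGEN.mean
    bulk_terr_d15n: float = 12.9
    bulk_mar_d15n: float = 17.5
    bulk_noise: float = 0.8

    def __post_init__(self) -> None:
        for sd in (
            self.marine_phe_em[1],
            self.terr_phe_em[1],
            self.analytical_sd_n,
            self.analytical_sd_c,
            self.eaa_sd,
            self.bulk_noise,
        ):
            if sd < 0:
                raise ValidationError("all spec SDs must be >= 0")
        if self.consumer_f_true is not None and any(
            not 0.0 <= f <= 1.0 for f in self.consumer_f_true
        ):
            raise ValidationError("consumer_f_true values must lie in [0, 1]")
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")


def _consumer_truth(spec: FoodWebSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if spec.consumer_f_true is not None:
        f = np.asarray(spec.consumer_f_true, dtype=float)
    else:
        f = np.full(spec.n_per_group, 0.5)
    if spec.consumer_tp_true is not None:
        tp = np.asarray(spec.consumer_tp_true, dtype=float)
        if tp.size != f.size:
            raise ValidationError("consumer_tp_true length must match consumer_f_true")
    else:
        tp = rng.uniform(spec.htl_lo, spec.htl_hi, size=f.size)
    return f, tp


def simulate_nitrogen(spec: FoodWebSpec) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Forward-simulate Glu/Phe delta-15N for producers and mixed consumers.

    Producer phenylalanine values are drawn from the two baseline end
    members; a consumer's phenylalanine is the f-weighted mixture of the end
    member *means* and its glutamic acid is set so the mixed-diet
    trophic-position equation holds exactly at (f_true, tp_true) before
    analytical noise is added.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    sd = spec.analytical_sd_n
    samples: list[SampleRecord] = []
    truth_rows = []

    def _glu(phe: float, tp: float, f: float) -> float:
        beta_mix = (1.0 - f) * spec.beta_terr + f * spec.beta_mar
        return phe + spec.trophic_step * (tp - 1.0) - beta_mix

    def _emit(sid: str, category: str, phe_true: float, tp: float, f: float, group: str) -> None:
        glu_true = _glu(phe_true, tp, f)
        phe = phe_true + rng.normal(scale=sd) if sd > 0 else phe_true
        glu = glu_true + rng.normal(scale=sd) if sd > 0 else glu_true
        samples.append(
            SampleRecord(
                sample_id=sid,
                category=category,
                origin="archaeological",
                cn_molar=3.2 if category != "plant" else None,
                aa_d15n={
                    "Glx": IsotopeValue(glu, sd, 6),
                    "Phe": IsotopeValue(phe, sd, 6),
                },
            )
        )
        truth_rows.append(
            {"sample_id": sid, "group_true": group, "f_true": f, "tp_true": tp}
        )

    # producers and a marine consumer baseline
    for i in range(spec.n_per_group):
        phe = rng.normal(spec.terr_phe_em[0], spec.terr_phe_em[1])
        _emit(f"PLANT{i:03d}", "plant", phe, 1.0, 0.0, "plant")
    for i in range(spec.n_per_group):
        phe = rng.normal(spec.marine_phe_em[0], spec.marine_phe_em[1])
        _emit(f"FISH{i:03d}", "fish", phe, 2.5, 1.0, "fish")

    f_true, tp_true = _consumer_truth(spec, rng)
    for i, (f, tp) in enumerate(zip(f_true, tp_true)):
        phe = f * spec.marine_phe_em[0] + (1.0 - f) * spec.terr_phe_em[0]
        _emit(f"HUM{i:03d}", "human", phe, float(tp), float(f), "human")

    return samples, pd.DataFrame(truth_rows)


def simulate_bulk(
    spec: FoodWebSpec,
    terr_em: EndMember | None = None,
    mar_em: EndMember | None = None,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Forward-simulate bulk collagen delta-13C/delta-15N for mixed consumers.

    ``bulk = terr + f (mar - terr) + noise`` on both isotopes; the nitrogen
    values exist only for plotting parity with bulk biplots.
    """
    if terr_em is None:
        terr_em = to_collagen_basis(TERRESTRIAL_TOTORA)
    if mar_em is None:
        mar_em = MARINE_COLLAGEN
    rng = np.random.default_rng(spec.seed + 1)
    f_true, _ = _consumer_truth(spec, rng)
    samples = []
    rows = []
    for i, f in enumerate(f_true):
        d13c = terr_em.mean + f * (mar_em.mean - terr_em.mean)
        d15n = spec.bulk_terr_d15n + f * (spec.bulk_mar_d15n - spec.bulk_terr_d15n)
        if spec.bulk_noise > 0:
            d13c += rng.normal(scale=spec.bulk_noise)
            d15n += rng.normal(scale=spec.bulk_noise)
        sid = f"BULK{i:03d}"
        samples.append(
            SampleRecord(
                sample_id=sid,
                category="human",
                origin="archaeological",
                bulk_d13c=float(d13c),
                bulk_d15n=float(d15n),
                cn_molar=3.2,
            )
        )
        rows.append({"sample_id": sid, "group_true": "human", "f_true": float(f)})
    return samples, pd.DataFrame(rows)


def simulate_eaa(
    spec: FoodWebSpec,
    consumer_mixtures: Sequence[Mapping[str, float]] | None = None,
) -> tuple[list[EAAPattern], list[EAAPattern], pd.DataFrame]:
    """Simulate centered EAA training patterns and mixed consumers.

    Returns ``(training, consumers, truth)``.  Training patterns are group
    mean + independent Gaussian noise per EAA; consumers are convex
    combinations of the group means plus noise.  All patterns are re-centered
    after noise so the centering invariant holds by construction.
    """
    groups = {g: dict(m) for g, m in spec.eaa_group_means.items()}
    if len(groups) < 2:
        raise ValidationError("need at least 2 source groups")
    means = {g: np.array([m[aa] for aa in EAA_SET]) for g, m in groups.items()}
    distinct = {tuple(v) for v in means.values()}
    if len(distinct) < len(means):
        import warnings

        warnings.warn("identical group means: fixture is non-identifiable", stacklevel=2)

    rng = np.random.default_rng(spec.seed + 2)
    sd = spec.analytical_sd_c

    def _pattern(sid: str, vec: np.ndarray) -> EAAPattern:
        noisy = vec + rng.normal(scale=spec.eaa_sd, size=vec.size) if spec.eaa_sd > 0 else vec
        raw = EAAPattern(
            sid, {aa: IsotopeValue(float(v), sd, 3) for aa, v in zip(EAA_SET, noisy)}
        )
        return center_pattern(raw, EAA_SET)

    training: list[EAAPattern] = []
    truth_rows = []
    for g in sorted(groups):
        for i in range(spec.n_per_group):
            sid = f"{g}-{i:02d}"
            training.append(_pattern(sid, means[g]))
            truth_rows.append({"sample_id": sid, "group_true": g, "role": "training"})

    if consumer_mixtures is None:
        consumer_mixtures = [DEFAULT_CONSUMER_MIXTURE] * spec.n_per_group
    consumers: list[EAAPattern] = []
    for i, mix in enumerate(consumer_mixtures):
        w = np.array([mix.get(g, 0.0) for g in sorted(groups)], dtype=float)
        if w.sum() <= 0:
            raise ValidationError("consumer mixture weights must sum to > 0")
        w = w / w.sum()
        vec = np.sum(
            [wi * means[g] for wi, g in zip(w, sorted(groups))], axis=0
        )
        sid = f"CONS{i:03d}"
        consumers.append(_pattern(sid, vec))
        row = {"sample_id": sid, "group_true": "consumer", "role": "consumer"}
        row.update({f"w_{g}": wi for g, wi in zip(sorted(groups), w)})
        truth_rows.append(row)

    return training, consumers, pd.DataFrame(truth_rows)


def _write_patterns(patterns: Sequence[EAAPattern], path: Path) -> None:
    rows = []
    for p in patterns:
        for aa in EAA_SET:
            v = p.values[aa]
            rows.append(
                {"sample_id": p.sample_id, "aa": aa, "mean": repr(float(v.mean)), "sd": repr(float(v.sd))}
            )
    pd.DataFrame(rows, columns=["sample_id", "aa", "mean", "sd"]).to_csv(path, index=False)


def _write_curve(path: Path, grid: np.ndarray, mu: np.ndarray, sigma: np.ndarray, name: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# synthetic calibration curve: {name}\n")
        fh.write("# cal BP, 14C age BP, sigma\n")
        for t, m, s in zip(grid, mu, sigma):
            fh.write(f"{t:.1f},{m:.4f},{s:.4f}\n")


def make_fixture_files(outdir, spec: FoodWebSpec | None = None) -> dict[str, Path]:
    """Write the deterministic CSV fixture set used by the test suite.

    Emits sample/AA tables, EAA training and consumer tables with the group
    assignment, synthetic atmospheric and marine calibration curves
    (labelled synthetic: they are smooth invented curves, not IntCal
    products), and a determinations table.  Byte-stable for a fixed spec.
    """
    spec = spec or FoodWebSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    nitro_samples, nitro_truth = simulate_nitrogen(spec)
    bulk_samples, bulk_truth = simulate_bulk(spec)
    samples = nitro_samples + bulk_samples
    paths = {
        "samples": outdir / "samples.csv",
        "aa": outdir / "aa.csv",
        "truth": outdir / "truth.csv",
        "eaa_training": outdir / "eaa_training.csv",
        "eaa_consumers": outdir / "eaa_consumers.csv",
        "assignment": outdir / "assignment.csv",
        "atm_curve": outdir / "synthetic_atm_curve.csv",
        "mar_curve": outdir / "synthetic_mar_curve.csv",
        "determinations": outdir / "determinations.csv",
    }
    write_samples(samples, paths["samples"], paths["aa"])
    pd.concat([nitro_truth, bulk_truth]).to_csv(paths["truth"], index=False)

    training, consumers, eaa_truth = simulate_eaa(spec)
    _write_patterns(training, paths["eaa_training"])
    _write_patterns(consumers, paths["eaa_consumers"])
    assignment = eaa_truth[eaa_truth["role"] == "training"][["sample_id", "group_true"]]
    assignment.rename(columns={"group_true": "group"}).to_csv(paths["assignment"], index=False)

    grid = np.arange(0.0, 2501.0, 5.0)
    mu_atm = 1.02 * grid + 15.0 * np.sin(grid / 120.0)
    sigma = 12.0 + 2.0 * np.cos(grid / 200.0)
    _write_curve(paths["atm_curve"], grid, mu_atm, sigma, "atmospheric (synthetic)")
    _write_curve(paths["mar_curve"], grid, mu_atm + 400.0, sigma, "marine (synthetic)")

    pd.DataFrame(
        [
            {"lab_id": "DET001", "c14_age": 490, "sd": 25, "f_marine": 0.384, "f_sd": 0.0},
            {"lab_id": "DET002", "c14_age": 440, "sd": 25, "f_marine": 0.564, "f_sd": 0.0},
            {"lab_id": "DET003", "c14_age": 110, "sd": 25, "f_marine": 0.0, "f_sd": 0.0},
        ]
    ).to_csv(paths["determinations"], index=False)

    return paths
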