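"""Pipeline orchestration and report tables.

:func:`run_pipeline` composes the analysis stages — QC, bulk delta-13C
mixing, Glu/Phe delta-15N trophic positions and marine fractions, EAA
fingerprinting, and diet-weighted calibration — over a flat key-value
configuration, and records every constant, seed, and input-file hash in a
run log so a run is fully reconstructable.  :func:`render_tables` writes the
bundle as full-precision CSV plus a rendered version rounded half-even to
two decimals (CSV or markdown).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from paleodiet import aa_nitrogen as nitro
from paleodiet import bulk_mixing as bulk
from paleodiet import eaa_fingerprinting as eaa
from paleodiet import radiocarbon as c14
from paleodiet.data_model import IsotopeValue, filter_cn, load_samples

logger = logging.getLogger("paleodiet")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending sample."""


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log_constants(log: list[str], stage: str, constants: Mapping[str, object]) -> None:
    for key, value in constants.items():
        line = f"{stage}.{key} = {value}"
        log.append(line)
        logger.info(line)


def _read_patterns(path, center: bool = True) -> list[eaa.EAAPattern]:
    table = pd.read_csv(path)
    patterns = []
    for sid, grp in table.groupby("sample_id", sort=False):
        values = {
            str(r.aa): IsotopeValue(float(r.mean), float(getattr(r, "sd", 0.0) or 0.0))
            for r in grp.itertuples(index=False)
        }
        raw = eaa.EAAPattern(str(sid), values)
        patterns.append(eaa.center_pattern(raw, eaa.EAA_SET) if center else raw)
    return patterns


def run_pipeline(config: Mapping[str, object]) -> dict:
    """Run every stage for which the configuration supplies inputs.

    Returns ``{"tables": {name: DataFrame}, "log": [str, ...]}``.  Any stage
    failure aborts with :class:`StageError` naming the stage (and sample
    where known).
    """
    cfg = dict(config)
    tables: dict[str, pd.DataFrame] = {}
    log: list[str] = []

    for key in ("io.samples", "io.aa", "fingerprint.training", "fingerprint.consumers",
                "calibrate.atm_curve", "calibrate.mar_curve", "calibrate.determinations"):
        if cfg.get(key):
            log.append(f"input {key} = {cfg[key]} sha256={_hash_file(cfg[key])}")

    samples = []
    if cfg.get("io.samples"):
        try:
            samples = load_samples(cfg["io.samples"], cfg.get("io.aa"))
        except Exception as exc:
            raise StageError(f"load: {exc}") from exc

    if samples:
        lo = float(cfg.get("qc.lo", 2.9))
        hi = float(cfg.get("qc.hi", 3.6))
        _log_constants(log, "qc", {"lo": lo, "hi": hi})
        report = filter_cn(samples, lo, hi)
        tables["qc"] = pd.DataFrame(
            [{"sample_id": s, "kept": True, "reason": ""} for s in report.kept]
            + [{"sample_id": s, "kept": False, "reason": r} for s, r in report.rejected]
        )
        kept = set(report.kept)
        samples = [s for s in samples if s.sample_id in kept]

    if samples and any(s.bulk_d13c is not None for s in samples):
        terr = bulk.EndMember(
            float(cfg.get("bulk.terr_mean", bulk.TERRESTRIAL_TOTORA.mean)),
            float(cfg.get("bulk.terr_sd", bulk.TERRESTRIAL_TOTORA.sd)),
            str(cfg.get("bulk.terr_basis", "plant_tissue")),
            "terrestrial",
        )
        offset = float(cfg.get("bulk.offset", bulk.DIET_TO_COLLAGEN_OFFSET))
        if terr.basis == "plant_tissue":
            terr = bulk.to_collagen_basis(terr, offset)
        mar = bulk.EndMember(
            float(cfg.get("bulk.mar_mean", bulk.MARINE_COLLAGEN.mean)),
            float(cfg.get("bulk.mar_sd", bulk.MARINE_COLLAGEN.sd)),
            "collagen",
            "marine",
        )
        _log_constants(
            log, "bulk",
            {"terr_mean": terr.mean, "terr_sd": terr.sd, "mar_mean": mar.mean,
             "mar_sd": mar.sd, "diet_to_collagen_offset": offset},
        )
        try:
            summary = bulk.population_summary(samples, terr, mar)
        except Exception as exc:
            raise StageError(f"bulk: {exc}") from exc
        tables["bulk"] = summary.table
        log.append(
            f"bulk.population mean={summary.mean_f} min={summary.min_f} max={summary.max_f}"
        )

    nitro_samples = [s for s in samples if "Glx" in s.aa_d15n and "Phe" in s.aa_d15n]
    if nitro_samples:
        k = nitro.NitrogenParams(
            beta_marine=float(cfg.get("nitrogen.beta_marine", -3.4)),
            beta_terrestrial=float(cfg.get("nitrogen.beta_terrestrial", 8.4)),
            delta_glu_phe=float(cfg.get("nitrogen.delta_glu_phe", 7.6)),
        )
        htl = nitro.HTLSpec(level=float(cfg.get("nitrogen.htl", 2.21)))
        terr_em = bulk.EndMember(
            float(cfg.get("nitrogen.terr_phe_mean", nitro.TERRESTRIAL_PHE.mean)),
            float(cfg.get("nitrogen.terr_phe_sd", nitro.TERRESTRIAL_PHE.sd)),
            "collagen", "terrestrial phe",
        )
        mar_em = bulk.EndMember(
            float(cfg.get("nitrogen.mar_phe_mean", nitro.MARINE_PHE_LOWEST_FISH.mean)),
            float(cfg.get("nitrogen.mar_phe_sd", nitro.MARINE_PHE_LOWEST_FISH.sd)),
            "collagen", "marine phe",
        )
        _log_constants(
            log, "nitrogen",
            {"beta_marine": k.beta_marine, "beta_terrestrial": k.beta_terrestrial,
             "delta_glu_phe": k.delta_glu_phe, "htl": htl.level,
             "terr_phe": f"{terr_em.mean}+-{terr_em.sd}",
             "mar_phe": f"{mar_em.mean}+-{mar_em.sd}"},
        )
        tp_rows, f_rows = [], []
        for s in nitro_samples:
            try:
                glu, phe = s.aa_d15n["Glx"], s.aa_d15n["Phe"]
                p = nitro.PairedDelta(glu.mean, phe.mean, glu.sd, phe.sd)
                t_mar = nitro.tp_marine(p, k)
                t_ter = nitro.tp_terrestrial(p, k)
                f_phe = nitro.f_marine_phe(p.d15n_phe, p.sd_phe, terr_em, mar_em)
                f_htl = nitro.f_marine_htl(p, htl, k)
                if f_phe.feasible:
                    t_mix = nitro.tp_mixed(p, f_phe.f, k, f_sd=f_phe.sd)
                    tp_mix, tp_mix_sd = t_mix.tp, t_mix.sd
                else:
                    tp_mix = tp_mix_sd = float("nan")
            except Exception as exc:
                raise StageError(f"nitrogen: sample {s.sample_id}: {exc}") from exc
            tp_rows.append(
                {"sample_id": s.sample_id, "category": s.category,
                 "tp_marine": t_mar.tp, "tp_marine_sd": t_mar.sd,
                 "tp_terrestrial": t_ter.tp, "tp_terrestrial_sd": t_ter.sd,
                 "tp_mixed": tp_mix, "tp_mixed_sd": tp_mix_sd}
            )
            f_rows.append(
                {"sample_id": s.sample_id, "category": s.category,
                 "f_htl": f_htl.f, "f_htl_sd": f_htl.sd,
                 "f_phe": f_phe.f, "f_phe_sd": f_phe.sd,
                 "feasible": f_phe.feasible and f_htl.feasible}
            )
        tables["trophic_positions"] = pd.DataFrame(tp_rows)
        tables["marine_fractions"] = pd.DataFrame(f_rows)

    if cfg.get("fingerprint.training") and cfg.get("fingerprint.consumers"):
        try:
            training = _read_patterns(cfg["fingerprint.training"])
            consumers = _read_patterns(cfg["fingerprint.consumers"])
            assignment_table = pd.read_csv(cfg["fingerprint.assignment"])
            assignment = dict(
                zip(assignment_table["sample_id"].astype(str), assignment_table["group"].astype(str))
            )
            sources = eaa.build_source_groups(training, assignment)
            n_steps = int(cfg.get("fingerprint.draws", 3000))
            mcmc = eaa.MCMCConfig(
                seed=int(cfg.get("fingerprint.seed", 0)),
                n_steps=n_steps,
                burn=min(1000, max(1, n_steps // 3)),
            )
            use = tuple(cfg.get("fingerprint.eaas", eaa.DEFAULT_MIXING_EAAS))
            _log_constants(
                log, "fingerprint",
                {"seed": mcmc.seed, "n_steps": mcmc.n_steps, "eaas": ",".join(use),
                 "model_error_sd": mcmc.model_error_sd},
            )
            rows = []
            for consumer in consumers:
                post = eaa.fit_mixture(consumer, sources, use, mcmc)
                marine = eaa.aggregate_marine(
                    post, [s.name for s in sources if s.name.lower().startswith("marine")]
                )
                row = {"sample_id": consumer.sample_id, "converged": post.converged,
                       "marine_mean": marine["mean"], "marine_sd": marine["sd"]}
                for name in post.source_names:
                    row[f"p_{name}"] = float(post.summary.loc[name, "mean"])
                    row[f"p_{name}_sd"] = float(post.summary.loc[name, "sd"])
                rows.append(row)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"fingerprint: {exc}") from exc
        tables["fingerprint"] = pd.DataFrame(rows)

    if cfg.get("calibrate.atm_curve") and cfg.get("calibrate.determinations"):
        try:
            atm = c14.parse_curve(cfg["calibrate.atm_curve"])
            mar = c14.parse_curve(cfg["calibrate.mar_curve"]) if cfg.get("calibrate.mar_curve") else None
            dr = c14.ReservoirCorrection(
                float(cfg.get("calibrate.delta_r", -83.0)),
                float(cfg.get("calibrate.delta_r_sd", 34.0)),
            )
            level = float(cfg.get("calibrate.level", 0.954))
            _log_constants(
                log, "calibrate",
                {"delta_r": dr.delta_r, "delta_r_sd": dr.sd, "level": level},
            )
            dets = pd.read_csv(cfg["calibrate.determinations"])
            rows = []
            for r in dets.itertuples(index=False):
                det = c14.Determination(
                    str(r.lab_id), float(r.c14_age), float(r.sd),
                    float(getattr(r, "f_marine", 0.0)), float(getattr(r, "f_sd", 0.0)),
                )
                if mar is not None and det.f_marine > 0:
                    res = c14.calibrate_with_diet(det, atm, mar, dr, level)
                else:
                    res = c14.calibrate(det, atm, level)
                for lo_ad, hi_ad, mass in res.intervals:
                    rows.append(
                        {"lab_id": det.lab_id, "f_marine": det.f_marine,
                         "from_ad": lo_ad, "to_ad": hi_ad, "mass": mass,
                         "level": level, "truncated": res.truncated}
                    )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"calibrate: {exc}") from exc
        tables["calibration"] = pd.DataFrame(rows)

    return {"tables": tables, "log": log}


# ---------------------------------------------------------------------------
# rendering


def _df_to_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def _round_half_even(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            # numpy rounds half to even; fixed-width formatting for report parity
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{np.round(v, decimals):.{decimals}f}"
            )
    return out


def render_tables(bundle: Mapping[str, object], outdir, format: str = "csv") -> list[Path]:
    """Write each bundle table: full-precision CSV plus a rendered version.

    Rendered numbers are rounded half-even to two decimals.  Empty tables
    are omitted with a log line.  Returns the written paths.
    """
    if format not in ("csv", "markdown"):
        raise ValueError(f"unknown format {format!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in bundle["tables"].items():
        if table is None or len(table) == 0:
            logger.info("table %s is empty; omitted", name)
            continue
        raw_path = outdir / f"{name}_raw.csv"
        table.to_csv(raw_path, index=False)
        written.append(raw_path)
        rendered = _round_half_even(table)
        if format == "csv":
            path = outdir / f"{name}.csv"
            rendered.to_csv(path, index=False)
        else:
            path = outdir / f"{name}.md"
            path.write_text(_df_to_markdown(rendered), encoding="utf-8")
        written.append(path)
    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(bundle["log"]) + "\n", encoding="utf-8")
    written.append(log_path)
    return written
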