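"""Domain records, tabular I/O, quality control, and instrument-level corrections.

The package starts from reduced isotope values (no chromatogram or raw IRMS
parsing): per-sample bulk collagen delta-13C (permil, V-PDB) and delta-15N
(permil, AIR), molar C:N, and per-amino-acid delta-15N / delta-13C with
replicate standard deviations.

File dialect
------------
Two comma-separated UTF-8 tables:

* a *sample table* with one row per specimen:
  ``sample_id, category, origin, bulk_d13c, bulk_d15n, cn_molar``
  (empty cells are absent optionals, never zeros);
* a *long-form amino-acid table* with one row per (sample, isotope, amino
  acid): ``sample_id, isotope, aa, mean, sd, n`` where ``isotope`` is
  ``d15n`` or ``d13c`` and ``aa`` is a three-letter code from
  :data:`AA_CODES`.

The long form is used because per-amino-acid replicate SDs and counts do not
fit a fixed wide schema.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Three-letter amino acid vocabulary (Asx/Glx are the acid-hydrolysis pools
#: of Asp+Asn and Glu+Gln; Glx carries the "glutamic acid" trophic signal).
AA_CODES = (
    "Gly", "Ser", "Phe", "Lys", "Ala", "Val", "Leu",
    "Ile", "Pro", "Asx", "Glx", "Thr", "Tyr",
)

CATEGORIES = (
    "human", "rat", "fish", "marine_mammal", "bird", "terrestrial_bird",
    "mussel", "plant", "soil", "reed",
)

ORIGINS = ("archaeological", "modern", "historic")

#: Commonly accepted molar C:N interval for well-preserved collagen,
#: treated as a closed interval.
CN_LO_DEFAULT = 2.9
CN_HI_DEFAULT = 3.6

SAMPLE_COLUMNS = ("sample_id", "category", "origin", "bulk_d13c", "bulk_d15n", "cn_molar")
AA_COLUMNS = ("sample_id", "isotope", "aa", "mean", "sd", "n")


class ValidationError(ValueError):
    """Raised when a record or argument violates a domain invariant."""


class ParseError(ValueError):
    """Raised for malformed input files, naming the offending row/column."""


@dataclass(frozen=True)
class IsotopeValue:
    """Replicate-averaged isotope measurement in permil."""

    mean: float
    sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValidationError(f"non-finite isotope mean {self.mean!r}")
        if self.sd < 0:
            raise ValidationError(f"negative isotope sd {self.sd!r}")
        if self.n < 1:
            raise ValidationError(f"replicate count must be >= 1, got {self.n!r}")


@dataclass
class SampleRecord:
    """One specimen with bulk and per-amino-acid isotope values."""

    sample_id: str
    category: str
    origin: str
    bulk_d13c: float | None = None
    bulk_d15n: float | None = None
    cn_molar: float | None = None
    aa_d15n: dict[str, IsotopeValue] = field(default_factory=dict)
    aa_d13c: dict[str, IsotopeValue] = field(default_factory=dict)
    #: provenance flag guarding against double application of the
    #: inter-laboratory delta-13C calibration offsets
    interlab_calibrated: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"{self.sample_id}: unknown category {self.category!r}"
            )
        if self.origin not in ORIGINS:
            raise ValidationError(f"{self.sample_id}: unknown origin {self.origin!r}")
        for mapping in (self.aa_d15n, self.aa_d13c):
            for code in mapping:
                if code not in AA_CODES:
                    raise ValidationError(
                        f"{self.sample_id}: unknown amino acid code {code!r}"
                    )


@dataclass(frozen=True)
class QCReport:
    """Partition of a dataset into kept and rejected sample ids."""

    kept: list[str]
    rejected: list[tuple[str, str]]


@dataclass(frozen=True)
class CorrectionSpec:
    """Numerical corrections applied to raw delta-13C values before inference.

    Parameters
    ----------
    x_fraction:
        Mole fraction of amino-acid carbon in the derivatized molecule, in
        (0, 1].  ``x_fraction = 1`` means no derivative carbon was added.
    d13c_iso:
        delta-13C (permil) of the isopropanol reagent added during
        esterification.
    interlab_offsets:
        Per-amino-acid permil offsets harmonizing measurements made in a
        second laboratory onto the primary laboratory's scale.
    suess_offset:
        Year-dependent correction (permil) for the industrial-era decline in
        atmospheric CO2 delta-13C, supplied by the user for the relevant
        collection year.
    """

    x_fraction: float = 1.0
    d13c_iso: float = 0.0
    interlab_offsets: Mapping[str, float] = field(default_factory=dict)
    suess_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.x_fraction <= 1.0):
            raise ValidationError(
                f"x_fraction must be in (0, 1], got {self.x_fraction!r}"
            )
        for aa, off in self.interlab_offsets.items():
            if aa not in AA_CODES:
                raise ValidationError(f"unknown amino acid code {aa!r} in offsets")
            if not math.isfinite(off):
                raise ValidationError(f"non-finite offset for {aa}")
        if not math.isfinite(self.suess_offset):
            raise ValidationError("non-finite suess_offset")


#: Inter-laboratory delta-13C calibration offsets (permil) harmonizing
#: N-acetylmethyl-ester measurements onto the trifluoroacetyl/isopropyl-ester
#: laboratory scale, derived from paired analyses of three modern fish.
INTERLAB_OFFSETS_DEFAULT = {"Leu": -0.86, "Lys": -0.32, "Phe": -3.75, "Val": -0.76}


# ---------------------------------------------------------------------------
# tabular I/O


def _parse_float(cell: str, row: int, column: str, path: str) -> float | None:
    text = (cell or "").strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"{path}: malformed numeric value {cell!r} at row {row}, column {column!r}"
        ) from None


def _parse_int(cell: str, row: int, column: str, path: str) -> int | None:
    value = _parse_float(cell, row, column, path)
    if value is None:
        return None
    if value != int(value):
        raise ParseError(
            f"{path}: non-integer value {cell!r} at row {row}, column {column!r}"
        )
    return int(value)


def load_samples(samples_path, aa_path=None) -> list[SampleRecord]:
    """Read sample records from the documented CSV dialect.

    Parameters
    ----------
    samples_path:
        Path of the per-sample header table.
    aa_path:
        Optional path of the long-form amino-acid table; rows are attached to
        the matching ``sample_id``.

    Returns
    -------
    list of :class:`SampleRecord`, in file order.  Missing cells become
    absent optionals (``None`` / absent dictionary keys), never zeros.
    """
    table = pd.read_csv(samples_path, dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{samples_path}: missing columns {missing}")

    records: dict[str, SampleRecord] = {}
    for i, row in enumerate(table.itertuples(index=False), start=2):
        sid = str(row.sample_id).strip()
        if not sid:
            raise ParseError(f"{samples_path}: empty sample_id at row {i}")
        if sid in records:
            raise ValidationError(f"{samples_path}: duplicate sample_id {sid!r}")
        records[sid] = SampleRecord(
            sample_id=sid,
            category=str(row.category).strip(),
            origin=str(row.origin).strip(),
            bulk_d13c=_parse_float(row.bulk_d13c, i, "bulk_d13c", str(samples_path)),
            bulk_d15n=_parse_float(row.bulk_d15n, i, "bulk_d15n", str(samples_path)),
            cn_molar=_parse_float(row.cn_molar, i, "cn_molar", str(samples_path)),
        )

    if aa_path is not None:
        aa_table = pd.read_csv(aa_path, dtype=str, keep_default_na=False)
        missing = [c for c in AA_COLUMNS if c not in aa_table.columns]
        if missing:
            raise ParseError(f"{aa_path}: missing columns {missing}")
        for i, row in enumerate(aa_table.itertuples(index=False), start=2):
            sid = str(row.sample_id).strip()
            if sid not in records:
                raise ValidationError(
                    f"{aa_path}: row {i} references unknown sample_id {sid!r}"
                )
            isotope = str(row.isotope).strip().lower()
            if isotope not in ("d15n", "d13c"):
                raise ParseError(
                    f"{aa_path}: row {i} has unknown isotope {row.isotope!r}"
                )
            aa = str(row.aa).strip()
            if aa not in AA_CODES:
                raise ValidationError(
                    f"{aa_path}: row {i} has unknown amino acid code {aa!r}"
                )
            mean = _parse_float(row.mean, i, "mean", str(aa_path))
            if mean is None:
                raise ParseError(f"{aa_path}: row {i} has empty mean")
            sd = _parse_float(row.sd, i, "sd", str(aa_path))
            n = _parse_int(row.n, i, "n", str(aa_path))
            value = IsotopeValue(mean, 0.0 if sd is None else sd, 1 if n is None else n)
            target = records[sid].aa_d15n if isotope == "d15n" else records[sid].aa_d13c
            if aa in target:
                raise ValidationError(
                    f"{aa_path}: duplicate ({sid}, {isotope}, {aa}) at row {i}"
                )
            target[aa] = value

    return list(records.values())


def _fmt(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def write_samples(records: Sequence[SampleRecord], samples_path, aa_path=None) -> None:
    """Write records in the dialect read by :func:`load_samples`.

    Floats are written with ``repr`` so that a load/write round trip
    preserves every value bit-for-bit.
    """
    rows = [
        {
            "sample_id": r.sample_id,
            "category": r.category,
            "origin": r.origin,
            "bulk_d13c": _fmt(r.bulk_d13c),
            "bulk_d15n": _fmt(r.bulk_d15n),
            "cn_molar": _fmt(r.cn_molar),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS)).to_csv(samples_path, index=False)

    if aa_path is not None:
        aa_rows = []
        for r in records:
            for isotope, mapping in (("d15n", r.aa_d15n), ("d13c", r.aa_d13c)):
                for aa, v in mapping.items():
                    aa_rows.append(
                        {
                            "sample_id": r.sample_id,
                            "isotope": isotope,
                            "aa": aa,
                            "mean": repr(float(v.mean)),
                            "sd": repr(float(v.sd)),
                            "n": v.n,
                        }
                    )
        pd.DataFrame(aa_rows, columns=list(AA_COLUMNS)).to_csv(aa_path, index=False)


# ---------------------------------------------------------------------------
# quality control


def filter_cn(
    samples: Iterable[SampleRecord],
    lo: float = CN_LO_DEFAULT,
    hi: float = CN_HI_DEFAULT,
) -> QCReport:
    """Partition samples by the collagen-preservation molar C:N criterion.

    Samples with ``cn_molar`` outside the closed interval ``[lo, hi]`` are
    rejected.  Samples without a C:N value (plants, soils, reeds have no
    collagen C:N) pass with a warning rather than failing.
    """
    if not lo < hi:
        raise ValidationError(f"require lo < hi, got [{lo}, {hi}]")
    kept: list[str] = []
    rejected: list[tuple[str, str]] = []
    no_cn: list[str] = []
    for s in samples:
        if s.cn_molar is None:
            no_cn.append(s.sample_id)
            kept.append(s.sample_id)
        elif lo <= s.cn_molar <= hi:
            kept.append(s.sample_id)
        else:
            rejected.append((s.sample_id, "C:N out of range"))
    if no_cn:
        warnings.warn(
            f"{len(no_cn)} sample(s) without molar C:N passed QC unchecked: "
            + ", ".join(no_cn),
            stacklevel=2,
        )
    return QCReport(kept=kept, rejected=rejected)


# ---------------------------------------------------------------------------
# corrections


def correct_derivatization(d13c_csia: float, spec: CorrectionSpec) -> float:
    """Remove derivative carbon from a measured amino-acid delta-13C value.

    Derivatization adds reagent carbon to each amino acid, so the measured
    value is a mole-fraction-weighted mixture.  Inverting the mixture::

        d13c_aa = (d13c_csia - (1 - X) * d13c_iso) / X

    where ``X`` is the mole fraction of amino-acid carbon in the derivative
    and ``d13c_iso`` is the reagent's isotopic composition.
    """
    x = spec.x_fraction
    if x <= 0:
        raise ValidationError(f"x_fraction must be positive, got {x!r}")
    return (d13c_csia - (1.0 - x) * spec.d13c_iso) / x


def apply_interlab_calibration(
    record: SampleRecord, spec: CorrectionSpec, subtract: bool = False
) -> SampleRecord:
    """Shift each listed amino acid's delta-13C by its inter-laboratory offset.

    The default convention *adds* the offsets (the published sign convention
    for harmonizing the secondary laboratory's values); ``subtract=True``
    applies the opposite convention.  Applying the calibration twice is an
    error, guarded by the record's provenance flag.
    """
    if record.interlab_calibrated:
        raise ValidationError(
            f"{record.sample_id}: inter-laboratory calibration already applied"
        )
    sign = -1.0 if subtract else 1.0
    new_d13c = dict(record.aa_d13c)
    for aa, offset in spec.interlab_offsets.items():
        if aa in new_d13c:
            v = new_d13c[aa]
            new_d13c[aa] = IsotopeValue(v.mean + sign * offset, v.sd, v.n)
    return replace(record, aa_d13c=new_d13c, interlab_calibrated=True)


def suess_correct(d13c: float, offset: float) -> float:
    """Apply a user-supplied Suess-effect offset (permil) to a delta-13C value.

    Modern plant tissue is depleted in 13C relative to the pre-industrial
    atmosphere; adding a positive era-dependent offset places a modern value
    on the pre-industrial scale for comparison with archaeological material.
    """
    return d13c + offset
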