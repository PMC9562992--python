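"""Reading and writing the plain-text table dialects.

All tables are UTF-8 TSV with a single header line, "." as decimal separator
and "NA" for missing values; HGVS strings contain no tabs so no quoting is
used.  Floats are written with ``repr`` so a written table re-reads to
bit-identical values.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence, Union

from .assay import ActivityMeasurement, VariantId, percent_of_wildtype
from .calibration import ControlVariant, KnownClass
from .evidence import ProteinBands, VariantObservations

__all__ = [
    "ParseError",
    "read_controls_tsv",
    "write_controls_tsv",
    "read_observations_tsv",
    "write_observations_tsv",
    "read_measurements_tsv",
    "write_measurements_tsv",
]

NA = "NA"


class ParseError(ValueError):
    """A table cell failed to parse; names the file, line, and column."""

    def __init__(self, path, lineno: int, column: str, message: str):
        super().__init__(f"{path}:{lineno} column {column!r}: {message}")
        self.path, self.lineno, self.column = str(path), lineno, column


def _fmt(value) -> str:
    if value is None:
        return NA
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_float(raw: str, path, lineno: int, column: str) -> Optional[float]:
    if raw == NA or raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise ParseError(path, lineno, column, f"not a number: {raw!r}") from None


def _parse_bool(raw: str, path, lineno: int, column: str) -> bool:
    if raw in ("true", "True", "1"):
        return True
    if raw in ("false", "False", "0", NA, ""):
        return False
    raise ParseError(path, lineno, column, f"not a boolean: {raw!r}")


def _write_rows(path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow([_fmt(v) for v in row])


def _read_rows(path) -> tuple[list[str], list[dict[str, str]]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(path, 1, "", "empty file, expected a header line")
        return list(reader.fieldnames), list(reader)


def _rep_columns(n: int) -> list[str]:
    return [f"rep{i + 1}" for i in range(n)]


def _measurement_row(m: ActivityMeasurement, n_rep: int) -> list:
    reps: list = list(m.replicates) + [None] * (n_rep - len(m.replicates))
    pct = None if m.below_detection else m.percent_wt
    return reps + [pct, m.below_detection]


def _measurement_from_row(
    row: dict[str, str], rep_cols: Sequence[str], path, lineno: int
) -> ActivityMeasurement:
    below = _parse_bool(row.get("below_detection", ""), path, lineno, "below_detection")
    if below:
        return ActivityMeasurement.not_detectable()
    reps = [
        v
        for c in rep_cols
        if (v := _parse_float(row.get(c, NA), path, lineno, c)) is not None
    ]
    pct = _parse_float(row.get("percent_wt", NA), path, lineno, "percent_wt")
    if reps:
        return ActivityMeasurement(replicates=reps)
    if pct is None:
        raise ParseError(
            path, lineno, "percent_wt", "no replicates and no percent_wt given"
        )
    return ActivityMeasurement.from_percent(pct)


# ---------------------------------------------------------------- controls


def write_controls_tsv(controls: Sequence[ControlVariant], path) -> None:
    n_rep = max((len(c.activity.replicates) for c in controls), default=0)
    header = ["variant_cdna", "variant_protein", "known_class"] + _rep_columns(
        n_rep
    ) + ["percent_wt", "below_detection"]
    rows = [
        [c.id.cdna, c.id.protein, c.known_class.value]
        + _measurement_row(c.activity, n_rep)
        for c in controls
    ]
    _write_rows(path, header, rows)


def read_controls_tsv(path) -> list[ControlVariant]:
    header, rows = _read_rows(path)
    rep_cols = [c for c in header if c.startswith("rep")]
    controls = []
    for lineno, row in enumerate(rows, start=2):
        try:
            cls = KnownClass(row.get("known_class", ""))
        except ValueError:
            raise ParseError(
                path, lineno, "known_class",
                f"unknown class {row.get('known_class')!r}",
            ) from None
        try:
            vid = VariantId(row.get("variant_cdna", ""), row.get("variant_protein", ""))
        except ValueError as e:
            raise ParseError(path, lineno, "variant_cdna", str(e)) from None
        controls.append(
            ControlVariant(vid, cls, _measurement_from_row(row, rep_cols, path, lineno))
        )
    _check_unique(controls, path)
    return controls


def _check_unique(records, path) -> None:
    seen: set[str] = set()
    for r in records:
        cdna = r.id.cdna
        if cdna in seen:
            raise ParseError(path, 0, "variant_cdna", f"duplicate variant {cdna!r}")
        seen.add(cdna)


# ------------------------------------------------------------ observations


def write_observations_tsv(observations: Sequence[VariantObservations], path) -> None:
    n_rep = max(
        (len(o.activity.replicates) for o in observations if o.activity is not None),
        default=0,
    )
    pops: list[str] = []
    for o in observations:
        for p in o.af_by_population:
            if p not in pops:
                pops.append(p)
    af_cols = [f"af_{p}" for p in pops]
    header = (
        ["variant_cdna", "variant_protein"]
        + _rep_columns(n_rep)
        + ["percent_wt", "below_detection"]
        + af_cols
        + [
            "in_trans_pathogenic",
            "trans_partner",
            "same_codon_pathogenic",
            "same_codon_variant",
            "same_codon_protein",
            "revel",
            "phenotype_consistent",
            "pseudodeficiency_excluded",
            "protein_bands",
        ]
    )
    rows = []
    for o in observations:
        meas = _measurement_row(o.activity, n_rep) if o.activity is not None else (
            [None] * n_rep + [None, False]
        )
        rows.append(
            [o.id.cdna, o.id.protein]
            + meas
            + [o.af_by_population.get(p) for p in pops]
            + [
                o.in_trans_pathogenic,
                o.trans_partner or None,
                o.same_codon_pathogenic,
                o.same_codon_variant_cdna or None,
                o.same_codon_variant_protein or None,
                o.revel,
                o.phenotype_consistent,
                o.pseudodeficiency_excluded,
                o.protein_bands.value,
            ]
        )
    _write_rows(path, header, rows)


def read_observations_tsv(path) -> list[VariantObservations]:
    header, rows = _read_rows(path)
    rep_cols = [c for c in header if c.startswith("rep")]
    af_cols = [c for c in header if c.startswith("af_")]
    observations = []
    for lineno, row in enumerate(rows, start=2):
        try:
            vid = VariantId(row.get("variant_cdna", ""), row.get("variant_protein", ""))
        except ValueError as e:
            raise ParseError(path, lineno, "variant_cdna", str(e)) from None
        af = {}
        for c in af_cols:
            v = _parse_float(row.get(c, NA), path, lineno, c)
            if v is not None:
                af[c[len("af_"):]] = v
        bands_raw = row.get("protein_bands", "") or ProteinBands.NOT_ASSAYED.value
        try:
            bands = ProteinBands(bands_raw)
        except ValueError:
            raise ParseError(
                path, lineno, "protein_bands", f"unknown value {bands_raw!r}"
            ) from None
        observations.append(
            VariantObservations(
                id=vid,
                activity=_measurement_from_row(row, rep_cols, path, lineno),
                af_by_population=af,
                in_trans_pathogenic=_parse_bool(
                    row.get("in_trans_pathogenic", ""), path, lineno, "in_trans_pathogenic"
                ),
                trans_partner=row.get("trans_partner", "") if row.get("trans_partner", NA) != NA else "",
                same_codon_pathogenic=_parse_bool(
                    row.get("same_codon_pathogenic", ""), path, lineno, "same_codon_pathogenic"
                ),
                same_codon_variant_cdna=row.get("same_codon_variant", "")
                if row.get("same_codon_variant", NA) != NA
                else "",
                same_codon_variant_protein=row.get("same_codon_protein", "")
                if row.get("same_codon_protein", NA) != NA
                else "",
                revel=_parse_float(row.get("revel", NA), path, lineno, "revel"),
                phenotype_consistent=_parse_bool(
                    row.get("phenotype_consistent", ""), path, lineno, "phenotype_consistent"
                ),
                pseudodeficiency_excluded=_parse_bool(
                    row.get("pseudodeficiency_excluded", ""),
                    path, lineno, "pseudodeficiency_excluded",
                ),
                protein_bands=bands,
            )
        )
    _check_unique(observations, path)
    return observations


# ------------------------------------------------------------ measurements


def write_measurements_tsv(
    measurements: dict[VariantId, ActivityMeasurement],
    path,
    units: str = "percent",
) -> None:
    """Write an assay measurement table (percent units).

    Raw-unit tables can be read (with the run's wild-type and mock controls
    supplied) but are always written back in percent of wild type, which is
    the quantity the replicates of an :class:`ActivityMeasurement` carry.
    """
    if units != "percent":
        raise ValueError("measurement tables are written in percent units")
    n_rep = max((len(m.replicates) for m in measurements.values()), default=0)
    header = ["variant_cdna", "variant_protein"] + _rep_columns(n_rep) + [
        "units", "percent_wt", "below_detection",
    ]
    rows = []
    for vid, m in measurements.items():
        reps: list = list(m.replicates) + [None] * (n_rep - len(m.replicates))
        pct = None if m.below_detection else m.percent_wt
        rows.append([vid.cdna, vid.protein] + reps + ["percent", pct, m.below_detection])
    _write_rows(path, header, rows)


def read_measurements_tsv(
    path,
    wildtype_raw: Optional[float] = None,
    mock_raw: float = 0.0,
) -> dict[VariantId, ActivityMeasurement]:
    """Read a measurement table; a ``units`` column of ``raw`` requires the
    run's wild-type (and optionally mock) raw activities for normalization."""
    header, rows = _read_rows(path)
    rep_cols = [c for c in header if c.startswith("rep")]
    out: dict[VariantId, ActivityMeasurement] = {}
    for lineno, row in enumerate(rows, start=2):
        try:
            vid = VariantId(row.get("variant_cdna", ""), row.get("variant_protein", ""))
        except ValueError as e:
            raise ParseError(path, lineno, "variant_cdna", str(e)) from None
        if vid in out:
            raise ParseError(path, lineno, "variant_cdna", f"duplicate variant {vid.cdna!r}")
        units = row.get("units", "percent") or "percent"
        if units == "raw":
            if wildtype_raw is None:
                raise ParseError(
                    path, lineno, "units",
                    "raw units require wildtype_raw for normalization",
                )
            below = _parse_bool(
                row.get("below_detection", ""), path, lineno, "below_detection"
            )
            if below:
                out[vid] = ActivityMeasurement.not_detectable()
                continue
            raws = [
                v
                for c in rep_cols
                if (v := _parse_float(row.get(c, NA), path, lineno, c)) is not None
            ]
            if not raws:
                raise ParseError(path, lineno, rep_cols[0] if rep_cols else "rep1",
                                 "raw units but no replicate values")
            pct = [percent_of_wildtype(r, wildtype_raw, mock_raw) for r in raws]
            out[vid] = ActivityMeasurement(replicates=pct)
        elif units == "percent":
            out[vid] = _measurement_from_row(row, rep_cols, path, lineno)
        else:
            raise ParseError(path, lineno, "units", f"unknown units {units!r}")
    return out
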