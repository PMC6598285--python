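"""Readers and writers for the pipeline's tabular artifacts.

All tables are tab-separated UTF-8 text with a mandatory header row, '.' as the
decimal separator and lines starting with '#' skipped.  Missing optional numeric
fields are written as ``NA`` so that "absent" never collides with zero.  Reporter
channels are fixed to the order 114, 115, 116, 117 both in file columns and in
memory; a silent channel permutation is therefore impossible by construction.

Formats
-------
psm.tsv        spectrum_id  peptide  protein_acc  log_e  has_label  in_target_db
               i114  i115  i116  i117
cog.tsv        protein_acc  cog
pathways.tsv   protein_acc  pathway_id            (one row per membership)
proteins.tsv   protein_acc  comparison  median_ratio  n_psm  p_value  status
ferm.tsv       condition_mM  h2_mL_L  co2_mL_L  ethanol_total_mg_L  acetate_mg_L
               cdw_mg_L
"""

from __future__ import annotations

import csv
import math
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from .errors import FormatError, ValidationError

#: Reporter-ion channels of the 4-plex reagent, in fixed file/memory order.
CHANNELS: tuple[int, int, int, int] = (114, 115, 116, 117)

INTENSITY_COLUMNS = tuple(f"i{c}" for c in CHANNELS)
PSM_COLUMNS = (
    "spectrum_id",
    "peptide",
    "protein_acc",
    "log_e",
    "has_label",
    "in_target_db",
    *INTENSITY_COLUMNS,
)
PROTEIN_COLUMNS = ("protein_acc", "comparison", "median_ratio", "n_psm", "p_value", "status")
FERM_COLUMNS = (
    "condition_mM",
    "h2_mL_L",
    "co2_mL_L",
    "ethanol_total_mg_L",
    "acetate_mg_L",
    "cdw_mg_L",
)

#: Single-letter COG functional categories (standard alphabet) accepted in cog.tsv.
COG_ALPHABET = tuple("JAKLBDYVTMNZWUOCGEFHIPQRS")

#: Category label used for proteins with no annotation hit at all.
UNANNOTATED = "no_hit"

_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}


@dataclass
class PSMRecord:
    """One peptide–spectrum match: the atomic input of quantitation.

    ``intensities`` holds the four reporter-ion intensities in channel order
    114, 115, 116, 117.  ``log_e`` is the log10 expectation score of the
    search-engine match (more negative = more confident).
    """

    spectrum_id: str
    peptide: str
    protein_acc: str
    log_e: float
    has_label: bool
    in_target_db: bool
    intensities: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.intensities)
        if len(vals) != 4:
            raise ValidationError(
                f"spectrum {self.spectrum_id!r}: expected 4 reporter intensities, got {len(vals)}"
            )
        for v in vals:
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"spectrum {self.spectrum_id!r}: intensities must be finite and >= 0, got {v}"
                )
        self.intensities = vals


@dataclass
class AnnotationMap:
    """Protein functional annotation: COG category letters and pathway memberships."""

    cog: dict[str, str] = field(default_factory=dict)
    pathways: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, pws in self.pathways.items():
            if not pws:
                raise ValidationError(f"protein {acc!r} mapped to an empty pathway set")
            self.pathways[acc] = frozenset(pws)
        for acc, letter in self.cog.items():
            if letter != UNANNOTATED and letter not in COG_ALPHABET:
                raise ValidationError(f"protein {acc!r}: unknown COG category {letter!r}")

    def cog_of(self, protein_acc: str) -> str:
        return self.cog.get(protein_acc, UNANNOTATED)

    def merged(self, other: "AnnotationMap") -> "AnnotationMap":
        """Combine two maps (e.g. one read from cog.tsv, one from pathways.tsv)."""
        cog = {**self.cog, **other.cog}
        pathways = {**self.pathways, **other.pathways}
        return AnnotationMap(cog=cog, pathways=pathways)


@contextmanager
def _reading(source: str | Path | IO[str]) -> Iterator[IO[str]]:
    if hasattr(source, "read"):
        yield source  # type: ignore[misc]
    else:
        with open(source, "r", encoding="utf-8", newline="") as fh:
            yield fh


@contextmanager
def _writing(sink: str | Path | IO[str]) -> Iterator[IO[str]]:
    if hasattr(sink, "write"):
        yield sink  # type: ignore[misc]
    else:
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            yield fh


def _rows(fh: IO[str]) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for data-bearing lines."""
    reader = csv.reader(fh, delimiter="\t")
    for lineno, fields in enumerate(reader, start=1):
        if not fields or (len(fields) == 1 and not fields[0].strip()):
            continue
        if fields[0].lstrip().startswith("#"):
            continue
        yield lineno, fields


def _header_index(fields: list[str], required: tuple[str, ...], lineno: int) -> dict[str, int]:
    idx = {name.strip(): i for i, name in enumerate(fields)}
    missing = [c for c in required if c not in idx]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}", line=lineno)
    return idx


def _parse_float(text: str, column: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"column {column!r}: not a number: {text!r}", line=lineno) from None


def _parse_optional_float(text: str, column: str, lineno: int) -> float | None:
    text = text.strip()
    if text == "NA" or text == "":
        return None
    return _parse_float(text, column, lineno)


def _parse_bool(text: str, column: str, lineno: int) -> bool:
    text = text.strip()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise FormatError(f"column {column!r}: not a boolean (0/1/true/false): {text!r}", line=lineno)


def _fmt(value: float | int | None) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, int):
        return str(value)
    return repr(float(value))


def read_psm_table(source: str | Path | IO[str]) -> list[PSMRecord]:
    """Parse a psm.tsv table into PSMRecords, preserving file order.

    Raises FormatError (with line number) on structural problems and
    ValidationError on negative intensities or duplicate spectrum ids.
    """
    records: list[PSMRecord] = []
    seen: set[str] = set()
    with _reading(source) as fh:
        rows = _rows(fh)
        try:
            lineno, header = next(rows)
        except StopIteration:
            raise FormatError("empty file: header row required") from None
        idx = _header_index(header, PSM_COLUMNS, lineno)
        for lineno, fields in rows:
            if len(fields) < len(header):
                raise FormatError(
                    f"expected {len(header)} fields, got {len(fields)}", line=lineno
                )
            get = lambda col: fields[idx[col]]  # noqa: E731
            intensities = tuple(
                _parse_float(get(c), c, lineno) for c in INTENSITY_COLUMNS
            )
            for c, v in zip(INTENSITY_COLUMNS, intensities):
                if not math.isfinite(v) or v < 0:
                    raise ValidationError(
                        f"column {c!r}: intensity must be finite and >= 0, got {v}", line=lineno
                    )
            spectrum_id = get("spectrum_id").strip()
            if spectrum_id in seen:
                raise ValidationError(f"duplicate spectrum_id {spectrum_id!r}", line=lineno)
            seen.add(spectrum_id)
            records.append(
                PSMRecord(
                    spectrum_id=spectrum_id,
                    peptide=get("peptide").strip(),
                    protein_acc=get("protein_acc").strip(),
                    log_e=_parse_float(get("log_e"), "log_e", lineno),
                    has_label=_parse_bool(get("has_label"), "has_label", lineno),
                    in_target_db=_parse_bool(get("in_target_db"), "in_target_db", lineno),
                    intensities=intensities,  # type: ignore[arg-type]
                )
            )
    return records


def write_psm_table(records: Iterable[PSMRecord], sink: str | Path | IO[str]) -> None:
    with _writing(sink) as fh:
        fh.write("\t".join(PSM_COLUMNS) + "\n")
        for r in records:
            fields = [
                r.spectrum_id,
                r.peptide,
                r.protein_acc,
                _fmt(r.log_e),
                _fmt(r.has_label),
                _fmt(r.in_target_db),
                *(_fmt(v) for v in r.intensities),
            ]
            fh.write("\t".join(fields) + "\n")


def read_annotation(source: str | Path | IO[str]) -> AnnotationMap:
    """Read either a cog.tsv (protein_acc, cog) or a pathways.tsv (protein_acc, pathway_id).

    The file kind is recognized from the header.  Proteins absent from the map
    are simply unannotated; use :meth:`AnnotationMap.merged` to combine a COG
    map with a pathway map.
    """
    with _reading(source) as fh:
        rows = _rows(fh)
        try:
            lineno, header = next(rows)
        except StopIteration:
            raise FormatError("empty file: header row required") from None
        names = [h.strip() for h in header]
        if names[:2] == ["protein_acc", "cog"]:
            kind = "cog"
        elif names[:2] == ["protein_acc", "pathway_id"]:
            kind = "pathway"
        else:
            raise FormatError(
                "header must be 'protein_acc<TAB>cog' or 'protein_acc<TAB>pathway_id'",
                line=lineno,
            )
        cog: dict[str, str] = {}
        pathways: dict[str, set[str]] = {}
        for lineno, fields in rows:
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError("expected two non-empty fields", line=lineno)
            acc, value = fields[0].strip(), fields[1].strip()
            if kind == "cog":
                if acc in cog and cog[acc] != value:
                    raise ValidationError(
                        f"protein {acc!r} mapped to conflicting COG categories", line=lineno
                    )
                cog[acc] = value
            else:
                pathways.setdefault(acc, set()).add(value)
    return AnnotationMap(cog=cog, pathways={a: frozenset(p) for a, p in pathways.items()})


def write_annotation_cog(ann: AnnotationMap, sink: str | Path | IO[str]) -> None:
    with _writing(sink) as fh:
        fh.write("protein_acc\tcog\n")
        for acc in sorted(ann.cog):
            fh.write(f"{acc}\t{ann.cog[acc]}\n")


def write_annotation_pathways(ann: AnnotationMap, sink: str | Path | IO[str]) -> None:
    with _writing(sink) as fh:
        fh.write("protein_acc\tpathway_id\n")
        for acc in sorted(ann.pathways):
            for pw in sorted(ann.pathways[acc]):
                fh.write(f"{acc}\t{pw}\n")


def write_protein_table(quants, sink: str | Path | IO[str]) -> None:
    """Write ProteinQuant rows, ordered by (accession, comparison)."""
    with _writing(sink) as fh:
        fh.write("\t".join(PROTEIN_COLUMNS) + "\n")
        for q in sorted(quants, key=lambda q: (q.protein_acc, q.comparison)):
            fields = [
                q.protein_acc,
                q.comparison,
                _fmt(q.median_ratio),
                _fmt(q.n_psm),
                _fmt(q.p_value),
                q.status,
            ]
            fh.write("\t".join(fields) + "\n")


def read_protein_table(source: str | Path | IO[str]):
    """Read a proteins.tsv back into ProteinQuant records."""
    from .quant import PROTEIN_STATUSES, ProteinQuant

    out = []
    with _reading(source) as fh:
        rows = _rows(fh)
        try:
            lineno, header = next(rows)
        except StopIteration:
            raise FormatError("empty file: header row required") from None
        idx = _header_index(header, PROTEIN_COLUMNS, lineno)
        for lineno, fields in rows:
            if len(fields) < len(PROTEIN_COLUMNS):
                raise FormatError(
                    f"expected {len(PROTEIN_COLUMNS)} fields, got {len(fields)}", line=lineno
                )
            status = fields[idx["status"]].strip()
            if status not in PROTEIN_STATUSES:
                raise ValidationError(f"unknown status {status!r}", line=lineno)
            try:
                n_psm = int(fields[idx["n_psm"]])
            except ValueError:
                raise FormatError(
                    f"column 'n_psm': not an integer: {fields[idx['n_psm']]!r}", line=lineno
                ) from None
            out.append(
                ProteinQuant(
                    protein_acc=fields[idx["protein_acc"]].strip(),
                    comparison=fields[idx["comparison"]].strip(),
                    median_ratio=_parse_float(fields[idx["median_ratio"]], "median_ratio", lineno),
                    n_psm=n_psm,
                    p_value=_parse_float(fields[idx["p_value"]], "p_value", lineno),
                    status=status,
                )
            )
    return out


def read_ferm_table(source: str | Path | IO[str]):
    """Read a fermentation yield table into FermentationRecords."""
    from .fermentation import FermentationRecord

    out = []
    with _reading(source) as fh:
        rows = _rows(fh)
        try:
            lineno, header = next(rows)
        except StopIteration:
            raise FormatError("empty file: header row required") from None
        idx = _header_index(header, ("condition_mM", "ethanol_total_mg_L"), lineno)

        def opt(fields, col, lineno):
            if col not in idx or idx[col] >= len(fields):
                return None
            return _parse_optional_float(fields[idx[col]], col, lineno)

        for lineno, fields in rows:
            out.append(
                FermentationRecord(
                    condition_mM=_parse_float(fields[idx["condition_mM"]], "condition_mM", lineno),
                    h2_mL_L=opt(fields, "h2_mL_L", lineno),
                    co2_mL_L=opt(fields, "co2_mL_L", lineno),
                    ethanol_total_mg_L=_parse_float(
                        fields[idx["ethanol_total_mg_L"]], "ethanol_total_mg_L", lineno
                    ),
                    acetate_mg_L=opt(fields, "acetate_mg_L", lineno),
                    cdw_mg_L=opt(fields, "cdw_mg_L", lineno),
                )
            )
    return out


def write_ferm_table(records, sink: str | Path | IO[str]) -> None:
    with _writing(sink) as fh:
        fh.write("\t".join(FERM_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: r.condition_mM):
            fields = [
                _fmt(r.condition_mM),
                _fmt(r.h2_mL_L),
                _fmt(r.co2_mL_L),
                _fmt(r.ethanol_total_mg_L),
                _fmt(r.acetate_mg_L),
                _fmt(r.cdw_mg_L),
            ]
            fh.write("\t".join(fields) + "\n")
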