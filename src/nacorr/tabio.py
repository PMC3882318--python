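"""Config-driven reading and writing of peak-table collections.

A collection is a delimited text file (CSV by default) with a header row
where each data row is one isotopologue peak of one molecule: a
molecular-formula column, one label-count column per tracer isotope, an
intensity column, and any number of pass-through metadata columns.  A
:class:`CollectionConfig` maps column names to roles and names the
tracer isotopes; rows are grouped into per-molecule datasets by the
formula column plus any user-listed grouping columns (sample, replicate,
time point), since replicates of one molecule must be corrected
independently.

Output mirrors the input byte-for-byte in the pass-through columns, with
a corrected-intensity column and a trailing QC-annotation column
appended; predicted-but-unobserved peaks are appended after each
dataset's rows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .formula import FormulaError, MolecularFormula, parse_formula
from .isotopes import DEFAULT_ISOTOPES, IsotopeSpec
from .correction import LabelOrder
from .qc import QCAnnotation, QCCode, ThresholdSpec

__all__ = [
    "PeakRecord",
    "CollectionConfig",
    "ConfigError",
    "read_collection",
    "write_collection",
    "isotope_from_label",
]

#: Names of the two columns appended to every output file.
CORRECTED_COLUMN = "corrected_intensity"
QC_COLUMN = "qc"
#: Marker placed in the QC column of appended predicted-peak rows.
PREDICTED_MARKER = "PREDICTED"


class ConfigError(ValueError):
    """Fatal configuration problem (missing file, column, bad key)."""


def isotope_from_label(
    label: str, abundance: Optional[float] = None
) -> IsotopeSpec:
    """Resolve an isotope name like ``"13C"`` to an :class:`IsotopeSpec`.

    Known labels take their default natural abundance unless *abundance*
    overrides it; unknown labels of the mass-number + element-symbol form
    require an explicit abundance.
    """
    if label in DEFAULT_ISOTOPES:
        base = DEFAULT_ISOTOPES[label]
        if abundance is None:
            return base
        return IsotopeSpec(label, base.element, abundance)
    element = label.lstrip("0123456789")
    if not element or element == label:
        raise ConfigError(f"cannot parse isotope label {label!r}")
    if abundance is None:
        raise ConfigError(
            f"isotope {label!r} has no default natural abundance; "
            "supply one in the configuration"
        )
    return IsotopeSpec(label, element, abundance)


@dataclass
class PeakRecord:
    """One input row: raw fields plus parsed formula, counts, intensity.

    Parsing failures leave the parsed fields ``None`` and attach a
    ``malformed_row`` annotation; the raw fields are always preserved for
    echoing to the output.
    """

    raw: List[str]
    row_index: int
    formula: Optional[MolecularFormula] = None
    counts: Optional[Tuple[int, ...]] = None
    intensity: Optional[float] = None
    annotations: List[QCAnnotation] = field(default_factory=list)
    corrected: Optional[float] = None

    @property
    def usable(self) -> bool:
        """True when the record can enter the correction array."""
        return (
            self.counts is not None
            and self.intensity is not None
            and not self.annotations
        )


@dataclass
class Dataset:
    """All peaks of one molecule within one grouping (sample/replicate)."""

    key: Tuple[str, ...]
    formula_text: str
    formula: Optional[MolecularFormula]
    records: List[PeakRecord] = field(default_factory=list)


@dataclass
class CollectionConfig:
    """Column mapping and run options for one collection."""

    input_path: str
    output_path: str
    formula_column: str
    intensity_column: str
    #: ordered mapping isotope label -> count column; order fixes the
    #: array dimensions.
    count_columns: Dict[str, str]
    delimiter: str = ","
    group_columns: List[str] = field(default_factory=list)
    abundances: Dict[str, float] = field(default_factory=dict)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    cache: bool = True
    processes: int = 1
    max_iterations: int = 100

    def label_order(self) -> LabelOrder:
        return LabelOrder(
            tuple(
                isotope_from_label(label, self.abundances.get(label))
                for label in self.count_columns
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CollectionConfig":
        """Load a configuration from a YAML document (keys in README)."""
        try:
            with open(path) as fh:
                doc = yaml.safe_load(fh)
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        if not isinstance(doc, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        try:
            isotopes = doc["isotopes"]
            count_columns: Dict[str, str] = {}
            abundances: Dict[str, float] = {}
            for entry in isotopes:
                label = str(entry["label"])
                count_columns[label] = str(entry["column"])
                if "abundance" in entry:
                    abundances[label] = float(entry["abundance"])
            thr = doc.get("threshold") or {}
            threshold = ThresholdSpec(
                percent=float(thr.get("percent", 0.0)),
                statistic=str(thr.get("statistic", "minimum")),
                scope=str(thr.get("scope", "collection")),
                enabled=bool(thr.get("enabled", bool(thr))),
            )
            return cls(
                input_path=str(doc["input"]),
                output_path=str(doc["output"]),
                formula_column=str(doc.get("formula_column", "formula")),
                intensity_column=str(doc.get("intensity_column", "intensity")),
                count_columns=count_columns,
                delimiter=str(doc.get("delimiter", ",")),
                group_columns=[str(c) for c in doc.get("group_columns", [])],
                abundances=abundances,
                threshold=threshold,
                cache=bool(doc.get("cache", True)),
                processes=int(doc.get("processes", 1)),
                max_iterations=int(doc.get("max_iterations", 100)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc.args[0]!r}") from exc


def _column_indices(header: Sequence[str], config: CollectionConfig) -> Dict[str, int]:
    idx: Dict[str, int] = {}
    wanted = (
        [config.formula_column, config.intensity_column]
        + list(config.count_columns.values())
        + config.group_columns
    )
    for name in wanted:
        if name not in header:
            raise ConfigError(
                f"configured column {name!r} not found in header {list(header)}"
            )
        idx[name] = header.index(name)
    return idx


def read_collection(
    config: CollectionConfig,
) -> Tuple[List[str], List[Dataset]]:
    """Read and group a peak collection.

    Returns the header and the list of per-molecule datasets in order of
    first appearance; within each dataset records keep file order.
    Unparseable rows are annotated ``malformed_row`` and carried along
    (they are echoed to the output but excluded from correction).
    """
    path = Path(config.input_path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=config.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ConfigError(f"input file {path} is empty (no header)") from None
        idx = _column_indices(header, config)
        datasets: Dict[Tuple[str, ...], Dataset] = {}
        order: List[Tuple[str, ...]] = []
        for row_index, raw in enumerate(reader):
            if not raw:
                continue
            rec = _parse_record(raw, row_index, idx, config)
            formula_text = (
                raw[idx[config.formula_column]]
                if idx[config.formula_column] < len(raw)
                else ""
            )
            group = tuple(
                raw[idx[c]] if idx[c] < len(raw) else ""
                for c in config.group_columns
            )
            key = (formula_text,) + group
            if key not in datasets:
                formula = rec.formula
                datasets[key] = Dataset(
                    key=key, formula_text=formula_text, formula=formula
                )
                order.append(key)
            ds = datasets[key]
            if ds.formula is None and rec.formula is not None:
                ds.formula = rec.formula
            ds.records.append(rec)
    return header, [datasets[k] for k in order]


def _parse_record(
    raw: List[str],
    row_index: int,
    idx: Dict[str, int],
    config: CollectionConfig,
) -> PeakRecord:
    rec = PeakRecord(raw=list(raw), row_index=row_index)
    problems: List[str] = []

    def cell(col: str) -> str:
        i = idx[col]
        return raw[i] if i < len(raw) else ""

    try:
        rec.formula = parse_formula(cell(config.formula_column))
    except FormulaError as exc:
        problems.append(f"formula: {exc}")

    counts: List[int] = []
    for label, col in config.count_columns.items():
        text = cell(col).strip()
        try:
            value = int(text)
            if value < 0:
                raise ValueError("negative")
            counts.append(value)
        except ValueError:
            problems.append(f"{label} count {text!r} is not a nonnegative integer")
    if len(counts) == len(config.count_columns):
        rec.counts = tuple(counts)

    text = cell(config.intensity_column).strip()
    try:
        value = float(text)
        if not value >= 0 or value != value or value in (float("inf"),):
            raise ValueError("not a finite nonnegative number")
        rec.intensity = value
    except ValueError:
        problems.append(f"intensity {text!r} is not a finite nonnegative number")

    if problems:
        rec.counts = None
        rec.intensity = None
        rec.annotations.append(
            QCAnnotation(QCCode.MALFORMED_ROW, "; ".join(problems))
        )
    return rec


def write_collection(
    header: Sequence[str],
    datasets: Sequence[Dataset],
    predicted: Dict[Tuple[str, ...], List[Tuple[Tuple[int, ...], float]]],
    config: CollectionConfig,
) -> int:
    """Write the corrected collection.

    Every input row is echoed in file order with its original columns,
    followed by the corrected intensity (full ``repr`` precision; blank
    for rows excluded from correction) and the joined QC annotations.
    Predicted-but-unobserved peaks for a dataset are appended directly
    after its last row, marked ``PREDICTED`` in the QC column.  Returns
    the number of rows written (excluding the header).
    """
    out_header = list(header) + [CORRECTED_COLUMN, QC_COLUMN]
    idx = _column_indices(header, config)

    # input rows in original file order, remembering each dataset's last row
    rows: List[Tuple[int, Dataset, PeakRecord]] = []
    for ds in datasets:
        for rec in ds.records:
            rows.append((rec.row_index, ds, rec))
    rows.sort(key=lambda t: t[0])
    last_row_of: Dict[Tuple[str, ...], int] = {}
    for pos, (_, ds, _rec) in enumerate(rows):
        last_row_of[ds.key] = pos

    written = 0
    with open(config.output_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=config.delimiter)
        writer.writerow(out_header)
        for pos, (_, ds, rec) in enumerate(rows):
            corrected = "" if rec.corrected is None else repr(rec.corrected)
            notes = "; ".join(str(a) for a in rec.annotations)
            writer.writerow(list(rec.raw) + [corrected, notes])
            written += 1
            if pos == last_row_of[ds.key]:
                for counts, intensity in predicted.get(ds.key, []):
                    writer.writerow(
                        _predicted_row(header, idx, ds, counts, intensity, config)
                    )
                    written += 1
    return written


def _predicted_row(
    header: Sequence[str],
    idx: Dict[str, int],
    ds: Dataset,
    counts: Tuple[int, ...],
    intensity: float,
    config: CollectionConfig,
) -> List[str]:
    row = [""] * len(header)
    row[idx[config.formula_column]] = ds.formula_text
    for gcol, gval in zip(config.group_columns, ds.key[1:]):
        row[idx[gcol]] = gval
    for (label, col), count in zip(config.count_columns.items(), counts):
        row[idx[col]] = str(count)
    row[idx[config.intensity_column]] = repr(intensity)
    return row + [
        "",
        f"{PREDICTED_MARKER}: predicted intensity {intensity!r} "
        "at or above threshold but not observed",
    ]
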