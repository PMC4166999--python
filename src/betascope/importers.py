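"""Parsers for the supported deposition formats.

Supported inputs: beta CSV tables (probes x samples), GenomeStudio-style
final reports (TSV with per-sample AVG_Beta columns), sample metadata as
JSON lines, BED12 gene models, and the probe annotation CSV. Everything
parses into in-memory objects that feed :meth:`Store.deposit_betas` and
friends.
"""

from __future__ import annotations

import csv
import io
import json
import math
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BetaRangeError, ParseError
from .types import GenomicRegion, ProbeAnnotation, SampleRecord

#: CSV cell tokens treated as a missing value (R and GenomeStudio exports differ).
MISSING_TOKENS = ("", "NA", "NaN")


@dataclass
class BetaMatrix:
    """A probes x samples grid of beta values with explicit missingness.

    ``values`` is a float DataFrame indexed by probe_id with sample_id
    columns; missing measurements are NaN and are never written as 0.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BetaRangeError(
                f"beta {arr[i, j]!r} for probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r} is outside [0, 1]"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def n_values(self) -> int:
        return int(self.values.notna().sum().sum())

    def sample_values(self, sample_id: str) -> dict[str, float]:
        """Non-missing probe -> beta map for one sample."""
        col = self.values[sample_id]
        return {pid: float(v) for pid, v in col.items() if not math.isnan(v)}

    def equals(self, other: "BetaMatrix") -> bool:
        """Value equality including the missing-cell pattern."""
        if self.probe_ids != other.probe_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values.to_numpy(float), other.values.to_numpy(float)
        return bool(np.all((np.isnan(a) & np.isnan(b)) | (a == b)))


def parse_beta_csv(stream) -> BetaMatrix:
    """Parse a beta CSV table: first column probe id, remaining columns one
    per sample; empty cells (or NA/NaN) are missing."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty beta CSV") from None
    if len(header) < 2:
        raise ParseError("beta CSV needs a probe-id column plus sample columns", line=1)
    sample_ids = header[1:]
    probe_ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, row in enumerate(reader, 2):
        if not row:
            continue
        if len(row) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(row)}", line=lineno
            )
        probe_id = row[0]
        if probe_id in seen:
            raise ParseError(f"duplicate probe row {probe_id!r}", line=lineno)
        seen.add(probe_id)
        probe_ids.append(probe_id)
        parsed = []
        for col, cell in zip(sample_ids, row[1:]):
            parsed.append(_parse_beta_cell(cell, lineno, col))
        rows.append(parsed)
    values = pd.DataFrame(rows, index=probe_ids, columns=sample_ids, dtype=float)
    return BetaMatrix(values)


def _parse_beta_cell(cell: str, lineno: int, column: str) -> float:
    cell = cell.strip()
    if cell in MISSING_TOKENS:
        return math.nan
    try:
        value = float(cell)
    except ValueError:
        raise ParseError(f"non-numeric beta {cell!r}", line=lineno, column=column) from None
    if math.isnan(value):
        return math.nan
    if not 0.0 <= value <= 1.0:
        raise ParseError(
            f"beta {value!r} outside [0, 1]", line=lineno, column=column
        )
    return value


def write_beta_csv(matrix: BetaMatrix, stream) -> None:
    """Inverse of :func:`parse_beta_csv`; missing cells become empty fields."""
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(["probe_id", *matrix.sample_ids])
    for probe_id, row in matrix.values.iterrows():
        writer.writerow(
            [probe_id] + ["" if math.isnan(v) else repr(float(v)) for v in row]
        )


# ------------------------------------------------------------- GenomeStudio

AVG_BETA_SUFFIX = ".AVG_Beta"
DETECTION_SUFFIX = ".Detection Pval"


def parse_genomestudio(stream, detection_pval_threshold: float | None = None) -> BetaMatrix:
    """Parse a GenomeStudio-style final report.

    Tab-separated with a ``TargetID`` column and per-sample ``<s>.AVG_Beta``
    columns; optional ``[Header]`` preamble lines are skipped up to the
    column-header row. When ``detection_pval_threshold`` is given and a
    ``<s>.Detection Pval`` column exists, betas with p above the threshold
    become missing (masking is opt-in: QC is an upstream decision).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if "TargetID" in line.split("\t"):
            header_idx = i
            break
    if header_idx is None:
        raise ParseError("no column-header row containing TargetID found")
    header = lines[header_idx].split("\t")
    target_col = header.index("TargetID")
    beta_cols = [
        (i, name[: -len(AVG_BETA_SUFFIX)])
        for i, name in enumerate(header)
        if name.endswith(AVG_BETA_SUFFIX)
    ]
    if not beta_cols:
        raise ParseError("report has no AVG_Beta columns")
    pval_cols = {
        name[: -len(DETECTION_SUFFIX)]: i
        for i, name in enumerate(header)
        if name.endswith(DETECTION_SUFFIX)
    }
    sample_ids = [sid for _, sid in beta_cols]
    probe_ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(fields)}", line=lineno
            )
        probe_id = fields[target_col]
        if probe_id in seen:
            raise ParseError(f"duplicate probe row {probe_id!r}", line=lineno)
        seen.add(probe_id)
        probe_ids.append(probe_id)
        row = []
        for i, sid in beta_cols:
            beta = _parse_beta_cell(fields[i], lineno, header[i])
            if (
                detection_pval_threshold is not None
                and sid in pval_cols
                and not math.isnan(beta)
            ):
                pcell = fields[pval_cols[sid]].strip()
                if pcell not in MISSING_TOKENS and float(pcell) > detection_pval_threshold:
                    beta = math.nan
            row.append(beta)
        rows.append(row)
    values = pd.DataFrame(rows, index=probe_ids, columns=sample_ids, dtype=float)
    return BetaMatrix(values)


# ------------------------------------------------------------ sample records


def parse_sample_json(stream) -> list[SampleRecord]:
    """Parse JSON-lines sample records.

    Each line is a flat object; ``sample_id`` and ``project`` are required,
    every other key becomes metadata verbatim (absent keys stay absent).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records = []
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed JSON: {exc.msg}", line=lineno) from exc
        if not isinstance(obj, dict):
            raise ParseError("sample record must be a JSON object", line=lineno)
        if "sample_id" not in obj:
            raise ParseError("sample record missing required key 'sample_id'", line=lineno)
        if "project" not in obj:
            raise ParseError("sample record missing required key 'project'", line=lineno)
        sample_id = obj.pop("sample_id")
        project = obj.pop("project")
        records.append(SampleRecord(sample_id=sample_id, project=project, metadata=obj))
    return records


def write_sample_json(records: Iterable[SampleRecord], stream) -> None:
    for rec in records:
        obj = {"sample_id": rec.sample_id, "project": rec.project}
        obj.update(rec.metadata)
        stream.write(json.dumps(obj, sort_keys=True))
        stream.write("\n")


# -------------------------------------------------------------- gene models


@dataclass
class GeneModel:
    """Gene structure for the visualization's gene track.

    All coordinates are 1-based inclusive (converted from BED's 0-based
    half-open convention).
    """

    name: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list = field(default_factory=list)  # list[tuple[int, int]]

    @property
    def introns(self) -> list:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def overlaps(self, region: GenomicRegion) -> bool:
        return (
            self.chromosome == region.chromosome
            and self.start <= region.end
            and self.end >= region.start
        )


def parse_gene_models(stream) -> list[GeneModel]:
    """Parse BED12 gene models into 1-based inclusive exon/intron intervals."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    genes = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(
                f"expected 12 BED fields, found {len(fields)}", line=lineno
            )
        try:
            chrom = fields[0]
            start0 = int(fields[1])
            end0 = int(fields[2])
            name = fields[3]
            strand = fields[5] if fields[5] in ("+", "-") else "unknown"
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed BED12 record: {exc}", line=lineno) from exc
        if len(sizes) != block_count or len(starts) != block_count:
            raise ParseError(
                f"blockCount {block_count} does not match block lists", line=lineno
            )
        if end0 <= start0:
            raise ParseError(f"end {end0} not after start {start0}", line=lineno)
        exons = []
        for size, offset in zip(sizes, starts):
            exon_start = start0 + offset + 1  # to 1-based inclusive
            exons.append((exon_start, exon_start + size - 1))
        genes.append(
            GeneModel(
                name=name,
                chromosome=chrom,
                start=start0 + 1,
                end=end0,
                strand=strand,
                exons=exons,
            )
        )
    return genes


# ----------------------------------------------------------- annotation CSV

ANNOTATION_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "strand",
    "genes",
    "island_class",
    "snp_in_probe",
    "snp_at_cpg",
    "reliable",
]


def _parse_bool(token: str, lineno: int, column: str) -> bool:
    token = token.strip().lower()
    if token == "true":
        return True
    if token == "false":
        return False
    raise ParseError(f"expected true/false, got {token!r}", line=lineno, column=column)


def parse_annotation_csv(stream) -> list[ProbeAnnotation]:
    """Parse the probe annotation table (genes ;-separated, booleans
    true/false)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty annotation CSV") from None
    if header != ANNOTATION_COLUMNS:
        raise ParseError(
            f"annotation header must be {','.join(ANNOTATION_COLUMNS)}", line=1
        )
    records = []
    for lineno, row in enumerate(reader, 2):
        if not row:
            continue
        if len(row) != len(ANNOTATION_COLUMNS):
            raise ParseError(
                f"expected {len(ANNOTATION_COLUMNS)} fields, found {len(row)}",
                line=lineno,
            )
        try:
            position = int(row[2])
        except ValueError:
            raise ParseError(
                f"non-integer position {row[2]!r}", line=lineno, column="position"
            ) from None
        genes = tuple(g for g in row[4].split(";") if g)
        records.append(
            ProbeAnnotation(
                probe_id=row[0],
                chromosome=row[1],
                position=position,
                strand=row[3],
                genes=genes,
                island_class=row[5],
                snp_in_probe=_parse_bool(row[6], lineno, "snp_in_probe"),
                snp_at_cpg=_parse_bool(row[7], lineno, "snp_at_cpg"),
                reliable=_parse_bool(row[8], lineno, "reliable"),
            )
        )
    return records


def write_annotation_csv(records: Iterable[ProbeAnnotation], stream) -> None:
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(ANNOTATION_COLUMNS)
    for rec in records:
        writer.writerow(
            [
                rec.probe_id,
                rec.chromosome,
                rec.position,
                rec.strand,
                ";".join(rec.genes),
                rec.island_class,
                "true" if rec.snp_in_probe else "false",
                "true" if rec.snp_at_cpg else "false",
                "true" if rec.reliable else "false",
            ]
        )


def deposit_matrix(store, project: str, matrix: BetaMatrix):
    """Deposit every sample column of a matrix; returns summed stats."""
    from .store import DepositStats

    total = DepositStats(0, 0)
    for sample_id in matrix.sample_ids:
        stats = store.deposit_betas(project, sample_id, matrix.sample_values(sample_id))
        total.n_written += stats.n_written
        total.n_unannotated_skipped += stats.n_unannotated_skipped
    return total
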