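"""Tabular I/O for the pulldown pipeline.

Everything the pipeline reads or writes is plain TSV (tab-separated,
UTF-8, mandatory header row, ``.`` or an empty cell meaning missing) or
JSON.  Protein identity is always the sequence name (e.g. ``F48F7.1``);
display names like ``ALG-1`` are decoration and never used as keys.

The module also ships a small packaged fixture: the published table of
proteins that co-precipitated with two or more miRNAs or with the
Argonaute ALG-1, with per-dataset average NSAF ratios and spectral
counts.  The fixture's presence/absence pattern across the four
datasets is the substrate of the overlap analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import (
    ConflictError,
    DuplicateRecordError,
    EmptyInputError,
    SchemaError,
    ValidationError,
)

MISSING_CELLS = {"", ".", "NA", "nan"}

#: Dataset identifiers of the packaged fixture, in publication order:
#: three 2'O-methyl oligo pulldowns and the ALG-1 immunoprecipitation.
TABLE1_DATASETS = ("let7_pd", "mir58_pd", "mir2_pd", "alg1_ip")


@dataclass(frozen=True)
class ProteinRecord:
    """Identity, length and annotation terms of one protein."""

    protein_id: str
    display_name: str = ""
    length_aa: int = 1
    terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if self.length_aa < 1:
            raise ValidationError(
                f"length_aa must be >= 1 for {self.protein_id!r}, got {self.length_aa}"
            )


@dataclass(frozen=True)
class SampleColumn:
    """One mass-spec sample: pulldown or scrambled control, replicate k."""

    sample_id: str
    condition: str  # "pulldown" | "control"
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in ("pulldown", "control"):
            raise ValidationError(
                f"condition must be 'pulldown' or 'control', got {self.condition!r}"
            )
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")


@dataclass
class ExperimentTable:
    """Spectral counts and unique-peptide counts per protein per sample.

    Missing (protein, sample) pairs are zero counts — shotgun MS tables
    are sparse by nature and absence of a row means "not detected".
    """

    bait_id: str
    samples: list[SampleColumn]
    counts: dict[tuple[str, str], int]
    peptides: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("sample_id values must be unique")
        keys = {(s.condition, s.replicate) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValidationError("(condition, replicate) pairs must be unique")
        for (pid, sid), v in self.counts.items():
            if v < 0:
                raise ValidationError(f"negative spectral count for ({pid}, {sid})")
        for (pid, sid), v in self.peptides.items():
            if v < 0:
                raise ValidationError(f"negative peptide count for ({pid}, {sid})")

    # -- accessors -----------------------------------------------------

    def count(self, protein_id: str, sample_id: str) -> int:
        return self.counts.get((protein_id, sample_id), 0)

    def peptide(self, protein_id: str, sample_id: str) -> int:
        return self.peptides.get((protein_id, sample_id), 0)

    def protein_ids(self) -> list[str]:
        return sorted({pid for pid, _ in self.counts} | {pid for pid, _ in self.peptides})

    def samples_of(self, condition: str) -> list[SampleColumn]:
        return sorted(
            (s for s in self.samples if s.condition == condition),
            key=lambda s: s.replicate,
        )


@dataclass(frozen=True)
class Table1Entry:
    """One dataset cell of the published overlap table."""

    avg_ratio: float
    spectral_count: float  # stored verbatim; unused by classification

    def __post_init__(self) -> None:
        if self.avg_ratio <= 0:
            raise ValidationError("avg_ratio must be positive")


@dataclass(frozen=True)
class Table1Row:
    protein_id: str
    display_name: str
    entries: Mapping[str, Table1Entry]  # dataset_id -> entry; absent = NA
    description: str = ""

    def datasets(self) -> frozenset[str]:
        return frozenset(self.entries)


@dataclass
class Table1Fixture:
    """The packaged published overlap table (41 proteins, 4 datasets)."""

    rows: list[Table1Row]
    dataset_ids: tuple[str, ...] = TABLE1_DATASETS

    def calls_by_dataset(self) -> dict[str, set[str]]:
        """Protein sets per dataset, the input to membership building."""
        out: dict[str, set[str]] = {d: set() for d in self.dataset_ids}
        for row in self.rows:
            for d in row.entries:
                out[d].add(row.protein_id)
        return out


# ---------------------------------------------------------------------
# readers


_LONG_COLUMNS = (
    "protein_id",
    "sample_id",
    "condition",
    "replicate",
    "spectral_count",
    "unique_peptides",
)


def _to_int(cell, what: str, where: str) -> int:
    try:
        value = int(float(cell))
    except (TypeError, ValueError):
        raise ValidationError(f"unparseable {what} {cell!r} at {where}") from None
    if float(cell) != value:
        raise ValidationError(f"non-integer {what} {cell!r} at {where}")
    return value


def read_counts_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    bait_id: str | None = None,
) -> ExperimentTable:
    """Read a long-format counts TSV into an :class:`ExperimentTable`.

    Parameters
    ----------
    path:
        TSV with one row per (protein, sample) observation.
    schema:
        Optional mapping from the canonical column names
        (``protein_id``, ``sample_id``, ``condition``, ``replicate``,
        ``spectral_count``, ``unique_peptides``) to the file's actual
        column names.
    bait_id:
        Bait label; defaults to a ``bait_id`` column if present, else
        the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    colmap = {canon: schema.get(canon, canon) for canon in _LONG_COLUMNS}
    for canon, actual in colmap.items():
        if actual not in df.columns:
            raise SchemaError(f"required column {actual!r} (for {canon!r}) not found")

    samples: dict[str, SampleColumn] = {}
    counts: dict[tuple[str, str], int] = {}
    peptides: dict[tuple[str, str], int] = {}
    positions = {canon: df.columns.get_loc(colmap[canon]) for canon in _LONG_COLUMNS}
    for i, values in enumerate(df.itertuples(index=False, name=None), start=2):
        pid = values[positions["protein_id"]]
        sid = values[positions["sample_id"]]
        where = f"{path.name}:{i}"
        if not pid or not sid:
            raise ValidationError(f"empty protein or sample id at {where}")
        cond = values[positions["condition"]]
        rep = _to_int(values[positions["replicate"]], "replicate", where)
        sample = SampleColumn(sid, cond, rep)
        if sid in samples:
            if samples[sid] != sample:
                raise ConflictError(f"sample {sid!r} redefined at {where}")
        else:
            samples[sid] = sample
        key = (pid, sid)
        if key in counts:
            raise DuplicateRecordError(f"duplicate record for {key} at {where}")
        counts[key] = _to_int(values[positions["spectral_count"]], "spectral count", where)
        peptides[key] = _to_int(values[positions["unique_peptides"]], "peptide count", where)

    if bait_id is None:
        bait_id = df["bait_id"].iloc[0] if "bait_id" in df.columns and len(df) else path.stem
    return ExperimentTable(
        bait_id=bait_id,
        samples=sorted(samples.values(), key=lambda s: (s.condition, s.replicate)),
        counts=counts,
        peptides=peptides,
    )


def read_lengths(path: str | Path, format: str = "tsv") -> dict[str, int]:
    """Read protein lengths (amino acids) from a TSV or FASTA file.

    TSV rows are ``protein_id<TAB>length``; a header line is detected by
    a non-numeric length cell and skipped.  For FASTA the length is the
    sequence length in residues.  Duplicate ids must agree on length.
    """
    path = Path(path)
    lengths: dict[str, int] = {}

    def _add(pid: str, length: int) -> None:
        if pid in lengths and lengths[pid] != length:
            raise ConflictError(
                f"conflicting lengths for {pid!r}: {lengths[pid]} vs {length}"
            )
        lengths[pid] = length

    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            _add(rec.id, len(rec.seq))
    elif format == "tsv":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValidationError(f"expected 2 columns at {path.name}:{lineno}")
                try:
                    length = int(float(parts[1]))
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise ValidationError(
                        f"unparseable length {parts[1]!r} at {path.name}:{lineno}"
                    ) from None
                if length < 1:
                    raise ValidationError(f"length must be >= 1 at {path.name}:{lineno}")
                _add(parts[0], length)
    else:
        raise ValidationError(f"unknown length format {format!r}")

    if not lengths:
        raise EmptyInputError(f"no length records in {path}")
    return lengths


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a protein → annotation-term map from a TSV.

    Columns: ``protein_id``, ``term_id`` and optionally ``namespace``
    (namespaces are folded into the term set as-is; filter upstream).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein_id", "term_id"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found")
    out: dict[str, set[str]] = {}
    for pid, term in zip(df["protein_id"], df["term_id"]):
        if not pid or not term:
            raise ValidationError("empty protein_id or term_id in annotations")
        out.setdefault(pid, set()).add(term)
    return out


def read_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read an undirected edge list TSV (columns protein_a, protein_b)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein_a", "protein_b"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found")
    return [(a, b) for a, b in zip(df["protein_a"], df["protein_b"])]


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged published overlap table (41 rows)."""
    text = resources.files("copre.data").joinpath("table1.tsv").read_text("utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    rows: list[Table1Row] = []
    for line in lines[1:]:
        cells = dict(zip(header, line.split("\t")))
        entries: dict[str, Table1Entry] = {}
        for ds in TABLE1_DATASETS:
            ratio, sc = cells[f"{ds}_ratio"], cells[f"{ds}_sc"]
            if ratio in MISSING_CELLS:
                continue
            entries[ds] = Table1Entry(avg_ratio=float(ratio), spectral_count=float(sc))
        if not entries:
            raise ValidationError(f"fixture row {cells['protein_id']} has no datasets")
        rows.append(
            Table1Row(
                protein_id=cells["protein_id"],
                display_name=cells["display_name"],
                entries=entries,
                description=cells.get("description", ""),
            )
        )
    return Table1Fixture(rows=rows)


# ---------------------------------------------------------------------
# writers


def write_experiment_table(table: ExperimentTable, path: str | Path) -> None:
    """Write an :class:`ExperimentTable` as a long-format TSV (round-trips)."""
    rows = []
    sample_by_id = {s.sample_id: s for s in table.samples}
    keys = sorted(set(table.counts) | set(table.peptides))
    for pid, sid in keys:
        s = sample_by_id[sid]
        rows.append(
            (pid, sid, s.condition, s.replicate, table.count(pid, sid), table.peptide(pid, sid))
        )
    df = pd.DataFrame(rows, columns=list(_LONG_COLUMNS))
    df.insert(0, "bait_id", table.bait_id)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_results(
    records: Iterable,
    path: str | Path,
    parameters: Mapping | None = None,
    seed: int | None = None,
) -> None:
    """Write result records as a deterministic TSV plus a JSON run summary.

    Records must be dataclass instances of a single type; columns follow
    the dataclass field order and rows are sorted lexicographically by
    the first field (then the second, for stability).  Rerunning on
    identical input yields byte-identical files: the summary holds only
    parameters, the seed and row counts, never timestamps.
    """
    records = list(records)
    path = Path(path)
    if records:
        if len({type(r) for r in records}) != 1 or not dataclasses.is_dataclass(records[0]):
            raise ValidationError("records must be dataclasses of a single type")
        fields = [f.name for f in dataclasses.fields(records[0])]
    else:
        fields = []

    def _cell(value) -> str:
        if isinstance(value, bool):
            return str(value).lower()
        if isinstance(value, (list, tuple)):
            return ",".join(_cell(v) for v in value)
        if isinstance(value, (frozenset, set)):
            return ",".join(sorted(map(str, value)))
        if isinstance(value, float):
            return repr(value)
        return str(value)

    lines = ["\t".join(fields)]
    table = sorted(
        ([_cell(getattr(r, f)) for f in fields] for r in records),
        key=lambda cells: cells[:2],
    )
    lines.extend("\t".join(cells) for cells in table)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    summary = {
        "n_records": len(records),
        "record_type": type(records[0]).__name__ if records else None,
        "parameters": dict(parameters or {}),
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2, default=str) + "\n", encoding="utf-8"
    )
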