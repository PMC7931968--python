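"""Core data carriers and file I/O.

The universal carrier is :class:`ExpressionMatrix`: a gene-by-sample matrix of
log2 treated/control expression ratios with optional per-sample metadata.
Gene identifiers are canonicalized (upper-cased, whitespace-trimmed HGNC-style
symbols) on construction so that panel matching is exact string equality.

Also provided: the :class:`BiomarkerPanel` gene list, the ternary call
vocabulary used by every classifier ("+", "+/-", "-"), per-agent fixture
records transcribing the published training and validation agent tables, and
readers/writers for delimited text and GCT 1.2 matrices.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, FormatError, ValidationError

__all__ = [
    "TernaryCall",
    "SampleMeta",
    "ExpressionMatrix",
    "BiomarkerPanel",
    "AgentRecord",
    "canonicalize_gene_id",
    "read_expression_table",
    "write_expression_table",
    "subset_to_panel",
    "load_fixture",
    "example_panel",
]


def canonicalize_gene_id(gene_id: str) -> str:
    """Upper-case and trim a gene symbol. Idempotent."""
    return str(gene_id).strip().upper()


class TernaryCall(Enum):
    """Three-valued classification outcome: positive, marginal, negative."""

    POS = "+"
    MARGINAL = "+/-"
    NEG = "-"

    @classmethod
    def from_text(cls, text: str) -> "TernaryCall":
        t = text.strip().replace("–", "-").replace("−", "-")
        for member in cls:
            if t == member.value:
                return member
        raise ValidationError(f"not a ternary call: {text!r} (expected '+', '+/-' or '-')")

    def __str__(self) -> str:  # emitted form always uses the plain hyphen
        return self.value


@dataclass
class SampleMeta:
    """Per-sample annotation attached to an expression matrix column."""

    agent: Optional[str] = None
    class_label: Optional[str] = None  # "DDI" or "NONDDI" when known
    dose: Optional[float] = None
    dose_unit: Optional[str] = None
    time_h: Optional[float] = None


class ExpressionMatrix:
    """Gene x sample matrix of log2 treated/control expression ratios.

    Parameters
    ----------
    gene_ids
        Row identifiers; canonicalized and required unique afterwards.
    sample_ids
        Column identifiers; required unique.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; all finite.
    samples_meta
        Optional per-sample :class:`SampleMeta`, keyed by sample id.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
        samples_meta: Optional[dict[str, SampleMeta]] = None,
        panel_coverage: Optional[float] = None,
    ):
        canon = [canonicalize_gene_id(g) for g in gene_ids]
        seen: dict[str, int] = {}
        for g in canon:
            seen[g] = seen.get(g, 0) + 1
        dups = sorted(g for g, c in seen.items() if c > 1)
        if dups:
            raise ValidationError(f"duplicate gene id(s) after canonicalization: {', '.join(dups)}")
        sids = [str(s) for s in sample_ids]
        if len(set(sids)) != len(sids):
            raise ValidationError("duplicate sample ids")
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2 or arr.shape != (len(canon), len(sids)):
            raise ValidationError(
                f"values shape {arr.shape} does not match {len(canon)} genes x {len(sids)} samples"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        self.gene_ids: list[str] = canon
        self.sample_ids: list[str] = sids
        self.values: np.ndarray = arr
        self.samples_meta: dict[str, SampleMeta] = samples_meta or {}
        self.panel_coverage = panel_coverage

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kw) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float), **kw)

    def sample_vector(self, sample_id: str) -> pd.Series:
        """One column as a Series indexed by gene id."""
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=sample_id)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        wanted = [canonicalize_gene_id(g) for g in gene_ids]
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in wanted if g not in pos]
        if missing:
            raise ValidationError(f"genes absent from matrix: {', '.join(missing)}")
        idx = [pos[g] for g in wanted]
        return ExpressionMatrix(wanted, self.sample_ids, self.values[idx, :], self.samples_meta)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


@dataclass
class BiomarkerPanel:
    """An ordered, non-empty list of canonical gene symbols with a name."""

    gene_ids: list[str]
    name: str = "panel"
    version: str = "1"

    def __post_init__(self) -> None:
        canon = [canonicalize_gene_id(g) for g in self.gene_ids]
        if not canon:
            raise ValidationError("panel is empty")
        if len(set(canon)) != len(canon):
            raise ValidationError("panel contains duplicate gene ids after canonicalization")
        self.gene_ids = canon

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_file(cls, path: str | Path, name: Optional[str] = None) -> "BiomarkerPanel":
        """Read one gene symbol per line; '#' lines are comments."""
        p = Path(path)
        genes = [
            ln.strip()
            for ln in p.read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        return cls(genes, name=name or p.stem)


@dataclass
class AgentRecord:
    """One row of an agent fixture table: identity, class and per-method calls.

    Training rows carry no calls (the development table prints none), so
    every call field is optional.
    """

    agent: str
    class_label: str
    pa: Optional[TernaryCall] = None
    c2dc: Optional[TernaryCall] = None
    pca: Optional[TernaryCall] = None
    overall: Optional[TernaryCall] = None
    cd: Optional[TernaryCall] = None
    ames: Optional[TernaryCall] = None
    solvent: Optional[str] = None
    dose_range: Optional[str] = None
    array_conc: Optional[str] = None


# ---------------------------------------------------------------------------
# Matrix I/O

_FORMATS = ("tsv", "csv", "gct")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise FormatError(f"cannot infer format from extension {path.suffix!r}; pass format=")


def _parse_delimited(text: str, sep: str, where: str) -> ExpressionMatrix:
    reader = csv.reader(io.StringIO(text), delimiter=sep)
    rows = [r for r in reader if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise FormatError(f"{where}: need a header line and at least one gene row")
    header = rows[0]
    sample_ids = [c.strip() for c in header[1:]]
    gene_ids: list[str] = []
    data: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{where}: line {i} has {len(row)} fields, expected {len(header)}")
        gene_ids.append(row[0])
        vals = []
        for j, cell in enumerate(row[1:], start=2):
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{where}: non-numeric cell {cell!r} at line {i}, column {j}"
                ) from None
        data.append(vals)
    return ExpressionMatrix(gene_ids, sample_ids, np.array(data, dtype=float))


def _parse_gct(text: str, where: str) -> ExpressionMatrix:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise FormatError(f"{where}: missing GCT '#1.2' version line")
    try:
        n_rows, n_cols = (int(tok) for tok in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        raise FormatError(f"{where}: malformed GCT dimensions line") from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
        raise FormatError(f"{where}: GCT header must start with Name\\tDescription")
    sample_ids = [c.strip() for c in header[2:]]
    if len(sample_ids) != n_cols:
        raise FormatError(
            f"{where}: header declares {n_cols} samples but data header has {len(sample_ids)}"
        )
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_rows:
        raise FormatError(f"{where}: header declares {n_rows} rows but file has {len(body)}")
    gene_ids, data = [], []
    for i, ln in enumerate(body, start=4):
        parts = ln.split("\t")
        if len(parts) != n_cols + 2:
            raise FormatError(f"{where}: line {i} has {len(parts)} fields, expected {n_cols + 2}")
        gene_ids.append(parts[0])
        try:
            data.append([float(c) for c in parts[2:]])
        except ValueError:
            raise FormatError(f"{where}: non-numeric cell at line {i}") from None
    return ExpressionMatrix(gene_ids, sample_ids, np.array(data, dtype=float))


def read_expression_table(
    path: str | Path, format: Optional[Literal["tsv", "csv", "gct"]] = None
) -> ExpressionMatrix:
    """Read a gene x sample log2-ratio matrix from TSV, CSV or GCT 1.2.

    Delimited files have the gene id in the first column and sample ids on
    the first row; GCT files must carry the ``#1.2`` version line and
    dimensions that match the data block.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    fmt = format or _infer_format(p)
    if fmt not in _FORMATS:
        raise FormatError(f"unsupported format {fmt!r}")
    text = p.read_text(encoding="utf-8")
    if fmt == "gct":
        return _parse_gct(text, str(p))
    return _parse_delimited(text, "\t" if fmt == "tsv" else ",", str(p))


def write_expression_table(
    m: ExpressionMatrix, path: str | Path, format: Optional[Literal["tsv", "csv", "gct"]] = None
) -> None:
    """Write a matrix in the format implied by the extension (or ``format``)."""
    p = Path(path)
    fmt = format or _infer_format(p)
    if fmt == "gct":
        with p.open("w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.n_genes}\t{m.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(m.sample_ids) + "\n")
            for g, row in zip(m.gene_ids, m.values):
                fh.write(g + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        return
    sep = "\t" if fmt == "tsv" else ","
    with p.open("w", encoding="utf-8") as fh:
        fh.write("gene" + sep + sep.join(m.sample_ids) + "\n")
        for g, row in zip(m.gene_ids, m.values):
            fh.write(g + sep + sep.join(repr(float(v)) for v in row) + "\n")


def subset_to_panel(
    m: ExpressionMatrix, panel: BiomarkerPanel, min_coverage: float = 0.90
) -> ExpressionMatrix:
    """Extract the panel rows of ``m``, in panel order.

    Panel genes absent from the matrix are dropped; if the matched fraction
    falls below ``min_coverage`` a :class:`CoverageError` lists the missing
    genes. The returned matrix records the matched fraction in
    ``panel_coverage``.
    """
    if not 0 < min_coverage <= 1:
        raise ValidationError("min_coverage must be in (0, 1]")
    present = set(m.gene_ids)
    kept = [g for g in panel.gene_ids if g in present]
    missing = [g for g in panel.gene_ids if g not in present]
    coverage = len(kept) / len(panel)
    if coverage < min_coverage:
        raise CoverageError(
            f"panel coverage {len(kept)}/{len(panel)} = {coverage:.3f} "
            f"below min_coverage {min_coverage}; missing: {', '.join(missing)}",
            missing=missing,
            coverage=coverage,
        )
    sub = m.subset_genes(kept)
    sub.panel_coverage = coverage
    return sub


# ---------------------------------------------------------------------------
# Packaged fixtures

_FIXTURES = {"training_agents": "training_agents.csv", "validation_calls": "validation_calls.csv"}


def _maybe_call(cell: str) -> Optional[TernaryCall]:
    cell = cell.strip()
    return TernaryCall.from_text(cell) if cell else None


def load_fixture(name: Literal["training_agents", "validation_calls"]) -> list[AgentRecord]:
    """Load a packaged agent table as :class:`AgentRecord` rows.

    ``training_agents`` transcribes the 28 development-set agent conditions
    (categories, solvents, dose ranges, selected array concentrations);
    ``validation_calls`` transcribes the 48 external validation agents with
    their per-method (PA/2DC/PCA), overall, chromosomal-damage and Ames calls.
    """
    if name not in _FIXTURES:
        raise LookupError(f"unknown fixture {name!r}; expected one of {sorted(_FIXTURES)}")
    text = resources.files("tgxddi.fixtures").joinpath(_FIXTURES[name]).read_text(encoding="utf-8")
    records: list[AgentRecord] = []
    for row in csv.DictReader(io.StringIO(text)):
        records.append(
            AgentRecord(
                agent=row["agent"].strip(),
                class_label=row["class"].strip(),
                pa=_maybe_call(row.get("pa", "")),
                c2dc=_maybe_call(row.get("c2dc", "")),
                pca=_maybe_call(row.get("pca", "")),
                overall=_maybe_call(row.get("overall", "")),
                cd=_maybe_call(row.get("cd", "")),
                ames=_maybe_call(row.get("ames", "")),
                solvent=(row.get("solvent") or None),
                dose_range=(row.get("dose_range") or None),
                array_conc=(row.get("array_conc") or None),
            )
        )
    names = [r.agent for r in records]
    if len(set(names)) != len(names):
        raise ValidationError(f"fixture {name} has duplicate agent names")
    return records


def example_panel(n_genes: int = 64, name: str = "example-ddi-panel") -> BiomarkerPanel:
    """A synthetic placeholder panel of ``n_genes`` generic symbols.

    The real DNA-damage biomarker panel is supplied by the user; this
    stand-in exists so examples and tests can exercise panel plumbing.
    """
    return BiomarkerPanel([f"DDIG{i:03d}" for i in range(1, n_genes + 1)], name=name, version="0")
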