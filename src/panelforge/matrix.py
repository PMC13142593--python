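"""Cohort abundance matrices and their file representation.

A :class:`CohortMatrix` is the unit every analysis stage consumes: a
protein-by-subject table of CSF abundances from one cohort, tagged with the
proteomic platform it was acquired on and the scale its values currently
live on (``raw``, ``log2`` or ``zscore``).  Every transformation appends a
line to a provenance log so the declared scale can be audited.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PLATFORMS",
    "SCALES",
    "MISSING_TOKENS",
    "ProteinId",
    "CohortMatrix",
    "read_matrix",
    "write_matrix",
    "collapse_analytes",
]

PLATFORMS = ("mass_spec", "aptamer", "pea")
SCALES = ("raw", "log2", "zscore")

#: Strings accepted as missing values in matrix files.  Anything else
#: non-numeric is a hard error (silent coercion hides transcription bugs).
MISSING_TOKENS = frozenset({"", "NA", "NaN", "na"})


@dataclass(frozen=True)
class ProteinId:
    """Protein identity keyed by gene symbol.

    Cross-study matching uses the gene symbol as primary key; platform
    analyte ids (e.g. aptamer ids) and UniProt accessions ride along.
    """

    gene_symbol: str
    uniprot: Optional[str] = None
    analyte_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")


@dataclass
class CohortMatrix:
    """Protein x subject abundance matrix for one cohort.

    Parameters
    ----------
    cohort_id : str
        Study / cohort identifier.
    platform : str
        One of ``mass_spec``, ``aptamer``, ``pea``.
    data : pandas.DataFrame
        Proteins as rows (index = gene symbols), subjects as columns.
        Missing entries are NaN.
    scale : str
        Scale the values are on: ``raw``, ``log2`` or ``zscore``.
    uniprot : dict, optional
        Gene symbol -> UniProt accession, when known.
    log : list of str
        Provenance log; each processing step appends one line.
    """

    cohort_id: str
    platform: str
    data: pd.DataFrame
    scale: str = "raw"
    uniprot: Optional[dict] = None
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        dup_p = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_p:
            raise ValueError(f"duplicate protein identifiers: {dup_p}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate subject identifiers: {dup_s}")

    # -- introspection -------------------------------------------------
    @property
    def proteins(self) -> list:
        return list(self.data.index)

    @property
    def subjects(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def missing_fraction(self) -> pd.Series:
        """Per-protein fraction of missing entries."""
        return self.data.isna().mean(axis=1)

    # -- plumbing ------------------------------------------------------
    def with_data(self, data: pd.DataFrame, scale: Optional[str] = None,
                  log_entry: Optional[str] = None) -> "CohortMatrix":
        """Return a copy carrying new values (and optionally a new scale)."""
        out = CohortMatrix(
            cohort_id=self.cohort_id,
            platform=self.platform,
            data=data,
            scale=scale if scale is not None else self.scale,
            uniprot=self.uniprot,
            log=list(self.log),
        )
        if log_entry:
            out.log.append(log_entry)
        return out

    def subset_proteins(self, symbols: Iterable[str]) -> "CohortMatrix":
        keep = [s for s in symbols if s in self.data.index]
        return self.with_data(self.data.loc[keep], log_entry=f"subset to {len(keep)} proteins")


def _parse_cell(raw: str, row: str, col: str):
    s = raw.strip() if isinstance(raw, str) else raw
    if isinstance(s, str):
        if s in MISSING_TOKENS:
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise ValueError(f"non-numeric cell {raw!r} at protein {row!r}, subject {col!r}") from None
    if s is None:
        return np.nan
    return float(s)


def read_matrix(path, orientation: str = "proteins_as_rows", format: Optional[str] = None,
                cohort_id: Optional[str] = None, platform: str = "mass_spec",
                scale: str = "raw") -> CohortMatrix:
    """Read a cohort abundance matrix from TSV/CSV.

    The first column holds gene symbols (an optional second column named
    ``uniprot`` is absorbed as annotation); the header row holds subject
    ids.  ``orientation='subjects_as_rows'`` transposes after reading.
    Missing tokens ("", "NA", "NaN", "na") become NaN; any other
    non-numeric cell raises with its location.
    """
    path = str(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "tsv"
    sep = "," if format == "csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    id_col = raw.columns[0]
    uniprot = None
    if len(raw.columns) > 1 and raw.columns[1].lower() == "uniprot":
        uniprot = dict(zip(raw[id_col], raw["uniprot"]))
        raw = raw.drop(columns=["uniprot"])
    index = raw[id_col].tolist()
    body = raw.drop(columns=[id_col])
    dup = sorted({x for x in index if index.count(x) > 1})
    if dup:
        kind = "protein" if orientation == "proteins_as_rows" else "subject"
        raise ValueError(f"duplicate {kind} identifiers in {path}: {dup}")
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col].tolist()):
            values[i, j] = _parse_cell(cell, index[i], col)
    data = pd.DataFrame(values, index=index, columns=list(body.columns))
    if orientation == "subjects_as_rows":
        data = data.T
    elif orientation != "proteins_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    m = CohortMatrix(cohort_id=cohort_id or path, platform=platform, data=data,
                     scale=scale, uniprot=uniprot)
    m.log.append(f"read {data.shape[0]} proteins x {data.shape[1]} subjects from {path}")
    return m


def write_matrix(m: CohortMatrix, path, format: Optional[str] = None,
                 precision: int = 17) -> None:
    """Write a matrix so that read_matrix round-trips values to ~1e-9.

    Values are rendered with ``precision`` significant digits in
    repr-style floats; NaN renders as ``NA``.
    """
    path = str(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "tsv"
    sep = "," if format == "csv" else "\t"
    buf = io.StringIO()
    buf.write("gene_symbol" + sep + sep.join(str(s) for s in m.subjects) + "\n")
    fmt = f"{{:.{precision}g}}"
    arr = m.data.to_numpy()
    for i, prot in enumerate(m.proteins):
        cells = ["NA" if np.isnan(v) else fmt.format(v) for v in arr[i]]
        buf.write(str(prot) + sep + sep.join(cells) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def collapse_analytes(frame: pd.DataFrame, symbol_of: dict) -> pd.DataFrame:
    """Collapse multiple analytes mapping to one gene symbol.

    Aptamer platforms measure several analytes per gene.  For each gene
    symbol the analyte row with the highest variance (observed values) is
    kept — deterministic and information-preserving.  ``frame`` is indexed
    by analyte id; ``symbol_of`` maps analyte id -> gene symbol.
    """
    variances = frame.var(axis=1, ddof=1)
    chosen: dict = {}
    for analyte in frame.index:
        sym = symbol_of.get(analyte, analyte)
        v = variances.loc[analyte]
        v = -np.inf if pd.isna(v) else v
        if sym not in chosen or v > chosen[sym][1] or (
                v == chosen[sym][1] and str(analyte) < str(chosen[sym][0])):
            chosen[sym] = (analyte, v)
    rows = {sym: frame.loc[analyte] for sym, (analyte, _) in chosen.items()}
    out = pd.DataFrame(rows).T
    out.index.name = frame.index.name
    return out
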