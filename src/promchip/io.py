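"""Readers and writers for the pipeline's plain-text formats.

Probe tables are TSV; peaks are a BED-like TSV; motif matrices come in
TRANSFAC count and UniPROBE probability dialects; sequences are FASTA and
gene sets GMT.  All genomic coordinates are integer base pairs relative to
the transcription start site (0 at the TSS, negative upstream), intervals
closed.  Readers validate rather than coerce: malformed values raise, and
rows dropped for known reasons (e.g. probes absent from the layout) are
counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, LayoutConsistencyError, MotifFormatError
from .motifs import MotifMatrix

logger = logging.getLogger(__name__)

CHIP_COLUMNS = ["probe_id", "gene_id", "offset_bp", "ip_intensity", "mock_intensity"]
EXPRESSION_COLUMNS = ["probe_id", "gene_id", "intensity", "time_h", "arm", "replicate"]
PEAK_COLUMNS = ["gene_id", "center_offset", "height", "llr", "pvalue", "condition"]

__all__ = [
    "ChipArraySet",
    "read_chip_tables",
    "write_chip_tables",
    "write_peaks",
    "read_peaks",
    "read_motif_matrix",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
]


@dataclass
class ChipArraySet:
    """Two-colour probe tables joined to a probe layout.

    ``tables`` maps ``(condition, replicate)`` to a probe table with the
    columns in :data:`CHIP_COLUMNS`; ``layout`` is the shared probe layout
    (``probe_id``, ``gene_id``, ``offset_bp``).  ``n_dropped`` counts rows
    discarded per table because their probe was absent from the layout.
    """

    layout: pd.DataFrame
    tables: dict
    n_dropped: dict = field(default_factory=dict)

    def conditions(self):
        return sorted({c for c, _ in self.tables})

    def replicates(self, condition: str):
        return sorted(r for c, r in self.tables if c == condition)

    def ratios(self, condition: str, replicate) -> pd.DataFrame:
        """IP/mock ratio per probe for one array, with gene and offset."""
        t = self.tables[(condition, replicate)]
        out = t[["probe_id", "gene_id", "offset_bp"]].copy()
        out["ratio"] = t["ip_intensity"].to_numpy() / t["mock_intensity"].to_numpy()
        return out


def _check_layout(layout: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("probe_id", "gene_id", "offset_bp") if c not in layout.columns]
    if missing:
        raise LayoutConsistencyError(f"layout lacks columns {missing}")
    if layout["probe_id"].duplicated().any():
        raise LayoutConsistencyError("duplicate probe_id in layout")
    return layout


def read_chip_tables(paths: Mapping, layout: pd.DataFrame) -> ChipArraySet:
    """Read two-colour probe tables keyed by ``(condition, replicate)``.

    Unknown probe IDs are dropped with a logged warning count; non-positive
    intensities raise a validation error; an empty file raises
    :class:`~promchip.errors.EmptyInputError`.
    """
    _check_layout(layout)
    known = set(layout["probe_id"])
    tables, dropped = {}, {}
    for key, path in paths.items():
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise EmptyInputError(f"probe table {path} contains no rows")
        missing = [c for c in CHIP_COLUMNS if c not in df.columns]
        if missing:
            raise LayoutConsistencyError(f"{path}: missing columns {missing}")
        bad = (df["ip_intensity"] <= 0) | (df["mock_intensity"] <= 0)
        if bad.any():
            raise ValueError(f"{path}: {int(bad.sum())} rows with non-positive intensity")
        alien = ~df["probe_id"].isin(known)
        n_alien = int(alien.sum())
        if n_alien:
            logger.warning("%s: dropped %d probes absent from layout", path, n_alien)
            df = df[~alien]
        tables[key] = df.reset_index(drop=True)
        dropped[key] = n_alien
        logger.info("%s: loaded %d probe rows", path, len(df))
    return ChipArraySet(layout=layout, tables=tables, n_dropped=dropped)


def write_chip_tables(arrays: ChipArraySet, outdir, prefix: str = "chip") -> dict:
    """Write each array's probe table as TSV; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for (cond, rep), df in arrays.tables.items():
        p = outdir / f"{prefix}_{cond}_rep{rep}.tsv"
        df[CHIP_COLUMNS].to_csv(p, sep="\t", index=False)
        paths[(cond, rep)] = p
    return paths


def write_peaks(peaks, path) -> None:
    """Write binding peaks as a BED-like TSV sorted by gene then condition.

    Numeric fields are written with 6 decimals; an empty collection yields
    a header-only file.
    """
    rows = [
        {
            "gene_id": p.gene_id,
            "center_offset": p.center,
            "height": p.height,
            "llr": p.llr,
            "pvalue": p.pvalue,
            "condition": p.condition,
        }
        for p in peaks
    ]
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    if not df.empty:
        if not np.all(np.isfinite(df[["center_offset", "height", "llr", "pvalue"]])):
            raise ValueError("peaks contain non-finite values")
        df = df.sort_values(["gene_id", "condition"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_peaks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing peak columns {missing}")
    return df


def _parse_transfac_counts(lines) -> np.ndarray:
    rows, in_block, order = [], False, None
    for line in lines:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "P0" or tok[0] == "PO":
            order = [t.upper() for t in tok[1:5]]
            if sorted(order) != list("ACGT"):
                raise MotifFormatError(f"unexpected TRANSFAC base order {order}")
            in_block = True
            continue
        if in_block:
            if tok[0] == "XX" or tok[0] == "//":
                break
            if len(tok) < 5:
                raise MotifFormatError(f"ragged TRANSFAC row: {line.strip()!r}")
            try:
                vals = [float(v) for v in tok[1:5]]
            except ValueError as exc:
                raise MotifFormatError(f"non-numeric TRANSFAC row: {line.strip()!r}") from exc
            rows.append(vals)
    if not rows:
        raise MotifFormatError("no count block found between P0 and XX")
    counts = np.array(rows)
    # reorder columns to A,C,G,T
    col = {b: i for i, b in enumerate(order)}
    return counts[:, [col["A"], col["C"], col["G"], col["T"]]]


def _parse_uniprobe_prob(lines) -> np.ndarray:
    per_base = {}
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        head, _, rest = stripped.partition(":")
        base = head.strip().upper()
        if base in ("A", "C", "G", "T") and rest:
            try:
                per_base[base] = [float(v) for v in rest.split()]
            except ValueError as exc:
                raise MotifFormatError(f"non-numeric UniPROBE row for {base}") from exc
    if sorted(per_base) != list("ACGT"):
        raise MotifFormatError(f"UniPROBE file lacks rows for all of A,C,G,T (got {sorted(per_base)})")
    widths = {len(v) for v in per_base.values()}
    if len(widths) != 1:
        raise MotifFormatError("ragged UniPROBE rows: base rows differ in length")
    return np.column_stack([per_base[b] for b in "ACGT"])


def read_motif_matrix(path, dialect: str, name: str | None = None, **kw) -> MotifMatrix:
    """Read a motif matrix in ``transfac_counts`` or ``uniprobe_prob`` dialect.

    TRANSFAC counts (the block between the ``P0`` header and ``XX``) are
    column-normalised to frequencies; UniPROBE per-base probability rows
    are validated to sum to 1 (+-1e-6) per position.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "transfac_counts":
        counts = _parse_transfac_counts(lines)
        return MotifMatrix.from_counts(counts, name=name or path.stem, **kw)
    if dialect == "uniprobe_prob":
        freq = _parse_uniprobe_prob(lines)
        if np.any(freq < 0):
            raise MotifFormatError("negative probability entry")
        return MotifMatrix(freq, name=name or path.stem, **kw)
    raise ValueError(f"unknown motif dialect {dialect!r}")


def read_fasta(path) -> dict:
    """Read FASTA into an ordered ``{record id: sequence string}`` map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path) -> dict:
    """Read a GMT gene-set file into ``{set name: member list}``."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs name, description and >=1 member: {line!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise EmptyInputError(f"GMT file {path} contains no sets")
    return sets


def write_gmt(sets: Mapping, path, descriptions: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
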