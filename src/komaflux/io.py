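"""Readers and writers for external formats.

All alignment readers normalize to the internal match-table convention:
0-based half-open coordinates, start < end on both sides, strand explicit
(PAF is already native; nucmer show-coords rows are converted from 1-based
inclusive, with reversed query spans recorded as reverse strand).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .correction import FragmentSpec
from .genome import MATCH_COLUMNS, empty_match_table
from .runlog import RunLog


# ---------------------------------------------------------------------------
# alignment match tables

def read_paf(path: str | Path, log: RunLog | None = None) -> pd.DataFrame:
    """Read a minimap2 PAF file into a match table.

    identity = matching bases (col 10) / alignment block length (col 11);
    mapq from col 12.  Parsing does not filter: mapq-0 matches are retained.
    """
    rows = []
    bad: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                bad.append((lineno, line))
                continue
            try:
                qstart, qend = int(fields[2]), int(fields[3])
                strand = fields[4]
                tstart, tend = int(fields[7]), int(fields[8])
                nmatch, blocklen = int(fields[9]), int(fields[10])
                mapq = int(fields[11])
            except ValueError:
                bad.append((lineno, line))
                continue
            if strand not in "+-" or blocklen <= 0:
                bad.append((lineno, line))
                continue
            rows.append((fields[0], qstart, qend, fields[5], tstart, tend,
                         strand, nmatch / blocklen, mapq))
    if bad:
        lineno, line = bad[0]
        raise ValueError(f"{len(bad)} malformed PAF line(s); first at line "
                         f"{lineno}: {line!r}")
    if not rows:
        if log is not None:
            log.warn(f"{path}: empty PAF file")
        return empty_match_table()
    if log is not None:
        log.log(f"{path}: read {len(rows)} PAF matches")
    return pd.DataFrame(rows, columns=MATCH_COLUMNS)


def read_coords(path: str | Path, log: RunLog | None = None) -> pd.DataFrame:
    """Read a nucmer show-coords table (-qldcoHT dialect: tab, headerless).

    Positional columns S1 E1 S2 E2 LEN1 LEN2 %IDY LENR LENQ COVR COVQ followed
    by reference and query names; extra trailing columns are ignored.
    1-based inclusive coordinates are converted to 0-based half-open; a
    reversed span (end < start) is recorded as reverse strand and normalized
    so start < end.  show-coords reports no mapping quality; mapq is set to
    255 so downstream quality filters keep every match.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 13:
                raise ValueError(f"show-coords line {lineno}: expected >= 13 "
                                 f"columns, got {len(fields)}")
            try:
                s1, e1, s2, e2 = (int(fields[i]) for i in range(4))
                pct_idy = float(fields[6])
            except ValueError as exc:
                raise ValueError(f"show-coords line {lineno}: non-numeric "
                                 f"coordinate ({exc})") from exc
            rname, qname = fields[11], fields[12]
            strand = "+"
            if e1 < s1:
                s1, e1 = e1, s1
                strand = "-"
            if e2 < s2:
                s2, e2 = e2, s2
                strand = "-"
            rows.append((qname, s2 - 1, e2, rname, s1 - 1, e1,
                         strand, pct_idy / 100.0, 255))
    if not rows:
        if log is not None:
            log.warn(f"{path}: empty coords file")
        return empty_match_table()
    if log is not None:
        log.log(f"{path}: read {len(rows)} show-coords matches")
    return pd.DataFrame(rows, columns=MATCH_COLUMNS)


def write_match_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a match table as TSV (also serves as the Circos link-table export)."""
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA

@dataclasses.dataclass
class FastaRecord:
    id: str
    seq: str
    has_ambiguous: bool  # contains characters outside ACGT (case-insensitive)

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, log: RunLog | None = None) -> list[FastaRecord]:
    """Read FASTA records, preserving order; duplicate ids and empty records error."""
    records: list[FastaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if len(seq) == 0:
            raise ValueError(f"zero-length FASTA record: {rec.id}")
        ambiguous = bool(set(seq.upper()) - set("ACGT"))
        if ambiguous and log is not None:
            log.warn(f"record {rec.id}: contains non-ACGT characters; "
                     "k-mers spanning them are skipped downstream")
        records.append(FastaRecord(rec.id, seq, ambiguous))
    return records


def write_fasta(records: list[FastaRecord] | dict[str, str], path: str | Path,
                width: int = 80) -> None:
    if isinstance(records, dict):
        items = list(records.items())
    else:
        items = [(r.id, r.seq) for r in records]
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# distance matrices

def write_distance_matrix(D: pd.DataFrame, path: str | Path) -> None:
    D.to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    D = pd.read_csv(path, sep="\t", index_col=0)
    D.columns = [str(c) for c in D.columns]
    D.index = [str(i) for i in D.index]
    if list(D.columns) != list(D.index):
        raise ValueError("distance matrix labels differ between rows and columns")
    return D


# ---------------------------------------------------------------------------
# GC-TOFMS measurement tables

@dataclasses.dataclass
class Measurement:
    """One measured fragment: intensity vector over m+0..m+K plus SDs."""

    fragment: FragmentSpec
    values: np.ndarray
    sd: np.ndarray

    @property
    def metabolite(self) -> str:
        return self.fragment.metabolite


def read_measurements(path: str | Path, log: RunLog | None = None) -> list[Measurement]:
    """Read a measurement CSV.

    Columns: metabolite, fragment_formula, n_backbone_carbons, then paired
    area/SD columns m0..mK and sd0..sdK (K may vary per row; missing tail
    entries are NaN).  If every SD cell of a row is missing, a uniform SD of
    1% of the maximum area is substituted with a warning.
    """
    df = pd.read_csv(path)
    required = {"metabolite", "fragment_formula", "n_backbone_carbons"}
    if not required.issubset(df.columns):
        raise ValueError(f"measurement CSV missing columns: "
                         f"{sorted(required - set(df.columns))}")
    m_cols = sorted((c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    sd_cols = [f"sd{c[1:]}" for c in m_cols]
    out: list[Measurement] = []
    for idx, row in df.iterrows():
        n = int(row["n_backbone_carbons"])
        frag = FragmentSpec.from_formula(
            str(row["metabolite"]), str(row["fragment_formula"]), n,
            retention_time=float(row["rt"]) if "rt" in df.columns
            and pd.notna(row.get("rt")) else None,
            adduct=str(row["adduct"]) if "adduct" in df.columns
            and pd.notna(row.get("adduct")) else None,
        )
        values = np.array([row[c] for c in m_cols], dtype=float)
        valid = ~np.isnan(values)
        values = values[valid]
        if len(values) < n + 1:
            raise ValueError(f"row {idx} ({frag.metabolite}): {len(values)} "
                             f"intensity columns but {n} backbone carbons")
        if np.any(values < 0):
            raise ValueError(f"row {idx} ({frag.metabolite}): negative area")
        sds = np.array([row[c] if c in df.columns else np.nan for c in sd_cols],
                       dtype=float)[valid]
        if len(sds) != len(values) or np.all(np.isnan(sds)):
            fallback = 0.01 * float(values.max())
            if log is not None:
                log.warn(f"row {idx} ({frag.metabolite}): SD columns missing; "
                         f"uniform fallback SD {fallback:.3g}")
            sds = np.full(len(values), fallback)
        else:
            sds = np.where(np.isnan(sds), np.nanmax(sds), sds)
        out.append(Measurement(frag, values, sds))
    return out


def write_measurements(measurements: list[Measurement], path: str | Path) -> None:
    kmax = max(len(m.values) for m in measurements) - 1
    cols = (["metabolite", "fragment_formula", "n_backbone_carbons"]
            + [f"m{i}" for i in range(kmax + 1)] + [f"sd{i}" for i in range(kmax + 1)])
    rows = []
    for m in measurements:
        formula = "".join(
            f"{el}{n if n > 1 else ''}" for el, n in sorted(m.fragment.elements.items())
            if n > 0)
        pad = kmax + 1 - len(m.values)
        rows.append([m.metabolite, formula, m.fragment.n_backbone_carbons]
                    + list(m.values) + [np.nan] * pad
                    + list(m.sd) + [np.nan] * pad)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# packaged data

def load_published_assembly_metrics() -> pd.DataFrame:
    """Printed assembly metrics of the eight newly assembled strains plus the
    two reference assemblies (sizes in Mbp)."""
    ref = importlib.resources.files("komaflux.data") / "assembly_metrics_published.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)
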