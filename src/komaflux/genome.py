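"""Whole-genome comparison statistics.

Operates on match tables (pandas DataFrames, one row per alignment match)
with the uniform internal convention: 0-based half-open coordinates,
``start < end`` on both sides, strand explicit.  Covers the pipeline from
raw aligner matches to per-chromosome identity/coverage summaries,
contig-to-chromosome assignment with orientation, and assembly metrics
(N50 and friends).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .runlog import RunLog

#: Canonical column order of a match table.
MATCH_COLUMNS = [
    "query_id", "query_start", "query_end",
    "target_id", "target_start", "target_end",
    "strand", "identity", "mapq",
]


def empty_match_table() -> pd.DataFrame:
    return pd.DataFrame(columns=MATCH_COLUMNS)


def _check_match_table(table: pd.DataFrame) -> None:
    missing = [c for c in MATCH_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"match table missing columns: {missing}")


def filter_matches(table: pd.DataFrame, min_len: int = 1000, min_mapq: int = 1,
                   log: RunLog | None = None) -> pd.DataFrame:
    """Keep matches with reference span >= min_len and mapq >= min_mapq.

    Row order is preserved; kept/dropped counts are recorded in the log.
    """
    _check_match_table(table)
    if len(table) == 0:
        return table.copy()
    span = table["target_end"] - table["target_start"]
    keep = (span >= min_len) & (table["mapq"] >= min_mapq)
    out = table.loc[keep].reset_index(drop=True)
    if log is not None:
        log.record_filter(f"filter(min_len={min_len},min_mapq={min_mapq})",
                          len(table), len(out))
    return out


def weighted_identity(table: pd.DataFrame, log: RunLog | None = None) -> pd.DataFrame:
    """Per-chromosome length-weighted identity.

    pct_id = 100 * sum(identity_i * len_i) / sum(len_i) grouped by reference
    chromosome, with len_i the reference span of each match (the table is
    organized by reference chromosome, so reference lengths are the weights).
    """
    _check_match_table(table)
    rows = []
    for chrom, grp in table.groupby("target_id", sort=True):
        span = (grp["target_end"] - grp["target_start"]).to_numpy(dtype=float)
        total = span.sum()
        if total <= 0:
            if log is not None:
                log.warn(f"chromosome {chrom}: zero total match length, omitted")
            continue
        pct_id = 100.0 * float((grp["identity"].to_numpy() * span).sum()) / total
        rows.append({"chromosome": chrom, "pct_id": pct_id,
                     "n_matches": int(len(grp)), "total_match_len": int(total)})
    return pd.DataFrame(rows, columns=["chromosome", "pct_id", "n_matches",
                                       "total_match_len"])


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent half-open intervals; returns sorted (m, 2) array."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=float)
    iv = np.asarray(intervals, dtype=float)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].copy()]
    for start, end in iv[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append(np.array([start, end]))
    return np.array(merged)


def coverage_fraction(table: pd.DataFrame, chrom_lengths: dict[str, int]) -> pd.Series:
    """Percent of each reference chromosome covered by the union of match spans.

    Overlapping spans are merged before summing ("covered fraction" is a set
    property).  Chromosomes listed in ``chrom_lengths`` but absent from the
    table get 0.0.
    """
    _check_match_table(table)
    out = {}
    grouped = dict(tuple(table.groupby("target_id"))) if len(table) else {}
    for chrom, length in chrom_lengths.items():
        grp = grouped.get(chrom)
        if grp is None or len(grp) == 0:
            out[chrom] = 0.0
            continue
        spans = grp[["target_start", "target_end"]].to_numpy(dtype=float)
        if np.any(spans[:, 1] > length):
            raise ValueError(f"match extends beyond chromosome {chrom} "
                             f"(length {length})")
        merged = merge_intervals(spans)
        out[chrom] = 100.0 * float((merged[:, 1] - merged[:, 0]).sum()) / length
    extra = set(grouped) - set(chrom_lengths)
    if extra:
        raise ValueError(f"matches on chromosomes without stated length: {sorted(extra)}")
    return pd.Series(out, name="pct_cov")


def assign_contigs(table: pd.DataFrame, ambiguity_threshold: float = 0.5,
                   log: RunLog | None = None) -> pd.DataFrame:
    """Assign each contig to a chromosome with orientation and order.

    The winning chromosome maximizes summed reference-span length (ties broken
    by chromosome name); orientation is the strand carrying the majority of
    matched bases on that chromosome; contigs are ordered along each
    chromosome by the median reference position of their matches.  Contigs
    whose winning chromosome holds less than ``ambiguity_threshold`` of their
    matched bases are flagged ambiguous but still assigned.
    """
    _check_match_table(table)
    records = []
    for contig, grp in table.groupby("query_id", sort=True):
        span = (grp["target_end"] - grp["target_start"]).to_numpy(dtype=float)
        per_chrom = grp.assign(_span=span).groupby("target_id")["_span"].sum()
        per_chrom = per_chrom.sort_index()  # name ties -> first alphabetically
        best_chrom = per_chrom.idxmax()
        support = float(per_chrom[best_chrom] / per_chrom.sum())
        on_best = grp[grp["target_id"] == best_chrom]
        best_span = (on_best["target_end"] - on_best["target_start"]).to_numpy(float)
        rev_bases = best_span[(on_best["strand"] == "-").to_numpy()].sum()
        orientation = "reverse" if rev_bases > best_span.sum() / 2 else "forward"
        midpoints = ((on_best["target_start"] + on_best["target_end"]) / 2).to_numpy()
        records.append({
            "contig": contig, "chromosome": best_chrom, "orientation": orientation,
            "median_position": float(np.median(midpoints)),
            "support_fraction": support,
            "ambiguous": support < ambiguity_threshold,
        })
        if support < ambiguity_threshold and log is not None:
            log.warn(f"contig {contig}: ambiguous assignment "
                     f"(support {support:.2f} on {best_chrom})")
    df = pd.DataFrame(records, columns=["contig", "chromosome", "orientation",
                                        "median_position", "support_fraction",
                                        "ambiguous"])
    if len(df) == 0:
        df["order_index"] = pd.Series(dtype=int)
        return df
    df = df.sort_values(["chromosome", "median_position", "contig"]).reset_index(drop=True)
    df["order_index"] = df.groupby("chromosome").cumcount()
    return df


@dataclasses.dataclass
class AssemblyMetrics:
    total_size: int
    n_contigs: int
    n50: int
    n50_number: int
    longest: int
    sum_top4: int


def assembly_metrics(contig_lengths: list[int]) -> AssemblyMetrics:
    """Standard assembly metrics.

    N50 is the length of the contig at which the cumulative sorted-descending
    length first reaches half the total; the N50 number is that contig's rank.
    """
    if len(contig_lengths) == 0:
        raise ValueError("empty contig length list")
    lengths = sorted((int(x) for x in contig_lengths), reverse=True)
    if lengths[-1] <= 0:
        raise ValueError("contig lengths must be positive")
    total = sum(lengths)
    cum = 0
    for rank, length in enumerate(lengths, start=1):
        cum += length
        if cum >= total / 2:
            return AssemblyMetrics(
                total_size=total, n_contigs=len(lengths), n50=length,
                n50_number=rank, longest=lengths[0], sum_top4=sum(lengths[:4]),
            )
    raise AssertionError("unreachable")
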