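"""Consensus circRNA quantification.

Reads per-sample caller outputs (one count-bearing primary table plus
detection-only secondary tables), applies the multi-caller consensus rule,
normalizes backsplice counts to circCPM, applies the expression filter and
computes circular-to-linear (CTL) ratios.

The consensus rule mirrors the combined-pipeline strategy used to suppress
false-positive backsplice calls: a circRNA is kept only if the primary
(count-bearing) caller found it AND at least ``consensus_min_secondary`` of
the detection-only callers found it too.  Filtering order is: consensus
first, then circCPM normalization on the consensus set, then the
25-circCPM / 7-sample expression filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .junctions import BackspliceJunction

logger = logging.getLogger(__name__)

PRIMARY_COLUMNS = ["circ_id", "chrom", "start", "end", "strand", "bsj_reads", "linear_reads"]


class ParseError(ValueError):
    """Malformed caller output row; carries the offending line number."""


@dataclass
class FilterThresholds:
    """Filtering knobs for the consensus/expression stage.

    min_circcpm : circCPM required to count a sample as "expressing" (inclusive).
    min_samples : number of expressing samples required to keep a circRNA (inclusive).
    consensus_min_secondary : number of secondary callers that must confirm a
        primary-caller junction.
    coord_slack_bp : endpoint tolerance when matching junctions across callers
        (0 = exact coordinates).
    """

    min_circcpm: float = 25.0
    min_samples: int = 7
    consensus_min_secondary: int = 1
    coord_slack_bp: int = 0
    stranded: bool = True

    def __post_init__(self) -> None:
        if self.min_circcpm < 0 or self.min_samples < 0:
            raise ValueError("thresholds must be non-negative")
        if self.consensus_min_secondary < 0 or self.coord_slack_bp < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class CountMatrix:
    """CircRNA counts over junction keys x samples.

    ``data`` is a DataFrame indexed by junction key with one column per
    sample; ``scale`` is "raw" (integer backsplice reads) or "circcpm".
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "circcpm"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate junction keys in count matrix")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def keys(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="key")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = "raw") -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="key")
        return cls(df, scale=scale)


def read_primary_caller(path: str | Path) -> pd.DataFrame:
    """Read a primary-caller (count-bearing) circRNA table for one sample.

    The primary dialect reports 1-based inclusive coordinates; they are
    shifted to the internal 0-based half-open convention on read.  Returns a
    DataFrame with columns ``key``, ``bsj_reads``, ``linear_reads``.

    Rows with start >= end (after conversion) are rejected and logged, not
    fatal; any other malformed row raises :class:`ParseError` with its line
    number.
    """
    path = Path(path)
    records: list[tuple[str, int, int]] = []
    n_rejected = 0
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in PRIMARY_COLUMNS[1:] if c not in header]
        if missing:
            raise ParseError(f"{path}: header missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                chrom = parts[idx["chrom"]]
                start1 = int(parts[idx["start"]])
                end1 = int(parts[idx["end"]])
                strand = parts[idx["strand"]]
                bsj = int(parts[idx["bsj_reads"]])
                linear = int(parts[idx["linear_reads"]])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if bsj < 0 or linear < 0:
                raise ParseError(f"{path}:{lineno}: negative counts")
            if start1 >= end1:  # degenerate in the caller's 1-based frame
                n_rejected += 1
                logger.warning("%s:%d: rejected degenerate interval %s:%d-%d",
                               path, lineno, chrom, start1, end1)
                continue
            start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            records.append((BackspliceJunction(chrom, start0, end0, strand).key, bsj, linear))
    df = pd.DataFrame(records, columns=["key", "bsj_reads", "linear_reads"])
    df.attrs["n_rejected"] = n_rejected
    return df


def read_secondary_caller(path: str | Path, dialect: str = "bed6") -> set[str]:
    """Read a detection-only secondary-caller file; returns junction keys.

    ``bed6`` input is natively 0-based half-open.  ``tsv`` uses the primary
    dialect (1-based inclusive, with header) minus the count columns.
    Duplicate rows collapse (set semantics).
    """
    path = Path(path)
    keys: set[str] = set()
    if dialect == "bed6":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    raise ParseError(f"{path}:{lineno}: expected >=6 BED fields")
                try:
                    bsj = BackspliceJunction(parts[0], int(parts[1]), int(parts[2]), parts[5])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                keys.add(bsj.key)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            keys.add(BackspliceJunction(str(row["chrom"]), int(row["start"]) - 1,
                                        int(row["end"]), str(row["strand"])).key)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return keys


def _match_with_slack(primary: Iterable[str], secondary: set[str], slack: int,
                      stranded: bool) -> set[str]:
    """Primary keys whose endpoints each lie within ``slack`` bp of a secondary key."""
    by_group: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for k in secondary:
        j = BackspliceJunction.from_key(k)
        strand = j.strand if stranded else "."
        by_group.setdefault((j.chrom, strand), []).append((j.start, j.end))
    hits: set[str] = set()
    for k in primary:
        j = BackspliceJunction.from_key(k)
        strand = j.strand if stranded else "."
        for s, e in by_group.get((j.chrom, strand), ()):
            if abs(s - j.start) <= slack and abs(e - j.end) <= slack:
                hits.add(k)
                break
    return hits


def consensus_filter(primary_keys: Iterable[str],
                     secondary_key_sets: Sequence[set[str]],
                     thresholds: FilterThresholds | None = None) -> set[str]:
    """Keep primary-caller junctions confirmed by enough secondary callers.

    Returns the subset of ``primary_keys`` matched by at least
    ``consensus_min_secondary`` of the ``secondary_key_sets``.  Matching is
    exact key equality when ``coord_slack_bp`` is 0, else both endpoints must
    agree within the slack on the same chromosome (and strand, if stranded).
    """
    thresholds = thresholds or FilterThresholds()
    if len(secondary_key_sets) == 0:
        raise ValueError("at least one secondary caller key set is required")
    primary = set(primary_keys)
    if thresholds.stranded:
        canon = {k: k for k in primary}
    else:
        canon = {BackspliceJunction.from_key(k).unstranded().key: k for k in primary}

    votes: dict[str, int] = {k: 0 for k in primary}
    for sec in secondary_key_sets:
        if thresholds.coord_slack_bp == 0:
            if thresholds.stranded:
                matched = primary & sec
            else:
                sec_un = {BackspliceJunction.from_key(k).unstranded().key for k in sec}
                matched = {canon[u] for u in (set(canon) & sec_un)}
        else:
            matched = _match_with_slack(primary, sec, thresholds.coord_slack_bp,
                                        thresholds.stranded)
        for k in matched:
            votes[k] += 1
    return {k for k, v in votes.items() if v >= thresholds.consensus_min_secondary}


def build_count_matrix(per_sample: Mapping[str, pd.DataFrame],
                       keys: Iterable[str] | None = None,
                       column: str = "bsj_reads") -> CountMatrix:
    """Assemble per-sample primary-caller records into a raw count matrix.

    ``per_sample`` maps sample id -> DataFrame from :func:`read_primary_caller`.
    If ``keys`` is given (e.g. the consensus set) the matrix is restricted to
    those junctions; otherwise the union of observed keys is used.
    """
    cols = {}
    for sample, df in per_sample.items():
        cols[sample] = df.set_index("key")[column]
    data = pd.DataFrame(cols).fillna(0).astype(int)
    if keys is not None:
        keys = sorted(set(keys))
        data = data.reindex(keys, fill_value=0)
    else:
        data = data.sort_index()
    return CountMatrix(data, scale="raw")


def circ_cpm(matrix: CountMatrix, denominator: str = "reads") -> CountMatrix:
    """Normalize raw backsplice counts to circular counts per million.

    circCPM divides each sample's counts by that sample's total backsplice
    reads (over the supplied key set) and multiplies by 1e6.  All-zero
    columns stay all-zero.  ``denominator="species"`` divides by the number
    of distinct detected circRNAs instead — a sensitivity-analysis variant;
    the read-sum default is the reading consistent with counts-per-million
    semantics.
    """
    if matrix.scale != "raw":
        raise ValueError("circ_cpm expects a raw-scale matrix")
    raw = matrix.data.to_numpy(dtype=float)
    if (raw < 0).any():
        raise ValueError("negative counts")
    if denominator == "reads":
        totals = raw.sum(axis=0)
    elif denominator == "species":
        totals = (raw > 0).sum(axis=0)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        cpm = np.where(totals > 0, raw / totals * 1e6, 0.0)
    return CountMatrix(pd.DataFrame(cpm, index=matrix.data.index,
                                    columns=matrix.data.columns), scale="circcpm")


def expression_filter(matrix: CountMatrix,
                      thresholds: FilterThresholds | None = None) -> set[str]:
    """Keep circRNAs expressed at >= min_circcpm in >= min_samples samples.

    Both comparisons are inclusive: a junction at exactly 25 circCPM in
    exactly 7 samples passes the default thresholds.
    """
    thresholds = thresholds or FilterThresholds()
    if matrix.scale != "circcpm":
        raise ValueError("expression_filter expects a circCPM-scale matrix")
    n_samples = matrix.data.shape[1]
    if thresholds.min_samples > n_samples:
        warnings.warn(
            f"min_samples={thresholds.min_samples} exceeds the {n_samples} available "
            "samples; no circRNA can pass", UserWarning, stacklevel=2)
    n_expressing = (matrix.data >= thresholds.min_circcpm).sum(axis=1)
    return set(matrix.data.index[n_expressing >= thresholds.min_samples])


def ctl_ratio(circ_reads: int, linear_reads: int) -> float:
    """Circular-to-linear ratio (2c)/(2c + l), in [0, 1].

    0 means no circular expression over the junction; 1 means circular-only
    (no linear reads).  Zero circular reads return 0 regardless of the
    linear count (including the 0/0 case).
    """
    if circ_reads < 0 or linear_reads < 0:
        raise ValueError("read counts must be non-negative")
    if circ_reads == 0:
        return 0.0
    return 2.0 * circ_reads / (2.0 * circ_reads + linear_reads)


def ctl_table(per_sample: Mapping[str, pd.DataFrame],
              keys: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-(junction, sample) CTL records from primary-caller tables.

    Returns a long DataFrame with columns key, sample, circ_reads,
    linear_reads, ctl, optionally restricted to ``keys``.
    """
    keep = None if keys is None else set(keys)
    rows = []
    for sample, df in per_sample.items():
        for _, r in df.iterrows():
            if keep is not None and r["key"] not in keep:
                continue
            rows.append((r["key"], sample, int(r["bsj_reads"]), int(r["linear_reads"]),
                         ctl_ratio(int(r["bsj_reads"]), int(r["linear_reads"]))))
    return pd.DataFrame(rows, columns=["key", "sample", "circ_reads", "linear_reads", "ctl"])
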