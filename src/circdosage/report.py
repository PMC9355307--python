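"""Summary reporting across pipeline stages.

Every number in the report is recomputed from the stage tables passed in,
so an independent re-tally of those tables reproduces the report exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .dosage import CollectiveShift
from .quantify import CountMatrix


@dataclass
class SummaryStats:
    """Dataset-description metrics recomputed from stage outputs."""

    n_consensus: int
    n_kept: int
    fraction_known: float
    fraction_exonic: float
    mean_exon_count: float
    per_tissue_detected: dict[str, int] = field(default_factory=dict)
    dec_counts: dict[str, int] = field(default_factory=dict)
    par_shifts: list[CollectiveShift] = field(default_factory=list)


def summarize(consensus_keys: Sequence[str], kept_keys: Sequence[str],
              circ_annotations: pd.DataFrame, cpm: CountMatrix,
              metadata: pd.DataFrame,
              de_results: Mapping[str, pd.DataFrame] | None = None,
              par_shifts: Sequence[CollectiveShift] = ()) -> SummaryStats:
    """Recompute summary metrics from the stage tables.

    ``fraction_known``/``fraction_exonic``/``mean_exon_count`` are over the
    kept (post-filter) circRNAs; per-tissue detection counts a circRNA as
    detected in a tissue when any sample of that tissue has nonzero circCPM.
    """
    ann = circ_annotations.set_index("key").loc[list(kept_keys)]
    n_kept = len(kept_keys)
    fraction_known = float((ann["known_id"].astype(bool)).mean()) if n_kept else 0.0
    fraction_exonic = float((ann["origin"] == "exonic").mean()) if n_kept else 0.0
    exonic = ann.loc[ann["origin"] == "exonic", "exon_count"]
    mean_exons = float(exonic.mean()) if len(exonic) else 0.0

    per_tissue: dict[str, int] = {}
    meta = metadata.set_index("sample_id")
    sub = cpm.data.loc[[k for k in kept_keys if k in cpm.data.index]]
    for tissue in sorted(meta["tissue"].unique()):
        samples = [s for s in sub.columns if meta.loc[s, "tissue"] == tissue]
        per_tissue[tissue] = int(((sub[samples] > 0).any(axis=1)).sum()) if samples else 0

    dec_counts = {}
    for label, res in (de_results or {}).items():
        dec_counts[label] = int(res["significant"].sum())

    return SummaryStats(n_consensus=len(consensus_keys), n_kept=n_kept,
                        fraction_known=fraction_known,
                        fraction_exonic=fraction_exonic,
                        mean_exon_count=mean_exons,
                        per_tissue_detected=per_tissue, dec_counts=dec_counts,
                        par_shifts=list(par_shifts))


def render(stats: SummaryStats) -> str:
    """Plain-text report of the summary metrics."""
    lines = [
        "circdosage summary",
        "==================",
        f"circRNAs passing consensus:          {stats.n_consensus}",
        f"circRNAs passing expression filter:  {stats.n_kept}",
        f"fraction in known catalogue:         {stats.fraction_known:.3f}",
        f"fraction exonic:                     {stats.fraction_exonic:.3f}",
        f"mean exon count (exonic circRNAs):   {stats.mean_exon_count:.2f}",
        "",
        "detected per tissue:",
    ]
    for tissue, n in stats.per_tissue_detected.items():
        lines.append(f"  {tissue:<8s} {n}")
    lines.append("")
    lines.append("differentially expressed circRNAs per contrast:")
    if stats.dec_counts:
        for label, n in stats.dec_counts.items():
            lines.append(f"  {label:<28s} {n}")
    else:
        lines.append("  (none computed)")
    if stats.par_shifts:
        lines.append("")
        lines.append("collective PAR shifts (one-sample t-test):")
        for s in stats.par_shifts:
            lines.append(f"  {s.tissue:<8s} {s.contrast:<16s} {s.region:<5s} "
                         f"n={s.n:<4d} mean log2FC={s.mean_log2fc:+.3f} "
                         f"t={s.t:+.3f} p={s.p:.3g} {s.stars}")
    return "\n".join(lines) + "\n"
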