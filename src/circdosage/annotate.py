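"""Genomic annotation of circRNAs.

Classifies each backsplice junction by origin (exonic / intronic /
intergenic), counts host exons, assigns pseudoautosomal-region (PAR)
membership, carries X-inactivation escape status over from the host gene,
and matches junctions against a known-circRNA catalogue.

PAR1 and PAR2 are the regions of X/Y homology; genes there are present on
every sex chromosome and escape X inactivation, so their dosage tracks the
total sex-chromosome count.  The PAR intervals are fixed constants in the
1-based inclusive frame in which they are conventionally printed, and
containment is evaluated in that frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .junctions import BackspliceJunction
from .quantify import CountMatrix

logger = logging.getLogger(__name__)

REGION_CLASSES = ("autosome", "chrX_escape", "chrX_inactive", "chrY", "PAR1", "PAR2")

#: PAR intervals on chrX/chrY, 1-based inclusive.
PAR_REGIONS: dict[str, tuple[int, int]] = {
    "PAR1": (10_001, 2_781_479),
    "PAR2": (155_701_383, 156_030_895),
}


@dataclass(frozen=True)
class Gene:
    """A gene model: strand, region class and exon intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    region_class: str
    exons: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


@dataclass
class Annotation:
    """Gene models indexed by id and by chromosome."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end))

    def overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose span intersects [start, end)."""
        return [g for g in self._by_chrom.get(chrom, [])
                if g.start < end and g.end > start]

    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def to_tsv(self, path: str | Path) -> None:
        """Write a GTF-like exon table (1-based inclusive coordinates)."""
        rows = []
        for g in self.genes.values():
            for i, (s, e) in enumerate(g.exons, start=1):
                rows.append((g.gene_id, g.chrom, g.strand, g.region_class, i, s + 1, e))
        pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "region_class",
                                    "exon_number", "start", "end"]
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Annotation":
        df = pd.read_csv(path, sep="\t")
        genes: dict[str, Gene] = {}
        for gene_id, grp in df.groupby("gene_id", sort=False):
            grp = grp.sort_values("exon_number")
            exons = tuple((int(s) - 1, int(e)) for s, e in zip(grp["start"], grp["end"]))
            first = grp.iloc[0]
            genes[str(gene_id)] = Gene(str(gene_id), str(first["chrom"]),
                                       str(first["strand"]), str(first["region_class"]),
                                       exons)
        return cls(genes)


def classify_origin(bsj: BackspliceJunction, annotation: Annotation,
                    boundary_tolerance: int = 0
                    ) -> tuple[str, list[str], int, int]:
    """Classify a junction's genomic origin against gene models.

    Returns ``(origin, host_gene_ids, exon_count, spliced_length)``.

    * exonic: both endpoints fall at/within exons of overlapping host genes
      (tolerance ``boundary_tolerance`` bp around exon edges); a junction
      spanning the ends of two adjacent genes reports both hosts.
    * intronic: inside at least one gene but not exonic.
    * intergenic: no gene overlap (exon_count 0).

    ``exon_count`` is the number of host exons (union over hosts) fully
    inside the junction interval; ``spliced_length`` is their total length.
    A chromosome absent from the annotation yields intergenic with a warning.
    """
    if bsj.chrom not in annotation.chromosomes():
        logger.warning("chromosome %s absent from annotation; %s treated as intergenic",
                       bsj.chrom, bsj.key)
        return "intergenic", [], 0, 0
    hosts = annotation.overlapping(bsj.chrom, bsj.start, bsj.end)
    if not hosts:
        return "intergenic", [], 0, 0

    tol = boundary_tolerance

    def in_exon(pos: int, last: bool) -> bool:
        # start endpoint uses [s, e), end endpoint uses (s, e]
        for g in hosts:
            for s, e in g.exons:
                if last and s - tol < pos <= e + tol:
                    return True
                if not last and s - tol <= pos < e + tol:
                    return True
        return False

    inner = sorted({(s, e) for g in hosts for s, e in g.exons
                    if s >= bsj.start - tol and e <= bsj.end + tol})
    exon_count = len(inner)
    spliced_length = sum(e - s for s, e in inner)
    host_ids = [g.gene_id for g in hosts]

    if in_exon(bsj.start, last=False) and in_exon(bsj.end, last=True):
        return "exonic", host_ids, exon_count, spliced_length
    return "intronic", host_ids, 0, 0


def assign_par(bsj: BackspliceJunction,
               par_regions: Mapping[str, tuple[int, int]] = PAR_REGIONS) -> str:
    """PAR membership of a junction: 'PAR1', 'PAR2' or 'none'.

    Assigned only when BOTH endpoints lie inside the same interval, with the
    comparison made in the printed 1-based inclusive frame.  Junctions off
    chrX/chrY return 'none'.
    """
    if bsj.chrom not in ("chrX", "chrY", "X", "Y"):
        return "none"
    start1, end1 = bsj.start + 1, bsj.end  # to 1-based inclusive
    for name, (lo, hi) in par_regions.items():
        if lo <= start1 and end1 <= hi:
            return name
    return "none"


def match_known(bsj: BackspliceJunction, catalogue: pd.DataFrame,
                stranded: bool = True) -> str | None:
    """Exact-coordinate match against a known-circRNA catalogue.

    ``catalogue`` has columns known_id, chrom, start, end, strand with
    coordinates already harmonized to the internal 0-based half-open
    convention and the same genome build.  Returns the catalogue id or None.
    """
    lut = _catalogue_index(catalogue, stranded)
    probe = (bsj.chrom, bsj.start, bsj.end, bsj.strand if stranded else ".")
    return lut.get(probe)


def _catalogue_index(catalogue: pd.DataFrame, stranded: bool
                     ) -> dict[tuple[str, int, int, str], str]:
    cache_key = f"_circdosage_lut_{stranded}"
    if cache_key not in catalogue.attrs:
        lut = {}
        for _, r in catalogue.iterrows():
            strand = str(r["strand"]) if stranded else "."
            lut[(str(r["chrom"]), int(r["start"]), int(r["end"]), strand)] = str(r["known_id"])
        catalogue.attrs[cache_key] = lut
    return catalogue.attrs[cache_key]


def annotate_circrnas(keys: Iterable[str], annotation: Annotation,
                      catalogue: pd.DataFrame | None = None,
                      par_regions: Mapping[str, tuple[int, int]] = PAR_REGIONS,
                      boundary_tolerance: int = 0) -> pd.DataFrame:
    """Full per-circRNA annotation table.

    Columns: key, origin, host_gene_ids (comma-joined), exon_count,
    spliced_length, par, escape_class, known_id.  ``escape_class`` is the
    host gene's region class (PAR assignment wins for intergenic PAR
    junctions); 'none' when no host.
    """
    rows = []
    for key in keys:
        bsj = BackspliceJunction.from_key(key)
        origin, hosts, n_exons, length = classify_origin(bsj, annotation,
                                                         boundary_tolerance)
        par = assign_par(bsj, par_regions)
        if hosts:
            escape = annotation.genes[hosts[0]].region_class
        elif par != "none":
            escape = par
        else:
            escape = "none"
        known = None
        if catalogue is not None:
            known = match_known(bsj, catalogue)
        rows.append((key, origin, ",".join(hosts), n_exons, length, par, escape,
                     known if known is not None else ""))
    return pd.DataFrame(rows, columns=["key", "origin", "host_gene_ids", "exon_count",
                                       "spliced_length", "par", "escape_class",
                                       "known_id"])


def isoforms_per_host(circ_annotations: pd.DataFrame,
                      cpm: CountMatrix) -> pd.DataFrame:
    """Circular-isoform counts and mean expression per host transcript.

    A junction spanning several hosts counts once per host.  Hosts with no
    kept junction are absent.  ``mean_expression`` is the grand mean circCPM
    over that host's junctions and all samples.
    """
    if cpm.scale != "circcpm":
        raise ValueError("isoforms_per_host expects a circCPM matrix")
    per_host: dict[str, list[str]] = {}
    for _, r in circ_annotations.iterrows():
        if not r["host_gene_ids"]:
            continue
        for host in str(r["host_gene_ids"]).split(","):
            if r["key"] in cpm.data.index:
                per_host.setdefault(host, []).append(r["key"])
    rows = [(host, len(keys), float(cpm.data.loc[keys].to_numpy().mean()))
            for host, keys in sorted(per_host.items())]
    return pd.DataFrame(rows, columns=["host_gene_id", "isoform_count",
                                       "mean_expression"])
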