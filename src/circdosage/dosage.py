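"""Sex-chromosome dosage analysis of PAR circRNAs and genes.

Pseudoautosomal (PAR) genes sit on both X and Y, escape X inactivation and
are expected to scale with the total sex-chromosome count: 1:2:2:3 across
45,X : 46,XY : 46,XX : 47,XXY.  The theoretical contrast lines are
log2(3/2) = 0.585 for 47,XXY vs 46,XY and log2(1/2) = -1 for 45,X vs 46,XX.
This module tests collective PAR log2FC shifts against zero (one-sample t),
profiles per-circRNA stoichiometry across karyotypes, and quantifies how
much of the mRNA dosage effect survives at the circRNA level (the
attenuation slope).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountMatrix
from .simulate import KARYOTYPE_SEX_CHROMOSOMES

STOICHIOMETRY_ORDER = ("45X", "46XY", "46XX", "47XXY")
STOICHIOMETRY = (1.0, 2.0, 2.0, 3.0)


def _normalize_karyotype(karyotype: str) -> str:
    k = re.sub(r"[,\s]", "", karyotype).upper()
    if k not in KARYOTYPE_SEX_CHROMOSOMES:
        raise ValueError(f"unknown karyotype {karyotype!r}")
    return k


def karyotype_copies(karyotype: str) -> tuple[int, int, int]:
    """(nX, nY, PAR copies = nX + nY) for a karyotype such as '47XXY' or '45,X'."""
    nx, ny = KARYOTYPE_SEX_CHROMOSOMES[_normalize_karyotype(karyotype)]
    return nx, ny, nx + ny


def expected_dosage_log2fc(case: str, control: str, region_class: str) -> float:
    """Theoretical log2 fold change (case vs control) for a region class.

    PAR features use total sex-chromosome copies (nX+nY); chrX escape
    features use nX; inactivated chrX and autosomal features expect 0; chrY
    features use nY.  Raises when the control copy number is zero.
    """
    nx1, ny1, par1 = karyotype_copies(case)
    nx0, ny0, par0 = karyotype_copies(control)
    if region_class in ("PAR", "PAR1", "PAR2"):
        c1, c0 = par1, par0
    elif region_class == "chrX_escape":
        c1, c0 = nx1, nx0
    elif region_class == "chrY":
        c1, c0 = ny1, ny0
    elif region_class in ("chrX_inactive", "autosome"):
        return 0.0
    else:
        raise ValueError(f"unknown region class {region_class!r}")
    if c0 == 0:
        raise ValueError(f"control karyotype {control} has zero copies for "
                         f"{region_class}")
    if c1 == 0:
        raise ValueError(f"case karyotype {case} has zero copies for {region_class}")
    return math.log2(c1 / c0)


def significance_stars(p: float) -> str:
    """Star notation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CollectiveShift:
    """One-sample t-test of a set of log2FCs against mu (default 0)."""

    tissue: str
    contrast: str
    region: str
    n: int
    mean_log2fc: float
    t: float
    p: float
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def one_sample_t(values: np.ndarray, mu: float = 0.0) -> tuple[float, float, bool]:
    """t = mean/(sd/sqrt(n)) with n-1 df, two-sided p.

    Returns (t, p, degenerate).  Zero variance is degenerate: p = 0 when the
    mean differs from mu, p = 1 otherwise.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need >= 2 values for a one-sample t-test, got {n}")
    sd = x.std(ddof=1)
    mean = x.mean()
    if sd == 0.0:
        return (math.inf if mean != mu else 0.0,
                0.0 if mean != mu else 1.0, True)
    t = (mean - mu) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return t, p, False


def collective_par_shift(de_results: pd.DataFrame, circ_annotations: pd.DataFrame,
                         tissue: str, contrast: str, region: str = "PAR1",
                         mu: float = 0.0) -> CollectiveShift:
    """Collective log2FC shift of PAR-assigned circRNAs for one contrast.

    Uses ALL circRNAs assigned to ``region`` that have a log2FC estimate
    (not only significant ones), testing their mean against ``mu`` with a
    two-sided one-sample t-test.  PAR2 circRNAs (missing escape status) are
    profiled by passing region='PAR2' but are excluded from dosage
    expectations elsewhere by default.
    """
    par_keys = set(circ_annotations.loc[circ_annotations["par"] == region, "key"])
    lfc = de_results.loc[de_results.index.isin(par_keys), "log2fc"].dropna().to_numpy()
    if lfc.size < 2:
        raise ValueError(f"only {lfc.size} {region} circRNA(s) with estimates "
                         f"in {tissue}/{contrast}; need >= 2")
    t, p, degenerate = one_sample_t(lfc, mu=mu)
    return CollectiveShift(tissue=tissue, contrast=contrast, region=region,
                           n=int(lfc.size), mean_log2fc=float(lfc.mean()),
                           t=float(t), p=float(p), degenerate=degenerate)


def stoichiometry_profile(cpm: CountMatrix, metadata: pd.DataFrame, key: str
                          ) -> pd.DataFrame:
    """Per-karyotype mean expression of one circRNA against the 1:2:2:3 line.

    Means are normalized so 46,XY = 2; karyotypes without samples (or with
    the key undetected) report mean 0 rather than being dropped.  The result
    carries the root-mean-square deviation from (1, 2, 2, 3) in
    ``df.attrs['rmsd']``.
    """
    if key not in cpm.data.index:
        raise KeyError(f"{key} not in matrix")
    meta = metadata.set_index("sample_id")
    expr = cpm.data.loc[key]
    means = []
    for kary in STOICHIOMETRY_ORDER:
        samples = meta.index[(meta["karyotype"] == kary)
                             & meta.index.isin(expr.index)]
        means.append(float(expr.loc[samples].mean()) if len(samples) else 0.0)
    means = np.asarray(means)
    ref = means[STOICHIOMETRY_ORDER.index("46XY")]
    scaled = means * (2.0 / ref) if ref > 0 else np.zeros_like(means)
    rmsd = float(np.sqrt(np.mean((scaled - np.asarray(STOICHIOMETRY)) ** 2)))
    out = pd.DataFrame({"karyotype": STOICHIOMETRY_ORDER, "mean_expression": means,
                        "scaled": scaled, "expected": STOICHIOMETRY})
    out.attrs["rmsd"] = rmsd
    return out


def circ_mrna_attenuation(circ_de: pd.DataFrame, gene_de: pd.DataFrame,
                          circ_annotations: pd.DataFrame, region: str = "PAR1",
                          through_origin: bool = True
                          ) -> tuple[pd.DataFrame, float, float]:
    """Pair PAR circRNA log2FCs with their host-gene log2FCs.

    Returns ``(pairs, pearson_r, slope)`` where ``slope`` regresses the
    circRNA log2FC on the mRNA log2FC (through the origin by default, since
    both axes are contrasts of the same groups).  A slope below 1 indicates
    dosage attenuation at the circRNA level; under the generator's model the
    slope estimates alpha.  Requires >= 3 circRNA-host pairs.
    """
    ann = circ_annotations
    if region is not None:
        ann = ann[ann["par"] == region]
    rows = []
    for _, r in ann.iterrows():
        key = r["key"]
        hosts = [h for h in str(r["host_gene_ids"]).split(",") if h]
        if key not in circ_de.index or not hosts:
            continue
        for host in hosts:
            if host in gene_de.index:
                rows.append((key, host, float(circ_de.loc[key, "log2fc"]),
                             float(gene_de.loc[host, "log2fc"])))
    pairs = pd.DataFrame(rows, columns=["key", "host_gene", "circ_log2fc",
                                        "gene_log2fc"])
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} circRNA-host pairs with both "
                         "estimates; need >= 3")
    x = pairs["gene_log2fc"].to_numpy()
    y = pairs["circ_log2fc"].to_numpy()
    r = float(np.corrcoef(x, y)[0, 1])
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
    else:
        slope = float(np.polyfit(x, y, 1)[0])
    return pairs, r, slope
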