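"""Synthetic circRNA study generator.

Builds a complete synthetic cohort with the statistical structure the
downstream analysis assumes: a gene annotation with autosomal, chrX
(escape / inactivated), chrY and pseudoautosomal (PAR1/PAR2) genes; a
subject cohort across karyotypes 45,X / 46,XX / 46,XY / 47,XXY and tissues;
negative-binomial circRNA, linear-junction and gene counts carrying
karyotype dosage effects, tissue effects, batch effects and per-sample
library sizes; noisy multi-caller detection files; a known-circRNA
catalogue; and circRNA-miRNA / miRNA-mRNA interaction tables with planted
sponge triplets.

The copy-number model: PAR genes sit on every sex chromosome, so their copy
number is nX + nY (1:2:2:3 across 45,X : 46,XY : 46,XX : 47,XXY); chrX
escape genes scale with nX; inactivated chrX genes are copy-invariant; chrY
genes scale with nY.  mRNA expression follows the copy ratio fully; the
circRNA-level dosage effect is attenuated by a single exponent alpha in
[0, 1] (alpha = 1: circRNAs track their hosts; alpha = 0: no circRNA
dosage response).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import Annotation, Gene, PAR_REGIONS
from .junctions import BackspliceJunction
from .quantify import CountMatrix

KARYOTYPE_SEX_CHROMOSOMES: dict[str, tuple[int, int]] = {
    "45X": (1, 0), "46XX": (2, 0), "46XY": (1, 1), "47XXY": (2, 1),
}

_STAGE = {"annotation": 0, "cohort": 1, "circ_features": 2, "counts": 3,
          "callers": 4, "catalogue": 5, "interactions": 6}

SECONDARY_CALLERS = ("caller_b", "caller_c")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-generator configuration.

    The defaults describe a modest multi-tissue aneuploidy cohort: all four
    karyotypes in three tissues, two library batches, and a circRNA
    complement dominated by exonic, autosomal junctions with a small
    sex-chromosome contingent.  ``circ_attenuation`` is the fraction of the
    mRNA log2 dosage effect retained at the circRNA level.
    """

    n_per_group: int = 10
    karyotypes: tuple[str, ...] = ("45X", "46XX", "46XY", "47XXY")
    tissues: tuple[str, ...] = ("blood", "muscle", "fat")
    n_batches: int = 2
    n_circ: int = 500
    frac_par1: float = 0.05
    frac_par2: float = 0.02
    frac_chrx_escape: float = 0.05
    frac_chrx_inactive: float = 0.05
    frac_chry: float = 0.02
    frac_exonic: float = 0.88
    frac_intronic: float = 0.07
    frac_known: float = 0.36
    n_background_genes: int = 60
    mean_log_expression: float = math.log(60.0)
    sd_log_expression: float = 1.0
    dispersion: float = 0.1
    mean_log_gene_expression: float = math.log(400.0)
    sd_log_gene_expression: float = 1.0
    mrna_dosage_full: bool = True
    circ_attenuation: float = 0.5
    fp_rate_per_caller: float = 0.05
    fn_rate_per_caller: float = 0.05
    primary_fp_rate: float = 0.0
    batch_sd: float = 0.1
    tissue_sd: float = 0.5
    lib_size_range: tuple[int, int] = (50_000, 150_000)
    gene_lib_factor_range: tuple[float, float] = (0.8, 1.2)
    frac_ctl_one: float = 0.10
    n_triplets: int = 5
    n_decoy_triplets: int = 3
    n_low_evidence_edges: int = 5
    n_noise_edges: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {"frac_par1": self.frac_par1, "frac_par2": self.frac_par2,
                 "frac_chrx_escape": self.frac_chrx_escape,
                 "frac_chrx_inactive": self.frac_chrx_inactive,
                 "frac_chry": self.frac_chry, "frac_known": self.frac_known,
                 "frac_exonic": self.frac_exonic, "frac_intronic": self.frac_intronic,
                 "frac_ctl_one": self.frac_ctl_one}
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"{name}={f} outside [0, 1]")
        region_sum = (self.frac_par1 + self.frac_par2 + self.frac_chrx_escape
                      + self.frac_chrx_inactive + self.frac_chry)
        if region_sum > 1.0 + 1e-12:
            raise ConfigError(f"region-class fractions sum to {region_sum} > 1")
        if self.frac_exonic + self.frac_intronic > 1.0 + 1e-12:
            raise ConfigError("origin fractions sum above 1")
        if not 0.0 <= self.circ_attenuation <= 1.0:
            raise ConfigError("circ_attenuation (alpha) must be in [0, 1]")
        if not self.karyotypes:
            raise ConfigError("karyotypes must be non-empty")
        if not self.tissues:
            raise ConfigError("tissues must be non-empty")
        for k in self.karyotypes:
            if k not in KARYOTYPE_SEX_CHROMOSOMES:
                raise ConfigError(f"unknown karyotype {k!r}")
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.dispersion < 0 or self.batch_sd < 0 or self.tissue_sd < 0:
            raise ConfigError("scale parameters must be non-negative")
        if not (0 <= self.fp_rate_per_caller <= 1 and 0 <= self.fn_rate_per_caller <= 1):
            raise ConfigError("caller error rates must be in [0, 1]")


def _rng(config: SimConfig, stage: str, *extra: int) -> np.random.Generator:
    """Deterministic per-stage random stream derived from the single seed."""
    key = (_STAGE[stage],) + tuple(extra)
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


@dataclass
class CallerOutputs:
    """Per-sample detection tables for one primary and N secondary callers."""

    primary: dict[str, pd.DataFrame]              # sample -> primary-dialect table
    secondary: dict[str, dict[str, set[str]]]     # caller -> sample -> keys
    injected: dict[str, dict[str, set[str]]]      # caller -> sample -> injected FP keys

    def primary_records(self) -> dict[str, pd.DataFrame]:
        """Per-sample (key, bsj_reads, linear_reads) records, as the primary
        reader would return them (the dialect's circ_id is the canonical key)."""
        return {s: df.rename(columns={"circ_id": "key"})[
                    ["key", "bsj_reads", "linear_reads"]]
                for s, df in self.primary.items()}

    def primary_keys(self) -> set[str]:
        return set().union(*(set(df["circ_id"]) for df in self.primary.values())) \
            if self.primary else set()

    def secondary_key_sets(self) -> list[set[str]]:
        """Dataset-level key set per secondary caller (union over samples)."""
        return [set().union(*per.values()) if per else set()
                for per in self.secondary.values()]


@dataclass
class TruthBundle:
    """Ground truth for parameter-recovery tests: everything the generator knows."""

    config: SimConfig
    annotation: Annotation
    cohort: pd.DataFrame
    circ_features: pd.DataFrame        # key, host_gene, origin, region_class, ctl_target
    true_circ_counts: CountMatrix
    true_linear_counts: pd.DataFrame
    true_gene_counts: pd.DataFrame
    true_effects: pd.DataFrame         # feature, kind, region_class, per-contrast log2FC
    catalogue: pd.DataFrame = field(default_factory=pd.DataFrame)
    caller_outputs: CallerOutputs | None = None
    circ_mirna: pd.DataFrame = field(default_factory=pd.DataFrame)
    mirna_targets: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_triplets: pd.DataFrame = field(default_factory=pd.DataFrame)
    decoy_triplets: pd.DataFrame = field(default_factory=pd.DataFrame)
    dec_directions: pd.DataFrame = field(default_factory=pd.DataFrame)
    deg_directions: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def true_keys(self) -> set[str]:
        return set(self.circ_features["key"])


# ---------------------------------------------------------------------------
# annotation

def _region_counts(config: SimConfig) -> dict[str, int]:
    n = config.n_circ
    counts = {
        "PAR1": round(config.frac_par1 * n),
        "PAR2": round(config.frac_par2 * n),
        "chrX_escape": round(config.frac_chrx_escape * n),
        "chrX_inactive": round(config.frac_chrx_inactive * n),
        "chrY": round(config.frac_chry * n),
    }
    counts["autosome"] = n - sum(counts.values())
    if counts["autosome"] < 0:
        raise ConfigError("region-class fractions leave no room for autosomal circRNAs")
    return counts

# compact gene geometry keeps PAR2 (329,512 bp printed) from overflowing
_GENE_GEOM = {"n_exons": (3, 9), "exon_len": (100, 401), "intron_len": (200, 1001),
              "gap": (2000, 5001)}

# 0-based half-open placement windows per region class
_REGION_SPACE: dict[str, list[tuple[str, int, int]]] = {
    "PAR1": [("chrX", 10_000, 2_781_479)],
    "PAR2": [("chrX", 155_701_382, 156_030_895)],
    "chrX_escape": [("chrX", 3_000_000, 60_000_000)],
    "chrX_inactive": [("chrX", 61_000_000, 120_000_000)],
    "chrY": [("chrY", 3_000_000, 25_000_000)],
    "autosome": [(f"chr{i}", 100_000, 200_000_000) for i in range(1, 6)],
}


def _make_gene(gene_id: str, chrom: str, cursor: int, region: str,
               rng: np.random.Generator) -> tuple[Gene, int]:
    n_exons = int(rng.integers(*_GENE_GEOM["n_exons"]))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = cursor
    for i in range(n_exons):
        length = int(rng.integers(*_GENE_GEOM["exon_len"]))
        exons.append((pos, pos + length))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(*_GENE_GEOM["intron_len"]))
    gene = Gene(gene_id, chrom, strand, region, tuple(exons))
    next_cursor = pos + int(rng.integers(*_GENE_GEOM["gap"]))
    return gene, next_cursor


def generate_annotation(config: SimConfig) -> Annotation:
    """Generate gene models for every region class.

    One host gene is created per planned circRNA (region classes follow the
    configured fractions, remainder autosomal) plus ``n_background_genes``
    autosomal genes without circRNAs.  Every PAR gene lies wholly within its
    PAR interval; overflow of a PAR window raises :class:`ConfigError`.
    """
    rng = _rng(config, "annotation")
    counts = _region_counts(config)
    genes: dict[str, Gene] = {}
    gene_idx = 0
    for region in ("PAR1", "PAR2", "chrX_escape", "chrX_inactive", "chrY", "autosome"):
        spaces = _REGION_SPACE[region]
        cursors = {(c, lo): lo for c, lo, _ in spaces}
        bounds = {(c, lo): hi for c, lo, hi in spaces}
        space_keys = list(cursors)
        for j in range(counts[region]):
            sk = space_keys[j % len(space_keys)]
            chrom = sk[0]
            gene_id = f"G{gene_idx:04d}"
            gene, nxt = _make_gene(gene_id, chrom, cursors[sk], region, rng)
            if gene.end > bounds[sk]:
                raise ConfigError(
                    f"too many {region} genes for the {chrom} window "
                    f"({counts[region]} requested)")
            genes[gene_id] = gene
            cursors[sk] = nxt
            gene_idx += 1
    # background autosomal genes (DE-universe padding, no circRNAs)
    spaces = _REGION_SPACE["autosome"]
    cursors = {c: 210_000_000 for c, _, _ in spaces}
    for j in range(config.n_background_genes):
        chrom = spaces[j % len(spaces)][0]
        gene_id = f"BG{j:04d}"
        gene, nxt = _make_gene(gene_id, chrom, cursors[chrom], "autosome", rng)
        genes[gene_id] = gene
        cursors[chrom] = nxt
    return Annotation(genes)


# ---------------------------------------------------------------------------
# cohort

def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """One sample per subject x tissue with karyotype, batch and pairing.

    Returns columns sample_id, subject_id, karyotype, tissue, batch, nX, nY.
    Subjects carry stable ids enabling paired designs; batches are assigned
    round-robin over samples ordered by (tissue, karyotype, subject).
    """
    subjects = []
    idx = 0
    for kary in config.karyotypes:
        for _ in range(config.n_per_group):
            subjects.append((f"S{idx:03d}", kary))
            idx += 1
    rows = []
    i = 0
    for tissue in config.tissues:
        for subj, kary in subjects:
            nx, ny = KARYOTYPE_SEX_CHROMOSOMES[kary]
            rows.append((f"{subj}_{tissue}", subj, kary, tissue,
                         f"batch{i % config.n_batches}", nx, ny))
            i += 1
    return pd.DataFrame(rows, columns=["sample_id", "subject_id", "karyotype",
                                       "tissue", "batch", "nX", "nY"])


# ---------------------------------------------------------------------------
# circRNA feature planting

def plant_circrnas(annotation: Annotation, config: SimConfig) -> pd.DataFrame:
    """Place one circRNA per host gene and assign origin and CTL target.

    Sex-chromosome circRNAs are exonic (so each has a host gene whose dosage
    it can attenuate); autosomal circRNAs draw origins from the configured
    exonic/intronic/intergenic mix.  Deterministic given (annotation, config).
    """
    rng = _rng(config, "circ_features")
    hosts = sorted((g for g in annotation.genes.values() if g.gene_id.startswith("G")),
                   key=lambda g: g.gene_id)
    rows = []
    for gene in hosts:
        region = gene.region_class
        if region == "autosome":
            u = rng.random()
            if u < config.frac_exonic:
                origin = "exonic"
            elif u < config.frac_exonic + config.frac_intronic:
                origin = "intronic"
            else:
                origin = "intergenic"
        else:
            origin = "exonic"
        exons = gene.exons
        if origin == "exonic":
            if len(exons) == 1:
                a = b = 0
            else:
                a = int(rng.integers(0, len(exons) - 1))
                b = int(rng.integers(a, len(exons)))
            bsj = BackspliceJunction(gene.chrom, exons[a][0], exons[b][1], gene.strand)
            host = gene.gene_id
        elif origin == "intronic" and len(exons) > 1:
            i = int(rng.integers(0, len(exons) - 1))
            lo, hi = exons[i][1], exons[i + 1][0]
            if hi - lo < 40:
                lo, hi = exons[i][0], exons[i][1]  # degenerate intron: fall back
                origin = "exonic"
                bsj = BackspliceJunction(gene.chrom, lo, hi, gene.strand)
            else:
                bsj = BackspliceJunction(gene.chrom, lo + 10, hi - 10, gene.strand)
            host = gene.gene_id
        else:  # intergenic: placed in the gap downstream of the gene
            start = gene.end + 200
            length = int(rng.integers(100, 800))
            bsj = BackspliceJunction(gene.chrom, start, start + length,
                                     "+" if rng.random() < 0.5 else "-")
            host = ""
            origin = "intergenic"
        if rng.random() < config.frac_ctl_one:
            ctl = 1.0
        else:
            ctl = float(np.clip(rng.beta(2.0, 5.0), 0.02, 0.95))
        rows.append((bsj.key, host, origin, region, ctl))
    df = pd.DataFrame(rows, columns=["key", "host_gene", "origin",
                                     "region_class", "ctl_target"])
    if df["key"].duplicated().any():
        df = df.drop_duplicates("key", keep="first").reset_index(drop=True)
    return df


def generate_catalogue(circ_features: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Known-circRNA catalogue covering ``frac_known`` of the true junctions.

    Adds a handful of decoy entries absent from the data (as any real
    catalogue has).  Columns: known_id, chrom, start, end, strand.
    """
    rng = _rng(config, "catalogue")
    n = len(circ_features)
    n_known = round(config.frac_known * n)
    known_idx = rng.choice(n, size=n_known, replace=False)
    rows = []
    cid = 0
    for i in sorted(known_idx):
        bsj = BackspliceJunction.from_key(circ_features["key"].iloc[int(i)])
        rows.append((f"hsa_circ_{cid:07d}", bsj.chrom, bsj.start, bsj.end, bsj.strand))
        cid += 1
    for _ in range(max(5, n // 50)):  # decoys
        chrom = f"chr{int(rng.integers(1, 6))}"
        start = int(rng.integers(250_000_000, 260_000_000))
        rows.append((f"hsa_circ_{cid:07d}", chrom, start, start + int(rng.integers(200, 2000)),
                     "+" if rng.random() < 0.5 else "-"))
        cid += 1
    return pd.DataFrame(rows, columns=["known_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# counts

def _copy_number(region: str, nx: int, ny: int) -> tuple[int, int]:
    """(copies, reference copies) for a region class in a karyotype."""
    if region in ("PAR1", "PAR2"):
        return nx + ny, 2
    if region == "chrX_escape":
        return nx, 2
    if region == "chrX_inactive":
        return 2, 2
    if region == "chrY":
        return ny, 1
    return 2, 2  # autosome


def _dosage_multiplier(region: str, nx: int, ny: int, alpha: float) -> float:
    copies, ref = _copy_number(region, nx, ny)
    ratio = copies / ref
    if ratio == 0.0:
        return 0.0
    return ratio ** alpha


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson negative binomial with mean mu and variance mu + disp*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(annotation: Annotation, cohort: pd.DataFrame,
                    config: SimConfig) -> TruthBundle:
    """Draw circRNA, linear-junction and gene counts for the cohort.

    Counts are negative-binomial with a log-link mean combining a per-feature
    baseline, tissue effect, batch effect, per-sample library factor and the
    region-dependent dosage multiplier (copy/ref)^alpha for circRNAs and
    copy/ref for mRNAs.  Linear counts are drawn so each feature's
    configured CTL target holds in expectation via l = 2c(1 - CTL)/CTL;
    CTL-target-1 features receive zero linear counts in every sample.
    """
    rng = _rng(config, "counts")
    circ = plant_circrnas(annotation, config)
    samples = list(cohort["sample_id"])
    n_c, n_s = len(circ), len(samples)
    tissues = list(config.tissues)
    batches = sorted(cohort["batch"].unique())
    alpha = config.circ_attenuation
    gene_alpha = 1.0 if config.mrna_dosage_full else alpha

    # per-feature baselines and tissue/batch multipliers (log-normal)
    base_c = np.exp(rng.normal(config.mean_log_expression, config.sd_log_expression, n_c))
    tis_c = np.exp(rng.normal(0.0, config.tissue_sd, (n_c, len(tissues))))
    bat_c = np.exp(rng.normal(0.0, config.batch_sd, (n_c, len(batches))))

    genes = sorted(annotation.genes)
    n_g = len(genes)
    gene_region = np.array([annotation.genes[g].region_class for g in genes])
    base_g = np.exp(rng.normal(config.mean_log_gene_expression,
                               config.sd_log_gene_expression, n_g))
    tis_g = np.exp(rng.normal(0.0, config.tissue_sd, (n_g, len(tissues))))
    bat_g = np.exp(rng.normal(0.0, config.batch_sd, (n_g, len(batches))))

    lib = rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1, n_s)
    lib_factor = lib / np.mean(config.lib_size_range)
    gene_lib = rng.uniform(*config.gene_lib_factor_range, n_s)

    t_idx = cohort["tissue"].map({t: i for i, t in enumerate(tissues)}).to_numpy()
    b_idx = cohort["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    nx = cohort["nX"].to_numpy()
    ny = cohort["nY"].to_numpy()

    circ_region = circ["region_class"].to_numpy()
    dose_c = np.array([[_dosage_multiplier(r, nx[s], ny[s], alpha) for s in range(n_s)]
                       for r in circ_region])
    dose_g = np.array([[_dosage_multiplier(r, nx[s], ny[s], gene_alpha)
                        for s in range(n_s)] for r in gene_region])

    mu_c = (base_c[:, None] * tis_c[:, t_idx] * bat_c[:, b_idx]
            * dose_c * lib_factor[None, :])
    mu_g = (base_g[:, None] * tis_g[:, t_idx] * bat_g[:, b_idx]
            * dose_g * gene_lib[None, :])

    circ_counts = _nb_counts(rng, mu_c, config.dispersion)
    ctl = circ["ctl_target"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_l = np.where(ctl[:, None] > 0, 2.0 * mu_c * (1.0 - ctl[:, None]) / ctl[:, None], 0.0)
    linear_counts = _nb_counts(rng, mu_l, config.dispersion)
    gene_counts = _nb_counts(rng, mu_g, config.dispersion)

    true_circ = CountMatrix(pd.DataFrame(circ_counts, index=circ["key"], columns=samples))
    true_linear = pd.DataFrame(linear_counts, index=circ["key"], columns=samples)
    true_gene = pd.DataFrame(gene_counts, index=genes, columns=samples)

    effects = _true_effects(circ, gene_region, genes, alpha, gene_alpha)
    return TruthBundle(config=config, annotation=annotation, cohort=cohort,
                       circ_features=circ, true_circ_counts=true_circ,
                       true_linear_counts=true_linear, true_gene_counts=true_gene,
                       true_effects=effects)


def _true_effects(circ: pd.DataFrame, gene_region: np.ndarray, genes: list[str],
                  alpha: float, gene_alpha: float) -> pd.DataFrame:
    contrasts = {"45X_vs_46XX": ("45X", "46XX"), "47XXY_vs_46XY": ("47XXY", "46XY")}
    rows = []

    def effect(region: str, case: str, control: str, a: float) -> float:
        nx1, ny1 = KARYOTYPE_SEX_CHROMOSOMES[case]
        nx0, ny0 = KARYOTYPE_SEX_CHROMOSOMES[control]
        m1 = _dosage_multiplier(region, nx1, ny1, a)
        m0 = _dosage_multiplier(region, nx0, ny0, a)
        if m1 == 0.0 or m0 == 0.0:
            return float("nan")
        return math.log2(m1 / m0)

    for _, r in circ.iterrows():
        rows.append([r["key"], "circ", r["region_class"]]
                    + [effect(r["region_class"], *kk, alpha)
                       for kk in contrasts.values()])
    for g, region in zip(genes, gene_region):
        rows.append([g, "gene", region]
                    + [effect(region, *kk, gene_alpha) for kk in contrasts.values()])
    return pd.DataFrame(rows, columns=["feature", "kind", "region_class",
                                       *contrasts.keys()])


# ---------------------------------------------------------------------------
# caller outputs

def emit_caller_outputs(truth: TruthBundle, config: SimConfig | None = None
                        ) -> CallerOutputs:
    """Derive noisy per-sample caller tables from the true counts.

    The primary (count-bearing) caller reports every junction with nonzero
    backsplice reads in that sample, preserving counts exactly.  Each
    secondary caller independently misses true detections at
    ``fn_rate_per_caller`` and injects novel false-positive junctions at
    ``fp_rate_per_caller`` (one Bernoulli trial per true junction); injected
    keys are disjoint from the truth and recorded.  The result is attached
    to ``truth.caller_outputs``.
    """
    config = config or truth.config
    circ = truth.circ_features
    counts = truth.true_circ_counts.data
    linear = truth.true_linear_counts
    true_keys = truth.true_keys
    samples = list(counts.columns)

    primary: dict[str, pd.DataFrame] = {}
    for s_i, sample in enumerate(samples):
        rows = []
        for key, c, l in zip(counts.index, counts[sample], linear[sample]):
            if c <= 0:
                continue
            bsj = BackspliceJunction.from_key(key)
            # primary dialect: 1-based inclusive coordinates
            rows.append((key, bsj.chrom, bsj.start + 1, bsj.end, bsj.strand,
                         int(c), int(l)))
        if config.primary_fp_rate > 0:
            rng_p = _rng(config, "callers", 99, s_i)
            mask = rng_p.random(len(circ)) < config.primary_fp_rate
            for j in np.nonzero(mask)[0]:
                fp = _novel_junction(rng_p, true_keys)
                rows.append((fp.key, fp.chrom, fp.start + 1, fp.end, fp.strand,
                             int(rng_p.integers(1, 10)), 0))
        primary[sample] = pd.DataFrame(
            rows, columns=["circ_id", "chrom", "start", "end", "strand",
                           "bsj_reads", "linear_reads"])

    secondary: dict[str, dict[str, set[str]]] = {}
    injected: dict[str, dict[str, set[str]]] = {}
    all_keys = list(counts.index)
    for c_i, caller in enumerate(SECONDARY_CALLERS):
        secondary[caller] = {}
        injected[caller] = {}
        for s_i, sample in enumerate(samples):
            rng = _rng(config, "callers", c_i, s_i)
            present = [k for k, c in zip(all_keys, counts[sample]) if c > 0]
            keep_mask = rng.random(len(present)) >= config.fn_rate_per_caller
            detected = {k for k, keep in zip(present, keep_mask) if keep}
            inject_mask = rng.random(len(all_keys)) < config.fp_rate_per_caller
            inj: set[str] = set()
            for _ in range(int(inject_mask.sum())):
                inj.add(_novel_junction(rng, true_keys | inj).key)
            secondary[caller][sample] = detected | inj
            injected[caller][sample] = inj
    outputs = CallerOutputs(primary=primary, secondary=secondary, injected=injected)
    truth.caller_outputs = outputs
    return outputs


def _novel_junction(rng: np.random.Generator, forbidden: set[str]) -> BackspliceJunction:
    while True:
        chrom = f"chr{int(rng.integers(1, 6))}"
        start = int(rng.integers(300_000_000, 310_000_000))
        bsj = BackspliceJunction(chrom, start, start + int(rng.integers(150, 1500)),
                                 "+" if rng.random() < 0.5 else "-")
        if bsj.key not in forbidden:
            return bsj


# ---------------------------------------------------------------------------
# interaction tables

def simulate_interaction_tables(annotation: Annotation, config: SimConfig,
                                truth: TruthBundle | None = None) -> TruthBundle | dict:
    """Plant circRNA-miRNA-mRNA sponge triplets plus structured noise.

    Planted sign-consistent triplets pair a circRNA and a target gene with
    the same direction label and >= 2 supporting CLIP experiments; decoy
    triplets are sign-inconsistent (circ and target directions differ) but
    otherwise pass every filter; low-evidence edges carry exactly one
    experiment; noise edges point miRNAs at background genes outside the
    DEG/PAR target universe.  Direction labels for the involved circRNAs
    and genes are recorded as planted truth.

    If ``truth`` is given the tables are attached to it and it is returned;
    otherwise a dict of the same tables is returned.
    """
    rng = _rng(config, "interactions")
    circ = plant_circrnas(annotation, config)
    catalogue = generate_catalogue(circ, config)
    key_by_coord = {(r["chrom"], r["start"], r["end"], r["strand"]): r["known_id"]
                    for _, r in catalogue.iterrows()}
    known_map: dict[str, str] = {}
    for key in circ["key"]:
        b = BackspliceJunction.from_key(key)
        kid = key_by_coord.get((b.chrom, b.start, b.end, b.strand))
        if kid is not None:
            known_map[key] = kid
    known_keys = sorted(known_map)
    host_genes = sorted(g for g in annotation.genes if g.startswith("G"))
    bg_genes = sorted(g for g in annotation.genes if g.startswith("BG"))

    n_trip = config.n_triplets
    n_decoy = config.n_decoy_triplets
    need = n_trip + n_decoy + config.n_low_evidence_edges + config.n_noise_edges
    if len(known_keys) < max(n_trip + n_decoy, 1) and need > 0:
        raise ConfigError("not enough catalogued circRNAs to plant the requested edges")

    mir_counter = 0

    def next_mir() -> str:
        nonlocal mir_counter
        mir_counter += 1
        return f"hsa-miR-{mir_counter:04d}-5p"

    circ_mirna_rows = []   # known_id, mirna, n_clip_experiments
    target_rows = []       # mirna, gene_id
    planted, decoys = [], []
    circ_dir: dict[str, str] = {}
    gene_dir: dict[str, str] = {}

    picked = list(rng.choice(len(known_keys), size=min(len(known_keys), n_trip + n_decoy),
                             replace=False))
    trip_circ = [known_keys[int(i)] for i in picked[:n_trip]]
    decoy_circ = [known_keys[int(i)] for i in picked[n_trip:n_trip + n_decoy]]
    gene_pool = [g for g in host_genes]

    for i, key in enumerate(trip_circ):
        direction = "up" if i % 2 == 0 else "down"
        mir = next_mir()
        gene = gene_pool[int(rng.integers(0, len(gene_pool)))]
        circ_dir[key] = direction
        gene_dir.setdefault(gene, direction)
        if gene_dir[gene] != direction:   # re-draw on conflict with earlier planting
            gene = gene_pool[(gene_pool.index(gene) + 1) % len(gene_pool)]
            gene_dir[gene] = direction
        circ_mirna_rows.append((known_map[key], mir, int(rng.integers(2, 6))))
        target_rows.append((mir, gene))
        planted.append((key, known_map[key], mir, gene, direction))

    for i, key in enumerate(decoy_circ):
        direction = "up" if i % 2 == 0 else "down"
        opposite = "down" if direction == "up" else "up"
        mir = next_mir()
        candidates = [g for g in gene_pool if gene_dir.get(g, opposite) == opposite]
        gene = candidates[int(rng.integers(0, len(candidates)))]
        circ_dir.setdefault(key, direction)
        gene_dir[gene] = opposite
        circ_mirna_rows.append((known_map[key], mir, int(rng.integers(2, 6))))
        target_rows.append((mir, gene))
        decoys.append((key, known_map[key], mir, gene, circ_dir[key], opposite))

    # low-evidence edges: would be sign-consistent, but only 1 CLIP experiment
    for _ in range(config.n_low_evidence_edges):
        key = known_keys[int(rng.integers(0, len(known_keys)))]
        mir = next_mir()
        direction = circ_dir.setdefault(key, "up" if rng.random() < 0.5 else "down")
        candidates = [g for g in gene_pool if gene_dir.get(g, direction) == direction]
        gene = candidates[int(rng.integers(0, len(candidates)))]
        gene_dir[gene] = direction
        circ_mirna_rows.append((known_map[key], mir, 1))
        target_rows.append((mir, gene))

    # noise: well-supported edges whose miRNAs only target background genes
    for _ in range(config.n_noise_edges):
        key = known_keys[int(rng.integers(0, len(known_keys)))]
        mir = next_mir()
        circ_mirna_rows.append((known_map[key], mir, int(rng.integers(2, 6))))
        if bg_genes:
            target_rows.append((mir, bg_genes[int(rng.integers(0, len(bg_genes)))]))

    tables = {
        "circ_mirna": pd.DataFrame(circ_mirna_rows,
                                   columns=["known_id", "mirna", "n_clip_experiments"]),
        "mirna_targets": pd.DataFrame(target_rows, columns=["mirna", "gene_id"]),
        "planted_triplets": pd.DataFrame(
            planted, columns=["key", "known_id", "mirna", "gene_id", "direction"]),
        "decoy_triplets": pd.DataFrame(
            decoys, columns=["key", "known_id", "mirna", "gene_id",
                             "circ_direction", "gene_direction"]),
        "dec_directions": pd.DataFrame(sorted(circ_dir.items()),
                                       columns=["key", "direction"]),
        "deg_directions": pd.DataFrame(sorted(gene_dir.items()),
                                       columns=["gene_id", "direction"]),
        "catalogue": catalogue,
    }
    if truth is not None:
        truth.circ_mirna = tables["circ_mirna"]
        truth.mirna_targets = tables["mirna_targets"]
        truth.planted_triplets = tables["planted_triplets"]
        truth.decoy_triplets = tables["decoy_triplets"]
        truth.dec_directions = tables["dec_directions"]
        truth.deg_directions = tables["deg_directions"]
        truth.catalogue = catalogue
        return truth
    return tables


# ---------------------------------------------------------------------------
# orchestration + writers

def simulate_study(config: SimConfig) -> TruthBundle:
    """Run the full generator: annotation, cohort, counts, callers, interactions."""
    annotation = generate_annotation(config)
    cohort = generate_cohort(config)
    truth = simulate_counts(annotation, cohort, config)
    emit_caller_outputs(truth)
    simulate_interaction_tables(annotation, config, truth=truth)
    return truth


def write_study(truth: TruthBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every generated artifact as plain-text files under ``outdir``.

    Primary caller tables are TSV (1-based inclusive coordinates), secondary
    caller tables BED6 (0-based half-open), cohort/annotation/catalogue/
    interaction tables TSV, and the ground truth a single JSON file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["cohort"] = outdir / "cohort.tsv"
    truth.cohort.to_csv(paths["cohort"], sep="\t", index=False)
    paths["annotation"] = outdir / "annotation.tsv"
    truth.annotation.to_tsv(paths["annotation"])
    paths["catalogue"] = outdir / "catalogue.tsv"
    truth.catalogue.to_csv(paths["catalogue"], sep="\t", index=False)
    paths["gene_counts"] = outdir / "gene_counts.tsv"
    truth.true_gene_counts.to_csv(paths["gene_counts"], sep="\t", index_label="gene_id")
    paths["circ_mirna"] = outdir / "circ_mirna.tsv"
    truth.circ_mirna.to_csv(paths["circ_mirna"], sep="\t", index=False)
    paths["mirna_targets"] = outdir / "mirna_targets.tsv"
    truth.mirna_targets.to_csv(paths["mirna_targets"], sep="\t", index=False)

    co = truth.caller_outputs
    if co is not None:
        pdir = outdir / "primary"
        pdir.mkdir(exist_ok=True)
        for sample, df in co.primary.items():
            df.to_csv(pdir / f"{sample}.tsv", sep="\t", index=False)
        paths["primary_dir"] = pdir
        for caller, per_sample in co.secondary.items():
            cdir = outdir / caller
            cdir.mkdir(exist_ok=True)
            for sample, keys in per_sample.items():
                with (cdir / f"{sample}.bed").open("w") as fh:
                    for key in sorted(keys):
                        b = BackspliceJunction.from_key(key)
                        fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{key}\t0\t{b.strand}\n")
            paths[caller] = cdir

    paths["truth"] = outdir / "truth.json"
    _write_truth_json(truth, paths["truth"])
    return paths


def _write_truth_json(truth: TruthBundle, path: Path) -> None:
    payload = {
        "config": asdict(truth.config),
        "circ_features": truth.circ_features.to_dict(orient="list"),
        "true_circ_counts": {
            "index": list(truth.true_circ_counts.data.index),
            "columns": list(truth.true_circ_counts.data.columns),
            "values": truth.true_circ_counts.data.to_numpy().tolist(),
        },
        "true_effects": truth.true_effects.to_dict(orient="list"),
        "planted_triplets": truth.planted_triplets.to_dict(orient="list"),
        "decoy_triplets": truth.decoy_triplets.to_dict(orient="list"),
        "dec_directions": truth.dec_directions.to_dict(orient="list"),
        "deg_directions": truth.deg_directions.to_dict(orient="list"),
        "injected_false_positives": {
            caller: {s: sorted(keys) for s, keys in per.items()}
            for caller, per in (truth.caller_outputs.injected.items()
                                if truth.caller_outputs else [])
        },
    }
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
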