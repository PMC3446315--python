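"""Synthetic methylome generator.

Emulates, at desk scale, the ingredients of a cross-tissue MeDIP-seq study:
a toy genome with CpG-island-like clusters and gene models, per-tissue /
per-individual methylation states with planted tissue-specific DMRs
concentrated in chosen feature classes, and bin-level MeDIP-like read
counts whose expectation depends jointly on methylation and local CpG
density through a saturating capture-efficiency curve.  Every downstream
stage of the pipeline is testable against the planted truth with no
download.

The count model is Poisson (optionally Gamma-mixed for overdispersion) at
bin level; fragment-level read simulation is deliberately skipped — the
pipeline's interval-counting operation is tested separately on hand-made
fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import genome_features as gf
from .coupling_norm import BinGrid
from .dmr_analysis import FeatureMethylationMatrix

logger = logging.getLogger("medipkit")

# Baseline methylation per feature class, mirroring the canonical ordering:
# promoter CGIs and HCPs hypomethylated, shores and gene bodies intermediate
# to high, LCPs the most methylated class.
CLASS_BASELINES = {
    "CGI_PROMOTER": 0.10,
    "HCP": 0.12,
    "CGI_INTRAGENIC": 0.35,
    "CGI_3UTR": 0.35,
    "CGI_INTERGENIC": 0.35,
    "ICP": 0.45,
    "SHORE_PROMOTER": 0.55,
    "SHORE_INTRAGENIC": 0.55,
    "SHORE_3UTR": 0.55,
    "SHORE_INTERGENIC": 0.55,
    "CDS": 0.65,
    "LCP": 0.80,
}

# painting precedence for bin-level truth (later paints win)
_PAINT_ORDER = ("CDS", "HCP", "ICP", "LCP") + gf.SHORE_CLASSES + gf.CGI_CLASSES


@dataclass
class SimulationConfig:
    """All knobs of the generator; a fixed seed makes every output
    byte-identical across runs."""

    # genome
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_cgis_per_chrom: int = 60
    cgi_length_mean: float = 1000.0
    cgi_length_sd: float = 300.0
    cgi_length_min: int = 200
    background_cpg_rate: float = 0.01
    island_cpg_rate: float = 0.08
    genes_per_chrom: int = 40
    gene_length_min: int = 3000
    gene_length_max: int = 15000
    utr3_len: int = 500
    gc_background: float = 0.40
    gc_island: float = 0.60
    # cohort
    tissues: tuple = ("cortex", "cerebellum", "blood")
    cortex_regions: int = 1
    n_individuals: int = 3
    # methylation structure
    dmr_fraction: dict = field(
        default_factory=lambda: {"CGI_INTRAGENIC": 0.20, "LCP": 0.15, "default": 0.05}
    )
    effect_delta: float = 0.4
    random_sign: bool = False
    noise_sd: float = 0.05
    individual_sd: float = 0.2
    rho_individual: float = 0.7
    tissue_effect_sd: float = 0.0
    baseline_jitter_sd: float = 0.05
    background_methylation: float = 0.75
    background_methylation_sd: float = 0.15
    # counts
    library_size: int = 500_000
    capture_k: float = 10.0
    count_background: float = 0.01
    dispersion: float = 0.0  # Gamma-mixing; 0 = pure Poisson
    seed: int = 0

    def __post_init__(self):
        for name in ("background_cpg_rate", "island_cpg_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.rho_individual <= 1:
            raise ValueError(
                "rho_individual must be in [0, 1]: the shared/private "
                "decomposition of individual effects does not extend to "
                "negative equicorrelation across 3+ tissues"
            )
        for name in ("noise_sd", "individual_sd", "tissue_effect_sd",
                     "baseline_jitter_sd", "dispersion", "count_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        bad = [k for k, v in self.dmr_fraction.items() if not 0 <= v <= 1]
        if bad:
            raise ValueError(f"dmr_fraction entries outside [0, 1]: {bad}")

    def rng(self, *spawn_key: int) -> np.random.Generator:
        """Stage-specific generator stably derived from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=spawn_key)
        )


@dataclass
class SyntheticGenome:
    """Toy genome: chromosome sizes, CpG positions, CGIs and gene models."""

    chrom_lengths: dict
    cpg_positions: dict  # chrom -> sorted int array
    cgis: pd.DataFrame
    genes: pd.DataFrame  # chrom, start, end, strand, gene_id, utr3_len
    gc_background: float = 0.40
    gc_island: float = 0.60

    def gc_fraction(self, chrom: str, start: int, end: int) -> float:
        """GC fraction of a window from the configured two-level GC track
        (island GC inside CGIs, background elsewhere), overlap-weighted."""
        if end <= start:
            return self.gc_background
        sub = self.cgis[self.cgis["chrom"] == chrom]
        overlap = np.minimum(sub["end"].to_numpy(), end) - np.maximum(
            sub["start"].to_numpy(), start
        )
        isl = int(np.clip(overlap, 0, None).sum())
        isl = min(isl, end - start)
        frac = isl / (end - start)
        return frac * self.gc_island + (1 - frac) * self.gc_background

    def annotate(self, **kwargs) -> pd.DataFrame:
        """Full annotated feature universe for this genome."""
        return gf.annotate_features(
            self.cgis, self.genes, self.chrom_lengths, self.cpg_positions,
            gc_fraction=self.gc_fraction, **kwargs,
        )


@dataclass
class TrueMethylome:
    """Planted truth: methylation in [0,1] per (feature, tissue group,
    individual), the planted DMRs, and the individual-effect correlation."""

    m: np.ndarray  # (n_features, n_groups, n_individuals)
    feature_ids: pd.Index
    groups: list
    individuals: list
    planted: pd.DataFrame  # feature, feature_class, group, delta
    rho: float


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Draw a toy genome.

    CpG positions follow a two-rate Bernoulli process (island rate inside
    CGIs, background elsewhere); genes are non-overlapping within each
    chromosome; CGIs are anchored at promoters, gene bodies, 3'UTRs and
    intergenic space so every location subtype is represented.
    """
    if config.island_cpg_rate <= config.background_cpg_rate and config.island_cpg_rate > 0:
        logger.warning(
            "simulate_genome: island CpG rate (%g) <= background rate (%g); "
            "islands will not be distinguishable",
            config.island_cpg_rate, config.background_cpg_rate,
        )
    rng = config.rng(0)
    chrom_lengths = {
        f"chr{i + 1}": int(config.chrom_length) for i in range(config.n_chroms)
    }
    genes_parts, cgi_parts, cpg = [], [], {}
    gene_counter = 0
    for chrom, L in chrom_lengths.items():
        genes = _place_genes(rng, chrom, L, config, gene_counter)
        gene_counter += len(genes)
        cgis = _place_cgis(rng, chrom, L, genes, config)
        rate = np.full(L, config.background_cpg_rate)
        for s, e in zip(cgis["start"], cgis["end"]):
            rate[s:e] = config.island_cpg_rate
        cpg[chrom] = np.flatnonzero(rng.random(L) < rate).astype(np.int64)
        genes_parts.append(genes)
        cgi_parts.append(cgis)
    return SyntheticGenome(
        chrom_lengths=chrom_lengths,
        cpg_positions=cpg,
        cgis=pd.concat(cgi_parts, ignore_index=True),
        genes=pd.concat(genes_parts, ignore_index=True),
        gc_background=config.gc_background,
        gc_island=config.gc_island,
    )


def _place_genes(rng, chrom, L, config, id_offset) -> pd.DataFrame:
    n = config.genes_per_chrom
    if n == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "gene_id", "utr3_len"]
        )
    lengths = rng.integers(config.gene_length_min, config.gene_length_max + 1, n)
    margin = 5000  # keep promoters/flanks on-chromosome
    slack = L - 2 * margin - int(lengths.sum())
    if slack < 0:
        raise ValueError(
            f"simulate_genome: {n} genes of total length {lengths.sum()} do "
            f"not fit on {chrom} (length {L})"
        )
    gaps = np.sort(rng.uniform(0, slack, n)).astype(np.int64)
    starts = margin + gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
    strands = rng.choice(["+", "-"], n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
            "gene_id": [f"G{id_offset + i:04d}" for i in range(n)],
            "utr3_len": config.utr3_len,
        }
    )


def _place_cgis(rng, chrom, L, genes, config) -> pd.DataFrame:
    n = config.n_cgis_per_chrom
    lengths = np.maximum(
        rng.normal(config.cgi_length_mean, config.cgi_length_sd, n),
        config.cgi_length_min,
    ).astype(np.int64)
    kinds = rng.choice(
        ["promoter", "intragenic", "utr3", "intergenic"], n,
        p=[0.25, 0.30, 0.15, 0.30],
    )
    tss = gf.gene_tss(genes) if len(genes) else np.array([], dtype=np.int64)
    utr3 = gf.gene_utr3(genes) if len(genes) else None
    starts = np.empty(n, dtype=np.int64)
    for i in range(n):
        ln = lengths[i]
        if kinds[i] == "promoter" and len(genes):
            g = rng.integers(len(genes))
            starts[i] = tss[g] - ln // 2
        elif kinds[i] == "intragenic" and len(genes):
            g = rng.integers(len(genes))
            gs, ge = genes["start"].iloc[g], genes["end"].iloc[g]
            center = (gs + ge) // 2 + rng.integers(-1000, 1001)
            starts[i] = center - ln // 2
        elif kinds[i] == "utr3" and len(genes):
            g = rng.integers(len(genes))
            starts[i] = (utr3["start"].iloc[g] + utr3["end"].iloc[g]) // 2 - ln // 2
        else:
            starts[i] = rng.integers(0, max(1, L - ln))
    starts = np.clip(starts, 0, None)
    ends = np.minimum(starts + lengths, L)
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
    df = df[df["start"] < df["end"]].sort_values("start").reset_index(drop=True)
    # enforce non-overlapping, sorted CGIs (drop later islands that collide)
    keep, last_end = [], -1
    for row in df.itertuples(index=False):
        if row.start >= last_end:
            keep.append(True)
            last_end = row.end
        else:
            keep.append(False)
    return df[np.asarray(keep, dtype=bool)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

def simulate_methylome(
    features: pd.DataFrame, config: SimulationConfig
) -> TrueMethylome:
    """Plant per-feature methylation with tissue and individual structure.

    Baselines follow :data:`CLASS_BASELINES` plus per-feature jitter.  A
    configured fraction of features per class receive a tissue-specific
    shift of magnitude ``effect_delta`` in one randomly chosen tissue; by
    default the sign points away from the nearer boundary of [0, 1] so
    planted effects are never clipped (random-sign mode clips and logs).
    Individual effects are shared across tissues with correlation
    ``rho_individual`` via the decomposition
    e = sd * (sqrt(rho) z_shared + sqrt(1 - rho) z_private).
    """
    rng = config.rng(1)
    groups = list(config.tissues)
    individuals = [f"ind{i + 1}" for i in range(config.n_individuals)]
    ids = pd.Index(features["name"], name="feature")
    n_f, n_g, n_i = len(ids), len(groups), len(individuals)

    classes = features["feature_class"].to_numpy()
    base = np.array([CLASS_BASELINES.get(c, 0.5) for c in classes])
    base = np.clip(base + rng.normal(0, config.baseline_jitter_sd, n_f), 0.02, 0.98)

    shift = np.zeros((n_f, n_g))
    planted_rows = []
    n_clipped = 0
    for cls in np.unique(classes):
        idx = np.flatnonzero(classes == cls)
        frac = config.dmr_fraction.get(cls, config.dmr_fraction.get("default", 0.0))
        n_plant = int(round(frac * len(idx)))
        if n_plant == 0:
            continue
        chosen = rng.choice(idx, n_plant, replace=False)
        target = rng.integers(0, n_g, n_plant)
        for f, g in zip(chosen, target):
            if config.random_sign:
                delta = config.effect_delta * rng.choice([-1.0, 1.0])
                if not 0 <= base[f] + delta <= 1:
                    n_clipped += 1
            else:
                delta = config.effect_delta if base[f] <= 0.5 else -config.effect_delta
            shift[f, g] += delta
            planted_rows.append(
                {"feature": ids[f], "feature_class": cls,
                 "group": groups[g], "delta": delta}
            )
    if n_clipped:
        logger.info("simulate_methylome: %d planted effects clipped at the "
                    "[0,1] boundary", n_clipped)

    tissue_eff = (
        rng.normal(0, config.tissue_effect_sd, (n_f, n_g))
        if config.tissue_effect_sd > 0 else 0.0
    )
    rho = config.rho_individual
    z_shared = rng.normal(0, 1, (n_f, 1, n_i))
    z_priv = rng.normal(0, 1, (n_f, n_g, n_i))
    ind_eff = config.individual_sd * (
        np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * z_priv
    )
    noise = rng.normal(0, config.noise_sd, (n_f, n_g, n_i))
    m = base[:, None, None] + shift[:, :, None]
    if config.tissue_effect_sd > 0:
        m = m + tissue_eff[:, :, None]
    m = np.clip(m + ind_eff + noise, 0.0, 1.0)
    planted = pd.DataFrame(
        planted_rows, columns=["feature", "feature_class", "group", "delta"]
    )
    return TrueMethylome(
        m=m, feature_ids=ids, groups=groups, individuals=individuals,
        planted=planted, rho=rho,
    )


def sample_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: one sample per (tissue region, individual); the cortex
    group may contain several cortical regions."""
    rows = []
    for group in config.tissues:
        n_regions = config.cortex_regions if group == "cortex" else 1
        for r in range(n_regions):
            tissue = group if n_regions == 1 else f"{group}{r + 1}"
            for i in range(config.n_individuals):
                ind = f"ind{i + 1}"
                rows.append(
                    {"sample_id": f"{tissue}_{ind}", "individual_id": ind,
                     "tissue": tissue, "tissue_group": group}
                )
    return pd.DataFrame(rows).set_index("sample_id")


def methylome_matrix(
    methylome: TrueMethylome,
    features: pd.DataFrame,
    config: SimulationConfig,
) -> FeatureMethylationMatrix:
    """Feature x sample matrix of true methylation values.

    Samples in multi-region groups get independent region-level noise
    (sd = noise_sd) on top of the group/individual value.
    """
    meta = sample_metadata(config)
    rng = config.rng(2)
    g_index = {g: k for k, g in enumerate(methylome.groups)}
    i_index = {i: k for k, i in enumerate(methylome.individuals)}
    cols = {}
    for sample_id, row in meta.iterrows():
        v = methylome.m[:, g_index[row["tissue_group"]], i_index[row["individual_id"]]]
        if row["tissue"] != row["tissue_group"]:  # one of several regions
            v = np.clip(v + rng.normal(0, config.noise_sd, len(v)), 0, 1)
        cols[sample_id] = v
    values = pd.DataFrame(cols, index=methylome.feature_ids)
    feats = features.set_index("name")[["feature_class", "chrom", "start", "end"]]
    return FeatureMethylationMatrix(values=values, features=feats, samples=meta)


# ---------------------------------------------------------------------------
# MeDIP-like counts
# ---------------------------------------------------------------------------

def capture_efficiency(cf: np.ndarray, k: float) -> np.ndarray:
    """Saturating capture curve g(CF) = CF / (CF + K): zero signal without
    CpGs, approaching full efficiency in dense islands."""
    cf = np.asarray(cf, dtype=float)
    return cf / (cf + k)


def bin_methylation(
    genome: SyntheticGenome,
    features: pd.DataFrame,
    methylome: TrueMethylome,
    grid: BinGrid,
    config: SimulationConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """True methylation per (bin, sample).

    Each bin takes the methylation of the feature covering its midpoint
    (CGIs taking precedence over shores, promoter classes and CDS);
    feature-free bins get a heterogeneous background level drawn once per
    bin (mean ``background_methylation``, sd ``background_methylation_sd``),
    shared across samples.
    """
    meta = sample_metadata(config)
    rng = config.rng(3)
    fid_of = {f: i for i, f in enumerate(methylome.feature_ids)}
    rank = {c: r for r, c in enumerate(_PAINT_ORDER)}
    paint = {c: np.full(int(L), -1, dtype=np.int64)
             for c, L in genome.chrom_lengths.items()}
    ordered = features.copy()
    ordered["_rank"] = [rank.get(c, -1) for c in ordered["feature_class"]]
    ordered = ordered.sort_values("_rank", kind="mergesort")
    for row in ordered.itertuples(index=False):
        if row.chrom in paint and row.name in fid_of:
            arr = paint[row.chrom]
            s, e = max(0, int(row.start)), min(len(arr), int(row.end))
            arr[s:e] = fid_of[row.name]

    mid = (grid.starts + grid.ends) // 2
    fidx = np.empty(grid.n_bins, dtype=np.int64)
    for chrom, (lo, hi) in grid.offsets.items():
        fidx[lo:hi] = paint[chrom][mid[lo:hi]]

    bg = np.clip(
        rng.normal(config.background_methylation,
                   config.background_methylation_sd, grid.n_bins),
        0.0, 1.0,
    )
    g_index = {g: k for k, g in enumerate(methylome.groups)}
    i_index = {i: k for k, i in enumerate(methylome.individuals)}
    out = np.empty((grid.n_bins, len(meta)))
    covered = fidx >= 0
    for j, (sample_id, row) in enumerate(meta.iterrows()):
        v = bg.copy()
        v[covered] = methylome.m[
            fidx[covered], g_index[row["tissue_group"]], i_index[row["individual_id"]]
        ]
        if row["tissue"] != row["tissue_group"]:
            v = np.clip(v + rng.normal(0, config.noise_sd, grid.n_bins), 0, 1)
        out[:, j] = v
    return out, meta


def simulate_medip_counts(
    bin_m: np.ndarray,
    cf: np.ndarray,
    config: SimulationConfig,
    seed_key: int = 4,
) -> np.ndarray:
    """Draw bin x sample MeDIP-like read counts.

    count(b, s) ~ Poisson(L_s * [m_bs * g(CF_b) + background]) with
    g(CF) = CF / (CF + K) and the per-sample factor L_s chosen so the
    expected library total equals ``library_size`` exactly (doubling the
    library size doubles every expected count).  ``dispersion`` > 0 mixes
    the rate with a Gamma(1/d, d) multiplier (negative-binomial-like
    overdispersion); the default is pure Poisson for analytic checkability.
    """
    bin_m = np.atleast_2d(np.asarray(bin_m, dtype=float))
    if bin_m.shape[0] == len(cf):
        pass
    elif bin_m.shape[1] == len(cf):
        bin_m = bin_m.T
    else:
        raise ValueError("simulate_medip_counts: bin_m / cf shape mismatch")
    if (bin_m < 0).any() or config.count_background < 0:
        raise ValueError("simulate_medip_counts: negative rates")
    rng = config.rng(seed_key)
    w = bin_m * capture_efficiency(cf, config.capture_k)[:, None] + config.count_background
    totals = w.sum(axis=0)
    lam = np.zeros_like(w)
    nz = totals > 0
    lam[:, nz] = config.library_size * w[:, nz] / totals[nz]
    if config.dispersion > 0:
        d = config.dispersion
        lam = lam * rng.gamma(1.0 / d, d, size=lam.shape)
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixtures(
    genome: SyntheticGenome,
    counts: np.ndarray,
    grid: BinGrid,
    metadata: pd.DataFrame,
    outdir,
) -> dict:
    """Write the simulated dataset as plain-text files.

    Emits CpG positions (1-bp BED), CGIs (BED), genes (BED6 + a gene-model
    table carrying the 3'UTR length), a bin x sample count matrix (rows
    keyed chrom:start-end), the sample sheet, and chromosome sizes / GC
    track parameters.  Everything round-trips losslessly through
    :func:`read_fixtures`.
    """
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        cpg_rows = []
        for chrom in genome.chrom_lengths:
            for p in genome.cpg_positions.get(chrom, ()):
                cpg_rows.append((chrom, int(p), int(p) + 1))
        cpg_df = pd.DataFrame(cpg_rows, columns=["chrom", "start", "end"])
        gf.write_bed(cpg_df, out / "cpg.bed")
        paths["cpg"] = out / "cpg.bed"
        gf.write_bed(genome.cgis[["chrom", "start", "end"]], out / "cgi.bed")
        paths["cgi"] = out / "cgi.bed"
        gbed = genome.genes.copy()
        gbed["name"] = gbed["gene_id"]
        gbed["score"] = 0
        gf.write_bed(gbed[["chrom", "start", "end", "name", "score", "strand"]],
                     out / "genes.bed")
        genome.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        paths["genes"] = out / "genes.tsv"
        cdf = pd.DataFrame(counts, index=grid.bin_ids(), columns=metadata.index)
        cdf.index.name = "bin"
        cdf.to_csv(out / "counts.tsv", sep="\t")
        paths["counts"] = out / "counts.tsv"
        metadata.to_csv(out / "metadata.tsv", sep="\t")
        paths["metadata"] = out / "metadata.tsv"
        with open(out / "genome.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "chrom_lengths": {k: int(v) for k, v in genome.chrom_lengths.items()},
                    "gc_background": float(genome.gc_background),
                    "gc_island": float(genome.gc_island),
                    "bin_size": int(grid.bin_size),
                    "step": int(grid.step),
                },
                fh,
            )
        paths["genome"] = out / "genome.yaml"
        return paths
    except OSError as exc:
        raise OSError(f"write_fixtures: cannot write under {out}: {exc}") from exc


def read_fixtures(outdir) -> tuple[SyntheticGenome, pd.DataFrame, pd.DataFrame, dict]:
    """Read a fixture directory back: (genome, counts bin x sample, sample
    metadata, genome-level parameters)."""
    out = Path(outdir)
    with open(out / "genome.yaml") as fh:
        params = yaml.safe_load(fh)
    cpg_bed = gf.read_bed(out / "cpg.bed")
    cpg = {
        chrom: sub["start"].to_numpy(np.int64)
        for chrom, sub in cpg_bed.groupby("chrom")
    }
    cgis = gf.read_bed(out / "cgi.bed")
    genes = pd.read_csv(out / "genes.tsv", sep="\t")
    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col=0)
    metadata = pd.read_csv(out / "metadata.tsv", sep="\t", index_col=0)
    genome = SyntheticGenome(
        chrom_lengths={k: int(v) for k, v in params["chrom_lengths"].items()},
        cpg_positions=cpg,
        cgis=cgis,
        genes=genes,
        gc_background=params["gc_background"],
        gc_island=params["gc_island"],
    )
    return genome, counts, metadata, params


def config_to_yaml(config: SimulationConfig, path) -> None:
    d = asdict(config)
    d["tissues"] = list(d["tissues"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "tissues" in d:
        d["tissues"] = tuple(d["tissues"])
    return SimulationConfig(**d)
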