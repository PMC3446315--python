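"""End-to-end pipeline: config validation, stage orchestration, manifest.

Stages run in method order — annotate, normalize, quantify, dmr, enrich,
structure, inddiff, metagene, network — on either user-supplied inputs
(BED annotations + count matrix + sample sheet) or a synthetic dataset
generated in place.  A single global seed fans out to per-stage seeds by
stable derivation, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling_norm as cn
from . import dmr_analysis as da
from . import genome_features as gf
from . import network as net
from . import synthetic as syn

logger = logging.getLogger("medipkit")

DEFAULT_CONFIG = {
    "paths": {
        "outdir": "medipkit_run",
        "cpg": None,
        "cgi": None,
        "genes": None,
        "counts": None,
        "metadata": None,
    },
    "simulate": {},  # SimulationConfig overrides; used when no input paths
    "annotate": {
        "shore_size": 2000,
        "promoter_upstream": 1000,
        "promoter_downstream": 500,
    },
    "normalize": {
        "bin_size": 500,
        "step": 250,
        "max_distance": 500,
        "min_bins_per_level": 10,
    },
    "quantify": {"mode": "mean_rms"},
    "dmr": {"group_by": "tissue_group", "top_k": 50, "cv_gt": None},
    "inddiff": {"ind_a": "ind1", "ind_b": "ind2", "n_permutations": 1000},
    "metagene": {"n_body_bins": 40, "flank": 2000, "n_flank_bins": 10},
    "network": {
        "power": 6,
        "auto_power": False,
        "signed": True,
        "min_module_size": 30,
        "cut_height": 0.95,
        "log_pseudocount": 1.0,
        "top_n_features": 2000,
    },
    "seed": 0,
    "log_level": "INFO",
}

_INPUT_KEYS = ("cpg", "cgi", "genes", "counts", "metadata")


class ConfigError(ValueError):
    """Invalid pipeline configuration; carries the full error list."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.errors))


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


# ---------------------------------------------------------------------------
# Config validation
# ---------------------------------------------------------------------------

def _merge_defaults(user: dict, defaults: dict, errors: list, prefix="") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict) and key != "simulate":
            out[key] = _merge_defaults(
                user.get(key, {}) or {}, dval, errors, prefix=f"{prefix}{key}."
            )
        else:
            out[key] = user.get(key, dval)
    for key in user:
        if key not in defaults:
            hint = difflib.get_close_matches(key, defaults.keys(), n=1)
            msg = f"unknown key '{prefix}{key}'"
            if hint:
                msg += f" (did you mean '{prefix}{hint[0]}'?)"
            errors.append(msg)
    return out


def validate_config(source) -> dict:
    """Parse + validate a config (path, YAML string, or dict).

    Fills defaults, rejects unknown keys (with a suggestion), checks types,
    ranges and referenced input paths, and reports every problem at once
    via :class:`ConfigError`.
    """
    if isinstance(source, dict):
        user = source
    else:
        p = Path(source)
        if p.exists():
            with open(p) as fh:
                user = yaml.safe_load(fh) or {}
        else:
            user = yaml.safe_load(str(source)) or {}
        if not isinstance(user, dict):
            raise ConfigError([f"config does not parse to a mapping: {source}"])

    errors: list = []
    cfg = _merge_defaults(user, DEFAULT_CONFIG, errors)

    norm = cfg["normalize"]
    if not isinstance(norm["bin_size"], int) or norm["bin_size"] <= 0:
        errors.append("normalize.bin_size must be a positive integer")
    elif not isinstance(norm["step"], int) or not 0 < norm["step"] <= norm["bin_size"]:
        errors.append(
            f"normalize.step must be in (0, bin_size={norm['bin_size']}]; "
            f"got {norm['step']}"
        )
    if norm["max_distance"] < 0:
        errors.append("normalize.max_distance must be >= 0")
    if cfg["quantify"]["mode"] not in ("mean_rms", "rpkm"):
        errors.append("quantify.mode must be 'mean_rms' or 'rpkm'")
    dmr = cfg["dmr"]
    if (dmr["top_k"] is None) == (dmr["cv_gt"] is None):
        errors.append("dmr: set exactly one of top_k / cv_gt")
    nw = cfg["network"]
    if not 0 < nw["cut_height"] <= 1:
        errors.append("network.cut_height must be in (0, 1]")
    if nw["power"] < 1:
        errors.append("network.power must be >= 1")
    try:
        syn.SimulationConfig(seed=cfg["seed"], **(cfg["simulate"] or {}))
    except (TypeError, ValueError) as exc:
        errors.append(f"simulate: {exc}")

    paths = cfg["paths"]
    given = [k for k in _INPUT_KEYS if paths.get(k)]
    if given and len(given) != len(_INPUT_KEYS):
        missing = [k for k in _INPUT_KEYS if not paths.get(k)]
        errors.append(
            f"paths: inputs are all-or-none; given {given}, missing {missing}"
        )
    for k in given:
        if not Path(paths[k]).exists():
            errors.append(f"paths.{k}: file not found: {paths[k]}")

    if errors:
        raise ConfigError(errors)
    return cfg


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def parameter_hash(cfg: dict) -> str:
    """Stable digest of the effective configuration (paths excluded)."""
    eff = {k: v for k, v in cfg.items() if k != "paths"}
    return hashlib.sha256(
        yaml.safe_dump(eff, sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(config) -> dict:
    """Run every stage; returns the manifest dict (also written to
    ``outdir/manifest.json``).

    On stage failure the partial outputs are kept, a ``FAILED_<stage>``
    marker is written, and :class:`StageError` is raised.
    """
    cfg = validate_config(config)
    logging.basicConfig(level=getattr(logging, cfg["log_level"], logging.INFO))
    outdir = Path(cfg["paths"]["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    logger.addHandler(fh)
    sim_cfg = syn.SimulationConfig(seed=cfg["seed"], **(cfg["simulate"] or {}))
    manifest = {
        "seed": cfg["seed"],
        "parameter_hash": parameter_hash(cfg),
        "python": sys.version.split()[0],
        "stages": [],
        "outputs": {},
    }
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        stage = "simulate"
        use_inputs = bool(cfg["paths"].get("counts"))
        grid_kw = cfg["normalize"]
        if use_inputs:
            cpg_bed = gf.read_bed(cfg["paths"]["cpg"])
            cpg = {c: s["start"].to_numpy(np.int64) for c, s in cpg_bed.groupby("chrom")}
            cgis = gf.read_bed(cfg["paths"]["cgi"])
            genes = pd.read_csv(cfg["paths"]["genes"], sep="\t")
            counts_df = pd.read_csv(cfg["paths"]["counts"], sep="\t", index_col=0)
            meta = pd.read_csv(cfg["paths"]["metadata"], sep="\t", index_col=0)
            chrom_lengths = _chrom_lengths_from_bins(counts_df.index)
            genome = syn.SyntheticGenome(
                chrom_lengths=chrom_lengths, cpg_positions=cpg,
                cgis=cgis, genes=genes,
            )
            grid = cn.make_bins(chrom_lengths, grid_kw["bin_size"], grid_kw["step"])
            counts = counts_df.to_numpy()
            methylome = None
        else:
            genome = syn.simulate_genome(sim_cfg)
            grid = cn.make_bins(genome.chrom_lengths, grid_kw["bin_size"], grid_kw["step"])
        manifest["stages"].append(stage)

        stage = "annotate"
        features = genome.annotate(
            shore_size=cfg["annotate"]["shore_size"],
            promoter_upstream=cfg["annotate"]["promoter_upstream"],
            promoter_downstream=cfg["annotate"]["promoter_downstream"],
        )
        gf.write_bed(features, outdir / "features.bed")
        manifest["stages"].append(stage)

        if not use_inputs:
            stage = "simulate_counts"
            methylome = syn.simulate_methylome(features, sim_cfg)
            cf_pre = cn.coupling_factor(grid, genome.cpg_positions,
                                        grid_kw["max_distance"])
            bin_m, meta = syn.bin_methylation(genome, features, methylome, grid, sim_cfg)
            counts = syn.simulate_medip_counts(bin_m, cf_pre, sim_cfg)
            syn.write_fixtures(genome, counts, grid, meta, outdir / "fixtures")
            manifest["stages"].append(stage)

        # --------------------------------------------------------- normalize
        stage = "normalize"
        cf = cn.coupling_factor(grid, genome.cpg_positions, grid_kw["max_distance"])
        rms_mat = np.empty((grid.n_bins, len(meta)))
        rpm_mat = np.empty_like(rms_mat)
        for j in range(len(meta)):
            r, s, _ = cn.normalize_counts(counts[:, j], cf,
                                          grid_kw["min_bins_per_level"])
            rpm_mat[:, j] = r
            rms_mat[:, j] = s
        rms_df = pd.DataFrame(rms_mat, index=grid.bin_ids(), columns=meta.index)
        rms_df.index.name = "bin"
        rms_df.to_csv(outdir / "rms.tsv", sep="\t")
        tracks = outdir / "tracks"
        tracks.mkdir(exist_ok=True)
        for j, sample in enumerate(meta.index):
            cn.write_bedgraph(rms_mat[:, j], grid, tracks / f"{sample}.rms.bedgraph")
        manifest["stages"].append(stage)

        # ---------------------------------------------------------- quantify
        stage = "quantify"
        mode = cfg["quantify"]["mode"]
        bin_values = rms_mat if mode == "mean_rms" else counts.astype(float)
        values = da.quantify_bins(bin_values, grid, features, list(meta.index), mode)
        matrix = da.FeatureMethylationMatrix(
            values=values,
            features=features.set_index("name")[["feature_class", "chrom", "start", "end"]],
            samples=meta,
        )
        values.to_csv(outdir / "feature_matrix.tsv", sep="\t")
        manifest["stages"].append(stage)

        # --------------------------------------------------------------- dmr
        stage = "dmr"
        records = da.cv_rank(matrix, group_by=cfg["dmr"]["group_by"])
        records.to_csv(outdir / "cv_ranked.tsv", sep="\t", index=False)
        dmrs = da.select_dmrs(records, top_k=cfg["dmr"]["top_k"],
                              cv_gt=cfg["dmr"]["cv_gt"])
        dmrs.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "enrich"
        enr = da.enrichment_oe(dmrs, features)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        # ----------------------------------------------------------- structure
        stage = "structure"
        corr = da.sample_correlation(matrix)
        corr.to_csv(outdir / "sample_correlation.tsv", sep="\t")
        link, leaves = da.cluster_samples(corr)
        pd.DataFrame(link, columns=["a", "b", "height", "size"]).to_csv(
            outdir / "linkage.tsv", sep="\t", index=False
        )
        (outdir / "leaf_order.txt").write_text("\n".join(leaves) + "\n")
        n_pc = min(3, len(meta) - 1)
        scores, variances = da.pca_samples(matrix, n_components=n_pc)
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        manifest["stages"].append(stage)

        stage = "inddiff"
        idc = cfg["inddiff"]
        inds = set(meta["individual_id"])
        if idc["ind_a"] in inds and idc["ind_b"] in inds:
            diff, diff_cor = da.individual_differences(
                matrix, idc["ind_a"], idc["ind_b"],
                n_permutations=idc["n_permutations"], seed=cfg["seed"],
            )
            diff.to_csv(outdir / "individual_differences.tsv", sep="\t")
            diff_cor.to_csv(outdir / "individual_difference_correlations.tsv",
                            sep="\t", index=False)
            da.variability_by_class(diff, matrix.features).to_csv(
                outdir / "individual_variability_by_class.tsv", sep="\t"
            )
        else:
            logger.warning("inddiff: individuals %s/%s not present; skipping",
                           idc["ind_a"], idc["ind_b"])
        manifest["stages"].append(stage)

        stage = "metagene"
        mg = cfg["metagene"]
        mean_rms = np.nanmean(rms_mat, axis=1)
        profile, n_used, n_skip = da.metagene_profile(
            mean_rms, grid, genome.genes, mg["n_body_bins"], mg["flank"],
            mg["n_flank_bins"],
        )
        pd.DataFrame({"position": np.arange(len(profile)), "mean_rms": profile}).to_csv(
            outdir / "metagene_profile.tsv", sep="\t", index=False
        )
        manifest["stages"].append(stage)

        # ------------------------------------------------------------ network
        stage = "network"
        nw = cfg["network"]
        logm = net.log_transform(values, nw["log_pseudocount"])
        logm = net.top_variance_features(logm, nw["top_n_features"])
        if nw["auto_power"]:
            power, _ = net.pick_soft_power(logm, signed=nw["signed"])
        else:
            power = nw["power"]
        ncfg = net.NetworkConfig(
            power=power, signed=nw["signed"],
            min_module_size=nw["min_module_size"], cut_height=nw["cut_height"],
            log_pseudocount=nw["log_pseudocount"],
        )
        A, kept = net.adjacency(logm, ncfg)
        labels = net.detect_modules(net.tom(A), kept, ncfg)
        mod_df = labels.to_frame()
        if (labels != net.UNASSIGNED).any():
            me = net.module_eigengenes(logm.loc[kept], labels)
            traits = net.tissue_traits(meta)
            stats_ = net.module_trait_stats(me, traits, logm.loc[kept], labels)
            me.to_csv(outdir / "module_eigengenes.tsv", sep="\t")
            stats_["module_trait"].to_csv(outdir / "module_trait.tsv",
                                          sep="\t", index=False)
            mod_df["module_membership"] = stats_["membership"]
            for t in stats_["significance"].columns:
                mod_df[f"GS_{t}"] = stats_["significance"][t]
        mod_df.to_csv(outdir / "modules.tsv", sep="\t")
        manifest["stages"].append(stage)

        for p in sorted(outdir.rglob("*")):
            if p.is_file() and p.name not in ("manifest.json", "run.log"):
                manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
        with open(outdir / "manifest.json", "w") as mf:
            json.dump(manifest, mf, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        (outdir / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(fh)
        fh.close()


def _chrom_lengths_from_bins(bin_ids) -> dict:
    out: dict = {}
    for b in bin_ids:
        chrom, rng = b.rsplit(":", 1)
        end = int(rng.split("-")[1])
        out[chrom] = max(out.get(chrom, 0), end)
    return out
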