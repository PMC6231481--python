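"""Configuration-driven orchestration of the full analysis chain.

Stages: site filtering -> population-genetic summaries -> FST-outlier scan
-> environment-association scan -> spatial eigenvectors -> gradient-forest
turnover per SNP set -> maps and genetic offset. Every stage writes plain
files into the output directory and the run manifest records seeds, counts
and file hashes, so deleting intermediates and re-running under the same
master seed reproduces identical results.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eascan, genio, mem, outlier, popgen, turnover
from .grids import CLIMATE_VARS, read_climate_grid

log = logging.getLogger("landgen")

SNP_SET_NAMES = ("all", "ea_candidates", "temperature", "precipitation", "double_outliers")
TEMPERATURE_VARS = ("bio4", "bio6")
PRECIPITATION_VARS = ("bio15", "bio16")


@dataclass
class PipelineConfig:
    """Validated run configuration; defaults follow the study settings."""

    vcf: str = ""
    sites: str = ""
    raster_dir: str = ""
    range_polygon: str | None = None
    outdir: str = "landgen_out"
    seed: int = 0

    # site filters / LD pruning
    min_call_rate: float = 0.95
    min_mean_depth: float = 5.0
    min_maf: float = 0.10
    vif_window: int = 5
    vif_step: int = 5
    vif_threshold: float = 2.0

    # popgen
    n_permutations: int = 9999

    # outlier scan
    prior_odds: float = 10.0
    n_out: int = 5000
    thin: int = 10
    pilot_runs: int = 20
    pilot_len: int = 5000
    burn_in: int = 50000
    q_threshold: float = 0.05

    # environment-association scan
    k_latent: int | str = 2       # an int, or "tracy-widom"
    n_runs: int = 5
    fdr: float = 0.05

    # turnover / offset
    n_trees: int = 2000
    correlation_threshold: float = 0.5
    min_polymorphic_pops: int = 3
    n_points: int = 10000
    snp_sets: tuple[str, ...] = SNP_SET_NAMES

    def __post_init__(self) -> None:
        if len(set(self.snp_sets)) != len(self.snp_sets):
            raise ValueError("SNP-set names must be unique")


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; all problems reported at once."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    problems = [f"unknown config key: {k!r}" for k in raw if k not in known]
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    for key in ("vcf", "sites"):
        val = getattr(cfg, key)
        if val and not Path(val).exists():
            problems.append(f"{key} file not found: {val}")
    if cfg.raster_dir and not Path(cfg.raster_dir).is_dir():
        problems.append(f"raster_dir not found: {cfg.raster_dir}")
    elif cfg.raster_dir:
        for prefix in ("current", "future"):
            for var in CLIMATE_VARS:
                p = Path(cfg.raster_dir) / f"{prefix}_{var}.asc"
                if not p.exists():
                    problems.append(f"missing raster: {p}")
    if cfg.range_polygon and not Path(cfg.range_polygon).exists():
        problems.append(f"range_polygon not found: {cfg.range_polygon}")
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    log.info("config loaded: %s", asdict(cfg))
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class StageRecord:
    name: str
    counts: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config), "stages": []}
    stage = "init"

    def record(rec: StageRecord):
        manifest["stages"].append(
            {"name": rec.name, "counts": rec.counts, "files": rec.files}
        )

    try:
        # ---- filter
        stage = "filter"
        sites = pd.read_csv(config.sites, sep="\t")
        matrix = genio.read_vcf(config.vcf)
        matrix, rep1 = genio.apply_site_filters(
            matrix, config.min_call_rate, config.min_mean_depth, config.min_maf
        )
        matrix, rep2 = genio.ld_prune_vif(
            matrix, config.vif_window, config.vif_step, config.vif_threshold
        )
        fpath = out / "filter_report.tsv"
        pd.concat([rep1.to_frame(), rep2.to_frame()]).to_csv(fpath, sep="\t", index=False)
        genio.write_dosage_tsv(matrix, out / "dosage.tsv")
        record(StageRecord("filter", {"n_loci": matrix.n_loci,
                                      "n_individuals": matrix.n_individuals},
                           {f.name: _sha256(f) for f in (fpath, out / "dosage.tsv")}))

        # ---- popgen
        stage = "popgen"
        freqs = popgen.pop_allele_freqs(matrix)
        div = popgen.diversity_fis(matrix)
        fst = popgen.wc_fst(matrix, pairwise=True)
        ibd = popgen.ibd_mantel(fst, sites, n_perm=config.n_permutations,
                                seed=config.seed)
        div.to_csv(out / "diversity.tsv", sep="\t")
        assert fst.pairwise is not None
        fst.pairwise.to_csv(out / "pairwise_fst.tsv", sep="\t")
        (out / "ibd.json").write_text(json.dumps(asdict(ibd), indent=2))
        record(StageRecord(
            "popgen",
            {"multilocus_fst": fst.multilocus_fst, "mantel_r": ibd.mantel_r,
             "mantel_p": ibd.mantel_p},
            {n: _sha256(out / n) for n in ("diversity.tsv", "pairwise_fst.tsv", "ibd.json")},
        ))

        # ---- FST outlier scan
        stage = "scan-fst"
        scan = outlier.fit_rjmcmc(
            freqs, prior_odds=config.prior_odds, n_out=config.n_out,
            thin=config.thin, pilot_runs=config.pilot_runs,
            pilot_len=config.pilot_len, burn_in=config.burn_in,
            seed=config.seed, q_threshold=config.q_threshold,
        )
        outlier.write_scan_tsv(scan, out / "fst_outliers.tsv")
        fst_outlier_ids = set(scan.table.loc[scan.table["outlier"], "locus"])
        record(StageRecord("scan-fst", {"n_outliers": len(fst_outlier_ids)},
                           {"fst_outliers.tsv": _sha256(out / "fst_outliers.tsv")}))

        # ---- EA scan
        stage = "scan-ea"
        if config.k_latent == "tracy-widom":
            K = eascan.choose_k_tracy_widom(matrix)
        else:
            K = int(config.k_latent)
        ea = eascan.ea_scan(matrix, sites, list(CLIMATE_VARS), K,
                            n_runs=config.n_runs, fdr=config.fdr, seed=config.seed)
        ea_path = out / "ea_scan.tsv"
        tbl = ea.z.copy()
        tbl.columns = [f"z_{c}" for c in tbl.columns]
        for c in ea.p_adj.columns:
            tbl[f"p_adj_{c}"] = ea.p_adj[c]
        tbl.to_csv(ea_path, sep="\t")
        ea.candidates.to_csv(out / "ea_candidates.tsv", sep="\t", index=False)
        record(StageRecord(
            "scan-ea",
            {"K": K, "lambda": ea.lam, "n_candidates": len(ea.candidates)},
            {p.name: _sha256(p) for p in (ea_path, out / "ea_candidates.tsv")},
        ))

        # ---- MEM
        stage = "mem"
        mems = mem.mem_predictors(sites)
        mems.attrs["coords"] = sites.set_index("pop").loc[mems.index, ["lon", "lat"]]
        mems.to_csv(out / "mem.tsv", sep="\t")
        record(StageRecord("mem", {"n_mem": mems.shape[1]},
                           {"mem.tsv": _sha256(out / "mem.tsv")}))

        # ---- turnover per SNP set
        stage = "turnover"
        cand = ea.candidates.set_index("locus")["variable"]
        ea_ids = set(cand.index)
        sets = {
            "all": set(freqs.locus_ids),
            "ea_candidates": ea_ids,
            "temperature": {l for l, v in cand.items() if v in TEMPERATURE_VARS},
            "precipitation": {l for l, v in cand.items() if v in PRECIPITATION_VARS},
            "double_outliers": ea_ids & fst_outlier_ids,
        }
        responses_all = turnover.prepare_responses(
            freqs, min_polymorphic_pops=config.min_polymorphic_pops
        )
        predictors = pd.concat(
            [sites.set_index("pop")[list(CLIMATE_VARS)], mems], axis=1
        ).loc[responses_all.index]
        current = read_climate_grid(config.raster_dir, "current", epoch="current")
        future = read_climate_grid(config.raster_dir, "future", epoch="future-mean")
        points = turnover.sample_range_points(
            sites, n_points=config.n_points, seed=config.seed, grid=current
        )
        settings = turnover.GfSettings(
            n_trees=config.n_trees,
            correlation_threshold=config.correlation_threshold,
            seed=config.seed,
        )
        spaces = {}
        for name in config.snp_sets:
            ids = [l for l in responses_all.columns if l in sets[name]]
            if not ids:
                log.info("SNP set %r is empty; turnover model skipped", name)
                record(StageRecord(f"turnover[{name}]", {"skipped": True, "n_snps": 0}))
                continue
            model = turnover.fit_turnover(responses_all[ids], predictors, settings)
            imp_path = out / f"importance_{name}.tsv"
            model.importance_frame().to_csv(imp_path, sep="\t", index=False)
            tab = turnover.points_predictor_table(current, points, mem_values=mems)
            space = turnover.transform_points(model, tab, epoch="current")
            scores, rgb = turnover.map_pca_rgb(space)
            rgb_path = out / f"map_rgb_{name}.tsv"
            pd.DataFrame(
                {"lon": points["lon"], "lat": points["lat"],
                 "R": rgb[:, 0], "G": rgb[:, 1], "B": rgb[:, 2]}
            ).to_csv(rgb_path, sep="\t", index=False)
            offs = turnover.genetic_offset(model, current, future, points,
                                           mem_values=mems)
            off_path = out / f"offset_{name}.tsv"
            offs.to_csv(off_path, sep="\t", index=False)
            spaces[name] = space
            record(StageRecord(
                f"turnover[{name}]",
                {"n_snps": len(ids),
                 "top_predictor": model.importance_frame().iloc[0]["predictor"],
                 "mean_offset": float(offs["offset"].mean())},
                {p.name: _sha256(p) for p in (imp_path, rgb_path, off_path)},
            ))

        # ---- Procrustes residuals of candidate sets against the full set
        stage = "procrustes"
        if "all" in spaces:
            for name, space in spaces.items():
                if name == "all":
                    continue
                resid = turnover.procrustes_residuals(spaces["all"], space)
                ppath = out / f"procrustes_{name}.tsv"
                pd.DataFrame({"lon": points["lon"], "lat": points["lat"],
                              "residual": resid}).to_csv(ppath, sep="\t", index=False)
                record(StageRecord(f"procrustes[{name}]",
                                   {"mean_residual": float(np.mean(resid))},
                                   {ppath.name: _sha256(ppath)}))
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (Path(config.outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
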