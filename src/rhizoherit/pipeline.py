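"""Pipeline orchestration: run the analysis stages from a config file.

Stages run in dependency order (simulate -> preprocess -> spatial ->
permdisp -> permanova -> heritability -> report); each stage reads the
previous stage's TSV artifacts from the run directory and writes its own,
so a rerun resumes from whatever already exists, and the whole run is
bit-reproducible under the configured seeds.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .community import STUDY_TERMS, NestedPermanova, Permdisp, bray_curtis
from .pedigree import additive_relationship, read_pedigree_csv, write_pedigree_csv
from .preprocess import identify_core, rarefy, remove_singletons, soil_pc1, sqrt_transform
from .quantgen import heritability_scan
from .simulate import AsvSimParams, simulate_study
from .spatial import spatial_correct_matrix

log = logging.getLogger("rhizoherit")

STAGES = ["simulate", "preprocess", "spatial", "permdisp", "permanova", "heritability", "report"]

DEFAULT_CONFIG = {
    "run_dir": "runs/default",
    "seed": 20260101,
    "simulate": {
        "enabled": True,
        "n_families": 28, "n_genotypes": 132, "ramets_per_genotype": 4,
        "generations": 3, "n_founders": 24, "block_capacity": 36,
        "n_asvs": 120, "overdispersion": 0.5,
    },
    "inputs": {  # used when simulate.enabled is false
        "counts": None, "metadata": None, "pedigree": None,
    },
    "preprocess": {"depth": 5000, "prevalence_threshold": 0.8},
    "spatial": {"smoothing": "gcv"},
    "permanova": {"n_perm": 999},
    "permdisp": {"n_perm": 999, "factors": ["family", "batch"]},
    "heritability": {},
}


@dataclass
class RunConfig:
    """Validated run configuration with provenance."""

    raw: dict
    path: Path | None = None
    config_hash: str = field(init=False)

    def __post_init__(self):
        cfg = dict(DEFAULT_CONFIG)
        for k, v in self.raw.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k] = {**cfg[k], **v}
            else:
                cfg[k] = v
        self.cfg = cfg
        blob = yaml.safe_dump(cfg, sort_keys=True).encode()
        self.config_hash = hashlib.sha256(blob).hexdigest()[:12]
        if not cfg["simulate"]["enabled"]:
            missing = [k for k in ("counts", "metadata", "pedigree")
                       if not cfg["inputs"].get(k)]
            if missing:
                raise ValueError(
                    f"simulate disabled but inputs missing: {missing}; "
                    "enable simulate or provide paths"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        return cls(yaml.safe_load(path.read_text()) or {}, path=path)

    def __getitem__(self, key):
        return self.cfg[key]


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": config.config_hash,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "version": __version__,
        "seed": config["seed"],
    }


def run_pipeline(config: RunConfig, stages: list[str] | None = None, force: bool = False) -> Path:
    """Execute the requested stages; returns the run directory.

    A stage whose outputs already exist is skipped unless ``force``. Any
    stage failure leaves prior outputs in place and a ``FAILED`` marker
    naming the stage.
    """
    stages = stages or STAGES
    run_dir = Path(config["run_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    marker = run_dir / "FAILED"
    current = "?"
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            current = stage
            _run_stage(stage, config, run_dir, seed, force)
        if marker.exists():
            marker.unlink()
    except Exception:
        marker.write_text(f"stage failed: {current}\n")
        raise
    return run_dir


def _done(run_dir: Path, name: str) -> Path:
    return run_dir / name


def _run_stage(stage: str, config: RunConfig, run_dir: Path, seed: int, force: bool) -> None:
    t0 = time.time()
    out = {
        "simulate": ["counts_raw.tsv", "metadata.tsv", "pedigree.csv", "truth.json"],
        "preprocess": ["counts_sqrt.tsv", "core_asvs.txt", "soil_pc1.tsv"],
        "spatial": ["residuals.tsv", "residuals_adjusted.tsv", "spatial_sidecar.json"],
        "permdisp": ["permdisp.json"],
        "permanova": ["permanova.tsv"],
        "heritability": ["heritability.tsv", "heritability_summary.json"],
        "report": ["summary.json"],
    }[stage]
    if not force and all((_done(run_dir, f)).exists() for f in out):
        log.info("stage %s: outputs exist, skipping", stage)
        return
    getattr(_Stages, stage)(config, run_dir, seed)
    log.info("stage %s: done in %.1fs", stage, time.time() - t0)


class _Stages:
    @staticmethod
    def simulate(config: RunConfig, run_dir: Path, seed: int) -> None:
        sim_cfg = config["simulate"]
        if not sim_cfg["enabled"]:
            # copy externally supplied inputs into the run directory layout
            counts = io.read_counts_tsv(config["inputs"]["counts"])
            meta = io.read_metadata_tsv(config["inputs"]["metadata"])
            ped = read_pedigree_csv(config["inputs"]["pedigree"])
            io.write_counts_tsv(counts, run_dir / "counts_raw.tsv")
            io.write_metadata_tsv(meta, run_dir / "metadata.tsv")
            write_pedigree_csv(ped, run_dir / "pedigree.csv")
            io.write_json({"external_inputs": True}, run_dir / "truth.json")
            return
        study = simulate_study(
            seed=seed,
            n_founders=sim_cfg["n_founders"],
            n_families=sim_cfg["n_families"],
            n_genotypes=sim_cfg["n_genotypes"],
            generations=sim_cfg["generations"],
            ramets_per_genotype=sim_cfg["ramets_per_genotype"],
            block_capacity=sim_cfg["block_capacity"],
            asv_params=AsvSimParams(
                n_asvs=sim_cfg["n_asvs"], overdispersion=sim_cfg["overdispersion"]
            ),
        )
        io.write_counts_tsv(study.counts, run_dir / "counts_raw.tsv")
        io.write_metadata_tsv(study.metadata, run_dir / "metadata.tsv")
        write_pedigree_csv(study.pedigree.pedigree, run_dir / "pedigree.csv")
        io.write_json(study.truth.to_json_dict(), run_dir / "truth.json")

    @staticmethod
    def preprocess(config: RunConfig, run_dir: Path, seed: int) -> None:
        cfg = config["preprocess"]
        counts = io.read_counts_tsv(run_dir / "counts_raw.tsv")
        meta = io.read_metadata_tsv(run_dir / "metadata.tsv")
        counts = remove_singletons(counts)
        rar, dropped = rarefy(counts, depth=int(cfg["depth"]), seed=seed + 1)
        core, core_abund = identify_core(rar, cfg["prevalence_threshold"])
        sqrt = sqrt_transform(rar)
        io.write_counts_tsv(sqrt, run_dir / "counts_sqrt.tsv")
        (run_dir / "core_asvs.txt").write_text("\n".join(core) + "\n")
        soil_cols = [c for c in ("pH", "moisture", "total_C", "total_N") if c in meta]
        pc1 = soil_pc1(meta.loc[sqrt.data.index, soil_cols])
        pc1.scores.to_frame().to_csv(run_dir / "soil_pc1.tsv", sep="\t")
        io.write_json(
            {
                "dropped_samples": dropped,
                "n_core": len(core),
                "core_mean_relative_abundance": core_abund,
                "soil_pc1_variance_explained": pc1.variance_explained,
                "soil_pc1_loadings": pc1.loadings.to_dict(),
                **_provenance(config),
            },
            run_dir / "preprocess_summary.json",
        )

    @staticmethod
    def spatial(config: RunConfig, run_dir: Path, seed: int) -> None:
        sqrt = io.read_counts_tsv(run_dir / "counts_sqrt.tsv", state="sqrt")
        meta = io.read_metadata_tsv(run_dir / "metadata.tsv")
        corr = spatial_correct_matrix(
            sqrt, meta[["x", "y"]], smoothing=config["spatial"]["smoothing"]
        )
        io.write_counts_tsv(corr.residuals, run_dir / "residuals.tsv")
        io.write_counts_tsv(corr.adjusted, run_dir / "residuals_adjusted.tsv")
        io.write_json(
            {
                "shift": corr.shifts.to_dict(),
                "smoothing": corr.smoothing.to_dict(),
                "edf": corr.edf.to_dict(),
            },
            run_dir / "spatial_sidecar.json",
        )

    @staticmethod
    def _load_community(run_dir: Path):
        adj = pd.read_csv(run_dir / "residuals_adjusted.tsv", sep="\t", index_col=0)
        meta = io.read_metadata_tsv(run_dir / "metadata.tsv")
        pc1 = pd.read_csv(run_dir / "soil_pc1.tsv", sep="\t", index_col=0)["soil_pc1"]
        meta = meta.loc[adj.index].copy()
        meta["soil_pc1"] = pc1.loc[adj.index]
        return bray_curtis(adj), meta

    @staticmethod
    def permdisp(config: RunConfig, run_dir: Path, seed: int) -> None:
        dist, meta = _Stages._load_community(run_dir)
        results = {}
        for factor in config["permdisp"]["factors"]:
            res = Permdisp(dist, meta[factor]).fit(
                n_perm=int(config["permdisp"]["n_perm"]), seed=seed + 2
            )
            results[factor] = {"F": res.statistic, "p_perm": res.p_value}
        io.write_json(results, run_dir / "permdisp.json")

    @staticmethod
    def permanova(config: RunConfig, run_dir: Path, seed: int) -> None:
        dist, meta = _Stages._load_community(run_dir)
        res = NestedPermanova(dist, meta, STUDY_TERMS).fit(
            n_perm=int(config["permanova"]["n_perm"]), seed=seed + 3
        )
        res.table.to_csv(run_dir / "permanova.tsv", sep="\t", index_label="term")

    @staticmethod
    def heritability(config: RunConfig, run_dir: Path, seed: int) -> None:
        resid = pd.read_csv(run_dir / "residuals.tsv", sep="\t", index_col=0)
        meta = io.read_metadata_tsv(run_dir / "metadata.tsv")
        pc1 = pd.read_csv(run_dir / "soil_pc1.tsv", sep="\t", index_col=0)["soil_pc1"]
        meta = meta.loc[resid.index].copy()
        meta["soil_pc1"] = pc1.loc[resid.index]
        ped = read_pedigree_csv(run_dir / "pedigree.csv")
        A = additive_relationship(ped)
        core = (run_dir / "core_asvs.txt").read_text().split()
        table, summary = heritability_scan(resid, meta, A, core_asvs=core)
        table.to_csv(run_dir / "heritability.tsv", sep="\t", index_label="asv_id")
        io.write_json(summary, run_dir / "heritability_summary.json")

    @staticmethod
    def report(config: RunConfig, run_dir: Path, seed: int) -> None:
        summary = {"provenance": _provenance(config), "stages": {}}
        for name in ("preprocess_summary", "permdisp", "heritability_summary"):
            p = run_dir / f"{name}.json"
            if p.exists():
                summary["stages"][name] = io.read_json(p)
        p = run_dir / "permanova.tsv"
        if p.exists():
            tab = pd.read_csv(p, sep="\t", index_col=0)
            summary["stages"]["permanova"] = tab[["sqrt_CV", "p_perm"]].round(4).to_dict(
                orient="index"
            )
        io.write_json(summary, run_dir / "summary.json")
        # minimal heritability histogram (log-count presentation)
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            h = pd.read_csv(run_dir / "heritability.tsv", sep="\t", index_col=0)
            fig, ax = plt.subplots(figsize=(5, 3))
            ax.hist(h["H2"].dropna(), bins=np.linspace(0, 1, 41), color="0.4")
            ax.axvline(0.1, color="red", lw=1)
            ax.axvline(0.2, color="blue", lw=1)
            ax.set_xlabel("broad-sense heritability $H^2$")
            ax.set_ylabel("ASV count")
            ax.set_yscale("log")
            fig.tight_layout()
            fig.savefig(run_dir / "heritability_hist.png", dpi=120)
            plt.close(fig)
        except Exception as err:  # plotting is best-effort
            log.warning("histogram skipped: %s", err)
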