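"""End-to-end orchestration: simulate -> preprocess -> infer (x6) ->
compare -> null tests -> enrichment, with one config and one root seed.

Every stage writes plain-text outputs into the run directory and the run
manifest records parameters, derived seeds and a SHA-256 checksum of
every file produced, so a re-run with the same config is verifiably
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import compare as nc
from .enrich import enrich as run_enrichment
from .enrich import membership_frame, process_membership, read_gmt, results_frame
from .inference import InferenceConfig, infer_network
from .networks import Network
from .nullmodel import lcc_null_test
from .preprocess import FilterConfig, filter_genes, load_dataset, quantile_normalize, split_groups
from .simulate import (
    STRATA,
    GroundTruth,
    SimulationConfig,
    generate_dataset,
    write_counts_tsv,
    write_metadata_tsv,
)

logger = logging.getLogger(__name__)


def derive_seed(root_seed: int, *keys: object) -> int:
    """Stable per-stage seed below 2**31 from the root seed and a key path."""
    tag = f"{root_seed}|" + "|".join(str(k) for k in keys)
    return int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "little") % 2**31


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """One run's settings; defaults match the reference study protocol
    (mean filter 10, zero fraction 0.5, k = 10,000 edges, 100,000 null
    simulations, FDR 0.05)."""

    outdir: str = "results/run"
    seed: int = 0
    counts: str | None = None
    metadata: str | None = None
    counts_dialect: str = "tsv"
    gmt: str | None = None
    universe: str | None = None
    fdr: float = 0.05
    n_sims: int = 100_000
    sample_with_replacement: bool = False
    filter: FilterConfig = field(default_factory=FilterConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    simulation: SimulationConfig | None = None
    run_nulls: bool = True
    run_enrichment: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "filter" in kwargs:
            kwargs["filter"] = FilterConfig(**kwargs["filter"])
        if "inference" in kwargs:
            kwargs["inference"] = InferenceConfig(**kwargs["inference"])
        if kwargs.get("simulation") is not None:
            sim = dict(kwargs["simulation"])
            if "base_mean_log_range" in sim:
                sim["base_mean_log_range"] = tuple(sim["base_mean_log_range"])
            kwargs["simulation"] = SimulationConfig(**sim)
        return cls(**kwargs)

    def validate(self) -> None:
        if self.simulation is None and (self.counts is None or self.metadata is None):
            raise ValueError(
                "config needs either a simulation section or counts+metadata paths"
            )


def _write_truth_gmt(truth: GroundTruth, path: Path) -> None:
    """Planted modules as a GMT library (term per module)."""
    with open(path, "w") as fh:
        for module, genes in sorted(truth.module_gene_sets().items()):
            strata = ",".join(sorted(truth.module_activity[module]))
            fh.write(
                f"MODULE_{module:02d}\tactive:{strata}\t" + "\t".join(sorted(genes)) + "\n"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns (and writes) the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            "filter": asdict(config.filter),
            "inference": {
                "k": config.inference.k,
                "n_bins": config.inference.n_bins,
                "dpi_tolerance": config.inference.dpi_tolerance,
                "dpi_enabled": config.inference.dpi_enabled,
            },
            "n_sims": config.n_sims,
            "fdr": config.fdr,
        },
        "stages": {},
        "outputs": {},
    }
    manifest_path = outdir / "manifest.json"

    def record(stage: str, t0: float, files: list[Path], extra: dict | None = None) -> None:
        entry: dict[str, Any] = {
            "wall_seconds": round(time.perf_counter() - t0, 3),
            "outputs": [f.name for f in files],
        }
        if extra:
            entry.update(extra)
        manifest["stages"][stage] = entry
        for f in files:
            manifest["outputs"][f.name] = sha256_file(f)
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        logger.info("stage %s done in %.2fs (%d files)", stage, entry["wall_seconds"], len(files))

    stage_name = "setup"
    try:
        # -- simulate ----------------------------------------------------
        truth: GroundTruth | None = None
        if config.simulation is not None:
            stage_name = "simulate"
            t0 = time.perf_counter()
            counts, meta, truth = generate_dataset(config.simulation)
            counts_path = outdir / "counts.tsv"
            meta_path = outdir / "metadata.tsv"
            truth_path = outdir / "truth.json"
            gmt_path = outdir / "modules.gmt"
            write_counts_tsv(counts, counts_path)
            write_metadata_tsv(meta, meta_path)
            truth.to_json(truth_path)
            _write_truth_gmt(truth, gmt_path)
            record(
                "simulate", t0, [counts_path, meta_path, truth_path, gmt_path],
                {"seed": config.simulation.seed},
            )
            counts_file, meta_file = counts_path, meta_path
        else:
            counts_file, meta_file = Path(config.counts), Path(config.metadata)

        # -- preprocess --------------------------------------------------
        stage_name = "preprocess"
        t0 = time.perf_counter()
        counts, meta = load_dataset(counts_file, meta_file, dialect=config.counts_dialect)
        filtered = filter_genes(counts, config.filter)
        normalized = quantile_normalize(filtered)
        strata = split_groups(normalized, meta)
        stratum_files = []
        for label in STRATA:
            path = outdir / f"{label}.tsv"
            strata[label].to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
            stratum_files.append(path)
        universe_path = outdir / "universe.txt"
        universe_path.write_text("\n".join(str(g) for g in filtered.index) + "\n")
        record(
            "preprocess", t0, stratum_files + [universe_path],
            {
                "genes_in": int(counts.shape[0]),
                "genes_kept": int(filtered.shape[0]),
                "samples": int(counts.shape[1]),
                "stratum_sizes": {s: int(strata[s].shape[1]) for s in STRATA},
            },
        )

        # -- infer -------------------------------------------------------
        stage_name = "infer"
        t0 = time.perf_counter()
        networks: dict[str, Network] = {}
        edge_files = []
        for label in STRATA:
            if strata[label].shape[1] == 0:
                logger.warning("skipping inference for empty stratum %s", label)
                continue
            net = infer_network(strata[label], config.inference, name=label)
            networks[label] = net
            path = outdir / f"network_{label}.tsv"
            net.write_tsv(path)
            edge_files.append(path)
        record("infer", t0, edge_files, {"edges_per_network": {n: len(v) for n, v in networks.items()}})

        net_list = [networks[s] for s in STRATA if s in networks]

        # -- compare -----------------------------------------------------
        stage_name = "compare"
        t0 = time.perf_counter()
        files = []
        if len(net_list) >= 2:
            for mode in ("edges", "genes"):
                overlap = nc.pairwise_overlap(net_list, mode=mode)
                for kind, frame in (("counts", overlap.counts_frame()),
                                    ("jaccard", overlap.jaccard_frame())):
                    path = outdir / f"overlap_{mode}_{kind}.csv"
                    frame.to_csv(path)
                    files.append(path)
        groups = {
            "all": [s for s in STRATA if s in networks],
            "men": [s for s in STRATA if s in networks and s.startswith("M")],
            "women": [s for s in STRATA if s in networks and s.startswith("F")],
        }
        conserved_sizes = {}
        for gname, members in groups.items():
            if len(members) < 2:
                continue
            cons = nc.conserved_edges([networks[s] for s in members], name=f"conserved_{gname}")
            path = outdir / f"conserved_{gname}.tsv"
            cons.write_tsv(path)
            files.append(path)
            conserved_sizes[gname] = len(cons)
        uniques: dict[str, Network] = {}
        summary_rows = []
        for label, net in networks.items():
            others = [n for s, n in networks.items() if s != label]
            uniq = nc.unique_edges(net, others, name=f"{label}_unique")
            uniques[label] = uniq
            path = outdir / f"unique_{label}.tsv"
            uniq.write_tsv(path)
            files.append(path)
            comp = nc.components(uniq)
            summary_rows.append(
                {
                    "network": label,
                    "unique_edges": len(uniq),
                    "unique_genes": len(uniq.genes),
                    "lcc_genes": comp.lcc_genes,
                    "n_components": comp.n_components,
                }
            )
        summary_path = outdir / "unique_summary.csv"
        pd.DataFrame(summary_rows).to_csv(summary_path, index=False)
        files.append(summary_path)
        record("compare", t0, files, {"conserved": conserved_sizes})

        # -- null models -------------------------------------------------
        if config.run_nulls:
            stage_name = "nulltest"
            t0 = time.perf_counter()
            files = []
            for label, uniq in uniques.items():
                if len(uniq) == 0:
                    logger.warning("no unique edges for %s; skipping null test", label)
                    continue
                comp = nc.components(uniq)
                result = lcc_null_test(
                    networks[label],
                    subset_size=len(uniq),
                    observed_lcc=comp.lcc_genes,
                    n_sims=config.n_sims,
                    seed=derive_seed(config.seed, "null", label),
                    replace=config.sample_with_replacement,
                )
                path = outdir / f"null_{label}.json"
                result.to_json(path)
                files.append(path)
            record("nulltest", t0, files, {"n_sims": config.n_sims})

        # -- enrichment --------------------------------------------------
        gmt_file = config.gmt
        if gmt_file is None and config.simulation is not None:
            gmt_file = str(outdir / "modules.gmt")
        if config.run_enrichment and gmt_file is not None:
            stage_name = "enrich"
            t0 = time.perf_counter()
            files = []
            collection = read_gmt(gmt_file)
            if config.universe:
                universe = {
                    line.strip().upper()
                    for line in Path(config.universe).read_text().splitlines()
                    if line.strip()
                }
            else:
                universe = {str(g).upper() for g in filtered.index}
            significant: dict[str, set[str]] = {}
            for label, uniq in uniques.items():
                results = run_enrichment(uniq.genes, collection, universe, threshold=config.fdr)
                path = outdir / f"enrichment_{label}.csv"
                results_frame(results).to_csv(path, index=False)
                files.append(path)
                significant[label] = {r.term for r in results if r.significant}
            if any(significant.values()):
                membership, _ = process_membership(significant)
                path = outdir / "process_membership.csv"
                membership_frame(membership).to_csv(path, index=False)
                files.append(path)
            record("enrich", t0, files, {"gmt": Path(gmt_file).name})
    except Exception as exc:
        manifest["failed_stage"] = stage_name
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        logger.error("stage %s failed: %s", stage_name, exc)
        raise

    return manifest
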