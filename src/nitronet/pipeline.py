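"""End-to-end pipeline: simulate/load -> diversity -> associations -> networks.

A single YAML config drives every stage; a machine-readable manifest records
parameters, per-stage seeds (spawned deterministically from the master seed)
and SHA-256 checksums of every output, so two runs with the same config are
bit-identical for deterministic stages and identical under the same master
seed for stochastic ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diversity, env_assoc, io_tables, network, synthetic

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything a full run needs; built from a YAML mapping."""

    input_paths: dict[str, str] | None  # counts, taxonomy, metadata
    synthetic_config: synthetic.SyntheticConfig | None
    pairs: list[tuple[str, str]]
    r_threshold: float = network.R_THRESHOLD
    p_threshold: float = network.P_THRESHOLD
    min_prevalence: float = 0.5
    min_mean_relabund: float = 0.0
    q_threshold: float = 0.05
    n_perm: int = 999
    robustness_fractions: list[float] = dataclasses.field(
        default_factory=lambda: [round(f, 2) for f in np.arange(0.05, 0.51, 0.05)]
    )
    robustness_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_paths is None and self.synthetic_config is None:
            raise ValueError("config must provide either input paths or a synthetic section")
        if self.input_paths is not None and self.synthetic_config is not None:
            raise ValueError("config must not provide both input paths and a synthetic section")
        if not self.pairs:
            raise ValueError("config must list at least one treatment pair")

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "PipelineConfig":
        syn = None
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = synthetic.SyntheticConfig(**raw["synthetic"])
        pairs = [tuple(p) for p in raw.get("pairs", [])]
        kwargs = {
            k: raw[k]
            for k in (
                "r_threshold", "p_threshold", "min_prevalence", "min_mean_relabund",
                "q_threshold", "n_perm", "robustness_fractions",
                "robustness_replicates", "seed",
            )
            if k in raw
        }
        return cls(
            input_paths=raw.get("input"),
            synthetic_config=syn,
            pairs=pairs,
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a mapping")
        return cls.from_mapping(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(master: int, stages: list[str]) -> dict[str, int]:
    """Deterministic per-stage 31-bit seeds spawned from the master seed."""
    children = np.random.SeedSequence(master).spawn(len(stages))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(stages, children)
    }


STAGES = ["simulate", "permanova", "betadisper", "mantel", "modules", "robustness"]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write tables, networks and a manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, STAGES)
    manifest: dict[str, Any] = {
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {
            "pairs": [list(p) for p in config.pairs],
            "r_threshold": config.r_threshold,
            "p_threshold": config.p_threshold,
            "min_prevalence": config.min_prevalence,
            "min_mean_relabund": config.min_mean_relabund,
            "q_threshold": config.q_threshold,
            "n_perm": config.n_perm,
            "robustness_fractions": list(config.robustness_fractions),
            "robustness_replicates": config.robustness_replicates,
        },
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, started: float, **extra: Any) -> None:
        # wall time goes to the log only; the manifest must be reproducible
        manifest["stages"].append({"stage": stage, **extra})
        logger.info("stage %s done in %.2fs", stage, time.time() - started)

    # ---- inputs -----------------------------------------------------------
    t0 = time.time()
    if config.synthetic_config is not None:
        syn_cfg = dataclasses.replace(config.synthetic_config, seed=seeds["simulate"])
        table, meta, tax, truth = synthetic.generate_community(syn_cfg)
        io_tables.write_count_table(table, outdir / "counts.tsv")
        io_tables.write_metadata(meta, outdir / "metadata.tsv")
        io_tables.write_taxonomy(tax, outdir / "taxonomy.tsv")
        truth.to_json(outdir / "truth.json")
        record("simulate", t0, seed=seeds["simulate"])
    else:
        paths = config.input_paths
        table = io_tables.read_count_table(paths["counts"], paths.get("orientation", "samples_as_rows"))
        tax = io_tables.read_taxonomy(paths["taxonomy"]) if "taxonomy" in paths else None
        meta = io_tables.read_metadata(paths["metadata"])
        record("load", t0, paths=dict(paths))

    # ---- alpha / beta diversity ------------------------------------------
    t0 = time.time()
    alpha = diversity.alpha_diversity(table)
    alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    dm = diversity.bray_curtis(table)
    ordination = diversity.pcoa(dm)
    with open(outdir / "pcoa_coordinates.tsv", "w", encoding="utf-8") as fh:
        fh.write("# eigenvalues: " + "\t".join(f"{v:.10g}" for v in ordination.eigenvalues) + "\n")
        fh.write("# proportion_explained: "
                 + "\t".join(f"{v:.10g}" for v in ordination.proportion_explained) + "\n")
        ordination.coordinates.to_csv(fh, sep="\t", index_label="sample_id")
    record("diversity", t0)

    # ---- permutation statistics ------------------------------------------
    t0 = time.time()
    perma = diversity.permanova(dm, meta.treatment, n_perm=config.n_perm, seed=seeds["permanova"])
    disp, dists = diversity.dispersion_homogeneity(
        dm, meta.treatment, n_perm=config.n_perm, seed=seeds["betadisper"]
    )
    stats_tab = pd.DataFrame(
        [
            {"test": "permanova", "statistic": perma.statistic_value,
             "effect_size_R2": perma.effect_size, "p": perma.p_value,
             "n_permutations": perma.n_permutations},
            {"test": "betadisper", "statistic": disp.statistic_value,
             "effect_size_R2": np.nan, "p": disp.p_value,
             "n_permutations": disp.n_permutations},
        ]
    )
    stats_tab.to_csv(outdir / "permutation_tests.tsv", sep="\t", index=False)
    dists.to_frame().to_csv(outdir / "distance_to_centroid.tsv", sep="\t")

    levels = meta.treatment_levels
    simper_frames = []
    for a, b in zip(levels[:-1], levels[1:]):
        sub = table.subset_samples(meta.samples_of(a, b))
        res = diversity.simper(sub, meta.treatment)
        frame = res.table.copy()
        frame.insert(0, "comparison", f"{a} vs {b}")
        simper_frames.append(frame.reset_index())
    pd.concat(simper_frames).to_csv(outdir / "simper.tsv", sep="\t", index=False)
    record("permutation_stats", t0, permanova_p=perma.p_value)

    # ---- taxon-environment association -----------------------------------
    t0 = time.time()
    if tax is not None:
        profile = env_assoc.preference_profile(
            table, meta, q_threshold=config.q_threshold, tax=tax, rank="phylum"
        )
        profile.table.to_csv(outdir / "preference_profile.tsv", sep="\t", index=False)
        mant = env_assoc.phylum_mantel_tests(
            table, tax, meta, n_perm=config.n_perm, seed=seeds["mantel"]
        )
        mant.to_csv(outdir / "mantel_tests.tsv", sep="\t", index=False)
    record("env_assoc", t0, seed=seeds["mantel"])

    # ---- networks ---------------------------------------------------------
    t0 = time.time()
    nets = network.paired_networks(
        table, meta, config.pairs, tax=tax,
        min_prevalence=config.min_prevalence,
        min_mean_relabund=config.min_mean_relabund,
        r_threshold=config.r_threshold, p_threshold=config.p_threshold,
    )
    topo_rows = []
    for k, net in enumerate(nets, start=1):
        partition = network.detect_modules(net)
        topo, _ = network.topology(net, partition)
        for node, mod in partition.items():
            net.graph.nodes[node]["module"] = int(mod)
        io_tables.write_network(net, outdir / f"network_{k}.graphml", "graphml")
        io_tables.write_network(net, outdir / f"network_{k}.edgelist.tsv", "edgelist")
        row = topo.as_series()
        row["network"] = net.label
        topo_rows.append(row)

        zp = network.zipi(net, partition)
        zp.to_csv(outdir / f"zipi_network_{k}.tsv", sep="\t", index=False)
        rc = network.robustness(
            net, fractions=config.robustness_fractions,
            n_replicates=config.robustness_replicates, seed=seeds["robustness"] + k,
        )
        rc.curve.to_csv(outdir / f"robustness_network_{k}.tsv", sep="\t", index=False)
        summary, inter = network.module_summary(net, partition, tax)
        summary.to_csv(outdir / f"modules_network_{k}.tsv", sep="\t", index=False)
        inter.to_csv(outdir / f"intermodule_links_network_{k}.tsv", sep="\t")
    pd.DataFrame(topo_rows).set_index("network").to_csv(outdir / "topology.tsv", sep="\t")

    comp_rows = []
    for i in range(len(nets)):
        for j in range(i + 1, len(nets)):
            nd, ed = network.network_dissimilarity(nets[i], nets[j])
            comp_rows.append({"network_a": nets[i].label, "network_b": nets[j].label,
                              "node_dissimilarity": nd, "edge_dissimilarity": ed})
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(outdir / "network_comparison.tsv", sep="\t", index=False)
    record("networks", t0, n_networks=len(nets))

    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
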