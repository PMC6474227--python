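"""End-to-end orchestration of the dual-transcriptome analysis.

``run_all`` executes: (optional) simulation -> normalization and
filtering -> per-gene response classification (both organisms) ->
module detection (host from the AMF-responsive gene pool, symbiont from
all retained genes) -> cross-organism module network, key genes and
permutation null -> module-trait association. All outputs are TSV /
GraphML / JSON; a manifest records the configuration hash and seed, and
a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import crossnet, io, traits as traits_mod, wgcna
from .preprocess import filter_genes, log2_cpm
from .response import classify_responses, select_by_fold_change
from .simulate import MOCK_LEVEL, SimConfig, simulate_dataset, write_dataset

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger("mycorrnet")

# response classes counted as "differentially expressed vs the
# mycorrhizal treatments": the host module pool
AMF_RESPONSIVE = ("mycorrhiza_conserved", "isolate_conserved", "interaction")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline with their canonical defaults."""

    # inputs; when simulate=True they are generated instead
    simulate: bool = True
    host_counts: str | None = None
    symbiont_counts: str | None = None
    metadata: str | None = None
    traits: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)

    # normalization / filtering
    prior: float = 0.5
    min_cpm: float = 1.0
    min_samples: int = 3

    # differential response
    de_alpha: float = 0.05
    fc_host: float = 2.0
    fc_symbiont: float = 4.0

    # modules
    power: float = 12.0
    min_module_size: int = 50
    merge_cut: float = 0.1
    cut_quantile: float = 0.995
    mode: str = "unsigned"

    # cross network / key genes / traits
    edge_alpha: float = 0.001
    quantile: float = 0.9
    kme_min: float = 0.8
    n_perm: int = 100

    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if not 0 < self.edge_alpha < 1 or not 0 < self.de_alpha < 1:
            raise ValueError("alpha thresholds must be in (0, 1)")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if not -1 <= self.kme_min <= 1:
            raise ValueError("kme_min must be in [-1, 1]")
        if self.power <= 0 or self.min_module_size < 1:
            raise ValueError("power must be > 0 and min_module_size >= 1")
        if not 0 <= self.merge_cut <= 2:
            raise ValueError("merge_cut must be in [0, 2]")
        if self.mode not in ("unsigned", "signed"):
            raise ValueError("mode must be unsigned or signed")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "sim" in raw and isinstance(raw["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(raw["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config key(s): {sorted(sim_unknown)}")
            raw = dict(raw)
            sim = dict(raw["sim"])
            for key in ("host_module_sizes", "sym_module_sizes", "lib_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "cross_links" in sim:
                sim["cross_links"] = [tuple(x) for x in sim["cross_links"]]
            if "trait_loadings" in sim:
                sim["trait_loadings"] = [tuple(x) for x in sim["trait_loadings"]]
            raw["sim"] = SimConfig(**sim)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    """Everything the pipeline computed, for programmatic use."""

    design: pd.DataFrame
    expr: dict
    de: dict
    partitions: dict
    cross_edges: pd.DataFrame
    network: nx.Graph
    key_genes: pd.DataFrame
    permutation: dict
    module_trait: dict
    trait_key_genes: pd.DataFrame
    truth: object | None
    outputs: dict
    manifest: dict


def _stage(name: str):
    logger.info("stage: %s", name)


def run_all(config: PipelineConfig | None = None, outdir=None) -> PipelineResult:
    """Run the complete pipeline; writes all declared outputs under
    ``config.outdir`` and returns the in-memory results."""
    if config is None:
        config = PipelineConfig()
    if outdir is not None:
        config = dataclasses.replace(config, outdir=str(outdir))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    ss = np.random.SeedSequence(config.seed)
    sim_seed, perm_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))

    truth = None
    try:
        if config.simulate:
            _stage("simulate")
            sim_cfg = dataclasses.replace(config.sim, seed=sim_seed)
            data = simulate_dataset(sim_cfg)
            outputs.update(write_dataset(data, out))
            design = data.design
            host_counts, sym_counts = data.host_counts, data.sym_counts
            trait_table = data.traits
            truth = data.truth
        else:
            _stage("load")
            design = io.read_metadata(config.metadata)
            host_counts = io.read_count_matrix(config.host_counts, organism="host")
            sym_counts = io.read_count_matrix(
                config.symbiont_counts, organism="symbiont"
            )
            trait_table = io.read_traits(config.traits) if config.traits else None
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage 'inputs' failed: {err}") from err

    inoculated = design.index[
        (design["fungal_treatment"] != MOCK_LEVEL).to_numpy()
    ]
    if len(inoculated) == 0:
        raise RuntimeError(
            "stage 'preprocess' failed: no inoculated samples in the design"
        )

    _stage("preprocess")
    expr = {}
    de = {}
    fcs = {}
    for organism, counts, fc_thresh in (
        ("host", host_counts, config.fc_host),
        ("symbiont", sym_counts, config.fc_symbiont),
    ):
        filtered = filter_genes(
            counts, config.min_cpm, config.min_samples, design=design
        )
        logger.info(
            "%s: %d/%d genes retained over %d samples",
            organism,
            filtered.n_genes,
            counts.n_genes,
            filtered.n_samples,
        )
        e = log2_cpm(filtered, prior=config.prior)
        expr[organism] = e
        sub_design = design.loc[e.sample_ids]
        table = classify_responses(e, sub_design, alpha=config.de_alpha)
        de[organism] = table
        iso_levels = [
            t for t in pd.unique(sub_design["fungal_treatment"]) if t != MOCK_LEVEL
        ]
        if len(iso_levels) >= 2:
            genes_fc, fc = select_by_fold_change(
                e,
                sub_design,
                iso_levels[0],
                iso_levels[1],
                min_abs_log2fc=fc_thresh,
                classification=table,
            )
        else:
            genes_fc, fc = pd.Index([]), pd.DataFrame(index=e.gene_ids)
        fcs[organism] = (genes_fc, fc)
        io.write_table(
            table.reset_index(), out / f"de_classes_{organism}.tsv"
        )
        outputs[f"de_classes_{organism}.tsv"] = str(out / f"de_classes_{organism}.tsv")
        fc_out = fc.copy()
        fc_out.insert(0, "gene_id", fc_out.index)
        fc_out.insert(1, "selected", fc_out["gene_id"].isin(set(genes_fc)))
        io.write_table(fc_out, out / f"foldchange_{organism}.tsv")
        outputs[f"foldchange_{organism}.tsv"] = str(out / f"foldchange_{organism}.tsv")
        counts_by_class = table["response_class"].value_counts().to_dict()
        logger.info("%s response classes: %s", organism, counts_by_class)

    _stage("modules")
    partitions = {}
    for organism in ("host", "symbiont"):
        e = expr[organism]
        if organism == "host":
            pool = de[organism].index[
                de[organism]["response_class"].isin(AMF_RESPONSIVE).to_numpy()
            ]
            e = e.subset_genes(pool)
            logger.info("host module pool: %d AMF-responsive genes", len(pool))
        try:
            part = wgcna.detect_modules(
                e,
                power=config.power,
                mode=config.mode,
                min_module_size=config.min_module_size,
                merge_cut=config.merge_cut,
                cut_quantile=config.cut_quantile,
            )
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"stage 'modules/{organism}' failed: {err}") from err
        partitions[organism] = part
        logger.info(
            "%s: %d modules (%d genes assigned)",
            organism,
            part.n_modules,
            int((part.labels > 0).sum()),
        )
        io.write_table(
            part.labels.rename("module_label").reset_index().rename(
                columns={"index": "gene_id"}
            ),
            out / f"modules_{organism}.tsv",
        )
        io.write_table(
            part.eigengenes.T.reset_index(names="module"),
            out / f"eigengenes_{organism}.tsv",
        )
        kme_out = part.kme.reset_index().rename(columns={"index": "gene_id"})
        io.write_table(kme_out, out / f"kme_{organism}.tsv")
        for name in ("modules", "eigengenes", "kme"):
            outputs[f"{name}_{organism}.tsv"] = str(out / f"{name}_{organism}.tsv")

    _stage("crossnet")
    me_h = partitions["host"].eigengenes
    me_s = partitions["symbiont"].eigengenes
    if me_h.shape[1] and me_s.shape[1]:
        edges = crossnet.correlate_module_sets(
            me_h, me_s, sample_subset=inoculated, edge_alpha=config.edge_alpha
        )
    else:
        edges = pd.DataFrame(
            columns=["module_host", "module_symbiont", "r", "p", "q", "n", "significant"]
        )
    net = crossnet.build_bipartite_network(
        edges, host_modules=list(me_h.columns), symbiont_modules=list(me_s.columns)
    )
    kg_frames = []
    for organism, partner in (("host", "symbiont"), ("symbiont", "host")):
        if not len(edges):
            continue
        kg = crossnet.key_genes(
            expr[organism],
            partitions[organism],
            partitions[partner].eigengenes,
            edges,
            organism,
            quantile=config.quantile,
            kme_min=config.kme_min,
            sample_subset=inoculated,
        )
        kg_frames.append(kg)
    key_gene_table = (
        pd.concat(kg_frames, ignore_index=True)
        if kg_frames
        else pd.DataFrame(
            columns=[
                "gene_id",
                "organism",
                "own_module",
                "partner_module",
                "GS",
                "kME",
                "passes",
            ]
        )
    )
    if me_h.shape[1] and me_s.shape[1]:
        perm = crossnet.permutation_null(
            partitions["host"].labels,
            partitions["symbiont"].labels,
            expr["host"],
            expr["symbiont"],
            n_perm=config.n_perm,
            seed=perm_seed,
            edge_alpha=config.edge_alpha,
            sample_subset=inoculated,
        )
    else:
        perm = {
            "observed_edges": 0,
            "null_counts": np.zeros(config.n_perm, dtype=int),
            "p_empirical": 1.0,
            "edge_alpha": config.edge_alpha,
            "n_perm": config.n_perm,
        }
    io.write_table(edges, out / "cross_edges.tsv")
    nx.write_graphml(net, out / "network.graphml")
    io.write_table(key_gene_table, out / "key_genes.tsv")
    io.write_table(
        pd.DataFrame({"permutation": np.arange(1, perm["n_perm"] + 1),
                      "significant_edges": perm["null_counts"]}),
        out / "permutation_null.tsv",
    )
    for name in ("cross_edges.tsv", "network.graphml", "key_genes.tsv", "permutation_null.tsv"):
        outputs[name] = str(out / name)
    logger.info(
        "cross network: %d significant edges, permutation p = %.4g",
        int(edges["significant"].sum()) if len(edges) else 0,
        perm["p_empirical"],
    )

    _stage("traits")
    module_trait = {}
    mt_frames = []
    tkg_frames = []
    if trait_table is not None:
        for organism in ("host", "symbiont"):
            part = partitions[organism]
            if not part.n_modules:
                continue
            subset = None if organism == "host" else inoculated
            mt = traits_mod.correlate_modules_traits(
                part.eigengenes, trait_table, sample_subset=subset
            )
            mt.insert(0, "organism", organism)
            module_trait[organism] = mt
            mt_frames.append(mt)
            for trait in trait_table.columns:
                tkg = traits_mod.key_genes_for_trait(
                    expr[organism],
                    part,
                    trait_table,
                    trait,
                    organism=organism,
                    alpha=config.edge_alpha,
                    quantile=config.quantile,
                    kme_min=config.kme_min,
                    sample_subset=subset,
                    module_trait=mt.drop(columns="organism"),
                )
                if len(tkg):
                    tkg_frames.append(tkg)
    mt_all = (
        pd.concat(mt_frames, ignore_index=True)
        if mt_frames
        else pd.DataFrame(columns=["organism", "module", "trait", "r", "p", "n", "q"])
    )
    tkg_all = (
        pd.concat(tkg_frames, ignore_index=True)
        if tkg_frames
        else pd.DataFrame(
            columns=[
                "gene_id",
                "organism",
                "own_module",
                "partner_module",
                "GS",
                "kME",
                "passes",
            ]
        )
    )
    io.write_table(mt_all, out / "module_trait.tsv")
    io.write_table(tkg_all, out / "trait_key_genes.tsv")
    outputs["module_trait.tsv"] = str(out / "module_trait.tsv")
    outputs["trait_key_genes.tsv"] = str(out / "trait_key_genes.tsv")

    _stage("manifest")
    manifest = io.write_manifest(
        out / "manifest.json", config.to_dict(), config.seed, outputs
    )
    outputs["manifest.json"] = str(out / "manifest.json")

    return PipelineResult(
        design=design,
        expr=expr,
        de=de,
        partitions=partitions,
        cross_edges=edges,
        network=net,
        key_genes=key_gene_table,
        permutation=perm,
        module_trait=module_trait,
        trait_key_genes=tkg_all,
        truth=truth,
        outputs=outputs,
        manifest=manifest,
    )
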