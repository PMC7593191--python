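"""Orchestration: load inputs from a YAML config and run the full analysis.

Produces the association report (Mantel / partial Mantel / MRM of genetic
vs geographic and linguistic distances), the AMOVA report grouped by
language phylum, the diversity report (rarefied allelic richness, IDW
surface, richness-by-word-class rank tests) and the overlay report (MST
with phylum assortativity, cluster-wise FST and migrant numbers, cognate x
cluster tables).  Every report embeds the config hash, the options in
effect, and the seed, so identical config + seed reproduces byte-identical
output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
import networkx as nx
import numpy as np

from . import io
from .amova import amova_report, amova_three_level
from .association import kruskal_dunn, mantel, mrm, partial_mantel, rank_test_by_class
from .genetic import (
    allelic_richness,
    jost_d_pairwise,
    linearize,
    migrants_from_fst,
    pairwise_fst,
)
from .model import (
    ClusterAssignment,
    CognateCatalog,
    GenotypeDataset,
    LanguageHierarchy,
    PopulationMetadata,
)
from .overlay import (
    cognate_chisq,
    cognate_cluster_table,
    minimum_spanning_tree,
    phylum_edge_assortativity,
)
from .predictors import greatcircle_matrix, idw_interpolate, linguistic_distance_matrix, log_distance
from .simulate import primary_phylum

log = logging.getLogger("bcpg")


@dataclass
class RunConfig:
    """Paths and estimator options for a pipeline run."""

    genotypes: str
    metadata: str
    hierarchy: str
    cognates: str | None = None
    qmatrix: str | None = None
    output_dir: str = "bcpg-out"
    d_averaging: str = "arithmetic"
    bilingual_rule: str = "min"
    admixture_threshold: float = 0.7
    log_floor_km: float = 1.0
    migrant_multiplier: float = 1.0
    idw_cell_size: float = 1.0
    idw_power: float = 2.0
    idw_neighbors: int = 12
    n_perm_mantel: int = 5000
    n_perm_amova: int = 1000
    n_perm_network: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        data = io.read_yaml(path)
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: int) -> np.random.Generator:
        # per-stage streams derived from the master seed via a counter
        return np.random.default_rng([self.seed, stage])


@dataclass
class LoadedInputs:
    genotypes: GenotypeDataset
    metadata: list[PopulationMetadata]
    hierarchy: LanguageHierarchy
    cognates: CognateCatalog | None
    clusters: ClusterAssignment | None


def load_inputs(cfg: RunConfig) -> LoadedInputs:
    hierarchy = io.read_hierarchy(cfg.hierarchy)
    metadata = io.read_metadata(cfg.metadata, hierarchy)
    genotypes = io.read_genepop(cfg.genotypes)
    sites = {m.site for m in metadata}
    unmatched = [p for p in genotypes.populations if p not in sites]
    if unmatched:
        raise ValueError(f"genotype populations missing from metadata: {unmatched}")
    # keep metadata in genotype population order, drop extra metadata rows
    order = {p: i for i, p in enumerate(genotypes.populations)}
    metadata = sorted(
        (m for m in metadata if m.site in order), key=lambda m: order[m.site]
    )
    cognates = io.read_cognates(cfg.cognates) if cfg.cognates else None
    clusters = (
        io.read_qmatrix(cfg.qmatrix, cfg.admixture_threshold) if cfg.qmatrix else None
    )
    log.info(
        "loaded %d populations, %d loci, %d sites",
        len(genotypes.populations),
        len(genotypes.loci),
        len(metadata),
    )
    return LoadedInputs(genotypes, metadata, hierarchy, cognates, clusters)


def _provenance(cfg: RunConfig) -> dict:
    return {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "options": {
            "d_averaging": cfg.d_averaging,
            "bilingual_rule": cfg.bilingual_rule,
            "admixture_threshold": cfg.admixture_threshold,
            "n_perm_mantel": cfg.n_perm_mantel,
            "n_perm_amova": cfg.n_perm_amova,
        },
    }


def association_matrices(
    inputs: LoadedInputs, cfg: RunConfig
) -> tuple:
    """d_GEN (Jost), linearized d_GEN, ln d_GEO, d_LAN — label-aligned."""
    d_gen = jost_d_pairwise(inputs.genotypes, averaging=cfg.d_averaging)
    d_lin = linearize(d_gen)
    d_geo = log_distance(greatcircle_matrix(inputs.metadata), cfg.log_floor_km)
    d_lan = linguistic_distance_matrix(
        inputs.metadata, inputs.hierarchy, aggregation=cfg.bilingual_rule
    )
    d_lin, d_geo, d_lan = d_lin.align(d_geo, d_lan)
    return d_gen, d_lin, d_geo, d_lan


def run_association(inputs: LoadedInputs, cfg: RunConfig) -> dict:
    """Mantel / partial Mantel / MRM report on d_GEN, d_GEO, d_LAN."""
    d_gen, d_lin, d_geo, d_lan = association_matrices(inputs, cfg)
    n_perm = cfg.n_perm_mantel
    tests = {
        "dGEN_x_dGEO": mantel(d_lin, d_geo, n_perm, cfg.stage_seed(10)),
        "dGEN_x_dLAN": mantel(d_lin, d_lan, n_perm, cfg.stage_seed(11)),
        "dGEO_x_dLAN": mantel(d_geo, d_lan, n_perm, cfg.stage_seed(12)),
        "partial_dGEN_x_dLAN_given_dGEO": partial_mantel(
            d_lin, d_lan, d_geo, n_perm, cfg.stage_seed(13)
        ),
    }
    model = mrm(
        d_lin, {"dGEO": d_geo, "dLAN": d_lan}, n_perm, cfg.stage_seed(14)
    )
    dg_aligned, dlan_aligned = d_gen.align(d_lan)
    classes = rank_test_by_class(dg_aligned, dlan_aligned)
    report = {
        "mantel": {
            name: {
                "r": res.r,
                "r2": res.r2,
                "p": res.p,
                "n_perm": res.n_perm,
                "tail": res.tail,
            }
            for name, res in tests.items()
        },
        "mrm": {
            "beta_geo": float(model.std_coefficients[0]),
            "beta_lan": float(model.std_coefficients[1]),
            "coef_geo": float(model.coefficients[1]),
            "coef_lan": float(model.coefficients[2]),
            "r2": model.r2,
            "p_r2": model.p_r2,
            "p_beta": [float(p) for p in model.p_coefficients],
        },
        "dgen_by_dlan_class": {
            "H": classes.h,
            "df": classes.df,
            "p": classes.p,
            "class_means": classes.class_summary.to_dict("records"),
            "dunn": classes.dunn.to_dict("records"),
        },
        "provenance": _provenance(cfg),
    }
    return report


def run_amova(inputs: LoadedInputs, cfg: RunConfig) -> dict:
    grouping = {
        m.site: primary_phylum(m, inputs.hierarchy) for m in inputs.metadata
    }
    result = amova_three_level(
        inputs.genotypes, grouping, cfg.n_perm_amova, cfg.stage_seed(20)
    )
    table = amova_report(result)
    return {
        "table": table.to_dict("records"),
        "percentages": list(result.percentages) if result.defined else None,
        "provenance": _provenance(cfg),
    }


def _pooled_richness_class(count: int) -> int:
    """Word-term richness class; counts >= 4 pooled into one class."""
    return min(count, 4)


def run_diversity(inputs: LoadedInputs, cfg: RunConfig) -> dict:
    """Rarefied richness, its IDW surface, and richness-by-word-class tests."""
    table = allelic_richness(inputs.genotypes, "auto")
    rs = {p: float(v) for p, v in zip(table.populations, table.rs)}
    coords = {m.site: (m.latitude, m.longitude) for m in inputs.metadata}
    sites = [(coords[p][0], coords[p][1], rs[p]) for p in table.populations]
    lats = [c[0] for c in sites]
    lons = [c[1] for c in sites]
    pad = cfg.idw_cell_size
    grid = idw_interpolate(
        sites,
        (min(lats) - pad, max(lats) + pad),
        (min(lons) - pad, max(lons) + pad),
        cell_size=cfg.idw_cell_size,
        power=cfg.idw_power,
        k_neighbors=cfg.idw_neighbors,
    )
    richness_class = np.array(
        [
            _pooled_richness_class(m.word_richness)
            for m in inputs.metadata
            if m.site in rs
        ]
    )
    values = np.array([rs[m.site] for m in inputs.metadata if m.site in rs])
    if np.unique(richness_class).size >= 2:
        kw = kruskal_dunn(values, richness_class)
        kw_report = {
            "H": kw.h,
            "df": kw.df,
            "p": kw.p,
            "class_means": kw.class_summary.to_dict("records"),
            "dunn": kw.dunn.to_dict("records"),
        }
    else:
        kw_report = None
        log.warning("only one word-richness class; rank test skipped")
    return {
        "rs": rs,
        "g_size": table.g_size,
        "dropped_loci": table.dropped_loci,
        "idw_grid": grid,
        "rs_by_word_richness": kw_report,
        "provenance": _provenance(cfg),
    }


def run_overlay(inputs: LoadedInputs, cfg: RunConfig) -> dict:
    """MST + assortativity; cluster FST / migrants; cognate tables."""
    d_gen = jost_d_pairwise(inputs.genotypes, averaging=cfg.d_averaging)
    phylum_of = {
        m.site: primary_phylum(m, inputs.hierarchy) for m in inputs.metadata
    }
    tree = minimum_spanning_tree(d_gen, inputs.metadata, phylum_of)
    report: dict = {"provenance": _provenance(cfg), "mst": tree}
    if len(set(phylum_of.values())) >= 2:
        frac, p = phylum_edge_assortativity(
            tree, cfg.n_perm_network, cfg.stage_seed(30)
        )
        report["assortativity"] = {"same_phylum_fraction": frac, "p": p}
    if inputs.clusters is None:
        log.warning("no Q-matrix supplied; cluster overlay skipped")
        return report
    labels = inputs.clusters.cluster_labels()
    grouping = {p: labels[p] for p in inputs.genotypes.populations if p in labels}
    fst_matrix, fst_frame = pairwise_fst(inputs.genotypes, grouping)
    report["cluster_fst"] = fst_frame.to_dict("records")
    if fst_matrix is not None:
        migrants = migrants_from_fst(fst_matrix, cfg.migrant_multiplier)
        report["migrants"] = [
            {
                "pair": f"{m.unit_a}|{m.unit_b}",
                "fst": m.fst,
                "M": m.migrants,
            }
            for m in migrants
        ]
    if inputs.cognates is not None:
        table = cognate_cluster_table(inputs.cognates, inputs.clusters)
        report["cognate_table"] = table.to_frame().to_dict()
        report["cognate_chisq"] = {
            mode: cognate_chisq(table, mode).to_dict("records")
            for mode in ("gof_half", "independence")
        }
    return report


def run_all(cfg: RunConfig) -> dict:
    """Load inputs once and produce every report; write them to output_dir."""
    inputs = load_inputs(cfg)
    reports = {
        "association": run_association(inputs, cfg),
        "amova": run_amova(inputs, cfg),
        "diversity": run_diversity(inputs, cfg),
        "overlay": run_overlay(inputs, cfg),
    }
    write_reports(reports, cfg)
    return reports


def write_reports(reports: dict, cfg: RunConfig) -> None:
    os.makedirs(cfg.output_dir, exist_ok=True)
    diversity = reports.get("diversity")
    if diversity and "idw_grid" in diversity:
        grid = diversity["idw_grid"]
        with open(os.path.join(cfg.output_dir, "rs_idw.asc"), "w") as fh:
            fh.write(grid.to_ascii_grid())
        with open(os.path.join(cfg.output_dir, "rs_idw.csv"), "w") as fh:
            fh.write("lon,lat,value\n")
            for lon, lat, v in grid.to_xyz_rows():
                fh.write(f"{lon},{lat},{v}\n")
    overlay = reports.get("overlay")
    if overlay and "mst" in overlay:
        tree = overlay["mst"]
        nx.write_graphml(tree, os.path.join(cfg.output_dir, "mst.graphml"))
        with open(os.path.join(cfg.output_dir, "mst_edges.csv"), "w") as fh:
            fh.write("a,b,weight\n")
            for a, b, w in tree.edges(data="weight"):
                fh.write(f"{a},{b},{w}\n")
    serializable = {
        name: _strip_objects(rep) for name, rep in reports.items()
    }
    io.write_yaml(serializable, os.path.join(cfg.output_dir, "reports.yaml"))


def _strip_objects(report: dict) -> dict:
    out = {}
    for k, v in report.items():
        if k in ("idw_grid", "mst"):
            continue
        out[k] = _to_builtin(v)
    return out


def _to_builtin(v):
    if isinstance(v, dict):
        return {str(k): _to_builtin(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_to_builtin(x) for x in v]
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return [_to_builtin(x) for x in v]
    return v
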