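"""End-to-end orchestration of the analysis battery.

A run loads and aligns the inputs, then per (region, ecosystem) stratum
fits the neutral model and builds the co-occurrence network with its
stability metrics, and globally runs ordination, PERMANOVA, distance
decay (compositional similarity and, when gene data are present, shared
gene counts), the geography-vs-environment partial Mantel pair,
environmental association, and the gene accumulation curve.  All stage
outputs land as TSV/JSON under the run directory, summarized in a
single report JSON whose bytes depend only on the inputs and the master
seed (no timestamps).

Stage seeds derive deterministically from the master seed and a stage
label so one user-facing seed controls every source of randomness
without correlating stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from aquassembly import biogeography as bio
from aquassembly import network as net
from aquassembly import neutral
from aquassembly.io import (
    align_inputs,
    read_abundance_table,
    read_gene_matrix,
    read_metadata,
    read_orf_catalog,
)

logger = logging.getLogger("aquassembly")


@dataclass
class RunConfig:
    """Inputs and parameters of a full run.

    Defaults mirror the standard analysis configuration: Spearman edges
    at |rho| >= 0.8 and p < 0.05, 1000 bootstrap replicates for the
    NCM bands, 100 random-graph nulls, extinction removal of 0–90% of
    nodes with 50 repeats, 5% gene-accumulation steps with 10 repeats,
    and 999 permutations for every permutation test.
    """

    table_path: str
    metadata_path: str
    out_dir: str
    genes_path: str | None = None
    orf_map_path: str | None = None
    stratify_by: tuple = ("region", "ecosystem")
    reference_region: str | None = None
    env_variables: tuple = ()
    detection_limit: float | str = "auto"
    n_bootstrap: int = 1000
    r_min: float = 0.8
    p_max: float = 0.05
    n_null: int = 100
    extinction_repeats: int = 50
    extinction_fractions: tuple = tuple(round(0.1 * k, 1) for k in range(10))
    accumulation_step: float = 0.05
    accumulation_repeats: int = 10
    n_permutations: int = 999
    min_stratum_samples: int = 5
    master_seed: int = 0


def stage_seed(master_seed: int, stage: str, stratum: str = "") -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(
        f"{master_seed}:{stage}:{stratum}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _validate(instance, schema, path="$") -> list[str]:
    """Minimal JSON-schema subset validator (type/required/properties)."""
    errors = []
    stype = schema.get("type")
    typemap = {"object": dict, "array": list, "string": str,
               "integer": int, "number": (int, float)}
    if stype and not isinstance(instance, typemap[stype]):
        return [f"{path}: expected {stype}"]
    if stype == "object":
        for req in schema.get("required", []):
            if req not in instance:
                errors.append(f"{path}.{req}: required")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errors += _validate(instance[key], sub, f"{path}.{key}")
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            for key, val in instance.items():
                if key not in schema.get("properties", {}):
                    errors += _validate(val, extra, f"{path}.{key}")
    return errors


def validate_report(report: dict) -> None:
    """Check a run report against the published schema; raise on failure."""
    schema = json.loads(
        resources.files("aquassembly").joinpath("report_schema.json")
        .read_text()
    )
    errors = _validate(report, schema)
    if errors:
        raise ValueError("report schema violations: " + "; ".join(errors))


def _stratum_analyses(table, cfg: RunConfig, label: str, out: Path) -> dict:
    result: dict = {"n_samples": table.n_samples}
    # --- neutral model
    try:
        stats = neutral.occurrence_stats(table, cfg.detection_limit)
        fit = neutral.bootstrap_ncm(
            stats, n_bootstrap=cfg.n_bootstrap,
            seed=stage_seed(cfg.master_seed, "ncm", label),
        )
        pd.DataFrame({
            "taxon": fit.taxon_ids,
            "p": fit.p,
            "f": fit.f,
            "predicted": fit.predicted,
            "lower": fit.ci_lower,
            "upper": fit.ci_upper,
            "partition": [fit.partition[t] for t in fit.taxon_ids],
        }).to_csv(out / f"ncm_{label}.tsv", sep="\t", index=False)
        result["ncm"] = {
            "nm": fit.nm,
            "r_squared": fit.r_squared,
            "detection_limit": fit.detection_limit,
            "n_bootstrap": fit.n_bootstrap,
            "partition_counts": fit.partition_counts(),
        }
    except (neutral.NCMFitError, ValueError) as exc:
        logger.warning("NCM skipped for %s: %s", label, exc)
        result["ncm"] = {"error": str(exc)}
    # --- network + stability
    try:
        screen = net.correlation_screen(table)
        graph = net.build_network(screen, cfg.r_min, cfg.p_max)
        topo = net.topology(graph)
        net.write_edge_list(graph, out / f"edges_{label}.tsv")
        pd.DataFrame(
            {"node": list(topo.module_assignment),
             "module": list(topo.module_assignment.values())}
        ).to_csv(out / f"modules_{label}.tsv", sep="\t", index=False)
        result["network"] = topo.to_dict()
        if graph.number_of_edges() >= 1 and net.global_efficiency(graph) > 0:
            stab = net.network_stability(
                graph, n_null=cfg.n_null, n_repeats=cfg.extinction_repeats,
                fractions=cfg.extinction_fractions,
                seed=stage_seed(cfg.master_seed, "stability", label),
            )
            pd.DataFrame(stab.extinction_curve).to_csv(
                out / f"extinction_{label}.tsv", sep="\t", index=False
            )
            result["stability"] = {
                "relative_modularity": stab.relative_modularity,
                "vulnerability": stab.vulnerability,
            }
        else:
            result["stability"] = {"error": "no usable edges"}
    except ValueError as exc:
        logger.warning("network skipped for %s: %s", label, exc)
        result["network"] = {"error": str(exc)}
        result["stability"] = {"error": str(exc)}
    return result


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis battery and write the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (cfg.table_path, cfg.metadata_path, cfg.genes_path,
                 cfg.orf_map_path):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")

    table = read_abundance_table(cfg.table_path)
    metadata = read_metadata(cfg.metadata_path, vocabulary=None)
    genes = (read_gene_matrix(cfg.genes_path)
             if cfg.genes_path is not None else None)
    bundle = align_inputs(table, metadata, genes)
    table, metadata, genes = bundle.table, bundle.metadata, bundle.genes

    stage_seeds: dict[str, int] = {}

    def seed_for(stage: str, stratum: str = "") -> int:
        s = stage_seed(cfg.master_seed, stage, stratum)
        stage_seeds[f"{stage}:{stratum}" if stratum else stage] = s
        return s

    # --- per-stratum analyses
    strata: dict[str, dict] = {}
    keys = [k for k in cfg.stratify_by if k in metadata.columns]
    group_iter = (
        metadata.groupby(list(keys), sort=True).groups.items()
        if keys else [(("all",), metadata.index)]
    )
    for key, samples in group_iter:
        label = "_".join(str(k) for k in np.atleast_1d(np.asarray(key, dtype=object)))
        label = label.replace(" ", "-").replace("/", "-")
        samples = [s for s in table.sample_ids if s in set(samples)]
        if len(samples) < cfg.min_stratum_samples:
            logger.info("stratum %s skipped: %d samples", label, len(samples))
            continue
        seed_for("ncm", label)
        seed_for("stability", label)
        strata[label] = _stratum_analyses(
            table.select_samples(samples), cfg, label, out
        )

    # --- global analyses
    global_block: dict = {}
    d_bc = bio.bray_curtis(table)
    ord_res = bio.pcoa(d_bc)
    n_axes = min(2, ord_res.coordinates.shape[1])
    pd.DataFrame(
        ord_res.coordinates[:, :n_axes],
        index=ord_res.sample_ids,
        columns=[f"PCo{k+1}" for k in range(n_axes)],
    ).rename_axis("sample").to_csv(out / "pcoa.tsv", sep="\t")

    eco = metadata["ecosystem"].reindex(table.sample_ids)
    counts = eco.value_counts()
    usable = eco.isin(counts[counts >= 2].index)
    if usable.all() and eco.nunique() >= 2:
        perma = bio.permanova(
            d_bc, eco.tolist(), cfg.n_permutations, seed_for("permanova")
        )
        global_block["permanova"] = {
            "pseudo_f": perma.pseudo_f, "r_squared": perma.r_squared,
            "p_value": perma.p_value,
            "n_permutations": perma.n_permutations,
        }
    else:
        global_block["permanova"] = {"error": "need >=2 ecosystems with "
                                              ">=2 samples each"}

    # distance decay, reference-anchored
    reference = (
        list(metadata.index[metadata["region"] == cfg.reference_region])
        if cfg.reference_region is not None
        else list(table.sample_ids)
    )
    decay_block: dict = {}
    d_geo = bio.geographic_distance(metadata).select(table.sample_ids)
    d_alt = bio.altitude_difference(metadata).select(table.sample_ids)
    sim = bio.similarity_matrix(table)
    responses = {"similarity": sim}
    if genes is not None:
        responses["shared_genes"] = bio.shared_gene_counts(genes)
    for rname, resp in responses.items():
        for dname, dmat in (("distance", d_geo), ("altitude", d_alt)):
            try:
                decay = bio.distance_decay(
                    resp, dmat, eco.tolist(), reference
                )
                decay.pair_table.to_csv(
                    out / f"decay_{rname}_{dname}.tsv", sep="\t", index=False
                )
                decay_block[f"{rname}_vs_{dname}"] = {
                    "spearman_r": decay.spearman_r,
                    "p_value": decay.p_value,
                    "n_pairs": decay.n_pairs,
                }
            except ValueError as exc:
                decay_block[f"{rname}_vs_{dname}"] = {"error": str(exc)}
    global_block["decay"] = decay_block

    # partial Mantel geography vs environment
    mantel_block: dict = {}
    if cfg.env_variables:
        try:
            res = bio.geo_env_partial_mantel(
                table, metadata, list(cfg.env_variables),
                cfg.n_permutations, seed_for("partial-mantel"),
            )
            mantel_block = {
                "r_geo_given_env": res["geo_given_env"].statistic,
                "p_geo_given_env": res["geo_given_env"].p_value,
                "r_env_given_geo": res["env_given_geo"].statistic,
                "p_env_given_geo": res["env_given_geo"].p_value,
                "n_samples": res["n_samples"],
            }
        except ValueError as exc:
            mantel_block = {"error": str(exc)}
    global_block["mantel"] = mantel_block

    # environmental association with FDR
    if cfg.env_variables:
        assoc = bio.env_association(
            table, metadata, list(cfg.env_variables),
            cfg.n_permutations, seed_for("env-association"),
        )
        assoc.to_csv(out / "env_association.tsv", sep="\t", index=False)
        global_block["env_association"] = assoc.to_dict("records")
    else:
        global_block["env_association"] = []

    # gene accumulation
    if cfg.orf_map_path is not None:
        catalog = read_orf_catalog(cfg.orf_map_path)
        fractions = [
            round(cfg.accumulation_step * k, 10)
            for k in range(1, int(round(1.0 / cfg.accumulation_step)) + 1)
        ]
        curve = bio.gene_accumulation(
            catalog, fractions, cfg.accumulation_repeats,
            seed_for("accumulation"),
        )
        curve.to_csv(out / "gene_accumulation.tsv", sep="\t", index=False)
        global_block["gene_accumulation"] = curve.to_dict("records")
    else:
        global_block["gene_accumulation"] = []

    from aquassembly import __version__

    cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    report = {
        "provenance": {
            "package_version": __version__,
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "master_seed": cfg.master_seed,
            "stage_seeds": stage_seeds,
        },
        "strata": strata,
        "global": global_block,
    }
    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
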