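"""End-to-end orchestration: simulate/load -> normalize -> QC -> differential
-> cluster/embed -> ORA, with deterministic, manifest-stamped outputs.

Normalization is fitted jointly across all arrays of a tissue (arrays of one
tissue share a hybridization batch and intensity regime); consistency
filtering and differential calling operate per contrast on the arrays of the
two groups being compared; clustering and the t-SNE embedding use the
peptides consistent across every array of the dataset.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import heatmap_export, pearson_distance_matrix, wpgma_cluster
from .differential import ContrastSpec, call_differential, compare_sets, table_records
from .io import (
    ArrayDesign,
    PeptideAnnotation,
    FIXTURE_NAMES,
    load_fixture_table,
    read_gmt,
    read_spot_table,
    write_differential_table,
    write_spot_table,
)
from .ora import OraQuery, map_peptides_to_accessions, run_ora
from .qc import average_replicates, chi2_consistency, consistent_peptides
from .simulate import SimulationConfig, simulate, truth_recovery_report
from .tsne import tsne_embed
from .vsn import apply_vsn, fit_vsn

__all__ = ["PipelineConfig", "run_pipeline", "fixtures_report"]

log = logging.getLogger("kinopipe")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``spot_table`` (a TSV path) or ``sim_config`` must be provided;
    with neither, a default simulation at ``seed`` is run.
    """

    output_dir: str = "kinopipe_out"
    seed: int = 1
    spot_table: str | None = None
    annotation_table: str | None = None
    n_tech_replicates: int = 9
    sim_config: SimulationConfig | None = None
    contrasts: tuple[tuple[str, str], ...] = (
        ("PCEP", "MUSCLE"), ("ALUM", "MUSCLE"),
        ("PCEP", "LYMPH_NODE"), ("ALUM", "LYMPH_NODE"),
    )
    alpha_consistency: float = 0.01
    alpha_differential: float = 0.05
    fdr_threshold: float = 0.05
    gmt_path: str | None = None
    tsne_restarts: int = 100
    tsne_iters: int = 1000
    run_embedding: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_consistency", "alpha_differential", "fdr_threshold"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.spot_table is not None and self.annotation_table is None:
            raise ValueError("an external spot_table requires annotation_table")
        for pname in ("spot_table", "annotation_table", "gmt_path"):
            p = getattr(self, pname)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{pname} {p!r} does not exist")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {k: repr(v) for k, v in sorted(vars(config).items())}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, schema_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# columns: {', '.join(map(str, df.columns))} -- {schema_note}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the result bundle to disk.

    Returns a dict of in-memory results (differential tables, Venn counts,
    recovery metrics when ground truth is available, manifest).  Identical
    config and seed yield byte-identical output files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def emit(df: pd.DataFrame, name: str, note: str) -> None:
        _write_tsv(df, out / name, note)
        artifacts.append(name)

    # ----- inputs -------------------------------------------------------
    truth = None
    if config.spot_table is not None:
        annot = pd.read_csv(config.annotation_table, sep="\t", dtype=str)
        catalogue = tuple(
            PeptideAnnotation(row.peptide_id, row.protein_name, row.phosphosite,
                              row.uniprot_accession)
            for row in annot.itertuples(index=False)
        )
        design = ArrayDesign(catalogue, config.n_tech_replicates)
        spots = read_spot_table(config.spot_table, design)
        log.info("read %d spots on %d arrays", len(spots), spots["array_id"].nunique())
    else:
        sim = config.sim_config or SimulationConfig(seed=config.seed)
        design = sim.design
        spots, truth = simulate(sim)
        write_spot_table(spots, out / "spots.tsv")
        artifacts.append("spots.tsv")
        log.info("simulated %d spots on %d arrays", len(spots),
                 spots["array_id"].nunique())

    results: dict = {"tables": {}, "recovery": {}}

    # ----- per-tissue normalization ------------------------------------
    norm_frames = []
    for tissue, tspots in spots.groupby("tissue", sort=True):
        fit = fit_vsn(tspots)
        norm_frames.append(apply_vsn(tspots, fit))
        emit(fit.frame(), f"vsn_fit_{tissue}.tsv",
             "per-array arsinh calibration y = arsinh(a + b*x)")
        log.info("VSN %s: %d iterations, converged=%s, residual sd %.4f",
                 tissue, fit.n_iterations, fit.converged, fit.residual_sd)
    norm = pd.concat(norm_frames, ignore_index=True)

    # ----- per-contrast QC, differential, ORA --------------------------
    venn_inputs = {}
    for treatment, tissue in config.contrasts:
        cname = f"{tissue}_{treatment}"
        sub = norm[
            (norm["tissue"] == tissue)
            & norm["treatment"].isin([treatment, "PBS"])
        ]
        if sub.empty:
            raise ValueError(f"contrast {cname}: no arrays in dataset")
        consistency = chi2_consistency(sub, alpha=config.alpha_consistency)
        emit(consistency, f"consistency_{cname}.tsv",
             "chi-squared technical-replicate consistency per (array, peptide)")
        kept = consistent_peptides(consistency)
        log.info("%s: %d/%d peptides consistent", cname, len(kept), design.n_peptides)

        profiles = average_replicates(sub, consistency)
        contrast = ContrastSpec(treatment=treatment, tissue=tissue,
                                alpha=config.alpha_differential)
        table = call_differential(profiles, contrast, design)
        results["tables"][cname] = table
        venn_inputs[cname] = table
        records = table_records(table)
        write_differential_table(
            records, out / f"differential_{cname}.tsv",
            extra={"t": table["t"].to_list(), "nu": table["nu"].to_list()},
        )
        artifacts.append(f"differential_{cname}.tsv")
        log.info("%s: %d differential peptides", cname, len(table))

        if truth is not None:
            rec = truth_recovery_report(truth, table["peptide_id"], treatment, tissue)
            results["recovery"][cname] = rec
            emit(pd.DataFrame([rec]), f"recovery_{cname}.tsv",
                 "recovery of planted truth by the differential calls")

        if config.gmt_path is not None and len(table):
            annot = design.annotation_frame()
            universe = map_peptides_to_accessions(kept, annot)
            query = map_peptides_to_accessions(records)
            ora = run_ora(
                OraQuery(query=query, universe=universe,
                         gene_sets=read_gmt(config.gmt_path)),
                fdr_threshold=config.fdr_threshold,
            )
            emit(ora, f"ora_{cname}.tsv",
                 "hypergeometric over-representation, BH-adjusted")
            results["tables"][f"ora_{cname}"] = ora

    # ----- Venn counts --------------------------------------------------
    if len(venn_inputs) >= 2:
        venn = compare_sets(venn_inputs)
        results["venn"] = venn
        with open(out / "venn.json", "w") as fh:
            json.dump(venn, fh, indent=2, sort_keys=True)
        artifacts.append("venn.json")

    # ----- clustering & embedding on dataset-wide consistent peptides ---
    consistency_all = chi2_consistency(norm, alpha=config.alpha_consistency)
    profiles_all = average_replicates(norm, consistency_all)
    mat = profiles_all.pivot(index="peptide_id", columns="array_id",
                             values="mean_intensity")
    col_tree = wpgma_cluster(pearson_distance_matrix(mat.T))
    row_tree = wpgma_cluster(pearson_distance_matrix(mat))
    export = heatmap_export(mat, row_tree, col_tree)
    emit(export["matrix"].reset_index(), "heatmap_matrix.tsv",
         "normalized mean intensities, rows/cols in dendrogram leaf order")
    for key, fname in (("row_newick", "peptide_dendrogram.nwk"),
                       ("col_newick", "array_dendrogram.nwk")):
        with open(out / fname, "w") as fh:
            fh.write(export[key] + "\n")
        artifacts.append(fname)
    results["dendrograms"] = {"rows": row_tree, "cols": col_tree}

    if config.run_embedding:
        emb = tsne_embed(mat.T, n_restarts=config.tsne_restarts,
                         iters=config.tsne_iters)
        coords = emb.coordinates.reset_index().rename(columns={"index": "array_id"})
        coords["objective"] = emb.objective
        emit(coords, "embedding.tsv",
             "t-SNE coordinates of arrays; objective = minimum KL over restarts")
        results["embedding"] = emb

    # ----- manifest -----------------------------------------------------
    manifest = {
        "package": "kinopipe",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "artifacts": sorted(artifacts),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results


def fixtures_report() -> pd.DataFrame:
    """Summary of the packaged published tables: per-fixture totals, counts
    by direction, fold-change extrema, and pairwise peptide-identity overlap."""
    rows = []
    tables = {}
    for name in FIXTURE_NAMES:
        records = load_fixture_table(name)
        tables[name] = records
        fcs = [r.fold_change for r in records]
        rows.append(
            {
                "fixture": name,
                "total": len(records),
                "increased": sum(r.direction == "INCREASED" for r in records),
                "decreased": sum(r.direction == "DECREASED" for r in records),
                "max_fc": max(fcs),
                "min_fc": min(fcs),
            }
        )
    report = pd.DataFrame(rows)
    venn = compare_sets(tables)
    report.attrs["venn"] = venn
    return report
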