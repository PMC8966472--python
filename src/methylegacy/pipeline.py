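"""End-to-end orchestration: load inputs, characterize, run DM + enrichment.

Every run writes its artifacts under one output directory together with a
machine-readable manifest (package version, config hash, seed, artifact
list, and the site-count funnel of every filter stage) so that re-runs
with the same config are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import assign_features, read_gene_models
from .dm import (bh_qvalues, classical_mds, mds_input, run_dm_pollutant,
                 summarize_deltas)
from .enrichment import (aggregate_genes, control_methylation_model,
                         delta_by_class_model, feature_enrichment, overlap_sets)
from .io import read_cytosine_report, read_sample_sheet
from .matrix import MethylomeMatrix, SampleDesign, merge_samples
from .profile import (cpg_density_profile, global_methylation, heavy_site_table,
                      methylation_landscape, repeatability)

log = logging.getLogger("methylegacy")


@dataclass
class RunConfig:
    """Parameters of a pipeline run; defaults follow the study's choices."""

    fixture_dir: str | None = None
    pollutants: tuple[str, ...] = ("Cd", "Gly", "Np")
    min_reads: int = 10
    max_missing_control: int = 2
    max_missing_treatment: int = 1
    low_pct: float = 1.0
    high_pct: float = 99.0
    alpha_fdr: float = 0.05
    heavy_threshold: float = 0.5
    landscape_bin_bp: int = 20
    landscape_loess: float = 0.3
    repeat_bounds: tuple[float, float] = (1.0, 99.0)
    repeat_n_sites: int = 10_000
    repeat_n_perm: int = 199
    mds_k: int = 2
    outdir: str = "run"
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_inputs(cfg: RunConfig):
    """Read the fixture directory: reports, sample sheet, gene models."""
    d = Path(cfg.fixture_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"fixture directory not found: {d}")
    design = read_sample_sheet(d / "samples.tsv")
    fragments = {}
    for sid in design.sample_ids:
        path = d / f"{sid}.CpG_report.txt"
        if not path.exists():
            raise FileNotFoundError(f"missing cytosine report for sample {sid}: {path}")
        fragments[sid] = read_cytosine_report(path)
    matrix = merge_samples(fragments, design)
    genes = read_gene_models(d / "genes.gff3")
    return matrix, design, genes


def _write_manifest(outdir: Path, cfg: RunConfig, artifacts: list[str], extra=None):
    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "config": asdict(cfg),
        "artifacts": sorted(artifacts),
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_characterize(cfg: RunConfig, inputs=None) -> dict:
    """Methylome characterization: global %, heavy sites, density, landscape,
    repeatability. Writes five artifacts plus a manifest."""
    matrix, design, genes = load_inputs(cfg) if inputs is None else inputs
    controls = design.controls()
    if not controls:
        raise ValueError("characterization requires >=1 control sample")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assignment = assign_features(matrix.sites, genes)

    gm = global_methylation(matrix, controls, min_reads=cfg.min_reads)
    (outdir / "global_methylation.json").write_text(
        json.dumps(
            {"mean_pct": gm.mean_pct, "ci_low": gm.ci_low, "ci_high": gm.ci_high,
             "per_sample_pct": gm.per_sample_pct},
            indent=2,
        )
    )
    heavy = heavy_site_table(matrix, controls, assignment,
                             threshold=cfg.heavy_threshold)
    heavy.to_csv(outdir / "heavy_sites.tsv", sep="\t")

    pooled = matrix.pooled_fraction(controls)
    heavy_mask = (~np.isnan(pooled)) & (pooled > cfg.heavy_threshold)
    density = cpg_density_profile(matrix.sites, heavy_mask)
    density.to_csv(outdir / "cpg_density.tsv", sep="\t", index=False)

    landscape = methylation_landscape(
        matrix, controls[0], assignment, bin_bp=cfg.landscape_bin_bp,
        loess_frac=cfg.landscape_loess,
    )
    landscape.to_csv(outdir / "landscape.tsv", sep="\t", index=False)

    rep = repeatability(
        matrix, controls, bounds=cfg.repeat_bounds, n_sites=cfg.repeat_n_sites,
        n_perm=cfg.repeat_n_perm, seed=cfg.seed, min_reads=cfg.min_reads,
    )
    (outdir / "repeatability.json").write_text(
        json.dumps(
            {"R": rep.R, "p_value": rep.p_value, "n_sites": rep.n_sites,
             "bounds": rep.bounds, "n_permutations": rep.n_permutations},
            indent=2,
        )
    )
    artifacts = ["global_methylation.json", "heavy_sites.tsv", "cpg_density.tsv",
                 "landscape.tsv", "repeatability.json"]
    _write_manifest(outdir, cfg, artifacts)
    return {"global": gm, "heavy": heavy, "repeatability": rep,
            "artifacts": artifacts}


def run_dm(cfg: RunConfig, inputs=None) -> dict:
    """Per-pollutant DM analysis, enrichment, gene aggregation, MDS."""
    matrix, design, genes = load_inputs(cfg) if inputs is None else inputs
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    funnel: list[dict] = []
    dm_tables: dict[str, pd.DataFrame] = {}
    gene_lists: dict[str, dict[str, set]] = {}

    for pollutant in cfg.pollutants:
        if not design.group(pollutant, "curtox") or not design.group(pollutant, "switch"):
            log.warning("pollutant %s lacks replicates in a group; skipped", pollutant)
            continue
        dm = run_dm_pollutant(
            matrix, design, pollutant,
            min_reads=cfg.min_reads, low=cfg.low_pct, high=cfg.high_pct,
            alpha=cfg.alpha_fdr, log=funnel,
        )
        dm_tables[pollutant] = dm
        dm.to_csv(outdir / f"dm_{pollutant}.tsv", sep="\t", index=False)
        artifacts.append(f"dm_{pollutant}.tsv")

        summarize_deltas(dm, alpha=cfg.alpha_fdr).to_csv(
            outdir / f"delta_summary_{pollutant}.tsv", sep="\t", index=False
        )
        artifacts.append(f"delta_summary_{pollutant}.tsv")

        sub_assignment = assign_features(dm[["contig", "pos", "strand"]], genes)
        enr = feature_enrichment(dm, sub_assignment)
        enr.to_csv(outdir / f"enrichment_{pollutant}.tsv", sep="\t", index=False)
        artifacts.append(f"enrichment_{pollutant}.tsv")

        try:
            by_type, by_feature, _ = delta_by_class_model(dm, sub_assignment,
                                                          alpha=cfg.alpha_fdr)
            marg, pairwise, disp = control_methylation_model(dm, sub_assignment,
                                                             alpha=cfg.alpha_fdr)
            by_type.to_csv(outdir / f"delta_marginal_{pollutant}.tsv", sep="\t",
                           index=False)
            marg.assign(dispersion=disp).to_csv(
                outdir / f"control_marginal_{pollutant}.tsv", sep="\t", index=False
            )
            artifacts += [f"delta_marginal_{pollutant}.tsv",
                          f"control_marginal_{pollutant}.tsv"]
        except ValueError as exc:
            log.warning("marginal models skipped for %s: %s", pollutant, exc)

        dmg = aggregate_genes(dm, sub_assignment, alpha=cfg.alpha_fdr)
        dmg.to_csv(outdir / f"dm_genes_{pollutant}.tsv", sep="\t", index=False)
        artifacts.append(f"dm_genes_{pollutant}.tsv")
        gene_lists[pollutant] = {
            cls: set(dmg.loc[dmg["gene_class"] == cls, "gene_id"])
            for cls in ("direct", "persistent", "legacy")
        }
        for cls, ids in gene_lists[pollutant].items():
            path = outdir / f"gene_list_{pollutant}_{cls}.txt"
            path.write_text("\n".join(sorted(ids)) + ("\n" if ids else ""))
            artifacts.append(path.name)

    overlaps = {}
    for cls in ("direct", "persistent", "legacy"):
        sets = {p: gene_lists[p][cls] for p in gene_lists}
        if len(sets) >= 2:
            overlaps[cls] = overlap_sets(sets)
    (outdir / "gene_overlaps.json").write_text(json.dumps(overlaps, indent=2))
    artifacts.append("gene_overlaps.json")

    mds_coords = None
    if dm_tables:
        # union of DM sites across pollutants, embedded over all samples
        key_cols = ["contig", "pos", "strand"]
        dm_keys = pd.concat(
            [t.loc[t["response_class"] != "none", key_cols] for t in dm_tables.values()]
        ).drop_duplicates()
        merged = matrix.sites.merge(dm_keys.assign(_dm=True), on=key_cols, how="left")
        dm_any = merged["_dm"].notna().to_numpy()
        X, used = mds_input(matrix, dm_any)
        if used.sum() >= 2 and X.shape[0] >= 3:
            coords, evals = classical_mds(X, k=cfg.mds_k)
            mds_coords = pd.DataFrame(
                coords, columns=[f"dim{i + 1}" for i in range(coords.shape[1])]
            )
            mds_coords.insert(0, "sample_id", matrix.samples)
            mds_coords.to_csv(outdir / "mds.tsv", sep="\t", index=False)
            artifacts.append("mds.tsv")

    for row in funnel:
        log.info("filter funnel %s/%s: %d sites", row["pollutant"], row["stage"],
                 row["n_sites"])
    _write_manifest(outdir, cfg, artifacts, extra={"filter_funnel": funnel})
    return {"dm_tables": dm_tables, "gene_lists": gene_lists,
            "overlaps": overlaps, "mds": mds_coords, "funnel": funnel,
            "artifacts": artifacts}
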