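"""Synthetic bisulfite methylome generator emulating a pollutant-exposure study.

The generator reproduces, at desk scale, the structure of a whole-genome
bisulfite experiment on clonal *Daphnia pulex* populations: six water
controls and, per pollutant (Cd, Gly, Np), three replicates still exposed
(``curtox``) and three returned to clean water (``switch``). Baseline
methylation is a sharply bimodal mixture — a low mode around ~1.3% and a
heavy mode around 80% occupied by ~0.7% of sites, with heavy sites
enriched in exons and promoters — tuned so pooled controls show ~1.9%
global methylation. Differential methylation is planted in three response
classes: *direct* (shifted only in curtox), *persistent* (same shift in
curtox and switch, drawn preferentially from high-baseline sites and
shifted down) and *legacy* (shifted only in switch, drawn from
low-baseline sites and shifted up). Shifts act on the logit scale.

Read counts are beta-binomial around each sample's per-site proportion
with negative-binomial coverage, so replicate overdispersion exists but
is mild by default. Everything is driven by one seeded generator; a
fixed :class:`SimConfig` reproduces outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotation import FeatureAssignment, GeneModel, assign_features, write_gff3
from .io import write_cytosine_report, write_sample_sheet, matrix_fragment
from .matrix import MethylomeMatrix, SampleDesign, make_sites

CLASSES = ("direct", "persistent", "legacy")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic methylome.

    Defaults emulate the source study's design constants: 26.5x mean
    coverage, ~1.9% global methylation with ~0.7% of sites heavily
    (>50%) methylated, heavy-site odds enriched 2.4-fold in exons and
    2.64-fold in promoters, a 6-control / 3-curtox / 3-switch design per
    pollutant, and planted effects averaging ~25 percentage points.
    """

    # genome / annotation
    n_genes: int = 120
    contig_length: int = 1_500_000
    n_contigs: int = 1
    n_cpgs: int = 20_000
    exons_per_gene_mean: float = 5.0
    exon_length_range: tuple[int, int] = (100, 400)
    intron_length_range: tuple[int, int] = (80, 500)
    min_intergenic_gap: int = 500
    # coverage model
    coverage_mean: float = 26.5
    coverage_dispersion: float = 0.15  # NB: var = m + d m^2; 0 -> Poisson
    # baseline mixture
    low_mode_mean: float = 0.0131
    low_mode_concentration: float = 8.0
    heavy_mode_mean: float = 0.80
    heavy_mode_concentration: float = 10.0
    heavy_fraction_genome: float = 0.0071
    heavy_enrichment_exon: float = 2.4
    heavy_enrichment_promoter: float = 2.64
    heavy_low_density_thin: float = 0.0  # optional CpG-density dip near heavy sites
    # planted effects
    effect_size_logit: float = 2.75
    n_direct: int = 300
    n_persistent: int = 300
    n_legacy: int = 300
    # replicate structure
    replicates: tuple[int, int, int] = (6, 3, 3)  # control, curtox, switch
    pollutants: tuple[str, ...] = ("Cd", "Gly", "Np")
    bb_dispersion: float = 0.01  # beta-binomial rho; 0 -> pure binomial
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_genes=self.n_genes, n_cpgs=self.n_cpgs, n_contigs=self.n_contigs,
            n_direct=self.n_direct, n_persistent=self.n_persistent,
            n_legacy=self.n_legacy,
        )
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        for name in ("low_mode_mean", "heavy_mode_mean", "heavy_fraction_genome",
                     "heavy_low_density_thin", "bb_dispersion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.coverage_dispersion < 0:
            raise ValueError("coverage_dispersion must be >= 0")
        if self.heavy_enrichment_exon < 1 or self.heavy_enrichment_promoter < 1:
            raise ValueError("heavy enrichment folds must be >= 1")
        if any(r < 0 for r in self.replicates):
            raise ValueError("replicate counts must be >= 0")


@dataclass
class SimResult:
    """Everything one simulation produced, incl. the ground truth."""

    config: SimConfig
    genes: list[GeneModel]
    assignment: FeatureAssignment
    baselines: np.ndarray  # true per-site methylation proportion
    truth: pd.DataFrame  # site_idx, site_id, pollutant, planted_class, planted_delta
    design: SampleDesign
    matrix: MethylomeMatrix


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_annotation(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Lay out non-overlapping genes and scatter CpG positions.

    Genes are placed contig by contig with random intergenic gaps; an
    explicit sizing error is raised when the requested genes cannot fit.
    CpG positions are uniform without replacement over each contig.
    """
    cfg.validate()
    rng = _rng(cfg.seed) if rng is None else rng
    contigs = [f"contig{i + 1}" for i in range(cfg.n_contigs)]
    per_contig = np.zeros(cfg.n_contigs, dtype=int)
    for i in range(cfg.n_genes):
        per_contig[i % cfg.n_contigs] += 1

    genes: list[GeneModel] = []
    for contig, n_genes_here in zip(contigs, per_contig):
        structures = []
        for _ in range(n_genes_here):
            n_exons = 1 + rng.poisson(max(cfg.exons_per_gene_mean - 1.0, 0.0))
            exon_lens = rng.integers(*cfg.exon_length_range, endpoint=True, size=n_exons)
            intron_lens = rng.integers(*cfg.intron_length_range, endpoint=True,
                                       size=max(n_exons - 1, 0))
            structures.append((exon_lens, intron_lens))
        spans = [int(e.sum() + i.sum()) for e, i in structures]
        needed = sum(spans) + (n_genes_here + 1) * cfg.min_intergenic_gap
        if needed > cfg.contig_length:
            raise ValueError(
                f"{contig} too short for {n_genes_here} genes: "
                f"need >= {needed} bp, have {cfg.contig_length}"
            )
        slack = cfg.contig_length - needed
        extra = rng.multinomial(slack, np.full(n_genes_here + 1, 1.0 / (n_genes_here + 1))) \
            if n_genes_here else np.array([slack])
        cursor = 0
        for k, (exon_lens, intron_lens) in enumerate(structures):
            cursor += cfg.min_intergenic_gap + int(extra[k])
            start = cursor + 1
            exons = []
            pos = start
            for j, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el) - 1))
                pos += int(el)
                if j < len(intron_lens):
                    pos += int(intron_lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"{contig}.g{k + 1}",
                    contig=contig,
                    strand=strand,
                    exons=exons,
                    contig_length=cfg.contig_length,
                )
            )
            cursor = exons[-1][1]

    per_contig_cpgs = np.zeros(cfg.n_contigs, dtype=int)
    for i in range(cfg.n_cpgs):
        per_contig_cpgs[i % cfg.n_contigs] += 1
    frames = []
    for contig, n_here in zip(contigs, per_contig_cpgs):
        if n_here == 0:
            continue
        pos = np.sort(rng.choice(cfg.contig_length, size=n_here, replace=False)) + 1
        strand = np.where(rng.random(n_here) < 0.5, "+", "-")
        frames.append(pd.DataFrame({"contig": contig, "pos": pos, "strand": strand}))
    sites = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["contig", "pos", "strand"])
    )
    return genes, make_sites(sites.get("contig", []), sites.get("pos", []),
                             sites.get("strand", []))


def _truncated_beta(rng, mean, concentration, lo, hi, size) -> np.ndarray:
    """Beta(mean*k, (1-mean)*k) draws rejected into (lo, hi]."""
    a = mean * concentration
    b = (1.0 - mean) * concentration
    out = rng.beta(a, b, size=size)
    for _ in range(200):
        bad = (out <= lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
    return np.clip(out, lo + 1e-9, hi)


def assign_baseline(
    sites: pd.DataFrame,
    assignment: FeatureAssignment,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-site true methylation proportions from the bimodal mixture.

    Heavy-site probability is set on the odds scale: exon and promoter
    sites get the configured fold over genome odds, and the probability
    for the remaining sites is solved so the genome-wide expected heavy
    fraction equals ``heavy_fraction_genome`` exactly.
    """
    cfg.validate()
    rng = _rng(cfg.seed + 1) if rng is None else rng
    n = len(sites)
    if n == 0:
        return np.empty(0)
    p_g = cfg.heavy_fraction_genome
    if p_g == 0.0:
        heavy = np.zeros(n, dtype=bool)
    else:
        odds_g = p_g / (1.0 - p_g)
        in_prom = assignment.membership("promoter")
        in_exon = assignment.membership("exon") & ~in_prom  # promoter fold wins on overlap
        p_exon = _odds_to_p(odds_g * cfg.heavy_enrichment_exon)
        p_prom = _odds_to_p(odds_g * cfg.heavy_enrichment_promoter)
        if max(p_exon, p_prom) >= 1.0:
            raise ValueError("heavy enrichment folds imply a probability >= 1")
        f_e, f_p = in_exon.mean(), in_prom.mean()
        f_o = 1.0 - f_e - f_p
        p_other = (p_g - f_e * p_exon - f_p * p_prom) / f_o if f_o > 0 else 0.0
        if p_other < 0:
            raise ValueError(
                "heavy enrichment folds and feature fractions are incompatible with "
                "the genome-wide heavy fraction (implied off-feature probability < 0)"
            )
        prob = np.full(n, p_other)
        prob[in_exon] = p_exon
        prob[in_prom] = p_prom
        heavy = rng.random(n) < prob
    baselines = np.empty(n)
    n_heavy = int(heavy.sum())
    if n_heavy:
        baselines[heavy] = _truncated_beta(
            rng, cfg.heavy_mode_mean, cfg.heavy_mode_concentration, 0.5, 1.0, n_heavy
        )
    n_low = n - n_heavy
    if n_low:
        baselines[~heavy] = _truncated_beta(
            rng, cfg.low_mode_mean, cfg.low_mode_concentration, 0.0, 0.5, n_low
        )
    return baselines


def _odds_to_p(odds: float) -> float:
    return odds / (1.0 + odds)


def _weighted_sample_without_replacement(rng, weights, k) -> np.ndarray:
    """Efraimidis-Spirakis exponential-key sampling; weights may be zero."""
    w = np.asarray(weights, dtype=float)
    keys = np.full(w.shape, np.inf)
    pos = w > 0
    keys[pos] = rng.exponential(size=int(pos.sum())) / w[pos]
    if k > int(pos.sum()):
        raise ValueError("not enough positively weighted items")
    return np.argpartition(keys, k - 1)[:k] if k else np.empty(0, dtype=int)


def plant_effects(
    baselines: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    site_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Choose DM sites per pollutant and record the planted truth.

    Persistent sites are drawn with weight proportional to baseline (so
    preferentially from the heavy mode) and shifted down; legacy sites
    with weight proportional to 1 - baseline and shifted up; direct sites
    uniformly, with a random sign. Within a pollutant the three classes
    are disjoint. Shifts add ``+/- effect_size_logit`` on the logit scale,
    clamped to (0.001, 0.999).
    """
    cfg.validate()
    rng = _rng(cfg.seed + 2) if rng is None else rng
    eligible = (baselines > 0.01) & (baselines < 0.99)
    n_needed = cfg.n_direct + cfg.n_persistent + cfg.n_legacy
    rows = []
    for pollutant in cfg.pollutants:
        avail = np.flatnonzero(eligible)
        if len(avail) < n_needed:
            for cls, k in zip(CLASSES, (cfg.n_direct, cfg.n_persistent, cfg.n_legacy)):
                if len(avail) < k:
                    raise ValueError(
                        f"only {len(avail)} eligible sites (baseline in (0.01, 0.99)) "
                        f"for {k} requested '{cls}' sites ({pollutant})"
                    )
            raise ValueError(
                f"only {len(avail)} eligible sites for {n_needed} planted sites ({pollutant})"
            )
        b = baselines[avail]
        taken = np.zeros(len(avail), dtype=bool)
        picks: dict[str, np.ndarray] = {}
        w_pers = np.where(taken, 0.0, b)
        idx = _weighted_sample_without_replacement(rng, w_pers, cfg.n_persistent)
        picks["persistent"] = avail[idx]
        taken[idx] = True
        w_leg = np.where(taken, 0.0, 1.0 - b)
        idx = _weighted_sample_without_replacement(rng, w_leg, cfg.n_legacy)
        picks["legacy"] = avail[idx]
        taken[idx] = True
        w_dir = np.where(taken, 0.0, 1.0)
        idx = _weighted_sample_without_replacement(rng, w_dir, cfg.n_direct)
        picks["direct"] = avail[idx]
        signs = {
            "persistent": -np.ones(cfg.n_persistent),
            "legacy": np.ones(cfg.n_legacy),
            "direct": np.where(rng.random(cfg.n_direct) < 0.5, 1.0, -1.0),
        }
        for cls in CLASSES:
            sidx = picks[cls]
            b0 = baselines[sidx]
            p1 = np.clip(expit(logit(b0) + signs[cls] * cfg.effect_size_logit), 0.001, 0.999)
            for s, d in zip(sidx, 100.0 * (p1 - b0)):
                rows.append((int(s), pollutant, cls, float(d)))
    truth = pd.DataFrame(rows, columns=["site_idx", "pollutant", "planted_class",
                                        "planted_delta"])
    if site_ids is not None and len(truth):
        truth.insert(1, "site_id", [site_ids[i] for i in truth["site_idx"]])
    elif site_ids is not None:
        truth.insert(1, "site_id", pd.Series(dtype=str))
    return truth


def make_design(cfg: SimConfig) -> SampleDesign:
    """Sample sheet for the 6-control + per-pollutant 3-curtox/3-switch design."""
    n_ctrl, n_cur, n_sw = cfg.replicates
    rows = [(f"water_control_{r + 1}", "water", "control", r + 1) for r in range(n_ctrl)]
    for pollutant in cfg.pollutants:
        rows += [(f"{pollutant}_curtox_{r + 1}", pollutant, "curtox", r + 1)
                 for r in range(n_cur)]
        rows += [(f"{pollutant}_switch_{r + 1}", pollutant, "switch", r + 1)
                 for r in range(n_sw)]
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "pollutant",
                                                    "treatment", "replicate"]))


def simulate_counts(
    sites: pd.DataFrame,
    baselines: np.ndarray,
    truth: pd.DataFrame,
    design: SampleDesign,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> MethylomeMatrix:
    """Draw beta-binomial read counts per sample around each site's proportion."""
    cfg.validate()
    rng = _rng(cfg.seed + 3) if rng is None else rng
    n = len(sites)
    samples = design.sample_ids
    meth = np.zeros((n, len(samples)))
    total = np.zeros((n, len(samples)))
    shifted: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (pollutant, cls), grp in truth.groupby(["pollutant", "planted_class"], sort=True):
        idx = grp["site_idx"].to_numpy(dtype=int)
        p1 = baselines[idx] + grp["planted_delta"].to_numpy() / 100.0
        treatments = {"direct": ("curtox",), "persistent": ("curtox", "switch"),
                      "legacy": ("switch",)}[cls]
        for t in treatments:
            prev = shifted.setdefault((pollutant, t), (np.empty(0, int), np.empty(0)))
            shifted[(pollutant, t)] = (np.concatenate([prev[0], idx]),
                                       np.concatenate([prev[1], p1]))
    for j, sid in enumerate(samples):
        row = design.table.loc[design.table["sample_id"] == sid].iloc[0]
        p = baselines.copy()
        key = (row["pollutant"], row["treatment"])
        if key in shifted:
            idx, p1 = shifted[key]
            p[idx] = p1
        if cfg.coverage_dispersion > 0:
            nb_n = 1.0 / cfg.coverage_dispersion
            nb_p = nb_n / (nb_n + cfg.coverage_mean)
            cov = rng.negative_binomial(nb_n, nb_p, size=n)
        else:
            cov = rng.poisson(cfg.coverage_mean, size=n)
        if cfg.bb_dispersion > 0:
            rho = cfg.bb_dispersion
            a = p * (1.0 - rho) / rho
            b = (1.0 - p) * (1.0 - rho) / rho
            interior = (p > 0) & (p < 1)
            p_draw = p.copy()
            if interior.any():
                p_draw[interior] = rng.beta(a[interior], b[interior])
        else:
            p_draw = p
        meth[:, j] = rng.binomial(cov, p_draw)
        total[:, j] = cov
    return MethylomeMatrix(sites=sites, meth=meth, total=total, samples=samples)


def site_ids(sites: pd.DataFrame) -> list[str]:
    return [f"{c}:{p}:{s}" for c, p, s in zip(sites["contig"], sites["pos"],
                                              sites["strand"])]


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator: annotation, baselines, effects, counts."""
    cfg.validate()
    rng = _rng(cfg.seed)
    genes, sites = generate_annotation(cfg, rng)
    assignment = assign_features(sites, genes)
    baselines = assign_baseline(sites, assignment, cfg, rng)
    if cfg.heavy_low_density_thin > 0 and len(sites):
        keep = _thin_near_heavy(sites, baselines, cfg, rng)
        sites = sites.loc[keep].reset_index(drop=True)
        baselines = baselines[keep]
        assignment = assign_features(sites, genes)
    truth = plant_effects(baselines, cfg, rng, site_ids=site_ids(sites))
    design = make_design(cfg)
    matrix = simulate_counts(sites, baselines, truth, design, cfg, rng)
    return SimResult(config=cfg, genes=genes, assignment=assignment,
                     baselines=baselines, truth=truth, design=design, matrix=matrix)


def _thin_near_heavy(sites, baselines, cfg, rng) -> np.ndarray:
    """Drop a fraction of non-heavy CpGs within 1 kb of heavy ones (density dip)."""
    keep = np.ones(len(sites), dtype=bool)
    for contig, grp in sites.groupby("contig", sort=False):
        pos = grp["pos"].to_numpy()
        idx = grp.index.to_numpy()
        heavy_pos = pos[baselines[idx] > 0.5]
        if len(heavy_pos) == 0:
            continue
        lo = np.searchsorted(heavy_pos, pos - 1000)
        hi = np.searchsorted(heavy_pos, pos + 1000, side="right")
        near = (hi > lo) & (baselines[idx] <= 0.5)
        drop = near & (rng.random(len(pos)) < cfg.heavy_low_density_thin)
        keep[idx[drop]] = False
    return keep


def write_fixture(outdir, sim: SimResult) -> dict[str, Path]:
    """Write cytosine reports, GFF3, sample sheet, and truth table to disk."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {outdir}: {exc}") from exc
    paths: dict[str, Path] = {}
    for sid in sim.matrix.samples:
        p = outdir / f"{sid}.CpG_report.txt"
        write_cytosine_report(matrix_fragment(sim.matrix, sid), p)
        paths[sid] = p
    paths["gff3"] = outdir / "genes.gff3"
    write_gff3(sim.genes, paths["gff3"],
               contig_lengths={f"contig{i + 1}": sim.config.contig_length
                               for i in range(sim.config.n_contigs)})
    paths["samples"] = outdir / "samples.tsv"
    write_sample_sheet(sim.design, paths["samples"])
    paths["truth"] = outdir / "truth.tsv"
    truth = sim.truth.copy()
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["baselines"] = outdir / "baselines.tsv"
    pd.DataFrame({"site_id": site_ids(sim.matrix.sites),
                  "baseline": sim.baselines}).to_csv(paths["baselines"], sep="\t",
                                                     index=False)
    return paths
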