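"""Methylome characterization: global methylation, heavy-site
overrepresentation, CpG density context, metagene landscape, and
repeatability of site-level methylation across replicate controls.

"Heavy" methylation means more than 50% of reads methylated with reads
pooled across the control samples. Global methylation is a per-sample
read-pooled percentage, summarized as mean with a t-based 95% CI across
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import FeatureAssignment
from .matrix import MethylomeMatrix


@dataclass
class GlobalMethylation:
    mean_pct: float
    ci_low: float
    ci_high: float
    per_sample_pct: dict[str, float]


def global_methylation(
    matrix: MethylomeMatrix, samples: Sequence[str], min_reads: int = 10
) -> GlobalMethylation:
    """Genome-wide methylation % per sample (sites with >= min_reads only).

    Per sample the value is 100 * sum(meth) / sum(total) over qualifying
    cells; the summary is the across-sample mean with a t-based 95% CI.
    """
    if len(samples) == 0:
        raise ValueError("global_methylation requires a non-empty sample subset")
    j = matrix.sample_index(samples)
    per_sample = {}
    for sid, jj in zip(samples, j):
        ok = matrix.total[:, jj] >= min_reads
        t = matrix.total[ok, jj].sum()
        m = matrix.meth[ok, jj].sum()
        per_sample[sid] = 100.0 * m / t if t > 0 else np.nan
    vals = np.array(list(per_sample.values()), dtype=float)
    mean = float(np.nanmean(vals))
    k = int(np.sum(~np.isnan(vals)))
    if k >= 2 and np.nanstd(vals, ddof=1) > 0:
        half = stats.t.ppf(0.975, k - 1) * np.nanstd(vals, ddof=1) / np.sqrt(k)
    else:
        half = 0.0
    return GlobalMethylation(mean, mean - half, mean + half, per_sample)


def heavy_site_table_from_counts(
    counts: dict[str, tuple[int, int]], genome_key: str = "genome"
) -> pd.DataFrame:
    """Heavy-site summary from (n_sites, n_heavy) tallies per feature class.

    The odds ratio compares a feature's heavy odds to the whole-genome
    heavy odds (genome including the feature). Rows with empty or
    degenerate tallies get NA statistics.
    """
    if genome_key not in counts:
        raise ValueError(f"counts must include the '{genome_key}' universe")
    gn, gh = counts[genome_key]
    genome_odds = gh / (gn - gh) if 0 < gh < gn else np.nan
    if not np.isfinite(genome_odds):
        warnings.warn("genome heavy odds undefined (all or no sites heavy)")
    rows = []
    for feature, (n, h) in counts.items():
        if n > 0:
            pct = 100.0 * h / n
            odds = h / (n - h) if 0 < h < n else np.nan
            if feature != genome_key and not np.isfinite(odds):
                warnings.warn(f"{feature}: heavy odds undefined")
            oratio = (
                np.nan
                if feature == genome_key
                else (odds / genome_odds if np.isfinite(odds) and np.isfinite(genome_odds)
                      else np.nan)
            )
        else:
            pct, oratio = np.nan, np.nan
        rows.append((feature, n, h, pct, oratio))
    return pd.DataFrame(rows, columns=["feature", "n_sites", "n_heavy", "pct_heavy",
                                       "odds_ratio"]).set_index("feature")


def heavy_site_table(
    matrix: MethylomeMatrix,
    controls: Sequence[str],
    assignment: FeatureAssignment,
    threshold: float = 0.5,
    test: str = "t",
    features: Sequence[str] = ("exon", "intron", "promoter"),
) -> pd.DataFrame:
    """Heavy-site overrepresentation by feature, with per-feature p-values.

    Heaviness at a site means pooled-control methylated reads / total
    reads strictly above ``threshold``. The default test is a paired
    t-test across control samples of the per-sample heavy fraction in the
    feature vs the genome; ``test='fisher'`` instead tests the pooled
    2x2 table (feature vs rest) x (heavy vs not).
    """
    pooled = matrix.pooled_fraction(list(controls))
    covered = ~np.isnan(pooled)
    heavy = covered & (pooled > threshold)
    counts = {"genome": (int(covered.sum()), int(heavy.sum()))}
    masks = {"genome": covered}
    for f in features:
        m = assignment.membership(f) & covered
        masks[f] = m
        counts[f] = (int(m.sum()), int((heavy & m).sum()))
    table = heavy_site_table_from_counts(counts)

    pvals = {}
    j = matrix.sample_index(list(controls))
    frac = matrix.fraction()[:, j]
    for f in features:
        m = masks[f]
        if counts[f][0] == 0:
            pvals[f] = np.nan
            continue
        if test == "t":
            with np.errstate(invalid="ignore"):
                heavy_cells = frac > threshold
            cov_cells = ~np.isnan(frac)
            feat_frac = np.array(
                [_safe_ratio(heavy_cells[m, s].sum(), cov_cells[m, s].sum())
                 for s in range(len(j))]
            )
            gen_frac = np.array(
                [_safe_ratio(heavy_cells[covered, s].sum(), cov_cells[covered, s].sum())
                 for s in range(len(j))]
            )
            ok = ~np.isnan(feat_frac) & ~np.isnan(gen_frac)
            if ok.sum() >= 2 and np.ptp(feat_frac[ok] - gen_frac[ok]) > 0:
                pvals[f] = float(stats.ttest_rel(feat_frac[ok], gen_frac[ok]).pvalue)
            else:
                pvals[f] = np.nan
        elif test == "fisher":
            n_f, h_f = counts[f]
            n_g, h_g = counts["genome"]
            table22 = [[h_f, n_f - h_f], [h_g - h_f, (n_g - n_f) - (h_g - h_f)]]
            pvals[f] = float(stats.fisher_exact(table22)[1])
        else:
            raise ValueError(f"unknown test '{test}'")
    table["p_value"] = pd.Series(pvals)
    return table


def _safe_ratio(a, b) -> float:
    return a / b if b > 0 else np.nan


def cpg_density_profile(
    sites: pd.DataFrame,
    focal: np.ndarray,
    window: int = 1000,
    bin_bp: int = 50,
) -> pd.DataFrame:
    """Density of neighbouring CpGs around focal (e.g. heavy) CpGs.

    Counts neighbours of each focal site per signed-distance bin within
    ``window`` bp either side, normalized per focal site and per bp.
    Returns columns ``bin_center`` and ``density`` (CpGs/bp).
    """
    focal = np.asarray(focal, dtype=bool)
    edges = np.arange(-window, window + bin_bp, bin_bp)
    hist = np.zeros(len(edges) - 1)
    n_focal = 0
    for _, grp in sites.groupby("contig", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        fpos = grp["pos"].to_numpy()[focal[grp.index.to_numpy()]]
        n_focal += len(fpos)
        for p in fpos:
            lo = np.searchsorted(pos, p - window)
            hi = np.searchsorted(pos, p + window, side="right")
            d = pos[lo:hi] - p
            d = d[d != 0]
            hist += np.histogram(d, bins=edges)[0]
    centers = (edges[:-1] + edges[1:]) / 2.0
    if n_focal == 0:
        return pd.DataFrame({"bin_center": centers, "density": np.zeros(len(centers))})
    return pd.DataFrame({"bin_center": centers, "density": hist / n_focal / bin_bp})


ORDINAL_POOL = 11  # exon/intron ordinals 11 and above share one group


def _ordinal_group(feature: str, ordinal: int) -> str:
    if feature in ("exon", "intron"):
        return f"{feature}{min(int(ordinal), ORDINAL_POOL)}" + (
            "+" if ordinal >= ORDINAL_POOL else ""
        )
    return {"promoter": "upstream2kb", "downstream": "downstream2kb"}[feature]


def methylation_landscape(
    matrix: MethylomeMatrix,
    sample: str,
    assignment: FeatureAssignment,
    bin_bp: int = 20,
    max_offset: int = 2000,
    min_reads: int = 1,
    loess_frac: float | None = None,
) -> pd.DataFrame:
    """Mean methylation of CpGs bucketed by feature, ordinal group and offset.

    Offsets are measured from each feature instance's 5' end in the
    direction of transcription and truncated at ``max_offset``. Returns
    columns ``feature`` (upstream2kb, exon1..exon11+, intron1..intron11+,
    downstream2kb), ``offset_bin`` (bp, bin start), ``mean_methylation``
    (%), ``n_cpgs`` and, when ``loess_frac`` is set, a lowess-smoothed
    column per feature.
    """
    j = matrix.sample_index([sample])[0]
    frac = matrix.fraction()[:, j]
    tab = assignment.table
    if len(tab) == 0:
        return pd.DataFrame(columns=["feature", "offset_bin", "mean_methylation", "n_cpgs"])
    site_idx = tab["site_idx"].to_numpy(dtype=int)
    ok = (~np.isnan(frac[site_idx])) & (matrix.total[site_idx, j] >= min_reads) \
        & (tab["offset"].to_numpy() < max_offset)
    sub = tab.loc[ok].copy()
    sub["pct"] = 100.0 * frac[sub["site_idx"].to_numpy(dtype=int)]
    sub["group"] = [_ordinal_group(f, o) for f, o in zip(sub["feature"], sub["ordinal"])]
    sub["offset_bin"] = (sub["offset"] // bin_bp) * bin_bp
    out = (
        sub.groupby(["group", "offset_bin"])["pct"]
        .agg(mean_methylation="mean", n_cpgs="size")
        .reset_index()
        .rename(columns={"group": "feature"})
    )
    if loess_frac is not None:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        smoothed = []
        for _, grp in out.groupby("feature", sort=False):
            if len(grp) >= 3:
                fit = lowess(grp["mean_methylation"], grp["offset_bin"],
                             frac=loess_frac, return_sorted=False)
            else:
                fit = grp["mean_methylation"].to_numpy()
            smoothed.append(pd.Series(fit, index=grp.index))
        out["loess"] = pd.concat(smoothed).sort_index()
    return out


@dataclass
class RepeatabilityResult:
    R: float
    p_value: float
    n_sites: int
    bounds: tuple[float, float]
    n_permutations: int


def _icc(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA intraclass correlation (unbalanced group sizes)."""
    df = pd.DataFrame({"y": values, "g": groups})
    stats_ = df.groupby("g")["y"].agg(["mean", "count"])
    grand = df["y"].mean()
    n_i = stats_["count"].to_numpy(dtype=float)
    k = len(stats_)
    N = n_i.sum()
    if k < 2 or N <= k:
        raise ValueError("repeatability needs >= 2 sites with replicated observations")
    ss_between = float((n_i * (stats_["mean"].to_numpy() - grand) ** 2).sum())
    ss_within = float(((df["y"] - df.groupby("g")["y"].transform("mean")) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (n_i**2).sum() / N) / (k - 1)
    var_between = max((ms_between - ms_within) / n0, 0.0)
    denom = var_between + ms_within
    return var_between / denom if denom > 0 else 0.0


def repeatability(
    matrix: MethylomeMatrix,
    controls: Sequence[str],
    bounds: tuple[float, float] = (1.0, 99.0),
    n_sites: int = 10_000,
    n_perm: int = 499,
    seed: int = 0,
    min_reads: int = 10,
) -> RepeatabilityResult:
    """Among-site variance share of methylation with a permutation null.

    Sites are filtered to pooled-control methylation strictly inside
    ``bounds`` (percent), a random subset of up to ``n_sites`` is taken,
    and R is the one-way variance decomposition of per-sample methylation
    fractions grouped by site. The null permutes site labels within each
    sample; p = (1 + #{R_perm >= R_obs}) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    pooled = 100.0 * matrix.pooled_fraction(list(controls))
    usable = (~np.isnan(pooled)) & (pooled > bounds[0]) & (pooled < bounds[1])
    idx = np.flatnonzero(usable)
    if len(idx) < 2:
        raise ValueError("fewer than 2 sites inside the repeatability bounds")
    if len(idx) > n_sites:
        idx = np.sort(rng.choice(idx, size=n_sites, replace=False))
    j = matrix.sample_index(list(controls))
    frac = matrix.fraction()[np.ix_(idx, j)]
    cov_ok = np.asarray(matrix.total[np.ix_(idx, j)] >= min_reads)
    obs_mask = (~np.isnan(frac)) & cov_ok
    site_of, sample_of = np.nonzero(obs_mask)
    y = frac[obs_mask]
    r_obs = _icc(y, site_of)
    exceed = 0
    for _ in range(n_perm):
        perm_sites = site_of.copy()
        for s in range(len(j)):
            sel = sample_of == s
            perm_sites[sel] = rng.permutation(perm_sites[sel])
        if _icc(y, perm_sites) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return RepeatabilityResult(R=float(r_obs), p_value=float(p), n_sites=len(idx),
                               bounds=bounds, n_permutations=n_perm)
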