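"""Per-CpG differential methylation testing and response classification.

Each pollutant is analyzed separately. Two contrasts share one filtered
site universe: curtox vs the six pooled water controls, and switch vs the
same controls. The site test is a binomial GLM likelihood-ratio test of a
two-level group factor against an intercept-only model; with two groups
this is exactly the G-test on the group-pooled 2x2 count table, which is
what the closed form below computes. p-values are Benjamini-Hochberg
corrected within each (pollutant, contrast) family and sites are classed
as *direct* (curtox only), *persistent* (both) or *legacy* (switch only)
at q < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .matrix import MethylomeMatrix, SampleDesign

RESPONSE_CLASSES = ("direct", "persistent", "legacy")


@dataclass
class ContrastSpec:
    pollutant: str
    treatment_group: list[str]
    control_group: list[str]
    alpha_fdr: float = 0.05

    def __post_init__(self) -> None:
        if set(self.treatment_group) & set(self.control_group):
            raise ValueError("treatment and control groups must be disjoint")
        if not self.treatment_group or not self.control_group:
            raise ValueError("both groups must be non-empty")


# ---------------------------------------------------------------- filters


def filter_coverage(matrix: MethylomeMatrix, min_reads: int = 10) -> MethylomeMatrix:
    """Mask cells with < min_reads total reads; drop sites missing everywhere."""
    total = matrix.total.copy()
    meth = matrix.meth.copy()
    with np.errstate(invalid="ignore"):
        low = total < min_reads
    total[low] = np.nan
    meth[low] = np.nan
    out = MethylomeMatrix(sites=matrix.sites.copy(), meth=meth, total=total,
                          samples=list(matrix.samples))
    keep = ~np.all(np.isnan(out.total), axis=1)
    return out.subset_sites(keep)


def filter_missingness(
    matrix: MethylomeMatrix,
    design: SampleDesign,
    pollutant: str,
    max_missing_control: int = 2,
    max_missing_treatment: int = 1,
) -> np.ndarray:
    """Keep sites with <=2 missing controls and <=1 missing curtox / switch cells."""
    groups = {
        "control": design.controls(),
        "curtox": design.group(pollutant, "curtox"),
        "switch": design.group(pollutant, "switch"),
    }
    for name, ids in groups.items():
        if not ids:
            raise ValueError(f"design has no '{name}' samples for pollutant {pollutant}")
    keep = np.ones(matrix.n_sites, dtype=bool)
    for name, ids in groups.items():
        j = matrix.sample_index(ids)
        n_missing = np.isnan(matrix.total[:, j]).sum(axis=1)
        cap = max_missing_control if name == "control" else max_missing_treatment
        keep &= n_missing <= cap
    return keep


def filter_extremes(
    matrix: MethylomeMatrix,
    samples: Sequence[str],
    low: float = 1.0,
    high: float = 99.0,
) -> np.ndarray:
    """Keep sites whose read-pooled methylation % across samples is in [low, high].

    The removal rule excludes strictly-below-low and strictly-above-high
    sites, so both bounds are kept inclusively.
    """
    pct = 100.0 * matrix.pooled_fraction(list(samples))
    with np.errstate(invalid="ignore"):
        return (~np.isnan(pct)) & (pct >= low) & (pct <= high)


# ---------------------------------------------------------------- site test


def _binomial_loglik(m, t, p) -> np.ndarray:
    return xlogy(m, p) + xlogy(t - m, 1.0 - p)


def pooled_lrt(m1, t1, m0, t0):
    """Vectorized binomial-GLM LRT (== G-test) on group-pooled counts.

    Parameters are per-site pooled methylated/total counts for the
    treatment (1) and control (0) groups. Returns (stat, p, degenerate);
    degenerate sites (a group with zero pooled reads) get stat 0, p 1.
    """
    m1, t1, m0, t0 = (np.asarray(a, dtype=float) for a in (m1, t1, m0, t0))
    degenerate = (t1 <= 0) | (t0 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(t1 > 0, m1 / t1, 0.0)
        p0 = np.where(t0 > 0, m0 / t0, 0.0)
        pp = np.where(t1 + t0 > 0, (m1 + m0) / (t1 + t0), 0.0)
    ll_full = _binomial_loglik(m1, t1, p1) + _binomial_loglik(m0, t0, p0)
    ll_null = _binomial_loglik(m1, t1, pp) + _binomial_loglik(m0, t0, pp)
    stat = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
    stat = np.where(degenerate, 0.0, stat)
    p = np.where(degenerate, 1.0, stats.chi2.sf(stat, df=1))
    return stat, p, degenerate


def test_site(
    meth_counts: Sequence[float],
    total_counts: Sequence[float],
    group_labels: Sequence[int],
) -> float:
    """Binomial GLM likelihood-ratio p-value for one site.

    ``group_labels`` is 0 for control and 1 for treatment samples; NaN
    cells are dropped. The group-factor GLM's LRT reduces to the G-test
    on the pooled 2x2 table, computed in closed form.
    """
    m = np.asarray(meth_counts, dtype=float)
    t = np.asarray(total_counts, dtype=float)
    g = np.asarray(group_labels)
    ok = ~np.isnan(t)
    m, t, g = m[ok], t[ok], g[ok]
    if not ((g == 0).any() and (g == 1).any()):
        raise ValueError("test_site needs >=1 non-missing sample per group")
    _, p, _ = pooled_lrt(m[g == 1].sum(), t[g == 1].sum(),
                         m[g == 0].sum(), t[g == 0].sum())
    return float(p)


def _quasi_f_pvalues(matrix, j_treat, j_ctrl):
    """Per-site quasibinomial F-test using per-sample cells (optional route)."""
    m = np.concatenate([matrix.meth[:, j_treat], matrix.meth[:, j_ctrl]], axis=1)
    t = np.concatenate([matrix.total[:, j_treat], matrix.total[:, j_ctrl]], axis=1)
    grp = np.concatenate([np.ones(len(j_treat)), np.zeros(len(j_ctrl))])
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nansum(np.where(grp == 1, m, np.nan), axis=1)
        t1 = np.nansum(np.where(grp == 1, t, np.nan), axis=1)
        m0 = np.nansum(np.where(grp == 0, m, np.nan), axis=1)
        t0 = np.nansum(np.where(grp == 0, t, np.nan), axis=1)
        p_g = np.where(grp == 1, (m1 / t1)[:, None], (m0 / t0)[:, None])
        p_n = ((m1 + m0) / (t1 + t0))[:, None]

    def dev(p_hat):
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 2.0 * (xlogy(m, m / (t * p_hat)) + xlogy(t - m, (t - m) / (t * (1 - p_hat))))
        return np.nansum(d, axis=1)

    d_full, d_null = dev(p_g), dev(p_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.nansum((m - t * p_g) ** 2 / (t * p_g * (1 - p_g)), axis=1)
    n_cells = np.sum(~np.isnan(t), axis=1)
    df_resid = np.maximum(n_cells - 2, 1)
    disp = np.maximum(pearson / df_resid, 1e-12)
    f = np.clip(d_null - d_full, 0, None) / disp
    return stats.f.sf(f, 1, df_resid)


# ---------------------------------------------------------------- contrasts


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_contrast(
    matrix: MethylomeMatrix,
    contrast: ContrastSpec,
    method: str = "lrt",
) -> pd.DataFrame:
    """Test every site for one contrast; BH-correct within the full set.

    Returns columns ``p``, ``q``, ``delta`` (treatment minus control
    pooled-read percentage points) and ``degenerate``.
    """
    if matrix.n_sites == 0:
        return pd.DataFrame(columns=["p", "q", "delta", "degenerate"])
    j1 = matrix.sample_index(contrast.treatment_group)
    j0 = matrix.sample_index(contrast.control_group)
    m1 = np.nansum(matrix.meth[:, j1], axis=1)
    t1 = np.nansum(matrix.total[:, j1], axis=1)
    m0 = np.nansum(matrix.meth[:, j0], axis=1)
    t0 = np.nansum(matrix.total[:, j0], axis=1)
    if method == "lrt":
        _, p, degenerate = pooled_lrt(m1, t1, m0, t0)
    elif method == "quasi":
        p = _quasi_f_pvalues(matrix, j1, j0)
        degenerate = (t1 <= 0) | (t0 <= 0)
        p = np.where(degenerate, 1.0, p)
    else:
        raise ValueError(f"unknown method '{method}'")
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = 100.0 * (np.where(t1 > 0, m1 / t1, np.nan)
                         - np.where(t0 > 0, m0 / t0, np.nan))
    return pd.DataFrame({"p": p, "q": bh_qvalues(p), "delta": delta,
                         "degenerate": degenerate})


def delta_methylation(
    matrix: MethylomeMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> np.ndarray:
    """Signed pp difference of read-pooled methylation % (a minus b)."""
    fa = matrix.pooled_fraction(list(group_a))
    fb = matrix.pooled_fraction(list(group_b))
    return 100.0 * (fa - fb)


def classify_responses(
    q_curtox: np.ndarray, q_switch: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """direct / persistent / legacy / none from the two contrasts' q-values."""
    q_c = np.asarray(q_curtox, dtype=float)
    q_s = np.asarray(q_switch, dtype=float)
    if q_c.shape != q_s.shape:
        raise ValueError("contrasts were computed on different site universes")
    sig_c, sig_s = q_c < alpha, q_s < alpha
    out = np.full(q_c.shape, "none", dtype=object)
    out[sig_c & ~sig_s] = "direct"
    out[sig_c & sig_s] = "persistent"
    out[~sig_c & sig_s] = "legacy"
    return out


def summarize_deltas(dm_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per (treatment, direction) count/mean/SD of significant deltas.

    Mirrors the study's effect-size table: significant sites are split by
    the sign of their pooled-read delta; zero deltas are excluded from
    both directions. SD uses the n-1 denominator (NA for singletons).
    """
    rows = []
    for treatment in ("curtox", "switch"):
        q = dm_table[f"q_{treatment}"].to_numpy(dtype=float)
        d = dm_table[f"delta_{treatment}"].to_numpy(dtype=float)
        sig = (q < alpha) & ~np.isnan(d)
        for direction, sel in (("+", sig & (d > 0)), ("-", sig & (d < 0))):
            vals = d[sel]
            rows.append(
                (
                    treatment,
                    direction,
                    int(sel.sum()),
                    float(np.mean(vals)) if len(vals) else np.nan,
                    float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                )
            )
    return pd.DataFrame(rows, columns=["treatment", "direction", "n_sites",
                                       "mean_change", "sd_change"])


def run_dm_pollutant(
    matrix: MethylomeMatrix,
    design: SampleDesign,
    pollutant: str,
    min_reads: int = 10,
    low: float = 1.0,
    high: float = 99.0,
    alpha: float = 0.05,
    method: str = "lrt",
    log: list | None = None,
) -> pd.DataFrame:
    """Full per-pollutant DM analysis: filters, both contrasts, classes.

    Filter order is coverage -> missingness -> extremes; the extremes
    percentage is computed over the pollutant's 12 samples after the
    coverage mask. Returns one row per tested site with p/q/delta for
    each contrast and the response class.
    """
    controls = design.controls()
    curtox = design.group(pollutant, "curtox")
    switch = design.group(pollutant, "switch")
    relevant = controls + curtox + switch
    sub = matrix.subset_samples(relevant)

    def note(stage, n):
        if log is not None:
            log.append({"pollutant": pollutant, "stage": stage, "n_sites": int(n)})

    note("input", sub.n_sites)
    sub = filter_coverage(sub, min_reads=min_reads)
    note("coverage", sub.n_sites)
    sub = sub.subset_sites(filter_missingness(sub, design, pollutant))
    note("missingness", sub.n_sites)
    sub = sub.subset_sites(filter_extremes(sub, relevant, low=low, high=high))
    note("extremes", sub.n_sites)

    res_c = run_contrast(sub, ContrastSpec(pollutant, curtox, controls, alpha), method)
    res_s = run_contrast(sub, ContrastSpec(pollutant, switch, controls, alpha), method)
    out = sub.sites.copy()
    out["p_curtox"], out["q_curtox"] = res_c["p"].to_numpy(), res_c["q"].to_numpy()
    out["p_switch"], out["q_switch"] = res_s["p"].to_numpy(), res_s["q"].to_numpy()
    out["delta_curtox"] = res_c["delta"].to_numpy()
    out["delta_switch"] = res_s["delta"].to_numpy()
    jc = sub.sample_index(controls)
    out["control_meth"] = np.nansum(sub.meth[:, jc], axis=1)
    out["control_total"] = np.nansum(sub.total[:, jc], axis=1)
    out["response_class"] = classify_responses(out["q_curtox"], out["q_switch"], alpha)
    out.attrs["pollutant"] = pollutant
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------- ordination


def classical_mds(X: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling of row vectors.

    Computes Euclidean distances between the rows of ``X``, double-centers
    the squared-distance matrix and takes the top-k eigenpairs; coordinates
    are eigenvectors scaled by sqrt(eigenvalue), defined up to rotation and
    reflection. If fewer than k positive eigenvalues exist, k is reduced
    with a warning. Returns (coordinates, eigenvalues_used).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    sq = np.sum(X**2, axis=1)
    d2 = np.clip(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0, None)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > max(evals.max(), 0) * 1e-12 if n else evals > 0
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing k from {k}")
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    return coords, evals[:k]


def mds_input(
    matrix: MethylomeMatrix, dm_any: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-by-site % matrix over DM sites with no missing cells anywhere."""
    complete = ~np.any(np.isnan(matrix.total), axis=1)
    sel = np.asarray(dm_any, dtype=bool) & complete
    frac = matrix.fraction()[sel]
    return 100.0 * frac.T, sel
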