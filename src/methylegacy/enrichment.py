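"""Feature enrichment of DM CpGs, gene-level aggregation, and models of
effect direction and baseline methylation.

Enrichment follows the tested-universe logic: the expected number of DM
CpGs in a feature is the class size scaled by the feature's share of all
tested sites, and a two-sided Fisher exact test (minimum-likelihood
convention) judges over/underrepresentation, BH-corrected within each
pollutant.

Gene aggregation uses the exclusivity rule: a gene is *direct* when all
its DM CpGs are curtox-significant only, *legacy* when switch-only, and
*persistent* when it contains both curtox- and switch-significant CpGs,
even if those CpGs are distinct positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .annotation import FeatureAssignment
from .dm import RESPONSE_CLASSES

ENRICH_FEATURES = ("promoter", "exon", "intron")

# response-type groups for the effect-direction / baseline models
GROUPS = ("curtox-direct", "curtox-persistent", "switch-persistent", "switch-legacy")

FEATURE_DISPLAY = {"exon": "exon", "intron": "intron",
                   "promoter": "5prime2kb", "downstream": "3prime2kb"}


def expected_count(n_dm: int, n_feature_tested: int, n_genome_tested: int) -> float:
    """Expected DM CpGs in a feature from its share of the tested universe."""
    if n_genome_tested <= 0:
        raise ValueError("tested universe must be non-empty")
    if n_feature_tested > n_genome_tested:
        raise ValueError("feature universe cannot exceed the genome universe")
    return n_dm * n_feature_tested / n_genome_tested


def feature_enrichment(
    dm_table: pd.DataFrame,
    assignment: FeatureAssignment,
    features: Sequence[str] = ENRICH_FEATURES,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher-exact over/underrepresentation of each DM class per feature.

    ``assignment`` must be built on the same (filtered) site universe as
    ``dm_table``. Rows are BH-corrected together (one family per
    pollutant's table). Empty classes yield observed 0 and p 1.
    """
    n_universe = len(dm_table)
    classes = dm_table["response_class"].to_numpy()
    rows = []
    for cls in RESPONSE_CLASSES:
        in_class = classes == cls
        n_dm = int(in_class.sum())
        for feature in features:
            in_feat = assignment.membership(feature)
            n_feat = int(in_feat.sum())
            observed = int((in_class & in_feat).sum())
            expected = expected_count(n_dm, n_feat, n_universe)
            table = np.array(
                [
                    [observed, n_dm - observed],
                    [n_feat - observed, (n_universe - n_dm) - (n_feat - observed)],
                ]
            )
            p = 1.0 if n_dm == 0 else float(stats.fisher_exact(table, alternative)[1])
            direction = ("over" if observed > expected
                         else ("under" if observed < expected else "none"))
            rows.append((cls, feature, n_dm, n_feat, observed, expected, p, direction))
    out = pd.DataFrame(
        rows,
        columns=["response_class", "feature", "n_dm_genome", "n_feature_tested",
                 "observed", "expected", "fisher_p", "direction"],
    )
    from .dm import bh_qvalues

    out["fisher_q"] = bh_qvalues(out["fisher_p"].to_numpy())
    return out


def aggregate_genes(
    dm_table: pd.DataFrame,
    assignment: FeatureAssignment,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Collapse DM CpGs onto genes and class each gene.

    Every feature label (promoter, exon, intron, downstream) attributes
    its CpG to the owning gene; intergenic CpGs attribute to none. Genes
    whose DM CpGs include both curtox- and switch-significant positions
    are persistent regardless of whether the positions coincide.
    """
    sig_c = dm_table["q_curtox"].to_numpy() < alpha
    sig_s = dm_table["q_switch"].to_numpy() < alpha
    gene_sets = assignment.gene_sets()
    genes_c: set[str] = set()
    genes_s: set[str] = set()
    for i in np.flatnonzero(sig_c | sig_s):
        genes = gene_sets.get(int(i), set())
        if sig_c[i]:
            genes_c |= genes
        if sig_s[i]:
            genes_s |= genes
    rows = [(g, "persistent") for g in genes_c & genes_s]
    rows += [(g, "direct") for g in genes_c - genes_s]
    rows += [(g, "legacy") for g in genes_s - genes_c]
    return pd.DataFrame(sorted(rows), columns=["gene_id", "gene_class"])


def overlap_sets(sets: Mapping[str, set]) -> dict:
    """Exact region counts and pairwise Jaccard for up to three sets."""
    names = list(sets)
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo)) if combo else set()
            outside = set.union(*(set(sets[n]) for n in names if n not in combo), set())
            regions["&".join(combo)] = len(inside - outside)
    jaccard = {}
    for a, b in combinations(names, 2):
        union = len(set(sets[a]) | set(sets[b]))
        jaccard[f"{a}|{b}"] = len(set(sets[a]) & set(sets[b])) / union if union else np.nan
    return {"regions": regions, "jaccard": jaccard}


# ----------------------------------------------- effect-direction model


def _dm_observations(
    dm_table: pd.DataFrame,
    assignment: FeatureAssignment,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per (DM CpG, feature label): response group, feature, deltas.

    Persistent CpGs contribute to both the curtox-persistent and
    switch-persistent groups, with the delta of the matching treatment.
    """
    cls = dm_table["response_class"].to_numpy()
    tab = assignment.table
    feat_per_site: dict[int, set[str]] = {}
    for sid, feat in zip(tab["site_idx"], tab["feature"]):
        feat_per_site.setdefault(int(sid), set()).add(feat)
    rows = []
    for i in np.flatnonzero(cls != "none"):
        feats = feat_per_site.get(int(i))
        if not feats:
            continue  # intergenic DM CpGs are outside the gene-feature models
        groups = {
            "direct": (("curtox-direct", "delta_curtox"),),
            "persistent": (("curtox-persistent", "delta_curtox"),
                           ("switch-persistent", "delta_switch")),
            "legacy": (("switch-legacy", "delta_switch"),),
        }[cls[i]]
        for feat in sorted(feats):
            for group, delta_col in groups:
                rows.append(
                    (int(i), group, FEATURE_DISPLAY[feat],
                     float(dm_table[delta_col].iloc[i]))
                )
    return pd.DataFrame(rows, columns=["site_idx", "response_type", "feature", "delta"])


def _marginal_means(result, obs: pd.DataFrame, factor: str, over: str,
                    scale_mult: float = 1.0):
    """Equal-weight least-squares means of one factor averaged over another."""
    from patsy import build_design_matrices

    design_info = result.model.data.design_info
    present = obs.groupby([factor, over]).size().reset_index()[[factor, over]]
    cov = result.cov_params()
    df_resid = getattr(result, "df_resid", np.inf)
    rows = []
    for level in obs[factor].unique():
        cells = present[present[factor] == level]
        if cells.empty:
            rows.append((level, np.nan, np.nan, np.nan, False, False))
            continue
        grid = pd.DataFrame({factor: level, over: cells[over].to_numpy()})
        X = np.asarray(build_design_matrices([design_info], grid)[0])
        a = X.mean(axis=0)
        est = float(a @ result.params)
        se = float(np.sqrt(a @ cov @ a)) * np.sqrt(scale_mult)
        tcrit = stats.t.ppf(0.975, df_resid) if np.isfinite(df_resid) else 1.959964
        lo, hi = est - tcrit * se, est + tcrit * se
        rows.append((level, est, lo, hi, bool(lo > 0 or hi < 0), True))
    return pd.DataFrame(rows, columns=[factor, "estimate", "ci_low", "ci_high",
                                       "differs_from_zero", "estimable"])


def fit_delta_model(obs: pd.DataFrame):
    """OLS of delta on response type x feature from an observation frame.

    ``obs`` needs columns ``response_type``, ``feature``, ``delta``.
    Returns (marginal means per response type, marginal means per
    feature, type-II ANOVA table). Marginal means average the factor
    grid with equal weights over the other factor's estimable levels.
    """
    if obs.empty:
        raise ValueError("no observations; nothing to model")
    model = smf.ols("delta ~ C(response_type) * C(feature)", data=obs)
    result = model.fit()
    from statsmodels.stats.anova import anova_lm

    try:
        anova = anova_lm(result, typ=2)
    except Exception:  # rank-deficient designs fall back to type-I
        anova = anova_lm(result, typ=1)
    by_type = _marginal_means(result, obs, "response_type", "feature")
    by_feature = _marginal_means(result, obs, "feature", "response_type")
    return by_type, by_feature, anova


def delta_by_class_model(
    dm_table: pd.DataFrame,
    assignment: FeatureAssignment,
    alpha: float = 0.05,
):
    """OLS of delta methylation on response type x gene feature (see
    :func:`fit_delta_model`) over one pollutant's DM CpGs."""
    obs = _dm_observations(dm_table, assignment, alpha)
    if obs.empty:
        raise ValueError("no DM CpGs in gene features; nothing to model")
    return fit_delta_model(obs)


def fit_control_model(obs: pd.DataFrame):
    """Quasibinomial logit GLM of pooled counts on response type + feature.

    ``obs`` needs columns ``response_type``, ``feature``, ``meth``,
    ``unmeth``. Dispersion is Pearson chi2 / df with the binomial trial
    counts folded in, and scales all Wald covariance. Returns (marginal
    means with logit and % columns, pairwise response-type contrasts on
    the logit scale, dispersion estimate).
    """
    if obs.empty:
        raise ValueError("no observations; nothing to model")
    model = smf.glm(
        "meth + unmeth ~ C(response_type) + C(feature)",
        data=obs,
        family=sm.families.Binomial(),
    )
    fit0 = model.fit()
    # Pearson chi2 with the binomial trial counts folded in (statsmodels'
    # own X2 scale ignores n for two-column endog)
    n_trials = (obs["meth"] + obs["unmeth"]).to_numpy(dtype=float)
    y = obs["meth"].to_numpy(dtype=float) / n_trials
    mu = np.asarray(fit0.fittedvalues, dtype=float)
    df_resid = max(len(obs) - len(fit0.params), 1)
    dispersion = float(np.sum(n_trials * (y - mu) ** 2 / (mu * (1.0 - mu))) / df_resid)
    result = model.fit(scale=dispersion)
    marg = _marginal_means(result, obs, "response_type", "feature")
    # transform logit-scale means to percent
    for col in ("estimate", "ci_low", "ci_high"):
        marg[f"{col}_pct"] = 100.0 / (1.0 + np.exp(-marg[col]))
    # pairwise contrasts on the logit scale
    from patsy import build_design_matrices

    design_info = result.model.data.design_info
    present = obs.groupby(["response_type", "feature"]).size().reset_index()
    cov = result.cov_params()
    reps = {}
    for level in obs["response_type"].unique():
        cells = present[present["response_type"] == level]
        grid = pd.DataFrame({"response_type": level, "feature": cells["feature"].to_numpy()})
        X = np.asarray(build_design_matrices([design_info], grid)[0])
        reps[level] = X.mean(axis=0)
    pairs = []
    for a, b in combinations(list(reps), 2):
        separation = _separated(obs, a) or _separated(obs, b)
        la = reps[a] - reps[b]
        est = float(la @ result.params)
        se = float(np.sqrt(la @ cov @ la))
        lo, hi = est - 1.959964 * se, est + 1.959964 * se
        pairs.append((a, b, est, lo, hi, not separation))
    pairwise = pd.DataFrame(pairs, columns=["group_a", "group_b", "logit_diff",
                                            "ci_low", "ci_high", "estimable"])
    return marg, pairwise, dispersion


def control_methylation_model(
    dm_table: pd.DataFrame,
    assignment: FeatureAssignment,
    alpha: float = 0.05,
):
    """Baseline-methylation model of DM CpGs in controls (see
    :func:`fit_control_model`); the response per observation is the DM
    table's pooled control ``control_meth`` / ``control_total`` reads."""
    obs = _dm_observations(dm_table, assignment, alpha)
    if obs.empty:
        raise ValueError("no DM CpGs in gene features; nothing to model")
    m = dm_table["control_meth"].to_numpy(dtype=float)
    t = dm_table["control_total"].to_numpy(dtype=float)
    obs = obs[t[obs["site_idx"]] > 0].copy()
    obs["meth"] = m[obs["site_idx"]]
    obs["unmeth"] = (t - m)[obs["site_idx"]]
    return fit_control_model(obs)


def _separated(obs: pd.DataFrame, group: str) -> bool:
    sub = obs[obs["response_type"] == group]
    return bool(sub["meth"].sum() == 0 or sub["unmeth"].sum() == 0)
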