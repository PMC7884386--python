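"""Fire-response trait classification and the downstream statistics.

Trait side: species are crossed on two binary traits — resprouting ability
(R+/R-) and propagule persistence (P+/P-) — into four fire-response types
(facultative, obligate resprouter, obligate seeder, non-persister); any
species with at least one positive trait counts as a fire persister.  A
conceptual framework then places species into Types A-E by range size
(restricted vs widespread), persistence and habitat fire history.

Statistics side: the battery applied to the per-species impact table —
Kruskal-Wallis rank-sum tests with pairwise Wilcoxon rank-sum post hocs
under Benjamini-Hochberg adjustment, linear quantile regression of
proportion burnt on range extent with rank-based slope confidence
intervals, one-way ANOVA (log10(x+1) transform) with Tukey HSD, Pearson
chi-square contingency tests, and distribution shape (moment skewness and
Shapiro-Wilk W).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.quantile_regression import QuantReg
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Trait vocabularies
# ---------------------------------------------------------------------------

LIFE_FORMS = ("AF", "GF", "PF", "AG", "PG", "LS", "MS", "TS", "LT", "MT",
              "TT", "CL", "EP", "SFC", "TFC", "AQ")

RF_CLASSES = ("RFPP", "RFP", "RFM", "RFN")  # RF++, RF+, RF, RF-

HABITAT_FLAGS = ("sclerophyll", "heath_shrubland", "rocky", "gully_gorge",
                 "swamp", "other")

FACULTATIVE = "FACULTATIVE"            # R+P+
OBLIGATE_RESPROUTER = "OBLIGATE_RESPROUTER"  # R+P-
OBLIGATE_SEEDER = "OBLIGATE_SEEDER"    # R-P+
NON_PERSISTER = "NON_PERSISTER"        # R-P-
UNKNOWN = "UNKNOWN"

#: Broader life-form groupings used for the range-class contingency test.
LIFE_FORM_GROUPS = {
    "LS": "low_shrubs", "MS": "medium_shrubs", "TS": "tall_shrubs",
    "LT": "trees", "MT": "trees", "TT": "trees",
    "GF": "perennial_forbs", "PF": "perennial_forbs",
}
OTHER_GROUP = "other"


@dataclass
class FireResponse:
    response_type: str
    persister: bool | None  # None when neither trait is known


def classify_fire_response(resprouter: str, propagule_persister: str) -> FireResponse:
    """Cross R+/R- and P+/P- into a fire-response type.

    ``resprouter`` and ``propagule_persister`` take values 'Rplus'/'Rminus'
    and 'Pplus'/'Pminus' or 'unknown'.  With partial data the type is
    UNKNOWN but a positive known trait already makes the species a
    persister; a negative known trait alone cannot settle persistence.
    """
    r = {"Rplus": True, "Rminus": False}.get(resprouter)
    p = {"Pplus": True, "Pminus": False}.get(propagule_persister)
    if r is not None and p is not None:
        if r and p:
            return FireResponse(FACULTATIVE, True)
        if r and not p:
            return FireResponse(OBLIGATE_RESPROUTER, True)
        if not r and p:
            return FireResponse(OBLIGATE_SEEDER, True)
        return FireResponse(NON_PERSISTER, False)
    known = r if r is not None else p
    if known is None:
        return FireResponse(UNKNOWN, None)
    return FireResponse(UNKNOWN, True if known else None)


def classify_framework_type(re_t_km: float, persister: bool,
                            fire_history: str,
                            restricted_max_km: float = 100.0,
                            widespread_min_km: float = 500.0) -> str | None:
    """Place a species in the range x persistence x fire-history framework.

    A = restricted persister in fire-prone habitat; D = widespread persister
    in fire-prone habitat; B = persister in infrequently burnt habitat
    (any range); C/E = restricted/widespread non-persister.  Species with
    intermediate ranges where the dichotomy matters are left unclassified.
    """
    if fire_history not in ("frequent", "infrequent"):
        raise ValueError("fire_history must be 'frequent' or 'infrequent'")
    restricted = re_t_km < restricted_max_km
    widespread = re_t_km >= widespread_min_km
    if persister:
        if fire_history == "infrequent":
            return "B"
        if restricted:
            return "A"
        if widespread:
            return "D"
    else:
        if restricted:
            return "C"
        if widespread:
            return "E"
    logger.info("framework type unresolved (re_t=%.1f km, persister=%s, %s)",
                re_t_km, persister, fire_history)
    return None


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    test: str
    statistic: float
    df: object
    p_value: float
    n: dict = field(default_factory=dict)
    adjustment: str = "none"
    extras: dict = field(default_factory=dict)


def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    arrays = [values[groups == g] for g in labels]
    return labels, arrays


def test_group_differences(values, groups, pairwise: bool = False) -> list[StatResult]:
    """Kruskal-Wallis rank-sum test (tie-corrected), optionally followed by
    pairwise two-sided Wilcoxon rank-sum tests with BH adjustment."""
    labels, arrays = _group_arrays(values, groups)
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    try:
        with np.errstate(invalid="ignore"):
            h, p = stats.kruskal(*arrays)
    except ValueError:
        h, p = np.nan, np.nan
    if np.isnan(h):  # all observations identical: no rank variation
        h, p = 0.0, 1.0
    results = [StatResult(
        test="kruskal_wallis", statistic=float(h), df=len(arrays) - 1,
        p_value=float(p), n={str(g): int(a.size) for g, a in zip(labels, arrays)},
        extras={"medians": {str(g): float(np.median(a))
                            for g, a in zip(labels, arrays)}})]
    if pairwise:
        pairs, raw = [], []
        for (gi, ai), (gj, aj) in itertools.combinations(zip(labels, arrays), 2):
            exact = (ai.size + aj.size <= 20
                     and np.unique(np.concatenate([ai, aj])).size == ai.size + aj.size)
            res = stats.mannwhitneyu(ai, aj, alternative="two-sided",
                                     method="exact" if exact else "asymptotic")
            pairs.append((gi, gj, float(res.statistic)))
            raw.append(float(res.pvalue))
        adj = benjamini_hochberg(raw)
        for (gi, gj, u), p_raw, p_adj in zip(pairs, raw, adj):
            results.append(StatResult(
                test="wilcoxon_rank_sum", statistic=u, df=None,
                p_value=p_adj, n={str(gi): None, str(gj): None},
                adjustment="BH", extras={"pair": (str(gi), str(gj)),
                                         "p_raw": p_raw}))
    return results


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p values (monotone, never below the raw p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _rank_score_stat(x, resid, tau):
    """Regression rank-score statistic for H0 at the given slope."""
    q = np.quantile(resid, tau, method="inverted_cdf")
    a = tau - (resid < q)
    xc = x - x.mean()
    denom = np.sqrt(tau * (1 - tau) * np.sum(xc ** 2))
    return float(np.sum(xc * a) / denom)


def rank_ci_slope(x, y, tau, alpha: float = 0.05,
                  tol: float = 1e-6) -> tuple[float, float]:
    """Confidence interval for the slope by inverting the quantile
    rank-score test (the rank method of classical quantile regression):
    a candidate slope b is in the interval when the rank-score statistic of
    the residuals y - b x stays within the normal alpha/2 bounds."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = stats.norm.ppf(1 - alpha / 2)
    scale = (np.std(y) / np.std(x)) if np.std(x) > 0 else 1.0
    scale = max(scale, 1e-9)

    def stat(b):
        return _rank_score_stat(x, y - b * x, tau)

    with np.errstate(divide="ignore", invalid="ignore"):
        b0 = float(QuantReg(y, np.column_stack([np.ones_like(x), x]))
                   .fit(q=tau).params[1])

    def search(direction):
        # the statistic decreases as b grows; find where it crosses +/-z
        lo = b0
        step = max(abs(b0), scale) * 0.5
        target = -z if direction > 0 else z
        hi = b0 + direction * step
        for _ in range(200):
            if direction * (stat(hi) - target) <= 0:
                break
            hi += direction * step
            step *= 2.0
        else:  # unbounded in this direction
            return direction * np.inf
        a, b = (lo, hi) if direction > 0 else (hi, lo)
        for _ in range(200):
            mid = 0.5 * (a + b)
            if stat(mid) > target if direction > 0 else stat(mid) >= target:
                a = mid
            else:
                b = mid
            if b - a < tol * max(1.0, abs(b0)):
                break
        return b if direction > 0 else a

    return search(-1), search(+1)


def quantile_pf_range(re_t, pf_m, taus=None, alpha: float = 0.05) -> pd.DataFrame:
    """Linear quantile regression of proportion burnt on range extent.

    One row per quantile tau with the fitted slope and intercept, the
    rank-based slope confidence interval and a significance flag (interval
    excluding zero).  Requires >= 20 observations and non-constant x.
    """
    x = np.asarray(re_t, dtype=float)
    y = np.asarray(pf_m, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 observations")
    if np.std(x) == 0:
        raise ValueError("degenerate regressor: constant range extent")
    taus = np.round(np.arange(0.1, 0.91, 0.1), 10) if taus is None else taus
    X = np.column_stack([np.ones_like(x), x])
    rows = []
    for tau in taus:
        with np.errstate(divide="ignore", invalid="ignore"):
            fit = QuantReg(y, X).fit(q=float(tau))
        lo, hi = rank_ci_slope(x, y, float(tau), alpha=alpha)
        rows.append({"tau": float(tau), "intercept": float(fit.params[0]),
                     "slope": float(fit.params[1]), "ci_low": lo, "ci_high": hi,
                     "significant": bool(lo > 0 or hi < 0)})
    return pd.DataFrame(rows)


def distribution_shape(values) -> StatResult:
    """Moment skewness g1 = m3 / m2^(3/2) and the Shapiro-Wilk W test."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    skew = float(stats.skew(v, bias=True))
    w, p = stats.shapiro(v)
    return StatResult(test="shapiro_wilk", statistic=float(w), df=None,
                      p_value=float(p), n={"all": int(v.size)},
                      extras={"skewness": skew})


def contingency_test(table) -> StatResult:
    """Pearson chi-square for an r x c count table (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return StatResult(test="pearson_chi2", statistic=float(chi2), df=int(df),
                      p_value=float(p), n={"total": int(t.sum())})


def anova_tukey(values, groups, transform=lambda v: np.log10(v + 1.0)) -> StatResult:
    """One-way ANOVA on transformed values with a Tukey HSD post hoc table.

    The default log10(x + 1) transform stabilises the strong right skew of
    range extents before the F test.
    """
    labels, arrays = _group_arrays(values, groups)
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    t_arrays = [transform(a) for a in arrays]
    f, p = stats.f_oneway(*t_arrays)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    tv = np.concatenate(t_arrays)
    tg = np.concatenate([np.repeat(str(g), a.size) for g, a in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(tv, tg)
    tukey_df = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])
    return StatResult(test="anova_oneway", statistic=float(f),
                      df=(k - 1, n_total - k), p_value=float(p),
                      n={str(g): int(a.size) for g, a in zip(labels, arrays)},
                      extras={"tukey": tukey_df})


# Alias matching the analysis of range extent across rainforest classes.
anova_rf = anova_tukey


# ---------------------------------------------------------------------------
# Reporting over the species-impact table
# ---------------------------------------------------------------------------

#: Range-extent bins (km) for the proportion-burnt comparison.
EIGHT_RANGE_BINS = (0, 10, 25, 100, 250, 500, 750, 1000, np.inf)

#: Collapsed range classes for the life-form contingency test (km bounds).
FOUR_RANGE_BINS = {"lt25": (0, 25), "25_100": (25, 100),
                   "100_500": (100, 500), "gt500": (500, np.inf)}


def life_form_group(code: str) -> str:
    return LIFE_FORM_GROUPS.get(code, OTHER_GROUP)


def _bin_range(re_t, bins=EIGHT_RANGE_BINS):
    idx = np.digitize(np.asarray(re_t, dtype=float), bins[1:-1], right=False)
    return idx  # 0..len(bins)-2


def species_report(species: pd.DataFrame,
                   traits: pd.DataFrame | None = None,
                   quantiles: bool = True) -> dict:
    """Recompute the headline species counts and test statistics from a
    per-species impact table (and optionally a trait table).

    ``species`` needs columns taxon, pf_sr, pf_br, pf_sdm (NaN allowed),
    pf_m, support_class, high_impact, re_t_km, endemism; ``traits`` adds
    life_form, rf_class, resprouter, propagule_persister.  Returns a dict
    of summary counts and :class:`StatResult`/DataFrame objects.
    """
    rep: dict = {}
    high = species[species["high_impact"].astype(bool)]
    rep["n_high_impact"] = int(len(high))
    sc = high["support_class"].dropna().astype(int)
    rep["support_class_counts"] = sc.value_counts().sort_index().to_dict()
    rep["n_multi_support"] = int((sc >= 4).sum())
    rep["endemism_counts"] = high["endemism"].value_counts().to_dict()

    endemic = high[high["endemism"] == "ENDEMIC"]
    rep["n_endemic_high_impact"] = int(len(endemic))
    if 3 <= len(endemic) <= 5000:
        rep["range_shape"] = distribution_shape(endemic["re_t_km"])
    if len(endemic) >= 20:
        bins = _bin_range(endemic["re_t_km"])
        present = np.unique(bins)
        if present.size >= 2:
            rep["kw_pf_by_range_class"] = test_group_differences(
                endemic["pf_m"], bins)[0]
        if quantiles and np.std(endemic["re_t_km"]) > 0:
            rep["quantile_regression"] = quantile_pf_range(
                endemic["re_t_km"], endemic["pf_m"])

    if traits is not None:
        merged = high.merge(traits, on="taxon", how="inner")
        if "rf_class" in merged and merged["rf_class"].nunique() >= 2:
            rep["kw_pf_by_rf_class"] = test_group_differences(
                merged["pf_m"], merged["rf_class"], pairwise=True)
            if (merged.groupby("rf_class")["re_t_km"].size() >= 2).all():
                rep["anova_re_by_rf_class"] = anova_tukey(
                    merged["re_t_km"].to_numpy(), merged["rf_class"].to_numpy())
        if "life_form" in merged and merged["life_form"].nunique() >= 2:
            rep["kw_re_by_life_form"] = test_group_differences(
                merged["re_t_km"], merged["life_form"])[0]
            groups = merged["life_form"].map(life_form_group)
            rbin = pd.cut(merged["re_t_km"], [0, 25, 100, 500, np.inf],
                          right=False, labels=list(FOUR_RANGE_BINS))
            ct = pd.crosstab(groups, rbin)
            ct = ct.loc[(ct.sum(axis=1) > 0), (ct.sum(axis=0) > 0)]
            if ct.shape[0] >= 2 and ct.shape[1] >= 2:
                rep["contingency_lifeform_range"] = contingency_test(ct.to_numpy())
        if {"resprouter", "propagule_persister"} <= set(merged.columns):
            responses = [classify_fire_response(r, p) for r, p in
                         zip(merged["resprouter"], merged["propagule_persister"])]
            known = [fr for fr in responses if fr.persister is not None]
            rep["n_fire_response_known"] = len(known)
            rep["n_persisters"] = sum(fr.persister for fr in known)
            rep["persister_pct"] = (100.0 * rep["n_persisters"] / len(known)
                                    if known else None)
            rep["response_type_counts"] = pd.Series(
                [fr.response_type for fr in responses]).value_counts().to_dict()
    return rep
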