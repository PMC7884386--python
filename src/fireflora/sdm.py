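"""Presence-background species distribution modelling and burn fractions.

The estimated-range route to a species burn fraction: fit a presence-
background model on 21 environmental predictors (a penalised binomial
model on linear + quadratic features of the standardised predictors, with
the complementary log-log link mapping the linear predictor to a [0, 1]
occurrence scale), binarise the predicted surface at three training-data
thresholds —

* ``kappa_t``: maximises Cohen's kappa of presence vs background,
* ``mtss_t``: maximises training sensitivity + specificity,
* ``p10_t``:  tenth-percentile training presence (fixes presence omission
  at no more than 10%),

— and overlay each binary range with the fire layer to obtain PF_K,
PF_MTSS and PF_10.  Kappa-based ranges with a training true-positive rate
below 0.80 are discarded.  When PF_MTSS exceeds both PF_K and PF_10 by at
least 0.2 the estimates are flagged discordant and a deterministic review
policy (default: fall back to the kappa estimate) replaces case-by-case
visual inspection.  PF_SDM then joins the two direct estimates:
PF_M = max(PF_SR, PF_BR, PF_SDM), with a support class 1-7 recording which
estimates individually exceed 0.50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .fire_layer import FireLayer, GridSpec

logger = logging.getLogger(__name__)

#: Canonical predictor codes: 11 bioclimatic, 4 evaporation/water-deficit,
#: 6 soil/landform variables.
ENV_VARIABLES = (
    "Bio04", "Bio05", "Bio06", "Bio10", "Bio11", "Bio12", "Bio15", "Bio17",
    "Bio28", "Bio31", "Bio32", "EAA", "EPI", "WDI", "WDX",
    "CLY", "SND", "NTO", "PTO", "BDW", "TWI3S",
)

MIN_UNIQUE_PRESENCES = 10
TPR_MIN = 0.80
DISCORDANCE_MARGIN = 0.2


class SDMRefusal(ValueError):
    """Raised when a model cannot responsibly be fitted for a taxon."""


@dataclass
class EnvStack:
    """Named predictor grids sharing one equal-area grid."""

    layers: dict[str, np.ndarray]
    grid: GridSpec

    def __post_init__(self):
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError("all predictor layers must share one shape")
        if shapes.pop() != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("layer shape does not match the grid")
        for name, a in self.layers.items():
            if not np.isfinite(a).any():
                raise ValueError(f"layer {name} has no finite values")
        self._design = None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def finite_mask(self) -> np.ndarray:
        m = np.ones((self.grid.n_rows, self.grid.n_cols), dtype=bool)
        for a in self.layers.values():
            m &= np.isfinite(a)
        return m

    def design_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, finite_flat): standardised linear + quadratic features for
        every grid cell (rows = cells in C order), cached after first use."""
        if self._design is None:
            stack = np.stack([a.astype(np.float64).ravel()
                              for a in self.layers.values()], axis=1)
            finite = np.isfinite(stack).all(axis=1)
            mu = np.nanmean(np.where(finite[:, None], stack, np.nan), axis=0)
            sd = np.nanstd(np.where(finite[:, None], stack, np.nan), axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            z = (stack - mu) / sd
            X = np.concatenate([z, z ** 2], axis=1).astype(np.float32)
            X[~finite] = 0.0
            self._design = (X, finite)
        return self._design

    def zero_variance(self) -> bool:
        _, finite = self.design_matrix()
        stack = np.stack([a.ravel() for a in self.layers.values()], axis=1)
        return bool(np.all(np.nanstd(stack[finite], axis=0) == 0))


@dataclass
class SDMConfig:
    n_background: int = 10_000
    regularisation_c: float = 1.0
    max_iter: int = 500
    policy: str = "max_valid"  # | mtss_only | kappa_only


@dataclass
class SDMResult:
    taxon: str
    prob_surface: np.ndarray           # [0,1] on the env grid, NaN off-mask
    presence_cells: np.ndarray         # flat indices of presence cells
    background_cells: np.ndarray       # flat indices of background cells
    thresholds: dict = field(default_factory=dict)
    tpr_kappa: float | None = None
    pf_k: float | None = None
    pf_mtss: float | None = None
    pf_10: float | None = None
    pf_sdm: float | None = None
    flags: dict = field(default_factory=lambda: {
        "kappa_invalid": False, "discordant": False,
        "manual_policy_applied": False})


# ---------------------------------------------------------------------------
# Background sampling and model fit
# ---------------------------------------------------------------------------

def sample_background(env: EnvStack, n: int = 10_000,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Flat cell indices of n background points drawn uniformly (with
    replacement) from cells with finite predictors."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    _, finite = env.design_matrix()
    idx = np.flatnonzero(finite)
    if idx.size == 0:
        raise ValueError("no cells with finite predictors")
    return rng.choice(idx, size=n, replace=True)


def presence_cells_from_lonlat(lons, lats, env: EnvStack) -> np.ndarray:
    """Unique presence locations -> flat env-grid cell indices (on-mask only)."""
    uniq = {(float(lo), float(la)) for lo, la in zip(lons, lats)}
    lo = np.array([p[0] for p in sorted(uniq)])
    la = np.array([p[1] for p in sorted(uniq)])
    row, col = env.grid.lonlat_to_rowcol(lo, la)
    inside = env.grid.inside(row, col)
    flat = row[inside] * env.grid.n_cols + col[inside]
    _, finite = env.design_matrix()
    return flat[finite[flat]]


def fit_sdm(taxon: str, presence_flat: np.ndarray, env: EnvStack,
            background_flat: np.ndarray,
            config: SDMConfig | None = None) -> SDMResult:
    """Fit the presence-background model and predict the occurrence surface.

    ``presence_flat`` must carry one entry per unique presence location
    (repeated cells allowed when distinct locations share a cell).  Refuses
    with :class:`SDMRefusal` below 10 unique locations or when every
    predictor is constant over the mask.
    """
    cfg = config or SDMConfig()
    if presence_flat.size < MIN_UNIQUE_PRESENCES:
        raise SDMRefusal(
            f"{taxon}: {presence_flat.size} unique locations "
            f"(minimum {MIN_UNIQUE_PRESENCES})")
    if env.zero_variance():
        raise SDMRefusal(f"{taxon}: predictors have zero variance everywhere")
    X, finite = env.design_matrix()
    Xy = np.concatenate([X[presence_flat], X[background_flat]])
    y = np.concatenate([np.ones(presence_flat.size), np.zeros(background_flat.size)])
    model = LogisticRegression(C=cfg.regularisation_c, max_iter=cfg.max_iter)
    model.fit(Xy, y)
    eta = X @ model.coef_[0] + model.intercept_[0]
    prob = 1.0 - np.exp(-np.exp(np.clip(eta, -30.0, 30.0)))  # cloglog scale
    surface = np.full(X.shape[0], np.nan)
    surface[finite] = prob[finite]
    return SDMResult(
        taxon=taxon,
        prob_surface=surface.reshape(env.grid.n_rows, env.grid.n_cols),
        presence_cells=np.asarray(presence_flat),
        background_cells=np.asarray(background_flat))


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def _confusion_curve(presence_scores, background_scores, candidates):
    ps = np.sort(presence_scores)
    bs = np.sort(background_scores)
    n_p, n_b = ps.size, bs.size
    tp = n_p - np.searchsorted(ps, candidates, side="left")
    fp = n_b - np.searchsorted(bs, candidates, side="left")
    fn = n_p - tp
    tn = n_b - fp
    return tp, fp, fn, tn


def cohen_kappa(tp, fp, fn, tn):
    """Cohen's kappa from confusion counts (vectorised)."""
    tp, fp, fn, tn = (np.asarray(a, dtype=float) for a in (tp, fp, fn, tn))
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(pe < 1.0, (po - pe) / (1.0 - pe), 0.0)
    return kappa


def p10_threshold(presence_scores) -> float:
    """Largest threshold whose strict-below presence omission is <= 10%.

    Lower-value (inverted-CDF style) percentile: with n distinct scores the
    threshold is the (floor(0.1 n) + 1)-th smallest score, so exactly
    floor(0.1 n) presences fall below it; ties sit at, not below, the
    threshold and are therefore kept.
    """
    s = np.sort(np.asarray(presence_scores, dtype=float))
    k = int(np.floor(0.1 * s.size))
    return float(s[min(k, s.size - 1)])


def compute_thresholds(result: SDMResult) -> SDMResult:
    """Brute-force kappa and MTSS maximisation over all candidate thresholds
    (the unique scored values plus infinite sentinels; ties resolve to the
    smallest maximiser), plus the P10 threshold and the kappa-range TPR."""
    surf = result.prob_surface.ravel()
    p_scores = surf[result.presence_cells]
    b_scores = surf[result.background_cells]
    candidates = np.unique(np.concatenate(
        [p_scores, b_scores, [-np.inf, np.inf]]))
    tp, fp, fn, tn = _confusion_curve(p_scores, b_scores, candidates)
    kappas = cohen_kappa(tp, fp, fn, tn)
    mtss = tp / p_scores.size + tn / b_scores.size
    kappa_t = float(candidates[int(np.argmax(kappas))])
    mtss_t = float(candidates[int(np.argmax(mtss))])
    result.thresholds = {"kappa_t": kappa_t, "mtss_t": mtss_t,
                         "p10_t": p10_threshold(p_scores)}
    result.tpr_kappa = float(np.mean(p_scores >= kappa_t))
    result.flags["kappa_invalid"] = result.tpr_kappa < TPR_MIN
    return result


# ---------------------------------------------------------------------------
# Burn fractions of binary ranges
# ---------------------------------------------------------------------------

def env_cell_burnt_mask(env: EnvStack, layer: FireLayer) -> np.ndarray:
    """Boolean env-grid raster: env cell centre falls in a burnt fire cell."""
    xs, ys = env.grid.cell_centres()
    row, col = layer.grid.xy_to_rowcol(xs.ravel(), ys.ravel())
    inside = layer.grid.inside(row, col)
    burnt = np.zeros(row.size, dtype=bool)
    fmask = layer.burnt_mask
    burnt[inside] = fmask[row[inside], col[inside]]
    return burnt.reshape(env.grid.n_rows, env.grid.n_cols)


def burnt_fraction_of_range(prob_surface: np.ndarray, threshold: float,
                            env_burnt: np.ndarray) -> float | None:
    """Fraction of range cells (prob >= threshold) whose fire cell burnt."""
    rng = prob_surface >= threshold  # NaN compares False
    n = int(rng.sum())
    if n == 0:
        return None
    return float((rng & env_burnt).sum() / n)


def resolve_pf_sdm(pf_k: float | None, pf_mtss: float | None,
                   pf_10: float | None, kappa_invalid: bool,
                   policy: str = "max_valid") -> tuple[float | None, bool, bool]:
    """Apply the discordance rule and review policy.

    Returns (pf_sdm, discordant, manual_policy_applied).  The kappa estimate
    is suppressed when its range failed the TPR screen.  Discordance means
    the MTSS estimate exceeds both the kappa and P10 estimates by >= 0.2;
    the deterministic stand-in for case-by-case inspection then keeps the
    (conservative) kappa estimate, or none when it is unavailable.
    """
    pf_k_valid = None if kappa_invalid else pf_k
    discordant = (pf_mtss is not None and pf_k_valid is not None
                  and pf_10 is not None
                  and pf_mtss - pf_k_valid >= DISCORDANCE_MARGIN
                  and pf_mtss - pf_10 >= DISCORDANCE_MARGIN)
    if discordant:
        return pf_k_valid, True, True
    available = [v for v in (pf_k_valid, pf_mtss) if v is not None]
    if not available:
        return None, False, False
    if policy == "max_valid":
        return max(available), False, False
    if policy == "mtss_only":
        return pf_mtss, False, False
    if policy == "kappa_only":
        return pf_k_valid, False, False
    raise ValueError(f"unknown policy {policy!r}")


def derive_pf_sdm(result: SDMResult, layer: FireLayer, env: EnvStack,
                  policy: str = "max_valid",
                  env_burnt: np.ndarray | None = None) -> SDMResult:
    """Binary ranges at each threshold -> PF_K / PF_MTSS / PF_10 -> PF_SDM."""
    if env_burnt is None:
        env_burnt = env_cell_burnt_mask(env, layer)
    t = result.thresholds
    result.pf_k = burnt_fraction_of_range(result.prob_surface, t["kappa_t"], env_burnt)
    result.pf_mtss = burnt_fraction_of_range(result.prob_surface, t["mtss_t"], env_burnt)
    result.pf_10 = burnt_fraction_of_range(result.prob_surface, t["p10_t"], env_burnt)
    pf_sdm, discordant, manual = resolve_pf_sdm(
        result.pf_k, result.pf_mtss, result.pf_10,
        result.flags["kappa_invalid"], policy)
    result.pf_sdm = pf_sdm
    result.flags["discordant"] = discordant
    result.flags["manual_policy_applied"] = manual
    return result


# ---------------------------------------------------------------------------
# Combination with direct estimates
# ---------------------------------------------------------------------------

HIGH_IMPACT_PF = 0.50

_SUPPORT_CLASS = {
    (True, False, False): 1, (False, True, False): 2, (False, False, True): 3,
    (True, True, False): 4, (True, False, True): 5, (False, True, True): 6,
    (True, True, True): 7,
}


def combine_pf(pf_sr: float, pf_br: float, pf_sdm: float | None = None,
               ) -> tuple[float, int | None, bool]:
    """(pf_m, support_class, high_impact).

    PF_M is the maximum of the available estimates (a deliberately
    conservative choice, since unsampled populations can only be missed).
    The support class 1-7 records which estimates individually exceed 0.50:
    1 = records only, 2 = binned cells only, 3 = model only, 4 = records +
    cells, 5 = records + model, 6 = cells + model, 7 = all three; None when
    no estimate exceeds 0.50.
    """
    estimates = [pf_sr, pf_br] + ([pf_sdm] if pf_sdm is not None else [])
    pf_m = max(estimates)
    key = (pf_sr > HIGH_IMPACT_PF, pf_br > HIGH_IMPACT_PF,
           pf_sdm is not None and pf_sdm > HIGH_IMPACT_PF)
    support = _SUPPORT_CLASS.get(key)
    return pf_m, support, pf_m > HIGH_IMPACT_PF
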