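"""Field-experiment statistics for paired thermal loggers.

Model frogs are deployed in pairs on leaves (low-NIR with high-NIR of the
same size; uncoated large with uncoated small), internal temperature is
logged every 5 min, and thermal images provide surface temperatures of each
model and its adjacent leaf.  This module implements the analysis chain:

* per-observation surface-minus-leaf temperature differences;
* daily 95th-percentile internal temperatures per model;
* within-pair difference series (LNIR − HNIR; large − small for uncoated);
* Gaussian linear mixed models with random intercepts and Type-II Wald
  chi-square tests for the fixed factors (coating, size, interaction);
* a paired-difference mixed model with first-order autoregressive (AR1)
  residual correlation within each series, fitted by maximum likelihood —
  a consistent nonzero intercept indicates that one member of each pair
  runs systematically warmer;
* detection of transient "sunspot" temperature spikes against a running
  baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "FieldSeries",
    "ThermalObservation",
    "DiffSeries",
    "WaldTerm",
    "StatTestResult",
    "SunspotEvent",
    "PairedSunspotEvent",
    "surface_leaf_delta",
    "daily_p95",
    "pair_difference",
    "fit_delta_lmm",
    "fit_p95_lmm",
    "fit_paired_ar1",
    "detect_sunspot_events",
    "paired_sunspot_events",
]

TREATMENTS = ("HNIR", "LNIR", "uncoated", "air")
SIZES = ("small", "large", "")


class FieldDataError(ValueError):
    """Raised for malformed field series or unsatisfiable pairings."""


@dataclass(frozen=True)
class FieldSeries:
    """One logger's internal-temperature series with deployment metadata."""

    times: np.ndarray  # datetime64[s]
    internal_C: np.ndarray
    model_id: str
    treatment: str
    size: str
    pair_id: str
    site_id: str
    logger_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype="datetime64[s]")
        v = np.asarray(self.internal_C, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "internal_C", v)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise FieldDataError("times and internal_C must be equal-length 1-D, length ≥ 2")
        if np.any(np.diff(t).astype(float) <= 0):
            raise FieldDataError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise FieldDataError("non-finite temperature")
        if self.treatment not in TREATMENTS:
            raise FieldDataError(f"treatment must be one of {TREATMENTS}")
        if self.size not in SIZES:
            raise FieldDataError(f"size must be one of {SIZES}")

    @property
    def seconds(self) -> np.ndarray:
        return self.times.astype("datetime64[s]").astype(float)


@dataclass(frozen=True)
class ThermalObservation:
    """Surface temperatures of one model and its adjacent leaf from one image."""

    pair_id: str
    model_id: str
    session: str  # morning | afternoon
    model_surface_C: float
    leaf_surface_C: Optional[float]
    treatment: str = ""
    size: str = ""
    site_id: str = ""
    air_C: Optional[float] = None


@dataclass(frozen=True)
class DiffSeries:
    """A within-pair temperature-difference series (first minus second)."""

    times: np.ndarray
    diff_C: np.ndarray
    pair_id: str
    site_id: str
    size: str = ""
    air_C: Optional[np.ndarray] = None
    orientation: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype="datetime64[s]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "diff_C", np.asarray(self.diff_C, dtype=float))
        if self.air_C is not None:
            object.__setattr__(self, "air_C", np.asarray(self.air_C, dtype=float))

    def __len__(self) -> int:
        return int(self.diff_C.size)


# ---------------------------------------------------------------------------
# Simple derived tables
# ---------------------------------------------------------------------------


def surface_leaf_delta(observations: Sequence[ThermalObservation]) -> pd.DataFrame:
    """Per-observation model-minus-leaf surface temperature differences.

    Observations with a missing leaf temperature are dropped (counted in
    the log).  Metadata columns are carried through for the mixed model.
    """
    if not observations:
        raise FieldDataError("no thermal observations")
    rows, dropped = [], 0
    for ob in observations:
        if ob.leaf_surface_C is None or not np.isfinite(ob.leaf_surface_C):
            dropped += 1
            continue
        rows.append(
            {
                "pair_id": ob.pair_id,
                "model_id": ob.model_id,
                "session": ob.session,
                "treatment": ob.treatment,
                "size": ob.size,
                "site_id": ob.site_id,
                "delta_C": ob.model_surface_C - ob.leaf_surface_C,
                "air_C": ob.air_C,
            }
        )
    if dropped:
        logger.info("surface_leaf_delta: dropped %d observations without leaf value", dropped)
    if not rows:
        raise FieldDataError("no observations with a leaf temperature")
    return pd.DataFrame(rows)


def daily_p95(series: FieldSeries, p: float = 0.95, min_samples: int = 20) -> pd.DataFrame:
    """Daily ``p`` quantile of internal temperature for one logger series.

    The quantile uses linear interpolation of order statistics at position
    (n − 1)·p + 1 (numpy's default), computed per calendar day of the
    deployment.  Days with fewer than ``min_samples`` samples are omitted
    with a warning.
    """
    days = series.times.astype("datetime64[D]")
    out = []
    for day in np.unique(days):
        vals = series.internal_C[days == day]
        if vals.size < min_samples:
            warnings.warn(
                f"{series.model_id}: day {day} has {vals.size} < {min_samples} samples; omitted",
                stacklevel=2,
            )
            continue
        out.append(
            {
                "model_id": series.model_id,
                "treatment": series.treatment,
                "size": series.size,
                "pair_id": series.pair_id,
                "site_id": series.site_id,
                "logger_id": series.logger_id or series.model_id,
                "day": str(day),
                "p95_C": float(np.percentile(vals, 100 * p)),
                "n_samples": int(vals.size),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Pair differences
# ---------------------------------------------------------------------------


def _match_times(ta: np.ndarray, tb: np.ndarray, tolerance_s: float) -> Tuple[np.ndarray, np.ndarray]:
    """One-to-one nearest-neighbour timestamp matching within a tolerance."""
    sa, sb = ta.astype(float), tb.astype(float)
    ia, ib = [], []
    last_j = -1
    for i, t in enumerate(sa):
        j = int(np.searchsorted(sb, t))
        best, best_d = None, tolerance_s + 1
        for cand in (j - 1, j):
            if last_j < cand < sb.size:
                d = abs(sb[cand] - t)
                if d < best_d:
                    best, best_d = cand, d
        if best is not None and best_d <= tolerance_s:
            ia.append(i)
            ib.append(best)
            last_j = best
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def pair_difference(
    a: FieldSeries,
    b: FieldSeries,
    tolerance_s: float = 150.0,
    orient: Optional[str] = "auto",
    air: Optional[FieldSeries] = None,
) -> DiffSeries:
    """Within-pair temperature difference series at matched timestamps.

    With ``orient="auto"`` the convention of the paired analysis is
    applied: LNIR − HNIR for coated pairs, large − small for uncoated
    pairs.  With ``orient=None`` the difference is simply ``a − b`` (so
    swapping the arguments negates the series).  Unmatched samples are
    dropped; fewer than 50% matched is an error.
    """
    if a.pair_id != b.pair_id:
        raise FieldDataError(f"series from different pairs: {a.pair_id!r} vs {b.pair_id!r}")
    first, second = a, b
    if orient == "auto":
        trts = {a.treatment, b.treatment}
        if trts == {"LNIR", "HNIR"}:
            first, second = (a, b) if a.treatment == "LNIR" else (b, a)
            orientation = "LNIR-HNIR"
        elif trts == {"uncoated"} and {a.size, b.size} == {"large", "small"}:
            first, second = (a, b) if a.size == "large" else (b, a)
            orientation = "large-small"
        else:
            orientation = f"{a.model_id}-{b.model_id}"
    else:
        orientation = f"{a.model_id}-{b.model_id}"

    ia, ib = _match_times(first.seconds, second.seconds, tolerance_s)
    n_possible = min(len(first.times), len(second.times))
    if ia.size < 0.5 * n_possible:
        raise FieldDataError(
            f"pair {a.pair_id!r}: only {ia.size}/{n_possible} timestamps matched "
            f"within {tolerance_s:g} s"
        )
    if ia.size < n_possible:
        logger.info("pair %s: %d unmatched samples dropped", a.pair_id, n_possible - ia.size)

    times = first.times[ia]
    diff = first.internal_C[ia] - second.internal_C[ib]
    air_vals = None
    if air is not None:
        ja, jb = _match_times(times.astype("datetime64[s]").astype(float), air.seconds, tolerance_s)
        full = np.full(times.shape, np.nan)
        full[ja] = air.internal_C[jb]
        air_vals = full
    size = first.size if first.size == second.size else ""
    return DiffSeries(
        times=times,
        diff_C=diff,
        pair_id=a.pair_id,
        site_id=a.site_id,
        size=size,
        air_C=air_vals,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# Mixed models with Wald chi-square tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaldTerm:
    chisq: float
    df: int
    p: float


@dataclass(frozen=True)
class StatTestResult:
    """Fixed-effect inference from a fitted mixed model.

    ``terms`` maps each fixed term to its Wald chi-square test;
    ``coefficients`` holds per-coefficient estimates with 95% CIs;
    ``group_means`` holds model-based cell/group means with 95% CIs;
    ``structure`` describes the random-effect / correlation structure that
    was actually fitted; ``flags`` records fallbacks (dropped variance
    components, AR1 non-convergence).
    """

    terms: Dict[str, WaldTerm]
    coefficients: pd.DataFrame
    group_means: Dict[str, Tuple[float, float, float]]
    structure: str
    flags: Tuple[str, ...] = ()
    intercept: Optional[Tuple[float, float, float]] = None
    ar1_phi: Optional[float] = None
    sigma2: Optional[float] = None

    @property
    def intercept_crosses_zero(self) -> Optional[bool]:
        if self.intercept is None:
            return None
        _, lo, hi = self.intercept
        return lo <= 0.0 <= hi


_Z95 = stats.norm.ppf(0.975)


def _wald_block(params: np.ndarray, cov: np.ndarray, idx: List[int]) -> WaldTerm:
    b = params[idx]
    V = cov[np.ix_(idx, idx)]
    try:
        w = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        w = float(b @ np.linalg.pinv(V) @ b)
    df = len(idx)
    return WaldTerm(chisq=w, df=df, p=float(stats.chi2.sf(w, df)))


def _fit_mixedlm(formula: str, data: pd.DataFrame, vc: Dict[str, str]):
    """Fit a MixedLM with crossed random intercepts; drop singular components.

    Random intercepts are supplied as variance components on a single
    all-encompassing group, which allows crossed factors (e.g. loggers that
    move between sites).  If the optimizer fails or a component collapses
    the offending component is removed and the model refitted; the flags
    name every component dropped.
    """
    import statsmodels.formula.api as smf

    data = data.copy()
    data["_one"] = 1
    flags: List[str] = []
    vc = dict(vc)
    while True:
        if not vc:
            # every variance component was singular: plain ML regression
            flags.append("all_components_dropped_ols_fallback")
            ols = smf.ols(formula, data).fit()
            return _OLSAdapter(ols), vc, tuple(flags)
        try:
            # REML: ML variance estimates are biased low with tens of
            # pair/site clusters, which makes Wald tests on between-pair
            # contrasts anti-conservative.  The profiled restricted
            # likelihood can defeat a single optimizer (and a refit after
            # dropping a component can land on a spurious optimum), so try
            # several optimizers in turn, keeping the first converged fit.
            res = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for method in ("lbfgs", "bfgs", "powell", "cg"):
                    model = smf.mixedlm(formula, data, groups="_one",
                                        re_formula="0", vc_formula=vc)
                    try:
                        res = model.fit(reml=True, method=method, maxiter=500)
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                    if res.converged and np.isfinite(res.llf):
                        return res, vc, tuple(flags)
            raise RuntimeError("MixedLM did not converge")
        except (np.linalg.LinAlgError, RuntimeError, ValueError) as err:
            # drop the component with the smallest fitted variance, or the
            # last-listed one if no fit is available
            try:
                vcomp = dict(zip(sorted(vc), res.vcomp))  # type: ignore[name-defined]
                worst = min(vcomp, key=vcomp.get)
            except Exception:
                worst = sorted(vc)[-1]
            vc.pop(worst)
            flags.append(f"dropped_singular_component:{worst}")


class _OLSAdapter:
    """Present an OLS fit through the slice of the MixedLM interface used here."""

    def __init__(self, res) -> None:
        self._res = res
        self.fe_params = res.params
        self.model = res.model
        self.scale = float(res.scale)
        self.converged = True
        self.vcomp = np.array([])

    def cov_params(self):
        return self._res.cov_params()


def _term_indices(param_names: Sequence[str]) -> Dict[str, List[int]]:
    """Group design-matrix columns into model terms by patsy naming."""
    groups: Dict[str, List[int]] = {}
    for i, name in enumerate(param_names):
        if name == "Intercept" or name.startswith("_"):
            continue
        if ":" in name:
            term = "interaction"
        elif name.startswith("C(treatment)"):
            term = "treatment"
        elif name.startswith("C(size)"):
            term = "size"
        else:
            term = name.split("[")[0]
        groups.setdefault(term, []).append(i)
    return groups


def _se_from_variance(var) -> np.ndarray:
    """Standard errors from (possibly non-PSD) covariance diagonals.

    Singular fits can leave tiny negative or NaN variances; report NaN
    rather than warn or fabricate a zero-width interval.
    """
    var = np.asarray(var, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(var >= 0, np.sqrt(np.abs(var)), np.nan)


def _coef_table(params: pd.Series, cov: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    se = _se_from_variance(np.diag(cov))
    est = np.asarray(params)[: len(names)]
    return pd.DataFrame(
        {
            "term": list(names),
            "estimate": est,
            "se": se[: len(names)],
            "ci_lo": est - _Z95 * se[: len(names)],
            "ci_hi": est + _Z95 * se[: len(names)],
        }
    )


def _group_means(res, data: pd.DataFrame, response: str) -> Dict[str, Tuple[float, float, float]]:
    """Model-based mean (with 95% CI) per treatment × size cell and per treatment."""
    from patsy import dmatrix

    design_info = res.model.data.design_info
    fe = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: fe.size, : fe.size]
    cells: Dict[str, np.ndarray] = {}
    trt_levels = sorted(data["treatment"].unique())
    size_levels = sorted(data["size"].unique()) if "size" in data.columns else [""]
    use_size = any(name.startswith("C(size)") for name in design_info.column_names)
    for trt in trt_levels:
        rows = []
        for size in size_levels:
            new = pd.DataFrame({"treatment": [trt], "size": [size]})
            L = np.asarray(dmatrix(design_info, new))[0]
            key = f"{trt}:{size}" if use_size else trt
            cells.setdefault(key, L)
            rows.append(L)
        if use_size:
            cells[trt] = np.mean(rows, axis=0)
    out = {}
    for key, L in cells.items():
        est = float(L @ fe)
        se = float(_se_from_variance(L @ cov @ L))
        out[key] = (est, est - _Z95 * se, est + _Z95 * se)
    return out


def _fit_factorial_lmm(
    data: pd.DataFrame,
    response: str,
    random_factors: Sequence[str],
) -> StatTestResult:
    """Shared machinery for the factorial field LMMs (Type-II Wald tests)."""
    for col in ("treatment", "size", *random_factors, response):
        if col not in data.columns:
            raise FieldDataError(f"missing column {col!r}")
    if data["treatment"].nunique() < 2 or data["size"].nunique() < 2:
        raise FieldDataError("need at least 2 levels of treatment and size")
    for rf in random_factors:
        if data[rf].nunique() < 3:
            raise FieldDataError(f"random factor {rf!r} has fewer than 3 groups")

    vc = {rf: f"0 + C({rf})" for rf in random_factors}
    full_formula = f"{response} ~ C(treatment) * C(size)"
    res_full, vc_used, flags = _fit_mixedlm(full_formula, data, vc)
    fe_names = list(res_full.model.data.param_names[: len(res_full.fe_params)])
    cov_full = np.asarray(res_full.cov_params())[: len(fe_names), : len(fe_names)]
    params_full = np.asarray(res_full.fe_params)
    idx_full = _term_indices(fe_names)

    terms: Dict[str, WaldTerm] = {}
    if "interaction" in idx_full:
        terms["treatment:size"] = _wald_block(params_full, cov_full, idx_full["interaction"])

    # Type-II main effects: test each factor in the additive model
    res_add, _, flags_add = _fit_mixedlm(f"{response} ~ C(treatment) + C(size)", data, dict(vc_used))
    add_names = list(res_add.model.data.param_names[: len(res_add.fe_params)])
    cov_add = np.asarray(res_add.cov_params())[: len(add_names), : len(add_names)]
    params_add = np.asarray(res_add.fe_params)
    idx_add = _term_indices(add_names)
    for term in ("treatment", "size"):
        if term in idx_add:
            terms[term] = _wald_block(params_add, cov_add, idx_add[term])

    structure = (
        f"LMM(REML): {full_formula}; random intercepts: "
        + (" + ".join(sorted(vc_used)) if vc_used else "none")
    )
    return StatTestResult(
        terms=terms,
        coefficients=_coef_table(res_full.fe_params, cov_full, fe_names),
        group_means=_group_means(res_full, data, response),
        structure=structure,
        flags=tuple(dict.fromkeys(flags + flags_add)),
        sigma2=float(res_full.scale),
    )


def fit_delta_lmm(deltas: pd.DataFrame, response: str = "delta_C") -> StatTestResult:
    """Surface-minus-leaf LMM: coating × size fixed, pair and site random.

    Fitted by maximum likelihood; fixed terms are tested with Type-II Wald
    chi-square tests (each main effect assessed in the additive model, the
    interaction in the full model).
    """
    return _fit_factorial_lmm(deltas, response, random_factors=("pair_id", "site_id"))


def fit_p95_lmm(p95_table: pd.DataFrame, response: str = "p95_C") -> StatTestResult:
    """Daily-95th-percentile LMM with pair, site and logger random intercepts."""
    return _fit_factorial_lmm(
        p95_table, response, random_factors=("pair_id", "site_id", "logger_id")
    )


# ---------------------------------------------------------------------------
# Paired-difference model with AR1 residuals
# ---------------------------------------------------------------------------


def _whiten_ar1(x: np.ndarray, phi: float) -> np.ndarray:
    """Transform W (applied to rows) with W'W = P(φ)⁻¹ for unit-marginal AR1.

    Works on vectors or on matrices column-wise.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    c = np.sqrt(1.0 - phi**2)
    out[0] = x[0] * c
    out[1:] = x[1:] - phi * x[:-1]
    return out / c


def _ar1_lmm_loglik_parts(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    z_block: np.ndarray,
    series_idx: List[np.ndarray],
):
    """Profile deviance pieces for the AR1 + random-intercepts model.

    theta = (arctanh φ, log γ_1, …, log γ_B) where γ_b are random-intercept
    variances relative to the residual innovation's marginal variance σ².
    V = σ² (P_AR1 + Σ_b γ_b Z_b Z_b'); σ² and β are profiled out.
    """
    phi = np.tanh(theta[0])
    gammas = np.exp(theta[1:])
    n = y.size

    Wy = np.empty_like(y)
    WX = np.empty_like(X)
    WZ = np.empty_like(Z)
    logdet_P = 0.0
    for idx in series_idx:
        Wy[idx] = _whiten_ar1(y[idx], phi)
        WX[idx] = _whiten_ar1(X[idx], phi)
        WZ[idx] = _whiten_ar1(Z[idx], phi)
        logdet_P += (idx.size - 1) * np.log(1.0 - phi**2)

    g = np.sqrt(gammas[z_block])
    U = WZ * g  # whitened, scaled random-effect design
    M = np.eye(U.shape[1]) + U.T @ U
    cM = np.linalg.cholesky(M)

    def vinv_mult(A: np.ndarray) -> np.ndarray:
        # V0^{-1} A with V0 = P + Z G Z', in whitened coordinates
        UA = U.T @ A
        return A - U @ np.linalg.solve(cM.T, np.linalg.solve(cM, UA))

    XtVi = WX.T @ vinv_mult(WX)
    XtViy = WX.T @ vinv_mult(Wy)
    beta = np.linalg.solve(XtVi, XtViy)
    r = Wy - WX @ beta
    quad = float(r @ vinv_mult(r))
    sigma2 = quad / n
    logdet_V0 = logdet_P + 2.0 * np.sum(np.log(np.diag(cM)))
    deviance = n * np.log(2 * np.pi * sigma2) + logdet_V0 + n
    return deviance, beta, sigma2, XtVi, phi, gammas


def fit_paired_ar1(
    diffs: Sequence[DiffSeries],
    include_air: bool = True,
    include_size: bool = True,
    min_samples: int = 30,
) -> StatTestResult:
    """Mixed model for paired difference series with AR1 residuals.

    The response is the within-pair temperature difference; the fixed part
    is an intercept plus (optionally) air temperature and model size, with
    random intercepts for site and pair and an AR1 correlation structure
    for the residuals within each series.  Fitted by maximum likelihood
    (the intercept estimate is the MLE); Wald 95% CIs.  A consistent
    within-pair difference shows up as an intercept CI that excludes zero.

    If the AR1 optimisation fails, the model falls back to independent
    residuals and flags it.
    """
    diffs = [d for d in diffs if len(d) >= min_samples]
    if not diffs:
        raise FieldDataError(f"no difference series with ≥ {min_samples} matched samples")

    rows_y, rows_x, series_idx = [], [], []
    pair_ids = sorted({d.pair_id for d in diffs})
    site_ids = sorted({d.site_id for d in diffs})
    size_levels = sorted({d.size for d in diffs})
    use_size = include_size and len(size_levels) > 1
    use_air = include_air and all(d.air_C is not None for d in diffs)

    names = ["Intercept"]
    if use_air:
        names.append("air_C_centred")
    if use_size:
        names.append(f"size[{size_levels[-1]}]")

    air_mean = (
        float(np.nanmean(np.concatenate([d.air_C for d in diffs]))) if use_air else 0.0
    )
    Z_cols = len(site_ids) + len(pair_ids)
    z_block = np.array([0] * len(site_ids) + [1] * len(pair_ids))
    rows_z = []
    pos = 0
    for d in diffs:
        y = d.diff_C.astype(float)
        keep = np.isfinite(y)
        if use_air:
            keep &= np.isfinite(d.air_C)
        y = y[keep]
        if y.size < min_samples:
            continue
        x = [np.ones(y.size)]
        if use_air:
            x.append(d.air_C[keep] - air_mean)
        if use_size:
            x.append(np.full(y.size, 1.0 if d.size == size_levels[-1] else 0.0))
        z = np.zeros((y.size, Z_cols))
        z[:, site_ids.index(d.site_id)] = 1.0
        z[:, len(site_ids) + pair_ids.index(d.pair_id)] = 1.0
        rows_y.append(y)
        rows_x.append(np.column_stack(x))
        rows_z.append(z)
        series_idx.append(np.arange(pos, pos + y.size))
        pos += y.size

    y = np.concatenate(rows_y)
    X = np.vstack(rows_x)
    Z = np.vstack(rows_z)

    flags: List[str] = []

    def objective(theta: np.ndarray) -> float:
        try:
            return _ar1_lmm_loglik_parts(theta, y, X, Z, z_block, series_idx)[0]
        except np.linalg.LinAlgError:
            return np.inf

    theta0 = np.array([np.arctanh(0.5), np.log(0.1), np.log(0.1)])
    res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    if not res.success or not np.isfinite(res.fun):
        flags.append("ar1_fit_nonconvergent_fallback_independent")
        theta_hat = np.array([0.0, np.log(0.1), np.log(0.1)])
        # optimise only the variance ratios with phi pinned at 0
        res2 = optimize.minimize(
            lambda th: objective(np.concatenate([[0.0], th])),
            theta_hat[1:],
            method="Nelder-Mead",
        )
        theta_hat = np.concatenate([[0.0], res2.x])
    else:
        theta_hat = res.x

    _, beta, sigma2, XtVi, phi, gammas = _ar1_lmm_loglik_parts(
        theta_hat, y, X, Z, z_block, series_idx
    )
    cov_beta = sigma2 * np.linalg.inv(XtVi)
    coefs = _coef_table(pd.Series(beta, index=names), cov_beta, names)
    terms = {
        name: _wald_block(beta, cov_beta, [i]) for i, name in enumerate(names)
    }
    est, lo, hi = (
        float(beta[0]),
        float(beta[0] - _Z95 * np.sqrt(cov_beta[0, 0])),
        float(beta[0] + _Z95 * np.sqrt(cov_beta[0, 0])),
    )
    structure = (
        "LMM(ML): diff ~ "
        + " + ".join(names)
        + "; random intercepts: site + pair; residual correlation: "
        + ("AR1" if "ar1_fit_nonconvergent_fallback_independent" not in flags else "independent")
    )
    return StatTestResult(
        terms=terms,
        coefficients=coefs,
        group_means={},
        structure=structure,
        flags=tuple(flags),
        intercept=(est, lo, hi),
        ar1_phi=float(phi),
        sigma2=float(sigma2),
    )


# ---------------------------------------------------------------------------
# Sunspot detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SunspotEvent:
    start_time: np.datetime64
    peak_time: np.datetime64
    peak_excess_C: float
    duration_min: float


@dataclass(frozen=True)
class PairedSunspotEvent:
    start_time: np.datetime64
    end_time: np.datetime64
    peak_excess_a_C: float
    peak_excess_b_C: float
    paired_excess_C: float  # max of (a − b) over the merged window


def _running_baseline(seconds: np.ndarray, temps: np.ndarray, baseline_s: float) -> np.ndarray:
    """Median of the preceding ``baseline_s`` seconds (exclusive), NaN when
    fewer than 3 preceding samples exist."""
    base = np.full(temps.shape, np.nan)
    for i in range(temps.size):
        lo = seconds[i] - baseline_s
        j0 = int(np.searchsorted(seconds, lo, side="left"))
        window = temps[j0:i]
        if window.size >= 3:
            base[i] = np.median(window)
    return base


def detect_sunspot_events(
    series: FieldSeries,
    rise_C: float = 2.0,
    window_min: float = 20.0,
    baseline_min: float = 60.0,
) -> List[SunspotEvent]:
    """Flag transient temperature spikes above a running baseline.

    The baseline at each sample is the median of the preceding
    ``baseline_min`` minutes.  A maximal run of samples whose excess over
    baseline is ≥ ``rise_C`` is an event, provided the rise from half the
    threshold to the threshold took at most ``window_min`` minutes (spikes
    from moving sunspots are sharp; slow drifts are not events).
    """
    sec = series.seconds
    temps = series.internal_C
    base = _running_baseline(sec, temps, baseline_min * 60.0)
    excess = np.where(np.isfinite(base), temps - base, 0.0)
    above = excess >= rise_C
    if not above.any():
        return []
    dt = float(np.median(np.diff(sec)))
    events: List[SunspotEvent] = []
    i = 0
    n = temps.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        # onset: last sample before the run with excess below half-threshold
        k = i
        while k - 1 >= 0 and excess[k - 1] >= 0.5 * rise_C:
            k -= 1
        rise_time_min = (sec[i] - sec[k]) / 60.0
        if rise_time_min <= window_min:
            peak = int(i + np.argmax(excess[i : j + 1]))
            events.append(
                SunspotEvent(
                    start_time=series.times[i],
                    peak_time=series.times[peak],
                    peak_excess_C=float(excess[peak]),
                    duration_min=float((sec[j] - sec[i]) / 60.0 + dt / 60.0),
                )
            )
        i = j + 1
    return events


def paired_sunspot_events(
    a: FieldSeries,
    b: FieldSeries,
    rise_C: float = 2.0,
    window_min: float = 20.0,
    baseline_min: float = 60.0,
    tolerance_s: float = 150.0,
) -> List[PairedSunspotEvent]:
    """Merge co-located pairs' overlapping sunspot events.

    For each pair of overlapping events the report carries the paired
    excess: the maximum of (a − b) over the merged window at matched
    timestamps — the quantity of interest when one coating heats more in a
    shared sunspot.
    """
    ev_a = detect_sunspot_events(a, rise_C, window_min, baseline_min)
    ev_b = detect_sunspot_events(b, rise_C, window_min, baseline_min)
    diff = pair_difference(a, b, tolerance_s=tolerance_s, orient=None)
    out: List[PairedSunspotEvent] = []
    for ea in ev_a:
        ea_end = ea.start_time + np.timedelta64(int(ea.duration_min * 60), "s")
        for eb in ev_b:
            eb_end = eb.start_time + np.timedelta64(int(eb.duration_min * 60), "s")
            start = max(ea.start_time, eb.start_time)
            end = min(ea_end, eb_end)
            if start >= end:
                continue
            mask = (diff.times >= start) & (diff.times <= end)
            paired = float(np.max(diff.diff_C[mask])) if mask.any() else float("nan")
            out.append(
                PairedSunspotEvent(
                    start_time=min(ea.start_time, eb.start_time),
                    end_time=max(ea_end, eb_end),
                    peak_excess_a_C=ea.peak_excess_C,
                    peak_excess_b_C=eb.peak_excess_C,
                    paired_excess_C=paired,
                )
            )
    return out
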