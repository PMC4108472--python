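"""Nonlinear least-squares estimation of cholinesterase kinetic parameters.

Estimators follow the scikit-learn protocol: ``fit(X, y)`` takes substrate
concentrations (µM, shape ``(n,)`` or ``(n, 1)``) and initial rates (U/mL),
fitted attributes carry a trailing underscore, and ``predict`` evaluates the
fitted rate law.  The Michaelian model (Vmax, Km) is nested inside the
two-site substrate-modulation model (Vmax, Km, Kss, b) at b = 1, so the two
are compared with an extra-sum-of-squares F-test (df = 2).

Replicates are fitted pooled, not averaged, preserving the error structure
for residual-resampling bootstrap intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import lmfit
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .assay import AssayConditions
from .kinetics import KineticParameters, rate_michaelis, rate_two_site

__all__ = [
    "RateCurve",
    "FitResult",
    "MichaelisMentenRegressor",
    "TwoSiteRegressor",
    "KineticModelSelector",
    "fit_michaelis",
    "fit_two_site",
    "select_model",
    "bootstrap_uncertainty",
]

#: Minimum distinct substrate concentrations per model.
MIN_POINTS_MICHAELIAN = 5
MIN_POINTS_TWO_SITE = 8


@dataclass(frozen=True)
class RateCurve:
    """A saturation curve: (substrate concentration, rate) measurements.

    ``s_um`` and ``v`` are parallel arrays (µM, U/mL); ``replicate`` labels
    pooled replicate measurements at the same design point.
    """

    s_um: np.ndarray
    v: np.ndarray
    replicate: np.ndarray | None = None
    conditions: AssayConditions | None = None
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.s_um, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if s.shape != v.shape or s.ndim != 1:
            raise ValueError("s_um and v must be 1-D arrays of equal length")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.any(v < 0):
            raise ValueError("rates must be nonnegative")
        rep = self.replicate
        rep = np.zeros(s.size, dtype=int) if rep is None else np.asarray(rep)
        if rep.shape != s.shape:
            raise ValueError("replicate labels must match the data length")
        object.__setattr__(self, "s_um", s)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "replicate", rep)

    @property
    def n_concentrations(self) -> int:
        return np.unique(self.s_um).size

    def __len__(self) -> int:
        return self.s_um.size


@dataclass(frozen=True)
class FitResult:
    """Outcome of one nonlinear fit (and, optionally, model selection)."""

    model: Literal["michaelian", "two_site"]
    params: KineticParameters | None
    std_errors: dict[str, float | None]
    rss: float
    n_points: int
    converged: bool
    identifiability_warning: bool = False
    selection: dict | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": None if self.params is None else self.params.to_dict(),
            "std_errors": dict(self.std_errors),
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "identifiability_warning": self.identifiability_warning,
            "selection": self.selection,
        }


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be (n,) or (n, 1) substrate concentrations")
    y = np.asarray(y, dtype=float)
    if y.shape != X.shape:
        raise ValueError("y must match X in length")
    if np.any(X <= 0):
        raise ValueError("substrate concentrations must be positive")
    if np.any(y < 0):
        raise ValueError("rates must be nonnegative")
    return X, y


def _hanes_woolf_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """(Vmax, Km) from the Hanes–Woolf linearization S/v = S/Vmax + Km/Vmax."""
    ok = v > 0
    s, v = s[ok], v[ok]
    if s.size < 2:
        return max(float(np.max(v, initial=1.0)), 1e-6), float(np.median(s))
    slope, intercept = np.polyfit(s, s / v, 1)
    if slope <= 0 or intercept <= 0:
        vmax0 = float(np.max(v)) * 1.2
        half = vmax0 / 2.0
        km0 = float(s[np.argmin(np.abs(v - half))])
        return vmax0, max(km0, 1e-3)
    return 1.0 / slope, intercept / slope


class _KineticRegressorBase(RegressorMixin, BaseEstimator):
    """Shared fitting machinery: lmfit least squares with jittered restarts."""

    #: parameters, in order, exposed as fitted attributes
    _param_names: tuple[str, ...] = ()
    _min_points: int = MIN_POINTS_MICHAELIAN

    def __init__(self, weighting="unweighted", max_restarts=5, rss_tol=1e-8):
        self.weighting = weighting
        self.max_restarts = max_restarts
        self.rss_tol = rss_tol

    # subclass hooks -------------------------------------------------------
    def _make_params(self, s: np.ndarray, v: np.ndarray) -> lmfit.Parameters:
        raise NotImplementedError

    def _model_rate(self, s: np.ndarray, params: lmfit.Parameters) -> np.ndarray:
        raise NotImplementedError

    # ----------------------------------------------------------------------
    def _residual(self, params: lmfit.Parameters, s, v):
        resid = self._model_rate(s, params) - v
        if self.weighting == "proportional":
            resid = resid / np.maximum(self._model_rate(s, params), 1e-12)
        return resid

    def fit(self, X, y):
        s, v = _validate_xy(X, y)
        if np.unique(s).size < self._min_points:
            raise ValueError(
                f"need at least {self._min_points} distinct substrate "
                f"concentrations, got {np.unique(s).size}"
            )
        if self.weighting not in ("unweighted", "proportional"):
            raise ValueError(f"unknown weighting: {self.weighting!r}")

        params0 = self._make_params(s, v)
        rng = np.random.default_rng(0)  # deterministic restart jitter
        best = None
        for attempt in range(self.max_restarts + 1):
            params = params0.copy()
            if attempt > 0:
                for p in params.values():
                    if p.vary:
                        jitter = rng.lognormal(0.0, 0.3)
                        p.value = np.clip(
                            p.value * jitter,
                            p.min * 1.001 if np.isfinite(p.min) else -np.inf,
                            p.max * 0.999 if np.isfinite(p.max) else np.inf,
                        )
            try:
                res = lmfit.minimize(
                    self._residual, params, args=(s, v), method="leastsq",
                    xtol=self.rss_tol, ftol=self.rss_tol,
                )
            except Exception:
                continue
            rss = float(np.sum((self._model_rate(s, res.params) - v) ** 2))
            if res.success and (best is None or rss < best[1] * (1 - 1e-12)):
                best = (res, rss)
                if attempt == 0:
                    break  # first try converged; restarts are a fallback

        self.n_points_ = s.size
        if best is None:
            self.converged_ = False
            self.rss_ = math.inf
            self.std_errors_ = {name: None for name in self._param_names}
            for name in self._param_names:
                setattr(self, f"{name}_", math.nan)
            return self

        res, rss = best
        self.converged_ = True
        self.rss_ = rss
        self.result_ = res
        self.std_errors_ = {
            name: (res.params[name].stderr if res.params[name].stderr else None)
            for name in self._param_names
        }
        for name in self._param_names:
            setattr(self, f"{name}_", float(res.params[name].value))
        self._post_fit(s, v)
        return self

    def _post_fit(self, s: np.ndarray, v: np.ndarray) -> None:
        pass

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        shape = X.shape
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        params = lmfit.Parameters()
        for name in self._param_names:
            params.add(name, value=getattr(self, f"{name}_"))
        out = self._model_rate(X, params)
        return out.reshape(shape[:1]) if len(shape) else float(out)

    # shared result packaging ---------------------------------------------
    def _to_fit_result(self, model: str) -> FitResult:
        params = self.kinetic_parameters_ if self.converged_ else None
        return FitResult(
            model=model,
            params=params,
            std_errors=dict(self.std_errors_),
            rss=self.rss_,
            n_points=self.n_points_,
            converged=self.converged_,
            identifiability_warning=getattr(self, "identifiability_warning_", False),
        )


class MichaelisMentenRegressor(_KineticRegressorBase):
    """Least-squares (Vmax, Km) estimator for the Michaelian rate law.

    Initialization comes from the Hanes–Woolf linearization; up to
    ``max_restarts`` jittered re-initializations are tried before the fit is
    declared non-converged (``converged_ = False``, parameters NaN — never
    silent garbage).
    """

    _param_names = ("vmax", "km")
    _min_points = MIN_POINTS_MICHAELIAN

    def _make_params(self, s, v):
        vmax0, km0 = _hanes_woolf_init(s, v)
        params = lmfit.Parameters()
        params.add("vmax", value=max(vmax0, 1e-9), min=0.0)
        params.add("km", value=max(km0, 1e-6), min=0.0)
        return params

    def _model_rate(self, s, params):
        return np.asarray(
            rate_michaelis(s, params["vmax"].value, params["km"].value)
        )

    @property
    def kinetic_parameters_(self) -> KineticParameters:
        return KineticParameters(vmax=self.vmax_, km_um=self.km_)


class TwoSiteRegressor(_KineticRegressorBase):
    """Least-squares (Vmax, Km, Kss, b) estimator for the two-site law.

    Initialization: (Vmax, Km) from a low-substrate Michaelian subfit
    (S ≤ 300 µM), b from the high-substrate plateau ratio, Kss at 1 mM.
    Bounds: all constants positive, b ∈ (0.01, 100).  A design with no
    point above 1 mM cannot pin down (Kss, b); such fits carry
    ``identifiability_warning_ = True``.
    """

    _param_names = ("vmax", "km", "kss", "b")
    _min_points = MIN_POINTS_TWO_SITE

    def _make_params(self, s, v):
        low = s <= 300.0
        if np.count_nonzero(low) >= 3:
            vmax0, km0 = _hanes_woolf_init(s[low], v[low])
        else:
            vmax0, km0 = _hanes_woolf_init(s, v)
        top = s >= np.quantile(np.unique(s), 0.8)
        plateau = float(np.mean(v[top])) if np.any(top) else float(np.max(v))
        b0 = np.clip(plateau / max(vmax0, 1e-12), 0.02, 90.0)
        params = lmfit.Parameters()
        params.add("vmax", value=max(vmax0, 1e-9), min=0.0)
        params.add("km", value=max(km0, 1e-6), min=0.0)
        params.add("kss", value=1000.0, min=0.0)  # µM
        params.add("b", value=b0, min=0.01, max=100.0)
        return params

    def _model_rate(self, s, params):
        vmax, km = params["vmax"].value, params["km"].value
        kss, b = params["kss"].value, params["b"].value
        s = np.asarray(s, dtype=float)
        core = vmax * s / (km + s)
        return core * (1.0 + b * s / kss) / (1.0 + s / kss)

    def _post_fit(self, s, v):
        self.identifiability_warning_ = bool(np.max(s) <= 1000.0)

    @property
    def kinetic_parameters_(self) -> KineticParameters:
        return KineticParameters(
            vmax=self.vmax_, km_um=self.km_, kss_mm=self.kss_ / 1000.0, b=self.b_
        )

    @property
    def std_errors_mm_(self) -> dict:
        """Standard errors with Kss rescaled to mM for reporting."""
        out = dict(self.std_errors_)
        if out.get("kss") is not None:
            out["kss"] = out["kss"] / 1000.0
        return out


class KineticModelSelector(RegressorMixin, BaseEstimator):
    """Nested model choice: Michaelian vs two-site by extra-sum-of-squares F.

    F = ((RSS_mm − RSS_2s)/2) / (RSS_2s/(n − 4)); the two-site model is
    chosen iff p < alpha.  With noiseless Michaelian data both RSS vanish
    and the simpler model is kept.
    """

    def __init__(self, alpha: float = 0.05, weighting="unweighted"):
        self.alpha = alpha
        self.weighting = weighting

    def fit(self, X, y):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.michaelian_ = MichaelisMentenRegressor(weighting=self.weighting).fit(X, y)
        self.two_site_ = TwoSiteRegressor(weighting=self.weighting).fit(X, y)
        if not (self.michaelian_.converged_ and self.two_site_.converged_):
            self.model_ = None
            self.f_statistic_ = math.nan
            self.p_value_ = math.nan
            self.best_estimator_ = None
            return self

        n = self.two_site_.n_points_
        rss_mm, rss_2s = self.michaelian_.rss_, self.two_site_.rss_
        df_extra, df_full = 2, n - 4
        if df_full <= 0:
            raise ValueError("need more points than two-site parameters")
        extra = max(rss_mm - rss_2s, 0.0)
        if rss_2s == 0.0:
            # perfect full-model fit: keep MM only if it is also perfect
            self.f_statistic_ = math.inf if extra > 0 else 0.0
            self.p_value_ = 0.0 if extra > 0 else 1.0
        else:
            self.f_statistic_ = (extra / df_extra) / (rss_2s / df_full)
            self.p_value_ = float(stats.f.sf(self.f_statistic_, df_extra, df_full))
        self.model_ = "two_site" if self.p_value_ < self.alpha else "michaelian"
        self.best_estimator_ = (
            self.two_site_ if self.model_ == "two_site" else self.michaelian_
        )
        return self

    def predict(self, X):
        if self.best_estimator_ is None:
            raise RuntimeError("model selection did not converge")
        return self.best_estimator_.predict(X)

    @property
    def selection_record_(self) -> dict:
        return {
            "f_statistic": self.f_statistic_,
            "p_value": self.p_value_,
            "alpha": self.alpha,
            "chosen": self.model_,
            "status": "ok" if self.model_ is not None else "deferred_nonconverged",
        }


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators


def fit_michaelis(curve: RateCurve, weighting="unweighted") -> FitResult:
    """Fit the Michaelian law (b fixed at 1, no Kss) to a saturation curve."""
    est = MichaelisMentenRegressor(weighting=weighting).fit(curve.s_um, curve.v)
    return est._to_fit_result("michaelian")


def fit_two_site(curve: RateCurve, weighting="unweighted") -> FitResult:
    """Fit the full two-site law (Vmax, Km, Kss, b) to a saturation curve."""
    est = TwoSiteRegressor(weighting=weighting).fit(curve.s_um, curve.v)
    result = est._to_fit_result("two_site")
    if est.converged_:
        result = FitResult(
            **{**result.__dict__, "std_errors": est.std_errors_mm_}
        )
    return result


def select_model(curve: RateCurve, alpha: float = 0.05,
                 weighting="unweighted") -> FitResult:
    """Fit both nested models and choose by the extra-sum-of-squares F-test."""
    sel = KineticModelSelector(alpha=alpha, weighting=weighting).fit(
        curve.s_um, curve.v
    )
    if sel.model_ is None:
        bad = sel.michaelian_ if not sel.michaelian_.converged_ else sel.two_site_
        result = bad._to_fit_result(
            "michaelian" if bad is sel.michaelian_ else "two_site"
        )
        return FitResult(**{**result.__dict__, "selection": sel.selection_record_})
    best = sel.best_estimator_
    result = best._to_fit_result(sel.model_)
    std_errors = (
        best.std_errors_mm_ if isinstance(best, TwoSiteRegressor)
        else dict(best.std_errors_)
    )
    return FitResult(
        **{**result.__dict__, "std_errors": std_errors,
           "selection": sel.selection_record_}
    )


def bootstrap_uncertainty(
    curve: RateCurve,
    fit: FitResult,
    B: int = 500,
    seed: int = 0,
    level: float = 0.68,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap percentile intervals for a converged fit.

    Residuals from the fitted curve are recentred, resampled with
    replacement, added back to the fitted values (rates clipped at 0), and
    the same model is refitted B times.  Reproducible under a fixed seed.
    """
    if B < 50:
        raise ValueError("B must be at least 50")
    if not fit.converged or fit.params is None:
        raise ValueError("bootstrap requires a converged fit")
    est_cls = (
        MichaelisMentenRegressor if fit.model == "michaelian" else TwoSiteRegressor
    )
    base = est_cls().fit(curve.s_um, curve.v)
    fitted = base.predict(curve.s_um)
    resid = curve.v - fitted
    resid = resid - resid.mean()
    rng = np.random.default_rng(seed)
    names = est_cls._param_names
    draws: dict[str, list[float]] = {n: [] for n in names}
    for _ in range(B):
        v_b = np.clip(fitted + rng.choice(resid, size=resid.size, replace=True), 0, None)
        try:
            est_b = est_cls().fit(curve.s_um, v_b)
        except ValueError:
            continue
        if est_b.converged_:
            for n in names:
                draws[n].append(getattr(est_b, f"{n}_"))
    lo_q, hi_q = 50 * (1 - level), 50 * (1 + level)
    intervals = {}
    for n in names:
        arr = np.asarray(draws[n])
        if arr.size == 0:
            intervals[n] = (math.nan, math.nan)
        else:
            intervals[n] = (
                float(np.percentile(arr, lo_q)),
                float(np.percentile(arr, hi_q)),
            )
    return intervals
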