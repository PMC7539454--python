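"""Model fitting, bootstrap intervals, selection tests and age dating.

The divergence of sample pair q is modelled as

    D_q = c + D*_q(Theta) + eps_q,      eps_q ~ N(0, sigma^2),

where D*_q is the expected divergence under the epimutation kernel with
parameters Theta = (alpha, beta, w, gamma).  Estimation minimizes

    sum_q (D_q - D*_q(Theta) - c)^2  +  M (p_bar_1 - p1(t_inf, Theta))^2

over the free parameters of the chosen model form, the second term
anchoring the equilibrium u/u proportion to its pooled empirical guess
(skipped for the no-accumulation null, whose equilibrium is undefined).
Minimization uses Nelder-Mead with seeded random restarts; bounded
parameters are logit-transformed to the real line and the intercept is
fitted on log scale, which stabilizes convergence of the highly
non-linear objective.

The public surface follows the statsmodels idiom: ``EpimutationModel``
is built from a :class:`~epiclock.divergence.DivergenceDataset` and its
``fit`` returns :class:`EpimutationResults` with estimates, residuals,
``summary()``, ``bootstrap()`` and ``compare_f_test()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as _opt
from scipy import stats as _stats
from scipy.special import expit, logit

from .divergence import DivergenceDataset, build_dataset, pair_divergence
from .kernels import (
    AB_NULL,
    INDICATOR_MATRIX,
    EpimutationParams,
    KernelPowers,
    ModelSpec,
    build_kernel,
    equilibrium_uu,
    founder_distribution,
)
from .methylome import MethylomeSample, state_proportions
from .pedigree import Pedigree

__all__ = [
    "FitOptions",
    "EpimutationModel",
    "EpimutationResults",
    "FTestResult",
    "BootstrapResult",
    "AgeProfile",
    "objective",
    "fit",
    "bootstrap",
    "compare_models",
    "profile_founder_age",
]

_BIG = 1e10


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    ``n_starts`` seeded random restarts guard against the unstable
    convergence of Nelder-Mead on this objective; each run is capped at
    ``maxfev`` function evaluations and the best run is polished by one
    further Nelder-Mead pass.  ``tol`` is a *relative* objective
    tolerance (the optimizer works on the log of the objective, so the
    same setting serves residual sums of squares of any magnitude).
    """

    n_starts: int = 50
    seed: int = 0
    maxfev: int = 2000
    tol: float = 1e-9
    xatol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0 or self.xatol <= 0:
            raise ValueError("tolerances must be > 0")


class _Design:
    """Precomputed arrays for fast repeated objective evaluation."""

    def __init__(self, data: DivergenceDataset):
        pairs = data.pairs
        self.D = pairs["D"].to_numpy(dtype=float)
        t_i = pairs["t_i"].to_numpy(dtype=float)
        t_j = pairs["t_j"].to_numpy(dtype=float)
        t_ij = pairs["t_ij"].to_numpy(dtype=float)
        if np.any(t_ij < 1.0 - 1e-9):
            raise ValueError("pair ancestor times below the internal founder time 1")
        if np.any(t_i < t_ij - 1e-9) or np.any(t_j < t_ij - 1e-9):
            raise ValueError("sample times precede ancestor times")
        exps = np.concatenate([t_ij - 1.0, t_i - t_ij, t_j - t_ij])
        exps = np.clip(np.round(exps, 12), 0.0, None)
        self.taus, inverse = np.unique(exps, return_inverse=True)
        m = len(self.D)
        self.idx_anc = inverse[:m]
        self.idx_i = inverse[m : 2 * m]
        self.idx_j = inverse[2 * m :]
        self.M = m
        self.p1_obs = data.p1_obs
        self.p3_obs = data.p3_obs
        self.p_bar_1 = data.p_bar_1
        dbar = self.D.mean() if m else 0.0
        self.tss = float(np.sum((self.D - dbar) ** 2))
        self.has_fractional = bool(np.any(np.abs(self.taus - np.round(self.taus)) > 1e-9))

    def with_response(self, d: np.ndarray) -> "_Design":
        import copy

        new = copy.copy(self)
        new.D = np.asarray(d, dtype=float)
        return new


# -- fast objective path -------------------------------------------------
#
# The optimizer evaluates the objective thousands of times; the general
# KernelPowers route (numpy eig + validated dataclasses) costs ~0.4 ms per
# call.  A row-stochastic 3x3 kernel always has eigenvalue 1 with right
# eigenvector (1,1,1); the remaining two eigenvalues solve
# lambda^2 - (trace - 1) lambda + det = 0 in closed form, and their
# eigenvectors are cross products of rows of (G - lambda I).  Degenerate
# spectra (repeated or complex roots) fall back to the reference path,
# which the results object and the public ``objective`` always use.


def _g_norm_fast(system: str, form: str, a: float, b: float, w: float) -> np.ndarray:
    ia, ib = 1.0 - a, 1.0 - b
    if system == "selfing":
        x, y = b + ia, a + ib
        g = np.array(
            [
                [ia * ia, 2.0 * ia * a, a * a],
                [0.25 * x * x, 0.5 * x * y, 0.25 * y * y],
                [b * b, 2.0 * ib * b, ib * ib],
            ]
        )
    else:
        g = np.array(
            [
                [ia * ia, 2.0 * ia * a, a * a],
                [b * ia, ia * ib + a * b, a * ib],
                [b * b, 2.0 * ib * b, ib * ib],
            ]
        )
    if form == "ABmm":
        g = g * (w, 0.5 * (w + 1.0), 1.0)
    elif form == "ABuu":
        g = g * (1.0, 0.5 * (w + 1.0), w)
    rs = g.sum(axis=1, keepdims=True)
    if rs.min() <= 0.0:
        raise ValueError("zero row sum in weighted kernel")
    return g / rs


def _eig3_stochastic(g: np.ndarray):
    """(evals, evecs, inv_evecs) of a row-stochastic 3x3, or None."""
    gf = g.ravel()
    det = (
        gf[0] * (gf[4] * gf[8] - gf[5] * gf[7])
        - gf[1] * (gf[3] * gf[8] - gf[5] * gf[6])
        + gf[2] * (gf[3] * gf[7] - gf[4] * gf[6])
    )
    p = gf[0] + gf[4] + gf[8] - 1.0
    disc = p * p - 4.0 * det
    if disc < 1e-13:
        return None
    r = np.sqrt(disc)
    l2, l3 = 0.5 * (p + r), 0.5 * (p - r)
    if abs(1.0 - l2) < 1e-10 or abs(1.0 - l3) < 1e-10 or abs(l2 - l3) < 1e-10:
        return None
    evecs = np.empty((3, 3))
    evecs[:, 0] = 1.0
    for col, lam in ((1, l2), (2, l3)):
        m0 = (gf[0] - lam, gf[1], gf[2])
        m1 = (gf[3], gf[4] - lam, gf[5])
        m2 = (gf[6], gf[7], gf[8] - lam)
        best_v, best_n2 = None, 0.0
        for ra, rb in ((m0, m1), (m0, m2), (m1, m2)):
            v = (
                ra[1] * rb[2] - ra[2] * rb[1],
                ra[2] * rb[0] - ra[0] * rb[2],
                ra[0] * rb[1] - ra[1] * rb[0],
            )
            n2 = v[0] * v[0] + v[1] * v[1] + v[2] * v[2]
            if n2 > best_n2:
                best_v, best_n2 = v, n2
        if best_n2 < 1e-60:
            return None
        norm = np.sqrt(best_n2)
        evecs[0, col] = best_v[0] / norm
        evecs[1, col] = best_v[1] / norm
        evecs[2, col] = best_v[2] / norm
    ef = evecs.ravel()
    dv = (
        ef[0] * (ef[4] * ef[8] - ef[5] * ef[7])
        - ef[1] * (ef[3] * ef[8] - ef[5] * ef[6])
        + ef[2] * (ef[3] * ef[7] - ef[4] * ef[6])
    )
    if abs(dv) < 1e-18:
        return None
    inv = (
        np.array(
            [
                [ef[4] * ef[8] - ef[5] * ef[7], ef[2] * ef[7] - ef[1] * ef[8], ef[1] * ef[5] - ef[2] * ef[4]],
                [ef[5] * ef[6] - ef[3] * ef[8], ef[0] * ef[8] - ef[2] * ef[6], ef[2] * ef[3] - ef[0] * ef[5]],
                [ef[3] * ef[7] - ef[4] * ef[6], ef[1] * ef[6] - ef[0] * ef[7], ef[0] * ef[4] - ef[1] * ef[3]],
            ]
        )
        / dv
    )
    return np.array([1.0, l2, l3]), evecs, inv


def _fast_objective(
    design: "_Design", spec: ModelSpec, a: float, b: float, w: float, gamma: float, c: float
) -> Optional[float]:
    """Objective via the closed-form spectrum; None on degeneracy."""
    try:
        g = _g_norm_fast(spec.system, spec.form, a, b, w)
    except ValueError:
        return None
    eig = _eig3_stochastic(g)
    if eig is None:
        return None
    evals, evecs, inv = eig
    if evals.min() < 0 and design.has_fractional:
        return None
    with np.errstate(invalid="ignore"):
        vpow = evals[None, :] ** design.taus[:, None]
    if not np.all(np.isfinite(vpow)):
        return None
    # powers[k] = evecs @ diag(vpow[k]) @ inv, batched as matmul
    powers = (evecs[None, :, :] * vpow[:, None, :]) @ inv
    powers[design.taus == 0.0] = np.eye(3)
    residual = max(1.0 - design.p1_obs - design.p3_obs, 0.0)
    pi = np.array(
        [design.p1_obs, residual + gamma * design.p3_obs, (1.0 - gamma) * design.p3_obs]
    )
    pi /= pi.sum()
    anc = pi @ powers[design.idx_anc]                      # (M, 3)
    inner = powers[design.idx_i] @ INDICATOR_MATRIX        # (M, 3, 3)
    per_anc = (inner * powers[design.idx_j]).sum(axis=2)   # (M, 3)
    d_star = np.clip((anc * per_anc).sum(axis=1), 0.0, 1.0)
    resid = design.D - d_star - c
    val = float(resid @ resid)
    if spec.form != AB_NULL:
        if spec.neutral or w == 1.0:
            if spec.system == "clonal":
                eq = b * b / (a + b) ** 2
            else:
                eq = (b * ((1 - b) ** 2 - (1 - a) ** 2 - 1)) / (
                    (a + b) * ((a + b - 1) ** 2 - 2)
                )
        else:
            st = inv[0]
            s = st.sum()
            if s == 0:
                return None
            eq = float(st[0] / s)
        val += design.M * (design.p_bar_1 - eq) ** 2
    return val if np.isfinite(val) else None


def _predict(design: _Design, spec: ModelSpec, params: EpimutationParams) -> np.ndarray:
    """Expected divergence D* for every pair (vectorized over pairs)."""
    kernel = build_kernel(spec, params)
    kp = KernelPowers(kernel.g_norm)
    powers = kp.powers(design.taus)
    gamma = 0.0 if spec.form == AB_NULL else params.gamma
    pi = founder_distribution(design.p1_obs, design.p3_obs, gamma).pi
    anc = np.einsum("a,mab->mb", pi, powers[design.idx_anc])
    a = powers[design.idx_i]
    b = powers[design.idx_j]
    inner = np.einsum("mnl,lk->mnk", a, INDICATOR_MATRIX)
    per_anc = np.einsum("mnk,mnk->mn", inner, b)
    return np.clip(np.einsum("mn,mn->m", anc, per_anc), 0.0, 1.0)


def _objective_value(design: _Design, spec: ModelSpec, params: EpimutationParams) -> float:
    d_star = _predict(design, spec, params)
    resid = design.D - d_star - params.c
    val = float(resid @ resid)
    if spec.form != AB_NULL:
        val += design.M * (design.p_bar_1 - equilibrium_uu(spec, params)) ** 2
    return val


def objective(
    theta: EpimutationParams, spec: ModelSpec, data: DivergenceDataset
) -> float:
    """Constrained least-squares objective at a parameter point."""
    if data.M < 1:
        raise ValueError("dataset has no pairs")
    return _objective_value(_Design(data), spec, theta)


# -- parameter transforms ------------------------------------------------

_EPS = 1e-12


def _to_x(params: EpimutationParams, spec: ModelSpec) -> np.ndarray:
    x = []
    for name in spec.free_parameters:
        v = getattr(params, name)
        if name == "c":
            x.append(np.log(max(v, _EPS)))
        else:
            x.append(logit(np.clip(v, _EPS, 1 - _EPS)))
    return np.array(x)


def _from_x(x: np.ndarray, spec: ModelSpec) -> EpimutationParams:
    vals = {"alpha": 0.0, "beta": 0.0, "w": 1.0, "gamma": 0.0, "c": 0.0}
    for name, xi in zip(spec.free_parameters, x):
        vals[name] = float(np.exp(xi)) if name == "c" else float(expit(xi))
    vals["c"] = min(vals["c"], 1.0)  # divergence is bounded by 1
    if vals["c"] < 1e-15:  # log-scale c can drift to denormals; report 0
        vals["c"] = 0.0
    return EpimutationParams(**vals)


def _start_points(
    design: _Design, spec: ModelSpec, options: FitOptions
) -> list[np.ndarray]:
    rng = np.random.default_rng(options.seed)
    delta_t = None
    c0 = max(float(design.D.min(initial=0.0)), 1e-8)
    # heuristic: regression slope of D on delta_t as a combined-rate guess
    slope = 1e-4
    starts = []
    heur = {"alpha": 1e-4, "beta": 1e-4, "w": 0.9, "gamma": 0.5, "c": c0}
    starts.append(
        np.array(
            [
                np.log(heur["c"]) if n == "c" else logit(np.clip(heur[n], _EPS, 1 - _EPS))
                for n in spec.free_parameters
            ]
        )
    )
    for _ in range(options.n_starts - 1):
        vals = {
            "alpha": 10 ** rng.uniform(-9, -1),
            "beta": 10 ** rng.uniform(-9, -1),
            "w": rng.uniform(0.05, 0.999),
            "gamma": rng.uniform(0.01, 0.99),
            "c": c0 * rng.uniform(0.5, 1.5) + 1e-10,
        }
        starts.append(
            np.array(
                [
                    np.log(vals[n]) if n == "c" else logit(np.clip(vals[n], _EPS, 1 - _EPS))
                    for n in spec.free_parameters
                ]
            )
        )
    return starts


@dataclass(frozen=True)
class FTestResult:
    """Nested-model F test: F = ((RSS_R - RSS_F)/df_num)/(RSS_F/df_den)."""

    F: float
    df_num: int
    df_den: int
    p_value: float
    rss_full: float
    rss_reduced: float
    optimizer_warning: bool = False


@dataclass
class BootstrapResult:
    """Residual-bootstrap replicate estimates and percentile intervals."""

    B: int
    seed: int
    level: float
    intervals: dict[str, tuple[float, float]]
    replicate_estimates: pd.DataFrame


@dataclass
class AgeProfile:
    """Least-squares profile of the founder age over a candidate grid."""

    ages: np.ndarray
    lsq: np.ndarray
    age_hat: float
    fits: list["EpimutationResults"]

    @property
    def best_fit(self) -> "EpimutationResults":
        return self.fits[int(np.argmin(self.lsq))]


class EpimutationResults:
    """Fit results: estimates, diagnostics and downstream analyses.

    Attributes follow the statsmodels convention (``params``,
    ``fittedvalues``, ``resid``, ``rsquared``, ``df_resid``); the
    aliases ``theta_hat``, ``rss``, ``r_squared`` and ``residuals``
    match the domain vocabulary.
    """

    def __init__(
        self,
        model: "EpimutationModel",
        params: EpimutationParams,
        objective_value: float,
        converged: bool,
        best_start: int,
        options: FitOptions,
    ):
        self.model = model
        self.spec = model.spec
        self.params = params
        self.theta_hat = params
        self.objective_value = float(objective_value)
        self.converged = bool(converged)
        self.best_start = int(best_start)
        self.options = options

        design = model._design
        d_star = _predict(design, self.spec, params)
        self.fittedvalues = d_star + params.c
        self.resid = design.D - self.fittedvalues
        self.rss = float(self.resid @ self.resid)
        self.nobs = design.M
        self.df_resid = design.M - self.spec.k
        self.sigma2_hat = self.rss / self.df_resid if self.df_resid > 0 else np.nan
        self.rsquared = 1.0 - self.rss / design.tss if design.tss > 0 else np.nan

    # spec-vocabulary aliases
    df = property(lambda self: self.df_resid)
    r_squared = property(lambda self: self.rsquared)
    residuals = property(lambda self: self.resid)
    fitted = property(lambda self: self.fittedvalues)

    def summary(self) -> str:
        lines = [
            "Epimutation model fit",
            "=" * 46,
            f"system: {self.spec.system:<12} form: {self.spec.form}",
            f"pairs (M): {self.nobs:<9} df resid: {self.df_resid}",
            f"RSS: {self.rss:.6e}   R^2: {self.rsquared:.4f}",
            f"sigma^2: {self.sigma2_hat:.6e}  converged: {self.converged}",
            "-" * 46,
        ]
        for name in self.spec.free_parameters:
            lines.append(f"{name:>8}: {getattr(self.params, name):.6e}")
        fixed = [n for n in ("alpha", "beta", "w", "gamma") if n not in self.spec.free_parameters]
        if fixed:
            lines.append(
                "fixed:    "
                + ", ".join(f"{n}={getattr(self.params, n):g}" for n in fixed)
            )
        lines.append("=" * 46)
        return "\n".join(lines)

    def bootstrap(
        self,
        B: int = 1000,
        seed: int = 0,
        level: float = 0.95,
        refit_starts: int = 1,
        maxfev: int = 400,
    ) -> BootstrapResult:
        """Residual bootstrap: resample fitted residuals with
        replacement, rebuild the response D_hat + eps*, refit, and take
        percentile intervals of the replicate estimates."""
        if B < 1:
            raise ValueError("B must be >= 1")
        design = self.model._design
        rng = np.random.default_rng(seed)
        base_x = _to_x(self.params, self.spec)
        opts = replace(
            self.options,
            n_starts=max(refit_starts, 1),
            maxfev=maxfev,
            tol=max(self.options.tol, 1e-7),
            xatol=max(self.options.xatol, 1e-4),
        )
        names = self.spec.free_parameters
        rows = np.empty((B, len(names)))
        for bi in range(B):
            eps = self.resid[rng.integers(0, design.M, design.M)]
            d_new = self.fittedvalues + eps
            boot_design = design.with_response(d_new)
            res_params, _, _, _ = _minimize(
                boot_design,
                self.spec,
                opts,
                extra_starts=[base_x],
                rng_seed=seed + 1 + bi,
                simplex_scale=0.05,
                polish=False,
            )
            rows[bi] = [getattr(res_params, n) for n in names]
        reps = pd.DataFrame(rows, columns=list(names))
        a = (1.0 - level) / 2.0
        intervals = {
            n: (float(np.quantile(reps[n], a)), float(np.quantile(reps[n], 1 - a)))
            for n in names
        }
        return BootstrapResult(B, seed, level, intervals, reps)

    def compare_f_test(self, reduced: "EpimutationResults") -> FTestResult:
        return compare_models(self, reduced)

    def plot_fit(self, ax=None):
        """Scatter of observed D against divergence time with the
        fitted expectation overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pairs = self.model.data.pairs
        ax.scatter(pairs["delta_t"], pairs["D"], s=12, alpha=0.6, label="observed")
        order = np.argsort(pairs["delta_t"].to_numpy())
        ax.plot(
            pairs["delta_t"].to_numpy()[order],
            self.fittedvalues[order],
            color="C3",
            label=f"{self.spec.form} fit",
        )
        ax.set_xlabel("divergence time")
        ax.set_ylabel("5mC divergence D")
        ax.legend()
        return ax


class EpimutationModel:
    """Epimutation rate model for a pedigree divergence dataset.

    Parameters
    ----------
    data
        Divergence dataset (all unique sample pairs plus founder-state
        proportions).
    spec
        Model specification; alternatively pass ``system=``/``form=``.
    """

    def __init__(
        self,
        data: DivergenceDataset,
        spec: Optional[ModelSpec] = None,
        system: Optional[str] = None,
        form: Optional[str] = None,
    ):
        if spec is None:
            spec = ModelSpec(system or "selfing", form or "ABneutral")
        self.data = data
        self.spec = spec
        self._design = _Design(data)

    @classmethod
    def from_samples(
        cls,
        pedigree: Pedigree,
        samples: Sequence[MethylomeSample],
        founder_sample: Optional[str] = None,
        common_loci: bool = False,
        **spec_kwargs,
    ) -> "EpimutationModel":
        data = build_dataset(pedigree, samples, founder_sample, common_loci)
        return cls(data, **spec_kwargs)

    @classmethod
    def from_divergence_table(cls, path, **spec_kwargs) -> "EpimutationModel":
        return cls(DivergenceDataset.from_tsv(path), **spec_kwargs)

    def fit(
        self,
        options: Optional[FitOptions] = None,
        warm_start: Optional[EpimutationParams] = None,
        **kwargs,
    ) -> EpimutationResults:
        """Fit by constrained least squares with seeded restarts.

        Deterministic given (data, spec, options.seed).  ``kwargs`` are
        forwarded to :class:`FitOptions`.
        """
        if options is None:
            options = FitOptions(**kwargs)
        elif kwargs:
            options = replace(options, **kwargs)
        design = self._design
        if design.M <= self.spec.k:
            raise ValueError(
                f"need more pairs (M={design.M}) than free parameters (k={self.spec.k})"
            )
        extra = [_to_x(warm_start, self.spec)] if warm_start is not None else None
        params, value, converged, best_start = _minimize(
            design, self.spec, options, extra_starts=extra
        )
        return EpimutationResults(self, params, value, converged, best_start, options)


def _minimize(
    design: _Design,
    spec: ModelSpec,
    options: FitOptions,
    extra_starts: Optional[list[np.ndarray]] = None,
    rng_seed: Optional[int] = None,
    simplex_scale: Optional[float] = None,
    polish: bool = True,
) -> tuple[EpimutationParams, float, bool, int]:
    """Best Nelder-Mead run over the start schedule; returns
    (params, objective value, converged flag, best start index)."""
    if spec.form == AB_NULL:
        # intercept-only: closed-form least squares over c >= 0
        params0 = EpimutationParams(0.0, 0.0, w=1.0, gamma=0.0, c=0.0)
        d_star = _predict(design, spec, params0)
        c_hat = float(np.clip(np.mean(design.D - d_star), 0.0, 1.0))
        params = replace(params0, c=c_hat)
        return params, _objective_value(design, spec, params), True, 0

    free = spec.free_parameters

    def fun(x: np.ndarray) -> float:
        vals = {"alpha": 0.0, "beta": 0.0, "w": 1.0, "gamma": 0.0, "c": 0.0}
        for name, xi in zip(free, x):
            vals[name] = float(np.exp(xi)) if name == "c" else float(expit(xi))
        vals["c"] = min(vals["c"], 1.0)
        val = _fast_objective(
            design, spec, vals["alpha"], vals["beta"], vals["w"], vals["gamma"], vals["c"]
        )
        if val is None:
            try:
                val = _objective_value(design, spec, _from_x(x, spec))
            except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                return _BIG
        return val if np.isfinite(val) else _BIG

    def logfun(x: np.ndarray) -> float:
        return float(np.log(max(fun(x), 1e-300)))

    opts = replace(options, seed=options.seed if rng_seed is None else rng_seed)
    starts = list(extra_starts or []) + _start_points(design, spec, opts)
    starts = starts[: max(options.n_starts, len(extra_starts or []))]

    nm_options = {
        "maxfev": options.maxfev,
        "fatol": max(options.tol, 1e-14),
        "xatol": options.xatol,
    }
    best = None
    best_idx = 0
    for i, x0 in enumerate(starts):
        run_opts = dict(nm_options)
        if simplex_scale is not None:
            simplex = np.vstack([x0, x0 + simplex_scale * np.eye(len(x0))])
            run_opts["initial_simplex"] = simplex
        res = _opt.minimize(logfun, x0, method="Nelder-Mead", options=run_opts)
        if best is None or res.fun < best.fun:
            best, best_idx = res, i
    converged = bool(best.success)
    if polish:
        second = _opt.minimize(logfun, best.x, method="Nelder-Mead", options=nm_options)
        if second.fun <= best.fun:
            best = second
        converged = bool(converged or second.success)
    params = _from_x(best.x, spec)
    return params, fun(best.x), converged, best_idx


def fit(
    data: DivergenceDataset, spec: ModelSpec, options: Optional[FitOptions] = None
) -> EpimutationResults:
    """Functional wrapper around :meth:`EpimutationModel.fit`."""
    return EpimutationModel(data, spec).fit(options)


def bootstrap(
    data: DivergenceDataset,
    fit_result: EpimutationResults,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapResult:
    """Functional wrapper around :meth:`EpimutationResults.bootstrap`."""
    return fit_result.bootstrap(B=B, seed=seed, level=level)


def _f_statistic(
    rss_reduced: float, rss_full: float, df_reduced: int, df_full: int
) -> tuple[float, int, int]:
    df_num = df_reduced - df_full
    if df_num <= 0 or df_full <= 0:
        raise ValueError("invalid degrees of freedom for nested comparison")
    f = ((rss_reduced - rss_full) / df_num) / (rss_full / df_full)
    return f, df_num, df_full


def compare_models(
    full: EpimutationResults, reduced: EpimutationResults
) -> FTestResult:
    """Nested F test of the full against the reduced model.

    A full-model RSS above the reduced one (beyond tolerance) indicates
    optimizer failure; the statistic is clamped to 0 and flagged.
    """
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError(
            f"{reduced.spec.form} is not nested in {full.spec.form} "
            "(or systems differ)"
        )
    if full.nobs != reduced.nobs or not np.allclose(
        full.model._design.D, reduced.model._design.D
    ):
        raise ValueError("full and reduced fits must use the same data")
    f, df_num, df_den = _f_statistic(reduced.rss, full.rss, reduced.df_resid, full.df_resid)
    flag = False
    if f < 0:
        if full.rss > reduced.rss * (1 + 1e-8) + 1e-12:
            warnings.warn(
                "full-model RSS exceeds reduced-model RSS; optimizer likely "
                "failed to converge — refit with more starts",
                RuntimeWarning,
            )
            flag = True
        f = 0.0
    p = float(_stats.f.sf(f, df_num, df_den))
    return FTestResult(float(f), df_num, df_den, p, full.rss, reduced.rss, flag)


def profile_founder_age(
    pedigree_builder: Callable[[float], Pedigree],
    samples: Sequence[MethylomeSample],
    spec: ModelSpec,
    age_grid: Sequence[float],
    options: Optional[FitOptions] = None,
    founder_sample: Optional[str] = None,
) -> AgeProfile:
    """Profile the least-squares objective over candidate founder ages.

    Pair divergences depend only on the methylomes and are computed
    once; each candidate age rebuilds the pedigree (hence the divergence
    times), refits the model and records the minimized objective.  The
    estimated age is the argmin, ties broken toward the smallest age.
    Successive fits warm-start at the previous optimum.
    """
    ages = np.sort(np.asarray(list(age_grid), dtype=float))
    if len(ages) == 0:
        raise ValueError("age grid is empty")
    if options is None:
        options = FitOptions()

    by_id = {s.sample_id: s for s in samples}
    ids = sorted(by_id)
    cache: dict[tuple[str, str], tuple[float, int]] = {}
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            si, sj = ids[a_idx], ids[b_idx]
            cache[(si, sj)] = pair_divergence(by_id[si], by_id[sj])

    props, p_bar_1 = state_proportions(list(by_id.values()))
    if founder_sample is not None:
        row = props.loc[founder_sample]
        p1_obs, p3_obs = row["x1"] / row["N"], row["x3"] / row["N"]
    else:
        p1_obs = float((props["x1"] / props["N"]).mean())
        p3_obs = float((props["x3"] / props["N"]).mean())

    from .divergence import PAIR_COLUMNS

    lsq = np.empty(len(ages))
    fits: list[EpimutationResults] = []
    warm: Optional[EpimutationParams] = None
    for gi, age in enumerate(ages):
        ped = pedigree_builder(float(age))
        rows = []
        for pt in ped.pair_times(ids):
            d, n = cache[(pt.sample_i, pt.sample_j)]
            rows.append(
                (pt.sample_i, pt.sample_j, pt.t_i, pt.t_j, pt.t_ij, pt.delta_t, d, n)
            )
        data = DivergenceDataset(
            pd.DataFrame(rows, columns=PAIR_COLUMNS),
            float(p1_obs),
            float(p3_obs),
            p_bar_1,
        )
        res = EpimutationModel(data, spec).fit(options, warm_start=warm)
        warm = res.params
        lsq[gi] = res.objective_value
        fits.append(res)
    age_hat = float(ages[int(np.argmin(lsq))])
    return AgeProfile(ages, lsq, age_hat, fits)
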