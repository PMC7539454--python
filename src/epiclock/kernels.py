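"""Markov transition kernels and expected 5mC divergence.

The diploid epigenotype at a cytosine locus is one of ``u/u`` (both
epialleles unmethylated), ``m/u`` (epiheterozygote) or ``m/m`` (both
methylated), coded numerically as 0, 0.5 and 1.  A locus evolves through
a pedigree as a three-state Markov chain.  The per-time-unit kernel is a
function of the per-allele gain rate ``alpha`` (probability of a
stochastic u -> m switch per time unit), the per-allele loss rate
``beta`` (m -> u), the propagation system (sexual selfing with Mendelian
segregation of epialleles, versus clonal/somatic mitotic propagation)
and, under selection, a fitness coefficient ``w`` in [0, 1] that weighs
transitions into the disfavoured epigenotypes.

Four model forms are distinguished:

``ABneutral``
    neutral accumulation (w = 1, alpha and/or beta > 0)
``ABmm``
    selection against the unmethylated epiallele u (w weighs u/u)
``ABuu``
    selection against the methylated epiallele m (w weighs m/m)
``ABnull``
    no accumulation (alpha = beta = 0, w = 1); intercept-only reference

The expected divergence between two samples descends from the state of
their most recent common ancestor: the ancestor state distribution is
``pi @ G'^(t_ij - 1)`` (with the pedigree founder at internal time 1)
and the two descendants evolve conditionally independently through
``G'^(t_i - t_ij)`` and ``G'^(t_j - t_ij)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as _sla

__all__ = [
    "SELFING",
    "CLONAL",
    "AB_NEUTRAL",
    "AB_MM",
    "AB_UU",
    "AB_NULL",
    "STATE_VALUES",
    "INDICATOR_MATRIX",
    "ModelSpec",
    "EpimutationParams",
    "TransitionKernel",
    "FounderDistribution",
    "raw_transition_matrix",
    "selection_weights",
    "normalized_kernel",
    "build_kernel",
    "KernelPowers",
    "kernel_power",
    "stationary_distribution",
    "founder_distribution",
    "expected_divergence",
    "equilibrium_uu",
]

SELFING = "selfing"
CLONAL = "clonal"
SYSTEMS = (SELFING, CLONAL)

AB_NEUTRAL = "ABneutral"
AB_MM = "ABmm"
AB_UU = "ABuu"
AB_NULL = "ABnull"
FORMS = (AB_NEUTRAL, AB_MM, AB_UU, AB_NULL)

#: state coding, fixed order (u/u, m/u, m/m)
STATE_VALUES = np.array([0.0, 0.5, 1.0])

#: divergence indicator I(l, m) = |s_l - s_m| on the 3x3 state grid
INDICATOR_MATRIX = np.abs(STATE_VALUES[:, None] - STATE_VALUES[None, :])

# (reduced, full) pairs of nested model forms
_NESTED_FORMS = {
    (AB_NULL, AB_NEUTRAL),
    (AB_NULL, AB_MM),
    (AB_NULL, AB_UU),
    (AB_NEUTRAL, AB_MM),
    (AB_NEUTRAL, AB_UU),
}


@dataclass(frozen=True)
class ModelSpec:
    """Selects the propagation system and the model form."""

    system: str = SELFING
    form: str = AB_NEUTRAL

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}; expected one of {SYSTEMS}")
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {FORMS}")

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of the parameters estimated under this form."""
        if self.form == AB_NULL:
            return ("c",)
        if self.form == AB_NEUTRAL:
            return ("alpha", "beta", "gamma", "c")
        return ("alpha", "beta", "w", "gamma", "c")

    @property
    def k(self) -> int:
        return len(self.free_parameters)

    @property
    def neutral(self) -> bool:
        """True if the form fixes w = 1."""
        return self.form in (AB_NEUTRAL, AB_NULL)

    def is_nested_in(self, full: "ModelSpec") -> bool:
        """True if this spec is a reduced version of ``full`` (same system)."""
        return self.system == full.system and (self.form, full.form) in _NESTED_FORMS


@dataclass(frozen=True)
class EpimutationParams:
    """Parameter vector Theta = (alpha, beta, w, gamma, c [, founder_age]).

    Parameters
    ----------
    alpha, beta
        Per-allele gain (u -> m) and loss (m -> u) probabilities per
        pedigree time unit (generations for MA lines, years for trees).
    w
        Selection coefficient in [0, 1]; 1 means neutrality.
    gamma
        Fraction of founder loci observed as fully methylated that are
        actually epiheterozygous; splits the observed m/m mass when
        building the founder distribution.
    c
        Intercept of the divergence model; absorbs measurement error.
    founder_age
        Optional total age of the pedigree founder (tree dating).
    """

    alpha: float
    beta: float
    w: float = 1.0
    gamma: float = 0.5
    c: float = 0.0
    founder_age: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "w", "gamma"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not np.isfinite(self.c) or self.c < 0:
            raise ValueError(f"intercept c={self.c} must be finite and >= 0")


def raw_transition_matrix(system: str, alpha: float, beta: float) -> np.ndarray:
    """Unweighted one-time-unit transition matrix, rows (u/u, m/u, m/m).

    For a selfing system the epiheterozygote row reflects Mendelian
    segregation of the two epialleles; for clonal/somatic propagation the
    two alleles switch independently with no segregation.
    """
    if not (0.0 <= alpha <= 1.0) or not (0.0 <= beta <= 1.0):
        raise ValueError(f"alpha={alpha}, beta={beta} must lie in [0, 1]")
    a, b = alpha, beta
    if system == SELFING:
        return np.array(
            [
                [(1 - a) ** 2, 2 * (1 - a) * a, a**2],
                [
                    0.25 * (b + 1 - a) ** 2,
                    0.5 * (b + 1 - a) * (a + 1 - b),
                    0.25 * (a + 1 - b) ** 2,
                ],
                [b**2, 2 * (1 - b) * b, (1 - b) ** 2],
            ]
        )
    if system == CLONAL:
        return np.array(
            [
                [(1 - a) ** 2, 2 * (1 - a) * a, a**2],
                [b * (1 - a), (1 - a) * (1 - b) + a * b, a * (1 - b)],
                [b**2, 2 * (1 - b) * b, (1 - b) ** 2],
            ]
        )
    raise ValueError(f"unknown system {system!r}")


def selection_weights(form: str, w: float = 1.0) -> np.ndarray:
    """Selection weight matrix W applied entrywise to the raw kernel.

    ``ABmm`` weighs against epiallele u (columns w, (w+1)/2, 1); ``ABuu``
    against epiallele m (columns 1, (w+1)/2, w).  The neutral and null
    forms return the all-ones matrix.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}")
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"w={w} outside [0, 1]")
    if form == AB_MM:
        cols = np.array([w, (w + 1) / 2, 1.0])
    elif form == AB_UU:
        cols = np.array([1.0, (w + 1) / 2, w])
    else:
        cols = np.ones(3)
    return np.tile(cols, (3, 1))


def normalized_kernel(g_raw: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-normalized kernel G' = diag(rowsums(G o W))^-1 (G o W)."""
    h = np.asarray(g_raw, dtype=float) * np.asarray(weights, dtype=float)
    rowsums = h.sum(axis=1)
    if np.any(rowsums <= 0):
        raise ValueError("zero row sum in weighted kernel; degenerate (alpha, beta, w)")
    return h / rowsums[:, None]


@dataclass(frozen=True)
class TransitionKernel:
    """Raw kernel, selection weights and the row-stochastic G'."""

    g_raw: np.ndarray
    weights: np.ndarray
    g_norm: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.g_norm < -1e-12):
            raise ValueError("negative entry in normalized kernel")
        if np.max(np.abs(self.g_norm.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("normalized kernel rows do not sum to 1")


def build_kernel(spec: ModelSpec, params: EpimutationParams) -> TransitionKernel:
    """Assemble the transition kernel for a model spec and parameters."""
    a, b = params.alpha, params.beta
    if spec.form == AB_NULL:
        a = b = 0.0
    w = 1.0 if spec.neutral else params.w
    g_raw = raw_transition_matrix(spec.system, a, b)
    weights = selection_weights(spec.form, w)
    return TransitionKernel(g_raw, weights, normalized_kernel(g_raw, weights))


class KernelPowers:
    """Real (possibly fractional) matrix powers of a 3x3 kernel.

    Uses the eigendecomposition G' = p V p^-1, so G'^tau = p V^tau p^-1
    for any tau >= 0.  Non-diagonalizable or numerically complex cases
    fall back to exact integer powers or to the matrix-logarithm route
    (scaling and squaring), with imaginary parts below 1e-9 clamped.
    """

    def __init__(self, g: np.ndarray):
        self.g = np.asarray(g, dtype=float)
        if self.g.shape != (3, 3):
            raise ValueError("kernel must be 3x3")
        evals, evecs = np.linalg.eig(self.g)
        self._evals = evals.astype(complex)
        self._evecs = evecs.astype(complex)
        self._diagonalizable = False
        try:
            self._inv = np.linalg.inv(self._evecs)
            recon = (self._evecs * self._evals) @ self._inv
            self._diagonalizable = np.max(np.abs(recon - self.g)) < 1e-9
        except np.linalg.LinAlgError:
            self._inv = None

    def powers(self, taus: Sequence[float]) -> np.ndarray:
        """Stack of G'^tau for each exponent, shape (len(taus), 3, 3)."""
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        if np.any(taus < -1e-12):
            raise ValueError("negative exponent")
        taus = np.clip(taus, 0.0, None)
        out = None
        if self._diagonalizable:
            with np.errstate(invalid="ignore"):
                v = self._evals[None, :] ** taus[:, None]
            cand = np.einsum("ab,kb,bc->kac", self._evecs, v, self._inv)
            if np.all(np.isfinite(cand.real)) and np.max(np.abs(cand.imag)) < 1e-9:
                out = cand.real
        if out is None:
            out = np.stack([self._fallback(t) for t in taus])
        out[taus == 0.0] = np.eye(3)
        return out

    def power(self, tau: float) -> np.ndarray:
        return self.powers([tau])[0]

    def _fallback(self, tau: float) -> np.ndarray:
        if abs(tau - round(tau)) < 1e-9:
            return np.linalg.matrix_power(self.g, int(round(tau)))
        cand = _sla.fractional_matrix_power(self.g, tau)
        if np.iscomplexobj(cand):
            if np.max(np.abs(cand.imag)) > 1e-9:
                raise ValueError(f"fractional power of kernel is complex at tau={tau}")
            cand = cand.real
        return cand

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution (dominant left eigenvector, sum 1)."""
        if self._diagonalizable:
            i = int(np.argmin(np.abs(self._evals - 1.0)))
            v = self._inv[i, :].real
        else:
            evals, evecs = np.linalg.eig(self.g.T)
            i = int(np.argmin(np.abs(evals - 1.0)))
            v = evecs[:, i].real
        v = v / v.sum()
        return np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum()


def kernel_power(g_norm: np.ndarray, tau: float) -> np.ndarray:
    """G'^tau via eigendecomposition; tau may be any non-negative real."""
    return KernelPowers(g_norm).power(tau)


def stationary_distribution(g_norm: np.ndarray) -> np.ndarray:
    return KernelPowers(g_norm).stationary


@dataclass(frozen=True)
class FounderDistribution:
    """Probability row vector pi = (p1, p2, p3) over (u/u, m/u, m/m)."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (3,):
            raise ValueError("founder distribution must have 3 components")
        if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-6:
            raise ValueError(f"invalid founder simplex {pi}")


def founder_distribution(p1_obs: float, p3_obs: float, gamma: float) -> FounderDistribution:
    """Founder state distribution from observed u/u and m/m proportions.

    Methylation callers rarely emit epiheterozygous calls, so the
    observed m/m mass ``p3_obs`` is split: a fraction ``gamma`` is
    assigned to the hidden m/u class.  Any residual mass
    ``1 - p1_obs - p3_obs`` (loci observed as intermediate) stays in the
    m/u class.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError(f"gamma={gamma} outside [0, 1]")
    if p1_obs < -1e-12 or p3_obs < -1e-12 or p1_obs + p3_obs > 1.0 + 1e-9:
        raise ValueError(f"invalid founder proportions p1={p1_obs}, p3={p3_obs}")
    residual = max(1.0 - p1_obs - p3_obs, 0.0)
    pi = np.array([p1_obs, residual + gamma * p3_obs, (1.0 - gamma) * p3_obs])
    total = pi.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"founder distribution sums to {total}, not 1")
    return FounderDistribution(pi / total)


def _unpack_times(times) -> tuple[float, float, float]:
    if hasattr(times, "t_i"):
        return float(times.t_i), float(times.t_j), float(times.t_ij)
    t_i, t_j, t_ij = times
    return float(t_i), float(t_j), float(t_ij)


def expected_divergence(
    params: EpimutationParams,
    spec: ModelSpec,
    times,
    pi: FounderDistribution,
) -> float:
    """Expected 5mC divergence D* between two samples under the model.

    ``times`` is a PairTimes-like object (attributes t_i, t_j, t_ij on
    the internal scale where the founder sits at time 1) or a
    (t_i, t_j, t_ij) triple.  The value is

        sum_n [pi G'^(t_ij-1)]_n  sum_l sum_m I(l, m)
              (G'^(t_i-t_ij))_{n,l} (G'^(t_j-t_ij))_{n,m}

    i.e. the indicator averaged over the ancestor distribution and the
    two conditionally independent descendant chains.
    """
    t_i, t_j, t_ij = _unpack_times(times)
    if t_ij < 1.0 - 1e-9:
        raise ValueError(f"t_ij={t_ij} < 1; internal times put the founder at 1")
    if t_i < t_ij - 1e-9 or t_j < t_ij - 1e-9:
        raise ValueError("sample times must not precede the ancestor time")
    kernel = build_kernel(spec, params)
    kp = KernelPowers(kernel.g_norm)
    anc = pi.pi @ kp.power(t_ij - 1.0)
    a = kp.power(max(t_i - t_ij, 0.0))
    b = kp.power(max(t_j - t_ij, 0.0))
    val = float(anc @ np.einsum("nl,lm,nm->n", a, INDICATOR_MATRIX, b))
    return float(min(max(val, 0.0), 1.0))


def equilibrium_uu(spec: ModelSpec, params: EpimutationParams) -> float:
    """Equilibrium proportion of u/u loci, p1(t_inf).

    Closed forms exist for the neutral (w = 1) selfing and clonal
    systems; under selection the u/u component of the numeric stationary
    distribution of G' is returned.
    """
    a, b = params.alpha, params.beta
    if a + b <= 0.0:
        raise ValueError("equilibrium undefined for alpha = beta = 0")
    w = 1.0 if spec.neutral else params.w
    if w == 1.0:
        if spec.system == CLONAL:
            return b * b / (a + b) ** 2
        return (b * ((1 - b) ** 2 - (1 - a) ** 2 - 1)) / (
            (a + b) * ((a + b - 1) ** 2 - 2)
        )
    kernel = build_kernel(spec, params)
    return float(KernelPowers(kernel.g_norm).stationary[0])
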