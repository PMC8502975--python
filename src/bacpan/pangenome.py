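"""Pan-genome partitioning, rarefaction curves, and openness fitting.

The presence-absence matrix is partitioned into core (present in all
strains), dispensable (in at least two but not all) and strain-specific
(exactly one) families. Random genome orderings produce pan/core/new-gene
accumulation curves whose per-depth medians are fitted with

* Heaps' law for the pan curve:  y = A_pan * x**B_pan + C_pan, where x is
  the number of genomes and y the cumulative family count. The exponent
  B_pan (the gamma of the infinitely-many-genes literature) classifies the
  pan-genome: strictly 0 < B_pan < 1 means the pan-genome grows without
  bound ("open"); B_pan <= 0 or >= 1 means it plateaus ("closed").
* an exponential decay for the core curve:  y = A_core * exp(B_core*x) + C_core.

Both fits are exposed statsmodels-style: construct a model from the curve,
call ``fit()``, and read estimates, standard errors and diagnostics off the
results object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, OptimizeWarning

from .cluster import PresenceAbsenceMatrix
from .errors import FitConvergenceError, InputError


@dataclass(frozen=True)
class PanPartition:
    n_pan: int
    n_core: int
    n_dispensable: int
    n_specific: int
    per_strain_specific: dict[str, int]

    @property
    def core_fraction(self) -> float:
        return self.n_core / self.n_pan if self.n_pan else float("nan")


@dataclass
class CurvePoint:
    x: int  # number of genomes
    y_median: float
    y_samples: list[float] = field(default_factory=list)


def partition(matrix: PresenceAbsenceMatrix) -> PanPartition:
    """Classify every family as core, dispensable, or strain-specific."""
    n_strains = len(matrix.strains)
    if n_strains < 2:
        raise InputError("partition needs at least 2 strains; with one strain "
                         "every family would be both core and specific")
    presence = matrix.presence()
    counts = presence.sum(axis=1)
    n_core = int((counts == n_strains).sum())
    n_specific = int((counts == 1).sum())
    n_pan = int(len(counts))
    specific = presence.loc[counts == 1]
    per_strain = {s: int(specific[s].sum()) for s in matrix.strains}
    return PanPartition(
        n_pan=n_pan,
        n_core=n_core,
        n_dispensable=n_pan - n_core - n_specific,
        n_specific=n_specific,
        per_strain_specific=per_strain,
    )


def sample_curves(matrix: PresenceAbsenceMatrix, n_orderings: int = 1000,
                  seed: int = 0) -> tuple[list[CurvePoint], list[CurvePoint], list[CurvePoint]]:
    """Pan/core/new-gene accumulation curves over random genome orderings.

    If the total number of orderings n! does not exceed ``n_orderings``, all
    permutations are enumerated (exact medians); otherwise ``n_orderings``
    random permutations are sampled with the given seed. Returns
    (pan, core, new_genes) curves; each point carries the per-ordering
    samples and their exact median.
    """
    if n_orderings < 1:
        raise InputError("n_orderings must be >= 1")
    presence = matrix.presence().to_numpy()
    strains = matrix.strains
    n = len(strains)
    total = math.factorial(n)
    if total <= n_orderings:
        orderings = [list(p) for p in permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        orderings = [list(rng.permutation(n)) for _ in range(n_orderings)]

    pan_samples = np.empty((len(orderings), n), dtype=float)
    core_samples = np.empty_like(pan_samples)
    new_samples = np.empty_like(pan_samples)
    for k, order in enumerate(orderings):
        seen = np.zeros(presence.shape[0], dtype=bool)
        inall = np.ones(presence.shape[0], dtype=bool)
        prev = 0
        for depth, strain_idx in enumerate(order):
            col = presence[:, strain_idx]
            seen |= col
            inall &= col
            pan = int(seen.sum())
            pan_samples[k, depth] = pan
            core_samples[k, depth] = int(inall.sum())
            new_samples[k, depth] = pan - prev
            prev = pan

    def collect(arr) -> list[CurvePoint]:
        return [CurvePoint(x=d + 1, y_median=float(np.median(arr[:, d])),
                           y_samples=arr[:, d].tolist())
                for d in range(n)]

    return collect(pan_samples), collect(core_samples), collect(new_samples)


def classify_openness(b_pan: float, boundary_atol: float = 1e-9) -> str:
    """Open iff the Heaps exponent lies strictly inside (0, 1).

    The boundary itself is closed (an exact power law with B = 1 grows
    linearly forever but is conventionally not "open"); estimates within
    ``boundary_atol`` of 0 or 1 are treated as sitting on the boundary so
    that floating-point jitter around an exactly linear curve cannot flip
    the verdict.
    """
    if not np.isfinite(b_pan):
        raise InputError("B_pan must be finite")
    return "open" if boundary_atol < b_pan < 1.0 - boundary_atol else "closed"


def _heaps(x, a, b, c):
    return a * np.power(x, b) + c


def _core_exp(x, a, b, c):
    return a * np.exp(b * x) + c


class _CurveModelBase:
    """Three-parameter nonlinear least squares with multi-start initialization."""

    _func: Callable
    _param_names: tuple[str, str, str]
    _model_label: str

    def __init__(self, x: Sequence[float], y: Sequence[float]):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise InputError("x and y must have equal length")
        if x.size < 4:
            raise InputError("need at least 4 points to fit 3 parameters")
        if not np.all(np.diff(x) > 0):
            raise InputError("x must be strictly increasing")
        self.x = x
        self.y = y

    @classmethod
    def from_curve(cls, points: Sequence[CurvePoint]):
        return cls([p.x for p in points], [p.y_median for p in points])

    def _starts(self) -> list[tuple[float, float, float]]:
        raise NotImplementedError

    _b_grid: tuple[float, float] = (-3.0, 3.0)

    def _basis(self, b: float) -> np.ndarray:
        """Column of the B-conditional linear model [basis(x; b), 1]."""
        raise NotImplementedError

    def _profile(self, b: float) -> tuple[float, float, float]:
        """For fixed B the model is linear in (A, C): solve and return
        (A, C, RSS)."""
        design = np.column_stack([self._basis(b), np.ones_like(self.x)])
        coef, *_ = np.linalg.lstsq(design, self.y, rcond=None)
        rss = float(np.sum((self.y - design @ coef) ** 2))
        return float(coef[0]), float(coef[1]), rss

    def fit(self):
        """Nonlinear least squares via B-profiling plus curve_fit polish.

        The exponent/rate B is profiled on a grid (the two remaining
        parameters are solved linearly), refined by bounded scalar
        minimization, then polished with full 3-parameter curve_fit from
        the profile solution and the conventional multi-starts. The
        profile path guarantees a converged answer even where the free
        optimizer diverges (e.g. a step-like core curve pushing B to the
        boundary); in that case the covariance is reported as NaN.
        """
        # Degenerate flat data: no scale to fit; report A=0, B=0, C=mean.
        if np.ptp(self.y) < 1e-12 * max(1.0, abs(self.y).max()):
            return self._make_results((0.0, 0.0, float(self.y.mean())),
                                      np.full((3, 3), np.nan), 0.0, degenerate=True)
        from scipy.optimize import minimize_scalar

        lo, hi = self._b_grid
        grid = np.linspace(lo, hi, 121)
        rss_grid = [self._profile(b)[2] for b in grid]
        k = int(np.argmin(rss_grid))
        b_lo = grid[max(k - 1, 0)]
        b_hi = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(lambda b: self._profile(b)[2],
                              bounds=(b_lo, b_hi), method="bounded",
                              options={"xatol": 1e-10})
        b_prof = float(res.x)
        a_prof, c_prof, rss_prof = self._profile(b_prof)
        best = ((a_prof, b_prof, c_prof), np.full((3, 3), np.nan), rss_prof)

        diagnostics = []
        for p0 in [(a_prof, b_prof, c_prof)] + self._starts():
            for method in ("lm", "trf"):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", OptimizeWarning)
                        popt, pcov = curve_fit(self._func, self.x, self.y, p0=p0,
                                               method=method, maxfev=20000)
                except (RuntimeError, ValueError) as exc:
                    diagnostics.append((p0, method, str(exc)))
                    continue
                rss = float(np.sum((self.y - self._func(self.x, *popt)) ** 2))
                if np.all(np.isfinite(popt)) and rss <= best[2] * (1 + 1e-12):
                    best = (tuple(popt), pcov, rss)
                break  # converged; skip the fallback method
        popt, pcov, rss = best
        if not np.all(np.isfinite(popt)):
            raise FitConvergenceError(
                f"{self._model_label}: no finite fit found", diagnostics)
        return self._make_results(tuple(popt), np.asarray(pcov), rss, degenerate=False)

    def _make_results(self, params, pcov, rss, degenerate):
        raise NotImplementedError


@dataclass
class _CurveResultsBase:
    """Shared results surface: params, covariance, diagnostics, summary()."""

    model: _CurveModelBase
    params: tuple[float, float, float]
    cov_params: np.ndarray
    residual_sum_squares: float
    degenerate: bool

    @property
    def bse(self) -> tuple[float, float, float]:
        d = np.sqrt(np.abs(np.diag(self.cov_params)))
        return tuple(float(v) for v in d)

    def predict(self, x) -> np.ndarray:
        return self.model._func(np.asarray(x, dtype=float), *self.params)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.x)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    def summary(self) -> str:
        names = self.model._param_names
        lines = [
            f"{self.model._model_label}",
            f"  n points: {self.model.x.size}   RSS: {self.residual_sum_squares:.6g}",
        ]
        for name, value, se in zip(names, self.params, self.bse):
            se_text = f" (se {se:.4g})" if np.isfinite(se) else ""
            lines.append(f"  {name} = {value:.6g}{se_text}")
        return "\n".join(lines)


class HeapsLawModel(_CurveModelBase):
    """Heaps-law pan-genome model y = A * x**B + C fitted to curve medians."""

    _func = staticmethod(_heaps)
    _param_names = ("A_pan", "B_pan", "C_pan")
    _model_label = "Heaps-law pan-genome fit: y = A*x^B + C"
    _b_grid = (-3.0, 3.0)

    def _basis(self, b):
        return np.power(self.x, b)

    def _starts(self):
        a0 = float(np.ptp(self.y))
        c0 = float(self.y.min())
        return [(max(a0, 1e-6), b0, c0) for b0 in (0.1, 0.5, 0.9)]

    def _make_results(self, params, pcov, rss, degenerate):
        return HeapsFitResults(self, params, np.asarray(pcov), rss, degenerate)


@dataclass
class HeapsFitResults(_CurveResultsBase):
    @property
    def A_pan(self) -> float:
        return self.params[0]

    @property
    def B_pan(self) -> float:
        return self.params[1]

    @property
    def C_pan(self) -> float:
        return self.params[2]

    @property
    def openness(self) -> str:
        if self.degenerate:
            return "closed"  # a flat pan curve cannot be open
        return classify_openness(self.B_pan)

    def new_genes_at_next(self, n: int) -> float:
        """Predicted pan(n+1) - pan(n): new families from one more genome."""
        if n < 1:
            raise InputError("n must be >= 1")
        return float(self.predict([n + 1])[0] - self.predict([n])[0])

    def summary(self) -> str:
        return super().summary() + f"\n  openness: {self.openness}"


class CoreExponentialModel(_CurveModelBase):
    """Core-genome decay model y = A * exp(B*x) + C fitted to curve medians."""

    _func = staticmethod(_core_exp)
    _param_names = ("A_core", "B_core", "C_core")
    _model_label = "Core-genome exponential fit: y = A*exp(B*x) + C"
    _b_grid = (-12.0, 2.0)

    def _basis(self, b):
        return np.exp(np.clip(b * self.x, -700.0, 700.0))

    def _starts(self):
        a0 = float(np.ptp(self.y))
        c0 = float(self.y.min())
        return [(max(a0, 1e-6), b0, c0) for b0 in (-0.1, -0.5, -1.0)]

    def _make_results(self, params, pcov, rss, degenerate):
        return CoreFitResults(self, params, np.asarray(pcov), rss, degenerate)


@dataclass
class CoreFitResults(_CurveResultsBase):
    @property
    def A_core(self) -> float:
        return self.params[0]

    @property
    def B_core(self) -> float:
        return self.params[1]

    @property
    def C_core(self) -> float:
        return self.params[2]


def fit_heaps(pan_medians: Sequence[CurvePoint]) -> HeapsFitResults:
    """Fit the Heaps pan-genome law to pan-curve medians."""
    return HeapsLawModel.from_curve(pan_medians).fit()


def fit_core_exponential(core_medians: Sequence[CurvePoint]) -> CoreFitResults:
    """Fit the exponential core-genome decay to core-curve medians."""
    return CoreExponentialModel.from_curve(core_medians).fit()


def new_genes_at_next(fit: HeapsFitResults, n: int) -> float:
    return fit.new_genes_at_next(n)


def curves_table(pan, core, new) -> pd.DataFrame:
    return pd.DataFrame({
        "n_genomes": [p.x for p in pan],
        "pan_median": [p.y_median for p in pan],
        "core_median": [p.y_median for p in core],
        "new_genes_median": [p.y_median for p in new],
    })
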