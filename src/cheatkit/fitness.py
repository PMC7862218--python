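"""Competitive success, frequency dependence and equilibrium frequency.

A cheater's competitive success in one pairwise competition is

    S = f_final / f_initial

the mutant's frequency after the competition divided by its realized
initial frequency (S = 1 at neutrality). Under negative
frequency-dependent selection S declines with the starting frequency and
crosses 1 at a stable internal equilibrium. The default fit regresses
log(S) on f_initial by least squares; the equilibrium is the root of the
fitted line (the smallest root inside the observed frequency range), and
uncertainty comes from a bootstrap over replicates. A quadratic
alternative is exposed because the true functional form of S(f) is not
identified by this design. One-sample t-tests on frequency ratios and
plain linear-regression summaries are provided as thin wrappers for
pipeline glue.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclasses.dataclass(frozen=True)
class CompetitionRecord:
    """One competition replicate: realized initial and final mutant frequency."""

    replicate: str
    f_initial: float
    f_final: float

    def __post_init__(self) -> None:
        for name, f in (("f_initial", self.f_initial), ("f_final", self.f_final)):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {f}")

    @property
    def S(self) -> float:
        return competitive_success(self.f_final, self.f_initial)


@dataclasses.dataclass(frozen=True)
class FrequencyDependenceFit:
    """Fitted frequency dependence of competitive success.

    ``coefficients`` are in increasing-power order for the model
    log S = c0 + c1·f (+ c2·f² for the quadratic form).
    ``equilibrium_frequency`` is the smallest root of S = 1 within the
    observed initial-frequency range, or None when the fitted curve does
    not cross 1 there. ``equilibrium_ci`` is the bootstrap 95% interval
    over replicates (None when too few bootstrap fits yield a root).
    """

    coefficients: tuple[float, ...]
    transform: str
    f_range: tuple[float, float]
    equilibrium_frequency: float | None
    equilibrium_ci: tuple[float, float] | None
    n_records: int
    flat: bool = False

    @property
    def slope(self) -> float:
        return self.coefficients[1]

    @property
    def intercept(self) -> float:
        return self.coefficients[0]

    def predict_logS(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return sum(c * f**i for i, c in enumerate(self.coefficients))


def competitive_success(f_final: float, f_initial: float) -> float:
    """S = f_final / f_initial; undefined (error) at f_initial = 0."""
    if f_initial <= 0.0:
        raise ValueError("competitive success is undefined for f_initial = 0")
    if f_final < 0.0:
        raise ValueError("f_final must be non-negative")
    return f_final / f_initial


def _fit_poly(f: np.ndarray, logS: np.ndarray, degree: int) -> np.ndarray:
    # increasing-power order
    X = np.vander(f, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, logS, rcond=None)
    return coef


def _smallest_root(coef: np.ndarray, f_lo: float, f_hi: float) -> float | None:
    """Smallest root of the fitted log S polynomial inside [f_lo, f_hi]."""
    roots = np.roots(coef[::-1]) if len(coef) > 1 else np.array([])
    real = sorted(
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 and f_lo - 1e-12 <= r.real <= f_hi + 1e-12
    )
    return real[0] if real else None


def fit_frequency_dependence(
    records: Sequence[CompetitionRecord],
    transform: str = "log",
    degree: int = 1,
    n_boot: int = 1000,
    seed: int | None = None,
    flat_slope_tol: float = 1e-8,
) -> FrequencyDependenceFit:
    """Fit S(f) and locate the equilibrium frequency where S = 1.

    Parameters
    ----------
    records :
        Competition replicates; at least 3 distinct initial frequencies
        (degree + 2 for the quadratic form).
    transform :
        ``"log"`` fits log S (default and only transform; kept explicit
        so output tables are self-describing).
    degree :
        1 for the log-linear default, 2 for the quadratic alternative.
    n_boot :
        Bootstrap resamples over replicates for the equilibrium 95% CI;
        0 disables the bootstrap.
    seed :
        Seed for the bootstrap resampling.
    flat_slope_tol :
        Below this absolute slope (and higher coefficients) the fit is
        reported flat: the equilibrium is everywhere or nowhere, and
        None is returned with ``flat=True``.
    """
    if transform != "log":
        raise ValueError(f"unknown transform {transform!r}")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 (log-linear) or 2 (quadratic)")
    usable = [r for r in records if r.f_initial > 0]
    if not usable:
        raise ValueError("no records with positive initial frequency; all S undefined")
    f = np.array([r.f_initial for r in usable])
    if len(np.unique(f)) < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} distinct initial frequencies, got {len(np.unique(f))}"
        )
    S = np.array([r.S for r in usable])
    if np.any(S <= 0):
        raise ValueError("zero final frequency gives S = 0; log transform undefined")
    logS = np.log(S)
    f_lo, f_hi = float(f.min()), float(f.max())

    coef = _fit_poly(f, logS, degree)
    flat = bool(np.all(np.abs(coef[1:]) < flat_slope_tol))
    eq = None if flat else _smallest_root(coef, f_lo, f_hi)

    ci = None
    if n_boot > 0 and not flat:
        rng = np.random.default_rng(seed)
        boots = []
        n = len(usable)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            fb, lb = f[idx], logS[idx]
            if len(np.unique(fb)) < degree + 2:
                continue
            root = _smallest_root(_fit_poly(fb, lb, degree), f_lo, f_hi)
            if root is not None:
                boots.append(root)
        if len(boots) >= max(20, n_boot // 10):
            ci = (
                float(np.percentile(boots, 2.5)),
                float(np.percentile(boots, 97.5)),
            )

    return FrequencyDependenceFit(
        coefficients=tuple(float(c) for c in coef),
        transform=transform,
        f_range=(f_lo, f_hi),
        equilibrium_frequency=eq,
        equilibrium_ci=ci,
        n_records=len(usable),
        flat=flat,
    )


def ratio_ttest(
    ratios: Sequence[float],
    null_value: float = 1.0,
    alternative: str = "two_sided",
) -> tuple[float, int, float]:
    """One-sample Student's t-test of frequency ratios against a null value.

    Returns (t, df, p) with df = n − 1. ``alternative`` is one of
    ``less``, ``greater``, ``two_sided``. Pipeline glue over
    scipy.stats.ttest_1samp.
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two ratios")
    if np.allclose(arr, arr[0]):
        raise ValueError("ratios have zero variance; t statistic undefined")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"alternative must be less/greater/two_sided, got {alternative!r}")
    res = stats.ttest_1samp(arr, popmean=null_value, alternative=alt)
    return float(res.statistic), int(arr.size - 1), float(res.pvalue)


def regression_summary(x: Sequence[float], y: Sequence[float]):
    """Ordinary least-squares y ~ x with full summary (glue, statsmodels)."""
    X = sm.add_constant(np.asarray(x, dtype=float))
    return sm.OLS(np.asarray(y, dtype=float), X).fit()


def read_competition_table(path: str) -> list[CompetitionRecord]:
    """Read a TSV with columns replicate, f_initial, f_final."""
    df = pd.read_csv(path, sep="\t")
    missing = {"replicate", "f_initial", "f_final"} - set(df.columns)
    if missing:
        raise ValueError(f"competition table is missing columns: {sorted(missing)}")
    return [
        CompetitionRecord(str(r.replicate), float(r.f_initial), float(r.f_final))
        for r in df.itertuples(index=False)
    ]
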