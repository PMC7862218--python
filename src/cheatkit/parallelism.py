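"""Exact binomial test for parallel evolution in a gene class.

When several independently evolved lines all acquire mutations in the
same functional class of genes (here: the ~75 known hyphal-fusion genes
out of ~10,000 protein-coding genes), the question is whether that
convergence could be chance. Treating each accumulated mutation as an
independent draw that hits a class gene with probability
``class_genes / total_genes``, the number of lines whose focal mutant
carries a class hit is compared against the binomial null with
``n_lines × mut_per_line`` draws.

The two-sided p-value follows the minimum-likelihood convention: it sums
the probabilities of all outcomes no more likely than the observed one
(the convention of R's ``binom.test`` and scipy's ``binomtest``). The
PMF is evaluated in log space so tail sums remain accurate down to
p-values around 1e-300.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

#: Relative slack when comparing point probabilities for the two-sided
#: rule, matching R's binom.test (relErr = 1 + 1e-7): outcomes whose
#: likelihood is within this factor of the observed one count as ties.
_REL_ERR = 1e-7

VALID_ALTERNATIVES = ("two_sided_minlik", "greater", "less")


def exact_binomial_pvalue(
    k: int,
    n: int,
    p: float,
    alternative: str = "two_sided_minlik",
) -> float:
    """Exact binomial p-value for ``k`` successes in ``n`` trials.

    Parameters
    ----------
    k, n :
        Observed successes and number of trials, ``0 <= k <= n``.
    p :
        Per-trial success probability in [0, 1].
    alternative :
        ``"two_sided_minlik"`` (default) sums the probabilities of all
        outcomes whose point probability does not exceed that of ``k``;
        ``"greater"`` and ``"less"`` are the upper/lower tail sums
        (inclusive of ``k``).
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"success probability must be in [0, 1], got {p}")
    if alternative not in VALID_ALTERNATIVES:
        raise ValueError(f"alternative must be one of {VALID_ALTERNATIVES}")

    ks = np.arange(n + 1)
    logpmf = binom.logpmf(ks, n, p)

    if alternative == "greater":
        return float(min(1.0, math.exp(logsumexp(logpmf[k:]))))
    if alternative == "less":
        return float(min(1.0, math.exp(logsumexp(logpmf[: k + 1]))))

    # minimum-likelihood two-sided rule
    cutoff = logpmf[k] + math.log1p(_REL_ERR)
    included = logpmf <= cutoff
    return float(min(1.0, math.exp(logsumexp(logpmf[included]))))


@dataclasses.dataclass(frozen=True)
class ParallelismInput:
    """Inputs to the parallel-mutation test.

    Attributes
    ----------
    k_lines_hit :
        Number of lines whose focal mutant carries a mutation in the
        gene class.
    n_lines :
        Number of independently evolved lines.
    mut_per_line :
        Mutations accumulated per line (a conservative per-line count
        supplied by the user, not fixed by the package).
    class_genes :
        Size of the gene class of interest (e.g. 75 fusion genes).
    total_genes :
        Total number of protein-coding genes (e.g. ~10,000).
    """

    k_lines_hit: int
    n_lines: int
    mut_per_line: int
    class_genes: int
    total_genes: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_lines_hit <= self.n_lines):
            raise ValueError("need 0 <= k_lines_hit <= n_lines")
        if not (0 < self.class_genes < self.total_genes):
            raise ValueError("need 0 < class_genes < total_genes")
        if self.mut_per_line <= 0:
            raise ValueError("mut_per_line must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_lines * self.mut_per_line

    @property
    def hit_probability(self) -> float:
        return self.class_genes / self.total_genes


def parallel_fusion_test(
    inp: ParallelismInput | None = None,
    *,
    k_lines_hit: int | None = None,
    n_lines: int | None = None,
    mut_per_line: int | None = None,
    class_genes: int | None = None,
    total_genes: int | None = None,
    alternative: str = "two_sided_minlik",
) -> float:
    """Probability that all class hits across lines arose by chance.

    Accepts either a :class:`ParallelismInput` or the five counts as
    keyword arguments. With 8 of 8 lines hit, ~15 mutations per line and
    a 75/10,000 per-mutation hit probability this gives p ≈ 3.99e-06.
    """
    if inp is None:
        inp = ParallelismInput(
            k_lines_hit=k_lines_hit,
            n_lines=n_lines,
            mut_per_line=mut_per_line,
            class_genes=class_genes,
            total_genes=total_genes,
        )
    return exact_binomial_pvalue(
        inp.k_lines_hit, inp.n_trials, inp.hit_probability, alternative=alternative
    )
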