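"""Two-condition differential-expression testing on normalized counts.

For each gene, R1 and R2 are the sums of upper-quartile-normalized counts
over the replicates of the two conditions.  Variances are estimated from
replicates when available; without true replicates the two conditions act
as surrogate replicates for each other, which is deliberately conservative.
A single mean-variance curve is smoothed across genes by Lowess (locally
weighted regression) and supplies the variance of the negative binomial
null model.  The test conditions on the total S = R1 + R2: the two-sided
P-value sums, over all splits (x, S - x), the probabilities no larger than
that of the observed split, each split scored as the product of two
negative binomial (or Poisson, when not overdispersed) pmfs.  Benjamini-
Hochberg q-values control the false discovery rate (cutoff 1% by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.multitest import multipletests

from .formats_io import NoExpressedGenes
from .quantify import CountTable, normalized_counts

logger = logging.getLogger("bacrnaseq")

_POISSON_EPS = 1e-8
_VAR_FLOOR = 1e-8


@dataclass
class NBParams:
    """Negative binomial parameterized by mean and variance.

    Falls back to Poisson when the variance does not exceed the mean
    (the NB size parameter would diverge)."""

    mean: float
    var: float

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("mean must be non-negative")
        self.var = max(self.var, self.mean * (1 + _VAR_FLOOR))
        self.poisson = self.var <= self.mean * (1 + _POISSON_EPS)
        if not self.poisson:
            self.size = self.mean ** 2 / (self.var - self.mean)
            self.prob = self.size / (self.size + self.mean)

    def pmf(self, x) -> np.ndarray:
        if self.mean == 0:
            x = np.asarray(x)
            return np.where(x == 0, 1.0, 0.0)
        if self.poisson:
            return stats.poisson.pmf(x, self.mean)
        return stats.nbinom.pmf(x, self.size, self.prob)


@dataclass
class DERecord:
    gene: str
    r1: float
    r2: float
    mean1: float
    mean2: float
    var1: float
    var2: float
    fold_change: float
    pvalue: float
    qvalue: float = 1.0


def estimate_variances(cond1: np.ndarray, cond2: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-gene replicate-level means and sample variances.

    ``cond1``/``cond2`` are genes x replicates matrices of normalized
    counts.  With true replicates in both conditions the per-condition
    sample statistics are returned (stacked, two rows of points per gene).
    With a single sample in either condition the two condition values are
    treated as surrogate replicates of one pooled condition.  Returns
    (means, variances, surrogate_flag); means/variances are flat arrays of
    smoothing points.
    """
    cond1 = np.atleast_2d(cond1)
    cond2 = np.atleast_2d(cond2)
    surrogate = cond1.shape[1] < 2 or cond2.shape[1] < 2
    if surrogate:
        r1 = cond1.sum(axis=1)
        r2 = cond2.sum(axis=1)
        pair = np.stack([r1, r2], axis=1)
        means = pair.mean(axis=1)
        variances = pair.var(axis=1, ddof=1)
    else:
        m1, v1 = cond1.mean(axis=1), cond1.var(axis=1, ddof=1)
        m2, v2 = cond2.mean(axis=1), cond2.var(axis=1, ddof=1)
        means = np.concatenate([m1, m2])
        variances = np.concatenate([v1, v2])
    return means, variances, surrogate


def lowess_smooth(means: np.ndarray, variances: np.ndarray,
                  frac: float = 0.3) -> Callable[[np.ndarray], np.ndarray]:
    """Smoothed variance as a function of the mean.

    Lowess with tricube weights and no robustness iterations: per-gene
    sample variances are strongly right-skewed, so robust reweighting
    would systematically pull the curve below the true conditional mean
    and make the test anticonservative.  The fitted curve is interpolated
    between observed means and floored at mu * (1 + 1e-8) so the negative
    binomial is always defined.  With fewer than five positive-mean points
    a method-of-moments quadratic v(mu) = mu + a * mu^2 is used instead.
    """
    means = np.asarray(means, float)
    variances = np.asarray(variances, float)
    keep = means > 0
    x, y = means[keep], variances[keep]
    if x.size < 5:
        logger.warning("too few genes for lowess; using pooled quadratic fit")
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.median((y - x) / x ** 2) if x.size else 0.0
        a = max(float(a), 0.0)

        def v_quad(mu):
            mu = np.asarray(mu, float)
            return np.maximum(mu + a * mu ** 2, mu * (1 + _VAR_FLOOR))

        return v_quad

    fitted = _sm_lowess(y, x, frac=frac, it=0, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    xs, idx = np.unique(xs, return_index=True)
    ys = ys[idx]

    def v(mu):
        mu = np.asarray(mu, float)
        out = np.interp(mu, xs, ys)
        # beyond the largest observed mean, extend quadratically in mu so
        # evaluating at a sum-scale mean keeps a sane dispersion
        big = mu > xs[-1]
        if np.any(big) and xs[-1] > 0:
            disp = max((ys[-1] - xs[-1]) / xs[-1] ** 2, 0.0)
            out = np.where(big, mu + disp * mu ** 2, out)
        return np.maximum(out, mu * (1 + _VAR_FLOOR))

    return v


def nb_exact_pvalue(r1: int, r2: int, nb1: NBParams, nb2: NBParams) -> float:
    """Conditional exact test: given S = R1 + R2, sum the probabilities of
    all splits at most as likely as the observed one."""
    r1, r2 = int(round(r1)), int(round(r2))
    if r1 < 0 or r2 < 0:
        raise ValueError("counts must be non-negative")
    s = r1 + r2
    if s == 0:
        return 1.0
    xs = np.arange(s + 1)
    p = nb1.pmf(xs) * nb2.pmf(xs[::-1])
    denom = p.sum()
    if denom <= 0 or not np.isfinite(denom):
        return 1.0
    p_obs = p[r1]
    # summation in sorted order keeps the result exactly invariant under
    # swapping the two conditions (same multiset of terms)
    num = float(np.sort(p[p <= p_obs]).sum())
    return float(min(1.0, num / np.sort(p).sum()))


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(table: CountTable, design: Mapping[str, str],
                            fdr: float = 0.01, lowess_frac: float = 0.3
                            ) -> list[DERecord]:
    """Run the full test between the two conditions of ``design``
    (sample name -> condition label); records are sorted by q-value."""
    conditions = sorted(set(design.values()))
    if len(conditions) != 2:
        raise ValueError("exactly two conditions are required")
    c1 = [s for s in table.samples if design[s] == conditions[0]]
    c2 = [s for s in table.samples if design[s] == conditions[1]]
    try:
        norm = normalized_counts(table)
    except NoExpressedGenes:
        logger.warning("a sample has no expressed genes; skipping normalization")
        norm = table.counts
    m1 = norm[c1].to_numpy()
    m2 = norm[c2].to_numpy()
    n1, n2 = len(c1), len(c2)
    r1 = m1.sum(axis=1)
    r2 = m2.sum(axis=1)
    if r1.sum() == 0 or r2.sum() == 0:
        logger.warning("a condition has zero total counts; all P-values are 1")
        pvals = np.ones(len(norm))
    else:
        means, variances, surrogate = estimate_variances(m1, m2)
        v = lowess_smooth(means, variances, frac=lowess_frac)
        q0 = (r1 + r2) / (n1 + n2)
        v_rep = v(q0)
        if not surrogate:
            # with true replicates, guard against genes whose own spread
            # exceeds the trend (conservative variance sharing)
            own = 0.5 * (m1.var(axis=1, ddof=1) + m2.var(axis=1, ddof=1))
            v_rep = np.maximum(v_rep, own)
        pvals = np.empty(len(norm))
        for i in range(len(norm)):
            nb1 = NBParams(mean=n1 * q0[i], var=n1 * float(v_rep[i]))
            nb2 = NBParams(mean=n2 * q0[i], var=n2 * float(v_rep[i]))
            pvals[i] = nb_exact_pvalue(r1[i], r2[i], nb1, nb2)
    qvals = bh_qvalues(pvals)
    recs = []
    for i, gene in enumerate(norm.index):
        recs.append(DERecord(
            gene=str(gene), r1=float(r1[i]), r2=float(r2[i]),
            mean1=float(m1[i].mean()), mean2=float(m2[i].mean()),
            var1=float(m1[i].var(ddof=1)) if n1 > 1 else float("nan"),
            var2=float(m2[i].var(ddof=1)) if n2 > 1 else float("nan"),
            fold_change=float((r2[i] + 1) / (r1[i] + 1)),
            pvalue=float(pvals[i]), qvalue=float(qvals[i])))
    recs.sort(key=lambda r: (r.qvalue, r.pvalue, r.gene))
    return recs
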