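"""Naive Bayes prediction of co-transcription for consecutive same-strand
gene pairs, and chaining of confident pairs into multi-gene operons.

The prior probability that an adjacent same-strand pair is co-transcribed
is 1 - (number of directons / number of adjacent same-strand pairs), a
directon being a maximal run of consecutive genes on one strand.  Two
features enter the classifier: the intergenic distance, whose class-
conditional densities are Epanechnikov kernel density estimates over
same-strand versus opposite-strand adjacent-pair distances, and the
Pearson correlation of log expression across samples, trained on proxy
labels (overlapping same-strand pairs as positives, opposite-strand pairs
as negatives).  The correlation feature is inert with fewer than three
samples, where a correlation coefficient carries no information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneAnnotation, to_external

logger = logging.getLogger("bacrnaseq")

_DENSITY_FLOOR = 1e-9


def epanechnikov_kde(samples: Sequence[float], bandwidth: float | None = None,
                     support: tuple[float, float] | None = None,
                     min_bandwidth: float = 0.0,
                     ) -> Callable[[np.ndarray], np.ndarray]:
    """Epanechnikov kernel density estimate, K(u) = 0.75 (1 - u^2) on |u|<=1.

    The default bandwidth is Silverman's rule of thumb rescaled for the
    Epanechnikov kernel (h = 2.34 sigma n^{-1/5}); evaluations are floored
    at 1e-9 so likelihood ratios stay finite.  When the variable lives on a
    bounded ``support`` (correlations on [-1, 1]) the estimate is boundary-
    corrected by reflecting the samples at both edges, otherwise the
    density would be biased low precisely at the boundaries.
    """
    x = np.asarray(samples, float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    if bandwidth is None:
        sd = float(np.std(x, ddof=1))
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        scale = min(sd, iqr / 1.34) if iqr > 0 else sd
        if scale <= 0:
            logger.warning("degenerate KDE samples; using unit bandwidth")
            scale = 1.0 / 2.34 * x.size ** 0.2  # yields h = 1
        bandwidth = 2.34 * scale * x.size ** (-0.2)
    h = float(max(bandwidth, min_bandwidth))
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    if support is not None:
        lo, hi = support
        pts = [x]
        if lo is not None and np.isfinite(lo):
            pts.append(2 * lo - x)
        if hi is not None and np.isfinite(hi):
            pts.append(2 * hi - x)
        pts = np.concatenate(pts)
    else:
        lo = hi = None
        pts = x

    def f(t):
        t = np.asarray(t, float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        u = (tt[:, None] - pts[None, :]) / h
        k = np.where(np.abs(u) <= 1, 0.75 * (1 - u ** 2), 0.0)
        dens = k.sum(axis=-1) / (x.size * h)
        if lo is not None and np.isfinite(lo):
            dens = np.where(tt < lo, 0.0, dens)
        if hi is not None and np.isfinite(hi):
            dens = np.where(tt > hi, 0.0, dens)
        dens = np.maximum(dens, _DENSITY_FLOOR)
        return float(dens[0]) if scalar else dens

    return f


@dataclass
class OperonModel:
    prior: float
    f_same: Callable  # distance density, co-transcribed class
    f_opp: Callable  # distance density, background class
    g_pos: Callable | None  # correlation density, co-transcribed class
    g_neg: Callable | None
    n_samples: int = 0

    @property
    def use_correlation(self) -> bool:
        return self.g_pos is not None and self.g_neg is not None and self.n_samples >= 3


@dataclass
class PairPrediction:
    upstream: str
    downstream: str
    strand: str
    distance: int
    correlation: float | None
    posterior: float


@dataclass
class Operon:
    genes: tuple[str, ...]
    strand: str
    start: int  # 0-based half-open, like Transcript
    end: int
    min_posterior: float


def compute_prior(annotations: Sequence[GeneAnnotation]) -> float:
    """Prior co-transcription probability 1 - D/P, clamped to [0.05, 0.95];
    D = directon count, P = adjacent same-strand pair count."""
    if len(annotations) < 2:
        raise ValueError("need at least two genes")
    strands = [g.strand for g in sorted(annotations, key=lambda g: (g.start, g.stop))]
    d = 1 + sum(1 for a, b in zip(strands, strands[1:]) if a != b)
    p = sum(1 for a, b in zip(strands, strands[1:]) if a == b)
    if p == 0:
        logger.warning("no adjacent same-strand pairs; prior set to 0.5")
        return 0.5
    return float(np.clip(1.0 - d / p, 0.05, 0.95))


def intergenic_distance(upstream: GeneAnnotation, downstream: GeneAnnotation) -> int:
    """Gap in nt between consecutive genes (negative when overlapping)."""
    return downstream.start - upstream.stop - 1


def _adjacent_pairs(annotations: Sequence[GeneAnnotation]):
    genes = sorted(annotations, key=lambda g: (g.start, g.stop))
    return list(zip(genes, genes[1:]))


def _log_correlations(expr: pd.DataFrame) -> pd.DataFrame:
    """Log expression with per-sample centering.

    Subtracting each sample's mean log expression removes sample-level
    common modes (residual normalization error, global activity shifts)
    that would otherwise induce a spurious positive correlation between
    every pair of genes."""
    log_expr = np.log1p(expr)
    return log_expr - log_expr.mean(axis=0)


def fit_operon_model(annotations: Sequence[GeneAnnotation],
                     expression: pd.DataFrame | None = None) -> OperonModel:
    """Fit prior, distance densities and (with >= 3 samples) correlation
    densities from the annotation layout and an expression matrix
    (genes x samples, indexed by locus id)."""
    prior = compute_prior(annotations)
    pairs = _adjacent_pairs(annotations)
    same = [(a, b) for a, b in pairs if a.strand == b.strand]
    opp = [(a, b) for a, b in pairs if a.strand != b.strand]
    d_same = [intergenic_distance(a, b) for a, b in same]
    d_opp = [intergenic_distance(a, b) for a, b in opp]
    if len(d_same) < 2:
        raise ValueError("need at least two same-strand adjacent pairs")
    # each density is evaluated with the distance censored to its own
    # training range: the kernel estimates have compact support, so an
    # extrapolated likelihood ratio far outside the data would be an
    # artifact of whichever class happened to reach further
    def _censored(kde, lo, hi):
        return lambda t: kde(np.clip(t, lo, hi))

    f_same = _censored(epanechnikov_kde(d_same),
                       float(min(d_same)), float(max(d_same)))
    if len(d_opp) >= 2:
        # opposite-strand spacings have a hard lower floor (adjacent
        # independent units still need terminator/promoter room); reflect
        # at the empirical minimum to undo the kernel's boundary bias
        f_opp = _censored(
            epanechnikov_kde(d_opp, support=(float(min(d_opp)), None)),
            float(min(d_opp)), float(max(d_opp)))
    else:
        logger.warning("too few opposite-strand pairs; uniform background density")
        lo, hi = min(d_same), max(d_same)
        width = max(hi - lo, 1)

        def f_opp(t):
            t = np.asarray(t, float)
            return np.maximum(np.where((t >= lo) & (t <= hi), 1.0 / width, 0.0),
                              _DENSITY_FLOOR)

    g_pos = g_neg = None
    n_samples = 0 if expression is None else expression.shape[1]
    if expression is not None and n_samples >= 3:
        log_expr = _log_correlations(expression)

        def corr(a: GeneAnnotation, b: GeneAnnotation) -> float | None:
            if a.locus_id not in log_expr.index or b.locus_id not in log_expr.index:
                return None
            x = log_expr.loc[a.locus_id].to_numpy()
            y = log_expr.loc[b.locus_id].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                return None
            return float(np.corrcoef(x, y)[0, 1])

        # proxy labels: overlapping same-strand pairs ~ co-transcribed,
        # opposite-strand pairs ~ not co-transcribed
        rho_pos = [r for a, b in same if intergenic_distance(a, b) <= 0
                   and (r := corr(a, b)) is not None]
        rho_neg = [r for a, b in opp if (r := corr(a, b)) is not None]
        if len(rho_pos) >= 2 and len(rho_neg) >= 2:
            # mix each class density with a uniform component on [-1, 1]:
            # the proxy samples are few, so a raw KDE can assign (near-)
            # zero likelihood to correlations it happened not to cover,
            # which would act as a hard veto in the naive Bayes product
            eps = 0.1
            kde_pos = epanechnikov_kde(rho_pos, support=(-1.0, 1.0))
            kde_neg = epanechnikov_kde(rho_neg, support=(-1.0, 1.0))
            g_pos = lambda t: (1 - eps) * kde_pos(t) + eps * 0.5
            g_neg = lambda t: (1 - eps) * kde_neg(t) + eps * 0.5
        else:
            logger.warning("too few proxy pairs; correlation feature disabled")
    return OperonModel(prior=prior, f_same=f_same, f_opp=f_opp,
                       g_pos=g_pos, g_neg=g_neg, n_samples=n_samples)


def predict_pair(model: OperonModel, distance: float,
                 correlation: float | None = None) -> float:
    """Posterior probability of co-transcription for one adjacent pair."""
    pi = model.prior
    num = pi * float(model.f_same(distance))
    den = (1 - pi) * float(model.f_opp(distance))
    if model.use_correlation and correlation is not None:
        num *= float(model.g_pos(correlation))
        den *= float(model.g_neg(correlation))
    return num / (num + den)


def predict_pairs(model: OperonModel, annotations: Sequence[GeneAnnotation],
                  expression: pd.DataFrame | None = None) -> list[PairPrediction]:
    """Posterior for every adjacent same-strand pair, in genome order."""
    log_expr = None
    if expression is not None and model.use_correlation:
        log_expr = _log_correlations(expression)
    out = []
    for a, b in _adjacent_pairs(annotations):
        if a.strand != b.strand:
            continue
        rho = None
        if log_expr is not None and a.locus_id in log_expr.index \
                and b.locus_id in log_expr.index:
            x = log_expr.loc[a.locus_id].to_numpy()
            y = log_expr.loc[b.locus_id].to_numpy()
            if np.std(x) > 0 and np.std(y) > 0:
                rho = float(np.corrcoef(x, y)[0, 1])
        d = intergenic_distance(a, b)
        out.append(PairPrediction(
            upstream=a.locus_id, downstream=b.locus_id, strand=a.strand,
            distance=d, correlation=rho,
            posterior=predict_pair(model, d, rho)))
    return out


def assemble_operons(annotations: Sequence[GeneAnnotation],
                     predictions: Sequence[PairPrediction],
                     cutoff: float = 0.5) -> list[Operon]:
    """Chain adjacent pairs with posterior above ``cutoff`` into maximal
    multi-gene operons."""
    by_pair = {(p.upstream, p.downstream): p for p in predictions}
    genes = sorted(annotations, key=lambda g: (g.start, g.stop))
    operons: list[Operon] = []
    chain = [genes[0]] if genes else []
    post: list[float] = []
    for a, b in zip(genes, genes[1:]):
        p = by_pair.get((a.locus_id, b.locus_id))
        if p is not None and a.strand == b.strand and p.posterior > cutoff:
            chain.append(b)
            post.append(p.posterior)
        else:
            if len(chain) >= 2:
                operons.append(Operon(
                    genes=tuple(g.locus_id for g in chain), strand=chain[0].strand,
                    start=min(g.start for g in chain) - 1,
                    end=max(g.stop for g in chain),
                    min_posterior=min(post)))
            chain = [b]
            post = []
    if len(chain) >= 2:
        operons.append(Operon(
            genes=tuple(g.locus_id for g in chain), strand=chain[0].strand,
            start=min(g.start for g in chain) - 1,
            end=max(g.stop for g in chain),
            min_posterior=min(post)))
    return operons
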