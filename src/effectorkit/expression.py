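"""Between-library normalisation and head-vs-body differential expression.

The expression stage mirrors the classic bulk RNA-seq workflow for
two-condition designs with a handful of biological replicates:

* TMM (trimmed mean of M-values) scaling factors computed against a
  reference library, so that compositional differences between libraries
  do not masquerade as differential expression;
* TMM-FPKM values for reporting digital expression;
* a two-sided exact negative-binomial test of head versus body totals at
  equalised effective library sizes, with a single common dispersion
  estimated by the method of moments.  With dispersion 0 the test
  degenerates to the conditional binomial (Poisson) exact test.

Calls are made at a raw p-value threshold (default p < 0.001); no
fold-change floor and no FDR correction are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "DECall",
    "tmm_factors",
    "tmm_fpkm",
    "exact_test_de",
    "de_table",
]

TISSUES = ("head", "body")


@dataclass
class CountMatrix:
    """Transcripts x libraries raw integer counts with a head/body design.

    Parameters
    ----------
    counts
        DataFrame indexed by transcript id, one column per library,
        non-negative integers (raw counts -- normalisation happens later).
    design
        DataFrame indexed by library id with columns ``tissue`` (one of
        ``head``/``body``) and ``replicate``.
    lengths
        Transcript lengths in bp (needed only for FPKM); optional.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            bad = self.counts.index[np.where(arr < 0)[0][0]]
            raise ValueError(f"negative count for transcript {bad!r}")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers (raw counts, not normalised)")
            self.counts = self.counts.astype(np.int64)
        missing = set(self.design.index) - set(self.counts.columns)
        if missing:
            raise ValueError(f"design references libraries absent from counts: {sorted(missing)}")
        bad_tissue = set(self.design["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValueError(f"unknown tissue labels {sorted(bad_tissue)}; expected {TISSUES}")
        # restrict and order columns to the design
        self.counts = self.counts[list(self.design.index)]
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if (self.lengths < 1).any():
                raise ValueError("transcript lengths must be >= 1")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def libraries_for(self, tissue: str) -> list[str]:
        return list(self.design.index[self.design["tissue"] == tissue])


@dataclass
class DECall:
    """One transcript's head-vs-body differential expression result."""

    id: str
    p_value: float
    log2_fold_change: float
    direction: str  # head_up | body_up | ns


def _upper_quartile(scaled: np.ndarray) -> float:
    pos = scaled[scaled > 0]
    if pos.size == 0:
        return 0.0
    return float(np.quantile(pos, 0.75))


def tmm_factors(
    counts: pd.DataFrame | CountMatrix,
    *,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM scaling factors, rescaled to geometric mean 1.

    The reference library is the one whose upper quartile of
    depth-scaled counts is closest to the mean upper quartile.  For each
    library, M (log2 ratio) and A (log2 abundance) values are computed
    against the reference over transcripts non-zero in both libraries;
    the most extreme 30% of M on each side and 5% of A on each side are
    trimmed, and the remaining M-values averaged with inverse
    approximate-variance (delta-method binomial) weights.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    libsize = mat.sum(axis=0)
    if (libsize == 0).any():
        bad = counts.columns[np.where(libsize == 0)[0][0]]
        raise ValueError(f"library {bad!r} has all-zero counts")

    scaled = mat / libsize
    uq = np.array([_upper_quartile(scaled[:, j]) for j in range(mat.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(mat.shape[1])
    yr, nr = mat[:, ref_j], libsize[ref_j]
    for j in range(mat.shape[1]):
        if j == ref_j:
            continue
        y, n = mat[:, j], libsize[j]
        ok = (y > 0) & (yr > 0)
        if not ok.any():
            continue
        yk, yrk = y[ok], yr[ok]
        m = np.log2((yk / n) / (yrk / nr))
        a = 0.5 * np.log2((yk / n) * (yrk / nr))
        var = (n - yk) / (n * yk) + (nr - yrk) / (nr * yrk)
        w = 1.0 / np.maximum(var, 1e-12)  # guard degenerate one-gene libraries

        keep = np.ones(m.size, dtype=bool)
        if m.size > 0:
            lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
            lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
            keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_fpkm(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """TMM-normalised FPKM: count * 1e9 / (effective library size * length bp)."""
    if counts.lengths is None:
        raise ValueError("transcript lengths are required for FPKM")
    if (counts.lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if factors is None:
        factors = tmm_factors(counts)
    eff = counts.counts.sum(axis=0) * factors.reindex(counts.counts.columns)
    fpkm = counts.counts * 1e9
    fpkm = fpkm.div(eff, axis=1).div(counts.lengths, axis=0)
    return fpkm


def _common_dispersion(scaled: np.ndarray, groups: list[np.ndarray]) -> float:
    """Pooled method-of-moments NB dispersion, floored at zero.

    For NB(mean m, dispersion phi), Var = m + phi m^2, so
    phi = (Var - m) / m^2.  A ratio-of-sums estimator over all
    transcripts and both tissues is used for stability:
    phi_hat = sum(v - m) / sum(m^2), with per-group sample moments on
    TMM-equalised counts.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        if idx.size < 2:
            continue
        sub = scaled[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float(np.sum(v[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2))
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def exact_test_de(
    counts: CountMatrix,
    alpha: float = 0.001,
    *,
    dispersion: float | None = None,
) -> list[DECall]:
    """Head-vs-body exact NB test per transcript at raw p < ``alpha``.

    Counts are first equalised to a common effective library size
    (column sum x TMM factor, scaled to their geometric mean) and summed
    within each tissue; the two totals are then compared with the exact
    conditional test of :func:`_conditional_pvalue`.  Direction comes
    from the sign of the log2 fold change of per-replicate means.
    """
    n1 = len(counts.libraries_for("head"))
    n2 = len(counts.libraries_for("body"))
    if n1 == 0 or n2 == 0:
        raise ValueError("both head and body tissues need at least one library")

    factors = tmm_factors(counts)
    eff = counts.counts.sum(axis=0).to_numpy(float) * factors.to_numpy(float)
    gm = float(np.exp(np.mean(np.log(eff))))
    scale = gm / eff
    mat = counts.counts.to_numpy(float) * scale[None, :]

    cols = np.array(counts.libraries)
    head_idx = np.where(np.isin(cols, counts.libraries_for("head")))[0]
    body_idx = np.where(np.isin(cols, counts.libraries_for("body")))[0]

    if dispersion is None:
        dispersion = _common_dispersion(mat, [head_idx, body_idx])

    calls: list[DECall] = []
    for i, tid in enumerate(counts.counts.index):
        t1 = int(round(mat[i, head_idx].sum()))
        t2 = int(round(mat[i, body_idx].sum()))
        if t1 + t2 == 0:
            calls.append(DECall(str(tid), 1.0, 0.0, "ns"))
            continue
        p = _conditional_pvalue(t1, t2, n1, n2, dispersion)
        lfc = math.log2(((t1 + 0.5) / n1) / ((t2 + 0.5) / n2))
        if p < alpha and lfc != 0.0:
            direction = "head_up" if lfc > 0 else "body_up"
        else:
            direction = "ns"
        calls.append(DECall(str(tid), p, lfc, direction))
    return calls


def _conditional_pvalue(t1: int, t2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact test of two group totals under a common NB mean.

    Conditional on the total T = t1 + t2, the head total follows a
    negative hypergeometric law with sizes r_i = n_i/phi -- independent
    of the common mean -- degenerating to Binomial(T, n1/(n1+n2)) as
    phi -> 0.  The p-value sums the conditional probabilities of all
    outcomes no more probable than the observed one.
    """
    total = t1 + t2
    if total == 0:
        return 1.0
    a = np.arange(total + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(a, total, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / phi, n2 / phi
        # joint NB log-pmf at an arbitrary common success prob; the prob
        # cancels on conditioning, so normalise by the log-sum
        logp = stats.nbinom.logpmf(a, r1, 0.5) + stats.nbinom.logpmf(total - a, r2, 0.5)
        logp = logp - _logsumexp(logp)
    obs = logp[t1]
    # outcomes no more probable than the observed one (small float slop
    # so exactly-tied probabilities are always included)
    mask = logp <= obs + 1e-10
    return float(min(1.0, np.exp(_logsumexp(logp[mask]))))


def _logsumexp(x: np.ndarray) -> float:
    m = float(np.max(x))
    return m + float(np.log(np.sum(np.exp(x - m))))


def de_table(calls: list[DECall]) -> pd.DataFrame:
    """DE calls as a DataFrame (id, log2FC, p, direction)."""
    return pd.DataFrame(
        {
            "id": [c.id for c in calls],
            "log2_fold_change": [c.log2_fold_change for c in calls],
            "p_value": [c.p_value for c in calls],
            "direction": [c.direction for c in calls],
        }
    ).set_index("id")
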