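"""Point-by-point nonparametric and randomization statistics.

Every test runs independently at each point of a domain (channels x samples,
or channels x frequencies x samples): observations live along axis 0 of the
input arrays and the remaining axes are the domain, so the returned
statistic and p-value maps have the domain's shape and can be written back
into the standard containers for inspection.

Conventions shared by all tests:

* two-sided by default; one-sided via ``alternative``;
* ties are handled with midranks;
* permutation/randomization p-values obey the add-one rule
  ``p = (1 + #{T* >= T}) / (1 + n_perm)`` so they are never exactly 0; when
  the design's full permutation group is small enough (<= 2^16
  rearrangements) it is enumerated exhaustively instead of sampled, and the
  p-value is the exact rank of the observed statistic in that group;
* multiple-comparison handling is explicit: Bonferroni, Benjamini-Hochberg
  FDR, the permutation maximum-statistic (strong FWER control), or a
  minimum-duration criterion on consecutive significant samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .containers import EvokedRecord, TFRecord
from .epochs import EpochSet
from .errors import ParameterError

__all__ = [
    "StatResult", "wilcoxon_paired", "t_test_paired", "kruskal_wallis",
    "quade", "randomization_test", "fdr_bh", "bonferroni",
    "duration_criterion", "baseline_emergence",
    "pvalues_to_evoked", "pvalues_to_tf",
]

EXHAUSTIVE_LIMIT = 2 ** 16


@dataclass
class StatResult:
    """Statistic and p-value maps over the tested domain."""

    statistic: np.ndarray
    p: np.ndarray
    test: str
    n: tuple
    correction: str = "none"
    mask: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _domain_iter(shape):
    if shape == ():
        yield ()
    else:
        yield from np.ndindex(*shape)


# ------------------------------------------------------------ paired tests

def wilcoxon_paired(a: np.ndarray, b: np.ndarray,
                    alternative: str = "two-sided") -> StatResult:
    """Wilcoxon signed-rank test of paired observations, per domain point.

    Zero differences are dropped point-wise. The exact null distribution is
    used for n <= 25 pairs when the remaining |differences| are tie-free;
    otherwise the normal approximation with tie and continuity correction.
    A point with all-zero differences gets statistic 0 and p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError("paired arrays must have identical shape")
    if a.shape[0] < 5:
        raise ParameterError("need at least 5 pairs")
    dom = a.shape[1:]
    stat = np.zeros(dom)
    p = np.ones(dom)
    d = a - b
    for idx in _domain_iter(dom):
        di = d[(slice(None),) + idx]
        nz = di[di != 0]
        if nz.size == 0:
            stat[idx], p[idx] = 0.0, 1.0
            continue
        ranks_tied = np.unique(np.abs(nz)).size < nz.size
        method = "exact" if (nz.size <= 25 and not ranks_tied) else "approx"
        res = sps.wilcoxon(nz, alternative=alternative, method=method,
                           correction=(method == "approx"))
        stat[idx], p[idx] = res.statistic, min(res.pvalue, 1.0)
    return StatResult(stat, p, "wilcoxon_paired", (a.shape[0],))


def t_test_paired(a: np.ndarray, b: np.ndarray,
                  alternative: str = "two-sided") -> StatResult:
    """Classical paired t test per domain point.

    Degenerate points (zero-variance, non-zero mean difference) get the
    smallest representable p and are flagged in ``extra['degenerate']``;
    identical inputs give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError("paired arrays must have identical shape")
    n = a.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 pairs")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = (sd == 0) & (mean != 0)
    zero = (sd == 0) & (mean == 0)
    t = np.where(zero, 0.0, t)
    t = np.where(degenerate, np.where(mean >= 0, np.inf, -np.inf), t)
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(np.abs(t), n - 1)
    elif alternative == "greater":
        p = sps.t.sf(t, n - 1)
    elif alternative == "less":
        p = sps.t.cdf(t, n - 1)
    else:
        raise ParameterError("alternative must be two-sided, greater or less")
    p = np.where(zero, 1.0, p)
    p = np.clip(p, np.finfo(np.float64).tiny, 1.0)
    return StatResult(np.asarray(t), np.asarray(p), "t_test_paired", (n,),
                      extra={"degenerate": degenerate})


# ------------------------------------------------------- k-sample and block

def kruskal_wallis(groups) -> StatResult:
    """Kruskal-Wallis rank test across independent groups, per point.

    Uses the tie-corrected H statistic with a chi-square reference
    (k - 1 df). Points where every pooled value is identical get H = 0,
    p = 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    for g in groups:
        if g.shape[0] < 3:
            raise ParameterError("each group needs n >= 3")
        if g.shape[1:] != groups[0].shape[1:]:
            raise ParameterError("groups must share the domain shape")
    dom = groups[0].shape[1:]
    stat = np.zeros(dom)
    p = np.ones(dom)
    for idx in _domain_iter(dom):
        vals = [g[(slice(None),) + idx] for g in groups]
        pooled = np.concatenate(vals)
        if np.all(pooled == pooled[0]):
            stat[idx], p[idx] = 0.0, 1.0
            continue
        res = sps.kruskal(*vals)
        stat[idx], p[idx] = res.statistic, min(res.pvalue, 1.0)
    return StatResult(stat, p, "kruskal_wallis",
                      tuple(g.shape[0] for g in groups))


def _quade_point(x: np.ndarray) -> tuple[float, float, float, float]:
    """Quade statistic pieces (F, A, B, df-ready) for one b x k table."""
    b_n, k = x.shape
    r = sps.rankdata(x, axis=1)  # within-block midranks
    ranges = x.max(axis=1) - x.min(axis=1)
    q = sps.rankdata(ranges)  # ranks of block ranges
    s = q[:, None] * (r - (k + 1) / 2.0)
    col = s.sum(axis=0)
    A = float((s ** 2).sum())
    B = float((col ** 2).sum() / b_n)
    return A, B, b_n, k


def quade(table: np.ndarray, seed: int = 0, n_perm: int = 2000) -> StatResult:
    """Quade test for randomized blocks (blocks x treatments [x domain]).

    Blocks are ranked by their within-block range so blocks that separate
    the treatments more get more weight; the weighted rank statistic is
    referred to F(k-1, (b-1)(k-1)). When the F denominator vanishes
    (A = B, perfect concordance) the p-value falls back to a within-block
    permutation estimate; when every treatment is identical in every block
    the statistic is degenerate and p = 1.
    """
    table = np.asarray(table, dtype=np.float64)
    if table.ndim < 2:
        raise ParameterError("table must be blocks x treatments [x domain]")
    b_n, k = table.shape[:2]
    if b_n < 3 or k < 2:
        raise ParameterError("need >= 3 blocks and >= 2 treatments")
    dom = table.shape[2:]
    stat = np.zeros(dom)
    p = np.ones(dom)
    rng = np.random.default_rng(seed)
    for idx in _domain_iter(dom):
        x = table[(slice(None), slice(None)) + idx]
        A, B, _, _ = _quade_point(x)
        if A == 0:  # all treatments identical in every block
            stat[idx], p[idx] = 0.0, 1.0
            continue
        if abs(A - B) < 1e-12 * max(A, 1.0):
            # perfect concordance: F undefined, rank the observed B among
            # within-block permutations of the same table
            count = 0
            for _ in range(n_perm):
                perm = np.stack([row[rng.permutation(k)] for row in x])
                _, Bp, _, _ = _quade_point(perm)
                count += Bp >= B
            stat[idx] = np.inf
            p[idx] = (1.0 + count) / (1.0 + n_perm)
            continue
        F = (b_n - 1) * B / (A - B)
        stat[idx] = F
        p[idx] = min(sps.f.sf(F, k - 1, (b_n - 1) * (k - 1)), 1.0)
    p = np.clip(p, np.finfo(np.float64).tiny, 1.0)
    return StatResult(stat, p, "quade", (b_n, k))


# ------------------------------------------------------ randomization tests

def _point_statistic(d: np.ndarray, statistic: str) -> np.ndarray:
    """Statistic of a paired-difference sample along axis 0."""
    if statistic == "mean_diff":
        return d.mean(axis=0)
    if statistic == "t":
        n = d.shape[0]
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = d.mean(axis=0) / (sd / np.sqrt(n))
        return np.where(np.isfinite(t), t, np.sign(d.mean(axis=0)) * 1e12)
    raise ParameterError("statistic must be 'mean_diff' or 't'")


def _group_diff(x: np.ndarray, y: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "mean_diff":
        return x.mean(axis=0) - y.mean(axis=0)
    n1, n2 = x.shape[0], y.shape[0]
    v1 = x.var(axis=0, ddof=1)
    v2 = y.var(axis=0, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x.mean(axis=0) - y.mean(axis=0)) / (sp * np.sqrt(1 / n1 + 1 / n2))
    return np.where(np.isfinite(t),
                    t, np.sign(x.mean(axis=0) - y.mean(axis=0)) * 1e12)


def randomization_test(groups, design: str, statistic: str = "mean_diff",
                       n_perm: int = 999, seed: int = 0,
                       correction: str = "none",
                       alternative: str = "two-sided") -> StatResult:
    """Randomization test over a map of points.

    Designs:

    ``paired_signflip``
        ``groups = (a, b)`` matched; the null flips each pair's difference
        sign. Exhaustive over all 2^n flips when n <= 16.
    ``twosample_shuffle``
        ``groups = (a, b)`` independent; the null permutes group labels.
        Exhaustive when the number of label assignments is <= 2^16.
    ``multisensory_additive``
        ``groups = (A, V, AV)`` single-condition and compound trials; the
        observed interaction is ``D = mean(AV) - mean(A) - mean(V)``. The
        null distribution comes from the additive model itself: unisensory
        trials are paired at random into synthetic sum trials ``A_i + V_j``
        (which have the multisensory mean under additivity), and condition
        labels are shuffled between the compound pool and the sum pool.
        This leaves each pool's trial content intact and breaks only the
        compound/additive distinction, so main effects never masquerade as
        interactions.

    ``correction='maxstat'`` compares each point's |T| against the
    permutation distribution of the maximum |T*| over all points, giving
    strong familywise error control.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    if correction not in ("none", "maxstat"):
        raise ParameterError("correction must be 'none' or 'maxstat'")
    if alternative not in ("two-sided", "greater"):
        raise ParameterError("alternative must be 'two-sided' or 'greater'")
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    for g in groups:
        if g.shape[0] == 0:
            raise ParameterError("empty group")
        if g.shape[1:] != groups[0].shape[1:]:
            raise ParameterError("groups must share the domain shape")
    rng = np.random.default_rng(seed)
    score = (lambda x: np.abs(x)) if alternative == "two-sided" else (lambda x: x)

    if design == "paired_signflip":
        a, b = groups
        if a.shape != b.shape:
            raise ParameterError("paired design needs equal-length groups")
        d = a - b
        n = d.shape[0]
        obs = _point_statistic(d, statistic)
        exhaustive = 2 ** n <= EXHAUSTIVE_LIMIT
        if exhaustive:
            total = 2 ** n
            bits = (np.arange(total)[:, None] >> np.arange(n)[None, :]) & 1
            signs = np.where(bits == 1, 1.0, -1.0)  # (total, n)
        else:
            total = n_perm
            signs = rng.choice([-1.0, 1.0], size=(total, n))
        d2 = d.reshape(n, -1)  # (n, M)
        means = (signs @ d2) / n  # (total, M); sign flips leave sum d^2 fixed
        if statistic == "mean_diff":
            nullf = means
        else:
            ss = (d2 ** 2).sum(axis=0)[None, :]
            var = np.clip((ss - n * means ** 2) / (n - 1), 0.0, None)
            sd = np.sqrt(var)
            with np.errstate(divide="ignore", invalid="ignore"):
                nullf = means / (sd / np.sqrt(n))
            nullf = np.where(np.isfinite(nullf), nullf,
                             np.sign(means) * 1e12)
        null = nullf.reshape((total,) + obs.shape)
        ns = (n,)
    elif design == "twosample_shuffle":
        a, b = groups
        pooled = np.concatenate([a, b], axis=0)
        n1, n2 = a.shape[0], b.shape[0]
        obs = _group_diff(a, b, statistic)
        from math import comb
        exhaustive = comb(n1 + n2, n1) <= EXHAUSTIVE_LIMIT
        if exhaustive:
            combos = itertools.combinations(range(n1 + n2), n1)
            total = comb(n1 + n2, n1)
            null = np.empty((total,) + obs.shape)
            allidx = set(range(n1 + n2))
            for j, sel in enumerate(combos):
                rest = sorted(allidx - set(sel))
                null[j] = _group_diff(pooled[list(sel)], pooled[rest],
                                      statistic)
        else:
            total = n_perm
            null = np.empty((total,) + obs.shape)
            for j in range(n_perm):
                perm = rng.permutation(n1 + n2)
                null[j] = _group_diff(pooled[perm[:n1]], pooled[perm[n1:]],
                                      statistic)
        ns = (n1, n2)
    elif design == "multisensory_additive":
        if len(groups) != 3:
            raise ParameterError("additive design needs (A, V, AV)")
        ga, gv, gav = groups
        sizes = (ga.shape[0], gv.shape[0], gav.shape[0])
        obs = gav.mean(axis=0) - ga.mean(axis=0) - gv.mean(axis=0)
        # synthetic additive trials: random unisensory pairings A_i + V_j
        n_pairs = min(sizes[0], sizes[1])
        pa = rng.permutation(sizes[0])[:n_pairs]
        pv = rng.permutation(sizes[1])[:n_pairs]
        sums = ga[pa] + gv[pv]
        pooled = np.concatenate([gav, sums], axis=0)
        n_av = sizes[2]
        n_all = pooled.shape[0]
        exhaustive = False
        total = n_perm
        null = np.empty((total,) + obs.shape)
        for j in range(n_perm):
            perm = rng.permutation(n_all)
            null[j] = (pooled[perm[:n_av]].mean(axis=0)
                       - pooled[perm[n_av:]].mean(axis=0))
        ns = sizes
    else:
        raise ParameterError(
            "design must be paired_signflip, twosample_shuffle or "
            "multisensory_additive")

    obs_s = score(obs)
    null_s = score(null)
    # tolerance so re-summed copies of the observed statistic count as ties
    eps = 1e-12 * (np.abs(obs_s) + 1.0)
    if correction == "maxstat":
        axes = tuple(range(1, null_s.ndim))
        ref = null_s.max(axis=axes) if axes else null_s
        counts = (ref.reshape((-1,) + (1,) * obs_s.ndim)
                  >= obs_s - eps).sum(axis=0)
    else:
        counts = (null_s >= obs_s - eps).sum(axis=0)
    if exhaustive:
        p = counts / total  # the identity rearrangement is in the group
    else:
        p = (1.0 + counts) / (1.0 + total)
    p = np.minimum(np.asarray(p, dtype=np.float64), 1.0)
    return StatResult(np.asarray(obs), p, f"randomization_{design}", ns,
                      correction=correction,
                      extra={"n_perm": total, "exhaustive": exhaustive,
                             "statistic": statistic, "seed": seed})


# ------------------------------------------------- multiple-comparison tools

def bonferroni(pmap: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni mask: reject where ``p < alpha / M`` (strict), M = #points."""
    pmap = np.asarray(pmap, dtype=np.float64)
    return pmap < alpha / pmap.size


def fdr_bh(pmap: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up FDR over all points of the map jointly.

    Returns ``(mask, threshold)`` where ``threshold`` is the largest
    rejected p-value (0.0 when nothing is rejected).
    """
    pmap = np.asarray(pmap, dtype=np.float64)
    if np.any(pmap <= 0) or np.any(pmap > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    flat = pmap.reshape(-1)
    reject, _, _, _ = multipletests(flat, alpha=q, method="fdr_bh")
    thr = float(flat[reject].max()) if reject.any() else 0.0
    return reject.reshape(pmap.shape), thr


def duration_criterion(pmap: np.ndarray, alpha: float = 0.05, L: int = 1
                       ) -> np.ndarray:
    """Minimum-duration mask over the last (time) axis.

    A sample is significant iff it belongs to a run of at least ``L``
    consecutive samples with ``p < alpha`` (strict) along time, separately
    for every channel (and frequency).
    """
    if L < 1:
        raise ParameterError("L must be >= 1")
    pmap = np.asarray(pmap, dtype=np.float64)
    below = pmap < alpha
    out = np.zeros_like(below)
    flat = below.reshape(-1, below.shape[-1])
    oflat = out.reshape(-1, out.shape[-1])
    for row, orow in zip(flat, oflat):
        n = row.size
        i = 0
        while i < n:
            if row[i]:
                j = i
                while j < n and row[j]:
                    j += 1
                if j - i >= L:
                    orow[i:j] = True
                i = j
            else:
                i += 1
    return out


# -------------------------------------------------------------- convenience

def baseline_emergence(e: EpochSet, bwin: tuple[float, float],
                       alternative: str = "two-sided") -> StatResult:
    """Wilcoxon test of response emergence against each trial's baseline.

    Each trial's per-channel baseline mean (over ``bwin``) is the paired
    reference for every sample of that trial, giving a channels x samples
    p-value map.
    """
    b0, b1 = bwin
    times = e.times
    mask = (times >= b0) & (times < b1)
    if not mask.any():
        raise ParameterError("baseline window outside epoch")
    base = e.data[:, :, mask].mean(axis=2)  # trials x channels
    ref = np.broadcast_to(base[:, :, None], e.data.shape)
    res = wilcoxon_paired(e.data, ref, alternative=alternative)
    res.test = "baseline_emergence"
    return res


def pvalues_to_evoked(res: StatResult, fs: float, t0: float, event_code: int,
                      channel_names) -> EvokedRecord:
    """Package a channels x samples p-map as an event-locked record."""
    n = int(res.n[0])
    return EvokedRecord(res.p, fs, t0, event_code, max(n, 1),
                        list(channel_names), ["p"] * res.p.shape[0])


def pvalues_to_tf(res: StatResult, freqs, fs: float, t0: float,
                  event_code: int, channel_names) -> TFRecord:
    """Package a channels x freqs x samples p-map as a TF record."""
    n = int(res.n[0])
    return TFRecord(res.p, freqs, fs, t0, event_code, max(n, 1), "pvalue",
                    list(channel_names), ["p"] * res.p.shape[0])
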