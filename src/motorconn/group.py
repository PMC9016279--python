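"""Connection grading (ICW) and longitudinal group statistics.

The Individual Connection Weight (ICW) of a directed connection is the
fraction of a session's epochs in which it was surrogate-significant
(0, 1/6, ..., 1 with six epochs). Group inference then runs three analyses:

* paired one-tailed Wilcoxon signed-rank tests on epoch-averaged band DC
  (spectral power transfer, T1 vs T0),
* exact-binomial McNemar tests on paired per-epoch detections (topographic
  ICW change, T1 vs T0),
* Spearman correlations between per-subject Delta %ICW and the clinical
  deltas (Delta FMA, Delta FAC),

each followed by Benjamini-Hochberg FDR correction over the tested
connection set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

WILCOXON_EXACT_MAX_N = 12


def compute_icw(flags) -> np.ndarray:
    """ICW matrix from a session's per-epoch binary connection maps.

    ``flags`` is a sequence (or (E, M, M) array) of boolean detection maps,
    one per epoch. Returns the (M, M) matrix of per-connection proportions
    of epochs flagged; the diagonal is 0 by construction.
    """
    arr = np.asarray(list(flags), dtype=bool)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("expected per-epoch square boolean maps")
    shapes = {a.shape for a in arr}
    if len(shapes) != 1:
        raise ValueError("inconsistent epoch map shapes")
    return arr.mean(axis=0)


def population_icw_percentage(icw_by_subject) -> np.ndarray:
    """Percentage of the population exhibiting each connection, ICW-weighted.

    The mean ICW across subjects times 100, per connection.
    """
    arr = np.asarray(list(icw_by_subject), dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected one ICW matrix per subject")
    return arr.mean(axis=0) * 100.0


def wilcoxon_paired_p(x_t1, x_t0, alternative: str = "greater") -> float:
    """One-tailed paired Wilcoxon signed-rank p-value (T1 vs T0).

    Zero differences are dropped (Wilcoxon's convention). For n <= 12
    retained pairs the p-value is computed by exhaustive enumeration of the
    2^n sign assignments on midranks, which remains exact under ties; larger
    samples defer to scipy.
    """
    d = np.asarray(x_t1, dtype=float) - np.asarray(x_t0, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if alternative == "less":
        d = -d
    elif alternative != "greater":
        raise ValueError("alternative must be 'greater' or 'less'")
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    if n <= WILCOXON_EXACT_MAX_N:
        return _wilcoxon_exact_enumeration(ranks, w_obs)
    res = stats.wilcoxon(d, alternative="greater", zero_method="wilcox",
                         method="auto")
    return float(res.pvalue)


def _wilcoxon_exact_enumeration(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) over all 2^n equally likely sign assignments."""
    n = len(ranks)
    count = 0
    for signs in itertools.product((0.0, 1.0), repeat=n):
        if np.dot(signs, ranks) >= w_obs - 1e-12:
            count += 1
    return count / 2 ** n


def mcnemar_exact_p(b: int, c: int):
    """Exact-binomial McNemar test on discordant pair counts.

    ``b`` pairs flagged at T0 only, ``c`` flagged at T1 only. Under the null
    the discordant pairs split Binomial(b + c, 1/2); the two-sided p-value is
    twice the smaller tail, capped at 1. Returns ``(p, direction)`` with
    direction +1 when detections increased at T1, -1 when they decreased,
    0 when b == c.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    direction = int(np.sign(c - b))
    if n == 0:
        return 1.0, 0
    p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
    return float(min(1.0, p)), direction


def fdr_bh(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(adjusted, rejected)``; rejection iff adjusted p <= q.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


@dataclass
class GroupResult:
    """Tidy per-connection group statistics for one analysis."""

    table: pd.DataFrame  # band, source, target, statistic columns, raw_p, adj_p

    def significant(self, q: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adj_p"] <= q]


def _offdiag_pairs(labels):
    return [(i, j) for i in range(len(labels)) for j in range(len(labels))
            if i != j]


def dc_group_comparison(dc_t0, dc_t1, labels, bands=("alpha", "beta"),
                        alternative: str = "greater", q: float = 0.05) -> GroupResult:
    """Paired Wilcoxon comparison of subject-level band DC at T1 vs T0.

    ``dc_t0[band]`` and ``dc_t1[band]`` are (n_subjects, M, M) arrays of
    epoch-averaged band |DC|^2. FDR correction is applied across the 20
    directed connections within each band.
    """
    rows = []
    for band in bands:
        a0 = np.asarray(dc_t0[band], dtype=float)
        a1 = np.asarray(dc_t1[band], dtype=float)
        if a0.shape != a1.shape:
            raise ValueError("T0/T1 DC arrays differ in shape")
        ps = []
        for i, j in _offdiag_pairs(labels):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = wilcoxon_paired_p(a1[:, i, j], a0[:, i, j],
                                      alternative=alternative)
            ps.append(p)
            rows.append({
                "band": band, "source": labels[j], "target": labels[i],
                "effect": float(np.median(a1[:, i, j] - a0[:, i, j])),
                "raw_p": p,
                "direction": "increase" if alternative == "greater" else "decrease",
            })
        adj, _ = fdr_bh(ps, q)
        for r, a in zip(rows[-len(ps):], adj):
            r["adj_p"] = float(a)
    return GroupResult(pd.DataFrame(rows))


def icw_group_comparison(flags_t0, flags_t1, labels,
                         bands=("alpha", "beta"), q: float = 0.05) -> GroupResult:
    """McNemar tests on paired per-epoch detections, per connection and band.

    ``flags_t0[band]`` / ``flags_t1[band]`` are (n_subjects, n_epochs, M, M)
    boolean arrays. The paired unit is the subject x epoch (e.g. 18 x 6 = 108
    pairs); the effect column reports the Delta T1-T0 population ICW
    percentage. FDR is applied across connections within each band.
    """
    rows = []
    for band in bands:
        f0 = np.asarray(flags_t0[band], dtype=bool)
        f1 = np.asarray(flags_t1[band], dtype=bool)
        if f0.shape != f1.shape:
            raise ValueError("T0/T1 detection arrays differ in shape")
        icw0 = f0.mean(axis=1)   # (S, M, M)
        icw1 = f1.mean(axis=1)
        ps = []
        for i, j in _offdiag_pairs(labels):
            at0 = f0[:, :, i, j].ravel()
            at1 = f1[:, :, i, j].ravel()
            b = int(np.sum(at0 & ~at1))
            c = int(np.sum(~at0 & at1))
            p, direction = mcnemar_exact_p(b, c)
            ps.append(p)
            rows.append({
                "band": band, "source": labels[j], "target": labels[i],
                "delta_pct_icw": float((icw1[:, i, j] - icw0[:, i, j]).mean()
                                       * 100.0),
                "b_t0_only": b, "c_t1_only": c,
                "raw_p": p,
                "direction": {1: "increase", -1: "decrease", 0: "none"}[direction],
            })
        adj, _ = fdr_bh(ps, q)
        for r, a in zip(rows[-len(ps):], adj):
            r["adj_p"] = float(a)
    return GroupResult(pd.DataFrame(rows))


def clinical_correlation(delta_pct_icw, clinical_deltas, labels,
                         bands=("alpha", "beta"),
                         scores=("FMA", "FAC"), q: float = 0.05) -> GroupResult:
    """Spearman correlation of per-subject Delta %ICW with clinical deltas.

    ``delta_pct_icw[band]`` is (n_subjects, M, M); ``clinical_deltas[score]``
    is (n_subjects,). All connection x score x band combinations are tested
    and FDR-corrected jointly. Connections with constant input on either
    side have undefined rho and are reported with missing statistics.
    """
    rows = []
    ps = []
    p_rows = []
    for band in bands:
        d = np.asarray(delta_pct_icw[band], dtype=float)
        if d.shape[0] < 4:
            raise ValueError("Spearman correlation needs >= 4 subjects")
        for score in scores:
            y = np.asarray(clinical_deltas[score], dtype=float)
            for i, j in _offdiag_pairs(labels):
                x = d[:, i, j]
                row = {"band": band, "score": score,
                       "source": labels[j], "target": labels[i]}
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    row.update(rho=np.nan, raw_p=np.nan)
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rho, p = stats.spearmanr(x, y)
                    row.update(rho=float(rho), raw_p=float(p))
                    ps.append(float(p))
                    p_rows.append(len(rows))
                rows.append(row)
    adj = np.full(len(rows), np.nan)
    if ps:
        adj_vals, _ = fdr_bh(np.clip(ps, np.nextafter(0, 1), 1.0), q)
        for k, a in zip(p_rows, adj_vals):
            adj[k] = a
    df = pd.DataFrame(rows)
    df["adj_p"] = adj
    return GroupResult(df)
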