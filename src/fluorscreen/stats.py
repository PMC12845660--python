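"""Paired upstream/downstream testing per compound.

Each settlement contributes one upstream and one downstream sample; the
per-settlement difference (downstream - upstream, non-detects as zero) is
tested with the Wilcoxon signed-rank test. For n <= 25 nonzero pairs the
two-sided p-value is exact, computed from the full null distribution of
the positive-rank sum over all 2^n sign assignments (evaluated by
generating-function convolution over doubled midranks, which is identical
to explicit enumeration); larger n uses the normal approximation with tie
correction. Normality of the paired differences is summarized with the
Shapiro-Wilk test, and p-values are adjusted across compounds with the
Benjamini-Hochberg false-discovery-rate procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class PairedTestResult:
    compound_id: str
    n_pairs: int
    n_nonzero_pairs: int
    w_statistic: float | None
    p_value: float | None
    p_adjusted: float | None = None
    shapiro_w: float | None = None
    shapiro_p: float | None = None


def paired_differences(records, meta):
    """Per-compound vectors of (downstream - upstream) per settlement.

    ``records`` are ConcentrationRecord-like (sample_id, compound_id, conc,
    status); non-detects and below-MQL records enter as 0. Returns
    ``{compound_id: {settlement: difference}}``. A settlement without
    exactly one upstream and one downstream sample raises a ValueError
    naming it.
    """
    pos = {}
    for m in meta:
        if m.is_blank:
            continue
        pos.setdefault(m.settlement, {})[m.position] = m.sample_id
    for settlement, d in pos.items():
        if set(d) != {"upstream", "downstream"}:
            raise ValueError(f"settlement {settlement!r} is not a complete "
                             f"upstream/downstream pair (has {sorted(d)})")
    conc = {}
    for r in records:
        c = 0.0 if r.status in ("not_detected", "below_mql") else r.conc
        conc[(r.sample_id, r.compound_id)] = c
    compounds = sorted({r.compound_id for r in records})
    out = {}
    for comp in compounds:
        out[comp] = {
            s: conc.get((d["downstream"], comp), 0.0)
               - conc.get((d["upstream"], comp), 0.0)
            for s, d in pos.items()}
    return out


def _signed_midranks(diffs: np.ndarray) -> np.ndarray:
    """Midranks of |d| for nonzero d (ties share the average rank)."""
    a = np.abs(diffs)
    return sps.rankdata(a)


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the positive-rank sum under the null.

    The null distribution of W+ over all 2^n equiprobable sign vectors is
    built by convolving the generating function prod_i (1 + x^(2 r_i)),
    using doubled ranks so midranks become integers.
    """
    dr = np.rint(2 * ranks).astype(int)
    total = int(dr.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in dr:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_le = dist[:w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def wilcoxon_signed_rank(differences, zero_policy: str = "drop",
                         exact_max_n: int = 25):
    """Wilcoxon signed-rank test; returns (W_plus, two-sided p).

    Zero differences are dropped (classical treatment) unless
    ``zero_policy='pratt'``, which keeps zeros in the ranking and drops
    them from the statistic. All differences zero -> (None, None).
    """
    d = np.asarray(list(differences), dtype=float)
    if zero_policy not in ("drop", "pratt"):
        raise ValueError("zero_policy must be 'drop' or 'pratt'")
    if zero_policy == "drop":
        d = d[d != 0]
        if d.size == 0:
            return None, None
        ranks = _signed_midranks(d)
        use = np.ones(d.size, dtype=bool)
    else:
        if not np.any(d != 0):
            return None, None
        ranks = sps.rankdata(np.abs(d))
        use = d != 0
    w_plus = float(ranks[use & (d > 0)].sum()) if zero_policy == "pratt" \
        else float(ranks[d > 0].sum())
    n = int(use.sum())
    active_ranks = ranks[use]
    if n <= exact_max_n:
        p = _exact_two_sided_p(active_ranks, w_plus)
    else:
        mu = active_ranks.sum() / 2.0
        # variance with tie correction via the actual midranks
        var = float((active_ranks ** 2).sum()) / 4.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return w_plus, p


def shapiro_wilk(differences):
    """Shapiro-Wilk W and p for 3 <= n <= 50 non-constant data."""
    d = np.asarray(list(differences), dtype=float)
    if d.size < 3 or d.size > 50:
        raise ValueError(f"Shapiro-Wilk defined here for 3 <= n <= 50, got {d.size}")
    if np.all(d == d[0]):
        raise ValueError("constant data: Shapiro-Wilk undefined")
    w, p = sps.shapiro(d)
    return float(w), float(p)


def fdr_adjust(p_values, method: str = "bh"):
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method != "bh":
        raise ValueError("only Benjamini-Hochberg ('bh') is supported")
    return multipletests(p, method="fdr_bh")[1]


def test_all_compounds(records, meta, alpha: float = 0.05):
    """Run the full paired-testing battery across compounds.

    Returns a list of :class:`PairedTestResult`, FDR-adjusted across the
    compounds with a defined Wilcoxon p.
    """
    diffs = paired_differences(records, meta)
    results = []
    for comp, by_settlement in sorted(diffs.items()):
        d = np.array(list(by_settlement.values()), dtype=float)
        w, p = wilcoxon_signed_rank(d)
        try:
            sw, sp = shapiro_wilk(d)
        except ValueError:
            sw, sp = None, None
        results.append(PairedTestResult(
            compound_id=comp, n_pairs=d.size,
            n_nonzero_pairs=int(np.sum(d != 0)),
            w_statistic=w, p_value=p, shapiro_w=sw, shapiro_p=sp))
    defined = [r for r in results if r.p_value is not None]
    if defined:
        adj = fdr_adjust([r.p_value for r in defined])
        for r, a in zip(defined, adj):
            r.p_adjusted = float(a)
    return results
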