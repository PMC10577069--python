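"""Windowed Hudson F_ST, invariant-aware D_XY, and Tajima's D.

F_ST is Hudson's estimator with the Bhatia et al. finite-sample
correction, aggregated per window as a ratio of summed per-site
numerators and denominators ("ratio of averages").  D_XY is the mean
between-population pairwise difference per comparable site, with
invariant sites contributing zero to the numerator but counted in the
denominator.  Tajima's D follows Tajima (1989), computed on
complete-case sites within the focal population.

Undefined values are returned as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix
from .windowing import WindowSet


# ---------------------------------------------------------------------------
# per-site building blocks

def pop_allele_counts(dosage: np.ndarray, idx: np.ndarray):
    """Alt-allele count and called-allele count per site for one population."""
    d = dosage[:, idx]
    called = d != MISSING
    an = 2 * called.sum(axis=1)
    ac = np.where(called, d, 0).sum(axis=1)
    return ac.astype(np.int64), an.astype(np.int64)


def hudson_site_components(ac1, an1, ac2, an2):
    """Per-site Hudson F_ST numerator/denominator and D_XY term.

    Returns (num, den, dxy, fst_ok, dxy_ok): fst_ok requires >=2 called
    alleles in each population (the sample-size correction divides by
    n-1); dxy_ok requires >=1 called allele in each.
    """
    ac1 = np.asarray(ac1, dtype=float)
    an1 = np.asarray(an1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float)
    an2 = np.asarray(an2, dtype=float)
    fst_ok = (an1 >= 2) & (an2 >= 2)
    dxy_ok = (an1 >= 1) & (an2 >= 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(an1 > 0, ac1 / an1, 0.0)
        p2 = np.where(an2 > 0, ac2 / an2, 0.0)
        num = ((p1 - p2) ** 2
               - np.where(fst_ok, p1 * (1 - p1) / (an1 - 1), 0.0)
               - np.where(fst_ok, p2 * (1 - p2) / (an2 - 1), 0.0))
    dxy = p1 * (1 - p2) + p2 * (1 - p1)
    den = dxy.copy()
    num = np.where(fst_ok, num, 0.0)
    den = np.where(fst_ok, den, 0.0)
    dxy = np.where(dxy_ok, dxy, 0.0)
    return num, den, dxy, fst_ok, dxy_ok


@dataclass
class SiteDivergenceComponents:
    p1: float
    p2: float
    n1: int
    n2: int
    fst_num: float
    fst_den: float
    dxy_site: float
    comparable: bool


def site_divergence_components(G: GenotypeMatrix, popA, popB,
                               site: int) -> SiteDivergenceComponents:
    """Single-site view of the Hudson/D_XY components (diagnostic surface)."""
    iA = np.asarray(popA, dtype=np.intp)
    iB = np.asarray(popB, dtype=np.intp)
    if np.intersect1d(iA, iB).size:
        raise ValueError("populations must be disjoint")
    ac1, an1 = pop_allele_counts(G.dosage[site:site + 1], iA)
    ac2, an2 = pop_allele_counts(G.dosage[site:site + 1], iB)
    num, den, dxy, fst_ok, dxy_ok = hudson_site_components(ac1, an1, ac2, an2)
    p1 = float(ac1[0] / an1[0]) if an1[0] else np.nan
    p2 = float(ac2[0] / an2[0]) if an2[0] else np.nan
    return SiteDivergenceComponents(
        p1=p1, p2=p2, n1=int(an1[0]), n2=int(an2[0]),
        fst_num=float(num[0]), fst_den=float(den[0]),
        dxy_site=float(dxy[0]), comparable=bool(fst_ok[0] or dxy_ok[0]),
    )


# ---------------------------------------------------------------------------
# window aggregation

def _window_sums(values: np.ndarray, spans: np.ndarray) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    return cs[spans[:, 1]] - cs[spans[:, 0]]


def windowed_fst_dxy(G: GenotypeMatrix, popA, popB, windows: WindowSet):
    """Hudson F_ST and D_XY per window for one population pair.

    Returns (fst, dxy, n_comparable) arrays over windows; NaN where the
    denominator is empty.
    """
    iA = np.asarray(popA, dtype=np.intp)
    iB = np.asarray(popB, dtype=np.intp)
    ac1, an1 = pop_allele_counts(G.dosage, iA)
    ac2, an2 = pop_allele_counts(G.dosage, iB)
    num, den, dxy, fst_ok, dxy_ok = hudson_site_components(ac1, an1, ac2, an2)
    spans = windows.site_spans(G.positions)
    num_w = _window_sums(num, spans)
    den_w = _window_sums(den, spans)
    dxy_w = _window_sums(dxy, spans)
    n_cmp = _window_sums(dxy_ok.astype(float), spans)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den_w > 0, num_w / np.where(den_w > 0, den_w, 1.0), np.nan)
        dxy_mean = np.where(n_cmp > 0, dxy_w / np.where(n_cmp > 0, n_cmp, 1.0),
                            np.nan)
    return fst, dxy_mean, n_cmp.astype(np.int64)


def window_fst(G: GenotypeMatrix, popA, popB, window) -> float:
    """Ratio-of-sums Hudson F_ST for one window (NaN when undefined)."""
    ws = _single(G, window)
    fst, _, _ = windowed_fst_dxy(G, popA, popB, ws)
    return float(fst[0])


def window_dxy(G: GenotypeMatrix, popA, popB, window) -> float:
    ws = _single(G, window)
    _, dxy, _ = windowed_fst_dxy(G, popA, popB, ws)
    return float(dxy[0])


def _single(G: GenotypeMatrix, window) -> WindowSet:
    s, e = window
    return WindowSet(G.chrom, np.array([s]), np.array([e]))


# ---------------------------------------------------------------------------
# Tajima's D

def tajima_constants(n: int) -> dict[str, float]:
    """The Tajima (1989) normalizing constants for n haplotypes."""
    if n < 2:
        raise ValueError("Tajima constants need n >= 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def windowed_tajima_d(G: GenotypeMatrix, pop, windows: WindowSet):
    """Tajima's D per window for one population.

    Sites with any missing call in the population are excluded from both
    S and pi (complete-case policy), so the haplotype count n is constant.
    Returns (D, S, pi) arrays; D is NaN where S == 0.
    """
    idx = np.asarray(pop, dtype=np.intp)
    if idx.size < 2:
        raise ValueError("Tajima's D needs >= 2 diploid samples")
    n = 2 * idx.size
    d = G.dosage[:, idx]
    complete = np.all(d != MISSING, axis=1)
    j = np.where(complete, d.sum(axis=1), 0).astype(np.int64)
    seg = complete & (j > 0) & (j < n)
    pi_site = np.where(seg, 2.0 * j * (n - j) / (n * (n - 1.0)), 0.0)
    spans = windows.site_spans(G.positions)
    S = _window_sums(seg.astype(float), spans)
    pi = _window_sums(pi_site, spans)
    k = tajima_constants(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_w = S / k["a1"]
        var = k["e1"] * S + k["e2"] * S * (S - 1.0)
        D = np.where(S > 0, (pi - theta_w) / np.sqrt(np.where(var > 0, var, 1.0)),
                     np.nan)
    return D, S.astype(np.int64), pi


def window_tajima_d(G: GenotypeMatrix, pop, window) -> float:
    D, _, _ = windowed_tajima_d(G, pop, _single(G, window))
    return float(D[0])
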