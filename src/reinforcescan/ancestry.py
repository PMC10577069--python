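"""Per-window two-component ancestry for parapatric M. fascicularis.

Three estimators share the binomial admixture log-likelihood

    sum_sites [ g log(q pM + (1-q) pF) + (2-g) log(1 - q pM - (1-q) pF) ]

over the mulatta-ancestry fraction q in [0,1]:

* ``supervised`` (default) — ADMIXTURE-style supervised EM: allopatric
  panel individuals have their ancestry pinned (mulatta panel q=1,
  fascicularis panel q=0) and both component frequency vectors are
  re-estimated each iteration from *all* samples, queries included.
  Re-estimation absorbs drift specific to the query population that a
  fixed panel would misread as admixture.
* ``projection`` — component frequencies fixed at the allopatric-panel
  estimates (pseudocount 1 per allele class); each query's q maximizes
  the concave log-likelihood by bounded 1-D optimization.  Cheap and
  exactly analyzable, but upward-biased when the query population has
  drifted from its panel.
* ``unsupervised`` — FRAPPE-style K=2 EM on all samples jointly; label
  switching is resolved by assigning the "mulatta" component to the one
  with the larger mean ancestry among allopatric M. mulatta samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .io import MISSING, GenotypeMatrix, PopulationAssignment
from .windowing import WindowSet
from .popgen import pop_allele_counts

_EPS = 1e-9


@dataclass
class AncestryEstimate:
    """K=2 ancestry for one window: Q[i] = mulatta fraction of sample i."""

    K: int
    sample_ids: list[str]
    Q: np.ndarray                  # NaN = undefined
    freq_mul: np.ndarray           # per-site component frequencies
    freq_fas: np.ndarray
    mean_para_fas_q: float


def panel_frequencies(G: GenotypeMatrix, panel_idx) -> np.ndarray:
    """Allele frequencies from a reference panel, pseudocount 1 per class."""
    ac, an = pop_allele_counts(G.dosage, np.asarray(panel_idx, dtype=np.intp))
    return (ac + 1.0) / (an + 2.0)


def _loglik(q: float, g, pm, pf) -> float:
    p = q * pm + (1.0 - q) * pf
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(np.sum(g * np.log(p) + (2.0 - g) * np.log1p(-p)))


def fit_q(g: np.ndarray, pm: np.ndarray, pf: np.ndarray) -> float:
    """Maximum-likelihood ancestry fraction for one individual.

    g: dosages with MISSING allowed; pm/pf: component frequencies.
    """
    called = g != MISSING
    if not called.any():
        return np.nan
    g = g[called].astype(float)
    pm_c, pf_c = pm[called], pf[called]
    if np.allclose(pm_c, pf_c):
        return np.nan                      # no ancestry-informative sites
    res = minimize_scalar(lambda q: -_loglik(q, g, pm_c, pf_c),
                          bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    q = float(res.x)
    # the bounded optimizer keeps a margin from the bounds; snap to a
    # boundary when it is at least as likely
    for b in (0.0, 1.0):
        if _loglik(b, g, pm_c, pf_c) >= _loglik(q, g, pm_c, pf_c):
            q = b
    return q


def estimate_window_ancestry(G: GenotypeMatrix, window, popmap: PopulationAssignment,
                             mode: str = "supervised",
                             seed: int = 0) -> AncestryEstimate:
    """Two-component ancestry for all samples over one window's sites."""
    s, e = window
    ws = WindowSet(G.chrom, np.array([s]), np.array([e]))
    i0, i1 = ws.site_spans(G.positions)[0]
    return _estimate_span(G, int(i0), int(i1), popmap, mode, seed)


def _estimate_span(G, i0, i1, popmap, mode, seed,
                   query_idx=None) -> AncestryEstimate:
    sub = G.dosage[i0:i1]
    variant = G.is_variant[i0:i1]
    sub = sub[variant]
    if sub.shape[0] == 0:
        Q = np.full(G.n_samples, np.nan)
        return _finish(G, popmap, Q, np.empty(0), np.empty(0))

    if mode in ("supervised", "projection"):
        pan_m = popmap.indices(G, "ALLO_MUL")
        pan_f = popmap.indices(G, "ALLO_FAS")
        if pan_m.size < 2 or pan_f.size < 2:
            raise ValueError("supervised mode needs >=2 samples in each "
                             "allopatric panel")
        pm = panel_frequencies_from(sub, pan_m)
        pf = panel_frequencies_from(sub, pan_f)
        if np.allclose(pm, pf):
            Q = np.full(G.n_samples, np.nan)
        elif mode == "projection":
            who = (range(G.n_samples) if query_idx is None
                   else np.asarray(query_idx, dtype=np.intp))
            Q = np.full(G.n_samples, np.nan)
            for i in who:
                Q[i] = fit_q(sub[:, i], pm, pf)
        else:
            Q, pm, pf = _em_supervised(sub, pan_m, pan_f, G.n_samples)
    elif mode == "unsupervised":
        Q, pm, pf = _em_k2(sub, popmap.indices(G, "ALLO_MUL"), seed)
    else:
        raise ValueError(f"unknown ancestry mode: {mode!r}")
    return _finish(G, popmap, Q, pm, pf)


def panel_frequencies_from(dosage_block: np.ndarray, panel_idx) -> np.ndarray:
    ac, an = pop_allele_counts(dosage_block, np.asarray(panel_idx, dtype=np.intp))
    return (ac + 1.0) / (an + 2.0)


def _finish(G, popmap, Q, pm, pf) -> AncestryEstimate:
    para_idx = popmap.indices(G, "PARA_FAS")
    q_para = Q[para_idx]
    defined = ~np.isnan(q_para)
    mean_q = float(np.mean(q_para[defined])) if defined.any() else np.nan
    return AncestryEstimate(K=2, sample_ids=list(G.sample_ids), Q=Q,
                            freq_mul=pm, freq_fas=pf,
                            mean_para_fas_q=mean_q)


def mean_parapatric_ancestry(est: AncestryEstimate,
                             popmap: PopulationAssignment) -> float:
    """Mean mulatta-ancestry over parapatric M. fascicularis individuals.

    Undefined individual estimates are dropped (NaN-mean); all-undefined
    windows return NaN, which can never pass the <2.5% admixture filter.
    """
    idx = [est.sample_ids.index(s) for s in popmap.samples("PARA_FAS")]
    vals = est.Q[np.asarray(idx, dtype=np.intp)]
    defined = ~np.isnan(vals)
    if not defined.any():
        return np.nan
    return float(np.mean(vals[defined]))


def windowed_mean_ancestry(G: GenotypeMatrix, windows: WindowSet,
                           popmap: PopulationAssignment,
                           mode: str = "supervised", seed: int = 0):
    """mean_para_fas_q per window plus the full per-sample Q matrix."""
    spans = windows.site_spans(G.positions)
    means = np.empty(len(windows))
    Qs = np.empty((len(windows), G.n_samples))
    # the windowed scan only uses parapatric M. fascicularis ancestry;
    # in projection mode skip the 1-D optimizer for everyone else
    query = popmap.indices(G, "PARA_FAS") if mode == "projection" else None
    for w, (i0, i1) in enumerate(spans):
        est = _estimate_span(G, int(i0), int(i1), popmap, mode, seed,
                             query_idx=query)
        means[w] = est.mean_para_fas_q
        Qs[w] = est.Q
    return means, Qs


# ---------------------------------------------------------------------------
# supervised K=2 EM (ADMIXTURE --supervised semantics)

def _em_supervised(dosage_block: np.ndarray, pan_m, pan_f, n_samples: int,
                   n_iter: int = 200, tol: float = 1e-8):
    """Supervised K=2 EM: panel labels fixed, frequencies re-estimated.

    Allopatric panel individuals have their ancestry pinned (mulatta
    panel q=1, fascicularis panel q=0); everyone's genotypes, queries
    included, update the two component frequencies each iteration (with
    a pseudocount of 1 per allele class).  Re-estimating frequencies
    with the queries absorbs query-specific drift that fixed-panel
    projection would misread as admixture.  Deterministic: no random
    initialization is needed.
    """
    pan_m = np.asarray(pan_m, dtype=np.intp)
    pan_f = np.asarray(pan_f, dtype=np.intp)
    d = dosage_block
    called = d != MISSING
    g = np.where(called, d, 0).astype(float)
    two = np.where(called, 2.0, 0.0)
    free = np.ones(n_samples, dtype=bool)
    free[pan_m] = False
    free[pan_f] = False
    q = np.full(n_samples, 0.5)
    q[pan_m] = 1.0
    q[pan_f] = 0.0
    f0 = panel_frequencies_from(d, pan_m)
    f1 = panel_frequencies_from(d, pan_f)
    prev = -np.inf
    for _ in range(n_iter):
        p = np.clip(np.outer(f0, q) + np.outer(f1, 1.0 - q), _EPS, 1 - _EPS)
        a1 = g * (np.outer(f0, q) / p)
        b1 = (two - g) * (np.outer(1.0 - f0, q) / (1.0 - p))
        q_new = (a1.sum(axis=0) + b1.sum(axis=0)) / np.maximum(
            two.sum(axis=0), _EPS)
        q[free] = np.clip(q_new[free], 0.0, 1.0)
        a2 = g - a1
        b2 = (two - g) - b1
        f0 = np.clip((a1.sum(axis=1) + 1.0)
                     / (a1.sum(axis=1) + b1.sum(axis=1) + 2.0), _EPS, 1 - _EPS)
        f1 = np.clip((a2.sum(axis=1) + 1.0)
                     / (a2.sum(axis=1) + b2.sum(axis=1) + 2.0), _EPS, 1 - _EPS)
        ll = float(np.sum(np.where(called, g * np.log(p)
                                   + (two - g) * np.log1p(-p), 0.0)))
        if abs(ll - prev) < tol * max(1.0, abs(ll)):
            break
        prev = ll
    return q, f0, f1


# ---------------------------------------------------------------------------
# unsupervised K=2 EM

def _em_k2(dosage_block: np.ndarray, allo_mul_idx, seed: int,
           n_iter: int = 300, tol: float = 1e-7):
    """FRAPPE-style EM at K=2 on all samples jointly.

    Deterministic given seed; the component with the larger mean ancestry
    among allopatric M. mulatta samples is reported as "mulatta".
    """
    rng = np.random.default_rng(seed)
    d = dosage_block
    called = d != MISSING
    g = np.where(called, d, 0).astype(float)
    two = np.where(called, 2.0, 0.0)
    n_sites, n_samples = d.shape
    q = rng.uniform(0.3, 0.7, size=n_samples)
    f = np.clip(rng.uniform(0.2, 0.8, size=(2, n_sites)), _EPS, 1 - _EPS)
    prev = -np.inf
    for _ in range(n_iter):
        # p[i,j] = q_i f1_j + (1-q_i) f2_j, shaped (sites, samples)
        p = np.clip(np.outer(f[0], q) + np.outer(f[1], 1.0 - q), _EPS, 1 - _EPS)
        # expected component-1 copies among alt / ref alleles
        a1 = g * (np.outer(f[0], q) / p)
        b1 = (two - g) * (np.outer(1.0 - f[0], q) / (1.0 - p))
        a2 = g - a1
        b2 = (two - g) - b1
        q = (a1.sum(axis=0) + b1.sum(axis=0)) / np.maximum(two.sum(axis=0), _EPS)
        q = np.clip(q, 0.0, 1.0)
        f0 = a1.sum(axis=1) / np.maximum(a1.sum(axis=1) + b1.sum(axis=1), _EPS)
        f1 = a2.sum(axis=1) / np.maximum(a2.sum(axis=1) + b2.sum(axis=1), _EPS)
        f = np.clip(np.vstack([f0, f1]), _EPS, 1 - _EPS)
        ll = float(np.sum(np.where(called, g * np.log(p) +
                                   (two - g) * np.log1p(-p), 0.0)))
        if abs(ll - prev) < tol:
            break
        prev = ll
    allo_mul_idx = np.asarray(allo_mul_idx, dtype=np.intp)
    if q[allo_mul_idx].mean() < 0.5:
        q = 1.0 - q
        f = f[::-1]
    return q, f[0], f[1]
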