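"""Candidate-window detection for reproductive character displacement.

Per window the scan computes the divergence difference

    D_d = D_p - D_a

(parapatric-pair minus allopatric-pair divergence, for both F_ST and
D_XY) against a permutation null built from reshuffled population
labels, the averaged Tajima's D contrast

    TD_d = ((TD_pf - TD_pm) + (TD_pf - TD_af)) / 2

with a strict < -1 cutoff, and the mean mulatta ancestry of parapatric
M. fascicularis with a strict < 2.5% cutoff.  A window is a candidate
when it is significant in (F_ST or D_XY) and Tajima's D and ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PopulationAssignment, GeneAnnotationSet
from .windowing import WindowSet
from .popgen import windowed_fst_dxy, windowed_tajima_d

logger = logging.getLogger(__name__)

TAJIMA_CUT = -1.0
ANCESTRY_CUT = 0.025
PERM_FRAC = 0.95
N_PERM = 100


@dataclass
class PermutationNull:
    """Shared reshuffled labelings and per-window permuted D_d values."""

    n_perm: int
    labelings: np.ndarray               # (n_perm, n_samples) of label strings
    dd_fst: np.ndarray                  # (n_perm, n_windows)
    dd_dxy: np.ndarray
    exceed_fst: np.ndarray = field(default=None)   # per window
    exceed_dxy: np.ndarray = field(default=None)
    n_defined_fst: np.ndarray = field(default=None)
    n_defined_dxy: np.ndarray = field(default=None)


def significance_from_exceedance(exceed, n_defined,
                                 perm_frac: float = PERM_FRAC) -> np.ndarray:
    """Strict exceedance rule: significant iff exceed/n_defined > perm_frac.

    With 100 permutations and the default 0.95 this requires >= 96
    exceedances — exactly 95/100 is *not* significant, and ties between
    the empirical and a permuted value never count as exceedance.
    """
    exceed = np.asarray(exceed, dtype=float)
    n_defined = np.asarray(n_defined, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_defined > 0, exceed / np.maximum(n_defined, 1.0),
                        np.nan)
    return (n_defined > 0) & (frac > perm_frac)


def divergence_difference(D_p: float, D_a: float) -> float:
    """Eq. D_d = D_p - D_a; NaN when either side is undefined."""
    return D_p - D_a


def tajima_difference(TD_pf: float, TD_pm: float, TD_af: float):
    """Averaged Tajima's D contrast and its strict cutoff flag."""
    TD_d = ((TD_pf - TD_pm) + (TD_pf - TD_af)) / 2.0
    td_sig = bool(TD_d < TAJIMA_CUT) if np.isfinite(TD_d) else False
    return TD_d, td_sig


def call_candidates(fst_sig, dxy_sig, td_sig, adm_sig):
    """candidate = (fst_sig OR dxy_sig) AND td_sig AND adm_sig."""
    return (np.asarray(fst_sig, bool) | np.asarray(dxy_sig, bool)) \
        & np.asarray(td_sig, bool) & np.asarray(adm_sig, bool)


def _dd_for_labels(G: GenotypeMatrix, windows: WindowSet, labels: np.ndarray):
    """Per-window D_d (F_ST and D_XY variants) under one sample labeling."""
    idx = {l: np.nonzero(labels == l)[0] for l in
           ("ALLO_MUL", "PARA_MUL", "ALLO_FAS", "PARA_FAS")}
    fst_p, dxy_p, _ = windowed_fst_dxy(G, idx["PARA_MUL"], idx["PARA_FAS"], windows)
    fst_a, dxy_a, _ = windowed_fst_dxy(G, idx["ALLO_MUL"], idx["ALLO_FAS"], windows)
    return fst_p - fst_a, dxy_p - dxy_a, (fst_p, fst_a, dxy_p, dxy_a)


def make_labelings(labels: np.ndarray, n_perm: int, seed: int) -> np.ndarray:
    """n_perm reshuffles of the label vector, each preserving group sizes."""
    rng = np.random.default_rng(seed)
    return np.stack([rng.permutation(labels) for _ in range(n_perm)])


def permutation_null(G: GenotypeMatrix, windows: WindowSet,
                     popmap: PopulationAssignment, n_perm: int = N_PERM,
                     seed: int = 0, perm_frac: float = PERM_FRAC):
    """Permutation null for D_d and the per-window significance flags.

    A window is significant for a statistic when its empirical D_d is
    strictly greater than more than ``perm_frac`` of the defined permuted
    values for that window (ties do not count as exceedance).  Permuted
    values that are undefined (NaN) are dropped from the comparison, with
    a logged count.  One shared set of labelings is used for every window
    and both statistics.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 makes the 95% criterion meaningless")
    for label, n in popmap.group_sizes().items():
        if n < 4:
            raise ValueError(f"permutation test needs >=4 samples per group; "
                             f"{label} has {n}")
    labels = popmap.labels_for(G.sample_ids)
    emp_fst, emp_dxy, raw = _dd_for_labels(G, windows, labels)
    labelings = make_labelings(labels, n_perm, seed)
    dd_fst = np.empty((n_perm, len(windows)))
    dd_dxy = np.empty((n_perm, len(windows)))
    for k in range(n_perm):
        dd_fst[k], dd_dxy[k], _ = _dd_for_labels(G, windows, labelings[k])

    def flags(emp, perm):
        defined = np.isfinite(perm)
        n_def = defined.sum(axis=0)
        exceed = np.sum(defined & (perm < emp[None, :]), axis=0)
        sig = np.isfinite(emp) & significance_from_exceedance(
            exceed, n_def, perm_frac)
        return sig, exceed, n_def

    fst_sig, ex_f, nd_f = flags(emp_fst, dd_fst)
    dxy_sig, ex_d, nd_d = flags(emp_dxy, dd_dxy)
    n_dropped = int((~np.isfinite(dd_fst)).sum() + (~np.isfinite(dd_dxy)).sum())
    if n_dropped:
        logger.info("permutation_null: dropped %d undefined permuted D_d values",
                    n_dropped)
    null = PermutationNull(n_perm=n_perm, labelings=labelings,
                           dd_fst=dd_fst, dd_dxy=dd_dxy,
                           exceed_fst=ex_f, exceed_dxy=ex_d,
                           n_defined_fst=nd_f, n_defined_dxy=nd_d)
    return null, emp_fst, emp_dxy, fst_sig, dxy_sig, raw


def scan_windows(G: GenotypeMatrix, windows: WindowSet,
                 popmap: PopulationAssignment, mean_ancestry: np.ndarray,
                 n_perm: int = N_PERM, seed: int = 0,
                 tajima_cut: float = TAJIMA_CUT,
                 ancestry_cut: float = ANCESTRY_CUT,
                 perm_frac: float = PERM_FRAC) -> pd.DataFrame:
    """Full per-window scan table with statistics, flags, candidate calls."""
    null, dd_fst, dd_dxy, fst_sig, dxy_sig, raw = permutation_null(
        G, windows, popmap, n_perm=n_perm, seed=seed, perm_frac=perm_frac)
    fst_p, fst_a, dxy_p, dxy_a = raw
    td_pf, _, _ = windowed_tajima_d(G, popmap.indices(G, "PARA_FAS"), windows)
    td_pm, _, _ = windowed_tajima_d(G, popmap.indices(G, "PARA_MUL"), windows)
    td_af, _, _ = windowed_tajima_d(G, popmap.indices(G, "ALLO_FAS"), windows)
    with np.errstate(invalid="ignore"):
        td_d = ((td_pf - td_pm) + (td_pf - td_af)) / 2.0
        td_sig = np.where(np.isfinite(td_d), td_d < tajima_cut, False).astype(bool)
        adm = np.asarray(mean_ancestry, dtype=float)
        adm_sig = np.where(np.isfinite(adm), adm < ancestry_cut, False).astype(bool)
    candidate = call_candidates(fst_sig, dxy_sig, td_sig, adm_sig)
    return pd.DataFrame({
        "chrom": windows.chrom,
        "start": windows.starts,
        "end": windows.ends,
        "fst_para": fst_p, "fst_allo": fst_a,
        "dxy_para": dxy_p, "dxy_allo": dxy_a,
        "dd_fst": dd_fst, "dd_dxy": dd_dxy,
        "td_pf": td_pf, "td_pm": td_pm, "td_af": td_af, "td_d": td_d,
        "mean_para_fas_q": adm,
        "exceed_fst": null.exceed_fst, "n_perm_fst": null.n_defined_fst,
        "exceed_dxy": null.exceed_dxy, "n_perm_dxy": null.n_defined_dxy,
        "fst_sig": fst_sig, "dxy_sig": dxy_sig,
        "td_sig": td_sig, "adm_sig": adm_sig,
        "candidate": candidate,
    })


def overlap_genes(candidates: WindowSet, genes: GeneAnnotationSet) -> pd.DataFrame:
    """Genes overlapped (>=1 base) by any candidate window.

    One row per gene, with all supporting windows joined; coordinates are
    0-based half-open on both sides, so abutting intervals do not overlap.
    """
    gene_chroms = {g.chrom for g in genes}
    if len(candidates) and gene_chroms and candidates.chrom not in gene_chroms:
        raise ValueError(
            f"contig name mismatch: windows on {candidates.chrom!r}, "
            f"annotation has {sorted(gene_chroms)}"
        )
    rows = []
    for g in genes:
        if g.chrom != candidates.chrom:
            continue
        hit = (candidates.starts < g.end) & (candidates.ends > g.start)
        if hit.any():
            wins = [f"{candidates.chrom}:{s}-{e}"
                    for s, e in zip(candidates.starts[hit], candidates.ends[hit])]
            rows.append({"gene_id": g.gene_id, "chrom": g.chrom,
                         "start": g.start, "end": g.end, "strand": g.strand,
                         "n_windows": int(hit.sum()),
                         "windows": ",".join(wins)})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "n_windows", "windows"])
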