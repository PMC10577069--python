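"""One-command orchestration of the full scan with a run manifest.

Stages: windows -> stats -> ancestry -> scan -> annotate.  Identical
config + seed gives byte-identical outputs (no timestamps enter any
output file).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from . import scan as rscan
from .ancestry import windowed_mean_ancestry
from .annotate import (annotate_effects, bsift_score, flank_sequences,
                       motif_uniqueness, unique_parapatric_sites,
                       write_flank_fasta)
from .windowing import WindowSet, windows_from_genotypes


@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    gtf: str
    fasta: str
    sift: str | None = None
    motifs: str | None = None
    out_dir: str = "scan_out"
    seed: int = 0
    n_perm: int = 100
    tajima_cut: float = -1.0
    ancestry_cut: float = 0.025
    perm_frac: float = 0.95
    fixed_window: int | None = None
    ancestry_mode: str = "supervised"
    motif_threshold: float = 0.85

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (permutation null is stochastic)")
        if not (0.5 <= self.perm_frac < 1.0):
            raise ValueError("perm_frac must be in [0.5, 1)")
        if not (0.0 <= self.ancestry_cut <= 1.0):
            raise ValueError("ancestry_cut must be in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dict.

    Any stage failure is re-raised with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}
    state: dict = {}
    stages = [
        ("windows", _stage_windows),
        ("stats", _stage_stats),
        ("ancestry", _stage_ancestry),
        ("scan", _stage_scan),
        ("annotate", _stage_annotate),
    ]
    for name, fn in stages:
        try:
            counts = fn(config, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"stage": name, **counts})
    import reinforcescan

    manifest["versions"] = {"reinforcescan": reinforcescan.__version__,
                            "numpy": np.__version__,
                            "pandas": pd.__version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_windows(config, out, state) -> dict:
    popmap = rio.read_population_map(config.popmap)
    G = rio.read_genotype_vcf(config.vcf, popmap=popmap)
    windows = windows_from_genotypes(G, fixed_window=config.fixed_window)
    rio.write_bed(((windows.chrom, s, e) for s, e in windows),
                  out / "windows.bed")
    state.update(G=G, popmap=popmap, windows=windows)
    return {"n_sites": G.n_sites, "n_variant": int(G.is_variant.sum()),
            "n_windows": len(windows)}


def _stage_stats(config, out, state) -> dict:
    # raw statistics are produced inside the scan stage (same code path as
    # its permutation null); this stage records per-population counts
    sizes = state["popmap"].group_sizes()
    return {"samples_per_pop": sizes}


def _stage_ancestry(config, out, state) -> dict:
    mean_q, Q = windowed_mean_ancestry(
        state["G"], state["windows"], state["popmap"],
        mode=config.ancestry_mode, seed=config.seed)
    state["mean_q"] = mean_q
    df = pd.DataFrame({"chrom": state["windows"].chrom,
                       "start": state["windows"].starts,
                       "end": state["windows"].ends,
                       "mean_para_fas_q": mean_q})
    rio.write_table(df, out / "ancestry.tsv")
    return {"n_windows": len(mean_q),
            "n_defined": int(np.isfinite(mean_q).sum())}


def _stage_scan(config, out, state) -> dict:
    table = rscan.scan_windows(
        state["G"], state["windows"], state["popmap"], state["mean_q"],
        n_perm=config.n_perm, seed=config.seed,
        tajima_cut=config.tajima_cut, ancestry_cut=config.ancestry_cut,
        perm_frac=config.perm_frac)
    rio.write_table(table, out / "scan.windows.tsv")
    cand = table[table["candidate"]]
    rio.write_bed(zip(cand["chrom"], cand["start"], cand["end"]),
                  out / "scan.candidates.bed")
    genes = rio.read_gene_annotation(config.gtf)
    cand_ws = WindowSet(state["windows"].chrom,
                        cand["start"].to_numpy(), cand["end"].to_numpy()) \
        if len(cand) else WindowSet(state["windows"].chrom,
                                    np.empty(0, np.int64), np.empty(0, np.int64) + 1)
    if len(cand):
        gene_df = rscan.overlap_genes(cand_ws, genes)
    else:
        gene_df = pd.DataFrame(columns=["gene_id", "chrom", "start", "end",
                                        "strand", "n_windows", "windows"])
    rio.write_table(gene_df, out / "scan.genes.tsv")
    state.update(scan_table=table, genes=genes, gene_df=gene_df)
    return {"n_windows": len(table),
            "n_fst_sig": int(table["fst_sig"].sum()),
            "n_dxy_sig": int(table["dxy_sig"].sum()),
            "n_td_sig": int(table["td_sig"].sum()),
            "n_adm_sig": int(table["adm_sig"].sum()),
            "n_candidates": int(table["candidate"].sum()),
            "n_genes": len(gene_df)}


def _stage_annotate(config, out, state) -> dict:
    return annotate_candidate_genes(
        state["G"], state["popmap"], state["genes"],
        set(state["gene_df"]["gene_id"]), config.fasta, out,
        sift=config.sift, motifs=config.motifs,
        motif_threshold=config.motif_threshold)


def annotate_candidate_genes(G, popmap, genes, gene_ids, fasta_path, out,
                             sift=None, motifs=None,
                             motif_threshold: float = 0.85) -> dict:
    """Annotate parapatric-unique sites inside the named candidate genes.

    Writes annot.unique_sites.vcf, annot.effects.tsv, annot.flanks.fasta,
    annot.bsift.tsv, annot.motifs.tsv under ``out``; returns row counts.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    regions = [(g.start, g.end) for g in genes if g.gene_id in gene_ids]
    sites = unique_parapatric_sites(G, popmap, regions=regions)
    rio.write_genotype_vcf(_subset(G, sites), out / "annot.unique_sites.vcf") \
        if sites.size else open(out / "annot.unique_sites.vcf", "w").close()
    if not sites.size:
        for name in ("annot.effects.tsv", "annot.bsift.tsv", "annot.motifs.tsv"):
            rio.write_table(pd.DataFrame(), out / name)
        open(out / "annot.flanks.fasta", "w").close()
        return {"n_unique_sites": 0}

    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    effects = annotate_effects(G, sites, genes, fasta)
    eff_df = pd.DataFrame([vars(e) for e in effects])
    rio.write_table(eff_df, out / "annot.effects.tsv")

    pairs = flank_sequences(G, sites, fasta)
    write_flank_fasta(pairs, out / "annot.flanks.fasta")

    n_bsift = n_motif = 0
    brows, mrows = [], []
    if sift:
        sift_table = rio.read_sift_table(sift)
        coding = {(e.pos) for e in effects
                  if e.effect in ("missense", "synonymous", "stop_gained")}
        for i in sites:
            pos = int(G.positions[i])
            if pos not in coding:
                continue
            rec = bsift_score(G.chrom, pos, str(G.ref_alleles[i]),
                              str(G.alt_alleles[i]), sift_table)
            brows.append(vars(rec))
        n_bsift = len(brows)
    rio.write_table(pd.DataFrame(brows), out / "annot.bsift.tsv")
    if motifs:
        lib = rio.read_motif_database(motifs)
        noncoding = {e.pos for e in effects
                     if e.effect in ("intron", "upstream_gene",
                                     "downstream_gene", "5_prime_UTR",
                                     "3_prime_UTR", "splice_region")}
        for p in pairs:
            if p.pos not in noncoding:
                continue
            ms = motif_uniqueness(p, lib, motif_threshold)
            mrows.append({"chrom": ms.chrom, "pos": ms.pos,
                          "motifs_ref": ",".join(sorted(ms.motifs_ref)),
                          "motifs_alt": ",".join(sorted(ms.motifs_alt)),
                          "unique_to_alt": ",".join(sorted(ms.unique_to_alt))})
        n_motif = len(mrows)
    rio.write_table(pd.DataFrame(mrows), out / "annot.motifs.tsv")
    return {"n_unique_sites": int(sites.size), "n_effect_rows": len(eff_df),
            "n_bsift": n_bsift, "n_motif_sites": n_motif}


def _subset(G, site_indices):
    from .io import GenotypeMatrix

    idx = np.asarray(site_indices, dtype=np.intp)
    return GenotypeMatrix(
        chrom=G.chrom, positions=G.positions[idx],
        ref_alleles=G.ref_alleles[idx], alt_alleles=G.alt_alleles[idx],
        dosage=G.dosage[idx], sample_ids=G.sample_ids,
        is_variant=G.is_variant[idx])
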