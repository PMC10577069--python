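"""Four-population genotype simulator with planted reinforcement windows.

The generator draws allele frequencies hierarchically (Balding-Nichols):
an ancestral frequency per site, species frequencies around it with
drift F_species, and population frequencies around those with F_pop.
Parapatric M. fascicularis receives admixture: each individual has a
mulatta-ancestry fraction q, and each of its two allele copies picks a
parapatric source population with probability q before being drawn from
that population's frequency.  This matches the binomial admixture
likelihood the ancestry estimator maximizes, so parameter recovery can
be tested exactly.

Planted windows carry the three reinforcement signatures: extra drift
(F_boost) in parapatric M. fascicularis only (elevated parapatric
divergence), forced private singletons (negative Tajima's D), and a
fixed low ancestry q_planted (the introgression filter).  Everything is
keyed to one seed; identical seeds give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as rio
from .io import MISSING, GenotypeMatrix, PopulationAssignment, MotifLibrary, Pwm
from .windowing import WindowSet

_POPS = ("ALLO_MUL", "PARA_MUL", "ALLO_FAS", "PARA_FAS")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedWindow:
    """A window interval carrying the planted reinforcement signatures."""

    start: int                       # 0-based half-open on the contig
    end: int
    F_boost: float = 0.5
    q_planted: float = 0.0
    singleton_fraction: float = 0.3


@dataclass(frozen=True)
class SimulationParams:
    """Stated world of the simulator; defaults mirror the study design.

    Sample sizes default to 10 per population (the real groups are
    10/10/11/9).  variant_fraction 0.1 keeps ~90% of sites invariant,
    the desk-scale analogue of a 2.37% genome-wide SNP density.
    F_species=0.3 is the order of macaque interspecies F_ST; F_pop=0.05
    a typical within-species value; q_intro=0.1 sits inside the observed
    0-18% mulatta ancestry of parapatric M. fascicularis.
    """

    n_per_pop: tuple[int, int, int, int] = (10, 10, 10, 10)
    n_sites: int = 50_000
    variant_fraction: float = 0.1
    F_species: float = 0.3
    F_pop: float = 0.05
    q_intro: float = 0.1
    q_concentration: float = 10.0
    sites_per_window: int = 200
    site_spacing: int = 10
    missing_rate: float = 0.0
    n_planted: int = 5
    planted_windows: tuple[PlantedWindow, ...] | None = None
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.F_species, self.F_pop):
            if not (0.0 < f < 1.0):
                raise ValueError("drift coefficients F must be in (0,1)")
        if not (0.0 <= self.q_intro <= 1.0):
            raise ValueError("q_intro must be in [0,1]")
        if self.planted_windows:
            for w in self.planted_windows:
                if not (0.0 <= w.singleton_fraction <= 1.0):
                    raise ValueError("singleton_fraction must be in [0,1]")
                if not (0.0 <= w.q_planted <= 1.0):
                    raise ValueError("q_planted must be in [0,1]")
                if w.end > self.contig_length or w.start < 0:
                    raise ValueError(f"planted window [{w.start},{w.end}) "
                                     "outside contig")
            ivs = sorted((w.start, w.end) for w in self.planted_windows)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError("planted windows must be disjoint")

    @property
    def contig_length(self) -> int:
        return self.n_sites * self.site_spacing + self.site_spacing

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_pop))


def site_positions(params: SimulationParams) -> np.ndarray:
    """1-based site coordinates: one site per ``site_spacing`` bases."""
    i = np.arange(params.n_sites, dtype=np.int64)
    return i * params.site_spacing + params.site_spacing // 2 + 1


def window_grid(params: SimulationParams) -> WindowSet:
    """The simulation's window partition: blocks of sites_per_window sites."""
    spw = params.sites_per_window
    edges_idx = np.arange(0, params.n_sites, spw, dtype=np.int64)
    starts = edges_idx * params.site_spacing
    ends = np.append(starts[1:], params.n_sites * params.site_spacing)
    return WindowSet(params.chrom, starts, ends)


def default_planted(params: SimulationParams) -> tuple[PlantedWindow, ...]:
    """n_planted evenly spaced grid windows (when none are given)."""
    grid = window_grid(params)
    n_w = len(grid)
    if params.n_planted > n_w:
        raise ValueError("more planted windows requested than grid windows")
    picks = np.linspace(0, n_w - 1, params.n_planted * 2 + 1,
                        dtype=np.int64)[1::2]
    return tuple(PlantedWindow(int(grid.starts[i]), int(grid.ends[i]))
                 for i in picks)


def resolve_planted(params: SimulationParams) -> tuple[PlantedWindow, ...]:
    if params.planted_windows is not None:
        return params.planted_windows
    if params.n_planted == 0:
        return ()
    return default_planted(params)


def sample_ids(params: SimulationParams) -> list[str]:
    prefixes = {"ALLO_MUL": "am", "PARA_MUL": "pm",
                "ALLO_FAS": "af", "PARA_FAS": "pf"}
    out = []
    for pop, n in zip(_POPS, params.n_per_pop):
        out += [f"{prefixes[pop]}_{i:02d}" for i in range(n)]
    return out


def population_assignment(params: SimulationParams) -> PopulationAssignment:
    mapping = dict(zip(sample_ids(params),
                       [p for p, n in zip(_POPS, params.n_per_pop)
                        for _ in range(n)]))
    return PopulationAssignment(mapping)


@dataclass
class WindowFrequencies:
    """Drawn frequencies for one window's sites (alt-allele scale)."""

    is_variant: np.ndarray          # drawn ancestral polymorphism flag
    singleton: np.ndarray           # planted private-singleton sites
    p_anc: np.ndarray
    p_mul_sp: np.ndarray
    p_fas_sp: np.ndarray
    p_am: np.ndarray
    p_pm: np.ndarray
    p_af: np.ndarray
    p_pf: np.ndarray


def _bn_draw(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols: Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    pc = np.clip(p, 1e-4, 1.0 - 1e-4)
    a = pc * (1.0 - F) / F
    b = (1.0 - pc) * (1.0 - F) / F
    draw = rng.beta(a, b)
    # degenerate inputs (p exactly 0/1) stay fixed
    return np.where((p <= 0.0) | (p >= 1.0), p, draw)


def draw_window_frequencies(params: SimulationParams,
                            planted: PlantedWindow | None,
                            n_sites: int,
                            rng: np.random.Generator) -> WindowFrequencies:
    """Hierarchical frequency draw for one window of ``n_sites`` sites."""
    is_variant = rng.uniform(size=n_sites) < params.variant_fraction
    p_anc = np.where(is_variant, rng.uniform(0.05, 0.95, size=n_sites), 0.0)

    singleton = np.zeros(n_sites, dtype=bool)
    if planted is not None and planted.singleton_fraction > 0:
        var_idx = np.nonzero(is_variant)[0]
        k = int(round(planted.singleton_fraction * var_idx.size))
        if k:
            chosen = rng.choice(var_idx, size=k, replace=False)
            singleton[chosen] = True
            p_anc[chosen] = 0.0      # all populations fixed ancestral

    p_mul_sp = _bn_draw(p_anc, params.F_species, rng)
    p_fas_sp = _bn_draw(p_anc, params.F_species, rng)
    F_pf = params.F_pop + (planted.F_boost if planted is not None else 0.0)
    F_pf = min(F_pf, 1.0 - 1e-6)
    p_am = _bn_draw(p_mul_sp, params.F_pop, rng)
    p_pm = _bn_draw(p_mul_sp, params.F_pop, rng)
    p_af = _bn_draw(p_fas_sp, params.F_pop, rng)
    p_pf = _bn_draw(p_fas_sp, F_pf, rng)
    for arr in (p_mul_sp, p_fas_sp, p_am, p_pm, p_af, p_pf):
        arr[singleton] = 0.0
        arr[~is_variant] = 0.0
    return WindowFrequencies(is_variant=is_variant, singleton=singleton,
                             p_anc=p_anc, p_mul_sp=p_mul_sp, p_fas_sp=p_fas_sp,
                             p_am=p_am, p_pm=p_pm, p_af=p_af, p_pf=p_pf)


def draw_individual_q(params: SimulationParams, planted: PlantedWindow | None,
                      n_ind: int, rng: np.random.Generator) -> np.ndarray:
    """Per-individual mulatta-ancestry fractions for one window."""
    if planted is not None:
        return np.full(n_ind, planted.q_planted)
    q0 = params.q_intro
    if q0 <= 0.0:
        return np.zeros(n_ind)
    if q0 >= 1.0:
        return np.ones(n_ind)
    c = params.q_concentration
    return rng.beta(q0 * c, (1.0 - q0) * c, size=n_ind)


def sample_genotypes(freqs: WindowFrequencies, params: SimulationParams,
                     planted: PlantedWindow | None,
                     rng: np.random.Generator):
    """Genotype block (sites x samples) for one window.

    Returns (dosage, q_true) with q_true the drawn ancestry fraction of
    each parapatric M. fascicularis individual.
    """
    n_sites = freqs.is_variant.size
    n_am, n_pm, n_af, n_pf = params.n_per_pop
    blocks = []
    for p_pop, n_ind in ((freqs.p_am, n_am), (freqs.p_pm, n_pm),
                         (freqs.p_af, n_af)):
        blocks.append(rng.binomial(2, p_pop[:, None],
                                   size=(n_sites, n_ind)).astype(np.int8))
    q_true = draw_individual_q(params, planted, n_pf, rng)
    # each of the two allele copies picks its source population
    anc1 = rng.uniform(size=(n_sites, n_pf)) < q_true[None, :]
    anc2 = rng.uniform(size=(n_sites, n_pf)) < q_true[None, :]
    copy1 = rng.uniform(size=(n_sites, n_pf)) < np.where(
        anc1, freqs.p_pm[:, None], freqs.p_pf[:, None])
    copy2 = rng.uniform(size=(n_sites, n_pf)) < np.where(
        anc2, freqs.p_pm[:, None], freqs.p_pf[:, None])
    pf_block = (copy1.astype(np.int8) + copy2.astype(np.int8))
    blocks.append(pf_block)
    dosage = np.concatenate(blocks, axis=1)

    # planted singletons: exactly one derived copy, private to para_fas
    sing = np.nonzero(freqs.singleton)[0]
    if sing.size:
        pf_off = n_am + n_pm + n_af
        carriers = rng.integers(0, n_pf, size=sing.size)
        dosage[sing, pf_off + carriers] = 1

    if params.missing_rate > 0:
        miss = rng.uniform(size=dosage.shape) < params.missing_rate
        dosage[miss] = MISSING
    return dosage, q_true


@dataclass
class SimulatedDataset:
    params: SimulationParams
    G: GenotypeMatrix
    popmap: PopulationAssignment
    windows: WindowSet
    truth_windows: pd.DataFrame
    truth_ancestry: pd.DataFrame
    reference: str
    genes_gtf: list[str]
    sift_records: list[tuple]
    motifs: MotifLibrary


def generate_matrix(params: SimulationParams):
    """Simulate the full contig window by window."""
    rng = np.random.default_rng(params.seed)
    seq = "".join(_BASES[rng.integers(0, 4, size=params.contig_length)])
    positions = site_positions(params)
    grid = window_grid(params)
    spans = grid.site_spans(positions)
    planted_map = _planted_by_window(params, grid)

    dosage_blocks, variant_flags = [], []
    wrows, arows = [], []
    pf_ids = [s for s in sample_ids(params) if s.startswith("pf_")]
    for w, (i0, i1) in enumerate(spans):
        planted = planted_map.get(w)
        freqs = draw_window_frequencies(params, planted, int(i1 - i0), rng)
        block, q_true = sample_genotypes(freqs, params, planted, rng)
        dosage_blocks.append(block)
        variant_flags.append(freqs.is_variant)
        wrows.append({
            "window_id": w, "chrom": params.chrom,
            "start": int(grid.starts[w]), "end": int(grid.ends[w]),
            "planted": planted is not None,
            "F_boost": planted.F_boost if planted else 0.0,
            "q_true": planted.q_planted if planted else params.q_intro,
            "singleton_fraction":
                planted.singleton_fraction if planted else 0.0,
        })
        for s, q in zip(pf_ids, q_true):
            arows.append({"window_id": w, "sample_id": s, "q_true": float(q)})

    dosage = np.concatenate(dosage_blocks, axis=0)
    drawn_variant = np.concatenate(variant_flags)
    observed_alt = (dosage > 0).any(axis=1)
    is_variant = drawn_variant & observed_alt

    ref = np.array([seq[p - 1] for p in positions], dtype=object)
    alt = np.array(["" for _ in positions], dtype=object)
    for i in np.nonzero(is_variant)[0]:
        others = [b for b in "ACGT" if b != ref[i]]
        alt[i] = others[rng.integers(0, 3)]
    dosage[~is_variant] = np.where(dosage[~is_variant] == MISSING, MISSING, 0)

    G = GenotypeMatrix(chrom=params.chrom, positions=positions,
                       ref_alleles=ref, alt_alleles=alt, dosage=dosage,
                       sample_ids=sample_ids(params), is_variant=is_variant)
    truth_w = pd.DataFrame(wrows)
    truth_a = pd.DataFrame(arows)
    return G, seq, grid, truth_w, truth_a, rng


def _planted_by_window(params: SimulationParams, grid: WindowSet):
    planted = resolve_planted(params)
    out: dict[int, PlantedWindow] = {}
    for pw in planted:
        hit = np.nonzero((grid.starts < pw.end) & (grid.ends > pw.start))[0]
        for w in hit:
            out[int(w)] = pw
    return out


def _make_genes(params: SimulationParams, grid: WindowSet,
                planted_map: dict) -> list[str]:
    """GTF lines: one gene inside every planted window, genes tiling
    every third null window.  1-based closed coordinates on disk."""
    lines = []
    for w in range(len(grid)):
        if w not in planted_map and w % 3 != 0:
            continue
        ws, we = int(grid.starts[w]), int(grid.ends[w])
        margin = max((we - ws) // 10, 1)
        gs, ge = ws + margin, we - margin
        utr = min(60, (ge - gs) // 4)
        cs = gs + utr
        ce = ge - utr
        ce = cs + ((ce - cs) // 3) * 3
        strand = "+" if w % 2 == 0 else "-"
        gid, tid = f"gene_{w:04d}", f"tx_{w:04d}"
        attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
        c = params.chrom
        lines.append(f'{c}\tsim\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\t'
                     f'gene_id "{gid}";')
        lines.append(f"{c}\tsim\ttranscript\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}")
        lines.append(f"{c}\tsim\texon\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}")
        lines.append(f"{c}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{strand}\t0\t{attrs}")
    return lines


def _make_sift(params: SimulationParams, G: GenotypeMatrix,
               gtf_lines: list[str], rng: np.random.Generator) -> list[tuple]:
    """SIFT rows for ref and alt alleles of every coding variant."""
    cds = []
    for ln in gtf_lines:
        f = ln.split("\t")
        if f[2] == "CDS":
            cds.append((int(f[3]) - 1, int(f[4])))
    rows = []
    for i in np.nonzero(G.is_variant)[0]:
        p = int(G.positions[i])
        if not any(s <= p - 1 < e for s, e in cds):
            continue
        ref_score = float(rng.uniform())
        alt_score = float(rng.uniform())
        low = bool(rng.uniform() < 0.05)
        rows.append((G.chrom, p, str(G.ref_alleles[i]), ref_score, low))
        rows.append((G.chrom, p, str(G.alt_alleles[i]), alt_score, low))
    return rows


def _make_motifs(rng: np.random.Generator) -> MotifLibrary:
    motifs = []
    for k, width in enumerate((8, 10, 13)):
        mat = rng.dirichlet([0.5] * 4, size=width).T
        motifs.append(Pwm(motif_id=f"sim_motif_{k}", matrix=mat))
    return MotifLibrary(motifs)


def generate_dataset(params: SimulationParams,
                     out_dir=None) -> SimulatedDataset:
    """Simulate the full bundle; optionally write every file to out_dir.

    Files written: sim.vcf, popmap.tsv, ref.fasta, genes.gtf, sift.tsv,
    motifs.meme, truth_windows.tsv, truth_ancestry.tsv, grid.bed.
    Identical seed => byte-identical files.
    """
    G, seq, grid, truth_w, truth_a, rng = generate_matrix(params)
    planted_map = _planted_by_window(params, grid)
    gtf_lines = _make_genes(params, grid, planted_map)
    sift_rows = _make_sift(params, G, gtf_lines, rng)
    motifs = _make_motifs(rng)
    popmap = population_assignment(params)
    ds = SimulatedDataset(params=params, G=G, popmap=popmap, windows=grid,
                          truth_windows=truth_w, truth_ancestry=truth_a,
                          reference=seq, genes_gtf=gtf_lines,
                          sift_records=sift_rows, motifs=motifs)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, str]:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: str(out / v) for k, v in {
        "vcf": "sim.vcf", "popmap": "popmap.tsv", "fasta": "ref.fasta",
        "gtf": "genes.gtf", "sift": "sift.tsv", "motifs": "motifs.meme",
        "truth_windows": "truth_windows.tsv",
        "truth_ancestry": "truth_ancestry.tsv", "grid": "grid.bed",
    }.items()}
    rio.write_genotype_vcf(ds.G, paths["vcf"],
                           contig_length=ds.params.contig_length)
    rio.write_population_map(ds.popmap, paths["popmap"])
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{ds.params.chrom}\n")
        for i in range(0, len(ds.reference), 80):
            fh.write(ds.reference[i:i + 80] + "\n")
    with open(paths["gtf"], "w") as fh:
        fh.write("\n".join(ds.genes_gtf) + "\n")
    rio.write_sift_table(ds.sift_records, paths["sift"])
    rio.write_motif_database(ds.motifs, paths["motifs"])
    rio.write_table(ds.truth_windows, paths["truth_windows"])
    rio.write_table(ds.truth_ancestry, paths["truth_ancestry"])
    rio.write_bed(zip([ds.params.chrom] * len(ds.windows),
                      ds.windows.starts, ds.windows.ends), paths["grid"])
    return paths
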