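"""Characterization of candidate-gene variants unique to parapatric
M. fascicularis: effect classes, 13-bp flank pairs, B-SIFT scores, and
transcription-factor motifs unique to the alternate allele.

B-SIFT is the SIFT tolerance score of the alternate allele minus that of
the reference allele (range -1..1): positive scores mark putatively
adaptive substitutions, zero neutral, negative deleterious.  The motif
step substitutes a transparent PWM log-odds scan (uniform background,
per-motif relative threshold, both strands) for a motif-to-motif
database comparison; the reported quantity — motifs matching the
alternate flank but not the reference flank — is the same.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np

from Bio.Seq import Seq

from .io import (MISSING, GenotypeMatrix, PopulationAssignment,
                 GeneAnnotationSet, Gene, Transcript, SiftTable, MotifLibrary,
                 Pwm)

logger = logging.getLogger(__name__)

#: effect classes, most severe first; classification reports the most
#: severe class per (site, transcript)
EFFECT_ORDER = (
    "stop_gained", "missense", "synonymous",
    "splice_donor", "splice_acceptor", "splice_region",
    "5_prime_UTR", "3_prime_UTR", "intron",
    "upstream_gene", "downstream_gene", "intergenic",
)

UPSTREAM_RADIUS = 5_000
SPLICE_CORE = 2          # first/last intronic bases -> donor/acceptor
SPLICE_REGION = 8        # intronic bases 3..8 from a junction
FLANK = 6                # bases each side of the variant; 13-mer total
MOTIF_THRESHOLD = 0.85


# ---------------------------------------------------------------------------
# parapatric-unique sites

def unique_parapatric_sites(G: GenotypeMatrix, popmap: PopulationAssignment,
                            regions=None) -> np.ndarray:
    """Indices of sites whose alt allele has >=1 called copy in parapatric
    M. fascicularis and none anywhere else.

    ``regions``: optional iterable of (start, end) 0-based half-open
    intervals (e.g. candidate gene spans) to restrict the search.
    """
    pf = popmap.indices(G, "PARA_FAS")
    others = np.setdiff1d(np.arange(G.n_samples), pf)
    d_pf = G.dosage[:, pf]
    d_ot = G.dosage[:, others]
    pf_has = (np.where(d_pf != MISSING, d_pf, 0) > 0).any(axis=1)
    ot_has = (np.where(d_ot != MISSING, d_ot, 0) > 0).any(axis=1)
    keep = G.is_variant & pf_has & ~ot_has
    if regions is not None:
        pos0 = G.positions - 1
        in_region = np.zeros(G.n_sites, dtype=bool)
        for s, e in regions:
            in_region |= (pos0 >= s) & (pos0 < e)
        keep &= in_region
    return np.nonzero(keep)[0]


# ---------------------------------------------------------------------------
# effect classification

@dataclass
class EffectAnnotation:
    chrom: str
    pos: int                 # 1-based
    allele: str
    transcript_id: str
    effect: str


def classify_effect(pos: int, ref_allele: str, alt_allele: str,
                    genes: GeneAnnotationSet, chrom: str,
                    ref_fasta) -> list[EffectAnnotation]:
    """Most-severe effect class of an allele per overlapping transcript.

    ``pos`` is 1-based; ``ref_fasta`` is a pyfaidx.Fasta (or any mapping
    of contig -> indexable sequence).  Transcripts within 5 kb are
    annotated as upstream/downstream by strand; sites hitting nothing
    yield a single intergenic record.
    """
    p0 = pos - 1
    out: list[EffectAnnotation] = []
    for gene in genes.by_chrom(chrom):
        for tx in gene.transcripts:
            effect = _classify_for_transcript(p0, ref_allele, alt_allele,
                                              gene, tx, chrom, ref_fasta)
            if effect is not None:
                out.append(EffectAnnotation(chrom=chrom, pos=pos,
                                            allele=alt_allele,
                                            transcript_id=tx.transcript_id,
                                            effect=effect))
    if not out:
        out.append(EffectAnnotation(chrom=chrom, pos=pos, allele=alt_allele,
                                    transcript_id="", effect="intergenic"))
    return out


def _classify_for_transcript(p0, ref_allele, alt_allele, gene: Gene,
                             tx: Transcript, chrom, ref_fasta) -> str | None:
    strand = gene.strand
    if p0 < tx.start or p0 >= tx.end:
        dist_left = tx.start - p0          # >0 when site is left of tx
        dist_right = p0 - (tx.end - 1)
        if 0 < dist_left <= UPSTREAM_RADIUS:
            return "upstream_gene" if strand == "+" else "downstream_gene"
        if 0 < dist_right <= UPSTREAM_RADIUS:
            return "downstream_gene" if strand == "+" else "upstream_gene"
        return None

    in_exon = any(s <= p0 < e for s, e in tx.exons)
    if in_exon:
        if not tx.is_coding:
            return "intron"                # non-coding transcript: no finer class
        in_cds = any(s <= p0 < e for s, e in tx.cds)
        if in_cds:
            return _coding_effect(p0, ref_allele, alt_allele, tx, strand,
                                  chrom, ref_fasta)
        cds_start = min(s for s, _ in tx.cds)
        cds_end = max(e for _, e in tx.cds)
        if p0 < cds_start:
            return "5_prime_UTR" if strand == "+" else "3_prime_UTR"
        if p0 >= cds_end:
            return "3_prime_UTR" if strand == "+" else "5_prime_UTR"
        return "intron"                    # between CDS chunks but exonic gap
    # intronic: distance to the nearest exon junction
    dists = []
    for s, e in tx.exons:
        if p0 < s:
            dists.append((s - p0, "left_of_exon"))
        elif p0 >= e:
            dists.append((p0 - e + 1, "right_of_exon"))
    if not dists:
        return "intron"
    dist, side = min(dists)
    if dist <= SPLICE_CORE:
        # donor = 5' end of the intron, acceptor = 3' end (strand-aware)
        if strand == "+":
            return "splice_donor" if side == "right_of_exon" else "splice_acceptor"
        return "splice_donor" if side == "left_of_exon" else "splice_acceptor"
    if dist <= SPLICE_REGION:
        return "splice_region"
    return "intron"


def _coding_effect(p0, ref_allele, alt_allele, tx: Transcript, strand,
                   chrom, ref_fasta) -> str | None:
    cds = sorted(tx.cds)
    total = sum(e - s for s, e in cds)
    if total % 3 != 0:
        logger.warning("transcript %s: CDS length %d not divisible by 3; "
                       "skipped", tx.transcript_id, total)
        return None
    # position within the spliced CDS, 5'->3' in transcript orientation
    offset = 0
    cds_pos = None
    for s, e in cds:
        if s <= p0 < e:
            cds_pos = offset + (p0 - s)
            break
        offset += e - s
    if strand == "-":
        cds_pos = total - 1 - cds_pos
    codon_idx = cds_pos // 3
    within = cds_pos % 3
    # collect the codon's genomic positions in transcript orientation
    genomic = np.concatenate([np.arange(s, e) for s, e in cds])
    if strand == "-":
        genomic = genomic[::-1]
    codon_pos = genomic[codon_idx * 3: codon_idx * 3 + 3]
    seq = ref_fasta[chrom]
    bases = [str(seq[int(g)]).upper() for g in codon_pos]
    if strand == "-":
        bases = [_COMP[b] for b in bases]
    ref_b, alt_b = ref_allele, alt_allele
    if strand == "-":
        ref_b, alt_b = _COMP[ref_allele], _COMP[alt_allele]
    if bases[within] != ref_b:
        raise ValueError(
            f"reference mismatch at {chrom}:{p0 + 1}: FASTA codon base "
            f"{bases[within]} != VCF REF {ref_b}"
        )
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:within] + alt_b + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gained"
    return "missense"


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def annotate_effects(G: GenotypeMatrix, site_indices, genes: GeneAnnotationSet,
                     ref_fasta) -> list[EffectAnnotation]:
    out = []
    for i in site_indices:
        out.extend(classify_effect(int(G.positions[i]),
                                   str(G.ref_alleles[i]),
                                   str(G.alt_alleles[i]),
                                   genes, G.chrom, ref_fasta))
    return out


# ---------------------------------------------------------------------------
# flank pairs

@dataclass
class FlankPair:
    chrom: str
    pos: int                  # 1-based
    allele: str
    ref_seq: str              # 13-mer, variant at 0-based index 6
    alt_seq: str


def flank_sequences(G: GenotypeMatrix, site_indices, ref_fasta,
                    contig_length: int | None = None) -> list[FlankPair]:
    """13-bp reference/alternate-consensus flank pairs for selected sites.

    The alternate sequence is taken from a consensus in which every
    selected site's reference base is replaced by its alt allele, so a
    flank overlapping two nearby selected variants carries both.  Sites
    closer than 6 bases to a contig end are skipped with a warning.
    """
    seq = str(ref_fasta[G.chrom][:]).upper()
    L = contig_length if contig_length is not None else len(seq)
    consensus = list(seq)
    for i in site_indices:
        p0 = int(G.positions[i]) - 1
        if seq[p0] != G.ref_alleles[i]:
            raise ValueError(
                f"reference base mismatch at {G.chrom}:{G.positions[i]}: "
                f"FASTA {seq[p0]} != VCF REF {G.ref_alleles[i]}"
            )
        consensus[p0] = str(G.alt_alleles[i])
    consensus = "".join(consensus)
    out: list[FlankPair] = []
    for i in site_indices:
        p0 = int(G.positions[i]) - 1
        if p0 - FLANK < 0 or p0 + FLANK + 1 > L:
            logger.warning("site %s:%d within %d b of contig end; skipped",
                           G.chrom, G.positions[i], FLANK)
            continue
        out.append(FlankPair(
            chrom=G.chrom, pos=int(G.positions[i]),
            allele=str(G.alt_alleles[i]),
            ref_seq=seq[p0 - FLANK: p0 + FLANK + 1],
            alt_seq=consensus[p0 - FLANK: p0 + FLANK + 1],
        ))
    return out


def write_flank_fasta(pairs: list[FlankPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.chrom}:{p.pos}:{p.allele}:ref\n{p.ref_seq}\n")
            fh.write(f">{p.chrom}:{p.pos}:{p.allele}:alt\n{p.alt_seq}\n")


# ---------------------------------------------------------------------------
# B-SIFT

@dataclass
class BsiftRecord:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    sift_ref: float           # NaN when no score
    sift_alt: float
    bsift: float
    low_confidence: bool
    effect_class: str         # adaptive / neutral / deleterious / no_score


def bsift_score(chrom: str, pos: int, ref_allele: str, alt_allele: str,
                sift: SiftTable) -> BsiftRecord:
    """B-SIFT = SIFT(alt) - SIFT(ref); class by sign.

    Low-confidence entries keep their score but are excluded from
    classification; missing scores yield a 'no_score' record.
    """
    r = sift.lookup(chrom, pos, ref_allele)
    a = sift.lookup(chrom, pos, alt_allele)
    if r is None or a is None:
        return BsiftRecord(chrom, pos, ref_allele, alt_allele,
                           np.nan if r is None else r[0],
                           np.nan if a is None else a[0],
                           np.nan, False, "no_score")
    low = r[1] or a[1]
    b = a[0] - r[0]
    if low:
        cls = "low_confidence"
    elif b > 0:
        cls = "adaptive"
    elif b < 0:
        cls = "deleterious"
    else:
        cls = "neutral"
    return BsiftRecord(chrom, pos, ref_allele, alt_allele, r[0], a[0], b,
                       low, cls)


# ---------------------------------------------------------------------------
# motif scan

@dataclass
class MotifMatchSet:
    chrom: str
    pos: int
    motifs_ref: frozenset
    motifs_alt: frozenset

    @property
    def unique_to_alt(self) -> frozenset:
        return self.motifs_alt - self.motifs_ref


def pwm_log_odds(pwm: Pwm) -> np.ndarray:
    """log2(p/0.25) with probabilities floored at 1e-6."""
    mat = np.clip(pwm.matrix, 1e-6, None)
    return np.log2(mat / 0.25)


def best_pwm_score(seq: str, pwm: Pwm) -> float:
    """Best log-odds score of the PWM over all offsets and both strands."""
    lo = pwm_log_odds(pwm)
    w = pwm.width
    if w > len(seq):
        raise ValueError("motif wider than sequence")
    idx = np.array([_BASE_IDX[b] for b in seq], dtype=np.intp)
    best = -np.inf
    cols = np.arange(w)
    for mat in (lo, lo[::-1, ::-1]):      # reverse complement = flip both axes
        for off in range(len(seq) - w + 1):
            window = idx[off:off + w]
            if (window < 0).any():
                continue                  # N in window: no match there
            best = max(best, float(mat[window, cols].sum()))
    return best


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


def motif_matches(seq: str, lib: MotifLibrary,
                  threshold_frac: float = MOTIF_THRESHOLD) -> frozenset:
    """Motif ids whose best score reaches threshold_frac of their maximum."""
    if not (0.0 < threshold_frac <= 1.0):
        raise ValueError("threshold_frac must be in (0, 1]")
    hits = set()
    for pwm in lib:
        if pwm.width > len(seq):
            logger.warning("motif %s wider than %d-mer; skipped",
                           pwm.motif_id, len(seq))
            continue
        max_score = float(pwm_log_odds(pwm).max(axis=0).sum())
        if best_pwm_score(seq, pwm) >= threshold_frac * max_score:
            hits.add(pwm.motif_id)
    return frozenset(hits)


def motif_uniqueness(pair: FlankPair, lib: MotifLibrary,
                     threshold_frac: float = MOTIF_THRESHOLD) -> MotifMatchSet:
    """Motifs matching each flank; ``unique_to_alt`` is the deliverable."""
    return MotifMatchSet(
        chrom=pair.chrom, pos=pair.pos,
        motifs_ref=motif_matches(pair.ref_seq, lib, threshold_frac),
        motifs_alt=motif_matches(pair.alt_seq, lib, threshold_frac),
    )
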