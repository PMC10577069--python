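"""Readers and writers for the external formats the scan touches.

Coordinate contract: VCF and GTF are 1-based on disk; everything in memory
is 0-based half-open except ``GenotypeMatrix.positions``, which keeps the
1-based VCF coordinate of each site (a site at POS p occupies the 0-based
interval [p-1, p)).  Conversions happen only in this module.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call in a dosage matrix
MISSING = -1

#: the four populations of the scan design
POPULATION_LABELS = ("ALLO_MUL", "PARA_MUL", "ALLO_FAS", "PARA_FAS")

_NUCS = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Sites x samples alt-allele dosage matrix for one contig.

    Invariant sites (``is_variant`` False) carry an empty alt allele and a
    dosage column of zeros/missing; they are retained because the absolute
    divergence D_XY needs every comparable site in its denominator.
    """

    chrom: str
    positions: np.ndarray          # int64, 1-based, strictly increasing
    ref_alleles: np.ndarray        # unicode, one base per site
    alt_alleles: np.ndarray        # unicode, "" at invariant sites
    dosage: np.ndarray             # int8 (n_sites, n_samples), MISSING = -1
    sample_ids: list[str]
    is_variant: np.ndarray         # bool per site
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.is_variant = np.asarray(self.is_variant, dtype=bool)
        self.ref_alleles = np.asarray(self.ref_alleles, dtype=object)
        self.alt_alleles = np.asarray(self.alt_alleles, dtype=object)
        if self.positions.ndim != 1:
            raise ValueError("positions must be 1-D")
        n = self.positions.size
        if self.dosage.shape != (n, len(self.sample_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{n} sites x {len(self.sample_ids)} samples"
            )
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing within a contig")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        bad = (self.dosage < MISSING) | (self.dosage > 2)
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or MISSING")

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=np.intp)


@dataclass
class PopulationAssignment:
    """Map from sample id to one of the four population labels."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - set(POPULATION_LABELS)
        if bad:
            raise ValueError(f"unknown population label(s): {sorted(bad)}")

    def samples(self, label: str) -> list[str]:
        if label not in POPULATION_LABELS:
            raise ValueError(f"unknown population label: {label!r}")
        return [s for s, l in self.mapping.items() if l == label]

    def indices(self, G: GenotypeMatrix, label: str) -> np.ndarray:
        return G.sample_indices(self.samples(label))

    def group_sizes(self) -> dict[str, int]:
        return {l: len(self.samples(l)) for l in POPULATION_LABELS}

    def labels_for(self, sample_ids) -> np.ndarray:
        return np.array([self.mapping[s] for s in sample_ids], dtype=object)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class Transcript:
    transcript_id: str
    start: int                      # 0-based half-open, within gene span
    end: int
    exons: list[tuple[int, int]]    # sorted 0-based half-open
    cds: list[tuple[int, int]]      # empty => non-coding

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript]


@dataclass
class GeneAnnotationSet:
    genes: list[Gene]

    def by_chrom(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


class SiftTable:
    """Lookup of (chrom, 1-based pos, allele) -> (score, low_confidence)."""

    def __init__(self, records: dict[tuple[str, int, str], tuple[float, bool]]):
        for key, (score, _) in records.items():
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"SIFT score out of [0,1] for {key}: {score}")
        self._records = dict(records)

    def lookup(self, chrom: str, pos: int, allele: str):
        """Return (score, low_confidence) or None when no score exists."""
        return self._records.get((chrom, int(pos), allele))

    def __len__(self) -> int:
        return len(self._records)


@dataclass
class Pwm:
    """Position weight matrix, rows A/C/G/T, columns sum to 1."""

    motif_id: str
    matrix: np.ndarray              # shape (4, width)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MotifLibrary:
    motifs: list[Pwm]

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)


# ---------------------------------------------------------------------------
# VCF

def read_genotype_vcf(path, region=None, popmap: PopulationAssignment | None = None
                      ) -> GenotypeMatrix:
    """Load biallelic SNPs plus invariant reference records from one contig.

    Multiallelic records and indels are skipped (counted in ``skipped``);
    half-calls and missing genotypes become :data:`MISSING`.  With ``region``
    (``"chrom"`` or ``"chrom:start-end"``, 1-based inclusive) only matching
    records are loaded; without it the VCF must contain a single contig.
    """
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    if popmap is not None:
        absent = [s for s in popmap.mapping if s not in header_samples]
        if absent:
            raise ValueError(f"popmap samples absent from VCF header: {absent}")

    want_chrom, want_lo, want_hi = _parse_region(region)

    positions, refs, alts, rows, variant_flags = [], [], [], [], []
    skipped = {"multiallelic": 0, "indel": 0, "other": 0}
    chrom_seen: str | None = None
    last_pos = -1
    for v in vcf:
        if want_chrom is not None:
            if v.CHROM != want_chrom:
                continue
            if want_lo is not None and not (want_lo <= v.POS <= want_hi):
                continue
        if chrom_seen is None:
            chrom_seen = v.CHROM
        elif v.CHROM != chrom_seen:
            raise ValueError(
                f"VCF spans multiple contigs ({chrom_seen!r}, {v.CHROM!r}); "
                "pass region= to select one"
            )
        alt_list = [a for a in v.ALT if a not in (".", "")]
        if len(alt_list) > 1:
            skipped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or any(len(a) != 1 for a in alt_list):
            skipped["indel"] += 1
            continue
        if v.REF not in _NUCS or any(a not in _NUCS for a in alt_list):
            skipped["other"] += 1
            continue
        if v.POS <= last_pos:
            raise ValueError(
                f"VCF not coordinate-sorted (or duplicated position) at "
                f"{v.CHROM}:{v.POS}"
            )
        last_pos = v.POS
        dos = np.empty(len(header_samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            dos[i] = MISSING if (a < 0 or b < 0) else a + b
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(alt_list[0] if alt_list else "")
        variant_flags.append(bool(alt_list))
        rows.append(dos)

    if chrom_seen is None:
        raise ValueError(f"no usable records in {path}" +
                         (f" for region {region}" if region else ""))
    dosage = np.vstack(rows) if rows else np.empty((0, len(header_samples)), np.int8)
    G = GenotypeMatrix(
        chrom=chrom_seen,
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=np.array(refs, dtype=object),
        alt_alleles=np.array(alts, dtype=object),
        dosage=dosage,
        sample_ids=header_samples,
        is_variant=np.array(variant_flags, dtype=bool),
        skipped=skipped,
    )
    if popmap is not None:
        order = G.sample_indices(list(popmap.mapping))
        G = GenotypeMatrix(
            chrom=G.chrom, positions=G.positions, ref_alleles=G.ref_alleles,
            alt_alleles=G.alt_alleles, dosage=G.dosage[:, order],
            sample_ids=list(popmap.mapping), is_variant=G.is_variant,
            skipped=skipped,
        )
    n_skip = sum(skipped.values())
    if n_skip:
        logger.info("read_genotype_vcf: skipped %d records (%s)", n_skip, skipped)
    return G


def _parse_region(region):
    if region is None:
        return None, None, None
    m = re.fullmatch(r"([^:]+)(?::(\d+)-(\d+))?", str(region))
    if not m:
        raise ValueError(f"bad region string: {region!r}")
    chrom, lo, hi = m.group(1), m.group(2), m.group(3)
    return chrom, (int(lo) if lo else None), (int(hi) if hi else None)


def write_genotype_vcf(G: GenotypeMatrix, path, contig_length: int | None = None
                       ) -> None:
    """Write a plain-text VCF 4.2 (invariant sites with ALT '.').

    Deterministic: identical matrices produce byte-identical files.
    """
    length = contig_length if contig_length is not None else int(G.positions[-1]) + 100
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={G.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for i in range(G.n_sites):
            alt = G.alt_alleles[i] if G.is_variant[i] else "."
            gts = "\t".join(gt_codes[int(d)] for d in G.dosage[i])
            fh.write(f"{G.chrom}\t{G.positions[i]}\t.\t{G.ref_alleles[i]}\t{alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# population map

def read_population_map(path) -> PopulationAssignment:
    """Two-column TSV: sample_id <tab> population label."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            sample, label = parts
            if label not in POPULATION_LABELS:
                raise ValueError(
                    f"{path}:{ln}: unknown population label {label!r} "
                    f"(expected one of {POPULATION_LABELS})"
                )
            if sample in mapping:
                raise ValueError(f"{path}:{ln}: duplicate sample id {sample!r}")
            mapping[sample] = label
    return PopulationAssignment(mapping)


def write_population_map(popmap: PopulationAssignment, path) -> None:
    with open(path, "w") as fh:
        for sample, label in popmap.mapping.items():
            fh.write(f"{sample}\t{label}\n")


# ---------------------------------------------------------------------------
# GTF

_GTF_FEATURES = {"gene", "transcript", "exon", "CDS"}


def read_gene_annotation(path) -> GeneAnnotationSet:
    """Parse an Ensembl-dialect GTF into genes with transcript structure.

    On-disk coordinates are 1-based closed; in memory they become 0-based
    half-open.  Genes are grouped from exon/CDS lines by gene_id via
    gffutils; a pre-scan reports malformed attribute columns with their
    line number (gffutils does not).
    """
    import gffutils

    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 tab-separated fields")
            if parts[2] in _GTF_FEATURES and "gene_id" not in parts[8]:
                raise ValueError(f"{path}:{ln}: attribute column lacks gene_id")

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: list[Gene] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts: list[Transcript] = []
        for t in db.children(g, featuretype="transcript", order_by="start"):
            exons = sorted((e.start - 1, e.end)
                           for e in db.children(t, featuretype="exon"))
            cds = sorted((c.start - 1, c.end)
                         for c in db.children(t, featuretype="CDS"))
            for s, e in exons + cds:
                if s >= e:
                    raise ValueError(
                        f"invalid interval in transcript {t.id}: [{s}, {e})")
            transcripts.append(Transcript(
                transcript_id=t.id, start=t.start - 1, end=t.end,
                exons=exons, cds=cds,
            ))
        genes.append(Gene(
            gene_id=g.id, chrom=g.seqid, start=g.start - 1, end=g.end,
            strand=g.strand, transcripts=transcripts,
        ))
    return GeneAnnotationSet(genes)


# ---------------------------------------------------------------------------
# SIFT table

def read_sift_table(path) -> SiftTable:
    """TSV with header: chrom, pos, allele, score, low_confidence (0/1)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str})
    required = {"chrom", "pos", "allele", "score", "low_confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SIFT table missing column(s): {sorted(missing)}")
    bad = df[(df["score"] < 0) | (df["score"] > 1)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"SIFT score out of [0,1] at {row['chrom']}:{row['pos']} "
            f"{row['allele']}: {row['score']}"
        )
    records = {
        (r.chrom, int(r.pos), r.allele): (float(r.score), bool(r.low_confidence))
        for r in df.itertuples()
    }
    return SiftTable(records)


def write_sift_table(records, path) -> None:
    """records: iterable of (chrom, pos, allele, score, low_confidence)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tallele\tscore\tlow_confidence\n")
        for chrom, pos, allele, score, low in records:
            fh.write(f"{chrom}\t{pos}\t{allele}\t{score:.6f}\t{int(low)}\n")


# ---------------------------------------------------------------------------
# MEME minimal motifs

def read_motif_database(path) -> MotifLibrary:
    """Parse a MEME minimal-format motif file into a PWM library.

    Parsed directly (Bio.motifs' minimal reader rounds probabilities to
    pseudo-counts, losing the precision the column check needs).
    Columns off unit mass by <= 1e-3 are renormalized; worse ones are an
    error naming the motif.
    """
    out: list[Pwm] = []
    name = None
    rows: list[list[float]] = []
    in_matrix = False

    def _flush():
        nonlocal name, rows, in_matrix
        if name is None:
            return
        if not rows:
            raise ValueError(f"motif {name!r} has no probability matrix")
        mat = np.array(rows, dtype=float).T        # rows A,C,G,T x width
        sums = mat.sum(axis=0)
        off = np.abs(sums - 1.0)
        if np.any(off > 1e-3):
            j = int(np.argmax(off))
            raise ValueError(
                f"motif {name!r}: column {j} sums to {sums[j]:.4f}, not 1")
        out.append(Pwm(motif_id=name, matrix=mat / sums))
        name, rows, in_matrix = None, [], False

    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("MOTIF"):
                _flush()
                name = s.split()[1]
            elif s.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix:
                parts = s.split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
                else:
                    in_matrix = False
        _flush()
    return MotifLibrary(out)


def write_motif_database(lib: MotifLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in lib:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= 20 E= 0\n")
            for j in range(pwm.width):
                fh.write(" ".join(f"{pwm.matrix[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED / TSV outputs

def write_bed(intervals, path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_table(df, path) -> None:
    """TSV with header, fixed column order, full float precision round-trip."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def read_table(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", na_values=["NA"])
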