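# Methods

## The scan

The unit of analysis is a genomic window on one contig.  For the four
populations — allopatric *M. mulatta* (AM), parapatric *M. mulatta*
(PM), allopatric *M. fascicularis* (AF), parapatric *M. fascicularis*
(PF) — each window receives:

**Divergence difference.**  `D_d = D(PM, PF) − D(AM, AF)` for two
divergence measures.  Hudson's F_ST is computed per site as

    num = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

with `p` the alt-allele frequency from called alleles and `n` the
called-allele count (the Bhatia finite-sample correction), then
aggregated per window as `Σnum / Σden` ("ratio of averages" — the less
biased aggregation for short windows).  Sites with fewer than two
called alleles in either population are excluded; negative window
values are reported, not clamped, because clamping would bias the
difference `D_d`.  D_XY is `Σ [p1(1−p2) + p2(1−p1)] / n_comparable`,
where every site with at least one called allele in both populations
counts in the denominator — invariant sites included, which is why the
input VCF must retain them.

The null distribution of `D_d` is built by reshuffling the
sample-to-population labeling (group sizes preserved) `n_perm = 100`
times; one shared set of labelings serves every window and both
divergence measures, and the permuted values are computed by the same
code path as the empirical ones.  A window is significant when its
empirical `D_d` is strictly greater than more than 95% of the defined
permuted values — with 100 permutations that means at least 96; exactly
95/100 does not qualify, and ties never count as exceedance.  Permuted
values that are undefined (e.g. an all-zero F_ST denominator after
reshuffling) are dropped from that window's comparison and logged.
Under exchangeability the per-window type-I error is ≈ 5/101 ≈ 0.05,
which the acceptance suite verifies empirically.

**Tajima's D contrast.**  Tajima's D is computed per window and
population from complete-case sites (any missing call in the focal
population drops the site from both the segregating-site count and π),
so the haplotype count `n` is constant and the 1989 normalizing
constants apply exactly.  Per-site π uses the unbiased estimator
`2j(n−j)/(n(n−1))` for derived count `j`.  The contrast
`TD_d = ((TD_pf − TD_pm) + (TD_pf − TD_af))/2` isolates selection
specific to PF against the hybridizing neighbour (PM) and the
conspecific control (AF); AM is not needed for the contrast, though the
library computes its D on request.  Cutoff: `TD_d < −1`, strict.

**Ancestry.**  A two-component (K = 2) admixture model: each of an
individual's two allele copies at a site derives from the
mulatta-like component with probability `q`, giving the binomial
log-likelihood `Σ g log(p_q) + (2−g) log(1−p_q)` with
`p_q = q·pM + (1−q)·pF`.  Three estimators are provided:

* `supervised` (default): ADMIXTURE-style supervised EM.  Allopatric
  individuals have `q` pinned (AM = 1, AF = 0); both component
  frequency vectors are re-estimated each EM iteration from **all**
  samples, with a pseudocount of 1 per allele class.  Deterministic (no
  random initialization).  This was adopted after the fixed-panel
  estimator below proved upward-biased in windows where PF has drifted
  away from AF (exactly the planted reinforcement windows, where extra
  drift is the divergence signal): drift gets misread as mulatta
  ancestry, inflating mean q̂ to ≈ 0.05 when the truth is 0 and
  defeating the 2.5% filter.  Frequency re-estimation absorbs the
  drift; measured null-window q̂ at q_true = 0 is ≈ 10⁻⁷–10⁻³.
* `projection`: component frequencies fixed at allopatric-panel
  estimates (pseudocount 1); each query's `q` maximizes the concave
  log-likelihood by bounded 1-D optimization.  Cheap, exactly
  analyzable (the optimum provably beats any grid), and accurate when
  the query population has not drifted from its panel — it is the
  estimator used in the ancestry-recovery validation — but biased under
  query-specific drift, hence not the scan default.
* `unsupervised`: FRAPPE-style K = 2 EM over all samples, seeded;
  label switching resolved by assigning the mulatta component to the
  one with the larger mean ancestry among AM samples.

The window statistic is the arithmetic mean of q̂ over PF individuals
(undefined individual estimates dropped, all-undefined windows get NaN
and can never pass the filter).  Cutoff: mean q̂ `< 0.025`, strict.

**Intersection.**  `candidate = (fst_sig OR dxy_sig) AND td_sig AND
adm_sig`.  Candidate windows are intersected with gene spans
(0-based half-open on both sides; ≥ 1 bp overlap; abutting intervals do
not overlap).

## Window definition

Per-site minor allele frequency (all samples pooled, called alleles
only) is fit with a cubic smoothing spline whose penalty is chosen by
generalized cross-validation; boundaries are placed at the integer
midpoint between consecutive sites where the spline's second derivative
changes sign, evaluated at the observed sites (boundaries between sites
are the only meaningful ones).  Windows tile the span from the first to
the last variant site; fewer than four sites or a constant signal give
a single window.  Numerical choices: the abscissa is rescaled to mean
spacing ≈ 1 before fitting, which (a) makes the GCV choice — and hence
the windows' site composition — exactly invariant under coordinate
scaling and (b) keeps the banded GCV solve well conditioned (a [0,1]
rescaling makes it near-singular for ~10³ sites); if the GCV solve
still fails, a fixed mild penalty (λ = 1 on that scale) is used.
Windowing is per contig.  A `--fixed-window N` tiling fallback exists
for degenerate inputs and testing.

## The simulator

The generator states a world, it is not tuned to tests.  Frequencies
are hierarchical Balding–Nichols: ancestral `p ~ U(0.05, 0.95)` at
polymorphic sites; species frequencies `Beta(p(1−F)/F, (1−p)(1−F)/F)`
with `F = F_species`; population frequencies likewise with `F_pop`
(plus `F_boost` for PF in planted windows).  Genotypes are
`Binomial(2, p_pop)`, except PF, where each allele copy independently
chooses the PM source with probability `q_i` — the exact generative
model of the ancestry estimator's likelihood, so parameter recovery is
a well-posed test.  Planted windows additionally force a fraction of
their variant sites to be singletons private to PF (exactly one derived
copy, all other populations fixed ancestral), which mechanically drives
PF Tajima's D negative without simulating sweeps.

Defaults and why: 10 samples per population (the real design is
10/10/11/9); 90% invariant sites (desk-scale stand-in for the ~2.4%
genome-wide SNP density, keeping D_XY denominators honest);
`F_species = 0.3` (the order of interspecies macaque F_ST);
`F_pop = 0.05` (typical within-species differentiation);
`q_intro = 0.1` with Beta(1, 9) individual variation (inside the
observed 0–18% mulatta ancestry of parapatric *M. fascicularis*);
planted windows default to `F_boost = 0.5`, `q_planted = 0`,
`singleton_fraction = 0.3`.  Invariant sites are fixed for the
reference allele (an alt allele fixed in everyone would contradict the
"invariant" record).  Sites are evenly spaced (1 per 10 bp); a
reference FASTA, a GTF (one gene inside every planted window, genes
tiling null regions), a SIFT table covering all coding variants and a
small PWM library are emitted alongside, all keyed to one seed
(byte-identical reruns).

What the generator does **not** emulate: linkage disequilibrium and
recombination structure (sites are conditionally independent given
window frequencies, and MAF has no spatial autocorrelation within
windows), coalescent genealogies, sex chromosomes, selection dynamics,
sequencing error.  Two consequences for interpreting green tests:
first, spline windows on simulated data align with planted intervals
only by chance, so end-to-end (spline-windowed) planted-gene recovery
is partial by construction — the scan's sensitivity (0.98 at the
stated planted settings) is therefore measured on windows aligned with
the simulation grid, and the end-to-end test asserts completion plus
partial recovery; second, the permutation null's exchangeability check
uses the simulator's own F → 0 limit and says nothing about LD-induced
correlation between windows in real data.

## Variant annotation

Parapatric-unique sites: the alt allele has ≥ 1 called copy in PF and
none elsewhere (reference-allele uniqueness deliberately does not
count: the downstream consensus substitutes alt alleles).  Effect
classes per overlapping transcript, most severe kept, with SnpEff-like
conventions: CDS variants translated strand-aware in transcript frame
(transcripts whose CDS length is not a multiple of 3 are skipped with a
warning); exonic non-CDS → UTR side relative to the CDS; intronic bases
1–2 from a junction → splice donor/acceptor (strand-aware), 3–8 →
splice region; within 5 kb outside the transcript → upstream/downstream
by strand; otherwise intron or intergenic.  Non-coding transcripts
contribute at most "intron".

Flank pairs are 13-mers centered on the variant (6 bases each side);
the alternate sequence comes from a consensus in which every selected
site's reference base is substituted, so nearby selected variants
appear in each other's flanks.  Sites within 6 bases of a contig end
are skipped, keeping the fixed width invariant.  B-SIFT is
`SIFT(alt) − SIFT(ref)` in [−1, 1], classified by sign (positive =
adaptive, zero = neutral, negative = deleterious); low-confidence
entries are excluded from classification and missing scores yield an
explicit no-score record.  The motif step replaces a motif-to-motif
database comparison with a transparent PWM log-odds scan: uniform 0.25
background, probabilities floored at 10⁻⁶, all offsets within the
13-mer on both strands, a motif "matches" a flank when its best score
reaches 85% (configurable) of its maximum achievable score, and the
deliverable is the set of motifs matching the alternate flank but not
the reference flank.

## Known limitations

- Windows, statistics and the scan operate per contig; multi-contig
  inputs are processed contig by contig via the `region` argument.
- The permutation null treats windows independently; no multiplicity
  correction beyond the per-window criterion is applied (by design).
- Supervised EM ancestry is slightly biased toward 0 when true
  admixture is substantial (queries pull the fascicularis component
  toward themselves); this is conservative for the < 2.5% filter's
  false-positive side and does not affect the q ≈ 0 regime the filter
  keys on.
- The effect classifier covers the class vocabulary above only — no
  HGVS, no regulatory features, no canonical-transcript logic.
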