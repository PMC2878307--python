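# Methods

This note documents the models, conventions and numerical choices behind
`alunuc`, and what its synthetic closed-loop validation does and does not
establish about real data.

## Coordinates and annotation handling

All coordinates are 0-based, half-open, on every interface. UCSC-style
`rmsk` tables already store `genoStart` 0-based, so both supported dialects
(`rmsk`, `bed6`) pass through unshifted; RepeatMasker's `C` strand symbol is
read as `-`. FASTA residues are uppercased and anything outside ACGTN maps
to N.

Alu classification is a two-step filter: a configurable repName pattern
table assigns a candidate class (defaults: names containing `FLAM` or equal
to `FAM` → FLAM, containing `FRAM` → FRAM, otherwise starting with `Alu` →
dimer), then a per-class length window — dimer 280–320 bp, FLAM 110–150 bp,
FRAM 150–190 bp, inclusive — discards truncated or expanded copies. The
element center is `floor((start+end)/2)`, a deterministic tie-break for odd
lengths. The default pattern table is an approximation of the full
subfamily-level mapping used on real annotations; it is overridable via a
two-column TSV because subfamily naming varies between RepeatMasker
library versions.

## Periodicity spectra

A step class is a strand-symmetric set of words: {A,T}, {G,C}, and the ten
dinucleotide classes obtained by pairing each dinucleotide with its reverse
complement (AT, TA, CG, GC are self-paired singletons). The twelve classes
partition the 4 mononucleotides and 16 dinucleotides, so every position of
a fragment contributes to exactly one dinucleotide class.

Fragments of 8,193 bp (2¹³ + 1) are sampled uniformly over all gap-free
windows; dinucleotide indicators then have length N = 8192, and
mononucleotide indicators are truncated to N − 1 bits so both share one FFT
length. Sampling is with replacement (independent uniform starts); at
genome scale the overlap between fragments is negligible, and the contract
is simpler than enforced disjointness.

**Mean-centering.** The indicator mean (≈ the step frequency, e.g. 0.18
for AA/TT at 30% A) is far from zero. Without centering, its Welch-window
sidelobes leak into the low-frequency bins and inflate the long-period end
of the spectrum by orders of magnitude at n = 1–3. The fragment mean is
therefore subtracted before windowing, and the DC bin is excluded from both
the background mean and the reported spectrum. With this convention the
spectrum of structureless sequence is flat apart from one intrinsic
feature: an overlapping-dinucleotide indicator is autocorrelated at lag 1
(AA at k and k+1 requires only AAA), which tilts the baseline smoothly
from ≈1.3 at long periods to ≈0.7 near the Nyquist period. This tilt is a
property of the method, not of any genome; periodicity strength should
always be read against the base-composition-matched random control
(`random_control`), which carries the identical tilt. The helper
`band_excess` integrates the S/N difference between a spectrum and such a
control over a period band, and is the measure used for all masking
comparisons.

**Peak reporting.** Long-period bins are sparse on the p = N/n axis, so
`find_peaks` smooths the S/N curve with a 5-bin moving average before
locating interior local maxima; each maximum is reported at the raw-S/N
argmax bin within the smoothing neighborhood, and ties rank the longer
period first.

## Nucleosome signals

Accepted tag pairs have inserts in [122, 172] bp (inclusive), the mapper
constraint used for 36-bp paired MNase reads around the 147-bp core; the
core center estimate is the floor midpoint of the two 5′ ends. The
"coarse-grain smoothing" of the center histogram is implemented as
convolution with a uniform kernel of odd width (default 21 bp — roughly the
positioning uncertainty left by MNase trimming); the width is a parameter
on every interface so alternatives can be tested. Signals are scaled to
p.p.b. (genome-wide sum 10⁹) after smoothing, which makes the normalization
exact regardless of edge effects, and every pipeline stage preserves this
sum. The background applies the identical pipeline to uniformly placed
147-bp fragments, with the fragment count a parameter defaulting to the
observed tag count.

Metaprofiles average the signal at offsets within ±1000 bp of an element
anchor (center or either end), flipping minus-strand elements by default
since Alu structure is oriented. A unique tag is attributed to an Alu by
its midpoint, not by any-overlap: midpoints are the analysis currency, and
a 36-bp read pair straddling an edge is better judged by where its inferred
core center sits.

Multi-hit rescue samples one hit uniformly per eligible tag (eligible =
all hits in Alu, or > 85% of hits in Alu). The accompanying dispersion
statistic is the per-tag SD (ddof = 1) of the unsigned distances from each
hit's midpoint to the nearest element center; unsigned, because homologous
positions in copies of opposite orientation mirror around the center. Small
mean dispersion justifies random assignment. On synthetic data, where
copies of a class are identical-length template copies, the statistic is
exactly 0.

Peak measurements on profiles: `profile_peaks` takes the maximum of an
11-bin-smoothed profile in a window; `phased_peaks` collects local maxima
of the 21-bin-smoothed profile merging any closer than 140 bp — just under
a core length, the physical lower bound on the spacing of two distinct
nucleosome peaks.

## Tiling profiles

Probes within 600 bp of an element edge are binned by signed distance
(5′ edge: negative = outside; 3′ edge: positive = outside; orientation
follows element strand), one row per probe-edge association — a probe near
a short element legitimately contributes to both edges. The background
shuffles hybridization values across all probes (positions, and hence
probe-edge associations, fixed), recomputes the profile per shuffle
(default 10), and reports the per-bin mean and SD. With distance bins of
1 bp and sparse probes the per-bin SD estimate from 10 shuffles is noisy;
the closed-loop tests bin at 25 bp, where each bin pools enough probes for
a stable z-score. Note the bin labelled 0 at the 3′ edge straddles the
edge (distances 0–24 include outside positions), so band membership is
judged on whole bins strictly inside or outside.

## Expression rates

The per-category rate is `(tags in category / total tags) × 10⁶ /
n_regions` — tags per million mapped per region. This form reproduces the
magnitudes expected for TSS windows versus repeat bodies given ~10⁶–10⁷
mapped tags and 10³–10⁴ regions per category; it is a reconstruction, as
the original rate formula is stated only as a unit (p.p.m). A tag counts
once per category if its 5′ position falls in any region (regions are
merged first); counting is strand-blind by default. Flank windows
([−900,−601] … [+601,+900], −1/+1 = positions immediately 5′/3′ of the
element) are oriented by element strand and are exactly 300 bp; TSS and
random windows are ±150 bp inclusive (301 bp). The random-site category is
regenerated independently (default 10×) and reported with its replicate
mean and SD.

## The synthetic generator

`SimConfig` defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| `alu_coverage` | 0.07 | dimeric-Alu genome fraction in human |
| `class_mix` | 0.92/0.06/0.02 | observed dimer/FLAM/FRAM count ratio |
| dimer template | 132+20+150+15 bp | left monomer + A-linker + right monomer + poly(A) = 317 bp, inside the dimer window |
| `monomer_gc` | 0.60 | GC-rich monomers |
| `monomer_homology` | 0.8 | right arm is a diverged copy of the left |
| `mutation_rate` | 0.05 | per-copy divergence from template |
| `slot_offsets` | 66, 230 | monomer centers, the two nucleosome slots |
| `slot_weights` | 1.0, 0.4 | right slot disfavored |
| `phasing_period` | 180 bp | nucleosome repeat length (170–200) |
| `phasing_decay` | 0.7 | per-nucleosome attenuation away from the element |
| `tag_density` | 0.02/bp | paired-tag depth, same order as ~0.01/bp genome-scale data |
| `tag_insert_range` | [122, 172] | mapper insert constraint |
| `probe_delta`, bands | 0.5; +150 bp outside / −100 bp inside | planted edge enrichment/depletion |
| `lambda_tss` ≫ `lambda_bg` > `lambda_alu` | 0.05 / 0.002 / 0.0002 per bp | promoter ≫ background > silenced repeat |

Element copies are template copies with per-instance substitutions,
inserted non-overlapping on random strands until target coverage. TSS
windows are placed with ≥1060 bp clearance from elements, emulating the
promoter-poor Alu neighborhoods the expression analysis measures — without
this the flank windows would contain promoters and flank and random-site
rates would coincide by construction. Background 5′ tags are excluded from
element bodies and TSS windows so each region type has exactly its
configured intensity. All stage RNGs spawn from one seed
(`numpy.random.SeedSequence`), making emitted files byte-identical across
reruns.

What the generator does *not* emulate: Alu subfamily phylogeny and length
variation within a class (copies of a class share one template length —
this is why the multi-hit dispersion statistic is exactly 0 on synthetic
data where real data shows a small positive value), sequencing error,
mappability structure, chromatin heterogeneity between cell types, and the
sequence composition of real monomers beyond GC enrichment and A-tracts.
Passing closed-loop tests therefore demonstrates that the analysis code
recovers planted structure of the paper's kind at realistic densities and
noise levels — not that any particular biological conclusion holds; for
that the pipeline must be pointed at real assemblies and data sets, which
it accepts in their standard formats.

## Problem sizes

The reference analysis used 10,000 fragments of a ~3.1-Gb genome and ~28M
tag pairs. The validation suite scales this down: spectra use 100–300
fragments; metaprofiles use a 1-Mb genome with ~20,000 tag pairs over ~230
elements; tiling and expression use 0.5-Mb genomes. The Alu-masking
comparison alone uses a 20-Mb genome: the masked control's uncertainty is
fixed-sequence periodogram noise, which decreases only with the number of
independent element-free 8.2-kb windows, and smaller genomes leave too few
for a stable fold estimate. Each sized run completes in seconds; the whole
suite in well under a minute of compute plus test overhead.

## Known limitations

- The default repName→class table is a coarse approximation of a full
  subfamily mapping; supply a curated table for real annotations.
- `find_peaks` reports bin-resolution periods; no sub-bin interpolation.
- The background tag model is uniform; real MNase backgrounds have
  accessibility structure.
- Expression counting double-counts a tag that falls in regions of two
  *different* categories (by design — categories are independent).
- SAM ingestion trusts proper-pair flags and `NH` tags; it does not
  re-pair mates itself.
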