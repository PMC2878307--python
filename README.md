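# alunuc

Genome-wide nucleotide periodicity and nucleosome positioning around Alu
elements.

## The scientific problem

In yeast, worm, fly and plant genomes, nucleosome positioning is associated
with ~10-bp periodic AA/TT dinucleotides, visible genome-wide as sharp peaks
in Fourier spectra of the dinucleotide indicator sequence. Primate genomes
behave differently: their dominant periodicities are broad peaks near 84 bp
and 167 bp — the latter close to a nucleosome core (147 bp) plus a
linker-histone footprint (~20 bp) — and these peaks largely vanish when Alu
SINE retrotransposons are masked. Dimeric Alu elements (~300 bp: two
GC-rich monomers flanking an A-rich linker, ending in a poly(A) tract)
carry one strong and one weak nucleosome "slot", deplete nucleosomes at
their A-rich boundaries, phase neighboring nucleosomes at the nucleosome
repeat length (~170–200 bp), and are nearly silent as promoters.

`alunuc` implements the full analysis pipeline behind these observations,
for anyone who wants to run it on genome assemblies, RepeatMasker tables,
MNase paired-end tags, tiling-array probes and 5′-end cDNA tags — plus a
synthetic-data generator that plants all of this structure with known
truth, so every stage can be validated end to end without external data.

## Methods at the core

**Periodicity spectra.** A nucleotide step γ (one of 12 strand-symmetric
classes: A/T, G/C and 10 dinucleotide classes such as AA/TT) is encoded
along a DNA fragment as an indicator B(k) (e.g. `CTTGAAT` → `010010` for
AA/TT). For fragments of 8,193 bp (so N = 2¹³ indicator bits) sampled from
gap-free genome sequence, the Welch-windowed power spectrum and its
signal-to-noise ratio are

    F(n) = | Σₖ (B(k) − B̄) · W(k) · e^(−2πi·nk/N) |²
    W(k) = 1 − ((k − (N−1)/2) / ((N−1)/2))²
    R(n) = F(n) / ⟨F(m)⟩,   m = 1 … N/2 − 1

and R is averaged bin-wise over fragments; R(n) measures the strength of
the periodicity p = N/n. A base-composition-matched random control provides
the reference curve, and masking (replacing annotated repeats with N before
sampling) isolates the contribution of an element family.

**Nucleosome signals.** Paired-end MNase tags with inserts in [122, 172] bp
mark nucleosome cores; the midpoint of the two 5′ ends is the core center.
Midpoint histograms are smoothed with a uniform 21-bp kernel and normalized
to parts per billion (genome-wide sum 10⁹), with a matched background from
uniformly placed 147-bp fragments. Signals are averaged around Alu element
anchors (strand-aware) to form metaprofiles; multi-hit tags concentrated in
Alu copies can be rescued by random hit assignment.

**Tiling arrays and expression.** Probe hybridization values are averaged
by signed distance from element edges against a 10× value-shuffle
background. 5′-tag expression rates are computed per region category (Alu
bodies, six 300-bp flank windows, TSS ± 150 bp, random sites ± 150 bp) as
tags per million mapped per region (p.p.m), with ten independent
random-site replicates providing error bars.

## Worked example

Closed loop on synthetic data — generate a 1-Mb genome with planted
elements and tags, then recover the planted nucleosome structure:

```python
import numpy as np
from alunuc import SimConfig, simulate_all, nucleosome_signal, align_profile
from alunuc.nucleosome import tag_midpoint, profile_peaks, phased_peaks

data = simulate_all(SimConfig(genome_len=1_000_000, seed=3))
mids = [(t.chrom, tag_midpoint(t)) for t in data.nuc_tags if t.n_hits <= 1]
sig = nucleosome_signal(mids, data.genome.lengths(), window_w=21)
dimers = [e for e in data.truth.elements if e.alu_class == "dimer"]
prof = align_profile(sig, dimers, anchor="center", flank=1000)

left = profile_peaks(prof, -148, 0)
right = profile_peaks(prof, 0, 148)
print(f"left-arm slot:  offset {left[0]:+d} bp, height {left[1]:.0f} p.p.b.")
print(f"right-arm slot: offset {right[0]:+d} bp, height {right[1]:.0f} p.p.b.")
print(f"right/left occupancy ratio: {right[1]/left[1]:.2f}")
peaks = phased_peaks(prof, 250, 950, min_sep=140)
print("phased flanking peaks:", peaks, "spacings:", list(np.diff(peaks)))
```

prints

```
left-arm slot:  offset -92 bp, height 18664 p.p.b.
right-arm slot: offset +72 bp, height 8342 p.p.b.
right/left occupancy ratio: 0.45
phased flanking peaks: [337, 519, 696, 879] spacings: [182, 177, 183]
```

The generator planted the dimer slots at 66 and 230 bp from the element 5′
end (offsets −92 and +72 from the center of a 317-bp dimer) with the right
slot at 0.4× the left slot's weight, and phased flanking nucleosomes every
180 bp — all three are recovered: the slots to the base pair, the weight
ratio as the 0.45 peak-height ratio, and the phasing as the 177–183 bp
peak spacings.

The same run from a shell, driving every stage from one config:

```sh
alunuc run-all --config examples/demo.yaml
```

writes per-stage TSVs (spectra for raw/masked/random modes, metaprofiles
per Alu class, the tiling distance profile, the p.p.m rate table) and a
manifest with per-stage seeds and a parameter hash, under `alunuc_demo/`.
Individual stages are also exposed as subcommands (`simulate`, `spectrum`,
`alu-profile`, `tiling-profile`, `expression`); `alunuc spectrum --fasta
genome.fa --step AA/TT --mode masked --mask-bed rmsk.bed ...` reproduces
the Alu-masking comparison on a real assembly.

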