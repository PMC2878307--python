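"""Synthetic genomes, Alu annotations, nucleosome tags, probes and 5' tags.

The generator plants the structure the analysis modules are built to
detect, so every stage has a closed-loop test with known truth:

* a random-base genome carrying non-overlapping Alu-like insertions copied
  from per-run template sequences (dimer = GC-rich left monomer + A-rich
  linker + GC-rich right monomer + poly(A); FLAM/FRAM = single monomers),
  mutated per instance, at a tunable genome coverage;
* optional planted periodic dinucleotides in the background sequence;
* nucleosome centers drawn from a mixture of in-element Gaussian slots
  (left slot stronger than right), phased flanking Gaussians at the
  nucleosome repeat length with geometric decay, and a uniform background;
  emitted as 36-bp-read paired-end tags with inserts in [122, 172], a
  configurable fraction flagged multi-hit at homologous positions of other
  element copies;
* tiling probes on a regular grid with planted band effects near element
  edges (+delta just outside, -delta just inside) plus Gaussian noise;
* Poisson 5' tags at separate intensities for TSS windows, element bodies
  and the rest of the genome.

All randomness derives from one seed via numpy SeedSequence spawning, so
per-stage outputs are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from alunuc.io_annotation import (
    AluElement,
    GeneAnnotation,
    GenomeSequence,
    RepeatFeature,
    classify_alu_table,
    write_bed6,
    write_fasta,
)
from alunuc.nucleosome import INSERT_MAX, INSERT_MIN, TagPair, write_tag_pairs
from alunuc.tiling import write_probes

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


@dataclass
class SimConfig:
    """Parameters of the synthetic data set (defaults = study conditions)."""

    genome_len: int = 300_000
    chrom_name: str = "chrSim"
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    # --- repeat structure ---
    alu_coverage: float = 0.07  # fraction of the genome inside elements
    class_mix: tuple[float, float, float] = (0.92, 0.06, 0.02)  # dimer/FLAM/FRAM
    left_monomer_len: int = 132
    a_linker_len: int = 20
    right_monomer_len: int = 150
    polya_len: int = 15
    monomer_gc: float = 0.6
    monomer_homology: float = 0.8  # arm sequence shared between monomers
    mutation_rate: float = 0.05  # per-instance substitution rate
    # --- planted background periodicity (off by default) ---
    periodic_word: str = "AA"
    periodic_period: int = 10
    periodic_prob: float = 0.0  # per-grid-point planting probability
    # --- nucleosome tags ---
    slot_offsets: tuple[int, int] = (66, 230)  # dimer slots, bp from 5' end
    slot_sd: float = 10.0
    slot_weights: tuple[float, float] = (1.0, 0.4)
    phasing_period: int = 180  # nucleosome repeat length, in [170, 200]
    phasing_decay: float = 0.7
    phasing_sd: float = 20.0
    n_phased: int = 4
    tag_density: float = 0.02  # tags per bp of genome
    bg_tag_fraction: float = 0.3
    multihit_fraction: float = 0.1
    multihit_copies: tuple[int, int] = (2, 5)  # extra hits per multi-hit tag
    tag_insert_range: tuple[int, int] = (INSERT_MIN, INSERT_MAX)
    # --- tiling probes ---
    probe_spacing: int = 50
    probe_baseline: float = 0.0
    probe_delta: float = 0.5
    probe_out_band: int = 150  # enriched band outside each edge (bp)
    probe_in_band: int = 100  # depleted band inside each edge (bp)
    probe_noise_sd: float = 0.1
    cell_types: tuple[str, ...] = ("cellA", "cellB")
    # --- 5' tags ---
    n_genes: int = 60
    gene_flank_clearance: int = 1060  # TSS windows avoid elements +- this (bp)
    lambda_tss: float = 0.05  # tags per bp inside TSS windows
    lambda_bg: float = 0.002
    lambda_alu: float = 0.0002
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.alu_coverage < 0.5:
            raise ValueError("alu_coverage must be in [0, 0.5)")
        if any(w < 0 for w in self.slot_weights):
            raise ValueError("slot weights must be nonnegative")
        if not 140 <= self.phasing_period <= 260:
            raise ValueError("phasing_period outside [140, 260]")

    @property
    def dimer_len(self) -> int:
        return (
            self.left_monomer_len
            + self.a_linker_len
            + self.right_monomer_len
            + self.polya_len
        )


@dataclass
class TruthSet:
    """Planted structure, consistent with the emitted files."""

    elements: list[AluElement]
    features: list[RepeatFeature]
    slot_offsets: dict[str, tuple[int, ...]]  # per class, bp from 5' end
    phasing_period: int
    probe_out_band: int
    probe_in_band: int
    probe_delta: float
    lambdas: dict[str, float]
    genes: list[GeneAnnotation] = field(default_factory=list)

    def summary(self) -> dict:
        per_class: dict[str, int] = {}
        for el in self.elements:
            per_class[el.alu_class] = per_class.get(el.alu_class, 0) + 1
        return {
            "n_elements": len(self.elements),
            "elements_per_class": per_class,
            "slot_offsets": {k: list(v) for k, v in self.slot_offsets.items()},
            "phasing_period": self.phasing_period,
            "probe_out_band": self.probe_out_band,
            "probe_in_band": self.probe_in_band,
            "probe_delta": self.probe_delta,
            "lambdas": self.lambdas,
            "n_genes": len(self.genes),
        }


def _stage_rngs(seed: int, n: int = 6) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_seq(n: int, p: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=np.asarray(p, dtype=float))]


def _gc_rich_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)
    return _random_seq(n, p, rng)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits):
        out[hits] = _BASES[rng.integers(0, 4, size=len(hits))]
    return out


def _make_templates(config: SimConfig, rng: np.random.Generator):
    """Left/right monomer, linker and poly(A) template arrays."""
    left = _gc_rich_seq(config.left_monomer_len, config.monomer_gc, rng)
    # right arm: homologous to the left (tiled copy) with divergence
    reps = int(np.ceil(config.right_monomer_len / config.left_monomer_len))
    right = np.tile(left, reps)[: config.right_monomer_len].copy()
    right = _mutate(right, 1.0 - config.monomer_homology, rng)
    linker_p = (0.85, 0.05, 0.05, 0.05)  # A-rich
    linker = _random_seq(config.a_linker_len, linker_p, rng)
    polya = np.frombuffer(b"A" * config.polya_len, dtype="S1").copy()
    return left, linker, right, polya


CLASS_NAMES = {"dimer": "AluSim", "FLAM": "FLAMSim", "FRAM": "FRAMSim"}


def make_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, list[RepeatFeature], TruthSet]:
    """Random-base genome with planted Alu-like insertions.

    Instances are copied from fixed per-run templates, mutated at
    ``mutation_rate``, inserted (replacing background bases) at uniform
    non-overlapping positions on random strands until the target coverage
    is reached. Raises if the coverage cannot be placed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genome = _random_seq(config.genome_len, config.base_composition, rng)
    if config.periodic_prob > 0:
        word = np.frombuffer(config.periodic_word.encode(), dtype="S1")
        grid = np.arange(0, config.genome_len - len(word), config.periodic_period)
        chosen = grid[rng.random(len(grid)) < config.periodic_prob]
        for off in range(len(word)):
            genome[chosen + off] = word[off]
    left, linker, right, polya = _make_templates(config, rng)
    templates = {
        "dimer": np.concatenate([left, linker, right, polya]),
        "FLAM": np.concatenate([left, polya]),
        "FRAM": np.concatenate([right, polya]),
    }
    import bisect

    target_bp = int(config.alu_coverage * config.genome_len)
    placed_bp = 0
    occ_starts: list[int] = []  # sorted; paired with occ_ends
    occ_ends: list[int] = []
    features: list[RepeatFeature] = []
    classes = ("dimer", "FLAM", "FRAM")
    mix = np.asarray(config.class_mix, dtype=float)
    mix = mix / mix.sum()
    max_tries = 200 * max(1, target_bp // 300 + 1)
    tries = 0
    margin = 50  # keep elements off chromosome ends
    while placed_bp < target_bp:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not reach coverage {config.alu_coverage} after {max_tries} tries"
            )
        cls = classes[int(rng.choice(3, p=mix))]
        tmpl = templates[cls]
        L = len(tmpl)
        if config.genome_len - L - margin <= margin:
            continue  # no room for this template at all
        start = int(rng.integers(margin, config.genome_len - L - margin))
        end = start + L
        # overlap (with 10 bp spacer) against sorted disjoint occupied intervals
        i = bisect.bisect_left(occ_starts, end + 10)
        if i > 0 and occ_ends[i - 1] + 10 > start:
            continue
        inst = _mutate(tmpl, config.mutation_rate, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            inst = np.frombuffer(
                _revcomp(inst.tobytes().decode()).encode(), dtype="S1"
            ).copy()
        genome[start:end] = inst
        j = bisect.bisect_left(occ_starts, start)
        occ_starts.insert(j, start)
        occ_ends.insert(j, end)
        features.append(
            RepeatFeature(config.chrom_name, start, end, strand, CLASS_NAMES[cls])
        )
        placed_bp += L
    features.sort(key=lambda f: f.start)
    gseq = GenomeSequence({config.chrom_name: genome.tobytes().decode()})
    elements = classify_alu_table(features)
    mono_center = config.left_monomer_len // 2
    truth = TruthSet(
        elements=elements,
        features=features,
        slot_offsets={
            "dimer": tuple(config.slot_offsets),
            "FLAM": (mono_center,),
            "FRAM": (config.right_monomer_len // 2,),
        },
        phasing_period=config.phasing_period,
        probe_out_band=config.probe_out_band,
        probe_in_band=config.probe_in_band,
        probe_delta=config.probe_delta,
        lambdas={
            "tss": config.lambda_tss,
            "bg": config.lambda_bg,
            "alu": config.lambda_alu,
        },
    )
    return gseq, features, truth


def _oriented_pos(el: AluElement, offset: int) -> int:
    """Genomic position of an oriented offset from the element 5' end."""
    if el.strand == "+":
        return el.start + offset
    return el.end - 1 - offset


def simulate_nucleosome_tags(
    genome: GenomeSequence,
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[TagPair]:
    """Paired-end tags from the planted nucleosome center mixture.

    Component means: per element, Gaussian slots at the class slot offsets
    (weights ``slot_weights``; density zero over the A-linker and poly(A)
    because the slots sit on the monomers), plus phased flanking Gaussians
    at +-k * phasing_period from the element edges with weight decay^k;
    a ``bg_tag_fraction`` of tags is uniform background. Each center emits a
    pair with insert uniform in the accepted range. ``multihit_fraction`` of
    element-borne tags carry a hit list at the homologous offset of other
    copies of the same class.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    chrom = genome.chrom_names[0]
    L = genome.length(chrom)
    n_tags = max(200, int(config.tag_density * L))
    means, sds, weights, el_idx = [], [], [], []
    by_class: dict[str, list[int]] = {}
    for i, el in enumerate(truth.elements):
        by_class.setdefault(el.alu_class, []).append(i)
        offs = truth.slot_offsets[el.alu_class]
        ws = config.slot_weights[: len(offs)] if el.alu_class == "dimer" else (1.0,)
        for o, w in zip(offs, ws):
            means.append(_oriented_pos(el, o))
            sds.append(config.slot_sd)
            weights.append(w)
            el_idx.append(i)
        for k in range(1, config.n_phased + 1):
            w = config.phasing_decay**k
            if w <= 0:
                break
            for pos in (
                el.start - k * config.phasing_period,
                el.end - 1 + k * config.phasing_period,
            ):
                means.append(pos)
                sds.append(config.phasing_sd)
                weights.append(w)
                el_idx.append(-1)
    means_a = np.array(means)
    sds_a = np.array(sds)
    w_a = np.array(weights, dtype=float)
    n_bg = int(round(n_tags * config.bg_tag_fraction))
    n_el = n_tags - n_bg
    pairs: list[TagPair] = []
    lo_ins, hi_ins = config.tag_insert_range

    def _emit(center: int, el_i: int):
        insert = int(rng.integers(lo_ins, hi_ins + 1))
        fwd5 = center - (insert - 1) // 2
        rev5 = fwd5 + insert - 1
        if fwd5 < 0 or rev5 >= L:
            return
        hit_list = None
        n_hits = 1
        if el_i >= 0 and rng.random() < config.multihit_fraction:
            el = truth.elements[el_i]
            others = [j for j in by_class[el.alu_class] if j != el_i]
            if others:
                k = int(rng.integers(config.multihit_copies[0], config.multihit_copies[1] + 1))
                k = min(k, len(others))
                picks = rng.choice(len(others), size=k, replace=False)
                # homologous hit = same oriented offset in another copy
                off = (
                    center - el.start if el.strand == "+" else el.end - 1 - center
                )
                hits = [(chrom, fwd5)]
                for j in picks:
                    oth = truth.elements[others[int(j)]]
                    hc = _oriented_pos(oth, off)
                    hf = hc - (insert - 1) // 2
                    if 0 <= hf and hf + insert - 1 < L:
                        hits.append((chrom, hf))
                if len(hits) > 1:
                    hit_list = tuple(hits)
                    n_hits = len(hits)
        pairs.append(TagPair(chrom, fwd5, rev5, n_hits, hit_list))

    if len(means_a) and n_el > 0:
        comp = rng.choice(len(means_a), size=n_el, p=w_a / w_a.sum())
        centers = np.rint(rng.normal(means_a[comp], sds_a[comp])).astype(int)
        for c, ci in zip(centers, comp):
            _emit(int(c), el_idx[int(ci)])
    for _ in range(n_bg):
        _emit(int(rng.integers(100, L - 100)), -1)
    return pairs


def simulate_probes(
    genome: GenomeSequence,
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Grid probes with planted edge-band effects and Gaussian noise.

    value = baseline + delta inside the ``probe_out_band`` just outside an
    element edge, - delta within ``probe_in_band`` just inside, + noise.
    One probe row per grid position per cell type.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    chrom = genome.chrom_names[0]
    L = genome.length(chrom)
    centers = np.arange(config.probe_spacing, L, config.probe_spacing)
    effect = np.zeros(L)
    for el in truth.elements:
        s, e = el.start, el.end
        effect[max(0, s - config.probe_out_band) : s] += config.probe_delta
        effect[e : min(L, e + config.probe_out_band)] += config.probe_delta
        inner_end = min(s + config.probe_in_band, e)
        inner_start = max(e - config.probe_in_band, s)
        effect[s:inner_end] -= config.probe_delta
        effect[inner_start:e] -= config.probe_delta
    frames = []
    for ct in config.cell_types:
        vals = (
            config.probe_baseline
            + effect[centers]
            + rng.normal(0.0, config.probe_noise_sd, size=len(centers))
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "center": centers,
                    "value": vals,
                    "cell_type": ct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_genes(
    genome: GenomeSequence,
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[GeneAnnotation]:
    """Random TSSs placed clear of elements and their flank neighborhoods.

    Real Alu surroundings are promoter-poor — the analysis this generator
    feeds measures exactly that — so TSS windows keep
    ``gene_flank_clearance`` bp of distance from every planted element.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    chrom = genome.chrom_names[0]
    L = genome.length(chrom)
    clear = config.gene_flank_clearance
    starts = np.array([el.start for el in truth.elements] or [L + 1])
    ends = np.array([el.end for el in truth.elements] or [L + 2])
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    genes: list[GeneAnnotation] = []
    tries = 0
    while len(genes) < config.n_genes and tries < 100 * config.n_genes:
        tries += 1
        pos = int(rng.integers(200, L - 200))
        i = int(np.searchsorted(starts, pos + 150 + clear, side="right")) - 1
        if i >= 0 and pos - 150 - clear < ends[i]:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(chrom, pos, strand))
    if len(genes) < config.n_genes:
        raise ValueError("could not place TSSs away from elements")
    return genes


def simulate_tss_tags(
    genome: GenomeSequence,
    truth: TruthSet,
    genes: Sequence[GeneAnnotation],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int, str]]:
    """Poisson 5' tags: lambda_tss in TSS+-150 windows, lambda_alu in
    element bodies, lambda_bg elsewhere."""
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    chrom = genome.chrom_names[0]
    L = genome.length(chrom)
    tags: list[tuple[str, int, str]] = []
    tss_iv = [(g.tss - 150, g.tss + 151) for g in genes]
    for s, e in tss_iv:
        s, e = max(s, 0), min(e, L)
        k = rng.poisson(config.lambda_tss * (e - s))
        for p in rng.integers(s, e, size=k):
            tags.append((chrom, int(p), "+" if rng.random() < 0.5 else "-"))
    for el in truth.elements:
        k = rng.poisson(config.lambda_alu * (el.end - el.start))
        for p in rng.integers(el.start, el.end, size=k):
            tags.append((chrom, int(p), el.strand))
    special = sorted(tss_iv + [(el.start, el.end) for el in truth.elements])
    merged: list[list[int]] = []
    for s, e in special:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    sp_s = np.array([m[0] for m in merged] or [L + 1])
    sp_e = np.array([m[1] for m in merged] or [L + 2])
    k_bg = rng.poisson(config.lambda_bg * L)
    for p in rng.integers(0, L, size=k_bg):
        i = int(np.searchsorted(sp_s, p, side="right")) - 1
        if i >= 0 and p < sp_e[i]:
            continue  # special regions keep their own intensity
        tags.append((chrom, int(p), "+" if rng.random() < 0.5 else "-"))
    return tags


@dataclass
class SimData:
    """Everything one simulation run produced."""

    config: SimConfig
    genome: GenomeSequence
    features: list[RepeatFeature]
    truth: TruthSet
    nuc_tags: list[TagPair]
    probes: pd.DataFrame
    tss_tags: list[tuple[str, int, str]]


def simulate_all(config: SimConfig, outdir: str | Path | None = None) -> SimData:
    """Run every generator stage from one seed; optionally write the files.

    Output files: genome.fa, elements.bed, tags.tsv, probes.tsv,
    tss_tags.bed, genes.tsv, truth.json. Per-stage RNGs are spawned from
    the config seed so reruns are byte-identical.
    """
    rngs = _stage_rngs(config.seed)
    genome, features, truth = make_genome(config, rngs[0])
    nuc_tags = simulate_nucleosome_tags(genome, truth, config, rngs[1])
    probes = simulate_probes(genome, truth, config, rngs[2])
    genes = make_genes(genome, truth, config, rngs[3])
    truth.genes = genes
    tss_tags = simulate_tss_tags(genome, truth, genes, config, rngs[4])
    data = SimData(config, genome, features, truth, nuc_tags, probes, tss_tags)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        write_bed6(features, outdir / "elements.bed")
        write_tag_pairs(nuc_tags, outdir / "tags.tsv")
        write_probes(probes, outdir / "probes.tsv")
        with open(outdir / "tss_tags.bed", "w") as fh:
            for c, p, s in tss_tags:
                fh.write(f"{c}\t{p}\t{p + 1}\t.\t0\t{s}\n")
        with open(outdir / "genes.tsv", "w") as fh:
            for g in genes:
                fh.write(f"{g.chrom}\t{g.tss}\t{g.strand}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {"config": dataclasses.asdict(config), "truth": truth.summary()},
                fh,
                indent=2,
            )
    return data
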