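"""Nucleosome-center signals from MNase paired-end tags and Alu metaprofiles.

The 5' ends of a nucleosomal DNA fragment are sequenced on both strands;
the midpoint of an accepted pair (insert 122-172 bp, bracketing the 147-bp
core) is taken as the nucleosome core center. Midpoint counts are smoothed
with a uniform kernel (coarse-grain smoothing) and normalized to parts per
billion (the genome-wide sum of the signal is 1e9), which makes data sets of
different depth directly comparable. A matched background is built from
uniformly placed 147-bp fragments. Signals are then averaged around Alu
element anchors to form metaprofiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from alunuc.io_annotation import AluElement, GenomeSequence

logger = logging.getLogger(__name__)

#: Inclusive insert-size bounds for an accepted pair (bp).
INSERT_MIN, INSERT_MAX = 122, 172

PPB = 1_000_000_000


@dataclass(frozen=True)
class TagPair:
    """A mapped paired-end tag: 5' ends of the two mates."""

    chrom: str
    fwd5: int  # 5' end of the plus-strand mate
    rev5: int  # 5' end of the minus-strand mate
    n_hits: int = 1
    hit_list: tuple[tuple[str, int], ...] | None = None  # (chrom, fwd5) per hit

    @property
    def insert(self) -> int:
        return self.rev5 - self.fwd5 + 1

    @property
    def midpoint(self) -> int:
        return (self.fwd5 + self.rev5) // 2


@dataclass
class NucleosomeSignal:
    """Per-chromosome smoothed center density in p.p.b."""

    signal: dict[str, np.ndarray]
    window_w: int
    total_tags: int

    def get(self, chrom: str) -> np.ndarray:
        return self.signal[chrom]

    def total(self) -> float:
        return float(sum(a.sum() for a in self.signal.values()))


@dataclass(frozen=True)
class TagCategoryCounts:
    unique_alu: int
    unique_other: int
    multi_complete: int
    multi_partial: int
    multi_none: int

    @property
    def total(self) -> int:
        return (
            self.unique_alu
            + self.unique_other
            + self.multi_complete
            + self.multi_partial
            + self.multi_none
        )


@dataclass
class MetaProfile:
    """Signal averaged over elements at offsets relative to an anchor."""

    offsets: np.ndarray  # bp, symmetric around 0
    mean_signal: np.ndarray
    mean_background: np.ndarray | None
    n_elements: int
    n_excluded: int = 0


class IntervalIndex:
    """Merged, sorted intervals per chromosome with O(log n) point queries."""

    def __init__(self, elements: Iterable[AluElement]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        self.centers: dict[str, np.ndarray] = {}
        centers: dict[str, list[int]] = {}
        for el in elements:
            by_chrom.setdefault(el.chrom, []).append((el.start, el.end))
            centers.setdefault(el.chrom, []).append(el.center)
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for c, ivs in by_chrom.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self.starts[c] = np.array([m[0] for m in merged])
            self.ends[c] = np.array([m[1] for m in merged])
            self.centers[c] = np.sort(np.array(centers[c]))

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self.starts:
            return False
        i = int(np.searchsorted(self.starts[chrom], pos, side="right")) - 1
        return i >= 0 and pos < self.ends[chrom][i]

    def nearest_center(self, chrom: str, pos: int) -> int | None:
        cs = self.centers.get(chrom)
        if cs is None or len(cs) == 0:
            return None
        i = int(np.searchsorted(cs, pos))
        cands = [j for j in (i - 1, i) if 0 <= j < len(cs)]
        return int(min((abs(cs[j] - pos), cs[j]) for j in cands)[1])


def tag_midpoint(pair: TagPair) -> int:
    """Midpoint of the two 5' ends (floor), presumed nucleosome core center."""
    return (pair.fwd5 + pair.rev5) // 2


def _parse_hits(s: str) -> tuple[tuple[str, int], ...]:
    out = []
    for h in s.split(";"):
        c, p = h.rsplit(":", 1)
        out.append((c, int(p)))
    return tuple(out)


def load_tag_pairs(
    path: str | Path,
    format: str = "tsv",
    known_chroms: set[str] | None = None,
) -> tuple[list[TagPair], int]:
    """Load paired-end tags; returns (accepted pairs, n_rejected).

    ``format="tsv"``: tab-separated chrom, fwd5, rev5, n_hits and an optional
    fifth column ``chrom:fwd5;chrom:fwd5;...`` listing all hits of a
    multi-hit tag. ``format="sam"``: properly paired reads via pysam, one
    pair per forward-strand mate (NH tag read as n_hits when present).
    Pairs with insert outside [122, 172] are dropped and counted; pairs on
    unknown chromosomes are dropped with a warning.
    """
    pairs: list[TagPair] = []
    n_rejected = 0
    n_unknown = 0

    def _push(chrom, fwd5, rev5, n_hits=1, hits=None):
        nonlocal n_rejected, n_unknown
        if known_chroms is not None and chrom not in known_chroms:
            n_unknown += 1
            return
        insert = rev5 - fwd5 + 1
        if not (INSERT_MIN <= insert <= INSERT_MAX):
            n_rejected += 1
            return
        pairs.append(TagPair(chrom, fwd5, rev5, n_hits, hits))

    if format == "tsv":
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                hits = _parse_hits(f[4]) if len(f) > 4 and f[4] else None
                _push(f[0], int(f[1]), int(f[2]), int(f[3]) if len(f) > 3 else 1, hits)
    elif format == "sam":
        import pysam

        with pysam.AlignmentFile(str(path), "r") as sam:
            for read in sam:
                if (
                    read.is_unmapped
                    or not read.is_proper_pair
                    or read.is_reverse
                    or read.is_secondary
                    or read.is_supplementary
                ):
                    continue
                fwd5 = read.reference_start
                rev5 = fwd5 + read.template_length - 1
                n_hits = read.get_tag("NH") if read.has_tag("NH") else 1
                _push(read.reference_name, fwd5, rev5, int(n_hits))
    else:
        raise ValueError(f"unknown format {format!r}")
    if n_unknown:
        logger.warning("%s: dropped %d pairs on unknown chromosomes", path, n_unknown)
    return pairs, n_rejected


def write_tag_pairs(pairs: Iterable[TagPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            hits = (
                ";".join(f"{c}:{x}" for c, x in p.hit_list) if p.hit_list else ""
            )
            fh.write(f"{p.chrom}\t{p.fwd5}\t{p.rev5}\t{p.n_hits}\t{hits}\n")


def categorize_tags(
    tags: Sequence[TagPair], alu_elements: Sequence[AluElement] | IntervalIndex
) -> TagCategoryCounts:
    """Split tags into unique (Alu / others) and multi-hit (complete /
    partial / none) categories by Alu overlap of their midpoints.

    A unique tag is Alu if its midpoint lies inside an element; a multi-hit
    tag is judged by the fraction of its hits whose midpoints lie inside
    elements: all -> complete, some -> partial, none -> none.
    """
    idx = (
        alu_elements
        if isinstance(alu_elements, IntervalIndex)
        else IntervalIndex(alu_elements)
    )
    ua = uo = mc = mp = mn = 0
    for t in tags:
        if t.n_hits <= 1:
            if idx.contains(t.chrom, t.midpoint):
                ua += 1
            else:
                uo += 1
        else:
            hits = t.hit_list or ((t.chrom, t.fwd5),)
            half = (t.insert - 1) // 2
            n_in = sum(idx.contains(c, p + half) for c, p in hits)
            if n_in == len(hits):
                mc += 1
            elif n_in == 0:
                mn += 1
            else:
                mp += 1
    return TagCategoryCounts(ua, uo, mc, mp, mn)


def nucleosome_signal(
    midpoints: Iterable[tuple[str, int]],
    genome_lengths: Mapping[str, int],
    window_w: int = 21,
) -> NucleosomeSignal:
    """Coarse-grain-smoothed, p.p.b.-normalized nucleosome center signal.

    The per-position midpoint histogram is convolved with a uniform kernel
    of odd width ``window_w`` and scaled so the genome-wide sum is 1e9.
    """
    if window_w % 2 != 1 or window_w < 1:
        raise ValueError("window_w must be odd and >= 1")
    hist = {c: np.zeros(L, dtype=np.float64) for c, L in genome_lengths.items()}
    n = 0
    for chrom, pos in midpoints:
        if 0 <= pos < genome_lengths[chrom]:
            hist[chrom][pos] += 1
            n += 1
    if n == 0:
        raise ValueError("no midpoints")
    kernel = np.ones(window_w) / window_w
    sig = {
        c: (np.convolve(h, kernel, mode="same") if window_w > 1 else h)
        for c, h in hist.items()
    }
    total = sum(a.sum() for a in sig.values())
    scale = PPB / total
    return NucleosomeSignal({c: a * scale for c, a in sig.items()}, window_w, n)


def background_signal(
    genome: GenomeSequence | Mapping[str, int],
    n_fragments: int,
    rng_seed: int | np.random.Generator = 0,
    window_w: int = 21,
    insert: int = 147,
) -> NucleosomeSignal:
    """Background signal from uniformly placed paired fragments.

    Fragment pairs with a fixed ``insert`` (147 bp, the nucleosome core) are
    dropped uniformly on each chromosome in proportion to its length; their
    midpoints go through the same smoothing and p.p.b. normalization as the
    data.
    """
    lengths = (
        genome.lengths() if isinstance(genome, GenomeSequence) else dict(genome)
    )
    rng = np.random.default_rng(rng_seed)
    chroms = list(lengths)
    sizes = np.array([max(lengths[c] - insert + 1, 0) for c in chroms], dtype=float)
    if sizes.sum() == 0:
        raise ValueError("genome shorter than one fragment")
    counts = rng.multinomial(n_fragments, sizes / sizes.sum())
    mids: list[tuple[str, int]] = []
    half = (insert - 1) // 2
    for c, k in zip(chroms, counts):
        if k == 0:
            continue
        fwd5 = rng.integers(0, lengths[c] - insert + 1, size=k)
        for p in fwd5:
            mids.append((c, int(p) + half))
    return nucleosome_signal(mids, lengths, window_w)


def _anchor_pos(el: AluElement, anchor: str) -> int:
    if anchor == "center":
        return el.center
    fwd = el.strand == "+"
    if anchor == "end5":
        return el.start if fwd else el.end - 1
    if anchor == "end3":
        return el.end - 1 if fwd else el.start
    raise ValueError(f"unknown anchor {anchor!r}")


def align_profile(
    signal: NucleosomeSignal,
    elements: Sequence[AluElement],
    anchor: str = "center",
    flank: int = 1000,
    strand_aware: bool = True,
    background: NucleosomeSignal | None = None,
) -> MetaProfile:
    """Average the signal over elements at offsets within +-flank of anchor.

    Minus-strand elements are coordinate-flipped when ``strand_aware`` so
    their oriented internal structure lines up. Elements whose flank window
    exceeds chromosome bounds are excluded and counted.
    """
    width = 2 * flank + 1
    acc = np.zeros(width)
    bg_acc = np.zeros(width) if background is not None else None
    n_used = n_excl = 0
    for el in elements:
        a = _anchor_pos(el, anchor)
        arr = signal.signal.get(el.chrom)
        if arr is None or a - flank < 0 or a + flank >= len(arr):
            n_excl += 1
            continue
        win = arr[a - flank : a + flank + 1]
        if strand_aware and el.strand == "-":
            win = win[::-1]
        acc += win
        if bg_acc is not None:
            bwin = background.signal[el.chrom][a - flank : a + flank + 1]
            if strand_aware and el.strand == "-":
                bwin = bwin[::-1]
            bg_acc += bwin
        n_used += 1
    if n_used == 0:
        raise ValueError("no element fits within chromosome bounds")
    return MetaProfile(
        offsets=np.arange(-flank, flank + 1),
        mean_signal=acc / n_used,
        mean_background=bg_acc / n_used if bg_acc is not None else None,
        n_elements=n_used,
        n_excluded=n_excl,
    )


def multihit_augment(
    tags: Sequence[TagPair],
    alu_elements: Sequence[AluElement] | IntervalIndex,
    policy: str = "complete_only",
    rng_seed: int | np.random.Generator = 0,
) -> tuple[list[tuple[str, int]], float]:
    """Rescue Alu-concentrated multi-hit tags by random hit assignment.

    Eligible tags (``complete_only``: every hit midpoint in an Alu element;
    ``ge85``: more than 85% of hits in Alu) contribute one uniformly chosen
    hit's midpoint. Returns the added midpoints and the mean over tags of
    the SD of hit distances (unsigned, so copies on either strand compare
    like for like) to the nearest Alu center — small dispersion means the
    hits occupy homologous positions in different copies, so random
    assignment does not distort the profile.
    """
    if policy not in ("complete_only", "ge85"):
        raise ValueError(f"unknown policy {policy!r}")
    idx = (
        alu_elements
        if isinstance(alu_elements, IntervalIndex)
        else IntervalIndex(alu_elements)
    )
    rng = np.random.default_rng(rng_seed)
    midpoints: list[tuple[str, int]] = []
    sds: list[float] = []
    for t in tags:
        if t.n_hits <= 1 or not t.hit_list:
            continue
        half = (t.insert - 1) // 2
        hit_mids = [(c, p + half) for c, p in t.hit_list]
        frac = sum(idx.contains(c, m) for c, m in hit_mids) / len(hit_mids)
        if policy == "complete_only" and frac < 1.0:
            continue
        if policy == "ge85" and frac <= 0.85:
            continue
        chosen = hit_mids[int(rng.integers(len(hit_mids)))]
        midpoints.append(chosen)
        dists = [
            abs(m - idx.nearest_center(c, m))
            for c, m in hit_mids
            if idx.nearest_center(c, m) is not None
        ]
        if len(dists) >= 2:
            sds.append(float(np.std(dists, ddof=1)))
        elif dists:
            sds.append(0.0)
    mean_sd = float(np.mean(sds)) if sds else float("nan")
    return midpoints, mean_sd


def phased_peaks(
    profile: MetaProfile,
    lo: int,
    hi: int,
    smooth: int = 21,
    min_sep: int = 100,
) -> list[int]:
    """Offsets of local maxima of the smoothed profile in [lo, hi].

    Maxima closer than ``min_sep`` bp are merged keeping the higher one;
    the result is sorted by offset. Used to measure the spacing of phased
    nucleosome peaks flanking an element.
    """
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(profile.mean_signal, kernel, mode="same")
    off = profile.offsets
    cand: list[tuple[int, float]] = []
    for i in range(1, len(sm) - 1):
        if lo <= off[i] <= hi and sm[i] >= sm[i - 1] and sm[i] > sm[i + 1]:
            cand.append((int(off[i]), float(sm[i])))
    cand.sort(key=lambda t: -t[1])  # keep highest within min_sep
    kept: list[tuple[int, float]] = []
    for pos, h in cand:
        if all(abs(pos - k) >= min_sep for k, _ in kept):
            kept.append((pos, h))
    return sorted(p for p, _ in kept)


def profile_peaks(
    profile: MetaProfile,
    lo: int,
    hi: int,
    smooth: int = 11,
) -> tuple[int, float]:
    """Position (offset bp) and height of the maximum of the smoothed
    profile restricted to offsets in [lo, hi]."""
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(profile.mean_signal, kernel, mode="same")
    mask = (profile.offsets >= lo) & (profile.offsets <= hi)
    if not mask.any():
        raise ValueError("empty offset range")
    i = np.nonzero(mask)[0][np.argmax(sm[mask])]
    return int(profile.offsets[i]), float(sm[i])
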