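"""Welch-windowed Fourier periodicity spectra of nucleotide steps.

A nucleotide step is a strand-symmetric mono- or dinucleotide category
(e.g. AA/TT); occurrences of the step along a DNA fragment are converted to
a 0/1 indicator sequence B(k), and the periodicity strength at period
p = N/n is measured by the signal-to-noise ratio

    R(n) = F(n) / mean_m F(m),      F(n) = |sum_k B(k) W(k) e^{-2*pi*i*n*k/N}|^2

where W is the Welch window. R is averaged bin-wise over many fragments
sampled from the genome. The indicator sequence is mean-centered before
windowing (see :func:`power_spectrum`) and the DC bin (n = 0) is excluded
from the background mean and from the reported spectrum, so the spectrum of
structureless sequence is flat at R = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from alunuc.io_annotation import GenomeSequence

#: Standard fragment length: 2^13 + 1 bp, giving indicator length N = 8192.
FRAGMENT_LENGTH = 8193

_BASE_CODE = {b: i for i, b in enumerate("ACGT")}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class StepClass:
    """A strand-symmetric nucleotide step (the analysis unit gamma)."""

    kind: str  # "mono" | "di"
    members: frozenset[str]
    label: str

    def __post_init__(self):
        wl = 1 if self.kind == "mono" else 2
        assert all(len(w) == wl for w in self.members)


def _revcomp(word: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(word))


def step_classes() -> list[StepClass]:
    """Enumerate the 12 step classes: 2 mono ({A,T},{G,C}) and 10 di.

    Dinucleotides are grouped with their reverse complement (AA with TT,
    CA with TG, ...); the four palindromic steps (AT, TA, CG, GC) are
    singleton classes. The classes partition the 4 mononucleotides and the
    16 dinucleotides.
    """
    out = [
        StepClass("mono", frozenset("AT"), "A/T"),
        StepClass("mono", frozenset("GC"), "G/C"),
    ]
    seen: set[str] = set()
    for a in "ACGT":
        for b in "ACGT":
            w = a + b
            if w in seen:
                continue
            rc = _revcomp(w)
            seen.update({w, rc})
            label = w if w == rc else f"{w}/{rc}"
            out.append(StepClass("di", frozenset({w, rc}), label))
    return out


def get_step(label: str) -> StepClass:
    """Look up a step class by label ("AA/TT", "TT/AA", "AT", "G/C", ...)."""
    want = frozenset(label.split("/"))
    for sc in step_classes():
        if want <= sc.members or label == sc.label:
            return sc
    raise KeyError(f"unknown step class {label!r}")


@dataclass
class SpectrumResult:
    """Averaged S/N spectrum for one step over a fragment set."""

    step: StepClass
    n_fragments: int
    sn: np.ndarray  # mean S/N at n = 1 .. N/2 - 1
    N: int  # indicator length (fragment length - 1)
    seed: int | None = None

    @property
    def n_index(self) -> np.ndarray:
        return np.arange(1, len(self.sn) + 1)

    @property
    def period(self) -> np.ndarray:
        """Period axis p = N/n (bp), strictly decreasing."""
        return self.N / self.n_index


def _eligible_starts(seq: str, frag_len: int) -> np.ndarray:
    """Start positions of all N-free windows of frag_len in one chromosome."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_n = (codes == ord("N")).astype(np.int64)
    if len(codes) < frag_len:
        return np.empty(0, dtype=np.int64)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    window_n = cs[frag_len:] - cs[:-frag_len]
    return np.nonzero(window_n == 0)[0]


def sample_fragments(
    genome: GenomeSequence,
    n_frag: int,
    frag_len: int = FRAGMENT_LENGTH,
    rng_seed: int | np.random.Generator = 0,
) -> list[str]:
    """Sample fragments uniformly over all gap-free windows of the genome.

    Starts are independent and uniform over every position (any chromosome)
    whose window of ``frag_len`` bp contains no N; sampling is with
    replacement, which is indistinguishable from without at genome scale.
    """
    rng = np.random.default_rng(rng_seed)
    chroms, starts_all = [], []
    for c in genome.chrom_names:
        st = _eligible_starts(genome.seq(c), frag_len)
        if len(st):
            chroms.append(c)
            starts_all.append(st)
    if not starts_all:
        raise ValueError(
            f"no gap-free window of length {frag_len} bp in the genome"
        )
    counts = np.array([len(s) for s in starts_all])
    cum = np.concatenate([[0], np.cumsum(counts)])
    idx = rng.integers(0, cum[-1], size=n_frag)
    frags = []
    for i in idx:
        ci = int(np.searchsorted(cum, i, side="right") - 1)
        start = int(starts_all[ci][i - cum[ci]])
        frags.append(genome.seq(chroms[ci])[start : start + frag_len])
    return frags


def random_control(
    base_composition: dict[str, float] | Sequence[float],
    n_frag: int,
    frag_len: int = FRAGMENT_LENGTH,
    rng_seed: int | np.random.Generator = 0,
) -> list[str]:
    """Generate i.i.d. random fragments with a given A/C/G/T composition."""
    if isinstance(base_composition, dict):
        p = np.array([base_composition[b] for b in "ACGT"], dtype=float)
    else:
        p = np.asarray(base_composition, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative base frequencies")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError(f"composition sums to {p.sum()}, not 1")
    rng = np.random.default_rng(rng_seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out = []
    for _ in range(n_frag):
        draw = rng.choice(4, size=frag_len, p=p)
        out.append(bases[draw].tobytes().decode())
    return out


def encode_step(sequence: str, step: StepClass) -> np.ndarray:
    """Convert a DNA fragment to the 0/1 indicator of a step.

    For a dinucleotide step, bit k is 1 iff the word at positions (k, k+1)
    belongs to the class (occurrences may overlap); the output has length
    L - 1. For a mononucleotide step, bit k indicates membership of base k,
    truncated to L - 1 so mono and di spectra share the same FFT length.
    Fragments must be N-free.
    """
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_CODE.items():
        lut[ord(b)] = i
    c = lut[codes]
    if np.any(c < 0):
        raise ValueError("sequence contains non-ACGT characters")
    if step.kind == "mono":
        member = np.zeros(4, dtype=bool)
        for w in step.members:
            member[_BASE_CODE[w]] = True
        return member[c[:-1]].astype(np.float64)
    member16 = np.zeros(16, dtype=bool)
    for w in step.members:
        member16[4 * _BASE_CODE[w[0]] + _BASE_CODE[w[1]]] = True
    words = 4 * c[:-1] + c[1:]
    return member16[words].astype(np.float64)


def welch_window(N: int) -> np.ndarray:
    """Welch (parabolic) window W(k) = 1 - ((k - (N-1)/2) / ((N-1)/2))^2."""
    if N < 3:
        raise ValueError("window length must be >= 3")
    k = np.arange(N)
    half = (N - 1) / 2.0
    return 1.0 - ((k - half) / half) ** 2


def power_spectrum(
    binary: np.ndarray,
    window: np.ndarray | None = None,
    center: bool = True,
) -> np.ndarray:
    """Windowed power spectrum F(n) = |DFT(B * W)(n)|^2 for n = 0..N/2-1.

    The indicator sequence has a large nonzero mean whose window sidelobes
    would otherwise leak into the low-frequency (long-period) bins; with
    ``center`` (default) the fragment mean is subtracted before windowing,
    which makes the spectrum of an i.i.d. fragment flat across all reported
    bins.
    """
    b = np.asarray(binary, dtype=np.float64)
    if b.size == 0:
        raise ValueError("empty input")
    if center:
        b = b - b.mean()
    W = welch_window(len(b)) if window is None else window
    X = np.fft.rfft(b * W)
    F = np.abs(X) ** 2
    return F[: len(b) // 2]


def sn_ratio(F: np.ndarray) -> np.ndarray:
    """S/N ratio R(n) = F(n) / mean(F), n = 1..N/2-1.

    The background noise is the average power over the reported bins; the DC
    bin is excluded from the mean and from the output, so the mean of R over
    reported bins is exactly 1.
    """
    body = np.asarray(F, dtype=np.float64)[1:]
    mean = body.mean()
    if mean == 0:
        raise ValueError("all-zero power spectrum: S/N undefined")
    return body / mean


def average_spectrum(
    fragments: Iterable[str],
    step: StepClass,
    seed: int | None = None,
) -> SpectrumResult:
    """Per-fragment S/N spectra averaged bin-wise over a fragment set."""
    sn_sum = None
    n = 0
    N = None
    window = None
    for frag in fragments:
        b = encode_step(frag, step)
        if N is None:
            N = len(b)
            window = welch_window(N)
        elif len(b) != N:
            raise ValueError("fragments have mixed lengths")
        r = sn_ratio(power_spectrum(b, window))
        sn_sum = r if sn_sum is None else sn_sum + r
        n += 1
    if n == 0:
        raise ValueError("no fragments")
    return SpectrumResult(step, n, sn_sum / n, N, seed=seed)


def find_peaks(
    spectrum: SpectrumResult,
    band_bp: tuple[float, float],
    top_k: int = 2,
    smooth_bins: int = 5,
) -> list[tuple[float, float]]:
    """Locate the dominant periodicities within a period band.

    The S/N curve is smoothed with a ``smooth_bins``-bin moving average
    (long-period bins are sparse on the p = N/n axis), interior local maxima
    with period inside ``band_bp = (min_p, max_p)`` are ranked by smoothed
    height, and the ``top_k`` highest are returned as (period_bp, sn) using
    the raw S/N at the maximal bin. Ties rank the longer period first.
    """
    lo, hi = band_bp
    if not (lo < hi):
        raise ValueError("empty period band")
    sn = spectrum.sn
    kernel = np.ones(smooth_bins) / smooth_bins
    sm = np.convolve(sn, kernel, mode="same")
    period = spectrum.period
    in_band = (period >= lo) & (period <= hi)
    if not in_band.any():
        raise ValueError(f"no frequency bin with period in [{lo}, {hi}]")
    half = smooth_bins // 2
    peaks = []
    seen: set[int] = set()
    for i in np.nonzero(in_band)[0]:
        if i == 0 or i == len(sm) - 1:
            continue
        left, right = sm[i - 1], sm[i + 1]
        if sm[i] >= left and sm[i] >= right and (sm[i] > left or sm[i] > right):
            # report the raw maximal bin within the smoothing neighborhood
            lo_i, hi_i = max(0, i - half), min(len(sn), i + half + 1)
            j = lo_i + int(np.argmax(sn[lo_i:hi_i]))
            if j in seen:
                continue
            seen.add(j)
            peaks.append((float(period[j]), float(sn[j]), float(sm[i]), i))
    # rank by smoothed height, ties toward smaller n (longer period)
    peaks.sort(key=lambda t: (-t[2], t[3]))
    return [(p, s) for p, s, _, _ in peaks[:top_k]]


def band_excess(
    spectrum: SpectrumResult,
    reference: SpectrumResult,
    band_bp: tuple[float, float],
) -> float:
    """Integrated S/N excess of a spectrum over a matched reference in a
    period band.

    The indicator of an overlapping dinucleotide step is intrinsically
    autocorrelated at lag 1, so even structureless sequence has a gently
    tilted S/N baseline; periodicity strength is therefore measured against
    the reference spectrum (a base-composition-matched random control), as
    the sum of the per-bin S/N differences over the band.
    """
    if spectrum.N != reference.N:
        raise ValueError("spectra have different lengths")
    lo, hi = band_bp
    band = (spectrum.period >= lo) & (spectrum.period <= hi)
    if not band.any():
        raise ValueError(f"no bin with period in [{lo}, {hi}]")
    return float(np.sum(spectrum.sn[band] - reference.sn[band]))


def spectrum_to_frame(spectrum: SpectrumResult):
    """Tabular view (n, period_bp, mean_sn) for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "n": spectrum.n_index,
            "period_bp": spectrum.period,
            "mean_sn": spectrum.sn,
        }
    )
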