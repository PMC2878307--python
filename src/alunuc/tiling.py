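"""Tiling-array hybridization profiles by distance from repeat element edges.

Probes whose centers fall within a maximum distance (600 bp) of an element
edge are binned by signed distance from that edge and their hybridization
values averaged. The background is built by shuffling the hybridization
values across all probes (positions fixed) and recomputing the profile; the
mean and SD over shuffles give a pointwise null band.

Sign convention (oriented by element strand): for the 5' edge, negative
distance = outside (upstream), positive = inside the element; for the 3'
edge, positive = outside (downstream), negative = inside.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from alunuc.io_annotation import AluElement

PROBE_COLUMNS = ["chrom", "center", "value", "cell_type"]


def read_probes(path: str | Path) -> pd.DataFrame:
    """Read a probe table TSV: chrom, center, value, cell_type."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=PROBE_COLUMNS,
        dtype={"chrom": str, "center": np.int64, "value": float, "cell_type": str},
        comment="#",
    )
    if not np.isfinite(df["value"]).all():
        raise ValueError("non-finite hybridization values")
    return df


def write_probes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=PROBE_COLUMNS)


def _edges(el: AluElement) -> tuple[int, int, int]:
    """(5' edge, 3' edge, orientation sign) in genomic coordinates."""
    if el.strand == "+":
        return el.start, el.end - 1, 1
    return el.end - 1, el.start, -1


def select_probes_near(
    probes: pd.DataFrame,
    elements: Sequence[AluElement],
    max_dist: int = 600,
) -> pd.DataFrame:
    """Associate probes with element edges within ``max_dist`` bp.

    Returns a frame with columns probe_idx, edge ("5p"/"3p"), distance,
    value, cell_type. A probe can associate with both edges (of the same or
    different elements); each association is one row.
    """
    rows_idx: list[int] = []
    rows_edge: list[str] = []
    rows_dist: list[int] = []
    order = probes.sort_values(["chrom", "center"])
    by_chrom = {
        c: (g["center"].to_numpy(), g.index.to_numpy())
        for c, g in order.groupby("chrom", sort=False)
    }
    for el in elements:
        got = by_chrom.get(el.chrom)
        if got is None:
            continue
        centers, idxs = got
        e5, e3, sign = _edges(el)
        for edge_name, epos in (("5p", e5), ("3p", e3)):
            lo = int(np.searchsorted(centers, epos - max_dist, side="left"))
            hi = int(np.searchsorted(centers, epos + max_dist, side="right"))
            for k in range(lo, hi):
                d = int(centers[k] - epos) * sign
                rows_idx.append(int(idxs[k]))
                rows_edge.append(edge_name)
                rows_dist.append(d)
    out = pd.DataFrame(
        {"probe_idx": rows_idx, "edge": rows_edge, "distance": rows_dist}
    )
    out["value"] = probes.loc[out["probe_idx"], "value"].to_numpy()
    out["cell_type"] = probes.loc[out["probe_idx"], "cell_type"].to_numpy()
    return out


def average_by_distance(
    assoc: pd.DataFrame,
    bin_width: int = 1,
    cell_filter: str | None = None,
) -> pd.DataFrame:
    """Mean hybridization value per (edge, distance bin).

    ``bin_width`` groups distances into bins labelled by their lower edge;
    width 1 keeps per-distance resolution. ``cell_filter`` restricts to one
    cell type. Output columns: edge, distance, mean, n.
    """
    df = assoc if cell_filter is None else assoc[assoc["cell_type"] == cell_filter]
    if bin_width > 1:
        b = (np.floor(df["distance"] / bin_width) * bin_width).astype(int)
    else:
        b = df["distance"]
    g = df.groupby([df["edge"], b.rename("distance")])["value"]
    out = g.agg(mean="mean", n="size").reset_index()
    return out


def shuffled_background(
    probes: pd.DataFrame,
    elements: Sequence[AluElement],
    n_shuffles: int = 10,
    rng_seed: int | np.random.Generator = 0,
    max_dist: int = 600,
    bin_width: int = 1,
    cell_filter: str | None = None,
    assoc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Permutation background: values shuffled across all probes, profile
    recomputed per shuffle; mean/SD over the shuffles per (edge, distance).

    Output columns: edge, distance, bg_mean, bg_sd. The shuffle permutes the
    value column only — probe positions, and hence the probe-to-edge
    associations, stay fixed.
    """
    if len(probes) < 2:
        raise ValueError("need at least 2 probes to shuffle")
    rng = np.random.default_rng(rng_seed)
    if assoc is None:
        assoc = select_probes_near(probes, elements, max_dist)
    work = assoc.copy()
    values = probes["value"].to_numpy()
    pos = probes.index.get_indexer(work["probe_idx"])
    profiles = []
    for s in range(n_shuffles):
        perm = rng.permutation(values)
        work["value"] = perm[pos]
        prof = average_by_distance(work, bin_width, cell_filter)
        prof["shuffle"] = s
        profiles.append(prof)
    allp = pd.concat(profiles, ignore_index=True)
    g = allp.groupby(["edge", "distance"])["mean"]
    out = g.agg(bg_mean="mean", bg_sd=lambda x: float(np.std(x))).reset_index()
    return out


def distance_profile(
    probes: pd.DataFrame,
    elements: Sequence[AluElement],
    max_dist: int = 600,
    bin_width: int = 1,
    cell_filter: str | None = None,
    n_shuffles: int = 10,
    rng_seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Full edge-distance profile with shuffled background.

    Output columns: edge, distance, mean, n, bg_mean, bg_sd.
    """
    assoc = select_probes_near(probes, elements, max_dist)
    obs = average_by_distance(assoc, bin_width, cell_filter)
    bg = shuffled_background(
        probes,
        elements,
        n_shuffles,
        rng_seed,
        max_dist,
        bin_width,
        cell_filter,
        assoc=assoc,
    )
    return obs.merge(bg, on=["edge", "distance"], how="left")
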