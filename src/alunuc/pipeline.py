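"""End-to-end orchestration: simulate -> spectra -> profiles -> rates.

A run is driven by a YAML/dict config with a single global seed; each stage
derives its own seed as the first 4 bytes of sha256("<seed>:<stage>"), so
stages are individually reproducible and the whole run is deterministic.
Every stage writes a TSV under the output directory and the run ends with a
manifest (parameter hash, per-stage seeds, outputs) sufficient to reproduce
byte-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from alunuc import __version__
from alunuc.expression import expression_rates, read_tag_positions
from alunuc.io_annotation import (
    classify_alu_table,
    mask_regions,
    read_fasta,
    read_genes,
    read_repeat_table,
)
from alunuc.nucleosome import (
    align_profile,
    background_signal,
    load_tag_pairs,
    multihit_augment,
    nucleosome_signal,
    tag_midpoint,
)
from alunuc.simulate import SimConfig, simulate_all
from alunuc.spectral import (
    average_spectrum,
    get_step,
    random_control,
    sample_fragments,
    spectrum_to_frame,
)
from alunuc.tiling import distance_profile, read_probes

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def config_hash(config: dict) -> str:
    """Hash of the scientific parameters (the output directory is not one)."""
    payload = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _require(paths: dict[str, Path]) -> None:
    missing = [f"{k}={v}" for k, v in paths.items() if not Path(v).exists()]
    if missing:
        raise StageError(f"validate: missing input paths: {', '.join(missing)}")


def run_all(config: dict[str, Any], outdir: str | Path | None = None) -> Path:
    """Execute all configured stages in dependency order.

    Config keys: ``seed``, ``outdir``, optional ``simulate`` (SimConfig
    fields; generates all inputs), optional ``inputs`` (paths: fasta,
    elements, tags, probes, genes, tss_tags), and per-stage parameter
    blocks ``spectrum``, ``profile``, ``tiling``, ``expression``. Any stage
    failure aborts the run with a stage-named error.
    """
    seed = int(config.get("seed", 0))
    out = Path(outdir if outdir is not None else config.get("outdir", "alunuc_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "stage_seeds": {},
        "outputs": [],
    }

    inputs = {k: Path(v) for k, v in config.get("inputs", {}).items()}
    if inputs:
        _require(inputs)

    if "simulate" in config:
        sim_seed = stage_seed(seed, "simulate")
        manifest["stage_seeds"]["simulate"] = sim_seed
        try:
            sim_cfg = SimConfig(**{**config["simulate"], "seed": sim_seed})
            simdir = out / "sim"
            simulate_all(sim_cfg, simdir)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"simulate: {e}") from e
        for name, fn in (
            ("fasta", "genome.fa"),
            ("elements", "elements.bed"),
            ("tags", "tags.tsv"),
            ("probes", "probes.tsv"),
            ("genes", "genes.tsv"),
            ("tss_tags", "tss_tags.bed"),
        ):
            inputs.setdefault(name, simdir / fn)
        manifest["outputs"].append(str(simdir))

    genome = read_fasta(inputs["fasta"]) if "fasta" in inputs else None
    features = (
        read_repeat_table(inputs["elements"], dialect="bed6")
        if "elements" in inputs
        else []
    )
    elements = classify_alu_table(features)

    if "spectrum" in config:
        sp = config["spectrum"]
        sseed = stage_seed(seed, "spectrum")
        manifest["stage_seeds"]["spectrum"] = sseed
        try:
            step = get_step(sp.get("step", "AA/TT"))
            n_frag = int(sp.get("n_frag", 1000))
            frag_len = int(sp.get("frag_len", 8193))
            for mode in sp.get("modes", ["raw"]):
                if mode == "raw":
                    frags = sample_fragments(genome, n_frag, frag_len, sseed)
                elif mode == "masked":
                    frags = sample_fragments(
                        mask_regions(genome, features), n_frag, frag_len, sseed
                    )
                elif mode == "random":
                    frags = random_control(
                        genome.base_composition(), n_frag, frag_len, sseed
                    )
                else:
                    raise ValueError(f"unknown spectrum mode {mode!r}")
                res = average_spectrum(frags, step, seed=sseed)
                path = out / f"spectrum_{mode}.tsv"
                spectrum_to_frame(res).to_csv(path, sep="\t", index=False)
                manifest["outputs"].append(str(path))
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError(f"spectrum: {e}") from e

    if "profile" in config:
        pf = config["profile"]
        pseed = stage_seed(seed, "profile")
        manifest["stage_seeds"]["profile"] = pseed
        try:
            pairs, _ = load_tag_pairs(inputs["tags"], format=pf.get("format", "tsv"))
            window_w = int(pf.get("window_w", 21))
            mids = [(t.chrom, tag_midpoint(t)) for t in pairs if t.n_hits <= 1]
            policy = pf.get("multihit", "none")
            if policy != "none":
                extra, mean_sd = multihit_augment(pairs, elements, policy, pseed)
                mids += extra
                manifest["multihit_mean_sd_bp"] = mean_sd
            sig = nucleosome_signal(mids, genome.lengths(), window_w)
            bg = background_signal(
                genome, n_fragments=len(mids), rng_seed=pseed, window_w=window_w
            )
            flank = int(pf.get("flank", 1000))
            for cls in pf.get("classes", ["dimer", "FLAM", "FRAM"]):
                els = [e for e in elements if e.alu_class == cls]
                if not els:
                    continue
                prof = align_profile(
                    sig,
                    els,
                    anchor=pf.get("anchor", "center"),
                    flank=flank,
                    background=bg,
                )
                path = out / f"profile_{cls}.tsv"
                pd.DataFrame(
                    {
                        "offset": prof.offsets,
                        "mean_signal": prof.mean_signal,
                        "mean_background": prof.mean_background,
                    }
                ).to_csv(path, sep="\t", index=False)
                manifest["outputs"].append(str(path))
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError(f"profile: {e}") from e

    if "tiling" in config:
        tl = config["tiling"]
        tseed = stage_seed(seed, "tiling")
        manifest["stage_seeds"]["tiling"] = tseed
        try:
            probes = read_probes(inputs["probes"])
            prof = distance_profile(
                probes,
                elements,
                max_dist=int(tl.get("max_dist", 600)),
                bin_width=int(tl.get("bin_width", 1)),
                cell_filter=tl.get("cell_filter"),
                n_shuffles=int(tl.get("shuffles", 10)),
                rng_seed=tseed,
            )
            path = out / "tiling.tsv"
            prof.to_csv(path, sep="\t", index=False)
            manifest["outputs"].append(str(path))
        except Exception as e:  # noqa: BLE001
            raise StageError(f"tiling: {e}") from e

    if "expression" in config:
        ex = config["expression"]
        eseed = stage_seed(seed, "expression")
        manifest["stage_seeds"]["expression"] = eseed
        try:
            genes = read_genes(inputs["genes"])
            fmt = "bed6" if str(inputs["tss_tags"]).endswith(".bed") else "tsv"
            tags = read_tag_positions(inputs["tss_tags"], format=fmt)
            rates = expression_rates(
                elements,
                genes,
                genome,
                tags,
                replicates=int(ex.get("replicates", 10)),
                rng_seed=eseed,
            )
            path = out / "expression.tsv"
            rates.to_csv(path, sep="\t", index=False)
            manifest["outputs"].append(str(path))
        except Exception as e:  # noqa: BLE001
            raise StageError(f"expression: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
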