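"""End-to-end pipelines tying the pieces together.

A run is: split cells into development/validation, fit the generative
model and the importance-score predictor on development cells, then test
every gene (and optionally every gene group at several resolutions) with
the CRT on validation cells, BH-correcting within each resolution.  One
master seed derives named substreams for every stochastic stage, so any
run can be replayed bit-for-bit from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import small_int_seed
from .crt import CRTResult, run_crt
from .data import CountDataset, DataSplit, ResponseVector, make_split
from .generative import NBVAE, draw_posterior_cache, normalized_expression
from .importance import fit_predictor, select_predictor
from .multires import GeneHierarchy, build_hierarchy, run_multires

__version__ = "0.1.0"


@dataclass
class RunOutput:
    results: dict[int | str, CRTResult]   # resolution -> result ("genes" for gene level)
    hierarchy: GeneHierarchy | None
    predictor_family: str
    manifest: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for res, result in self.results.items():
            df = result.to_frame()
            df.insert(0, "resolution", res)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def run_pipeline(dataset: CountDataset, response: ResponseVector,
                 resolutions: list | None = None,
                 predictor_family: str = "auto",
                 n_mc: int = 500, alpha: float = 0.1,
                 dev_fraction: float = 0.7, seed: int = 0,
                 gen_config: dict | None = None,
                 predictor_config: dict | None = None) -> RunOutput:
    """Full CRT run on one response.

    ``predictor_family="auto"`` fits linear and MLP candidates and keeps
    the one with the best held-out predictive loss.  ``resolutions``
    switches on multi-resolution testing; the gene hierarchy is built
    from the generative model's normalized expression on validation
    cells.
    """
    split = make_split(dataset.n_cells, dev_fraction,
                       seed=small_int_seed(seed, "split"))
    dev = dataset.subset(split.dev_idx)
    y_dev = response.subset(split.dev_idx)

    gen = NBVAE(**(gen_config or {}), seed=seed).fit(dev)
    predictor = _fit_or_select(dev, y_dev, predictor_family,
                               predictor_config, seed)

    results: dict = {}
    hierarchy = None
    if resolutions:
        val = dataset.subset(split.val_idx)
        cache = draw_posterior_cache(gen, val, seed)
        hierarchy = build_hierarchy(normalized_expression(gen, cache),
                                    resolutions=resolutions,
                                    gene_names=dataset.gene_names)
        results = dict(run_multires(dataset, response, split, gen, predictor,
                                    hierarchy, n_mc=n_mc, alpha=alpha, seed=seed))
    else:
        results["genes"] = run_crt(dataset, response, split, gen, predictor,
                                   n_mc=n_mc, alpha=alpha, seed=seed)
    return RunOutput(results=results, hierarchy=hierarchy,
                     predictor_family=predictor.family)


def run_many_responses(dataset: CountDataset, responses: list[ResponseVector],
                       **kwargs) -> dict[str, RunOutput]:
    """Independent per-dimension runs of a multivariate response.

    The generative model depends only on the counts, so it is fit once
    and shared; predictors and CRT runs (and BH correction) are per
    dimension.
    """
    seed = kwargs.pop("seed", 0)
    dev_fraction = kwargs.pop("dev_fraction", 0.7)
    gen_config = kwargs.pop("gen_config", None)
    predictor_family = kwargs.pop("predictor_family", "auto")
    predictor_config = kwargs.pop("predictor_config", None)
    n_mc = kwargs.pop("n_mc", 500)
    alpha = kwargs.pop("alpha", 0.1)
    resolutions = kwargs.pop("resolutions", None)
    if kwargs:
        raise TypeError(f"unknown arguments {sorted(kwargs)}")

    split = make_split(dataset.n_cells, dev_fraction,
                       seed=small_int_seed(seed, "split"))
    dev = dataset.subset(split.dev_idx)
    gen = NBVAE(**(gen_config or {}), seed=seed).fit(dev)

    out = {}
    for dim, resp in enumerate(responses):
        dim_seed = small_int_seed(seed, "predictor_fit", 50_000 + dim)
        predictor = _fit_or_select(dev, resp.subset(split.dev_idx),
                                   predictor_family, predictor_config, dim_seed)
        results: dict = {}
        hierarchy = None
        if resolutions:
            val = dataset.subset(split.val_idx)
            cache = draw_posterior_cache(gen, val, seed)
            hierarchy = build_hierarchy(normalized_expression(gen, cache),
                                        resolutions=resolutions,
                                        gene_names=dataset.gene_names)
            results = dict(run_multires(dataset, resp, split, gen, predictor,
                                        hierarchy, n_mc=n_mc, alpha=alpha,
                                        seed=seed))
        else:
            results["genes"] = run_crt(dataset, resp, split, gen, predictor,
                                       n_mc=n_mc, alpha=alpha, seed=seed)
        out[resp.name] = RunOutput(results=results, hierarchy=hierarchy,
                                   predictor_family=predictor.family)
    return out


def _fit_or_select(dev: CountDataset, y_dev: ResponseVector, family: str,
                   config: dict | None, seed: int):
    if family == "auto":
        fams = (["mlp_bernoulli"] if y_dev.family == "bernoulli"
                else ["linear_gaussian", "mlp_gaussian"])
        candidates = [fit_predictor(dev.counts, y_dev, dev.nuisance, family=f,
                                    config=config, seed=seed) for f in fams]
        return select_predictor(candidates)
    return fit_predictor(dev.counts, y_dev, dev.nuisance, family=family,
                         config=config, seed=seed)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(command: str, args: dict, seed: int,
                   input_paths: list[str]) -> dict:
    import datetime

    from ._seeds import STREAMS

    return {
        "command": command,
        "args": {k: v for k, v in args.items() if not k.startswith("_")},
        "master_seed": int(seed),
        "stream_labels": dict(STREAMS),
        "version": __version__,
        "input_checksums": {os.path.basename(p): file_checksum(p)
                            for p in input_paths if p and os.path.exists(p)},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
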