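"""Posterior persistence: a directory with a documented columnar schema.

Layout::

    <dir>/params.parquet   long format: chain, draw, param, index0, index1, value
    <dir>/latent_n.npy     int array (chains*draws, S, J, T)
    <dir>/meta.json        variant, labels, seed, MCMC settings, diagnostics
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .nmix import MCMCSettings, ModelPosterior, ModelSpec, PriorSettings


def write_posterior(posterior: ModelPosterior, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, arr in posterior.draws.items():
        ch, dr = arr.shape[:2]
        rest = arr.shape[2:]
        flatrest = int(np.prod(rest)) if rest else 1
        a = arr.reshape(ch, dr, flatrest)
        idx = np.array(
            [np.unravel_index(k, rest) if rest else (0,) for k in range(flatrest)]
        )
        for k in range(flatrest):
            i0 = int(idx[k][0]) if rest else -1
            i1 = int(idx[k][1]) if len(rest) > 1 else -1
            df = pd.DataFrame(
                {
                    "chain": np.repeat(np.arange(ch), dr),
                    "draw": np.tile(np.arange(dr), ch),
                    "param": name,
                    "index0": i0,
                    "index1": i1,
                    "value": a[:, :, k].ravel(),
                }
            )
            rows.append(df)
    pd.concat(rows, ignore_index=True).to_parquet(out / "params.parquet")
    np.save(out / "latent_n.npy", posterior.latent_n)
    meta = {
        "variant": posterior.variant,
        "species": list(posterior.species),
        "sites": list(posterior.sites),
        "seed": int(posterior.seed),
        "spec": dataclasses.asdict(posterior.spec),
        "diagnostics": posterior.diagnostics.to_dict(orient="list"),
        "shapes": {k: list(v.shape) for k, v in posterior.draws.items()},
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def read_posterior(out_dir) -> ModelPosterior:
    out = Path(out_dir)
    meta = json.loads((out / "meta.json").read_text())
    df = pd.read_parquet(out / "params.parquet")
    draws = {}
    for name, shape in meta["shapes"].items():
        sub = df[df["param"] == name].sort_values(["index0", "index1", "chain", "draw"])
        arr = np.zeros(shape)
        ch, dr = shape[0], shape[1]
        rest = tuple(shape[2:])
        flatrest = int(np.prod(rest)) if rest else 1
        vals = sub["value"].to_numpy().reshape(flatrest, ch, dr)
        arr = np.moveaxis(vals.reshape(rest + (ch, dr)) if rest else vals[0],
                          (-2, -1), (0, 1)) if rest else vals[0]
        draws[name] = np.ascontiguousarray(arr)
    spec_d = dict(meta["spec"])
    spec_d["priors"] = PriorSettings(**spec_d["priors"])
    spec_d["mcmc"] = MCMCSettings(**spec_d["mcmc"])
    spec = ModelSpec(**spec_d)
    return ModelPosterior(
        draws=draws,
        latent_n=np.load(out / "latent_n.npy"),
        species=meta["species"],
        sites=meta["sites"],
        variant=meta["variant"],
        spec=spec,
        diagnostics=pd.DataFrame(meta["diagnostics"]),
        seed=meta["seed"],
    )
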