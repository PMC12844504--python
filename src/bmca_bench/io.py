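"""Tidy-CSV serialization for datasets, ground truth tables and posteriors."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ground_truth import ControlCoefficientSet
from .bmca_inference import PosteriorSamples
from .simulation import NormalizedDataset

__all__ = [
    "dataset_to_csv",
    "dataset_from_csv",
    "control_coefficients_to_csv",
    "save_posterior",
    "load_posterior",
]


def dataset_to_csv(ds: NormalizedDataset, path: str | Path) -> None:
    """Write a normalized dataset as tidy CSV plus a JSON sidecar.

    CSV columns: level, experiment, kind (v_hat/e_hat/chi/gamma), id, value.
    The sidecar (<path>.meta.json) carries reference values and exclusions.
    """
    path = Path(path)
    rows = []
    for kind, df in (
        ("v_hat", ds.v_hat), ("e_hat", ds.e_hat), ("chi", ds.chi), ("gamma", ds.gamma)
    ):
        tidy = df.stack().rename("value").reset_index()
        tidy.columns = ["experiment", "id", "value"]
        tidy.insert(0, "kind", kind)
        rows.append(tidy)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "level", ds.level)
    out.to_csv(path, index=False)
    meta = {
        "level": ds.level,
        "v_star": ds.v_star.to_dict(),
        "e_star": ds.e_star.to_dict(),
        "x_star": ds.x_star.to_dict(),
        "y_star": ds.y_star.to_dict(),
        "excluded": [list(e) for e in ds.excluded],
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def dataset_from_csv(path: str | Path) -> NormalizedDataset:
    path = Path(path)
    tidy = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    blocks = {}
    for kind in ("v_hat", "e_hat", "chi", "gamma"):
        sub = tidy[tidy["kind"] == kind]
        blocks[kind] = sub.pivot(index="experiment", columns="id", values="value")
    # restore the original experiment ordering (reference first)
    order = tidy["experiment"].drop_duplicates().tolist()
    blocks = {k: v.reindex(order).dropna(how="all") for k, v in blocks.items()}
    return NormalizedDataset(
        level=float(meta["level"]),
        v_hat=blocks["v_hat"],
        e_hat=blocks["e_hat"],
        chi=blocks["chi"],
        gamma=blocks["gamma"],
        v_star=pd.Series(meta["v_star"]),
        e_star=pd.Series(meta["e_star"]),
        x_star=pd.Series(meta["x_star"]),
        y_star=pd.Series(meta["y_star"]),
        excluded=tuple((e[0], e[1]) for e in meta["excluded"]),
    )


def control_coefficients_to_csv(cc: ControlCoefficientSet, path: str | Path) -> None:
    """Long-format CSV: coefficient, row id, column id, value (+HDI bounds)."""
    rows = []
    for name, df, lo, hi in (
        ("FCC", cc.CJ, cc.CJ_low, cc.CJ_high),
        ("CCC", cc.CS, cc.CS_low, cc.CS_high),
    ):
        tidy = df.stack().rename("value").reset_index()
        tidy.columns = ["row", "enzyme", "value"]
        tidy.insert(0, "coefficient", name)
        if lo is not None and hi is not None:
            tidy["hdi_low"] = lo.stack().values
            tidy["hdi_high"] = hi.stack().values
        tidy["provenance"] = cc.provenance
        rows.append(tidy)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def save_posterior(samples: PosteriorSamples, path: str | Path) -> None:
    """Persist draws + metadata as a self-describing npz/JSON pair."""
    path = Path(path)
    np.savez_compressed(path, **samples.draws)
    meta = {
        "method": samples.method,
        "seed": samples.seed,
        "coords": samples.coords,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def load_posterior(path: str | Path) -> PosteriorSamples:
    path = Path(path)
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as z:
        draws = {k: z[k] for k in z.files}
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return PosteriorSamples(
        draws=draws, coords=meta["coords"], method=meta["method"], seed=meta["seed"]
    )
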