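"""Flat-file I/O: Q-matrix and parameter CSVs, run manifests, test fixtures.

File conventions
----------------
Q-matrix CSV: header ``item,a1,...,aK``, one row per item, 0/1 cells.
Parameter CSV: DINA/DINO columns ``item,slip,guess``; R-RUM columns
``item,pistar,r1,...,rK`` with ``rk`` blank where the item does not measure
attribute k. Item identifiers are 1-based in files and 0-based internally.

All outputs are plain CSV/JSON so results diff cleanly under version
control.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cdm_core import ItemParameters, Model, QMatrix
from .class_distance import StackedDistanceMatrix

__all__ = [
    "read_qmatrix",
    "write_qmatrix",
    "read_parameters",
    "write_parameters",
    "write_distances",
    "write_selection",
    "RunManifest",
    "make_fixture",
]

#: Generating range of slip/guess parameters; values outside it are accepted
#: with a warning (they are legal probabilities, just unusual).
SLIP_GUESS_RANGE = (0.05, 0.4)


def read_qmatrix(path) -> QMatrix:
    """Read and validate a Q-matrix CSV (header ``item,a1,...,aK``)."""
    df = pd.read_csv(path)
    if df.columns[0] != "item":
        raise ValueError(f"first column must be 'item', got {df.columns[0]!r}")
    cells = df.iloc[:, 1:].to_numpy()
    bad = np.argwhere(~np.isin(cells, (0, 1)))
    if bad.size:
        i, k = bad[0]
        raise ValueError(
            f"non-binary Q cell {cells[i, k]!r} at item {df['item'].iloc[i]}, "
            f"column {df.columns[k + 1]}"
        )
    return QMatrix(cells)


def write_qmatrix(q: QMatrix, path) -> None:
    cols = {"item": np.arange(1, q.n_items + 1)}
    for k in range(q.n_attributes):
        cols[f"a{k + 1}"] = q.entries[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_parameters(path, model: Model | str) -> ItemParameters:
    """Read a model-specific item-parameter CSV, validating ranges."""
    model = Model.coerce(model)
    df = pd.read_csv(path)
    if model in (Model.DINA, Model.DINO):
        missing = {"item", "slip", "guess"} - set(df.columns)
        if missing:
            raise ValueError(f"{model.value} parameter file missing columns {sorted(missing)}")
        slip = df["slip"].to_numpy(float)
        guess = df["guess"].to_numpy(float)
        for name, v in (("slip", slip), ("guess", guess)):
            lo, hi = SLIP_GUESS_RANGE
            out = (v < lo) | (v > hi)
            if out.any():
                j = int(np.argmax(out))
                warnings.warn(
                    f"{name}={v[j]:.3f} for item {df['item'].iloc[j]} is outside "
                    f"the usual generating range U{SLIP_GUESS_RANGE}",
                    stacklevel=2,
                )
        return ItemParameters(model=model, slip=slip, guess=guess)
    if "pistar" not in df.columns:
        raise ValueError("RRUM parameter file missing 'pistar' column")
    rcols = [c for c in df.columns if c.startswith("r") and c[1:].isdigit()]
    rcols.sort(key=lambda c: int(c[1:]))
    penalty = df[rcols].to_numpy(float)
    return ItemParameters(model=model, baseline=df["pistar"].to_numpy(float),
                          penalty=penalty)


def write_parameters(params: ItemParameters, path) -> None:
    items = np.arange(1, params.n_items + 1)
    if params.model in (Model.DINA, Model.DINO):
        df = pd.DataFrame({"item": items, "slip": params.slip, "guess": params.guess})
    else:
        cols = {"item": items, "pistar": params.baseline}
        for k in range(params.penalty.shape[1]):
            cols[f"r{k + 1}"] = params.penalty[:, k]
        df = pd.DataFrame(cols)
    df.to_csv(path, index=False)


def validate_parameters_against_q(params: ItemParameters, q: QMatrix) -> None:
    """Check R-RUM penalties exist exactly where the Q-matrix requires them."""
    if params.model is not Model.RRUM:
        return
    need = q.entries == 1
    absent = np.isnan(params.penalty)
    missing = need & absent
    if missing.any():
        j, k = np.argwhere(missing)[0]
        raise ValueError(f"missing R-RUM penalty for item {j + 1}, attribute {k + 1}")
    extra = ~need & ~absent
    if extra.any():
        warnings.warn(
            "R-RUM penalties present for unmeasured attributes are ignored",
            stacklevel=2,
        )


def write_distances(V: StackedDistanceMatrix, path, space=None) -> None:
    """Export a stacked distance matrix as CSV (pair_u, pair_v, item_1..)."""
    pairs = V.index.pairs
    cols: dict = {"pair_u": pairs[:, 0], "pair_v": pairs[:, 1]}
    if space is not None:
        bits = space.bitstrings()
        cols["pattern_u"] = [bits[u] for u in pairs[:, 0]]
        cols["pattern_v"] = [bits[v] for v in pairs[:, 1]]
    for j in range(V.n_items):
        cols[f"item_{j + 1}"] = V.V[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_selection(solution, q: QMatrix, path) -> None:
    """Write an assembly solution as JSON (1-based item ids, audit info)."""
    items = solution.items
    sub_q = q.entries[items]
    payload = {
        "method": solution.method.value,
        "status": solution.status.value,
        "items": (items + 1).tolist(),
        "objective": None if np.isnan(solution.objective) else solution.objective,
        "y": None if np.isnan(solution.y) else solution.y,
        "per_attribute_coverage": sub_q.sum(axis=0).tolist(),
        "per_stratum_counts": {
            int(a): int((sub_q.sum(axis=1) == a).sum())
            for a in np.unique(sub_q.sum(axis=1))
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    seed: int | None
    config: dict
    artifacts: list[str]
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def make_fixture(name: str, seed: int = 0):
    """Deterministic toy objects used by the test suite and examples.

    - ``milp-oracle-6x2``: a 6-item, 2-attribute DINA bank small enough for
      exhaustive subset enumeration against the MILP.
    - ``pairs-k3``: the 3-attribute class space whose simplified pair set
      has 24 ordered pairs.
    - ``eq5-coefficients``: a 2x2 distance matrix with hand-computed
      objective coefficients.
    """
    from .cdm_core import enumerate_latent_classes

    if name == "milp-oracle-6x2":
        rng = np.random.default_rng(seed)
        from .sim_eval import generate_item_bank

        return generate_item_bank(6, 2, Model.DINA, rng)
    if name == "pairs-k3":
        from .class_distance import minimal_pairs

        return minimal_pairs(enumerate_latent_classes(3))
    if name == "eq5-coefficients":
        V = np.array([[1.0, 3.0], [2.0, 1.0]])
        return {
            "V": V,
            "J": 1,
            "f1": np.array([-1.5, -2.0]),
            "f2": 1.75,
            "b": np.array([2.0, 1.5]),
        }
    raise KeyError(f"unknown fixture {name!r}")
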