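"""Auto-Contractive Map: variable encoding and contractive training.

The Auto-Contractive Map (Auto-CM) is a three-layer connectionist data
mining method that learns a many-to-many association structure among
variables. All weights start from one identical value and contract toward
a positive constant ``C`` during training, so the procedure is fully
deterministic: identical data and hyperparameters give bit-identical
weights on every run.

For an input pattern ``m^s`` (one record, entries in [0, 1]) the forward
pass is

    hidden    m^h_i = m^s_i * (1 - v_i / C)
    net input Net_i = sum_j m^h_j * (1 - w_ij / C)
    output    m^t_i = m^h_i * (1 - Net_i / C)

and the contractive updates, accumulated as a batch mean over the records
of an epoch and applied with learning rate ``lr``, are

    dv_i   = (m^s_i - m^h_i) * (1 - v_i / C)
    dw_ij  = (m^h_i - m^t_i) * (1 - w_ij / C) * m^h_j

Both deltas are non-negative, so weights grow monotonically, and the
``(1 - w/C)`` factor keeps them strictly below ``C`` for any learning rate
with ``lr * max_update < C``. Pairs of variables that co-activate often
accumulate weight fastest; the final hidden-to-output weights, scaled by
``C``, are read as connection strengths in [0, 1] and converted to
distances ``d = 1 - s`` for the spanning-tree filter.

The cohort enters as a binary "map variable" matrix: every dichotomous
attribute contributes a complementary pair of dummy columns (hyposmic and
normosmic poles, obesity and overweight, and so on), so each pair sums to
one on every record and both poles appear as nodes of the final map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, StateError

DEFAULT_AGE_CUTOFF = 55.0

#: (positive label, negative label, profile column, truthy value) in map order.
_PAIR_SPECS = [
    ("Hypo-TDI", "Norm-TDI", "class_tdi", "hyposmic"),
    ("Hypo-T", "Norm-T", "class_t", "hyposmic"),
    ("Hypo-D", "Norm-D", "class_d", "hyposmic"),
    ("Hypo-I", "Norm-I", "class_i", "hyposmic"),
    ("OW", "Ob", "bmi_class", "overweight"),
    ("High BP", "Norm BP", "high_bp", True),
    ("High Gly", "Norm Gly", "high_gly", True),
    ("High TG", "Norm TG", "high_tg", True),
    ("Low HDL", "Norm HDL", "low_hdl", True),
    ("MS", "no-MS", "mets", True),
    ("High MDS", "Low MDS", "mds_high", True),
    ("F", "M", "sex", "F"),
]


@dataclass
class BinaryDataset:
    """Records x map-variable matrix with entries in [0, 1]."""

    variable_names: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.variable_names):
            raise ParameterError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.variable_names)} variable names"
            )
        if self.matrix.size and (
            self.matrix.min() < 0 or self.matrix.max() > 1
        ):
            raise ParameterError("matrix entries must lie in [0, 1]")

    @property
    def n_records(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.variable_names)


def encode_variables(
    profiles: pd.DataFrame, age_cutoff: float = DEFAULT_AGE_CUTOFF
) -> BinaryDataset:
    """Encode a classified cohort into the complementary dummy matrix.

    ``profiles`` must hold one row per record with the classification
    columns produced by the pipeline (``class_tdi`` .. ``class_i``,
    ``bmi_class``, the metabolic flags, ``mds_high``, ``sex``, ``age``,
    ``smoker``). Age is dichotomized at ``age_cutoff`` into the
    older/young pair. Any missing value raises a :class:`DataError`
    naming the record and field. An empty cohort yields an empty matrix
    with the full header.
    """
    names: list[str] = []
    for pos, neg, _, _ in _PAIR_SPECS:
        names += [pos, neg]
    names += ["older age", "young age", "smoker", "non-smoker"]

    n = len(profiles)
    matrix = np.zeros((n, len(names)), dtype=float)
    if n == 0:
        return BinaryDataset(names, matrix)

    ids = (
        profiles["id"].tolist()
        if "id" in profiles.columns
        else [str(ix) for ix in profiles.index]
    )

    def column(col: str) -> pd.Series:
        if col not in profiles.columns:
            raise DataError(f"profiles table lacks required column {col!r}")
        ser = profiles[col]
        if ser.isna().any():
            bad = ids[int(np.flatnonzero(ser.isna().to_numpy())[0])]
            raise DataError(f"record {bad!r} is unclassified in field {col!r}")
        return ser

    j = 0
    for pos, neg, col, truthy in _PAIR_SPECS:
        hit = (column(col) == truthy).to_numpy()
        matrix[:, j] = hit
        matrix[:, j + 1] = ~hit
        j += 2
    older = (column("age").to_numpy(dtype=float) >= age_cutoff)
    matrix[:, j] = older
    matrix[:, j + 1] = ~older
    smoker = column("smoker").to_numpy(dtype=bool)
    matrix[:, j + 2] = smoker
    matrix[:, j + 3] = ~smoker
    return BinaryDataset(names, matrix)


@dataclass
class AutoCMModel:
    """Trained Auto-CM: contraction constant and final weight layers."""

    C: float
    v: np.ndarray                  # (k,) input -> hidden weights
    w: np.ndarray                  # (k, k) hidden -> output weights
    epochs_run: int
    converged: bool
    variable_names: list[str]
    history: dict = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return self.epochs_run > 0


def train_autocm(
    data: BinaryDataset,
    C: float = 1.0,
    lr: float = 0.01,
    max_epochs: int = 1000,
    tol: float = 1e-6,
    init_fraction: float = 0.01,
) -> AutoCMModel:
    """Train the Auto-CM on a binary dataset.

    All weights start at ``init_fraction * C``. Each epoch computes the
    forward pass for every record with the current weights, averages the
    contractive deltas over records, and applies them once (batch
    accumulation in fixed input order). Training stops when the mean output
    magnitude falls below ``tol`` — the contracted state in which the
    network reproduces nothing of its input — or when the weight updates
    themselves become smaller than ``tol`` (stationary weights), whichever
    comes first; otherwise at ``max_epochs``. The ``converged`` flag
    reflects either criterion. No randomness enters anywhere.
    """
    if C <= 0:
        raise ParameterError(f"contraction constant C must be positive, got {C}")
    if data.n_records < 1 or data.n_variables < 2:
        raise ParameterError(
            "training needs at least 1 record and 2 variables, got "
            f"{data.n_records} x {data.n_variables}"
        )
    if not (0 < lr):
        raise ParameterError("learning rate must be positive")

    X = data.matrix
    n, k = X.shape
    v = np.full(k, init_fraction * C, dtype=float)
    w = np.full((k, k), init_fraction * C, dtype=float)
    history: dict = {"mean_output": [], "max_w": [], "max_v": []}
    converged = False
    epoch = 0

    for epoch in range(1, max_epochs + 1):
        Mh = X * (1.0 - v / C)                     # (n, k)
        Net = Mh @ (1.0 - w / C).T                 # Net[r, i] = sum_j Mh[r, j] (1 - w_ij/C)
        Mt = Mh * (1.0 - Net / C)
        dv = ((X - Mh) * (1.0 - v / C)).mean(axis=0)
        dw = (1.0 - w / C) * ((Mh - Mt).T @ Mh) / n
        v += lr * dv
        w += lr * dw
        # the contractive factors guarantee v, w < C; guard against any
        # numerically pathological hyperparameter choice
        np.clip(v, 0.0, C * (1 - 1e-12), out=v)
        np.clip(w, 0.0, C * (1 - 1e-12), out=w)

        mean_out = float(np.abs(Mt).mean())
        history["mean_output"].append(mean_out)
        history["max_w"].append(float(w.max()))
        history["max_v"].append(float(v.max()))
        if mean_out < tol or lr * max(
            float(np.abs(dv).max()), float(np.abs(dw).max())
        ) < tol:
            converged = True
            break

    return AutoCMModel(
        C=C,
        v=v,
        w=w,
        epochs_run=epoch,
        converged=converged,
        variable_names=list(data.variable_names),
        history=history,
    )


def connection_strengths(model: AutoCMModel) -> np.ndarray:
    """Symmetric connection-strength matrix in [0, 1].

    ``s_ij = (w_ij + w_ji) / (2 C)``; the diagonal is zeroed (self-links
    are not map edges).
    """
    if not model.trained:
        raise StateError("model has not been trained")
    s = (model.w + model.w.T) / (2.0 * model.C)
    np.fill_diagonal(s, 0.0)
    return np.clip(s, 0.0, 1.0)


def distance_matrix(model: AutoCMModel) -> np.ndarray:
    """Distances ``d = 1 - s``: strongly connected variables sit close."""
    if not model.trained:
        raise StateError("model has not been trained")
    d = 1.0 - connection_strengths(model)
    np.fill_diagonal(d, 0.0)
    return d


def strengths_frame(model: AutoCMModel) -> pd.DataFrame:
    """Connection strengths as a labelled square DataFrame (CSV-ready)."""
    return pd.DataFrame(
        connection_strengths(model),
        index=model.variable_names,
        columns=model.variable_names,
    )
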