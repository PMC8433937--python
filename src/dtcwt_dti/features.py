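"""Fixed-length protein descriptors from the dual-tree transform of a PSSM.

The transform of a P x 20 profile yields subbands whose sizes grow with
P, but the classifier needs one fixed-length vector per protein.  The
convention implemented here pools subband *magnitudes* onto fixed grids:

* each of the 12 oriented high-pass subbands (2 levels x 6 orientations)
  is adaptive-average-pooled to a 4 x 5 grid  -> 12 x 20 = 240 features;
* the four level-2 low-pass images are averaged into one, divided by
  2**J (so a constant profile of value c maps to low-pass features ~ c),
  column-averaged and pooled to 16 row bins                -> 16 features.

Concatenated in level-then-orientation order (+15, +45, +75, -15, -45,
-75; level 1 first, row-major pools) followed by the 16 low-pass bins,
this gives exactly 256 values for any protein length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pssm import PSSM
from .transform import ORIENTATIONS, dtcwt2d
from .filters import FilterBank

__all__ = [
    "N_FEATURES", "ProteinFeatures", "adaptive_avg_pool2d", "extract_features",
    "extract_feature_table", "write_feature_table", "read_feature_table",
]

N_FEATURES = 256
_HIGH_POOL = (4, 5)
_LOW_BINS = 16


@dataclass
class ProteinFeatures:
    protein_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        self.vector = v


def adaptive_avg_pool2d(a: np.ndarray, out_rows: int, out_cols: int) -> np.ndarray:
    """Average-pool ``a`` onto an ``out_rows x out_cols`` grid.

    Bin i covers input rows [floor(i*R/O), ceil((i+1)*R/O)); bins tile the
    input completely whatever its size, so the output shape never depends
    on the input shape.
    """
    a = np.asarray(a, dtype=float)
    R, C = a.shape
    if R < 1 or C < 1:
        raise ValueError("cannot pool an empty array")
    out = np.empty((out_rows, out_cols))
    r_lo = [int(np.floor(i * R / out_rows)) for i in range(out_rows)]
    r_hi = [int(np.ceil((i + 1) * R / out_rows)) for i in range(out_rows)]
    c_lo = [int(np.floor(j * C / out_cols)) for j in range(out_cols)]
    c_hi = [int(np.ceil((j + 1) * C / out_cols)) for j in range(out_cols)]
    for i in range(out_rows):
        for j in range(out_cols):
            out[i, j] = a[r_lo[i]:r_hi[i], c_lo[j]:c_hi[j]].mean()
    return out


def _prepare_matrix(p: PSSM, levels: int) -> np.ndarray:
    m = np.asarray(p.matrix, dtype=float)
    if m.shape[0] < 8:           # very short peptides: reflect rows up to 8
        m = np.pad(m, ((0, 8 - m.shape[0]), (0, 0)), mode="symmetric")
    block = 2 ** levels
    pad = (-m.shape[0]) % block  # reflect rows to the next multiple of 2**J
    if pad:
        m = np.pad(m, ((0, pad), (0, 0)), mode="symmetric")
    return m


def extract_features(p: PSSM, levels: int = 2, normalize: str = "none",
                     filters: FilterBank | None = None) -> ProteinFeatures:
    """Compute the 256-dimensional descriptor of one protein profile."""
    m = _prepare_matrix(p.normalized(normalize), levels)
    res = dtcwt2d(m, levels=levels, filters=filters)
    parts: list[np.ndarray] = []
    for level in range(levels):
        for orientation in ORIENTATIONS:
            mag = np.abs(res.highpass[level][orientation])
            parts.append(adaptive_avg_pool2d(mag, *_HIGH_POOL).ravel())
    low = res.lowpass_mean() / (2 ** levels)
    parts.append(adaptive_avg_pool2d(low.mean(axis=1, keepdims=True), _LOW_BINS, 1).ravel())
    vector = np.concatenate(parts)
    return ProteinFeatures(protein_id=p.protein_id, vector=vector)


def extract_feature_table(pssms: dict[str, PSSM], levels: int = 2,
                          normalize: str = "none") -> dict[str, ProteinFeatures]:
    return {pid: extract_features(p, levels=levels, normalize=normalize)
            for pid, p in pssms.items()}


def write_feature_table(features: dict[str, ProteinFeatures], path: str | Path) -> None:
    cols = [f"f{i + 1:03d}" for i in range(N_FEATURES)]
    df = pd.DataFrame({pid: f.vector for pid, f in features.items()}).T
    df.columns = cols
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_feature_table(path: str | Path) -> dict[str, ProteinFeatures]:
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    if df.shape[1] != N_FEATURES:
        raise ValueError(f"feature table must have {N_FEATURES} columns, found {df.shape[1]}")
    return {str(pid): ProteinFeatures(str(pid), row.to_numpy(dtype=float))
            for pid, row in df.iterrows()}
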