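"""Fiber- and time-series-based connectivity features.

Fiber connectivity between a region pair (i, j):

* NFC — fiber-count connectivity: fibers incident on both regions divided
  by fibers incident on either (a Jaccard fraction in [0, 1]);
* FAC — FA connectivity: the unweighted mean over connecting fibers of
  each fiber's mean voxel fractional anisotropy.

"Passing through or connecting" a region is represented as plain region
incidence per fiber (endpoints and traversals are not distinguished).

Resting-state connectivity is the Pearson correlation matrix of the
per-region time series.  Hemispheric Δ features subtract a homologous
right-hemisphere edge from its left counterpart; the lateralization
feature vector (F4–F6) and categorization vector (F1–F3) for the margin
classifiers are assembled from named edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Fiber:
    """One streamline: region incidence plus per-voxel FA samples."""

    regions_traversed: frozenset
    fa_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0 <= fa <= 1 for fa in self.fa_values):
            raise ValueError("FA values must lie in [0, 1]")

    @property
    def mean_fa(self) -> float:
        if not self.fa_values:
            raise ValueError("fiber without FA samples")
        return float(np.mean(self.fa_values))


@dataclass
class FiberSet:
    """Fibers plus the region inventory they are allowed to touch."""

    fibers: list[Fiber]
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        known = set(self.regions)
        for k, fiber in enumerate(self.fibers):
            unknown = set(fiber.regions_traversed) - known
            if unknown:
                raise ValueError(
                    f"fiber {k} touches unknown regions {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.fibers)


def make_fiber(regions, fa_values) -> Fiber:
    return Fiber(regions_traversed=frozenset(regions),
                 fa_values=tuple(float(v) for v in fa_values))


def nfc(fs: FiberSet, i, j) -> float | None:
    """Fiber-count connectivity of regions *i*, *j* in [0, 1].

    ``None`` (missing) when no fiber touches either region.
    """
    both = either = 0
    for fiber in fs.fibers:
        hit_i = i in fiber.regions_traversed
        hit_j = j in fiber.regions_traversed
        if hit_i or hit_j:
            either += 1
            if hit_i and hit_j:
                both += 1
    if either == 0:
        return None
    return both / either


def fac(fs: FiberSet, i, j) -> float | None:
    """Mean fiber FA over fibers connecting *i* and *j* (``None`` if none)."""
    means = [fiber.mean_fa for fiber in fs.fibers
             if i in fiber.regions_traversed and j in fiber.regions_traversed]
    if not means:
        return None
    return float(np.mean(means))


def fiber_connectivity_matrix(fs: FiberSet, kind: str = "NFC",
                              ) -> pd.DataFrame:
    """Region×region symmetric matrix of NFC or FAC values (NaN = missing)."""
    func = {"NFC": nfc, "FAC": fac}[kind]
    n = len(fs.regions)
    values = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a, n):
            v = func(fs, fs.regions[a], fs.regions[b])
            if v is not None:
                values[a, b] = values[b, a] = v
    return pd.DataFrame(values, index=fs.regions, columns=fs.regions)


def pearson_connectivity(ts: pd.DataFrame | np.ndarray,
                         regions: tuple[str, ...] | None = None,
                         ) -> pd.DataFrame:
    """Pearson correlation matrix of region time series.

    *ts* is region × time.  Needs at least 3 time points; constant series
    get NaN rows/columns (unit diagonal preserved).
    """
    if isinstance(ts, pd.DataFrame):
        regions = tuple(ts.index)
        data = ts.to_numpy(dtype=float)
    else:
        data = np.asarray(ts, dtype=float)
        if regions is None:
            regions = tuple(f"region_{k}" for k in range(data.shape[0]))
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("need a region x time matrix with >=3 time points")
    constant = data.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=regions, columns=regions)


# ---------------------------------------------------------------------------
# hemispheric differences and feature assembly

def _edge(cm: pd.DataFrame, i: str, j: str) -> float | None:
    if i not in cm.index or j not in cm.columns:
        return None
    v = cm.loc[i, j]
    return None if pd.isna(v) else float(v)


def hemispheric_delta(cm: pd.DataFrame, i: str, j: str,
                      left_prefix: str = "left_",
                      right_prefix: str = "right_") -> float | None:
    """Δ(i, j) = value(left i, left j) − value(right i, right j).

    *i*, *j* are unprefixed region names; ``None`` when either homologous
    edge is missing.
    """
    left = _edge(cm, left_prefix + i, left_prefix + j)
    right = _edge(cm, right_prefix + i, right_prefix + j)
    if left is None or right is None:
        return None
    return left - right


#: named edges of the printed feature vectors; categorization features are
#: single left-hemisphere edges, lateralization features are hemispheric Δs
CATEGORIZATION_EDGES = {
    "F1": ("FAC", "parietal_superior_gyrus", "parietal_superior_gyrus"),
    "F2": ("NFC", "ventral_dc", "marginal_cingulate_sulcus"),
    "F3": ("NFC", "hippocampus", "ventral_dc"),
}
LATERALIZATION_EDGES = {
    "F4": ("NFC", "hippocampus", "hippocampus"),
    "F5": ("FAC", "amygdala", "lateral_superior_temporal_gyrus"),
    "F6": ("FAC", "putamen", "inferior_temporal_sulcus"),
}


@dataclass
class FeatureVector:
    """Printed connectivity features for the margin classifiers."""

    values: dict[str, float | None] = field(default_factory=dict)

    def as_array(self, names) -> np.ndarray:
        return np.array([np.nan if self.values.get(n) is None
                         else self.values[n] for n in names], dtype=float)

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(n for n, v in self.values.items() if v is None)


def _overall_or_none(cm: pd.DataFrame, region: str) -> float | None:
    if region not in cm.index:
        return None
    return overall_connectivity(cm, region)


def assemble_features(matrices: dict[str, pd.DataFrame]) -> FeatureVector:
    """Build F1–F6 from NFC/FAC matrices with left_/right_ prefixed regions.

    F1–F3 (categorization) are left-hemisphere values; F4–F6
    (lateralization) are left-minus-right differences of homologous values.
    A feature naming a single region (F1, F4) is that region's overall
    connectivity (row sum); a feature naming a pair is the edge value.
    Features whose regions or edges are absent come out ``None``.
    """
    out: dict[str, float | None] = {}
    for name, (kind, i, j) in CATEGORIZATION_EDGES.items():
        cm = matrices.get(kind)
        if cm is None:
            out[name] = None
        elif i == j:
            out[name] = _overall_or_none(cm, "left_" + i)
        else:
            out[name] = _edge(cm, "left_" + i, "left_" + j)
    for name, (kind, i, j) in LATERALIZATION_EDGES.items():
        cm = matrices.get(kind)
        if cm is None:
            out[name] = None
        elif i == j:
            left = _overall_or_none(cm, "left_" + i)
            right = _overall_or_none(cm, "right_" + i)
            out[name] = None if left is None or right is None \
                else left - right
        else:
            out[name] = hemispheric_delta(cm, i, j)
    return FeatureVector(values=out)


def overall_connectivity(cm: pd.DataFrame, region: str) -> float:
    """Summed connectivity of one region to all others (row sum, no diag)."""
    if region not in cm.index:
        raise KeyError(region)
    row = cm.loc[region].drop(labels=[region])
    return float(row.sum(skipna=True))


# ---------------------------------------------------------------------------
# line-oriented text format for fiber sets

def write_fiber_set(fs: FiberSet, path: str | Path) -> None:
    """One header line with the region inventory, then one fiber per line:
    ``region,region,...|fa fa fa``."""
    with open(path, "w") as fh:
        fh.write("# regions: " + ",".join(fs.regions) + "\n")
        for fiber in fs.fibers:
            regions = ",".join(sorted(fiber.regions_traversed))
            fas = " ".join(f"{v:.6g}" for v in fiber.fa_values)
            fh.write(f"{regions}|{fas}\n")


def read_fiber_set(path: str | Path) -> FiberSet:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# regions:"):
            raise ValueError("fiber-set file lacks a region header")
        regions = tuple(r for r in header.split(":", 1)[1].strip().split(",")
                        if r)
        fibers = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            region_part, _, fa_part = line.partition("|")
            fibers.append(make_fiber(
                region_part.split(","),
                [float(v) for v in fa_part.split()] if fa_part else []))
    return FiberSet(fibers=fibers, regions=regions)
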