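"""Per-modality asymmetry features from labeled intensity volumes.

A :class:`LabeledVolume` couples a 3-D intensity grid (T1 in arbitrary
units, FLAIR in arbitrary units, or PET in SUV units) with an integer ROI
label map on the same grid, the voxel spacing in mm, and the grid axis that
runs anterior→posterior (coronal slices are fixed indices along it).

Features computed here:

* normalized hippocampal volumes f1/f2 — each hippocampal volume as a
  percentage of total brain volume;
* FLAIR intensity ratios f3/f4 — left/right ratios of the hippocampal
  FLAIR mean and standard deviation, restricted to an anterior–posterior
  slice range supplied by the caller (landmark detection is upstream);
* tristructural asymmetries — 100(vL − vR)/(vL + vR) for hippocampus,
  amygdala and thalamus;
* the PET hypometabolism-asymmetry (HA) profile — per coronal slice, a
  Welch two-sample test on the left vs right hippocampal SUV samples; when
  the side means differ significantly the slice's HA is the relative SUV
  deficit, negative when the left side is hypometabolic:
  ``HA = (SUVl − SUVr)/SUVr`` if left < right, ``(SUVl − SUVr)/SUVl`` if
  right < left, and 0 when not significant, so HA ∈ [−1, 1].

An empty required ROI raises :class:`SegmentationFailure`, the condition
recorded as ``F`` in cohort tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import decisions as dec

# canonical structure names used in label keys
HIPP_L, HIPP_R = "hippocampus_left", "hippocampus_right"
AMYG_L, AMYG_R = "amygdala_left", "amygdala_right"
THAL_L, THAL_R = "thalamus_left", "thalamus_right"
BRAIN = "brain"


class SegmentationFailure(ValueError):
    """A required ROI is empty or unusable; tabulated as ``F``."""


@dataclass
class LabeledVolume:
    """3-D intensity grid with ROI labels, spacing and axis convention."""

    intensities: np.ndarray            # float, shape (i, j, k)
    labels: np.ndarray                 # int, same shape
    spacing: tuple[float, float, float]
    label_key: dict[int, str]          # label value -> structure name
    ap_axis: int = 1                   # grid axis running anterior->posterior

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.intensities.shape != self.labels.shape:
            raise ValueError("intensity and label grids differ in shape")
        if self.intensities.ndim != 3:
            raise ValueError("expected a 3-D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not 0 <= self.ap_axis <= 2:
            raise ValueError("ap_axis must be 0, 1 or 2")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.label_key)
        if unknown:
            raise ValueError(f"labels without a key entry: {sorted(unknown)}")

    @property
    def voxel_volume(self) -> float:
        """mm³ per voxel (product of spacings; no partial-volume model)."""
        return float(np.prod(self.spacing))

    def _label_value(self, structure: str) -> int:
        for value, name in self.label_key.items():
            if name == structure:
                return value
        raise KeyError(f"no label for structure {structure!r}")

    def mask(self, structure: str) -> np.ndarray:
        return self.labels == self._label_value(structure)

    def roi_values(self, structure: str) -> np.ndarray:
        return self.intensities[self.mask(structure)]

    def roi_voxel_count(self, structure: str) -> int:
        return int(self.mask(structure).sum())

    def roi_volume(self, structure: str) -> float:
        """ROI volume in mm³."""
        return self.roi_voxel_count(structure) * self.voxel_volume

    def mirrored(self) -> "LabeledVolume":
        """Left↔right reflected copy (for symmetry checks).

        Flips the grids along the left–right axis (the first non-AP axis)
        and swaps ``_left``/``_right`` in the label key.
        """
        lr_axis = 0 if self.ap_axis != 0 else 1
        swap = {}
        for value, name in self.label_key.items():
            if name.endswith("_left"):
                swap[value] = name[:-5] + "_right"
            elif name.endswith("_right"):
                swap[value] = name[:-6] + "_left"
            else:
                swap[value] = name
        return LabeledVolume(
            intensities=np.flip(self.intensities, axis=lr_axis).copy(),
            labels=np.flip(self.labels, axis=lr_axis).copy(),
            spacing=self.spacing, label_key=swap, ap_axis=self.ap_axis)


def _require_nonempty(vol: LabeledVolume, structure: str) -> None:
    if vol.roi_voxel_count(structure) == 0:
        raise SegmentationFailure(f"empty ROI: {structure}")


def normalized_hippocampal_volumes(vol: LabeledVolume) -> tuple[float, float]:
    """(f1, f2): left/right hippocampal volume as % of brain volume.

    The brain volume is the volume of all labeled voxels (the brain-mask
    label plus the structure labels carved out of it).
    """
    for s in (HIPP_L, HIPP_R, BRAIN):
        _require_nonempty(vol, s)
    brain = int(np.count_nonzero(vol.labels)) * vol.voxel_volume
    f1 = vol.roi_volume(HIPP_L) / brain * 100.0
    f2 = vol.roi_volume(HIPP_R) / brain * 100.0
    return f1, f2


def _bounded_roi_values(vol: LabeledVolume, structure: str,
                        ap_bounds: tuple[int, int] | None) -> np.ndarray:
    mask = vol.mask(structure)
    if ap_bounds is not None:
        lo, hi = ap_bounds
        keep = np.zeros_like(mask)
        index = [slice(None)] * 3
        index[vol.ap_axis] = slice(lo, hi)
        keep[tuple(index)] = True
        mask = mask & keep
    return vol.intensities[mask]


def flair_intensity_ratios(flair: LabeledVolume,
                           ap_bounds: tuple[int, int] | None = None,
                           ) -> tuple[float, float]:
    """(f3, f4): left/right ratios of hippocampal FLAIR mean and SD.

    *ap_bounds* is a half-open coronal slice range ``(lo, hi)`` standing in
    for the anatomical anterior/posterior boundary planes.
    """
    left = _bounded_roi_values(flair, HIPP_L, ap_bounds)
    right = _bounded_roi_values(flair, HIPP_R, ap_bounds)
    if left.size == 0 or right.size == 0:
        raise SegmentationFailure("empty hippocampal ROI within bounds")
    right_sd = right.std(ddof=0)
    if right_sd == 0:
        raise ValueError("right hippocampal FLAIR SD is zero; f4 undefined")
    f3 = float(left.mean() / right.mean())
    f4 = float(left.std(ddof=0) / right_sd)
    return f3, f4


@dataclass(frozen=True)
class TristructuralAsymmetry:
    """Normalized volume asymmetries 100(vL − vR)/(vL + vR)."""

    a_hipp: float
    a_amyg: float
    a_thal: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a_hipp, self.a_amyg, self.a_thal])


def _normalized_asymmetry(v_left: float, v_right: float) -> float:
    return 100.0 * (v_left - v_right) / (v_left + v_right)


def tristructural_asymmetries(vol: LabeledVolume) -> TristructuralAsymmetry:
    """Hippocampal, amygdalar and thalamic normalized volume asymmetries."""
    pairs = ((HIPP_L, HIPP_R), (AMYG_L, AMYG_R), (THAL_L, THAL_R))
    values = []
    for left, right in pairs:
        _require_nonempty(vol, left)
        _require_nonempty(vol, right)
        values.append(_normalized_asymmetry(vol.roi_volume(left),
                                            vol.roi_volume(right)))
    return TristructuralAsymmetry(*values)


def suv_slice_profile(suv: LabeledVolume,
                      ap_bounds: tuple[int, int] | None = None,
                      ) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Per-coronal-slice hippocampal SUV samples.

    Returns ``(slice_index, left_samples, right_samples)`` for every
    coronal slice (within *ap_bounds*, half-open) where both hippocampal
    ROIs are present; slices with only one side are excluded.
    """
    left_mask = suv.mask(HIPP_L)
    right_mask = suv.mask(HIPP_R)
    n_slices = suv.intensities.shape[suv.ap_axis]
    lo, hi = ap_bounds if ap_bounds is not None else (0, n_slices)
    out = []
    for idx in range(max(lo, 0), min(hi, n_slices)):
        sl = [slice(None)] * 3
        sl[suv.ap_axis] = idx
        sl = tuple(sl)
        lvals = suv.intensities[sl][left_mask[sl]]
        rvals = suv.intensities[sl][right_mask[sl]]
        if lvals.size and rvals.size:
            out.append((idx, lvals, rvals))
    if not out:
        raise SegmentationFailure(
            "no coronal slice with both hippocampal ROIs present")
    return out


@dataclass(frozen=True)
class HASlice:
    slice_index: int
    ha: float
    p_value: float
    n_left: int
    n_right: int


@dataclass
class HAProfile:
    """Per-slice hypometabolism asymmetry plus a scalar summary."""

    slices: list[HASlice]
    summary: float
    alpha: float = 0.05

    def ha_values(self) -> np.ndarray:
        return np.array([s.ha for s in self.slices])


def _slice_ha(left: np.ndarray, right: np.ndarray, alpha: float,
              ) -> tuple[float, float]:
    """HA and Welch p-value for one slice's SUV samples."""
    lmean, rmean = float(left.mean()), float(right.mean())
    if left.std(ddof=1) == 0 and right.std(ddof=1) == 0:
        # degenerate variances: identical means carry no evidence either way
        if lmean == rmean:
            return 0.0, 1.0
        p = 0.0
    else:
        p = float(stats.ttest_ind(left, right, equal_var=False).pvalue)
    if p >= alpha or lmean == rmean:
        return 0.0, p
    if lmean < rmean:
        return (lmean - rmean) / rmean, p
    return (lmean - rmean) / lmean, p


def hypometabolism_asymmetry(
        samples: list[tuple[int, np.ndarray, np.ndarray]],
        alpha: float = 0.05) -> HAProfile:
    """HA profile from per-slice left/right SUV samples.

    Each slice needs at least two voxels per side for the Welch test.
    """
    if not samples:
        raise ValueError("empty SUV slice profile")
    slices = []
    for idx, left, right in samples:
        left = np.asarray(left, dtype=float)
        right = np.asarray(right, dtype=float)
        if left.size < 2 or right.size < 2:
            raise ValueError(
                f"slice {idx}: need >=2 voxels per side for the Welch test")
        ha, p = _slice_ha(left, right, alpha)
        slices.append(HASlice(slice_index=idx, ha=ha, p_value=p,
                              n_left=left.size, n_right=right.size))
    summary = float(np.mean([s.ha for s in slices]))
    return HAProfile(slices=slices, summary=summary, alpha=alpha)


def pet_laterality_summary(profile: HAProfile, t_unc: float = 0.05,
                           t_def: float = 0.15) -> tuple[float, str]:
    """Summarize an HA profile into (summary value, five-level decision).

    The summary is the unweighted mean of the per-slice HA values; negative
    values indicate left-sided hypometabolism.  Symmetric thresholds band
    the summary: |s| ≤ t_unc → U, t_unc < |s| ≤ t_def → UL/UR,
    |s| > t_def → L/R.
    """
    if not profile.slices:
        raise ValueError("empty HA profile")
    if not 0 < t_unc < t_def:
        raise ValueError("need 0 < t_unc < t_def")
    summary = profile.summary
    decision = dec.banded_decision(summary, t_unc, t_def, positive=dec.R)
    return summary, decision
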