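"""Synthetic cohorts with known ground-truth laterality.

These generators emulate the *inputs* of the lateralization pipeline —
tabular per-subject features, labeled intensity volumes, fiber sets and
region time series — for a control group tight around hemispheric symmetry
and left/right epileptogenic cases displaced the way mesial temporal
sclerosis displaces them: ipsilateral hippocampal volume loss, elevated
ipsilateral FLAIR intensity, ipsilateral PET hypometabolism with
anterior–posterior structure, elevated ipsilateral hippocampal mean
diffusivity with reduced tract FA, and reduced ipsilateral connectivity.

Default effect sizes are chosen as typical of an affected mesial temporal
lobe (≈30 % hippocampal volume loss, ≈10 % FLAIR signal elevation, ≈15 %
SUV reduction, ≈30 % connectivity reduction) with measurement noise well
below the effects, so that a correctly implemented pipeline should
lateralize nearly all cases.  One integer seed drives everything; all
sub-generators derive independent streams from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable, SubjectRecord
from .connectivity import Fiber, FiberSet
from .roi_features import (AMYG_L, AMYG_R, BRAIN, HIPP_L, HIPP_R, THAL_L,
                           THAL_R, LabeledVolume)

#: paired (unprefixed) region inventory used for fibers and time series
DEFAULT_REGIONS = (
    "hippocampus", "amygdala", "putamen", "inferior_temporal_sulcus",
    "lateral_superior_temporal_gyrus", "ventral_dc",
    "marginal_cingulate_sulcus", "parietal_superior_gyrus",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of a synthetic cohort.

    Effects are fractional ipsilateral changes (all ≥ 0); ``noise_sd``
    maps a channel name to its additive noise scale.
    """

    n_controls: int = 50
    n_left: int = 50
    n_right: int = 50
    volume_asymmetry_effect: float = 0.30   # ipsilateral volume reduction
    flair_effect: float = 0.10              # ipsilateral FLAIR mean increase
    suv_effect: float = 0.15                # ipsilateral SUV reduction
    connectivity_effect: float = 0.30       # ipsilateral strength reduction
    noise_sd: dict = field(default_factory=lambda: dict(
        volume=0.010,        # on normalized-volume features (% units)
        flair=0.020,         # on intensity ratios
        suv=0.030,           # on the HA summary
        suv_voxel=0.40,      # on per-voxel SUV samples (SUV units)
        diffusion=0.020,     # on diffusion asymmetries
        connectivity=0.050,  # on hemispheric Δ features
    ))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("volume_asymmetry_effect", "flair_effect",
                     "suv_effect", "connectivity_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_controls", "n_left", "n_right"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_effects(self, value: float) -> "SyntheticSpec":
        """Copy with every effect set to *value* (0 → null cohort)."""
        return replace(self, volume_asymmetry_effect=value,
                       flair_effect=value, suv_effect=value,
                       connectivity_effect=value)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for sub-stream *stream* of the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


# ---------------------------------------------------------------------------
# tabular feature cohorts

FEATURE_COLUMNS = (
    "f1", "f2", "f3", "f4", "a_hipp", "a_amyg", "a_thal", "pet_summary",
    "md_asym", "cingulum_fa_asym", "fornix_fa_asym", "delta_nfc_hipp",
)


def _subject_features(group: str, spec: SyntheticSpec,
                      rng: np.random.Generator) -> dict[str, float]:
    sgn = {"control": 0.0, "left": 1.0, "right": -1.0}[group]
    noise = spec.noise_sd
    # normalized hippocampal volumes (percent of brain volume)
    base = rng.normal(0.25, 0.03)
    e_v = spec.volume_asymmetry_effect
    f1 = base * (1 - e_v * (sgn > 0)) + rng.normal(0, noise["volume"])
    f2 = base * (1 - e_v * (sgn < 0)) + rng.normal(0, noise["volume"])
    # FLAIR left/right intensity ratios
    e_f = spec.flair_effect * sgn
    f3 = (1 + e_f) + rng.normal(0, noise["flair"])
    f4 = (1 + e_f) + rng.normal(0, noise["flair"])
    # tristructural normalized asymmetries; amygdala and thalamus are
    # involved less than the hippocampus
    def asym(effect_frac):
        left = 1 - effect_frac * (sgn > 0)
        right = 1 - effect_frac * (sgn < 0)
        return (100 * (left - right) / (left + right)
                + rng.normal(0, 100 * noise["volume"]))
    a_hipp = asym(e_v)
    a_amyg = asym(0.5 * e_v)
    a_thal = asym(0.25 * e_v)
    # PET hypometabolism-asymmetry summary (negative = left hypometabolic):
    # roughly three quarters of hippocampal slices reach significance
    pet = -sgn * 0.75 * spec.suv_effect + rng.normal(0, noise["suv"])
    pet = float(np.clip(pet, -1.0, 1.0))
    # diffusion asymmetries: MD up, tract FA down ipsilaterally
    e_d = spec.connectivity_effect * 0.3
    md = sgn * e_d + rng.normal(0, noise["diffusion"])
    cing = -sgn * e_d + rng.normal(0, noise["diffusion"])
    forn = -sgn * e_d + rng.normal(0, noise["diffusion"])
    # hemispheric Δ of overall hippocampal fiber-count connectivity
    d_nfc = -sgn * spec.connectivity_effect + rng.normal(
        0, noise["connectivity"])
    return dict(f1=f1, f2=f2, f3=f3, f4=f4, a_hipp=a_hipp, a_amyg=a_amyg,
                a_thal=a_thal, pet_summary=pet, md_asym=md,
                cingulum_fa_asym=cing, fornix_fa_asym=forn,
                delta_nfc_hipp=d_nfc)


def generate_feature_cohort(spec: SyntheticSpec,
                            ) -> tuple[CohortTable, pd.DataFrame]:
    """Synthetic per-subject raw features with ground-truth laterality.

    Returns the cohort table (records carry the ground-truth side) and a
    feature frame with one row per subject and a ``group`` column in
    {control, left, right}.
    """
    if spec.n_controls + spec.n_left + spec.n_right == 0:
        raise ValueError("empty cohort: all group counts are zero")
    rng = spec.rng(0)
    rows, records = [], []
    groups = (["control"] * spec.n_controls + ["left"] * spec.n_left
              + ["right"] * spec.n_right)
    for k, group in enumerate(groups):
        sid = f"S{k + 1:03d}"
        rows.append({"subject_id": sid, "group": group,
                     **_subject_features(group, spec, rng)})
        records.append(SubjectRecord(
            subject_id=sid,
            operated_side=group if group != "control" else "none",
            procedure="resection" if group != "control" else "none",
            engel_24="1A" if group != "control" else None))
    table = CohortTable(records, provenance="synthetic", seed=spec.seed)
    return table, pd.DataFrame(rows).set_index("subject_id")


# ---------------------------------------------------------------------------
# labeled volumes

GRID = 64
SPACING = (1.0, 1.0, 1.0)
LABELS = {1: HIPP_L, 2: HIPP_R, 3: AMYG_L, 4: AMYG_R, 5: THAL_L,
          6: THAL_R, 7: BRAIN}

# ellipsoid centers/radii on the 64³ grid; axis 0 is left–right (left =
# low index, with right centers mirrored so that a grid flip is exact),
# axis 1 anterior→posterior, axis 2 inferior→superior
_X_L, _X_R = 22, GRID - 1 - 22
_SHAPES = {
    "hippocampus": dict(center_y=36, center_z=28, radii=(4.0, 11.0, 4.0)),
    "amygdala": dict(center_y=18, center_z=28, radii=(3.0, 4.0, 3.0)),
    "thalamus": dict(center_y=38, center_z=38, radii=(4.0, 5.0, 4.0)),
}
# volume effect of the epileptogenic side relative to the hippocampal one
_STRUCTURE_EFFECT = {"hippocampus": 1.0, "amygdala": 0.5, "thalamus": 0.25}


def _ellipsoid(grid: tuple[np.ndarray, ...], center, radii) -> np.ndarray:
    x, y, z = grid
    cx, cy, cz = center
    rx, ry, rz = radii
    return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
            + ((z - cz) / rz) ** 2) <= 1.0


def generate_labeled_volume(side: str, spec: SyntheticSpec,
                            ) -> dict[str, LabeledVolume]:
    """T1-, FLAIR- and SUV-like volumes sharing one ROI label map.

    *side* is the epileptogenic side ("left", "right" or "none"): its
    hippocampus (and, to a lesser degree, amygdala and thalamus) shrinks,
    its hippocampal FLAIR mean rises, and its hippocampal SUV falls with
    an anterior→posterior gradient (hypometabolism strongest toward the
    anterior head).  Returns ``{"t1": ..., "flair": ..., "suv": ...}``.
    """
    if side not in ("left", "right", "none"):
        raise ValueError(f"bad side {side!r}")
    rng = spec.rng(1)
    grid = np.meshgrid(*(np.arange(GRID),) * 3, indexing="ij")
    labels = np.zeros((GRID,) * 3, dtype=np.int16)
    brain = _ellipsoid(grid, (GRID / 2 - 0.5, GRID / 2 - 0.5, GRID / 2 - 0.5),
                       (28.0, 30.0, 28.0))
    labels[brain] = 7
    shrink = {"left": {"left"}, "right": {"right"}, "none": set()}[side]
    label_of = {("hippocampus", "left"): 1, ("hippocampus", "right"): 2,
                ("amygdala", "left"): 3, ("amygdala", "right"): 4,
                ("thalamus", "left"): 5, ("thalamus", "right"): 6}
    for structure, shape in _SHAPES.items():
        for hemi, cx in (("left", _X_L), ("right", _X_R)):
            radii = np.array(shape["radii"], dtype=float)
            if hemi in shrink:
                frac = spec.volume_asymmetry_effect * \
                    _STRUCTURE_EFFECT[structure]
                radii = radii * (1.0 - frac) ** (1.0 / 3.0)
            mask = _ellipsoid(grid, (cx, shape["center_y"],
                                     shape["center_z"]), radii)
            if np.any(labels[mask] != 7):
                raise ValueError(
                    f"ROI collision placing {hemi} {structure}")
            labels[mask] = label_of[(structure, hemi)]

    def volume(intensities):
        return LabeledVolume(intensities=intensities, labels=labels,
                             spacing=SPACING, label_key=LABELS, ap_axis=1)

    t1 = np.where(brain, 100.0, 0.0) + rng.normal(0, 2.0, labels.shape)

    flair = np.where(brain, 100.0, 0.0)
    for hemi, lab in (("left", 1), ("right", 2)):
        if hemi in shrink:
            flair[labels == lab] *= 1.0 + spec.flair_effect
    flair = flair + rng.normal(0, 2.0, labels.shape)

    suv = np.where(brain, 10.0, 0.0)
    y = grid[1]
    for hemi, lab in (("left", 1), ("right", 2)):
        if hemi in shrink:
            mask = labels == lab
            y0, y1 = _SHAPES["hippocampus"]["center_y"] - 11, \
                _SHAPES["hippocampus"]["center_y"] + 11
            # hypometabolism tapers from the anterior head to the tail
            taper = 1.0 - 0.5 * (y[mask] - y0) / max(y1 - y0, 1)
            suv[mask] *= 1.0 - spec.suv_effect * taper
    suv = suv + rng.normal(0, spec.noise_sd["suv_voxel"], labels.shape)

    return {"t1": volume(t1), "flair": volume(flair), "suv": volume(suv)}


# ---------------------------------------------------------------------------
# fiber sets and time series

def _paired(regions) -> list[str]:
    return [f"{hemi}_{r}" for hemi in ("left", "right") for r in regions]


def generate_fiber_set(spec: SyntheticSpec, side: str = "none",
                       regions: tuple[str, ...] = DEFAULT_REGIONS,
                       fibers_per_pair: int = 20,
                       fa_mean: float = 0.5) -> FiberSet:
    """Fibers linking within-hemisphere region pairs.

    The epileptogenic hemisphere loses a ``connectivity_effect`` fraction
    of its expected fiber count and FA.  ``fibers_per_pair=0`` gives an
    empty fiber set (downstream NFC then comes out missing).
    """
    if len(regions) < 2:
        raise ValueError("need at least 2 paired regions")
    rng = spec.rng(2)
    inventory = tuple(_paired(regions))
    fibers: list[Fiber] = []
    for hemi in ("left", "right"):
        reduce = spec.connectivity_effect if hemi == side else 0.0
        for a in range(len(regions)):
            for b in range(a + 1, len(regions)):
                lam = fibers_per_pair * (1.0 - reduce)
                n = rng.poisson(lam) if lam > 0 else 0
                for _ in range(n):
                    fa = np.clip(
                        rng.normal(fa_mean * (1.0 - 0.5 * reduce), 0.05,
                                   size=10), 0.0, 1.0)
                    fibers.append(Fiber(
                        regions_traversed=frozenset(
                            {f"{hemi}_{regions[a]}", f"{hemi}_{regions[b]}"}),
                        fa_values=tuple(fa)))
    return FiberSet(fibers=fibers, regions=inventory)


def correlated_timeseries(target_corr: np.ndarray, n_timepoints: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Gaussian series (regions × time) with the given target correlation."""
    corr = np.asarray(target_corr, dtype=float)
    chol = np.linalg.cholesky(corr + 1e-9 * np.eye(corr.shape[0]))
    return chol @ rng.standard_normal((corr.shape[0], n_timepoints))


def generate_timeseries(spec: SyntheticSpec, side: str = "none",
                        regions: tuple[str, ...] = DEFAULT_REGIONS,
                        n_timepoints: int = 145,
                        within_corr: float = 0.5,
                        between_corr: float = 0.1) -> pd.DataFrame:
    """Region × time matrix with hemispheric correlation structure.

    Within-hemisphere correlation is ``within_corr``, reduced by the
    connectivity effect on the epileptogenic side; across hemispheres it
    is ``between_corr``.  The 145 default time points correspond to a
    five-minute resting acquisition at 2 s after discarding the
    equilibration volumes.
    """
    if len(regions) < 2:
        raise ValueError("need at least 2 paired regions")
    rng = spec.rng(3)
    inventory = _paired(regions)
    n = len(inventory)
    corr = np.full((n, n), between_corr)
    half = len(regions)
    for block, hemi in ((slice(0, half), "left"), (slice(half, n), "right")):
        rho = within_corr
        if hemi == side:
            rho = within_corr * (1.0 - spec.connectivity_effect)
        corr[block, block] = rho
    np.fill_diagonal(corr, 1.0)
    data = correlated_timeseries(corr, n_timepoints, rng)
    return pd.DataFrame(data, index=inventory)
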