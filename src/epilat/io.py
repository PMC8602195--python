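"""NIfTI round-trip for labeled volumes."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .roi_features import LabeledVolume


def save_labeled_volume(vol: LabeledVolume, intensity_path: str | Path,
                        labels_path: str | Path) -> None:
    """Write intensities (float32) and labels (int16) as NIfTI-1 pairs."""
    affine = np.diag([*vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine),
             str(intensity_path))
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), affine),
             str(labels_path))


def load_labeled_volume(intensity_path: str | Path,
                        labels_path: str | Path,
                        label_key: dict[int, str],
                        ap_axis: int = 1) -> LabeledVolume:
    """Read an intensity/label NIfTI pair back into a labeled volume.

    The voxel spacing is taken from the intensity image header; the axis
    convention (which voxel axis runs anterior→posterior) is supplied by
    the caller, as in the generated phantoms.
    """
    img = nib.load(str(intensity_path))
    lab = nib.load(str(labels_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabeledVolume(
        intensities=np.asarray(img.dataobj, dtype=float),
        labels=np.asarray(lab.dataobj).astype(int),
        spacing=spacing, label_key=label_key, ap_axis=ap_axis)
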