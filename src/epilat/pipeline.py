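"""End-to-end lateralization: features → banded decisions → fused decision.

Calibrates the per-modality classifiers on a training feature cohort
(controls plus lateralized cases), applies them to a test cohort, and
fuses the per-subject decisions by majority voting.  Works on the feature
frames produced by :mod:`epilat.synthetic` or on equally shaped frames
extracted from real volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decisions as dec
from .classifiers import (EigenlineClassifier, HVUClassifier,
                          TristructuralLogisticClassifier)
from .fusion import fuse

FUSED_MODALITIES = ("volumetry", "flair", "msa", "pet")


@dataclass
class LateralizationPipeline:
    """Fitted per-modality classifiers plus PET banding thresholds."""

    volumetry: EigenlineClassifier
    flair: EigenlineClassifier
    msa: TristructuralLogisticClassifier
    hvu: HVUClassifier | None = None
    pet_t_unc: float = 0.05
    pet_t_def: float = 0.15

    def decide(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-modality five-level decisions plus the fused decision.

        *features* needs columns f1, f2, f3, f4, a_hipp, a_amyg, a_thal
        and pet_summary (diffusion asymmetry columns are used when an HVU
        model is fitted).
        """
        out = pd.DataFrame(index=features.index)
        out["volumetry"] = self.volumetry.predict(
            features[["f1", "f2"]].to_numpy())
        out["flair"] = self.flair.predict(
            features[["f3", "f4"]].to_numpy())
        out["msa"] = self.msa.predict(
            features[["a_hipp", "a_amyg", "a_thal"]].to_numpy())
        out["pet"] = [
            dec.banded_decision(float(s), self.pet_t_unc, self.pet_t_def,
                                positive=dec.R)
            for s in features["pet_summary"]]
        if self.hvu is not None:
            out["dti_uncertainty"] = self.hvu.predict(features[
                ["md_asym", "cingulum_fa_asym", "fornix_fa_asym"]
            ].to_numpy())
        out["mmm"] = [
            fuse([row[m] for m in FUSED_MODALITIES]).decision
            for _, row in out.iterrows()]
        return out


def fit_pipeline(features: pd.DataFrame, groups: pd.Series | None = None,
                 **pet_thresholds) -> LateralizationPipeline:
    """Calibrate all modality classifiers from a labeled feature cohort.

    *groups* (default: the frame's ``group`` column) holds
    control/left/right labels; controls calibrate the eigenlines and HVU
    thresholds, cases train the logistic model and orient the eigenlines.
    """
    if groups is None:
        groups = features["group"]
    y = np.asarray(groups, dtype=object)
    cases = (y == "left") | (y == "right")
    controls = y == "control"
    if controls.sum() == 0 or cases.sum() == 0:
        raise ValueError("need both controls and lateralized cases to fit")
    vol = EigenlineClassifier().fit(features[["f1", "f2"]].to_numpy(), y)
    flair = EigenlineClassifier().fit(features[["f3", "f4"]].to_numpy(), y)
    msa = TristructuralLogisticClassifier().fit(
        features.loc[cases, ["a_hipp", "a_amyg", "a_thal"]].to_numpy(),
        y[cases])
    hvu = None
    if {"md_asym", "cingulum_fa_asym", "fornix_fa_asym"} <= \
            set(features.columns):
        hvu = HVUClassifier().fit(features.loc[
            controls, ["md_asym", "cingulum_fa_asym", "fornix_fa_asym"]
        ].to_numpy())
    return LateralizationPipeline(volumetry=vol, flair=flair, msa=msa,
                                  hvu=hvu, **pet_thresholds)


def lateralization_accuracy(decisions: pd.Series, truth: pd.Series) -> float:
    """Fraction of cases whose decision points to the true side.

    Definitive and weak same-side decisions both count as correct;
    indeterminate and opposite-side decisions count as wrong.  Controls
    (truth not left/right) are excluded.
    """
    mask = truth.isin(["left", "right"])
    if mask.sum() == 0:
        raise ValueError("no lateralized cases to score")
    pointed = decisions[mask].map(dec.side_of)
    return float((pointed == truth[mask]).mean())
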