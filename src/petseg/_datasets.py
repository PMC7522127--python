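"""Helpers to reload phantom datasets written by :func:`petseg.phantom.generate_dataset`."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .imaging_io import Modality, PetCtStudy, load_volume

__all__ = ["load_manifest_studies"]


def load_manifest_studies(data_dir: str | Path):
    """Return (studies, truth_masks) for every entry in a dataset manifest."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    studies, masks = [], []
    for entry in manifest["entries"]:
        pet = load_volume(data_dir / entry["pet"], Modality.PET_SUV)
        ct = load_volume(data_dir / entry["ct"], Modality.CT_HU)
        mask = load_volume(data_dir / entry["truth_mask"], Modality.MASK)
        studies.append(PetCtStudy(pet=pet, ct=ct, study_id=entry["study_id"]))
        masks.append(np.asarray(mask.data, np.uint8))
    return studies, masks
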