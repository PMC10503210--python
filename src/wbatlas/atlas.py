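"""Stratified normal-atlas construction and transport to native space.

A normal atlas summarises a registered healthy cohort voxel-wise: per
channel (typically WF, b=900 DWI and ADC) the mean, sample SD (n-1
denominator) and percentage coefficient of variation CV = 100*SD/mean,
together with the component count. Cohorts are stratified by sex and BMI
class with the boundary BMI of 25 kg/m^2 assigned to the overweight
class. Atlas statistics can be transported into a patient's native space
by driving the registration pipeline with the patient's water/fat images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from .masks import MaskSet, WeightMap
from .registration import DeformationField, apply_deformation, pre_register, register_main
from .volume import Volume

__all__ = ["AtlasChannel", "Atlas", "build_atlas", "stratify", "atlas_to_native"]

BMI_CUT = 25.0  # kg/m^2; boundary goes to the >= 25 class


@dataclass(frozen=True)
class AtlasChannel:
    """Voxel-wise mean / SD / %CV of one atlas channel."""

    mean: Volume
    sd: Volume
    cv: Volume  # percent; NaN where mean <= 0 (flagged undefined)
    n: int


@dataclass(frozen=True)
class Atlas:
    """Per-stratum normal atlas over one or more channels."""

    channels: dict[str, AtlasChannel]
    stratum: tuple[str, str]  # (sex, bmi_class)
    n: int
    reference_subject_id: str | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, name: str) -> AtlasChannel:
        return self.channels[name]

    def to_directory(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, ch in self.channels.items():
            ch.mean.to_nifti(out_dir / f"{name}_mean.nii.gz")
            ch.sd.to_nifti(out_dir / f"{name}_sd.nii.gz")
            ch.cv.to_nifti(out_dir / f"{name}_cv.nii.gz")
        (out_dir / "atlas.json").write_text(
            json.dumps(
                {
                    "stratum": list(self.stratum),
                    "n": self.n,
                    "channels": list(self.channels),
                    "reference_subject_id": self.reference_subject_id,
                    "provenance": {k: str(v) for k, v in self.provenance.items()},
                },
                indent=2,
            )
        )
        return out_dir


def _channel_stats(volumes: Sequence[Volume], ddof: int) -> AtlasChannel:
    grid = volumes[0]
    for v in volumes[1:]:
        if not grid.same_grid(v):
            raise ValueError("atlas components must share the reference grid")
    stack = np.stack([np.asarray(v.values, dtype=float) for v in volumes])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / np.where(mean > 0, mean, 1.0), np.nan)
    return AtlasChannel(
        mean=grid.with_values(mean),
        sd=grid.with_values(sd),
        cv=grid.with_values(cv),
        n=len(volumes),
    )


def build_atlas(
    registered_channels: Mapping[str, Sequence[Volume]],
    stratum: tuple[str, str] = ("M", "ge25"),
    *,
    sd_kind: str = "sample",
    reference_subject_id: str | None = None,
) -> Atlas:
    """Combine registered subject volumes into a stratum atlas.

    ``registered_channels`` maps channel name -> list of per-subject
    volumes already in reference space. Sample SD (n-1) is the default;
    ``sd_kind='population'`` switches to the n denominator. %CV is
    flagged undefined (NaN) where the voxel mean is not positive.
    """
    if not registered_channels:
        raise ValueError("no channels supplied")
    ddof = 1 if sd_kind == "sample" else 0
    ns = {name: len(vols) for name, vols in registered_channels.items()}
    if min(ns.values()) < 2:
        raise ValueError("an atlas needs at least 2 subjects per channel")
    channels = {
        name: _channel_stats(list(vols), ddof) for name, vols in registered_channels.items()
    }
    return Atlas(
        channels=channels,
        stratum=tuple(stratum),
        n=min(ns.values()),
        reference_subject_id=reference_subject_id,
        provenance={"sd_kind": sd_kind},
    )


def stratify(
    manifest: Sequence[Mapping[str, Any]], bmi_cut: float = BMI_CUT
) -> dict[tuple[str, str], list[Any]]:
    """Partition a cohort manifest into sex x BMI-class strata.

    Each manifest entry needs ``sex`` (0 = female, 1 = male, or 'F'/'M')
    and ``bmi``. BMI exactly at the cut goes to the >= class. Returns all
    four strata (possibly empty lists).
    """
    out: dict[tuple[str, str], list[Any]] = {
        ("F", "lt25"): [],
        ("F", "ge25"): [],
        ("M", "lt25"): [],
        ("M", "ge25"): [],
    }
    for entry in manifest:
        if "sex" not in entry or "bmi" not in entry:
            raise ValueError("manifest entries need 'sex' and 'bmi'")
        sex = entry["sex"]
        sex_name = sex if sex in ("F", "M") else ("M" if int(sex) == 1 else "F")
        bmi_class = "ge25" if float(entry["bmi"]) >= bmi_cut else "lt25"
        out[(sex_name, bmi_class)].append(entry)
    return out


def atlas_to_native(
    atlas: Atlas,
    patient_water: Volume,
    patient_fat: Volume,
    atlas_water: Volume,
    atlas_fat: Volume,
    *,
    patient_masks: MaskSet | None = None,
    atlas_masks: MaskSet | None = None,
    weight_map: WeightMap | None = None,
    params: dict[str, Any] | None = None,
) -> tuple[Atlas, DeformationField]:
    """Transport atlas statistics into a patient's native space.

    The atlas reference anatomy (its water/fat channels) is registered to
    the patient (patient = fixed), then every channel mean and SD is
    resampled with linear interpolation through the resulting field; the
    component count n is carried as metadata and %CV recomputed from the
    transported mean/SD. Returns the transported atlas and the field.
    """
    init = None
    if patient_masks is not None and atlas_masks is not None:
        init = pre_register(patient_masks, atlas_masks, params)
    def_field = register_main(
        patient_water,
        patient_fat,
        atlas_water,
        atlas_fat,
        weight_map=weight_map,
        cost_mask=patient_masks.dilated_body if patient_masks is not None else None,
        init=init,
        params=params,
    )
    channels = {}
    for name, ch in atlas.channels.items():
        mean_t = apply_deformation(ch.mean, def_field, interpolation="linear")
        sd_t = apply_deformation(ch.sd, def_field, interpolation="linear")
        sd_t = sd_t.with_values(np.maximum(sd_t.values, 0.0))
        m = np.asarray(mean_t.values)
        s = np.asarray(sd_t.values)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(m > 0, 100.0 * s / np.where(m > 0, m, 1.0), np.nan)
        channels[name] = AtlasChannel(mean=mean_t, sd=sd_t, cv=mean_t.with_values(cv), n=ch.n)
    transported = Atlas(
        channels=channels,
        stratum=atlas.stratum,
        n=atlas.n,
        reference_subject_id=atlas.reference_subject_id,
        provenance={**atlas.provenance, "space": "patient-native"},
    )
    return transported, def_field
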