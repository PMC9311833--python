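"""Perfusion quantification: ROI means, partial-volume correction, perfusion indexes.

The quantification substrate is a per-scan ROI activity table: one row per atlas
structure with the number of grey-matter voxels and the mean tracer activity
(counts per voxel).  Tables are computed from co-registered activity / atlas
label / grey-matter mask volumes, or supplied directly as CSV.

The perfusion index (PI) of a structure is its mean activity divided by the
mean activity of the *rest* of the grey matter (voxel-count-weighted,
leave-one-out); PI > 1 indicates relative hyperperfusion.  A ``global``
denominator mode (mean over all grey matter including the structure) is
available for comparability.

Partial-volume correction follows the region-based geometric-transfer-matrix
approach: the observed ROI means are modelled as a mixing matrix W applied to
the true means, with W[i, j] the mean over ROI i of the point-spread-blurred
indicator of ROI j, and the correction solves that linear system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RoiActivityTable",
    "PerfusionVector",
    "PsfModel",
    "compute_roi_means",
    "pvc_region_gtm",
    "perfusion_index",
    "change_vector",
]

STATES = ("interictal", "ictal")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class QuantifyError(ValueError):
    pass


def _asarray(vol) -> np.ndarray:
    """Accept numpy arrays or nibabel spatial images."""
    if hasattr(vol, "get_fdata"):
        return np.asarray(vol.get_fdata())
    return np.asarray(vol)


@dataclass
class RoiActivityTable:
    """Mean activity (counts/voxel) per atlas structure for one scan.

    ``data`` is indexed by structure name with columns ``n_voxels`` (int >= 1)
    and ``mean_counts`` (float >= 0).  Structures absent after grey-matter
    masking are simply not present (never encoded as zero rows).
    """

    patient_id: str
    state: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise QuantifyError(f"state must be one of {STATES}, got {self.state!r}")
        d = self.data
        if not {"n_voxels", "mean_counts"}.issubset(d.columns):
            raise QuantifyError("table needs columns n_voxels, mean_counts")
        if d.index.has_duplicates:
            raise QuantifyError("duplicate structure rows")
        if (d["n_voxels"] < 1).any():
            raise QuantifyError("n_voxels must be >= 1 for included structures")
        mc = d["mean_counts"].to_numpy(dtype=float)
        if not np.all(np.isfinite(mc)) or (mc < 0).any():
            raise QuantifyError("mean_counts must be finite and >= 0")

    @property
    def structures(self) -> list[str]:
        return list(self.data.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "state", self.state)
        out.insert(0, "patient", self.patient_id)
        return out.reset_index(names="structure")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "list[RoiActivityTable]":
        """Split a long CSV frame (patient,state,structure,n_voxels,mean_counts)."""
        tables = []
        for (patient, state), grp in frame.groupby(["patient", "state"], sort=True):
            data = grp.set_index("structure")[["n_voxels", "mean_counts"]]
            tables.append(cls(patient_id=str(patient), state=str(state), data=data))
        return tables


@dataclass
class PerfusionVector:
    """Perfusion indexes (or relative interictal->ictal changes) for one scan.

    ``values`` is a Series indexed by structure.  For states interictal/ictal
    all values are > 0; for state ``change`` values are relative fractions
    (> -1), 0 meaning invariant perfusion.
    """

    patient_id: str
    state: str
    values: pd.Series

    def __post_init__(self) -> None:
        if self.state not in STATES + ("change",):
            raise QuantifyError(f"bad state {self.state!r}")
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise QuantifyError("perfusion values must be finite")
        if self.state == "change":
            if (v <= -1).any():
                raise QuantifyError("change values must be > -1")
        elif (v <= 0).any():
            raise QuantifyError("perfusion indexes must be > 0")

    @property
    def structures(self) -> list[str]:
        return list(self.values.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.rename("value").rename_axis("structure").reset_index()
        out.insert(0, "state", self.state)
        out.insert(0, "patient", self.patient_id)
        return out


@dataclass(frozen=True)
class PsfModel:
    """Isotropic-by-axis Gaussian point-spread model, FWHM in millimetres."""

    fwhm_mm: float | tuple[float, float, float] = 8.0
    voxel_size_mm: float | tuple[float, float, float] = 1.0

    def sigma_voxels(self) -> np.ndarray:
        fwhm = np.broadcast_to(np.asarray(self.fwhm_mm, dtype=float), (3,))
        vox = np.broadcast_to(np.asarray(self.voxel_size_mm, dtype=float), (3,))
        if (fwhm < 0).any():
            raise QuantifyError("PSF FWHM must be >= 0")
        if (vox <= 0).any():
            raise QuantifyError("voxel size must be > 0")
        return fwhm * _FWHM_TO_SIGMA / vox

    def blur(self, volume: np.ndarray) -> np.ndarray:
        sigma = self.sigma_voxels()
        if np.all(sigma == 0):
            return np.asarray(volume, dtype=float)
        # zero outside the field of view: activity beyond the brain is ~0
        return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma, mode="constant")


def compute_roi_means(activity, labels, gm_mask, atlas, *, patient_id="?", state="interictal") -> RoiActivityTable:
    """Mean activity per structure over voxels with that label inside the GM mask.

    Ventricular / extracerebral voxels are excluded by the mask from every
    computation.  Structures with no surviving voxels are omitted (absent, not
    zero).
    """
    act = _asarray(activity).astype(float)
    lab = _asarray(labels)
    gm = _asarray(gm_mask)
    if not (act.shape == lab.shape == gm.shape):
        raise QuantifyError(
            f"volume shapes differ: activity {act.shape}, labels {lab.shape}, mask {gm.shape}"
        )
    lab = np.rint(lab).astype(int)
    gm = gm > 0
    if not gm.any():
        raise QuantifyError("grey-matter mask is empty")
    masked_labels = np.where(gm, lab, 0)
    ids = np.asarray(atlas.ids)
    counts = ndimage.sum_labels(np.ones_like(act), labels=masked_labels, index=ids)
    sums = ndimage.sum_labels(act, labels=masked_labels, index=ids)
    present = counts > 0
    data = pd.DataFrame(
        {
            "n_voxels": counts[present].astype(int),
            "mean_counts": sums[present] / counts[present],
            "label_id": ids[present].astype(int),
        },
        index=pd.Index([atlas.by_id(int(i)).name for i in ids[present]], name="structure"),
    )
    return RoiActivityTable(patient_id=patient_id, state=state, data=data.sort_index())


def pvc_region_gtm(
    table: RoiActivityTable,
    labels,
    gm_mask,
    psf: PsfModel,
    *,
    cond_threshold: float = 1e8,
) -> RoiActivityTable:
    """Region-based geometric-transfer-matrix partial-volume correction.

    W[i, j] = mean over ROI_i of (PSF (*) indicator of ROI_j); corrected means
    solve W x = observed.  Rows of W sum to <= 1 (signal spilling outside all
    ROIs is lost, not redistributed).  With FWHM 0 the system is the identity
    and the table is returned unchanged.
    """
    structures = table.structures
    if len(structures) < 2:
        raise QuantifyError(
            "partial-volume correction needs >= 2 regions to model cross-talk"
        )
    sigma = psf.sigma_voxels()
    if np.all(sigma == 0):
        return RoiActivityTable(table.patient_id, table.state, table.data.copy())

    lab = np.rint(_asarray(labels)).astype(int)
    gm = _asarray(gm_mask) > 0
    if lab.shape != gm.shape:
        raise QuantifyError("label and mask shapes differ")
    masked_labels = np.where(gm, lab, 0)

    if "label_id" not in table.data.columns:
        raise QuantifyError(
            "table needs a label_id column linking structures to the labels volume "
            "(tables from compute_roi_means carry it)"
        )
    region_masks: dict[str, np.ndarray] = {}
    missing = []
    for name in structures:
        mask = masked_labels == int(table.data.loc[name, "label_id"])
        if not mask.any():
            missing.append(name)
        region_masks[name] = mask
    if missing:
        raise QuantifyError(f"regions without voxels in the labels volume: {missing[:5]}")

    n = len(structures)
    W = np.empty((n, n), dtype=float)
    blurred = {}
    for j, name in enumerate(structures):
        blurred[j] = psf.blur(region_masks[name].astype(float))
    for i, name in enumerate(structures):
        mask_i = region_masks[name]
        m = mask_i.sum()
        for j in range(n):
            W[i, j] = blurred[j][mask_i].sum() / m
    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise QuantifyError(
            f"geometric transfer matrix is ill-conditioned (cond={cond:.3g}); "
            "use larger ROIs or a smaller PSF"
        )
    observed = table.data["mean_counts"].to_numpy(dtype=float)
    corrected = np.linalg.solve(W, observed)
    data = table.data.copy()
    data["mean_counts"] = np.clip(corrected, 0.0, None)
    return RoiActivityTable(table.patient_id, table.state, data)


def perfusion_index(table: RoiActivityTable, *, denominator: str = "rest") -> PerfusionVector:
    """Perfusion index per structure: ROI mean over reference grey-matter mean.

    ``denominator='rest'`` (default): voxel-count-weighted mean over all
    grey-matter voxels *not* in the structure (leave-one-out).
    ``denominator='global'``: mean over all grey-matter voxels.
    """
    if denominator not in ("rest", "global"):
        raise QuantifyError(f"unknown PI denominator mode {denominator!r}")
    d = table.data
    if len(d) < 2:
        raise QuantifyError("perfusion index needs >= 2 structures")
    n = d["n_voxels"].to_numpy(dtype=float)
    m = d["mean_counts"].to_numpy(dtype=float)
    total_counts = float(np.sum(n * m))
    total_vox = float(np.sum(n))
    if denominator == "global":
        denom = np.full(len(d), total_counts / total_vox)
    else:
        denom = (total_counts - n * m) / (total_vox - n)
    if np.any(denom <= 0):
        raise QuantifyError("reference grey-matter mean is zero; cannot form PI")
    values = pd.Series(m / denom, index=d.index, name="pi")
    return PerfusionVector(patient_id=table.patient_id, state=table.state, values=values)


def change_vector(interictal: PerfusionVector, ictal: PerfusionVector) -> PerfusionVector:
    """Relative interictal->ictal change per structure: (ictal - interictal)/interictal."""
    if interictal.patient_id != ictal.patient_id:
        raise QuantifyError("change vector requires the same patient in both states")
    if interictal.state != "interictal" or ictal.state != "ictal":
        raise QuantifyError("arguments must be (interictal, ictal) perfusion vectors")
    if set(interictal.structures) != set(ictal.structures):
        raise QuantifyError("structure sets differ between states")
    inter = interictal.values
    ict = ictal.values.reindex(inter.index)
    change = (ict - inter) / inter
    return PerfusionVector(patient_id=interictal.patient_id, state="change", values=change)
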