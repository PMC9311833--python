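"""Synthetic desk-scale cohorts with the statistical structure the analysis assumes.

No imaging data for the reference cohort are deposited, so every downstream
stage is exercised on synthetic inputs with planted ground truth:

* a nine-patient cohort whose per-scan perfusion indexes sit on five planted
  levels (hypoperfused 0.53, low-normal 0.85, normal 1.00, high-normal 1.08,
  hyperperfused 1.31).  Level values shift patient-to-patient (so cluster
  means span the published 0.42-0.64 / 1.16-1.46 ranges) and structures get
  independent Gaussian observation noise on the PI scale;
* an interictal->ictal change map that raises hyperperfused structures ~+30%
  and lowers hypoperfused ones ~-20%, except in high-risk patients
  (SUDEP-7 > 5) whose ipsilateral putamen, entorhinal area and middle temporal
  gyrus do not change — the planted biomarker signal;
* clinical items reproducing the reference cohort's SUDEP-7 scores
  (3,5,7,7,7,4,7,7,4) and seizure-onset sides;
* small blurred / optionally Poisson-sampled block phantoms for testing the
  ROI-mean and partial-volume-correction machinery.

ROI tables are emitted in counts/voxel such that leave-one-out perfusion-index
quantification returns the planted PI values exactly for every structure on a
non-normal level (the 45 normal-level structures absorb the global-reference
constraint through a common rescaling of order 1%; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasSpec
from .quantify import PsfModel, RoiActivityTable
from .sudep import DEFAULT_WEIGHTS, score_sudep7

__all__ = [
    "LevelSpec",
    "CohortConfig",
    "PhantomConfig",
    "GeneratedCohort",
    "paperlike_config",
    "generate_roi_cohort",
    "generate_phantom",
]

NOISE_TRUNC = 0.05  # observation noise is a Gaussian truncated at +-0.05 PI
PI_FLOOR = 0.05  # and PIs never drop below this, keeping them positive


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class LevelSpec:
    """One planted perfusion level: mean PI, between-patient SD, clip bounds."""

    mean: float
    between_sd: float
    lo: float
    hi: float


@dataclass
class CohortConfig:
    """Parameters of a synthetic ROI cohort; ``paperlike_config()`` is the default."""

    n_patients: int
    seed: int
    pi_levels: dict  # level name -> LevelSpec
    membership: dict  # structure token (may use _ipsi/_contra) -> level name
    change_by_level: dict  # level name -> ictal multiplicative factor
    change_overrides: dict  # structure token -> factor (beats level default)
    high_risk_no_change: tuple  # tokens forced to factor 1.0 in high-risk patients
    noise_sd: float
    clinical_items: list  # per patient: 7 booleans (i1..i7)
    onset_sides: list  # per patient: "left" | "right"
    injection_times_s: list
    seizure_durations_s: list
    sudep7_weights: tuple = DEFAULT_WEIGHTS
    n_voxels: int = 100
    global_scale: float = 100.0  # counts/voxel of the grand reference

    def validate(self, atlas: AtlasSpec) -> None:
        if self.n_patients < 2:
            raise SyntheticError("n_patients must be >= 2")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")
        for name, lv in self.pi_levels.items():
            if lv.mean <= 0:
                raise SyntheticError(f"level {name!r}: mean must be > 0")
            if not (lv.lo <= lv.mean <= lv.hi):
                raise SyntheticError(f"level {name!r}: mean outside clip bounds")
        if "normal" not in self.pi_levels:
            raise SyntheticError("a 'normal' reference level is required")
        for token, level in self.membership.items():
            if level not in self.pi_levels:
                raise SyntheticError(f"structure {token!r} assigned to unknown level {level!r}")
            self._check_token(token, atlas)
        for token in list(self.change_overrides) + list(self.high_risk_no_change):
            self._check_token(token, atlas)
        for seq, what in ((self.clinical_items, "clinical_items"),
                          (self.onset_sides, "onset_sides"),
                          (self.injection_times_s, "injection times"),
                          (self.seizure_durations_s, "seizure durations")):
            if len(seq) != self.n_patients:
                raise SyntheticError(f"{what} must have one entry per patient")
        for side in self.onset_sides:
            if side not in ("left", "right"):
                raise SyntheticError(f"unknown onset side {side!r}")

    @staticmethod
    def _check_token(token: str, atlas: AtlasSpec) -> None:
        try:
            atlas.resolve_side(token, "left")
        except KeyError as exc:
            raise SyntheticError(f"structure {token!r} absent from atlas") from exc


@dataclass
class PhantomConfig:
    """Block-phantom parameters for testing ROI means and PVC."""

    grid_shape: tuple = (48, 48, 48)
    psf_fwhm_mm: float = 8.0
    voxel_size_mm: float = 3.0
    poisson_scale: float = 500.0  # expected counts/voxel at PI = 1
    poisson: bool = False
    seed: int = 0
    block_voxels: int = 6
    gap_voxels: int = 2

    def validate(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise SyntheticError("psf_fwhm_mm must be >= 0")
        if self.poisson_scale <= 0:
            raise SyntheticError("poisson_scale must be > 0")
        if self.block_voxels < 1 or self.gap_voxels < 0:
            raise SyntheticError("bad block/gap sizes")


@dataclass
class GeneratedCohort:
    """Synthetic cohort: ROI tables, clinical table and the planted truth."""

    tables: dict  # (patient, state) -> RoiActivityTable
    clinical: pd.DataFrame  # indexed by patient
    truth: pd.DataFrame  # patient, state, structure, level, true_pi, change_factor

    @property
    def patients(self) -> list[str]:
        return list(self.clinical.index)

    def roi_frame(self) -> pd.DataFrame:
        """All ROI tables as one long CSV-ready frame."""
        return pd.concat([t.to_frame() for t in self.tables.values()], ignore_index=True)


# --------------------------------------------------------------------------
# the "paperlike" study conditions

_PAPERLIKE_ITEMS = [
    (0, 1, 0, 0, 0, 1, 0),  # P1: 3
    (0, 1, 0, 0, 1, 1, 0),  # P2: 5
    (1, 1, 1, 0, 0, 1, 1),  # P3: 7
    (1, 1, 1, 0, 0, 1, 1),  # P4: 7
    (1, 1, 1, 0, 0, 1, 1),  # P5: 7
    (1, 1, 0, 0, 0, 1, 0),  # P6: 4
    (1, 1, 1, 0, 0, 1, 1),  # P7: 7
    (1, 1, 1, 0, 0, 1, 1),  # P8: 7
    (1, 0, 0, 0, 0, 1, 0),  # P9: 4
]


def paperlike_config(seed: int = 42, noise_sd: float = 0.02) -> CohortConfig:
    """The default nine-patient study conditions with planted K = 5 structure."""
    levels = {
        "hypo": LevelSpec(0.53, 0.06, 0.42, 0.64),
        "low_normal": LevelSpec(0.85, 0.015, 0.82, 0.88),
        "normal": LevelSpec(1.00, 0.015, 0.97, 1.03),
        "high_normal": LevelSpec(1.08, 0.015, 1.05, 1.11),
        "hyper": LevelSpec(1.31, 0.08, 1.16, 1.46),
    }
    membership = {
        # hypoperfused: brainstem / deep structures + ipsilateral entorhinal
        "medulla": "hypo",
        "red_nucleus_L": "hypo", "red_nucleus_R": "hypo",
        "substantia_nigra_L": "hypo", "substantia_nigra_R": "hypo",
        "entorhinal_ipsi": "hypo",
        # hyperperfused: bilateral rectus, putamen, cingulate + ipsilateral pallidum
        "rectus_L": "hyper", "rectus_R": "hyper",
        "putamen_L": "hyper", "putamen_R": "hyper",
        "globus_pallidus_ipsi": "hyper",
        "cingulate_L": "hyper", "cingulate_R": "hyper",
        # modestly hypoperfused occipital band
        "lingual_L": "low_normal", "lingual_R": "low_normal",
        "cuneus_L": "low_normal", "cuneus_R": "low_normal",
        "inferior_occipital_L": "low_normal", "inferior_occipital_R": "low_normal",
        "superior_occipital_L": "low_normal", "superior_occipital_R": "low_normal",
        # modestly hyperperfused perisylvian/sensorimotor band
        "superior_temporal_L": "high_normal", "superior_temporal_R": "high_normal",
        "insula_L": "high_normal", "insula_R": "high_normal",
        "precentral_L": "high_normal", "precentral_R": "high_normal",
        "postcentral_L": "high_normal", "postcentral_R": "high_normal",
    }
    return CohortConfig(
        n_patients=9,
        seed=seed,
        pi_levels=levels,
        membership=membership,
        change_by_level={"hypo": 0.80, "low_normal": 1.0, "normal": 1.0,
                         "high_normal": 1.0, "hyper": 1.30},
        change_overrides={"middle_temporal_ipsi": 1.15},
        high_risk_no_change=("putamen_ipsi", "entorhinal_ipsi", "middle_temporal_ipsi"),
        noise_sd=noise_sd,
        clinical_items=[tuple(bool(v) for v in row) for row in _PAPERLIKE_ITEMS],
        onset_sides=["left", "left", "right", "right", "right",
                     "right", "left", "left", "right"],
        injection_times_s=[7, 17, 2, 8, 4, 6, 10, 5, 3],
        seizure_durations_s=[109, 62, 95, 66, 19, 56, 35, 72, 73],
    )


def get_config(name: str, seed: int = 42) -> CohortConfig:
    if name == "paperlike":
        return paperlike_config(seed=seed)
    raise SyntheticError(f"unknown named configuration {name!r}")


# --------------------------------------------------------------------------
# ROI cohort generation

def _counts_for_targets(
    targets: pd.Series, absorb: set, n_voxels: int, global_scale: float
) -> pd.Series:
    """Mean counts/voxel realizing the target leave-one-out PIs.

    With equal-size ROIs the leave-one-out PI of structure s with mean counts
    u_s is (m-1) u_s / (U - u_s) where m is the number of structures and U the
    sum of mean counts.  Inverting gives u_s = p_s U / (m - 1 + p_s); the sum
    constraint cannot hold for an arbitrary PI vector, so the structures in
    ``absorb`` are rescaled by a common factor to close it (their realized PI
    shifts by that common factor, order 1%), while every other structure's PI
    is realized exactly.
    """
    m = len(targets)
    if m < 2:
        raise SyntheticError("need >= 2 structures")
    if not absorb:
        raise SyntheticError("need a non-empty absorber set to close the PI constraint")
    U = m * global_scale
    p = targets.to_numpy(dtype=float)
    u = p * U / (m - 1 + p)
    is_absorb = targets.index.isin(absorb)
    fixed_sum = u[~is_absorb].sum()
    absorb_sum = u[is_absorb].sum()
    if fixed_sum >= U:
        raise SyntheticError("planted PIs too extreme to realize with this absorber set")
    beta = (U - fixed_sum) / absorb_sum
    u[is_absorb] *= beta
    return pd.Series(u, index=targets.index, name="mean_counts")


def generate_roi_cohort(config: CohortConfig, atlas: AtlasSpec) -> GeneratedCohort:
    """Generate per-patient interictal/ictal ROI tables plus the clinical table.

    Deterministic given ``config.seed``: per-patient level shifts are drawn
    once, the ictal truth is the interictal truth times the structure's change
    factor, and independent truncated-Gaussian observation noise (sd
    ``config.noise_sd``, floor 0.05) lands on the PI scale before counts are
    constructed.
    """
    config.validate(atlas)
    rng = np.random.default_rng(config.seed)
    patients = [f"P{i + 1}" for i in range(config.n_patients)]

    # clinical table + risk strata first: the change map depends on them
    clin_rows = []
    for pid, items, side, t_inj, t_sz in zip(
        patients, config.clinical_items, config.onset_sides,
        config.injection_times_s, config.seizure_durations_s,
    ):
        rec = score_sudep7(items, config.sudep7_weights, patient_id=pid)
        clin_rows.append(
            {"patient": pid, **{f"i{j+1}": items[j] for j in range(7)},
             "onset_side": side, "injection_time_s": t_inj,
             "seizure_duration_s": t_sz, "sudep7_score": rec.score,
             "stratum": rec.stratum}
        )
    clinical = pd.DataFrame(clin_rows).set_index("patient")

    level_names = sorted(config.pi_levels)
    tables: dict = {}
    truth_rows = []
    for pid in patients:
        side = clinical.loc[pid, "onset_side"]
        high_risk = clinical.loc[pid, "stratum"] == "high"

        # resolve tokens for this patient's onset side
        level_of = {name: "normal" for name in atlas.names}
        for token, level in config.membership.items():
            level_of[atlas.resolve_side(token, side)] = level
        factor_of = {name: config.change_by_level.get(level_of[name], 1.0)
                     for name in atlas.names}
        for token, f in config.change_overrides.items():
            factor_of[atlas.resolve_side(token, side)] = f
        if high_risk:
            for token in config.high_risk_no_change:
                factor_of[atlas.resolve_side(token, side)] = 1.0

        # one level shift per (patient, level), clipped to the level's band
        shift = {}
        for name in level_names:
            lv = config.pi_levels[name]
            val = lv.mean + rng.normal(0.0, lv.between_sd) if lv.between_sd > 0 else lv.mean
            shift[name] = float(np.clip(val, lv.lo, lv.hi))

        names = sorted(atlas.names)
        inter_truth = pd.Series({n: shift[level_of[n]] for n in names})
        ictal_truth = pd.Series({n: inter_truth[n] * factor_of[n] for n in names})

        for state, tru in (("interictal", inter_truth), ("ictal", ictal_truth)):
            # absorber set closing the leave-one-out PI sum constraint: the
            # normal-level structures whose target in THIS state is the plain
            # reference level (interictally all of them; ictally those whose
            # change factor is 1).  Every other structure's PI is exact.
            absorb = {n for n in names
                      if level_of[n] == "normal"
                      and (state == "interictal" or factor_of[n] == 1.0)}
            if config.noise_sd > 0:
                noise = np.clip(
                    rng.normal(0.0, config.noise_sd, size=len(tru)),
                    -NOISE_TRUNC, NOISE_TRUNC,
                )
                observed = np.maximum(tru.to_numpy() + noise, PI_FLOOR)
            else:
                observed = tru.to_numpy()
            observed = pd.Series(observed, index=tru.index)
            counts = _counts_for_targets(
                observed, absorb, config.n_voxels, config.global_scale
            )
            data = pd.DataFrame(
                {"n_voxels": config.n_voxels, "mean_counts": counts}
            )
            data.index.name = "structure"
            tables[(pid, state)] = RoiActivityTable(
                patient_id=pid, state=state, data=data
            )
            for n in names:
                truth_rows.append(
                    {"patient": pid, "state": state, "structure": n,
                     "level": level_of[n], "true_pi": float(tru[n]),
                     "observed_pi": float(observed[n]),
                     "change_factor": factor_of[n]}
                )

    truth = pd.DataFrame(truth_rows)
    return GeneratedCohort(tables=tables, clinical=clinical, truth=truth)


# --------------------------------------------------------------------------
# block phantoms

def generate_phantom(config: PhantomConfig, atlas: AtlasSpec, true_pi: pd.Series):
    """Block phantom: (activity, labels, gm_mask) volumes for the given PIs.

    Each structure in ``true_pi`` gets a disjoint cubic ROI on a regular
    lattice (``block_voxels`` wide, ``gap_voxels`` apart; a gap of 0 makes
    neighbouring blocks adjacent so the PSF mixes them).  Noiseless activity
    is ``true_pi * poisson_scale`` inside the ROI, then the volume is blurred
    with the Gaussian PSF and optionally Poisson-sampled.
    """
    config.validate()
    shape = tuple(int(s) for s in config.grid_shape)
    pitch = config.block_voxels + config.gap_voxels
    slots_per_axis = [max((s - config.gap_voxels) // pitch, 0) for s in shape]
    n_slots = int(np.prod(slots_per_axis))
    names = list(true_pi.index)
    if len(names) > n_slots:
        raise SyntheticError(
            f"grid {shape} fits {n_slots} ROIs of {config.block_voxels}^3 "
            f"(gap {config.gap_voxels}); {len(names)} requested"
        )
    labels = np.zeros(shape, dtype=np.int32)
    activity = np.zeros(shape, dtype=float)
    for idx, name in enumerate(names):
        iz, rem = divmod(idx, slots_per_axis[0] * slots_per_axis[1])
        iy, ix = divmod(rem, slots_per_axis[0])
        origin = [config.gap_voxels + i * pitch for i in (ix, iy, iz)]
        sl = tuple(slice(o, o + config.block_voxels) for o in origin)
        if labels[sl].any():
            raise SyntheticError(f"ROI placement overlap at {name!r}")
        labels[sl] = atlas.by_name(name).id
        activity[sl] = float(true_pi[name]) * config.poisson_scale
    gm_mask = labels > 0
    psf = PsfModel(fwhm_mm=config.psf_fwhm_mm, voxel_size_mm=config.voxel_size_mm)
    blurred = psf.blur(activity)
    if config.poisson:
        rng = np.random.default_rng(config.seed)
        blurred = rng.poisson(np.clip(blurred, 0.0, None)).astype(float)
    return blurred, labels, gm_mask
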