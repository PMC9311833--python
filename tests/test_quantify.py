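"""ROI means, partial-volume correction, perfusion indexes and change vectors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfuse_sudep.quantify import (
    PsfModel,
    QuantifyError,
    RoiActivityTable,
    change_vector,
    compute_roi_means,
    perfusion_index,
    pvc_region_gtm,
)


def _volumes(atlas):
    """3x3x3 grid with two 4-voxel ROIs (values 8 and 2) inside the GM mask."""
    act = np.zeros((3, 3, 3))
    lab = np.zeros((3, 3, 3), dtype=int)
    gm = np.zeros((3, 3, 3), dtype=bool)
    id_a = atlas.by_name("rectus_L").id
    id_b = atlas.by_name("rectus_R").id
    coords_a = [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)]
    coords_b = [(2, 0, 0), (2, 0, 1), (2, 1, 0), (2, 1, 1)]
    for c in coords_a:
        act[c], lab[c], gm[c] = 8.0, id_a, True
    for c in coords_b:
        act[c], lab[c], gm[c] = 2.0, id_b, True
    return act, lab, gm


def test_roi_means_by_direct_summation(atlas):
    act, lab, gm = _volumes(atlas)
    table = compute_roi_means(act, lab, gm, atlas)
    assert table.data.loc["rectus_L", "mean_counts"] == 8.0
    assert table.data.loc["rectus_R", "mean_counts"] == 2.0
    assert (table.data["n_voxels"] == 4).all()
    assert len(table.data) == 2  # absent structures omitted, not zeroed


def test_roi_means_constant_field_and_mask_exclusion(atlas):
    act = np.full((3, 3, 3), 3.7)
    _a, lab, gm = _volumes(atlas)
    table = compute_roi_means(act, lab, gm, atlas)
    assert np.allclose(table.data["mean_counts"], 3.7)
    # voxels outside the GM mask never contribute
    act2 = act.copy()
    act2[~gm] = 1e6
    table2 = compute_roi_means(act2, lab, gm, atlas)
    pd.testing.assert_frame_equal(table.data, table2.data)


def test_roi_means_input_validation(atlas):
    act, lab, gm = _volumes(atlas)
    with pytest.raises(QuantifyError, match="shapes"):
        compute_roi_means(act[:2], lab, gm, atlas)
    with pytest.raises(QuantifyError, match="mask is empty"):
        compute_roi_means(act, lab, np.zeros_like(gm), atlas)


def test_pvc_identity_at_zero_fwhm(atlas):
    act, lab, gm = _volumes(atlas)
    table = compute_roi_means(act, lab, gm, atlas)
    out = pvc_region_gtm(table, lab, gm, PsfModel(fwhm_mm=0.0))
    pd.testing.assert_frame_equal(out.data, table.data)


def test_pvc_inverts_forward_blur(atlas):
    """Forward-blur oracle: blur planted activity, correct, recover within 1%."""
    act, lab, gm = _volumes(atlas)
    psf = PsfModel(fwhm_mm=2.0, voxel_size_mm=1.0)
    observed = compute_roi_means(psf.blur(act), lab, gm, atlas)
    # blur mixes the ROIs: observed means are biased
    assert observed.data.loc["rectus_L", "mean_counts"] < 8.0
    corrected = pvc_region_gtm(observed, lab, gm, psf)
    assert corrected.data.loc["rectus_L", "mean_counts"] == pytest.approx(8.0, rel=0.01)
    assert corrected.data.loc["rectus_R", "mean_counts"] == pytest.approx(2.0, rel=0.01)


def test_pvc_needs_at_least_two_regions(atlas):
    act, lab, gm = _volumes(atlas)
    single = compute_roi_means(act, lab, gm, atlas)
    single = RoiActivityTable("?", "interictal", single.data.iloc[:1])
    with pytest.raises(QuantifyError, match=">= 2 regions"):
        pvc_region_gtm(single, lab, gm, PsfModel(fwhm_mm=2.0))


def _table(means, n_voxels=None):
    n = n_voxels or [10] * len(means)
    data = pd.DataFrame(
        {"n_voxels": n, "mean_counts": list(means)},
        index=pd.Index([f"s{i}" for i in range(len(means))], name="structure"),
    )
    return RoiActivityTable("T", "interictal", data)


def test_perfusion_index_leave_one_out_arithmetic():
    pi = perfusion_index(_table([2.0, 1.0, 1.0]))
    assert pi.values["s0"] == pytest.approx(2.0)
    assert pi.values["s1"] == pytest.approx(1.0 / 1.5)
    assert pi.values["s2"] == pytest.approx(1.0 / 1.5)


def test_perfusion_index_homogeneous_and_global_mode():
    pi = perfusion_index(_table([5.0, 5.0, 5.0, 5.0]))
    assert np.allclose(pi.values, 1.0)
    g = perfusion_index(_table([2.0, 1.0, 1.0]), denominator="global")
    assert g.values["s0"] == pytest.approx(2.0 / (4.0 / 3.0))
    with pytest.raises(QuantifyError, match="denominator mode"):
        perfusion_index(_table([1.0, 2.0]), denominator="other")


def test_perfusion_index_errors():
    with pytest.raises(QuantifyError, match=">= 2"):
        perfusion_index(_table([1.0]))
    with pytest.raises(QuantifyError, match="zero"):
        perfusion_index(_table([0.0, 0.0]))


@settings(max_examples=50, derandomize=True)
@given(
    means=st.lists(st.floats(0.1, 10.0), min_size=3, max_size=10),
    scale=st.floats(0.01, 100.0),
)
def test_perfusion_index_is_scale_invariant(means, scale):
    base = perfusion_index(_table(means)).values
    scaled = perfusion_index(_table([m * scale for m in means])).values
    assert np.allclose(base, scaled, rtol=1e-9)


def test_change_vector_relative_arithmetic():
    inter = perfusion_index(_table([2.0, 1.0, 1.0]))
    same = change_vector(inter, _as_state(inter, "ictal"))
    assert np.allclose(same.values, 0.0)
    ict = _as_state(inter, "ictal")
    ict.values["s0"] *= 1.3
    up = change_vector(inter, ict)
    assert up.values["s0"] == pytest.approx(0.30)
    ict2 = _as_state(inter, "ictal")
    ict2.values["s1"] *= 0.8
    down = change_vector(inter, ict2)
    assert down.values["s1"] == pytest.approx(-0.20)


def _as_state(vec, state):
    from perfuse_sudep.quantify import PerfusionVector

    return PerfusionVector(vec.patient_id, state, vec.values.copy())


def test_change_vector_requires_matching_structures():
    inter = perfusion_index(_table([2.0, 1.0, 1.0]))
    ict = _as_state(inter, "ictal")
    ict.values = ict.values.drop("s2")
    with pytest.raises(QuantifyError, match="structure sets"):
        change_vector(inter, ict)
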