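"""Shared fixtures.

The heavier fixtures (full-size candy-cane phantom and its complete
analysis) are session-scoped so the geometry, conservation and
antisymmetry tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from aortaflow import geometry as geo
from aortaflow import hemodynamics as hd
from aortaflow import phantom as ph


@pytest.fixture(scope="session")
def small_straight():
    """Small noiseless straight tube with a constant waveform (fast)."""
    spec = ph.PhantomSpec(
        geometry="straight-tube",
        radius=10.0,
        length=100.0,
        n_frames=10,
        waveform=np.full(10, 0.3),
    )
    fld, truth = ph.generate(spec)
    return spec, fld, truth


@pytest.fixture(scope="session")
def candy_forward():
    """Default-size noiseless candy-cane with pure forward flow."""
    wave = ph.default_waveform(20, peak=0.5, retro_lobe=0.0)
    spec = ph.PhantomSpec(geometry="candy-cane", waveform=wave, seed=1)
    fld, truth = ph.generate(spec)
    return spec, fld, truth


@pytest.fixture(scope="session")
def candy_pipeline(candy_forward):
    """Full analysis products for the forward-flow candy-cane phantom."""
    spec, fld, truth = candy_forward
    iso, mask_iso = hd.interpolate_isotropic(fld, truth.mask)
    cl = geo.extract_centerline(mask_iso, iso.spacing, origin=iso.origin)
    asn = geo.assign_voxels(mask_iso, cl, iso.spacing, origin=iso.origin)
    cl, asn, _ = hd.ensure_downstream_orientation(iso, cl, asn)
    ff, rf = hd.forward_reverse_flow(iso, asn, cl)
    return {
        "spec": spec,
        "field": fld,
        "truth": truth,
        "iso": iso,
        "mask_iso": mask_iso,
        "centerline": cl,
        "assignment": asn,
        "ff": ff,
        "rf": rf,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_field(velocity, spacing=(1.0, 1.0, 1.0), frame_duration=50.0, venc=1.5, magnitude=None):
    """Convenience builder for hand-crafted velocity fields."""
    from aortaflow.field import VelocityField4D

    velocity = np.asarray(velocity, float)
    if magnitude is None:
        magnitude = np.ones(velocity.shape[:4])
    return VelocityField4D(
        velocity=velocity,
        magnitude=magnitude,
        spacing=spacing,
        frame_duration=frame_duration,
        venc=venc,
    )
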