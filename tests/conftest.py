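import numpy as np
import pytest

from plgic.synth import (MotionSpec, PentamerSpec, apply_domain_transform,
                         build_ideal_pentamer)


@pytest.fixture(scope="session")
def pentamer():
    """Ideal C5 pentamer with default (closed-state) gate ring radii."""
    return build_ideal_pentamer(PentamerSpec())


def radial_unit(model, chain):
    com = model.coords[model.chain_id == chain].mean(axis=0)
    u = np.array([com[0], com[1], 0.0])
    return u / np.linalg.norm(u)


def make_desensitized(model, tmd_tilt=7.0, tmd_rot=14.2, tmd_shift=2.8,
                      ecd_tilt=4.3, ecd_rot=6.3, noise_sigma=0.0, seed=0):
    """Closed→desensitized-like symmetric motion applied to all subunits."""
    out = model
    for i, ch in enumerate(model.receptor_chains()):
        u = radial_unit(model, ch)
        out = apply_domain_transform(out, MotionSpec(
            chain=ch, domain="TMD", tilt_deg=tmd_tilt, rotation_deg=tmd_rot,
            com_shift_vec=tuple(tmd_shift * u), noise_sigma=noise_sigma,
            seed=seed * 10 + i))
        out = apply_domain_transform(out, MotionSpec(
            chain=ch, domain="ECD", tilt_deg=ecd_tilt, rotation_deg=ecd_rot,
            noise_sigma=noise_sigma, seed=seed * 10 + i + 5))
    out.label = "desensitized-like"
    return out


@pytest.fixture(scope="session")
def desensitized(pentamer):
    return make_desensitized(pentamer)
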