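import numpy as np
import pytest

from colonychirality import (
    SyntheticColonySpec,
    extract_traces,
    generate_boundaries,
    render_colony,
)

# Small colony used by fast pipeline tests (full-size colonies are
# exercised in the acceptance suite).
SMALL = dict(
    n_sectors=12,
    r_i=150.0,
    r_max=1500.0,
    pixel_size=5.0,
    image_px=640,
)


@pytest.fixture(scope="session")
def noiseless_colony():
    """Wiggle-free pinwheel colony at theta = 8 deg, with ground truth."""
    spec = SyntheticColonySpec(theta_true=8.0, wiggle_D=0.0, seed=11, **SMALL)
    bounds = generate_boundaries(spec)
    pair = render_colony(bounds, spec)
    return spec, bounds, pair


@pytest.fixture(scope="session")
def noiseless_traceset(noiseless_colony):
    spec, bounds, pair = noiseless_colony
    return extract_traces(pair, colony_id="noiseless")


def gt_points_px(bounds, spec, n_dense=2000):
    """Ground-truth boundary points in pixel coordinates (x, y)."""
    c = (spec.image_px - 1) / 2.0
    pts = []
    for b in bounds:
        u = np.linspace(0, np.log(spec.r_max / spec.r_i), n_dense)
        r = spec.r_i * np.exp(u)
        phi = np.interp(u, np.log(b.r / spec.r_i), b.phi)
        x = c + r * np.cos(phi) / spec.pixel_size
        y = c + r * np.sin(phi) / spec.pixel_size
        pts.append(np.column_stack([x, y]))
    return np.vstack(pts)
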