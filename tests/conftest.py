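import numpy as np
import pytest

from hemoptics.forward_models import DTOF, Geometry, OpticalProperties, convolve_irf, td_reflectance
from hemoptics.pipeline import PhysioSeries


@pytest.fixture
def op():
    return OpticalProperties(mua=0.01, musp=1.0, wavelength=785.0)


@pytest.fixture
def geom():
    return Geometry(rho=25.0)


@pytest.fixture
def t_bins():
    return np.arange(400) * 10.0 + 5.0  # ps


@pytest.fixture
def gaussian_irf(t_bins):
    irf = np.exp(-0.5 * ((t_bins - 500.0) / 60.0) ** 2)
    return irf / irf.sum() * 1e6


def make_dtof(op, geom, t_bins, irf, total_counts=1e6, rng=None):
    """Forward-generate a DTOF (Poisson-sampled when rng given)."""
    refl = td_reflectance(op, geom, t_bins)
    model = convolve_irf(refl, irf, float(t_bins[1] - t_bins[0]))
    lam = model / model.sum() * total_counts
    counts = lam if rng is None else rng.poisson(lam).astype(float)
    return DTOF(t_bins=t_bins, counts=counts, irf=irf, wavelength=op.wavelength)


def make_series(time, subject="S01", mask="FFP2", hemi="left", **channels):
    return PhysioSeries(
        subject_id=subject,
        mask_type=mask,
        hemisphere=hemi,
        time=np.asarray(time, float),
        channels={k: np.asarray(v, float) for k, v in channels.items()},
    )
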