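"""Shared helper: wrap bare monthly-mean layers in a CloudClimatology."""

import numpy as np

from cloudclim.climatology import CloudClimatology
from cloudclim.grid import GridTransform


def clim_from_mu(mu, transform=GridTransform(0.0, 0.0, 0.01, 0.01)):
    mu = np.asarray(mu, float)
    shape = mu.shape[1:]
    nanf = np.full(shape, np.nan)
    return CloudClimatology(
        mu=mu, sigma=np.full_like(mu, np.nan), mean_annual=nanf,
        intra_annual=nanf, inter_annual=nanf, spatial_var=nanf,
        concentration=nanf, peak_month=nanf,
        months_available=np.full(shape, 12), transform=transform)
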