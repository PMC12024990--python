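"""Free Brownian diffusion of a 50 nm particle in interstitial fluid.

Runs the particle mover in an obstacle-free domain, fits the diffusion
coefficient from the mean-squared displacement, and compares with the
Stokes-Einstein value k_B T / zeta for the configured drag law.
"""

from nanodiff import constants as c
from nanodiff.analysis import compute_msd, fit_diffusion
from nanodiff.forces import NanoparticleProps
from nanodiff.transport import (
    TransportConfig,
    free_diffusion_coefficient,
    simulate,
)

props = NanoparticleProps()  # 50 nm, density 5000 kg/m^3
cfg = TransportConfig(
    props=props,
    lattice=None,               # unbounded free space
    viscosity=c.WATER_VISCOSITY,
    dt=1e-4,
    n_steps=2000,
    n_particles=200,
    sample_every=2,
    replicates=1,
    seed=11,
    brownian_mode="gaussian",   # fluctuation-dissipation kicks
    init="uniform",
)
result = simulate(cfg)
fit = fit_diffusion(compute_msd(result.records))
d_se = free_diffusion_coefficient(props, c.WATER_VISCOSITY, c.BODY_TEMPERATURE)

print(f"fitted D      = {fit.d_total:.4e} m^2/s")
print(f"Stokes-Einstein = {d_se:.4e} m^2/s")
print(f"ratio         = {fit.d_total / d_se:.3f}")
# the ratio should sit within a few percent of 1: the mover's free-space
# diffusion is the thermodynamically consistent one.
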