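"""Physical constants and default material properties (SI units).

Defaults describe a 50 nm ligand-coated particle in tumor interstitial fluid
at body temperature.  Every value here is configurable at run time; these are
the documented baseline conditions used throughout the package.
"""

# Fundamental
K_B = 1.380649e-23  # Boltzmann constant, J/K
EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

# Interstitial fluid (water-like, 310 K)
WATER_VISCOSITY = 7.0e-4  # dynamic viscosity, Pa s
WATER_DENSITY = 1.0e3  # kg/m^3
WATER_EPS_R = 78.5  # relative permittivity
BODY_TEMPERATURE = 310.0  # K

# Electrolyte screening (physiological saline)
DEBYE_LENGTH = 1.0e-9  # m

# Surface chemistry baseline.  The Hamaker constant sits at the low end of the
# Lifshitz range for hydrated biopolymer/polymer interfaces across water
# (1e-21..1e-20 J); at this value a double-layer barrier can form for surface
# potentials of a few tens of mV, which is the regime the zeta-potential
# studies operate in.
HAMAKER = 1.0e-21  # J
CONTACT_DISTANCE = 0.157e-9  # minimum-contact (equilibrium) distance d0, m
AB_DECAY_LENGTH = 0.6e-9  # acid-base decay length lambda, m

# Nanoparticle baseline (magnetite-like core)
NP_DIAMETER = 50e-9  # m
NP_DENSITY = 5.0e3  # kg/m^3
NP_MSAT = 4.8e5  # saturation magnetization, A/m

# Surface-tension acid-base components of water, J/m^2 (van Oss convention)
GAMMA_W_PLUS = 25.5e-3
GAMMA_W_MINUS = 25.5e-3

# Per-contact sticking probability of an adhesion-capable wall encounter.
# The wall chemistry decides *whether* a surface can capture a particle (the
# barrier / force-balance classification in `forces.adhesion_profile`); this
# single kinetic constant decides how fast capture happens on the lattice.
# Calibrated once (`experiments.calibrate_sticking_probability`) so the
# baseline fiber-network condition reproduces the reference hindered
# diffusivity of ~3.8e-13 m^2/s for the 50 nm baseline particle; held fixed
# across all experiments.
STICK_PROBABILITY = 9.5e-3

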