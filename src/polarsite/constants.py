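"""Unit system: energies in eV, charges in e, lengths in Å, potentials in V,
fields in V/Å, times in ps, temperatures in K.

In these units Q*phi (e·V) and mu·E (e·Å · V/Å) are already energies in eV,
so no conversion factors appear in the Hamiltonian.
"""

#: Boltzmann constant, eV/K.
K_B = 8.617333e-5

#: Coulomb constant e^2/(4*pi*eps0) in eV·Å; converts a sum-over-states
#: polarizability in e^2·Å^2/eV to the conventional volume unit Å^3.
ALPHA_TO_A3 = 14.3996


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in eV."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return K_B * temperature
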