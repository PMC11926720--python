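"""Shared physical constants (SI, CODATA 2018)."""

R_GAS = 8.314462618        # J/(mol K)
K_BOLTZMANN = 1.380649e-23  # J/K
N_AVOGADRO = 6.02214076e23  # 1/mol
P_ATM = 101325.0            # Pa
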