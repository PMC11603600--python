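"""Eckart tunneling factors for a hydrogen-transfer-like barrier.

An asymmetric one-dimensional Eckart barrier is fitted to ZPE-corrected
forward/reverse barrier heights and the saddle-point imaginary frequency;
kappa(T) is the Boltzmann average of the transmission probability.
"""

from ratepath.rates import EckartBarrier, eckart_kappa

# light-atom transfer: tall thin barrier, large imaginary frequency
barrier = EckartBarrier(forward_barrier=6.0, reverse_barrier=14.0,
                        imaginary_frequency=1500.0)

print("dV1 = 6.0, dV2 = 14.0 kcal/mol, nu* = 1500 cm^-1")
print(f"{'T/K':>7} {'kappa':>10}")
for T in (250.0, 298.15, 350.0, 450.0, 650.0, 1000.0):
    print(f"{T:7.1f} {eckart_kappa(barrier, T):10.3f}")

print("""
kappa multiplies the classical rate constant.  At room temperature a
hydrogen transfer through a barrier like this proceeds an order of
magnitude faster than classical TST predicts; the correction decays toward
1 as the temperature rises.""")
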