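"""Evaluate a Prony series in time and frequency domain and check viability.

The normalized relaxation spectrum (g_k, tau_k, g_inf) determines both the
relaxation modulus mu(t) and the storage/loss moduli u'(w), u''(w); at t = 0
and w -> infinity both equal g_inf + sum(g_k) = 1.
"""

import numpy as np

from pronyfit import (PronySeries, loss_modulus, relaxation_modulus,
                      storage_modulus, viability_check)

p = PronySeries(g=[0.1, 0.15, 0.2], tau=[0.005, 0.05, 0.5])
print(f"order N = {p.order}, g_inf = {p.g_inf:.2f}, viable = {viability_check(p)}")

for t in (0.0, 0.05, 0.5, 5.0):
    print(f"mu({t:4.2f} s)   = {relaxation_modulus(p, t):.4f}")

for f_hz in (1.0, 10.0, 90.0):
    w = 2 * np.pi * f_hz
    print(f"f = {f_hz:5.1f} Hz: u' = {storage_modulus(p, w):.4f}, "
          f"u'' = {loss_modulus(p, w):.4f}")

print()
print(p.to_abaqus_table())
# mu(t) decays from 1 toward g_inf = 0.55 as each branch relaxes; the storage
# modulus rises with frequency between the same limits while the loss modulus
# peaks near w*tau_k = 1 of each branch.  The table is the solver-ready
# normalized Prony form.
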