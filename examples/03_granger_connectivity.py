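"""Directed connectivity from a coupled-oscillator simulation.

Simulates five region signals where the fronto-central region drives
the central region through a theta-resonant (6 Hz) coupling, then
estimates time-domain and spectral Granger causality in both
directions.  Causality is directional: the forward value is large, the
reverse near zero, and the spectral measure peaks inside theta (4-8 Hz).
"""

import numpy as np

from neuromkl import granger, synthdata

spec = synthdata.theta_coupled_spec(strength=0.4)
eeg = synthdata.gen_coupled_var(spec, trials=1, n_samples=8192, seed=2)
f_idx = eeg.channels.index("FCENTRAL")
c_idx = eeg.channels.index("CENTRAL")
x_source = eeg.data[0, f_idx]
x_target = eeg.data[0, c_idx]

p = granger.select_order_bic(x_target, x_source)
print(f"BIC-selected VAR order: {p}")

F_fwd = granger.gc_time(x_target, x_source, p)
F_rev = granger.gc_time(x_source, x_target, p)
print(f"time-domain causality  F(FCENTRAL->CENTRAL) = {F_fwd:.3f}")
print(f"                       F(CENTRAL->FCENTRAL) = {F_rev:.4f}")

model = granger.fit_var_pair(x_target, x_source, p)
freqs = np.arange(0.0, eeg.fs / 2 + 0.25, 0.5)
I = granger.spectral_gc(model, freqs, eeg.fs)
in_theta = (freqs >= 4) & (freqs <= 8)
print(f"spectral causality peak at {freqs[np.argmax(I)]:.1f} Hz "
      f"(theta-band mean {I[in_theta].mean():.3f})")
# The coupling was injected at a 6 Hz resonance, so the spectral
# causality concentrates in the theta band and only in the F->C direction.
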