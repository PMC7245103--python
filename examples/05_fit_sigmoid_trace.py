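"""Sigmoidal kinetics: simulate a stopped-flow-style trace and fit it.

Generates a noisy synthetic concentration trace from the two-step
autocatalytic rate law (slow uncatalyzed nucleation A -> B plus
autocatalytic growth A + B -> 2B), computes the finite-difference rate
curve, fits the closed form back and reports the recovered constants and
the lag time.
"""

import numpy as np

from moblue.analysis import lag_time
from moblue.kinetics import finite_difference_rate, fit_sigmoid, simulate_sigmoid

t = np.linspace(0.0, 4000.0, 300)          # seconds
true = dict(k1=1e-4, k2=1.2, A0=0.25 / 36, B0=0.0)
trace = simulate_sigmoid(times=t, noise_sd=1e-4, seed=1, **true)

rate = finite_difference_rate(trace)
print(f"rate curve peaks at t = {t[np.argmax(rate.signal)]:.0f} s "
      "(the autocatalytic inflection)")

fit = fit_sigmoid(trace, fixed={"B0": 0.0})
print(f"k1 (uncatalyzed, s^-1):      true {true['k1']:.2e}  fit {fit.k1:.2e}")
print(f"k2 (autocatalytic, M^-1s^-1): true {true['k2']:.2f}    fit {fit.k2:.2f}")
print(f"A0 (precursor, M):           true {true['A0']:.4f}  fit {fit.A0:.4f}")
print(f"lag time: {lag_time(t, fit.predict(t)):.0f} s")
# With 2% noise the constants come back within a few percent; the lag is
# the tangent-intercept induction period of the sigmoid.
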