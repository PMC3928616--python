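"""Activation threshold of an active fiber by dichotomy (bisection).

An excitable fiber (classic squid-axon Na/K channels) sits in the field
of a point-source electrode.  The stimulus amplitude multiplying a 0.2-ms
cathodic pulse is bisected until the smallest current eliciting an action
potential is bracketed to 1%.
"""

import math

import numpy as np

from neurostimfem.cable import (Waveform, compartmentalize, find_threshold,
                                straight_fiber)
from neurostimfem.membrane import MembraneParams, mS_per_cm2, ohm_cm, uF_per_cm2

SIGMA = 0.2
params = MembraneParams(cm=uF_per_cm2(1.0), gl=mS_per_cm2(0.3), El=-65e-3,
                        active=True)
model = compartmentalize(straight_fiber(120e-6, 2e-6), 2e-6,
                         Ra=ohm_cm(100.0), params=params)

pulse = Waveform.rect(0.0, 2e-4, -1.0)   # 0.2-ms cathodic pulse
print(f"{'electrode distance':>20} {'threshold multiplier':>22}")
for z in (20e-6, 40e-6, 60e-6):
    r = np.linalg.norm(model.centers - np.array([0, 60e-6, -z]), axis=1)
    ve = 1e-6 / (4 * math.pi * SIGMA * r)   # field of a 1-uA point source
    res = find_threshold(model, ve, pulse, detect=-10e-3,
                         bracket=(0.01, 300.0), dt=2e-5, T=2e-3)
    print(f"{z * 1e6:18.0f} um {res.amplitude:20.2f} x")
# The threshold (in units of the 1-uA reference field) grows with
# electrode-to-fiber distance: farther electrodes need more current to
# trigger the all-or-none sodium spike.
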