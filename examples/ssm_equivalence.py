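"""Discretize a random stable state-space model and show that the recurrent
scan, the convolutional scan and the structured kernel's impulse response
all describe the same linear system.

Run:  python examples/ssm_equivalence.py
"""

import numpy as np

from multiphys.ssm_core import (
    SSMParams,
    build_kernel,
    discretize,
    scan_convolutional,
    scan_recurrent,
)

rng = np.random.default_rng(0)
n, L = 4, 32

A = rng.normal(size=(n, n))
A -= (np.abs(np.linalg.eigvals(A).real).max() + 0.5) * np.eye(n)  # make it stable
params = SSMParams(A=A, B=rng.normal(size=(n, 1)), C=rng.normal(size=(1, n)), delta=0.2)
disc = discretize(params)
print(f"state size {n}, delta {params.delta}, B_bar branch: {disc.method}")
print(f"spectral radius of A_bar: {np.abs(np.linalg.eigvals(disc.A_bar)).max():.4f}  (< 1: stable)")

rho = rng.normal(size=L)
rec = scan_recurrent(disc, rho)
conv = scan_convolutional(disc, rho)
print(f"max |conv - recurrent| over {L} steps: {np.abs(conv - rec).max():.2e}")

impulse = np.zeros(L)
impulse[0] = 1.0
kernel = build_kernel(disc, L).k
print(f"max |impulse response - kernel|: {np.abs(scan_recurrent(disc, impulse) - kernel).max():.2e}")
print("The two deviations are at numerical round-off: the recurrence and the")
print("causal convolution with the structured kernel are the same operator.")
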