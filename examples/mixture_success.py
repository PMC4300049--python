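"""Estimate how often random three-strand mixtures assemble correctly.

Draws random 60-80 nt targets split into two 20-40 nt main chains with one
helper across the split, and scores each mixture with the decreasing-
temperature folding-order check.  A small pilot here; the full study uses
10000 trials (scripts/acceptance.py).
"""

from lcrgene import EnergyModel, MixtureTrialConfig, estimate_success_rate

config = MixtureTrialConfig(n_trials=300, seed=1)
fraction, (lo, hi) = estimate_success_rate(config, EnergyModel())
print(f"{config.n_trials} random mixtures, seed {config.seed}:")
print(f"  success fraction {fraction:.3f} (95% Wilson CI {lo:.3f}-{hi:.3f})")
print("A mixture fails when an undesigned duplex (a hairpin, a self-dimer or")
print("a spurious cross-pairing) melts at or above the weakest designed")
print("junction, so it would fold before assembly completes.")
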