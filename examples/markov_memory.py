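"""Spin-memory loss of 15NH4+ under successive proton exchange events.

Classical Markov chain: each event swaps one uniformly chosen proton for an
unpolarized bath proton.  Three memory metrics are tracked; all collapse
within roughly ten events, which is why a dissociation rate of ~20 1/s
destroys the ZULF signal during a 0.5 s shuttle.
"""

from zulfsim import MarkovConfig, analytic_survival, run_chain

curve = run_chain(MarkovConfig(n_sites=4, n_events=15, n_trials=50_000, seed=1))
frame = curve.to_frame()
print(frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

k = 10
print(f"\nafter {k} events:")
print(f"  surviving original sites: {curve.survival[k]:.4f} "
      f"(closed form {analytic_survival(4, k):.4f})")
print(f"  still in |aaaa>: {curve.p_initial[k]:.4f} "
      f"(1/16 = 0.0625 is complete randomization)")
print(f"  normalized configuration entropy: {curve.entropy[k]:.4f} (max 1)")
print("-> ten exchange events essentially erase the initial spin state")
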