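"""Estimate polymerase fidelity from (simulated) amplicon sequencing counts.

Run:  python examples/05_fidelity_estimation.py
"""

from taqdesign import SeqSimConfig, estimate_fidelity, simulate_counts

cfg = SeqSimConfig(true_p=3e-5, efficiency=2.0, cycles=30, coverage=100_000,
                   seed=42)
counts = simulate_counts(cfg)  # 99-bp amplicon, 20-bp primers masked

result = estimate_fidelity(counts, cfg.efficiency, cfg.cycles)
print(f"Pool substitution frequency f = {result.f:.3e}")
print(f"Per-cycle error rate p = E*f/n = {result.p:.3e} "
      f"(simulated truth {cfg.true_p:.1e})")
print(f"Fidelity: {result.fidelity_nt_per_error:,.0f} nt/error")
s = result.spectrum
print(f"Transitions {s.transitions:,} vs transversions {s.transversions:,} "
      f"(tv:ts ratio {s.transversion_transition_ratio:.2f})")
# the simulation weights transitions 2:1, so roughly half of all errors are
# the four transition types
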