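"""How many reads does a selection experiment need?

Sweeps knock-in frequency and effect size through the depth-guidance
calculator (normal approximation on the log fold change, Monte-Carlo
verified) and prints recommended reads per sample alongside the number of
knock-in clones tracked at a 100 ng template.
"""

from crisprselect import recommend_depth, simulate_power

print(f"{'KI freq':>8}{'effect':>8}{'reads':>9}{'clones':>8}{'MC power':>10}")
for ki in (0.08, 0.02, 0.01):
    for effect in (0.2, 0.5):
        rec = recommend_depth(ki, effect, alpha=0.05, power=0.9)
        mc = simulate_power(rec.recommended_reads, ki, effect, n_sim=4000, seed=1)
        print(f"{ki:>8.2%}{effect:>8.1f}{rec.recommended_reads:>9}"
              f"{rec.clones:>8.0f}{mc:>10.2f}")

print("\nAt 2% knock-in and a 5-fold effect, well under the typical")
print("30,000-50,000 reads per target site suffice; shallow effects at low")
print("knock-in frequencies are what drive depth requirements up.")
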