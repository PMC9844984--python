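"""Choose a phasing window size automatically.

Fits the window-size beta regression on a freshly simulated training grid
(small datasets spanning gamete counts, coverages, error and recombination
rates), then asks it for window proportions at a few study designs.  The
coefficient signs show the trade-off: more data supports larger windows,
faster recombination demands smaller ones.
"""

import meioscan as ms

model = ms.fit_window_model(seed=5)

print("fitted coefficients (logit scale):")
for name in ("n_gametes", "coverage", "error_rate", "recomb_rate"):
    print(f"  {name:>12}: {model.coefficient(name):+.2e}")

print("\nrecommended window length for a 30,000-hetSNP chromosome:")
for n_gam, cov, rec in [(30, 0.2, 1.0), (150, 0.2, 1.0), (150, 1.0, 1.0), (150, 1.0, 4.0)]:
    w = model.predict_window_length(
        30_000, n_gametes=n_gam, coverage=cov, error_rate=0.005, recomb_rate=rec)
    print(f"  {n_gam:>5} gametes at {cov}x, r={rec}: {w} SNPs")

# designs outside the training grid are clamped to its hull with a warning
w = model.predict_window_length(
    30_000, n_gametes=1000, coverage=0.01, error_rate=0.005, recomb_rate=1.0)
print(f"\nSperm-seq-like design (clamped to the training hull): {w} SNPs")
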