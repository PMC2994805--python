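"""Closeness-of-fit grid search over (r, n) at a fixed dominance composition.

Sweeps the frequency ratio r and the required locus count n, solves the
admissible x-range per cell, predicts prevalence and the five relative-class
recurrence risks, and scores each cell against the observed epidemiological
targets.  CoF < 4 (chi-square, 1 df) counts as an acceptable fit.
"""
import mssusmod as m

cells = m.sweep(composition=(0.2, 0.8, 0.0))   # 20% dominant, 80% recessive
best, acceptable = m.find_optimum(cells)

print("Best fit: r=%g, n=%d, x in [%d, %d], CoF=%.2f"
      % (best.r, best.n, best.solution.x_low, best.solution.x_high, best.cof))
print("Acceptable cells (CoF < 4): %d, spanning n=%d..%d, r>=%g"
      % (len(acceptable), min(c.n for c in acceptable),
         max(c.n for c in acceptable), min(c.r for c in acceptable)))
print()
print("Predictions at the optimum (low - high over the x-range):")
for name, (lo, hi) in best.predictions.items():
    print("  %-20s %.2f - %.2f%%" % (name, 100 * lo, 100 * hi))
print()
dom_cells = m.sweep(composition=(1.0, 0.0, 0.0))
dom_best, dom_acceptable = m.find_optimum(dom_cells)
print("All-dominant composition: min CoF = %.1f, acceptable cells: %d"
      % (dom_best.cof, len(dom_acceptable)))
print()
print("Reading: mostly-recessive architectures fit the family data; a purely")
print("dominant architecture over-predicts first-degree recurrence and never")
print("reaches an acceptable fit.")
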