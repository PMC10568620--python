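# Default rate constants for the four-genotype EGFR-TKI resistance model.
# Growth rates (a, b, c, f) and mutation rates (g, h, k, p, q) are per day.
#   A = erlotinib (first-/second-generation EGFR-TKI)
#   B = osimertinib (third-generation EGFR-TKI)
#   C = erlotinib + osimertinib combination
parameters:
  A: {a: -0.17, b: 0.045, c: -0.13, f: 0.022,
      g: 1.0e-7, h: 1.0e-7, k: 1.0e-7, p: 1.0e-7, q: 1.0e-7}
  B: {a: -0.32, b: -0.15, c: 0.024, f: 0.022,
      g: 1.0e-7, h: 1.0e-7, k: 1.0e-7, p: 1.0e-7, q: 1.0e-7}
  C: {a: -0.064, b: -0.0335, c: -0.0335, f: 0.022,
      g: 1.0e-7, h: 1.0e-7, k: 1.0e-7, p: 1.0e-7, q: 1.0e-7}
# Standard initial composition: 1e9 total cells, X0 = Y0 = 1e4, Z0 = 10,
# W0 the remainder.
initial: {total: 1.0e+9, x0: 1.0e+4, y0: 1.0e+4, z0: 10.0}
# Clinically motivated switch days (median progression-free survival under
# each first-line drug) and simulation horizon in days.
schedule: {switch_a_first: 307, switch_b_first: 567, horizon: 1000}
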