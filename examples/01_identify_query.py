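"""Authenticate a query sample against a reference panel.

Builds a synthetic 30-line reference panel, fits the null distribution of
unrelated-pair correlations, then identifies a query that is one panel line
with FREQ measurement noise added.  The printed table mirrors the standard
report: candidate line, correlation of allele frequencies over the shared
variant set, tail p-value under the null, and the classification call.
"""

from lineauth import (
    PanelSimSpec,
    add_freq_noise,
    fit_null,
    generate_panel,
    identify_full,
    pairwise_matrix,
)
from lineauth.identification import write_match_report

sim = generate_panel(PanelSimSpec(n_cells=30, n_sites=4000, seed=7))
null = fit_null(pairwise_matrix(sim.panel).upper_triangle())
print(f"null model: mu={null.mu:.3f} sigma={null.sigma:.3f} "
      f"(fit on {null.n_used} unrelated pairwise correlations)\n")

query = add_freq_noise(sim.profiles[11], sigma=5.0, seed=1)
results = identify_full(query, sim.panel, null)
print(write_match_report(results))
print("Pass 1 (permissive: every variant with depth >= 10 and FREQ > 0 in")
print("either sample) puts the true source CELL_011 on top at rho ~ 0.97 and")
print("flags a handful of borderline lines near the significance cut.  That")
print("ambiguity triggers pass 2, restricted to sites that discriminate the")
print("candidates (FREQ spread > 10, depth >= 20): the true line stays at")
print("rho ~ 0.96 while every other candidate collapses to background and is")
print("called unrelated.")
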