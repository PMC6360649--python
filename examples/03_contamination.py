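"""Estimate cross-contamination with the robust linear mixture model.

Mixes two panel lines at 85/15 (with per-site proportion noise and FREQ
noise, as in the simulation protocol), then deconvolves the mixture: the
dominant line is identified first, every other panel line is screened as a
contaminant by no-intercept robust regression on discriminative sites, and
components are added while their proportions stay positive and significant.
"""

from lineauth import (
    MixtureSimSpec,
    PanelSimSpec,
    find_contaminants,
    fit_null,
    generate_panel,
    pairwise_matrix,
    simulate_mixture,
)

sim = generate_panel(PanelSimSpec(n_cells=30, n_sites=4000, seed=7))
null = fit_null(pairwise_matrix(sim.panel).upper_triangle())

mix = simulate_mixture(
    sim.profiles[10],  # dominant line (85%)
    sim.profiles[20],  # contaminant   (15%)
    MixtureSimSpec(q1=0.85, sigma_q=0.05, sigma_f=1.0, seed=3),
)
est = find_contaminants(mix, sim.panel, null)
print(est.summary())
c = est.components[1]
print(f"\nThe possible mixture is {c.cell_id}, with proportion "
      f"q2 = {100 * c.q:.1f}%, with t-stat = {c.t_stat:.1f}")
print("\nThe planted 15% contaminant is recovered within a few percent; the")
print("search stopped once the next-best candidate no longer carried a")
print("positive, significant proportion.")
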