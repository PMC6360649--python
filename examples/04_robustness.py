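"""Robustness of identification to FREQ noise, position permutation and
variant dropout.

Three stress tests on a synthetic panel with a replicate pair:
(1) Gaussian noise added to both members' allele frequencies -- the pair's
correlation decays and identifiability is lost around sigma 15-20;
(2) randomly permuting a query's mutation positions -- the best match drops
to background, bounding the false-positive risk;
(3) keeping only 15% of a query's variants (read-subsampling emulation) --
the true line still ranks first.
"""

import numpy as np

from lineauth import (
    PanelSimSpec,
    add_freq_noise,
    build_panel,
    fit_null,
    generate_panel,
    identify,
    pairwise_matrix,
    permute_positions,
    simulate_dropout,
    threshold,
)

sim = generate_panel(PanelSimSpec(n_cells=30, n_sites=4000,
                                  related_pairs=((0, 1, 0.01),), seed=7))
null = fit_null(pairwise_matrix(sim.panel).upper_triangle())
L = threshold(1e-3, null)
print(f"relatedness threshold L_0.001 = {L:.3f}\n")

parent, child = sim.profiles[0], sim.profiles[1]
print("FREQ noise on the replicate pair:")
for sigma in (0, 5, 10, 15, 20):
    rhos = [
        pairwise_matrix(build_panel([
            add_freq_noise(parent, sigma, seed=rep),
            add_freq_noise(child, sigma, seed=100 + rep),
        ])).rho.iloc[0, 1]
        for rep in range(5)
    ]
    flag = "related" if np.mean(rhos) > L else "NOT identifiable"
    print(f"  sigma = {sigma:2d}: mean rho = {np.mean(rhos):.3f}  ({flag})")

best = [
    identify(permute_positions(sim.profiles[5], sim.panel.sites, seed=s),
             sim.panel, null).best().rho
    for s in range(50)
]
print(f"\npermuted positions: mean best-match rho = {np.mean(best):.3f} "
      "(background level -- no false match)")

hits = sum(
    identify(simulate_dropout(sim.profiles[9], 0.15, seed=s), sim.panel, null)
    .best().cell_id == "CELL_009"
    for s in range(10)
)
print(f"15% variant retention: true line ranked first in {hits}/10 runs")
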