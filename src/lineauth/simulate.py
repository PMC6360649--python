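"""Synthetic variant panels, mixtures, and robustness perturbations.

The panel generator emulates the statistical shape of RNA-seq variant
profiles from a large cancer cell-line collection:

* a *shared* pool of sites carried by every cell (germline-like variation in
  expressed transcripts), where each site has a population hom-alt
  probability drawn from a U-shaped Beta distribution, each cell draws its
  zygosity from it, and FREQ scatters around the heterozygous (~50%) or
  homozygous (~100%) center;
* *private* sites per cell (somatic/line-specific variants);
* over-dispersed read depths (negative binomial);
* optional related pairs (replicates / derivative lines) that share a
  (1 - divergence) fraction of the parent's variants with matched FREQ.

With the default parameters the pairwise correlation between unrelated cells
is centered near 0.46 with spread of a few hundredths, replicate pairs sit
above 0.9, and Gaussian FREQ noise of sigma 15-20 percent destroys
identifiability -- the regime the method is designed for.

Mixtures z of two profiles are formed per site with Gaussian-perturbed
proportions normalized to average 1,

    z = x1 * N(q1, sigma_q) + x2 * N(q2, sigma_q),   q2 = 1 - q1,

applied to both FREQ and DP, followed by Gaussian FREQ noise sigma_f and
clipping of FREQ into [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel_io import Panel, Profile, VariantKey, VariantRecord, build_panel

__all__ = [
    "MixtureSimSpec",
    "PanelSimSpec",
    "PanelSim",
    "simulate_mixture",
    "generate_panel",
    "add_freq_noise",
    "permute_positions",
    "simulate_dropout",
]

# hom-alt probability across shared sites: U-shaped Beta with mean ~0.18.
# Together with the 50/100 FREQ centers and per-cell jitter below this puts
# the unrelated-pair correlation near 0.46 (see docs/methods.md).
HOM_BETA = (0.055, 0.25)
HET_FRACTION_PRIVATE = 0.7  # zygosity mix of private (line-specific) variants
NB_DISPERSION = 4.0  # negative-binomial shape for read depth


@dataclass(frozen=True)
class MixtureSimSpec:
    """Two-component mixture simulation settings.

    q1 is the dominant proportion (contaminant gets 1 - q1); sigma_q is the
    SD of per-site Gaussian noise on the proportions; sigma_f the SD of
    Gaussian FREQ noise in percent units.
    """

    q1: float
    sigma_q: float = 0.05
    sigma_f: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q1 < 1.0:
            raise ValueError("q1 must be in (0, 1)")
        if self.sigma_q < 0 or not 0.0 <= self.sigma_f <= 100.0:
            raise ValueError("invalid noise SDs")


@dataclass(frozen=True)
class PanelSimSpec:
    """Synthetic panel settings (defaults emulate a CCLE-like collection,
    scaled down to desk size)."""

    n_cells: int = 50
    n_sites: int = 5000
    shared_fraction: float = 0.3
    private_rate: float = 0.008
    het_freq_mean: float = 50.0
    hom_freq_mean: float = 100.0
    freq_sd: float = 7.0
    dp_mean: float = 60.0
    related_pairs: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.dp_mean <= 0:
            raise ValueError("dp_mean must be positive")
        for parent, child, div in self.related_pairs:
            if not 0.0 <= div <= 1.0:
                raise ValueError("divergence must be in [0, 1]")
            if not (0 <= parent < self.n_cells and 0 <= child < self.n_cells):
                raise ValueError("related pair indices out of range")


@dataclass
class PanelSim:
    """A generated panel with its source profiles and ground truth."""

    panel: Panel
    profiles: list[Profile]
    truth: dict


def _site_universe(rng: np.random.Generator, n_sites: int) -> list[VariantKey]:
    """Deterministic set of n_sites distinct variant keys."""
    bases = np.array(list("ACGT"))
    positions = np.cumsum(rng.integers(1, 1000, size=n_sites))
    chrom_of = lambda p: f"chr{int(p) % 22 + 1}"
    refs = bases[rng.integers(0, 4, size=n_sites)]
    alts = bases[(rng.integers(1, 4, size=n_sites) + rng.integers(0, 4, size=n_sites)) % 4]
    keys = []
    for p, r, a in zip(positions, refs, alts):
        alt = a if a != r else bases[(list(bases).index(r) + 1) % 4]
        keys.append(VariantKey(chrom_of(p), int(p), str(r), str(alt)))
    return keys


def _draw_freq(rng: np.random.Generator, is_hom: np.ndarray, spec: PanelSimSpec,
               jitter_scale: float = 1.0) -> np.ndarray:
    center = np.where(is_hom, spec.hom_freq_mean, spec.het_freq_mean)
    f = center + rng.normal(0.0, spec.freq_sd * jitter_scale, size=is_hom.shape)
    return np.clip(f, 5.0, 100.0)


def _draw_dp(rng: np.random.Generator, n: int, dp_mean: float) -> np.ndarray:
    p = NB_DISPERSION / (NB_DISPERSION + dp_mean)
    return np.maximum(1, rng.negative_binomial(NB_DISPERSION, p, size=n))


def generate_panel(spec: PanelSimSpec) -> PanelSim:
    """Generate a synthetic panel; bit-reproducible under spec.seed."""
    rng = np.random.default_rng(spec.seed)
    universe = _site_universe(rng, spec.n_sites)
    n_shared = round(spec.shared_fraction * spec.n_sites)
    n_private = round(spec.private_rate * spec.n_sites)
    children = {child for _, child, _ in spec.related_pairs}
    n_base = spec.n_cells - len(children)
    pool_needed = n_base * n_private
    if n_shared + pool_needed > spec.n_sites:
        raise ValueError(
            f"infeasible spec: {n_shared} shared + {pool_needed} private sites "
            f"exceed the {spec.n_sites}-site universe"
        )

    order = rng.permutation(spec.n_sites)
    shared_idx = np.sort(order[:n_shared])
    pool = list(order[n_shared:])

    # per-cell jitter scale: library-quality heterogeneity across cells
    jitter = rng.uniform(0.5, 1.5, size=spec.n_cells)
    p_hom = rng.beta(*HOM_BETA, size=n_shared)

    cells: list[dict] = [None] * spec.n_cells
    pool_cursor = 0
    for c in range(spec.n_cells):
        if c in children:
            continue  # filled from parent below
        z_shared = rng.random(n_shared) < p_hom
        f_shared = _draw_freq(rng, z_shared, spec, jitter[c])
        own_private = np.sort(np.array(pool[pool_cursor : pool_cursor + n_private], dtype=int))
        pool_cursor += n_private
        z_priv = rng.random(own_private.size) >= HET_FRACTION_PRIVATE
        f_priv = _draw_freq(rng, z_priv, spec, jitter[c])
        idx = np.concatenate([shared_idx, own_private]).astype(int)
        f = np.concatenate([f_shared, f_priv])
        cells[c] = {"idx": idx, "freq": f}

    leftover = pool[pool_cursor:]
    for parent, child, divergence in spec.related_pairs:
        src = cells[parent]
        if src is None:
            raise ValueError("related-pair parent may not itself be a child")
        n_par = src["idx"].size
        n_drop = round(divergence * n_par)
        keep = np.sort(rng.choice(n_par, size=n_par - n_drop, replace=False))
        # the child accumulates its own private variants at the panel's
        # private rate, scaled by how far it has diverged
        n_gain = min(round(divergence * n_private), len(leftover))
        gained = np.array(sorted(rng.choice(len(leftover), size=n_gain,
                                            replace=False)), dtype=int)
        gained_idx = np.array([leftover[g] for g in gained], dtype=int)
        z_gain = rng.random(gained_idx.size) >= HET_FRACTION_PRIVATE
        f_gain = _draw_freq(rng, z_gain, spec, jitter[child])
        cells[child] = {
            "idx": np.concatenate([src["idx"][keep], gained_idx]),
            "freq": np.concatenate([src["freq"][keep], f_gain]),  # matched FREQ on kept sites
        }

    profiles = []
    for c, cell in enumerate(cells):
        dp = _draw_dp(rng, cell["idx"].size, spec.dp_mean)
        recs = tuple(
            VariantRecord(universe[s], float(f), int(d))
            for s, f, d in zip(cell["idx"], cell["freq"], dp)
        )
        profiles.append(Profile(f"CELL_{c:03d}", recs))

    panel = build_panel(profiles, coverage_mode="assume_covered")
    truth = {
        "related_pairs": [
            (profiles[p].cell_id, profiles[c].cell_id, d) for p, c, d in spec.related_pairs
        ],
        "shared_sites": [universe[s] for s in shared_idx],
        "spec": spec,
    }
    return PanelSim(panel, profiles, truth)


def _union_vectors(x1: Profile, x2: Profile):
    """FREQ/DP vectors of two profiles on the sorted union of their sites.

    A site absent from one profile's calls carries FREQ 0 there but real
    sequencing coverage (the profiles emulate deep RNA-seq over expressed
    transcripts), so its depth is filled with that profile's median called
    depth.  This mirrors mixing full FREQ/DP matrices rather than sparse
    call sets; without it a low-proportion contaminant's own variants would
    vanish below the depth threshold and with them the strongest
    deconvolution signal.
    """
    sites = sorted(x1.sites | x2.sites)
    if not sites:
        raise ValueError("empty site universe")
    index = {k: s for s, k in enumerate(sites)}
    out = []
    for prof in (x1, x2):
        typical = float(np.median([r.dp for r in prof.records])) if prof.records else 0.0
        f = np.zeros(len(sites))
        d = np.full(len(sites), typical)
        for r in prof.records:
            f[index[r.key]] = r.freq
            d[index[r.key]] = r.dp
        out.append((f, d))
    return sites, out[0], out[1]


def simulate_mixture(x1: Profile, x2: Profile, spec: MixtureSimSpec) -> Profile:
    """Mix two profiles at proportions (q1, 1-q1) with per-site proportion
    noise (normalized to average 1) and Gaussian FREQ noise, FREQ clipped to
    [0, 100].  DP mixes with the same per-site proportions, rounded."""
    rng = np.random.default_rng(spec.seed)
    sites, (f1, d1), (f2, d2) = _union_vectors(x1, x2)
    L = len(sites)
    w1 = rng.normal(spec.q1, spec.sigma_q, size=L)
    w2 = rng.normal(1.0 - spec.q1, spec.sigma_q, size=L)
    scale = np.mean(w1 + w2)
    w1, w2 = w1 / scale, w2 / scale
    z = w1 * f1 + w2 * f2
    y = np.clip(z + rng.normal(0.0, spec.sigma_f, size=L), 0.0, 100.0)
    dp = np.maximum(0, np.rint(w1 * d1 + w2 * d2)).astype(int)
    recs = tuple(
        VariantRecord(k, float(fy), int(fd)) for k, fy, fd in zip(sites, y, dp)
    )
    return Profile(f"{x1.cell_id}+{x2.cell_id}", recs)


def add_freq_noise(profile: Profile, sigma: float, seed: int = 0) -> Profile:
    """Add zero-mean Gaussian noise (SD sigma percent) to every FREQ,
    clipped to [0, 100]; DP unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return profile
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=len(profile.records))
    recs = tuple(
        VariantRecord(r.key, float(np.clip(r.freq + e, 0.0, 100.0)), r.dp)
        for r, e in zip(profile.records, noise)
    )
    return Profile(profile.cell_id, recs)


def permute_positions(profile: Profile, panel_sites, seed: int = 0) -> Profile:
    """Reassign each record's FREQ/DP to a distinct uniformly sampled site
    from ``panel_sites``; the FREQ/DP multiset is preserved."""
    sites = list(panel_sites)
    if len(sites) < len(profile.records):
        raise ValueError(
            f"site universe ({len(sites)}) smaller than profile ({len(profile.records)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(sites), size=len(profile.records), replace=False)
    recs = tuple(
        VariantRecord(sites[s], r.freq, r.dp) for s, r in zip(chosen, profile.records)
    )
    return Profile(profile.cell_id, recs)


def simulate_dropout(profile: Profile, retain_fraction: float, seed: int = 0) -> Profile:
    """Keep a uniform random fraction of records, rescaling DP by the same
    fraction (floor 1) -- a variant-level emulation of read subsampling."""
    if not 0.0 < retain_fraction <= 1.0:
        raise ValueError("retain_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_keep = round(retain_fraction * len(profile.records))
    keep = np.sort(rng.choice(len(profile.records), size=n_keep, replace=False))
    recs = tuple(
        VariantRecord(
            profile.records[k].key,
            profile.records[k].freq,
            max(1, round(profile.records[k].dp * retain_fraction)),
        )
        for k in keep
    )
    return Profile(profile.cell_id, recs)
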