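"""Query-vs-panel identification with two-pass disambiguation.

Pass 1 correlates the query against every panel cell over the variant set
with DP >= 10 in both and FREQ > 0 in at least one (the permissive
first-pass frequency rule), ranks cells by rho, and classifies each against
the fitted null.  If two or more cells pass the relatedness cut -- the
signature of synonymous/derivative lines such as MCF7 and KPL-1 -- a second
pass restricts to *discriminative* sites (FREQ spread across the candidates
above 10 percent, DP >= 20 everywhere) and re-correlates on those alone.

Coverage asymmetry: panel cells follow the panel's coverage mode at sites
they did not call (default: assumed covered, depth sentinel +inf), while the
query's uncalled sites always count as depth 0 -- the query's VCF is the
only coverage evidence we have for it, and a sparsely covered query (e.g.
shallow sequencing) must not be compared at sites it could not call.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import null_model
from .null_model import TruncatedNormalNull
from .panel_io import ASSUMED_DP, Panel, Profile, VariantKey
from .profile_compare import _pearson, _select


@dataclass(frozen=True)
class MatchEntry:
    cell_id: str
    rho: float
    n_sites: int
    p: float
    classification: str


@dataclass
class MatchResult:
    """Ranked candidate matches for one identification pass."""

    query_id: str
    matches: list[MatchEntry]
    pass_number: int = 1
    n_variants_used: int = 0
    inconclusive: bool = False

    def best(self) -> MatchEntry:
        return self.matches[0]

    def candidates(self, classes=("possibly_related", "same_origin")) -> list[str]:
        return [m.cell_id for m in self.matches if m.classification in classes]

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "pass_number": self.pass_number,
            "n_variants_used": self.n_variants_used,
            "inconclusive": self.inconclusive,
            "matches": [
                {
                    "cell_id": m.cell_id,
                    "rho": None if math.isnan(m.rho) else round(m.rho, 6),
                    "n_sites": m.n_sites,
                    "p": None if math.isnan(m.p) else m.p,
                    "classification": m.classification,
                }
                for m in self.matches
            ],
        }


def join_query(panel: Panel, query: Profile):
    """Map a query profile and the panel onto the union of their sites.

    Returns (sites, panel_freq, panel_dp, query_freq, query_dp).  New
    (query-only) sites extend the panel matrices per the panel's coverage
    mode; the query gets dp 0 at sites it did not call.
    """
    extra = sorted(query.sites - set(panel.sites))
    sites = list(panel.sites) + extra  # panel order first, then new sites
    index = {k: s for s, k in enumerate(sites)}
    n_new = len(extra)
    p_freq = np.hstack([panel.freq, np.zeros((panel.n_cells, n_new))])
    fill = ASSUMED_DP if panel.coverage_mode == "assume_covered" else 0.0
    p_dp = np.hstack([panel.dp, np.full((panel.n_cells, n_new), fill)])
    q_freq = np.zeros(len(sites))
    q_dp = np.zeros(len(sites))
    for r in query.records:
        s = index[r.key]
        q_freq[s] = r.freq
        q_dp[s] = r.dp
    return sites, p_freq, p_dp, q_freq, q_dp


def _rank(entries: list[MatchEntry]) -> list[MatchEntry]:
    # rho descending, NaN last, ties by cell id
    return sorted(
        entries,
        key=lambda m: (-(m.rho if math.isfinite(m.rho) else -math.inf), m.cell_id),
    )


def identify(
    query: Profile,
    panel: Panel,
    null: TruncatedNormalNull,
    dp_min: float = 10,
    freq_min_first_pass: float = 0,
    top_k: int = 3,
    alpha_related: float = 1e-3,
    alpha_same: float = 1e-4,
) -> MatchResult:
    """First-pass ranking of all panel cells against the query.

    Returns the top_k matches plus every cell passing p < alpha_related.
    Raises if no variant qualifies against any panel cell.
    """
    if not query.records:
        raise ValueError("query profile has no records")
    sites, p_freq, p_dp, q_freq, q_dp = join_query(panel, query)
    entries = []
    any_sites = False
    for c, cid in enumerate(panel.cell_ids):
        sel = _select(q_freq, q_dp, p_freq[c], p_dp[c], dp_min, freq_min_first_pass)
        any_sites = any_sites or sel.size > 0
        rho = _pearson(q_freq[sel], p_freq[c][sel])
        p = null_model.p_value(rho, null) if math.isfinite(rho) else float("nan")
        cls = null_model.classify(rho, null, alpha_related, alpha_same)
        entries.append(MatchEntry(cid, rho, int(sel.size), p, cls))
    if not any_sites:
        raise ValueError("zero selectable variants against every panel cell")
    ranked = _rank(entries)
    keep = {m.cell_id for m in ranked[:top_k]}
    keep |= {m.cell_id for m in ranked if m.classification != "unrelated"}
    matches = [m for m in ranked if m.cell_id in keep]
    return MatchResult(query.cell_id, matches, 1, matches[0].n_sites if matches else 0)


def disambiguate(
    query: Profile,
    panel: Panel,
    candidates: list[str],
    null: TruncatedNormalNull,
    dp_min_second: float = 20,
    freq_diff_min: float = 10,
    min_sites: int = 10,
    alpha_related: float = 1e-3,
    alpha_same: float = 1e-4,
) -> MatchResult:
    """Second pass: re-correlate on sites that discriminate the candidates.

    Keeps sites where the FREQ spread across the candidates (max - min)
    exceeds ``freq_diff_min`` and DP >= ``dp_min_second`` in the query and
    every candidate; fewer than ``min_sites`` such sites is inconclusive.
    """
    if len(candidates) < 2:
        raise ValueError("disambiguation needs at least 2 candidates")
    sites, p_freq, p_dp, q_freq, q_dp = join_query(panel, query)
    idx = [panel.cell_index(c) for c in candidates]
    cand_freq = p_freq[idx]
    spread = cand_freq.max(axis=0) - cand_freq.min(axis=0)
    depth_ok = (q_dp >= dp_min_second) & np.all(p_dp[idx] >= dp_min_second, axis=0)
    mask = (spread > freq_diff_min) & depth_ok
    n_used = int(mask.sum())
    if n_used < min_sites:
        return MatchResult(query.cell_id, [], 2, n_used, inconclusive=True)
    entries = []
    for cid, row in zip(candidates, cand_freq):
        rho = _pearson(q_freq[mask], row[mask])
        p = null_model.p_value(rho, null) if math.isfinite(rho) else float("nan")
        cls = null_model.classify(rho, null, alpha_related, alpha_same)
        entries.append(MatchEntry(cid, rho, n_used, p, cls))
    return MatchResult(query.cell_id, _rank(entries), 2, n_used)


def identify_full(
    query: Profile,
    panel: Panel,
    null: TruncatedNormalNull,
    dp_min: float = 10,
    freq_min_first_pass: float = 0,
    dp_min_second: float = 20,
    freq_diff_min: float = 10,
    top_k: int = 3,
    alpha_related: float = 1e-3,
    alpha_same: float = 1e-4,
    min_sites_second: int = 10,
) -> list[MatchResult]:
    """Run pass 1 and, if several cells pass the relatedness cut, pass 2."""
    first = identify(
        query, panel, null, dp_min, freq_min_first_pass, top_k, alpha_related, alpha_same
    )
    candidates = first.candidates()
    results = [first]
    if len(candidates) >= 2:
        results.append(
            disambiguate(
                query,
                panel,
                candidates,
                null,
                dp_min_second,
                freq_diff_min,
                min_sites_second,
                alpha_related,
                alpha_same,
            )
        )
    return results


def write_match_report(results: list[MatchResult], tsv_path=None, json_path=None) -> str:
    """Per-pass report: TSV mirroring (sample, match cell, rho, p) columns
    plus a machine-readable JSON document.  Returns the TSV text."""
    lines = ["sample\tpass\tmatch_cell\tcorr_coef\tp_value\tn_sites\tclassification"]
    for res in results:
        if res.inconclusive:
            lines.append(f"{res.query_id}\t{res.pass_number}\t.\t.\t.\t{res.n_variants_used}\tinconclusive")
        for m in res.matches:
            rho = f"{m.rho:.4f}" if math.isfinite(m.rho) else "NA"
            p = f"{m.p:.4g}" if math.isfinite(m.p) else "NA"
            lines.append(
                f"{res.query_id}\t{res.pass_number}\t{m.cell_id}\t{rho}\t{p}\t"
                f"{m.n_sites}\t{m.classification}"
            )
    text = "\n".join(lines) + "\n"
    if tsv_path:
        with open(tsv_path, "w") as fh:
            fh.write(text)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump([r.to_dict() for r in results], fh, indent=1)
    return text
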