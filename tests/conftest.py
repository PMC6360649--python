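import numpy as np
import pytest

from lineauth import PanelSimSpec, build_panel, generate_panel
from lineauth.panel_io import Panel, Profile, VariantKey, VariantRecord


def make_profile(cell_id, triples):
    """Profile from (pos, freq, dp) triples on chr1 with A->G alleles."""
    recs = tuple(
        VariantRecord(VariantKey("chr1", pos, "A", "G"), float(freq), int(dp))
        for pos, freq, dp in triples
    )
    return Profile(cell_id, recs)


def make_panel(freq, dp, coverage_mode="assume_covered", called=None):
    """Panel straight from cells x sites freq/dp arrays (all sites called
    unless a mask is given)."""
    freq = np.asarray(freq, dtype=float)
    dp = np.asarray(dp, dtype=float)
    n_c, n_s = freq.shape
    sites = [VariantKey("chr1", 100 + k, "A", "G") for k in range(n_s)]
    if called is None:
        called = np.ones((n_c, n_s), dtype=bool)
    return Panel([f"C{c}" for c in range(n_c)], sites, freq, dp, np.asarray(called), coverage_mode)


TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Variant allele frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE_A
chr1\t12345\t.\tA\tG\t.\tPASS\t.\tGT:DP:FREQ\t0/1:52:45.45%
chr1\t20000\t.\tC\tT\t.\tPASS\t.\tGT:DP:FREQ\t1/1:80:99.9%
chr2\t500\t.\tG\tA\t.\tPASS\t.\tGT:DP:FREQ\t0/1:15:12.5
chr2\t700\t.\tT\tG,C\t.\tPASS\t.\tGT:DP:FREQ\t0/1:33:28.0%
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture(scope="session")
def sim_panel():
    """Session-wide synthetic panel: 30 cells, 4000 sites, one replicate
    pair (CELL_000/CELL_001) and one derivative pair (CELL_002/CELL_003)."""
    spec = PanelSimSpec(
        n_cells=30,
        n_sites=4000,
        related_pairs=((0, 1, 0.01), (2, 3, 0.05)),
        seed=42,
    )
    return generate_panel(spec)


@pytest.fixture(scope="session")
def sim_null(sim_panel):
    from lineauth import fit_null, pairwise_matrix

    mat = pairwise_matrix(sim_panel.panel)
    return fit_null(mat.upper_triangle())
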