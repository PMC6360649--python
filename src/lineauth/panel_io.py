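"""Variant-profile and panel I/O.

A *profile* is one sample's set of called variants, each carrying the
VarScan per-sample FORMAT fields DP (depth of coverage) and FREQ (altered
allele frequency in percent).  A *panel* stacks many profiles onto the
union of their sites as cells x sites matrices of FREQ and DP plus a
"called" mask, and is what every downstream comparison consumes.

VCFs only report called sites, but pairwise comparison needs a depth at
*uncalled* sites too (a site absent from one sample's VCF may simply not be
covered).  Three coverage modes make that assumption explicit:

``assume_covered``
    Uncalled sites get FREQ 0 and a +inf depth sentinel, i.e. they pass any
    depth threshold.  Appropriate for deep RNA-seq panels where expressed
    transcripts are near-universally covered.  Default.
``strict``
    Uncalled sites get depth 0 and are excluded from any depth-thresholded
    comparison.
``external``
    Uncalled depths are supplied by the caller (e.g. from a coverage track).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

PANEL_FORMAT_VERSION = "1"
COVERAGE_MODES = ("assume_covered", "strict", "external")

#: depth sentinel for uncalled sites in assume_covered mode
ASSUMED_DP = math.inf


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic identity of a variant: (chrom, 1-based pos, ref, alt).

    Site identity includes both alleles; two records at the same position
    with different alternate alleles are distinct sites.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise DataError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise DataError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class VariantRecord:
    """One called variant: key plus FREQ (percent) and DP (reads)."""

    key: VariantKey
    freq: float
    dp: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq <= 100.0:
            raise DataError(f"FREQ {self.freq} outside [0, 100] at {self.key}")
        if self.dp < 0:
            raise DataError(f"DP {self.dp} negative at {self.key}")


@dataclass(frozen=True)
class Profile:
    """One sample's variant profile; records unique by VariantKey."""

    cell_id: str
    records: tuple[VariantRecord, ...]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise DataError(f"duplicate variant keys in profile {self.cell_id}: {sorted(dupes)[:3]}")

    @property
    def sites(self) -> frozenset[VariantKey]:
        return frozenset(r.key for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SiteList:
    """A set of variant keys used to restrict a panel (COSMIC-style)."""

    keys: frozenset[VariantKey]

    def __len__(self) -> int:
        return len(self.keys)


@dataclass
class Panel:
    """Sites x cell-lines store of FREQ and DP with a called mask.

    Matrices are cells x sites; ``sites`` is sorted by VariantKey order and
    ``called[c, s]`` is True where cell c's VCF contained site s.  Where
    called is False, freq is 0 and dp follows the coverage mode.
    """

    cell_ids: list[str]
    sites: list[VariantKey]
    freq: np.ndarray
    dp: np.ndarray
    called: np.ndarray
    coverage_mode: str = "assume_covered"

    def __post_init__(self) -> None:
        shape = (len(self.cell_ids), len(self.sites))
        for name in ("freq", "dp", "called"):
            m = getattr(self, name)
            if m.shape != shape:
                raise DataError(f"panel {name} matrix has shape {m.shape}, expected {shape}")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DataError("duplicate cell ids in panel")
        if any(self.sites[k] >= self.sites[k + 1] for k in range(len(self.sites) - 1)):
            raise DataError("panel sites must be unique and sorted")
        if self.coverage_mode not in COVERAGE_MODES:
            raise DataError(f"unknown coverage_mode {self.coverage_mode!r}")
        if np.any(self.freq[~self.called] != 0.0):
            raise DataError("uncalled entries must have freq == 0")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def cell_index(self, cell_id: str) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise KeyError(f"unknown cell id {cell_id!r}") from None

    def profile(self, cell_id: str) -> Profile:
        """Extract one cell's called records back out as a Profile."""
        c = self.cell_index(cell_id)
        recs = tuple(
            VariantRecord(self.sites[s], float(self.freq[c, s]), int(self.dp[c, s]))
            for s in np.flatnonzero(self.called[c])
        )
        return Profile(cell_id, recs)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x cells matrix of non-negative RPKM values."""

    gene_ids: list[str]
    cell_ids: list[str]
    rpkm: np.ndarray

    def __post_init__(self) -> None:
        if self.rpkm.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError("rpkm matrix shape does not match gene/cell id counts")
        if np.any(self.rpkm < 0):
            raise DataError("negative RPKM values")

    def cell_index(self, cell_id: str) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise KeyError(f"unknown cell id {cell_id!r}") from None


# ---------------------------------------------------------------------------
# VCF input / output


def _parse_freq(raw) -> float:
    """Parse a VarScan FREQ value: '45.45%' or bare '45.45'."""
    if raw is None:
        raise ValueError("missing FREQ")
    if isinstance(raw, (tuple, list)):
        raw = raw[0]
    if isinstance(raw, bytes):
        raw = raw.decode()
    s = str(raw).strip()
    if s.endswith("%"):
        s = s[:-1]
    return float(s)


def read_varscan_vcf(path: str | Path, sample: str | None = None) -> Profile:
    """Read one sample's variant profile from a VarScan-dialect VCF.

    The FORMAT column must carry DP and FREQ (percent, with or without a
    trailing '%').  Multi-allelic rows are split into one record per
    alternate allele, each inheriting the row's DP/FREQ.  Records with
    missing or unparseable DP/FREQ are skipped with a warning; if the file
    has data lines but every one is rejected, that is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise DataError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if sample is None:
        if len(samples) != 1:
            raise DataError(
                f"{path} has {len(samples)} samples; specify which one to read"
            )
        sample = samples[0]
    elif sample not in samples:
        raise DataError(f"sample {sample!r} not present in {path} (has {samples})")

    records: dict[VariantKey, VariantRecord] = {}
    n_rows = n_rejected = 0
    for rec in vf:
        n_rows += 1
        sd = rec.samples[sample]
        try:
            dp = sd.get("DP")
            freq = _parse_freq(sd.get("FREQ"))
            if dp is None:
                raise ValueError("missing DP")
            if not 0.0 <= freq <= 100.0:
                raise ValueError(f"FREQ {freq} outside [0, 100]")
        except (ValueError, TypeError, KeyError) as exc:
            log.warning("%s:%s skipped: %s", rec.chrom, rec.pos, exc)
            n_rejected += 1
            continue
        for alt in rec.alts or ():
            key = VariantKey(rec.chrom, rec.pos, rec.ref, str(alt))
            if key in records:
                log.warning("duplicate record at %s, keeping first", key)
                continue
            records[key] = VariantRecord(key, freq, int(dp))
    vf.close()
    if n_rows and not records:
        raise DataError(f"all {n_rows} records in {path} were rejected")
    if n_rejected:
        log.warning("%s: skipped %d/%d records", path, n_rejected, n_rows)
    return Profile(sample, tuple(records.values()))


def write_profile_vcf(profile: Profile, path: str | Path) -> None:
    """Write a profile as a minimal VarScan-dialect VCF (GT:DP:FREQ)."""
    path = Path(path)
    recs = sorted(profile.records, key=lambda r: r.key)
    chroms = sorted({r.key.chrom for r in recs})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=FREQ,Number=1,Type=String,'
            'Description="Variant allele frequency (percent)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + profile.cell_id.replace(" ", "_")
            + "\n"
        )
        for r in recs:
            fh.write(
                f"{r.key.chrom}\t{r.key.pos}\t.\t{r.key.ref}\t{r.key.alt}\t.\tPASS\t.\t"
                f"GT:DP:FREQ\t0/1:{r.dp}:{r.freq:.4f}%\n"
            )


# ---------------------------------------------------------------------------
# Panel construction and serialization


def build_panel(
    profiles: Sequence[Profile],
    coverage_mode: str = "assume_covered",
    external_depths: Mapping[str, Mapping[VariantKey, float]] | None = None,
) -> Panel:
    """Stack profiles onto the sorted union of their sites.

    Uncalled (cell, site) entries get freq 0 and a depth chosen by
    ``coverage_mode``; in ``external`` mode ``external_depths[cell_id][key]``
    must supply a depth for every uncalled entry.
    """
    if not profiles:
        raise DataError("need at least one profile")
    ids = [p.cell_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate cell ids among profiles")
    if coverage_mode not in COVERAGE_MODES:
        raise DataError(f"unknown coverage_mode {coverage_mode!r}")
    if coverage_mode == "external" and external_depths is None:
        raise DataError("external coverage mode requires external_depths")

    sites = sorted(set().union(*(p.sites for p in profiles)))
    index = {k: s for s, k in enumerate(sites)}
    n_c, n_s = len(profiles), len(sites)
    freq = np.zeros((n_c, n_s))
    called = np.zeros((n_c, n_s), dtype=bool)
    if coverage_mode == "assume_covered":
        dp = np.full((n_c, n_s), ASSUMED_DP)
    else:
        dp = np.zeros((n_c, n_s))
    for c, p in enumerate(profiles):
        if coverage_mode == "external":
            try:
                lookup = external_depths[p.cell_id]
                dp[c] = [lookup[k] for k in sites]
            except KeyError as exc:
                raise DataError(f"external depth lookup failed for {p.cell_id}: {exc}") from exc
        for r in p.records:
            s = index[r.key]
            freq[c, s] = r.freq
            dp[c, s] = r.dp
            called[c, s] = True
    return Panel(list(ids), sites, freq, dp, called, coverage_mode)


def _fmt_dp(v: float) -> str:
    if math.isinf(v):
        return "inf"
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_panel(panel: Panel, path: str | Path) -> None:
    """Serialize a panel to a directory of TSV tables plus JSON metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "sites.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for k in panel.sites:
            fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n")

    def _write_matrix(name: str, fmt) -> None:
        with open(path / f"{name}.tsv", "w") as fh:
            fh.write("cell_id\t" + "\t".join(str(s) for s in range(panel.n_sites)) + "\n")
            for c, cid in enumerate(panel.cell_ids):
                row = "\t".join(fmt(v) for v in getattr(panel, name)[c])
                fh.write(f"{cid}\t{row}\n")

    _write_matrix("freq", lambda v: f"{v:.6f}")
    _write_matrix("dp", _fmt_dp)
    _write_matrix("called", lambda v: "1" if v else "0")
    meta = {
        "format_version": PANEL_FORMAT_VERSION,
        "coverage_mode": panel.coverage_mode,
        "n_cells": panel.n_cells,
        "n_sites": panel.n_sites,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_panel(path: str | Path) -> Panel:
    """Read a panel written by :func:`write_panel`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("format_version") != PANEL_FORMAT_VERSION:
        raise DataError(
            f"panel format version {meta.get('format_version')!r} != {PANEL_FORMAT_VERSION!r}"
        )
    sites_df = pd.read_csv(path / "sites.tsv", sep="\t", dtype={"chrom": str})
    sites = [
        VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in sites_df.itertuples()
    ]

    def _read_matrix(name: str) -> tuple[list[str], np.ndarray]:
        df = pd.read_csv(path / f"{name}.tsv", sep="\t", index_col=0)
        return [str(i) for i in df.index], df.to_numpy(dtype=float)

    cell_ids, freq = _read_matrix("freq")
    ids_dp, dp = _read_matrix("dp")
    ids_called, called_f = _read_matrix("called")
    if not (cell_ids == ids_dp == ids_called):
        raise DataError("cell id mismatch between panel matrices")
    expected = (meta["n_cells"], meta["n_sites"])
    for name, m in (("freq", freq), ("dp", dp), ("called", called_f)):
        if m.shape != expected or len(sites) != expected[1]:
            raise DataError(
                f"panel component {name} has shape {m.shape}, metadata says {expected}"
            )
    return Panel(cell_ids, sites, freq, dp, called_f.astype(bool), meta["coverage_mode"])


def restrict_panel(panel: Panel, sites: SiteList) -> Panel:
    """Keep only panel sites present in ``sites`` (order preserved)."""
    keep = np.array([k in sites.keys for k in panel.sites], dtype=bool)
    return Panel(
        list(panel.cell_ids),
        [k for k, m in zip(panel.sites, keep) if m],
        panel.freq[:, keep].copy(),
        panel.dp[:, keep].copy(),
        panel.called[:, keep].copy(),
        panel.coverage_mode,
    )


# ---------------------------------------------------------------------------
# Site lists and expression matrices


def read_site_list(path: str | Path) -> SiteList:
    """Read a site list from a VCF or a 4-column chrom/pos/ref/alt TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat"):
        profile_keys = set()
        vf = pysam.VariantFile(str(path))
        for rec in vf:
            for alt in rec.alts or ():
                profile_keys.add(VariantKey(rec.chrom, rec.pos, rec.ref, str(alt)))
        vf.close()
        if not profile_keys:
            raise DataError(f"no sites in {path}")
        return SiteList(frozenset(profile_keys))

    keys: set[VariantKey] = set()
    n_bad = n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            n_rows += 1
            try:
                keys.add(VariantKey(parts[0], int(parts[1]), parts[2], parts[3]))
            except (IndexError, ValueError, DataError) as exc:
                if n_rows == 1:  # tolerate a header row silently
                    n_rows -= 1
                    continue
                log.warning("%s line %d skipped: %s", path, lineno, exc)
                n_bad += 1
    if not keys:
        raise DataError(f"no parseable sites in {path}")
    return SiteList(frozenset(keys))


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x cells TSV of RPKM values (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise DataError("duplicate gene ids in expression matrix")
    if df.columns.duplicated().any():
        raise DataError("duplicate cell ids in expression matrix")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"non-numeric expression values: {exc}") from exc
    if np.isnan(values).any():
        raise DataError("missing values in expression matrix")
    return ExpressionMatrix([str(g) for g in df.index], [str(c) for c in df.columns], values)
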