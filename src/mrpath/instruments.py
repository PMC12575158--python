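"""Instrumental-variable selection for two-sample MR.

The QC chain, applied in fixed order to one trait's summary statistics:

1. p-value threshold (strict ``p < threshold``; 1e-5 forward, 5e-5 reverse);
2. exclusion of the MHC region (chr6:28,477,897-33,448,354, GRCh37), whose
   dense LD and pervasive immune pleiotropy make instruments there suspect;
3. greedy LD clumping (keep the best-p variant, discard neighbours within
   the window whose r^2 with it exceeds the threshold; PLINK-style defaults
   window = 10,000 kb, r^2 < 0.001);
4. weak-instrument filter on the F-statistic beta^2/se^2 (strict F > 10).

Every stage is non-increasing in record count; :func:`select_instruments`
runs the chain and returns the per-stage counts for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .sumstats import SnpAssociation

logger = logging.getLogger(__name__)

#: MHC region on chromosome 6 (GRCh37, 1-based inclusive bounds).
MHC_REGION = ("6", 28_477_897, 33_448_354)


@dataclass(frozen=True)
class ClumpConfig:
    """Parameters of the instrument-selection chain.

    Defaults are the forward-MR settings for microbiome/immune traits:
    p < 1e-5, 10,000 kb window, r^2 < 0.001, MHC excluded, F > 10. Use
    ``window_kb=1000`` for the denser metabolite panels and
    ``p_threshold=5e-5`` for reverse MR.
    """

    p_threshold: float = 1e-5
    window_kb: float = 10_000.0
    r2_max: float = 0.001
    mhc_region: tuple | None = MHC_REGION
    min_f: float = 10.0

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if self.window_kb <= 0:
            raise ConfigurationError("window_kb must be positive")
        if not (0 <= self.r2_max < 1):
            raise ConfigurationError("r2_max must be in [0, 1)")
        if self.min_f < 0:
            raise ConfigurationError("min_f must be non-negative")
        if self.mhc_region is not None:
            chrom, start, end = self.mhc_region
            if start > end:
                raise ConfigurationError("mhc_region start > end")

    @classmethod
    def from_file(cls, path) -> "ClumpConfig":
        """Load from a YAML key-value file; unknown keys are rejected."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ConfigurationError(f"unknown ClumpConfig keys: {sorted(extra)}")
        if "mhc_region" in raw and raw["mhc_region"] is not None:
            c, s, e = raw["mhc_region"]
            raw["mhc_region"] = (str(c), int(s), int(e))
        return cls(**raw)


@dataclass
class LdMatrix:
    """Pairwise LD r^2 values over an ordered set of variants.

    Symmetric with unit diagonal; values in [0, 1].
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.snp_ids)
        if self.r2.shape != (m, m):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be 1")
        if np.any(self.r2 < -1e-12) or np.any(self.r2 > 1 + 1e-12):
            raise ValueError("r2 values must be in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def lookup(self, snp_a: str, snp_b: str) -> float:
        return float(self.r2[self._index[snp_a], self._index[snp_b]])

    @classmethod
    def identity(cls, snp_ids: list[str]) -> "LdMatrix":
        return cls(snp_ids=list(snp_ids), r2=np.eye(len(snp_ids)))

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, snp_ids: list[str] | None = None) -> "LdMatrix":
        """Build from a long table with columns (snp_a, snp_b, r2);
        unlisted pairs default to r^2 = 0."""
        if snp_ids is None:
            snp_ids = sorted(set(pairs["snp_a"]) | set(pairs["snp_b"]))
        idx = {s: i for i, s in enumerate(snp_ids)}
        r2 = np.eye(len(snp_ids))
        for a, b, v in pairs[["snp_a", "snp_b", "r2"]].itertuples(index=False):
            i, j = idx[str(a)], idx[str(b)]
            r2[i, j] = r2[j, i] = float(v)
        return cls(snp_ids=list(snp_ids), r2=r2)

    @classmethod
    def from_pairs_tsv(cls, path, snp_ids: list[str] | None = None) -> "LdMatrix":
        return cls.from_pairs(pd.read_csv(path, sep="\t"), snp_ids=snp_ids)

    def to_pairs_tsv(self, path) -> None:
        rows = []
        m = len(self.snp_ids)
        for i in range(m):
            for j in range(i + 1, m):
                if self.r2[i, j] != 0.0:
                    rows.append((self.snp_ids[i], self.snp_ids[j], self.r2[i, j]))
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(path, sep="\t", index=False)


def filter_pvalue(snps: list[SnpAssociation], threshold: float) -> list[SnpAssociation]:
    """Retain records with ``pval < threshold`` (strict), preserving order."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    return [s for s in snps if s.pval < threshold]


def exclude_region(snps: list[SnpAssociation], region: tuple) -> list[SnpAssociation]:
    """Remove records inside ``region = (chrom, start, end)``, 1-based and
    inclusive on both ends."""
    chrom, start, end = region
    if start > end:
        raise ValueError("region start > end")
    chrom = str(chrom)
    return [s for s in snps if not (s.chrom == chrom and start <= s.pos <= end)]


def _chrom_key(chrom: str):
    # numeric chromosomes sort numerically, then X/Y/MT etc. lexically
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


def ld_clump(snps: list[SnpAssociation], ld: LdMatrix | None,
             window_kb: float = 10_000.0, r2_max: float = 0.001,
             strict: bool = True) -> list[SnpAssociation]:
    """Greedy LD clumping.

    Sort candidates by p-value ascending (ties by genomic coordinate);
    repeatedly promote the best remaining variant to index status and
    discard remaining variants on the same chromosome within ``window_kb``
    of it with r^2 >= ``r2_max``. Index variants are returned in selection
    order.

    A variant absent from ``ld`` raises ``KeyError`` in strict mode; in
    lenient mode (or with ``ld=None``) it is treated as independent of
    everything and logged.
    """
    order = sorted(snps, key=lambda s: (s.pval, _chrom_key(s.chrom), s.pos))
    window_bp = window_kb * 1000.0
    kept: list[SnpAssociation] = []
    alive = list(order)

    def r2_of(a: SnpAssociation, b: SnpAssociation) -> float:
        if ld is None:
            return 0.0
        missing = [s.snp_id for s in (a, b) if s.snp_id not in ld]
        if missing:
            if strict:
                raise KeyError(f"variant(s) {missing} absent from LD matrix")
            logger.info("variant(s) %s absent from LD matrix; treated as independent", missing)
            return 0.0
        return ld.lookup(a.snp_id, b.snp_id)

    while alive:
        index = alive.pop(0)
        kept.append(index)
        alive = [
            s for s in alive
            if not (s.chrom == index.chrom
                    and abs(s.pos - index.pos) <= window_bp
                    and r2_of(index, s) >= r2_max)
        ]
    return kept


def f_statistic(snp: SnpAssociation) -> float:
    """Instrument-strength F-statistic, beta^2 / se^2."""
    return snp.beta ** 2 / snp.se ** 2


def filter_weak(snps: list[SnpAssociation], min_f: float = 10.0) -> list[SnpAssociation]:
    """Retain records with F-statistic strictly greater than ``min_f``."""
    if min_f < 0:
        raise ValueError("min_f must be non-negative")
    return [s for s in snps if f_statistic(s) > min_f]


def select_instruments(snps: list[SnpAssociation], ld: LdMatrix | None = None,
                       config: ClumpConfig | None = None,
                       strict_ld: bool = False):
    """Run the full QC chain: p-filter -> region-exclude -> clump -> F-filter.

    Returns ``(selected, stage_counts)`` where ``stage_counts`` is an
    ordered dict of record counts after each stage (monotone non-increasing).
    """
    cfg = config or ClumpConfig()
    counts = {"input": len(snps)}
    out = filter_pvalue(snps, cfg.p_threshold)
    counts["p_filter"] = len(out)
    if cfg.mhc_region is not None:
        out = exclude_region(out, cfg.mhc_region)
    counts["region_exclude"] = len(out)
    out = ld_clump(out, ld, window_kb=cfg.window_kb, r2_max=cfg.r2_max, strict=strict_ld)
    counts["ld_clump"] = len(out)
    out = filter_weak(out, cfg.min_f)
    counts["f_filter"] = len(out)
    logger.info("instrument chain: %s", counts)
    return out, counts
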