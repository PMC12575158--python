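"""Reading, validation, and allele harmonization of GWAS summary statistics.

A summary-statistic record is one variant's association with one trait:
effect allele, other allele, effect-allele frequency (EAF), additive effect
``beta`` (log-odds for binary traits, SD units for continuous ones), its
standard error, p-value, and sample size.

Two-sample MR combines per-variant effects from an exposure GWAS and an
outcome GWAS, so both must be expressed relative to the *same* effect
allele. :func:`harmonize` intersects the two variant sets, flips outcome
effects reported on the opposite allele (or opposite strand), and drops
palindromic (A/T, C/G) variants whose strand cannot be resolved because the
effect-allele frequency is close to 0.5 or missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError, NoOverlapError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column names for summary-statistic tables (TSV/CSV).
CANONICAL_COLUMNS = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's summary-statistic record for one trait.

    Raises ``ValueError`` on construction when an invariant is violated
    (se <= 0, alleles outside {A,C,G,T}, identical alleles, EAF outside
    [0, 1], p-value outside (0, 1]).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: p-value {self.pval} outside (0, 1]")
        if self.n <= 0:
            raise ValueError(f"{self.snp_id}: sample size must be positive")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: non-finite beta")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class StudyMeta:
    """Descriptors of one GWAS: trait name/type, sample sizes, ancestry."""

    trait_name: str
    trait_type: str = "continuous"  # {continuous, binary}
    n_total: int = 0
    n_cases: int | None = None
    ancestry_label: str = ""

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        if self.n_cases is not None and self.n_cases > self.n_total:
            raise ValueError("n_cases exceeds n_total")


@dataclass
class HarmonizedInstruments:
    """Allele-aligned exposure/outcome effect pairs ready for estimation.

    All arrays are parallel over the retained variants; outcome effects are
    expressed per copy of the exposure's effect allele.
    """

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf: np.ndarray
    n_dropped_palindromic: int = 0
    n_flipped: int = 0
    n_dropped_incompatible: int = 0

    def __post_init__(self):
        for name in ("beta_exp", "se_exp", "beta_out", "se_out", "eaf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        j = len(self.snp_ids)
        if j < 1:
            raise ValueError("HarmonizedInstruments requires at least one variant")
        for name in ("beta_exp", "se_exp", "beta_out", "se_out", "eaf"):
            if len(getattr(self, name)) != j:
                raise ValueError(f"{name} length != number of snp_ids")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask) -> "HarmonizedInstruments":
        """Select instruments by boolean mask or integer index array
        (an index array may also reorder)."""
        arr = np.asarray(mask)
        idx = np.flatnonzero(arr) if arr.dtype == bool else arr.astype(int)
        return HarmonizedInstruments(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta_exp=self.beta_exp[idx], se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx], se_out=self.se_out[idx],
            eaf=self.eaf[idx],
            n_dropped_palindromic=self.n_dropped_palindromic,
            n_flipped=self.n_flipped,
            n_dropped_incompatible=self.n_dropped_incompatible,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "SNP": self.snp_ids,
            "beta_exp": self.beta_exp, "se_exp": self.se_exp,
            "beta_out": self.beta_out, "se_out": self.se_out,
            "eaf": self.eaf,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HarmonizedInstruments":
        df = pd.read_csv(path, sep="\t")
        return cls(
            snp_ids=df["SNP"].astype(str).tolist(),
            beta_exp=df["beta_exp"].to_numpy(), se_exp=df["se_exp"].to_numpy(),
            beta_out=df["beta_out"].to_numpy(), se_out=df["se_out"].to_numpy(),
            eaf=df["eaf"].to_numpy(),
        )


def read_summary_table(path, column_map: dict | None = None,
                       meta: StudyMeta | None = None,
                       rejects: list | None = None) -> list[SnpAssociation]:
    """Read a delimited summary-statistic table into validated records.

    Parameters
    ----------
    path
        TSV/CSV file (gzip transparent; delimiter sniffed from the header).
    column_map
        Mapping from :class:`SnpAssociation` field names to column names in
        the file. Defaults to :data:`CANONICAL_COLUMNS`. ``eaf`` and ``n``
        may be omitted; a missing ``n`` column falls back to
        ``meta.n_total``.
    meta
        Optional study descriptors, used for the sample-size fallback.
    rejects
        Optional list; invalid rows are appended as ``(row_index, reason)``.

    Rows violating a record invariant are rejected (logged, and reported via
    ``rejects``), not fatal. Zero valid rows raises :class:`EmptyInputError`.
    """
    cmap = dict(CANONICAL_COLUMNS)
    if column_map:
        cmap.update(column_map)
    # sniff the delimiter from the header, then parse with round-trip
    # float precision (the sniffing python engine is lossy on floats)
    header = pd.read_csv(path, sep="\0", nrows=1, header=None, engine="python").iloc[0, 0]
    sep = "\t" if str(header).count("\t") >= str(header).count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = [f for f in cmap if f not in ("eaf", "n")]
    for fld in required:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(f"mapped column {cmap[fld]!r} (field {fld!r}) not in {path}")
    has_eaf = cmap["eaf"] in df.columns
    has_n = cmap["n"] in df.columns
    if not has_n and (meta is None or meta.n_total <= 0):
        raise ConfigurationError(f"no sample-size column {cmap['n']!r} and no meta.n_total fallback")

    records: list[SnpAssociation] = []
    for i, row in df.iterrows():
        try:
            eaf = float(row[cmap["eaf"]]) if has_eaf and pd.notna(row[cmap["eaf"]]) else None
            n = int(row[cmap["n"]]) if has_n else meta.n_total
            rec = SnpAssociation(
                snp_id=str(row[cmap["snp_id"]]),
                chrom=str(row[cmap["chrom"]]),
                pos=int(row[cmap["pos"]]),
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                eaf=eaf,
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pval=float(row[cmap["pval"]]),
                n=n,
            )
        except (ValueError, TypeError, KeyError) as exc:
            logger.warning("row %d rejected: %s", i, exc)
            if rejects is not None:
                rejects.append((int(i), str(exc)))
            continue
        records.append(rec)
    if not records:
        raise EmptyInputError(f"no valid summary-statistic rows in {path}")
    return records


def write_summary_table(records: list[SnpAssociation], path) -> None:
    """Write records as TSV using the canonical column set (round-trips
    with :func:`read_summary_table`)."""
    df = pd.DataFrame({
        "SNP": [r.snp_id for r in records],
        "CHR": [r.chrom for r in records],
        "POS": [r.pos for r in records],
        "EA": [r.effect_allele for r in records],
        "OA": [r.other_allele for r in records],
        "EAF": [r.eaf if r.eaf is not None else np.nan for r in records],
        "BETA": [r.beta for r in records],
        "SE": [r.se for r in records],
        "P": [r.pval for r in records],
        "N": [r.n for r in records],
    })
    # shortest round-trip representation: float64 values survive the text trip
    df.to_csv(path, sep="\t", index=False,
              float_format=lambda v: repr(float(v)))


def _orientation(exp: SnpAssociation, out: SnpAssociation) -> str | None:
    """Classify the outcome record's allele orientation relative to the
    exposure: 'same', 'swap', or None when the pairs are irreconcilable."""
    ea, oa = exp.effect_allele, exp.other_allele
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    pair = (out.effect_allele, out.other_allele)
    if pair == (ea, oa) or pair == (cea, coa):
        return "same"
    if pair == (oa, ea) or pair == (coa, cea):
        return "swap"
    return None


def harmonize(exposure: list[SnpAssociation], outcome: list[SnpAssociation],
              palindrome_eaf_window: float = 0.08,
              match_on_position: bool = False) -> HarmonizedInstruments:
    """Align outcome effects to the exposure's effect alleles.

    Variants are matched on ``snp_id`` (or on ``(chrom, pos)`` when
    ``match_on_position``). When the outcome's allele pair is the swap (or
    reverse-complement swap) of the exposure's, the outcome beta sign is
    flipped and its EAF reflected. Palindromic variants with EAF missing or
    within ``0.5 ± palindrome_eaf_window`` in either study are dropped; an
    unambiguous palindromic variant is additionally strand-checked by
    requiring its EAFs to lie on the same side of 0.5 after alignment.
    Irreconcilable allele pairs (e.g. A/G vs A/C) are dropped with a
    warning. Empty intersection raises :class:`NoOverlapError`.
    """
    if not (0.0 <= palindrome_eaf_window <= 0.5):
        raise ValueError("palindrome_eaf_window must be in [0, 0.5]")
    key = (lambda r: (r.chrom, r.pos)) if match_on_position else (lambda r: r.snp_id)
    out_by_key = {key(r): r for r in outcome}
    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window

    ids, b_exp, s_exp, b_out, s_out, eafs = [], [], [], [], [], []
    n_pal = n_flip = n_bad = 0
    for exp in exposure:
        out = out_by_key.get(key(exp))
        if out is None:
            continue
        orient = _orientation(exp, out)
        if orient is None:
            logger.warning("%s: irreconcilable alleles %s/%s vs %s/%s; dropped",
                           exp.snp_id, exp.effect_allele, exp.other_allele,
                           out.effect_allele, out.other_allele)
            n_bad += 1
            continue
        beta_out = out.beta if orient == "same" else -out.beta
        eaf_out = out.eaf if orient == "same" else (None if out.eaf is None else 1 - out.eaf)
        flipped = orient == "swap"
        if exp.is_palindromic:
            ambiguous = (
                exp.eaf is None or eaf_out is None
                or lo <= exp.eaf <= hi or lo <= eaf_out <= hi
            )
            if ambiguous:
                n_pal += 1
                continue
            # letters cannot resolve strand for palindromes; trust frequency
            if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
                beta_out = -beta_out
                eaf_out = 1 - eaf_out
                flipped = not flipped
        if flipped:
            n_flip += 1
        ids.append(exp.snp_id)
        b_exp.append(exp.beta)
        s_exp.append(exp.se)
        b_out.append(beta_out)
        s_out.append(out.se)
        eafs.append(exp.eaf if exp.eaf is not None else np.nan)
    if not ids:
        raise NoOverlapError("no variants retained after harmonization")
    return HarmonizedInstruments(
        snp_ids=ids, beta_exp=b_exp, se_exp=s_exp,
        beta_out=b_out, se_out=s_out, eaf=eafs,
        n_dropped_palindromic=n_pal, n_flipped=n_flip,
        n_dropped_incompatible=n_bad,
    )
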