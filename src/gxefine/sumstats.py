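"""Data model and I/O for GWAS gene-environment summary statistics.

The central record is :class:`JointStat`, the per-variant output of a joint
main-effect/interaction ("Model 1") regression: the genetic main effect
``beta_g``, the variant-by-exposure interaction ``beta_gxe``, their standard
errors and sampling covariance, and the 1df interaction and 2df joint test
p-values.  :class:`MarginalStat` holds the exposure-free ("Model 2") marginal
effect.  Regional LD is carried as a :class:`LDMatrix` aligned to an ordered
variant index.

File formats are plain tab-delimited text.  Coordinates are 1-based,
inclusive, following GWAS summary-statistic convention.  Sex chromosomes and
the mitochondrial genome are out of scope and rejected at the key level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "JointStat",
    "MarginalStat",
    "LDMatrix",
    "KnownLocusCatalog",
    "RowError",
    "SumstatsFormatError",
    "JOINT_COLUMNS",
    "MARGINAL_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "read_marginal",
    "write_marginal",
    "read_ld",
    "write_ld",
    "read_known_loci",
    "harmonize_to_reference",
]

#: Canonical column order for joint (Model 1) summary-statistic files.
JOINT_COLUMNS = [
    "SNPID", "CHR", "POS", "EA", "NEA", "EAF", "N", "N_E0", "N_E1", "INFO",
    "BETA_G", "SE_G", "BETA_GXE", "SE_GXE", "COV_G_GXE", "P_1DF", "P_2DF",
]

#: Canonical column order for marginal (Model 2) summary-statistic files.
MARGINAL_COLUMNS = ["SNPID", "CHR", "POS", "EA", "NEA", "EAF", "N", "BETA", "SE", "P"]

_EXCLUDED_CHROMS = {"X", "Y", "MT", "M", "CHRX", "CHRY", "CHRMT", "CHRM"}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsFormatError(ValueError):
    """A summary-statistic file violates the expected format."""


@dataclass(frozen=True)
class RowError:
    """A row that failed parsing or validation, with its reason."""

    line: int
    reason: str


@dataclass(frozen=True)
class VariantKey:
    """Identity of a genetic variant: position plus allele orientation."""

    chrom: str
    pos: int
    ea: str
    oa: str
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        object.__setattr__(self, "ea", self.ea.upper())
        object.__setattr__(self, "oa", self.oa.upper())
        object.__setattr__(self, "chrom", str(self.chrom))
        if self.ea == self.oa:
            raise ValueError(f"effect and other allele identical: {self.ea}")
        if self.chrom.upper() in _EXCLUDED_CHROMS:
            raise ValueError(
                f"chromosome {self.chrom!r} excluded: autosomes only"
            )

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G pairs, whose strand cannot be resolved."""
        return _COMPLEMENT.get(self.ea) == self.oa

    def label(self) -> str:
        return self.rsid or f"{self.chrom}:{self.pos}:{self.ea}_{self.oa}"


@dataclass
class JointStat:
    """Bivariate per-variant record from a joint main/interaction model."""

    key: VariantKey
    eaf: float
    n: float
    beta_g: float
    se_g: float
    beta_gxe: float
    se_gxe: float
    cov_g_gxe: float
    p_1df: float
    p_2df: float
    n_e0: float | None = None
    n_e1: float | None = None
    info: float = 1.0
    df_all: float | None = None
    df_e0: float | None = None
    df_e1: float | None = None

    def validate(self) -> None:
        if not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"EAF out of [0,1]: {self.eaf}")
        if self.se_g <= 0 or self.se_gxe <= 0:
            raise ValueError("standard errors must be positive")
        if abs(self.cov_g_gxe) > self.se_g * self.se_gxe * (1 + 1e-12):
            raise ValueError("covariance exceeds Cauchy-Schwarz bound")
        for p in (self.p_1df, self.p_2df):
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p-value out of (0,1]: {p}")
        if self.n_e0 is not None and self.n_e1 is not None:
            if abs((self.n_e0 + self.n_e1) - self.n) > 0.5:
                raise ValueError("n != n_e0 + n_e1")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    def covariance(self) -> np.ndarray:
        """2x2 sampling covariance of (beta_g, beta_gxe)."""
        return np.array(
            [
                [self.se_g**2, self.cov_g_gxe],
                [self.cov_g_gxe, self.se_gxe**2],
            ]
        )


@dataclass
class MarginalStat:
    """Per-variant marginal genetic effect (exposure-free model)."""

    key: VariantKey
    eaf: float
    n: float
    beta: float
    se: float
    p: float

    def validate(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value out of (0,1]: {self.p}")


@dataclass
class LDMatrix:
    """Signed dosage-correlation matrix for a region, aligned to ``keys``."""

    keys: list[VariantKey]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise SumstatsFormatError("LD matrix must be square")
        if len(self.keys) != self.r.shape[0]:
            raise SumstatsFormatError(
                f"index has {len(self.keys)} variants but matrix is "
                f"{self.r.shape[0]}x{self.r.shape[1]}"
            )
        # symmetrize and pin the diagonal; asymmetric text dumps are common
        self.r = (self.r + self.r.T) / 2.0
        np.fill_diagonal(self.r, 1.0)

    def __len__(self) -> int:
        return len(self.keys)

    def r2(self, i: int, j: int) -> float:
        return float(self.r[i, j] ** 2)

    def repaired_psd(self, regularize: float = 1e-4) -> "LDMatrix":
        """Return a positive-semidefinite copy.

        Negative eigenvalues (from estimation noise or text truncation) are
        clipped at zero, the matrix is rescaled back to unit diagonal, then
        off-diagonals are shrunk by ``1 - regularize`` to guard exactly
        singular blocks.
        """
        w, v = np.linalg.eigh(self.r)
        if w.min() >= 0 and regularize == 0:
            return self
        w = np.clip(w, 0.0, None)
        m = (v * w) @ v.T
        d = np.sqrt(np.clip(np.diag(m), 1e-12, None))
        m = m / np.outer(d, d)
        if regularize:
            off = ~np.eye(len(m), dtype=bool)
            m[off] *= 1.0 - regularize
        np.fill_diagonal(m, 1.0)
        return LDMatrix(self.keys, m)


@dataclass
class KnownLocusCatalog:
    """Positions of previously reported trait-associated variants."""

    entries: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, pos, _trait in self.entries:
            if pos < 1:
                raise ValueError(f"catalog position must be >= 1, got {pos}")

    def positions_on(self, chrom: str) -> np.ndarray:
        return np.array(
            [p for c, p, _ in self.entries if str(c) == str(chrom)], dtype=int
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _resolve_columns(
    header: Sequence[str], required: Sequence[str], dialect: Mapping[str, str] | None
) -> dict[str, str]:
    dialect = dict(dialect or {})
    resolved = {}
    for canon in required:
        actual = dialect.get(canon, canon)
        if actual not in header:
            raise SumstatsFormatError(f"missing required column {canon!r}")
        resolved[canon] = actual
    return resolved


_OPTIONAL_JOINT = {"SNPID", "N_E0", "N_E1", "INFO"}


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    return_report: bool = False,
):
    """Read a joint summary-statistic TSV into :class:`JointStat` records.

    ``dialect`` maps canonical column names to the file's actual names.
    Rows that fail type coercion or validation are collected as
    :class:`RowError` (and logged), never silently dropped; pass
    ``return_report=True`` to receive ``(records, errors)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [c for c in JOINT_COLUMNS if c not in _OPTIONAL_JOINT]
    cols = _resolve_columns(df.columns, required, dialect)
    for canon in _OPTIONAL_JOINT:
        actual = (dialect or {}).get(canon, canon)
        if actual in df.columns:
            cols[canon] = actual

    records: list[JointStat] = []
    errors: list[RowError] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        try:
            key = VariantKey(
                chrom=row[cols["CHR"]],
                pos=int(float(row[cols["POS"]])),
                ea=row[cols["EA"]],
                oa=row[cols["NEA"]],
                rsid=row[cols["SNPID"]] if "SNPID" in cols and pd.notna(row[cols["SNPID"]]) else None,
            )
            rec = JointStat(
                key=key,
                eaf=float(row[cols["EAF"]]),
                n=float(row[cols["N"]]),
                n_e0=_opt_float(row, cols, "N_E0"),
                n_e1=_opt_float(row, cols, "N_E1"),
                info=_opt_float(row, cols, "INFO", default=1.0),
                beta_g=float(row[cols["BETA_G"]]),
                se_g=float(row[cols["SE_G"]]),
                beta_gxe=float(row[cols["BETA_GXE"]]),
                se_gxe=float(row[cols["SE_GXE"]]),
                cov_g_gxe=float(row[cols["COV_G_GXE"]]),
                p_1df=float(row[cols["P_1DF"]]),
                p_2df=float(row[cols["P_2DF"]]),
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            errors.append(RowError(line=line, reason=str(exc)))
            continue
        records.append(rec)

    if errors:
        logger.warning(
            "%s: %d row(s) failed validation (first: line %d, %s)",
            path, len(errors), errors[0].line, errors[0].reason,
        )
    if return_report:
        return records, errors
    return records


def _opt_float(row, cols, canon, default=None):
    if canon not in cols:
        return default
    val = row[cols[canon]]
    if pd.isna(val) or val == "":
        return default
    return float(val)


def write_sumstats(records: Sequence[JointStat], path: str | Path) -> None:
    """Write joint records in canonical column order.

    Floats are rendered with shortest round-trip repr, so read-after-write
    reproduces every numeric field exactly.
    """
    if not records:
        logger.warning("writing header-only summary file: no records")
    rows = []
    for r in records:
        rows.append(
            {
                "SNPID": r.key.label(),
                "CHR": r.key.chrom,
                "POS": r.key.pos,
                "EA": r.key.ea,
                "NEA": r.key.oa,
                "EAF": r.eaf,
                "N": r.n,
                "N_E0": "" if r.n_e0 is None else r.n_e0,
                "N_E1": "" if r.n_e1 is None else r.n_e1,
                "INFO": r.info,
                "BETA_G": r.beta_g,
                "SE_G": r.se_g,
                "BETA_GXE": r.beta_gxe,
                "SE_GXE": r.se_gxe,
                "COV_G_GXE": r.cov_g_gxe,
                "P_1DF": r.p_1df,
                "P_2DF": r.p_2df,
            }
        )
    df = pd.DataFrame(rows, columns=JOINT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_marginal(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[MarginalStat]:
    """Read a marginal (Model 2) summary-statistic TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [c for c in MARGINAL_COLUMNS if c != "SNPID"]
    cols = _resolve_columns(df.columns, required, dialect)
    actual_snpid = (dialect or {}).get("SNPID", "SNPID")
    if actual_snpid in df.columns:
        cols["SNPID"] = actual_snpid
    records = []
    for _, row in df.iterrows():
        key = VariantKey(
            chrom=row[cols["CHR"]],
            pos=int(float(row[cols["POS"]])),
            ea=row[cols["EA"]],
            oa=row[cols["NEA"]],
            rsid=row[cols["SNPID"]] if "SNPID" in cols and pd.notna(row[cols["SNPID"]]) else None,
        )
        rec = MarginalStat(
            key=key,
            eaf=float(row[cols["EAF"]]),
            n=float(row[cols["N"]]),
            beta=float(row[cols["BETA"]]),
            se=float(row[cols["SE"]]),
            p=float(row[cols["P"]]),
        )
        rec.validate()
        records.append(rec)
    return records


def write_marginal(records: Sequence[MarginalStat], path: str | Path) -> None:
    rows = [
        {
            "SNPID": r.key.label(),
            "CHR": r.key.chrom,
            "POS": r.key.pos,
            "EA": r.key.ea,
            "NEA": r.key.oa,
            "EAF": r.eaf,
            "N": r.n,
            "BETA": r.beta,
            "SE": r.se,
            "P": r.p,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MARGINAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ld(path_matrix: str | Path, path_index: str | Path) -> LDMatrix:
    """Read a whitespace-delimited square LD matrix plus its variant index.

    The matrix is symmetrized as (M + M')/2 and the diagonal reset to 1.
    """
    m = np.loadtxt(path_matrix, ndmin=2)
    idx = pd.read_csv(path_index, sep="\t", dtype=str)
    keys = [
        VariantKey(
            chrom=row["CHR"],
            pos=int(float(row["POS"])),
            ea=row["EA"],
            oa=row["NEA"],
            rsid=row.get("SNPID"),
        )
        for _, row in idx.iterrows()
    ]
    return LDMatrix(keys, m)


def write_ld(ld: LDMatrix, path_matrix: str | Path, path_index: str | Path) -> None:
    np.savetxt(path_matrix, ld.r, fmt="%.10g")
    pd.DataFrame(
        {
            "SNPID": [k.label() for k in ld.keys],
            "CHR": [k.chrom for k in ld.keys],
            "POS": [k.pos for k in ld.keys],
            "EA": [k.ea for k in ld.keys],
            "NEA": [k.oa for k in ld.keys],
        }
    ).to_csv(path_index, sep="\t", index=False)


def read_known_loci(path: str | Path) -> KnownLocusCatalog:
    """Read a known-locus catalog TSV with columns CHR, POS, TRAIT."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    for col in ("CHR", "POS"):
        if col not in df.columns:
            raise SumstatsFormatError(f"missing required column {col!r}")
    trait = df["TRAIT"] if "TRAIT" in df.columns else [""] * len(df)
    return KnownLocusCatalog(
        entries=[
            (str(c), int(p), str(t))
            for c, p, t in zip(df["CHR"], df["POS"], trait)
        ]
    )


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------


def harmonize_to_reference(
    records: Iterable[JointStat],
    reference: Mapping[tuple[str, int], tuple[str, str]],
) -> tuple[list[JointStat], int]:
    """Orient records to a reference (ea, oa) per (chrom, pos).

    A record whose alleles are swapped relative to the reference has its
    effects negated and EAF mirrored.  Records whose alleles match only via
    strand complement are ambiguous for palindromic SNPs and unverifiable in
    general, so any record requiring a strand flip is dropped; the dropped
    count is returned and logged.
    """
    out: list[JointStat] = []
    dropped = 0
    for rec in records:
        ref = reference.get((rec.key.chrom, rec.key.pos))
        if ref is None:
            out.append(rec)
            continue
        ref_ea, ref_oa = ref[0].upper(), ref[1].upper()
        if (rec.key.ea, rec.key.oa) == (ref_ea, ref_oa):
            out.append(rec)
        elif (rec.key.ea, rec.key.oa) == (ref_oa, ref_ea):
            flipped_key = replace(rec.key, ea=ref_ea, oa=ref_oa)
            out.append(
                replace(
                    rec,
                    key=flipped_key,
                    eaf=1.0 - rec.eaf,
                    beta_g=-rec.beta_g,
                    beta_gxe=-rec.beta_gxe,
                    cov_g_gxe=rec.cov_g_gxe,
                )
            )
        else:
            dropped += 1
    if dropped:
        logger.warning("harmonization dropped %d strand-inconsistent record(s)", dropped)
    return out, dropped
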