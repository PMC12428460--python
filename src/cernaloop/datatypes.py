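"""Domain types shared by every pipeline stage.

The pipeline follows a candidate "funnel": a gene signature defines the
transcripts of interest; validated miRNA→target records select candidate
miRNAs; circRNA↔miRNA sponge records (with AGO-CLIP-supported binding-site
counts) select candidate circRNAs; and the surviving triples are screened
for feed-forward-loop motifs.  Expression analysis consumes a log2-scale
normalized matrix with per-sample clinical annotation, and qPCR validation
consumes a Ct table with a reference transcript.

Conventions
-----------
* Gene symbols are compared case-insensitively and stored upper-cased;
  miRNA identifiers are compared verbatim (arm suffixes are
  case-meaningful by convention).
* Genomic coordinates are 0-based, half-open.
* Missing values are ``NaN`` (numeric) or ``None``/``"NA"`` (categorical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

logger = logging.getLogger("cernaloop")

#: annotation levels accepted for yes/no clinical flags (None == missing)
YES_NO = ("yes", "no")
#: molecular subtype levels (C is the most aggressive)
MENG_SUBTYPES = ("A", "B", "C")
#: WHO grades covered by the cohort contract
WHO_GRADES = (1, 2)

ANNOTATION_COLUMNS = (
    "who_grade",
    "recurrent",
    "meng_subtype",
    "chr1p_loss",
    "chr22q_loss",
    "necrosis",
    "ki67_index",
)


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene set (e.g. a transcriptomic risk biomarker)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        upper = tuple(g.strip().upper() for g in self.genes)
        if not upper:
            raise ValueError("gene signature must be non-empty")
        if len(set(upper)) != len(upper):
            dupes = sorted({g for g in upper if upper.count(g) > 1})
            raise ValueError(f"duplicate symbols in signature: {dupes}")
        object.__setattr__(self, "genes", upper)

    def __contains__(self, gene: str) -> bool:
        return gene.strip().upper() in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class MirTargetRecord:
    """One validated miRNA→target interaction."""

    mirna_id: str
    target_gene: str
    evidence: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_gene", self.target_gene.strip().upper())
        object.__setattr__(self, "mirna_id", self.mirna_id.strip())


@dataclass(frozen=True)
class CircRecord:
    """A circRNA with its host gene and genomic span.

    ``spliced_length`` (nt) is preferred for the size of the molecule when
    known; otherwise the genomic span ``end - start`` is used.
    """

    circ_id: str
    host_gene: str
    chrom: str
    start: int
    end: int
    spliced_length: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "host_gene", self.host_gene.strip().upper())
        if self.end <= self.start:
            raise ValueError(
                f"{self.circ_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.spliced_length is not None and self.spliced_length <= 0:
            raise ValueError(f"{self.circ_id}: spliced_length must be positive")

    def size(self, mode: str = "auto") -> int:
        """Molecule size in nt.

        mode='auto' prefers spliced length, falling back to genomic span;
        'spliced' requires it; 'span' always uses the genomic span.
        """
        if mode == "span":
            return self.end - self.start
        if mode == "spliced":
            if self.spliced_length is None:
                raise ValueError(f"{self.circ_id}: spliced_length unknown")
            return self.spliced_length
        if mode != "auto":
            raise ValueError(f"unknown size mode {mode!r}")
        return self.spliced_length if self.spliced_length is not None else self.end - self.start


@dataclass(frozen=True)
class SpongeRecord:
    """A circRNA↔miRNA sponge edge backed by AGO-CLIP evidence.

    ``agoclip_p_bound`` is an upper bound on the AGO-CLIP region p-value
    (tables often print it as "≤10^-12").
    """

    circ_id: str
    mirna_id: str
    n_sites: int
    agoclip_p_bound: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError(f"{self.circ_id}~{self.mirna_id}: n_sites must be >= 1")
        if not (0.0 < self.agoclip_p_bound <= 1.0):
            raise ValueError(
                f"{self.circ_id}~{self.mirna_id}: agoclip_p_bound must be in (0, 1]"
            )


def check_sponge_integrity(
    sponges: list[SpongeRecord], circs: list[CircRecord]
) -> None:
    """Raise IntegrityError if any sponge edge names an unannotated circRNA."""
    known = {c.circ_id for c in circs}
    orphans = sorted({s.circ_id for s in sponges} - known)
    if orphans:
        raise IntegrityError(
            f"sponge edges reference {len(orphans)} circRNA id(s) absent from the "
            f"annotation: {orphans}"
        )


def _validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    ann = annotation.copy()
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise FormatError(f"sample annotation lacks column(s): {missing_cols}")

    grades = pd.to_numeric(ann["who_grade"], errors="coerce")
    bad = ann.index[~grades.isin(WHO_GRADES)]
    if len(bad):
        raise FormatError(
            f"who_grade outside {WHO_GRADES} for sample(s) {list(bad[:5])}; "
            "the cohort contract covers WHO grades 1 and 2 only"
        )
    ann["who_grade"] = grades.astype(int)

    def _norm_cat(col: str, levels: tuple[str, ...], allow_missing: bool) -> None:
        vals = ann[col].astype(object)
        vals = vals.where(~vals.isin(["", "NA", "nan", None, np.nan]), None)
        vals = vals.map(lambda v: v if v is None else str(v).strip())
        ok = vals.map(lambda v: v is None or v in levels)
        if not ok.all():
            offenders = sorted({v for v in vals[~ok]})
            raise FormatError(f"{col}: unknown level(s) {offenders}; allowed {levels}")
        if not allow_missing and vals.isna().any():
            raise FormatError(f"{col}: missing values are not allowed")
        ann[col] = vals

    _norm_cat("recurrent", YES_NO, allow_missing=False)
    _norm_cat("meng_subtype", MENG_SUBTYPES, allow_missing=True)
    for col in ("chr1p_loss", "chr22q_loss", "necrosis"):
        _norm_cat(col, YES_NO, allow_missing=True)

    ki67 = pd.to_numeric(ann["ki67_index"], errors="coerce")
    if (ki67.dropna() < 0).any():
        raise FormatError("ki67_index must be non-negative")
    ann["ki67_index"] = ki67
    return ann


@dataclass
class ExpressionDataset:
    """Log2-scale normalized expression (genes × samples) plus annotation.

    ``values`` rows are upper-cased gene symbols; columns are sample ids
    aligned to ``annotation`` (indexed by sample id).  Values are expected
    on the log2 scale of a variance-stabilized normalization.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.copy()
        vals.index = [str(g).strip().upper() for g in vals.index]
        if vals.index.duplicated().any():
            dupes = sorted(vals.index[vals.index.duplicated()])
            raise FormatError(f"duplicate gene rows in matrix: {dupes}")
        ann = _validate_annotation(self.annotation)
        missing = [s for s in ann.index if s not in vals.columns]
        if missing:
            raise IntegrityError(
                f"annotated sample(s) absent from expression matrix: {missing}"
            )
        extra = [s for s in vals.columns if s not in set(ann.index)]
        if extra:
            logger.info("dropping %d unannotated sample column(s)", len(extra))
        vals = vals.loc[:, list(ann.index)].astype(float)
        if not np.isfinite(vals.to_numpy()).all():
            raise FormatError("expression matrix contains non-finite values")
        self.values = vals
        self.annotation = ann

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CtTable:
    """qPCR Ct cycle values, assays × tissues, with a reference assay.

    Valid Ct values lie in (0, 45]; NaN marks a failed/absent assay.
    """

    ct: pd.DataFrame
    reference: str = "GAPDH"

    def __post_init__(self) -> None:
        ct = self.ct.astype(float)
        if self.reference not in ct.index:
            raise ValueError(f"reference assay {self.reference!r} absent from Ct table")
        inside = ct.to_numpy()
        ok = np.isnan(inside) | ((inside > 0) & (inside <= 45))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise FormatError(
                f"Ct value out of (0, 45] at assay {ct.index[bad[0]]!r}, "
                f"tissue {ct.columns[bad[1]]!r}"
            )
        self.ct = ct

    @property
    def assays(self) -> list[str]:
        return list(self.ct.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.ct.columns)


@dataclass
class RbpSiteTable:
    """RNA-binding-protein site counts per circRNA, split into a candidate
    set and a size-matched background set."""

    counts: pd.DataFrame  # circ_id × RBP, integer counts >= 0
    roles: pd.Series = field(default=None)  # circ_id -> {candidate, background}

    def __post_init__(self) -> None:
        counts = self.counts.astype(int)
        if (counts.to_numpy() < 0).any():
            raise ValueError("RBP site counts must be non-negative")
        roles = self.roles.reindex(counts.index)
        if roles.isna().any():
            raise IntegrityError("every circRNA in the RBP table needs a role flag")
        bad = sorted(set(roles) - {"candidate", "background"})
        if bad:
            raise FormatError(f"unknown role flag(s): {bad}")
        if (roles == "candidate").sum() < 1 or (roles == "background").sum() < 1:
            raise ValueError("need at least one candidate and one background circRNA")
        self.counts = counts
        self.roles = roles

    @property
    def candidates(self) -> pd.DataFrame:
        return self.counts.loc[self.roles == "candidate"]

    @property
    def background(self) -> pd.DataFrame:
        return self.counts.loc[self.roles == "background"]
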