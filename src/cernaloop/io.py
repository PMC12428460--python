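"""Readers and writers for every tabular format the pipeline touches.

All tables are TSV with a header row; missing values are written as empty
strings and read as missing.  circRNA coordinates may also arrive as
6-column BED (name field ``circ_id|host_gene``).  AGO-CLIP p-value bounds
are accepted both as plain floats and in the "≤10^-12" style that
interaction tables print.

Floats round-trip to 12 significant digits; integers round-trip exactly.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ANNOTATION_COLUMNS,
    CircRecord,
    CtTable,
    ExpressionDataset,
    GeneSignature,
    MirTargetRecord,
    RbpSiteTable,
    SpongeRecord,
    check_sponge_integrity,
)
from .errors import FormatError

logger = logging.getLogger("cernaloop")

FLOAT_FORMAT = "%.12g"

_MIRNA_COLUMNS = ("mirna_id", "mirna", "mir", "mirna id")
_TARGET_COLUMNS = ("target_gene", "target gene", "target", "gene", "gene_symbol")
_EVIDENCE_COLUMNS = ("evidence", "support_type", "experiments", "evidence_class")


def _find_column(df: pd.DataFrame, names: tuple[str, ...], what: str, path) -> str:
    lowered = {str(c).strip().lower(): c for c in df.columns}
    for name in names:
        if name in lowered:
            return lowered[name]
    raise FormatError(
        f"{path}: no {what} column found (looked for any of {list(names)}; "
        f"header has {list(df.columns)})"
    )


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without a header") from exc


def read_mir_target_table(path) -> list[MirTargetRecord]:
    """Read a miRTarBase-like miRNA→target TSV.

    Duplicate (miRNA, target) pairs collapse to one record (count logged);
    identifiers not in the "hsa-..." dialect are accepted verbatim with a
    logged warning.
    """
    df = _read_tsv(path)
    mir_col = _find_column(df, _MIRNA_COLUMNS, "miRNA", path)
    tgt_col = _find_column(df, _TARGET_COLUMNS, "target gene", path)
    try:
        ev_col = _find_column(df, _EVIDENCE_COLUMNS, "evidence", path)
    except FormatError:
        ev_col = None

    records: dict[tuple[str, str], MirTargetRecord] = {}
    n_dupes = 0
    odd_ids = set()
    for _, row in df.iterrows():
        rec = MirTargetRecord(
            mirna_id=row[mir_col],
            target_gene=row[tgt_col],
            evidence=row[ev_col] if ev_col else "",
        )
        if not rec.mirna_id.startswith("hsa-"):
            odd_ids.add(rec.mirna_id)
        key = (rec.mirna_id, rec.target_gene)
        if key in records:
            n_dupes += 1
        else:
            records[key] = rec
    if n_dupes:
        logger.info("%s: collapsed %d duplicate miRNA-target pair(s)", path, n_dupes)
    if odd_ids:
        logger.warning(
            "%s: %d miRNA id(s) outside the 'hsa-' dialect accepted verbatim: %s",
            path, len(odd_ids), sorted(odd_ids)[:5],
        )
    return list(records.values())


def write_mir_target_table(records: list[MirTargetRecord], path) -> None:
    pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "target_gene": [r.target_gene for r in records],
            "evidence": [r.evidence for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


_P_BOUND_RE = re.compile(r"^10\^?(?P<exp>[+-]?\d+(\.\d+)?)$")


def parse_p_bound(text) -> float:
    """Parse an AGO-CLIP p-value bound: '≤10^−12', '<=10^-6', '1e-6', '0.01'."""
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        value = float(text)
    else:
        s = str(text).strip()
        s = s.replace("≤", "").replace("<=", "").replace("<", "").replace("=", "")
        s = s.replace("−", "-").replace("⁻", "-")
        s = s.replace(" ", "").rstrip("^")
        m = _P_BOUND_RE.match(s)
        try:
            value = 10.0 ** float(m.group("exp")) if m else float(s)
        except ValueError as exc:
            raise FormatError(f"unparseable p-value bound: {text!r}") from exc
    if not (0.0 < value <= 1.0):
        raise FormatError(f"p-value bound out of (0, 1]: {text!r}")
    return value


_CIRC_COLUMNS = ("circ_id", "circrna", "circrna_id", "circbase_id")
_SITES_COLUMNS = ("n_sites", "binding_sites", "num_sites", "sites")
_PBOUND_COLUMNS = ("agoclip_p_bound", "agoclip_p", "ago_clip_p", "p_bound", "clip_p_value")


def read_circ_annotation(path, coords: str | None = None) -> list[CircRecord]:
    """Read circRNA annotation from TSV (or 6-column BED).

    ``coords`` selects the input coordinate dialect: 'bed' (0-based
    half-open, the default for .bed files and for TSV) or 'one_based'
    (1-based inclusive, converted on read).
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        rows = []
        for line_no, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{line_no}: BED needs >= 4 columns")
            name = fields[3]
            circ_id, _, host = name.partition("|")
            if not host:
                raise FormatError(
                    f"{path}:{line_no}: BED name must be 'circ_id|host_gene', got {name!r}"
                )
            rows.append(
                CircRecord(
                    circ_id=circ_id,
                    host_gene=host,
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                )
            )
        return rows

    df = _read_tsv(path)
    circ_col = _find_column(df, _CIRC_COLUMNS, "circRNA id", path)
    for needed in ("host_gene", "chrom", "start", "end"):
        if needed not in df.columns:
            raise FormatError(f"{path}: missing required column {needed!r}")
    shift = 1 if coords == "one_based" else 0
    records = []
    for _, row in df.iterrows():
        spliced = row.get("spliced_length", "")
        records.append(
            CircRecord(
                circ_id=row[circ_col],
                host_gene=row["host_gene"],
                chrom=row["chrom"],
                start=int(row["start"]) - shift,
                end=int(row["end"]),
                spliced_length=int(spliced) if str(spliced).strip() else None,
            )
        )
    return records


def write_circ_annotation(circs: list[CircRecord], path) -> None:
    pd.DataFrame(
        {
            "circ_id": [c.circ_id for c in circs],
            "host_gene": [c.host_gene for c in circs],
            "chrom": [c.chrom for c in circs],
            "start": [c.start for c in circs],
            "end": [c.end for c in circs],
            "spliced_length": [
                "" if c.spliced_length is None else c.spliced_length for c in circs
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sponge_tables(
    interaction_path, annotation_path, coords: str | None = None
) -> tuple[list[SpongeRecord], list[CircRecord]]:
    """Read an ENCORI-like sponge-edge TSV plus circRNA annotation.

    Referential integrity is enforced: every sponge edge must name an
    annotated circRNA.
    """
    circs = read_circ_annotation(annotation_path, coords=coords)
    df = _read_tsv(interaction_path)
    circ_col = _find_column(df, _CIRC_COLUMNS, "circRNA id", interaction_path)
    mir_col = _find_column(df, _MIRNA_COLUMNS, "miRNA", interaction_path)
    sites_col = _find_column(df, _SITES_COLUMNS, "binding-site count", interaction_path)
    try:
        p_col = _find_column(df, _PBOUND_COLUMNS, "AGO-CLIP p bound", interaction_path)
    except FormatError:
        p_col = None
    sponges = []
    for _, row in df.iterrows():
        sponges.append(
            SpongeRecord(
                circ_id=row[circ_col].strip(),
                mirna_id=row[mir_col].strip(),
                n_sites=int(row[sites_col]),
                agoclip_p_bound=parse_p_bound(row[p_col]) if p_col else 1.0,
            )
        )
    check_sponge_integrity(sponges, circs)
    return sponges, circs


def write_sponge_table(sponges: list[SpongeRecord], path) -> None:
    pd.DataFrame(
        {
            "circ_id": [s.circ_id for s in sponges],
            "mirna_id": [s.mirna_id for s in sponges],
            "n_sites": [s.n_sites for s in sponges],
            "agoclip_p_bound": [FLOAT_FORMAT % s.agoclip_p_bound for s in sponges],
        }
    ).to_csv(path, sep="\t", index=False)


def read_signature(path, name: str | None = None) -> GeneSignature:
    """Read a gene signature: one symbol per line, '#' comments allowed."""
    path = Path(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return GeneSignature(name=name or path.stem, genes=tuple(genes))


def write_signature(signature: GeneSignature, path) -> None:
    Path(path).write_text("\n".join(signature.genes) + "\n")


def read_expression_dataset(matrix_path, annotation_path) -> ExpressionDataset:
    """Read a genes × samples log2 expression TSV plus sample annotation.

    The matrix's first column holds gene symbols.  A non-numeric cell is a
    format error naming the offending row and column; categorical
    annotation levels are validated on construction.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy() & (raw.to_numpy() != ""))
    if len(bad):
        r, c = bad[0]
        raise FormatError(
            f"{matrix_path}: non-numeric cell {raw.iat[r, c]!r} at "
            f"gene {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
    id_col = _find_column(ann, ("sample_id", "sample", "id"), "sample id", annotation_path)
    ann = ann.set_index(id_col)
    ann = ann.replace("", None)
    return ExpressionDataset(values=values, annotation=ann)


def write_expression_dataset(ds: ExpressionDataset, matrix_path, annotation_path) -> None:
    ds.values.to_csv(matrix_path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)
    ann = ds.annotation.copy()
    ann["ki67_index"] = ann["ki67_index"].map(
        lambda v: "" if pd.isna(v) else FLOAT_FORMAT % v
    )
    for col in ann.columns:
        if col != "ki67_index":
            ann[col] = ann[col].map(lambda v: "" if v is None or pd.isna(v) else v)
    ann.to_csv(annotation_path, sep="\t", index_label="sample_id")


def read_ct_table(path, reference: str = "GAPDH") -> CtTable:
    """Read an assays × tissues Ct TSV (empty cells = missing)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    ct = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(ct.isna().to_numpy() & (raw.to_numpy() != ""))
    if len(bad):
        r, c = bad[0]
        raise FormatError(
            f"{path}: non-numeric Ct {raw.iat[r, c]!r} at assay {raw.index[r]!r}, "
            f"tissue {raw.columns[c]!r}"
        )
    return CtTable(ct=ct, reference=reference)


def write_ct_table(table: CtTable, path) -> None:
    table.ct.to_csv(path, sep="\t", index_label="assay", float_format=FLOAT_FORMAT)


def read_rbp_table(path) -> RbpSiteTable:
    """Read a circRNA × RBP site-count TSV with a 'role' column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "role" not in df.columns:
        raise FormatError(f"{path}: missing required column 'role'")
    roles = df["role"].astype(str)
    counts = df.drop(columns=["role"])
    return RbpSiteTable(counts=counts, roles=roles)


def write_rbp_table(table: RbpSiteTable, path) -> None:
    out = table.counts.copy()
    out.insert(0, "role", table.roles)
    out.to_csv(path, sep="\t", index_label="circ_id")


# ---------------------------------------------------------------------------
# Packaged worked example
# ---------------------------------------------------------------------------

def load_demo_network():
    """Load the packaged circCHEK1/circPIM1 demo network.

    Returns ``(targets, sponges, circs, signature)``: the published
    sponge table of the two feed-forward-loop host genes (CHEK1, PIM1),
    their four tumor-suppressor miRNAs, the validated miRNA→target
    records, and the 11-host-gene demo signature.  Genomic coordinates
    and per-edge site counts in the fixture are illustrative.
    """
    from importlib.resources import files

    data = files("cernaloop") / "data"
    targets = read_mir_target_table(str(data / "demo_targets.tsv"))
    sponges, circs = read_sponge_tables(
        str(data / "demo_sponges.tsv"), str(data / "demo_circs.tsv")
    )
    signature = read_signature(str(data / "demo_signature.txt"), name="hr-mng-hosts")
    return targets, sponges, circs, signature
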