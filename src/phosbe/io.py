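"""Readers and writers for the toolkit's file formats.

Everything tabular is tab-separated UTF-8 with LF line endings, the
convention of the screen-analysis ecosystem; sequences travel as FASTA.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library_design import CodingRecord, LibraryTable, DesignReport, PhosphoSite
from .screen_analysis import CountMatrix

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["protein_id", "position", "residue"]


class ValidationError(ValueError):
    """Input file failed validation."""


def read_fasta(path: str | Path) -> dict[str, CodingRecord]:
    """Read coding sequences from FASTA, keyed by protein id.

    Ids are taken up to the first whitespace; sequences are upper-cased
    and must be A/C/G/T (RNA with U is rejected).
    """
    records: dict[str, CodingRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in records:
            raise ValidationError(f"duplicate FASTA id {pid!r} in {path}")
        seq = str(rec.seq).upper()
        bad = sorted(set(seq) - set("ACGT"))
        if bad:
            raise ValidationError(
                f"record {pid!r} in {path} has non-A/C/G/T characters: {bad}"
            )
        records[pid] = CodingRecord(pid, seq)
    return records


def write_fasta(records: Iterable[CodingRecord] | dict[str, CodingRecord], path: str | Path) -> None:
    if isinstance(records, dict):
        records = records.values()
    seqs = [SeqRecord(Seq(r.cds), id=r.protein_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_site_table(path: str | Path, strict: bool = False) -> list[PhosphoSite]:
    """Read a phosphosite annotation TSV (protein_id, position, residue).

    Invalid rows are dropped with a warning (or abort in strict mode);
    duplicated (protein, position) pairs collapse to one site.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"site table {path} lacks columns {sorted(missing)}")
    sites: list[PhosphoSite] = []
    seen: set[tuple[str, int]] = set()
    for i, row in df.iterrows():
        try:
            site = PhosphoSite(str(row["protein_id"]), int(row["position"]), str(row["residue"]))
        except (ValueError, TypeError) as exc:
            msg = f"site table row {i + 2}: {exc}"
            if strict:
                raise ValidationError(msg) from exc
            logger.warning("%s (row dropped)", msg)
            continue
        key = (site.protein_id, site.position)
        if key in seen:
            logger.warning("duplicate site %s collapsed", site.key)
            continue
        seen.add(key)
        sites.append(site)
    return sites


def write_site_table(sites: Iterable[PhosphoSite], path: str | Path) -> None:
    pd.DataFrame(
        [{"protein_id": s.protein_id, "position": s.position, "residue": s.residue} for s in sites],
        columns=SITE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_library(library: LibraryTable, path: str | Path) -> None:
    library.table.to_csv(path, sep="\t", index=False)


def read_library(path: str | Path) -> LibraryTable:
    table = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"protein_id": str})
    table["is_control"] = table["is_control"].astype(str).str.lower().isin(["true", "1"])
    table["duplicate_protospacer"] = (
        table["duplicate_protospacer"].astype(str).str.lower().isin(["true", "1"])
    )
    table["position"] = table["position"].astype(int)
    return LibraryTable(table=table)


def write_design_report(report: DesignReport, path: str | Path) -> None:
    report.site_status.to_csv(path, sep="\t", index=False)


def write_counts(matrix: CountMatrix, counts_path: str | Path, roles_path: str | Path) -> None:
    """Write a count matrix and its sample-role sidecar TSV."""
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.roles.rename_axis("sample").to_frame().to_csv(roles_path, sep="\t")


def read_counts(
    counts_path: str | Path,
    roles_path: str | Path,
    library: LibraryTable | None = None,
) -> CountMatrix:
    """Read a guide x sample counts TSV plus its sample-role sidecar.

    When a library is given, guide ids are matched against it: counts
    for unknown guides raise, library guides missing from the file are
    zero-filled with a warning, and control flags come from the library.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{counts_path}: ragged or missing cells")
    arr = df.to_numpy()
    if not (arr == arr.astype(int)).all():
        raise ValidationError(f"{counts_path}: non-integer counts")
    if (arr < 0).any():
        raise ValidationError(f"{counts_path}: negative counts")
    df = df.astype(int)

    roles_df = pd.read_csv(roles_path, sep="\t", index_col=0)
    roles = roles_df.iloc[:, 0].rename("role")

    if library is not None:
        lib_ids = library.table["guide_id"]
        unknown = set(df.index) - set(lib_ids)
        if unknown:
            raise ValidationError(f"counts contain guides not in library: {sorted(unknown)[:5]}")
        missing = [g for g in lib_ids if g not in df.index]
        if missing:
            logger.warning("%d library guides missing from counts; zero-filled", len(missing))
        df = df.reindex(lib_ids, fill_value=0)
        is_control = pd.Series(
            library.table["is_control"].to_numpy(), index=lib_ids.to_numpy(), name="is_control"
        )
    else:
        is_control = pd.Series(False, index=df.index, name="is_control")
    return CountMatrix(counts=df, roles=roles, is_control=is_control)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict, inputs: Iterable[str | Path]) -> Path:
    """Record config, seed and input checksums for provenance."""
    from . import __version__

    manifest = {
        "tool": "phosbe",
        "version": __version__,
        "config": config,
        "inputs": {str(p): sha256_of(p) for p in inputs if Path(p).is_file()},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
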