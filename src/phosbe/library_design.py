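"""Design of phosphosite-disrupting base-editor gRNA libraries.

Given coding sequences and a table of annotated Ser/Thr/Tyr phosphosites,
scan both strands for protospacer placements whose NGG PAM and editing
window put an editable base of the target codon under the deaminase,
predict the complete-edit outcome, and keep guides whose primary
substitution removes the phospho-acceptor without introducing a stop or
changing local charge (acidic/basic products are excluded because they
mimic rather than disrupt phosphorylation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .editing_model import (
    ACIDIC,
    BASIC,
    STOP,
    PHOSPHO_RESIDUES,
    EditorSpec,
    complement_base,
    pam_matches,
    reverse_complement,
    translate,
)

logger = logging.getLogger(__name__)


class SubstitutionClass(str, Enum):
    SILENT = "SILENT"
    ALLOWED_MISSENSE = "ALLOWED_MISSENSE"
    CHARGE_ALTERING = "CHARGE_ALTERING"
    NONSENSE = "NONSENSE"


class AnnotationMismatchError(ValueError):
    """The site table's residue disagrees with the coding sequence."""


class SiteRangeError(ValueError):
    """The site position falls outside the coding sequence."""


@dataclass(frozen=True)
class PhosphoSite:
    """One annotated phosphorylatable residue on a protein."""

    protein_id: str
    position: int  # 1-based residue index
    residue: str  # S, T or Y

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be S/T/Y, got {self.residue!r}")

    @property
    def key(self) -> str:
        return f"{self.protein_id}_{self.residue}{self.position}"


@dataclass(frozen=True)
class CodingRecord:
    """A protein-coding sequence, optionally with flanking context.

    The CDS must be a multiple of 3 with no internal stop; flanks are
    untranslated sequence used only to extend the protospacer/PAM search
    space past the CDS ends.
    """

    protein_id: str
    cds: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        for name, seq in (("cds", self.cds), ("flank5", self.flank5), ("flank3", self.flank3)):
            if any(b not in "ACGT" for b in seq):
                raise ValueError(f"{name} of {self.protein_id} contains non-ACGT characters")
        if len(self.cds) % 3:
            raise ValueError(f"CDS length of {self.protein_id} not divisible by 3")
        aa = [translate(self.cds[i : i + 3]) for i in range(0, len(self.cds), 3)]
        if STOP in aa[:-1]:
            raise ValueError(f"CDS of {self.protein_id} has an internal stop codon")

    @property
    def full_sequence(self) -> str:
        return self.flank5 + self.cds + self.flank3

    @property
    def n_residues(self) -> int:
        return len(self.cds) // 3


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer placement predicted to edit a target phosphosite.

    ``protospacer`` is given in protospacer-strand orientation (what the
    gRNA spacer matches); ``cds_start`` is the 1-based CDS coordinate of
    the placement's leftmost base on the sense strand (<= 0 when it
    begins in 5' flank).  ``window_positions`` are the protospacer
    positions (PAM-distal = 1) of editable target-codon bases.
    ``bystander_changes`` lists amino-acid changes in non-target codons
    touched by the complete edit.
    """

    site: PhosphoSite
    protospacer: str
    pam: str
    strand: str  # "sense" | "antisense" relative to the CDS
    cds_start: int
    window_positions: tuple[int, ...]
    ref_aa: str
    alt_aa: str
    substitution_class: SubstitutionClass
    bystander_changes: tuple[tuple[int, str, str], ...] = ()


@dataclass
class DesignReport:
    """Per-site design outcome plus summary statistics."""

    site_status: pd.DataFrame  # protein_id, position, residue, status, n_guides
    n_sites_attempted: int
    n_sites_targeted: int

    @property
    def fraction_targetable(self) -> float:
        if self.n_sites_attempted == 0:
            return float("nan")
        return self.n_sites_targeted / self.n_sites_attempted


LIBRARY_COLUMNS = [
    "guide_id",
    "protein_id",
    "position",
    "residue",
    "protospacer",
    "pam",
    "strand",
    "cds_start",
    "window_positions",
    "ref_aa",
    "alt_aa",
    "class",
    "bystanders",
    "duplicate_protospacer",
    "is_control",
]


@dataclass
class LibraryTable:
    """Designed guides plus non-targeting control rows, as a DataFrame."""

    table: pd.DataFrame
    report: DesignReport | None = None

    def __post_init__(self) -> None:
        if not self.table.empty and self.table["guide_id"].duplicated().any():
            raise ValueError("guide ids must be unique")

    @property
    def n_guides(self) -> int:
        return int((~self.table["is_control"]).sum())

    @property
    def n_controls(self) -> int:
        return int(self.table["is_control"].sum())

    @property
    def n_sites(self) -> int:
        t = self.table[~self.table["is_control"]]
        return t.drop_duplicates(["protein_id", "position"]).shape[0]

    def targeting(self) -> pd.DataFrame:
        return self.table[~self.table["is_control"]]

    def site_of_guide(self) -> pd.Series:
        """guide_id -> site key, for targeting guides."""
        t = self.targeting()
        keys = (
            t["protein_id"].astype(str)
            + "_"
            + t["residue"].astype(str)
            + t["position"].astype(int).astype(str)
        )
        return pd.Series(keys.values, index=t["guide_id"].values)


def map_site_to_codon(site: PhosphoSite, record: CodingRecord) -> tuple[int, str]:
    """Locate the codon encoding a phosphosite.

    Returns ``(codon_index, codon)`` with a 1-based codon index; raises
    if the position is out of range or the codon does not translate to
    the annotated residue.
    """
    if record.protein_id != site.protein_id:
        raise ValueError(f"record {record.protein_id} does not match site {site.protein_id}")
    if 3 * site.position > len(record.cds):
        raise SiteRangeError(
            f"{site.key}: position {site.position} beyond CDS ({record.n_residues} codons)"
        )
    codon = record.cds[3 * (site.position - 1) : 3 * site.position]
    aa = translate(codon)
    if aa != site.residue:
        raise AnnotationMismatchError(
            f"{site.key}: codon {codon} translates to {aa}, annotation says {site.residue}"
        )
    return site.position, codon


def classify_substitution(
    ref_aa: str,
    alt_aa: str,
    acidic_set: frozenset[str] = ACIDIC,
    basic_set: frozenset[str] = BASIC,
) -> SubstitutionClass:
    """Classify a predicted substitution at a phospho-residue."""
    valid = set("ACDEFGHIKLMNPQRSTVWY") | {STOP}
    if ref_aa not in PHOSPHO_RESIDUES:
        raise ValueError(f"reference residue must be S/T/Y, got {ref_aa!r}")
    if alt_aa not in valid:
        raise ValueError(f"unknown amino acid letter {alt_aa!r}")
    if alt_aa == ref_aa:
        return SubstitutionClass.SILENT
    if alt_aa == STOP:
        return SubstitutionClass.NONSENSE
    if alt_aa in acidic_set or alt_aa in basic_set:
        return SubstitutionClass.CHARGE_ALTERING
    return SubstitutionClass.ALLOWED_MISSENSE


def scan_guides(
    record: CodingRecord,
    codon_index: int,
    editor: EditorSpec,
    site: PhosphoSite | None = None,
    acidic_set: frozenset[str] = ACIDIC,
    basic_set: frozenset[str] = BASIC,
) -> list[GuideCandidate]:
    """Enumerate all protospacer placements able to edit a target codon.

    Both strands of the record (CDS plus flanking context) are scanned
    for PAM-adjacent 20-mers that put at least one editable base of the
    target codon inside the editing window.  Each candidate carries the
    complete-edit primary substitution at the target codon and the
    amino-acid changes of any bystander codons touched by window edits.
    Placements needing sequence beyond the record are not returned.
    """
    if not (1 <= codon_index <= record.n_residues):
        raise SiteRangeError(f"codon {codon_index} outside CDS of {record.protein_id}")
    codon = record.cds[3 * (codon_index - 1) : 3 * codon_index]
    if site is None:
        site = PhosphoSite(record.protein_id, codon_index, translate(codon))

    full = record.full_sequence
    off = len(record.flank5)
    n = len(full)
    L = editor.protospacer_length
    plen = len(editor.pam)
    win = list(editor.window_positions())
    # 0-based sense positions of the target codon within `full`
    sense_target = {off + 3 * (codon_index - 1) + k for k in range(3)}

    def cds_codon_of(sense_pos: int) -> int | None:
        q = sense_pos - off
        return q // 3 + 1 if 0 <= q < len(record.cds) else None

    candidates: list[GuideCandidate] = []
    for strand in ("sense", "antisense"):
        if strand == "sense":
            scan_seq = full
            to_sense = lambda p: p  # noqa: E731
        else:
            scan_seq = reverse_complement(full)
            to_sense = lambda p: n - 1 - p  # noqa: E731
        target_scan = {p for p in range(n) if to_sense(p) in sense_target}
        lo = max(0, min(target_scan) - L + 1)
        hi = min(n - L - plen, max(target_scan))
        for start in range(lo, hi + 1):
            pam = scan_seq[start + L : start + L + plen]
            if not pam_matches(editor.pam, pam):
                continue
            window_scan = [start + w - 1 for w in win]
            editable_target = sorted(
                p for p in window_scan if p in target_scan and scan_seq[p] == editor.source_base
            )
            if not editable_target:
                continue
            # complete-edit model: every window base equal to the source
            # base on the protospacer strand converts, bystanders included
            edited_scan = [p for p in window_scan if scan_seq[p] == editor.source_base]
            sense_new = editor.edited_base(strand)
            edited_full = list(full)
            for p in edited_scan:
                edited_full[to_sense(p)] = sense_new
            edited_full = "".join(edited_full)

            touched = sorted(
                {ci for ci in (cds_codon_of(to_sense(p)) for p in edited_scan) if ci is not None}
            )
            ref_aa = alt_aa = None
            bystanders: list[tuple[int, str, str]] = []
            for ci in touched:
                s0 = off + 3 * (ci - 1)
                r = translate(full[s0 : s0 + 3])
                a = translate(edited_full[s0 : s0 + 3])
                if ci == codon_index:
                    ref_aa, alt_aa = r, a
                elif r != a:
                    bystanders.append((ci, r, a))
            assert ref_aa is not None  # editable_target nonempty
            candidates.append(
                GuideCandidate(
                    site=site,
                    protospacer=scan_seq[start : start + L],
                    pam=pam,
                    strand=strand,
                    cds_start=(
                        start - off + 1 if strand == "sense" else (n - L - start) - off + 1
                    ),
                    window_positions=tuple(p - start + 1 for p in editable_target),
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    substitution_class=classify_substitution(
                        ref_aa, alt_aa, acidic_set, basic_set
                    ),
                    bystander_changes=tuple(bystanders),
                )
            )
    return candidates


def generate_nontargeting(
    n: int,
    exclusion_records: Iterable[CodingRecord] = (),
    length: int = 20,
    seed: int | np.random.Generator = 0,
    max_tries_per_guide: int = 1000,
) -> list[str]:
    """Random non-targeting protospacers absent from all records.

    Each 20-mer is rejected if it occurs exactly, in either orientation,
    anywhere in an exclusion record (CDS plus flanks).  Deterministic for
    a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    haystack = " ".join(r.full_sequence for r in exclusion_records)
    out: list[str] = []
    seen: set[str] = set()
    tries = 0
    while len(out) < n:
        if tries > max_tries_per_guide * max(n, 1):
            raise RuntimeError("could not generate enough non-targeting sequences")
        tries += 1
        proto = "".join(rng.choice(list("ACGT"), size=length))
        if proto in seen:
            continue
        if proto in haystack or reverse_complement(proto) in haystack:
            continue
        seen.add(proto)
        out.append(proto)
    return out


def _candidate_row(gc: GuideCandidate, guide_id: str) -> dict:
    return {
        "guide_id": guide_id,
        "protein_id": gc.site.protein_id,
        "position": gc.site.position,
        "residue": gc.site.residue,
        "protospacer": gc.protospacer,
        "pam": gc.pam,
        "strand": gc.strand,
        "cds_start": gc.cds_start,
        "window_positions": ",".join(map(str, gc.window_positions)),
        "ref_aa": gc.ref_aa,
        "alt_aa": gc.alt_aa,
        "class": gc.substitution_class.value,
        "bystanders": ";".join(f"{ci}:{r}>{a}" for ci, r, a in gc.bystander_changes),
        "is_control": False,
    }


def design_library(
    sites: Iterable[PhosphoSite],
    records: Mapping[str, CodingRecord] | Iterable[CodingRecord],
    editor: EditorSpec,
    n_controls: int = 0,
    seed: int = 0,
    keep_nonsense: bool = False,
    acidic_set: frozenset[str] = ACIDIC,
    basic_set: frozenset[str] = BASIC,
) -> LibraryTable:
    """Design a phosphosite-disrupting gRNA library.

    For every site with a coding record, candidate guides are scanned on
    both strands and those whose primary (complete-edit) substitution is
    ALLOWED_MISSENSE are kept (optionally NONSENSE too).  Identical
    protospacers hitting different sites remain distinct rows flagged
    ``duplicate_protospacer``.  ``n_controls`` non-targeting guides are
    appended, excluded against every record.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("empty site table")
    if not isinstance(records, Mapping):
        records = {r.protein_id: r for r in records}

    keep_classes = {SubstitutionClass.ALLOWED_MISSENSE}
    if keep_nonsense:
        keep_classes.add(SubstitutionClass.NONSENSE)

    rows: list[dict] = []
    status_rows: list[dict] = []
    guide_counter = 0
    for site in sites:
        status = {"protein_id": site.protein_id, "position": site.position,
                  "residue": site.residue, "n_guides": 0}
        record = records.get(site.protein_id)
        if record is None:
            status["status"] = "missing_record"
            status_rows.append(status)
            logger.warning("no coding record for %s; skipped", site.key)
            continue
        try:
            codon_index, _ = map_site_to_codon(site, record)
        except (SiteRangeError, AnnotationMismatchError) as exc:
            status["status"] = (
                "out_of_range" if isinstance(exc, SiteRangeError) else "annotation_mismatch"
            )
            status_rows.append(status)
            logger.warning("%s", exc)
            continue
        cands = scan_guides(record, codon_index, editor, site, acidic_set, basic_set)
        kept = [c for c in cands if c.substitution_class in keep_classes]
        if not kept:
            if not cands:
                status["status"] = "no_pam_in_reach"
            else:
                classes = {c.substitution_class for c in cands}
                status["status"] = "only_" + "/".join(sorted(c.value.lower() for c in classes))
            status_rows.append(status)
            continue
        for gc in kept:
            guide_counter += 1
            rows.append(_candidate_row(gc, f"g{guide_counter:06d}"))
        status["status"] = "targeted"
        status["n_guides"] = len(kept)
        status_rows.append(status)

    table = pd.DataFrame(rows, columns=[c for c in LIBRARY_COLUMNS if c != "duplicate_protospacer"])
    if len(table):
        table["duplicate_protospacer"] = table["protospacer"].duplicated(keep=False)
    else:
        table["duplicate_protospacer"] = pd.Series(dtype=bool)
        logger.warning("no site was targetable; emitting an empty library")

    controls = generate_nontargeting(n_controls, list(records.values()), seed=seed)
    ctrl_rows = [
        {
            "guide_id": f"ctrl{i + 1:04d}",
            "protein_id": "",
            "position": -1,
            "residue": "",
            "protospacer": proto,
            "pam": "",
            "strand": "",
            "cds_start": 0,
            "window_positions": "",
            "ref_aa": "",
            "alt_aa": "",
            "class": "",
            "bystanders": "",
            "duplicate_protospacer": False,
            "is_control": True,
        }
        for i, proto in enumerate(controls)
    ]
    table = pd.concat([table, pd.DataFrame(ctrl_rows, columns=LIBRARY_COLUMNS)], ignore_index=True)
    table = table[LIBRARY_COLUMNS]
    table["is_control"] = table["is_control"].astype(bool)
    table["duplicate_protospacer"] = table["duplicate_protospacer"].astype(bool)
    table["position"] = table["position"].astype(int)
    table["cds_start"] = table["cds_start"].astype(int)

    status_df = pd.DataFrame(
        status_rows, columns=["protein_id", "position", "residue", "status", "n_guides"]
    )
    report = DesignReport(
        site_status=status_df,
        n_sites_attempted=len(sites),
        n_sites_targeted=int((status_df["status"] == "targeted").sum()),
    )
    return LibraryTable(table=table, report=report)
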