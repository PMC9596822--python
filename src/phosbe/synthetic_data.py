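"""Synthetic proteomes and pooled-screen simulation.

Two generators make the analysis stack testable end-to-end without any
real data:

* :func:`generate_toy_proteome` builds random coding sequences with
  planted phosphosites whose designability is guaranteed by
  construction — designable sites sit inside a hand-verified cassette
  carrying exactly one valid guide; undesignable sites are insulated by
  G/C-free flanks long enough that no NGG PAM (on either strand) can
  reach them.

* :func:`simulate_screen` models the drug-resistance selection: cells at
  a given per-guide coverage, rounds of binomial survival at
  ``p = min(1, base_survival * 2**s)`` followed by regrowth to constant
  population, and sequencing reads with negative-binomial noise.  A
  guide with selection coefficient ``s`` gains a per-round abundance
  fold-change of ``2**s`` relative to neutral guides, so planted truths
  are analytically checkable (s = 2 over three rounds gives log2FC 6).

All randomness flows from one integer seed through named substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .library_design import CodingRecord, LibraryTable, PhosphoSite
from .screen_analysis import CountMatrix

# --------------------------------------------------------------------------
# toy proteome with planted sites
# --------------------------------------------------------------------------

# Cassettes are written 5'->3' on the sense strand and are in frame
# (length divisible by 3).  Each designable cassette embeds one valid
# protospacer+NGG whose complete-edit outcome at the site codon is an
# allowed missense change; `codon_offset` is the 0-based codon index of
# the site codon within the cassette.
#
# CBE cassette: protospacer AATATCAATTATTATTATTA + PAM TGG; the Ser
# codon TCA has its C at window position 6 and no other window C, so the
# complete edit gives TCA->TTA (Ser->Leu, allowed).
# ABE cassette: protospacer TTTTAGTTTATTATTATTAT + PAM TGG; the Ser
# codon AGT has its A at window position 5 and no other window A, so the
# complete edit gives AGT->GGT (Ser->Gly, allowed).
_DESIGNABLE_CASSETTES = {
    "CBE": ("ATA" + "ATATCAATT" + "ATTATTATTATGGTA", 2, "S"),
    "ABE": ("ATT" + "TTTAGTTTA" + "TTATTATTATTGGTA", 2, "S"),
}
# sanity on the literals above: both are 27 nt, site codon at codons[2]
assert all(len(c[0]) == 27 for c in _DESIGNABLE_CASSETTES.values())
assert _DESIGNABLE_CASSETTES["CBE"][0][6:9] == "TCA"
assert _DESIGNABLE_CASSETTES["ABE"][0][6:9] == "AGT"

# Undesignable cassette: the site codon AGT (Ser) flanked by 21 nt of
# A/T-only sequence on each side.  A window-compatible PAM must lie
# within 19 nt of an editable site-codon base, so every reachable PAM
# position is inside the flanks — which contain no GG (sense PAM) and no
# CC (antisense PAM).  No guide can therefore target the site.
_UNDESIGNABLE_FLANK = "ATT" * 7
_UNDESIGNABLE_CASSETTE = (_UNDESIGNABLE_FLANK + "AGT" + _UNDESIGNABLE_FLANK, 7, "S")

# stop-free filler codons, A/T rich to keep incidental PAM density low
# but not PAM-free (the proteome should not be trivially scannable)
_FILLER_CODONS = ("GCT", "AAA", "ATT", "CTG", "GAT", "TTC", "CAA", "GTT")


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator derived from (seed, label)."""
    tag = zlib.crc32(label.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass
class ToyProteome:
    """Synthetic proteome with ground-truth site designability."""

    records: dict[str, CodingRecord]
    sites: list[PhosphoSite]
    truth: pd.DataFrame  # protein_id, position, residue, designable


def generate_toy_proteome(
    n_proteins: int = 10,
    cds_length_range: tuple[int, int] = (120, 240),
    n_designable_sites: int = 12,
    n_undesignable_sites: int = 4,
    seed: int = 0,
    editor_name: str = "CBE",
) -> ToyProteome:
    """Random CDSs with planted phosphosites of known designability.

    Designable sites are guaranteed at least one valid guide for the
    named editor; undesignable sites are guaranteed none (no PAM within
    reach on either strand).  Deterministic for a fixed seed.
    """
    if n_proteins < 0 or n_designable_sites < 0 or n_undesignable_sites < 0:
        raise ValueError("counts must be >= 0")
    if n_proteins == 0:
        if n_designable_sites or n_undesignable_sites:
            raise ValueError("cannot plant sites with zero proteins")
        return ToyProteome({}, [], pd.DataFrame(
            columns=["protein_id", "position", "residue", "designable"]))
    if editor_name not in _DESIGNABLE_CASSETTES:
        raise KeyError(f"no designable cassette for editor {editor_name!r}")

    rng = _substream(seed, "proteome")
    # assign sites to proteins round-robin so every protein gets some
    assignments: list[list[bool]] = [[] for _ in range(n_proteins)]
    flags = [True] * n_designable_sites + [False] * n_undesignable_sites
    rng.shuffle(flags)
    for i, f in enumerate(flags):
        assignments[i % n_proteins].append(f)

    records: dict[str, CodingRecord] = {}
    sites: list[PhosphoSite] = []
    truth_rows = []
    lo, hi = cds_length_range
    for pi, planted in enumerate(assignments):
        pid = f"PROT{pi + 1:03d}"
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        filler = lambda k: "".join(rng.choice(_FILLER_CODONS, size=k))  # noqa: E731
        parts = ["ATG"]
        codon_cursor = 1
        spacer = max(2, n_codons // (len(planted) + 1))
        for designable in planted:
            parts.append(filler(spacer))
            codon_cursor += spacer
            cassette, offset, residue = (
                _DESIGNABLE_CASSETTES[editor_name] if designable else _UNDESIGNABLE_CASSETTE
            )
            parts.append(cassette)
            site_pos = codon_cursor + 1 + offset  # cassette starts at codon_cursor+1
            codon_cursor += len(cassette) // 3
            site = PhosphoSite(pid, site_pos, residue)
            sites.append(site)
            truth_rows.append(
                {"protein_id": pid, "position": site_pos, "residue": residue,
                 "designable": designable}
            )
        parts.append(filler(spacer))
        cds = "".join(parts)
        records[pid] = CodingRecord(pid, cds)

    truth = pd.DataFrame(truth_rows, columns=["protein_id", "position", "residue", "designable"])
    return ToyProteome(records=records, sites=sites, truth=truth)


def make_abstract_library(
    n_sites: int, guides_per_site: int, n_controls: int
) -> LibraryTable:
    """Sequence-free library skeleton for screen simulation and analysis.

    Carries only what the simulator and analysis need — guide ids, site
    grouping and control flags — with placeholder sequence columns.
    Useful for calibration studies where guide sequences are irrelevant.
    """
    rows = []
    for i in range(n_sites * guides_per_site):
        rows.append(dict(
            guide_id=f"g{i:05d}", protein_id=f"P{i // guides_per_site:04d}",
            position=10, residue="S", protospacer="A" * 20, pam="AGG",
            strand="sense", cds_start=1, window_positions="6", ref_aa="S",
            alt_aa="L", bystanders="", duplicate_protospacer=False,
            is_control=False, **{"class": "ALLOWED_MISSENSE"},
        ))
    for i in range(n_controls):
        rows.append(dict(
            guide_id=f"c{i:04d}", protein_id="", position=-1, residue="",
            protospacer="T" * 20, pam="", strand="", cds_start=0,
            window_positions="", ref_aa="", alt_aa="", bystanders="",
            duplicate_protospacer=False, is_control=True, **{"class": ""},
        ))
    from .library_design import LIBRARY_COLUMNS

    return LibraryTable(table=pd.DataFrame(rows, columns=LIBRARY_COLUMNS))


# --------------------------------------------------------------------------
# pooled-screen simulation
# --------------------------------------------------------------------------


@dataclass
class SimParams:
    """Pooled-screen simulation parameters.

    coverage:
        Average transduced cells per guide at infection (default 500).
    rounds:
        Drug-selection rounds (default 3: one treatment plus two more).
    base_survival:
        Survival fraction of neutral guides per round (default 0.20,
        i.e. ~20% of cells alive after each treatment).
    effect_map:
        guide id -> selection coefficient ``s``; per-round survival is
        ``min(1, base_survival * 2**s)``; unlisted guides are neutral.
    depth:
        Sequencing reads per sample.
    dispersion:
        Negative-binomial overdispersion of read counts (variance
        ``mu + dispersion * mu**2``); 0 falls back to multinomial
        sampling with exact column sums.
    n_baseline, n_treated:
        Replicate counts (default 3 each).
    init_sigma:
        Log-normal sigma of the initial guide representation.
    """

    coverage: int = 500
    rounds: int = 3
    base_survival: float = 0.20
    effect_map: Mapping[str, float] = field(default_factory=dict)
    depth: int = 10_000_000
    dispersion: float = 0.05
    seed: int = 0
    n_baseline: int = 3
    n_treated: int = 3
    init_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if not (0 < self.base_survival <= 1):
            raise ValueError("base_survival must be in (0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.n_baseline < 1 or self.n_treated < 1:
            raise ValueError("need at least one baseline and one treated sample")


def plant_effects(
    library: LibraryTable,
    frac_enriched: float = 0.0,
    frac_depleted: float = 0.0,
    effect_size: float = 2.0,
    seed: int = 0,
) -> dict[str, float]:
    """Assign selection coefficients to random targeting guides.

    ``frac_enriched`` of the targeting guides receive ``s = +effect_size``
    and ``frac_depleted`` receive ``s = -effect_size``; everything else,
    and every control, stays neutral (s = 0 guides are omitted from the
    returned map).
    """
    if frac_enriched < 0 or frac_depleted < 0 or frac_enriched + frac_depleted > 1:
        raise ValueError("fractions must be >= 0 and sum to <= 1")
    rng = _substream(seed, "effects")
    targeting = library.targeting()["guide_id"].to_numpy()
    n_up = int(round(frac_enriched * len(targeting)))
    n_dn = int(round(frac_depleted * len(targeting)))
    chosen = rng.choice(targeting, size=n_up + n_dn, replace=False)
    effects: dict[str, float] = {}
    for gid in chosen[:n_up]:
        effects[str(gid)] = float(effect_size)
    for gid in chosen[n_up:]:
        effects[str(gid)] = -float(effect_size)
    return effects


def plant_site_effects(
    library: LibraryTable,
    n_enriched_sites: int = 0,
    n_depleted_sites: int = 0,
    effect_size: float = 2.0,
    seed: int = 0,
) -> tuple[dict[str, float], set[str], set[str]]:
    """Assign one selection coefficient to every guide of random sites.

    Site-coherent planting for testing site-level aggregation: all
    guides of ``n_enriched_sites`` random sites get ``s = +effect_size``
    and all guides of ``n_depleted_sites`` get the negative.  Returns
    (effect_map, enriched site keys, depleted site keys).
    """
    rng = _substream(seed, "effects")
    site_of_guide = library.site_of_guide()
    sites = pd.unique(site_of_guide.values)
    if n_enriched_sites + n_depleted_sites > len(sites):
        raise ValueError("more planted sites than sites in the library")
    chosen = rng.choice(sites, size=n_enriched_sites + n_depleted_sites, replace=False)
    up, dn = set(chosen[:n_enriched_sites]), set(chosen[n_enriched_sites:])
    effects: dict[str, float] = {}
    for gid, site_key in site_of_guide.items():
        if site_key in up:
            effects[str(gid)] = float(effect_size)
        elif site_key in dn:
            effects[str(gid)] = -float(effect_size)
    return effects, up, dn


def _sample_reads(
    rng: np.random.Generator, abundance: np.ndarray, depth: int, dispersion: float
) -> np.ndarray:
    """Sequencing reads for one sample from relative abundances."""
    frac = abundance / abundance.sum()
    if dispersion == 0:
        return rng.multinomial(depth, frac)
    mu = depth * frac
    # gamma-poisson mixture: var = mu + dispersion * mu^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_screen(library: LibraryTable, params: SimParams) -> CountMatrix:
    """Simulate a pooled resistance screen over a designed library.

    The baseline samples are sequenced from the infected population
    before selection; treated samples after ``rounds`` cycles of
    survival-and-regrowth.  Returns a guide x sample count matrix with
    sample roles and control flags.
    """
    guide_ids = library.table["guide_id"].to_numpy()
    is_control = library.table["is_control"].to_numpy(dtype=bool)
    unknown = set(params.effect_map) - set(map(str, guide_ids))
    if unknown:
        raise ValueError(f"effect_map keys not in library: {sorted(unknown)[:5]} ...")
    s = np.array([float(params.effect_map.get(str(g), 0.0)) for g in guide_ids])
    if np.any(s[is_control] != 0):
        raise ValueError("control guides must be neutral (s = 0)")

    rng = _substream(params.seed, "screen")
    G = len(guide_ids)
    # initial representation: lognormal spread scaled to coverage
    rep = rng.lognormal(mean=0.0, sigma=params.init_sigma, size=G)
    total_cells = params.coverage * G
    cells = rng.multinomial(total_cells, rep / rep.sum()).astype(np.int64)
    initial_cells = cells.copy()

    survival = np.minimum(1.0, params.base_survival * np.exp2(s))
    for _ in range(params.rounds):
        survivors = rng.binomial(cells, survival)
        if survivors.sum() == 0:
            raise RuntimeError("population went extinct during selection")
        # regrowth to constant population size
        cells = rng.multinomial(total_cells, survivors / survivors.sum()).astype(np.int64)

    counts = {}
    roles = {}
    for i in range(params.n_baseline):
        name = f"baseline_{i + 1}"
        counts[name] = _sample_reads(rng, initial_cells.astype(float), params.depth, params.dispersion)
        roles[name] = "baseline"
    for i in range(params.n_treated):
        name = f"treated_{i + 1}"
        counts[name] = _sample_reads(rng, cells.astype(float), params.depth, params.dispersion)
        roles[name] = "treated"

    counts_df = pd.DataFrame(counts, index=pd.Index(guide_ids, name="guide_id"))
    return CountMatrix(
        counts=counts_df,
        roles=pd.Series(roles, name="role"),
        is_control=pd.Series(is_control, index=counts_df.index, name="is_control"),
    )
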