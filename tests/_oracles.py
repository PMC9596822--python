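"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own scanning/enumeration code
paths: plain dictionaries, character loops and naive full-sequence
scans, so that agreement with the package is a meaningful check.
"""

from __future__ import annotations

from itertools import chain, combinations

from Bio.Seq import Seq

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def aa_of(codon: str) -> str:
    out = str(Seq(codon).translate())
    return out


def powerset_nonempty(items):
    items = sorted(items)
    return chain.from_iterable(combinations(items, r) for r in range(1, len(items) + 1))


def brute_codon_outcomes(codon, source, product, strand):
    """(edited_positions, edited_codon, alt_aa) for every nonempty subset of
    editable offsets, mutating position by position."""
    if strand == "antisense":
        source, product = COMP[source], COMP[product]
    editable = [i for i in (0, 1, 2) if codon[i] == source]
    results = set()
    for subset in powerset_nonempty(editable):
        edited = codon
        for i in subset:
            edited = edited[:i] + product + edited[i + 1 :]
        results.add((frozenset(j + 1 for j in subset), edited, aa_of(edited)))
    return results


def brute_accessible(residue, source, product, include_charge=True):
    """Reachable amino acids for a phospho-residue, by brute enumeration
    over its codons and both edit strands."""
    codons = {
        "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
        "T": ["ACT", "ACC", "ACA", "ACG"],
        "Y": ["TAT", "TAC"],
    }[residue]
    out = set()
    for codon in codons:
        for strand in ("sense", "antisense"):
            for _, _, alt in brute_codon_outcomes(codon, source, product, strand):
                if alt not in {"S", "T", "Y", "*", residue}:
                    out.add(alt)
    if not include_charge:
        out -= set("DEKRH")
    return out


def brute_scan(full, cds_off, cds_len, codon_index, source, product,
               window=(4, 8), plen=20):
    """Every protospacer placement able to edit the target codon.

    Returns a list of dicts with strand, protospacer, pam, and the
    complete-edit (ref_aa, alt_aa) of the target codon.  Naive scan of
    every start position on both orientations.
    """
    n = len(full)
    codon_lo = cds_off + 3 * (codon_index - 1)
    target = {codon_lo, codon_lo + 1, codon_lo + 2}
    hits = []
    for strand in ("sense", "antisense"):
        seq = full if strand == "sense" else rc(full)
        back = (lambda p: p) if strand == "sense" else (lambda p: n - 1 - p)
        for st in range(0, n - plen - 3 + 1):
            pam = seq[st + plen : st + plen + 3]
            if pam[1:] != "GG":
                continue
            wpos = [st + w - 1 for w in range(window[0], window[1] + 1)]
            editable = [p for p in wpos if back(p) in target and seq[p] == source]
            if not editable:
                continue
            edited = list(seq)
            for p in wpos:
                if seq[p] == source:
                    edited[p] = product
            edited = "".join(edited)
            if strand == "antisense":
                sense_edited = rc(edited)
            else:
                sense_edited = edited
            ref_codon = full[codon_lo : codon_lo + 3]
            alt_codon = sense_edited[codon_lo : codon_lo + 3]
            hits.append(
                {
                    "strand": strand,
                    "protospacer": seq[st : st + plen],
                    "pam": pam,
                    "ref_aa": aa_of(ref_codon),
                    "alt_aa": aa_of(alt_codon),
                }
            )
    return hits


def brute_targetable(full, cds_off, cds_len, codon_index, source, product,
                     charge="DEKRH"):
    """Is the site targetable: any placement with an allowed missense
    complete-edit outcome at the target codon?"""
    kept = []
    for h in brute_scan(full, cds_off, cds_len, codon_index, source, product):
        alt = h["alt_aa"]
        if alt == h["ref_aa"] or alt == "*" or alt in "STY" or alt in charge:
            continue
        kept.append(h)
    return kept


def stepup_bh(pvals):
    """Benjamini-Hochberg step-up, written from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[idx] * m / rank)
        q[idx] = val
        prev = val
    return q
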