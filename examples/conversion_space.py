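"""Which amino acids can base editors install at phosphosites?

Enumerates, for each phospho-residue (Ser/Thr/Tyr) and each editor
(CBE C->T, ABE A->G), every amino acid reachable by same-strand window
edits of the residue's codons, before and after the charge filter that
removes acidic/basic (phosphomimetic or charge-flipping) products.
"""

import phosbe as pb

cbe, abe = pb.get_editor("CBE"), pb.get_editor("ABE")

print("residue  editor  reachable        after charge filter")
for residue in "STY":
    for editor in (cbe, abe):
        full = sorted(pb.accessible_substitutions(residue, editor))
        kept = sorted(pb.accessible_substitutions(residue, editor, include_charge_altering=False))
        print(f"{residue:>7}  {editor.name:>6}  {','.join(full) or '-':<15} {','.join(kept) or '-'}")

union = pb.conversion_space()
print(f"\ntwo-editor union: {','.join(sorted(union))} ({len(union)} amino acids)")
print("Tyr is CBE-untargetable (silent edits only), so CBE libraries carry only Ser/Thr sites.")
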