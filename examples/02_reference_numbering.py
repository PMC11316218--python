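"""Transfer reference residue numbering onto a query sequence.

Diagnostic residues are defined on reference coordinates (e.g. "Gly225"
on the ASCL reference). This example aligns a query carrying an insertion
against the packaged ASCL-style profile and shows how each annotated
reference position maps to a (shifted) query position.
"""

from pks3.classify import align_to_reference, map_position
from pks3.io import SequenceRecord, load_default_profiles

ascl = next(p for p in load_default_profiles() if p.class_tag == "ASCL")

# query = the reference with 5 residues inserted after position 200
ref = ascl.record.residues
query = SequenceRecord(id="query", residues=ref[:200] + "WWWWW" + ref[200:])

aln = align_to_reference(query, ascl)
print(f"alignment score: {aln.score:.0f}")
for site in ascl.diagnostic_positions + ascl.triad_positions:
    qpos = map_position(aln, site.position)
    obs = query.residues[qpos - 1] if isinstance(qpos, int) else "-"
    print(f"reference {site.position:>3} -> query {qpos:>3}  observed {obs}")

# Positions up to 200 map 1:1; annotated positions beyond the insertion
# (218, 225, 240, 277, 286, 305, 338) map 5 residues downstream, so the
# diagnostic readout is unaffected by the indel.
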