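"""Screen proteins for the GH18 chitinase signature motifs.

Builds three small proteins — an active chitinase, a chitinase-like protein
with the catalytic glutamate substituted (IDGF-like), and an unrelated
sequence — and runs the candidate screen on each.
"""

from chitfam import ProteinRecord, classify_candidate

proteins = [
    ProteinRecord("active_chitinase", "GSTNKAAAAAGGWGSTNFDGVDLDWEYPGSTNMAYDQTGGSTN"),
    ProteinRecord("idgf_like", "GSTNFDGVDLDWQYPGSTN"),
    ProteinRecord("unrelated", "GSTNQGSTNQGSTNQGSTNQ"),
]

for rec in proteins:
    call = classify_candidate(rec)
    print(
        f"{rec.id:18s} candidate={call.is_candidate!s:5s} tier={call.tier:9s} "
        f"active_site={call.active_site:11s} hits={len(call.hits)}"
    )

print()
print("tier 'primary' = full FDGXDLDWEYP signature present; 'substituted'")
print("means a DW?YP site exists but the catalytic E is replaced, the")
print("hallmark of enzymatically dead chitinase-like proteins (IDGFs).")
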