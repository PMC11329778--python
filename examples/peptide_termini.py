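"""Semi-tryptic cleavage evidence from an in-silico digest.

Digests a synthetic parent protein with trypsin specificity (cleave
after K/R, one missed cleavage) and plants three extra cleavages after
leucine/isoleucine — the favorable collagenase-1 P1 motif.  Each peptide
is then classified by its terminal specificity, and the per-protein
summary counts total, semi-/non-tryptic, and favorable peptides.
"""

from detensio import (
    ProteomeSpec,
    classify_terminal_specificity,
    simulate_proteome,
    summarize_cleavage_evidence,
)

_, peptides, truth = simulate_proteome(ProteomeSpec(seed=6))
pid = next(iter(truth["parents"]))
protein = truth["parents"][pid]

evidences = [
    classify_terminal_specificity(
        row["peptide"], pid, row["start"], row["end"], protein
    )
    for row in peptides.to_dict("records")
]
summary = summarize_cleavage_evidence(evidences, pid)

print(f"parent protein {pid}: {len(protein)} residues")
print(f"peptides: {summary['n_total']} total, "
      f"{summary['n_semi_or_non']} semi-/non-tryptic, "
      f"{summary['n_favorable']} with favorable Leu/Ile P1")
print(f"(the generator planted {truth['n_planted']} Leu/Ile cleavages)")
print("\nsemi-tryptic evidence:")
for ev in evidences:
    if ev.terminal_class != "tryptic":
        print(f"  {ev.sequence:25s} {ev.start:>4}-{ev.end:<4} "
              f"P1={''.join(ev.p1_residues)} favorable={ev.favorable}")
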