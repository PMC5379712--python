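"""b/y fragment ions for the CENP-A K124 peptide VTLFPKDVQLAR.

Computes the theoretical b/y ladder for the acetylated and monomethylated
forms (the modification sits on K at position 6, i.e. K124 in the protein),
the precursor m/z, and annotates a few observed peaks.  Diagnostic ions
(b6 and up, y7 and up) shift by the modification mass and distinguish the
two forms.
"""

from nucleodyn import Peptide, annotate_spectrum, peptide_mass, precursor_mz
from nucleodyn.ions import render_ion_table

for mod in ("acetyl", "methyl"):
    pep = Peptide("VTLFPKDVQLAR", {6: mod})
    print(f"-- VTLFPK({mod})DVQLAR: neutral mass {peptide_mass(pep):.4f} Da, "
          f"precursor 2+ {precursor_mz(pep, 2):.3f}, 3+ {precursor_mz(pep, 3):.3f}")
    print(render_ion_table(pep, charges=(1, 2)).to_string(index=False))

pep = Peptide("VTLFPKDVQLAR", {6: "acetyl"})
observed = [461.30969, 871.6875, 1115.70525]
matched = [e for e in annotate_spectrum(pep, observed, tol=0.4, charges=(1,))
           if e.matched_mz is not None]
print("annotated peaks (0.4 Da ion-trap tolerance):")
for e in matched:
    print(f"  {e.label}: theoretical {e.theoretical_mz:.5f}, "
          f"observed {e.matched_mz:.5f}, delta {e.delta:+.4f} Da")
print("The K-Acetyl row (residue 6) shifts all b ions from b6 on and all "
      "y ions from y7 on by +42.011 Da; methylation shifts them by +14.016 Da.")
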